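"""Reference-panel hidden Markov model for haplotype-mosaic reconstruction.

A sample's chromosome is modeled as a mosaic of segments copied from a panel
of H reference haplotypes.  The hidden state at each marker is the haplotype
being copied (haploid mode) or the unordered pair of haplotypes (diploid
mode, H(H+1)/2 states).  Between adjacent markers separated by d centimorgans
each chromosome of ancestry stays on its haplotype with probability
exp(-jump_rate * d) and otherwise switches uniformly to one of the
alternatives; diploid transitions factor as two independent haploid
chromosomes.  Emissions allow a symmetric per-allele error: each allele of
the state-implied genotype is observed correctly with probability 1 - eps.
Missing observations are uninformative (emission 1 for every state).

All arithmetic is in log space, which is ample at the tens-of-thousands-of-
markers scale this package targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import MISSING, SNPArrayError

logger = logging.getLogger(__name__)

LOG0 = -np.inf


@dataclass
class HMMSpec:
    """A compiled haplotype-mosaic decoder.

    panel: markers x H matrix of reference haplotype alleles (0/1);
    map_cM: non-decreasing genetic positions; jump_rate: expected ancestry
    switches per cM per chromosome of ancestry; error_rate: per-allele
    genotyping/mutation error in (0, 0.5); mode: "haploid" or "diploid".
    """
    panel: np.ndarray
    map_cM: np.ndarray
    jump_rate: float
    error_rate: float
    mode: str
    state_labels: List = field(repr=False, default=None)
    #: for diploid mode: (i, j) haplotype indices per state
    _pairs: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def n_markers(self) -> int:
        return self.panel.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.panel.shape[1]

    @property
    def n_states(self) -> int:
        return len(self.state_labels)


def build_hmm(panel, map_cM, jump_rate: float, error_rate: float,
              mode: str = "haploid", haplotype_names=None) -> HMMSpec:
    """Compile a panel + genetic map + rates into an :class:`HMMSpec`."""
    panel = np.asarray(panel)
    map_cM = np.asarray(map_cM, dtype=float)
    if panel.ndim != 2 or panel.shape[1] < 2:
        raise SNPArrayError("panel must be markers x H with H >= 2")
    if not np.isin(panel, (0, 1)).all():
        raise SNPArrayError("panel alleles must be 0/1")
    if panel.shape[0] != map_cM.size:
        raise SNPArrayError("panel and genetic map cover different markers")
    if np.any(np.diff(map_cM) < 0):
        raise SNPArrayError("genetic map must be non-decreasing")
    if jump_rate <= 0:
        raise SNPArrayError("jump_rate must be positive")
    if not 0 < error_rate < 0.5:
        raise SNPArrayError("error_rate must lie in (0, 0.5)")
    if mode not in ("haploid", "diploid"):
        raise SNPArrayError(f"mode must be haploid or diploid, got {mode!r}")

    H = panel.shape[1]
    if haplotype_names is None:
        haplotype_names = [f"hap{i}" for i in range(H)]
    if mode == "haploid":
        labels = list(haplotype_names)
        pairs = None
    else:
        pairs = np.array([(i, j) for i in range(H) for j in range(i, H)])
        labels = [(haplotype_names[i], haplotype_names[j]) for i, j in pairs]
    return HMMSpec(panel=panel, map_cM=map_cM, jump_rate=jump_rate,
                   error_rate=error_rate, mode=mode, state_labels=labels,
                   _pairs=pairs)


# ---------------------------------------------------------------------------
# model matrices
# ---------------------------------------------------------------------------

def _haploid_transition(hmm: HMMSpec, d_cM: float) -> np.ndarray:
    # Li-Stephens form: no ancestry jump with probability exp(-rate*d);
    # otherwise the new haplotype is uniform over the whole panel.  This makes
    # transitions compose exactly across merged intervals
    # (T(d1) @ T(d2) == T(d1+d2)) and tend to the uniform distribution as
    # d grows, with identity at d = 0.
    H = hmm.n_haplotypes
    stay = np.exp(-hmm.jump_rate * d_cM)
    return stay * np.eye(H) + (1.0 - stay) / H * np.ones((H, H))

def transition_matrix(hmm: HMMSpec, d_cM: float) -> np.ndarray:
    """Inter-marker transition matrix for a gap of ``d_cM`` centimorgans."""
    T = _haploid_transition(hmm, d_cM)
    if hmm.mode == "haploid":
        return T
    p = hmm._pairs
    i, j = p[:, 0][:, None], p[:, 1][:, None]
    k, l = p[:, 0][None, :], p[:, 1][None, :]
    out = T[i, k] * T[j, l] + np.where(k != l, T[i, l] * T[j, k], 0.0)
    return out


def _emission_logprobs(hmm: HMMSpec, obs: np.ndarray) -> np.ndarray:
    """markers x states log emission probabilities; missing observations
    (MISSING or NaN) contribute log 1 = 0 for every state."""
    eps = hmm.error_rate
    obs = np.asarray(obs, dtype=float)
    missing = np.isnan(obs) | (obs == MISSING)
    if hmm.mode == "haploid":
        implied = hmm.panel  # markers x H
        # a dosage of 2 on a hemizygous observation means the "1" allele
        o = np.minimum(np.where(missing, 0, obs).astype(int), 1)[:, None]
        logp = np.where(implied == o, np.log1p(-eps), np.log(eps))
    else:
        implied = (hmm.panel[:, hmm._pairs[:, 0]]
                   + hmm.panel[:, hmm._pairs[:, 1]])  # markers x states
        # P(observed dosage | implied genotype): two independent per-allele
        # flips with probability eps each
        table = np.array([
            [(1 - eps) ** 2, 2 * eps * (1 - eps), eps ** 2],
            [eps * (1 - eps), (1 - eps) ** 2 + eps ** 2, eps * (1 - eps)],
            [eps ** 2, 2 * eps * (1 - eps), (1 - eps) ** 2],
        ])
        o = np.clip(np.where(missing, 0, obs).astype(int), 0, 2)[:, None]
        logp = np.log(table)[implied, o]
    logp[missing] = 0.0
    return logp


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

@dataclass
class MosaicPath:
    """A decoded haplotype mosaic: per-marker states plus constant-state runs."""
    states: np.ndarray
    labels: List
    segments: pd.DataFrame
    log_prob: float


def _segments(states: np.ndarray, labels, map_cM: np.ndarray) -> pd.DataFrame:
    rows = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            rows.append(dict(state=labels[states[start]],
                             start_marker=start, end_marker=i - 1,
                             cM_span=map_cM[i - 1] - map_cM[start]))
            start = i
    return pd.DataFrame(rows, columns=["state", "start_marker", "end_marker",
                                       "cM_span"])


def viterbi(hmm: HMMSpec, observed_dosages) -> MosaicPath:
    """Maximum a posteriori state path (uniform prior over states).

    Ties break toward the lowest-index state.  An all-missing observation
    vector decodes, with a warning, to the prior argmax (state 0 throughout).
    """
    obs = np.asarray(observed_dosages, dtype=float)
    if obs.size != hmm.n_markers:
        raise SNPArrayError("observations do not align with the panel markers")
    if np.all(np.isnan(obs) | (obs == MISSING)):
        warnings.warn("all observations missing; returning the prior argmax")
    logE = _emission_logprobs(hmm, obs)
    S = hmm.n_states
    delta = -np.log(S) + logE[0]
    back = np.zeros((hmm.n_markers, S), dtype=np.int64)
    gaps = np.diff(hmm.map_cM)
    for t in range(1, hmm.n_markers):
        with np.errstate(divide="ignore"):
            logT = np.log(transition_matrix(hmm, gaps[t - 1]))
        cand = delta[:, None] + logT  # prev x cur
        back[t] = np.argmax(cand, axis=0)  # first max = lowest prev index
        delta = cand[back[t], np.arange(S)] + logE[t]
    states = np.empty(hmm.n_markers, dtype=np.int64)
    states[-1] = int(np.argmax(delta))
    for t in range(hmm.n_markers - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return MosaicPath(states=states, labels=hmm.state_labels,
                      segments=_segments(states, hmm.state_labels, hmm.map_cM),
                      log_prob=float(delta.max()))


def posterior(hmm: HMMSpec, observed_dosages) -> np.ndarray:
    """Forward-backward posterior state probabilities (markers x states);
    every row sums to 1."""
    obs = np.asarray(observed_dosages, dtype=float)
    if obs.size != hmm.n_markers:
        raise SNPArrayError("observations do not align with the panel markers")
    logE = _emission_logprobs(hmm, obs)
    n, S = hmm.n_markers, hmm.n_states
    gaps = np.diff(hmm.map_cM)
    logTs = []
    for d in gaps:
        with np.errstate(divide="ignore"):
            logTs.append(np.log(transition_matrix(hmm, d)))
    fwd = np.empty((n, S))
    fwd[0] = -np.log(S) + logE[0]
    for t in range(1, n):
        fwd[t] = logsumexp(fwd[t - 1][:, None] + logTs[t - 1], axis=0) + logE[t]
    bwd = np.zeros((n, S))
    for t in range(n - 2, -1, -1):
        bwd[t] = logsumexp(logTs[t] + (logE[t + 1] + bwd[t + 1])[None, :],
                           axis=1)
    log_post = fwd + bwd
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post)


def path_log_prob(hmm: HMMSpec, states, observed_dosages) -> float:
    """Joint log probability of a specific state path and the observations
    (uniform initial distribution).  Exposed so small instances can be
    checked against exhaustive enumeration."""
    obs = np.asarray(observed_dosages, dtype=float)
    logE = _emission_logprobs(hmm, obs)
    states = np.asarray(states, dtype=int)
    lp = -np.log(hmm.n_states) + logE[0, states[0]]
    gaps = np.diff(hmm.map_cM)
    for t in range(1, hmm.n_markers):
        with np.errstate(divide="ignore"):
            lp += np.log(transition_matrix(hmm, gaps[t - 1])[states[t - 1],
                                                             states[t]])
        lp += logE[t, states[t]]
    return float(lp)


def simulate_mosaic(hmm: HMMSpec, rng: np.random.Generator,
                    observe_error: Optional[float] = None):
    """Draw a true state path and noisy observations from the model itself;
    returns ``(states, observations)``.  Used for parameter-recovery tests."""
    n, S = hmm.n_markers, hmm.n_states
    gaps = np.diff(hmm.map_cM)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.integers(S)
    for t in range(1, n):
        T = transition_matrix(hmm, gaps[t - 1])
        states[t] = rng.choice(S, p=T[states[t - 1]])
    eps = hmm.error_rate if observe_error is None else observe_error
    if hmm.mode == "haploid":
        alleles = hmm.panel[np.arange(n), states]
        flips = rng.random(n) < eps
        obs = np.where(flips, 1 - alleles, alleles)
    else:
        a1 = hmm.panel[np.arange(n), hmm._pairs[states, 0]]
        a2 = hmm.panel[np.arange(n), hmm._pairs[states, 1]]
        f1 = rng.random(n) < eps
        f2 = rng.random(n) < eps
        obs = np.where(f1, 1 - a1, a1) + np.where(f2, 1 - a2, a2)
    return states, obs.astype(float)
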