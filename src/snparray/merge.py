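"""Merging datasets with allele-encoding harmonization, and recoding
genotypes against parental lines.

Two arrays (or two genotyping rounds) may report the same SNP with swapped
A/B labels or on opposite DNA strands — e.g. an (A/G) SNP reported as (T/C).
Merging therefore reconciles the second dataset's allele encoding to the
first's marker by marker: identical encodings are kept, swapped labels flip
the dosage (d -> 2 - d), complementary pairs are complemented first, and
strand-ambiguous SNPs (A/T or C/G, where complementation is indistinguishable
from a swap) are dropped whenever the encodings conflict.
"""

from __future__ import annotations

import logging
import warnings
from typing import Tuple

import numpy as np
import pandas as pd

from .core import (COMPLEMENT, MISSING, UNKNOWN_ALLELE, GenotypeSet,
                   SNPArrayError, make_genotype_set, subset)

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}


def _reconcile_alleles(aA, aB, bA, bB):
    """How to transform dataset b's dosages at one marker to dataset a's
    encoding: "keep", "flip", or None (irreconcilable).  Ambiguous
    (A/T, C/G) SNPs reconcile only when encodings are identical or plainly
    swapped — after complementation those cases are indistinguishable."""
    if UNKNOWN_ALLELE in (aA, aB, bA, bB):
        return "keep" if (aA, aB) == (bA, bB) else None
    ambiguous = frozenset((bA, bB)) in AMBIGUOUS_PAIRS
    if (bA, bB) == (aA, aB):
        return "keep"
    if (bA, bB) == (aB, aA):
        return "flip"
    if ambiguous:
        return None
    cA, cB = COMPLEMENT[bA], COMPLEMENT[bB]
    if (cA, cB) == (aA, aB):
        return "keep"
    if (cA, cB) == (aB, aA):
        return "flip"
    return None


def merge_sets(a: GenotypeSet, b: GenotypeSet,
               max_drop_fraction: float = 0.5
               ) -> Tuple[GenotypeSet, pd.DataFrame]:
    """Merge two datasets on their shared markers, reconciling b's allele
    encoding to a's.

    Markers are joined by name and must agree on chromosome and position
    (disagreements are dropped with a warning).  The result covers the shared
    reconciled markers and the union of samples; intensities are carried only
    when both inputs have them (BAF/LRR tracks are dropped — re-normalize the
    merged set).  Returns ``(merged, drop_report)`` where the report lists
    (marker, reason) for every shared marker that was dropped.  Raises if
    sample ids collide or more than ``max_drop_fraction`` of shared markers
    are dropped.
    """
    clash = a.sample_ids.intersection(b.sample_ids)
    if len(clash):
        raise SNPArrayError(f"sample ids present in both sets: {clash[:5].tolist()}")
    shared = a.marker_names.intersection(b.marker_names)
    if not len(shared):
        raise SNPArrayError("no shared markers to merge on")

    am = a.markers.loc[shared]
    bm = b.markers.loc[shared]
    drops = []
    actions = {}
    for name in shared:
        if (am.at[name, "chrom"] != bm.at[name, "chrom"]
                or am.at[name, "pos"] != bm.at[name, "pos"]):
            drops.append((name, "position_mismatch"))
            continue
        action = _reconcile_alleles(
            am.at[name, "allele_A"], am.at[name, "allele_B"],
            bm.at[name, "allele_A"], bm.at[name, "allele_B"])
        if action is None:
            reason = ("ambiguous_strand"
                      if frozenset((bm.at[name, "allele_A"],
                                    bm.at[name, "allele_B"])) in AMBIGUOUS_PAIRS
                      else "irreconcilable_alleles")
            drops.append((name, reason))
        else:
            actions[name] = action
    drop_report = pd.DataFrame(drops, columns=["marker", "reason"])
    if len(drops):
        warnings.warn(f"{len(drops)} of {len(shared)} shared markers dropped "
                      "during reconciliation")
    if len(drops) > max_drop_fraction * len(shared):
        raise SNPArrayError(
            f"{len(drops)}/{len(shared)} shared markers dropped; datasets "
            "look incompatible")

    keep = [n for n in shared if n in actions]
    a_sub = subset(a, markers=keep)
    b_sub = subset(b, markers=keep)
    flip = np.array([actions[n] == "flip" for n in a_sub.marker_names])
    b_calls = b_sub.calls.copy()
    fl = b_calls[flip]
    fl[fl != MISSING] = 2 - fl[fl != MISSING]
    b_calls[flip] = fl

    calls = np.concatenate([a_sub.calls, b_calls], axis=1)
    both_xy = all(g.x is not None and g.y is not None for g in (a_sub, b_sub))
    x = np.concatenate([a_sub.x, b_sub.x], axis=1) if both_xy else None
    y = np.concatenate([a_sub.y, b_sub.y], axis=1) if both_xy else None
    samples = pd.concat([a_sub.samples, b_sub.samples])
    merged = make_genotype_set(calls, a_sub.markers.reset_index(), samples,
                               x=x, y=y)
    return merged, drop_report


def recode_by_parents(gset: GenotypeSet, parentA_id: str, parentB_id: str
                      ) -> Tuple[GenotypeSet, pd.Series]:
    """Re-express dosages as counts of the parentB allele at markers where
    the two parental lines are opposite homozygotes.

    Markers where either parent is missing or heterozygous carry no
    line-of-origin information and are masked out.  Returns ``(recoded,
    informative)``: the recoded set restricted to informative markers, and a
    boolean Series over the original markers.
    """
    for pid in (parentA_id, parentB_id):
        if pid not in gset.sample_ids:
            raise SNPArrayError(f"parent sample {pid!r} not in dataset")
    pa = gset.calls[:, gset.sample_ids.get_loc(parentA_id)]
    pb = gset.calls[:, gset.sample_ids.get_loc(parentB_id)]
    informative = ((pa == 0) & (pb == 2)) | ((pa == 2) & (pb == 0))
    flip = (pa == 2) & (pb == 0)

    out = subset(gset, markers=informative)
    flip_sub = flip[informative]
    calls = out.calls
    fl = calls[flip_sub]
    fl[fl != MISSING] = 2 - fl[fl != MISSING]
    calls[flip_sub] = fl
    out.calls = calls
    return out, pd.Series(informative, index=gset.marker_names,
                          name="informative")
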