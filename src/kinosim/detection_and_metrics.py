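"""Differential-phosphorylation detection and classification performance.

Detection compares a template/replicate pair peptide by peptide with a
two-sided paired t-test on the ``l`` spot values, paired by replicate
index, at significance level ``alpha`` (no multiple-testing correction --
one raw test per peptide).  Given the seeded ground-truth positives, the
detected set is scored with the standard confusion sets and the four
derived measures (specificity, sensitivity, precision, accuracy).

The module also exposes the two distributional tests used to validate
synthesized arrays: Shapiro-Wilk on per-array peptide means (real kinome
arrays reject normality) and the two-sample Kolmogorov-Smirnov test between
a template's and a replicate's peptide-mean distributions (replicates
should not differ detectably).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from scipy import stats

from .arrays_io import ArrayValidationError, KinomeArray
from .normalization import NormalizedArray, raw_values

__all__ = [
    "ConfusionSets",
    "PerformanceRecord",
    "detect_differential",
    "paired_t_statistics",
    "confusion_sets",
    "performance_measures",
    "shapiro_wilk_peptide_means",
    "ks_two_sample",
]


def _as_normalized(array) -> NormalizedArray:
    if isinstance(array, KinomeArray):
        return raw_values(array)
    if isinstance(array, NormalizedArray):
        return array
    raise TypeError(f"expected KinomeArray or NormalizedArray, got {type(array).__name__}")


def paired_t_statistics(array_a, array_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-peptide paired t statistics and two-sided p-values.

    Spots are paired by replicate index.  Degenerate peptides follow the
    detection rules: all differences zero -> ``(t=0, p=1)``; constant
    nonzero differences -> ``(t=+/-inf, p=0)``.
    """
    a = _as_normalized(array_a)
    b = _as_normalized(array_b)
    if a.peptide_ids != b.peptide_ids or a.l != b.l:
        raise ArrayValidationError("arrays are not comparable")
    if a.l < 2:
        raise ArrayValidationError("paired t-test needs at least 2 replicate spots")
    diffs = b.values - a.values
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    l = a.l
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(l))
        p = 2.0 * stats.t.sf(np.abs(t), l - 1)
    zero_sd = sd == 0
    degenerate_t = np.where(mean == 0, 0.0, np.where(mean > 0, np.inf, -np.inf))
    t = np.where(zero_sd, degenerate_t, t)
    p = np.where(zero_sd, np.where(mean == 0, 1.0, 0.0), p)
    return t, p


def detect_differential(array_a, array_b, alpha: float = 0.05) -> frozenset[str]:
    """Peptides of ``array_b`` differentially phosphorylated vs ``array_a``.

    Accepts raw :class:`KinomeArray` or transformed :class:`NormalizedArray`
    inputs.  Spots are paired by replicate index; a peptide is detected iff
    the two-sided paired t-test p-value is below ``alpha``.  Degenerate
    peptides: all paired differences exactly zero -> never detected (p
    treated as 1); constant nonzero differences -> always detected (t
    diverges).
    """
    a = _as_normalized(array_a)
    b = _as_normalized(array_b)
    if a.peptide_ids != b.peptide_ids or a.l != b.l:
        raise ArrayValidationError("arrays are not comparable")
    if a.l < 2:
        raise ArrayValidationError("paired t-test needs at least 2 replicate spots")
    if not 0.0 < alpha < 1.0:
        raise ArrayValidationError("alpha must be in (0, 1)")
    _, p = paired_t_statistics(a, b)
    detected = p < alpha
    return frozenset(pid for pid, hit in zip(a.peptide_ids, detected) if hit)


@dataclasses.dataclass(frozen=True)
class ConfusionSets:
    """TP/FP/TN/FN partition of the peptides of one array pair."""

    tp: frozenset[str]
    fp: frozenset[str]
    tn: frozenset[str]
    fn: frozenset[str]
    positives: frozenset[str]
    detected: frozenset[str]
    all_peptides: frozenset[str]


def confusion_sets(
    seeded: Iterable[str], detected: Iterable[str], all_peptides: Iterable[str]
) -> ConfusionSets:
    """Apply the set formulas TP = P∩F, FP = (N−P)∩F, TN = (N−P)∩(N−F), FN = P∩(N−F)."""
    positives = frozenset(seeded)
    found = frozenset(detected)
    universe = frozenset(all_peptides)
    if not positives <= universe:
        raise ArrayValidationError(f"seeded set is not a subset of all peptides: {sorted(positives - universe)[:5]}")
    if not found <= universe:
        raise ArrayValidationError(f"detected set is not a subset of all peptides: {sorted(found - universe)[:5]}")
    negatives = universe - positives
    undetected = universe - found
    return ConfusionSets(
        tp=positives & found,
        fp=negatives & found,
        tn=negatives & undetected,
        fn=positives & undetected,
        positives=positives,
        detected=found,
        all_peptides=universe,
    )


@dataclasses.dataclass(frozen=True)
class PerformanceRecord:
    """The four classification measures for one array pair and method.

    ``flags`` records vacuous/undefined ratios: ``precision`` with no
    detections is defined as 0 (flag ``precision_undefined``); sensitivity
    with an empty positive set and specificity with an empty negative set
    are vacuously 1 (flags ``sensitivity_vacuous`` / ``specificity_vacuous``)
    so aggregate averaging stays total while flagged rows can be excluded.
    """

    specificity: float
    sensitivity: float
    precision: float
    accuracy: float
    pair_id: str | None = None
    method: str | None = None
    flags: frozenset[str] = frozenset()


def performance_measures(
    c: ConfusionSets, pair_id: str | None = None, method: str | None = None
) -> PerformanceRecord:
    """Specificity, sensitivity, precision and accuracy from confusion sets."""
    tp, fp, tn, fn = len(c.tp), len(c.fp), len(c.tn), len(c.fn)
    flags = set()
    if tn + fp > 0:
        specificity = tn / (tn + fp)
    else:
        specificity = 1.0
        flags.add("specificity_vacuous")
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity = 1.0
        flags.add("sensitivity_vacuous")
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        flags.add("precision_undefined")
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    return PerformanceRecord(
        specificity=specificity,
        sensitivity=sensitivity,
        precision=precision,
        accuracy=accuracy,
        pair_id=pair_id,
        method=method,
        flags=frozenset(flags),
    )


def shapiro_wilk_peptide_means(array: KinomeArray) -> float:
    """Shapiro-Wilk normality p-value of the per-peptide mean intensities."""
    if array.m < 3:
        raise ArrayValidationError("Shapiro-Wilk needs at least 3 peptides")
    means = array.peptide_means()
    if np.ptp(means) == 0:
        raise ArrayValidationError("degenerate input: all peptide means identical")
    return float(stats.shapiro(means).pvalue)


def ks_two_sample(array1: KinomeArray, array2: KinomeArray) -> float:
    """Two-sample KS p-value between the arrays' peptide-mean distributions."""
    if not array1.comparable_with(array2):
        raise ArrayValidationError("arrays are not comparable")
    return float(stats.ks_2samp(array1.peptide_means(), array2.peptide_means()).pvalue)
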