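"""Inter-array replicate synthesis and artificial differential phosphorylation.

This is the generator's core.  Given a pool ("repository") of measured
peptide replicate sets from ``n`` real or simulated arrays, two procedures
construct arrays with known ground truth:

* :func:`synthesize_replicate` builds an inter-array technical replicate
  ``Y`` of a template ``X`` -- an array with *no* differentially
  phosphorylated peptides relative to ``X``.  For a fraction ``theta`` of
  peptides it deliberately perturbs the signal within fold-change bounds
  ``[w, v]`` derived from a threshold ``T``; for the rest it selects a
  repository entry whose mean is statistically indistinguishable from the
  template peptide's mean.  If no entry qualifies, the template's own spots
  are copied.

* :func:`seed_phosphorylation` turns selected peptides of ``Y`` into known
  differentially phosphorylated ones ("phosphorylate": replacement mean
  statistically above ``v``; "dephosphorylate": statistically below ``w``),
  producing ``Y'`` together with the ground-truth seeded set.  Peptides for
  which no qualifying entry exists (e.g., already saturated) are reported
  as failed and left unchanged.

All replacements move entire ``l``-spot replicate sets with their raw
foreground/background values, so no intensity value is ever invented: every
output peptide is bit-identical to either the template peptide or a
repository entry.  Candidate scanning uses a fresh seeded random permutation
of the repository per peptide, taking the first qualifier; runs are fully
deterministic given inputs and seed.

Statistical predicates follow the literal reading of the procedure: "not
statistically bigger/less than" are one-sided one-sample t-tests on a
candidate's background-corrected values, "not significantly different" is a
two-sided one-sample t-test against the template peptide's mean, all at
significance level ``alpha`` with no multiple-testing correction.
Zero-variance candidates fall back to exact mean comparison (the limiting
behaviour of the t-test as the spot standard deviation goes to zero).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .arrays_io import (
    ArrayValidationError,
    KinomeArray,
    PeptideReplicateSet,
    peptide_mean_abc,
)

__all__ = [
    "SIGN_CROSSING",
    "FoldChangeBounds",
    "SynthesisParams",
    "SeedSpec",
    "Repository",
    "build_repository",
    "generalized_fold_change",
    "fold_change_bounds",
    "mean_within_bounds",
    "mean_equivalent",
    "one_sample_t",
    "synthesize_replicate",
    "seed_phosphorylation",
    "SynthesisResult",
    "SeedingResult",
    "PeptideProvenance",
]


class _SignCrossing:
    """Marker for fold changes undefined by the same-sign ratio definition."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "SIGN_CROSSING"


#: Returned by :func:`generalized_fold_change` when the initial and final
#: values differ in sign or either is zero.  It is a value, not an error:
#: the synthesis decisions themselves never need a fold change for such
#: pairs (they use the bound t-tests, defined for any signs).
SIGN_CROSSING = _SignCrossing()


def generalized_fold_change(initial: float, final: float):
    """Fold change generalized to negative intensities.

    ``final/initial`` when both are positive, ``initial/final`` when both
    are negative (so a 4-fold "increase in magnitude towards zero" of a
    negative pair also reads as 4), and :data:`SIGN_CROSSING` when the
    signs differ or either value is zero.
    """
    if initial > 0 and final > 0:
        return final / initial
    if initial < 0 and final < 0:
        return initial / final
    return SIGN_CROSSING


@dataclasses.dataclass(frozen=True)
class FoldChangeBounds:
    """Mean-intensity bounds ``[w, v]`` equivalent to a fold-change band."""

    v: float
    w: float

    def __post_init__(self) -> None:
        if self.v < self.w:
            raise ArrayValidationError(f"upper bound v={self.v} below lower bound w={self.w}")


def fold_change_bounds(abc: float, T: float) -> FoldChangeBounds:
    """Bounds on a peptide mean corresponding to fold-change threshold ``T``.

    For ``abc > 0``: ``v = T*abc``, ``w = abc/T``; for ``abc <= 0`` the
    branch mirrors so that ``v >= w`` still holds (``v = abc/T``,
    ``w = abc*T``).  At ``abc == 0`` both bounds collapse to zero.
    """
    if not T > 1:
        raise ArrayValidationError(f"fold-change threshold T must be > 1, got {T}")
    if abc <= 0:
        return FoldChangeBounds(v=abc / T, w=abc * T)
    return FoldChangeBounds(v=T * abc, w=abc / T)


@dataclasses.dataclass(frozen=True)
class SynthesisParams:
    """Tuning parameters of replicate synthesis.

    ``fold_change_threshold`` (T) sets the perturbation band,
    ``noisy_fraction`` (theta) the expected fraction of peptides routed
    through the perturbation branch, and ``significance_level`` (alpha) the
    level of all candidate t-tests.
    """

    fold_change_threshold: float = 2.0
    noisy_fraction: float = 0.05
    significance_level: float = 0.05
    seed: object = None

    def __post_init__(self) -> None:
        if not self.fold_change_threshold > 1:
            raise ArrayValidationError("fold_change_threshold must be > 1")
        if not 0.0 <= self.noisy_fraction <= 1.0:
            raise ArrayValidationError("noisy_fraction must be in [0, 1]")
        if not 0.0 < self.significance_level < 1.0:
            raise ArrayValidationError("significance_level must be in (0, 1)")


@dataclasses.dataclass(frozen=True)
class SeedSpec:
    """Which template peptides to (de)phosphorylate.

    ``peptide_indices`` are distinct 1-based indices into the template's
    peptide order; ``directions`` holds 1 for phosphorylation (upward) and
    0 for dephosphorylation (downward).  Real kinome experiments show about
    10-15% of probes differentially phosphorylated, so a spec covering more
    than 15% of peptides triggers a warning.
    """

    peptide_indices: tuple[int, ...]
    directions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide_indices", tuple(int(i) for i in self.peptide_indices))
        object.__setattr__(self, "directions", tuple(int(d) for d in self.directions))
        if len(self.peptide_indices) != len(self.directions):
            raise ArrayValidationError("peptide_indices and directions must have equal length")
        if len(set(self.peptide_indices)) != len(self.peptide_indices):
            raise ArrayValidationError("peptide_indices must be distinct")
        if any(d not in (0, 1) for d in self.directions):
            raise ArrayValidationError("directions must be 0 or 1")

    def validate_against(self, m: int) -> None:
        bad = [i for i in self.peptide_indices if not 1 <= i <= m]
        if bad:
            raise ArrayValidationError(f"peptide indices out of range 1..{m}: {bad}")
        if len(self.peptide_indices) > 0.15 * m:
            warnings.warn(
                f"seeding {len(self.peptide_indices)} of {m} peptides exceeds the ~15% "
                "differential fraction typical of real kinome arrays",
                UserWarning,
                stacklevel=3,
            )


class Repository:
    """Immutable pool of peptide replicate sets from ``n`` comparable arrays.

    Per-entry means and standard deviations of the background-corrected
    values are precomputed so that candidate scans over the whole pool are
    vectorized.
    """

    def __init__(self, arrays: Sequence[KinomeArray]):
        arrays = list(arrays)
        if not arrays:
            raise ArrayValidationError("repository requires at least one array")
        first = arrays[0]
        for other in arrays[1:]:
            if other.l != first.l:
                raise ArrayValidationError(
                    f"arrays {first.array_id!r} and {other.array_id!r} differ in replicate count "
                    f"({first.l} vs {other.l})"
                )
            if other.peptide_ids != first.peptide_ids:
                mismatch = sorted(set(first.peptide_ids) ^ set(other.peptide_ids)) or ["<order differs>"]
                raise ArrayValidationError(
                    f"arrays {first.array_id!r} and {other.array_id!r} are not comparable; "
                    f"mismatching peptide_ids: {mismatch[:10]}"
                )
        entries: list[PeptideReplicateSet] = []
        source_index: list[tuple[str, str]] = []
        values = []
        for array in arrays:
            for peptide in array.peptides:
                entries.append(peptide)
                source_index.append((array.array_id, peptide.peptide_id))
                values.append(peptide.corrected_values())
        self._entries = tuple(entries)
        self._source_index = tuple(source_index)
        self._values = np.asarray(values, dtype=float)
        self._means = self._values.mean(axis=1)
        self._l = first.l
        self._sds = self._values.std(axis=1, ddof=1) if self._l > 1 else np.zeros(len(entries))
        self._template_ids = first.peptide_ids

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def l(self) -> int:
        return self._l

    @property
    def entries(self) -> tuple[PeptideReplicateSet, ...]:
        return self._entries

    @property
    def source_index(self) -> tuple[tuple[str, str], ...]:
        return self._source_index

    def entry(self, i: int) -> PeptideReplicateSet:
        return self._entries[i]

    def source(self, i: int) -> tuple[str, str]:
        return self._source_index[i]

    def entry_means(self) -> np.ndarray:
        return self._means.copy()

    def compatible_with(self, array: KinomeArray) -> bool:
        return array.l == self._l and array.peptide_ids == self._template_ids


def build_repository(arrays: Sequence[KinomeArray]) -> Repository:
    """Pool all peptide replicate sets of ``arrays`` into one repository."""
    return Repository(arrays)


# ---------------------------------------------------------------------------
# Candidate predicates.  Vectorized mask helpers operate on the repository's
# precomputed (mean, sd) columns; the public functions wrap them for a
# single candidate replicate set.

def _crit_one_sided(l: int, alpha: float) -> float:
    return float(stats.t.ppf(1.0 - alpha, l - 1))


def _crit_two_sided(l: int, alpha: float) -> float:
    return float(stats.t.ppf(1.0 - alpha / 2.0, l - 1))


def _t_stats(means: np.ndarray, sds: np.ndarray, l: int, reference: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return (means - reference) / (sds / np.sqrt(l))


def _mask_significantly_greater(means, sds, l, v, alpha) -> np.ndarray:
    """mean statistically bigger than v (one-sided, level alpha)."""
    if l < 2:
        return means > v
    crit = _crit_one_sided(l, alpha)
    t = _t_stats(means, sds, l, v)
    return np.where(sds > 0, t > crit, means > v)


def _mask_significantly_less(means, sds, l, w, alpha) -> np.ndarray:
    """mean statistically less than w (one-sided, level alpha)."""
    if l < 2:
        return means < w
    crit = _crit_one_sided(l, alpha)
    t = _t_stats(means, sds, l, w)
    return np.where(sds > 0, t < -crit, means < w)


def _mask_within_bounds(means, sds, l, bounds: FoldChangeBounds, alpha) -> np.ndarray:
    """Neither statistically bigger than v nor statistically less than w."""
    too_high = _mask_significantly_greater(means, sds, l, bounds.v, alpha)
    too_low = _mask_significantly_less(means, sds, l, bounds.w, alpha)
    return ~(too_high | too_low)


def _mask_equivalent(means, sds, l, target, alpha) -> np.ndarray:
    """Not significantly different from target (two-sided, level alpha)."""
    if l < 2:
        return means == target
    crit = _crit_two_sided(l, alpha)
    t = _t_stats(means, sds, l, target)
    return np.where(sds > 0, np.abs(t) <= crit, means == target)


def one_sample_t(values, popmean: float, alternative: str = "two-sided") -> tuple[float, float]:
    """One-sample t statistic and p-value used by the candidate predicates.

    ``alternative`` is ``"two-sided"``, ``"greater"`` or ``"less"``.
    Returns ``(t, p)``; with zero sample variance the statistic is
    ``+/-inf`` (or 0 at exact equality) and the p-value degenerates to 0/1.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ArrayValidationError("one-sample t-test needs at least 2 values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        if mean == popmean:
            t = 0.0
        else:
            t = np.inf if mean > popmean else -np.inf
    else:
        t = (mean - popmean) / (sd / np.sqrt(n))
    df = n - 1
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        p = min(p, 1.0)
    elif alternative == "greater":
        p = float(stats.t.sf(t, df)) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
    elif alternative == "less":
        p = float(stats.t.cdf(t, df)) if np.isfinite(t) else (0.0 if t < 0 else 1.0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), p


def _candidate_stats(candidate: PeptideReplicateSet) -> tuple[np.ndarray, np.ndarray, int]:
    values = candidate.corrected_values()
    l = values.shape[0]
    if l < 2:
        raise ArrayValidationError("candidate needs at least 2 replicate spots for a t-test")
    mean = np.array([values.mean()])
    sd = np.array([values.std(ddof=1)])
    return mean, sd, l


def mean_within_bounds(candidate: PeptideReplicateSet, bounds: FoldChangeBounds, alpha: float) -> bool:
    """True iff the candidate's mean is not statistically outside ``[w, v]``.

    Implemented as two one-sided one-sample t-tests of the candidate's
    background-corrected values (alternative mean > v, and mean < w); the
    candidate passes iff neither is significant at ``alpha``.  With zero
    within-replicate variance the exact mean is compared to the interval.
    """
    mean, sd, l = _candidate_stats(candidate)
    if sd[0] == 0:
        return bool(bounds.w <= mean[0] <= bounds.v)
    return bool(_mask_within_bounds(mean, sd, l, bounds, alpha)[0])


def mean_equivalent(candidate: PeptideReplicateSet, target_mean: float, alpha: float) -> bool:
    """True iff a two-sided one-sample t-test against ``target_mean`` is not
    significant at ``alpha`` (zero variance: exact equality)."""
    mean, sd, l = _candidate_stats(candidate)
    if sd[0] == 0:
        return bool(mean[0] == target_mean)
    return bool(_mask_equivalent(mean, sd, l, target_mean, alpha)[0])


# ---------------------------------------------------------------------------
# Algorithm drivers

@dataclasses.dataclass(frozen=True)
class PeptideProvenance:
    """Where one output peptide's measurements came from."""

    peptide_id: str
    branch: str  # "perturb" | "equivalence" | "phosphorylate" | "dephosphorylate" | "unchanged"
    entry_index: int | None  # repository index, or None if the template/replicate spots were kept
    source: tuple[str, str] | None  # (array_id, peptide_id) of the repository entry
    fallback: bool  # True when no repository entry qualified


@dataclasses.dataclass(frozen=True)
class SynthesisResult:
    """Synthesized replicate plus per-peptide provenance."""

    array: KinomeArray
    provenance: tuple[PeptideProvenance, ...]

    @property
    def perturbed_fraction(self) -> float:
        """Fraction of peptides routed through the perturbation branch."""
        n = sum(1 for p in self.provenance if p.branch == "perturb")
        return n / len(self.provenance)


def _first_qualifier(mask: np.ndarray, rng: np.random.Generator) -> int | None:
    """Index of the first True entry under a fresh random permutation."""
    perm = rng.permutation(mask.shape[0])
    hits = np.flatnonzero(mask[perm])
    if hits.size == 0:
        return None
    return int(perm[hits[0]])


def synthesize_replicate(
    repo: Repository, template: KinomeArray, params: SynthesisParams | None = None
) -> SynthesisResult:
    """Synthesize an inter-array technical replicate ``Y`` of ``template``.

    Per peptide ``t``: a uniform draw routes it to the perturbation branch
    with probability ``theta`` (candidates must sit within the fold-change
    bounds around the template peptide's mean ``abc_t``) or otherwise to the
    equivalence branch (candidates must be statistically indistinguishable
    from ``abc_t``).  The repository is scanned in a fresh seeded random
    permutation and the first qualifying entry's spots are assigned; if none
    qualifies the template's own spots are kept.  At the degenerate bound
    ``abc_t == 0`` (where both bounds collapse) the perturbation branch
    falls back to the equivalence test against zero.

    The result is comparable with the template and deterministic given
    ``(repo, template, params)`` including the seed.
    """
    params = params if params is not None else SynthesisParams()
    if len(repo) == 0:
        raise ArrayValidationError("repository is empty")
    if not repo.compatible_with(template):
        raise ArrayValidationError("template is not comparable with the repository's source arrays")
    rng = np.random.default_rng(params.seed)
    alpha = params.significance_level
    new_peptides = list(template.peptides)
    provenance = []
    for t, peptide in enumerate(template.peptides):
        abc_t = peptide_mean_abc(peptide)
        perturb = rng.random() <= params.noisy_fraction
        if perturb and abc_t != 0:
            bounds = fold_change_bounds(abc_t, params.fold_change_threshold)
            mask = _mask_within_bounds(repo._means, repo._sds, repo.l, bounds, alpha)
            branch = "perturb"
        else:
            mask = _mask_equivalent(repo._means, repo._sds, repo.l, abc_t, alpha)
            branch = "perturb" if perturb else "equivalence"
        idx = _first_qualifier(mask, rng)
        if idx is None:
            provenance.append(PeptideProvenance(peptide.peptide_id, branch, None, None, True))
        else:
            new_peptides[t] = PeptideReplicateSet(peptide.peptide_id, repo.entry(idx).spots)
            provenance.append(PeptideProvenance(peptide.peptide_id, branch, idx, repo.source(idx), False))
    out = KinomeArray(f"{template.array_id}~rep", tuple(new_peptides))
    return SynthesisResult(out, tuple(provenance))


@dataclasses.dataclass(frozen=True)
class SeedingResult:
    """Artificially phosphorylated array plus ground truth bookkeeping."""

    array: KinomeArray
    seeded: frozenset[str]
    failed: frozenset[str]
    provenance: tuple[PeptideProvenance, ...]


def seed_phosphorylation(
    repo: Repository,
    template: KinomeArray,
    replicate: KinomeArray,
    spec: SeedSpec,
    fold_change_threshold: float = 2.0,
    significance_level: float = 0.05,
    seed=None,
) -> SeedingResult:
    """Seed known differential phosphorylation into ``replicate``.

    ``Y'`` starts as a copy of ``replicate``.  For each 1-based index in
    ``spec`` with direction 1 (phosphorylate), the repository is scanned in
    a fresh seeded random permutation for the first entry whose mean is
    statistically bigger than the upper bound ``v`` derived from the
    *template* peptide's mean; direction 0 (dephosphorylate) is symmetric
    against the lower bound ``w``.  The qualifying entry's spots replace the
    peptide and its id joins ``seeded``; if no entry qualifies (small
    repository, or the peptide is already extreme), the peptide joins
    ``failed`` and keeps the replicate's spots.
    """
    if len(repo) == 0:
        raise ArrayValidationError("repository is empty")
    if not template.comparable_with(replicate):
        raise ArrayValidationError("template and replicate are not comparable")
    spec.validate_against(template.m)
    if not 1 < fold_change_threshold:
        raise ArrayValidationError("fold_change_threshold must be > 1")
    rng = np.random.default_rng(seed)
    alpha = significance_level
    new_peptides = list(replicate.peptides)
    seeded: set[str] = set()
    failed: set[str] = set()
    provenance = []
    for index, direction in zip(spec.peptide_indices, spec.directions):
        t = index - 1
        peptide_id = template.peptides[t].peptide_id
        abc_t = peptide_mean_abc(template.peptides[t])
        bounds = fold_change_bounds(abc_t, fold_change_threshold)
        if direction == 1:
            mask = _mask_significantly_greater(repo._means, repo._sds, repo.l, bounds.v, alpha)
            branch = "phosphorylate"
        else:
            mask = _mask_significantly_less(repo._means, repo._sds, repo.l, bounds.w, alpha)
            branch = "dephosphorylate"
        idx = _first_qualifier(mask, rng)
        if idx is None:
            failed.add(peptide_id)
            provenance.append(PeptideProvenance(peptide_id, branch, None, None, True))
        else:
            new_peptides[t] = PeptideReplicateSet(peptide_id, repo.entry(idx).spots)
            seeded.add(peptide_id)
            provenance.append(PeptideProvenance(peptide_id, branch, idx, repo.source(idx), False))
    out = KinomeArray(f"{replicate.array_id}~seeded", tuple(new_peptides))
    return SeedingResult(out, frozenset(seeded), frozenset(failed), tuple(provenance))
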