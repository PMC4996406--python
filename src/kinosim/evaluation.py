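"""End-to-end performance evaluation of normalization methods.

For each of ``n'`` template arrays the pipeline (i) synthesizes an
inter-array technical replicate, (ii) seeds up to ``nd`` randomly chosen
peptides with artificial (de)phosphorylation -- peptides that cannot be
differentially phosphorylated are excluded from the ground-truth positive
set -- (iii) normalizes the template/seeded pair with each method under
comparison, (iv) detects differential peptides with the paired t-test and
(v) scores specificity, sensitivity, precision and accuracy against the
seeded truth.  Methods are then compared per measure with a Brown-Forsythe
(median-centered) Levene test for equality of variances and a paired t-test
on the per-pair values (df = n' - 1); a Welch two-sample t-test is reported
alongside as a sensitivity check.

Every source of randomness derives deterministically from ``master_seed``
via spawned child seeds, so identical inputs give identical record tables.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays_io import ArrayValidationError, KinomeArray
from .detection_and_metrics import confusion_sets, detect_differential, performance_measures
from .normalization import log2_transform, raw_values, vsn_glog_transform
from .synthesis import (
    Repository,
    SeedSpec,
    SynthesisParams,
    build_repository,
    seed_phosphorylation,
    synthesize_replicate,
)

__all__ = [
    "EvaluationConfig",
    "EvaluationResult",
    "MethodComparison",
    "MeasureComparison",
    "run_performance_evaluation",
    "compare_methods",
    "qc_plots",
    "rms_deviation",
]

KNOWN_METHODS = ("raw", "log2", "vsn_glog")
MEASURES = ("specificity", "sensitivity", "precision", "accuracy")


@dataclasses.dataclass(frozen=True)
class EvaluationConfig:
    """Parameters of the evaluation run.

    Defaults mirror the reference study conditions: 48 template/replicate
    pairs, at most 30 seeded peptides per pair, fold-change threshold 2,
    5% noisy peptides and significance level 0.05.
    """

    n_pairs: int = 48
    max_seeds: int = 30
    fold_change_threshold: float = 2.0
    noisy_fraction: float = 0.05
    significance_level: float = 0.05
    methods: tuple[str, ...] = ("raw", "log2", "vsn_glog")
    master_seed: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "methods", tuple(self.methods))
        if self.n_pairs < 1:
            raise ArrayValidationError("n_pairs must be >= 1")
        if self.max_seeds < 0:
            raise ArrayValidationError("max_seeds must be >= 0")
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown or not self.methods:
            raise ArrayValidationError(f"methods must be a nonempty subset of {KNOWN_METHODS}, got {self.methods}")

    @classmethod
    def from_dict(cls, config: Mapping) -> "EvaluationConfig":
        return cls(**dict(config))


@dataclasses.dataclass(frozen=True)
class EvaluationResult:
    """Record table (one row per pair x method) plus run provenance."""

    records: pd.DataFrame
    provenance: tuple[dict, ...]


def _normalized_pair(template: KinomeArray, seeded_array: KinomeArray, method: str):
    if method == "raw":
        return raw_values(template), raw_values(seeded_array)
    if method == "log2":
        return log2_transform(template), log2_transform(seeded_array)
    if method == "vsn_glog":
        (norm_a, norm_b), _ = vsn_glog_transform([template, seeded_array])
        return norm_a, norm_b
    raise ArrayValidationError(f"unknown method {method!r}")


def run_performance_evaluation(
    repository_arrays: Sequence[KinomeArray], config: EvaluationConfig | None = None
) -> EvaluationResult:
    """Run the full synthesize / seed / normalize / detect / score pipeline.

    ``repository_arrays`` provide both the measurement repository and the
    templates: pair ``q`` uses array ``q`` as template (``n_pairs <= n``).
    Returns one record per pair and method, plus per-pair provenance
    (child seeds, seeded and failed peptide sets).
    """
    config = config if config is not None else EvaluationConfig()
    arrays = list(repository_arrays)
    if config.n_pairs > len(arrays):
        raise ArrayValidationError(
            f"n_pairs={config.n_pairs} exceeds the {len(arrays)} available template arrays"
        )
    repo = build_repository(arrays)
    m = arrays[0].m
    root = np.random.SeedSequence(config.master_seed)
    rows = []
    provenance = []
    for q, child in enumerate(root.spawn(config.n_pairs), start=1):
        synth_seed, subset_seed, algo2_seed = (int(s) for s in child.generate_state(3) % (2**31))
        template = arrays[q - 1]
        synthesis = synthesize_replicate(
            repo,
            template,
            SynthesisParams(
                fold_change_threshold=config.fold_change_threshold,
                noisy_fraction=config.noisy_fraction,
                significance_level=config.significance_level,
                seed=synth_seed,
            ),
        )
        subset_rng = np.random.default_rng(subset_seed)
        n_seeds = min(config.max_seeds, m)
        indices = np.sort(subset_rng.choice(m, size=n_seeds, replace=False)) + 1
        directions = subset_rng.integers(0, 2, size=n_seeds)
        spec = SeedSpec(tuple(int(i) for i in indices), tuple(int(d) for d in directions))
        seeding = seed_phosphorylation(
            repo,
            template,
            synthesis.array,
            spec,
            fold_change_threshold=config.fold_change_threshold,
            significance_level=config.significance_level,
            seed=algo2_seed,
        )
        pair_id = template.array_id
        all_ids = set(template.peptide_ids)
        for method in config.methods:
            norm_a, norm_b = _normalized_pair(template, seeding.array, method)
            detected = detect_differential(norm_a, norm_b, alpha=config.significance_level)
            record = performance_measures(
                confusion_sets(seeding.seeded, detected, all_ids), pair_id=pair_id, method=method
            )
            rows.append(
                {
                    "pair_id": pair_id,
                    "method": method,
                    "specificity": record.specificity,
                    "sensitivity": record.sensitivity,
                    "precision": record.precision,
                    "accuracy": record.accuracy,
                    "n_seeded": len(seeding.seeded),
                    "n_detected": len(detected),
                    "flags": ";".join(sorted(record.flags)),
                }
            )
        provenance.append(
            {
                "pair_id": pair_id,
                "synth_seed": synth_seed,
                "subset_seed": subset_seed,
                "algo2_seed": algo2_seed,
                "seeded": seeding.seeded,
                "failed": seeding.failed,
            }
        )
    return EvaluationResult(pd.DataFrame(rows), tuple(provenance))


@dataclasses.dataclass(frozen=True)
class MeasureComparison:
    """Comparison of one performance measure between two methods."""

    measure: str
    levene_stat: float
    levene_p: float
    t_stat: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float
    welch_t: float
    welch_p: float
    degenerate: bool  # True when the paired differences have zero variance


@dataclasses.dataclass(frozen=True)
class MethodComparison:
    method_a: str
    method_b: str
    n_pairs: int
    measures: dict[str, MeasureComparison]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(m) for m in self.measures.values()])


def compare_methods(
    records: pd.DataFrame, method_a: str, method_b: str, alpha: float = 0.05
) -> MethodComparison:
    """Levene (Brown-Forsythe) + paired t comparison of two methods.

    A paired t-test has a single difference variance, so the equal/unequal
    variance distinction does not apply to it; the Levene result is
    reported alongside for workflow fidelity and a Welch two-sample t-test
    is included as a sensitivity check.  Zero-variance paired differences
    are reported degenerately: all-zero -> t = 0, p = 1; constant nonzero
    -> a deterministic difference (t infinite, p = 0, flagged).
    """
    from scipy import stats

    sub_a = records[records["method"] == method_a].set_index("pair_id").sort_index()
    sub_b = records[records["method"] == method_b].set_index("pair_id").sort_index()
    if sub_a.empty or sub_b.empty:
        raise ArrayValidationError(f"records lack method {method_a!r} or {method_b!r}")
    if list(sub_a.index) != list(sub_b.index):
        raise ArrayValidationError("pair ids differ between methods")
    n = len(sub_a)
    measures = {}
    for measure in MEASURES:
        x = sub_a[measure].to_numpy(dtype=float)
        y = sub_b[measure].to_numpy(dtype=float)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            levene_stat, levene_p = np.nan, np.nan
        else:
            levene_stat, levene_p = stats.levene(x, y, center="median")
        diffs = y - x
        degenerate = False
        # constant differences up to float rounding have no variance to test
        if np.ptp(diffs) <= 1e-12 * max(1.0, float(np.max(np.abs(diffs), initial=0.0))):
            if diffs[0] == 0:
                t_stat, p_value = 0.0, 1.0
            else:
                t_stat = np.inf if diffs[0] > 0 else -np.inf
                p_value = 0.0
                degenerate = True
        else:
            res = stats.ttest_rel(y, x)
            t_stat, p_value = float(res.statistic), float(res.pvalue)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            welch_t, welch_p = 0.0, 1.0
        else:
            welch = stats.ttest_ind(y, x, equal_var=False)
            welch_t, welch_p = float(welch.statistic), float(welch.pvalue)
        measures[measure] = MeasureComparison(
            measure=measure,
            levene_stat=float(levene_stat),
            levene_p=float(levene_p),
            t_stat=float(t_stat),
            df=n - 1,
            p_value=float(p_value),
            mean_a=float(x.mean()),
            mean_b=float(y.mean()),
            welch_t=welch_t,
            welch_p=welch_p,
            degenerate=degenerate,
        )
    return MethodComparison(method_a=method_a, method_b=method_b, n_pairs=n, measures=measures)


def rms_deviation(template: KinomeArray, replicate: KinomeArray) -> float:
    """Root-mean-square deviation of peptide means from the identity line."""
    if not template.comparable_with(replicate):
        raise ArrayValidationError("arrays are not comparable")
    delta = replicate.peptide_means() - template.peptide_means()
    return float(np.sqrt(np.mean(delta**2)))


def _scatter_figure(template: KinomeArray, replicate: KinomeArray, seeded: frozenset[str]):
    from matplotlib.figure import Figure

    x = template.peptide_means()
    y = replicate.peptide_means()
    highlight = np.array([pid in seeded for pid in template.peptide_ids])
    fig = Figure(figsize=(5, 5))
    ax = fig.add_subplot(111)
    ax.scatter(x[~highlight], y[~highlight], s=12, color="tab:gray", label="peptides")
    if highlight.any():
        ax.scatter(x[highlight], y[highlight], s=18, color="tab:red", label="seeded")
    lo = float(min(x.min(), y.min()))
    hi = float(max(x.max(), y.max()))
    ax.plot([lo, hi], [lo, hi], color="black", linewidth=0.8)
    ax.set_xlabel(f"{template.array_id}: mean background-corrected intensity")
    ax.set_ylabel(f"{replicate.array_id}: mean background-corrected intensity")
    ax.legend(loc="upper left", frameon=False)
    return fig


def _histogram_figure(array: KinomeArray):
    from matplotlib.figure import Figure
    from scipy import stats

    means = array.peptide_means()
    fig = Figure(figsize=(5, 4))
    ax = fig.add_subplot(111)
    ax.hist(means, bins=40, density=True, color="tab:green", alpha=0.7)
    if np.ptp(means) > 0:
        grid = np.linspace(means.min(), means.max(), 300)
        ax.plot(grid, stats.gaussian_kde(means)(grid), color="tab:red")
    ax.set_xlabel("mean background-corrected intensity")
    ax.set_ylabel("density")
    ax.set_title(array.array_id)
    return fig


def qc_plots(
    template: KinomeArray,
    replicate: KinomeArray,
    seeded: Iterable[str] = (),
    out_dir=".",
) -> list:
    """Write QC figures for a template/replicate pair; returns file paths.

    Produces a peptide-mean scatter with the identity line (seeded peptides
    highlighted) and per-array histograms with a kernel-density curve.
    """
    from pathlib import Path

    if not template.comparable_with(replicate):
        raise ArrayValidationError("arrays are not comparable")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeded = frozenset(seeded)
    paths = []
    fig = _scatter_figure(template, replicate, seeded)
    path = out_dir / f"scatter_{template.array_id}_vs_{replicate.array_id}.png"
    fig.savefig(path, dpi=120)
    paths.append(path)
    for array in (template, replicate):
        fig = _histogram_figure(array)
        path = out_dir / f"hist_{array.array_id}.png"
        fig.savefig(path, dpi=120)
        paths.append(path)
    return paths
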