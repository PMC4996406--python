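"""Simulation of realistic template kinome arrays and array repositories.

Replicate synthesis needs a pool of "actual" arrays to draw measurements
from.  This module generates such arrays from the Rocke-Durbin two-component
measurement-error model

    Y = alpha + mu * exp(gamma) + epsilon

where ``alpha`` is the residual offset of unphosphorylated probes after
background correction, ``mu`` is the noise-free phosphorylation intensity of
a peptide, ``gamma ~ N(0, sigma_multiplicative^2)`` is the multiplicative
(proportional) error and ``epsilon ~ N(0, sigma_additive^2)`` the additive
error.  The model produces the two signatures of real kinome intensity data
that matter downstream: spot variance that grows with mean intensity
(heteroscedasticity), and a nonzero fraction of spots whose
background-corrected intensity is negative.

Peptide-level intensities ``mu`` are drawn from a right-skewed lognormal
mixture with a point mass at zero (unphosphorylated probes), so the
per-array distribution of peptide means is non-normal -- Shapiro-Wilk
rejects normality for essentially every simulated array, as it does for
real kinome arrays.

The simulator emits raw foreground/background pairs: the model value ``Y``
is the *background-corrected* signal, an explicit background channel
``B ~ N(background_mean, background_sd^2)`` (truncated at zero) is added,
and the stored foreground is ``F = max(Y + B, 0)``.  Negativity therefore
enters only through ``F - B``, as on a real scanner.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .arrays_io import (
    ArrayValidationError,
    KinomeArray,
    PeptideReplicateSet,
    SpotMeasurement,
)

__all__ = [
    "NoiseModel",
    "MuDistribution",
    "simulate_template_array",
    "simulate_repository",
    "DEFAULT_N_ARRAYS",
    "DEFAULT_N_PEPTIDES",
    "DEFAULT_N_REPLICATES",
    "DEFAULT_BETWEEN_ARRAY_SD",
]

#: Dimensions of the emulated reference dataset: 48 arrays, 297 peptides,
#: 9 within-array replicate spots per peptide.
DEFAULT_N_ARRAYS = 48
DEFAULT_N_PEPTIDES = 297
DEFAULT_N_REPLICATES = 9

#: Log-scale standard deviation of peptide intensity anchors between arrays
#: of the same repository (biological + run-to-run variation, well below a
#: 2-fold change).
DEFAULT_BETWEEN_ARRAY_SD = 0.10


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Parameters of the two-component measurement-error model.

    Attributes
    ----------
    alpha_offset:
        Mean background-corrected intensity of unphosphorylated probes
        (arbitrary fluorescence units).  Zero by default: background
        subtraction is assumed unbiased on average.
    sigma_additive:
        Standard deviation of the additive error ``epsilon``; dominates at
        low intensity and generates negative background-corrected spots.
    sigma_multiplicative:
        Standard deviation of the log-scale multiplicative error ``gamma``;
        dominates at high intensity (roughly the spot CV of bright probes).
    background_mean, background_sd:
        Mean and standard deviation of the simulated raw background channel.
    """

    alpha_offset: float = 0.0
    sigma_additive: float = 60.0
    sigma_multiplicative: float = 0.10
    background_mean: float = 800.0
    background_sd: float = 80.0

    def __post_init__(self) -> None:
        for name in ("sigma_additive", "sigma_multiplicative", "background_sd"):
            if getattr(self, name) < 0:
                raise ArrayValidationError(f"{name} must be >= 0")
        for name in dataclasses.fields(self):
            if not math.isfinite(getattr(self, name.name)):
                raise ArrayValidationError(f"{name.name} must be finite")

    @classmethod
    def from_dict(cls, config: Mapping) -> "NoiseModel":
        return cls(**dict(config))


@dataclasses.dataclass(frozen=True)
class MuDistribution:
    """Right-skewed peptide intensity distribution: lognormal mixture + zeros.

    A fraction ``zero_fraction`` of peptides is unphosphorylated
    (``mu = 0``); the rest draw ``mu`` from a mixture of lognormals.  The
    defaults span roughly two orders of magnitude of intensity and make the
    distribution of per-array peptide means strongly right-skewed and
    non-normal.

    ``probe_offset_sd`` adds a persistent probe-specific location offset
    ``delta_j ~ N(0, probe_offset_sd^2)`` to every spot of peptide ``j``
    (the same offset on every array of a repository).  It models
    probe-dependent background binding and overcorrection, which is what
    gives real kinome arrays a genuine range of *negative* mean
    background-corrected intensities rather than a tight cluster at zero.
    """

    component_log_means: tuple[float, ...] = (6.0, 7.8)
    component_log_sds: tuple[float, ...] = (1.0, 0.8)
    component_weights: tuple[float, ...] = (0.55, 0.45)
    zero_fraction: float = 0.20
    probe_offset_sd: float = 250.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "component_log_means", tuple(float(x) for x in self.component_log_means))
        object.__setattr__(self, "component_log_sds", tuple(float(x) for x in self.component_log_sds))
        object.__setattr__(self, "component_weights", tuple(float(x) for x in self.component_weights))
        k = len(self.component_log_means)
        if not (len(self.component_log_sds) == len(self.component_weights) == k) or k == 0:
            raise ArrayValidationError("mixture component sequences must be nonempty and equal-length")
        if any(s <= 0 for s in self.component_log_sds):
            raise ArrayValidationError("component_log_sds must be positive")
        if any(w < 0 for w in self.component_weights) or not math.isclose(
            sum(self.component_weights), 1.0, rel_tol=0, abs_tol=1e-9
        ):
            raise ArrayValidationError("component_weights must be nonnegative and sum to 1")
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ArrayValidationError("zero_fraction must be in [0, 1]")
        if self.probe_offset_sd < 0:
            raise ArrayValidationError("probe_offset_sd must be >= 0")

    @classmethod
    def from_dict(cls, config: Mapping) -> "MuDistribution":
        config = dict(config)
        for key in ("component_log_means", "component_log_sds", "component_weights"):
            if key in config:
                config[key] = tuple(config[key])
        return cls(**config)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``size`` noise-free peptide intensities ``mu >= 0``."""
        component = rng.choice(len(self.component_weights), size=size, p=self.component_weights)
        mu = np.exp(
            rng.normal(
                np.asarray(self.component_log_means)[component],
                np.asarray(self.component_log_sds)[component],
            )
        )
        mu[rng.random(size) < self.zero_fraction] = 0.0
        return mu

    def sample_probe_offsets(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw per-peptide location offsets ``delta_j`` (may be negative)."""
        if self.probe_offset_sd == 0:
            return np.zeros(size)
        return rng.normal(0.0, self.probe_offset_sd, size=size)


def _spots_from_mu(
    mu: np.ndarray, delta: np.ndarray, l: int, noise: NoiseModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Foreground/background matrices (m, l) for peptide intensities ``mu``."""
    m = mu.shape[0]
    gamma = rng.normal(0.0, noise.sigma_multiplicative, size=(m, l))
    epsilon = rng.normal(0.0, noise.sigma_additive, size=(m, l))
    signal = noise.alpha_offset + delta[:, None] + mu[:, None] * np.exp(gamma) + epsilon
    background = np.clip(rng.normal(noise.background_mean, noise.background_sd, size=(m, l)), 0.0, None)
    foreground = np.clip(signal + background, 0.0, None)
    return foreground, background


def _build_array(
    array_id: str, peptide_ids: Sequence[str], foreground: np.ndarray, background: np.ndarray
) -> KinomeArray:
    peptides = tuple(
        PeptideReplicateSet(
            pid,
            tuple(SpotMeasurement(float(f), float(b)) for f, b in zip(fg_row, bg_row)),
        )
        for pid, fg_row, bg_row in zip(peptide_ids, foreground, background)
    )
    return KinomeArray(array_id, peptides)


def _default_peptide_ids(m: int) -> tuple[str, ...]:
    width = len(str(m))
    return tuple(f"pep_{j + 1:0{width}d}" for j in range(m))


def simulate_template_array(
    m: int = DEFAULT_N_PEPTIDES,
    l: int = DEFAULT_N_REPLICATES,
    mu_dist: MuDistribution | None = None,
    noise: NoiseModel | None = None,
    seed=None,
    *,
    array_id: str = "sim_array",
) -> KinomeArray:
    """Simulate one template array of ``m`` peptides x ``l`` replicate spots.

    One ``mu_j`` is drawn per peptide from ``mu_dist``; each spot then gets
    independent multiplicative and additive errors per the two-component
    model, plus a simulated background channel.  Identical seeds give
    identical arrays.
    """
    if m < 1 or l < 1:
        raise ArrayValidationError("m and l must be >= 1")
    mu_dist = mu_dist if mu_dist is not None else MuDistribution()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    mu = mu_dist.sample(m, rng)
    delta = mu_dist.sample_probe_offsets(m, rng)
    foreground, background = _spots_from_mu(mu, delta, l, noise, rng)
    return _build_array(array_id, _default_peptide_ids(m), foreground, background)


def simulate_repository(
    n: int = DEFAULT_N_ARRAYS,
    m: int = DEFAULT_N_PEPTIDES,
    l: int = DEFAULT_N_REPLICATES,
    mu_dist: MuDistribution | None = None,
    noise: NoiseModel | None = None,
    seed=None,
    *,
    between_array_sd: float = DEFAULT_BETWEEN_ARRAY_SD,
    array_id_prefix: str = "A",
) -> list[KinomeArray]:
    """Simulate ``n`` comparable arrays sharing peptide-level anchors.

    Anchor intensities ``mu_j`` are drawn once from ``mu_dist``; each array
    re-draws its own peptide intensities around the anchors with a log-scale
    between-array factor ``exp(N(0, between_array_sd^2))``, so the same
    peptide is similar but not identical across arrays.  With all noise
    parameters and ``between_array_sd`` at zero the arrays are identical.
    """
    if n < 1:
        raise ArrayValidationError("n must be >= 1")
    if between_array_sd < 0:
        raise ArrayValidationError("between_array_sd must be >= 0")
    if m < 1 or l < 1:
        raise ArrayValidationError("m and l must be >= 1")
    mu_dist = mu_dist if mu_dist is not None else MuDistribution()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    anchors = mu_dist.sample(m, rng)
    delta = mu_dist.sample_probe_offsets(m, rng)
    peptide_ids = _default_peptide_ids(m)
    arrays = []
    width = len(str(n))
    for i in range(n):
        mu_i = anchors * np.exp(rng.normal(0.0, between_array_sd, size=m)) if between_array_sd > 0 else anchors
        foreground, background = _spots_from_mu(mu_i, delta, l, noise, rng)
        arrays.append(_build_array(f"{array_id_prefix}-{i + 1:0{width}d}", peptide_ids, foreground, background))
    return arrays


def repository_from_config(config: Mapping, seed=None) -> list[KinomeArray]:
    """Build a simulated repository from a config mapping (YAML/JSON block).

    Recognized keys: ``n, m, l, seed, between_array_sd, noise (mapping),
    mu (mapping)``.  An explicit ``seed`` argument overrides the config.
    """
    config = dict(config)
    noise = NoiseModel.from_dict(config.get("noise", {}))
    mu_dist = MuDistribution.from_dict(config.get("mu", {}))
    return simulate_repository(
        n=int(config.get("n", DEFAULT_N_ARRAYS)),
        m=int(config.get("m", DEFAULT_N_PEPTIDES)),
        l=int(config.get("l", DEFAULT_N_REPLICATES)),
        mu_dist=mu_dist,
        noise=noise,
        seed=seed if seed is not None else config.get("seed"),
        between_array_sd=float(config.get("between_array_sd", DEFAULT_BETWEEN_ARRAY_SD)),
    )
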