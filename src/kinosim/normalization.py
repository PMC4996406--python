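"""Variance-stabilization methods: Log2 and a calibrated generalized log.

Two transforms of background-corrected spot intensities are compared by the
evaluation pipeline:

* **Log2** -- ``log2(x)`` for positive ``x``, and 0 for every nonpositive
  value.  Simple and fold-change preserving on the positive range, but it
  collapses all nonpositive background-corrected values to a single point
  (destroying their information content) and inflates variance near zero.

* **VSN-style glog** -- a per-array affine calibration followed by an
  inverse hyperbolic sine:  ``h_i(x) = arcsinh((x - a_i) / b_i)``.  Under
  the two-component error model ``Y = alpha + mu e^gamma + eps`` this
  family stabilizes variance across the whole intensity range: it behaves
  like ``ln(2(x - a)/b)`` for large ``x`` and like a linear map near zero,
  and negative inputs map to finite negative values rather than being
  discarded.

The glog calibration parameters are fitted by minimizing a robust profile
negative log-likelihood: the pooled within-peptide variance of transformed
values across all arrays (peptides act as replicate groups, which is what
ties the arrays to a common scale), with the arcsinh Jacobian term fixing
the overall scale of the transform.  A least-trimmed-squares step keeps the
fraction of peptides with the smallest within-group scatter (default 0.9),
so a minority of genuinely differentially phosphorylated peptides cannot
drag the calibration.  This is a re-implementation of the transform class,
not of any particular released VSN code; agreement is at the level of the
variance-stabilization property, not bit-exact numerics.

Transformers follow the scikit-learn estimator contract (``fit`` /
``transform`` on an ``(n_arrays, n_spots)`` matrix, ``get_params`` /
``set_params``, fitted attributes with trailing underscores) and the
module-level functions wrap them for :class:`~kinosim.arrays_io.KinomeArray`
inputs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .arrays_io import ArrayValidationError, KinomeArray

__all__ = [
    "NormalizedArray",
    "GlogParams",
    "Log2Transform",
    "VsnGlogTransform",
    "log2_transform",
    "vsn_glog_transform",
    "raw_values",
]


@dataclasses.dataclass(frozen=True)
class NormalizedArray:
    """Per-spot transformed values of one array (shape ``(m, l)``)."""

    array_id: str
    peptide_ids: tuple[str, ...]
    values: np.ndarray
    method: str  # "raw" | "log2" | "vsn_glog"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(self.peptide_ids):
            raise ArrayValidationError("values must be an (m, l) matrix matching peptide_ids")
        if not np.all(np.isfinite(values)):
            raise ArrayValidationError("transformed values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "peptide_ids", tuple(self.peptide_ids))

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def l(self) -> int:
        return self.values.shape[1]

    def peptide_means(self) -> np.ndarray:
        return self.values.mean(axis=1)


@dataclasses.dataclass(frozen=True)
class GlogParams:
    """Fitted calibration of one array: ``h(x) = arcsinh((x - offset)/scale)``."""

    offset: float
    scale: float
    iterations_run: int
    converged: bool

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ArrayValidationError("scale must be positive")


def raw_values(array: KinomeArray) -> NormalizedArray:
    """Untransformed background-corrected values as a NormalizedArray."""
    return NormalizedArray(array.array_id, array.peptide_ids, array.corrected_matrix(), "raw")


class Log2Transform(TransformerMixin, BaseEstimator):
    """Elementwise Log2: positive values -> log2, nonpositive values -> 0.

    Stateless; ``fit`` only records the input width.  Zero is mapped with
    the negatives (log2 is undefined there), making the transform constant
    on the whole nonpositive range -- the information-destroying behaviour
    the evaluation pipeline quantifies.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._validate(X)
        out = np.zeros_like(X)
        positive = X > 0
        out[positive] = np.log2(X[positive])
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D (n_arrays, n_spots) matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        return X


class VsnGlogTransform(TransformerMixin, BaseEstimator):
    """Per-array affine calibration + arcsinh, fitted for variance stability.

    Parameters
    ----------
    n_replicates:
        Number of consecutive columns forming one peptide's within-array
        replicate group (1 means each column is its own group across
        arrays, the classic expression-matrix layout).
    trim:
        Least-trimmed-squares fraction: the share of peptide groups with the
        smallest within-group scatter kept in the objective; guards the fit
        against differentially phosphorylated peptides.
    max_iter, tol:
        Outer coordinate-descent sweeps over arrays stop when the objective
        decreases by less than ``tol`` or after ``max_iter`` sweeps.

    Attributes
    ----------
    offsets_, scales_ : ndarray of shape (n_arrays,)
        Fitted ``a_i`` and ``b_i``.
    n_iter_ : int
        Coordinate-descent sweeps run.
    converged_ : bool
        Whether the stopping tolerance was reached before ``max_iter``.
    objective_ : float
        Final trimmed profile negative log-likelihood.
    """

    def __init__(self, n_replicates: int = 1, trim: float = 0.9, max_iter: int = 100, tol: float = 1e-8):
        self.n_replicates = n_replicates
        self.trim = trim
        self.max_iter = max_iter
        self.tol = tol

    # -- objective -------------------------------------------------------

    def _group_terms(self, X: np.ndarray, a: np.ndarray, b: np.ndarray):
        """Per-group residual sums of squares and Jacobian log-terms."""
        n_arrays, n_spots = X.shape
        l = self.n_replicates
        m = n_spots // l
        centered = X - a[:, None]
        H = np.arcsinh(centered / b[:, None])
        Hg = H.reshape(n_arrays, m, l)
        gmean = Hg.mean(axis=(0, 2))
        rss = ((Hg - gmean[None, :, None]) ** 2).sum(axis=(0, 2))
        # log h'(x) = -0.5 * log(b^2 + (x - a)^2)
        logjac = -0.5 * np.log(b[:, None] ** 2 + centered**2)
        jac = logjac.reshape(n_arrays, m, l).sum(axis=(0, 2))
        return rss, jac

    def _objective(self, X: np.ndarray, a: np.ndarray, b: np.ndarray, keep: np.ndarray) -> float:
        rss, jac = self._group_terms(X, a, b)
        n_in = keep.size * X.shape[0] * self.n_replicates
        total_rss = float(rss[keep].sum())
        if total_rss <= 0:
            total_rss = np.finfo(float).tiny
        return 0.5 * n_in * np.log(total_rss / n_in) - float(jac[keep].sum())

    def _keep_set(self, X: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        rss, _ = self._group_terms(X, a, b)
        m = rss.shape[0]
        n_keep = max(2, int(np.ceil(self.trim * m)))
        return np.sort(np.argsort(rss)[:n_keep])

    # -- initialization --------------------------------------------------

    def _initialize(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_arrays, n_spots = X.shape
        l = self.n_replicates
        m = n_spots // l
        a0 = np.empty(n_arrays)
        b0 = np.empty(n_arrays)
        for i in range(n_arrays):
            groups = X[i].reshape(m, l)
            means = groups.mean(axis=1)
            sds = groups.std(axis=1, ddof=1) if l > 1 else np.abs(groups[:, 0] - np.median(means))
            order = np.argsort(means)
            low = order[: max(2, m // 5)]
            high = order[int(0.7 * m) :]
            a0[i] = float(np.median(groups[low]))
            sd_add = float(np.median(sds[low]))
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = sds[high] / np.maximum(means[high] - a0[i], np.finfo(float).tiny)
            rel = rel[np.isfinite(rel) & (rel > 0)]
            rel_med = float(np.median(rel)) if rel.size else 0.1
            b0[i] = max(sd_add / max(rel_med, 1e-3), 1e-6 * (np.ptp(X[i]) or 1.0))
        return a0, b0

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D (n_arrays, n_spots) matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        n_arrays, n_spots = X.shape
        if n_arrays < 2:
            raise ValueError("glog calibration needs at least 2 arrays")
        if self.n_replicates < 1 or n_spots % self.n_replicates != 0:
            raise ValueError("n_spots must be a multiple of n_replicates")
        if not 0.0 < self.trim <= 1.0:
            raise ValueError("trim must be in (0, 1]")
        if np.ptp(X) == 0:
            raise ValueError("degenerate input: all values identical")
        a, b = self._initialize(X)
        keep = self._keep_set(X, a, b)
        objective = self._objective(X, a, b, keep)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            for i in range(n_arrays):
                def per_array(params, i=i):
                    a_try = a.copy()
                    b_try = b.copy()
                    a_try[i] = params[0]
                    b_try[i] = np.exp(params[1])
                    return self._objective(X, a_try, b_try, keep)

                res = optimize.minimize(
                    per_array,
                    np.array([a[i], np.log(b[i])]),
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 200},
                )
                if res.fun < self._objective(X, a, b, keep):
                    a[i] = res.x[0]
                    b[i] = float(np.exp(res.x[1]))
            keep = self._keep_set(X, a, b)
            new_objective = self._objective(X, a, b, keep)
            if objective - new_objective < self.tol:
                objective = min(objective, new_objective)
                converged = True
                break
            objective = new_objective
        self.offsets_ = a
        self.scales_ = b
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.objective_ = float(objective)
        self.n_features_in_ = n_spots
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "offsets_"):
            raise ValueError("VsnGlogTransform is not fitted")
        if X.shape != (self.offsets_.shape[0], self.n_features_in_):
            raise ValueError(
                "calibration is per-array: transform expects the same "
                f"(n_arrays, n_spots) shape as fit, {(self.offsets_.shape[0], self.n_features_in_)}"
            )
        return np.arcsinh((X - self.offsets_[:, None]) / self.scales_[:, None])


def log2_transform(array: KinomeArray) -> NormalizedArray:
    """Log2-transform one array's background-corrected values."""
    matrix = array.corrected_matrix()
    values = Log2Transform().fit_transform(matrix.reshape(1, -1)).reshape(matrix.shape)
    return NormalizedArray(array.array_id, array.peptide_ids, values, "log2")


def vsn_glog_transform(
    arrays: Sequence[KinomeArray],
    trim: float = 0.9,
    max_iter: int = 100,
    tol: float = 1e-8,
    seed=None,
) -> tuple[list[NormalizedArray], list[GlogParams]]:
    """Jointly calibrate and glog-transform two or more comparable arrays.

    The fit is deterministic given the inputs; ``seed`` is accepted for
    interface uniformity with the stochastic pipeline stages and is unused.
    """
    arrays = list(arrays)
    if len(arrays) < 2:
        raise ArrayValidationError("vsn_glog_transform needs at least 2 comparable arrays")
    first = arrays[0]
    for other in arrays[1:]:
        if not first.comparable_with(other):
            raise ArrayValidationError(
                f"arrays {first.array_id!r} and {other.array_id!r} are not comparable"
            )
    X = np.stack([a.corrected_matrix().ravel() for a in arrays])
    transformer = VsnGlogTransform(n_replicates=first.l, trim=trim, max_iter=max_iter, tol=tol)
    H = transformer.fit_transform(X)
    normalized = [
        NormalizedArray(a.array_id, a.peptide_ids, H[i].reshape(a.m, a.l), "vsn_glog")
        for i, a in enumerate(arrays)
    ]
    params = [
        GlogParams(
            offset=float(transformer.offsets_[i]),
            scale=float(transformer.scales_[i]),
            iterations_run=transformer.n_iter_,
            converged=transformer.converged_,
        )
        for i in range(len(arrays))
    ]
    return normalized, params
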