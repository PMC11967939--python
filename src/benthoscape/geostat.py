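"""Variogram estimation, ordinary kriging and cross-validation diagnostics.

The spatial predictor throughout the package is ordinary kriging: the best
linear unbiased predictor under an intrinsically stationary, isotropic
random-field model, with weights constrained to sum to one and driven by a
fitted variogram.  The workflow mirrors automatic-fitting geostatistics
practice: estimate an empirical semivariogram, fit spherical / exponential
/ gaussian candidates by weighted least squares (weights N(h)/h^2), keep
the best family, then solve the ordinary-kriging system per target point,
reporting both predictions and prediction standard errors.

:class:`OrdinaryKriging` is an sklearn-style estimator (``fit(X, y)`` on
n x 2 planar coordinates in metres, ``predict(X, return_std=True)``) so it
composes with scikit-learn model selection; the module-level functions
:func:`krige` and :func:`cross_validate` are thin wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "VariogramModel", "EmpiricalVariogram", "KrigingResult", "CVReport",
    "empirical_variogram", "fit_variogram", "OrdinaryKriging", "krige",
    "cross_validate", "DEFAULT_FAMILIES",
]

DEFAULT_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic variogram gamma(h) = nugget + partial_sill * g(h / range_m).

    Uses the gstat parameterisation: for the exponential and gaussian
    families ``range_m`` is the distance parameter of the exponential, not
    the practical range (the distance at ~95% of the sill); use
    :attr:`practical_range` to compare ranges across families.
    gamma(0) = 0 by convention (the nugget is a discontinuity at the
    origin, not a value at distance zero).
    """

    family: str
    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.range_m <= 0:
            raise ValueError("range_m must be positive")

    @property
    def sill(self) -> float:
        """Total sill (nugget + partial sill), the plateau semivariance."""
        return self.nugget + self.partial_sill

    @property
    def practical_range(self) -> float:
        """Distance at which gamma reaches ~95% of the sill."""
        if self.family == "spherical":
            return self.range_m
        if self.family == "exponential":
            return 3.0 * self.range_m
        return np.sqrt(3.0) * self.range_m  # gaussian

    def __call__(self, h: np.ndarray | float) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = h / self.range_m
        if self.family == "spherical":
            g = np.where(r < 1.0, 1.5 * r - 0.5 * r ** 3, 1.0)
        elif self.family == "exponential":
            g = 1.0 - np.exp(-r)
        else:
            g = 1.0 - np.exp(-r ** 2)
        out = self.nugget + self.partial_sill * g
        return np.where(h > 0, out, 0.0)

    def covariance(self, h: np.ndarray | float) -> np.ndarray:
        """C(h) = sill - gamma(h), with C(0) = sill."""
        return self.sill - self(h)


@dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariance estimates."""

    bin_centres: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.bin_centres = np.asarray(self.bin_centres, dtype=float)
        self.semivariances = np.asarray(self.semivariances, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not (len(self.bin_centres) == len(self.semivariances)
                == len(self.pair_counts)):
            raise ValueError("variogram arrays must have equal length")
        if np.any(self.semivariances < 0) or np.any(self.pair_counts < 0):
            raise ValueError("semivariances and pair counts must be >= 0")
        if np.any(np.diff(self.bin_centres) <= 0):
            raise ValueError("bins must be ordered by increasing distance")


@dataclass
class KrigingResult:
    predictions: np.ndarray
    standard_errors: np.ndarray


@dataclass
class CVReport:
    """k-fold cross-validation diagnostics for a kriging configuration.

    ME: mean error (pred - obs); MPSE: mean predicted standard error;
    MSNE: mean square normalised error, mean(((pred-obs)/SE)^2), ~1 when
    the model's uncertainty is well calibrated; COP: Pearson correlation
    of observed with predicted; CPR: Pearson correlation of predicted with
    residual (pred - obs).
    """

    ME: float
    MPSE: float
    MSNE: float
    COP: float
    CPR: float
    seed: int
    k: int
    observed: np.ndarray = field(repr=False, default=None)
    predicted: np.ndarray = field(repr=False, default=None)
    standard_errors: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict[str, float]:
        return {"ME": self.ME, "MPSE": self.MPSE, "MSNE": self.MSNE,
                "COP": self.COP, "CPR": self.CPR}


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar "
                         "coordinates in metres")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


def empirical_variogram(points: np.ndarray, values: np.ndarray,
                        cutoff: float | None = None,
                        n_bins: int = 15) -> EmpiricalVariogram:
    """Method-of-moments semivariogram on uniform distance bins.

    gamma(h) = sum over pairs in the bin of (z_i - z_j)^2 / (2 N(h)).
    ``cutoff`` defaults to one third of the maximum pairwise distance;
    empty bins are omitted.  Bin centres are the mean pair distance within
    each bin.
    """
    pts = _as_points(points)
    z = np.asarray(values, dtype=float).ravel()
    if len(z) != len(pts):
        raise ValueError("points and values lengths differ")
    if len(pts) < 2:
        raise ValueError("need at least 2 points for a variogram")
    d = pdist(pts)
    if cutoff is None:
        cutoff = d.max() / 3.0
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sq = 0.5 * pdist(z[:, None], metric="sqeuclidean")
    keep = d <= cutoff
    if not keep.any():
        raise ValueError("no point pairs within the cutoff distance")
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    idx = np.clip(np.digitize(d[keep], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    gamma_sum = np.bincount(idx, weights=sq[keep], minlength=n_bins)
    dist_sum = np.bincount(idx, weights=d[keep], minlength=n_bins)
    nz = counts > 0
    gamma = gamma_sum[nz] / counts[nz]
    centres = dist_sum[nz] / counts[nz]
    if np.allclose(gamma, 0.0):
        warnings.warn("constant field: all semivariances are zero",
                      stacklevel=2)
    return EmpiricalVariogram(centres, gamma, counts[nz], cutoff)


def _fit_one_family(family: str, h: np.ndarray, gamma: np.ndarray,
                    w: np.ndarray, cutoff: float):
    """Weighted least-squares fit of one family; returns (model, wsse)."""
    gmax = float(gamma.max())
    gmin = float(gamma.min())
    span = max(gmax - gmin, 1e-12 * max(gmax, 1.0))
    sw = np.sqrt(w)

    def resid(theta):
        m = VariogramModel(family, theta[0], theta[1], theta[2])
        return sw * (m(h) - gamma)

    lo = [0.0, 0.0, h[0] * 1e-3]
    hi = [np.inf, np.inf, 10.0 * cutoff]
    starts = [
        (max(gmin, 0.0), span, cutoff / 2.0),
        (0.0, gmax, cutoff / 5.0),
        (0.5 * gmax, 0.5 * span, cutoff),
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None, np.inf
    model = VariogramModel(family, float(best.x[0]), float(best.x[1]),
                           float(max(best.x[2], h[0] * 1e-3)))
    return model, 2.0 * float(best.cost)


def fit_variogram(emp: EmpiricalVariogram,
                  candidates: tuple[str, ...] = DEFAULT_FAMILIES,
                  ) -> VariogramModel:
    """Fit candidate variogram families, keeping the lowest weighted SSE.

    The objective is sum over bins of N(h)/h^2 * (gamma_emp - gamma_model)^2,
    the weighting of automatic variogram-fitting practice: short, well
    populated lags dominate.  Parameters are bounded nonnegative.
    """
    h = emp.bin_centres
    gamma = emp.semivariances
    if len(h) < 3:
        raise ValueError("need at least 3 non-empty bins to fit a variogram")
    if np.allclose(gamma, 0.0):
        warnings.warn("all-zero empirical variogram: degenerate flat model",
                      stacklevel=2)
        return VariogramModel(candidates[0], 0.0, 0.0, float(h[0]))
    w = emp.pair_counts / h ** 2
    best_model, best_sse = None, np.inf
    for fam in candidates:
        model, sse = _fit_one_family(fam, h, gamma, w, emp.cutoff)
        if model is not None and sse < best_sse:
            best_model, best_sse = model, sse
    if best_model is None:
        raise RuntimeError(
            f"variogram fit failed to converge for all families {candidates}")
    return best_model


class OrdinaryKriging(RegressorMixin, BaseEstimator):
    """Ordinary kriging with automatic variogram fitting.

    Parameters
    ----------
    variogram : "auto" or VariogramModel
        Fixed variogram model, or "auto" to fit one from the training data.
    families : tuple of str
        Candidate families for automatic fitting.
    cutoff : float or None
        Empirical-variogram cutoff in metres (None: 1/3 max pair distance).
    n_bins : int
        Number of distance bins for the empirical variogram.

    Attributes
    ----------
    X_ : (n, 2) training coordinates (duplicates averaged).
    y_ : (n,) training values.
    variogram_ : the VariogramModel used for prediction.
    """

    def __init__(self, variogram="auto", families=DEFAULT_FAMILIES,
                 cutoff=None, n_bins=15):
        self.variogram = variogram
        self.families = families
        self.cutoff = cutoff
        self.n_bins = n_bins

    def fit(self, X, y):
        X = _as_points(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if len(X) < 1:
            raise ValueError("need at least one data point")
        X, y = self._deduplicate(X, y)
        if isinstance(self.variogram, VariogramModel):
            self.variogram_ = self.variogram
        elif self.variogram == "auto":
            emp = empirical_variogram(X, y, cutoff=self.cutoff,
                                      n_bins=self.n_bins)
            self.variogram_ = fit_variogram(emp, tuple(self.families))
        else:
            raise ValueError("variogram must be 'auto' or a VariogramModel")
        self.X_, self.y_ = X, y
        n = len(X)
        # Augmented OK system [Gamma 1; 1' 0]; factorised once per fit.
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = self.variogram_(squareform(pdist(X))) if n > 1 else 0.0
        a[:n, n] = 1.0
        a[n, :n] = 1.0
        a[n, n] = 0.0
        self._lu = lu_factor(a)
        return self

    @staticmethod
    def _deduplicate(X, y):
        uniq, inv = np.unique(X, axis=0, return_inverse=True)
        if len(uniq) < len(X):
            warnings.warn(
                f"{len(X) - len(uniq)} duplicate coordinates averaged before "
                "kriging", stacklevel=3)
            sums = np.bincount(inv, weights=y)
            counts = np.bincount(inv)
            return uniq, sums / counts
        return X, y

    def predict(self, X, return_std: bool = False):
        """Krige at target points; optionally return standard errors.

        Prediction at t is sum(lambda_i z_i) with weights solving the
        ordinary-kriging system; the kriging variance is
        sum(lambda_i gamma(d_i,t)) + mu, clamped at zero before the root.
        """
        if not hasattr(self, "X_"):
            raise RuntimeError("estimator is not fitted")
        T = _as_points(X)
        n = len(self.X_)
        g0 = np.empty((n + 1, len(T)))
        g0[:n] = self.variogram_(cdist(self.X_, T))
        g0[n] = 1.0
        sol = lu_solve(self._lu, g0)
        lam = sol[:n]
        mu = sol[n]
        preds = lam.T @ self.y_
        var = np.einsum("it,it->t", lam, g0[:n]) + mu
        if not return_std:
            return preds
        return preds, np.sqrt(np.maximum(var, 0.0))

    def weights(self, target) -> tuple[np.ndarray, float]:
        """Kriging weights and Lagrange multiplier for one target point."""
        if not hasattr(self, "X_"):
            raise RuntimeError("estimator is not fitted")
        t = _as_points(np.atleast_2d(target))
        n = len(self.X_)
        g0 = np.concatenate([self.variogram_(cdist(self.X_, t)).ravel(), [1.0]])
        sol = lu_solve(self._lu, g0)
        return sol[:n], float(sol[n])


def krige(points, values, model: VariogramModel, targets) -> KrigingResult:
    """Ordinary kriging of ``values`` at ``points`` onto ``targets``."""
    ok = OrdinaryKriging(variogram=model).fit(points, values)
    preds, se = ok.predict(targets, return_std=True)
    return KrigingResult(preds, se)


def cross_validate(points, values, model_spec="auto", k: int = 5,
                   seed: int = 0, families=DEFAULT_FAMILIES,
                   cutoff=None, n_bins: int = 15) -> CVReport:
    """k-fold cross-validation of the kriging configuration.

    Stations are partitioned into k random folds by ``seed``; each fold is
    predicted from the remaining folds.  With ``model_spec="auto"`` the
    variogram is refitted inside every training split so the diagnostics
    carry no information leakage; a fixed :class:`VariogramModel` is used
    as-is.  Points with SE = 0 are skipped in MSNE (with a warning).
    """
    pts = _as_points(points)
    z = np.asarray(values, dtype=float).ravel()
    n = len(pts)
    if not 2 <= k <= n:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    pred = np.empty(n)
    se = np.empty(n)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        if len(train) < 2:
            raise ValueError("a fold left fewer than 2 training points")
        ok = OrdinaryKriging(variogram=model_spec, families=families,
                             cutoff=cutoff, n_bins=n_bins)
        ok.fit(pts[train], z[train])
        pred[fold], se[fold] = ok.predict(pts[fold], return_std=True)
    err = pred - z
    ok_se = se > 0
    if not ok_se.all():
        warnings.warn(f"{np.sum(~ok_se)} points with SE=0 skipped in MSNE",
                      stacklevel=2)
    msne = float(np.mean((err[ok_se] / se[ok_se]) ** 2)) if ok_se.any() \
        else np.nan
    cop = float(np.corrcoef(z, pred)[0, 1]) if np.std(pred) > 0 else np.nan
    cpr = float(np.corrcoef(pred, err)[0, 1]) if np.std(pred) > 0 and \
        np.std(err) > 0 else np.nan
    return CVReport(ME=float(err.mean()), MPSE=float(se.mean()), MSNE=msne,
                    COP=cop, CPR=cpr, seed=seed, k=k,
                    observed=z, predicted=pred, standard_errors=se)
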