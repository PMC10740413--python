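"""Surrogate modelling of the nozzle flow-rate surface Q(n, K, P).

Repeated flow solves over the printable-ink parameter box — power-law
index n in [0.45, 0.7], consistency coefficient K in [10, 100] Pa*s,
extrusion pressure P in [50, 350] kPa — are replaced by a cheap trained
approximator:

1. Latin-hypercube sampling fills the box with one point per equal
   stratum on every axis (300 training points by default).
2. The quasi-1D solver evaluates Q at each point.
3. A one-hidden-layer tanh network with an L2 (ridge) penalty, trained by
   deterministic L-BFGS on standardized inputs/outputs, approximates the
   surface; a thin-plate radial-basis interpolant is available as an
   alternative backend under the same interface.
4. Accuracy is scored on fresh random points by MAE and RMSE, reported
   both raw (uL/s) and as a percentage of the observed flow-rate range.
5. k-means (k = 3) on the standardized (n, K, Q) surface at fixed
   pressure partitions the inks into low/medium/high-viscosity regimes,
   labelled canonically by descending mean flow rate (high viscosity =
   low flow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.stats import qmc
from sklearn.cluster import KMeans
from sklearn.neural_network import MLPRegressor

from .nozzleflow import NozzleGeometry, default_geometry, solve_flow_rate
from .rheology import PowerLawParams

__all__ = [
    "SAMPLING_BOX",
    "SampleSet",
    "SurrogateModel",
    "ErrorReport",
    "latin_hypercube",
    "build_flow_dataset",
    "train_surrogate",
    "evaluate_surrogate",
    "classify_regimes",
    "flow_surface",
]

#: Default sampling box: (low, high) per input, matching the printable-ink
#: screening ranges (pressure in kPa).
SAMPLING_BOX: dict[str, tuple[float, float]] = {
    "n": (0.45, 0.7),
    "K_pa_s": (10.0, 100.0),
    "P_kpa": (50.0, 350.0),
}

_INPUTS = ("n", "K_pa_s", "P_kpa")


@dataclass(frozen=True)
class SampleSet:
    """LHS (or random) points over the (n, K, P) box, with Q once evaluated.

    ``points`` has columns n, K_pa_s, P_kpa and, after
    :func:`build_flow_dataset`, Q_ul_s.  ``failures`` records indices of
    points the solver could not evaluate (never silently dropped).
    """

    points: pd.DataFrame
    bounds: dict[str, tuple[float, float]]
    seed: int
    failures: tuple[int, ...] = field(default=())

    @property
    def has_flow(self) -> bool:
        return "Q_ul_s" in self.points.columns

    def __len__(self) -> int:
        return len(self.points)


def _check_bounds(bounds: dict[str, tuple[float, float]]) -> None:
    for k in _INPUTS:
        if k not in bounds:
            raise ValueError(f"bounds missing '{k}'")
        lo, hi = bounds[k]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"degenerate bounds for {k}: ({lo}, {hi})")


def latin_hypercube(bounds: dict[str, tuple[float, float]] | None = None,
                    n_samples: int = 300, seed: int = 0) -> SampleSet:
    """Latin-hypercube sample of the (n, K, P) box.

    Exactly one point falls in each of ``n_samples`` equal strata on every
    axis; reproducible for a fixed seed.
    """
    if bounds is None:
        bounds = SAMPLING_BOX
    _check_bounds(bounds)
    if n_samples < 1:
        raise ValueError("need at least one sample")
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    unit = sampler.random(n_samples)
    lo = np.array([bounds[k][0] for k in _INPUTS])
    hi = np.array([bounds[k][1] for k in _INPUTS])
    pts = qmc.scale(unit, lo, hi)
    return SampleSet(points=pd.DataFrame(pts, columns=list(_INPUTS)),
                     bounds=dict(bounds), seed=seed)


def build_flow_dataset(samples: SampleSet,
                       geometry: NozzleGeometry | None = None) -> SampleSet:
    """Evaluate the flow solver at every sample point, filling Q_ul_s.

    Solver failures are recorded by point index in ``failures`` with NaN
    flow, never dropped.
    """
    geometry = geometry or default_geometry()
    q = np.full(len(samples), np.nan)
    failures: list[int] = []
    for i, row in enumerate(samples.points.itertuples(index=False)):
        try:
            sol = solve_flow_rate(PowerLawParams(n=row.n, K=row.K_pa_s),
                                  geometry, row.P_kpa)
            q[i] = sol.q_ul_s
        except Exception:
            failures.append(i)
    pts = samples.points.copy()
    pts["Q_ul_s"] = q
    return replace(samples, points=pts, failures=tuple(failures))


# ---------------------------------------------------------------------------
# Surrogate
# ---------------------------------------------------------------------------

class TrainingDivergenceError(RuntimeError):
    """Training produced a non-finite loss or predictions."""


@dataclass(frozen=True)
class SurrogateModel:
    """Trained flow-rate approximator over the sampling box.

    Inputs are standardized with the stored training means/scales; the
    prediction de-standardizes the output.  Points outside the training
    box are still evaluated but flagged by :meth:`extrapolating`.
    """

    backend: str                      # "mlp" | "rbf"
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    bounds: dict[str, tuple[float, float]]
    seed: int
    ridge: float
    hidden_units: int
    log_space: bool = True
    _net: MLPRegressor | None = field(default=None, compare=False, repr=False)
    _rbf: RBFInterpolator | None = field(default=None, compare=False, repr=False)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_scale

    def predict(self, X) -> np.ndarray:
        """Predicted flow rate uL/s at rows of (n, K_pa_s, P_kpa)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = self._standardize(X)
        if self.backend == "mlp":
            y = self._net.predict(Z)
        else:
            y = self._rbf(Z)
        y = y * self.y_scale + self.y_mean
        return np.exp(y) if self.log_space else y

    def extrapolating(self, X) -> np.ndarray:
        """Boolean mask: rows outside the training box."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo = np.array([self.bounds[k][0] for k in _INPUTS])
        hi = np.array([self.bounds[k][1] for k in _INPUTS])
        return np.any((X < lo) | (X > hi), axis=1)

    # -- serialization (weights + normalization; mlp backend only) --------
    def to_json(self) -> str:
        if self.backend != "mlp":
            raise ValueError("only the mlp backend serializes to JSON")
        return json.dumps({
            "backend": self.backend,
            "x_mean": self.x_mean.tolist(), "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean, "y_scale": self.y_scale,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed, "ridge": self.ridge,
            "hidden_units": self.hidden_units, "log_space": self.log_space,
            "coefs": [w.tolist() for w in self._net.coefs_],
            "intercepts": [b.tolist() for b in self._net.intercepts_],
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        d = json.loads(text)
        net = MLPRegressor(hidden_layer_sizes=(d["hidden_units"],),
                           activation="tanh")
        net.coefs_ = [np.asarray(w) for w in d["coefs"]]
        net.intercepts_ = [np.asarray(b) for b in d["intercepts"]]
        net.n_layers_ = 3
        net.out_activation_ = "identity"
        net.n_outputs_ = 1
        return cls(backend="mlp",
                   x_mean=np.asarray(d["x_mean"]), x_scale=np.asarray(d["x_scale"]),
                   y_mean=d["y_mean"], y_scale=d["y_scale"],
                   bounds={k: tuple(v) for k, v in d["bounds"].items()},
                   seed=d["seed"], ridge=d["ridge"],
                   hidden_units=d["hidden_units"],
                   log_space=d.get("log_space", True), _net=net)


def train_surrogate(dataset: SampleSet, hidden_units: int = 8,
                    ridge: float = 1e-5, seed: int = 0,
                    backend: str = "mlp", log_space: bool = True,
                    restarts: int = 3) -> SurrogateModel:
    """Train the flow-rate surrogate on an evaluated sample set.

    ``backend='mlp'`` (default): one hidden tanh layer of ``hidden_units``
    neurons with L2 penalty ``ridge``, optimised by L-BFGS; ``restarts``
    seed-derived initialisations are tried and the lowest training loss
    kept — deterministic given the seed.  ``backend='rbf'``:
    thin-plate-spline radial basis interpolant with ``ridge`` as smoothing
    (ignores ``hidden_units``/``seed``).  With ``log_space=True`` (default)
    the target is log Q, the natural scale for a positive flow rate
    spanning decades over the box; predictions are exponentiated back.
    """
    if not dataset.has_flow:
        raise ValueError("dataset has no flow rates; run build_flow_dataset first")
    pts = dataset.points.dropna(subset=["Q_ul_s"])
    if len(pts) < 30:
        raise ValueError(f"need >= 30 training points, got {len(pts)}")
    X = pts[list(_INPUTS)].to_numpy()
    y = pts["Q_ul_s"].to_numpy()
    if log_space and np.any(y <= 0):
        raise ValueError("log-space training needs strictly positive flow rates")
    t = np.log(y) if log_space else y
    x_mean, x_scale = X.mean(axis=0), X.std(axis=0)
    y_mean, y_scale = float(t.mean()), float(t.std())
    if np.any(x_scale == 0) or y_scale == 0:
        raise ValueError("degenerate training data: zero variance")
    Z = (X - x_mean) / x_scale
    t = (t - y_mean) / y_scale

    if backend == "mlp":
        best = None
        for r in range(max(restarts, 1)):
            net = MLPRegressor(hidden_layer_sizes=(hidden_units,),
                               activation="tanh", solver="lbfgs", alpha=ridge,
                               max_iter=5000, tol=1e-12,
                               random_state=seed + 7919 * r)
            net.fit(Z, t)
            if best is None or net.loss_ < best.loss_:
                best = net
        if not np.isfinite(best.loss_):
            raise TrainingDivergenceError(f"non-finite training loss {best.loss_}")
        model = SurrogateModel(backend="mlp", x_mean=x_mean, x_scale=x_scale,
                               y_mean=y_mean, y_scale=y_scale,
                               bounds=dict(dataset.bounds), seed=seed,
                               ridge=ridge, hidden_units=hidden_units,
                               log_space=log_space, _net=best)
    elif backend == "rbf":
        rbf = RBFInterpolator(Z, t, kernel="thin_plate_spline", smoothing=ridge)
        model = SurrogateModel(backend="rbf", x_mean=x_mean, x_scale=x_scale,
                               y_mean=y_mean, y_scale=y_scale,
                               bounds=dict(dataset.bounds), seed=seed,
                               ridge=ridge, hidden_units=0,
                               log_space=log_space, _rbf=rbf)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    if not np.all(np.isfinite(model.predict(X))):
        raise TrainingDivergenceError("non-finite predictions on training data")
    return model


@dataclass(frozen=True)
class ErrorReport:
    """Surrogate accuracy: MAE = mean|y - yhat|, RMSE = sqrt(mean (y-yhat)^2).

    Percentages are relative to the observed flow-rate range of the test
    set (``q_range``); raw values are in uL/s.  RMSE >= MAE always.
    """

    mae: float
    rmse: float
    mae_pct_of_range: float
    rmse_pct_of_range: float
    q_range: float
    residuals: np.ndarray
    n_test: int


def evaluate_surrogate(model: SurrogateModel, test_points,
                       true_q) -> ErrorReport:
    """Score the surrogate on test points with known solver flow rates."""
    X = np.atleast_2d(np.asarray(test_points, dtype=float))
    y = np.asarray(true_q, dtype=float)
    if y.size == 0:
        raise ValueError("empty test set")
    resid = y - model.predict(X)
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    rng = float(np.ptp(y)) if y.size > 1 else float(abs(y[0]))
    denom = rng if rng > 0 else np.nan
    return ErrorReport(mae=mae, rmse=rmse,
                       mae_pct_of_range=100.0 * mae / denom,
                       rmse_pct_of_range=100.0 * rmse / denom,
                       q_range=rng, residuals=resid, n_test=int(y.size))


# ---------------------------------------------------------------------------
# Regime classification and surface export
# ---------------------------------------------------------------------------

REGIME_LABELS = ("high-viscosity", "medium-viscosity", "low-viscosity")


def classify_regimes(surface: pd.DataFrame, k: int = 3,
                     seed: int = 0) -> pd.DataFrame:
    """Partition the flow surface into viscosity regimes by k-means.

    ``surface`` needs columns n, K_pa_s, Q_ul_s; clustering runs on the
    standardized (n, K, Q) features with k-means++ seeding (deterministic
    for a fixed seed).  Clusters are relabelled canonically by ascending
    mean flow rate: lowest Q = 'high-viscosity', highest Q =
    'low-viscosity'.  Returns a copy with 'cluster' (0..k-1 in that
    canonical order) and 'regime' columns.
    """
    req = {"n", "K_pa_s", "Q_ul_s"}
    if not req.issubset(surface.columns):
        raise ValueError(f"surface needs columns {sorted(req)}")
    if len(surface) < k:
        raise ValueError(f"k={k} exceeds number of points {len(surface)}")
    F = surface[["n", "K_pa_s", "Q_ul_s"]].to_numpy()
    Z = (F - F.mean(axis=0)) / F.std(axis=0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(Z)
    mean_q = [surface["Q_ul_s"].to_numpy()[raw == c].mean() for c in range(k)]
    order = np.argsort(mean_q)  # ascending Q: high viscosity first
    canon = np.empty(k, dtype=int)
    canon[order] = np.arange(k)
    out = surface.copy()
    out["cluster"] = canon[raw]
    if k == 3:
        out["regime"] = [REGIME_LABELS[c] for c in out["cluster"]]
    return out


def flow_surface(pressure_kpa: float, grid_steps: int = 20,
                 model: SurrogateModel | None = None,
                 geometry: NozzleGeometry | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 ) -> pd.DataFrame:
    """Tabulate Q over an (n, K) grid at fixed pressure.

    With ``model`` given, Q comes from the surrogate (rows outside its
    training box are flagged in an 'extrapolated' column); otherwise each
    grid point is solved directly.  Surrogate and solver surfaces agree
    closely over the interior of the box; the largest deviations sit at
    the steep low-n/low-K corner where the training-sample density
    vanishes.
    """
    bounds = dict(bounds or SAMPLING_BOX)
    ns = np.linspace(*bounds["n"], grid_steps)
    ks = np.linspace(*bounds["K_pa_s"], grid_steps)
    N, K = np.meshgrid(ns, ks, indexing="ij")
    X = np.column_stack([N.ravel(), K.ravel(),
                         np.full(N.size, float(pressure_kpa))])
    df = pd.DataFrame(X, columns=list(_INPUTS))
    if model is not None:
        df["Q_ul_s"] = model.predict(X)
        df["extrapolated"] = model.extrapolating(X)
    else:
        geometry = geometry or default_geometry()
        df["Q_ul_s"] = [
            solve_flow_rate(PowerLawParams(n=r[0], K=r[1]), geometry, r[2]).q_ul_s
            for r in X]
    return df
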