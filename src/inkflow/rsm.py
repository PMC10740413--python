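"""Box-Behnken response-surface modelling of ink rheology versus composition.

The ink is a three-component blend of gelatin (Gel), sodium alginate (SA)
and methylcellulose (MC), dosed in wt%.  A three-factor Box-Behnken design
(12 edge-midpoint runs + centre replicates) supports a full second-order
polynomial

    Y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j + eps

for each rheological response: Y1 = power-law index n, Y2 = consistency
coefficient K.  The module provides

* design construction and coded/uncoded mapping,
* OLS fitting with classical ANOVA diagnostics (per-term F/p, lack-of-fit
  from the centre replicates, R^2 / adjusted R^2 / predicted R^2 via the
  leave-one-out PRESS identity),
* backward elimination with a predicted-R^2 retention override and term
  hierarchy,
* the published final prediction polynomials for n and K over the design
  cube Gel 6-10, SA 3-5, MC 2-4 wt%, and
* helpers: Pareto ordering of standardized effects, feasible-region
  enumeration, and the prediction-accuracy convention used to validate
  the models.

The published K polynomial's coefficients evaluate to values 1000x the
consistency coefficient in Pa*s (they were exported in mPa*s); the stored
model therefore carries an explicit ``output_scale`` of 1e-3, confirmed by
evaluating the polynomial at all five validation compositions.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompositionRatio",
    "BBDesign",
    "QuadraticModel",
    "AnovaReport",
    "DESIGN_CUBE",
    "PUBLISHED_N_MODEL",
    "PUBLISHED_K_MODEL",
    "make_bb_design",
    "full_quadratic_terms",
    "fit_quadratic",
    "backward_eliminate",
    "predict_n",
    "predict_K",
    "prediction_accuracy",
    "pareto_effects",
    "enumerate_feasible_region",
    "read_design_csv",
    "write_design_csv",
]

#: Factor ranges of the composition design cube, wt% (low, centre, high).
DESIGN_CUBE: dict[str, tuple[float, float, float]] = {
    "Gel": (6.0, 8.0, 10.0),
    "SA": (3.0, 4.0, 5.0),
    "MC": (2.0, 3.0, 4.0),
}


class SingularDesignError(ValueError):
    """Design matrix rank-deficient for the requested term set."""


@dataclass(frozen=True)
class CompositionRatio:
    """An ink composition a:b:c = gel:sa:mc in wt%.

    Compositions outside the design cube trigger a warning (extrapolation
    of the fitted surface), not an error.
    """

    gel: float
    sa: float
    mc: float

    def __post_init__(self) -> None:
        for name, v in (("gel", self.gel), ("sa", self.sa), ("mc", self.mc)):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} wt% must be finite and >= 0, got {v}")
        cube = [DESIGN_CUBE["Gel"], DESIGN_CUBE["SA"], DESIGN_CUBE["MC"]]
        vals = (self.gel, self.sa, self.mc)
        if any(not (lo <= v <= hi) for v, (lo, _, hi) in zip(vals, cube)):
            warnings.warn(
                f"composition {self.gel}:{self.sa}:{self.mc} lies outside the "
                "design cube Gel[6,10], SA[3,5], MC[2,4] wt%; predictions are "
                "extrapolations", stacklevel=3)

    def as_array(self) -> np.ndarray:
        return np.array([self.gel, self.sa, self.mc], dtype=float)


# ---------------------------------------------------------------------------
# Box-Behnken design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BBDesign:
    """A three-factor Box-Behnken design.

    ``coded`` holds the run matrix in {-1, 0, +1} units, in deterministic
    order: for each factor pair (lexicographic) the four sign combinations
    (-,-), (-,+), (+,-), (+,+) with the third factor at centre, followed by
    the centre replicates.
    """

    factor_names: tuple[str, ...]
    levels: tuple[tuple[float, float, float], ...]  # (low, centre, high) per factor
    coded: np.ndarray
    center_replicates: int

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def to_uncoded(self, coded: np.ndarray | None = None) -> np.ndarray:
        """Affine map from coded {-1,0,+1} units to factor (wt%) units."""
        c = self.coded if coded is None else np.asarray(coded, dtype=float)
        lo = np.array([lv[0] for lv in self.levels])
        ce = np.array([lv[1] for lv in self.levels])
        hi = np.array([lv[2] for lv in self.levels])
        # asymmetric half-ranges support non-centred level triples
        half_lo, half_hi = ce - lo, hi - ce
        return ce + np.where(c >= 0, c * half_hi, c * half_lo)

    def to_coded(self, uncoded: np.ndarray) -> np.ndarray:
        u = np.asarray(uncoded, dtype=float)
        lo = np.array([lv[0] for lv in self.levels])
        ce = np.array([lv[1] for lv in self.levels])
        hi = np.array([lv[2] for lv in self.levels])
        d = u - ce
        return np.where(d >= 0, d / (hi - ce), d / (ce - lo))


def make_bb_design(levels: dict[str, tuple[float, float, float]] | None = None,
                   center_replicates: int = 5) -> BBDesign:
    """Construct the three-factor Box-Behnken design.

    12 edge-midpoint runs (each with exactly one factor at its centre and
    the other two at +-1) plus ``center_replicates`` all-centre runs; the
    default levels and 5 centre replicates give the classical 17-run plan.
    """
    if levels is None:
        levels = DESIGN_CUBE
    if len(levels) != 3:
        raise ValueError("the Box-Behnken constructor here is for exactly 3 factors")
    if center_replicates < 1:
        raise ValueError("need at least one centre run")
    names = tuple(levels)
    triples = []
    for name in names:
        lo, ce, hi = levels[name]
        if not (lo < ce < hi):
            raise ValueError(f"levels for {name} must satisfy low < centre < high, "
                             f"got {levels[name]}")
        triples.append((lo, ce, hi))
    rows = []
    for i, j in itertools.combinations(range(3), 2):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend([[0.0, 0.0, 0.0]] * center_replicates)
    return BBDesign(factor_names=names, levels=tuple(triples),
                    coded=np.array(rows), center_replicates=center_replicates)


# ---------------------------------------------------------------------------
# Quadratic model + ANOVA
# ---------------------------------------------------------------------------

def full_quadratic_terms(factor_names: tuple[str, ...]) -> tuple[str, ...]:
    """Canonical term names of the full second-order model (intercept '1')."""
    names = list(factor_names)
    terms = ["1"] + names
    terms += [f"{f}^2" for f in names]
    terms += [f"{a}*{b}" for a, b in itertools.combinations(names, 2)]
    return tuple(terms)


def _term_column(term: str, X: np.ndarray, factor_names: tuple[str, ...]) -> np.ndarray:
    idx = {f: k for k, f in enumerate(factor_names)}
    if term == "1":
        return np.ones(X.shape[0])
    if term.endswith("^2"):
        return X[:, idx[term[:-2]]] ** 2
    if "*" in term:
        a, b = term.split("*")
        return X[:, idx[a]] * X[:, idx[b]]
    return X[:, idx[term]]


def design_matrix(X: np.ndarray, factor_names: tuple[str, ...],
                  terms: tuple[str, ...]) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([_term_column(t, X, factor_names) for t in terms])


@dataclass(frozen=True)
class QuadraticModel:
    """A (possibly reduced) second-order polynomial response model.

    ``coefficients`` maps term name -> coefficient; absent terms are
    excluded by the mask.  ``output_scale`` multiplies the polynomial value
    on prediction (used by the published K model, whose printed
    coefficients are in mPa*s).
    """

    response_name: str
    factor_names: tuple[str, ...]
    coefficients: dict[str, float]
    output_scale: float = 1.0
    residual_sd: float | None = None

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict(self, X) -> np.ndarray | float:
        """Evaluate the polynomial at composition(s) X (uncoded units)."""
        if isinstance(X, CompositionRatio):
            X = X.as_array()
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        M = design_matrix(arr, self.factor_names, self.terms)
        beta = np.array([self.coefficients[t] for t in self.terms])
        y = (M @ beta) * self.output_scale
        return float(y[0]) if np.asarray(X).ndim == 1 else y

    def to_json(self) -> str:
        return json.dumps({
            "response_name": self.response_name,
            "factor_names": list(self.factor_names),
            "coefficients": self.coefficients,
            "output_scale": self.output_scale,
            "residual_sd": self.residual_sd,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QuadraticModel":
        d = json.loads(text)
        return cls(response_name=d["response_name"],
                   factor_names=tuple(d["factor_names"]),
                   coefficients=dict(d["coefficients"]),
                   output_scale=d["output_scale"],
                   residual_sd=d.get("residual_sd"))


@dataclass(frozen=True)
class AnovaReport:
    """Classical ANOVA diagnostics for a fitted quadratic model.

    Per-term partial F and p (single-df terms, F = t^2), the model F test,
    the lack-of-fit test partitioning pure error from replicate groups,
    R^2 / adjusted R^2 / predicted R^2 (from PRESS via the leave-one-out
    hat-matrix identity), and standardized effects (t statistics) for
    Pareto ordering.  ``zero_variance`` flags a constant response, for
    which R^2 is reported as 0.
    """

    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    term_f: np.ndarray
    term_p: np.ndarray
    model_f: float
    model_p: float
    lack_of_fit_f: float | None
    lack_of_fit_p: float | None
    r_squared: float
    adj_r_squared: float
    pred_r_squared: float
    press: float
    ss_residual: float
    df_residual: int
    zero_variance: bool = False

    def standardized_effects(self) -> dict[str, float]:
        return {t: float(v) for t, v in zip(self.terms, self.t_values) if t != "1"}


def fit_quadratic(design: BBDesign, responses, term_mask: tuple[str, ...] | None = None,
                  response_name: str = "Y", uncoded: bool = True,
                  ) -> tuple[QuadraticModel, AnovaReport]:
    """OLS fit of a second-order polynomial to one response per design run.

    ``term_mask`` selects the included terms (default: the full 10-term
    model); the intercept is always included.  ``uncoded=True`` (default)
    fits in factor (wt%) units, matching how the published models are
    printed; ``uncoded=False`` fits in coded {-1,0,+1} units.
    """
    y = np.asarray(responses, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValueError(f"need one response per run: expected {design.n_runs}, "
                         f"got {y.shape}")
    terms = term_mask if term_mask is not None else full_quadratic_terms(design.factor_names)
    if "1" not in terms:
        terms = ("1",) + tuple(terms)
    terms = tuple(terms)
    X = design.to_uncoded() if uncoded else design.coded
    M = design_matrix(X, design.factor_names, terms)
    n, p = M.shape
    if n < p + 1:
        raise ValueError(f"{p} terms need at least {p + 1} runs, design has {n}")
    if np.linalg.matrix_rank(M) < p:
        raise SingularDesignError(f"design is rank-deficient for terms {terms}")

    MtM_inv = np.linalg.inv(M.T @ M)
    beta = MtM_inv @ (M.T @ y)
    fitted = M @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    dfe = n - p
    mse = ss_res / dfe if dfe > 0 else np.nan
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    zero_var = ss_tot == 0.0

    se = np.sqrt(np.maximum(np.diag(MtM_inv) * mse, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    # 0/0 (zero coefficient, perfect fit) -> no effect; x/0 -> infinite effect
    tvals = np.where(np.isnan(tvals), 0.0, tvals)
    term_f = tvals ** 2
    term_p = stats.f.sf(term_f, 1, dfe) if dfe > 0 else np.full(p, np.nan)

    # model F test (all non-intercept terms jointly)
    df_model = p - 1
    if zero_var or df_model == 0 or dfe == 0:
        model_f, model_p = np.nan, np.nan
    else:
        ms_model = (ss_tot - ss_res) / df_model
        model_f = ms_model / mse
        model_p = float(stats.f.sf(model_f, df_model, dfe))

    # PRESS via the leave-one-out identity e_i / (1 - h_ii)
    h = np.einsum("ij,jk,ik->i", M, MtM_inv, M)
    with np.errstate(divide="ignore", invalid="ignore"):
        press_resid = resid / (1.0 - h)
    press = float(np.sum(press_resid ** 2))

    if zero_var:
        r2 = adj_r2 = pred_r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (ss_res / dfe) / (ss_tot / (n - 1)) if dfe > 0 else np.nan
        pred_r2 = 1.0 - press / ss_tot

    # lack of fit: pure error from replicated design points
    lof_f = lof_p = None
    _, inverse = np.unique(np.round(X, 12), axis=0, return_inverse=True)
    ss_pe, df_pe = 0.0, 0
    for g in np.unique(inverse):
        yg = y[inverse == g]
        if yg.size > 1:
            ss_pe += float(np.sum((yg - yg.mean()) ** 2))
            df_pe += yg.size - 1
    df_lof = dfe - df_pe
    if df_pe > 0 and df_lof > 0:
        ss_lof = max(ss_res - ss_pe, 0.0)
        ms_pe = ss_pe / df_pe
        if ms_pe > 0:
            lof_f = float((ss_lof / df_lof) / ms_pe)
            lof_p = float(stats.f.sf(lof_f, df_lof, df_pe))

    model = QuadraticModel(
        response_name=response_name,
        factor_names=design.factor_names,
        coefficients={t: float(b) for t, b in zip(terms, beta)},
        residual_sd=float(np.sqrt(mse)) if dfe > 0 else None,
    )
    report = AnovaReport(
        terms=terms, coefficients=beta, standard_errors=se, t_values=tvals,
        term_f=term_f, term_p=np.asarray(term_p, dtype=float),
        model_f=float(model_f) if np.isfinite(model_f) else np.nan,
        model_p=float(model_p) if np.isfinite(np.asarray(model_p, dtype=float)) else np.nan,
        lack_of_fit_f=lof_f, lack_of_fit_p=lof_p,
        r_squared=r2, adj_r_squared=adj_r2, pred_r_squared=pred_r2,
        press=press, ss_residual=ss_res, df_residual=dfe, zero_variance=zero_var,
    )
    return model, report


def _hierarchy_protected(term: str, terms: tuple[str, ...]) -> bool:
    """A linear term is protected while any surviving higher term contains it."""
    if term == "1":
        return True
    if "^2" in term or "*" in term:
        return False
    for t in terms:
        if t == term:
            continue
        if t == f"{term}^2" or (("*" in t) and term in t.split("*")):
            return True
    return False


def backward_eliminate(design: BBDesign, responses, alpha: float = 0.05,
                       term_mask: tuple[str, ...] | None = None,
                       response_name: str = "Y", uncoded: bool = True,
                       ) -> tuple[QuadraticModel, AnovaReport]:
    """Backward term elimination with a predicted-R^2 retention override.

    Starting from the full (or masked) model, repeatedly remove the
    highest-p term among those with p > alpha, UNLESS removing it would
    decrease the predicted R^2 (such non-significant terms are retained
    because they improve the model's predictive power); linear terms are
    protected while any surviving square/interaction contains them, and
    the intercept is never removed.
    """
    terms = tuple(term_mask) if term_mask is not None else full_quadratic_terms(design.factor_names)
    model, report = fit_quadratic(design, responses, terms, response_name, uncoded)
    while True:
        order = np.argsort(-report.term_p)  # highest p first
        removed = False
        for k in order:
            term = report.terms[k]
            if term == "1" or report.term_p[k] <= alpha:
                continue
            if _hierarchy_protected(term, report.terms):
                continue
            reduced = tuple(t for t in report.terms if t != term)
            red_model, red_report = fit_quadratic(design, responses, reduced,
                                                  response_name, uncoded)
            if red_report.pred_r_squared < report.pred_r_squared:
                continue  # retention beneficial for predictive power
            model, report = red_model, red_report
            removed = True
            break
        if not removed:
            return model, report


# ---------------------------------------------------------------------------
# Published prediction models
# ---------------------------------------------------------------------------

_FACTORS = ("Gel", "SA", "MC")

#: Final reduced model for the power-law index n over the composition cube.
PUBLISHED_N_MODEL = QuadraticModel(
    response_name="n",
    factor_names=_FACTORS,
    coefficients={
        "1": -0.256,
        "Gel": 0.1638, "SA": 0.1596, "MC": 0.1828,
        "Gel^2": -0.01107, "SA^2": -0.0259, "MC^2": -0.0213,
        "Gel*MC": -0.01348,
    },
)

#: Final model for the consistency coefficient; printed coefficients are in
#: mPa*s, hence the 1e-3 output scale to report K in Pa*s.
PUBLISHED_K_MODEL = QuadraticModel(
    response_name="K",
    factor_names=_FACTORS,
    coefficients={
        "1": 2014481.0,
        "Gel": -277312.0, "SA": -345128.0, "MC": -329307.0,
        "Gel^2": 10161.0, "SA^2": 18857.0, "MC^2": 19065.0,
        "Gel*SA": 22029.0, "Gel*MC": 21509.0, "SA*MC": 22724.0,
    },
    output_scale=1e-3,
)


def predict_n(ratio: CompositionRatio) -> float:
    """Power-law index predicted by the published composition model."""
    return PUBLISHED_N_MODEL.predict(ratio)


def predict_K(ratio: CompositionRatio) -> float:
    """Consistency coefficient (Pa*s) predicted by the published model."""
    return PUBLISHED_K_MODEL.predict(ratio)


def prediction_accuracy(predicted: float, measured: float) -> float:
    """Accuracy fraction 1 - |predicted - measured| / predicted.

    The normalisation by the predicted value is the convention that
    reproduces the published validation table's K-accuracy column cell by
    cell (normalising by the measured value does not); its n-accuracy
    column is not reproducible from the table's own rounded entries under
    either convention.
    """
    if measured <= 0:
        raise ValueError(f"measured response must be > 0, got {measured}")
    if predicted <= 0:
        raise ValueError(f"predicted response must be > 0, got {predicted}")
    return 1.0 - abs(predicted - measured) / predicted


def pareto_effects(report: AnovaReport) -> list[tuple[str, float]]:
    """Terms ranked by |standardized effect| descending; ties alphabetical."""
    eff = report.standardized_effects()
    return sorted(((t, abs(v)) for t, v in eff.items()),
                  key=lambda kv: (-kv[1], kv[0]))


def enumerate_feasible_region(grid_steps: int = 9,
                              n_model: QuadraticModel = PUBLISHED_N_MODEL,
                              k_model: QuadraticModel = PUBLISHED_K_MODEL,
                              ) -> pd.DataFrame:
    """Evaluate the (n, K) response pair on a regular composition grid.

    Enumerates ``grid_steps`` points per factor (endpoints included) over
    the design cube and returns a frame with the generating compositions
    and both predicted responses — the attainable-rheology scatter.
    """
    if grid_steps < 2:
        raise ValueError("need at least 2 grid steps per factor")
    axes = [np.linspace(lo, hi, grid_steps) for lo, _, hi in
            (DESIGN_CUBE["Gel"], DESIGN_CUBE["SA"], DESIGN_CUBE["MC"])]
    G, S, M = np.meshgrid(*axes, indexing="ij")
    X = np.column_stack([G.ravel(), S.ravel(), M.ravel()])
    return pd.DataFrame({
        "gel_wtpct": X[:, 0], "sa_wtpct": X[:, 1], "mc_wtpct": X[:, 2],
        "n": n_model.predict(X), "K_pa_s": k_model.predict(X),
    })


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = ["run", "gel_wtpct", "sa_wtpct", "mc_wtpct", "n", "K_pa_s"]


def write_design_csv(design: BBDesign, responses_n, responses_K, path) -> None:
    """Write a design/response table with one row per run."""
    X = design.to_uncoded()
    pd.DataFrame({
        "run": np.arange(1, design.n_runs + 1),
        "gel_wtpct": X[:, 0], "sa_wtpct": X[:, 1], "mc_wtpct": X[:, 2],
        "n": np.asarray(responses_n, dtype=float),
        "K_pa_s": np.asarray(responses_K, dtype=float),
    }).to_csv(path, index=False)


def read_design_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design CSV missing columns: {missing}")
    return df
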