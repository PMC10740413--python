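"""Synthetic data generators mirroring the pipeline's measurement protocols.

Every stage of the composition -> rheology -> flow -> printability pipeline
can be exercised without instrument data:

* :func:`synth_rheometry` emulates a rotational-rheometer flow sweep: 21
  shear-rate points spaced uniformly in log coordinates over 1-100 1/s,
  viscosities from the published composition models' (n, K) through the
  power law, with multiplicative log-normal noise (rheometer error scales
  with the reading).
* :func:`synth_bb_responses` emulates the 17-run Box-Behnken response
  table, drawing n and K per run from the published polynomials plus
  additive Gaussian noise; the generating truth is stored for recovery
  tests.
* :func:`synth_flow_dataset` emulates the simulation campaign: LHS (or
  uniform-random) points over the (n, K, P) box evaluated by the nozzle
  solver, default 300 training + 50 test points, with optional additive
  noise on Q.

Noise magnitudes default to sigma_log = 0.03 on log viscosity and
sigma_n = 0.005, sigma_K = 2 Pa*s on the responses — conventions chosen so
synthetic validation accuracies land in the high-90s%/low-80s% ranges the
real measurements show; they are assumptions, not measured error models.
All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nozzleflow import NozzleGeometry, default_geometry
from .rheology import PowerLawParams, ShearViscosityCurve, power_law_viscosity
from .rsm import BBDesign, CompositionRatio, predict_K, predict_n
from .surrogate import (SAMPLING_BOX, SampleSet, build_flow_dataset,
                        latin_hypercube)

__all__ = [
    "SynthConfig",
    "synth_rheometry",
    "synth_bb_responses",
    "synth_flow_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Noise model and grid settings for the generators.

    ``sigma_log_viscosity`` is the standard deviation of the log-normal
    multiplicative viscosity noise; ``sigma_n``/``sigma_K_pa_s`` the
    additive Gaussian response noise; the shear grid is endpoint-inclusive
    log-uniform.
    """

    seed: int = 0
    sigma_log_viscosity: float = 0.03
    sigma_n: float = 0.005
    sigma_K_pa_s: float = 2.0
    n_shear_points: int = 21
    shear_rate_range: tuple[float, float] = (1.0, 100.0)
    temperature_c: float = 30.0

    def __post_init__(self) -> None:
        for name, v in (("sigma_log_viscosity", self.sigma_log_viscosity),
                        ("sigma_n", self.sigma_n),
                        ("sigma_K_pa_s", self.sigma_K_pa_s)):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        lo, hi = self.shear_rate_range
        if not (0 < lo < hi):
            raise ValueError(f"bad shear-rate range ({lo}, {hi})")
        if self.n_shear_points < 2:
            raise ValueError("need at least 2 shear points")


def synth_rheometry(ratio: CompositionRatio,
                    config: SynthConfig | None = None) -> ShearViscosityCurve:
    """Synthesise a flow curve for an ink composition.

    Ground-truth (n, K) come from the published composition models;
    viscosities are the power law evaluated on the log-uniform shear grid,
    multiplied by exp(sigma_log * z) noise.  With sigma_log = 0 the curve
    is an exact fixed point of the power-law fit.
    """
    config = config or SynthConfig()
    truth = PowerLawParams(n=predict_n(ratio), K=predict_K(ratio))
    lo, hi = config.shear_rate_range
    rates = np.geomspace(lo, hi, config.n_shear_points)
    visc = power_law_viscosity(truth, rates)
    if config.sigma_log_viscosity > 0:
        rng = np.random.default_rng(config.seed)
        visc = visc * np.exp(config.sigma_log_viscosity
                             * rng.standard_normal(rates.size))
    return ShearViscosityCurve(rates, visc, temperature_c=config.temperature_c)


def synth_bb_responses(design: BBDesign, sigma_n: float = 0.005,
                       sigma_K_pa_s: float = 2.0, seed: int = 0) -> pd.DataFrame:
    """Synthesise Box-Behnken responses from the published models.

    Returns one row per run with the composition, noisy responses
    ``n``/``K_pa_s`` and the noise-free truth ``n_true``/``K_true_pa_s``.
    Centre replicates differ only by their noise draws (identical at
    sigma = 0).
    """
    X = design.to_uncoded()
    n_true = np.array([predict_n(CompositionRatio(*row)) for row in X])
    k_true = np.array([predict_K(CompositionRatio(*row)) for row in X])
    rng = np.random.default_rng(seed)
    n_obs = n_true + sigma_n * rng.standard_normal(design.n_runs)
    k_obs = k_true + sigma_K_pa_s * rng.standard_normal(design.n_runs)
    return pd.DataFrame({
        "run": np.arange(1, design.n_runs + 1),
        "gel_wtpct": X[:, 0], "sa_wtpct": X[:, 1], "mc_wtpct": X[:, 2],
        "n": n_obs, "K_pa_s": k_obs,
        "n_true": n_true, "K_true_pa_s": k_true,
    })


def synth_flow_dataset(n_train: int = 300, n_test: int = 50,
                       bounds: dict[str, tuple[float, float]] | None = None,
                       geometry: NozzleGeometry | None = None,
                       sigma_q_ul_s: float = 0.0, seed: int = 0,
                       mode: str = "lhs") -> tuple[SampleSet, SampleSet]:
    """Synthesise the flow-simulation campaign: train + test sample sets.

    Training points are LHS-stratified (``mode='lhs'``) or uniform random
    (``mode='uniform'``); test points are always uniform random, mirroring
    a validation protocol of fresh random draws.  Q comes from the solver,
    with optional additive Gaussian noise of scale ``sigma_q_ul_s``.
    """
    bounds = dict(bounds or SAMPLING_BOX)
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    train_seed = int(rng.integers(2 ** 31))
    test_seed = int(rng.integers(2 ** 31))

    if mode == "lhs":
        train = latin_hypercube(bounds, n_train, seed=train_seed)
    elif mode == "uniform":
        train = _uniform_samples(bounds, n_train, train_seed)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    test = _uniform_samples(bounds, n_test, test_seed)

    train = build_flow_dataset(train, geometry)
    test = build_flow_dataset(test, geometry)
    if sigma_q_ul_s > 0:
        noise_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        for ds in (train, test):
            ds.points["Q_ul_s"] += sigma_q_ul_s * noise_rng.standard_normal(len(ds))
    return train, test


def _uniform_samples(bounds: dict[str, tuple[float, float]], n: int,
                     seed: int) -> SampleSet:
    rng = np.random.default_rng(seed)
    cols = {}
    for k in ("n", "K_pa_s", "P_kpa"):
        lo, hi = bounds[k]
        cols[k] = rng.uniform(lo, hi, n)
    return SampleSet(points=pd.DataFrame(cols), bounds=dict(bounds), seed=seed)
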