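"""Synthetic pseudo-experimental datasets for calibration and recovery.

The model's calibration targets are behaviours (decay half-lives,
normalized phospho time courses, dose-response levels), not deposited raw
data, so this module manufactures datasets with the statistical structure
the fitting layer assumes: a noise-free model curve times multiplicative
lognormal noise.  Lognormal noise is the natural choice because every
observable is a positive concentration or fraction; the coefficient of
variation defaults to 0.05.

For normalized observables the noise is applied *after* normalization by
default, so the t=0 anchor stays exactly 1; the switch is recorded in the
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .experiments import run_dose_scan, run_licl, run_pulse_chase
from .model import CellModel, make_cell_model
from .params import RateParameters, default_parameters


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise with a given coefficient of variation."""

    cv: float = 0.05
    seed: int = 0
    kind: str = "multiplicative-lognormal"

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def sample(self, curve: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Noisy observations with E[log obs] = log(curve)."""
        curve = np.asarray(curve, float)
        if self.cv == 0.0:
            return curve.copy()
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return curve * rng.lognormal(mean=0.0, sigma=sigma, size=curve.shape)


@dataclass
class SyntheticDataset:
    kind: str                       # decay | licl | dose_response
    design: np.ndarray              # time points (s) or relative doses
    observations: dict[str, np.ndarray]
    truth: dict                     # true parameters and protocol record
    noise: NoiseModel
    noise_after_normalization: bool = True

    def __post_init__(self):
        for name, obs in self.observations.items():
            if np.any(np.asarray(obs) < 0):
                raise ValueError(f"negative observation in {name}")


def _truth_record(params: RateParameters) -> dict:
    return {name: getattr(params, name) for name in params.numeric_fields()}


def gen_decay(params: RateParameters | None = None, *, protocol: str = "shutoff",
              s33_37_mutant: bool = False, n_points: int = 12,
              noise: NoiseModel | None = None, seed: int = 0,
              t_end: float | None = None) -> SyntheticDataset:
    """Pulse-chase decay of total beta-catenin, noised.

    The design spans four half-lives by default (``t_end`` overrides).
    """
    if n_points < 3:
        raise ValueError("need at least 3 time points")
    params = params or default_parameters()
    noise = noise or NoiseModel(seed=seed)
    cell = make_cell_model("normal", s33_37_mutant=s33_37_mutant, params=params)
    res = run_pulse_chase(cell, protocol)
    if t_end is None:
        t_end = res.t[-1]
    t = np.linspace(0.0, t_end, n_points)
    clean = np.interp(t, res.t, res.level)
    rng = np.random.default_rng(seed)
    obs = noise.sample(clean, rng)
    return SyntheticDataset(
        kind="decay", design=t, observations={"level": obs},
        truth={**_truth_record(params), "protocol": protocol,
               "s33_37_mutant": s33_37_mutant,
               "half_life_min": res.half_life_min, "clean": clean},
        noise=noise)


def gen_licl(params: RateParameters | None = None, *, fold: float = 20.0,
             n_points: int = 13, noise: NoiseModel | None = None, seed: int = 0,
             t_end: float = 7200.0,
             noise_after_normalization: bool = True) -> SyntheticDataset:
    """Normalized pS45 / pS33-37 time courses under kinase inhibition."""
    if n_points < 3:
        raise ValueError("need at least 3 time points")
    params = params or default_parameters()
    noise = noise or NoiseModel(seed=seed)
    cell = make_cell_model("normal", params=params)
    res = run_licl(cell, fold=fold, t_end=t_end, n_points=n_points)
    rng = np.random.default_rng(seed)
    observations = {}
    for name in ("pS45_rel", "pS33_37_rel"):
        clean = res[name]
        noisy = noise.sample(clean, rng)
        if noise_after_normalization:
            noisy[0] = clean[0]   # the t=0 anchor is exact by construction
        observations[name] = noisy
    return SyntheticDataset(
        kind="licl", design=res["t"], observations=observations,
        truth={**_truth_record(params), "fold": fold,
               "clean": {n: res[n] for n in ("pS45_rel", "pS33_37_rel")}},
        noise=noise, noise_after_normalization=noise_after_normalization)


def gen_dose_response(params: RateParameters | None = None, *,
                      background: str = "SW480", construct: str = "B",
                      doses=None, noise: NoiseModel | None = None,
                      seed: int = 0) -> SyntheticDataset:
    """Steady-state BCAT_relative per transfection dose, noised."""
    params = params or default_parameters()
    noise = noise or NoiseModel(seed=seed)
    curve = run_dose_scan(background, construct, doses, params)
    rng = np.random.default_rng(seed)
    obs = noise.sample(curve.values, rng)
    return SyntheticDataset(
        kind="dose_response", design=curve.doses,
        observations={"BCAT_relative": obs},
        truth={**_truth_record(params), "background": background,
               "construct": construct, "clean": curve.values},
        noise=noise)
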