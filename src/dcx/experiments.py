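"""The virtual experiments: transfection scans, pulse-chase, kinase
inhibition, interface ablation, phosphorylation-competition scans and local
sensitivity analysis.

Conventions
-----------
* Transfection dose scans (APC constructs added to a cell) express dose as
  exogenous protein relative to the endogenous 100 nM of the background's
  APC form; the transfected amount is added on top of the endogenous pool.
* The Axin-association scans express the x-axis as the *total* amount of
  the background's APC form relative to its nominal 100 nM (grid spans
  scarcity through excess, which is where the scaffold bell lives).
* "Relative beta-catenin level" always means total beta-catenin divided by
  the 35 nM nominal level of a normal cell.

All experiments are pure functions of (scenario, parameters): identical
inputs reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .assemble import assemble
from .model import CellModel, make_cell_model
from .network import ReactionNetwork
from .params import RateParameters, default_parameters
from .sim import (
    MassActionSystem,
    SimulationError,
    SteadyStateResult,
    build_derivative,
    find_steady_state,
    half_life,
    simulate,
)

# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseCurve:
    doses: np.ndarray                  # relative units (x nominal 100 nM)
    values: np.ndarray
    observable: str
    background: str
    construct: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.doses, float)
        if np.any(d < 0) or np.any(np.diff(d) < 0):
            raise ValueError("doses must be non-negative and sorted")


@dataclass
class HalfLifeResult:
    half_life_min: float
    protocol: str                      # shutoff | cohort
    t: np.ndarray                      # seconds
    level: np.ndarray                  # tracked pool, normalized to t=0

    def __post_init__(self):
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")


@dataclass
class AblationResult:
    interface: str
    relative_level: float              # vs the unperturbed normal cell


@dataclass
class SensitivityTable:
    rows: list[tuple[str, float]]      # (parameter, normalized coefficient)

    def as_dict(self) -> dict[str, float]:
        return dict(self.rows)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _weights(net: ReactionNetwork, kind: str) -> np.ndarray:
    if kind == "BCAT":
        return np.array([g.composition().get("BCAT", 0) for g in net.species], float)
    if kind == "pS45":
        return np.array(
            [sum(1 for n, st in g.molecules if n == "BCAT" and st["S45"] == "p")
             for g in net.species], float)
    if kind == "pS33_37":
        return np.array(
            [sum(1 for n, st in g.molecules if n == "BCAT" and st["S33_37"] == "p")
             for g in net.species], float)
    if kind == "AXIN":
        return np.array([g.composition().get("AXIN", 0) for g in net.species], float)
    raise KeyError(kind)


@lru_cache(maxsize=512)
def steady_state(cell: CellModel) -> tuple[ReactionNetwork, SteadyStateResult]:
    """Expand (cached) and relax the scenario to its steady state.

    Scenarios are frozen dataclasses, so identical scenarios share one
    steady-state solve; callers must treat the returned state as
    read-only.
    """
    net, y0 = assemble(cell)
    system = build_derivative(net, cell.effective_params(),
                              gsk_fold=cell.gsk_inhibition_fold)
    return net, find_steady_state(system, y0)


def total_bcat(cell: CellModel) -> float:
    net, ss = steady_state(cell)
    return float(_weights(net, "BCAT") @ ss.state)


# ---------------------------------------------------------------------------
# transfection experiments (Figs 4-6)
# ---------------------------------------------------------------------------


def run_transfection_panel(background: str = "SW480", classes: str = "ABCDEF",
                           dose: float = 100.0,
                           params: RateParameters | None = None) -> dict[str, float]:
    """Relative steady-state beta-catenin after transfecting each class.

    Returns BCAT_relative (vs the 35 nM normal-cell nominal) per class at
    the given dose (nM) on top of the endogenous background.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    params = params or default_parameters()
    out = {}
    for cls in classes:
        cell = make_cell_model(background, [(cls, dose)], params=params)
        out[cls] = total_bcat(cell) / params.BCAT_tot
    return out


def run_dose_scan(background: str, construct: str, doses=None,
                  params: RateParameters | None = None) -> DoseResponseCurve:
    """BCAT_relative vs exogenous dose of one construct (Figs 5-6).

    ``doses`` are relative to the endogenous 100 nM (default log grid over
    [0.01, 10]); dose 0 is prepended as an untransfected reference.
    """
    params = params or default_parameters()
    if doses is None:
        doses = np.logspace(-2, 1, 7)
    doses = np.asarray(doses, float)
    values = []
    for x in doses:
        cell = make_cell_model(background, [(construct, 100.0 * x)], params=params)
        values.append(total_bcat(cell) / params.BCAT_tot)
    return DoseResponseCurve(doses=doses, values=np.array(values),
                             observable="BCAT_relative", background=background,
                             construct=construct)


# ---------------------------------------------------------------------------
# pulse-chase half-lives (Fig S1)
# ---------------------------------------------------------------------------


class _FrozenLinearSystem:
    """Linear dynamics of the beta-catenin-containing species with every
    beta-catenin-free species frozen at its steady-state concentration.

    Because at most one beta-catenin occupies any complex, every reaction
    touching the tracked pool is linear in it, so the labelled ("cohort")
    pool decays under z' = A z exactly while the unlabelled background
    maintains the steady state around it.
    """

    def __init__(self, net: ReactionNetwork, rates: np.ndarray,
                 ss_state: np.ndarray) -> None:
        has_b = np.array([g.composition().get("BCAT", 0) > 0 for g in net.species])
        self.sub = np.flatnonzero(has_b)
        pos = {int(i): k for k, i in enumerate(self.sub)}
        n = len(self.sub)
        A = np.zeros((n, n))
        for rxn, k in zip(net.reactions, rates):
            bc_r = [i for i in rxn.reactants if has_b[i]]
            if not bc_r:
                continue  # synthesis or background-only reaction: unlabelled
            if len(bc_r) > 1:
                raise SimulationError("cohort protocol requires <=1 tracked reactant")
            i = bc_r[0]
            k_eff = float(k)
            for j in rxn.reactants:
                if j != i:
                    k_eff *= ss_state[j]   # background partner at steady state
            A[pos[i], pos[i]] -= k_eff
            for jp in rxn.products:
                if has_b[jp]:
                    A[pos[jp], pos[i]] += k_eff
        self.A = A
        self.n_species = n

    def __call__(self, t, z):
        return self.A @ z

    def jac(self, t, z):
        return self.A

    jac_sparse = jac

    @property
    def solver_kwargs(self):
        return {"method": "LSODA", "jac": self.jac}


def run_pulse_chase(cell: CellModel, protocol: str = "shutoff",
                    n_points: int = 60) -> HalfLifeResult:
    """Decay of the pre-existing beta-catenin pool from steady state.

    ``shutoff``: synthesis is stopped at t=0 and total beta-catenin is
    tracked (the default protocol).  ``cohort``: a labelled pool starting
    from the steady-state distribution decays against a background held at
    steady state (synthesis replaces only unlabelled protein).
    """
    net, ss = steady_state(cell)
    params = cell.effective_params()
    wB = _weights(net, "BCAT")
    if protocol == "shutoff":
        system = build_derivative(net, params, gsk_fold=cell.gsk_inhibition_fold,
                                  rate_overrides={"syn_bcat": 0.0})
        y0 = ss.state
        weights = wB
    elif protocol == "cohort":
        rates = net.rate_vector(params, gsk_fold=cell.gsk_inhibition_fold)
        system = _FrozenLinearSystem(net, rates, ss.state)
        y0 = ss.state[system.sub]
        weights = wB[system.sub]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    t_half = half_life(system, y0, weights)
    t_grid = np.linspace(0.0, 4.0 * t_half, n_points)
    tc = simulate(system, y0, t_grid)
    level = (tc.y @ weights) / float(weights @ y0)
    return HalfLifeResult(half_life_min=t_half / 60.0, protocol=protocol,
                          t=tc.t, level=level)


def run_phospho_shutoff(cell: CellModel) -> HalfLifeResult:
    """Decay of the phospho-S45 pool when both beta-catenin phosphorylation
    rate constants are set to zero at steady state (dephosphorylation
    anchor; the target half-life is the ~10 min phospho turnover)."""
    net, ss = steady_state(cell)
    system = build_derivative(
        net, cell.effective_params(), gsk_fold=cell.gsk_inhibition_fold,
        rate_overrides={"phos_S45": 0.0, "phos_S33_37": 0.0})
    w45 = _weights(net, "pS45")
    t_half = half_life(system, ss.state, w45)
    t_grid = np.linspace(0.0, 4.0 * t_half, 40)
    tc = simulate(system, ss.state, t_grid)
    level = (tc.y @ w45) / float(w45 @ ss.state)
    return HalfLifeResult(half_life_min=t_half / 60.0, protocol="shutoff",
                          t=tc.t, level=level)


# ---------------------------------------------------------------------------
# LiCl kinase inhibition (Fig S2)
# ---------------------------------------------------------------------------


def run_licl(cell: CellModel, fold: float = 20.0, t_end: float = 7200.0,
             n_points: int = 49) -> dict[str, np.ndarray]:
    """Divide the GSK-3beta-mediated phosphorylation rates by ``fold`` at
    t=0 (starting from the untreated steady state) and report pS45 and
    pS33/37 relative to their untreated steady-state levels."""
    if fold < 1:
        raise ValueError("inhibition fold must be >= 1")
    net, ss = steady_state(cell)
    params = cell.effective_params()
    system = build_derivative(net, params, gsk_fold=fold)
    t_grid = np.linspace(0.0, t_end, n_points)
    tc = simulate(system, ss.state, t_grid)
    w45 = _weights(net, "pS45")
    w33 = _weights(net, "pS33_37")
    return {
        "t": tc.t,
        "pS45_rel": (tc.y @ w45) / float(w45 @ ss.state),
        "pS33_37_rel": (tc.y @ w33) / float(w33 @ ss.state),
    }


# ---------------------------------------------------------------------------
# cyclic-complex interface ablation (Fig 9)
# ---------------------------------------------------------------------------

INTERFACES = ("bcat_apc_15aa", "bcat_axin", "apc_axin")


def run_interface_ablation(params: RateParameters | None = None) -> list[AblationResult]:
    """Set each protein-protein interface's association rate to zero in the
    normal-cell model and report steady-state beta-catenin relative to the
    unperturbed normal cell."""
    params = params or default_parameters()
    reference = total_bcat(make_cell_model("normal", params=params))
    out = []
    for iface in INTERFACES:
        cell = make_cell_model("normal", ablations=[iface], params=params)
        out.append(AblationResult(iface, total_bcat(cell) / reference))
    return out


# ---------------------------------------------------------------------------
# APC phosphorylation competition (Fig 7)
# ---------------------------------------------------------------------------


def run_apc_phospho_scan(ratios=(0.0, 0.2, 1.0, 5.0), doses=None,
                         params: RateParameters | None = None) -> dict:
    """SW480 background: vary the APC phosphorylation/dephosphorylation
    ratio (1 = the default equal rates; 0 = never phosphorylated) and
    report BCAT_relative and the fraction of Axin in complex with
    beta-catenin per (ratio, dose)."""
    params = params or default_parameters()
    if doses is None:
        doses = np.array([0.0, 1.0, 3.0])
    doses = np.asarray(doses, float)
    result = {"ratios": np.asarray(ratios, float), "doses": doses,
              "BCAT_relative": {}, "frac_axin_with_bcat": {}}
    for ratio in ratios:
        if ratio < 0:
            raise ValueError("ratio must be >= 0")
        p = params.replace(kp_apc=params.kdp_apc * ratio)
        brel, fax = [], []
        for x in doses:
            cell = make_cell_model("SW480", [("B", 100.0 * x)], params=p)
            net, ss = steady_state(cell)
            wB = _weights(net, "BCAT")
            wA = _weights(net, "AXIN")
            with_b = np.array(
                [g.composition().get("AXIN", 0)
                 * (g.composition().get("BCAT", 0) > 0) for g in net.species], float)
            brel.append(float(wB @ ss.state) / params.BCAT_tot)
            fax.append(float(with_b @ ss.state) / float(wA @ ss.state))
        result["BCAT_relative"][ratio] = np.array(brel)
        result["frac_axin_with_bcat"][ratio] = np.array(fax)
    return result


# ---------------------------------------------------------------------------
# sequestration scans (Fig 8)
# ---------------------------------------------------------------------------


def run_axin_association_scan(background: str, doses=None,
                              params: RateParameters | None = None
                              ) -> dict[str, DoseResponseCurve]:
    """Fraction of beta-catenin associated (directly or indirectly) with
    Axin, and fraction directly bound to the background's APC form, as the
    *total* amount of that form spans ``doses`` x 100 nM."""
    params = params or default_parameters()
    if doses is None:
        doses = np.logspace(-2, 1, 7)
    doses = np.asarray(doses, float)
    apc_name = "APC" if background == "normal" else "APC1338"
    frac_ax, frac_apc = [], []
    for x in doses:
        cell = make_cell_model(background, params=params.replace(APC_tot=100.0 * x))
        net, ss = steady_state(cell)
        wB = _weights(net, "BCAT")
        tot = float(wB @ ss.state)
        with_ax = np.array(
            [(g.composition().get("BCAT", 0) > 0)
             and (g.composition().get("AXIN", 0) > 0) for g in net.species], float)
        direct = np.zeros(net.n_species())
        for i, g in enumerate(net.species):
            for (a, _sa), (b, _sb) in g.bonds:
                if {g.molecules[a][0], g.molecules[b][0]} == {"BCAT", apc_name}:
                    direct[i] = 1.0
        frac_ax.append(float((with_ax * wB) @ ss.state) / tot)
        frac_apc.append(float((direct * wB) @ ss.state) / tot)
    return {
        "frac_bcat_with_axin": DoseResponseCurve(
            doses, np.array(frac_ax), "frac_bcat_with_axin", background, apc_name),
        "bcat_direct_apc": DoseResponseCurve(
            doses, np.array(frac_apc), "bcat_direct_apc", background, apc_name),
    }


# ---------------------------------------------------------------------------
# local sensitivity analysis (Table S1)
# ---------------------------------------------------------------------------


def local_sensitivity(cell: CellModel | None = None,
                      parameters: list[str] | None = None,
                      delta: float = 0.05) -> SensitivityTable:
    """Normalized local sensitivity coefficients S = (p/Y)(dY/dp) of
    steady-state total beta-catenin, by central finite differences."""
    if not (0 < delta < 1):
        raise ValueError("delta must be in (0, 1)")
    cell = cell or make_cell_model("normal")
    params = cell.params
    if parameters is None:
        parameters = [n for n in params.numeric_fields() if n != "volume"]
    y0 = total_bcat(cell)
    rows = []
    for name in parameters:
        p = getattr(params, name)
        if p == 0.0:
            rows.append((name, 0.0))
            continue
        hi = total_bcat(cell_with(cell, params.replace(**{name: p * (1 + delta)})))
        lo = total_bcat(cell_with(cell, params.replace(**{name: p * (1 - delta)})))
        rows.append((name, (hi - lo) / (2.0 * delta * y0)))
    return SensitivityTable(rows)


def cell_with(cell: CellModel, params: RateParameters) -> CellModel:
    from dataclasses import replace
    return replace(cell, params=params)
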