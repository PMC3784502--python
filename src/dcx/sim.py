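"""Deterministic mass-action dynamics on an expanded reaction network.

The network's reactions are compiled once into index arrays; the derivative
is ``dy/dt = S @ v(y)`` with a sparse stoichiometry matrix ``S`` and flux
vector ``v`` (``k [A]`` unimolecular, ``k [A][B]`` bimolecular, constant for
synthesis).  Integration uses LSODA/BDF with an analytic sparse Jacobian;
steady states are found by long-horizon integration with doubling horizons
until a residual criterion holds, which avoids root-finding onto
unphysical branches.

Observables are pattern-based weighted sums over species, so the same
observable definition applies across regenerated networks for different
model variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .graphs import ANY, Pattern, SpeciesGraph, match, mol_pat
from .network import ReactionNetwork
from .params import RateParameters


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# compiled dynamics
# ---------------------------------------------------------------------------


class MassActionSystem:
    """Compiled mass-action right-hand side for one network + rate vector."""

    def __init__(self, net: ReactionNetwork, rates: np.ndarray) -> None:
        n_sp = net.n_species()
        n_rx = len(net.reactions)
        self.n_species = n_sp
        self.rates = np.asarray(rates, dtype=float)

        uni_idx, uni_r = [], []
        bi_idx, bi_r1, bi_r2 = [], [], []
        zero_idx = []
        rows, cols, vals = [], [], []
        for k, rxn in enumerate(net.reactions):
            delta: dict[int, int] = {}
            for i in rxn.reactants:
                delta[i] = delta.get(i, 0) - 1
            for i in rxn.products:
                delta[i] = delta.get(i, 0) + 1
            for i, d in delta.items():
                if d != 0:
                    rows.append(i)
                    cols.append(k)
                    vals.append(float(d))
            if len(rxn.reactants) == 0:
                zero_idx.append(k)
            elif len(rxn.reactants) == 1:
                uni_idx.append(k)
                uni_r.append(rxn.reactants[0])
            else:
                bi_idx.append(k)
                bi_r1.append(rxn.reactants[0])
                bi_r2.append(rxn.reactants[1])
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_sp, n_rx)
        )
        self.zero_idx = np.array(zero_idx, dtype=int)
        self.uni_idx = np.array(uni_idx, dtype=int)
        self.uni_r = np.array(uni_r, dtype=int)
        self.bi_idx = np.array(bi_idx, dtype=int)
        self.bi_r1 = np.array(bi_r1, dtype=int)
        self.bi_r2 = np.array(bi_r2, dtype=int)
        self._n_rx = n_rx
        # Jacobian structure: dv/dy entries
        jrows = np.concatenate([self.uni_idx, self.bi_idx, self.bi_idx])
        jcols = np.concatenate([self.uni_r, self.bi_r1, self.bi_r2])
        self._jrows = jrows
        self._jcols = jcols

    def flux(self, y: np.ndarray) -> np.ndarray:
        v = np.zeros(self._n_rx)
        if self.zero_idx.size:
            v[self.zero_idx] = self.rates[self.zero_idx]
        if self.uni_idx.size:
            v[self.uni_idx] = self.rates[self.uni_idx] * y[self.uni_r]
        if self.bi_idx.size:
            v[self.bi_idx] = self.rates[self.bi_idx] * y[self.bi_r1] * y[self.bi_r2]
        return v

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.S @ self.flux(y)

    def jac_sparse(self, t: float, y: np.ndarray):
        data = np.concatenate([
            self.rates[self.uni_idx],
            self.rates[self.bi_idx] * y[self.bi_r2],
            self.rates[self.bi_idx] * y[self.bi_r1],
        ])
        D = sparse.csr_matrix(
            (data, (self._jrows, self._jcols)), shape=(self._n_rx, self.n_species)
        )
        return self.S @ D

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.jac_sparse(t, y).toarray()

    @property
    def solver_kwargs(self) -> dict:
        """Stiff-solver choice: LSODA with a dense Jacobian for small
        systems, BDF with the sparse Jacobian for large ones."""
        if self.n_species <= 900:
            return {"method": "LSODA", "jac": self.jac}
        return {"method": "BDF", "jac": self.jac_sparse}


def build_derivative(net: ReactionNetwork, params: RateParameters, *,
                     gsk_fold: float = 1.0,
                     rate_overrides: dict[str, float] | None = None) -> MassActionSystem:
    """Compile the network's mass-action derivative for one parameter set.

    ``rate_overrides`` zeroes or rescales the rates of named rules post hoc
    (used by the pulse-chase and phospho-shutoff protocols).
    """
    rates = net.rate_vector(params, gsk_fold=gsk_fold)
    if rate_overrides:
        for k, rxn in enumerate(net.reactions):
            if rxn.rule_name in rate_overrides:
                rates[k] = rates[k] * rate_overrides[rxn.rule_name]
    return MassActionSystem(net, rates)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


@dataclass
class ObservableDef:
    """Weighted pattern-count observable, optionally a fraction.

    value = sum_s conc_s * sum_(pat, w) w * n_matches(pat, s), divided by
    the same sum for ``denominator`` patterns (or by ``denom_const``) when
    given.  A custom per-species weight callable may replace the numerator
    patterns for counts that are not plain embedding counts.
    """

    name: str
    numerator: list[tuple[Pattern, float]] = field(default_factory=list)
    denominator: list[tuple[Pattern, float]] | None = None
    denom_const: float | None = None
    weight_fn: Callable[[SpeciesGraph], float] | None = None

    def species_weights(self, species: Sequence[SpeciesGraph]) -> np.ndarray:
        w = np.zeros(len(species))
        for i, g in enumerate(species):
            if self.weight_fn is not None:
                w[i] = self.weight_fn(g)
            else:
                w[i] = sum(wt * len(match(pat, g)) for pat, wt in self.numerator)
        return w

    def denom_weights(self, species: Sequence[SpeciesGraph]) -> np.ndarray | None:
        if self.denominator is None:
            return None
        w = np.zeros(len(species))
        for i, g in enumerate(species):
            w[i] = sum(wt * len(match(pat, g)) for pat, wt in self.denominator)
        return w


def evaluate_observable(obs: ObservableDef, state: np.ndarray,
                        net: ReactionNetwork) -> float:
    num = float(obs.species_weights(net.species) @ state)
    dw = obs.denom_weights(net.species)
    if dw is not None:
        den = float(dw @ state)
        if den <= 0.0:
            raise ZeroDivisionError(f"observable {obs.name}: zero denominator")
        return num / den
    if obs.denom_const is not None:
        return num / obs.denom_const
    return num


def _contains(g: SpeciesGraph, type_name: str) -> bool:
    return g.composition().get(type_name, 0) > 0


def builtin_observables(params: RateParameters,
                        apc_type_names: Sequence[str] = ()) -> dict[str, ObservableDef]:
    """The observables reported in the virtual experiments.

    * ``BCAT_total`` -- total beta-catenin (nM) over all species.
    * ``BCAT_relative`` -- the same divided by the nominal 35 nM.
    * ``pS45_total`` / ``pS33_37_total`` -- phospho-site totals (nM).
    * ``frac_axin_with_bcat`` -- fraction of Axin in a complex containing
      beta-catenin.
    * ``frac_bcat_with_axin`` -- fraction of beta-catenin associated,
      directly or indirectly, with Axin.
    * ``bcat_direct_apc[T]`` -- fraction of beta-catenin directly bound
      (either interface) to APC-like type T.
    """
    bcat = Pattern((mol_pat("BCAT"),))
    axin = Pattern((mol_pat("AXIN"),))
    obs = {
        "BCAT_total": ObservableDef("BCAT_total", [(bcat, 1.0)]),
        "BCAT_relative": ObservableDef("BCAT_relative", [(bcat, 1.0)],
                                       denom_const=params.BCAT_tot),
        "pS45_total": ObservableDef(
            "pS45_total", [(Pattern((mol_pat("BCAT", S45=("p",)),)), 1.0)]),
        "pS33_37_total": ObservableDef(
            "pS33_37_total", [(Pattern((mol_pat("BCAT", S33_37=("p",)),)), 1.0)]),
        # BCAT is capped at one copy per complex, so embedding counts of the
        # two-component pattern equal the Axin copy number of the complex
        "frac_axin_with_bcat": ObservableDef(
            "frac_axin_with_bcat",
            [(Pattern((mol_pat("AXIN"), mol_pat("BCAT"))), 1.0)],
            denominator=[(axin, 1.0)]),
        "frac_bcat_with_axin": ObservableDef(
            "frac_bcat_with_axin",
            [],
            denominator=[(bcat, 1.0)],
            weight_fn=lambda g: float(_contains(g, "BCAT") and _contains(g, "AXIN"))),
    }
    for t in apc_type_names:
        def direct_weight(g: SpeciesGraph, t=t) -> float:
            n = 0
            for (i, _si), (j, _sj) in g.bonds:
                ti = g.molecules[i][0]
                tj = g.molecules[j][0]
                if {ti, tj} == {"BCAT", t}:
                    n = 1  # one BCAT per complex: bound directly or not
            return float(n)
        obs[f"bcat_direct_apc[{t}]"] = ObservableDef(
            f"bcat_direct_apc[{t}]", [], denominator=[(bcat, 1.0)],
            weight_fn=direct_weight)
    return obs


# ---------------------------------------------------------------------------
# time courses and steady states
# ---------------------------------------------------------------------------


@dataclass
class TimeCourse:
    t: np.ndarray                       # seconds, monotone
    y: np.ndarray                       # (n_times, n_species) nM
    observables: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SteadyStateResult:
    state: np.ndarray
    residual: float                     # max |dy/dt| / max(y, floor), /s
    horizon: float                      # integration time reached, s
    iterations: int


def initial_state(net: ReactionNetwork, seeds: list[tuple[SpeciesGraph, float]]) -> np.ndarray:
    y0 = np.zeros(net.n_species())
    canon_to_idx = {g.canonical(): i for i, g in enumerate(net.species)}
    for g, conc in seeds:
        y0[canon_to_idx[g.canonical()]] += conc
    return y0


def simulate(system: MassActionSystem, y0: np.ndarray, t_grid: np.ndarray, *,
             net: ReactionNetwork | None = None,
             observables: dict[str, ObservableDef] | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             events=None) -> TimeCourse:
    """Integrate and evaluate observables on the grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.asarray(y0) < 0):
        raise ValueError("initial state must be non-negative")
    sol = solve_ivp(
        system, (t_grid[0], t_grid[-1]), np.asarray(y0, dtype=float),
        t_eval=t_grid, rtol=rtol, atol=atol, events=events,
        **system.solver_kwargs,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")
    tc = TimeCourse(t=sol.t, y=sol.y.T)
    if observables and net is not None:
        for name, obs in observables.items():
            w = obs.species_weights(net.species)
            dw = obs.denom_weights(net.species)
            vals = tc.y @ w
            if dw is not None:
                vals = vals / (tc.y @ dw)
            elif obs.denom_const is not None:
                vals = vals / obs.denom_const
            tc.observables[name] = vals
    return tc


def find_steady_state(system: MassActionSystem, y0: np.ndarray, *,
                      tol: float = 1e-10, t_start: float = 1e5,
                      t_max: float = 1e10, rtol: float = 1e-8,
                      atol: float = 1e-10) -> SteadyStateResult:
    """Integrate with doubling horizons until max |dy_i/dt| / max(y_i, 1e-6 nM)
    falls below ``tol`` (per second).

    BDF with the analytic sparse Jacobian is used for every leg: restarting
    an integration from (solver-tolerance distance of) the fixed point is
    exactly the regime where LSODA's stiffness switching can stall on tiny
    steps, while BDF remains well behaved.  Solver-tolerance negative
    concentrations are clipped only in the returned state, not between
    legs, to keep the trajectory smooth for the restarted solver.
    """
    y = np.asarray(y0, dtype=float)
    horizon = t_start
    iterations = 0
    while True:
        sol = solve_ivp(system, (0.0, horizon), y, method="BDF",
                        jac=system.jac_sparse, rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"steady-state integration failed: {sol.message}")
        y = sol.y[:, -1]
        iterations += 1
        yc = np.maximum(y, 0.0)
        resid = float(np.max(np.abs(system(0.0, yc)) / np.maximum(yc, 1e-6)))
        if resid < tol:
            return SteadyStateResult(state=yc, residual=resid,
                                     horizon=horizon, iterations=iterations)
        if horizon >= t_max:
            raise SimulationError(
                f"no steady state below residual {tol:g} by t={t_max:g}s "
                f"(residual {resid:g})")
        horizon *= 2.0


def half_life(system: MassActionSystem, y0: np.ndarray,
              weights: np.ndarray, *, t_max: float = 3e6) -> float:
    """Time (s) at which ``weights @ y`` falls to half its initial value."""
    target = 0.5 * float(weights @ y0)
    if target <= 0:
        raise ValueError("tracked pool is empty at t=0")

    def crossing(t, y):
        return float(weights @ y) - target

    crossing.terminal = True
    crossing.direction = -1
    sol = solve_ivp(system, (0.0, t_max), np.asarray(y0, dtype=float),
                    rtol=1e-9, atol=1e-11, events=crossing,
                    **system.solver_kwargs)
    if not sol.success:
        raise SimulationError(f"half-life integration failed: {sol.message}")
    if not sol.t_events[0].size:
        raise SimulationError(f"pool did not reach half its start by t={t_max:g}s")
    return float(sol.t_events[0][0])
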