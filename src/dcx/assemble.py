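"""Scenario -> expanded network -> initial state.

Network structure depends only on which molecule types, rules and caps a
scenario uses -- not on doses or rate values -- so expansions are cached on
a structural key and shared across dose scans and calibration moves.
"""

from __future__ import annotations

import numpy as np

from .model import CellModel, build_rule_set, seed_species
from .network import ReactionNetwork, expand
from .sim import initial_state

_CACHE: dict[tuple, ReactionNetwork] = {}


def structural_key(cell: CellModel) -> tuple:
    labels = tuple(sorted({l for l, _ in cell.transfections}))
    caps = tuple(sorted(cell.caps().items()))
    return (cell.background, labels, cell.s33_37_mutant, cell.apc_e_mode, caps)


def assemble(cell: CellModel, *, use_cache: bool = True) -> tuple[ReactionNetwork, np.ndarray]:
    """Expand the scenario's rule set and build its seed state vector."""
    key = structural_key(cell)
    net = _CACHE.get(key) if use_cache else None
    if net is None:
        rules = build_rule_set(cell)
        seeds = seed_species(cell)
        net = expand(rules, [g for g, _ in seeds], cell.caps())
        if use_cache:
            _CACHE[key] = net
    y0 = initial_state(net, seed_species(cell))
    return net, y0


def clear_cache() -> None:
    _CACHE.clear()
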