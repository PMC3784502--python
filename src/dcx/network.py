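"""Expansion of a rule set into a finite mass-action reaction network.

Breadth-first closure: every rule is applied to every known species (or
species pair, for intermolecular binding) and each product is
canonicalized; new species join the worklist; iteration proceeds to a fixed
point.  Unbounded polymer growth is prevented by per-complex stoichiometry
caps (maximum copies of a molecule type inside one complex); a candidate
reaction whose product would exceed a cap is discarded, which is how the
reference rule-based engines bound network generation.

Reactions store their rule, channel (intracomplex or not) and embedding
multiplicity; rate constants are recomputed on demand from a parameter set,
so re-rating (ablation, kinase inhibition, calibration) does not require
re-expansion.  For the degenerate case of a symmetric self-binding rule
applied to two copies of one species, the folded rate carries a factor 1/2
so that the mass-action flux ``k [A]^2`` counts each event once (not
exercised by the destruction-complex model, but kept for generality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import SpeciesGraph, match
from .params import RateParameters
from .rules import RuleSpec


class ExpansionError(RuntimeError):
    pass


@dataclass(frozen=True)
class Reaction:
    """A concrete reaction between network species (indices)."""

    reactants: tuple[int, ...]     # 0, 1 or 2 species indices
    products: tuple[int, ...]      # 0..3 species indices
    rule_name: str
    intracomplex: bool = False
    multiplicity: int = 1
    symmetry_factor: float = 1.0   # 0.5 for symmetric self-binding


@dataclass
class ReactionNetwork:
    species: list[SpeciesGraph]
    reactions: list[Reaction]
    rules: list[RuleSpec]
    seeds: list[int]
    caps: dict[str, int]

    _rule_by_name: dict[str, RuleSpec] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._rule_by_name = {r.name: r for r in self.rules}

    def n_species(self) -> int:
        return len(self.species)

    def rule(self, name: str) -> RuleSpec:
        return self._rule_by_name[name]

    def rate_vector(self, params: RateParameters, *, gsk_fold: float = 1.0) -> np.ndarray:
        """Rate constant per reaction (embedding multiplicity folded in)."""
        rates = np.empty(len(self.reactions))
        for k, rxn in enumerate(self.reactions):
            law = self._rule_by_name[rxn.rule_name].rate
            rates[k] = (
                rxn.multiplicity
                * rxn.symmetry_factor
                * law.value(params, intracomplex=rxn.intracomplex, gsk_fold=gsk_fold)
            )
        return rates

    # -- exports ---------------------------------------------------------

    def species_table(self) -> list[dict]:
        rows = []
        for i, g in enumerate(self.species):
            comp = g.composition()
            rows.append(
                {"index": i, "canonical": g.canonical(),
                 "composition": ";".join(f"{t}:{n}" for t, n in sorted(comp.items()))}
            )
        return rows

    def reaction_table(self, params: RateParameters | None = None) -> list[dict]:
        rates = self.rate_vector(params) if params is not None else None
        rows = []
        for k, rxn in enumerate(self.reactions):
            rows.append(
                {"index": k,
                 "reactants": ",".join(map(str, rxn.reactants)),
                 "products": ",".join(map(str, rxn.products)),
                 "rule": rxn.rule_name,
                 "intracomplex": int(rxn.intracomplex),
                 "multiplicity": rxn.multiplicity,
                 "rate": (float(rates[k]) if rates is not None else "")}
            )
        return rows


def _within_caps(comp: dict[str, int], caps: dict[str, int]) -> bool:
    for t, n in comp.items():
        if n > caps.get(t, 10**9):
            return False
    max_agg = caps.get("__max_agg__")
    if max_agg is not None and sum(comp.values()) > max_agg:
        return False
    return True


def expand(
    rules: list[RuleSpec],
    seeds: list[SpeciesGraph],
    caps: dict[str, int] | None = None,
    *,
    max_species: int = 20000,
    max_iter: int = 10**7,
) -> ReactionNetwork:
    """Expand a rule set from seed species into a closed reaction network.

    Species order is deterministic: discovery order (breadth-first over the
    worklist, rules in list order, canonical string as tie-break on
    products within one application).

    ``caps`` maps molecule type name -> maximum copies per complex; the
    reserved key ``"__max_agg__"`` additionally bounds the total number of
    molecules per complex (the max-aggregate convention of rule-based
    network generators).
    """
    caps = dict(caps or {})
    for s in seeds:
        if not _within_caps(s.composition(), caps):
            raise ExpansionError(f"seed exceeds caps: {s.canonical()}")

    species: list[SpeciesGraph] = []
    index: dict[str, int] = {}
    reactions: dict[tuple, list] = {}  # key -> [multiplicity]

    def add_species(g: SpeciesGraph) -> int:
        c = g.canonical()
        i = index.get(c)
        if i is None:
            i = len(species)
            if i >= max_species:
                raise ExpansionError(
                    f"species ceiling {max_species} exceeded; "
                    "check stoichiometry caps / rule set for unbounded growth"
                )
            species.append(g)
            index[c] = i
        return i

    def record(reactants: tuple[int, ...], products: tuple[int, ...], rule: RuleSpec,
               intracomplex: bool, sym: float = 1.0) -> None:
        key = (rule.name, intracomplex, tuple(sorted(reactants)), tuple(sorted(products)), sym)
        if key in reactions:
            reactions[key][0] += 1
        else:
            reactions[key] = [1, reactants, products, rule.name, intracomplex, sym]

    seed_idx = [add_species(s) for s in seeds]

    bind_rules = [r for r in rules if r.kind == "bind"]
    unary_rules = [r for r in rules if r.kind in ("unbind", "state_change", "degrade")]
    synth_rules = [r for r in rules if r.kind == "synthesize"]

    for r in synth_rules:
        pidx = add_species(r.product)
        record((), (pidx,), r, False)

    # per bind rule: species seen so far matching each side, with embeddings
    side_a: dict[str, list[tuple[int, list]]] = {r.name: [] for r in bind_rules}
    side_b: dict[str, list[tuple[int, list]]] = {r.name: [] for r in bind_rules}

    def do_bind_pair(rule: RuleSpec, ia: int, embs_a: list, ib: int, embs_b: list) -> None:
        ga, gb = species[ia], species[ib]
        comp: dict[str, int] = dict(ga.composition())
        for t, n in gb.composition().items():
            comp[t] = comp.get(t, 0) + n
        if not _within_caps(comp, caps):
            return
        symmetric = (
            ia == ib
            and rule.patterns[0] == rule.patterns[1]
            and rule.bind_sites[0] == rule.bind_sites[1]
        )
        sym = 0.5 if symmetric else 1.0
        for ea in embs_a:
            for eb in embs_b:
                prod = rule.apply_bimolecular(ga, gb, ea, eb)[0]
                record((ia, ib), (add_species(prod),), rule, False, sym)

    n_done = 0
    guard = 0
    while n_done < len(species):
        i = n_done
        n_done += 1
        g = species[i]
        guard += 1
        if guard > max_iter:
            raise ExpansionError("iteration ceiling exceeded during expansion")

        for rule in unary_rules:
            for emb in match(rule.patterns[0], g):
                prods = rule.apply_unary(g, emb)
                pidx = tuple(sorted(add_species(p) for p in prods))
                record((i,), pidx, rule, False)

        for rule in bind_rules:
            pat_a, pat_b = rule.patterns
            embs_a = match(pat_a, g)
            embs_b = match(pat_b, g)
            # intracomplex channel: both patterns inside this one species,
            # with disjoint molecule images (tethered partner sites)
            if embs_a and embs_b:
                for ea in embs_a:
                    sa = set(ea)
                    for eb in embs_b:
                        if sa.isdisjoint(eb):
                            prod = rule.apply_intracomplex(g, ea, eb)[0]
                            record((i,), (add_species(prod),), rule, True)
            # intermolecular channel against all previously seen partners
            if embs_a:
                for jb, embs_jb in side_b[rule.name]:
                    do_bind_pair(rule, i, embs_a, jb, embs_jb)
            if embs_b:
                for ja, embs_ja in side_a[rule.name]:
                    do_bind_pair(rule, ja, embs_ja, i, embs_b)
            if embs_a and embs_b:
                do_bind_pair(rule, i, embs_a, i, embs_b)
            if embs_a:
                side_a[rule.name].append((i, embs_a))
            if embs_b:
                side_b[rule.name].append((i, embs_b))

    rxn_list = [
        Reaction(reactants=v[1], products=v[2], rule_name=v[3], intracomplex=v[4],
                 multiplicity=v[0], symmetry_factor=v[5])
        for v in reactions.values()
    ]
    return ReactionNetwork(species=species, reactions=rxn_list, rules=list(rules),
                           seeds=seed_idx, caps=caps)


def verify_closure(net: ReactionNetwork) -> None:
    """Assert the network is closed under every rule (raises on violation)."""
    known = {g.canonical() for g in net.species}
    for i, g in enumerate(net.species):
        for rule in net.rules:
            if rule.kind == "synthesize":
                if rule.product.canonical() not in known:
                    raise AssertionError(f"synthesis product missing from network")
                continue
            if rule.kind == "bind":
                pat_a, pat_b = rule.patterns
                embs_a = match(pat_a, g)
                embs_b = match(pat_b, g)
                for ea in embs_a:
                    for eb in embs_b:
                        if set(ea).isdisjoint(eb):
                            p = rule.apply_intracomplex(g, ea, eb)[0]
                            if p.canonical() not in known:
                                raise AssertionError(
                                    f"not closed: {rule.name} intracomplex on species {i}")
                for j, h in enumerate(net.species):
                    embs_jb = match(pat_b, h)
                    if not embs_a or not embs_jb:
                        continue
                    comp = dict(g.composition())
                    for t, n in h.composition().items():
                        comp[t] = comp.get(t, 0) + n
                    if not _within_caps(comp, net.caps):
                        continue
                    for ea in embs_a:
                        for eb in embs_jb:
                            p = rule.apply_bimolecular(g, h, ea, eb)[0]
                            if p.canonical() not in known:
                                raise AssertionError(
                                    f"not closed: {rule.name} on species {i}+{j}")
            else:
                for emb in match(rule.patterns[0], g):
                    for p in rule.apply_unary(g, emb):
                        if p.canonical() not in known:
                            raise AssertionError(
                                f"not closed: {rule.name} on species {i}")
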