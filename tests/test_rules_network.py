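"""Rule application, rate assignment, and network expansion.

The expansion oracle here is deliberately naive and independent of the
engine: species identity is decided by VF2 isomorphism (networkx),
embeddings are enumerated by brute force over all injections, and graph
surgery is done on plain (molecules, bonds) tuples.  The engine must agree
species-for-species and rate-for-rate on randomized mini-models.
"""

import random

import networkx as nx
import pytest

import dcx
from dcx.graphs import ANY, UNBOUND, Pattern, SpeciesGraph, mol_pat
from dcx.model import build_rule_set, free_bcat, seed_species
from dcx.network import expand, verify_closure
from dcx.params import default_parameters
from dcx.rules import RateLaw, RuleSpec, apply_rule

from oracle_utils import engine_flux, iso, oracle_expand, plain

P = default_parameters()


# ---------------------------------------------------------------------------
# rule application
# ---------------------------------------------------------------------------


def cyclic_ternary():
    mols = [
        ("APC", {"aa15": None, "r20_3": "p", "samp": None}),
        ("AXIN", {"rgs": None, "bcat": None, "gid": None, "ck1": None}),
        ("BCAT", {"arm34": None, "arm59": None, "S45": "u", "S33_37": "u"}),
    ]
    bonds = [((0, "samp"), (1, "rgs")), ((1, "bcat"), (2, "arm34")),
             ((0, "aa15"), (2, "arm59"))]
    return SpeciesGraph(mols, bonds)


def degrade_rule():
    return RuleSpec(
        name="deg", kind="degrade",
        rate=RateLaw("first_order", param="kdeg_slow"),
        patterns=(Pattern((mol_pat("BCAT"),)),),
    )


class TestApply:
    def test_degradation_in_cyclic_complex_leaves_apc_axin(self):
        """Deleting beta-catenin from the cyclic ternary complex leaves a
        single APC-Axin complex behind."""
        g = cyclic_ternary()
        rule = degrade_rule()
        emb = (2,)
        products = apply_rule(rule, [g], emb)
        assert len(products) == 1
        comp = products[0].composition()
        assert comp == {"APC": 1, "AXIN": 1}

    def test_degradation_of_bridge_releases_partners(self):
        """Without the SAMP-RGS bond, degrading the bridging beta-catenin
        releases APC and Axin as two separate species."""
        g = cyclic_ternary().without_bond((0, "samp"), (1, "rgs"))
        products = apply_rule(degrade_rule(), [g], (2,))
        comps = sorted(tuple(sorted(p.composition().items())) for p in products)
        assert comps == [(("APC", 1),), (("AXIN", 1),)]

    def test_bimolecular_bind_gives_dimer(self):
        rule = RuleSpec(
            name="b", kind="bind", rate=RateLaw("assoc", arrow_key="kf_ga"),
            patterns=(Pattern((mol_pat("GSK3B", ax=(ANY, UNBOUND)),)),
                      Pattern((mol_pat("AXIN", gid=(ANY, UNBOUND)),))),
            bind_sites=((0, "ax"), (0, "gid")),
        )
        gsk = SpeciesGraph([("GSK3B", {"ax": None})])
        axin = SpeciesGraph([("AXIN", {"rgs": None, "bcat": None, "gid": None,
                                       "ck1": None})])
        prods = apply_rule(rule, [gsk, axin], (((0,), (0,))))
        assert len(prods) == 1
        assert prods[0].composition() == {"GSK3B": 1, "AXIN": 1}
        assert prods[0].is_bound(0, "ax")


class TestRates:
    def test_intracomplex_closure_rate_is_kf_chi(self):
        law = RateLaw("assoc", arrow_key="kf2_bap")
        assert law.value(P, intracomplex=True) == pytest.approx(P.kf * P.chi)

    def test_intermolecular_rate_is_kf(self):
        law = RateLaw("assoc", arrow_key="kf1_bap")
        assert law.value(P) == pytest.approx(P.kf)

    def test_unbinding_rate_is_kf_times_kd(self):
        """The dissociation rate of the 15aa-ARM59 bond is kf * 273 nM."""
        law = RateLaw("dissoc", param="KD1_bap")
        assert law.value(P) == pytest.approx(P.kf * 273.0)

    def test_ablated_interface_keeps_dissociation(self):
        p0 = P.with_overrides(kf_apa=0.0)
        assert RateLaw("assoc", arrow_key="kf_apa").value(p0) == 0.0
        assert RateLaw("dissoc", param="KD_apa").value(p0) == pytest.approx(
            P.kf * P.KD_apa)

    def test_gsk_fold_divides_only_marked_rules(self):
        marked = RateLaw("first_order", param="kp_bcat", gsk_mediated=True)
        plain = RateLaw("first_order", param="kp_bcat")
        assert marked.value(P, gsk_fold=20.0) == pytest.approx(P.kp_bcat / 20.0)
        assert plain.value(P, gsk_fold=20.0) == pytest.approx(P.kp_bcat)


# ---------------------------------------------------------------------------
# expansion basics
# ---------------------------------------------------------------------------


def toy_ab_rules():
    fwd = RuleSpec(
        name="bind_ab", kind="bind", rate=RateLaw("assoc", arrow_key=None),
        patterns=(Pattern((mol_pat("A", b=(ANY, UNBOUND)),)),
                  Pattern((mol_pat("B", a=(ANY, UNBOUND)),))),
        bind_sites=((0, "b"), (0, "a")),
    )
    rev = RuleSpec(
        name="unbind_ab", kind="unbind", rate=RateLaw("dissoc", param="KD_ba"),
        patterns=(Pattern((mol_pat("A", b=(ANY, 1)), mol_pat("B", a=(ANY, 1)))),),
        bind_sites=((0, "b"), (1, "a")),
    )
    return [fwd, rev]


def toy_seeds():
    return [SpeciesGraph([("A", {"b": None})]), SpeciesGraph([("B", {"a": None})])]


class TestExpand:
    def test_reversible_pair_three_species_two_reactions(self):
        net = expand(toy_ab_rules(), toy_seeds(), {"A": 1, "B": 1})
        assert net.n_species() == 3
        assert len(net.reactions) == 2

    def test_empty_rule_list_gives_seeds_only(self):
        net = expand([], toy_seeds(), {})
        assert net.n_species() == 2
        assert net.reactions == []

    def test_species_ceiling_raises_with_diagnostics(self):
        from dcx.network import ExpansionError
        cell = dcx.make_cell_model("normal")
        rules = build_rule_set(cell)
        seeds = [g for g, _ in seed_species(cell)]
        with pytest.raises(ExpansionError, match="ceiling"):
            expand(rules, seeds, {"BCAT": 2, "AXIN": 3, "GSK3B": 3, "CK1A": 3,
                                  "APC": 3}, max_species=200)

    def test_closure_and_determinism_of_sw480_network(self):
        cell = dcx.make_cell_model("SW480")
        rules = build_rule_set(cell)
        seeds = [g for g, _ in seed_species(cell)]
        net1 = expand(rules, seeds, cell.caps())
        net2 = expand(rules, seeds, cell.caps())
        assert [g.canonical() for g in net1.species] == \
               [g.canonical() for g in net2.species]
        verify_closure(net1)

    def test_base_network_closure(self, base_network):
        verify_closure(base_network[0])

    def test_reaction_mass_balance(self, base_network):
        """Every reaction conserves APC/Axin/GSK/CK1A counts; beta-catenin
        changes only via synthesis (+1) and degradation (-1)."""
        net, _ = base_network
        for rxn in net.reactions:
            for t in ("APC", "AXIN", "GSK3B", "CK1A"):
                before = sum(net.species[i].composition().get(t, 0)
                             for i in rxn.reactants)
                after = sum(net.species[i].composition().get(t, 0)
                            for i in rxn.products)
                assert before == after, (rxn.rule_name, t)
            db = (sum(net.species[i].composition().get("BCAT", 0) for i in rxn.products)
                  - sum(net.species[i].composition().get("BCAT", 0) for i in rxn.reactants))
            if rxn.rule_name == "syn_bcat":
                assert db == 1
            elif rxn.rule_name.startswith("deg_"):
                assert db == -1
            else:
                assert db == 0, rxn.rule_name


# ---------------------------------------------------------------------------
# independent brute-force oracle on mini-models
# ---------------------------------------------------------------------------


def _mini_model(seed: int):
    """A small randomized rule system over three molecule types."""
    rng = random.Random(seed)
    a = SpeciesGraph([("A", {"x": None})])
    b = SpeciesGraph([("B", {"y": None, "s": "u"})])
    c = SpeciesGraph([("C", {"x": None, "y": None})])
    rules = []
    rules += [
        RuleSpec("bind_ac", "bind", RateLaw("assoc", arrow_key=None),
                 patterns=(Pattern((mol_pat("A", x=(ANY, UNBOUND)),)),
                           Pattern((mol_pat("C", x=(ANY, UNBOUND)),))),
                 bind_sites=((0, "x"), (0, "x"))),
        RuleSpec("unbind_ac", "unbind", RateLaw("dissoc", param="KD_ba"),
                 patterns=(Pattern((mol_pat("A", x=(ANY, 1)),
                                    mol_pat("C", x=(ANY, 1)))),),
                 bind_sites=((0, "x"), (1, "x"))),
    ]
    if rng.random() < 0.8:
        state_req = rng.choice([ANY, "u", "p"])
        rules.append(
            RuleSpec("bind_bc", "bind", RateLaw("assoc", arrow_key=None),
                     patterns=(Pattern((mol_pat("B", y=(ANY, UNBOUND),
                                                s=(state_req,)),)),
                               Pattern((mol_pat("C", y=(ANY, UNBOUND)),))),
                     bind_sites=((0, "y"), (0, "y"))))
    if rng.random() < 0.8:
        rules.append(
            RuleSpec("flip_b", "state_change",
                     RateLaw("first_order", param="kp_bcat"),
                     patterns=(Pattern((mol_pat("B", s=("u",)),)),),
                     state_target=(0, "s", "p")))
    if rng.random() < 0.5:
        rules.append(
            RuleSpec("deg_a", "degrade",
                     RateLaw("first_order", param="kdeg_slow"),
                     patterns=(Pattern((mol_pat("A"),)),)))
    caps = {"A": rng.choice([1, 2]), "B": 1, "C": rng.choice([1, 2])}
    return rules, [a, b, c], caps


@pytest.mark.parametrize("seed", range(8))
def test_expand_matches_bruteforce_oracle(seed):
    """On randomized mini-models the engine's species set and aggregated
    per-channel rates equal those of the naive enumerator."""
    rules, seeds, caps = _mini_model(seed)
    net = expand(rules, seeds, caps)
    oracle_species, oracle_flux = oracle_expand(rules, seeds, caps, P)

    assert net.n_species() == len(oracle_species)
    mapping = {}
    for i, g in enumerate(net.species):
        matches = [j for j, sp in enumerate(oracle_species)
                   if len(sp[0]) == g.n_molecules() and iso(sp, plain(g))]
        assert len(matches) == 1, f"species {g.canonical()} unmatched"
        mapping[i] = matches[0]

    engine = {}
    for (rule, intra, r_idx, p_idx), k in engine_flux(net, P).items():
        key = (rule, intra, tuple(sorted(mapping[i] for i in r_idx)),
               tuple(sorted(mapping[i] for i in p_idx)))
        engine[key] = engine.get(key, 0.0) + k
    assert set(engine) == set(oracle_flux)
    for key in engine:
        assert engine[key] == pytest.approx(oracle_flux[key]), key


def test_synthesis_product_present(base_network):
    net, _ = base_network
    assert any(g.canonical() == free_bcat().canonical() for g in net.species)
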