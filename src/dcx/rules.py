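"""Reaction rules: bind / unbind / state change / synthesize / degrade.

Each rule carries patterns, a transformation and a :class:`RateLaw`.  Rate
constants are resolved lazily from a :class:`~dcx.params.RateParameters`
instance, so an expanded network can be re-rated (for ablations, kinase
inhibition, or calibration moves) without re-expanding.

Binding rules describe both reaction channels of a reversible interaction's
forward direction: when the two reactant patterns are matched in two
separate species the reaction is bimolecular with rate ``kf`` (per nM per
s); when both match inside one species (the partner sites are tethered) the
closure is unimolecular with rate ``kf * chi``.  Unbinding always proceeds
at ``kf * KD`` regardless of context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graphs import Pattern, SpeciesGraph, merge, split_components
from .params import RateParameters


@dataclass(frozen=True)
class RateLaw:
    """How a rule's rate constant is computed from parameters.

    ``kind``:
      * ``assoc`` -- forward binding; value ``forward_kf(arrow_key)``,
        multiplied by ``chi`` for the intracomplex channel;
      * ``dissoc`` -- unbinding; value ``kf * KD`` using the *global* kf
        (an ablated interface keeps its dissociation rate);
      * ``first_order`` -- value of the named parameter, per second;
      * ``zeroth`` -- the synthesis rate in nM/s.

    ``gsk_mediated`` marks GSK-3beta-catalysed phosphorylations whose rate
    is divided by the kinase-inhibition fold (LiCl virtual experiment).
    """

    kind: str
    param: str | None = None          # KD name for dissoc, rate name for first_order
    arrow_key: str | None = None      # association-rate override / ablation key
    gsk_mediated: bool = False

    def value(self, params: RateParameters, *, intracomplex: bool = False,
              gsk_fold: float = 1.0) -> float:
        if self.kind == "assoc":
            k = params.forward_kf(self.arrow_key)
            return k * params.chi if intracomplex else k
        if self.kind == "dissoc":
            return params.kf * getattr(params, self.param)
        if self.kind == "first_order":
            k = getattr(params, self.param)
            return k / gsk_fold if self.gsk_mediated else k
        if self.kind == "zeroth":
            return params.ksyn
        raise ValueError(f"unknown rate-law kind {self.kind!r}")


@dataclass(frozen=True)
class RuleSpec:
    """One reaction rule.

    ``kind`` in {bind, unbind, state_change, synthesize, degrade}.

    * bind: ``patterns = (pat_a, pat_b)``; ``bind_sites = ((mol_in_a, site),
      (mol_in_b, site))``; both designated sites must be free in the
      patterns.
    * unbind: single pattern containing the labelled bond to remove, named
      by ``bind_sites`` into that pattern.
    * state_change: single (possibly multi-component) pattern;
      ``state_target = (mol_idx, site, new_state)``.
    * synthesize: ``product`` graph created at the zeroth-order rate.
    * degrade: single pattern; pattern molecule 0 is deleted and the
      remainder split into connected components ("releases any binding
      partner(s) upon degradation").
    """

    name: str
    kind: str
    rate: RateLaw
    patterns: tuple[Pattern, ...] = ()
    bind_sites: tuple[tuple[int, str], tuple[int, str]] | None = None
    state_target: tuple[int, str, str] | None = None
    product: SpeciesGraph | None = None
    arrow: int | None = None          # which interaction arrow (1..10), if any

    # -- applications ----------------------------------------------------

    def apply_bimolecular(self, ga: SpeciesGraph, gb: SpeciesGraph,
                          emb_a: tuple[int, ...], emb_b: tuple[int, ...]) -> list[SpeciesGraph]:
        """Join two species by the designated bond."""
        assert self.kind == "bind" and self.bind_sites is not None
        (ma, sa), (mb, sb) = self.bind_sites
        off = ga.n_molecules()
        joined = merge(ga, gb)
        return [joined.with_bond((emb_a[ma], sa), (off + emb_b[mb], sb))]

    def apply_intracomplex(self, g: SpeciesGraph, emb_a: tuple[int, ...],
                           emb_b: tuple[int, ...]) -> list[SpeciesGraph]:
        assert self.kind == "bind" and self.bind_sites is not None
        (ma, sa), (mb, sb) = self.bind_sites
        return [g.with_bond((emb_a[ma], sa), (emb_b[mb], sb))]

    def apply_unary(self, g: SpeciesGraph, emb: tuple[int, ...]) -> list[SpeciesGraph]:
        """Apply an unbind / state_change / degrade rule at one embedding."""
        if self.kind == "unbind":
            assert self.bind_sites is not None
            (ma, sa), (mb, sb) = self.bind_sites
            cut = g.without_bond((emb[ma], sa), (emb[mb], sb))
            return split_components(cut)
        if self.kind == "state_change":
            assert self.state_target is not None
            mi, site, new_state = self.state_target
            return [g.with_state(emb[mi], site, new_state)]
        if self.kind == "degrade":
            return g.without_molecule(emb[0])
        raise ValueError(f"apply_unary on rule kind {self.kind!r}")


def apply_rule(rule: RuleSpec, reactants: list[SpeciesGraph],
               embedding) -> list[SpeciesGraph]:
    """Uniform entry point used by tests and the network expander.

    ``embedding``: for bind rules a pair ``(emb_a, emb_b)``; otherwise a
    single embedding tuple.  For a bimolecular bind, ``reactants`` holds two
    graphs; all other kinds take exactly one (or zero for synthesize).
    """
    if rule.kind == "synthesize":
        assert rule.product is not None
        return [rule.product]
    if rule.kind == "bind":
        emb_a, emb_b = embedding
        if len(reactants) == 2:
            return rule.apply_bimolecular(reactants[0], reactants[1], emb_a, emb_b)
        return rule.apply_intracomplex(reactants[0], emb_a, emb_b)
    return rule.apply_unary(reactants[0], embedding)
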