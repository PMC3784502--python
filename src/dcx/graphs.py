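"""Site-graphs: the structured species of the rule-based model.

A :class:`SpeciesGraph` is a connected graph of molecule instances.  Each
molecule carries a type name and a mapping from site names to internal
states (``None`` for pure binding sites); each bond joins two (molecule,
site) endpoints and a site holds at most one bond.  Chemical identity is
isomorphism of labelled site-graphs, decided by an exact canonical form
(partition refinement plus backtracking on ties, not hashing).

A :class:`Pattern` is a partially specified site-graph used for rule
application and observables: sites may be omitted, states wildcarded, and
bond requirements expressed as free / bound / any / bound-to-a-named
partner.  Pattern components need not be connected; all pattern molecules
must embed into one species, which realises "in the same complex as"
contexts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

Endpoint = tuple[int, str]          # (molecule index, site name)
Bond = tuple[Endpoint, Endpoint]    # stored with endpoints sorted

ANY = "?"        # wildcard state in patterns
UNBOUND = "."    # bond requirement: site must be free
BOUND = "+"      # bond requirement: site must be bound (to anything)
WILD = "*"       # bond requirement: don't care


def _norm_bond(a: Endpoint, b: Endpoint) -> Bond:
    return (a, b) if a <= b else (b, a)


class SpeciesGraph:
    """A connected site-graph of molecule instances, site states and bonds.

    ``molecules``: sequence of ``(type_name, {site: state})``.
    ``bonds``: iterable of endpoint pairs.
    """

    __slots__ = ("molecules", "bonds", "_adj", "_canon", "_comp")

    def __init__(
        self,
        molecules: Sequence[tuple[str, Mapping[str, str | None]]],
        bonds: Iterable[tuple[Endpoint, Endpoint]] = (),
    ) -> None:
        self.molecules: tuple[tuple[str, dict[str, str | None]], ...] = tuple(
            (name, dict(states)) for name, states in molecules
        )
        self.bonds: frozenset[Bond] = frozenset(_norm_bond(a, b) for a, b in bonds)
        adj: dict[Endpoint, Endpoint] = {}
        for a, b in self.bonds:
            if a in adj or b in adj:
                raise ValueError(f"site participates in more than one bond: {a} / {b}")
            adj[a] = b
            adj[b] = a
        self._adj = adj
        self._canon: str | None = None
        self._comp: dict[str, int] | None = None

    # -- basic queries ---------------------------------------------------

    def n_molecules(self) -> int:
        return len(self.molecules)

    def partner(self, mol: int, site: str) -> Endpoint | None:
        return self._adj.get((mol, site))

    def is_bound(self, mol: int, site: str) -> bool:
        return (mol, site) in self._adj

    def composition(self) -> dict[str, int]:
        """Molecule count per type name."""
        if self._comp is None:
            comp: dict[str, int] = {}
            for name, _ in self.molecules:
                comp[name] = comp.get(name, 0) + 1
            self._comp = comp
        return self._comp

    def neighbours(self, mol: int) -> list[int]:
        out = []
        for (i, _s), (j, _t) in self._adj.items():
            if i == mol:
                out.append(j)
        return out

    def is_connected(self) -> bool:
        n = len(self.molecules)
        if n <= 1:
            return True
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in self.neighbours(i):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n

    # -- canonical form --------------------------------------------------

    def canonical(self) -> str:
        """Exact canonical string: equal iff isomorphic as labelled site-graphs."""
        if self._canon is None:
            self._canon = _canonical_form(self)
        return self._canon

    def __eq__(self, other) -> bool:  # identity by canonical form
        return isinstance(other, SpeciesGraph) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        return f"SpeciesGraph({self.canonical()})"

    # -- editing helpers (return new graphs) -----------------------------

    def with_state(self, mol: int, site: str, state: str) -> "SpeciesGraph":
        mols = [(n, dict(s)) for n, s in self.molecules]
        mols[mol][1][site] = state
        return SpeciesGraph(mols, self.bonds)

    def with_bond(self, a: Endpoint, b: Endpoint) -> "SpeciesGraph":
        return SpeciesGraph(self.molecules, set(self.bonds) | {_norm_bond(a, b)})

    def without_bond(self, a: Endpoint, b: Endpoint) -> "SpeciesGraph":
        bond = _norm_bond(a, b)
        if bond not in self.bonds:
            raise KeyError(f"no such bond: {bond}")
        return SpeciesGraph(self.molecules, set(self.bonds) - {bond})

    def without_molecule(self, mol: int) -> list["SpeciesGraph"]:
        """Delete one molecule (and its bonds); return the connected remainder(s)."""
        keep = [i for i in range(len(self.molecules)) if i != mol]
        remap = {old: new for new, old in enumerate(keep)}
        mols = [self.molecules[i] for i in keep]
        bonds = [
            ((remap[a[0]], a[1]), (remap[b[0]], b[1]))
            for a, b in self.bonds
            if a[0] != mol and b[0] != mol
        ]
        if not mols:
            return []
        return split_components(SpeciesGraph(mols, bonds))


def merge(a: SpeciesGraph, b: SpeciesGraph) -> SpeciesGraph:
    """Disjoint union of two species (offsets b's molecule indices)."""
    off = len(a.molecules)
    mols = list(a.molecules) + list(b.molecules)
    bonds = list(a.bonds) + [((i + off, s), (j + off, t)) for (i, s), (j, t) in b.bonds]
    return SpeciesGraph(mols, bonds)


def split_components(g: SpeciesGraph) -> list[SpeciesGraph]:
    """Connected components of a (possibly disconnected) site-graph."""
    n = len(g.molecules)
    comp = [-1] * n
    n_comp = 0
    for start in range(n):
        if comp[start] != -1:
            continue
        comp[start] = n_comp
        stack = [start]
        while stack:
            i = stack.pop()
            for j in g.neighbours(i):
                if comp[j] == -1:
                    comp[j] = n_comp
                    stack.append(j)
        n_comp += 1
    if n_comp == 1:
        return [g]
    out = []
    for c in range(n_comp):
        keep = [i for i in range(n) if comp[i] == c]
        remap = {old: new for new, old in enumerate(keep)}
        mols = [g.molecules[i] for i in keep]
        bonds = [
            ((remap[a[0]], a[1]), (remap[b[0]], b[1]))
            for a, b in g.bonds
            if comp[a[0]] == c
        ]
        out.append(SpeciesGraph(mols, bonds))
    return out


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------


def _canonical_form(g: SpeciesGraph) -> str:
    if not g.is_connected():
        raise ValueError("canonical form is defined for connected species only")
    n = len(g.molecules)
    # initial colour: type + sorted internal states
    colours: list[tuple] = [
        (name, tuple(sorted((s, v) for s, v in states.items())))
        for name, states in g.molecules
    ]
    # iterative refinement by bonded neighbourhood
    for _ in range(n):
        sig = []
        for i in range(n):
            nb = []
            for site, state in g.molecules[i][1].items():
                p = g.partner(i, site)
                if p is not None:
                    j, t = p
                    nb.append((site, t, colours[j]))
            sig.append((colours[i], tuple(sorted(nb))))
        if len(set(sig)) == len(set(colours)) and all(
            (sig[i] == sig[j]) == (colours[i] == colours[j])
            for i in range(n)
            for j in range(i + 1, n)
        ):
            break
        colours = sig
    # order molecules by colour; permute within tied colour classes and take
    # the lexicographically smallest serialization (exact, not heuristic)
    order_classes: dict[tuple, list[int]] = {}
    for i, c in enumerate(colours):
        order_classes.setdefault(c, []).append(i)
    sorted_keys = sorted(order_classes, key=repr)
    groups = [order_classes[k] for k in sorted_keys]
    best: str | None = None
    for perm_parts in itertools.product(*(itertools.permutations(grp) for grp in groups)):
        order = [i for part in perm_parts for i in part]
        s = _serialize(g, order)
        if best is None or s < best:
            best = s
    assert best is not None
    return best


def _serialize(g: SpeciesGraph, order: Sequence[int]) -> str:
    pos = {old: new for new, old in enumerate(order)}
    bond_ids: dict[Bond, int] = {}
    parts = []
    for old in order:
        name, states = g.molecules[old]
        site_parts = []
        for site in sorted(states):
            token = site
            state = states[site]
            if state is not None:
                token += f"~{state}"
            p = g.partner(old, site)
            if p is not None:
                bond = _norm_bond((old, site), p)
                if bond not in bond_ids:
                    bond_ids[bond] = len(bond_ids) + 1
                token += f"!{bond_ids[bond]}"
            site_parts.append(token)
        parts.append(f"{name}({','.join(site_parts)})")
    return ".".join(parts)


# ---------------------------------------------------------------------------
# patterns and matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SitePattern:
    """Constraint on one site: state requirement and bond requirement.

    ``state``: required internal state, or :data:`ANY`.
    ``bond``: :data:`UNBOUND`, :data:`BOUND`, :data:`WILD`, or an integer
    bond label shared with exactly one other site pattern in the same
    :class:`Pattern` (bound-to-specified-partner).
    """

    state: str = ANY
    bond: str | int = WILD


@dataclass(frozen=True)
class MoleculePattern:
    type_name: str
    sites: tuple[tuple[str, SitePattern], ...] = ()

    def site_map(self) -> dict[str, SitePattern]:
        return dict(self.sites)


@dataclass(frozen=True)
class Pattern:
    """A partially specified site-graph; components may be disconnected.

    All molecules of a pattern must embed (injectively) into a single
    species graph, so multi-component patterns express same-complex
    ("colocalized") constraints.
    """

    molecules: tuple[MoleculePattern, ...]

    def __post_init__(self):
        labels: dict[int, int] = {}
        for mp in self.molecules:
            for _s, sp in mp.sites:
                if isinstance(sp.bond, int):
                    labels[sp.bond] = labels.get(sp.bond, 0) + 1
        bad = [l for l, k in labels.items() if k != 2]
        if bad:
            raise ValueError(f"bond labels must appear exactly twice: {bad}")

    @staticmethod
    def parse(spec: Sequence[tuple[str, dict[str, tuple]]]) -> "Pattern":
        """Build from ``[(type, {site: (state, bond)})...]`` shorthand."""
        mols = tuple(
            MoleculePattern(
                name,
                tuple(sorted((s, SitePattern(state=v[0], bond=v[1])) for s, v in sites.items())),
            )
            for name, sites in spec
        )
        return Pattern(mols)


def mol_pat(type_name: str, **sites) -> MoleculePattern:
    """Convenience: ``mol_pat("BCAT", S45=("u", WILD), arm34=(ANY, UNBOUND))``."""
    parsed = []
    for site, v in sites.items():
        if isinstance(v, tuple):
            state, bond = (v + (WILD,))[:2] if len(v) < 2 else v
        else:
            state, bond = v, WILD
        parsed.append((site, SitePattern(state=state, bond=bond)))
    return MoleculePattern(type_name, tuple(sorted(parsed)))


def match(pattern: Pattern, g: SpeciesGraph) -> list[tuple[int, ...]]:
    """All embeddings of ``pattern`` into ``g``.

    An embedding is a tuple giving, for each pattern molecule, the index of
    its image molecule in ``g``.  Embeddings are injective monomorphisms
    respecting molecule types, site states, bond statuses and labelled
    pattern bonds; the list is exhaustive.
    """
    pm = pattern.molecules
    n = len(pm)
    if n == 0:
        return [()]
    # candidates per pattern molecule by local constraints
    cands: list[list[int]] = []
    for mp in pm:
        sm = mp.site_map()
        ok = []
        for gi, (gname, gstates) in enumerate(g.molecules):
            if gname != mp.type_name:
                continue
            good = True
            for site, sp in sm.items():
                if site not in gstates:
                    good = False
                    break
                if sp.state != ANY and gstates[site] != sp.state:
                    good = False
                    break
                bound = g.is_bound(gi, site)
                if sp.bond == UNBOUND and bound:
                    good = False
                    break
                if (sp.bond == BOUND or isinstance(sp.bond, int)) and not bound:
                    good = False
                    break
            if good:
                ok.append(gi)
        if not ok:
            return []
        cands.append(ok)

    # labelled bonds: label -> [(pattern mol idx, site), (pattern mol idx, site)]
    label_sites: dict[int, list[tuple[int, str]]] = {}
    for pi, mp in enumerate(pm):
        for site, sp in mp.sites:
            if isinstance(sp.bond, int):
                label_sites.setdefault(sp.bond, []).append((pi, site))

    results: list[tuple[int, ...]] = []
    assignment: list[int] = [-1] * n

    def consistent(pi: int, gi: int) -> bool:
        mp = pm[pi]
        for site, sp in mp.sites:
            if isinstance(sp.bond, int):
                (a_pi, a_site), (b_pi, b_site) = label_sites[sp.bond]
                o_pi, o_site = (b_pi, b_site) if (a_pi, a_site) == (pi, site) else (a_pi, a_site)
                partner = g.partner(gi, site)
                if partner is None:
                    return False
                if partner[1] != o_site:
                    return False
                if assignment[o_pi] != -1 and partner[0] != assignment[o_pi]:
                    return False
        return True

    def backtrack(pi: int) -> None:
        if pi == n:
            results.append(tuple(assignment))
            return
        for gi in cands[pi]:
            if gi in assignment[:pi]:
                continue
            assignment[pi] = gi
            if consistent(pi, gi):
                # re-check labelled bonds of earlier molecules that point here
                ok = all(consistent(qj, assignment[qj]) for qj in range(pi))
                if ok:
                    backtrack(pi + 1)
            assignment[pi] = -1

    backtrack(0)
    return results
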