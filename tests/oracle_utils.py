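"""Naive reference implementations used to cross-check the rule engine.

Species identity here is decided by VF2 graph isomorphism, embeddings by
exhaustive enumeration over injections, and graph surgery on plain
(molecules, bonds) tuples -- all independent of the engine's
canonicalization and matching code paths.
"""

import itertools

import networkx as nx

from dcx.graphs import ANY, UNBOUND, Pattern, SpeciesGraph


def nx_of(mols, bonds):
    G = nx.Graph()
    for i, (name, states) in enumerate(mols):
        G.add_node(i, label=(name, tuple(sorted(states.items()))))
    for (i, s), (j, t) in bonds:
        G.add_edge(i, j, key=frozenset([(mols[i][0], s), (mols[j][0], t)]))
    return G


def iso(a, b):
    return nx.is_isomorphic(nx_of(*a), nx_of(*b),
                            node_match=lambda x, y: x["label"] == y["label"],
                            edge_match=lambda x, y: x["key"] == y["key"])


def plain(g: SpeciesGraph):
    return (tuple((n, dict(s)) for n, s in g.molecules), set(g.bonds))


def components(mols, bonds):
    n = len(mols)
    adj = {i: set() for i in range(n)}
    for (i, _s), (j, _t) in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], []
        seen.add(s)
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(sorted(comp))
    out = []
    for comp in comps:
        remap = {old: new for new, old in enumerate(comp)}
        cm = tuple((mols[i][0], dict(mols[i][1])) for i in comp)
        cb = {((remap[a[0]], a[1]), (remap[b[0]], b[1]))
              for a, b in bonds if a[0] in remap}
        out.append((cm, cb))
    return out


def naive_embeddings(pattern: Pattern, plain):
    """All injective embeddings of a pattern, by exhaustive enumeration."""
    mols, bonds = plain
    partner = {}
    for a, b in bonds:
        partner[a] = b
        partner[b] = a
    k = len(pattern.molecules)
    found = []
    for cand in itertools.permutations(range(len(mols)), k):
        ok = True
        label_ends = {}
        for pi, mp in enumerate(pattern.molecules):
            gi = cand[pi]
            if mols[gi][0] != mp.type_name:
                ok = False
                break
            for site, sp in mp.sites:
                if site not in mols[gi][1]:
                    ok = False
                    break
                if sp.state != ANY and mols[gi][1][site] != sp.state:
                    ok = False
                    break
                bound = (gi, site) in partner
                if sp.bond == UNBOUND and bound:
                    ok = False
                    break
                if sp.bond == "+" and not bound:
                    ok = False
                    break
                if isinstance(sp.bond, int):
                    if not bound:
                        ok = False
                        break
                    label_ends.setdefault(sp.bond, []).append((gi, site))
            if not ok:
                break
        if ok:
            for ends in label_ends.values():
                if len(ends) == 2 and partner.get(ends[0]) != ends[1]:
                    ok = False
        if ok:
            found.append(cand)
    return found


def oracle_expand(rules, seeds, caps, params):
    """Reference expansion: naive embeddings + VF2 identity."""
    species = []

    def find(plain):
        for idx, sp in enumerate(species):
            if len(sp[0]) == len(plain[0]) and iso(sp, plain):
                return idx
        return None

    def add(plain):
        idx = find(plain)
        if idx is None:
            species.append(plain)
            idx = len(species) - 1
        return idx

    def within_caps(mols):
        counts = {}
        for name, _ in mols:
            counts[name] = counts.get(name, 0) + 1
        return all(v <= caps.get(k, 10**9) for k, v in counts.items())

    for s in seeds:
        add(plain(s))
    for r in rules:
        if r.kind == "synthesize":
            add(plain(r.product))

    flux = {}

    def record(rule, intracomplex, r_idx, p_idx, rate):
        key = (rule.name, intracomplex, tuple(sorted(r_idx)), tuple(sorted(p_idx)))
        flux[key] = flux.get(key, 0.0) + rate

    changed = True
    while changed:
        changed = False
        n0 = len(species)
        snapshot = list(species)
        flux.clear()
        for i, sp in enumerate(snapshot):
            mols, bonds = sp
            for r in rules:
                if r.kind == "synthesize":
                    record(r, False, (), (find(plain(r.product)),),
                           r.rate.value(params))
                    continue
                if r.kind == "bind":
                    ea = naive_embeddings(r.patterns[0], sp)
                    eb = naive_embeddings(r.patterns[1], sp)
                    (ma, sa), (mb, sb) = r.bind_sites
                    for a in ea:
                        for b in eb:
                            if set(a) & set(b):
                                continue
                            nb = set(bonds) | {tuple(sorted(((a[ma], sa), (b[mb], sb))))}
                            record(r, True, (i,), (add((mols, nb)),),
                                   r.rate.value(params, intracomplex=True))
                    for j, sp2 in enumerate(snapshot):
                        eb2 = naive_embeddings(r.patterns[1], sp2)
                        if not ea or not eb2:
                            continue
                        m2, b2 = sp2
                        off = len(mols)
                        jm = mols + tuple((n, dict(s)) for n, s in m2)
                        if not within_caps(jm):
                            continue
                        jb = set(bonds) | {((x[0] + off, x[1]), (y[0] + off, y[1]))
                                           for x, y in b2}
                        for a in ea:
                            for b in eb2:
                                nb = jb | {tuple(sorted(
                                    ((a[ma], sa), (b[mb] + off, sb))))}
                                rate = r.rate.value(params)
                                if i == j and r.patterns[0] == r.patterns[1] \
                                        and r.bind_sites[0] == r.bind_sites[1]:
                                    rate *= 0.5
                                record(r, False, (i, j), (add((jm, nb)),), rate)
                    continue
                for emb in naive_embeddings(r.patterns[0], sp):
                    if r.kind == "unbind":
                        (ma, sa), (mb, sb) = r.bind_sites
                        bond = tuple(sorted(((emb[ma], sa), (emb[mb], sb))))
                        nb = set(bonds) - {bond, (bond[1], bond[0])}
                        nb = {tuple(sorted(x)) for x in nb}
                        comps = components(mols, nb)
                    elif r.kind == "state_change":
                        mi, site, new = r.state_target
                        nm = tuple((n, dict(s)) for n, s in mols)
                        nm[emb[mi]][1][site] = new
                        comps = [(nm, set(bonds))]
                    else:  # degrade
                        keep = [x for x in range(len(mols)) if x != emb[0]]
                        remap = {o: n for n, o in enumerate(keep)}
                        nm = tuple((mols[x][0], dict(mols[x][1])) for x in keep)
                        nb = {((remap[a[0]], a[1]), (remap[b[0]], b[1]))
                              for a, b in bonds if a[0] != emb[0] and b[0] != emb[0]}
                        comps = components(nm, nb) if nm else []
                    record(r, False, (i,), tuple(add(c) for c in comps),
                           r.rate.value(params))
        if len(species) != n0:
            changed = True
    return species, flux


def engine_flux(net, params):
    out = {}
    rates = net.rate_vector(params)
    for rxn, k in zip(net.reactions, rates):
        key = (rxn.rule_name, rxn.intracomplex, tuple(sorted(rxn.reactants)),
               tuple(sorted(rxn.products)))
        out[key] = out.get(key, 0.0) + float(k)
    return out


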