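"""Definition of the destruction-complex model and its scenario variants.

Five proteins are explicit: beta-catenin (BCAT), APC (full-length or a
truncation/construct class), Axin (AXIN), GSK-3beta (GSK3B) and CK1alpha
(CK1A).  CK1epsilon and the phosphatases act implicitly through rule
contexts.  Sites follow the structural regions that mediate each
interaction:

* BCAT: ``arm59`` (ARM repeats 5-9, binds APC 15-aa region), ``arm34``
  (ARM repeats 3-4, binds Axin *or* a phosphorylated APC 20-aa repeat --
  the two compete for this one site), phospho-sites ``S45`` and ``S33_37``.
* APC: ``aa15`` (15-aa repeat region), one lumped 20-aa repeat site
  (``r20_3``, the high-affinity third repeat, on full-length APC;
  ``r20_1``, the first repeat, on APC1338-like truncations), ``samp``
  (SAMP repeats, bind the Axin RGS domain; lost in oncogenic truncation).
* AXIN: ``rgs``, ``bcat``, ``gid`` (GSK-3beta), ``ck1`` (CK1alpha).
* GSK3B / CK1A: single Axin-binding site ``ax``.

Ten interaction arrows map onto the rules: six reversible bindings
(15aa-arm59; phospho-20aa-arm34; Axin-arm34; SAMP-RGS; GSK3B-GID;
CK1A-Axin), and four catalytic relationships (CK1A phosphorylates S45;
GSK3B phosphorylates S33/37 after S45; CK1A+GSK3B phosphorylate the APC
20-aa repeats when APC is colocalized with Axin-bound GSK3B).
Dephosphorylation of beta-catenin is context-free first order;
dephosphorylation of APC happens only in complex with Axin (which recruits
PP2A) and only at an exposed site.  Beta-catenin is synthesized at a
zeroth-order rate and degraded slowly (S33/37 unphosphorylated) or fast
(S33/37 phosphorylated) regardless of its bound state, releasing partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graphs import ANY, BOUND, UNBOUND, WILD, Pattern, SpeciesGraph, mol_pat
from .params import INTERFACE_TO_KF, RateParameters, default_parameters
from .rules import RateLaw, RuleSpec

# ---------------------------------------------------------------------------
# molecule types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteDef:
    name: str
    state_labels: tuple[str, ...] = ()   # empty -> pure binding site


@dataclass(frozen=True)
class MoleculeTypeDef:
    name: str
    sites: tuple[SiteDef, ...]

    def __post_init__(self):
        names = [s.name for s in self.sites]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate site names in {self.name}")


PHOS = ("u", "p")

BCAT_TYPE = MoleculeTypeDef(
    "BCAT",
    (SiteDef("arm34"), SiteDef("arm59"), SiteDef("S45", PHOS), SiteDef("S33_37", PHOS)),
)
AXIN_TYPE = MoleculeTypeDef(
    "AXIN", (SiteDef("rgs"), SiteDef("bcat"), SiteDef("gid"), SiteDef("ck1"))
)
GSK_TYPE = MoleculeTypeDef("GSK3B", (SiteDef("ax"),))
CK1A_TYPE = MoleculeTypeDef("CK1A", (SiteDef("ax"),))


# ---------------------------------------------------------------------------
# APC construct classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstructClass:
    """One of the six functional classes of APC constructs.

    ``present_sites`` is the subset of {aa15, r20, samp} the construct
    retains; ``r20_affinity_mode`` selects which lumped 20-aa repeat site
    represents the region: the full-length third repeat (high affinity),
    the truncated first repeat (low affinity), or none.
    """

    label: str
    present_sites: frozenset[str]
    r20_affinity_mode: str  # full_length_r3 | truncated_r1 | none


CONSTRUCT_CLASSES: dict[str, ConstructClass] = {
    "A": ConstructClass("A", frozenset({"aa15", "r20", "samp"}), "full_length_r3"),
    "B": ConstructClass("B", frozenset({"aa15", "r20"}), "truncated_r1"),
    "C": ConstructClass("C", frozenset({"aa15"}), "none"),
    "D": ConstructClass("D", frozenset({"r20"}), "truncated_r1"),
    "E": ConstructClass("E", frozenset({"r20", "samp"}), "full_length_r3"),
    "F": ConstructClass("F", frozenset(), "none"),
}

#: KD parameter name per 20-aa affinity mode
_R20_SITE = {"full_length_r3": "r20_3", "truncated_r1": "r20_1"}
_R20_KD = {"full_length_r3": "KD2_bap_full", "truncated_r1": "KD2_bap_1338"}


@dataclass(frozen=True)
class ApcTypeSpec:
    """A concrete APC-like molecule type in a scenario, with its dose."""

    type_name: str
    construct: ConstructClass
    r20_mode: str           # resolved affinity mode (handles the APC-E switch)
    amount_nM: float

    @property
    def r20_site(self) -> str | None:
        return _R20_SITE.get(self.r20_mode)

    @property
    def r20_kd_param(self) -> str | None:
        return _R20_KD.get(self.r20_mode)

    def molecule_type(self) -> MoleculeTypeDef:
        sites = []
        if "aa15" in self.construct.present_sites:
            sites.append(SiteDef("aa15"))
        if self.r20_site is not None:
            sites.append(SiteDef(self.r20_site, PHOS))
        if "samp" in self.construct.present_sites:
            sites.append(SiteDef("samp"))
        return MoleculeTypeDef(self.type_name, tuple(sites))


# ---------------------------------------------------------------------------
# cell model
# ---------------------------------------------------------------------------

#: default per-complex stoichiometry caps (copies of a type per complex).
#: APC-like types are capped at 1 each (binary APC complexes are 1:1); one
#: beta-catenin per complex; up to two Axins (one on the SAMP arm, one on
#: ARM 3-4), each able to carry its own kinases.
DEFAULT_CAPS = {"BCAT": 1, "AXIN": 2, "GSK3B": 2, "CK1A": 2}
APC_CAP = 1


@dataclass(frozen=True)
class CellModel:
    """A configured scenario: background, transfections, perturbations."""

    background: str = "normal"                     # normal | SW480
    transfections: tuple[tuple[str, float], ...] = ()
    ablated_interfaces: frozenset[str] = frozenset()
    gsk_inhibition_fold: float = 1.0
    s33_37_mutant: bool = False
    params: RateParameters = field(default_factory=default_parameters)
    apc_e_mode: str = "full_length_r3"             # APC-E 20-aa affinity switch
    caps_override: tuple[tuple[str, int], ...] = ()

    def apc_types(self) -> list[ApcTypeSpec]:
        """The distinct APC-like molecule types present, with amounts.

        The endogenous form carries ``APC_tot``.  Transfecting the class
        that matches the endogenous protein (A into a normal cell, B into
        SW480) raises the endogenous total rather than adding a second,
        functionally identical type; any other class becomes its own type.
        """
        if self.background == "normal":
            endo_label, endo_name = "A", "APC"
        elif self.background == "SW480":
            endo_label, endo_name = "B", "APC1338"
        else:
            raise ValueError(f"unknown background {self.background!r}")

        endo_amount = self.params.APC_tot
        extra: dict[str, float] = {}
        for label, dose in self.transfections:
            if label not in CONSTRUCT_CLASSES:
                raise ValueError(f"unknown construct class {label!r}")
            if dose < 0:
                raise ValueError("transfection dose must be >= 0")
            if label == endo_label:
                endo_amount += dose
            else:
                extra[label] = extra.get(label, 0.0) + dose

        cls = CONSTRUCT_CLASSES[endo_label]
        specs = [ApcTypeSpec(endo_name, cls, cls.r20_affinity_mode, endo_amount)]
        for label in sorted(extra):
            cc = CONSTRUCT_CLASSES[label]
            mode = self.apc_e_mode if label == "E" else cc.r20_affinity_mode
            specs.append(ApcTypeSpec(f"APC_{label}", cc, mode, extra[label]))
        return specs

    def caps(self) -> dict[str, int]:
        caps = dict(DEFAULT_CAPS)
        for spec in self.apc_types():
            caps[spec.type_name] = APC_CAP
        caps.update(dict(self.caps_override))
        return caps

    def effective_params(self) -> RateParameters:
        """Parameters with interface ablations folded in as kf overrides."""
        p = self.params
        overrides = {}
        for iface in self.ablated_interfaces:
            if iface not in INTERFACE_TO_KF:
                raise ValueError(f"unknown interface {iface!r}")
            overrides[INTERFACE_TO_KF[iface]] = 0.0
        return p.with_overrides(**overrides) if overrides else p


def make_cell_model(
    background: str = "normal",
    transfections=(),
    ablations=(),
    overrides: dict | None = None,
    **kwargs,
) -> CellModel:
    """Build a :class:`CellModel` for any scenario.

    ``transfections``: iterable of ``(class label, dose in nM)``.
    ``overrides``: RateParameters field overrides (e.g. calibrated values).
    """
    params = kwargs.pop("params", None) or default_parameters()
    if overrides:
        params = params.replace(**overrides)
    cell = CellModel(
        background=background,
        transfections=tuple((str(l), float(d)) for l, d in transfections),
        ablated_interfaces=frozenset(ablations),
        params=params,
        **kwargs,
    )
    # validate eagerly
    cell.apc_types()
    cell.effective_params()
    return cell


def build_molecule_types(cell: CellModel) -> list[MoleculeTypeDef]:
    """Molecule type definitions for a scenario (one per APC-like form)."""
    return [BCAT_TYPE, AXIN_TYPE, GSK_TYPE, CK1A_TYPE] + [
        spec.molecule_type() for spec in cell.apc_types()
    ]


# ---------------------------------------------------------------------------
# rule inventory
# ---------------------------------------------------------------------------


def _bind_rule(name: str, arrow: int, pat_a: Pattern, pat_b: Pattern,
               sites, kd_param: str, arrow_key: str) -> list[RuleSpec]:
    """A reversible binding interaction: forward bind + unbind rule pair."""
    fwd = RuleSpec(
        name=name, kind="bind", arrow=arrow,
        rate=RateLaw("assoc", arrow_key=arrow_key),
        patterns=(pat_a, pat_b), bind_sites=sites,
    )
    # unbind pattern: the same two molecules joined by the designated bond
    (ma, sa), (mb, sb) = sites
    a_mols = list(pat_a.molecules)
    b_mols = list(pat_b.molecules)

    def with_bond(mp, site, label):
        sm = dict(mp.sites)
        from .graphs import SitePattern
        sm[site] = SitePattern(state=sm[site].state if site in sm else ANY, bond=label)
        return type(mp)(mp.type_name, tuple(sorted(sm.items())))

    a_mols[ma] = with_bond(a_mols[ma], sa, 1)
    b_mols[mb] = with_bond(b_mols[mb], sb, 1)
    rev_pat = Pattern(tuple(a_mols + b_mols))
    rev = RuleSpec(
        name=f"un{name}", kind="unbind", arrow=arrow,
        rate=RateLaw("dissoc", param=kd_param),
        patterns=(rev_pat,), bind_sites=((ma, sa), (len(a_mols) + mb, sb)),
    )
    return [fwd, rev]


def build_rule_set(cell: CellModel) -> list[RuleSpec]:
    """The complete rule inventory for a scenario.

    Interface ablations and kinase inhibition do not change the inventory;
    they re-rate it (the association constant of an ablated interface
    evaluates to zero, exactly as the variant model files set kf to 0).
    """
    rules: list[RuleSpec] = []

    for spec in cell.apc_types():
        t = spec.type_name
        # arrow 1: 15-aa repeats <-> ARM 5-9 (constitutive)
        if "aa15" in spec.construct.present_sites:
            rules += _bind_rule(
                f"bind_aa15[{t}]", 1,
                Pattern((mol_pat(t, aa15=(ANY, UNBOUND)),)),
                Pattern((mol_pat("BCAT", arm59=(ANY, UNBOUND)),)),
                ((0, "aa15"), (0, "arm59")),
                "KD1_bap", "kf1_bap",
            )
        # arrow 2: phosphorylated 20-aa repeat <-> ARM 3-4
        if spec.r20_site is not None:
            r20 = spec.r20_site
            rules += _bind_rule(
                f"bind_r20[{t}]", 2,
                Pattern((mol_pat(t, **{r20: ("p", UNBOUND)}),)),
                Pattern((mol_pat("BCAT", arm34=(ANY, UNBOUND)),)),
                ((0, r20), (0, "arm34")),
                spec.r20_kd_param, "kf2_bap",
            )
            # arrows 9/10: phosphorylation of the 20-aa repeats when APC is
            # colocalized with Axin-bound GSK-3beta (CK1epsilon implicit)
            rules.append(RuleSpec(
                name=f"phos_r20[{t}]", kind="state_change", arrow=9,
                rate=RateLaw("first_order", param="kp_apc", gsk_mediated=True),
                patterns=(Pattern((
                    mol_pat(t, **{r20: ("u", WILD)}),
                    mol_pat("GSK3B", ax=(ANY, 1)),
                    mol_pat("AXIN", gid=(ANY, 1)),
                )),),
                state_target=(0, r20, "p"),
            ))
            # dephosphorylation by Axin-recruited PP2A: only in complex with
            # Axin and only at an exposed (unbound) site
            rules.append(RuleSpec(
                name=f"dephos_r20[{t}]", kind="state_change",
                rate=RateLaw("first_order", param="kdp_apc"),
                patterns=(Pattern((
                    mol_pat(t, **{r20: ("p", UNBOUND)}),
                    mol_pat("AXIN"),
                )),),
                state_target=(0, r20, "u"),
            ))
        # arrow 4: SAMP repeats <-> Axin RGS domain
        if "samp" in spec.construct.present_sites:
            rules += _bind_rule(
                f"bind_samp[{t}]", 4,
                Pattern((mol_pat(t, samp=(ANY, UNBOUND)),)),
                Pattern((mol_pat("AXIN", rgs=(ANY, UNBOUND)),)),
                ((0, "samp"), (0, "rgs")),
                "KD_apa", "kf_apa",
            )

    # arrow 3: Axin <-> ARM 3-4 (competes with arrow 2 for the same site)
    rules += _bind_rule(
        "bind_axin_bcat", 3,
        Pattern((mol_pat("AXIN", bcat=(ANY, UNBOUND)),)),
        Pattern((mol_pat("BCAT", arm34=(ANY, UNBOUND)),)),
        ((0, "bcat"), (0, "arm34")),
        "KD_ba", "kf_ba",
    )
    # arrows 5, 6: kinase recruitment to Axin
    rules += _bind_rule(
        "bind_gsk_axin", 5,
        Pattern((mol_pat("GSK3B", ax=(ANY, UNBOUND)),)),
        Pattern((mol_pat("AXIN", gid=(ANY, UNBOUND)),)),
        ((0, "ax"), (0, "gid")),
        "KD_ga", "kf_ga",
    )
    rules += _bind_rule(
        "bind_ck1_axin", 6,
        Pattern((mol_pat("CK1A", ax=(ANY, UNBOUND)),)),
        Pattern((mol_pat("AXIN", ck1=(ANY, UNBOUND)),)),
        ((0, "ax"), (0, "ck1")),
        "KD_ca", "kf_ca",
    )

    # arrow 7: CK1alpha phosphorylates S45 when colocalized via Axin
    rules.append(RuleSpec(
        name="phos_S45", kind="state_change", arrow=7,
        rate=RateLaw("first_order", param="kp_bcat"),
        patterns=(Pattern((
            mol_pat("BCAT", S45=("u", WILD)),
            mol_pat("CK1A", ax=(ANY, 1)),
            mol_pat("AXIN", ck1=(ANY, 1)),
        )),),
        state_target=(0, "S45", "p"),
    ))
    # arrow 8: GSK-3beta phosphorylates S33/37 after S45 priming
    if not cell.s33_37_mutant:
        rules.append(RuleSpec(
            name="phos_S33_37", kind="state_change", arrow=8,
            rate=RateLaw("first_order", param="kp_bcat", gsk_mediated=True),
            patterns=(Pattern((
                mol_pat("BCAT", S45=("p", WILD), S33_37=("u", WILD)),
                mol_pat("GSK3B", ax=(ANY, 1)),
                mol_pat("AXIN", gid=(ANY, 1)),
            )),),
            state_target=(0, "S33_37", "p"),
        ))
    # context-free first-order dephosphorylation of beta-catenin
    rules.append(RuleSpec(
        name="dephos_S45", kind="state_change",
        rate=RateLaw("first_order", param="kdp_bcat"),
        patterns=(Pattern((mol_pat("BCAT", S45=("p", WILD)),)),),
        state_target=(0, "S45", "u"),
    ))
    rules.append(RuleSpec(
        name="dephos_S33_37", kind="state_change",
        rate=RateLaw("first_order", param="kdp_bcat"),
        patterns=(Pattern((mol_pat("BCAT", S33_37=("p", WILD)),)),),
        state_target=(0, "S33_37", "u"),
    ))

    # synthesis (zeroth order) and degradation (slow/fast, bound or free)
    rules.append(RuleSpec(
        name="syn_bcat", kind="synthesize",
        rate=RateLaw("zeroth"),
        product=free_bcat(),
    ))
    rules.append(RuleSpec(
        name="deg_slow", kind="degrade",
        rate=RateLaw("first_order", param="kdeg_slow"),
        patterns=(Pattern((mol_pat("BCAT", S33_37=("u", WILD)),)),),
    ))
    rules.append(RuleSpec(
        name="deg_fast", kind="degrade",
        rate=RateLaw("first_order", param="kdeg_fast"),
        patterns=(Pattern((mol_pat("BCAT", S33_37=("p", WILD)),)),),
    ))
    return rules


# ---------------------------------------------------------------------------
# seed species
# ---------------------------------------------------------------------------


def free_bcat() -> SpeciesGraph:
    return SpeciesGraph([("BCAT", {"arm34": None, "arm59": None, "S45": "u", "S33_37": "u"})])


def free_species(tdef: MoleculeTypeDef) -> SpeciesGraph:
    states = {s.name: (s.state_labels[0] if s.state_labels else None) for s in tdef.sites}
    return SpeciesGraph([(tdef.name, states)])


def seed_species(cell: CellModel) -> list[tuple[SpeciesGraph, float]]:
    """Seed species with initial concentrations (nM).

    All proteins start free and unmodified; beta-catenin starts at zero and
    is built up by synthesis (the steady state is initialization-
    independent, which the test suite probes).
    """
    p = cell.params
    seeds = [(free_bcat(), 0.0)]
    for spec in cell.apc_types():
        seeds.append((free_species(spec.molecule_type()), spec.amount_nM))
    seeds.append((free_species(AXIN_TYPE), p.AXIN_tot))
    seeds.append((free_species(GSK_TYPE), p.GSK_tot))
    seeds.append((free_species(CK1A_TYPE), p.CK1A_tot))
    return seeds
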