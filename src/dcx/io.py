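"""Configuration documents, result tables and model export.

Config files are JSON with two blocks: ``parameters`` (RateParameters
overrides, including the per-interaction association-rate keys) and
``scenario`` (background, transfections, ablations, kinase-inhibition
fold, mutant flag), plus optional ``caps``, ``tolerances`` and ``seed``.
Unknown keys are rejected by name so typos cannot silently revert to
defaults.

The model exporter renders a scenario's molecule types, seed species,
parameters and rules in a BNGL-flavoured text dialect.  Intracomplex
binding channels are not separate rules here (the engine derives them
structurally), so each binding rule is annotated with its tethered-rate
variant; a machine-readable annotation line per rule makes the export
round-trippable, which the test suite uses to check exporter/parser
agreement.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .graphs import ANY, BOUND, UNBOUND, WILD, Pattern, SpeciesGraph
from .model import (
    CellModel,
    build_molecule_types,
    build_rule_set,
    make_cell_model,
    seed_species,
)
from .params import ARROW_KF_KEYS, RateParameters, default_parameters
from .rules import RuleSpec

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {"background", "transfections", "ablations", "licl_fold",
                  "s33_37_mutant", "apc_e_mode"}
_TOP_KEYS = {"parameters", "scenario", "caps", "tolerances", "seed"}


@dataclass
class ConfigDocument:
    parameters: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    caps: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)
    seed: int = 0

    def rate_parameters(self) -> RateParameters:
        base = default_parameters()
        plain = {k: v for k, v in self.parameters.items() if k not in ARROW_KF_KEYS}
        overrides = {k: v for k, v in self.parameters.items() if k in ARROW_KF_KEYS}
        p = base.replace(**plain) if plain else base
        return p.with_overrides(**overrides) if overrides else p

    def cell_model(self) -> CellModel:
        sc = dict(self.scenario)
        kwargs = {}
        if "licl_fold" in sc:
            kwargs["gsk_inhibition_fold"] = float(sc["licl_fold"])
        if "s33_37_mutant" in sc:
            kwargs["s33_37_mutant"] = bool(sc["s33_37_mutant"])
        if "apc_e_mode" in sc:
            kwargs["apc_e_mode"] = sc["apc_e_mode"]
        if self.caps:
            kwargs["caps_override"] = tuple(sorted(self.caps.items()))
        return make_cell_model(
            sc.get("background", "normal"),
            [(t["class"], t["dose_nM"]) for t in sc.get("transfections", [])],
            ablations=sc.get("ablations", []),
            params=self.rate_parameters(),
            **kwargs,
        )

    def digest(self) -> str:
        blob = json.dumps(
            {"parameters": self.parameters, "scenario": self.scenario,
             "caps": self.caps, "tolerances": self.tolerances, "seed": self.seed},
            sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class ConfigError(ValueError):
    pass


def load_config(path) -> ConfigDocument:
    """Load and validate a JSON config document (unknown keys rejected)."""
    raw = json.loads(Path(path).read_text())
    return validate_config(raw)


def validate_config(raw: dict) -> ConfigDocument:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    params = raw.get("parameters", {})
    valid_params = set(RateParameters().numeric_fields()) | set(ARROW_KF_KEYS)
    bad = set(params) - valid_params
    if bad:
        raise ConfigError(f"unknown parameter key(s): parameters.{sorted(bad)}")
    for k, v in params.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"parameters.{k} must be a number, got {v!r}")
    scenario = raw.get("scenario", {})
    bad = set(scenario) - _SCENARIO_KEYS
    if bad:
        raise ConfigError(f"unknown scenario key(s): scenario.{sorted(bad)}")
    for t in scenario.get("transfections", []):
        if set(t) != {"class", "dose_nM"}:
            raise ConfigError(
                f"transfection entries need exactly 'class' and 'dose_nM': {t}")
    doc = ConfigDocument(
        parameters=dict(params), scenario=dict(scenario),
        caps=dict(raw.get("caps", {})), tolerances=dict(raw.get("tolerances", {})),
        seed=int(raw.get("seed", 0)),
    )
    doc.cell_model()   # validates classes / backgrounds / interfaces eagerly
    return doc


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_COLUMNS = ("experiment", "condition", "observable", "value", "units")


@dataclass
class ResultTable:
    records: list[dict] = field(default_factory=list)
    config_digest: str = ""
    provenance: dict = field(default_factory=dict)

    def add(self, experiment: str, condition: str, observable: str,
            value: float, units: str) -> None:
        self.records.append(dict(experiment=experiment, condition=condition,
                                 observable=observable, value=float(value),
                                 units=units))


def write_results(table: ResultTable, path) -> Path:
    """Write a CSV (stable column order) plus a JSON sidecar with
    provenance; identical inputs give byte-identical files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# dcx {_pkg_version()} config={table.config_digest}\n")
        writer = csv.DictWriter(fh, fieldnames=_COLUMNS)
        writer.writeheader()
        for rec in table.records:
            out = dict(rec)
            out["value"] = repr(rec["value"])
            writer.writerow(out)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"version": _pkg_version(), "config_digest": table.config_digest,
         "provenance": table.provenance, "records": table.records},
        sort_keys=True, indent=1) + "\n")
    return path


def read_results(path) -> ResultTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        digest = header.split("config=")[-1] if "config=" in header else ""
        reader = csv.DictReader(fh)
        records = []
        for row in reader:
            row["value"] = float(row["value"])
            records.append(row)
    return ResultTable(records=records, config_digest=digest)


def _pkg_version() -> str:
    from . import __version__
    return __version__


# ---------------------------------------------------------------------------
# species / pattern serialization (BNGL-flavoured)
# ---------------------------------------------------------------------------


def species_to_str(g: SpeciesGraph) -> str:
    return g.canonical()


def parse_species(text: str) -> SpeciesGraph:
    """Parse ``TYPE(site~state!1,...).TYPE(...)`` back into a species."""
    mols = []
    half_bonds: dict[str, tuple[int, str]] = {}
    bonds = []
    for mi, mol_txt in enumerate(text.strip().split(".")):
        name, _, rest = mol_txt.partition("(")
        if not rest.endswith(")"):
            raise ValueError(f"malformed molecule {mol_txt!r}")
        states: dict[str, str | None] = {}
        body = rest[:-1]
        for tok in filter(None, (t.strip() for t in body.split(","))):
            site = tok
            state = None
            bond_tag = None
            if "!" in site:
                site, bond_tag = site.split("!", 1)
            if "~" in site:
                site, state = site.split("~", 1)
            states[site] = state
            if bond_tag is not None:
                if bond_tag in half_bonds:
                    bonds.append((half_bonds.pop(bond_tag), (mi, site)))
                else:
                    half_bonds[bond_tag] = (mi, site)
        mols.append((name, states))
    if half_bonds:
        raise ValueError(f"dangling bond label(s): {sorted(half_bonds)}")
    return SpeciesGraph(mols, bonds)


_BOND_TO_TXT = {UNBOUND: "", BOUND: "!+", WILD: "!?"}


def pattern_to_str(p: Pattern) -> str:
    parts = []
    for mp in p.molecules:
        toks = []
        for site, sp in mp.sites:
            tok = site
            if sp.state != ANY:
                tok += f"~{sp.state}"
            tok += f"!{sp.bond}" if isinstance(sp.bond, int) else _BOND_TO_TXT[sp.bond]
            toks.append(tok)
        parts.append(f"{mp.type_name}({','.join(toks)})")
    return ".".join(parts)


def parse_pattern(text: str) -> Pattern:
    spec = []
    for mol_txt in text.strip().split("."):
        name, _, rest = mol_txt.partition("(")
        body = rest[:-1]
        sites: dict[str, tuple] = {}
        for tok in filter(None, (t.strip() for t in body.split(","))):
            site = tok
            state: str = ANY
            bond: str | int = UNBOUND
            if "!" in site:
                site, tag = site.split("!", 1)
                bond = {"+": BOUND, "?": WILD}.get(tag, None)
                if bond is None:
                    bond = int(tag)
            if "~" in site:
                site, state = site.split("~", 1)
            sites[site] = (state, bond)
        spec.append((name, sites))
    return Pattern.parse(spec)


# ---------------------------------------------------------------------------
# model export (BNGL dialect)
# ---------------------------------------------------------------------------


def _rule_annotation(r: RuleSpec) -> dict:
    return {
        "name": r.name,
        "kind": r.kind,
        "arrow": r.arrow,
        "rate": {"kind": r.rate.kind, "param": r.rate.param,
                 "arrow_key": r.rate.arrow_key, "gsk_mediated": r.rate.gsk_mediated},
        "patterns": [pattern_to_str(p) for p in r.patterns],
        "bind_sites": r.bind_sites,
        "state_target": r.state_target,
        "product": species_to_str(r.product) if r.product is not None else None,
    }


def export_bngl_dialect(cell: CellModel) -> str:
    """Render a scenario in a BNGL-flavoured, annotated text format.

    The ``#@`` lines carry a JSON annotation per rule; they make the export
    parseable back into the exact rule set (see :func:`parse_bngl_dialect`)
    and record the intracomplex rate convention (tethered forward rate =
    kf * chi, derived structurally rather than written as separate bridge
    rules).
    """
    params = cell.effective_params()
    lines = [f"# dcx model export v{_pkg_version()} (BNGL dialect)",
             "# intracomplex channel: tethered reactant sites bind at kf*chi",
             "begin parameters"]
    for name in params.numeric_fields():
        lines.append(f"  {name} {getattr(params, name)!r}")
    for key, val in params.kf_overrides:
        lines.append(f"  {key} {val!r}")
    lines.append("end parameters")

    lines.append("begin molecule types")
    for t in build_molecule_types(cell):
        toks = [s.name + "".join(f"~{l}" for l in s.state_labels) for s in t.sites]
        lines.append(f"  {t.name}({','.join(toks)})")
    lines.append("end molecule types")

    lines.append("begin seed species")
    for g, conc in seed_species(cell):
        lines.append(f"  {species_to_str(g)} {conc!r}")
    lines.append("end seed species")

    lines.append("begin reaction rules")
    for r in build_rule_set(cell):
        if r.kind == "bind":
            (ma, sa), (mb, sb) = r.bind_sites
            human = (f"{pattern_to_str(r.patterns[0])} + "
                     f"{pattern_to_str(r.patterns[1])} -> bond({sa}!{sb})")
        elif r.kind == "unbind":
            human = f"{pattern_to_str(r.patterns[0])} -> break bond"
        elif r.kind == "state_change":
            _mi, site, new = r.state_target
            human = f"{pattern_to_str(r.patterns[0])} -> {site}~{new}"
        elif r.kind == "synthesize":
            human = f"0 -> {species_to_str(r.product)}"
        else:
            human = f"{pattern_to_str(r.patterns[0])} -> deletion + release"
        lines.append(f"  {r.name}: {human}")
        lines.append(f"  #@ {json.dumps(_rule_annotation(r), sort_keys=True)}")
    lines.append("end reaction rules")
    return "\n".join(lines) + "\n"


def parse_bngl_dialect(text: str) -> list[dict]:
    """Recover the rule annotations from an export (round-trip check)."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#@ "):
            ann = json.loads(line[3:])
            # JSON turns tuples into lists; normalize for comparison
            if ann["bind_sites"] is not None:
                ann["bind_sites"] = tuple(tuple(x) for x in ann["bind_sites"])
            if ann["state_target"] is not None:
                ann["state_target"] = tuple(ann["state_target"])
            out.append(ann)
    return out


def rule_set_summary(rules: list[RuleSpec]) -> list[dict]:
    """Canonical summaries of a rule list, comparable to a parsed export."""
    return [_rule_annotation(r) for r in rules]
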