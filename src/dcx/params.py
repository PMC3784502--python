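"""Rate constants, dissociation constants and protein totals for the model.

All binding interactions share one intrinsic association rate constant
``kf`` (per nM per s); each dissociation rate constant is ``kf * KD`` for
the interaction's equilibrium dissociation constant ``KD`` (nM).
Intracomplex (tethered) binding multiplies the forward rate by the
enhancement factor ``chi`` (nM), which plays the role of an effective local
concentration, giving a first-order closure rate ``kf * chi``.

Parameters marked *provisional* below are not pinned by direct measurements;
they are set by behavioural calibration (see :mod:`dcx.calibrate`) against
the steady-state beta-catenin level, the wild-type and S33/S37-mutant
half-lives, and the phospho-pool decay anchor.  The values stored here are
the calibrated defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator

from .units import CELL_VOLUME_L, molec_per_s_to_nm_per_s

#: interaction keys for per-arrow association-rate overrides.  Setting one of
#: these to 0.0 ablates the corresponding interface (the dissociation rate,
#: being a separate constant ``kf * KD``, is left untouched).
ARROW_KF_KEYS = ("kf1_bap", "kf2_bap", "kf_ba", "kf_apa", "kf_ga", "kf_ca")

#: protein-protein interface labels accepted for ablation experiments,
#: mapped to the association-rate key they zero.
INTERFACE_TO_KF = {
    "bcat_apc_15aa": "kf1_bap",
    "bcat_axin": "kf_ba",
    "apc_axin": "kf_apa",
}


@dataclass(frozen=True)
class RateParameters:
    """Every rate constant, dissociation constant and total of the model."""

    # association rate constant shared by all binding reactions, /nM/s
    kf: float = 1e-3
    # intracomplex enhancement factor (effective local concentration), nM
    chi: float = 1e4

    # equilibrium dissociation constants, nM
    KD1_bap: float = 273.0        # beta-catenin ARM 5-9 <-> APC 15-aa region
    KD2_bap_full: float = 0.27    # ARM 3-4 <-> phospho third 20-aa repeat (full APC)
    KD2_bap_1338: float = 80.0    # ARM 3-4 <-> phospho first 20-aa repeat (APC1338)
    KD_ba: float = 500.0          # ARM 3-4 <-> Axin central region (calibrated)
    KD_apa: float = 100.0         # APC SAMP repeats <-> Axin RGS domain
    KD_ga: float = 100.0          # GSK-3beta <-> Axin GID domain
    KD_ca: float = 100.0          # CK1alpha <-> Axin

    # phosphorylation / dephosphorylation rate constants, /s
    kp_bcat: float = 0.064132459  # beta-catenin S45 and S33/S37 (calibrated)
    kdp_bcat: float = 7.83336e-4  # beta-catenin, both sites (calibrated anchor)
    kp_apc: float = 0.03          # APC 20-aa repeat (provisional; = kdp_apc)
    kdp_apc: float = 0.03         # APC 20-aa repeat, Axin-complex-restricted

    # beta-catenin synthesis and degradation
    kdeg_slow: float = math.log(2.0) / 16200.0  # 4.5 h half-life, /s
    kdeg_fast: float = 2.0e-3                   # S33/S37-phosphorylated, /s (calibrated)
    ksyn_molec: float = 4.0                     # molecules per second

    # cytoplasmic volume, litres
    volume: float = CELL_VOLUME_L

    # total protein concentrations, nM
    BCAT_tot: float = 35.0
    APC_tot: float = 100.0
    AXIN_tot: float = 10.0
    GSK_tot: float = 100.0
    CK1A_tot: float = 100.0

    # per-interaction association-rate overrides (None -> use global kf)
    kf_overrides: tuple = field(default_factory=tuple)

    @property
    def ksyn(self) -> float:
        """Zeroth-order beta-catenin synthesis rate, nM/s."""
        return molec_per_s_to_nm_per_s(self.ksyn_molec, self.volume)

    def forward_kf(self, arrow_key: str | None) -> float:
        """Association rate constant for an interaction, honouring overrides."""
        if arrow_key is not None:
            for key, value in self.kf_overrides:
                if key == arrow_key:
                    return value
        return self.kf

    def with_overrides(self, **kf_values: float) -> "RateParameters":
        """Return a copy with per-interaction association-rate overrides set."""
        unknown = set(kf_values) - set(ARROW_KF_KEYS)
        if unknown:
            raise KeyError(f"unknown interaction key(s): {sorted(unknown)}")
        merged = dict(self.kf_overrides)
        merged.update(kf_values)
        return replace(self, kf_overrides=tuple(sorted(merged.items())))

    def replace(self, **changes) -> "RateParameters":
        return replace(self, **changes)

    def numeric_fields(self) -> Iterator[str]:
        """Names of the scalar numeric parameters (for sensitivity scans)."""
        for f in fields(self):
            if f.name != "kf_overrides":
                yield f.name

    def validate(self) -> None:
        for name in self.numeric_fields():
            value = getattr(self, name)
            if not (value >= 0.0) or not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")


#: parameters whose values come from behavioural calibration rather than a
#: direct literature number.
PROVISIONAL = frozenset(
    {"kf", "chi", "KD2_bap_full", "KD_ba", "KD_apa", "KD_ga", "KD_ca",
     "kp_bcat", "kdp_bcat", "kp_apc", "kdp_apc", "kdeg_fast"}
)


def default_parameters() -> RateParameters:
    """The default (calibrated) parameter set.

    Literature-pinned entries: ``KD1_bap`` = 273 nM, ``KD2_bap_1338`` = 80 nM,
    the five protein totals, the synthesis rate of 4.0 molecules/s, the
    cytoplasmic volume, and the two first-order anchors ``kdeg_slow`` =
    ln2 / 4.5 h and the ~10-minute phospho-turnover that pins ``kdp_bcat``
    near ln2 / 600 s.  Entries in :data:`PROVISIONAL` carry calibrated
    defaults and are the natural free set for re-calibration.
    """
    p = RateParameters()
    p.validate()
    return p
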