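"""Analyte panel, molecular constants and unit conversions.

The pipeline quantifies 16 serum analytes: eight apolipoproteins
(A-I, A-II, A-IV, B-100, C-I, C-II, C-III, E), three non-polar lipid
classes (free cholesterol FC, cholesteryl esters CE, triglycerides TG)
and five phospholipid classes (PC, SM, PE, PI, LPC).  All internal
arithmetic is carried out in canonical units — mol/L for concentrations,
nm for lengths, nm**3 for volumes — and every public table declares the
unit of each column.  This module is the single source of truth for the
panel membership, the molecular volumes entering the core/surface volume
sums and the mass/molar conversion conventions.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

#: Avogadro's number, 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23


class AnalyteClass(str, enum.Enum):
    PROTEIN = "protein"
    NONPOLAR_LIPID = "nonpolar_lipid"
    POLAR_LIPID = "polar_lipid"


class Analyte(str, enum.Enum):
    """The 16 quantified analytes."""

    APOA1 = "A-I"
    APOA2 = "A-II"
    APOA4 = "A-IV"
    APOB = "B-100"
    APOC1 = "C-I"
    APOC2 = "C-II"
    APOC3 = "C-III"
    APOE = "E"
    FC = "FC"
    CE = "CE"
    TG = "TG"
    PC = "PC"
    SM = "SM"
    PE = "PE"
    PI = "PI"
    LPC = "LPC"

    def __str__(self) -> str:  # keeps table output compact
        return self.value

    @property
    def analyte_class(self) -> AnalyteClass:
        if self in PROTEINS:
            return AnalyteClass.PROTEIN
        if self in NONPOLAR_LIPIDS:
            return AnalyteClass.NONPOLAR_LIPID
        return AnalyteClass.POLAR_LIPID


PROTEINS = (
    Analyte.APOA1,
    Analyte.APOA2,
    Analyte.APOA4,
    Analyte.APOB,
    Analyte.APOC1,
    Analyte.APOC2,
    Analyte.APOC3,
    Analyte.APOE,
)
NONPOLAR_LIPIDS = (Analyte.FC, Analyte.CE, Analyte.TG)
POLAR_LIPIDS = (Analyte.PC, Analyte.SM, Analyte.PE, Analyte.PI, Analyte.LPC)
ALL_ANALYTES = PROTEINS + NONPOLAR_LIPIDS + POLAR_LIPIDS

#: Mature-chain apolipoprotein molecular weights, kDa.  The values come
#: from the canonical processed sequences; apoA-II is counted per monomer
#: (the circulating disulfide homodimer contributes two monomers to the
#: molar concentration as quantified by tryptic-peptide LC-MS/MS).
DEFAULT_PROTEIN_MW_KDA: dict[Analyte, float] = {
    Analyte.APOA1: 28.1,
    Analyte.APOA2: 8.7,
    Analyte.APOA4: 43.4,
    Analyte.APOB: 512.7,
    Analyte.APOC1: 6.6,
    Analyte.APOC2: 8.9,
    Analyte.APOC3: 8.8,
    Analyte.APOE: 34.2,
}

#: Average molecular weights (g/mol) used to convert mg/dL lipid panels
#: to molar units.  FC and CE use the cholesterol moiety mass so that
#: Total-C = CE + FC closes in mg/dL (cholesterol-equivalent reporting,
#: the clinical convention); TG uses the standard clinical average
#: (factor 0.01129 mmol/L per mg/dL).
DEFAULT_LIPID_MW_G_MOL: dict[Analyte, float] = {
    Analyte.FC: 386.65,
    Analyte.CE: 386.65,
    Analyte.TG: 885.7,
}


class UnitError(ValueError):
    """Raised for invalid unit conversions or non-physical inputs."""


@dataclass(frozen=True)
class VolumetricConstants:
    """Molecular volumes and hydration parameters of the particle model.

    Parameters
    ----------
    v_fc, v_ce, v_tg, v_pl
        Partial molecular volumes in nm**3/molecule of free cholesterol,
        cholesteryl esters, triglycerides and phospholipids (class
        averages).
    v_protein_specific
        Protein partial specific volume, nm**3 per kDa of chain mass.
    n_hydration_layers, hydration_thickness_nm
        Number and thickness (nm) of bound water layers subtracted from
        the hydrodynamic diameter to obtain the dehydrated diameter.
    fc_partition_kappa
        Surface/core partitioning coefficient of free cholesterol
        between the polar and non-polar lipid phases.
    """

    v_fc: float = 0.610
    v_ce: float = 1.179
    v_tg: float = 1.575
    v_pl: float = 1.307
    v_protein_specific: float = 1.212
    n_hydration_layers: int = 1
    hydration_thickness_nm: float = 0.3
    fc_partition_kappa: float = 5.0
    avogadro: float = AVOGADRO
    protein_mw_kda: Mapping[Analyte, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_MW_KDA)
    )
    lipid_mw_g_mol: Mapping[Analyte, float] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_MW_G_MOL)
    )

    def __post_init__(self) -> None:
        for name in ("v_fc", "v_ce", "v_tg", "v_pl", "v_protein_specific"):
            if getattr(self, name) <= 0:
                raise UnitError(f"{name} must be positive")
        if self.fc_partition_kappa < 0:
            raise UnitError("fc_partition_kappa must be non-negative")

    @property
    def hydration_shell_nm(self) -> float:
        """Total diameter reduction 2*n*w_h, nm."""
        return 2.0 * self.n_hydration_layers * self.hydration_thickness_nm

    def with_overrides(self, **kwargs) -> "VolumetricConstants":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "VolumetricConstants":
        """Load constant overrides from a JSON or YAML config file.

        Keys mirror the field names; ``protein_mw_kda`` / ``lipid_mw_g_mol``
        entries are keyed by analyte id and merged over the defaults.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = data or {}
        kwargs: dict = {}
        for key, value in data.items():
            if key == "protein_mw_kda":
                table = dict(DEFAULT_PROTEIN_MW_KDA)
                table.update({Analyte(k): float(v) for k, v in value.items()})
                kwargs[key] = table
            elif key == "lipid_mw_g_mol":
                table = dict(DEFAULT_LIPID_MW_G_MOL)
                table.update({Analyte(k): float(v) for k, v in value.items()})
                kwargs[key] = table
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class ShapeModel:
    """Particle shape used for the dehydrated particle volume.

    ``sphere`` is the default; ``ellipsoid`` models discoidal particles as
    an oblate spheroid with short axis d_a = k * d_dehydrated and the two
    long axes equal to the dehydrated diameter, so the volume (and hence
    every per-particle stoichiometry) scales by exactly k.
    """

    kind: str = "sphere"
    axial_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "ellipsoid"):
            raise UnitError(f"unknown shape kind {self.kind!r}")
        if not (0.0 < self.axial_ratio <= 1.0):
            raise UnitError("axial_ratio must be in (0, 1]")
        if self.kind == "sphere" and self.axial_ratio != 1.0:
            raise UnitError("sphere implies axial_ratio == 1")


def protein_molecular_volume(mw_kda: float, constants: VolumetricConstants) -> float:
    """Molecular volume of a protein in nm**3 from its chain mass in kDa."""
    if mw_kda <= 0:
        raise UnitError(f"molecular weight must be positive, got {mw_kda}")
    return mw_kda * constants.v_protein_specific


def lipid_mass_to_molar(conc_mg_dl: float, mw_g_mol: float) -> float:
    """Convert a lipid concentration from mg/dL to µM.

    µM = mg/dL * 10000 / MW  (mg/dL → mg/L ×10; mg/L → mmol/L ÷MW; ×1000).
    """
    if mw_g_mol <= 0:
        raise UnitError(f"molecular weight must be positive, got {mw_g_mol}")
    if conc_mg_dl < 0:
        raise UnitError(f"concentration must be non-negative, got {conc_mg_dl}")
    return conc_mg_dl * 10000.0 / mw_g_mol


def lipid_molar_to_mass(conc_um: float, mw_g_mol: float) -> float:
    """Inverse of :func:`lipid_mass_to_molar` (µM → mg/dL)."""
    if mw_g_mol <= 0:
        raise UnitError(f"molecular weight must be positive, got {mw_g_mol}")
    return conc_um * mw_g_mol / 10000.0


_UNIT_TO_MOLAR = {
    "mol/L": 1.0,
    "mmol/L": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "umol/L": 1e-6,
    "nM": 1e-9,
    "nmol/L": 1e-9,
}


def to_mol_per_l(
    value: float,
    unit: str,
    analyte: Analyte | str | None = None,
    constants: VolumetricConstants | None = None,
) -> float:
    """Convert a declared-unit concentration to mol/L.

    mg/dL values require a lipid analyte so the class-average molecular
    weight can be looked up.
    """
    if unit in _UNIT_TO_MOLAR:
        return value * _UNIT_TO_MOLAR[unit]
    if unit == "mg/dL":
        if analyte is None:
            raise UnitError("mg/dL conversion requires the analyte identity")
        analyte = Analyte(analyte)
        constants = constants or VolumetricConstants()
        mw = constants.lipid_mw_g_mol.get(analyte)
        if mw is None:
            raise UnitError(f"no mass→molar molecular weight for {analyte}")
        return lipid_mass_to_molar(value, mw) * 1e-6
    raise UnitError(f"unknown concentration unit {unit!r}")
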