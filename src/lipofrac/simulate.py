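"""Forward simulation of AF4-fractionated serum lipoprotein datasets.

The generator inverts the volumetric model: lipoprotein species are
defined by a hydrodynamic diameter and a per-particle stoichiometry whose
total molecular volume closes exactly on the dehydrated particle volume,
then their analyte content is spread over the 40-fraction AF4 schedule by
Gaussian band broadening in diameter space, attenuated by per-analyte
channel losses, and perturbed by class-level multiplicative measurement
noise.  Whole-serum totals are computed loss-free from the species, so
every pipeline stage (recovery, particle number, stoichiometry, ratio
panels) can be checked against known ground truth.

Cohort simulation draws whole-serum totals from truncated normal
distributions with the published category-level means/SDs/ranges for the
four lipid phenotypes (NL/HC/HL/HT) and allocates them over a default
species library by non-negative least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import norm, truncnorm

from .analytes import (
    ALL_ANALYTES,
    Analyte,
    AnalyteClass,
    NONPOLAR_LIPIDS,
    POLAR_LIPIDS,
    PROTEINS,
    ShapeModel,
    UnitError,
    VolumetricConstants,
    lipid_mass_to_molar,
)
from .calibration import ElutionSchedule, QuadraticCalibration, fraction_volumes
from .volumetrics import SerumRecord, dehydrated_particle_volume

#: Default synthetic fraction→size calibration: monotone quadratic placing
#: albumin-size material (~7 nm) near fraction 6, the HDL range (7–13 nm)
#: in ~12 fractions, the LDL range (18–30 nm) in ~12 fractions and the
#: purge fractions above 30 nm — mirroring a typical serum run.
DEFAULT_CALIBRATION = QuadraticCalibration(
    c0=5.188,
    c1=0.30022,
    c2=0.011752,
    batch_id="synthetic-default",
    n_points=40,
    fraction_range=(1.0, 40.0),
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesSpec:
    """One lipoprotein species: diameter, stoichiometry, abundance.

    ``stoichiometry`` maps analytes to molecules per particle and is
    volume-consistent: the summed molecular volume equals the dehydrated
    particle volume implied by the hydrodynamic diameter (within 1%,
    enforced by :func:`build_species`).
    """

    name: str
    hydrodynamic_diameter_nm: float
    stoichiometry: Mapping[Analyte, float]
    particle_conc_mol_l: float = 0.0
    broadening_sigma_nm: float = 0.75

    def total_volume_nm3(self, constants: VolumetricConstants) -> float:
        """Summed molecular volume of one particle, nm³."""
        vol = 0.0
        per_molecule = {
            Analyte.FC: constants.v_fc,
            Analyte.CE: constants.v_ce,
            Analyte.TG: constants.v_tg,
        }
        for analyte, count in self.stoichiometry.items():
            analyte = Analyte(analyte)
            if analyte in PROTEINS:
                vol += count * constants.protein_mw_kda[analyte] * constants.v_protein_specific
            elif analyte in POLAR_LIPIDS:
                vol += count * constants.v_pl
            else:
                vol += count * per_molecule[analyte]
        return vol

    def with_abundance(self, particle_conc_mol_l: float) -> "SpeciesSpec":
        return replace(self, particle_conc_mol_l=particle_conc_mol_l)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise and channel-loss model.

    CVs are relative (lognormal multiplicative noise, unit mean) by
    analyte class, reflecting the inter-day reproducibility of the three
    LC-MS/MS assays (non-polar lipids ~9%, phospholipid classes ~8%,
    proteins ~18% with apoE at 25%).  Channel losses are the per-analyte
    fraction of injected material recovered across the AF4 fractions;
    TG recovers worst because large TG-rich particles are lost during
    injection/focusing.
    """

    cv_nonpolar: float = 0.09
    cv_polar: float = 0.08
    cv_protein: float = 0.18
    cv_overrides: Mapping[Analyte, float] = field(
        default_factory=lambda: {Analyte.APOE: 0.25}
    )
    channel_loss: Mapping[Analyte, float] = field(
        default_factory=lambda: {
            Analyte.APOA1: 0.52,
            Analyte.APOB: 0.46,
            Analyte.PC: 0.72,
            Analyte.FC: 0.66,
            Analyte.CE: 0.66,
            Analyte.TG: 0.33,
        }
    )
    default_loss: float = 0.55
    enabled: bool = True

    def __post_init__(self) -> None:
        for cv in (self.cv_nonpolar, self.cv_polar, self.cv_protein):
            if cv < 0:
                raise UnitError("CVs must be non-negative")
        for analyte, loss in self.channel_loss.items():
            if not (0.0 < loss <= 1.0):
                raise UnitError(f"channel loss for {analyte} must be in (0, 1]")

    def cv_for(self, analyte: Analyte) -> float:
        if not self.enabled:
            return 0.0
        if analyte in self.cv_overrides:
            return self.cv_overrides[analyte]
        cls = analyte.analyte_class
        if cls is AnalyteClass.PROTEIN:
            return self.cv_protein
        if cls is AnalyteClass.NONPOLAR_LIPID:
            return self.cv_nonpolar
        return self.cv_polar

    def loss_for(self, analyte: Analyte) -> float:
        return self.channel_loss.get(analyte, self.default_loss)

    @classmethod
    def noiseless(cls, lossless: bool = False) -> "NoiseModel":
        if lossless:
            return cls(enabled=False, channel_loss={}, default_loss=1.0)
        return cls(enabled=False)


def build_species(
    name: str,
    diameter_nm: float,
    protein_counts: Mapping[Analyte, float],
    lipid_class_fractions: Mapping[Analyte, float],
    constants: VolumetricConstants = VolumetricConstants(),
    shape: ShapeModel = ShapeModel(),
    broadening_sigma_nm: float = 0.75,
) -> SpeciesSpec:
    """Construct a volume-consistent species from composition templates.

    Protein copy numbers are taken as given; lipid counts are scaled so
    that the summed molecular volume exactly equals the dehydrated
    particle volume implied by the hydrodynamic diameter (which makes
    generator→pipeline particle-number round trips exact by
    construction).  ``lipid_class_fractions`` are relative mole fractions
    over {FC, CE, TG, PC, SM, PE, PI, LPC}.
    """
    if diameter_nm <= constants.hydration_shell_nm:
        raise SimulationError("diameter must exceed the hydration shell")
    target = dehydrated_particle_volume(diameter_nm, constants, shape)
    per_molecule = {
        Analyte.FC: constants.v_fc,
        Analyte.CE: constants.v_ce,
        Analyte.TG: constants.v_tg,
        **{a: constants.v_pl for a in POLAR_LIPIDS},
    }
    protein_vol = sum(
        count * constants.protein_mw_kda[Analyte(a)] * constants.v_protein_specific
        for a, count in protein_counts.items()
    )
    budget = target - protein_vol
    if budget <= 0:
        raise SimulationError(
            f"protein volume {protein_vol:.1f} nm³ exceeds the {target:.1f} nm³ "
            f"particle volume of {name}"
        )
    fracs = {Analyte(a): float(v) for a, v in lipid_class_fractions.items() if v > 0}
    if not fracs:
        raise SimulationError("at least one lipid class fraction must be positive")
    unit_volume = sum(frac * per_molecule[a] for a, frac in fracs.items())
    scale = budget / unit_volume
    stoich: dict[Analyte, float] = {
        Analyte(a): float(c) for a, c in protein_counts.items() if c > 0
    }
    stoich.update({a: scale * frac for a, frac in fracs.items()})
    species = SpeciesSpec(
        name=name,
        hydrodynamic_diameter_nm=diameter_nm,
        stoichiometry=stoich,
        broadening_sigma_nm=broadening_sigma_nm,
    )
    closure = species.total_volume_nm3(constants) / target
    if abs(closure - 1.0) > 0.01:
        raise SimulationError(f"volume closure failed for {name}: {closure:.4f}")
    return species


# --- default species library ------------------------------------------------

#: Lipid-moiety mole-fraction templates (FC, CE, TG, total PL).  The
#: CE-rich / TG-rich variants at each size bracket the composition space
#: so the abundance fit can match a sample's non-polar lipid profile;
#: values follow classical compositional analyses of density-isolated
#: lipoprotein classes (e.g. LDL ≈ 600 FC / 1600 CE / 170 TG / 700 PL
#: molecules per particle).
_LIPID_TEMPLATES: dict[str, tuple[float, float, float, float]] = {
    "SMALL": (0.05, 0.02, 0.01, 0.92),  # albumin-size lipid carriers
    "HDL": (0.09, 0.25, 0.03, 0.63),
    "HDL_CE": (0.11, 0.35, 0.02, 0.52),
    "HDL_TG": (0.07, 0.12, 0.15, 0.66),
    "LPE": (0.11, 0.30, 0.08, 0.51),
    "LDL": (0.19, 0.50, 0.05, 0.26),
    "LDL_CE": (0.20, 0.58, 0.02, 0.20),
    "LDL_TG": (0.14, 0.30, 0.30, 0.26),
    "VLDL": (0.08, 0.10, 0.55, 0.27),
}

#: Extra LPC weighting of the small albumin-like carrier (LPC rides
#: albumin rather than lipoprotein surfaces).
_LPC_BIAS: dict[str, float] = {"SMALL": 2.5}

#: (name, hydrodynamic diameter nm, protein copies, lipid template).
#: apoB-bearing species carry exactly one apoB-100.
_DEFAULT_LIBRARY_SPEC: tuple[tuple[str, float, dict, str], ...] = (
    ("alb_7", 6.8, {}, "SMALL"),
    ("hdl_8_ce", 8.0, {"A-I": 2, "A-II": 2}, "HDL_CE"),
    ("hdl_8", 8.0, {"A-I": 2, "A-II": 2}, "HDL"),
    ("hdl_85", 8.6, {"A-I": 3, "A-II": 1}, "HDL"),
    ("hdl_9", 9.0, {"A-I": 2, "A-II": 3}, "HDL"),
    ("hdl_9_a4", 9.5, {"A-IV": 2}, "HDL"),
    ("hdl_10_ce", 10.0, {"A-I": 3, "A-II": 2}, "HDL_CE"),
    ("hdl_10", 10.0, {"A-I": 3, "A-II": 3}, "HDL"),
    ("hdl_10_tg", 10.0, {"A-I": 3, "A-II": 3}, "HDL_TG"),
    ("hdl_11", 11.0, {"A-I": 3, "A-II": 3, "C-I": 1}, "HDL"),
    ("hdl_12_ce", 12.0, {"A-I": 4, "A-II": 3, "C-I": 2, "C-III": 1}, "HDL_CE"),
    ("hdl_12", 12.0, {"A-I": 4, "A-II": 3, "C-I": 2, "C-III": 1}, "HDL"),
    ("hdl_13", 13.0, {"A-I": 4, "A-II": 2, "C-I": 2, "C-II": 1, "C-III": 2},
     "HDL"),
    ("lpe_14", 14.0, {"A-I": 2, "A-II": 2, "E": 0.5, "C-I": 2, "C-II": 1,
                      "C-III": 2}, "LPE"),
    ("lpe_16", 16.0, {"E": 1, "C-I": 3, "C-II": 2, "C-III": 4}, "LPE"),
    ("lpe_17_tg", 17.0, {"E": 1, "C-I": 2, "C-II": 2, "C-III": 4}, "LDL_TG"),
    ("ldl_20", 20.0, {"B-100": 1}, "LDL"),
    ("ldl_22_ce", 22.0, {"B-100": 1, "C-III": 1}, "LDL_CE"),
    ("ldl_22", 22.0, {"B-100": 1, "C-III": 1}, "LDL"),
    ("ldl_22_tg", 22.0, {"B-100": 1, "C-II": 1, "C-III": 2}, "LDL_TG"),
    ("ldl_24_ce", 24.0, {"B-100": 1, "C-I": 1, "C-III": 2}, "LDL_CE"),
    ("ldl_24", 24.0, {"B-100": 1, "C-I": 1, "C-III": 2}, "LDL"),
    ("ldl_26_ce", 26.0, {"B-100": 1, "C-I": 1, "C-II": 1, "C-III": 2}, "LDL_CE"),
    ("ldl_26_tg", 26.0, {"B-100": 1, "C-I": 2, "C-II": 2, "C-III": 3, "E": 0.5},
     "LDL_TG"),
    ("idl_30", 30.0, {"B-100": 1, "C-I": 2, "C-II": 1, "C-III": 3, "E": 1},
     "LDL_TG"),
    ("vldl_34", 34.0, {"B-100": 1, "C-I": 3, "C-II": 2, "C-III": 6, "E": 1.5},
     "VLDL"),
    ("vldl_36", 36.0, {"B-100": 1, "C-I": 4, "C-II": 3, "C-III": 8, "E": 2},
     "VLDL"),
)

#: Reference phospholipid class split (PC, SM, PE, PI, LPC) of normal
#: serum, used when no sample totals are supplied.
_REFERENCE_PL_SPLIT = (0.649, 0.132, 0.048, 0.017, 0.153)

#: Reference whole-serum FC/CE molar ratio (cholesterol equivalents); the
#: template FC shares are rescaled by a sample's own ratio relative to it.
_REFERENCE_FC_CE = 0.293


def default_species_library(
    constants: VolumetricConstants = VolumetricConstants(),
    broadening_sigma_nm: float = 0.75,
    serum_totals: Mapping[Analyte, float] | None = None,
) -> list[SpeciesSpec]:
    """The default particle library spanning HDL, LpE, LDL and TG-rich sizes.

    When ``serum_totals`` are given the library adapts to the sample: the
    phospholipid-class split of every species follows the sample's serum
    PL pool (surface monolayer composition tracks the circulating pool),
    and the template FC share is rescaled by the sample's FC/CE ratio.
    """
    if serum_totals is not None:
        pl = np.array([serum_totals.get(a, 0.0) for a in POLAR_LIPIDS], dtype=float)
        pl_split = pl / pl.sum() if pl.sum() > 0 else np.array(_REFERENCE_PL_SPLIT)
        ce_total = serum_totals.get(Analyte.CE, 0.0)
        fc_scale = (
            (serum_totals.get(Analyte.FC, 0.0) / ce_total) / _REFERENCE_FC_CE
            if ce_total > 0
            else 1.0
        )
        fc_scale = float(np.clip(fc_scale, 0.4, 2.5))
    else:
        pl_split = np.array(_REFERENCE_PL_SPLIT)
        fc_scale = 1.0

    library = []
    for name, d, proteins, template in _DEFAULT_LIBRARY_SPEC:
        fc, ce, tg, pl_total = _LIPID_TEMPLATES[template]
        fc_adj = min(fc * fc_scale, fc + 0.6 * ce)
        ce_adj = ce + (fc - fc_adj)  # keep the lipid moiety total fixed
        split = pl_split.copy()
        if template in _LPC_BIAS:
            split = split * np.array([1.0, 1.0, 1.0, 1.0, _LPC_BIAS[template]])
            split = split / split.sum()
        fractions = {"FC": fc_adj, "CE": ce_adj, "TG": tg}
        fractions.update(
            {str(a): pl_total * s for a, s in zip(POLAR_LIPIDS, split)}
        )
        library.append(
            build_species(name, d, proteins, fractions, constants,
                          broadening_sigma_nm=broadening_sigma_nm)
        )
    return library


def species_table(species: Sequence[SpeciesSpec]) -> pd.DataFrame:
    """Tidy ground-truth table of a species list."""
    rows = []
    for sp in species:
        row = {
            "species": sp.name,
            "diameter_nm": sp.hydrodynamic_diameter_nm,
            "particle_conc_mol_l": sp.particle_conc_mol_l,
            "broadening_sigma_nm": sp.broadening_sigma_nm,
        }
        row.update({str(a): c for a, c in sp.stoichiometry.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# --- forward simulation -----------------------------------------------------


def _broadening_weights(
    species_d: float, sigma: float, fraction_diameters: np.ndarray
) -> np.ndarray:
    """Gaussian band-broadening weights over fractions, in diameter space.

    Fractions own half-open diameter intervals with edges midway between
    consecutive fraction diameters; the terminal intervals extend to
    ±infinity, so mass from species outside the calibrated range piles
    into the end (purge) fractions and the weights always sum to one.
    ``sigma == 0`` collapses to the single nearest fraction interval.
    """
    edges = np.concatenate(
        [[-np.inf], 0.5 * (fraction_diameters[1:] + fraction_diameters[:-1]), [np.inf]]
    )
    if sigma <= 0:
        idx = int(np.searchsorted(edges, species_d, side="right") - 1)
        w = np.zeros(fraction_diameters.size)
        w[idx] = 1.0
        return w
    cdf = norm.cdf(edges, loc=species_d, scale=sigma)
    return np.diff(cdf)


@dataclass
class SimulatedSample:
    """Observed tables plus ground truth for one simulated serum sample."""

    serum: SerumRecord
    fractions: pd.DataFrame  # wide: fraction_number, volume_ml, diameter_dls_nm, analytes
    dls: pd.DataFrame  # batch_id, sample_id, fraction_number, diameter_nm, qc_flag
    truth: pd.DataFrame  # species table with abundances
    category: str | None = None


def simulate_sample_profile(
    species: Sequence[SpeciesSpec],
    calibration: QuadraticCalibration = DEFAULT_CALIBRATION,
    schedule: ElutionSchedule = ElutionSchedule(),
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | int | None = 0,
    sample_id: str = "synthetic",
    injected_volume_ml: float = 0.050,
    category: str | None = None,
) -> SimulatedSample:
    """Forward-simulate one AF4-LC-MS/MS dataset from abundant species.

    Each species' analyte amounts (stoichiometry × particle concentration,
    mol per liter of serum) are spread over fractions by Gaussian band
    broadening in diameter space; per-analyte channel losses attenuate
    the fractions uniformly; lognormal unit-mean noise is applied per
    analyte per fraction; the per-fraction DLS diameter is the
    particle-number-weighted mean species diameter.  Whole-serum totals
    are computed loss-free from the species (with their own measurement
    noise draw when noise is enabled).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    volumes = fraction_volumes(schedule)
    n_frac = volumes.size
    frac_numbers = np.arange(1, n_frac + 1)
    frac_diameters = calibration.predict(frac_numbers.astype(float))

    amount_serum = {a: np.zeros(n_frac) for a in ALL_ANALYTES}  # mol/L serum scale
    particle_weight = np.zeros(n_frac)
    diameter_weight = np.zeros(n_frac)
    for sp in species:
        if sp.particle_conc_mol_l <= 0:
            continue
        w = _broadening_weights(
            sp.hydrodynamic_diameter_nm, sp.broadening_sigma_nm, frac_diameters
        )
        particle_weight += sp.particle_conc_mol_l * w
        diameter_weight += sp.particle_conc_mol_l * w * sp.hydrodynamic_diameter_nm
        for analyte, count in sp.stoichiometry.items():
            amount_serum[Analyte(analyte)] += count * sp.particle_conc_mol_l * w

    with np.errstate(invalid="ignore"):
        dls = np.where(particle_weight > 0, diameter_weight / np.maximum(particle_weight, 1e-300), np.nan)

    frame = pd.DataFrame(
        {
            "fraction_number": frac_numbers,
            "volume_ml": volumes,
            "diameter_dls_nm": dls,
        }
    )
    totals: dict[Analyte, float] = {}
    for analyte in ALL_ANALYTES:
        total = float(np.sum([
            sp.stoichiometry.get(analyte, 0.0) * sp.particle_conc_mol_l
            for sp in species
        ]))
        loss = noise.loss_for(analyte)
        conc_fraction = amount_serum[analyte] * loss * injected_volume_ml / volumes
        cv = noise.cv_for(analyte)
        if cv > 0:
            sigma_ln = math.sqrt(math.log1p(cv**2))
            conc_fraction = conc_fraction * rng.lognormal(
                -0.5 * sigma_ln**2, sigma_ln, size=n_frac
            )
            total = total * float(rng.lognormal(-0.5 * sigma_ln**2, sigma_ln))
        frame[analyte] = conc_fraction
        totals[analyte] = total

    serum = SerumRecord(
        sample_id=sample_id,
        total_conc_mol_l=totals,
        injected_volume_ml=injected_volume_ml,
        category=category,
    )
    dls_table = pd.DataFrame(
        {
            "batch_id": calibration.batch_id or "batch-1",
            "sample_id": sample_id,
            "fraction_number": frac_numbers,
            "diameter_nm": dls,
            "qc_flag": np.where(np.isfinite(dls), "", "empty"),
        }
    )
    return SimulatedSample(
        serum=serum,
        fractions=frame,
        dls=dls_table,
        truth=species_table([sp for sp in species if sp.particle_conc_mol_l > 0]),
        category=category,
    )


# --- cohort simulation ------------------------------------------------------

#: Whole-serum analyte distributions by lipid phenotype: (mean, SD, low,
#: high).  Non-polar lipid entries are mg/dL (Total-C and Total-TG define
#: the phenotype; CE is derived as Total-C − FC in cholesterol-equivalent
#: mass); polar lipids and apolipoproteins are µM.  Values reproduce the
#: category-level summary statistics of the 110-sample serum panel the
#: generator emulates.
SERUM_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "NL": {
        "Total-C": (181, 29, 124, 217), "Total-TG": (74, 28, 33, 136),
        "FC": (41, 8, 27, 56),
        "PC": (2176, 404, 1273, 2905), "SM": (443, 89, 316, 629),
        "PE": (162, 54, 64, 275), "PI": (58, 14, 34, 91),
        "LPC": (514, 82, 370, 694),
        "A-I": (48.8, 10.5, 35.5, 75.4), "A-II": (41.8, 8.6, 25.2, 55.7),
        "A-IV": (1.88, 1.01, 0.5, 4.66), "B-100": (1.28, 0.42, 0.79, 2.5),
        "C-I": (9.45, 3.48, 2.59, 16.1), "C-II": (2.92, 1.58, 1.16, 7.86),
        "C-III": (8.22, 4.33, 3.84, 21.91), "E": (1.29, 0.46, 0.64, 2.15),
    },
    "HC": {
        "Total-C": (269, 21, 232, 311), "Total-TG": (90, 32, 50, 144),
        "FC": (52, 7, 35, 62),
        "PC": (2539, 530, 1814, 3897), "SM": (653, 75, 549, 745),
        "PE": (183, 65, 91, 291), "PI": (65, 15, 43, 92),
        "LPC": (812, 232, 507, 1362),
        "A-I": (57.7, 16.4, 33.4, 92.9), "A-II": (40.1, 10.1, 26.0, 55.9),
        "A-IV": (1.78, 0.59, 1.01, 3.18), "B-100": (1.91, 0.42, 1.14, 2.71),
        "C-I": (13.17, 3.52, 8.73, 19.97), "C-II": (4.47, 1.85, 2.61, 8.71),
        "C-III": (12.18, 5.7, 4.1, 25.87), "E": (2.06, 1.06, 0.80, 4.57),
    },
    "HL": {
        "Total-C": (280, 31, 232, 355), "Total-TG": (279, 107, 155, 573),
        "FC": (56, 9, 31, 89),
        "PC": (2884, 671, 2016, 5415), "SM": (601, 85, 412, 879),
        "PE": (341, 155, 136, 866), "PI": (90, 22, 55, 168),
        "LPC": (878, 218, 508, 1507),
        "A-I": (51.7, 13.2, 33.8, 91.7), "A-II": (43.9, 11.5, 23.5, 72.1),
        "A-IV": (2.31, 0.98, 0.92, 5.95), "B-100": (2.47, 0.6, 1.35, 3.75),
        "C-I": (14.81, 6.14, 8.67, 43.1), "C-II": (7.22, 2.61, 2.0, 17.05),
        "C-III": (19.21, 6.73, 8.68, 43.39), "E": (2.30, 0.77, 1.13, 3.97),
    },
    "HT": {
        "Total-C": (188, 23, 135, 226), "Total-TG": (268, 91, 161, 650),
        "FC": (41, 8, 20, 58),
        "PC": (2219, 344, 1666, 2912), "SM": (442, 73, 339, 602),
        "PE": (269, 82, 134, 472), "PI": (68, 10, 51, 92),
        "LPC": (645, 188, 444, 1557),
        "A-I": (43.9, 8.96, 25.7, 70.3), "A-II": (38.9, 6.9, 23.3, 51.6),
        "A-IV": (2.35, 0.87, 0.65, 4.72), "B-100": (1.69, 0.48, 1.06, 3.13),
        "C-I": (11.05, 2.05, 5.71, 14.67), "C-II": (5.43, 1.79, 1.98, 9.99),
        "C-III": (13.69, 4.41, 6.55, 27.41), "E": (1.96, 0.63, 1.04, 3.87),
    },
}


def _draw_truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    if sd <= 0:
        return float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def draw_serum_totals(
    category: str,
    rng: np.random.Generator,
    constants: VolumetricConstants = VolumetricConstants(),
) -> dict[Analyte, float]:
    """Draw one sample's whole-serum analyte totals (mol/L) for a category.

    Total-C, Total-TG and FC are drawn in mg/dL from their truncated
    normal distributions and CE is derived as Total-C − FC so the
    phenotype-defining totals follow the published distributions exactly.
    """
    params = SERUM_DISTRIBUTIONS[category]
    total_c = _draw_truncnorm(rng, *params["Total-C"])
    fc = _draw_truncnorm(rng, *params["FC"])
    fc = min(fc, 0.9 * total_c)
    tg = _draw_truncnorm(rng, *params["Total-TG"])
    ce = total_c - fc
    totals: dict[Analyte, float] = {
        Analyte.FC: lipid_mass_to_molar(fc, constants.lipid_mw_g_mol[Analyte.FC]) * 1e-6,
        Analyte.CE: lipid_mass_to_molar(ce, constants.lipid_mw_g_mol[Analyte.CE]) * 1e-6,
        Analyte.TG: lipid_mass_to_molar(tg, constants.lipid_mw_g_mol[Analyte.TG]) * 1e-6,
    }
    for analyte in list(POLAR_LIPIDS) + list(PROTEINS):
        totals[analyte] = _draw_truncnorm(rng, *params[str(analyte)]) * 1e-6
    return totals


#: Relative weights of the abundance fit: apoB (the one-per-particle
#:  anchor), Total-TG and apoA-I — the analytes that define the phenotype
#:  and the particle-number checks — are matched preferentially.
_ALLOCATION_PRIORITIES: dict[Analyte, float] = {
    Analyte.APOB: 3.0,
    Analyte.TG: 2.0,
    Analyte.APOA1: 2.0,
}
_TOTAL_C_PRIORITY = 3.0


def allocate_species(
    target_totals: Mapping[Analyte, float],
    library: Sequence[SpeciesSpec],
    priorities: Mapping[Analyte, float] | None = None,
) -> list[SpeciesSpec]:
    """Fit species abundances to whole-serum totals by non-negative least squares.

    Rows are weighted by the inverse target so relative misfit is
    balanced across analytes spanning six orders of magnitude, with
    priority factors up-weighting the phenotype-defining quantities
    (apoB, Total-TG, apoA-I and an explicit Total-C = FC + CE row).
    """
    priorities = _ALLOCATION_PRIORITIES if priorities is None else priorities
    analytes = [a for a in ALL_ANALYTES if target_totals.get(a, 0.0) > 0]
    S = np.array(
        [[sp.stoichiometry.get(a, 0.0) for sp in library] for a in analytes]
    )
    b = np.array([target_totals[a] for a in analytes])
    weights = np.array([priorities.get(a, 1.0) for a in analytes]) / b
    A = S * weights[:, None]
    rhs = b * weights
    tc_target = target_totals.get(Analyte.FC, 0.0) + target_totals.get(Analyte.CE, 0.0)
    if tc_target > 0:
        tc_row = np.array(
            [
                sp.stoichiometry.get(Analyte.FC, 0.0)
                + sp.stoichiometry.get(Analyte.CE, 0.0)
                for sp in library
            ]
        )
        A = np.vstack([A, (tc_row / tc_target * _TOTAL_C_PRIORITY)[None, :]])
        rhs = np.concatenate([rhs, [_TOTAL_C_PRIORITY]])
    x, _ = nnls(A, rhs)
    return [sp.with_abundance(float(abund)) for sp, abund in zip(library, x)]


def simulate_cohort(
    n_per_category: Mapping[str, int],
    seed: int | np.random.Generator = 0,
    constants: VolumetricConstants = VolumetricConstants(),
    library: Sequence[SpeciesSpec] | None = None,
    calibration: QuadraticCalibration = DEFAULT_CALIBRATION,
    schedule: ElutionSchedule = ElutionSchedule(),
    noise: NoiseModel = NoiseModel(),
) -> list[SimulatedSample]:
    """Simulate a multi-category cohort of AF4-LC-MS/MS datasets.

    For each sample: draw whole-serum totals from the category's
    truncated-normal distributions, allocate them over the species
    library by non-negative least squares, then forward-simulate the
    fraction and DLS tables.  The emitted serum totals are the
    species-implied (loss-free) totals, keeping generator and pipeline
    mass-consistent; the NNLS residual is the only difference from the
    drawn targets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples: list[SimulatedSample] = []
    for category, n in n_per_category.items():
        if category not in SERUM_DISTRIBUTIONS:
            raise SimulationError(f"unknown category {category!r}")
        for i in range(int(n)):
            totals = draw_serum_totals(category, rng, constants)
            sample_library = (
                list(library)
                if library is not None
                else default_species_library(constants, serum_totals=totals)
            )
            species = allocate_species(totals, sample_library)
            sample = simulate_sample_profile(
                species,
                calibration=calibration,
                schedule=schedule,
                noise=noise,
                rng=rng,
                sample_id=f"{category}-{i + 1:03d}",
                category=category,
            )
            samples.append(sample)
    return samples
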