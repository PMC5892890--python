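"""Volumetric particle-number model for size-fractionated serum.

Each AF4 fraction is treated as one lipoprotein species with a single
hydrodynamic diameter.  The chain of calculations is:

1. recovery-correct per-fraction analyte concentrations back to a
   per-liter-of-serum scale (fraction concentration × fraction volume /
   injected serum volume / channel recovery);
2. the channel recovery itself is the summed fraction amounts over the
   whole-serum amount, per analyte per sample;
3. split free cholesterol between the particle core and surface phases
   using a partition coefficient kappa between the non-polar and polar
   lipid phases: at (CE+TG)/PL = 1, a fraction kappa/(kappa+1) of FC sits
   on the surface;
4. sum core volume (CE, TG, core FC × molecular volumes × N_A) and
   surface volume (PL, surface FC, proteins at 1.212 nm³/kDa) per liter
   of serum;
5. divide by the dehydrated single-particle volume — hydrodynamic
   diameter minus 2·n·w_h of bound water, sphere or oblate ellipsoid —
   to obtain the molar particle number Lp-P;
6. analyte molecules per particle are the molar ratio of recovery-
   corrected serum concentration to Lp-P.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analytes import (
    ALL_ANALYTES,
    AVOGADRO,
    Analyte,
    POLAR_LIPIDS,
    PROTEINS,
    ShapeModel,
    UnitError,
    VolumetricConstants,
)
from .calibration import bin_label

#: Default molar particle-number floor (mol/L); per-particle stoichiometry
#: is masked below it to avoid blow-ups in near-empty fractions.
LP_P_FLOOR = 1e-12

#: Fractions whose DLS diameter is below the hydration shell plus this
#: margin (nm) are excluded from particle math (degenerate dehydrated
#: volume) but kept in concentration sums.
MIN_DIAMETER_MARGIN_NM = 1.0

#: Eq-4 recoveries outside this range are flagged as suspect.
RECOVERY_PLAUSIBLE = (0.05, 1.5)


class VolumetricsError(ValueError):
    """Raised for non-physical inputs to the particle-number equations."""


@dataclass
class FractionRecord:
    """One AF4 fraction of one sample."""

    sample_id: str
    fraction_number: int
    volume_ml: float
    diameter_dls_nm: float | None
    conc_mol_l: dict[Analyte, float]
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise VolumetricsError("fraction volume must be positive")
        for analyte, c in self.conc_mol_l.items():
            if c < 0:
                raise VolumetricsError(f"negative concentration for {analyte}")


@dataclass
class SerumRecord:
    """Whole-serum totals of one sample plus the injected volume."""

    sample_id: str
    total_conc_mol_l: dict[Analyte, float]
    injected_volume_ml: float = 0.050
    category: str | None = None

    def __post_init__(self) -> None:
        if self.injected_volume_ml <= 0:
            raise VolumetricsError("injected volume must be positive")


# --- scalar / vector operations --------------------------------------------


def serum_conc_by_fraction(
    conc_fraction_mol_l,
    volume_ml,
    injected_volume_ml: float,
    recovery: float,
):
    """Recovery-corrected analyte concentration per liter of serum.

    conc_serum = conc_fraction * fraction_volume / injected_volume / recovery
    """
    if recovery <= 0:
        raise VolumetricsError(f"recovery must be positive, got {recovery}")
    if injected_volume_ml <= 0:
        raise VolumetricsError("injected volume must be positive")
    return (
        np.asarray(conc_fraction_mol_l)
        * np.asarray(volume_ml)
        / injected_volume_ml
        / recovery
    )


def af4_recovery(
    conc_fraction_mol_l: Sequence[float],
    volume_ml: Sequence[float],
    total_conc_mol_l: float,
    injected_volume_ml: float,
) -> float:
    """AF4 channel recovery: summed fraction amount over injected amount."""
    if total_conc_mol_l <= 0:
        raise VolumetricsError("serum total must be positive for a recovery")
    amount = float(np.sum(np.asarray(conc_fraction_mol_l) * np.asarray(volume_ml)))
    return amount / (total_conc_mol_l * injected_volume_ml)


def partition_fc(fc, ce, tg, pl, kappa: float = 5.0):
    """Split free cholesterol between core and surface phases.

    fc_core    = 1/(kappa+1) * fc * (ce+tg)/pl
    fc_surface = fc - fc_core

    A negative surface share (when (CE+TG)/PL > kappa+1, e.g. TG-rich
    purge fractions) is clamped to zero with all FC assigned to the core;
    PL = 0 with FC present likewise sends all FC to the core.  Returns
    ``(fc_core, fc_surface, clamped)``.
    """
    fc = np.asarray(fc, dtype=float)
    ce = np.asarray(ce, dtype=float)
    tg = np.asarray(tg, dtype=float)
    pl = np.asarray(pl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pl > 0, (ce + tg) / np.where(pl > 0, pl, 1.0), np.inf)
    core_share = ratio / (kappa + 1.0)
    clamped = (core_share > 1.0) & (fc > 0)
    core_share = np.clip(core_share, 0.0, 1.0)
    core_share = np.where(np.isfinite(core_share), core_share, 1.0)
    fc_core = fc * core_share
    fc_surface = fc - fc_core
    if fc.ndim == 0:
        return float(fc_core), float(fc_surface), bool(clamped)
    return fc_core, fc_surface, clamped


def core_volume_per_liter(ce, tg, fc_core, constants: VolumetricConstants):
    """Total particle core volume per liter of serum, nm³/L."""
    return (
        constants.v_ce * np.asarray(ce)
        + constants.v_tg * np.asarray(tg)
        + constants.v_fc * np.asarray(fc_core)
    ) * constants.avogadro


def surface_volume_per_liter(
    pl_total,
    fc_surface,
    protein_conc: Mapping[Analyte, float],
    constants: VolumetricConstants,
):
    """Total particle surface volume per liter of serum, nm³/L.

    The protein term sums MW_protein × v_protein × concentration over the
    quantified apolipoproteins; particles are assumed to carry no other
    proteins.
    """
    protein_term = 0.0
    for analyte, conc in protein_conc.items():
        analyte = Analyte(analyte)
        mw = constants.protein_mw_kda.get(analyte)
        if mw is None:
            raise VolumetricsError(f"no molecular weight for protein {analyte}")
        protein_term = protein_term + mw * constants.v_protein_specific * np.asarray(conc)
    return (
        constants.v_pl * np.asarray(pl_total)
        + constants.v_fc * np.asarray(fc_surface)
        + protein_term
    ) * constants.avogadro


def dehydrated_particle_volume(
    d_dls_nm,
    constants: VolumetricConstants,
    shape: ShapeModel = ShapeModel(),
):
    """Dehydrated single-particle volume, nm³.

    Subtracts the hydration shell (2·n·w_h) from the hydrodynamic
    diameter.  Sphere: (4π/3)(d/2)³; oblate ellipsoid: the short axis is
    k·d so the volume is k times the sphere volume.
    """
    d = np.asarray(d_dls_nm, dtype=float)
    shell = constants.hydration_shell_nm
    if np.any(d <= shell):
        raise VolumetricsError(
            f"hydrodynamic diameter must exceed the hydration shell ({shell} nm)"
        )
    d_dehyd = d - shell
    volume = (4.0 * math.pi / 3.0) * (d_dehyd / 2.0) ** 3 * shape.axial_ratio
    return float(volume) if volume.ndim == 0 else volume


def particle_number(core_vol_nm3_l, surface_vol_nm3_l, particle_vol_nm3, avogadro=AVOGADRO):
    """Molar lipoprotein particle number Lp-P, mol/L.

    Lp-P = (core volume + surface volume per liter) / (N_A × particle volume).
    """
    particle_vol = np.asarray(particle_vol_nm3, dtype=float)
    if np.any(particle_vol <= 0):
        raise VolumetricsError("particle volume must be positive")
    return (np.asarray(core_vol_nm3_l) + np.asarray(surface_vol_nm3_l)) / (
        particle_vol * avogadro
    )


def analyte_per_particle(serum_conc_mol_l, lp_p_mol_l, floor: float = LP_P_FLOOR):
    """Analyte molecules per particle: molar ratio of the two concentrations.

    Values where Lp-P is below ``floor`` are masked (NaN).
    """
    lp_p = np.asarray(lp_p_mol_l, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(lp_p >= floor, np.asarray(serum_conc_mol_l) / lp_p, np.nan)
    return float(out) if out.ndim == 0 else out


def particle_geometry(core_vol_nm3_l, surface_vol_nm3_l, lp_p_mol_l, avogadro=AVOGADRO):
    """Sphere-equivalent core diameter, surface thickness, surface/core ratio.

    The per-particle core volume defines a sphere-equivalent core
    diameter; the total per-particle volume defines the outer diameter;
    the surface thickness is half the difference.
    """
    lp_p = np.asarray(lp_p_mol_l, dtype=float)
    if np.any(lp_p <= 0):
        raise VolumetricsError("Lp-P must be positive for geometry")
    core = np.asarray(core_vol_nm3_l, dtype=float)
    surf = np.asarray(surface_vol_nm3_l, dtype=float)
    v_core = core / (lp_p * avogadro)
    v_total = (core + surf) / (lp_p * avogadro)
    d_core = np.cbrt(6.0 * v_core / math.pi)
    d_total = np.cbrt(6.0 * v_total / math.pi)
    thickness = (d_total - d_core) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(core > 0, surf / np.where(core > 0, core, 1.0), np.inf)
    if v_core.ndim == 0:
        return float(d_core), float(thickness), float(ratio)
    return d_core, thickness, ratio


# --- per-sample pipeline ----------------------------------------------------


def compute_recoveries(
    fractions: pd.DataFrame,
    serum: SerumRecord,
    analytes: Sequence[Analyte] = ALL_ANALYTES,
) -> pd.Series:
    """Eq-4 channel recovery per analyte for one sample.

    ``fractions`` is a wide frame (one row per fraction) with a
    ``volume_ml`` column and one column per analyte in mol/L.  Analytes
    with zero whole-serum totals get NaN (flagged, excluded downstream).
    """
    out = {}
    for analyte in analytes:
        total = serum.total_conc_mol_l.get(analyte, 0.0)
        if total <= 0 or analyte not in fractions:
            out[analyte] = np.nan
            continue
        out[analyte] = af4_recovery(
            fractions[analyte].to_numpy(),
            fractions["volume_ml"].to_numpy(),
            total,
            serum.injected_volume_ml,
        )
    rec = pd.Series(out, name="recovery")
    suspect = rec[(rec < RECOVERY_PLAUSIBLE[0]) | (rec > RECOVERY_PLAUSIBLE[1])]
    for analyte in suspect.index:
        warnings.warn(
            f"suspect AF4 recovery {rec[analyte]:.3g} for {analyte} in sample "
            f"{serum.sample_id}",
            stacklevel=2,
        )
    return rec


def compute_sample_metrics(
    fractions: pd.DataFrame,
    serum: SerumRecord,
    constants: VolumetricConstants = VolumetricConstants(),
    shape: ShapeModel = ShapeModel(),
    recoveries: pd.Series | None = None,
    correct_recovery: bool = True,
    lp_p_floor: float = LP_P_FLOOR,
) -> pd.DataFrame:
    """Run the full volumetric chain for one sample.

    Parameters
    ----------
    fractions
        Wide per-fraction frame with columns ``fraction_number``,
        ``volume_ml``, ``diameter_dls_nm`` and one column per analyte
        (mol/L in-fraction concentrations).
    serum
        Whole-serum totals and injected volume.
    recoveries
        Optional precomputed per-analyte recoveries; computed from the
        sample itself when omitted.
    correct_recovery
        Disable to skip the 1/recovery correction (sensitivity analysis).

    Returns a tidy per-fraction frame carrying serum-scale concentrations
    (``serum_<analyte>``), core/surface volumes, Lp-P, per-particle
    stoichiometries (``per_particle_<analyte>``), geometry and flags.
    Fractions without a usable diameter keep their concentration columns
    but have particle quantities masked.
    """
    analytes = [a for a in ALL_ANALYTES if a in fractions.columns]
    if recoveries is None:
        recoveries = compute_recoveries(fractions, serum, analytes)

    out = fractions[["fraction_number", "volume_ml", "diameter_dls_nm"]].copy()
    out["sample_id"] = serum.sample_id

    # Eq 3 per analyte
    for analyte in analytes:
        rec = recoveries.get(analyte, np.nan)
        if correct_recovery:
            if not np.isfinite(rec) or rec <= 0:
                out[f"serum_{analyte}"] = np.nan
                continue
        else:
            rec = 1.0
        out[f"serum_{analyte}"] = serum_conc_by_fraction(
            fractions[analyte].to_numpy(),
            fractions["volume_ml"].to_numpy(),
            serum.injected_volume_ml,
            rec,
        )

    def col(analyte: Analyte) -> np.ndarray:
        name = f"serum_{analyte}"
        if name in out:
            return np.nan_to_num(out[name].to_numpy(), nan=0.0)
        return np.zeros(len(out))

    fc, ce, tg = col(Analyte.FC), col(Analyte.CE), col(Analyte.TG)
    pl = np.sum([col(a) for a in POLAR_LIPIDS], axis=0)
    fc_core, fc_surface, clamped = partition_fc(
        fc, ce, tg, pl, constants.fc_partition_kappa
    )
    out["fc_core"] = fc_core
    out["fc_surface"] = fc_surface
    out["fc_clamped"] = clamped

    out["core_volume_nm3_l"] = core_volume_per_liter(ce, tg, fc_core, constants)
    out["surface_volume_nm3_l"] = surface_volume_per_liter(
        pl, fc_surface, {a: col(a) for a in PROTEINS if f"serum_{a}" in out}, constants
    )

    d = out["diameter_dls_nm"].to_numpy(dtype=float)
    usable = np.isfinite(d) & (d > constants.hydration_shell_nm + MIN_DIAMETER_MARGIN_NM)
    out["particle_math_excluded"] = ~usable

    pvol = np.full(len(out), np.nan)
    pvol[usable] = dehydrated_particle_volume(d[usable], constants, shape)
    out["dehydrated_particle_volume_nm3"] = pvol

    lp_p = np.full(len(out), np.nan)
    lp_p[usable] = particle_number(
        out["core_volume_nm3_l"].to_numpy()[usable],
        out["surface_volume_nm3_l"].to_numpy()[usable],
        pvol[usable],
        constants.avogadro,
    )
    out["lp_p_mol_l"] = lp_p

    for analyte in analytes:
        out[f"per_particle_{analyte}"] = analyte_per_particle(
            out[f"serum_{analyte}"].to_numpy(), lp_p, lp_p_floor
        )

    geom_ok = usable & np.isfinite(lp_p) & (lp_p >= lp_p_floor)
    d_core = np.full(len(out), np.nan)
    thickness = np.full(len(out), np.nan)
    ratio = np.full(len(out), np.nan)
    if geom_ok.any():
        d_core[geom_ok], thickness[geom_ok], ratio[geom_ok] = particle_geometry(
            out["core_volume_nm3_l"].to_numpy()[geom_ok],
            out["surface_volume_nm3_l"].to_numpy()[geom_ok],
            lp_p[geom_ok],
            constants.avogadro,
        )
    out["core_diameter_nm"] = d_core
    out["surface_thickness_nm"] = thickness
    out["surface_to_core_ratio"] = ratio

    labels = []
    for di, ok in zip(d, usable):
        labels.append(bin_label(di) if ok else None)
    out["size_bin"] = labels
    return out
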