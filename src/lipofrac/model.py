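"""Model/results interface over the volumetric particle pipeline.

`VolumetricParticleModel` bundles the three input tables of an
AF4-LC-MS/MS study (per-fraction concentrations, whole-serum totals,
per-fraction DLS sizes), and `fit()` runs the complete chain — per-batch
quadratic size calibration, per-analyte channel recoveries, the
volumetric particle-number equations, size binning and the ratio panels
— returning a `VolumetricParticleResults` carrying tidy result tables,
diagnostics and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analytes import ALL_ANALYTES, Analyte, ShapeModel, VolumetricConstants
import warnings

from .calibration import CalibrationError, QuadraticCalibration, fit_size_calibration
from .cohort import (
    CategoryRule,
    aggregate_by_bin,
    categorize_sample,
    summarize_bins,
)
from .volumetrics import SerumRecord, compute_recoveries, compute_sample_metrics


class VolumetricParticleModel:
    """Volumetric lipoprotein particle model for one or more samples.

    Parameters
    ----------
    fractions
        Wide per-fraction frame with columns ``sample_id``,
        ``fraction_number``, ``volume_ml`` and one mol/L column per
        analyte.  A ``diameter_dls_nm`` column may be present; otherwise
        (or when ``use_fitted_sizes``) diameters come from the DLS table
        through the per-batch quadratic calibration.
    serum
        Mapping sample_id → :class:`SerumRecord`.
    dls
        Optional DLS table (``batch_id, sample_id, fraction_number,
        diameter_nm, qc_flag``) used to fit one quadratic calibration per
        batch.
    use_fitted_sizes
        When True (default, matching the study pathway) per-fraction
        diameters are the calibration predictions at the fraction
        numbers; when False the measured per-fraction DLS values are used
        directly.
    """

    def __init__(
        self,
        fractions: pd.DataFrame,
        serum: Mapping[str, SerumRecord],
        dls: pd.DataFrame | None = None,
        constants: VolumetricConstants = VolumetricConstants(),
        shape: ShapeModel = ShapeModel(),
        use_fitted_sizes: bool = True,
        correct_recovery: bool = True,
        category_rule: CategoryRule = CategoryRule(),
    ) -> None:
        self.fractions = fractions
        self.serum = dict(serum)
        self.dls = dls
        self.constants = constants
        self.shape = shape
        self.use_fitted_sizes = use_fitted_sizes
        self.correct_recovery = correct_recovery
        self.category_rule = category_rule

    @classmethod
    def from_simulation(
        cls,
        samples: Sequence,
        constants: VolumetricConstants = VolumetricConstants(),
        shape: ShapeModel = ShapeModel(),
        use_fitted_sizes: bool = True,
        **kwargs,
    ) -> "VolumetricParticleModel":
        """Build a model from :func:`lipofrac.simulate` sample objects."""
        frames = []
        serum: dict[str, SerumRecord] = {}
        dls_frames = []
        for s in samples:
            frame = s.fractions.copy()
            frame.insert(0, "sample_id", s.serum.sample_id)
            frames.append(frame)
            serum[s.serum.sample_id] = s.serum
            dls_frames.append(s.dls)
        return cls(
            pd.concat(frames, ignore_index=True),
            serum,
            dls=pd.concat(dls_frames, ignore_index=True),
            constants=constants,
            shape=shape,
            use_fitted_sizes=use_fitted_sizes,
            **kwargs,
        )

    def _fit_calibrations(self) -> dict[str, QuadraticCalibration]:
        calibrations: dict[str, QuadraticCalibration] = {}
        if self.dls is None:
            return calibrations
        usable = self.dls[self.dls["qc_flag"].astype(str).isin(["", "nan"])]
        for batch_id, grp in usable.groupby("batch_id"):
            pts = list(zip(grp["fraction_number"], grp["diameter_nm"]))
            try:
                calibrations[str(batch_id)] = fit_size_calibration(
                    pts, batch_id=str(batch_id)
                )
            except CalibrationError as exc:
                warnings.warn(
                    f"batch {batch_id}: {exc}; falling back to measured "
                    "per-fraction DLS diameters",
                    stacklevel=2,
                )
        return calibrations

    def fit(self) -> "VolumetricParticleResults":
        calibrations = self._fit_calibrations() if self.use_fitted_sizes else {}
        sample_batch: dict[str, str] = {}
        if self.dls is not None:
            sample_batch = (
                self.dls.groupby("sample_id")["batch_id"].first().astype(str).to_dict()
            )

        recoveries: dict[str, pd.Series] = {}
        metrics_frames = []
        for sample_id, grp in self.fractions.groupby("sample_id", sort=False):
            sample_id = str(sample_id)
            if sample_id not in self.serum:
                raise KeyError(f"no whole-serum record for sample {sample_id!r}")
            grp = grp.sort_values("fraction_number").reset_index(drop=True)
            cal = calibrations.get(sample_batch.get(sample_id, ""))
            if self.use_fitted_sizes and cal is not None:
                grp = grp.copy()
                # purge fractions may sit past the last measurable DLS point;
                # extrapolating the quadratic there is expected
                grp["diameter_dls_nm"] = cal.predict(
                    grp["fraction_number"].to_numpy(dtype=float),
                    extrapolation_margin=10.0,
                )
            elif "diameter_dls_nm" not in grp and self.dls is not None:
                dsub = self.dls[self.dls["sample_id"] == sample_id]
                merged = grp.merge(
                    dsub[["fraction_number", "diameter_nm"]], on="fraction_number",
                    how="left",
                )
                grp = merged.rename(columns={"diameter_nm": "diameter_dls_nm"})
            serum = self.serum[sample_id]
            rec = compute_recoveries(grp, serum)
            recoveries[sample_id] = rec
            metrics_frames.append(
                compute_sample_metrics(
                    grp,
                    serum,
                    constants=self.constants,
                    shape=self.shape,
                    recoveries=rec,
                    correct_recovery=self.correct_recovery,
                )
            )
        fraction_metrics = pd.concat(metrics_frames, ignore_index=True)
        recovery_table = pd.DataFrame(recoveries).T.rename_axis("sample_id")
        recovery_table.columns = [str(c) for c in recovery_table.columns]
        bin_metrics = aggregate_by_bin(fraction_metrics)

        categories = {}
        for sample_id, serum in self.serum.items():
            if serum.category:
                categories[sample_id] = serum.category
            else:
                tc, tg = _serum_tc_tg_mg_dl(serum, self.constants)
                categories[sample_id] = categorize_sample(tc, tg, self.category_rule)

        return VolumetricParticleResults(
            model=self,
            calibrations=calibrations,
            recoveries=recovery_table,
            fraction_metrics=fraction_metrics,
            bin_metrics=bin_metrics,
            categories=pd.Series(categories, name="category"),
        )


def _serum_tc_tg_mg_dl(serum: SerumRecord, constants: VolumetricConstants):
    """Whole-serum Total-C and Total-TG in mg/dL from molar totals."""
    mw = constants.lipid_mw_g_mol
    fc = serum.total_conc_mol_l.get(Analyte.FC, 0.0)
    ce = serum.total_conc_mol_l.get(Analyte.CE, 0.0)
    tg = serum.total_conc_mol_l.get(Analyte.TG, 0.0)
    # mol/L × g/mol = g/L; ×100 → mg/dL
    tc_mg_dl = (fc * mw[Analyte.FC] + ce * mw[Analyte.CE]) * 100.0
    tg_mg_dl = tg * mw[Analyte.TG] * 100.0
    return tc_mg_dl, tg_mg_dl


@dataclass
class VolumetricParticleResults:
    """Fitted results: calibrations, recoveries, particle metrics, bins."""

    model: VolumetricParticleModel
    calibrations: dict[str, QuadraticCalibration]
    recoveries: pd.DataFrame
    fraction_metrics: pd.DataFrame
    bin_metrics: pd.DataFrame
    categories: pd.Series

    def bin_summary(self, value_cols=None) -> pd.DataFrame:
        """Per-bin per-category mean/SD/95% CI table."""
        return summarize_bins(self.bin_metrics, self.categories, value_cols)

    def peak_bin(
        self, lower_nm: float = 0.0, upper_nm: float = np.inf, value: str = "lp_p_mol_l"
    ) -> str:
        """Size bin with the maximal across-sample mean of ``value``."""
        sub = self.bin_metrics[
            (self.bin_metrics["bin_lower_nm"] >= lower_nm)
            & (self.bin_metrics["bin_lower_nm"] < upper_nm)
        ]
        if sub.empty:
            raise ValueError("no bins in the requested size window")
        return str(sub.groupby("size_bin")[value].mean().idxmax())

    def mean_per_particle(self, analyte: Analyte | str, size_bin: str) -> float:
        """Across-sample mean per-particle stoichiometry in one bin."""
        col = f"per_particle_{Analyte(analyte)}"
        sub = self.bin_metrics[self.bin_metrics["size_bin"] == size_bin]
        return float(sub[col].mean())

    def summary(self) -> str:
        lines = ["Volumetric lipoprotein particle analysis", "=" * 42]
        n_samples = self.fraction_metrics["sample_id"].nunique()
        lines.append(f"samples: {n_samples}   fractions/sample: "
                     f"{len(self.fraction_metrics) // max(n_samples, 1)}")
        counts = self.categories.value_counts().to_dict()
        lines.append("categories: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
        lines.append("")
        lines.append("Mean AF4 channel recovery by analyte:")
        means = self.recoveries.mean(axis=0)
        for analyte, value in means.items():
            if np.isfinite(value):
                lines.append(f"  {analyte:>6}: {100 * value:5.1f}%")
        lines.append("")
        for label, lo, hi in (("HDL", 8.0, 13.0), ("LDL", 18.0, 30.0)):
            try:
                peak = self.peak_bin(lo, hi)
            except ValueError:
                continue
            sub = self.bin_metrics[self.bin_metrics["size_bin"] == peak]
            lp_p = sub["lp_p_mol_l"].mean()
            lines.append(
                f"{label} particle-number peak bin {peak}: "
                f"Lp-P = {1e6 * lp_p:.2f} umol/L"
            )
            for analyte in (Analyte.APOA1, Analyte.APOB):
                col = f"per_particle_{analyte}"
                if col in sub and np.isfinite(sub[col].mean()):
                    lines.append(f"    {analyte}/Lp-P = {sub[col].mean():.2f}")
        return "\n".join(lines)
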