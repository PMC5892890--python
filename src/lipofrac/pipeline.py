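"""End-to-end pipeline configuration, execution and report generation.

`run_pipeline` ties the stages together: read (or simulate) the three
input tables, fit the volumetric particle model, aggregate bins, compute
the category comparisons and ratio correlations, and write a bundle of
tidy delimited-text outputs stamped with a config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .analytes import ShapeModel, VolumetricConstants
from .cohort import RATIO_PAIRS, CategoryRule, compare_groups, correlate_ratios
from .io import (
    fractions_to_tidy,
    read_dls_table,
    read_fraction_table,
    read_serum_table,
    serum_to_tidy,
    write_table,
)
from .model import VolumetricParticleModel, VolumetricParticleResults
from .simulate import NoiseModel, simulate_cohort

logger = logging.getLogger("lipofrac")


class PipelineConfig(BaseModel):
    """Run configuration; mirrors the CLI flags."""

    fraction_table: Optional[str] = None
    serum_table: Optional[str] = None
    dls_table: Optional[str] = None
    simulate: Optional[dict[str, int]] = Field(
        default=None,
        description="Simulate a cohort instead of reading tables: "
        "category → sample count.",
    )
    seed: int = 0
    noise: bool = True
    constants_file: Optional[str] = None
    constants_overrides: dict[str, float] = Field(default_factory=dict)
    shape_kind: str = "sphere"
    axial_ratio: float = 1.0
    use_fitted_sizes: bool = True
    correct_recovery: bool = True
    tc_cutoff_mg_dl: float = 230.0
    tg_cutoff_mg_dl: float = 150.0
    output_dir: str = "lipofrac_out"

    def constants(self) -> VolumetricConstants:
        base = (
            VolumetricConstants.from_file(self.constants_file)
            if self.constants_file
            else VolumetricConstants()
        )
        return base.with_overrides(**self.constants_overrides) if self.constants_overrides else base

    def shape(self) -> ShapeModel:
        return ShapeModel(kind=self.shape_kind, axial_ratio=self.axial_ratio)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ResultBundle:
    config: PipelineConfig
    results: VolumetricParticleResults
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    provenance: dict


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full workflow described by ``config``."""
    constants = config.constants()
    shape = config.shape()
    rule = CategoryRule(config.tc_cutoff_mg_dl, config.tg_cutoff_mg_dl)

    if config.simulate:
        noise = NoiseModel() if config.noise else NoiseModel.noiseless()
        samples = simulate_cohort(
            config.simulate, seed=config.seed, constants=constants, noise=noise
        )
        model = VolumetricParticleModel.from_simulation(
            samples,
            constants=constants,
            shape=shape,
            use_fitted_sizes=config.use_fitted_sizes,
            correct_recovery=config.correct_recovery,
            category_rule=rule,
        )
    else:
        if not (config.fraction_table and config.serum_table):
            raise ValueError(
                "either 'simulate' or fraction_table + serum_table must be set"
            )
        fractions = read_fraction_table(config.fraction_table, constants)
        serum = read_serum_table(config.serum_table, constants)
        dls = read_dls_table(config.dls_table) if config.dls_table else None
        model = VolumetricParticleModel(
            fractions,
            serum,
            dls=dls,
            constants=constants,
            shape=shape,
            use_fitted_sizes=config.use_fitted_sizes,
            correct_recovery=config.correct_recovery,
            category_rule=rule,
        )

    results = model.fit()

    # category comparisons of the ratio panels per size bin
    ratio_cols = [f"{n}/{d}" for n, d in RATIO_PAIRS]
    bm = results.bin_metrics.copy()
    bm["category"] = bm["sample_id"].map(results.categories)
    comparison_frames = []
    for size_bin, grp in bm.groupby("size_bin", sort=False):
        for ratio in ratio_cols:
            if ratio not in grp:
                continue
            groups = {
                cat: sub[ratio].dropna().to_numpy()
                for cat, sub in grp.groupby("category")
            }
            groups = {k: v for k, v in groups.items() if v.size}
            if len(groups) < 2:
                continue
            cmp = compare_groups(groups)
            cmp.insert(0, "size_bin", size_bin)
            cmp.insert(1, "variable", ratio)
            comparison_frames.append(cmp)
    comparisons = (
        pd.concat(comparison_frames, ignore_index=True)
        if comparison_frames
        else pd.DataFrame()
    )

    present = [c for c in ratio_cols if c in bm.columns]
    correlations = correlate_ratios(bm[present]) if present else pd.DataFrame()

    provenance = {
        "lipofrac_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "constants": {
            k: v
            for k, v in vars(constants).items()
            if isinstance(v, (int, float))
        },
        "shape": {"kind": shape.kind, "axial_ratio": shape.axial_ratio},
    }
    return ResultBundle(config, results, comparisons, correlations, provenance)


def write_bundle(bundle: ResultBundle, output_dir: str | Path | None = None) -> Path:
    """Write every result table of a bundle as delimited text."""
    out = Path(output_dir or bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = bundle.results
    write_table(res.fraction_metrics, out / "fraction_metrics.tsv")
    write_table(res.bin_metrics, out / "bin_metrics.tsv")
    write_table(res.bin_summary(), out / "bin_summary.tsv")
    write_table(res.recoveries.reset_index(), out / "recoveries.tsv")
    if len(bundle.comparisons):
        write_table(bundle.comparisons, out / "comparisons.tsv")
    if len(bundle.correlations):
        write_table(bundle.correlations, out / "correlations.tsv")
    cal_rows = [
        {
            "batch_id": b,
            "c0": c.c0,
            "c1": c.c1,
            "c2": c.c2,
            "n_points": c.n_points,
            "rms_residual_nm": c.rms_residual_nm,
            "monotone": c.monotone,
        }
        for b, c in res.calibrations.items()
    ]
    if cal_rows:
        write_table(pd.DataFrame(cal_rows), out / "calibrations.tsv")
    (out / "provenance.json").write_text(json.dumps(bundle.provenance, indent=2))
    (out / "report.md").write_text(write_report(bundle))
    return out


def write_report(bundle: ResultBundle) -> str:
    """Human-readable markdown summary of a result bundle."""
    res = bundle.results
    lines = ["# Volumetric lipoprotein particle report", ""]
    lines.append(f"- config hash: `{bundle.provenance['config_hash']}`")
    lines.append(f"- seed: {bundle.provenance['seed']}")
    lines.append(f"- samples: {res.recoveries.shape[0]}")
    counts = res.categories.value_counts().to_dict()
    lines.append("- categories: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    lines.append("")

    lines.append("## AF4 channel recovery by analyte")
    lines.append("")
    lines.append("| analyte | mean recovery | SD |")
    lines.append("|---|---|---|")
    means, sds = res.recoveries.mean(axis=0), res.recoveries.std(axis=0)
    for analyte in res.recoveries.columns:
        m, s = means[analyte], sds[analyte]
        m_txt = f"{100 * m:.1f}%" if np.isfinite(m) else "masked"
        s_txt = f"{100 * s:.1f}%" if np.isfinite(s) else "NA"
        lines.append(f"| {analyte} | {m_txt} | {s_txt} |")
    lines.append("")

    lines.append("## Particle-number peaks")
    lines.append("")
    lines.append("```")
    lines.append(res.summary())
    lines.append("```")
    lines.append("")

    lines.append("## Significant category differences (ratio panels)")
    lines.append("")
    sig = (
        bundle.comparisons[bundle.comparisons["significant"] == True]  # noqa: E712
        if len(bundle.comparisons)
        else pd.DataFrame()
    )
    if len(sig) == 0:
        lines.append("No significant differences at p < 0.05.")
    else:
        lines.append("| size bin | ratio | comparison | t | p | direction |")
        lines.append("|---|---|---|---|---|---|")
        for row in sig.itertuples():
            direction = (
                f"{row.group_1} > {row.group_2}"
                if row.mean_diff > 0
                else f"{row.group_1} < {row.group_2}"
            )
            lines.append(
                f"| {row.size_bin} | {row.variable} | {row.group_1} vs {row.group_2} "
                f"| {row.t_stat:.2f} | {row.p_value:.2g} | {direction} |"
            )
    lines.append("")
    return "\n".join(lines)
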