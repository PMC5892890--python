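"""Sample categorization, size-bin aggregation, ratio panels and group stats.

Samples are assigned to four lipid-phenotype categories from whole-serum
Total-C and Total-TG (cutoffs 230 and 150 mg/dL): normolipidemic (NL),
hypercholesterolemic (HC), hyperlipidemic (HL) and hypertriglyceridemic
(HT).  Per-fraction particle metrics are aggregated into the integer
size bins (concentrations and Lp-P summed; per-particle stoichiometries
averaged weighted by Lp-P), and composition is compared across groups by
pairwise Student's t-tests and Pearson correlations of molar
analyte/analyte ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analytes import ALL_ANALYTES, Analyte, POLAR_LIPIDS, UnitError


@dataclass(frozen=True)
class CategoryRule:
    """Lipid-phenotype cutoffs in mg/dL; values at a cutoff count as high."""

    tc_cutoff_mg_dl: float = 230.0
    tg_cutoff_mg_dl: float = 150.0

    def __post_init__(self) -> None:
        if self.tc_cutoff_mg_dl <= 0 or self.tg_cutoff_mg_dl <= 0:
            raise UnitError("category cutoffs must be positive")


CATEGORIES = ("NL", "HC", "HL", "HT")


def categorize_sample(
    total_c_mg_dl: float, total_tg_mg_dl: float, rule: CategoryRule = CategoryRule()
) -> str:
    """Assign NL/HC/HL/HT from whole-serum Total-C and Total-TG."""
    if total_c_mg_dl < 0 or total_tg_mg_dl < 0:
        raise UnitError("serum totals must be non-negative")
    high_c = total_c_mg_dl >= rule.tc_cutoff_mg_dl
    high_tg = total_tg_mg_dl >= rule.tg_cutoff_mg_dl
    if high_c:
        return "HL" if high_tg else "HC"
    return "HT" if high_tg else "NL"


#: The nine analyte/analyte molar ratio panels; "PL" denotes the summed
#: five phospholipid classes.
RATIO_PAIRS: tuple[tuple[str, str], ...] = (
    ("A-I", "A-II"),
    ("C-II", "C-I"),
    ("C-II", "C-III"),
    ("E", "C-III"),
    ("FC", "PL"),
    ("SM", "PL"),
    ("PE", "PL"),
    ("PI", "PL"),
    ("LPC", "PL"),
)


def ratio_panel(conc_mol_l: Mapping[str, float]) -> dict[str, float]:
    """Molar ratios of the nine analyte pairs from a concentration map.

    Ratios with a non-positive denominator are masked (NaN).
    """
    conc = {str(k): float(v) for k, v in conc_mol_l.items()}
    pl = sum(conc.get(str(a), 0.0) for a in POLAR_LIPIDS)
    out: dict[str, float] = {}
    for num, den in RATIO_PAIRS:
        denominator = pl if den == "PL" else conc.get(den, 0.0)
        numerator = conc.get(num, np.nan)
        out[f"{num}/{den}"] = numerator / denominator if denominator > 0 else np.nan
    return out


def aggregate_by_bin(metrics: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-fraction particle metrics into size bins.

    Serum-scale concentrations, Lp-P and the core/surface volume columns
    are summed within each bin; per-particle stoichiometries and geometry
    are averaged weighted by Lp-P (matching their volumetric definition
    as ratios of summed concentrations).  Fractions excluded from
    particle math (no usable diameter) carry no bin and are dropped here;
    their concentrations remain available in the per-fraction table.
    """
    df = metrics[metrics["size_bin"].notna()].copy()
    sum_cols = (
        [c for c in df.columns if c.startswith("serum_")]
        + ["lp_p_mol_l", "core_volume_nm3_l", "surface_volume_nm3_l"]
    )
    mean_cols = [c for c in df.columns if c.startswith("per_particle_")] + [
        "core_diameter_nm",
        "surface_thickness_nm",
        "surface_to_core_ratio",
        "diameter_dls_nm",
    ]
    rows = []
    for (sample_id, size_bin), grp in df.groupby(["sample_id", "size_bin"], sort=False):
        row: dict = {"sample_id": sample_id, "size_bin": size_bin}
        row["bin_lower_nm"] = float(size_bin.strip("[)").split(",")[0])
        row["n_fractions"] = len(grp)
        for c in sum_cols:
            if c in grp:
                row[c] = grp[c].sum(skipna=True)
        w = grp["lp_p_mol_l"].to_numpy(dtype=float)
        for c in mean_cols:
            if c not in grp:
                continue
            v = grp[c].to_numpy(dtype=float)
            ok = np.isfinite(v) & np.isfinite(w) & (w > 0)
            row[c] = float(np.sum(v[ok] * w[ok]) / np.sum(w[ok])) if ok.any() else np.nan
        conc = {
            str(a): row.get(f"serum_{a}", np.nan)
            for a in ALL_ANALYTES
            if f"serum_{a}" in row
        }
        row.update(ratio_panel(conc))
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["sample_id", "bin_lower_nm"]).reset_index(drop=True) if len(out) else out


def summarize_bins(
    bin_metrics: pd.DataFrame,
    categories: pd.Series,
    value_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean, SD and 95% CI per size bin per category for selected columns."""
    df = bin_metrics.copy()
    df["category"] = df["sample_id"].map(categories)
    if value_cols is None:
        value_cols = [
            c
            for c in df.columns
            if c.startswith(("serum_", "per_particle_"))
            or "/" in c
            or c in ("lp_p_mol_l", "core_diameter_nm", "surface_thickness_nm",
                     "surface_to_core_ratio")
        ]
    rows = []
    for (size_bin, category), grp in df.groupby(["size_bin", "category"], sort=False):
        for c in value_cols:
            v = grp[c].dropna().to_numpy(dtype=float)
            if v.size == 0:
                continue
            mean = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
            half = 1.96 * sd / np.sqrt(v.size) if v.size > 1 else np.nan
            rows.append(
                {
                    "size_bin": size_bin,
                    "bin_lower_nm": float(size_bin.strip("[)").split(",")[0]),
                    "category": category,
                    "variable": c,
                    "n": v.size,
                    "mean": mean,
                    "sd": sd,
                    "ci95_low": mean - half,
                    "ci95_high": mean + half,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["variable", "bin_lower_nm", "category"]).reset_index(drop=True) if len(out) else out


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    welch: bool = False,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sample t-tests across groups.

    Classic pooled-variance Student's t by default (``welch=True`` for
    unequal variances); two-tailed p with a significance flag at
    ``alpha``.  Groups with fewer than two finite observations, or pairs
    where both groups have zero variance, are skipped with a flag.
    Benjamini–Hochberg adjustment across the emitted comparisons is off
    by default.
    """
    clean = {
        k: np.asarray([x for x in v if np.isfinite(x)], dtype=float)
        for k, v in values_by_group.items()
    }
    rows = []
    for g1, g2 in combinations(clean, 2):
        a, b = clean[g1], clean[g2]
        row: dict = {"group_1": g1, "group_2": g2, "n_1": a.size, "n_2": b.size}
        if a.size < 2 or b.size < 2:
            row.update(t_stat=np.nan, p_value=np.nan, significant=False,
                       skipped="insufficient_n")
        elif np.var(a) == 0 and np.var(b) == 0:
            row.update(t_stat=np.nan, p_value=np.nan, significant=False,
                       skipped="zero_variance")
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            row.update(
                t_stat=float(t),
                p_value=float(p),
                mean_diff=float(np.mean(a) - np.mean(b)),
                significant=bool(p < alpha),
                skipped="",
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if benjamini_hochberg and len(out):
        from statsmodels.stats.multitest import multipletests

        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            _, p_adj, _, _ = multipletests(out.loc[ok, "p_value"], method="fdr_bh")
            adj[ok.to_numpy()] = p_adj
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    return out


def correlate_ratios(ratio_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson correlations among ratio columns.

    Rows with missing values are dropped pairwise; pairs with fewer than
    three complete observations or a constant vector are masked.
    """
    cols = list(ratio_table.columns)
    rows = []
    for c1, c2 in combinations(cols, 2):
        sub = ratio_table[[c1, c2]].dropna()
        row: dict = {"ratio_1": c1, "ratio_2": c2, "n": len(sub)}
        x, y = sub[c1].to_numpy(), sub[c2].to_numpy()
        if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            row.update(r=np.nan, p_value=np.nan, significant=False)
        else:
            r, p = stats.pearsonr(x, y)
            row.update(r=float(r), p_value=float(p), significant=bool(p < alpha))
        rows.append(row)
    return pd.DataFrame(rows)
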