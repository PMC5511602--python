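"""Population statistics of the strain-based injury predictors.

Per subject and brain region, the injury metrics are the worst-case peaks
over the region's elements: maximum axonal strain (MAS) and maximum
principal Green-St. Venant strain (MPS), with the argmax element's
centroid recorded as the peak location. Across subjects the module
reports mean, sample SD and CV per region, compares loading conditions
with a two-sample t test for equality of means (pooled variance by
default, Welch optionally), and summarizes how tightly the peak location
clusters (per-axis ranges after 1.5 IQR outlier removal and the bounding
volume in cm^3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

REQUIRED_PEAK_COLUMNS = ("subject_id", "element_id", "region", "mas", "mps", "x", "y", "z")


def region_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-region peak MAS/MPS with argmax element locations.

    ``peaks`` holds one row per (subject, element) with columns
    subject_id, element_id, region, mas, mps, x, y, z. The regional peak
    is the max over the region's elements; ties go to the lower
    element_id. Empty regions simply produce no rows.
    """
    missing = [c for c in REQUIRED_PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peaks table missing columns {missing}")
    rows = []
    ordered = peaks.sort_values(["subject_id", "region", "element_id"], kind="stable")
    for (subject, region), grp in ordered.groupby(["subject_id", "region"], sort=True):
        row = {"subject_id": subject, "region": region, "n_elements": len(grp)}
        for metric in ("mas", "mps"):
            values = grp[metric].to_numpy()
            i = int(np.argmax(values))  # first maximum -> lowest element_id
            best = grp.iloc[i]
            row[metric] = float(values[i])
            row[f"{metric}_element"] = int(best["element_id"])
            row[f"{metric}_x"] = float(best["x"])
            row[f"{metric}_y"] = float(best["y"])
            row[f"{metric}_z"] = float(best["z"])
        rows.append(row)
    return pd.DataFrame(rows)


def population_summary(
    region_table: pd.DataFrame, metrics: tuple[str, ...] = ("mas", "mps")
) -> pd.DataFrame:
    """Across-subject mean, sample SD (n-1) and CV = 100 SD/mean per region."""
    rows = []
    for region, grp in region_table.groupby("region", sort=True):
        row = {"region": region, "n_subjects": len(grp)}
        for metric in metrics:
            v = grp[metric].to_numpy(dtype=float)
            mean = v.mean()
            sd = v.std(ddof=1) if len(v) > 1 else 0.0
            row[f"{metric}_mean"] = mean
            row[f"{metric}_sd"] = sd
            row[f"{metric}_cv_percent"] = 100.0 * sd / mean if mean > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sample t test for equality of means.

    Pooled (equal-variance) form by default; ``equal_var=False`` switches
    to Welch. Returns (t, two-sided p, significant at ``alpha``).
    Degenerate zero-variance samples: equal means give (0, 1), unequal
    means give (+/- inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, True
    t, p = sp_stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), bool(p < alpha)


def condition_ttests(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metrics: tuple[str, ...] = ("mas", "mps"),
    equal_var: bool = True,
) -> pd.DataFrame:
    """Region-wise t tests between two loading conditions."""
    rows = []
    regions = sorted(set(table_a["region"]) & set(table_b["region"]))
    for region in regions:
        row = {"region": region}
        for metric in metrics:
            a = table_a.loc[table_a["region"] == region, metric].to_numpy()
            b = table_b.loc[table_b["region"] == region, metric].to_numpy()
            t, p, sig = two_sample_ttest(a, b, equal_var=equal_var)
            row[f"{metric}_t"] = t
            row[f"{metric}_p"] = p
            row[f"{metric}_significant"] = sig
        rows.append(row)
    return pd.DataFrame(rows)


def _iqr_keep(x: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)


def localization_stats(locations: np.ndarray) -> dict:
    """Dispersion of peak-strain locations across subjects.

    Outliers are removed independently per axis with the 1.5 IQR rule;
    the reported volume is the product of the remaining per-axis ranges,
    converted from mm^3 to cm^3. Also returns a frequency table of
    distinct locations (rounded to 1e-6 mm for grouping).
    """
    pts = np.asarray(locations, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need an (n >= 2, 3) array of locations")
    ranges = np.empty(3)
    kept_counts = np.empty(3, dtype=int)
    for ax in range(3):
        keep = _iqr_keep(pts[:, ax])
        kept = pts[keep, ax]
        ranges[ax] = kept.max() - kept.min()
        kept_counts[ax] = keep.sum()
    volume_cm3 = float(np.prod(ranges) / 1000.0)
    uniq, counts = np.unique(np.round(pts, 6), axis=0, return_counts=True)
    freq = pd.DataFrame(
        {"x": uniq[:, 0], "y": uniq[:, 1], "z": uniq[:, 2], "count": counts}
    ).sort_values("count", ascending=False, ignore_index=True)
    return {
        "axis_ranges_mm": ranges,
        "kept_counts": kept_counts,
        "volume_cm3": volume_cm3,
        "frequency": freq,
    }
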