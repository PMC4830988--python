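"""ROI summarization and cohort-level statistics.

Group contrasts follow the study design: each (ROI, metric) value is
compared between two groups with an ordinary-least-squares general linear
model adjusting for gestational age, postmenstrual age and birth weight,

    value ~ intercept + group + GA + PMA + BW,

with the two-tailed Wald t on the group coefficient at alpha = 0.05.  No
multiple-comparison correction is applied by default (an optional
Bonferroni helper is provided).  Observer agreement uses Cohen's kappa with
the conventional category scale; cohort proportions use half-up rounding to
one decimal and a continuity-corrected chi-square (exact test for small
expected cells).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ROISummary",
    "GroupComparison",
    "roi_summary",
    "glm_group_compare",
    "compare_all",
    "cohen_kappa",
    "proportion",
    "compare_proportions",
    "KAPPA_SCALE",
]

COVARIATES = ("GA_weeks", "PMA_weeks", "BW_grams")

#: Cohen's kappa category scale (upper bound inclusive -> label)
KAPPA_SCALE = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


# ---------------------------------------------------------------------------
# ROI summaries

@dataclass
class ROISummary:
    table: pd.DataFrame  # columns: roi, metric, mean, sd, n_voxels


def roi_summary(maps: dict | np.ndarray, atlas, metric_name: str = "value",
                valid: np.ndarray | None = None) -> pd.DataFrame:
    """Mean and SD of each metric map over each atlas region.

    ``maps`` is either a single 3-D array (named ``metric_name``) or a dict
    {metric: 3-D array}.  Non-finite voxels and voxels outside ``valid``
    (if given) are excluded; a region with no usable voxel yields a missing
    row (NaN mean) with a warning.
    """
    if not isinstance(maps, dict):
        maps = {metric_name: maps}
    rows = []
    any_overlap = False
    for lab, roi in sorted(atlas.name_map.items()):
        region = atlas.labels == lab
        for metric, arr in maps.items():
            arr = np.asarray(arr)
            if arr.shape != atlas.labels.shape:
                raise ValueError(
                    f"map {metric!r} shape {arr.shape} != atlas shape "
                    f"{atlas.labels.shape}"
                )
            sel = region & np.isfinite(arr)
            if valid is not None:
                sel &= valid
            n = int(sel.sum())
            if n == 0:
                warnings.warn(f"ROI {roi!r}: no usable voxels for {metric!r}")
                rows.append({"roi": roi, "metric": metric, "mean": np.nan,
                             "sd": np.nan, "n_voxels": 0})
                continue
            any_overlap = True
            vals = arr[sel]
            rows.append({
                "roi": roi, "metric": metric,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
                "n_voxels": n,
            })
    if not any_overlap:
        raise ValueError("no overlap between usable voxels and any atlas label")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate-adjusted group comparison

@dataclass
class GroupComparison:
    metric: str
    roi: str
    group_a: str
    group_b: str
    effect: float  # adjusted mean difference, group_b - group_a
    se: float
    t: float
    p: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _column(cohort: pd.DataFrame, roi: str, metric: str) -> str:
    col = f"{roi}_{metric}"
    if col not in cohort.columns:
        raise KeyError(f"cohort table has no column {col!r}")
    return col


def glm_group_compare(cohort: pd.DataFrame, metric: str, roi: str,
                      contrast: tuple[str, str],
                      covariates=COVARIATES) -> GroupComparison:
    """Two-group comparison of one ROI metric, adjusted for GA, PMA and BW.

    OLS of the metric on an intercept, a group indicator (1 for the second
    group of ``contrast``) and the covariates, restricted to the two
    contrasted groups; the reported p is the two-tailed Wald t on the group
    coefficient.  Zero-variance covariates are dropped with a warning (they
    are unidentifiable next to the intercept); any remaining exact
    collinearity raises with the offending columns.
    """
    a, b = contrast
    sub = cohort[cohort["group"].isin([a, b])]
    n_a = int((sub["group"] == a).sum())
    n_b = int((sub["group"] == b).sum())
    if min(n_a, n_b) < 3:
        raise ValueError(f"need >= 3 subjects per group, got {n_a} vs {n_b}")
    col = _column(sub, roi, metric)

    used = []
    for c in covariates:
        if np.std(sub[c].to_numpy(float)) == 0:
            warnings.warn(f"covariate {c!r} has zero variance; dropped")
        else:
            used.append(c)
    X = pd.DataFrame({
        "const": 1.0,
        "group": (sub["group"] == b).astype(float),
        **{c: sub[c].astype(float) for c in used},
    })
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols: list[str] = []
        M = np.empty((len(X), 0))
        for c in X.columns:
            M2 = np.column_stack([M, X[c].to_numpy(float)])
            if np.linalg.matrix_rank(M2) == M.shape[1]:
                bad.append(c)
            else:
                M = M2
        raise ValueError(f"collinear design; offending columns: {bad}")
    res = sm.OLS(sub[col].astype(float).to_numpy(), X).fit()
    return GroupComparison(
        metric=metric, roi=roi, group_a=a, group_b=b,
        effect=float(res.params["group"]), se=float(res.bse["group"]),
        t=float(res.tvalues["group"]), p=float(res.pvalues["group"]),
        n_a=n_a, n_b=n_b,
    )


def compare_all(cohort: pd.DataFrame, contrasts, rois, metrics,
                bonferroni: bool = False) -> pd.DataFrame:
    """Run every (contrast, ROI, metric) GLM; mirrors the ROI-table layout
    (per-group mean +/- SD and the adjusted p per contrast)."""
    rows = []
    for roi in rois:
        for metric in metrics:
            col = f"{roi}_{metric}"
            if col not in cohort.columns:
                continue
            row = {"roi": roi, "metric": metric}
            for g, gdf in cohort.groupby("group"):
                row[f"{g}_mean"] = gdf[col].mean()
                row[f"{g}_sd"] = gdf[col].std(ddof=1)
            for a, b in contrasts:
                cmp_ = glm_group_compare(cohort, metric, roi, (a, b))
                row[f"p_{a}_vs_{b}"] = cmp_.p
                row[f"effect_{a}_vs_{b}"] = cmp_.effect
            rows.append(row)
    out = pd.DataFrame(rows)
    if bonferroni:
        pcols = [c for c in out.columns if c.startswith("p_")]
        m = len(out) * len(pcols)
        for c in pcols:
            out[c + "_bonf"] = np.minimum(out[c] * m, 1.0)
    return out


# ---------------------------------------------------------------------------
# agreement and proportions

def cohen_kappa(confusion) -> tuple[float, str]:
    """Cohen's kappa of a square confusion-count table, with the
    conventional category label (poor/slight/fair/moderate/substantial/
    almost perfect)."""
    T = np.asarray(confusion, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("confusion table must be square")
    if np.any(T < 0) or not np.allclose(T, np.round(T)):
        raise ValueError("confusion table must hold nonnegative counts")
    total = T.sum()
    if total == 0:
        raise ValueError("confusion table is all zeros")
    po = np.trace(T) / total
    pe = float((T.sum(axis=0) * T.sum(axis=1)).sum()) / total ** 2
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    # scale: 0 poor; (0,0.2] slight; (0.2,0.4] fair; (0.4,0.6] moderate;
    # (0.6,0.8] substantial; (0.8,1] almost perfect.
    # boundaries compared on a rounded value so 0.6000000000000001 is 0.6
    k = round(kappa, 10)
    if k <= 0.0:
        label = "poor"
    elif k <= 0.20:
        label = "slight"
    elif k <= 0.40:
        label = "fair"
    elif k <= 0.60:
        label = "moderate"
    elif k <= 0.80:
        label = "substantial"
    else:
        label = "almost perfect"
    return float(kappa), label


def proportion(numerator: int, denominator: int) -> float:
    """Percentage 100*numerator/denominator, half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compare_proportions(a: tuple[int, int], b: tuple[int, int],
                        method: str = "auto") -> float:
    """Two-tailed p for a difference in proportions, a = (hits, n).

    ``auto`` (default): continuity-corrected chi-square, falling back to
    Fisher's exact test when any expected cell count is below 5.  ``chi2``,
    ``chi2_uncorrected`` and ``exact`` force a specific variant.
    """
    (k1, n1), (k2, n2) = a, b
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table < 0) or n1 <= 0 or n2 <= 0:
        raise ValueError("invalid 2x2 counts")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("degenerate margins in 2x2 table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if method == "auto":
        method = "exact" if expected.min() < 5 else "chi2"
    if method == "exact":
        return float(sps.fisher_exact(table.astype(int))[1])
    if method == "chi2":
        return float(sps.chi2_contingency(table, correction=True)[1])
    if method == "chi2_uncorrected":
        return float(sps.chi2_contingency(table, correction=False)[1])
    raise ValueError(f"unknown method {method!r}")
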