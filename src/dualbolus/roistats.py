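"""ROI summaries, the K^trans/rCBV decoupling analysis, and group tests.

K^trans is the permeability-surface product P_CA * S: it confounds how leaky
the capillary walls are (P_CA) with how much vessel wall there is (S).  Under
the cylindrical-vessel approximation CBV = S * d / 4, so the ratio

    K^trans / CBV = 4 * P_CA / d

cancels the surface area and isolates permeability per unit vessel caliber
(proportional to the extravasation rate constant k_pe).  A ratio that stays
flat while K^trans itself moves indicates that the K^trans changes are
driven by vascularization (S) rather than by wall permeability.  The ratio
is computed against contralateral-normalized rCBV, whose proportionality
constants cancel, matching how blood volume is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "roi_mean",
    "ktrans_over_rcbv",
    "DecouplingResult",
    "group_compare",
    "permutation_pvalue",
]

GROUPS = ("untreated", "cediranib", "SC68896", "combo")


def roi_mean(map_2d: np.ndarray, mask: np.ndarray, flags: np.ndarray | None = None) -> float:
    """Arithmetic mean of a map over unflagged masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if flags is not None:
        mask = mask & np.asarray(flags, dtype=bool)
    if not mask.any():
        raise ValueError("empty effective mask")
    return float(np.asarray(map_2d, dtype=float)[mask].mean())


@dataclass
class DecouplingResult:
    """Per-row K^trans/rCBV ratios plus group trends and contrasts."""

    ratios: pd.DataFrame          # input rows + 'ratio' column
    group_slopes: pd.DataFrame    # group, slope (per day), intercept, n
    overall_fit: dict             # slope/intercept of the fit to group means
    group_contrasts: pd.DataFrame # pairwise Welch t-tests on the ratios


def ktrans_over_rcbv(
    summary: pd.DataFrame,
    exclude_group_posttreatment: str | None = "SC68896",
    treatment_start_day: float = 0.0,
) -> DecouplingResult:
    """Decoupling analysis of per-animal-day ROI summaries.

    ``summary`` needs columns ``animal_id, group, day, mean_ktrans_per_min,
    rcbv``.  Computes the per-row ratio, a least-squares slope of ratio vs
    day within each group, an overall line fit to the group-by-day mean
    ratios (with the post-treatment means of ``exclude_group_posttreatment``
    excluded from that fit), and pairwise group contrasts (Welch t).
    """
    req = {"animal_id", "group", "day", "mean_ktrans_per_min", "rcbv"}
    missing = req - set(summary.columns)
    if missing:
        raise ValueError(f"summary missing columns {sorted(missing)}")
    if (summary["rcbv"] <= 0).any():
        raise ValueError("rcbv must be positive to form the ratio")
    df = summary.copy()
    df["ratio"] = df["mean_ktrans_per_min"] / df["rcbv"]

    slope_rows = []
    for g, sub in df.groupby("group", sort=False):
        if sub["day"].nunique() >= 2:
            fit = stats.linregress(sub["day"], sub["ratio"])
            slope, intercept = float(fit.slope), float(fit.intercept)
        else:
            slope, intercept = float("nan"), float(sub["ratio"].mean())
        slope_rows.append({"group": g, "slope_per_day": slope,
                           "intercept": intercept, "n": len(sub)})

    means = df.groupby(["group", "day"], as_index=False)["ratio"].mean()
    fit_means = means
    if exclude_group_posttreatment is not None:
        fit_means = means[~((means["group"] == exclude_group_posttreatment)
                            & (means["day"] > treatment_start_day))]
    if fit_means["day"].nunique() >= 2:
        ofit = stats.linregress(fit_means["day"], fit_means["ratio"])
        overall = {"slope_per_day": float(ofit.slope),
                   "intercept": float(ofit.intercept),
                   "n_means": int(len(fit_means))}
    else:
        overall = {"slope_per_day": float("nan"),
                   "intercept": float(fit_means["ratio"].mean()),
                   "n_means": int(len(fit_means))}

    contrast_rows = []
    for a, b in combinations(df["group"].unique(), 2):
        va = df.loc[df["group"] == a, "ratio"].to_numpy()
        vb = df.loc[df["group"] == b, "ratio"].to_numpy()
        if min(va.size, vb.size) >= 2 and (va.std() > 0 or vb.std() > 0):
            t, p = group_compare(va, vb, tail="two", welch=True)
        else:
            t, p = float("nan"), float("nan")
        contrast_rows.append({"group_a": a, "group_b": b, "t": t, "p": p})

    return DecouplingResult(
        ratios=df,
        group_slopes=pd.DataFrame(slope_rows),
        overall_fit=overall,
        group_contrasts=pd.DataFrame(contrast_rows),
    )


def group_compare(values_a, values_b, tail: str = "two", welch: bool = False):
    """Student's t test between two groups.

    ``tail="two"`` is the two-sided test; ``tail="one"`` tests the
    hypothesized direction mean(a) > mean(b).  ``welch=True`` drops the
    equal-variance assumption (Welch's correction).  Returns ``(t, p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("zero variance in both groups")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    alternative = "two-sided" if tail == "two" else "greater"
    res = stats.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def permutation_pvalue(values_a, values_b, tail: str = "two") -> float:
    """Exact permutation p-value for the difference in means.

    Enumerates every assignment of the pooled observations to the two group
    sizes (intended for n_a + n_b <= ~12, where the enumeration is exact).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    n = pooled.size
    na = a.size
    obs = a.mean() - b.mean()
    total = pooled.sum()
    count = 0
    n_perm = 0
    for idx in combinations(range(n), na):
        sa = pooled[list(idx)].sum()
        diff = sa / na - (total - sa) / (n - na)
        if tail == "two":
            hit = abs(diff) >= abs(obs) - 1e-12
        else:
            hit = diff >= obs - 1e-12
        count += hit
        n_perm += 1
    return count / n_perm
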