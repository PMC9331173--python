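"""Trait statistics: group comparison (ANOVA + Tukey HSD) and MLR.

Two analyses relate image-derived traits to experimental conditions:

* one-way ANOVA across water-treatment groups with Tukey's honestly-
  significant-difference post-hoc pairwise comparison at a 95% confidence
  level, with the usual significance stars (* p<0.05, ** p<0.01,
  *** p<0.001);
* multivariate linear regression (MLR) of a measured growth response
  (above-ground dry matter ADM, or the radiometer-measured extinction
  coefficient K) on a chosen combination of traits, scored by the Pearson
  correlation between fitted and measured response.

Measured responses are consumed from the trait table; K in particular is
never derived from images.  Canonical feature sets for both responses are
provided as :data:`ADM_FEATURE_SETS` and :data:`K_FEATURE_SETS`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: Trait combinations regressed against above-ground dry matter.
ADM_FEATURE_SETS = [
    ["f_tillers", "ph", "ala_deg", "la"],
    ["gpar", "par", "ph"],
    ["gpar", "par"],
    ["rhc", "ph"],
    ["fit_a", "fit_b", "rhc", "ph"],
    ["fit_a", "fit_b", "rhc"],
]

#: Trait combinations regressed against the extinction coefficient.
K_FEATURE_SETS = [
    ["f_tillers", "ph", "ala_deg", "la"],
    ["gpar", "par"],
    ["fit_a", "fit_b"],
]


class StatsError(ValueError):
    pass


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    trait: str
    f_stat: float
    p_value: float
    stars: str
    pairwise: pd.DataFrame          # group1, group2, meandiff, p_adj, stars
    degenerate: bool = False        # zero within-group variance convention used


@dataclass
class MLRResult:
    features: list[str]
    response: str
    coefficients: np.ndarray        # per feature
    intercept: float
    fitted: np.ndarray
    pearson_r: float
    dropped: list[str] = field(default_factory=list)


def anova_tukey(table: pd.DataFrame, trait: str, group_col: str) -> GroupComparison:
    """One-way ANOVA on a trait across groups, with Tukey HSD post hoc.

    Requires at least 2 groups with at least 2 observations each.  With zero
    within-group variance the F statistic is undefined; the limiting
    convention is reported instead (p -> 0 when any means differ, p = 1 when
    all observations are equal) with the ``degenerate`` flag set.
    """
    if trait not in table.columns or group_col not in table.columns:
        raise StatsError(f"columns {trait!r}/{group_col!r} not in table")
    sub = table[[trait, group_col]].dropna()
    groups = [g[trait].to_numpy(dtype=float) for _, g in sub.groupby(group_col)]
    names = [str(k) for k, _ in sub.groupby(group_col)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise StatsError("need >= 2 groups with >= 2 observations each")

    within_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    degenerate = within_ss == 0.0
    if degenerate:
        if np.ptp(means) == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = means[j] - means[i]
                p_adj = 1.0 if diff == 0.0 else 0.0
                rows.append((names[i], names[j], diff, p_adj,
                             significance_stars(p_adj)))
        pairwise = pd.DataFrame(
            rows, columns=["group1", "group2", "meandiff", "p_adj", "stars"]
        )
    else:
        f_stat, p = sps.f_oneway(*groups)
        tk = pairwise_tukeyhsd(
            sub[trait].to_numpy(dtype=float),
            sub[group_col].astype(str).to_numpy(),
            alpha=0.05,
        )
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=[c for c in tk.summary().data[0]]
        )[["group1", "group2", "meandiff", "p-adj"]].rename(
            columns={"p-adj": "p_adj"}
        )
        pairwise["stars"] = [significance_stars(v) for v in pairwise["p_adj"]]
    return GroupComparison(
        trait=trait,
        f_stat=float(f_stat),
        p_value=float(p),
        stars=significance_stars(float(p)),
        pairwise=pairwise,
        degenerate=degenerate,
    )


def mlr_fit(table: pd.DataFrame, features: list[str], response: str) -> MLRResult:
    """OLS regression of a measured response on a trait combination.

    Returns coefficients, intercept, fitted values and the Pearson
    correlation between fitted and measured response.  Collinear or constant
    feature columns are dropped (QR pivoting) with a warning.
    """
    missing = [c for c in [*features, response] if c not in table.columns]
    if missing:
        raise StatsError(f"columns missing from table: {missing}")
    sub = table[[*features, response]].dropna()
    n = len(sub)
    if n <= len(features) + 1:
        raise StatsError(
            f"need n > #features + 1 observations, got n={n} for "
            f"{len(features)} features"
        )
    X = sub[features].to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)

    keep = list(range(len(features)))
    dropped: list[str] = []
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # drop columns until full rank, preferring to keep earlier features
        keep = []
        base = np.ones((n, 1))
        for j in range(len(features)):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                base = cand
                keep.append(j)
            else:
                dropped.append(features[j])
        warnings.warn(
            f"collinear/constant features dropped from MLR: {dropped}",
            stacklevel=2,
        )
        design = base

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    if np.std(fitted) < 1e-12 or np.std(y) < 1e-12:
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    coefs = np.zeros(len(features))
    coefs[keep] = beta[1:]
    return MLRResult(
        features=list(features),
        response=response,
        coefficients=coefs,
        intercept=float(beta[0]),
        fitted=fitted,
        pearson_r=r,
        dropped=dropped,
    )
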