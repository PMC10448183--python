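"""Convergent validity: model features vs SIPS negative-symptom items.

Participants are dichotomised per item into symptom *absent* (score 0-1)
vs *present* (score >= 2) and each feature is compared between the two
groups with a two-sided Wilcoxon rank-sum test (tie-corrected normal
approximation; exact distribution for small untied samples).  Per-group
means with normal-theory 95% confidence intervals accompany each test.
No multiple-testing correction is applied by default, matching per-feature
reporting; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ABSENT = "absent"
PRESENT = "present"


def dichotomize_symptom(scores: Sequence[float]) -> np.ndarray:
    """SIPS item scores to absent (0-1) / present (>= 2); NaN stays missing."""
    x = np.asarray(scores, dtype=float)
    finite = x[np.isfinite(x)]
    if len(finite) and ((finite < 0) | (finite > 6)).any():
        raise ValueError("SIPS item scores must lie in [0, 6]")
    out = np.full(len(x), None, dtype=object)
    out[np.isfinite(x) & (x < 2)] = ABSENT
    out[np.isfinite(x) & (x >= 2)] = PRESENT
    return out


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    m = float(np.mean(x))
    if len(x) < 2:
        return m, np.nan, np.nan
    half = sps.t.ppf(0.5 + level / 2, len(x) - 1) * np.std(x, ddof=1) / np.sqrt(len(x))
    return m, m - half, m + half


@dataclasses.dataclass
class ValidityResult:
    feature: str
    item: str
    n_absent: int
    n_present: int
    statistic: float  # rank sum of the symptom-present group
    p_value: float
    mean_absent: float
    ci_absent: tuple[float, float]
    mean_present: float
    ci_present: tuple[float, float]
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def ranksum_test(
    feature_values: Sequence[float],
    groups: Sequence,
    *,
    feature: str = "",
    item: str = "",
    exact_max_n: int = 12,
) -> ValidityResult:
    """Two-sided Wilcoxon rank-sum test of a feature between two groups.

    ``groups`` holds ``absent``/``present`` labels (missing entries are
    dropped together with missing feature values).  The exact null
    distribution is used when both groups have at most ``exact_max_n``
    untied observations, otherwise the tie-corrected normal approximation
    (no continuity correction, so two identical samples give p = 1).
    """
    x = np.asarray(feature_values, dtype=float)
    g = np.asarray(groups, dtype=object)
    keep = np.isfinite(x) & np.isin(g, (ABSENT, PRESENT))
    x, g = x[keep], g[keep]
    a = x[g == ABSENT]
    b = x[g == PRESENT]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    ties = len(np.unique(x)) < len(x)
    if max(len(a), len(b)) <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        b, a, alternative="two-sided", method=method, use_continuity=False
    )
    ranksum = float(res.statistic) + len(b) * (len(b) + 1) / 2.0
    mean_a, lo_a, hi_a = _mean_ci(a)
    mean_b, lo_b, hi_b = _mean_ci(b)
    return ValidityResult(
        feature=feature,
        item=item,
        n_absent=len(a),
        n_present=len(b),
        statistic=ranksum,
        p_value=float(res.pvalue),
        mean_absent=mean_a,
        ci_absent=(lo_a, hi_a),
        mean_present=mean_b,
        ci_present=(lo_b, hi_b),
        method=method,
    )


def convergent_validity_table(
    features: pd.DataFrame,
    sips_scores: pd.DataFrame,
    items: Sequence[str] | None = None,
    feature_names: Sequence[str] | None = None,
    *,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Rank-sum tests of every (feature, item) combination.

    ``features``: participants x features; ``sips_scores``: participants x
    items, aligned on index.  Returns one row per combination; with
    ``bh_correction`` a Benjamini-Hochberg adjusted p column is added.
    """
    items = list(items) if items is not None else list(sips_scores.columns)
    feature_names = (
        list(feature_names) if feature_names is not None else list(features.columns)
    )
    scores_aligned = sips_scores.loc[features.index]
    rows = []
    for item in items:
        groups = dichotomize_symptom(scores_aligned[item].to_numpy(dtype=float))
        for name in feature_names:
            try:
                r = ranksum_test(
                    features[name].to_numpy(), groups, feature=name, item=item
                )
            except ValueError:
                continue
            rows.append(
                {
                    "feature": r.feature,
                    "item": r.item,
                    "n_absent": r.n_absent,
                    "n_present": r.n_present,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "mean_absent": r.mean_absent,
                    "mean_present": r.mean_present,
                    "method": r.method,
                }
            )
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
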