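"""Group statistics: 2-SD outlier removal, one-way ANOVA, Dunnett many-to-one comparisons.

Outlier removal is a single pass per arm: a value is dropped when it lies
more than k (default 2) sample standard deviations from its arm mean, both
computed including the candidate. Endpoints are then analyzed with a one-way
fixed-effects ANOVA and Dunnett's test against a designated reference arm
(two-sided, multivariate-t based via scipy); percent-of-reference
normalization is reporting-only — tests run on the raw scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateInputError
from .tfr import percent_of_reference

logger = logging.getLogger(__name__)

DEFAULT_K_SD = 2.0
STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Star annotation for an adjusted p-value (α tiers 0.05/0.01/0.001/0.0001)."""
    for tier, stars in STAR_TIERS:
        if p <= tier:
            return stars
    return "ns"


def remove_outliers(
    gt: pd.DataFrame, k: float = DEFAULT_K_SD,
    value_col: str = "value", arm_col: str = "arm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass per-arm outlier removal at ``k`` sample SDs.

    Returns ``(cleaned, removed)``. Arms with fewer than 3 values are left
    untouched; an all-equal arm (SD 0) removes nothing. Raises
    :class:`DegenerateInputError` if removal would leave an arm with fewer
    than 2 values.
    """
    keep = np.ones(len(gt), dtype=bool)
    for arm, grp in gt.groupby(arm_col, sort=False):
        v = grp[value_col].to_numpy(dtype=float)
        if len(v) < 3:
            continue
        sd = v.std(ddof=1)
        if sd == 0:
            continue
        bad = np.abs(v - v.mean()) > k * sd
        if bad.any() and (len(v) - bad.sum()) < 2:
            raise DegenerateInputError(f"arm {arm!r} reduced below 2 values by outlier removal")
        keep[gt.index.get_indexer(grp.index[bad])] = False
    removed = gt[~keep]
    if len(removed):
        logger.info("remove_outliers: removed %d values beyond %g SD", len(removed), k)
    return gt[keep].reset_index(drop=True), removed.reset_index(drop=True)


@dataclass
class StatsResult:
    """One endpoint's group-statistics summary."""

    endpoint: str
    f_stat: float
    df_between: int
    df_within: int
    p_anova: float
    comparisons: pd.DataFrame  # arm, n, mean_diff, p_dunnett, stars
    group_summary: pd.DataFrame  # arm, n, mean, sem, percent_mean, percent_sem
    outliers_removed: pd.DataFrame
    reference_arm: str


def anova_dunnett(
    gt: pd.DataFrame,
    reference_arm: str,
    endpoint: str = "endpoint",
    k_sd: float | None = DEFAULT_K_SD,
    value_col: str = "value",
    arm_col: str = "arm",
) -> StatsResult:
    """Outlier removal (optional), one-way ANOVA, and Dunnett tests vs the reference arm.

    ``k_sd=None`` skips outlier removal. Group means are also reported as
    percent of the reference-arm mean with SEMs on that scale; when the
    reference mean is not positive the percent columns are NaN and raw values
    stand alone.
    """
    arms = list(dict.fromkeys(gt[arm_col]))
    if reference_arm not in arms:
        raise ConfigurationError(f"reference arm {reference_arm!r} not present")
    if len(arms) < 2:
        raise ConfigurationError("need at least 2 arms")

    if k_sd is not None:
        clean, removed = remove_outliers(gt, k=k_sd, value_col=value_col, arm_col=arm_col)
    else:
        clean, removed = gt.reset_index(drop=True), gt.iloc[0:0]

    groups = {a: clean.loc[clean[arm_col] == a, value_col].to_numpy(dtype=float) for a in arms}
    if any(len(v) < 2 for v in groups.values()):
        raise DegenerateInputError("every arm needs >= 2 values after outlier removal")
    if all(np.var(v) == 0 for v in groups.values()):
        raise DegenerateInputError("zero within-group variance in every arm")

    f_stat, p_anova = sps.f_oneway(*groups.values())
    n_total = sum(len(v) for v in groups.values())
    df_between, df_within = len(arms) - 1, n_total - len(arms)

    treat_labels = [a for a in arms if a != reference_arm]
    # fixed rng: the QMC integration inside dunnett must not break run determinism
    dun = sps.dunnett(*[groups[a] for a in treat_labels], control=groups[reference_arm],
                      alternative="two-sided", rng=np.random.default_rng(718281828))
    ref_mean = groups[reference_arm].mean()
    comparisons = pd.DataFrame(
        {
            "arm": treat_labels,
            "n": [len(groups[a]) for a in treat_labels],
            "mean_diff": [groups[a].mean() - ref_mean for a in treat_labels],
            "p_dunnett": dun.pvalue,
        }
    )
    comparisons["stars"] = comparisons["p_dunnett"].map(significance_stars)

    try:
        pct = percent_of_reference(clean[value_col], clean[arm_col], reference_arm)
    except Exception:
        pct = pd.Series(np.nan, index=clean.index)
    summ_rows = []
    for a in arms:
        v = groups[a]
        pv = pct[clean[arm_col] == a].to_numpy(dtype=float)
        pv = pv[np.isfinite(pv)]
        summ_rows.append(
            {
                "arm": a,
                "n": len(v),
                "mean": v.mean(),
                "sem": v.std(ddof=1) / np.sqrt(len(v)),
                "percent_mean": pv.mean() if len(pv) else np.nan,
                "percent_sem": (pv.std(ddof=1) / np.sqrt(len(pv))) if len(pv) > 1 else np.nan,
            }
        )
    return StatsResult(
        endpoint=endpoint,
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_anova=float(p_anova),
        comparisons=comparisons,
        group_summary=pd.DataFrame(summ_rows),
        outliers_removed=removed,
        reference_arm=reference_arm,
    )


def build_report(results: dict[str, StatsResult]) -> pd.DataFrame:
    """Assemble per-endpoint results into one machine-readable table.

    One row per endpoint × arm: n, raw mean ± SEM, percent-of-reference mean
    ± SEM, Dunnett p and stars (reference-arm rows carry no comparison).
    Empty endpoints are skipped with a warning.
    """
    rows = []
    for name, res in results.items():
        if res is None:
            logger.warning("build_report: endpoint %r empty, omitted", name)
            continue
        pmap = res.comparisons.set_index("arm")
        for _, g in res.group_summary.iterrows():
            arm = g["arm"]
            is_ref = arm == res.reference_arm
            rows.append(
                {
                    "endpoint": name,
                    "arm": arm,
                    "n": int(g["n"]),
                    "mean": g["mean"],
                    "sem": g["sem"],
                    "percent_of_reference": g["percent_mean"],
                    "percent_sem": g["percent_sem"],
                    "anova_F": res.f_stat,
                    "anova_p": res.p_anova,
                    "p_dunnett": np.nan if is_ref else pmap.loc[arm, "p_dunnett"],
                    "stars": "" if is_ref else pmap.loc[arm, "stars"],
                }
            )
    return pd.DataFrame(rows)
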