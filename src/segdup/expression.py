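"""Expression and methylation contrasts for genes inside vs outside SDs.

Expression is compared on log10(RPKM + pseudocount) per condition with a
Welch two-sample t-test and a Bonferroni adjustment over the number of
conditions tested.  The same machinery serves per-gene methylation levels,
with the special case that an SD group with no methylation at all is
reported as such rather than tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class ConditionContrast:
    condition: str
    t_statistic: float
    p_raw: float
    p_adjusted: float
    mean_sd: float
    mean_other: float
    n_sd: int
    n_other: int
    direction: str  # sd_lower | sd_higher | equal


def _welch(x: np.ndarray, y: np.ndarray) -> tuple:
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def contrast_expression(
    table: pd.DataFrame,
    sd_gene_set: Iterable[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    alpha: float = 0.05,
    pooled: bool = False,
) -> List[ConditionContrast]:
    """Per-condition contrast of log expression, SD genes vs the rest.

    ``table`` needs columns gene_id / condition / rpkm with unique
    (gene, condition) rows and rpkm >= 0.  Bonferroni factor = number of
    conditions tested (1 when ``pooled``).  Conditions where either group
    has fewer than two genes are skipped with a warning.
    """
    if (table["rpkm"] < 0).any():
        raise ValueError("negative RPKM values")
    if table.duplicated(["gene_id", "condition"]).any():
        raise ValueError("duplicate (gene, condition) rows")
    sd = set(sd_gene_set)
    work = table.copy()
    work["log_value"] = np.log10(work["rpkm"] + pseudocount)
    work["in_sd"] = work["gene_id"].isin(sd)
    if pooled:
        groups = [("pooled", work)]
    else:
        groups = list(work.groupby("condition", sort=True))
    results: List[ConditionContrast] = []
    import logging

    log = logging.getLogger(__name__)
    for cond, sub in groups:
        x = sub.loc[sub["in_sd"], "log_value"].to_numpy()
        y = sub.loc[~sub["in_sd"], "log_value"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            log.warning("condition %s skipped: a group has < 2 genes", cond)
            continue
        t, p = _welch(x, y)
        direction = (
            "sd_lower" if x.mean() < y.mean()
            else ("sd_higher" if x.mean() > y.mean() else "equal")
        )
        results.append(
            ConditionContrast(
                condition=str(cond),
                t_statistic=t,
                p_raw=p,
                p_adjusted=p,  # filled below
                mean_sd=float(x.mean()),
                mean_other=float(y.mean()),
                n_sd=len(x),
                n_other=len(y),
                direction=direction,
            )
        )
    factor = len(results)
    for r in results:
        r.p_adjusted = min(1.0, r.p_raw * factor)
    return results


@dataclass
class MethylationContrast:
    sd_all_zero: bool
    t_statistic: Optional[float]
    p_value: Optional[float]
    mean_sd: float
    mean_other: float
    n_sd: int
    n_other: int
    note: str = ""


def contrast_methylation(
    table: pd.DataFrame, sd_gene_set: Iterable[str]
) -> MethylationContrast:
    """Contrast per-gene methylation levels (values in [0, 1]).

    When the SD group carries no methylation at all the result reports
    that finding directly and performs no test.
    """
    if ((table["level"] < 0) | (table["level"] > 1)).any():
        raise ValueError("methylation levels must lie in [0, 1]")
    sd = set(sd_gene_set)
    x = table.loc[table["gene_id"].isin(sd), "level"].to_numpy(dtype=float)
    y = table.loc[~table["gene_id"].isin(sd), "level"].to_numpy(dtype=float)
    if len(x) and (x == 0).all():
        return MethylationContrast(
            sd_all_zero=True,
            t_statistic=None,
            p_value=None,
            mean_sd=0.0,
            mean_other=float(y.mean()) if len(y) else math.nan,
            n_sd=len(x),
            n_other=len(y),
            note="no methylation in SD gene bodies",
        )
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two genes per group for a test")
    t, p = _welch(x, y)
    return MethylationContrast(
        sd_all_zero=False,
        t_statistic=t,
        p_value=p,
        mean_sd=float(x.mean()),
        mean_other=float(y.mean()),
        n_sd=len(x),
        n_other=len(y),
    )


def summary_table(
    table: pd.DataFrame, sd_gene_set: Iterable[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Boxplot-style summary: per condition and group, median and quartiles
    of log10(RPKM + pseudocount)."""
    sd = set(sd_gene_set)
    work = table.copy()
    work["log_value"] = np.log10(work["rpkm"] + pseudocount)
    work["group"] = np.where(work["gene_id"].isin(sd), "sd", "other")
    rows = []
    for (cond, grp), sub in work.groupby(["condition", "group"], sort=True):
        q1, med, q3 = np.percentile(sub["log_value"], [25, 50, 75])
        rows.append({"condition": cond, "group": grp, "q1": q1, "median": med, "q3": q3,
                     "n": len(sub)})
    return pd.DataFrame(rows)
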