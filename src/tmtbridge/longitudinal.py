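"""Longitudinal (stage-vs-myoblast) analysis and the MR call.

Within one condition, every protein's early-myotube/myoblast (EM_vs_M) and
late-myotube/myoblast (LM_vs_M) log2 fold change is the difference of group
means of log2 bridged abundances, tested with a two-tailed pooled-variance
Student t test and BH-adjusted per comparison family. A protein is
myogenically regulated (MR) when BOTH comparisons are significant
(adjusted p <= alpha) AND EITHER |log2FC| clears the magnitude threshold
(default 1, i.e. a two-fold change).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .normalize import BridgedAbundance
from .stats import bh_adjust, pooled_ttest_rows

COMPARISONS = {"EM_vs_M": ("EM", "M"), "LM_vs_M": ("LM", "M")}


def stage_ratio(
    bridged: BridgedAbundance, condition: str, comparison: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein ratio results for one condition and one comparison family.

    Proteins with fewer than 2 quantified replicates in either group are
    excluded from the family (not just given NaN). Columns: condition,
    comparison, log2fc, t, df, p_value, adj_p, n_stage, n_m, degenerate.
    """
    if comparison not in COMPARISONS:
        raise ValidationError(f"unknown comparison {comparison!r}")
    later, base = COMPARISONS[comparison]
    a = bridged.group_values(condition, later).to_numpy()
    b = bridged.group_values(condition, base).to_numpy()
    res = pooled_ttest_rows(a, b, equal_var=equal_var)
    res.index = bridged.log2.index
    res = res[res["p_value"].notna()].copy()
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    res.insert(0, "comparison", comparison)
    res.insert(0, "condition", condition)
    return res.rename(columns={"n_a": "n_stage", "n_b": "n_m"})


def stage_ratios(
    bridged: BridgedAbundance, condition: str, equal_var: bool = True
) -> pd.DataFrame:
    """Both comparison families for one condition, stacked long."""
    return pd.concat(
        [stage_ratio(bridged, condition, cmp, equal_var=equal_var) for cmp in COMPARISONS],
        axis=0,
    )


def call_mr(
    ratios: pd.DataFrame, alpha: float = 0.05, fc_threshold_log2: float = 1.0
) -> pd.DataFrame:
    """Apply the MR rule to stacked ratio results of one condition.

    Proteins missing either comparison are excluded. Returns per protein:
    is_mr, passed_significance_both, passed_magnitude_either, plus the two
    log2fc and adj_p values (columns suffixed _em and _lm).
    """
    em = ratios[ratios["comparison"] == "EM_vs_M"]
    lm = ratios[ratios["comparison"] == "LM_vs_M"]
    both = em.index.intersection(lm.index)
    em = em.loc[both]
    lm = lm.loc[both]
    sig = (em["adj_p"] <= alpha) & (lm["adj_p"] <= alpha)
    mag = (em["log2fc"].abs() >= fc_threshold_log2) | (lm["log2fc"].abs() >= fc_threshold_log2)
    return pd.DataFrame(
        {
            "log2fc_em": em["log2fc"],
            "log2fc_lm": lm["log2fc"],
            "adj_p_em": em["adj_p"],
            "adj_p_lm": lm["adj_p"],
            "passed_significance_both": sig,
            "passed_magnitude_either": mag,
            "is_mr": sig & mag,
        },
        index=both,
    )


def mr_analysis(
    bridged: BridgedAbundance,
    condition: str,
    alpha: float = 0.05,
    fc_threshold_log2: float = 1.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Ratios plus MR calls for one condition in one call."""
    return call_mr(
        stage_ratios(bridged, condition, equal_var=equal_var), alpha, fc_threshold_log2
    )


def mr_set(calls: pd.DataFrame) -> set[str]:
    return set(calls.index[calls["is_mr"]])


def _standardize(x: pd.Series) -> pd.Series:
    """Median-center, population-SD scale (the trajectory convention)."""
    sd = float(np.std(x.to_numpy(), ddof=0))
    if sd == 0 or not np.isfinite(sd):
        return pd.Series(np.nan, index=x.index)
    return (x - float(np.median(x))) / sd


def marker_report(
    bridged: BridgedAbundance,
    markers: list[str],
    conditions: tuple[str, ...] = ("untreated", "vehicle", "tmx"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardized marker trajectories with stagewise significance flags.

    For each quantified marker and condition: the standardized log2 mean
    myoblast intensity, the standardized EM_vs_M and LM_vs_M log2FC (each
    component standardized over the marker panel, median 0 / SD 1), and the
    BH-adjusted p-values from the full-proteome families. Markers absent from
    the data are returned separately, not raised.
    """
    present = [m for m in markers if m in bridged.log2.index]
    absent = [m for m in markers if m not in bridged.log2.index]
    rows = []
    for condition in conditions:
        ratios = stage_ratios(bridged, condition)
        em = ratios[ratios["comparison"] == "EM_vs_M"]
        lm = ratios[ratios["comparison"] == "LM_vs_M"]
        m_mean = bridged.group_values(condition, "M").loc[present].mean(axis=1)
        usable = [p for p in present if p in em.index and p in lm.index]
        frame = pd.DataFrame(
            {
                "condition": condition,
                "m_log2_std": _standardize(m_mean.loc[usable]),
                "log2fc_em_std": _standardize(em.loc[usable, "log2fc"]),
                "log2fc_lm_std": _standardize(lm.loc[usable, "log2fc"]),
                "adj_p_em": em.loc[usable, "adj_p"],
                "adj_p_lm": lm.loc[usable, "adj_p"],
            },
            index=usable,
        )
        frame["significant_both_stages"] = (
            (frame["adj_p_em"] <= alpha) & (frame["adj_p_lm"] <= alpha)
        )
        rows.append(frame)
    report = pd.concat(rows, axis=0)
    report.index.name = "protein_id"
    return report, absent
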