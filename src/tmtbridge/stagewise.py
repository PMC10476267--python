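"""Within-multiplex vehicle-corrected differential expression.

Within each multiplex (stage), the log2 values of the vehicle and TMX+vehicle
channels are expressed relative to the per-protein mean of the untreated
replicates in that same multiplex. Because TMX is dissolved in the vehicle,
any solvent effect loads on both corrected groups and cancels in the
TMX-vs-vehicle contrast; the correction therefore isolates the TMX-specific
effect. DE at a stage requires |log2FC| >= 1 and BH-adjusted p strictly
below alpha (the -log10 adjusted p >= 1.3 convention at alpha = 0.05) — note
the strict inequality, unlike the MR rule's <=.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .normalize import BridgedAbundance
from .stats import bh_adjust, pooled_ttest_rows

STAGES = ("M", "EM", "LM")


def vehicle_correct(
    bridged: BridgedAbundance, stage: str
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Baseline-correct vehicle and TMX channels at one stage.

    corrected(channel) = log2(channel) - mean(log2 untreated replicates of
    that protein, same multiplex). Returns (corrected TMX frame, corrected
    vehicle frame, excluded protein IDs); a protein with no quantified
    untreated replicate at the stage has no baseline and is excluded there.
    """
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    untreated = bridged.group_values("untreated", stage)
    baseline = untreated.mean(axis=1)  # NaN-aware; NaN if no untreated value
    excluded = list(baseline.index[baseline.isna()])
    kept = baseline.index[baseline.notna()]
    tmx = bridged.group_values("tmx", stage).loc[kept].sub(baseline.loc[kept], axis=0)
    veh = bridged.group_values("vehicle", stage).loc[kept].sub(baseline.loc[kept], axis=0)
    return tmx, veh, excluded


def stage_de(
    bridged: BridgedAbundance,
    stage: str,
    alpha: float = 0.05,
    fc_threshold_log2: float = 1.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """TMX-vs-vehicle DE calls at one stage across the whole proteome.

    Pooled-variance two-tailed t test on corrected log2 values, BH over all
    proteins tested at the stage. Columns: stage, log2fc, t, df, p_value,
    adj_p, n_tmx, n_vehicle, degenerate, is_de.
    """
    tmx, veh, _excluded = vehicle_correct(bridged, stage)
    res = pooled_ttest_rows(tmx.to_numpy(), veh.to_numpy(), equal_var=equal_var)
    res.index = tmx.index
    res = res[res["p_value"].notna()].copy()
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    res["is_de"] = (res["log2fc"].abs() >= fc_threshold_log2) & (res["adj_p"] < alpha)
    res.insert(0, "stage", stage)
    return res.rename(columns={"n_a": "n_tmx", "n_b": "n_vehicle"})


def de_all_stages(
    bridged: BridgedAbundance, alpha: float = 0.05, fc_threshold_log2: float = 1.0
) -> dict[str, pd.DataFrame]:
    return {s: stage_de(bridged, s, alpha, fc_threshold_log2) for s in STAGES}


def de_set(calls: pd.DataFrame) -> set[str]:
    return set(calls.index[calls["is_de"]])


def de_union(calls_by_stage: dict[str, pd.DataFrame]) -> set[str]:
    """Proteins DE at one or more stages (a protein DE twice counts once)."""
    out: set[str] = set()
    for calls in calls_by_stage.values():
        out |= de_set(calls)
    return out
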