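"""Set logic combining MR calls across conditions and DE calls across stages.

The three-condition Venn partition of MR sets isolates vehicle(solvent)-only
regulation: proteins regulated only when the vehicle is present (the regions
containing vehicle but not untreated) are removed from the TMX longitudinal
set before clustering. DE calls are intersected with MR sets to separate TMX
effects inside vs outside the myogenic program, and proteins DE at two or
more stages are flagged as highly regulated.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

VENN_REGIONS = (
    "untreated_only", "vehicle_only", "tmx_only",
    "untreated_vehicle", "untreated_tmx", "vehicle_tmx",
    "all_three",
)


def mr_venn(
    untreated: set[str], vehicle: set[str], tmx: set[str]
) -> dict[str, set[str]]:
    """Exact seven-region partition of the three MR sets."""
    return {
        "untreated_only": untreated - vehicle - tmx,
        "vehicle_only": vehicle - untreated - tmx,
        "tmx_only": tmx - untreated - vehicle,
        "untreated_vehicle": (untreated & vehicle) - tmx,
        "untreated_tmx": (untreated & tmx) - vehicle,
        "vehicle_tmx": (vehicle & tmx) - untreated,
        "all_three": untreated & vehicle & tmx,
    }


def venn_sizes(partitions: dict[str, set[str]]) -> dict[str, int]:
    return {region: len(partitions[region]) for region in VENN_REGIONS}


def exclude_vehicle_only(partitions: dict[str, set[str]]) -> set[str]:
    """TMX clustering input: the TMX MR set minus vehicle-dependent regions.

    Kept regions: regulated in all three conditions, in TMX only, and in
    untreated+TMX only. Removed: TMX regions that require the vehicle without
    the untreated condition (regulation attributable to the solvent).
    """
    return (
        partitions["all_three"]
        | partitions["tmx_only"]
        | partitions["untreated_tmx"]
    )


def de_mr_intersections(
    de_total: set[str], mr_untreated: set[str], mr_tmx: set[str]
) -> dict[str, set[str]]:
    """Split the DE union by its relation to the myogenic program.

    ``de_and_mr_untreated``: TMX-DE proteins inside the normal program;
    ``added_to_program``: DE proteins MR under TMX but not untreated (added
    to the program by treatment); ``outside_program``: DE in neither MR set.
    """
    return {
        "de_and_mr_untreated": de_total & mr_untreated,
        "added_to_program": (de_total & mr_tmx) - mr_untreated,
        "outside_program": de_total - mr_untreated - mr_tmx,
    }


def highly_regulated(
    calls_by_stage: dict[str, pd.DataFrame], min_stages: int = 2
) -> pd.DataFrame:
    """Proteins DE at >= ``min_stages`` stages, with per-stage flags.

    Sorted by descending stage count then protein ID. Columns: one boolean
    ``de_<stage>`` per stage plus ``n_stages``.
    """
    union = sorted(set().union(*(set(c.index) for c in calls_by_stage.values())))
    frame = pd.DataFrame(
        {
            f"de_{stage}": calls["is_de"].reindex(union, fill_value=False).astype(bool)
            for stage, calls in calls_by_stage.items()
        },
        index=union,
    )
    if frame.empty:
        frame["n_stages"] = pd.Series(dtype=int)
        frame.index.name = "protein_id"
        return frame
    frame["n_stages"] = frame.sum(axis=1)
    frame = frame[frame["n_stages"] >= min_stages]
    frame = (
        frame.assign(_pid=frame.index.astype(str))
        .sort_values(["n_stages", "_pid"], ascending=[False, True])
        .drop(columns="_pid")
    )
    frame.index.name = "protein_id"
    return frame


def external_overlap(mr_set: set[str], reference: set[str]) -> tuple[int, int]:
    """Overlap of an MR set with a caller-supplied homolog reference list.

    Returns (|intersection|, percent of the reference covered, rounded to the
    nearest integer). The homolog mapping is an input; no ortholog lookup is
    performed.
    """
    if not reference:
        raise ValidationError("reference protein list is empty")
    inter = len(mr_set & reference)
    return inter, int(round(100.0 * inter / len(reference)))
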