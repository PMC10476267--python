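"""Reading, writing and validation of reporter matrices and multiplex designs.

The on-disk format is plain TSV throughout. A reporter matrix has one row per
protein (first column ``protein_id``) and one column per TMT channel; a design
file maps every (multiplex, channel) pair to a condition, a myogenic stage and
a replicate index, or marks it as the bridge channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

#: Canonical TMT 10-plex reporter labels, low to high mass.
TMT10_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
)

CONDITIONS = ("untreated", "vehicle", "tmx")
TIMEPOINTS = ("M", "EM", "LM")
BRIDGE = "bridge"

DESIGN_COLUMNS = ("multiplex", "channel", "condition", "timepoint", "replicate", "is_bridge")


@dataclass(frozen=True)
class MultiplexDesign:
    """Validated channel layout for a set of TMT multiplexes.

    ``entries`` has columns multiplex, channel, condition, timepoint,
    replicate (nullable Int64) and is_bridge (bool). Sample channels of one
    multiplex all share a single timepoint; each multiplex carries exactly one
    bridge channel, and every condition has exactly three replicates per
    timepoint.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_design(self.entries)

    @property
    def multiplexes(self) -> list[str]:
        return list(dict.fromkeys(self.entries["multiplex"]))

    def timepoint_of(self, multiplex: str) -> str:
        rows = self.entries[(self.entries["multiplex"] == multiplex) & ~self.entries["is_bridge"]]
        if rows.empty:
            raise DesignError(f"unknown multiplex {multiplex!r}")
        return rows["timepoint"].iloc[0]

    def multiplex_of_timepoint(self, timepoint: str) -> str:
        rows = self.entries[(self.entries["timepoint"] == timepoint) & ~self.entries["is_bridge"]]
        if rows.empty:
            raise DesignError(f"no multiplex covers timepoint {timepoint!r}")
        return rows["multiplex"].iloc[0]

    def channels(self, multiplex: str) -> list[str]:
        rows = self.entries[self.entries["multiplex"] == multiplex]
        return list(rows["channel"])

    def bridge_channel(self, multiplex: str) -> str:
        rows = self.entries[(self.entries["multiplex"] == multiplex) & self.entries["is_bridge"]]
        if rows.empty:
            raise DesignError(f"multiplex {multiplex!r} has no bridge channel")
        return rows["channel"].iloc[0]

    def sample_channels(
        self, multiplex: str, condition: str | None = None
    ) -> list[str]:
        rows = self.entries[(self.entries["multiplex"] == multiplex) & ~self.entries["is_bridge"]]
        if condition is not None:
            rows = rows[rows["condition"] == condition]
        return list(rows["channel"])


def _validate_design(df: pd.DataFrame) -> None:
    missing = [c for c in ("multiplex", "channel", "condition", "timepoint") if c not in df.columns]
    if missing:
        raise DesignError(f"design is missing columns: {missing}")
    bad_cond = set(df["condition"]) - set(CONDITIONS) - {BRIDGE}
    if bad_cond:
        raise DesignError(f"unknown conditions in design: {sorted(bad_cond)}")
    bad_tp = set(df.loc[df["condition"] != BRIDGE, "timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise DesignError(f"unknown timepoints in design: {sorted(bad_tp)}")

    dup_chan = df.duplicated(subset=["multiplex", "channel"])
    if dup_chan.any():
        dups = df.loc[dup_chan, ["multiplex", "channel"]].to_records(index=False).tolist()
        raise DesignError(f"duplicate (multiplex, channel) pairs: {dups}")

    for mux, grp in df.groupby("multiplex", sort=False):
        n_bridge = int(grp["is_bridge"].sum())
        if n_bridge != 1:
            raise DesignError(f"multiplex {mux!r} has {n_bridge} bridge channels; expected exactly 1")
        tps = set(grp.loc[~grp["is_bridge"], "timepoint"])
        if len(tps) != 1:
            raise DesignError(
                f"multiplex {mux!r} sample channels span timepoints {sorted(tps)}; expected one"
            )

    samples = df[~df["is_bridge"]]
    triple = samples[["condition", "timepoint", "replicate"]]
    dup = triple.duplicated()
    if dup.any():
        dups = triple[dup].to_records(index=False).tolist()
        raise DesignError(f"duplicate (condition, timepoint, replicate) triples: {dups}")
    counts = samples.groupby(["condition", "timepoint"], sort=False)["replicate"].nunique()
    wrong = counts[counts != 3]
    if not wrong.empty:
        raise DesignError(
            "expected exactly 3 replicates per condition per timepoint; got "
            + "; ".join(f"{idx}: {n}" for idx, n in wrong.items())
        )


def default_design(
    multiplex_ids: Sequence[str] = TIMEPOINTS,
    timepoints: Sequence[str] = TIMEPOINTS,
    channels: Sequence[str] = TMT10_CHANNELS,
) -> MultiplexDesign:
    """The study layout: one 10-plex per stage, 3 conditions x 3 replicates + bridge.

    Channels are assigned in label order: untreated r1-3, vehicle r1-3,
    tmx r1-3, bridge last.
    """
    rows = []
    for mux, tp in zip(multiplex_ids, timepoints):
        i = 0
        for cond in CONDITIONS:
            for rep in (1, 2, 3):
                rows.append((mux, channels[i], cond, tp, rep, False))
                i += 1
        rows.append((mux, channels[i], BRIDGE, tp, pd.NA, True))
    df = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    df["replicate"] = df["replicate"].astype("Int64")
    return MultiplexDesign(df)


def read_design(path: str | Path) -> MultiplexDesign:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"design file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"multiplex": str, "channel": str})
    if "is_bridge" not in df.columns:
        df["is_bridge"] = df["condition"] == BRIDGE
    df["is_bridge"] = df["is_bridge"].astype(bool)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    return MultiplexDesign(df[list(DESIGN_COLUMNS)])


def write_design(design: MultiplexDesign, path: str | Path) -> None:
    design.entries.to_csv(path, sep="\t", index=False)


@dataclass
class ReporterMatrix:
    """Raw (or normalized) reporter intensities for one multiplex.

    ``data`` is proteins x channels, nonnegative and finite; zeros are legal
    on read and treated as missing downstream (log2 of 0 is undefined; absence
    of reporter signal means the protein was not quantified in that channel).
    """

    multiplex_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise FormatError(f"duplicate protein IDs in multiplex {self.multiplex_id!r}: {dup}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError(f"non-finite intensities in multiplex {self.multiplex_id!r}")
        if (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)].tolist()
            raise FormatError(
                f"negative intensities in multiplex {self.multiplex_id!r} for proteins {bad[:5]}"
            )
        self.data = self.data.astype(float)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.data.columns)


def read_reporter_matrix(
    path: str | Path, design: MultiplexDesign, multiplex_id: str
) -> ReporterMatrix:
    """Read one multiplex TSV and validate its channels against the design."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col="protein_id", float_precision="round_trip")
    df.index = df.index.astype(str)
    expected = set(design.channels(multiplex_id))
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise FormatError(
            f"channel columns {unknown} in {path.name} are absent from the design "
            f"for multiplex {multiplex_id!r}"
        )
    missing = sorted(expected - set(df.columns))
    if missing:
        raise FormatError(f"matrix {path.name} is missing design channels {missing}")
    return ReporterMatrix(multiplex_id, df[design.channels(multiplex_id)])


def write_reporter_matrix(matrix: ReporterMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="protein_id")


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a result table as TSV (full-precision decimal text)."""
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, float_precision="round_trip")


def intersect_proteins(matrices: Iterable[ReporterMatrix]) -> list[str]:
    """Protein IDs quantified in every multiplex, in first-matrix order."""
    mats = list(matrices)
    common = set(mats[0].protein_ids)
    for m in mats[1:]:
        common &= set(m.protein_ids)
    return [p for p in mats[0].protein_ids if p in common]
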