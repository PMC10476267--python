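"""Two-layer cross-multiplex normalization.

Layer 1 (``channel_normalize``) is a sample-loading correction: every
channel's intensities are rescaled so all channel totals equal the grand mean
of the channel totals across all multiplexes. Layer 2 (``bridge_correct``)
aligns multiplexes per protein: each protein's log2 values in a non-reference
multiplex are shifted by the log2 difference between its bridge value in the
reference multiplex and its bridge value there. Because the bridge sample is
identical in every multiplex, that offset is an estimate of the multiplex
batch term and cancels it exactly in the noiseless limit.

Zero intensities are treated as missing (log2 undefined); a protein with a
missing bridge in any multiplex cannot be aligned and is dropped (and listed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NormalizationError
from .io import MultiplexDesign, ReporterMatrix, intersect_proteins


def channel_normalize(
    matrices: list[ReporterMatrix],
) -> tuple[list[ReporterMatrix], pd.Series]:
    """Scale every channel to the grand-mean channel total.

    Operates on the intersection of the protein universes so every channel
    total is computed over the same proteins. Returns the rescaled matrices
    and the per-channel scale factors (indexed by "multiplex:channel").
    """
    if not matrices:
        raise NormalizationError("no matrices given")
    common = intersect_proteins(matrices)
    if not common:
        raise NormalizationError("protein intersection across multiplexes is empty")

    totals: dict[str, float] = {}
    for mat in matrices:
        sub = mat.data.loc[common]
        for ch in mat.channel_ids:
            totals[f"{mat.multiplex_id}:{ch}"] = float(sub[ch].sum())
    zero = [k for k, v in totals.items() if v == 0]
    if zero:
        raise NormalizationError(f"channel total is zero for: {zero}")

    grand_mean = float(np.mean(list(totals.values())))
    factors = pd.Series({k: grand_mean / v for k, v in totals.items()}, name="scale_factor")

    scaled = []
    for mat in matrices:
        data = mat.data.loc[common].copy()
        for ch in mat.channel_ids:
            data[ch] = data[ch] * factors[f"{mat.multiplex_id}:{ch}"]
        scaled.append(ReporterMatrix(mat.multiplex_id, data))
    return scaled, factors


@dataclass
class BridgedAbundance:
    """Log2 abundances aligned across multiplexes via the bridge channel.

    ``log2`` holds the 27 sample channels (columns "multiplex:channel", NaN =
    not quantified in that channel); ``bridge_log2`` holds the corrected
    per-multiplex bridge values, identical across multiplexes by construction.
    """

    log2: pd.DataFrame = field(repr=False)
    bridge_log2: pd.DataFrame = field(repr=False)
    design: MultiplexDesign
    reference: str
    dropped: list[str] = field(default_factory=list)
    channel_factors: pd.Series | None = None

    @property
    def protein_ids(self) -> list[str]:
        return list(self.log2.index)

    def columns_for(self, condition: str, timepoint: str) -> list[str]:
        """Sample columns of one condition at one stage (its multiplex)."""
        mux = self.design.multiplex_of_timepoint(timepoint)
        return [f"{mux}:{ch}" for ch in self.design.sample_channels(mux, condition)]

    def group_values(self, condition: str, timepoint: str) -> pd.DataFrame:
        return self.log2[self.columns_for(condition, timepoint)]


def bridge_correct(
    matrices: list[ReporterMatrix],
    design: MultiplexDesign,
    reference: str = "M",
    channel_factors: pd.Series | None = None,
) -> BridgedAbundance:
    """Per-protein bridge alignment of all multiplexes to the reference.

    For protein p in multiplex m, offset(p, m) = log2 bridge(p, reference) -
    log2 bridge(p, m) is added to every log2 channel value of p in m. The
    reference multiplex is unchanged. Proteins with a zero bridge anywhere are
    dropped and reported in ``dropped``.
    """
    muxes = [m.multiplex_id for m in matrices]
    if reference not in muxes:
        raise ConfigurationError(f"reference multiplex {reference!r} not among {muxes}")
    by_id = {m.multiplex_id: m for m in matrices}
    common = intersect_proteins(matrices)

    with np.errstate(divide="ignore"):
        log2 = {
            mux: np.log2(by_id[mux].data.loc[common].where(by_id[mux].data.loc[common] > 0))
            for mux in muxes
        }

    bridge_cols = {mux: design.bridge_channel(mux) for mux in muxes}
    bridge_raw = pd.DataFrame({mux: log2[mux][bridge_cols[mux]] for mux in muxes})
    ok = bridge_raw.notna().all(axis=1)
    dropped = [p for p in common if not ok[p]]
    kept = [p for p in common if ok[p]]
    if not kept:
        raise NormalizationError("no protein has a positive bridge value in all multiplexes")

    sample_frames = []
    bridge_corrected = {}
    for mux in muxes:
        offset = bridge_raw.loc[kept, reference] - bridge_raw.loc[kept, mux]
        frame = log2[mux].loc[kept].add(offset, axis=0)
        bridge_corrected[mux] = frame[bridge_cols[mux]]
        samples = frame[design.sample_channels(mux)]
        samples.columns = [f"{mux}:{ch}" for ch in samples.columns]
        sample_frames.append(samples)

    return BridgedAbundance(
        log2=pd.concat(sample_frames, axis=1),
        bridge_log2=pd.DataFrame(bridge_corrected),
        design=design,
        reference=reference,
        dropped=dropped,
        channel_factors=channel_factors,
    )


def normalize(
    matrices: list[ReporterMatrix],
    design: MultiplexDesign,
    reference: str = "M",
    channel_normalization: bool = True,
) -> BridgedAbundance:
    """Full normalization: channel scaling (optional) then bridge correction."""
    factors = None
    if channel_normalization:
        matrices, factors = channel_normalize(matrices)
    return bridge_correct(matrices, design, reference=reference, channel_factors=factors)


def bridge_spread(bridged: BridgedAbundance) -> float:
    """Max over proteins of the log2 bridge spread across multiplexes.

    Zero (to floating tolerance) certifies that the multiplexes are aligned.
    """
    b = bridged.bridge_log2
    return float((b.max(axis=1) - b.min(axis=1)).abs().max())
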