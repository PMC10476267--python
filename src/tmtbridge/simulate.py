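"""Synthetic bridged-TMT data with a ledger of planted effects.

The generator emulates the study design: three 10-plex multiplexes, one per
myogenic stage (M = myoblast, EM = early myotube, LM = late myotube), each
carrying {untreated, vehicle, TMX} x 3 replicates plus one identical bridge
channel. Protein programs follow five trajectory archetypes (the canonical
cluster shapes), treatment effects are additive on the log2 scale, and
measurement noise is multiplicative (additive Gaussian on log2) because TMT
reporter CVs are approximately constant on the log scale.

The bridge channel is a linear-scale mean of one designated replicate per
condition x timepoint, so its expectation is identical across multiplexes
before the per-multiplex batch and per-channel loading factors — exactly the
property bridge correction exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    CONDITIONS,
    TIMEPOINTS,
    MultiplexDesign,
    ReporterMatrix,
    default_design,
    write_design,
    write_reporter_matrix,
    write_table,
)

#: Archetype (M, EM, LM) log2 offsets. C5's +2 jump (a quadrupling between the
#: M and EM stages, held through LM) is the one magnitude anchored to the
#: biology; the others encode the qualitative cluster trends and are
#: configurable.
DEFAULT_ARCHETYPE_OFFSETS: Mapping[str, tuple[float, float, float]] = {
    "C1_decrease": (0.0, -1.0, -2.0),
    "C2_dip_recover": (0.0, -1.0, 0.5),
    "C3_peak_EM": (0.0, 1.0, 0.0),
    "C4_gradual_up": (0.0, 0.7, 1.4),
    "C5_early_jump": (0.0, 2.0, 2.0),
}

FLAT = "flat"

#: Archetype prevalences per 10,000 quantified proteins, mirroring the
#: observed cluster sizes (306/346/182/166/62 of ~10,000).
DEFAULT_FRACTIONS: Mapping[str, float] = {
    "C1_decrease": 0.0306,
    "C2_dip_recover": 0.0346,
    "C3_peak_EM": 0.0182,
    "C4_gradual_up": 0.0166,
    "C5_early_jump": 0.0062,
}

#: Planted treatment effects: (condition, timepoint(s), log2 effect, fraction).
#: "vehicle" effects load on both vehicle and TMX channels (TMX is dissolved in
#: the vehicle); "tmx" effects are TMX-specific. Comma-joined timepoints put
#: the effect at several stages in the same protein subset. Fractions chosen so
#: a 10,000-protein run plants ~150 vehicle-only regulated proteins, per-stage
#: TMX-specific DE of ~145/5/63, and ~10 multi-stage ("highly regulated")
#: proteins of which ~1 is affected at all three stages.
DEFAULT_EFFECT_GRID: tuple[tuple[str, str, float, float], ...] = (
    ("vehicle", "EM,LM", 1.5, 0.0150),
    ("tmx", "M", -1.5, 0.0135),
    ("tmx", "EM", -1.5, 0.0004),
    ("tmx", "LM", -1.5, 0.0053),
    ("tmx", "M,LM", -1.5, 0.0009),
    ("tmx", "M,EM,LM", 1.5, 0.0001),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_proteins: int = 10_000
    fraction_per_archetype: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    archetype_offsets: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_OFFSETS)
    )
    base_log2_mean: float = 14.0
    base_log2_sd: float = 2.0
    #: Optional archetype -> shared baseline log2. When set, proteins of that
    #: archetype all start at the given abundance, making the myoblast
    #: intensity component of a trajectory informative about the archetype
    #: (as it is for real co-regulated protein classes). Others keep the
    #: random baseline.
    base_log2_by_archetype: Mapping[str, float] | None = None
    noise_sd_log2: float = 0.25
    multiplex_batch_log2: tuple[float, float, float] = (0.0, 0.3, -0.2)
    #: Explicit 3 x 10 per-channel loading offsets (log2); None draws each from
    #: N(0, channel_loading_sd_log2) once per run.
    channel_loading_log2: Sequence[Sequence[float]] | None = None
    channel_loading_sd_log2: float = 0.15
    effect_grid: Sequence[tuple[str, str, float, float]] = DEFAULT_EFFECT_GRID
    seed: int = 0
    #: Replicate index pooled into the bridge for each condition x timepoint.
    bridge_replicate: int = 1

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        fracs = dict(self.fraction_per_archetype)
        unknown = set(fracs) - set(self.archetype_offsets)
        if unknown:
            raise ConfigurationError(
                f"fraction_per_archetype names unknown archetypes: {sorted(unknown)}"
            )
        if any(f < 0 for f in fracs.values()):
            raise ConfigurationError("fraction_per_archetype contains negative fractions")
        if sum(fracs.values()) > 1 + 1e-12:
            raise ConfigurationError(
                f"fraction_per_archetype sums to {sum(fracs.values()):.4f} > 1"
            )
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be nonnegative")
        for cond, tps, eff, frac in self.effect_grid:
            if cond not in ("vehicle", "tmx"):
                raise ConfigurationError(f"effect_grid condition must be vehicle/tmx, got {cond!r}")
            for tp in tps.split(","):
                if tp not in TIMEPOINTS:
                    raise ConfigurationError(f"effect_grid names unknown timepoint {tp!r}")
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"effect_grid fraction {frac} outside [0, 1]")
        if len(self.multiplex_batch_log2) != 3:
            raise ConfigurationError("multiplex_batch_log2 must have length 3")


TRUTH_COLUMNS = [
    "protein_id", "archetype", "base_log2",
    "offset_M", "offset_EM", "offset_LM",
    "vehicle_M", "vehicle_EM", "vehicle_LM",
    "tmx_M", "tmx_EM", "tmx_LM",
]


def generate_ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """Draw the per-protein abundance programs and planted-effect ledger.

    Returns one row per protein with the archetype, its baseline, the
    archetype (M, EM, LM) log2 offsets, and the planted vehicle- and
    TMX-effect log2 values per timepoint. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_proteins
    width = len(str(n - 1)) if n > 1 else 1
    ids = [f"P{i:0{width}d}" for i in range(n)]

    counts = {a: int(round(f * n)) for a, f in config.fraction_per_archetype.items()}
    if sum(counts.values()) > n:
        raise ConfigurationError(
            f"fraction_per_archetype rounds to {sum(counts.values())} proteins > n_proteins={n}"
        )
    archetypes = np.array([FLAT] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for name in config.fraction_per_archetype:  # insertion order, reproducible
        k = counts[name]
        archetypes[order[pos:pos + k]] = name
        pos += k

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    if config.base_log2_by_archetype:
        for name, value in config.base_log2_by_archetype.items():
            base[archetypes == name] = float(value)
    offsets = np.zeros((n, 3))
    for name, (om, oem, olm) in config.archetype_offsets.items():
        mask = archetypes == name
        offsets[mask] = (om, oem, olm)

    veh = np.zeros((n, 3))
    tmx = np.zeros((n, 3))
    tp_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    for cond, tps, eff, frac in config.effect_grid:
        k = int(round(frac * n))
        chosen = rng.choice(n, size=k, replace=False)
        target = veh if cond == "vehicle" else tmx
        for tp in tps.split(","):
            target[chosen, tp_index[tp]] += eff

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "archetype": archetypes,
            "base_log2": base,
            "offset_M": offsets[:, 0],
            "offset_EM": offsets[:, 1],
            "offset_LM": offsets[:, 2],
            "vehicle_M": veh[:, 0],
            "vehicle_EM": veh[:, 1],
            "vehicle_LM": veh[:, 2],
            "tmx_M": tmx[:, 0],
            "tmx_EM": tmx[:, 1],
            "tmx_LM": tmx[:, 2],
        },
        columns=TRUTH_COLUMNS,
    )
    return truth.set_index("protein_id")


def _program_log2(truth: pd.DataFrame, condition: str, timepoint: str) -> np.ndarray:
    """Noise-free log2 abundance of every protein under condition x timepoint."""
    prog = truth["base_log2"].to_numpy() + truth[f"offset_{timepoint}"].to_numpy()
    if condition in ("vehicle", "tmx"):
        prog = prog + truth[f"vehicle_{timepoint}"].to_numpy()
    if condition == "tmx":
        prog = prog + truth[f"tmx_{timepoint}"].to_numpy()
    return prog


def bridge_program_linear(truth: pd.DataFrame) -> np.ndarray:
    """Linear-scale bridge abundance: mean over the 9 condition x timepoint pools.

    The designated replicate has the same expectation as any other, so the
    bridge is a pure function of the truth table.
    """
    pools = [
        2.0 ** _program_log2(truth, cond, tp)
        for cond in CONDITIONS
        for tp in TIMEPOINTS
    ]
    return np.mean(pools, axis=0)


def simulate_multiplexes(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[list[ReporterMatrix], MultiplexDesign]:
    """Render the truth into three 10-channel reporter matrices plus design.

    Sample intensity = 2^(base + archetype offset + condition effects + batch
    + loading + N(0, noise_sd)); bridge intensity = bridge program x
    2^(batch + loading + N(0, noise_sd)). Per-protein noise substreams are
    spawned deterministically from the seed, so any protein subset is
    reproducible independent of the rest.
    """
    config.validate()
    if truth.empty:
        raise ConfigurationError("truth table is empty")
    design = default_design()
    n = len(truth)

    if config.channel_loading_log2 is not None:
        loading = np.asarray(config.channel_loading_log2, dtype=float)
        if loading.shape != (3, 10):
            raise ConfigurationError(
                f"channel_loading_log2 must be 3 x 10, got {loading.shape}"
            )
    else:
        loading_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
        loading = loading_rng.normal(0.0, config.channel_loading_sd_log2, size=(3, 10))

    # One noise substream per protein; each consumes a fixed-size 3 x 10 block.
    if config.noise_sd_log2 > 0:
        children = np.random.SeedSequence([int(config.seed), 2]).spawn(n)
        noise = np.empty((n, 3, 10))
        for i, child in enumerate(children):
            noise[i] = np.random.default_rng(child).normal(
                0.0, config.noise_sd_log2, size=(3, 10)
            )
    else:
        noise = np.zeros((n, 3, 10))

    bridge_linear = bridge_program_linear(truth)
    matrices: list[ReporterMatrix] = []
    for m, mux in enumerate(design.multiplexes):
        tp = design.timepoint_of(mux)
        channels = design.channels(mux)
        cols = {}
        for c, channel in enumerate(channels):
            entry = design.entries[
                (design.entries["multiplex"] == mux) & (design.entries["channel"] == channel)
            ].iloc[0]
            scale = config.multiplex_batch_log2[m] + loading[m, c] + noise[:, m, c]
            if entry["is_bridge"]:
                cols[channel] = bridge_linear * 2.0 ** scale
            else:
                cols[channel] = 2.0 ** (_program_log2(truth, entry["condition"], tp) + scale)
        data = pd.DataFrame(cols, index=truth.index)
        matrices.append(ReporterMatrix(mux, data))
    return matrices, design


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, list[ReporterMatrix], MultiplexDesign]:
    """Convenience: ground truth plus rendered multiplexes in one call."""
    truth = generate_ground_truth(config)
    matrices, design = simulate_multiplexes(truth, config)
    return truth, matrices, design


def write_simulation(
    truth: pd.DataFrame,
    matrices: Sequence[ReporterMatrix],
    design: MultiplexDesign,
    outdir: str | Path,
) -> dict[str, str]:
    """Write matrices, design and the ground-truth ledger as TSV; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for mat in matrices:
        p = outdir / f"matrix_{mat.multiplex_id}.tsv"
        write_reporter_matrix(mat, p)
        paths[f"matrix_{mat.multiplex_id}"] = str(p)
    write_design(design, outdir / "design.tsv")
    paths["design"] = str(outdir / "design.tsv")
    write_table(truth, outdir / "ground_truth.tsv", index_label="protein_id")
    paths["ground_truth"] = str(outdir / "ground_truth.tsv")
    return paths


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
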