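# tmtbridge

Analysis pipeline for **bridged multi-multiplex TMT proteomics** of drug-treated
in vitro myogenesis — and, more generally, for any time-course design in which
each timepoint is measured as one isobaric (TMT 10-plex) multiplex carrying an
identical pooled *bridge channel*.

The motivating experiment: C2C12 myoblasts differentiate into myotubes over
nine days while cultured untreated, with vehicle (EtOH), or with tamoxifen
(TMX) in vehicle. Cells are sampled in triplicate at day 0 (myoblasts, M),
day 5 (early myotubes, EM) and day 9 (late myotubes, LM); each stage becomes
one TMT 10-plex with 9 sample channels ({untreated, vehicle, TMX} × 3
replicates) plus the shared bridge as the 10th. The pipeline answers two
questions: which proteins are regulated *by differentiation itself*, and which
are regulated *by the drug* at each stage, with solvent effects removed.

## What it computes

1. **Normalization** — every channel is scaled to the grand-mean channel total
   (sample loading), then each protein's log2 values in the day-5 and day-9
   multiplexes are shifted by its bridge offset
   `log2 bridge(reference) − log2 bridge(multiplex)`, aligning all three
   multiplexes to day 0. After correction a protein's bridge value is identical
   in every multiplex.
2. **Myogenically regulated (MR) proteins** — per condition, EM/M and LM/M
   log2 fold changes as differences of group means, two-tailed pooled-variance
   Student t tests, Benjamini–Hochberg adjustment per comparison family. A
   protein is MR iff *both* comparisons have adjusted p ≤ 0.05 *and* either
   |log2FC| ≥ 1.
3. **Trajectory clustering** — MR proteins are summarized as
   (standardized log2 mean M abundance, standardized log2FC EM/M, standardized
   log2FC LM/M), each component median-centered and SD-scaled, and clustered
   with k-means (k = 5, k-means++, best of 50 restarts). Clusters from two
   conditions are matched by minimum-cost assignment on centroid distances.
4. **Stagewise differential expression (DE)** — within each multiplex, vehicle
   and TMX channels are corrected to the per-protein mean of the untreated
   replicates; TMX-vs-vehicle t tests with BH over the whole proteome per
   stage. DE iff |log2FC| ≥ 1 and adjusted p < 0.05. Because TMX is dissolved
   in the vehicle, solvent effects load on both groups and cancel.
5. **Set logic** — three-condition Venn partition of the MR sets; removal of
   vehicle-dependent regulation from the TMX clustering input
   (all-three ∪ TMX-only ∪ untreated∩TMX); DE ∩ MR splits; proteins DE at
   ≥ 2 stages ("highly regulated"); overlap against a caller-supplied homolog
   reference list.
6. **Synthetic data** — a generator reproducing the exact design (five
   trajectory archetypes, per-multiplex batch factors, per-channel loading,
   vehicle-only and TMX-specific planted effects, log-normal noise) with a
   ground-truth ledger, used for recovery testing throughout.

## Worked example

```python
import tmtbridge as tb

cfg = tb.SimulationConfig(n_proteins=10_000, seed=0)   # the emulated design
truth, matrices, design = tb.simulate(cfg)

bridged = tb.normalize(matrices, design)               # loading + bridge
print("bridge spread:", tb.bridge_spread(bridged))

mr = {c: tb.mr_analysis(bridged, c) for c in ("untreated", "vehicle", "tmx")}
for c, calls in mr.items():
    print(f"MR {c}: {int(calls['is_mr'].sum())} of {len(calls)} tested")

parts = tb.mr_venn(*(tb.mr_set(mr[c]) for c in ("untreated", "vehicle", "tmx")))
keep = tb.exclude_vehicle_only(parts)
print("tmx cluster input:", len(keep),
      "excluded:", len(tb.mr_set(mr["tmx"])) - len(keep))

traj = tb.build_trajectories(bridged, tb.mr_set(mr["untreated"]), "untreated")
model = tb.kmeans_cluster(traj, k=5, seed=17, n_restarts=50)
print("cluster sizes:", model.sizes.to_dict())

de = tb.de_all_stages(bridged)
print("DE per stage:", {s: int(d["is_de"].sum()) for s, d in de.items()})
```

prints:

```text
bridge spread: 0.0
MR untreated: 251 of 10000 tested
MR vehicle: 377 of 10000 tested
MR tmx: 501 of 10000 tested
tmx cluster input: 377 excluded: 124
cluster sizes: {0: 40, 1: 74, 2: 54, 3: 29, 4: 54}
DE per stage: {'M': 3, 'EM': 0, 'LM': 1}
```

Reading the numbers: the bridge spread of 0 certifies that the three
multiplexes are exactly aligned per protein. 251 proteins pass the MR rule in
the untreated arm (fewer than the ~1,060 planted trajectory proteins — with
n = 3 replicates and log2 noise SD 0.25, archetypes whose smaller stage offset
is near ±1 often miss proteome-wide BH significance; see
`docs/methods.md` on power). The 124 proteins regulated only when vehicle is
present are excluded before the TMX trajectories are clustered into the five
trends. Stagewise DE picks out TMX-specific effects only: planted vehicle
effects never appear here.

A full run with TSV outputs and a JSON manifest:

```bash
tmtbridge run-all --config run.yaml     # or: python -m tmtbridge.cli ...
```

where `run.yaml` holds e.g. `simulation: {n_proteins: 10000}`, `seed: 0`,
`outdir: results/`. Subcommands `simulate`, `normalize`, `longitudinal`,
`cluster`, `match`, `de` expose the individual stages.

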