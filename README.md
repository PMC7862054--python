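# cytoprof

Deep immune-profiling analysis for two-arm, two-timepoint mass-cytometry
(CyTOF) studies — the kind that asks how a therapy reshapes a patient's
immune compartment: which populations expand or deplete, how marker
distributions shift within persisting cells, whether the T-cell
repertoire clonally focuses, and which bulk gene-expression changes are
real transcription rather than cell-composition artifacts. It is written
for computational immunologists and biostatisticians who need the full
stack as tested, scriptable Python rather than point-and-click gating
software.

## What's inside

- **`cytoprof.synthetic`** — a cohort generator (event matrices, sample
  metadata, TCRβ clone tables, immune-panel gene counts) with spiked,
  truth-logged treatment effects, so every downstream method is testable
  without patient data.
- **`cytoprof.preprocessing`** — `asinh(x/5)` transform, the
  \>10,000-live-singlet-event retention rule with paired-exclusion
  propagation, Earth Mover's Distance composition QC and MEM scores.
- **`cytoprof.spade`** — SPADE: density-dependent downsampling, clustering
  to a fixed node count (default 150, 10% downsampling), a minimum
  spanning tree over node medians in L1, upsampling, threshold gating into
  a population hierarchy, and %total / %parent accounting.
- **`cytoprof.differential`** — mean marker intensity (MMI) tables, Welch
  tests, within-patient fold changes, single-step **maxT bootstrap**
  multiplicity correction over the dependent (unit, marker) family,
  positivity/quadrant fractions and subset ratios.
- **`cytoprof.bins`** — centile bins with tie merging and a **sample-
  weighted ECDF permutation test** for distributional shifts:

  adj. statistic  `D = sup_x |F_a(x) − F_b(x)|`,  each cell weighted
  `1/(n_cells(sample)·n_samples)`, null built by permuting condition
  labels at the sample level, `p = (1 + #{D* ≥ D}) / (B + 1)`.
- **`cytoprof.repertoire`** — clonality `1 − H/ln R`, richness, paired
  Wilcoxon comparisons, Spearman link to CD8⁺ expansion, Kaplan–Meier and
  log-rank survival stratification by baseline richness.
- **`cytoprof.expression`** — housekeeping normalization, paired
  differential expression, and abundance-corrected DE that conditions the
  treatment term on within-patient logit-fraction changes of
  cytometry-derived cell abundances.
- **`cytoprof.viz`** — SPADE blend coloring, Radviz projections and
  fan-chart centile tables as plot-ready data frames.
- **`cytoprof.pipeline` / `cytoprof` CLI** — one-config orchestration
  (`cytoprof all --seed 7 --outdir run/`) with per-stage child seeds and a
  checksummed run manifest.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a paired cohort with the default spiked effects (CD38
downregulation, CD56dim-biased NK depletion, CD8⁺ memory expansion, Treg
depletion, clonality rise coupled to CD8 expansion), gate cells, and test
the treated arm on-treatment vs baseline:

```python
import numpy as np
from cytoprof import synthetic as syn
from cytoprof.spade import gate_cells
from cytoprof.differential import (GroupComparison, build_mmi_table,
                                   run_group_comparison)
from cytoprof.repertoire import clonality, paired_metric_test

cfg = syn.default_config(seed=1)
cfg.n_patients_per_arm = {"treated": 12, "control": 12}
cfg.paired_fraction = {"treated": 1.0, "control": 1.0}
cfg.n_controls, cfg.cells_per_sample_mean = 4, 800
ds = syn.generate_cohort(cfg)

hier = syn.default_gating_hierarchy()
md = ds.metadata.set_index("sample_id")
labels = {s: gate_cells(m.values, m.channels, hier)
          for s, m in ds.events.items()}
post = sorted(md[(md.arm == "treated") & (md.timepoint == "on_treatment")].index)
base = sorted(md[(md.arm == "treated") & (md.timepoint == "baseline")].index)

def nk_rollup(lab):
    out = np.array(["other"] * len(lab), dtype=object)
    out[np.isin(lab, ["NK cells"] + hier.descendants("NK cells"))] = "NK cells"
    return out

mmi = build_mmi_table({s: ds.events[s].values for s in post + base},
                      syn.default_channels(),
                      {s: nk_rollup(labels[s]) for s in post + base})
res = run_group_comparison(mmi, GroupComparison(post, base), B=500, rng=0)
row = res.set_index(["unit", "marker"]).loc[("NK cells", "CD38")]
print(f"NK CD38: fold_change={row.fold_change:+.2f} adj_p={row.adj_p:.4f}")

pairs = {}
for r in ds.metadata[ds.metadata.arm == "treated"].itertuples(index=False):
    pairs.setdefault(r.patient_id, {})[r.timepoint] = \
        clonality(ds.repertoires[r.sample_id])
b, a = zip(*[(v["baseline"], v["on_treatment"]) for v in pairs.values()])
mb, ma, p = paired_metric_test(np.array(b), np.array(a))
print(f"clonality: {mb:.3f} -> {ma:.3f}  wilcoxon p={p:.2e}")
```

Output:

```
NK CD38: fold_change=-0.97 adj_p=0.0020
clonality: 0.178 -> 0.256  wilcoxon p=4.88e-04
```

The CD38 fold change recovers the spiked −1.0 arcsinh shift with a
family-wise-corrected p-value, and median clonality rises on treatment in
the treated arm, as spiked.

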