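"""End-to-end orchestration: simulate -> QC -> SPADE -> gate -> analyses.

One config drives the whole run; one global seed fans out to per-stage
child seeds by stable hashing of stage names, so toggling a stage never
shifts another stage's random stream. Every stage reads and writes
serialized artifacts in the run directory, making the pipeline re-runnable
stage by stage, and a manifest records parameters, seed and output
checksums (identical config + seed reproduces identical checksums).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bins as bins_mod
from . import differential as diff_mod
from . import expression as expr_mod
from . import repertoire as rep_mod
from . import spade as spade_mod
from . import synthetic as syn
from . import viz as viz_mod
from ._utils import child_seed
from .preprocessing import composition_emd, qc_cluster_samples, qc_retain_samples

__all__ = ["RunConfig", "run_full_analysis"]

DEFAULT_STAGES = ("simulate", "qc", "cluster", "gate", "diff", "bins", "tcr",
                  "expression", "viz")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Defaults carry the canonical analysis settings: arcsinh cofactor 5,
    150 SPADE nodes at 10% downsampling, a 10,000 live-singlet event
    threshold, 100 centile bins, 1000 bootstrap/permutation iterations and
    alpha 0.05.
    """

    seed: int = 0
    outdir: str = "cytoprof_run"
    stages: tuple[str, ...] = DEFAULT_STAGES
    cofactor: float = 5.0
    n_nodes: int = 150
    downsample: float = 0.10
    min_events: int = 10_000
    n_centiles: int = 100
    b_boot: int = 1000
    b_perm: int = 1000
    alpha: float = 0.05
    bin_markers: tuple[str, ...] = ("CD38", "CD69")
    bin_population: str = "NK cells"
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    def validate(self) -> None:
        if not (0 < self.downsample <= 1):
            raise ValueError("downsample must be in (0, 1]")
        if self.cofactor <= 0 or self.n_nodes < 1 or self.min_events < 0:
            raise ValueError("invalid parameter ranges")
        if self.b_boot < 100 or self.b_perm < 100:
            raise ValueError("resampling counts must be >= 100")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        if "bin_markers" in payload:
            payload["bin_markers"] = tuple(payload["bin_markers"])
        return cls(**payload)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "outdir": self.outdir,
            "stages": list(self.stages), "cofactor": self.cofactor,
            "n_nodes": self.n_nodes, "downsample": self.downsample,
            "min_events": self.min_events, "n_centiles": self.n_centiles,
            "b_boot": self.b_boot, "b_perm": self.b_perm, "alpha": self.alpha,
            "bin_markers": list(self.bin_markers),
            "bin_population": self.bin_population, "cohort": self.cohort,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(config: RunConfig) -> Path:
    """Run the enabled stages and return the run directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, **kw)
        written.append(path)

    # ---- simulate ------------------------------------------------------
    if "simulate" not in stages:
        raise ValueError("the bundled pipeline starts from the simulate stage")
    cohort_cfg = syn.default_config(
        seed=child_seed(config.seed, "simulate"), **config.cohort
    )
    ds = syn.generate_cohort(cohort_cfg)
    ds.write(out / "dataset")
    written.extend(sorted((out / "dataset").rglob("*.*")))
    hierarchy = syn.default_gating_hierarchy()
    hierarchy.to_json(out / "gating_hierarchy.json")
    written.append(out / "gating_hierarchy.json")

    # ---- qc ------------------------------------------------------------
    retained_ids = list(ds.events)
    if "qc" in stages:
        patient_meta = ds.metadata[~ds.metadata["control"].astype(bool)]
        report = qc_retain_samples(patient_meta, min_events=config.min_events)
        control_ids = ds.metadata.loc[
            ds.metadata["control"].astype(bool), "sample_id"
        ].tolist()
        retained_ids = report.retained + control_ids
        # composition-EMD clustering of samples for batch-effect QC
        fracs = ds.abundances.loc[retained_ids]
        roots = [c for c in fracs.columns
                 if hierarchy.parent(c) is None]
        comp = fracs[roots].copy()
        comp["rest"] = 1.0 - comp.sum(axis=1)
        dm = np.zeros((len(comp), len(comp)))
        arr = comp.to_numpy()
        for i in range(len(comp)):
            for j in range(i + 1, len(comp)):
                d = 0.5 * np.abs(arr[i] - arr[j]).sum()  # unit-cost EMD
                dm[i, j] = dm[j, i] = d
        clus = qc_cluster_samples(
            pd.DataFrame(dm, index=comp.index, columns=comp.index),
            control_ids,
        )
        qc_payload = report.to_dict() | {
            "controls_co_cluster": clus.controls_co_cluster
        }
        (out / "qc_report.json").write_text(json.dumps(qc_payload, indent=1))
        written.append(out / "qc_report.json")

    samples = [ds.events[s] for s in retained_ids]
    meta = ds.metadata.set_index("sample_id").loc[retained_ids].reset_index()

    # ---- cluster (SPADE) ----------------------------------------------
    tree = None
    if "cluster" in stages:
        tree = spade_mod.fit_spade(
            samples,
            n_nodes=config.n_nodes,
            downsample_fraction=config.downsample,
            rng=child_seed(config.seed, "cluster"),
        )
        tree.to_json(out / "spade_tree.json")
        written.append(out / "spade_tree.json")
        emit(tree.per_sample_node_counts, "node_counts.csv")

    # ---- gate ----------------------------------------------------------
    pop_labels = {
        s.sample_id: spade_mod.gate_cells(s.values, s.channels, hierarchy)
        for s in samples
    }
    counts = spade_mod.population_counts(pop_labels, hierarchy)
    fractions = spade_mod.population_fractions(counts, hierarchy)
    if "gate" in stages:
        emit(fractions, "population_fractions.csv", index=False)
        if tree is not None:
            node_pops = spade_mod.gate_nodes_to_populations(tree, hierarchy)
            emit(pd.Series(node_pops, name="population").rename_axis("node")
                 .reset_index(), "node_populations.csv", index=False)

    # ---- diff ----------------------------------------------------------
    diff_table = None
    if "diff" in stages:
        treated = meta[(meta["arm"] == "treated")]
        cmp = diff_mod.GroupComparison(
            group_a=treated.loc[
                treated["timepoint"] == "on_treatment", "sample_id"
            ].tolist(),
            group_b=treated.loc[
                treated["timepoint"] == "baseline", "sample_id"
            ].tolist(),
            label_a="on_treatment",
            label_b="baseline",
        )
        mmi = diff_mod.build_mmi_table(
            {s.sample_id: s.values for s in samples
             if s.sample_id in cmp.group_a + cmp.group_b},
            samples[0].channels,
            {sid: lab for sid, lab in pop_labels.items()
             if sid in cmp.group_a + cmp.group_b},
        )
        diff_table = diff_mod.run_group_comparison(
            mmi, cmp, B=config.b_boot, rng=child_seed(config.seed, "diff")
        )
        emit(diff_table, "diff_treated_on_vs_baseline.csv", index=False)

    # ---- bins ----------------------------------------------------------
    if "bins" in stages:
        rows = []
        pop = config.bin_population
        treated = meta[meta["arm"] == "treated"]
        ids_a = treated.loc[treated["timepoint"] == "on_treatment",
                            "sample_id"].tolist()
        ids_b = treated.loc[treated["timepoint"] == "baseline",
                            "sample_id"].tolist()
        members = {
            sid: np.isin(
                pop_labels[sid],
                [pop] + hierarchy.descendants(pop),
            )
            for sid in ids_a + ids_b
        }
        for marker in config.bin_markers:
            ch = samples[0].channels.index(marker)
            sa = {s: ds.events[s].values[members[s], ch]
                  for s in ids_a if members[s].sum() > 0}
            sb = {s: ds.events[s].values[members[s], ch]
                  for s in ids_b if members[s].sum() > 0}
            pooled = np.concatenate(
                [v for v in sa.values()] + [v for v in sb.values()]
            )
            partition = bins_mod.build_centile_bins(pooled, config.n_centiles)
            res = bins_mod.ecdf_difference_test(
                sa, sb, B=config.b_perm,
                rng=child_seed(config.seed, f"bins:{marker}"),
                partition=partition,
            )
            rows.append({"population": pop, "marker": marker,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "n_permutations": res.n_permutations})
            res.per_bin_fractions.to_csv(
                out / f"bins_{pop.replace(' ', '_')}_{marker}.csv", index=False
            )
            written.append(out / f"bins_{pop.replace(' ', '_')}_{marker}.csv")
        emit(pd.DataFrame(rows), "bin_tests.csv", index=False)

    # ---- tcr -----------------------------------------------------------
    if "tcr" in stages:
        recs = []
        for sid, cnts in ds.repertoires.items():
            if sid not in set(retained_ids):
                continue
            recs.append({
                "sample_id": sid,
                "clonality": rep_mod.clonality(cnts),
                "richness": rep_mod.richness(cnts),
            })
        tcr = pd.DataFrame(recs).merge(
            ds.metadata[["sample_id", "patient_id", "arm", "timepoint",
                         "pfs_time", "pfs_event"]],
            on="sample_id",
        )
        emit(tcr, "tcr_metrics.csv", index=False)
        surv_rows, tests = [], []
        for arm, sub in tcr.groupby("arm"):
            wide = sub.pivot_table(index="patient_id", columns="timepoint",
                                   values="clonality")
            if {"baseline", "on_treatment"} <= set(wide.columns):
                paired = wide.dropna()
                if len(paired) >= 3:
                    mb, ma, p = rep_mod.paired_metric_test(
                        paired["baseline"], paired["on_treatment"]
                    )
                    tests.append({"arm": arm, "metric": "clonality",
                                  "median_baseline": mb,
                                  "median_on_treatment": ma, "p": p})
            base = sub[sub["timepoint"] == "baseline"]
            for r in base.itertuples(index=False):
                surv_rows.append({"patient_id": r.patient_id, "arm": arm,
                                  "time": r.pfs_time, "event": r.pfs_event,
                                  "baseline_richness": r.richness})
        if tests:
            emit(pd.DataFrame(tests), "tcr_paired_tests.csv", index=False)
        surv = pd.DataFrame(surv_rows)
        km_rows = []
        for arm, sub in surv.groupby("arm"):
            if sub["event"].sum() >= 5:
                split = rep_mod.richness_survival_split(sub, split="median")
                km_rows.append({"arm": arm,
                                "logrank_p": split["logrank_p"],
                                **{f"n_{g}": n for g, n
                                   in split["group_sizes"].items()}})
        if km_rows:
            emit(pd.DataFrame(km_rows), "tcr_survival.csv", index=False)

    # ---- expression -----------------------------------------------------
    if "expression" in stages:
        norm = expr_mod.normalize_expression(
            ds.expression, list(cohort_cfg.expression.housekeeping_genes)
        )
        meta_expr = ds.metadata[
            ds.metadata["sample_id"].isin(norm.columns)
        ]
        for arm, sub in meta_expr.groupby("arm"):
            de = expr_mod.paired_differential_expression(norm, sub)
            emit(de, f"de_{arm}_uncorrected.csv", index=False)
            corrected = expr_mod.abundance_corrected_de(
                norm, sub, ds.abundances[["NK cells", "CD8 T cells"]]
            )
            emit(corrected, f"de_{arm}_abundance_corrected.csv", index=False)
        emit(expr_mod.analysis_group_sizes(meta_expr),
             "expression_group_sizes.csv", index=False)

    # ---- viz ------------------------------------------------------------
    if "viz" in stages and diff_table is not None:
        blend = viz_mod.spade_blend_coloring(diff_table, alpha=config.alpha)
        emit(blend.reset_index(), "viz_blend.csv", index=False)
        nk_ids = [s.sample_id for s in samples][:4]
        nk_channels = ["CD56", "CD16", "CD38", "CD69", "CD27", "CD137"]
        idxs = [samples[0].channels.index(c) for c in nk_channels]
        cells = np.vstack([ds.events[s].values[:200, idxs] for s in nk_ids])
        layout = viz_mod.radviz_projection(cells, nk_channels)
        emit(pd.DataFrame(layout.points, columns=["x", "y"]),
             "viz_radviz_points.csv", index=False)
        fan = viz_mod.fan_chart_centiles({
            "baseline": np.concatenate(
                [ds.events[s].values[:, samples[0].channels.index("CD38")]
                 for s in meta.loc[meta["timepoint"] == "baseline",
                                   "sample_id"]]
            ),
        })
        emit(fan.rename_axis("condition").reset_index(), "viz_fan_CD38.csv",
             index=False)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_samples": len(retained_ids),
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
            if p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
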