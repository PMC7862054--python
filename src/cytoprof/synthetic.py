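"""Synthetic two-arm, two-timepoint immune-profiling cohort generator.

Emulates the data structure of an anti-CD38 antibody combination therapy
versus control-arm myeloma trial: per-sample single-cell event matrices over a CyTOF-style
marker panel, sample metadata (patients, arms, timepoints, response labels,
survival), clonally structured TCR repertoires, and immune-panel gene
counts driven by cell-type abundances. Treatment effects — CD38
downregulation, NK depletion biased to the CD56dim subset, CD8+ memory
expansion, depletion of CD38+ regulatory T cells and monocytic MDSCs, and a
clonality rise coupled to the CD8 expansion — are spiked into the treated
arm's on-treatment samples and recorded in a truth log, so every downstream
analysis can be validated against known ground truth.

Intensities are generated directly on the arcsinh-transformed scale (the
scale all analyses operate on); a raw-scale export is available through the
inverse transform. Paired samples share patient-level random effects so
paired analyses see genuine within-patient correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import rng_from
from .preprocessing import EventMatrix
from .spade import GatingHierarchy, PopulationRule

__all__ = [
    "PopulationSpec",
    "EffectSpec",
    "RepertoireConfig",
    "ExpressionConfig",
    "CohortConfig",
    "CohortDataset",
    "default_channels",
    "default_populations",
    "default_effects",
    "default_gating_hierarchy",
    "default_config",
    "generate_cohort",
    "sample_population_events",
    "generate_repertoire",
    "generate_expression_counts",
    "study_qc_metadata",
    "study_expression_metadata",
]

OTHER = "other"  # sink label for cells outside the named hierarchy


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One immune population: place in the hierarchy, abundance, phenotype.

    ``fraction_of_parent`` is the population's share of its parent's cells;
    siblings may sum to less than 1, the remainder staying as unsubdivided
    parent cells. ``marker_locations``/``marker_spreads`` override the
    inherited phenotype on the arcsinh scale for the listed channels only.
    """

    name: str
    parent: str | None
    fraction_of_parent: float
    marker_locations: dict[str, float] = field(default_factory=dict)
    marker_spreads: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.fraction_of_parent <= 1):
            raise ValueError(f"{self.name}: fraction_of_parent outside [0, 1]")
        if any(s <= 0 for s in self.marker_spreads.values()):
            raise ValueError(f"{self.name}: spreads must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """A spiked treatment effect applied to one arm's on-treatment samples.

    ``abundance_multiplier`` scales the population's cell fraction
    (descendants included); ``marker_shifts`` add to channel locations on
    the arcsinh scale for the population's cells.
    """

    arm: str  # {"treated", "control"}
    population: str
    abundance_multiplier: float = 1.0
    marker_shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.abundance_multiplier <= 0:
            raise ValueError("abundance_multiplier must be positive")
        if self.arm not in ("treated", "control"):
            raise ValueError(f"unknown arm {self.arm!r}")


@dataclass(frozen=True)
class RepertoireConfig:
    """TCR repertoire generation: clone pool and expansion behaviour.

    Clone frequencies follow a rank power law p_i ~ i^(-s); the skew
    parameter s is ``baseline_strength`` at baseline and gains
    ``on_treatment_delta[arm]`` on treatment.
    """

    n_clones: int = 400
    total_templates: int = 20_000
    baseline_strength: float = 0.90
    on_treatment_delta: dict[str, float] = field(
        default_factory=lambda: {"treated": 0.15, "control": 0.0}
    )
    richness_sd: float = 0.30  # lognormal sd of the patient clone-pool size


@dataclass(frozen=True)
class ExpressionConfig:
    """Immune-panel gene counts: abundance-linked, shifted and stable genes.

    ``abundance_linked_genes`` maps gene -> population whose %total fraction
    drives the gene's expected count (composition signal only);
    ``treatment_shift_genes`` maps gene -> log2 fold change applied to the
    treated arm's on-treatment samples (true transcriptional signal).
    Remaining genes, housekeeping included, have constant expectation.
    """

    n_genes: int = 120
    abundance_linked_genes: dict[str, str] = field(
        default_factory=lambda: {
            **{f"NKG{i}": "NK cells" for i in range(1, 9)},
            **{f"CD8G{i}": "CD8 T cells" for i in range(1, 9)},
        }
    )
    treatment_shift_genes: dict[str, float] = field(
        default_factory=lambda: {"ACTG1X": 1.0, "ACTG2X": 1.0, "ACTG3X": -1.0}
    )
    housekeeping_genes: tuple[str, ...] = ("HK1", "HK2", "HK3", "HK4", "HK5")
    linked_scale: float = 2000.0  # expected counts per unit fraction
    base_count: float = 250.0  # constant expectation of unlinked genes
    floor_count: float = 1.0  # expectation floor at zero abundance
    noise_sd: float = 0.15  # lognormal sd of multiplicative noise


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort run."""

    n_patients_per_arm: dict[str, int] = field(
        default_factory=lambda: {"treated": 40, "control": 45}
    )
    paired_fraction: dict[str, float] = field(
        default_factory=lambda: {"treated": 31 / 40, "control": 33 / 45}
    )
    n_controls: int = 38
    cells_per_sample_mean: int = 1500
    populations: list[PopulationSpec] = field(default_factory=lambda: default_populations())
    effects: list[EffectSpec] = field(default_factory=lambda: default_effects())
    repertoire: RepertoireConfig = field(default_factory=RepertoireConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    responder_fraction: dict[str, float] = field(
        default_factory=lambda: {"treated": 0.925, "control": 0.778}
    )
    acquired_events_mean: float = 60_000.0  # instrument live-singlet counts
    patient_abundance_sd: float = 0.25
    sample_abundance_sd: float = 0.12
    marker_offset_sd: float = 0.05
    response_coupling_sd: float = 0.25  # couples effect strength & clonality
    pfs_median_months: float = 18.0
    pfs_richness_loghr: float = 0.6  # treated arm only
    pfs_censor_months: float = 48.0  # admin censoring window -> ~70% events
    seed: int = 0

    def __post_init__(self):
        for arm, n in self.n_patients_per_arm.items():
            if n < 1:
                raise ValueError(f"{arm}: need at least one patient")
        for arm, f in self.paired_fraction.items():
            if not (0 <= f <= 1):
                raise ValueError(f"{arm}: paired_fraction outside [0, 1]")
        if self.n_controls < 0 or self.cells_per_sample_mean < 1:
            raise ValueError("invalid control or cell counts")


@dataclass
class CohortDataset:
    """Everything one synthetic study produces, plus the ground truth."""

    events: dict[str, EventMatrix]
    metadata: pd.DataFrame
    repertoires: dict[str, "pd.Series"]
    expression: pd.DataFrame  # genes x samples
    abundances: pd.DataFrame  # samples x populations (%total, truth)
    cell_labels: dict[str, np.ndarray]  # truth population per cell
    truth: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        (out / "events").mkdir(parents=True, exist_ok=True)
        (out / "repertoires").mkdir(exist_ok=True)
        for sid, m in self.events.items():
            m.to_csv(out / "events" / f"{sid}.csv")
        self.metadata.to_csv(out / "metadata.csv", index=False)
        for sid, counts in self.repertoires.items():
            pd.DataFrame({"clone_id": counts.index, "count": counts.values}).to_csv(
                out / "repertoires" / f"{sid}.tsv", sep="\t", index=False
            )
        self.expression.to_csv(out / "expression.csv")
        self.abundances.to_csv(out / "abundances.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

def default_channels() -> list[str]:
    return [
        "CD3", "CD4", "CD8", "CD19", "CD14", "CD56", "CD16", "CD25",
        "CD127", "CD45RA", "CD27", "CD38", "HLA-DR", "CD69", "CD137", "GrB",
    ]


NEGATIVE_LOC = 0.3  # arcsinh location of an unexpressed marker
DEFAULT_SPREAD = 0.35


def default_populations() -> list[PopulationSpec]:
    """A literature-style whole-blood immune hierarchy.

    Fractions are plausible healthy/myeloma whole-blood values (overridable
    in the config); locations are on the arcsinh scale with ~3 for bright
    markers, ~0.3 for unexpressed ones.
    """
    p = PopulationSpec
    return [
        p("T cells", None, 0.45,
          {"CD3": 3.2, "CD127": 2.3, "CD38": 1.0, "CD27": 2.5}),
        p("CD4 T cells", "T cells", 0.60, {"CD4": 3.0, "CD8": 0.3}),
        p("Treg", "CD4 T cells", 0.08,
          {"CD25": 3.0, "CD127": 0.3, "CD38": 2.5, "CD45RA": 0.3}),
        p("CD4 naive", "CD4 T cells", 0.42,
          {"CD45RA": 3.0, "CD27": 3.0, "CD25": 0.3}),
        p("CD4 memory", "CD4 T cells", 0.50,
          {"CD45RA": 0.3, "CD27": 3.0, "CD25": 0.4, "HLA-DR": 1.0}),
        p("CD8 T cells", "T cells", 0.35, {"CD8": 3.0, "CD4": 0.3, "GrB": 1.0}),
        p("CD8 naive", "CD8 T cells", 0.35, {"CD45RA": 3.0, "CD27": 3.0}),
        p("CD8 memory", "CD8 T cells", 0.30,
          {"CD45RA": 0.3, "CD27": 3.0, "HLA-DR": 1.2}),
        p("CD8 TEM", "CD8 T cells", 0.22,
          {"CD45RA": 0.3, "CD27": 0.3, "GrB": 2.2, "HLA-DR": 1.2}),
        p("CD8 TEMRA", "CD8 T cells", 0.13,
          {"CD45RA": 3.0, "CD27": 0.3, "GrB": 3.0}),
        p("NK cells", None, 0.12,
          {"CD56": 2.0, "CD16": 2.5, "CD38": 2.5, "CD127": 0.3, "GrB": 2.5}),
        p("NK CD56dim", "NK cells", 0.90, {"CD56": 1.8, "CD16": 3.0}),
        p("NK CD56bright", "NK cells", 0.10,
          {"CD56": 4.2, "CD16": 0.4, "CD127": 2.0}),
        p("B cells", None, 0.10, {"CD19": 3.0, "HLA-DR": 2.8, "CD38": 1.8}),
        p("Monocytes", None, 0.22,
          {"CD14": 3.2, "HLA-DR": 3.0, "CD38": 2.2, "CD16": 1.0}),
        p("MDSC", "Monocytes", 0.06, {"HLA-DR": 0.4, "CD38": 2.8}),
    ]


def default_effects() -> list[EffectSpec]:
    """The spiked treated-arm effects the downstream analyses must recover."""
    e = EffectSpec
    return [
        e("treated", "NK cells", 1.0, {"CD38": -1.0}),
        e("treated", "B cells", 1.0, {"CD38": -1.0}),
        e("treated", "Monocytes", 1.0, {"CD38": -1.0}),
        e("treated", "CD4 T cells", 1.0, {"CD38": -1.0}),
        e("treated", "NK CD56dim", 0.40,
          {"CD69": 0.8, "CD27": 0.8, "CD137": 0.5, "HLA-DR": 0.5}),
        e("treated", "NK CD56bright", 0.75, {"CD69": 0.6, "CD127": -0.5}),
        e("treated", "CD8 memory", 1.6, {"HLA-DR": 0.5}),
        e("treated", "CD8 TEM", 1.5, {"HLA-DR": 0.5}),
        e("treated", "CD8 TEMRA", 1.4, {}),
        e("treated", "Treg", 0.55, {}),
        e("treated", "MDSC", 0.50, {}),
    ]


def default_gating_hierarchy() -> GatingHierarchy:
    """Marker-threshold gates matching :func:`default_populations`."""
    r = PopulationRule
    return GatingHierarchy([
        r("T cells", None, (("CD3", "above", 1.5),)),
        r("CD4 T cells", "T cells", (("CD4", "above", 1.5), ("CD8", "below", 1.5))),
        r("Treg", "CD4 T cells", (("CD25", "above", 1.5), ("CD127", "below", 1.2))),
        r("CD4 naive", "CD4 T cells",
          (("CD45RA", "above", 1.5), ("CD27", "above", 1.5), ("CD25", "below", 1.5))),
        r("CD4 memory", "CD4 T cells",
          (("CD45RA", "below", 1.5), ("CD27", "above", 1.5), ("CD127", "above", 1.2))),
        r("CD8 T cells", "T cells", (("CD8", "above", 1.5), ("CD4", "below", 1.5))),
        r("CD8 naive", "CD8 T cells",
          (("CD45RA", "above", 1.5), ("CD27", "above", 1.5))),
        r("CD8 memory", "CD8 T cells",
          (("CD45RA", "below", 1.5), ("CD27", "above", 1.5))),
        r("CD8 TEM", "CD8 T cells",
          (("CD45RA", "below", 1.5), ("CD27", "below", 1.5))),
        r("CD8 TEMRA", "CD8 T cells",
          (("CD45RA", "above", 1.5), ("CD27", "below", 1.5))),
        r("NK cells", None, (("CD3", "below", 1.5), ("CD56", "above", 1.0),
                             ("CD19", "below", 1.5), ("CD14", "below", 1.5))),
        r("NK CD56dim", "NK cells", (("CD56", "below", 3.0), ("CD16", "above", 1.5))),
        r("NK CD56bright", "NK cells", (("CD56", "above", 3.0),)),
        r("B cells", None, (("CD19", "above", 1.5), ("CD3", "below", 1.5))),
        r("Monocytes", None, (("CD14", "above", 1.5), ("CD3", "below", 1.5))),
        r("MDSC", "Monocytes", (("HLA-DR", "below", 1.2), ("CD38", "above", 1.5))),
    ])


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    return CohortConfig(seed=seed, **overrides)


# --------------------------------------------------------------------------
# hierarchy resolution
# --------------------------------------------------------------------------

class _PopTree:
    """Resolved population tree: inherited phenotypes and leaf weights."""

    def __init__(self, populations: list[PopulationSpec], channels: list[str]):
        self.channels = channels
        self.by_name = {p.name: p for p in populations}
        if len(self.by_name) != len(populations):
            raise ValueError("duplicate population names")
        self.order = [p.name for p in populations]
        # validate parents + cycles
        for p in populations:
            seen, cur = set(), p.name
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in population hierarchy at {cur!r}")
                seen.add(cur)
                nxt = self.by_name.get(cur)
                if nxt is None:
                    raise ValueError(f"unknown parent {cur!r}")
                cur = nxt.parent
        for parent in set(p.parent for p in populations):
            sibs = [p for p in populations if p.parent == parent]
            total = sum(p.fraction_of_parent for p in sibs)
            if total > 1 + 1e-9:
                raise ValueError(
                    f"sibling fractions under {parent!r} sum to {total:.3f} > 1"
                )

        self.locations: dict[str, np.ndarray] = {}
        self.spreads: dict[str, np.ndarray] = {}
        base_loc = np.full(len(channels), NEGATIVE_LOC)
        base_spread = np.full(len(channels), DEFAULT_SPREAD)
        self.locations[OTHER] = base_loc
        self.spreads[OTHER] = base_spread
        for name in self.order:
            loc, spr = self._resolve_phenotype(name)
            self.locations[name] = loc
            self.spreads[name] = spr

        # generation units: every population contributes an "own cells" unit
        # holding the share of its parent not claimed by children, plus the
        # root-level remainder sink
        self.units: list[tuple[str, float]] = []  # (population, base weight)
        root_claim = 0.0
        for name in self.order:
            w = self._path_weight(name) * (1.0 - self._children_fraction(name))
            if w > 0:
                self.units.append((name, w))
        root_claim = sum(
            p.fraction_of_parent for p in self.by_name.values() if p.parent is None
        )
        if root_claim < 1:
            self.units.append((OTHER, 1.0 - root_claim))

    def _resolve_phenotype(self, name):
        chain = []
        cur: str | None = name
        while cur is not None:
            chain.append(self.by_name[cur])
            cur = self.by_name[cur].parent
        loc = np.full(len(self.channels), NEGATIVE_LOC)
        spr = np.full(len(self.channels), DEFAULT_SPREAD)
        for pop in reversed(chain):  # root first, leaf overrides last
            for ch, v in pop.marker_locations.items():
                if ch not in self.channels:
                    raise ValueError(f"{pop.name}: unknown channel {ch!r}")
                loc[self.channels.index(ch)] = v
            for ch, v in pop.marker_spreads.items():
                spr[self.channels.index(ch)] = v
        return loc, spr

    def _path_weight(self, name) -> float:
        w, cur = 1.0, name
        while cur is not None:
            w *= self.by_name[cur].fraction_of_parent
            cur = self.by_name[cur].parent
        return w

    def _children_fraction(self, name) -> float:
        return sum(
            p.fraction_of_parent for p in self.by_name.values() if p.parent == name
        )

    def lineage(self, name: str) -> list[str]:
        """The population and all its ancestors (for effect targeting)."""
        if name == OTHER:
            return [OTHER]
        out, cur = [], name
        while cur is not None:
            out.append(cur)
            cur = self.by_name[cur].parent
        return out


# --------------------------------------------------------------------------
# elementary generators
# --------------------------------------------------------------------------

def sample_population_events(
    spec_or_location,
    n_cells: int,
    shifts: dict[str, float] | None,
    rng,
    channels: list[str] | None = None,
    spreads=None,
) -> np.ndarray:
    """Draw ``n_cells`` events for one population on the arcsinh scale.

    Accepts either a :class:`PopulationSpec` (with ``channels`` giving the
    panel) or a pre-resolved location vector plus ``spreads``. Each channel
    is normal around location + shift. Returns an n_cells x channels array
    (empty with the right width for n_cells = 0).
    """
    rng = rng_from(rng)
    if isinstance(spec_or_location, PopulationSpec):
        if channels is None:
            raise ValueError("channels required with a PopulationSpec")
        loc = np.full(len(channels), NEGATIVE_LOC)
        spr = np.full(len(channels), DEFAULT_SPREAD)
        for ch, v in spec_or_location.marker_locations.items():
            if ch not in channels:
                raise ValueError(f"unknown channel {ch!r}")
            loc[channels.index(ch)] = v
        for ch, v in spec_or_location.marker_spreads.items():
            spr[channels.index(ch)] = v
    else:
        loc = np.asarray(spec_or_location, dtype=float).copy()
        spr = np.asarray(spreads, dtype=float)
        channels = channels if channels is not None else [
            f"ch{i}" for i in range(loc.size)
        ]
    if shifts:
        for ch, dv in shifts.items():
            if ch not in channels:
                raise ValueError(f"unknown channel in shifts: {ch!r}")
            loc[channels.index(ch)] += dv
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells == 0:
        return np.empty((0, len(channels)))
    return rng.normal(loc, spr, size=(n_cells, len(channels)))


def generate_repertoire(
    n_clones: int,
    expansion_strength: float,
    total_templates: int,
    rng,
) -> pd.Series:
    """Clone-count table with rank power-law frequencies p_i ~ i^(-s).

    s = 0 gives a near-uniform repertoire (clonality ~ 0); larger s
    concentrates templates in the top clones, raising clonality. Counts are
    multinomial and sum to ``total_templates``; clones drawn zero times are
    dropped (unobserved).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if total_templates < n_clones:
        raise ValueError("total_templates must be >= n_clones")
    if expansion_strength < 0:
        raise ValueError("expansion_strength must be >= 0")
    rng = rng_from(rng)
    ranks = np.arange(1, n_clones + 1, dtype=float)
    probs = ranks ** (-expansion_strength)
    probs /= probs.sum()
    counts = rng.multinomial(total_templates, probs)
    ids = [f"clone{i:05d}" for i in range(1, n_clones + 1)]
    s = pd.Series(counts, index=ids)
    return s[s > 0]


def generate_expression_counts(
    abundances: pd.DataFrame,
    config: ExpressionConfig,
    rng,
    log2_shifts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genes x samples counts driven by per-sample population fractions.

    Abundance-linked genes have expectation
    max(linked_scale * fraction, floor_count) — proportional to the linked
    population's %total, floored at ``floor_count`` when the population is
    absent. Unlinked genes (housekeeping included) have constant
    expectation. ``log2_shifts`` (genes x samples) injects true
    transcriptional effects multiplicatively. Counts are Poisson around the
    expectation times lognormal noise of sd ``noise_sd``.
    """
    rng = rng_from(rng)
    for gene, pop in config.abundance_linked_genes.items():
        if pop not in abundances.columns:
            raise ValueError(f"gene {gene!r} linked to unknown population {pop!r}")
    genes = _gene_names(config)
    samples = list(abundances.index)
    mu = np.empty((len(genes), len(samples)))
    for i, g in enumerate(genes):
        if g in config.abundance_linked_genes:
            frac = abundances[config.abundance_linked_genes[g]].to_numpy(float)
            mu[i] = np.maximum(config.linked_scale * frac, config.floor_count)
        elif g in config.housekeeping_genes:
            mu[i] = 2.0 * config.base_count
        else:
            mu[i] = config.base_count
    if log2_shifts is not None:
        mu = mu * np.power(
            2.0, log2_shifts.reindex(index=genes, columns=samples).fillna(0.0)
        ).to_numpy()
    if config.noise_sd > 0:
        mu = mu * rng.lognormal(0.0, config.noise_sd, size=mu.shape)
    counts = rng.poisson(mu) if config.noise_sd > 0 else mu
    return pd.DataFrame(counts, index=genes, columns=samples)


def _gene_names(config: ExpressionConfig) -> list[str]:
    named = (
        list(config.housekeeping_genes)
        + list(config.abundance_linked_genes)
        + list(config.treatment_shift_genes)
    )
    fillers = [f"G{i:04d}" for i in range(1, max(config.n_genes - len(named), 0) + 1)]
    return named + fillers


# --------------------------------------------------------------------------
# the full cohort
# --------------------------------------------------------------------------

def generate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate the complete synthetic study. Deterministic given the seed."""
    cfg = config if config is not None else default_config()
    rng = np.random.default_rng(cfg.seed)
    channels = default_channels()
    tree = _PopTree(cfg.populations, channels)
    unit_names = [u for u, _ in tree.units]
    base_w = np.array([w for _, w in tree.units])

    effects_by_arm: dict[str, list[EffectSpec]] = {"treated": [], "control": []}
    for e in cfg.effects:
        if e.population not in tree.by_name:
            raise ValueError(f"effect targets unknown population {e.population!r}")
        effects_by_arm[e.arm].append(e)

    # ---- patient table -------------------------------------------------
    patients = []
    for arm in sorted(cfg.n_patients_per_arm):
        n = cfg.n_patients_per_arm[arm]
        n_paired = int(round(cfg.paired_fraction.get(arm, 0.0) * n))
        n_nonresp = int(round((1 - cfg.responder_fraction.get(arm, 1.0)) * n))
        paired_flags = np.zeros(n, dtype=bool)
        paired_flags[rng.choice(n, size=n_paired, replace=False)] = True
        resp_flags = np.ones(n, dtype=bool)
        resp_flags[rng.choice(n, size=n_nonresp, replace=False)] = False
        for i in range(n):
            patients.append(
                {
                    "patient_id": f"{arm[:2].upper()}{i + 1:03d}",
                    "arm": arm,
                    "paired": bool(paired_flags[i]),
                    "responder": bool(resp_flags[i]),
                    # latent depth-of-response: scales every spiked effect
                    "coupling_z": float(rng.normal()),
                    # latent clone-pool size: drives richness and (treated) PFS
                    "richness_z": float(rng.normal()),
                }
            )

    events: dict[str, EventMatrix] = {}
    cell_labels: dict[str, np.ndarray] = {}
    meta_rows = []
    abundance_rows = {}
    repertoires: dict[str, pd.Series] = {}

    def _marker_offsets():
        return rng.normal(0.0, cfg.marker_offset_sd, size=len(channels))

    def _make_sample(sid, weights, shift_map, offsets):
        n_cells = max(int(rng.poisson(cfg.cells_per_sample_mean)), 50)
        p = weights / weights.sum()
        counts = rng.multinomial(n_cells, p)
        blocks, labels = [], []
        for (unit, _), cnt in zip(tree.units, counts):
            if cnt == 0:
                continue
            loc = tree.locations[unit] + offsets
            shift = shift_map.get(unit)
            block = sample_population_events(
                loc if shift is None else loc + shift,
                cnt, None, rng, channels=channels, spreads=tree.spreads[unit],
            )
            blocks.append(block)
            labels.append(np.repeat(unit, cnt))
        values = np.vstack(blocks)
        labs = np.concatenate(labels)
        perm = rng.permutation(n_cells)
        events[sid] = EventMatrix(sid, channels, values[perm], scale="arcsinh")
        cell_labels[sid] = labs[perm]
        abundance_rows[sid] = {
            name: float(np.mean([l in _lineage_cache[name] for l in labs]))
            for name in tree.order
        }
        return n_cells

    # cells count toward a population when their generating unit lies in
    # that population's subtree
    _lineage_cache = {
        name: frozenset(
            u for u, _ in tree.units if name in tree.lineage(u)
        )
        for name in tree.order
    }

    def _effect_weights_and_shifts(arm, coupling_z):
        """Per-unit abundance multipliers and marker-shift vectors."""
        mult = np.ones(len(tree.units))
        shifts: dict[str, np.ndarray] = {}
        scale = float(np.exp(cfg.response_coupling_sd * coupling_z))
        for e in effects_by_arm.get(arm, []):
            for k, (unit, _) in enumerate(tree.units):
                if e.population in tree.lineage(unit):
                    mult[k] *= e.abundance_multiplier ** scale
                    if e.marker_shifts:
                        vec = shifts.setdefault(unit, np.zeros(len(channels)))
                        for ch, dv in e.marker_shifts.items():
                            if ch not in channels:
                                raise ValueError(f"unknown channel {ch!r}")
                            vec[channels.index(ch)] += dv * scale
        return mult, shifts

    # ---- patient samples ----------------------------------------------
    for pat in patients:
        pid, arm = pat["patient_id"], pat["arm"]
        pat_w = base_w * rng.lognormal(0.0, cfg.patient_abundance_sd,
                                       size=len(tree.units))
        offsets = _marker_offsets()
        n_clones_i = max(int(round(cfg.repertoire.n_clones
                                   * np.exp(cfg.repertoire.richness_sd
                                            * pat["richness_z"]))), 5)
        timepoints = ["baseline", "on_treatment"] if pat["paired"] else ["baseline"]
        for tp in timepoints:
            sid = f"{pid}_{'B' if tp == 'baseline' else 'T'}"
            w = pat_w * rng.lognormal(0.0, cfg.sample_abundance_sd,
                                      size=len(tree.units))
            shift_map: dict[str, np.ndarray] = {}
            if tp == "on_treatment":
                mult, shift_map = _effect_weights_and_shifts(arm, pat["coupling_z"])
                w = w * mult
            _make_sample(sid, w, shift_map, offsets)

            strength = cfg.repertoire.baseline_strength
            if tp == "on_treatment":
                strength += cfg.repertoire.on_treatment_delta.get(arm, 0.0) * float(
                    np.exp(cfg.response_coupling_sd * pat["coupling_z"])
                )
            repertoires[sid] = generate_repertoire(
                n_clones_i, strength, cfg.repertoire.total_templates, rng
            )
            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "arm": arm,
                    "timepoint": tp,
                    "response": "responder" if pat["responder"] else "nonresponder",
                    "control": False,
                    "n_events": float(
                        rng.lognormal(np.log(cfg.acquired_events_mean), 0.3)
                    ),
                }
            )

    # ---- technical control samples -------------------------------------
    control_offsets = _marker_offsets()  # one shared donor profile
    for i in range(cfg.n_controls):
        sid = f"CTRL{i + 1:03d}"
        w = base_w * rng.lognormal(0.0, 0.04, size=len(tree.units))
        _make_sample(sid, w, {}, control_offsets)
        meta_rows.append(
            {
                "sample_id": sid,
                "patient_id": sid,
                "arm": pd.NA,
                "timepoint": "control",
                "response": pd.NA,
                "control": True,
                "n_events": float(
                    rng.lognormal(np.log(cfg.acquired_events_mean), 0.2)
                ),
            }
        )

    metadata = pd.DataFrame(meta_rows)

    # ---- progression-free survival -------------------------------------
    pfs_time, pfs_event = {}, {}
    base_rate = np.log(2) / cfg.pfs_median_months
    for pat in patients:
        rate = base_rate
        if pat["arm"] == "treated":
            rate = base_rate * float(np.exp(-cfg.pfs_richness_loghr
                                            * pat["richness_z"]))
        t = float(rng.exponential(1.0 / rate))
        c = float(rng.uniform(0.5 * cfg.pfs_censor_months, cfg.pfs_censor_months))
        pfs_time[pat["patient_id"]] = min(t, c)
        pfs_event[pat["patient_id"]] = int(t <= c)
    metadata["pfs_time"] = metadata["patient_id"].map(pfs_time)
    metadata["pfs_event"] = metadata["patient_id"].map(pfs_event)

    abundances = pd.DataFrame.from_dict(abundance_rows, orient="index")[tree.order]

    # ---- expression (paired patients' samples) --------------------------
    pt_meta = metadata[~metadata["control"]]
    paired_patients = set(
        pt_meta.groupby("patient_id")["timepoint"]
        .nunique()
        .pipe(lambda s: s[s > 1])
        .index
    )
    paired_ids = [
        r["sample_id"] for r in meta_rows
        if not r["control"] and r["patient_id"] in paired_patients
    ]
    expr_abund = abundances.loc[paired_ids]
    shifts = pd.DataFrame(0.0, index=_gene_names(cfg.expression),
                          columns=paired_ids)
    meta_idx = metadata.set_index("sample_id")
    for g, lfc in cfg.expression.treatment_shift_genes.items():
        on_treated = [
            s for s in paired_ids
            if meta_idx.loc[s, "timepoint"] == "on_treatment"
            and meta_idx.loc[s, "arm"] == "treated"
        ]
        shifts.loc[g, on_treated] = lfc
    expression = generate_expression_counts(
        expr_abund, cfg.expression, rng, log2_shifts=shifts
    )

    truth = {
        "seed": cfg.seed,
        "effects": [asdict(e) for e in cfg.effects],
        "repertoire": asdict(cfg.repertoire),
        "expression": {
            "abundance_linked_genes": dict(cfg.expression.abundance_linked_genes),
            "treatment_shift_genes": dict(cfg.expression.treatment_shift_genes),
        },
        "patients": patients,
    }
    return CohortDataset(
        events=events,
        metadata=metadata,
        repertoires=repertoires,
        expression=expression,
        abundances=abundances,
        cell_labels=cell_labels,
        truth=truth,
    )


# --------------------------------------------------------------------------
# bookkeeping fixtures mirroring the reference cohort's printed accounting
# --------------------------------------------------------------------------

def study_qc_metadata(
    n_retained_baseline: tuple[int, int] = (40, 45),
    n_retained_on_treatment: tuple[int, int] = (31, 33),
    n_qc_failures_with_partner: int = 9,
    n_qc_failures_other: int = 34,
    passing_events: float = 60_000.0,
    failing_events: float = 5_000.0,
) -> pd.DataFrame:
    """Acquisition-level metadata reproducing the reference QC bookkeeping.

    Builds the sample table of a two-arm cohort as acquired on the
    instrument: the samples that pass the live-singlet threshold, a set of
    QC failures, and the on-treatment partners of failed baselines (which
    pass the threshold themselves but lose their paired comparison). With
    the defaults, 201 acquired samples resolve to 149 retained + 43 QC
    failures + 9 paired exclusions under :func:`~cytoprof.preprocessing.
    qc_retain_samples`.
    """
    rows = []

    def add(sample_id, patient_id, arm, timepoint, n_events):
        rows.append(
            {"sample_id": sample_id, "patient_id": patient_id, "arm": arm,
             "timepoint": timepoint, "control": False, "n_events": n_events}
        )

    arms = ("treated", "control")
    for arm, n_base, n_post in zip(arms, n_retained_baseline,
                                   n_retained_on_treatment):
        for i in range(n_base):
            add(f"{arm[:2]}{i:03d}_B", f"{arm[:2]}{i:03d}", arm, "baseline",
                passing_events)
        for i in range(n_post):
            add(f"{arm[:2]}{i:03d}_T", f"{arm[:2]}{i:03d}", arm,
                "on_treatment", passing_events)
    for i in range(n_qc_failures_with_partner):
        add(f"fx{i:03d}_B", f"fx{i:03d}", "treated", "baseline", failing_events)
        add(f"fx{i:03d}_T", f"fx{i:03d}", "treated", "on_treatment",
            passing_events)
    for i in range(n_qc_failures_other):
        add(f"fy{i:03d}_B", f"fy{i:03d}", "control", "baseline", failing_events)
    return pd.DataFrame(rows)


def study_expression_metadata(
    paired: tuple[int, int] = (71, 65),
    baseline_only: tuple[int, int] = (4, 5),
    on_treatment_only: tuple[int, int] = (6, 5),
) -> pd.DataFrame:
    """Sample table matching the reference expression-cohort group sizes.

    Defaults give treated-arm groups of 75 baseline / 77 on-treatment
    (71 paired) and control-arm groups of 70 / 70 (65 paired): 292 samples.
    """
    rows = []
    for arm, n_pair, n_b, n_t in zip(
        ("treated", "control"), paired, baseline_only, on_treatment_only
    ):
        for i in range(n_pair):
            pid = f"{arm[:2]}p{i:03d}"
            rows.append({"sample_id": f"{pid}_B", "patient_id": pid,
                         "arm": arm, "timepoint": "baseline"})
            rows.append({"sample_id": f"{pid}_T", "patient_id": pid,
                         "arm": arm, "timepoint": "on_treatment"})
        for i in range(n_b):
            pid = f"{arm[:2]}b{i:03d}"
            rows.append({"sample_id": f"{pid}_B", "patient_id": pid,
                         "arm": arm, "timepoint": "baseline"})
        for i in range(n_t):
            pid = f"{arm[:2]}t{i:03d}"
            rows.append({"sample_id": f"{pid}_T", "patient_id": pid,
                         "arm": arm, "timepoint": "on_treatment"})
    return pd.DataFrame(rows)
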