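"""SPADE: spanning-tree progression analysis of density-normalized events.

The pipeline is the classical one: (1) density-dependent downsampling so
rare phenotypes survive clustering, (2) clustering of the pooled downsampled
cells to a fixed node count, (3) a minimum spanning tree over the node
medians, (4) upsampling — every cell of every sample is assigned to its
nearest node. Nodes are then gated into a named immune-population hierarchy
by marker-threshold rules on the node medians, and per-sample population
counts yield %total and %parent fractions.

L1 (Manhattan) distance is used throughout, configurable to L2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import AgglomerativeClustering, MiniBatchKMeans

from ._utils import rng_from
from .preprocessing import EventMatrix

__all__ = [
    "SpadeTree",
    "GatingHierarchy",
    "PopulationRule",
    "density_dependent_downsample",
    "cluster_to_nodes",
    "build_mst",
    "assign_cells",
    "fit_spade",
    "gate_nodes_to_populations",
    "gate_cells",
    "population_counts",
    "population_fractions",
]

UNGATED = "ungated"


@dataclass
class SpadeTree:
    """Fitted SPADE result: node medians, MST edges and cell assignments."""

    channels: list[str]
    node_medians: np.ndarray  # nodes x channels
    edges: list[tuple[int, int]]
    assignments: dict[str, np.ndarray] = field(default_factory=dict)
    per_sample_node_counts: pd.DataFrame | None = None  # samples x nodes

    @property
    def n_nodes(self) -> int:
        return self.node_medians.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "channels": self.channels,
            "node_medians": self.node_medians.tolist(),
            "edges": [list(e) for e in self.edges],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SpadeTree":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            channels=payload["channels"],
            node_medians=np.asarray(payload["node_medians"], dtype=float),
            edges=[tuple(e) for e in payload["edges"]],
        )


@dataclass(frozen=True)
class PopulationRule:
    """One gated population: name, parent and marker-threshold rules.

    Each rule is (channel, direction, threshold) with direction "above" or
    "below"; thresholds live on the arcsinh scale. A node (or cell) belongs
    to the population when it satisfies the population's own rules and those
    of every ancestor.
    """

    name: str
    parent: str | None
    rules: tuple[tuple[str, str, float], ...]


class GatingHierarchy:
    """A rooted forest of marker-threshold population definitions."""

    def __init__(self, populations: list[PopulationRule]):
        self.populations = list(populations)
        self._by_name = {p.name: p for p in self.populations}
        if len(self._by_name) != len(self.populations):
            raise ValueError("duplicate population names")
        for p in self.populations:
            if p.parent is not None and p.parent not in self._by_name:
                raise ValueError(f"{p.name}: unknown parent {p.parent!r}")
            for ch, direction, _ in p.rules:
                if direction not in ("above", "below"):
                    raise ValueError(f"{p.name}: bad rule direction {direction!r}")
        # cycle check + depth computation
        self._depth = {}
        for p in self.populations:
            seen, cur, d = set(), p.name, 0
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in hierarchy at {cur!r}")
                seen.add(cur)
                cur = self._by_name[cur].parent
                d += 1
            self._depth[p.name] = d
        for p in self.populations:
            self._check_consistent(self.rule_chain(p.name), p.name)

    @staticmethod
    def _check_consistent(chain, name):
        lo, hi = {}, {}
        for ch, direction, thr in chain:
            if direction == "above":
                lo[ch] = max(lo.get(ch, -np.inf), thr)
            else:
                hi[ch] = min(hi.get(ch, np.inf), thr)
        for ch in set(lo) & set(hi):
            if lo[ch] >= hi[ch]:
                raise ValueError(
                    f"{name}: contradictory rules on {ch} "
                    f"(above {lo[ch]} and below {hi[ch]})"
                )

    def __contains__(self, name):
        return name in self._by_name

    def __getitem__(self, name) -> PopulationRule:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    def depth(self, name: str) -> int:
        return self._depth[name]

    def parent(self, name: str) -> str | None:
        return self._by_name[name].parent

    def children(self, name: str | None) -> list[str]:
        return [p.name for p in self.populations if p.parent == name]

    def descendants(self, name: str) -> list[str]:
        out = []
        stack = [name]
        while stack:
            cur = stack.pop()
            kids = self.children(cur)
            out.extend(kids)
            stack.extend(kids)
        return out

    def rule_chain(self, name: str) -> list[tuple[str, str, float]]:
        """All rules of the population and its ancestors, root first."""
        chain: list = []
        cur: str | None = name
        while cur is not None:
            pop = self._by_name[cur]
            chain = list(pop.rules) + chain
            cur = pop.parent
        return chain

    def to_json(self, path) -> None:
        payload = [
            {"name": p.name, "parent": p.parent, "rules": [list(r) for r in p.rules]}
            for p in self.populations
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GatingHierarchy":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [
                PopulationRule(
                    d["name"],
                    d["parent"],
                    tuple((c, s, float(t)) for c, s, t in d["rules"]),
                )
                for d in payload
            ]
        )


def density_dependent_downsample(
    m: EventMatrix | np.ndarray,
    target_fraction: float = 0.10,
    rng=0,
    radius_alpha: float = 5.0,
) -> np.ndarray:
    """Keep cells with probability inversely proportional to local density.

    Local density is the number of neighbors within radius
    r = radius_alpha x median nearest-neighbor distance. A target density TD
    is tuned by bisection so that the expected kept fraction,
    sum_i min(1, TD / density_i) / n, matches ``target_fraction``; cell i is
    then kept with probability min(1, TD / density_i). Dense regions are
    thinned hard while rare cells are kept, flattening the density landscape.

    Returns sorted unique kept-cell indices.
    """
    values = m.values if isinstance(m, EventMatrix) else np.asarray(m, float)
    if isinstance(m, EventMatrix) and m.scale != "arcsinh":
        raise ValueError("downsampling expects arcsinh-scale data")
    if not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must be in (0, 1]")
    n = values.shape[0]
    if n < 2:
        return np.arange(n)
    if target_fraction == 1:
        return np.arange(n)

    rng = rng_from(rng)
    tree = cKDTree(values)
    nn_dist = tree.query(values, k=2, p=1)[0][:, 1]
    r = radius_alpha * np.median(nn_dist)
    if r <= 0:
        # degenerate: many exact duplicates; fall back to uniform thinning
        keep = rng.random(n) < target_fraction
        return np.flatnonzero(keep)
    density = np.asarray(
        tree.query_ball_point(values, r=r, p=1, return_length=True), dtype=float
    )

    target_n = target_fraction * n

    def expected_kept(td: float) -> float:
        return float(np.minimum(1.0, td / density).sum())

    lo, hi = 0.0, float(density.max())
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expected_kept(mid) < target_n:
            lo = mid
        else:
            hi = mid
    td = 0.5 * (lo + hi)
    keep_prob = np.minimum(1.0, td / density)
    kept = np.flatnonzero(rng.random(n) < keep_prob)
    return kept


def cluster_to_nodes(
    cells: np.ndarray,
    n_nodes: int = 150,
    rng=0,
    metric: str = "cityblock",
    agglomerative_max: int = 3000,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster downsampled cells into exactly ``n_nodes`` non-empty nodes.

    Small inputs use average-linkage agglomerative clustering in the chosen
    metric; larger inputs use (mini-batch) k-means for tractability. Empty
    clusters are repaired by splitting the largest cluster. Node medians are
    the per-channel medians of cluster members.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.size == 0:
        raise ValueError("no cells to cluster")
    n = cells.shape[0]
    if n < n_nodes:
        warnings.warn(
            f"only {n} cells for {n_nodes} nodes; reducing node count to {n}",
            stacklevel=2,
        )
        n_nodes = n

    if n == n_nodes:
        labels = np.arange(n)
    elif n <= agglomerative_max:
        model = AgglomerativeClustering(
            n_clusters=n_nodes,
            metric="manhattan" if metric == "cityblock" else metric,
            linkage="average",
        )
        labels = model.fit_predict(cells)
    else:
        seed = int(rng_from(rng).integers(2**31))
        model = MiniBatchKMeans(
            n_clusters=n_nodes,
            random_state=seed,
            n_init=3,
            batch_size=4096,
            max_iter=100,
        )
        labels = model.fit_predict(cells)
        labels = _repair_empty_clusters(cells, labels, n_nodes)

    medians = np.vstack(
        [np.median(cells[labels == k], axis=0) for k in range(n_nodes)]
    )
    return labels, medians


def _repair_empty_clusters(cells, labels, n_nodes):
    """Reassign members of over-full clusters to fill any empty node ids."""
    counts = np.bincount(labels, minlength=n_nodes)
    empty = np.flatnonzero(counts == 0)
    for node in empty:
        donor = int(np.argmax(np.bincount(labels, minlength=n_nodes)))
        members = np.flatnonzero(labels == donor)
        # move the member farthest from the donor centroid
        centroid = cells[members].mean(axis=0)
        far = members[np.argmax(np.abs(cells[members] - centroid).sum(axis=1))]
        labels = labels.copy()
        labels[far] = node
    return labels


def build_mst(node_medians: np.ndarray, metric: str = "cityblock") -> list[tuple[int, int]]:
    """Minimum spanning tree over node medians; returns sorted edge list."""
    medians = np.asarray(node_medians, dtype=float)
    n = medians.shape[0]
    if n <= 1:
        return []
    dist = squareform(pdist(medians, metric=metric))
    mst = minimum_spanning_tree(dist)
    rows, cols = mst.nonzero()
    edges = sorted(tuple(sorted((int(i), int(j)))) for i, j in zip(rows, cols))
    return edges


def assign_cells(
    node_medians: np.ndarray,
    values: np.ndarray,
    metric: str = "cityblock",
    chunk: int = 20_000,
) -> np.ndarray:
    """Map each cell to its nearest node median (ties -> lowest node id)."""
    values = np.asarray(values, dtype=float)
    medians = np.asarray(node_medians, dtype=float)
    if values.shape[1] != medians.shape[1]:
        raise ValueError("channel mismatch between cells and node medians")
    out = np.empty(values.shape[0], dtype=int)
    for start in range(0, values.shape[0], chunk):
        block = values[start : start + chunk]
        d = cdist(block, medians, metric=metric)
        out[start : start + chunk] = np.argmin(d, axis=1)  # argmin -> lowest id
    return out


def fit_spade(
    samples: list[EventMatrix],
    n_nodes: int = 150,
    downsample_fraction: float = 0.10,
    rng=0,
    metric: str = "cityblock",
) -> SpadeTree:
    """Run the full SPADE pipeline over a cohort of samples.

    Each sample is density-downsampled independently; the pooled kept cells
    are clustered into ``n_nodes`` nodes; an MST links the node medians; and
    every cell of every sample (not only the kept ones) is assigned to its
    nearest node, filling the samples x nodes count table. Zero counts are
    allowed — a node can be empty for a given sample.
    """
    if not samples:
        raise ValueError("no samples")
    channels = samples[0].channels
    for s in samples:
        if s.channels != channels:
            raise ValueError(f"{s.sample_id}: channel mismatch")
        if s.scale != "arcsinh":
            raise ValueError(f"{s.sample_id}: expected arcsinh scale")
    rng = rng_from(rng)

    pooled = []
    for s in samples:
        kept = density_dependent_downsample(s, downsample_fraction, rng=rng)
        pooled.append(s.values[kept])
    pooled = np.vstack(pooled)
    _, medians = cluster_to_nodes(pooled, n_nodes=n_nodes, rng=rng, metric=metric)
    edges = build_mst(medians, metric=metric)

    assignments = {}
    counts = np.zeros((len(samples), medians.shape[0]), dtype=int)
    for i, s in enumerate(samples):
        lab = assign_cells(medians, s.values, metric=metric)
        assignments[s.sample_id] = lab
        counts[i] = np.bincount(lab, minlength=medians.shape[0])
    count_df = pd.DataFrame(
        counts,
        index=[s.sample_id for s in samples],
        columns=list(range(medians.shape[0])),
    )
    return SpadeTree(channels, medians, edges, assignments, count_df)


def _satisfies(vector: np.ndarray, channels: list[str], chain) -> bool:
    for ch, direction, thr in chain:
        v = vector[channels.index(ch)]
        if direction == "above" and not v > thr:
            return False
        if direction == "below" and not v < thr:
            return False
    return True


def gate_nodes_to_populations(
    tree: SpadeTree, hierarchy: GatingHierarchy
) -> dict[int, str]:
    """Assign each node to the deepest population whose rule chain its median
    satisfies; nodes matching no root rule are "ungated"."""
    order = sorted(hierarchy.names, key=hierarchy.depth, reverse=True)
    out = {}
    for node in range(tree.n_nodes):
        med = tree.node_medians[node]
        label = UNGATED
        for name in order:
            if _satisfies(med, tree.channels, hierarchy.rule_chain(name)):
                label = name
                break
        out[node] = label
    return out


def gate_cells(
    values: np.ndarray, channels: list[str], hierarchy: GatingHierarchy
) -> np.ndarray:
    """Per-cell gating variant: deepest satisfied population per cell."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    labels = np.array([UNGATED] * n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    order = sorted(hierarchy.names, key=hierarchy.depth, reverse=True)
    idx = {ch: i for i, ch in enumerate(channels)}
    for name in order:
        if not unassigned.any():
            break
        mask = unassigned.copy()
        for ch, direction, thr in hierarchy.rule_chain(name):
            col = values[:, idx[ch]]
            mask &= (col > thr) if direction == "above" else (col < thr)
        labels[mask] = name
        unassigned &= ~mask
    return labels


def population_counts(
    labels_by_sample: dict[str, np.ndarray],
    hierarchy: GatingHierarchy,
) -> pd.DataFrame:
    """Per-sample population cell counts from deepest-gate labels.

    A cell gated into a population also counts toward every ancestor, so the
    child-count <= parent-count invariant holds by construction. The "total"
    column is the sample's full cell count (the root denominator).
    """
    names = hierarchy.names
    rows = {}
    for sid, labels in labels_by_sample.items():
        labels = np.asarray(labels, dtype=object)
        direct = pd.Series(labels).value_counts()
        counts = {}
        for name in names:
            members = [name] + hierarchy.descendants(name)
            counts[name] = int(sum(direct.get(m, 0) for m in members))
        counts["total"] = int(labels.size)
        rows[sid] = counts
    return pd.DataFrame.from_dict(rows, orient="index")[names + ["total"]]


def population_fractions(
    counts: pd.DataFrame, hierarchy: GatingHierarchy
) -> pd.DataFrame:
    """Long-form %total / %parent table from a population count table.

    %total = population count / total live cells of the sample;
    %parent = population count / its parent's count. When a parent count is
    zero, %parent is NaN (the unit is excluded downstream, the table
    equivalent of graying out an empty node).
    """
    records = []
    for sid, row in counts.iterrows():
        total = row["total"]
        for name in hierarchy.names:
            parent = hierarchy.parent(name)
            parent_count = row["total"] if parent is None else row[parent]
            cnt = row[name]
            pct_total = cnt / total if total > 0 else np.nan
            pct_parent = cnt / parent_count if parent_count > 0 else np.nan
            records.append(
                {
                    "sample_id": sid,
                    "population": name,
                    "count": int(cnt),
                    "pct_total": pct_total,
                    "pct_parent": pct_parent,
                }
            )
    return pd.DataFrame.from_records(records)
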