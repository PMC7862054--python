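"""Preprocessing and sample-level quality control for mass-cytometry cohorts.

Covers the variance-stabilizing arcsinh transform, the live-singlet
event-count retention rule with paired-exclusion propagation, Earth Mover's
Distance between sample compositions (for batch-effect QC clustering), and
marker enrichment (MEM) scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import linprog
from scipy.spatial.distance import squareform

__all__ = [
    "EventMatrix",
    "QcReport",
    "QcClustering",
    "arcsinh_transform",
    "inverse_arcsinh",
    "qc_retain_samples",
    "composition_emd",
    "qc_cluster_samples",
    "mem_score",
]


@dataclass
class EventMatrix:
    """One sample's cells x channels intensity table.

    ``scale`` records whether the values are raw ion counts or
    arcsinh-transformed intensities; analyses downstream require ``arcsinh``.
    """

    sample_id: str
    channels: list[str]
    values: np.ndarray
    scale: str = "raw"  # {"raw", "arcsinh"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, len(self.channels))
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.sample_id}: {self.values.shape[1]} columns for "
                f"{len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.scale not in ("raw", "arcsinh"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channels)

    @classmethod
    def from_csv(cls, path, sample_id: str | None = None, scale: str = "arcsinh"):
        df = pd.read_csv(path)
        sid = sample_id if sample_id is not None else str(path)
        return cls(sid, list(df.columns), df.to_numpy(float), scale=scale)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class QcReport:
    """Bookkeeping of the sample-retention decision.

    Every input sample lands in exactly one of ``retained``, ``excluded_qc``
    (failed the event-count threshold or an explicit QC flag) or
    ``excluded_paired`` (on-treatment sample whose baseline partner failed).
    """

    retained: list[str]
    excluded_qc: list[str]
    excluded_paired: list[str]
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.excluded_qc) + len(self.excluded_paired)

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "excluded_qc": self.excluded_qc,
            "excluded_paired": self.excluded_paired,
            "reasons": self.reasons,
        }


@dataclass
class QcClustering:
    linkage_matrix: np.ndarray
    labels: pd.Series
    controls_co_cluster: bool


def arcsinh_transform(m: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """Apply asinh(x / cofactor) to every intensity.

    The transform is near-linear around zero and logarithmic for large
    counts, stabilizing the variance of ion-count data. Cofactor 5 is the
    convention for mass cytometry.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if m.scale != "raw":
        raise ValueError(f"{m.sample_id}: expected raw scale, got {m.scale!r}")
    return replace(m, values=np.arcsinh(m.values / cofactor), scale="arcsinh")


def inverse_arcsinh(m: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """Invert :func:`arcsinh_transform`: sinh(x) * cofactor."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if m.scale != "arcsinh":
        raise ValueError(f"{m.sample_id}: expected arcsinh scale, got {m.scale!r}")
    return replace(m, values=np.sinh(m.values) * cofactor, scale="raw")


def qc_retain_samples(
    metadata: pd.DataFrame,
    min_events: int = 10_000,
    failed_qc: set[str] | frozenset[str] = frozenset(),
) -> QcReport:
    """Apply the event-count QC rule and propagate exclusions to pairs.

    A sample is excluded when its live-singlet event count is not strictly
    greater than ``min_events`` or it carries an explicit QC failure flag.
    An on-treatment sample whose baseline partner (same patient) was excluded
    is itself excluded (``excluded_paired``): its paired comparison is gone.

    ``metadata`` needs columns sample_id, patient_id, timepoint
    ("baseline"/"on_treatment") and n_events.
    """
    meta = metadata.reset_index(drop=True)
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dupes}")
    failed_qc = set(failed_qc)

    retained, excl_qc, excl_paired, reasons = [], [], [], {}
    qc_failed_patients_baseline = set()
    for row in meta.itertuples(index=False):
        if row.n_events <= min_events:
            excl_qc.append(row.sample_id)
            reasons[row.sample_id] = (
                f"{row.n_events} events <= threshold {min_events}"
            )
        elif row.sample_id in failed_qc:
            excl_qc.append(row.sample_id)
            reasons[row.sample_id] = "flagged by QC"
        else:
            continue
        if row.timepoint == "baseline":
            qc_failed_patients_baseline.add(row.patient_id)

    excluded_set = set(excl_qc)
    for row in meta.itertuples(index=False):
        if row.sample_id in excluded_set:
            continue
        if (
            row.timepoint == "on_treatment"
            and row.patient_id in qc_failed_patients_baseline
        ):
            excl_paired.append(row.sample_id)
            reasons[row.sample_id] = "baseline partner excluded by QC"
        else:
            retained.append(row.sample_id)

    return QcReport(retained, excl_qc, excl_paired, reasons)


def _as_fraction_vector(fractions, index=None):
    s = pd.Series(fractions, dtype=float)
    if index is not None:
        s = s.reindex(index)
    return s


def composition_emd(
    fractions_a,
    fractions_b,
    ground_distance: pd.DataFrame | np.ndarray | None = None,
    atol: float = 1e-6,
) -> float:
    """Earth Mover's Distance between two immune-composition vectors.

    Solves the optimal-transport linear program: move the probability mass of
    composition ``a`` onto composition ``b`` at minimum total cost, where
    moving one unit of mass from population i to population j costs
    ``ground_distance[i, j]``. The default ground distance is the unit cost
    (0 on the diagonal, 1 elsewhere), under which the EMD equals half the L1
    distance between the compositions.
    """
    a = _as_fraction_vector(fractions_a)
    b = _as_fraction_vector(fractions_b, index=a.index)
    if b.isna().any() or len(a) != len(pd.Series(fractions_b)):
        raise ValueError("mismatched population sets")
    if abs(a.sum() - 1) > atol or abs(b.sum() - 1) > atol:
        raise ValueError("compositions must each sum to 1")

    k = len(a)
    if ground_distance is None:
        dist = 1.0 - np.eye(k)
    elif isinstance(ground_distance, pd.DataFrame):
        dist = ground_distance.reindex(index=a.index, columns=a.index).to_numpy(float)
        if np.isnan(dist).any():
            raise ValueError("ground_distance missing population pairs")
    else:
        dist = np.asarray(ground_distance, dtype=float)
        if dist.shape != (k, k):
            raise ValueError("ground_distance has wrong shape")

    # LP over the k*k transport plan: row sums = a, column sums = b.
    c = dist.ravel()
    a_eq = np.zeros((2 * k, k * k))
    for i in range(k):
        a_eq[i, i * k : (i + 1) * k] = 1.0  # row marginal
        a_eq[k + i, i::k] = 1.0  # column marginal
    b_eq = np.concatenate([a.to_numpy(), b.to_numpy()])
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - highs is robust on feasible OT
        raise RuntimeError(f"EMD linear program failed: {res.message}")
    return float(res.fun)


def qc_cluster_samples(
    distance_matrix: pd.DataFrame,
    control_ids,
    linkage: str = "average",
    n_clusters: int = 2,
) -> QcClustering:
    """Hierarchically cluster samples by composition distance.

    The batch-effect QC passes when all control samples fall in a single flat
    cluster at the chosen cut (``n_clusters`` groups, default 2), i.e. the
    replicate controls behave as technical replicates and are not scattered
    among patient samples.
    """
    dm = distance_matrix
    arr = dm.to_numpy(float) if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    ids = (
        list(dm.index)
        if isinstance(dm, pd.DataFrame)
        else [str(i) for i in range(arr.shape[0])]
    )
    np.fill_diagonal(arr, 0.0)
    z = sch.linkage(squareform(arr, checks=False), method=linkage)
    flat = sch.fcluster(z, t=n_clusters, criterion="maxclust")
    labels = pd.Series(flat, index=ids, name="cluster")
    control_ids = [c for c in control_ids if c in labels.index]
    co_cluster = len(set(labels.loc[control_ids])) <= 1 if control_ids else True
    return QcClustering(z, labels, bool(co_cluster))


def mem_score(
    pop_values,
    ref_values,
    epsilon: float = 1e-6,
) -> float:
    """Marker enrichment score of a population against a reference.

    score = sign(dMed) * (|dMed| + IQR_ref / IQR_pop - 1), with
    dMed = median(pop) - median(ref) and both IQRs floored at ``epsilon``.
    Positive scores mean the marker is specifically enriched in the
    population (brighter and/or tighter than the reference); a population
    identical to its reference scores 0.
    """
    pop = np.asarray(pop_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if pop.size == 0 or ref.size == 0:
        raise ValueError("both value sets must be nonempty")
    d_med = np.median(pop) - np.median(ref)
    q75p, q25p = np.percentile(pop, [75, 25])
    q75r, q25r = np.percentile(ref, [75, 25])
    iqr_pop = max(q75p - q25p, epsilon)
    iqr_ref = max(q75r - q25r, epsilon)
    return float(np.sign(d_med) * (abs(d_med) + iqr_ref / iqr_pop - 1.0))
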