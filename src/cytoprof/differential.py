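"""Per-unit differential statistics for marker intensities and fractions.

A "unit" is a SPADE node or a gated population. For each (unit, marker) the
mean marker intensity (MMI — arithmetic mean of arcsinh intensities over the
unit's cells in a sample) is compared between groups with a Welch two-sample
t-test, and multiplicity over the many dependent (unit, marker) hypotheses
is corrected with a single-step maxT bootstrap. Fold change for paired
designs is the within-patient MMI difference between timepoints, averaged
per group. Positivity fractions, quadrant fractions and subset ratios
support the threshold-based readouts (e.g. MSI > 0.25 for CD137+).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_from

__all__ = [
    "mean_marker_intensity",
    "build_mmi_table",
    "welch_t_test",
    "welch_t_vectorized",
    "paired_fold_change",
    "bootstrap_adjust_pvalues",
    "positivity_fraction",
    "subset_ratio",
    "quadrant_fractions",
    "run_group_comparison",
]


def mean_marker_intensity(events_in_unit) -> float:
    """Arithmetic mean intensity over the cells of one unit in one sample.

    Undefined (raises) for an empty unit — an empty node contributes no MMI
    and is excluded from comparisons, never imputed as zero.
    """
    v = np.asarray(events_in_unit, dtype=float)
    if v.size == 0:
        raise ValueError("MMI undefined for an empty unit")
    return float(v.mean())


def build_mmi_table(
    samples: dict[str, np.ndarray],
    channels: list[str],
    unit_labels: dict[str, np.ndarray],
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy (sample_id, unit, marker) -> MMI table.

    ``samples`` maps sample_id to its cells x channels matrix on the arcsinh
    scale, ``unit_labels`` maps sample_id to a per-cell unit label (node id
    or population name). Units with zero cells in a sample simply have no
    row for that sample.
    """
    markers = markers if markers is not None else channels
    cols = [channels.index(m) for m in markers]
    records = []
    for sid, values in samples.items():
        labels = np.asarray(unit_labels[sid])
        values = np.asarray(values, dtype=float)
        for unit in pd.unique(labels):
            mask = labels == unit
            n = int(mask.sum())
            means = values[np.ix_(mask, cols)].mean(axis=0)
            for m, mu in zip(markers, means):
                records.append(
                    {"sample_id": sid, "unit": unit, "marker": m,
                     "mmi": float(mu), "n_cells": n}
                )
    return pd.DataFrame.from_records(records)


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Returns (t, Satterthwaite df, p). Degenerate conventions: both groups
    zero-variance with equal means -> (0, df, 1); zero-variance with unequal
    means -> p = 0 (the separation is infinitely many standard errors).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = _welch_df(va, vb, a.size, b.size)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(df), float(p)


def _welch_df(va, vb, na, nb):
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    return float(num / den) if den > 0 else float(na + nb - 2)


def welch_t_vectorized(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t statistics for H hypotheses at once.

    ``a`` and ``b`` are H x n_a and H x n_b matrices (rows = hypotheses).
    Zero-variance rows yield t = 0 when means agree, +/-inf otherwise.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    t[np.isnan(t)] = 0.0
    return t


def paired_fold_change(
    mmi: pd.DataFrame,
    metadata: pd.DataFrame,
    value_col: str = "mmi",
) -> pd.DataFrame:
    """Within-patient fold changes (on-treatment minus baseline) per unit/marker.

    On the arcsinh scale an additive difference of means is the natural
    "fold change" (a shift of the transformed intensity). Patients missing
    either timepoint for a (unit, marker) are excluded. Returns one row per
    (patient, unit, marker) with the difference, ready for group averaging.
    """
    meta = metadata.set_index("sample_id")
    df = mmi.copy()
    df["patient_id"] = df["sample_id"].map(meta["patient_id"])
    df["timepoint"] = df["sample_id"].map(meta["timepoint"])
    wide = df.pivot_table(
        index=["patient_id", "unit", "marker"],
        columns="timepoint",
        values=value_col,
        aggfunc="mean",
    )
    if "baseline" not in wide.columns or "on_treatment" not in wide.columns:
        raise ValueError("need both baseline and on_treatment samples")
    wide = wide.dropna(subset=["baseline", "on_treatment"])
    out = wide.reset_index()
    out["fold_change"] = out["on_treatment"] - out["baseline"]
    return out[["patient_id", "unit", "marker", "baseline", "on_treatment",
                "fold_change"]]


def bootstrap_adjust_pvalues(
    group_a: np.ndarray,
    group_b: np.ndarray,
    B: int = 1000,
    rng=0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-step maxT bootstrap adjustment over H dependent hypotheses.

    ``group_a``/``group_b`` are H x n matrices of per-sample values (one row
    per hypothesis; columns are samples, shared across hypotheses so the
    dependence structure is preserved). The null is enforced by centering
    each group at its own mean per hypothesis; each bootstrap iteration
    resamples sample indices with replacement within groups, recomputes all
    H Welch statistics, and records max_j |t*_j|. Then

        adj_p_i = (1 + #{b : max_j |t*_bj| >= |t_i|}) / (B + 1),

    followed by monotonicity enforcement (larger |t| never gets a larger
    adjusted p). Returns (t_obs, raw_p, adj_p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("group matrices must be H x n with matching H")
    h = a.shape[0]
    if h == 0:
        return np.array([]), np.array([]), np.array([])
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = rng_from(rng)
    na, nb = a.shape[1], b.shape[1]

    t_obs = welch_t_vectorized(a, b)
    df = np.array(
        [_welch_df(a[i].var(ddof=1), b[i].var(ddof=1), na, nb) for i in range(h)]
    )
    finite = np.isfinite(t_obs)
    raw_p = np.empty(h)
    raw_p[finite] = 2 * stats.t.sf(np.abs(t_obs[finite]), df[finite])
    raw_p[~finite] = 0.0

    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    max_t = np.empty(B)
    for it in range(B):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        t_star = welch_t_vectorized(ac[:, ia], bc[:, ib])
        max_t[it] = np.abs(t_star).max()

    abs_t = np.abs(t_obs)
    adj = (1 + (max_t[None, :] >= abs_t[:, None]).sum(axis=1)) / (B + 1)
    # enforce monotonicity: sort by decreasing |t|, take running max
    order = np.argsort(-abs_t, kind="stable")
    running = np.maximum.accumulate(adj[order])
    adj_mono = np.empty(h)
    adj_mono[order] = running
    return t_obs, raw_p, np.minimum(adj_mono, 1.0)


def positivity_fraction(events, threshold: float) -> float:
    """Fraction of cells with intensity strictly above ``threshold``."""
    v = np.asarray(events, dtype=float)
    if v.size == 0:
        raise ValueError("positivity fraction undefined for empty input")
    return float((v > threshold).mean())


def subset_ratio(count_a: float, count_b: float) -> float:
    """Ratio of two subset sizes (e.g. CD56dim / CD56bright); NaN when the
    denominator is zero (excluded downstream)."""
    if count_b == 0:
        return float("nan")
    return float(count_a) / float(count_b)


def quadrant_fractions(
    events_xy: np.ndarray, thr_x: float, thr_y: float
) -> dict[str, float]:
    """Two-marker quadrant fractions with strict thresholds.

    Returns fractions for keys "--", "+-", "-+", "++" (x sign first); the
    four fractions sum to 1.
    """
    xy = np.asarray(events_xy, dtype=float)
    if xy.size == 0:
        raise ValueError("quadrant fractions undefined for empty input")
    x_pos = xy[:, 0] > thr_x
    y_pos = xy[:, 1] > thr_y
    n = xy.shape[0]
    return {
        "--": float((~x_pos & ~y_pos).sum() / n),
        "+-": float((x_pos & ~y_pos).sum() / n),
        "-+": float((~x_pos & y_pos).sum() / n),
        "++": float((x_pos & y_pos).sum() / n),
    }


@dataclass
class GroupComparison:
    """Input description for :func:`run_group_comparison`."""

    group_a: list[str]  # sample ids
    group_b: list[str]
    label_a: str = "a"
    label_b: str = "b"


def run_group_comparison(
    mmi: pd.DataFrame,
    comparison: GroupComparison,
    B: int = 1000,
    rng=0,
    exclude_patients: set | None = None,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Welch + maxT differential analysis of MMI across two sample groups.

    Each (unit, marker) present with an MMI in *every* sample of both groups
    becomes one hypothesis; units empty for any sample in the comparison are
    dropped (the tabular analogue of graying out nodes that are empty for
    one patient sample). ``exclude_patients`` removes all samples of the
    listed patients before testing — the hook for re-running an analysis
    without outlier patients.

    Returns a deterministic table: unit, marker, n_a, n_b, mean_a, mean_b,
    fold_change (mean_a - mean_b), t, raw_p, adj_p.
    """
    ga, gb = list(comparison.group_a), list(comparison.group_b)
    if exclude_patients:
        if metadata is None:
            raise ValueError("exclude_patients requires metadata")
        pat = metadata.set_index("sample_id")["patient_id"]
        ga = [s for s in ga if pat.get(s) not in exclude_patients]
        gb = [s for s in gb if pat.get(s) not in exclude_patients]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 samples")

    wide = mmi.pivot_table(
        index=["unit", "marker"], columns="sample_id", values="mmi"
    )
    missing = [s for s in ga + gb if s not in wide.columns]
    if missing:
        raise ValueError(f"samples without MMI rows: {missing}")
    complete = wide[ga + gb].dropna()
    complete = complete.sort_index()
    if complete.empty:
        return pd.DataFrame(
            columns=["unit", "marker", "n_a", "n_b", "mean_a", "mean_b",
                     "fold_change", "t", "raw_p", "adj_p"]
        )
    mat_a = complete[ga].to_numpy()
    mat_b = complete[gb].to_numpy()
    t_obs, raw_p, adj_p = bootstrap_adjust_pvalues(mat_a, mat_b, B=B, rng=rng)
    out = complete.index.to_frame(index=False)
    out["n_a"] = len(ga)
    out["n_b"] = len(gb)
    out["mean_a"] = mat_a.mean(axis=1)
    out["mean_b"] = mat_b.mean(axis=1)
    out["fold_change"] = out["mean_a"] - out["mean_b"]
    out["t"] = t_obs
    out["raw_p"] = raw_p
    out["adj_p"] = adj_p
    return out.sort_values(["unit", "marker"], key=lambda s: s.astype(str)).reset_index(
        drop=True
    )
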