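"""TCR repertoire metrics and their treatment / survival analyses.

A repertoire is a clone-identifier -> template-count table from TCRbeta
sequencing. Clonality is 1 minus the Pielou evenness of the clone-frequency
distribution (1 - H / ln R with Shannon entropy H in nats and richness R);
0 means a perfectly even repertoire, 1 a monoclonal one (the R = 1 limit is
defined as 1). Richness is the number of distinct clones observed.

Paired before/after comparisons use the Wilcoxon signed-rank test; the link
between clonality gain and CD8+ T-cell expansion uses Spearman rank
correlation; and a baseline-richness split is assessed with Kaplan-Meier
curves and a two-group log-rank test, both computed from first principles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Repertoire",
    "clonality",
    "richness",
    "paired_metric_test",
    "clonality_cd8_correlation",
    "kaplan_meier",
    "logrank_test",
    "richness_survival_split",
]


@dataclass
class Repertoire:
    """Clone counts for one sample; counts are template (read) counts >= 1."""

    sample_id: str
    counts: pd.Series  # index clone_id, values int >= 1

    def __post_init__(self):
        self.counts = pd.Series(self.counts).astype(int)
        self.counts = self.counts[self.counts > 0]

    @property
    def total_templates(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "Repertoire":
        df = pd.read_csv(path, sep="\t")
        sid = sample_id if sample_id is not None else str(path)
        return cls(sid, pd.Series(df["count"].values, index=df["clone_id"]))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"clone_id": self.counts.index, "count": self.counts.values}
        ).to_csv(path, sep="\t", index=False)


def _freqs(r) -> np.ndarray:
    counts = r.counts.to_numpy(float) if isinstance(r, Repertoire) else np.asarray(
        list(r.values()) if isinstance(r, dict) else r, dtype=float
    )
    counts = counts[counts > 0]
    if counts.size == 0:
        return counts
    return counts / counts.sum()


def clonality(r) -> float:
    """1 - H / ln(R): normalized departure from an even clone distribution."""
    p = _freqs(r)
    if p.size == 0:
        raise ValueError("clonality undefined for an empty repertoire")
    if p.size == 1:
        return 1.0  # monoclonal limit
    h = float(-(p * np.log(p)).sum())
    return 1.0 - h / np.log(p.size)


def richness(r) -> int:
    """Number of distinct clones with at least one template."""
    if isinstance(r, Repertoire):
        return int((r.counts > 0).sum())
    return int(_freqs(r).size)


def paired_metric_test(baseline, on_treatment) -> tuple[float, float, float]:
    """Paired before/after comparison of a repertoire metric.

    Input vectors are aligned per patient. Returns (median_before,
    median_after, p) with p from the Wilcoxon signed-rank test on the paired
    differences; when all differences are zero p = 1 by convention.
    """
    b = np.asarray(baseline, dtype=float)
    a = np.asarray(on_treatment, dtype=float)
    if b.shape != a.shape:
        raise ValueError("baseline and on-treatment vectors must align")
    if b.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    if np.all(diffs == 0):
        return float(np.median(b)), float(np.median(a)), 1.0
    p = float(stats.wilcoxon(a, b).pvalue)
    return float(np.median(b)), float(np.median(a)), p


def clonality_cd8_correlation(delta_clonality, delta_cd8) -> tuple[float, float]:
    """Spearman correlation between per-patient clonality change and CD8+
    T-cell fraction change; returns (rho, two-sided p)."""
    dc = np.asarray(delta_clonality, dtype=float)
    d8 = np.asarray(delta_cd8, dtype=float)
    if dc.size != d8.size or dc.size < 5:
        raise ValueError("need >= 5 patients with both measures")
    if np.all(dc == dc[0]) or np.all(d8 == d8[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(dc, d8)
    return float(rho), float(p)


def kaplan_meier(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival estimate.

    Returns a table with one row per distinct event time: time, n_at_risk,
    n_events and the survival probability S(t) (right-continuous step
    function; S = 1 before the first event).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("negative survival times")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n = t.size
    for ut in np.unique(t[e == 1]):
        at_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": ut, "n_at_risk": at_risk, "n_events": d,
                     "survival": s})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                       "survival"])


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test from the 2x2 table at each failure time.

    At each distinct event time the observed group-1 events are compared
    with the hypergeometric expectation given the risk sets; the summed
    (O - E) over its variance gives a chi-square statistic on 1 df.
    Returns (chi2, p).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank test needs exactly 2 groups")
    in1 = g == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == ut) & (e == 1)).sum())
        d1 = int(((t == ut) & (e == 1) & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def richness_survival_split(
    records: pd.DataFrame, split: str = "median"
) -> dict:
    """Stratify survival by baseline repertoire richness.

    ``records`` needs columns patient_id, time, event, baseline_richness.
    ``split="median"`` contrasts patients above vs at-or-below the median
    richness; ``"quartile"`` contrasts the top vs bottom quartile. Returns
    the per-group Kaplan-Meier tables, group sizes and the log-rank p.
    """
    df = records.copy()
    if int(df["event"].sum()) < 5:
        raise ValueError("need at least 5 events")
    r = df["baseline_richness"].astype(float)
    if split == "median":
        cut = r.median()
        df["group"] = np.where(r > cut, "high", "low")
    elif split == "quartile":
        lo, hi = r.quantile([0.25, 0.75])
        df = df[(r <= lo) | (r >= hi)].copy()
        df["group"] = np.where(df["baseline_richness"] >= hi, "high", "low")
    else:
        raise ValueError("split must be 'median' or 'quartile'")
    sizes = df["group"].value_counts()
    if sizes.size < 2 or (sizes == 0).any():
        raise ValueError("a richness group is empty")
    chi2, p = logrank_test(df["time"], df["event"], df["group"])
    curves = {
        name: kaplan_meier(sub["time"], sub["event"])
        for name, sub in df.groupby("group")
    }
    return {
        "curves": curves,
        "group_sizes": sizes.to_dict(),
        "logrank_chi2": chi2,
        "logrank_p": p,
    }
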