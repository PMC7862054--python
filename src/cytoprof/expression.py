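"""Immune-gene differential expression with cell-abundance correction.

Bulk immune-panel counts confound two signals: a gene can move because its
cell type expanded or shrank (composition), or because transcription per
cell changed. The paired model here tests the on-treatment vs baseline
change per arm via explicit within-patient differencing; the
abundance-corrected variant adds within-patient changes of cytometry-derived
cell-type fractions (logit scale) as covariates, so the treatment term is
tested conditional on composition shifts. A gene that merely tracks, say,
the NK-cell fraction loses significance under correction, while a genuine
transcriptional effect survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_expression",
    "paired_differential_expression",
    "abundance_corrected_de",
    "analysis_group_sizes",
]

LOGIT_EPS = 1e-4


def normalize_expression(
    counts: pd.DataFrame, reference_genes: list[str],
    target_level: float = 500.0,
) -> pd.DataFrame:
    """Housekeeping normalization followed by log2(x + 1).

    Each sample's counts are scaled so that the geometric mean of its
    reference (housekeeping) genes equals the fixed ``target_level``;
    because the factor depends only on the sample's own counts, doubling
    every count of one sample leaves its normalized values unchanged.
    ``counts`` is genes x samples.
    """
    missing = [g for g in reference_genes if g not in counts.index]
    if missing or not reference_genes:
        raise ValueError(f"reference genes absent from matrix: {missing}")
    ref = counts.loc[reference_genes].astype(float)
    geo = np.exp(np.log(ref.replace(0, np.nan)).mean(axis=0))
    if geo.isna().any() or (geo <= 0).any():
        bad = geo.index[geo.isna() | (geo <= 0)].tolist()
        raise ValueError(f"zero geometric mean of reference genes in {bad}")
    scale = target_level / geo
    return np.log2(counts.astype(float).mul(scale, axis=1) + 1.0)


@dataclass
class PairedDesign:
    """Within-patient difference matrix and its provenance."""

    diffs: pd.DataFrame  # genes x patients, on_treatment - baseline
    patients: list


def _paired_diffs(norm_expr: pd.DataFrame, meta: pd.DataFrame) -> PairedDesign:
    m = meta.set_index("sample_id")
    base = m[m["timepoint"] == "baseline"]
    post = m[m["timepoint"] == "on_treatment"]
    paired = sorted(set(base["patient_id"]) & set(post["patient_id"]))
    cols_b = {p: base.index[base["patient_id"] == p][0] for p in paired}
    cols_t = {p: post.index[post["patient_id"] == p][0] for p in paired}
    avail = [p for p in paired
             if cols_b[p] in norm_expr.columns and cols_t[p] in norm_expr.columns]
    diffs = pd.DataFrame(
        {p: norm_expr[cols_t[p]] - norm_expr[cols_b[p]] for p in avail}
    )
    return PairedDesign(diffs, avail)


def _ols_t_tests(y: np.ndarray, x: np.ndarray):
    """OLS of each row of y (G x n) on design x (n x p); t-test of column 0.

    The design is shared across genes, so a single pseudo-inverse serves all
    of them. Returns (beta0, se0, t, p, df_resid).
    """
    n, p = x.shape
    xtx_inv = np.linalg.pinv(x.T @ x)
    h = xtx_inv @ x.T  # p x n
    beta = y @ h.T  # G x p
    resid = y - beta @ x.T
    dof = n - np.linalg.matrix_rank(x)
    if dof <= 0:
        raise ValueError("not enough pairs for the design")
    sigma2 = (resid**2).sum(axis=1) / dof
    se0 = np.sqrt(sigma2 * xtx_inv[0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 0] / se0
    p_val = np.where(
        se0 > 0, 2 * stats.t.sf(np.abs(np.where(se0 > 0, t, 0.0)), dof), 1.0
    )
    t = np.where(se0 > 0, t, 0.0)
    return beta[:, 0], se0, t, p_val, dof


def _results_frame(genes, effect, se, t, p, flavor) -> pd.DataFrame:
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": genes,
            "effect": effect,
            "se": se,
            "t": t,
            "raw_p": p,
            "adj_p": adj,
            "model": flavor,
        }
    )


def paired_differential_expression(
    norm_expr: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene paired treatment effect within one arm.

    For each gene the within-patient difference (on-treatment minus
    baseline, log2 scale) is regressed on an intercept; the intercept t-test
    asks whether treatment shifted expression. Benjamini-Hochberg adjusts
    across genes. Pass a metadata subset to analyze one arm at a time.
    Zero-variance genes get p = 1.
    """
    design = _paired_diffs(norm_expr, metadata)
    if len(design.patients) < 3:
        raise ValueError("need at least 3 paired patients")
    y = design.diffs.to_numpy(float)
    x = np.ones((y.shape[1], 1))
    eff, se, t, p, _ = _ols_t_tests(y, x)
    return _results_frame(design.diffs.index, eff, se, t, p, "uncorrected")


def abundance_corrected_de(
    norm_expr: pd.DataFrame,
    metadata: pd.DataFrame,
    abundances: pd.DataFrame,
) -> pd.DataFrame:
    """Paired model with cell-abundance-change covariates.

    ``abundances`` is samples x populations of %total fractions from the
    cytometry arm. Fractions are logit-transformed (epsilon 1e-4), and the
    within-patient change of each population enters the design next to the
    intercept; the reported test is the treatment (intercept) term
    conditional on those composition changes. Covariate columns that are
    collinear (or constant) are dropped with a warning.
    """
    design = _paired_diffs(norm_expr, metadata)
    if len(design.patients) < 3:
        raise ValueError("need at least 3 paired patients")
    m = metadata.set_index("sample_id")
    base = m[m["timepoint"] == "baseline"]
    post = m[m["timepoint"] == "on_treatment"]

    logit = lambda f: np.log((f + LOGIT_EPS) / (1 - f + LOGIT_EPS))  # noqa: E731
    cov_rows = []
    for p_id in design.patients:
        sb = base.index[base["patient_id"] == p_id][0]
        st = post.index[post["patient_id"] == p_id][0]
        if sb not in abundances.index or st not in abundances.index:
            raise ValueError(f"abundances missing for patient {p_id}")
        cov_rows.append(
            logit(abundances.loc[st].astype(float))
            - logit(abundances.loc[sb].astype(float))
        )
    cov = pd.DataFrame(cov_rows, index=design.patients)

    keep = []
    for col in cov.columns:
        candidate = cov[keep + [col]].to_numpy(float)
        full = np.column_stack([np.ones(len(cov)), candidate])
        if np.linalg.matrix_rank(full) == full.shape[1]:
            keep.append(col)
        else:
            warnings.warn(f"dropping collinear abundance covariate {col!r}",
                          stacklevel=2)
    x = np.column_stack([np.ones(len(cov)), cov[keep].to_numpy(float)])
    y = design.diffs.to_numpy(float)
    eff, se, t, p, _ = _ols_t_tests(y, x)
    return _results_frame(design.diffs.index, eff, se, t, p,
                          "abundance_corrected")


def analysis_group_sizes(metadata: pd.DataFrame) -> pd.DataFrame:
    """Sample accounting per (arm, timepoint) analysis group.

    Returns the per-group sample counts, the number of paired patients per
    arm (patients contributing both timepoints), and a "total" row whose
    count is the expression matrix's full sample tally.
    """
    df = metadata.copy()
    rows = []
    for (arm, tp), sub in df.groupby(["arm", "timepoint"], sort=True):
        rows.append({"arm": arm, "timepoint": tp, "n_samples": len(sub)})
    for arm, sub in df.groupby("arm", sort=True):
        b = set(sub.loc[sub["timepoint"] == "baseline", "patient_id"])
        t = set(sub.loc[sub["timepoint"] == "on_treatment", "patient_id"])
        rows.append({"arm": arm, "timepoint": "paired", "n_samples": len(b & t)})
    rows.append({"arm": "total", "timepoint": "all", "n_samples": len(df)})
    return pd.DataFrame(rows)
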