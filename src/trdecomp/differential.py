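"""Contrast testing, BH adjustment, population-vs-activation classification.

Condition contrasts are Wald tests on the natural-log scale: the difference
``beta_A - beta_B`` of independent fits is Gaussian with variance
``V_A + V_B``; TR contrasts use ``beta1``/``var_beta1``, TSS-level contrasts
``beta0``/``var_beta0``.  Fold changes are reported on the log2 scale and
significance is the conjunction |log2FC| > lfc_thresh and BH FDR <
fdr_thresh (defaults 1 and 0.1, i.e. twofold at FDR 10%).

The BH universe is the user-selected gene set: genes untestable in either
contrasted condition (zero counts or missing fits) are removed before the
step-up procedure rather than padded with p = 1, so they do not inflate m.

Classification reads the TR/TSS significance pair as the two axes of the
tissue decomposition: a TR-only change means transcriptional activation or
repression within a resident population (``activation_up``/``_down``); a
TSS-only change means the locus-engaged cell population grew or shrank,
e.g. immune-cell migration (``population_up``/``_down``); ``both`` and
``neither`` cover the remaining cells of the pair.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "contrast",
    "contrast_table",
    "bh_adjust",
    "classify_gene",
    "classify_table",
    "assign_tr_clusters",
    "log2fc_matrix",
]

LN2 = float(np.log(2.0))
_MEASURE_COLS = {"TR": ("beta1", "var_beta1"), "TSS": ("beta0", "var_beta0")}
LABELS = (
    "activation_up", "activation_down",
    "population_up", "population_down",
    "both", "neither",
)


def _coef(fit, measure: str) -> tuple[float, float, str]:
    b, v = _MEASURE_COLS[measure]
    get = fit.get if hasattr(fit, "get") else lambda k: getattr(fit, k)
    return float(get(b)), float(get(v)), str(get("status"))


def contrast(fit_a, fit_b, measure: str = "TR") -> dict:
    """Wald contrast of one gene between conditions A and B.

    Accepts :class:`~trdecomp.model.TRFit` objects or rows of the
    :func:`~trdecomp.model.fit_all` table.  Non-ok fits yield an untestable
    result (p and fdr NaN) that is excluded from BH adjustment.
    """
    if measure not in _MEASURE_COLS:
        raise ValueError(f"unknown measure {measure!r}")
    ba, va, st_a = _coef(fit_a, measure)
    bb, vb, st_b = _coef(fit_b, measure)
    ok = st_a == "ok" and st_b == "ok"
    if measure == "TSS":  # beta0 is defined for zero_tes fits too
        ok = st_a in ("ok", "zero_tes") and st_b in ("ok", "zero_tes")
    if not ok:
        return {
            "measure": measure, "delta_log2": np.nan, "se_log2": np.nan,
            "z": np.nan, "p": np.nan, "testable": False,
        }
    delta = ba - bb
    se = float(np.sqrt(va + vb))
    z = delta / se if se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {
        "measure": measure,
        "delta_log2": delta / LN2,
        "se_log2": se / LN2,
        "z": float(z),
        "p": max(p, np.finfo(float).tiny),
        "testable": True,
    }


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_table(
    fits: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    measure: str = "TR",
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene contrasts of ``cond_a`` vs ``cond_b`` with BH-adjusted FDR.

    ``genes`` restricts the BH universe to a selected gene set; by default
    every gene testable in both conditions is adjusted.  Untestable genes are
    kept in the output, flagged, with NaN statistics.
    """
    if measure not in _MEASURE_COLS:
        raise ValueError(f"unknown measure {measure!r}")
    b, v = _MEASURE_COLS[measure]
    gene_ids = (
        pd.Index(genes) if genes is not None else pd.Index(fits["gene_id"].drop_duplicates())
    )
    sub = fits[fits["condition"].isin([cond_a, cond_b])]
    beta = sub.pivot(index="gene_id", columns="condition", values=b).reindex(gene_ids)
    var = sub.pivot(index="gene_id", columns="condition", values=v).reindex(gene_ids)
    stat = sub.pivot(index="gene_id", columns="condition", values="status").reindex(gene_ids)
    for c in (cond_a, cond_b):
        for frame in (beta, var, stat):
            if c not in frame.columns:
                frame[c] = np.nan
    ok_status = ("ok", "zero_tes") if measure == "TSS" else ("ok",)
    testable = (
        stat[cond_a].isin(ok_status) & stat[cond_b].isin(ok_status)
    ).to_numpy()
    delta = beta[cond_a].to_numpy() - beta[cond_b].to_numpy()
    se = np.sqrt(var[cond_a].to_numpy() + var[cond_b].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, delta / se, 0.0)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "measure": measure,
            "condition_a": cond_a,
            "condition_b": cond_b,
            "delta_log2": np.where(testable, delta / LN2, np.nan),
            "se_log2": np.where(testable, se / LN2, np.nan),
            "z": np.where(testable, z, np.nan),
            "p": np.where(testable, p, np.nan),
            "testable": testable,
        }
    )
    out["fdr"] = np.nan
    testable = out["testable"].to_numpy()
    if testable.any():
        out.loc[testable, "fdr"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    n_excl = int((~testable).sum())
    if n_excl:
        logger.info("%d untestable gene(s) excluded from BH (m=%d)", n_excl, testable.sum())
    cols = [
        "gene_id", "measure", "condition_a", "condition_b",
        "delta_log2", "se_log2", "z", "p", "fdr", "testable",
    ]
    return out[cols]


def _significant(delta_log2: float, fdr: float, lfc: float, fdr_thresh: float) -> bool:
    return (
        np.isfinite(delta_log2)
        and np.isfinite(fdr)
        and abs(delta_log2) > lfc
        and fdr < fdr_thresh
    )


def classify_gene(
    tr_res, tss_res, lfc_thresh: float = 1.0, fdr_thresh: float = 0.1
) -> str:
    """Label one gene from its TR and TSS contrast results."""
    get = lambda r, k: (r.get(k) if hasattr(r, "get") else getattr(r, k))
    tr_sig = _significant(
        float(get(tr_res, "delta_log2")), float(get(tr_res, "fdr")), lfc_thresh, fdr_thresh
    )
    tss_sig = _significant(
        float(get(tss_res, "delta_log2")), float(get(tss_res, "fdr")), lfc_thresh, fdr_thresh
    )
    if tr_sig and tss_sig:
        return "both"
    if tr_sig:
        return "activation_up" if float(get(tr_res, "delta_log2")) > 0 else "activation_down"
    if tss_sig:
        return "population_up" if float(get(tss_res, "delta_log2")) > 0 else "population_down"
    return "neither"


def classify_table(
    tr_results: pd.DataFrame,
    tss_results: pd.DataFrame,
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.1,
) -> pd.DataFrame:
    """Join TR and TSS contrast tables and label every gene."""
    merged = tr_results.merge(
        tss_results, on="gene_id", suffixes=("_tr", "_tss"), how="inner"
    )
    tr_sig = (
        (merged["delta_log2_tr"].abs() > lfc_thresh)
        & (merged["fdr_tr"] < fdr_thresh)
    ).fillna(False)
    tss_sig = (
        (merged["delta_log2_tss"].abs() > lfc_thresh)
        & (merged["fdr_tss"] < fdr_thresh)
    ).fillna(False)
    label = np.select(
        [
            tr_sig & tss_sig,
            tr_sig & (merged["delta_log2_tr"] > 0),
            tr_sig,
            tss_sig & (merged["delta_log2_tss"] > 0),
            tss_sig,
        ],
        ["both", "activation_up", "activation_down", "population_up", "population_down"],
        default="neither",
    )
    out = merged[
        ["gene_id", "delta_log2_tr", "fdr_tr", "delta_log2_tss", "fdr_tss"]
    ].copy()
    out["label"] = label
    out["untestable"] = ~(
        merged["testable_tr"].astype(bool) & merged["testable_tss"].astype(bool)
    )
    return out


def assign_tr_clusters(tr_by_timepoint: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene to cluster C1..Ck by its peak (maximal-TR) timepoint.

    ``tr_by_timepoint`` is genes x ordered timepoints (columns in design
    order).  Ties go to the earliest timepoint; genes with any missing TR are
    excluded and flagged.
    """
    if tr_by_timepoint.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    vals = tr_by_timepoint.to_numpy(dtype=float)
    complete = np.isfinite(vals).all(axis=1)
    if not complete.any():
        raise ValueError("all genes have missing TR values")
    peak = np.full(len(vals), -1)
    peak[complete] = np.argmax(vals[complete], axis=1)  # argmax: first of ties
    out = pd.DataFrame(
        {
            "gene_id": tr_by_timepoint.index,
            "cluster": [f"C{i + 1}" if i >= 0 else "" for i in peak],
            "peak_timepoint": [
                tr_by_timepoint.columns[i] if i >= 0 else "" for i in peak
            ],
            "excluded": ~complete,
        }
    ).reset_index(drop=True)
    n_excl = int((~complete).sum())
    if n_excl:
        logger.warning("%d gene(s) with missing TR excluded from clustering", n_excl)
    return out


def log2fc_matrix(
    fits: pd.DataFrame, reference_condition: str, measures: Sequence[str] = ("TR", "TSS")
) -> pd.DataFrame:
    """Heatmap-ready genes x (timepoint, measure) matrix of log2FC vs reference."""
    frames = {}
    conds = [c for c in fits["condition"].drop_duplicates() if c != reference_condition]
    for measure in measures:
        b, _ = _MEASURE_COLS[measure]
        wide = fits.pivot(index="gene_id", columns="condition", values=b)
        for cond in conds:
            frames[(cond, measure)] = (wide[cond] - wide[reference_condition]) / LN2
    out = pd.DataFrame(frames)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "measure"])
    return out
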