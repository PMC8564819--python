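"""Interval-set statistics: peak concordance, tissue specificity, SE filter.

Overlap semantics follow bedtools: a "hit" for recall/precision and the odds
ratio is any >= 1 bp overlap at the peak level; the Jaccard index is taken at
the base-pair level (intersection bp / union bp).  Overlapping intervals
within a set are merged before any bp-level arithmetic, so within-set
redundancy never changes a metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

__all__ = [
    "merge_peaks",
    "read_peaks",
    "recall_precision",
    "jaccard_bp",
    "odds_ratio",
    "OddsResult",
    "select_super_enhancers",
    "peak_gene_overlap",
]

_COLMAP = {"chrom": "Chromosome", "start": "Start", "end": "End"}


def _as_pyranges(peaks: pd.DataFrame) -> pr.PyRanges:
    if len(peaks) == 0:
        return pr.PyRanges()
    df = peaks.rename(columns=_COLMAP)
    bad = df["Start"] >= df["End"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} invalid interval(s) with start >= end")
    return pr.PyRanges(df[["Chromosome", "Start", "End"]])


def merge_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/bookended intervals within a set (internal columns)."""
    if len(peaks) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    merged = _as_pyranges(peaks).merge().df
    return merged.rename(columns={v: k for k, v in _COLMAP.items()})


def read_peaks(path: str) -> pd.DataFrame:
    """BED peak file -> internal chrom/start/end frame (extra columns kept)."""
    df = pr.read_bed(path).df
    out = df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end", "Name": "name"}
    )
    out["chrom"] = out["chrom"].astype(str)
    return out


def _n_hits(query: pr.PyRanges, target: pr.PyRanges) -> int:
    """Number of query intervals with >= 1 bp overlap against target."""
    return len(query.overlap(target))


def recall_precision(
    query: pd.DataFrame, reference: pd.DataFrame, level: str = "peak"
) -> tuple[float, float]:
    """Peak-set concordance against a reference.

    recall = fraction of reference peaks overlapped by >= 1 query peak;
    precision = fraction of query peaks overlapping >= 1 reference peak.
    ``level='bp'`` computes both on merged base pairs instead of peak counts.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("recall/precision undefined for an empty peak set")
    q = _as_pyranges(merge_peaks(query))
    r = _as_pyranges(merge_peaks(reference))
    if level == "peak":
        return _n_hits(r, q) / len(r), _n_hits(q, r) / len(q)
    if level == "bp":
        inter = q.set_intersect(r).length
        return inter / r.length, inter / q.length
    raise ValueError(f"unknown level {level!r}")


def jaccard_bp(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-pair Jaccard index of two peak sets (bedtools-jaccard semantics)."""
    ga, gb = _as_pyranges(merge_peaks(a)), _as_pyranges(merge_peaks(b))
    union = ga.length + gb.length - (inter := ga.set_intersect(gb).length)
    if union == 0:
        raise ValueError("Jaccard undefined: both sets empty")
    return inter / union


@dataclass(frozen=True)
class OddsResult:
    """Tissue-specificity odds ratio of a query peak set.

    ``p`` is the proportion of query peaks hitting the target tissue's
    enhancer list, ``q`` the proportion hitting any other tissue's list;
    ``or_value = (p/(1-p)) / (q/(1-q))``.
    """

    p: float
    q: float
    or_value: float
    n_query: int
    n_target_hits: int
    n_other_hits: int
    degenerate: bool = False


def odds_ratio(
    query: pd.DataFrame,
    target_list: pd.DataFrame,
    other_lists: Sequence[pd.DataFrame],
    haldane: bool = False,
) -> OddsResult:
    """Specificity of ``query`` for the target tissue's enhancer list.

    With ``haldane`` on, 0.5 is added to each of the four implied counts
    (hits/misses against target and other) whenever any is zero; otherwise a
    degenerate proportion yields an infinite/zero OR flagged as such.
    """
    if len(query) == 0:
        raise ValueError("query peak set is empty")
    q_ranges = _as_pyranges(merge_peaks(query))
    n = len(q_ranges.df)
    target_hits = _n_hits(q_ranges, _as_pyranges(merge_peaks(target_list)))
    other = pd.concat(list(other_lists), ignore_index=True)
    other_hits = _n_hits(q_ranges, _as_pyranges(merge_peaks(other)))
    a, b = float(target_hits), float(n - target_hits)
    c, d = float(other_hits), float(n - other_hits)
    degenerate = 0.0 in (a, b, c, d)
    if degenerate and haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        degenerate = False
    p, qq = a / (a + b), c / (c + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        orv = float((a * d) / (b * c)) if b * c > 0 else math.inf
    if degenerate:
        logger.warning("degenerate odds ratio (p=%g, q=%g); consider haldane=True", p, qq)
    return OddsResult(p, qq, orv, n, target_hits, other_hits, degenerate)


def select_super_enhancers(
    tag_counts: pd.DataFrame,
    coords: pd.DataFrame | None = None,
    top_frac: float = 0.05,
    min_reps: int = 2,
    exclude: Sequence[pd.DataFrame] = (),
) -> pd.Series:
    """Reproducible top-ranked enhancer (SE) filter.

    ``tag_counts`` is candidates x replicates (index = candidate id).  A
    candidate is selected iff its tag count lies in the top ``top_frac`` of
    all candidates in at least ``min_reps`` replicates, and (when ``coords``
    maps candidate ids to chrom/start/end) it overlaps none of the
    ``exclude`` interval sets (other tissues' SEs).  The top cut keeps the
    ``n - ceil((1 - top_frac) * n)`` highest candidates, ties included; for
    small n this slice is empty and a warning is issued.  Output order is
    the index order of ``tag_counts``, invariant to input ordering.
    """
    if tag_counts.shape[1] < min_reps:
        raise ValueError("fewer replicates than min_reps")
    n = len(tag_counts)
    k = n - math.ceil((1.0 - top_frac) * n)
    if k <= 0:
        logger.warning("top %.0f%% of %d candidates is empty", top_frac * 100, n)
        return pd.Series(False, index=tag_counts.index, name="selected")
    in_top = pd.DataFrame(index=tag_counts.index)
    for col in tag_counts.columns:
        vals = tag_counts[col].to_numpy(dtype=float)
        thresh = np.sort(vals)[::-1][k - 1]
        in_top[col] = vals >= thresh  # ties kept
    selected = in_top.sum(axis=1) >= min_reps
    if selected.any() and len(exclude) and coords is not None:
        excl = _as_pyranges(merge_peaks(pd.concat(list(exclude), ignore_index=True)))
        cand = coords.loc[selected[selected].index]
        gpr = pr.PyRanges(
            cand.rename(columns=_COLMAP).assign(cand_id=cand.index.astype(str))[
                ["Chromosome", "Start", "End", "cand_id"]
            ]
        )
        hit_ids = set(gpr.overlap(excl).df.get("cand_id", pd.Series(dtype=str)))
        selected &= ~tag_counts.index.astype(str).isin(hit_ids)
    return selected.rename("selected")


def peak_gene_overlap(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 1000,
) -> tuple[pd.DataFrame, Mapping[str, float]]:
    """Categorize genes as Common / RNA_only / ChIL_only.

    ``genes`` needs ``gene_id``, ``chrom``, ``tss`` and a boolean
    ``expressed`` column (defined upstream, e.g. TPM > 0).  A gene has a peak
    iff any peak overlaps TSS +/- ``flank``.  Proportions are over the union
    of expressed and peak-hit genes.
    """
    if len(peaks) == 0 or len(genes) == 0:
        raise ValueError("empty peaks or gene table")
    tss_win = pd.DataFrame(
        {
            "Chromosome": genes["chrom"],
            "Start": np.maximum(genes["tss"] - flank, 0),
            "End": genes["tss"] + flank + 1,
            "gene_id": genes["gene_id"],
        }
    )
    hit_ids = set(
        pr.PyRanges(tss_win).overlap(_as_pyranges(merge_peaks(peaks))).df.get(
            "gene_id", pd.Series(dtype=str)
        )
    )
    has_peak = genes["gene_id"].isin(hit_ids)
    expressed = genes["expressed"].astype(bool)
    category = np.select(
        [expressed & has_peak, expressed, has_peak],
        ["Common", "RNA_only", "ChIL_only"],
        default="",
    )
    out = pd.DataFrame({"gene_id": genes["gene_id"], "category": category})
    out = out[out["category"] != ""].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no expressed or peak-hit genes")
    props = (out["category"].value_counts() / len(out)).to_dict()
    return out, {k: props.get(k, 0.0) for k in ("Common", "RNA_only", "ChIL_only")}
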