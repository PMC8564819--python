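"""Strand-aware window construction, read counting and library QC statistics.

Coordinates are 0-based half-open throughout: BED input is used natively and
GTF (1-based, closed) is converted on load.  The TSS of a transcript is its
``start`` on the + strand and ``end - 1`` on the - strand; the TES is the
opposite end.  Counting windows follow the convention of pausing-index
analyses of PolII data:

* TSS window: ``[tss - tss_half, tss + tss_half)`` — symmetric, so identical
  on both strands (default half-width 750 bp, i.e. -750..+750);
* TES window: 0 to +``tes_len`` bp downstream of the TES in the direction of
  transcription (default 1,500 bp) — ``[tes, tes + 1500)`` on +,
  ``[tes - 1499, tes + 1)`` on -;
* optional gene-body (GB) window: the region strictly between the two windows
  in the transcription direction, empty when they touch or overlap.

Reads are counted by their strand-aware 5' coordinate by default (the natural
unit for deduplicated single-end data; a long read can then never hit both
windows of a short gene twice), with a >=1 bp overlap mode as an option.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

__all__ = [
    "load_annotation",
    "build_windows",
    "five_prime_positions",
    "count_sites",
    "count_design",
    "select_representative_transcripts",
    "bin_counts",
    "bin_matrix",
    "correlation_matrix",
    "detect_genes",
    "cumulative_read_share",
    "read_bed_reads",
    "read_chrom_sizes",
]

GENE_COLUMNS = ["transcript_id", "gene_id", "chrom", "strand", "start", "end", "tss", "tes"]


def _finalize_genes(df: pd.DataFrame, source: str) -> pd.DataFrame:
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        i = int(np.flatnonzero(bad_strand.to_numpy())[0])
        raise ValueError(
            f"{source}: unknown strand {df['strand'].iloc[i]!r} at record {i + 1}"
        )
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{source}: start >= end at record {i + 1}")
    df = df.copy()
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df["tes"] = np.where(df["strand"] == "+", df["end"] - 1, df["start"])
    return df[GENE_COLUMNS].reset_index(drop=True)


def load_annotation(path: str, fmt: str | None = None) -> pd.DataFrame:
    """Load transcript models from GTF or BED(12) into 0-based half-open rows.

    ``fmt`` is ``"GTF"`` or ``"BED12"``; inferred from the extension when
    omitted.  Returns one row per transcript with derived ``tss``/``tes``.
    """
    if fmt is None:
        low = str(path).lower()
        fmt = "GTF" if low.endswith((".gtf", ".gff")) else "BED12"
    fmt = fmt.upper()
    with open(path) as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        logger.warning("empty annotation file %s", path)
        return pd.DataFrame(columns=GENE_COLUMNS)
    if fmt == "GTF":
        gr = pr.read_gtf(path)  # converts to 0-based half-open
        df = gr.df
        if df.empty:
            logger.warning("empty annotation file %s", path)
            return pd.DataFrame(columns=GENE_COLUMNS)
        if "Feature" in df.columns:
            df = df[df["Feature"] == "transcript"]
            if df.empty:  # exon-only GTFs: derive transcript spans
                df = gr.df[gr.df["Feature"] == "exon"]
                df = (
                    df.groupby("transcript_id", sort=False)
                    .agg(
                        gene_id=("gene_id", "first"),
                        Chromosome=("Chromosome", "first"),
                        Strand=("Strand", "first"),
                        Start=("Start", "min"),
                        End=("End", "max"),
                    )
                    .reset_index()
                )
        out = pd.DataFrame(
            {
                "transcript_id": df["transcript_id"].astype(str),
                "gene_id": df.get("gene_id", df["transcript_id"]).astype(str),
                "chrom": df["Chromosome"].astype(str),
                "strand": df["Strand"].astype(str),
                "start": df["Start"].astype(np.int64),
                "end": df["End"].astype(np.int64),
            }
        )
    elif fmt in ("BED", "BED6", "BED12"):
        try:
            df = pr.read_bed(path).df
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed BED ({exc})") from exc
        if df.empty:
            logger.warning("empty annotation file %s", path)
            return pd.DataFrame(columns=GENE_COLUMNS)
        if "Strand" not in df.columns:
            raise ValueError(f"{path}: BED annotation needs >= 6 columns (strand)")
        name = df["Name"].astype(str) if "Name" in df.columns else df.index.astype(str)
        out = pd.DataFrame(
            {
                "transcript_id": name,
                "gene_id": name,
                "chrom": df["Chromosome"].astype(str),
                "strand": df["Strand"].astype(str),
                "start": df["Start"].astype(np.int64),
                "end": df["End"].astype(np.int64),
            }
        )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return _finalize_genes(out, str(path))


def build_windows(
    genes: pd.DataFrame,
    tss_half: int = 750,
    tes_len: int = 1500,
    with_gb: bool = False,
) -> pd.DataFrame:
    """Build TSS/TES (and optional GB) windows, one row per transcript x site.

    Negative coordinates are clipped to 0 and flagged in the ``clipped``
    column.  GB rows are emitted only when non-empty.
    """
    if tss_half <= 0 or tes_len <= 0:
        raise ValueError("tss_half and tes_len must be > 0")
    g = genes.reset_index(drop=True)
    plus = (g["strand"] == "+").to_numpy()
    tss = g["tss"].to_numpy()
    tes = g["tes"].to_numpy()

    tss_start, tss_end = tss - tss_half, tss + tss_half
    tes_start = np.where(plus, tes, tes - tes_len + 1)
    tes_end = np.where(plus, tes + tes_len, tes + 1)
    # region strictly between the windows, in transcription direction
    gb_start = np.where(plus, tss_end, tes_end)
    gb_end = np.where(plus, tes_start, tss_start)

    frames = []
    for site, (s, e) in {
        "TSS": (tss_start, tss_end),
        "TES": (tes_start, tes_end),
        "GB": (gb_start, gb_end),
    }.items():
        if site == "GB" and not with_gb:
            continue
        keep = (e > s) if site == "GB" else np.ones_like(s, dtype=bool)
        clipped = s < 0
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": g["transcript_id"],
                    "gene_id": g["gene_id"],
                    "chrom": g["chrom"],
                    "strand": g["strand"],
                    "site": site,
                    "start": np.maximum(s, 0),
                    "end": np.maximum(e, 0),
                    "clipped": clipped,
                }
            )[keep]
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def five_prime_positions(reads: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware 5' coordinate of each read (chrom, pos)."""
    pos = np.where(
        reads["strand"].to_numpy() == "-",
        reads["end"].to_numpy() - 1,
        reads["start"].to_numpy(),
    )
    return pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "pos": pos})


def count_sites(
    reads: pd.DataFrame,
    windows: pd.DataFrame,
    mode: str = "five_prime",
    condition: str | None = None,
    replicate: object = None,
) -> pd.DataFrame:
    """Count reads of one replicate into every window.

    ``mode='five_prime'`` counts a read iff its strand-aware 5' coordinate
    lies in the half-open window; ``'overlap'`` iff the read overlaps the
    window by >= 1 bp.  A read in both windows of a gene counts in both.
    The library size is the total number of input reads (in millions),
    including reads on chromosomes absent from the annotation (warned).
    """
    if mode not in ("five_prime", "overlap"):
        raise ValueError(f"unknown counting mode {mode!r}")
    out = windows.copy()
    counts = np.zeros(len(windows), dtype=np.int64)
    known = set(windows["chrom"].unique())
    extra = set(reads["chrom"].unique()) - known
    if extra:
        logger.warning(
            "%d read chromosome(s) absent from annotation (library size only): %s",
            len(extra), ", ".join(sorted(extra)[:5]),
        )
    if mode == "five_prime":
        fp = five_prime_positions(reads)
        for chrom, sub in fp.groupby("chrom", sort=False):
            sel = (windows["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            pos = np.sort(sub["pos"].to_numpy())
            lo = np.searchsorted(pos, windows.loc[sel, "start"].to_numpy(), "left")
            hi = np.searchsorted(pos, windows.loc[sel, "end"].to_numpy(), "left")
            counts[sel] = hi - lo
    else:
        for chrom, sub in reads.groupby("chrom", sort=False):
            sel = (windows["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            starts = np.sort(sub["start"].to_numpy())
            ends = np.sort(sub["end"].to_numpy())
            # overlap iff read.start < w.end and read.end > w.start
            n_start_before_wend = np.searchsorted(
                starts, windows.loc[sel, "end"].to_numpy(), "left"
            )
            n_end_at_or_before_wstart = np.searchsorted(
                ends, windows.loc[sel, "start"].to_numpy(), "right"
            )
            counts[sel] = n_start_before_wend - n_end_at_or_before_wstart
    out["count"] = counts
    out["library_size_millions"] = len(reads) / 1e6
    if condition is not None:
        out["condition"] = condition
    if replicate is not None:
        out["replicate"] = replicate
    return out


def count_design(
    read_sets: Mapping[tuple[str, object], pd.DataFrame],
    windows: pd.DataFrame,
    mode: str = "five_prime",
    library_sizes: Mapping[tuple[str, object], float] | None = None,
) -> pd.DataFrame:
    """Count every replicate of a design; keys are (condition, replicate).

    ``library_sizes`` (millions) overrides the per-file read totals, for the
    case where the supplied BED is a windowed subset of the mapped reads.
    """
    frames = []
    for (cond, rep), reads in read_sets.items():
        c = count_sites(reads, windows, mode=mode, condition=cond, replicate=rep)
        if library_sizes is not None:
            c["library_size_millions"] = float(library_sizes[(cond, rep)])
        frames.append(c)
    return pd.concat(frames, ignore_index=True)


def select_representative_transcripts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per gene, keep the transcript with the highest pooled TSS+TES count.

    Ties go to the longest transcript, then the lexicographically smallest
    transcript id.  Requires ``transcript_id`` and window ``start``/``end``
    columns (as produced by :func:`count_sites`).
    """
    pooled = (
        counts.assign(span=counts["end"] - counts["start"])
        .groupby(["gene_id", "transcript_id"], sort=False)
        .agg(total=("count", "sum"), span=("span", "sum"))
        .reset_index()
    )
    pooled = pooled.sort_values(
        ["gene_id", "total", "span", "transcript_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    keep = pooled.drop_duplicates("gene_id")["transcript_id"]
    return counts[counts["transcript_id"].isin(set(keep))].reset_index(drop=True)


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column ``chrom<TAB>size`` file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def bin_counts(
    reads: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_width: int = 10_000,
) -> pd.Series:
    """Per-bin read counts for one sample; bins tile each chromosome.

    Every read is assigned to exactly one bin by its strand-aware 5'
    coordinate.  A read on a chromosome without a size entry is an error.
    """
    fp = five_prime_positions(reads)
    missing = set(fp["chrom"].unique()) - set(chrom_sizes)
    if missing:
        raise KeyError(f"missing chromosome size for: {', '.join(sorted(missing))}")
    index = []
    for chrom in sorted(chrom_sizes):
        nbins = math.ceil(chrom_sizes[chrom] / bin_width)
        index += [(chrom, i * bin_width) for i in range(nbins)]
    out = pd.Series(
        0,
        index=pd.MultiIndex.from_tuples(index, names=["chrom", "bin_start"]),
        dtype=np.int64,
    )
    binned = fp.assign(bin_start=(fp["pos"] // bin_width) * bin_width)
    tally = binned.groupby(["chrom", "bin_start"]).size()
    out.loc[tally.index] = tally
    return out


def bin_matrix(
    samples: Mapping[str, pd.DataFrame],
    chrom_sizes: Mapping[str, int],
    bin_width: int = 10_000,
) -> pd.DataFrame:
    """Bins x samples count matrix (columns in mapping order)."""
    return pd.DataFrame(
        {name: bin_counts(reads, chrom_sizes, bin_width) for name, reads in samples.items()}
    )


def correlation_matrix(bins: pd.DataFrame, pseudo: float = 0.5) -> pd.DataFrame:
    """Pearson correlation of log(count + pseudo) across all bins.

    Zero-variance samples yield NaN rows/columns (flagged with a warning);
    the diagonal is 1 for valid samples.
    """
    if bins.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    logc = np.log(bins.to_numpy(dtype=float) + pseudo)
    sd = logc.std(axis=0)
    if np.any(sd == 0):
        flat = [c for c, s in zip(bins.columns, sd) if s == 0]
        logger.warning("zero-variance sample(s), correlation undefined: %s", flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(logc, rowvar=False)
    r = pd.DataFrame(r, index=bins.columns, columns=bins.columns)
    for c, s in zip(bins.columns, sd):
        if s > 0:
            r.loc[c, c] = 1.0
    return r


def detect_genes(
    reads: pd.DataFrame, genes: pd.DataFrame, flank: int = 1000
) -> pd.DataFrame:
    """A gene is detected iff >= 1 read 5' end falls in [start-flank, end+flank)."""
    fp = five_prime_positions(reads)
    detected = np.zeros(len(genes), dtype=bool)
    for chrom, sub in fp.groupby("chrom", sort=False):
        sel = (genes["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = np.sort(sub["pos"].to_numpy())
        lo = np.searchsorted(pos, genes.loc[sel, "start"].to_numpy() - flank, "left")
        hi = np.searchsorted(pos, genes.loc[sel, "end"].to_numpy() + flank, "left")
        detected[sel] = hi > lo
    return pd.DataFrame({"gene_id": genes["gene_id"], "detected": detected})


def cumulative_read_share(per_gene_counts: Iterable[float]) -> pd.DataFrame:
    """Cumulative fraction of reads vs. gene rank (descending by count).

    Mirrors dynamic-range curves comparing, e.g., PolII TSS counts against
    RNA-seq exon counts: a steep curve means few genes consume most reads.
    """
    c = np.asarray(list(per_gene_counts), dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    total = c.sum()
    if total == 0:
        logger.warning("all-zero counts: empty cumulative curve")
        return pd.DataFrame(columns=["rank_fraction", "cumulative_fraction"])
    c = np.sort(c)[::-1]
    return pd.DataFrame(
        {
            "rank_fraction": np.arange(1, c.size + 1) / c.size,
            "cumulative_fraction": np.cumsum(c) / total,
        }
    )


def read_bed_reads(path: str) -> pd.DataFrame:
    """Read aligned reads from BED into the internal column layout."""
    df = pr.read_bed(path).df
    out = pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(np.int64),
            "end": df["End"].astype(np.int64),
        }
    )
    out["name"] = df["Name"].astype(str) if "Name" in df.columns else "."
    out["score"] = df["Score"] if "Score" in df.columns else 0
    out["strand"] = df["Strand"].astype(str) if "Strand" in df.columns else "+"
    return out
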