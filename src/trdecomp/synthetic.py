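"""Synthetic tissue PolII count generator with known population/activation dynamics.

The generator emulates what a bulk-tissue PolII ChIL-seq experiment measures at
a gene: a TSS-window count proportional to the number of cells in which the
locus is engaged, and a TES-window count further scaled by the gene's traveling
ratio (TR).  For gene *g* of a cell type with population ``N_t`` at timepoint
*t*, replicate *i* with library size ``M_i`` (millions of mapped reads):

    y_TSS ~ Poisson(M_i * alpha_g * N_t)
    y_TES ~ Poisson(M_i * alpha_g * N_t * TR_gt)

``alpha_g`` is the per-cell TSS signal coefficient (CPM per cell unit), so
``alpha_g * N_t`` is the gene's true TSS CPM.  The per-cell signal is assumed
linear in population size; this is the simplest generative model consistent
with interpreting the TSS level as a cell-population proxy, and users can
substitute non-linear mixes by supplying their own trajectories.

Four canonical scenarios mirror the two-axis decomposition the downstream
model is meant to recover:

* ``activation`` — population constant, TR steps 0.3 -> 1.2 (pause release
  within a resident population);
* ``migration``  — TR constant, population steps 1000 -> 4000 (influx of cells
  that already transcribe the gene);
* ``mixed``      — both change;
* ``null``       — both constant.

Randomness contract: a single root seed; each gene draws from its own stream
derived deterministically from ``(seed, gene_id)``, so adding genes to a
design never perturbs the counts of existing genes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTypeTrajectory",
    "GeneSpec",
    "SimConfig",
    "make_scenarios",
    "truth_table",
    "simulate_counts",
    "make_gene_models",
    "simulate_reads",
]

SCENARIOS = ("activation", "migration", "mixed", "null")


@dataclass(frozen=True)
class CellTypeTrajectory:
    """Population size of one cell type over the ordered timepoints."""

    name: str
    population: tuple[float, ...]

    def __post_init__(self) -> None:
        pop = np.asarray(self.population, dtype=float)
        if pop.size == 0 or not np.all(np.isfinite(pop)) or np.any(pop < 0):
            raise ValueError(f"population of {self.name!r} must be finite and >= 0")


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth parameters of one synthetic gene."""

    gene_id: str
    cell_type: str
    alpha: float  # per-cell TSS CPM coefficient
    tr_true: tuple[float, ...]  # one TR per timepoint
    scenario: str

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha of {self.gene_id!r} must be > 0")
        tr = np.asarray(self.tr_true, dtype=float)
        if not np.all(np.isfinite(tr)) or np.any(tr < 0):
            raise ValueError(f"tr_true of {self.gene_id!r} must be finite and >= 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass(frozen=True)
class SimConfig:
    """Design of the simulated experiment.

    ``library_sizes`` are millions of mapped reads, one per replicate, reused
    at every timepoint.  They deliberately differ across replicates (default
    1, 2, 4 M) so that the model's library-size offset is actually exercised.
    ``noise_mode='expectation'`` emits the rounded Poisson means (half-up) and
    is fully deterministic; ``'poisson'`` draws seeded Poisson counts.
    """

    timepoints: tuple[str, ...] = ("t0", "t1")
    library_sizes: tuple[float, ...] = (1.0, 2.0, 4.0)
    seed: int = 0
    noise_mode: str = "poisson"

    def __post_init__(self) -> None:
        if len(self.timepoints) < 1:
            raise ValueError("need at least one timepoint")
        if len(self.library_sizes) < 1 or any(m <= 0 for m in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if self.noise_mode not in ("poisson", "expectation"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")

    @property
    def replicates_per_timepoint(self) -> int:
        return len(self.library_sizes)


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    # crc32 is stable across runs/platforms, unlike hash()
    return np.random.default_rng([seed, zlib.crc32(gene_id.encode())])


def _step(first: float, later: float, n: int) -> tuple[float, ...]:
    """Value at the first timepoint, then ``later`` from the second on."""
    return (first,) + (later,) * (n - 1)


# Default trajectories: chosen so the total expected TSS count per condition
# (sum over 1+2+4 M replicates) stays >= 200 even in the low-population arm.
_DEFAULT_ALPHA = 0.05  # CPM per cell -> 100 CPM at N=2000
_RESIDENT_N = 2000.0
_MIGRANT_N = (1000.0, 4000.0)  # 4x influx
_TR_LOW, _TR_HIGH = 0.3, 1.2
_TR_CONST = 0.6


def make_scenarios(
    n_genes_per_scenario: int, config: SimConfig
) -> tuple[list[GeneSpec], dict[str, CellTypeTrajectory]]:
    """Build the four scenario gene groups and their cell-type trajectories.

    Returns ``n_genes_per_scenario`` genes per scenario; deterministic (no
    randomness is consumed here — parameters are fixed by the defaults).
    """
    if n_genes_per_scenario < 1:
        raise ValueError("n_genes_per_scenario must be >= 1")
    nt = len(config.timepoints)
    trajectories = {
        "resident": CellTypeTrajectory("resident", (_RESIDENT_N,) * nt),
        "migrant": CellTypeTrajectory(
            "migrant", _step(_MIGRANT_N[0], _MIGRANT_N[1], nt)
        ),
    }
    per_scenario = {
        "activation": ("resident", _step(_TR_LOW, _TR_HIGH, nt)),
        "migration": ("migrant", (_TR_CONST,) * nt),
        "mixed": ("migrant", _step(_TR_LOW, _TR_HIGH, nt)),
        "null": ("resident", (_TR_CONST,) * nt),
    }
    specs: list[GeneSpec] = []
    for scenario in SCENARIOS:
        cell_type, tr = per_scenario[scenario]
        for k in range(n_genes_per_scenario):
            specs.append(
                GeneSpec(
                    gene_id=f"{scenario}_{k:05d}",
                    cell_type=cell_type,
                    alpha=_DEFAULT_ALPHA,
                    tr_true=tr,
                    scenario=scenario,
                )
            )
    return specs, trajectories


def truth_table(
    specs: Sequence[GeneSpec],
    trajectories: Mapping[str, CellTypeTrajectory],
    config: SimConfig,
) -> pd.DataFrame:
    """One row per gene x timepoint with true_tss_cpm, true_tr and scenario."""
    rows = []
    for spec in specs:
        pop = trajectories[spec.cell_type].population
        if len(pop) != len(config.timepoints) or len(spec.tr_true) != len(
            config.timepoints
        ):
            raise ValueError(
                f"gene {spec.gene_id!r}: trajectory/TR length does not match timepoints"
            )
        for t, tp in enumerate(config.timepoints):
            rows.append(
                (spec.gene_id, tp, spec.alpha * pop[t], spec.tr_true[t], spec.scenario)
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "timepoint", "true_tss_cpm", "true_tr", "scenario"]
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def simulate_counts(
    specs: Sequence[GeneSpec],
    trajectories: Mapping[str, CellTypeTrajectory],
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the per-gene TSS/TES count table and its ground truth.

    Returns ``(counts, truth)``.  ``counts`` has one row per
    gene x timepoint x replicate x site with columns
    ``gene_id, replicate, condition, site, count, library_size_millions``.
    """
    truth = truth_table(specs, trajectories, config)
    lam_tss = truth["true_tss_cpm"].to_numpy()
    lam_tes = lam_tss * truth["true_tr"].to_numpy()
    mlib = np.asarray(config.library_sizes, dtype=float)

    frames = []
    # truth is ordered gene-major, timepoint-minor; draw per gene in one block
    # so each gene's stream is independent of all other genes.
    nt = len(config.timepoints)
    nrep = mlib.size
    for g, spec in enumerate(specs):
        lam = np.empty((nt, nrep, 2))
        lam[:, :, 0] = np.outer(lam_tss[g * nt : (g + 1) * nt], mlib)
        lam[:, :, 1] = np.outer(lam_tes[g * nt : (g + 1) * nt], mlib)
        if config.noise_mode == "poisson":
            y = _gene_rng(config.seed, spec.gene_id).poisson(lam)
        else:
            y = _round_half_up(lam)
        frames.append(y.reshape(-1))
    counts = pd.DataFrame(
        {
            "gene_id": np.repeat([s.gene_id for s in specs], nt * nrep * 2),
            "condition": np.tile(np.repeat(config.timepoints, nrep * 2), len(specs)),
            "replicate": np.tile(np.repeat(np.arange(1, nrep + 1), 2), len(specs) * nt),
            "site": np.tile(["TSS", "TES"], len(specs) * nt * nrep),
            "count": np.concatenate(frames) if frames else np.array([], dtype=np.int64),
            "library_size_millions": np.tile(np.repeat(mlib, 2), len(specs) * nt),
        }
    )
    return counts, truth


def make_gene_models(
    gene_ids: Iterable[str],
    gene_length: int = 20_000,
    spacing: int = 10_000,
    chrom: str = "chr1",
    start: int = 5_000,
) -> pd.DataFrame:
    """Lay synthetic genes head-to-tail on one chromosome, alternating strand.

    Spacing and the default gene length keep the 1.5-kb TSS/TES windows of
    neighbouring genes disjoint, so read -> count round trips are exact.
    """
    rows = []
    pos = start
    for k, gid in enumerate(gene_ids):
        strand = "+" if k % 2 == 0 else "-"
        rows.append((gid, gid, chrom, strand, pos, pos + gene_length))
        pos += gene_length + spacing
    df = pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "chrom", "strand", "start", "end"]
    )
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df["tes"] = np.where(df["strand"] == "+", df["end"] - 1, df["start"])
    return df


def simulate_reads(
    counts: pd.DataFrame,
    windows: pd.DataFrame,
    seed: int,
    read_length: int = 50,
) -> pd.DataFrame:
    """Emit one BED read per counted unit, 5' ends uniform within the window.

    ``windows`` is the long-form table from :func:`trdecomp.counts.build_windows`
    (one row per transcript x site).  Each (gene, condition, replicate, site)
    cell with count *y* yields exactly *y* reads whose strand-aware 5'
    coordinate is uniform in the matching window, so re-counting them with
    ``count_sites`` in five-prime mode reproduces ``counts`` exactly.
    """
    win = windows.set_index(["gene_id", "site"])
    rows = []
    ordered = counts.sort_values(
        ["gene_id", "condition", "replicate", "site"], kind="mergesort"
    )
    for gid, sub in ordered.groupby("gene_id", sort=True):
        rng = _gene_rng(seed, str(gid))
        for cond, rep, site, y in zip(
            sub["condition"], sub["replicate"], sub["site"], sub["count"]
        ):
            try:
                w = win.loc[(gid, site)]
            except KeyError:
                raise KeyError(
                    f"no {site} window for counted gene {gid!r}"
                ) from None
            y = int(y)
            if y == 0:
                continue
            five = rng.integers(int(w["start"]), int(w["end"]), size=y)
            strand = str(w["strand"])
            if strand == "+":
                starts, ends = five, five + read_length
            else:
                starts, ends = np.maximum(five + 1 - read_length, 0), five + 1
            name = f"{gid}|{cond}|rep{rep}|{site}"
            for s, e in zip(starts, ends):
                rows.append((str(w["chrom"]), int(s), int(e), name, 0, strand, cond, rep))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "condition", "replicate",
        ],
    )
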