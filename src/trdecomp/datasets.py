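"""Small bundled reference tables.

Currently a single table: cell numbers counted in the triplicate single thin
tissue sections (10 um, ~3x3 mm) used for ChIL-seq profiling of mouse heart,
liver, testis and tibialis anterior (TA) muscle.  It serves as a worked
example of section-level input sizes (10^3-10^4 cells per section).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["section_cell_counts", "mean_section_cell_counts"]

_REPS = ["rep1", "rep2", "rep3"]


def section_cell_counts() -> pd.DataFrame:
    """Per-section cell counts, one row per tissue x antibody combination."""
    with resources.files("trdecomp.data").joinpath("section_cell_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def mean_section_cell_counts() -> pd.Series:
    """Arithmetic mean of the triplicate section cell counts, rounded half-up
    to whole cells (the convention of the source table)."""
    df = section_cell_counts().set_index("tissue_section")
    mean = df[_REPS].mean(axis=1)
    return np.floor(mean + 0.5).astype(int).rename("average_cells")
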