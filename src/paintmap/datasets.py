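"""Packaged reference tables and synthetic stand-ins.

Two small tables ship with the package: the published probe-set x
chromosome alignment-count matrix for the ten maize painting pools
against the ten sorghum chromosomes, and the published *T. arundinaceum*
metaphase karyotype table (arm means/SDs over 10 cells). Both are used
as fixtures and as defaults for the simulators.

`synthetic_signal_patterns` is a SYNTHETIC stand-in for window-resolved
signal morphology: the printed count matrix has no positional
information, so qualitative distribution shapes (uniform paint on a
probe's own chromosome, offset distal blocks elsewhere) are generated
procedurally for cells at candidate level. It exists so that
pattern-disambiguation machinery can be exercised against the printed
matrix; it is not measured data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io_formats import MeasurementRecord, read_count_matrix
from .signals import DensityProfile, SignalThresholds


def _data_path(name: str):
    return resources.files("paintmap.data").joinpath(name)


def load_sorghum_mcp_counts() -> pd.DataFrame:
    """The published 10x10 count matrix (MCP1..MCP10 x Sorghum1..Sorghum10)."""
    with resources.as_file(_data_path("sorghum_mcp_counts.tsv")) as p:
        return read_count_matrix(p)


def load_tripidium_karyotype() -> pd.DataFrame:
    """The published karyotype table: arm means and SDs in micrometres."""
    with resources.as_file(_data_path("tripidium_karyotype.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col=0)


def karyotype_true_arms() -> dict[str, tuple[float, float]]:
    """(long, short) arm means per chromosome, for use as simulation truth."""
    table = load_tripidium_karyotype()
    return {
        str(label): (float(row["long_mean"]), float(row["short_mean"]))
        for label, row in table.iterrows()
    }


def single_cell_measurements_from_table() -> list[MeasurementRecord]:
    """One noise-free pseudo-cell whose arms equal the published means."""
    return [
        MeasurementRecord("cell01", label, long_um, short_um)
        for label, (long_um, short_um) in karyotype_true_arms().items()
    ]


def synthetic_signal_patterns(
    matrix: pd.DataFrame,
    thresholds: SignalThresholds | None = None,
    n_windows: int = 20,
    block_windows: int = 6,
) -> DensityProfile:
    """SYNTHETIC window-density morphology for candidate-level cells.

    A probe paints its own chromosome uniformly (row i on column i); on
    other chromosomes it occupies a block of ``block_windows`` windows
    whose offset, (3i + 5j) mod 13 for row i and column j, is chosen so
    that any two chromosomes lit by the same probe get total-variation-
    separable shapes. Window width is nominal (500 kb).
    """
    thresholds = thresholds or SignalThresholds()
    window_bp = 500_000
    chrom_lengths = {str(c): n_windows * window_bp for c in matrix.columns}
    counts: dict[tuple[str, str], np.ndarray] = {}
    for i, probe in enumerate(matrix.index):
        for j, chrom in enumerate(matrix.columns):
            cell = int(matrix.loc[probe, chrom])
            vec = np.zeros(n_windows, dtype=int)
            if cell >= thresholds.candidate_min:
                if i == j:
                    vec[:] = max(1, cell // n_windows)
                else:
                    offset = (3 * i + 5 * j) % 13
                    vec[offset : offset + block_windows] = max(1, cell // block_windows)
            counts[(str(probe), str(chrom))] = vec
    return DensityProfile(window_bp=window_bp, chrom_lengths=chrom_lengths, counts=counts)
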