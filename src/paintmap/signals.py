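"""From retained hits to FISH-signal predictions.

The count matrix tallies, per probe set and chromosome, the number of
distinct oligos with at least one retained hit — an oligo hitting one
chromosome twice counts once there, but an oligo hitting three
homoeologous chromosomes counts on each. Windowed density profiles keep
locus multiplicity (one count per retained start locus). Threshold-based
calls translate counts into predicted signal levels: below the candidate
threshold a probe is not expected to produce a visible signal; between
candidate and confident thresholds the prediction is uncertain (counts
near 1000-3000 have produced both observed and unobserved signals under
the microscope); above it a signal is expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import AlignmentSet

LEVELS = ("none", "uncertain", "present")
_LEVEL_RANK = {lev: i for i, lev in enumerate(LEVELS)}


def count_per_chromosome(hits: AlignmentSet) -> pd.DataFrame:
    """Distinct-oligo counts per (probe set, chromosome).

    Rows are the library's probe sets and columns the genome's chromosomes,
    both in input order and both complete even when all-zero.
    """
    matrix = pd.DataFrame(
        0, index=pd.Index(hits.probe_sets, name="probe_set"), columns=hits.chrom_names
    )
    seen: set[tuple[str, str]] = set()
    for h in hits.hits:
        key = (h.oligo_id, h.chrom_name)
        if key in seen:
            continue
        seen.add(key)
        matrix.loc[h.probe_set, h.chrom_name] += 1
    return matrix


@dataclass(frozen=True)
class MatrixExtrema:
    min_value: int
    min_cells: tuple[tuple[str, str], ...]
    max_value: int
    max_cells: tuple[tuple[str, str], ...]


def matrix_extrema(matrix: pd.DataFrame) -> MatrixExtrema:
    """Minimum and maximum cells with their labels; ties in label order."""
    if matrix.empty:
        raise ValueError("empty count matrix")
    values = matrix.to_numpy()
    vmin, vmax = int(values.min()), int(values.max())

    def cells_at(v: int) -> tuple[tuple[str, str], ...]:
        out = [
            (str(r), str(c))
            for r in matrix.index
            for c in matrix.columns
            if int(matrix.loc[r, c]) == v
        ]
        return tuple(sorted(out))

    return MatrixExtrema(vmin, cells_at(vmin), vmax, cells_at(vmax))


@dataclass
class DensityProfile:
    """Per-window hit counts, one vector per (probe_set, chromosome).

    Windows are fixed-width (default 500 kb), 0-based half-open; the last
    window of a chromosome may be short. A hit lands in the window holding
    its start coordinate; no per-oligo deduplication is applied here, so
    window sums carry locus multiplicity and are >= the count-matrix cell.
    """

    window_bp: int
    chrom_lengths: dict[str, int]
    counts: dict[tuple[str, str], np.ndarray]

    @property
    def probe_sets(self) -> list[str]:
        return sorted({ps for ps, _ in self.counts})

    def n_windows(self, chrom: str) -> int:
        return max(1, math.ceil(self.chrom_lengths[chrom] / self.window_bp))


def bin_density(hits: AlignmentSet, window_bp: int = 500_000) -> DensityProfile:
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    counts: dict[tuple[str, str], np.ndarray] = {}
    for ps in hits.probe_sets:
        for chrom, length in hits.chrom_lengths.items():
            counts[(ps, chrom)] = np.zeros(max(1, math.ceil(length / window_bp)), dtype=int)
    for h in hits.hits:
        counts[(h.probe_set, h.chrom_name)][h.start // window_bp] += 1
    return DensityProfile(window_bp=window_bp, chrom_lengths=dict(hits.chrom_lengths), counts=counts)


@dataclass(frozen=True)
class SignalThresholds:
    """Count thresholds separating no-signal / uncertain / confident calls."""

    candidate_min: int = 1000
    confident_min: int = 3000

    def __post_init__(self) -> None:
        if self.candidate_min > self.confident_min:
            raise ValueError("candidate_min must be <= confident_min")

    def level(self, count: int) -> str:
        if count >= self.confident_min:
            return "present"
        if count >= self.candidate_min:
            return "uncertain"
        return "none"


@dataclass
class SignalCall:
    """Predicted signal level per (probe set, chromosome), plus patterns.

    ``levels`` is a probe-set x chromosome frame over {none, uncertain,
    present}. ``patterns`` maps candidate-level cells to their window-density
    vector normalized to sum 1 (below-candidate profiles are noise and get
    no pattern).
    """

    levels: pd.DataFrame
    thresholds: SignalThresholds
    patterns: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    counts: pd.DataFrame | None = None

    @property
    def probe_sets(self) -> list[str]:
        return [str(x) for x in self.levels.index]

    @property
    def chromosomes(self) -> list[str]:
        return [str(x) for x in self.levels.columns]

    def level(self, probe_set: str, chrom: str) -> str:
        return str(self.levels.loc[probe_set, chrom])

    def chroms_at_level(self, probe_set: str, min_level: str = "uncertain") -> list[str]:
        """Chromosomes where the probe's level is at least ``min_level``."""
        rank = _LEVEL_RANK[min_level]
        return [
            c for c in self.chromosomes
            if _LEVEL_RANK[self.level(probe_set, c)] >= rank
        ]

    def candidate_set(self, probe_set: str) -> list[str]:
        return self.chroms_at_level(probe_set, "uncertain")

    def present_set(self, probe_set: str) -> list[str]:
        return self.chroms_at_level(probe_set, "present")


def call_signals(
    matrix: pd.DataFrame,
    thresholds: SignalThresholds | None = None,
    profile: DensityProfile | None = None,
) -> SignalCall:
    """Apply signal thresholds to a count matrix, attaching patterns.

    When a profile is given it must cover the matrix labels; patterns are
    normalized window vectors for cells at candidate level or above.
    """
    thresholds = thresholds or SignalThresholds()
    levels = matrix.map(lambda v: thresholds.level(int(v)))
    patterns: dict[tuple[str, str], np.ndarray] = {}
    if profile is not None:
        for ps in matrix.index:
            for chrom in matrix.columns:
                if (str(ps), str(chrom)) not in profile.counts:
                    raise ValueError(
                        f"density profile lacks cell ({ps}, {chrom}); "
                        "matrix and profile labels are inconsistent"
                    )
        for ps in matrix.index:
            for chrom in matrix.columns:
                if int(matrix.loc[ps, chrom]) >= thresholds.candidate_min:
                    vec = np.asarray(profile.counts[(str(ps), str(chrom))], dtype=float)
                    total = vec.sum()
                    if total > 0:
                        patterns[(str(ps), str(chrom))] = vec / total
    return SignalCall(levels=levels, thresholds=thresholds, patterns=patterns, counts=matrix)


@dataclass(frozen=True)
class BarcodeResult:
    """Binary presence barcodes over a probe subset, with collision report.

    ``collision_groups`` lists chromosome groups sharing a barcode (size
    >= 2). ``zero_chromosomes`` lists chromosomes with the all-zero barcode:
    they carry no positive identification even when alone.
    """

    probe_subset: tuple[str, ...]
    barcodes: dict[str, tuple[int, ...]]
    collision_groups: tuple[tuple[str, ...], ...]
    zero_chromosomes: tuple[str, ...]

    @property
    def all_distinct(self) -> bool:
        return not self.collision_groups


def barcode_chromosomes(
    calls: SignalCall, probe_subset: list[str], min_level: str = "uncertain"
) -> BarcodeResult:
    """Binary barcode (level != none by default) per chromosome."""
    unknown = [p for p in probe_subset if p not in calls.probe_sets]
    if unknown:
        raise ValueError(f"probe subset not in calls: {unknown}")
    rank = _LEVEL_RANK[min_level]
    barcodes = {
        chrom: tuple(
            1 if _LEVEL_RANK[calls.level(p, chrom)] >= rank else 0 for p in probe_subset
        )
        for chrom in calls.chromosomes
    }
    groups: dict[tuple[int, ...], list[str]] = {}
    for chrom, code in barcodes.items():
        groups.setdefault(code, []).append(chrom)
    collision_groups = tuple(
        tuple(sorted(members)) for code, members in sorted(groups.items())
        if len(members) > 1
    )
    zero = tuple(sorted(groups.get(tuple([0] * len(probe_subset)), [])))
    return BarcodeResult(
        probe_subset=tuple(probe_subset),
        barcodes=barcodes,
        collision_groups=collision_groups,
        zero_chromosomes=zero,
    )


def pattern_distance(p: np.ndarray, q: np.ndarray, grid: int = 60) -> float:
    """Total-variation distance between two window-density patterns.

    Patterns from chromosomes of different lengths have different window
    counts, so both are resampled as densities over relative chromosome
    position onto a common grid before comparison. Range [0, 1].
    """
    def resample(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.sum() <= 0:
            return np.full(grid, 1.0 / grid)
        v = v / v.sum()
        centers = (np.arange(len(v)) + 0.5) / len(v)
        dense = np.interp((np.arange(grid) + 0.5) / grid, centers, v * len(v))
        total = dense.sum()
        return dense / total if total > 0 else np.full(grid, 1.0 / grid)

    return float(0.5 * np.abs(resample(p) - resample(q)).sum())
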