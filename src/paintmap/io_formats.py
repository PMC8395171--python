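"""Readers and writers for the pipeline's external representations.

Everything on disk is plain text: FASTA for genomes and oligo libraries,
TSV for count matrices and metaphase arm measurements, a BED5-like format
for windowed probe densities, and JSON for plans, karyotypes and idiograms.
All genomic coordinates are 0-based, half-open.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("paintmap")

DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OligoRecord:
    """A single painting oligo: short probe sequence with its pool label.

    ``probe_set`` is the chromosome-painting pool the oligo belongs to
    (e.g. ``MCP1``..``MCP10`` for the maize pools). Sequences are uppercase
    DNA over {A,C,G,T,N}; N never matches anything downstream.
    """

    oligo_id: str
    probe_set: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.probe_set:
            raise FormatError(f"oligo {self.oligo_id!r}: empty probe_set label")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"oligo {self.oligo_id!r}: invalid characters {sorted(bad)} in sequence"
            )
        if len(self.sequence) < 20:
            raise FormatError(
                f"oligo {self.oligo_id!r}: length {len(self.sequence)} < 20 nt"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class OligoLibrary:
    """A probe-set-labelled collection of painting oligos."""

    records: list[OligoRecord]
    library_id: str = "library"

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("empty oligo library")
        seen: set[str] = set()
        for rec in self.records:
            if rec.oligo_id in seen:
                raise FormatError(f"duplicate oligo ID {rec.oligo_id!r}")
            seen.add(rec.oligo_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OligoRecord]:
        return iter(self.records)

    @property
    def probe_sets(self) -> list[str]:
        """Probe-set labels in first-seen order."""
        out: list[str] = []
        for rec in self.records:
            if rec.probe_set not in out:
                out.append(rec.probe_set)
        return out

    @property
    def by_set(self) -> dict[str, list[OligoRecord]]:
        grouped: dict[str, list[OligoRecord]] = {}
        for rec in self.records:
            grouped.setdefault(rec.probe_set, []).append(rec)
        return grouped

    def set_sizes(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.by_set.items()}


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome (or pseudomolecule) of a target/reference genome."""

    chrom_name: str
    sequence: str

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """An ordered collection of chromosomes with unique names."""

    chromosomes: list[GenomeSequence]
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise FormatError("empty genome")
        names = [c.chrom_name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome names in genome")

    def __iter__(self) -> Iterator[GenomeSequence]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def chrom_names(self) -> list[str]:
        return [c.chrom_name for c in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.chrom_name: c.length_bp for c in self.chromosomes}

    def __getitem__(self, name: str) -> GenomeSequence:
        for c in self.chromosomes:
            if c.chrom_name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class MeasurementRecord:
    """One homolog copy's arm lengths in one metaphase cell, in micrometres."""

    cell_id: str
    chrom_label: str
    long_arm_um: float
    short_arm_um: float

    def __post_init__(self) -> None:
        if not (self.long_arm_um >= self.short_arm_um > 0):
            raise FormatError(
                f"cell {self.cell_id!r} {self.chrom_label!r}: need "
                f"long >= short > 0, got {self.long_arm_um}/{self.short_arm_um}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_fasta(path: str | Path):
    """Parse FASTA strictly enough to name the offending line on failure."""
    with _open_text(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}")
        break
    else:
        raise FormatError(f"{path}: no FASTA records found")
    return list(SeqIO.parse(io.StringIO(text), "fasta"))


def read_oligo_library(path: str | Path, set_delimiter: str = "_") -> OligoLibrary:
    """Read a probe library from FASTA.

    The probe-set label is encoded as the record-ID prefix before the first
    ``set_delimiter`` (``MCP1_0001`` -> set ``MCP1``). IDs without the
    delimiter fall into a probe set equal to the whole ID.
    """
    records = []
    for rec in _parse_fasta(path):
        probe_set = rec.id.split(set_delimiter, 1)[0]
        records.append(OligoRecord(rec.id, probe_set, str(rec.seq).upper()))
    return OligoLibrary(records, library_id=Path(path).stem)


def write_oligo_library(library: OligoLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in library:
            fh.write(f">{rec.oligo_id}\n{rec.sequence}\n")


def read_genome_fasta(path: str | Path) -> Genome:
    chroms = [
        GenomeSequence(rec.id, str(rec.seq).upper()) for rec in _parse_fasta(path)
    ]
    return Genome(chroms, genome_id=Path(path).stem)


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in genome:
            fh.write(f">{c.chrom_name}\n")
            for i in range(0, c.length_bp, width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe-set x chromosome count matrix from TSV.

    Thousands separators ("27,169") are accepted on input because printed
    tables carry them; cells are validated as non-negative integers and
    stored as plain ints.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, thousands=",", dtype=object)
    if df.empty:
        raise FormatError(f"{path}: empty count matrix")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str))
    for r in df.index:
        for c in df.columns:
            raw = str(df.loc[r, c]).replace(",", "")
            try:
                as_float = float(raw)
            except ValueError:
                raise FormatError(f"count matrix cell ({r}, {c}) = {raw!r} is not a number")
            if not as_float.is_integer():
                raise FormatError(f"count matrix cell ({r}, {c}) = {raw!r} is not an integer")
            val = int(as_float)
            if val < 0:
                raise FormatError(f"count matrix cell ({r}, {c}) = {val} is negative")
            out.loc[r, c] = val
    out.index.name = df.index.name or "probe_set"
    return out.astype(int)


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a count matrix as TSV, plain integers, no thousands separators."""
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "probe_set")


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ["cell_id", "chrom_label", "long_arm_um", "short_arm_um"]


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read per-cell arm measurements from TSV.

    Records with short > long are swapped with a logged warning rather than
    rejected: arm identity can be mislabelled at measurement time but the pair
    of lengths is still usable.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing measurement columns {missing}")
    records = []
    for _, row in df.iterrows():
        long_um = float(row["long_arm_um"])
        short_um = float(row["short_arm_um"])
        if short_um > long_um:
            logger.warning(
                "measurement %s/%s: short arm %.3f > long arm %.3f, swapping",
                row["cell_id"], row["chrom_label"], short_um, long_um,
            )
            long_um, short_um = short_um, long_um
        records.append(
            MeasurementRecord(str(row["cell_id"]), str(row["chrom_label"]), long_um, short_um)
        )
    return records


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.cell_id, r.chrom_label, r.long_arm_um, r.short_arm_um) for r in records],
        columns=MEASUREMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Density BED
# ---------------------------------------------------------------------------

def write_density_bed(profile, path: str | Path) -> None:
    """Serialize a DensityProfile as BED5-like text.

    Columns: chrom, start, end, probe_set, count; 0-based half-open windows;
    sorted by (chrom, start, probe_set). Every window of every chromosome is
    emitted, including a short trailing window, with its true end coordinate.
    """
    if not profile.counts:
        raise FormatError("refusing to write an empty density profile")
    lines = []
    for chrom in sorted(profile.chrom_lengths):
        length = profile.chrom_lengths[chrom]
        n_windows = max(1, math.ceil(length / profile.window_bp))
        for w in range(n_windows):
            start = w * profile.window_bp
            end = min(start + profile.window_bp, length)
            for probe_set in sorted(profile.probe_sets):
                count = int(profile.counts[(probe_set, chrom)][w])
                lines.append(f"{chrom}\t{start}\t{end}\t{probe_set}\t{count}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_density_bed(path: str | Path):
    """Read a BED5-like density file back into a DensityProfile."""
    from .signals import DensityProfile  # local import avoids a cycle

    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise FormatError(f"{path}: line {lineno}: expected 5 columns, got {len(parts)}")
        chrom, start, end, probe_set, count = parts
        rows.append((chrom, int(start), int(end), probe_set, int(count)))
    if not rows:
        raise FormatError(f"{path}: empty density file")
    window_bp = max(end - start for _, start, end, _, _ in rows)
    chrom_lengths: dict[str, int] = {}
    for chrom, _, end, _, _ in rows:
        chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), end)
    probe_sets = sorted({r[3] for r in rows})
    counts = {
        (ps, chrom): [0] * math.ceil(chrom_lengths[chrom] / window_bp)
        for ps in probe_sets
        for chrom in chrom_lengths
    }
    for chrom, start, _, probe_set, count in rows:
        counts[(probe_set, chrom)][start // window_bp] = count
    import numpy as np

    return DensityProfile(
        window_bp=window_bp,
        chrom_lengths=chrom_lengths,
        counts={k: np.asarray(v, dtype=int) for k, v in counts.items()},
    )


# ---------------------------------------------------------------------------
# JSON documents
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
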