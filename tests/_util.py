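"""Shared test helpers: random instances and independent oracles.

The brute-force aligner here is deliberately separate from the package:
it scores every fully-contained placement of every oligo on both strands
by direct window comparison, with no seeding heuristic, and serves as
the independent oracle for the screen.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from paintmap import (
    Genome,
    GenomeSequence,
    OligoLibrary,
    OligoRecord,
    ScreenParams,
    reverse_complement,
)

_N = ord("N")


def random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> Genome:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms = [
        GenomeSequence(name, bases[rng.integers(0, 4, size=n)].tobytes().decode())
        for name, n in lengths.items()
    ]
    return Genome(chroms, genome_id="random")


def random_oligo(rng: np.random.Generator, length: int = 45) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.integers(0, 4, size=length)].tobytes().decode()


def sampled_library(
    rng: np.random.Generator,
    genome: Genome,
    n_sampled: int,
    n_random: int = 0,
    length: int = 45,
    probe_set: str = "CP1",
) -> OligoLibrary:
    """Oligos sampled verbatim from the genome, plus unrelated random ones."""
    records = []
    for i in range(n_sampled):
        chrom = genome.chromosomes[int(rng.integers(0, len(genome)))]
        start = int(rng.integers(0, chrom.length_bp - length + 1))
        seq = chrom.sequence[start : start + length]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        records.append(OligoRecord(f"{probe_set}_s{i:04d}", probe_set, seq))
    for i in range(n_random):
        records.append(OligoRecord(f"{probe_set}_r{i:04d}", probe_set, random_oligo(rng, length)))
    return OligoLibrary(records, library_id="test-lib")


def brute_force_retained(
    library: OligoLibrary, genome: Genome, params: ScreenParams
) -> set[tuple[str, str, str, int, int]]:
    """All retained fully-contained placements, by exhaustive scan.

    Returns {(oligo_id, chrom, strand, start, matched_bases)}.
    """
    out = set()
    gbytes = {
        c.chrom_name: np.frombuffer(c.sequence.encode(), dtype=np.uint8)
        for c in genome
    }
    for oligo in library:
        L = oligo.length
        need = params.required_matches(L)
        for strand, seq in (("+", oligo.sequence), ("-", reverse_complement(oligo.sequence))):
            obytes = np.frombuffer(seq.encode(), dtype=np.uint8)
            for chrom, g in gbytes.items():
                if len(g) < L:
                    continue
                windows = sliding_window_view(g, L)
                matched = ((windows == obytes) & (obytes != _N)).sum(axis=1)
                for start in np.nonzero(matched >= need)[0]:
                    out.add((oligo.oligo_id, chrom, strand, int(start), int(matched[start])))
    return out


def mc_estimands(long_true, short_true, sd, copies, n_cells, n_mc=100_000, seed=0):
    """Monte-Carlo estimands of the karyotype summary under enforced
    per-record arm ordering: (mean, SE) of long, short and ratio."""
    rng = np.random.default_rng(seed)
    x = rng.normal(long_true, sd, (n_mc, copies))
    y = rng.normal(short_true, sd, (n_mc, copies))
    hi, lo = np.maximum(x, y), np.minimum(x, y)
    cell_long, cell_short = hi.mean(axis=1), lo.mean(axis=1)
    cell_ratio = cell_long / cell_short
    out = {}
    for key, v in (("long", cell_long), ("short", cell_short), ("ratio", cell_ratio)):
        out[key] = (float(v.mean()), float(v.std(ddof=1) / np.sqrt(n_cells)))
    return out


def screen_retained_set(aset) -> set[tuple[str, str, str, int, int]]:
    return {
        (h.oligo_id, h.chrom_name, h.strand, h.start, h.matched_bases)
        for h in aset.hits
    }
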