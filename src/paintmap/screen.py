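"""Oligo-to-genome homology screen.

Every painting oligo is aligned to the target genome by exact k-mer
seeding followed by ungapped extension over the full oligo placement, on
both strands. A hit is retained when its matched bases reach both an
absolute floor (default 32 bp) and a fraction of the oligo length
(default 70%) — the joint criterion used to decide whether a probe can
still find its target after cross-species divergence.

The aligner is deliberately ungapped: painting oligos are ~45 nt and the
retention criterion is a matched-length cutoff, so indel handling buys
nothing the screen measures. N bases never match.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import FormatError, Genome, OligoLibrary, OligoRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_N = ord("N")

# base -> 2-bit code; anything outside ACGT is invalid (255)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _seq_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _encode_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer of a 2-bit coded sequence into uint64 keys.

    Returns (keys, valid) where valid masks out k-mers containing non-ACGT.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    keys = np.zeros(n, dtype=np.uint64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        keys = (keys << np.uint64(2)) | window.astype(np.uint64)
        invalid |= window == 255
    return keys, ~invalid


@dataclass(frozen=True)
class ScreenParams:
    """Tunable knobs of the retention criterion and the seeding heuristic.

    min_match_bp and min_homology_frac jointly define retention:
    matched_bases >= max(min_match_bp, ceil(min_homology_frac * oligo_length)).
    seed_k is the exact-seed length; smaller seeds are more sensitive to
    diverged targets at higher lookup cost.
    """

    seed_k: int = 16
    min_match_bp: int = 32
    min_homology_frac: float = 0.70
    max_hits_per_oligo: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.min_homology_frac <= 1):
            raise ValueError("min_homology_frac must be in (0, 1]")
        if self.seed_k > self.min_match_bp:
            raise ValueError("seed_k must not exceed min_match_bp")
        if self.max_hits_per_oligo < 1:
            raise ValueError("max_hits_per_oligo must be >= 1")

    def required_matches(self, oligo_length: int) -> int:
        return max(self.min_match_bp, math.ceil(self.min_homology_frac * oligo_length))

    def to_dict(self) -> dict:
        return {
            "seed_k": self.seed_k,
            "min_match_bp": self.min_match_bp,
            "min_homology_frac": self.min_homology_frac,
            "max_hits_per_oligo": self.max_hits_per_oligo,
        }


@dataclass(frozen=True)
class AlignmentHit:
    """One retained ungapped placement of an oligo on the genome.

    start/end are the 0-based half-open genomic interval actually covered
    (clipped at chromosome edges); identity is matched_bases over the full
    oligo length. Minus-strand hits are reported in plus-strand coordinates.
    """

    oligo_id: str
    probe_set: str
    chrom_name: str
    start: int
    end: int
    strand: str
    matched_bases: int
    oligo_length: int

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def identity(self) -> float:
        return self.matched_bases / self.oligo_length


class SeedIndex:
    """Exact k-mer index of a genome, both strands.

    Minus-strand sites are stored under the reverse-complement key at the
    plus-strand coordinate of the site, so a lookup returns
    (chrom, plus_position, strand) triples directly.
    """

    def __init__(self, genome: Genome, k: int):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        if k > 32:
            raise ValueError("seed length k must be <= 32 (uint64 packing)")
        if k > max(c.length_bp for c in genome):
            raise ValueError(f"k={k} exceeds the length of every chromosome")
        self.k = k
        self.genome = genome
        self.chrom_names = genome.chrom_names
        self.chrom_lengths = genome.chrom_lengths
        # raw ASCII byte arrays per chromosome, for extension scoring
        self.chrom_bytes: dict[str, np.ndarray] = {
            c.chrom_name: _seq_bytes(c.sequence) for c in genome
        }

        keys_parts, chrom_parts, pos_parts, strand_parts = [], [], [], []
        for ci, chrom in enumerate(genome):
            codes = _CODE[self.chrom_bytes[chrom.chrom_name]]
            L = chrom.length_bp
            fwd_keys, fwd_ok = _encode_kmers(codes, k)
            n = len(fwd_keys)
            if n:
                keys_parts.append(fwd_keys[fwd_ok])
                pos = np.nonzero(fwd_ok)[0]
                pos_parts.append(pos)
                chrom_parts.append(np.full(len(pos), ci, dtype=np.int32))
                strand_parts.append(np.zeros(len(pos), dtype=np.uint8))
            rc_codes = np.where(codes == 255, 255, 3 - codes)[::-1]
            rc_keys, rc_ok = _encode_kmers(rc_codes, k)
            if len(rc_keys):
                keys_parts.append(rc_keys[rc_ok])
                q = np.nonzero(rc_ok)[0]
                pos_parts.append(L - k - q)  # plus-strand coordinate of the site
                chrom_parts.append(np.full(len(q), ci, dtype=np.int32))
                strand_parts.append(np.ones(len(q), dtype=np.uint8))

        keys = np.concatenate(keys_parts) if keys_parts else np.empty(0, dtype=np.uint64)
        order = np.argsort(keys, kind="stable")
        self._keys = keys[order]
        self._chrom = np.concatenate(chrom_parts)[order] if chrom_parts else np.empty(0, np.int32)
        self._pos = np.concatenate(pos_parts)[order].astype(np.int64) if pos_parts else np.empty(0, np.int64)
        self._strand = np.concatenate(strand_parts)[order] if strand_parts else np.empty(0, np.uint8)

    def lookup_encoded(self, key: int):
        """Yield (chrom_index, plus_pos, strand_code) for one packed k-mer."""
        lo = np.searchsorted(self._keys, key, side="left")
        hi = np.searchsorted(self._keys, key, side="right")
        return zip(self._chrom[lo:hi], self._pos[lo:hi], self._strand[lo:hi])

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """Sites of an exact k-mer, as (chrom_name, plus_position, strand)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} nt")
        codes = _CODE[_seq_bytes(kmer.upper())]
        if (codes == 255).any():
            return []
        key = np.uint64(0)
        for c in codes:
            key = (key << np.uint64(2)) | np.uint64(c)
        out = [
            (self.chrom_names[ci], int(p), "+" if s == 0 else "-")
            for ci, p, s in self.lookup_encoded(key)
        ]
        return sorted(set(out))


def build_seed_index(genome: Genome, k: int) -> SeedIndex:
    return SeedIndex(genome, k)


def _placement_matches(
    oriented: np.ndarray, gbytes: np.ndarray, start: int
) -> tuple[int, int, int]:
    """Matched bases of a full-oligo placement, clipped at chromosome edges."""
    L = len(oriented)
    s0 = max(start, 0)
    s1 = min(start + L, len(gbytes))
    if s1 <= s0:
        return 0, s0, s0
    o = oriented[s0 - start : s1 - start]
    g = gbytes[s0:s1]
    matched = int(np.count_nonzero((g == o) & (o != _N)))
    return matched, s0, s1


def align_oligo(
    oligo: OligoRecord, index: SeedIndex, params: ScreenParams
) -> list[AlignmentHit]:
    """Seed-and-extend one oligo against the indexed genome.

    Each exact seed fixes a gapless diagonal; all seeds on the same
    (chrom, strand, diagonal) collapse to a single full-length placement,
    which is scored in one pass. Hits meeting the retention criterion are
    returned best-first (matched_bases desc, then chrom, then start), at
    most max_hits_per_oligo of them.
    """
    seq = oligo.sequence
    L = len(seq)
    if L < params.min_match_bp:
        raise ValueError(
            f"oligo {oligo.oligo_id!r} shorter ({L}) than min_match_bp ({params.min_match_bp})"
        )
    k = index.k
    need = params.required_matches(L)

    fwd = _seq_bytes(seq)
    rev = _seq_bytes(reverse_complement(seq))
    codes = _CODE[fwd]
    keys, ok = _encode_kmers(codes, k)

    placements: set[tuple[int, int, int]] = set()  # (chrom_idx, strand_code, start)
    for q in np.nonzero(ok)[0]:
        for ci, p, s in index.lookup_encoded(keys[q]):
            if s == 0:
                start = int(p) - int(q)
            else:
                # oligo k-mer at offset q matches the minus strand at plus-pos p;
                # in the reverse complement of the oligo that k-mer sits at L-q-k
                start = int(p) - (L - int(q) - k)
            placements.add((int(ci), int(s), start))

    hits: list[AlignmentHit] = []
    for ci, s, start in placements:
        chrom = index.chrom_names[ci]
        oriented = fwd if s == 0 else rev
        matched, s0, s1 = _placement_matches(oriented, index.chrom_bytes[chrom], start)
        if matched >= need:
            hits.append(
                AlignmentHit(
                    oligo_id=oligo.oligo_id,
                    probe_set=oligo.probe_set,
                    chrom_name=chrom,
                    start=s0,
                    end=s1,
                    strand="+" if s == 0 else "-",
                    matched_bases=matched,
                    oligo_length=L,
                )
            )
    hits.sort(key=lambda h: (-h.matched_bases, h.chrom_name, h.start))
    return hits[: params.max_hits_per_oligo]


@dataclass
class AlignmentSet:
    """All retained hits of a library against a genome, plus provenance."""

    hits: list[AlignmentHit]
    params: ScreenParams
    genome_id: str
    library_id: str
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    probe_sets: list[str]
    probe_set_sizes: dict[str, int]

    def retained_per_set(self) -> dict[str, int]:
        """Number of oligos per probe set with at least one retained hit."""
        seen: dict[str, set[str]] = {s: set() for s in self.probe_sets}
        for h in self.hits:
            seen.setdefault(h.probe_set, set()).add(h.oligo_id)
        return {s: len(v) for s, v in seen.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (h.oligo_id, h.probe_set, h.chrom_name, h.start, h.end, h.strand,
                 h.matched_bases, h.oligo_length, round(h.identity, 6))
                for h in self.hits
            ],
            columns=["oligo_id", "probe_set", "chrom", "start", "end", "strand",
                     "matched_bases", "oligo_length", "identity"],
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write hits TSV plus a sidecar .meta.json with screen provenance."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {
            "genome_id": self.genome_id,
            "library_id": self.library_id,
            "chrom_names": self.chrom_names,
            "chrom_lengths": self.chrom_lengths,
            "probe_sets": self.probe_sets,
            "probe_set_sizes": self.probe_set_sizes,
            "params": self.params.to_dict(),
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlignmentSet":
        meta_path = Path(str(path) + ".meta.json")
        if not meta_path.exists():
            raise FormatError(f"missing sidecar metadata {meta_path}")
        meta = json.loads(meta_path.read_text())
        df = pd.read_csv(path, sep="\t")
        hits = [
            AlignmentHit(
                oligo_id=str(r.oligo_id), probe_set=str(r.probe_set),
                chrom_name=str(r.chrom), start=int(r.start), end=int(r.end),
                strand=str(r.strand), matched_bases=int(r.matched_bases),
                oligo_length=int(r.oligo_length),
            )
            for r in df.itertuples()
        ]
        return cls(
            hits=hits,
            params=ScreenParams(**meta["params"]),
            genome_id=meta["genome_id"],
            library_id=meta["library_id"],
            chrom_names=list(meta["chrom_names"]),
            chrom_lengths={k: int(v) for k, v in meta["chrom_lengths"].items()},
            probe_sets=list(meta["probe_sets"]),
            probe_set_sizes={k: int(v) for k, v in meta["probe_set_sizes"].items()},
        )

    def serialize(self) -> str:
        """Canonical text form; byte-identical for identical inputs."""
        return self.to_frame().to_csv(sep="\t", index=False)


def screen_library(
    library: OligoLibrary,
    genome: Genome,
    params: ScreenParams | None = None,
    index: SeedIndex | None = None,
) -> AlignmentSet:
    """Align every oligo in the library and keep retained hits.

    Deterministic for identical inputs: oligos are processed in library
    order and each oligo's hits are coordinate-sorted by align_oligo.
    """
    params = params or ScreenParams()
    if index is None:
        index = build_seed_index(genome, params.seed_k)
    elif index.k != params.seed_k:
        raise ValueError("provided index was built with a different seed_k")
    hits: list[AlignmentHit] = []
    for oligo in library:
        hits.extend(align_oligo(oligo, index, params))
    return AlignmentSet(
        hits=hits,
        params=params,
        genome_id=genome.genome_id,
        library_id=library.library_id,
        chrom_names=genome.chrom_names,
        chrom_lengths=genome.chrom_lengths,
        probe_sets=library.probe_sets,
        probe_set_sizes=library.set_sizes(),
    )
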