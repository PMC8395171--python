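"""Synthetic inputs with known ground truth.

The generator emulates the study system at desk scale: a reference
genome of 10 chromosomes (0.8–2.0 Mb), a 45-nt painting-oligo library
tiling each chromosome at 0.25 oligos/kb with a single-copy filter, a
diverged target genome (per-site substitutions at a scenario rate,
optionally with a tagged-segment translocation mimicking an rDNA-site
move), a polyploid chromosome complement (default 2n=60, x=10), and
noisy metaphase arm measurements over ~10 cells. Every simulated entity
is recorded in a truth log; divergence is substitution-only to stay
consistent with the ungapped screen.

Scenario labels map million-year divergences onto substitution rates
through a crude fixed clock (0.01 substitutions/site per MY); the labels
organize experiments and claim no evolutionary realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    Genome,
    GenomeSequence,
    MeasurementRecord,
    OligoLibrary,
    OligoRecord,
)
from .karyotype import Ploidy
from .screen import ScreenParams, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: rough desk clock tying scenario labels to substitution rates
CLOCK_SUBS_PER_SITE_PER_MY = 0.01


@dataclass(frozen=True)
class DivergenceScenario:
    """A named substitution rate, optionally labelled with a divergence time."""

    name: str
    subs_per_site: float
    label_my: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.subs_per_site <= 0.75):
            raise ValueError("subs_per_site must be in [0, 0.75]")

    @classmethod
    def from_my(cls, name: str, my: float) -> "DivergenceScenario":
        return cls(name, subs_per_site=my * CLOCK_SUBS_PER_SITE_PER_MY, label_my=my)


SCENARIOS = {
    "identity": DivergenceScenario("identity", 0.0),
    "sorghum-tripidium": DivergenceScenario.from_my("sorghum-tripidium", 9.0),
    "maize-sorghum": DivergenceScenario.from_my("maize-sorghum", 11.9),
    "maize-tripidium": DivergenceScenario.from_my("maize-tripidium", 18.0),
}


@dataclass(frozen=True)
class Translocation:
    """Move [start, end) of source_chrom into dest_chrom at dest_pos."""

    source_chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_pos: int
    tag: str = ""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study system (see module docstring)."""

    seed: int
    n_chrom: int = 10
    chrom_lengths_bp: tuple[int, ...] | None = None
    oligo_len_nt: int = 45
    oligo_density_per_kb: float = 0.25
    scenario: DivergenceScenario = SCENARIOS["sorghum-tripidium"]
    ploidy: Ploidy = Ploidy(60, 10)
    per_copy_jitter_rate: float = 0.02
    measurement_noise_sd_um: float = 0.15
    n_cells: int = 10
    missing_copy_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.oligo_len_nt < 20:
            raise ValueError("n_chrom must be >= 1 and oligo_len_nt >= 20")
        if self.oligo_density_per_kb <= 0:
            raise ValueError("oligo density must be positive")
        lengths = self.lengths()
        if min(lengths) < self.oligo_len_nt:
            raise ValueError("chromosomes shorter than the oligo length")
        if min(lengths) * self.oligo_density_per_kb / 1000 < 1:
            raise ValueError("density x length must yield >= 1 oligo per chromosome")

    def lengths(self) -> tuple[int, ...]:
        if self.chrom_lengths_bp is not None:
            return tuple(self.chrom_lengths_bp)
        # longest chromosome first, like a real karyotype
        return tuple(
            int(round(x))
            for x in np.linspace(2_000_000, 800_000, self.n_chrom)
        )


class TruthLog:
    """Ground truth of every simulated entity, serializable to JSON."""

    def __init__(self) -> None:
        self.oligos: dict[str, dict] = {}
        self.chromosomes: dict[str, dict] = {}
        self.rearrangements: list[dict] = []
        self.rdna: dict[str, dict] = {}
        self.arms: dict[str, dict] = {}

    def to_dict(self) -> dict:
        return {
            "oligos": self.oligos,
            "chromosomes": self.chromosomes,
            "rearrangements": self.rearrangements,
            "rdna": self.rdna,
            "arms": self.arms,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLog":
        data = json.loads(Path(path).read_text())
        log = cls()
        log.oligos = data["oligos"]
        log.chromosomes = data["chromosomes"]
        log.rearrangements = data["rearrangements"]
        log.rdna = data["rdna"]
        log.arms = data["arms"]
        return log


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_reference_genome(config: SimulationConfig) -> tuple[Genome, TruthLog]:
    """I.i.d. uniform-base chromosomes, with tagged rDNA-analog intervals.

    The 5S analog sits pericentromerically on the chr9 analog and the 35S
    analog distally on the chr6 analog (tags only; the underlying sequence
    is ordinary random DNA).
    """
    rng = np.random.default_rng(config.seed)
    log = TruthLog()
    chroms = []
    for i, length in enumerate(config.lengths(), start=1):
        name = f"chr{i}"
        chroms.append(GenomeSequence(name, _random_sequence(rng, length)))
        log.chromosomes[name] = {"role": "reference", "length_bp": length}
    genome = Genome(chroms, genome_id=f"ref-seed{config.seed}")
    site = max(2000, min(l for l in config.lengths()) // 100)
    if config.n_chrom >= 9:
        mid = genome["chr9"].length_bp // 2
        log.rdna["5S"] = {"chrom": "chr9", "start": mid, "end": mid + site}
    if config.n_chrom >= 6:
        L6 = genome["chr6"].length_bp
        log.rdna["35S"] = {"chrom": "chr6", "start": L6 - 2 * site, "end": L6 - site}
    return genome, log


def design_oligo_library(
    genome: Genome, config: SimulationConfig
) -> tuple[OligoLibrary, TruthLog]:
    """Evenly spaced oligos per chromosome, single-copy filtered.

    One probe set per source chromosome (CP1..CPn). Oligos whose sequence
    occurs more than once in the genome (either strand) are replaced by a
    nearby start within the same spacing interval; if no single-copy
    replacement exists the achieved density is reported in the error.
    """
    m = config.oligo_len_nt
    if m > min(c.length_bp for c in genome):
        raise ValueError("oligo length exceeds the shortest chromosome")
    spacing = max(m, int(round(1000 / config.oligo_density_per_kb)))
    candidates: list[tuple[str, str, int]] = []  # (probe_set, chrom, start)
    for i, chrom in enumerate(genome, start=1):
        for start in range(0, chrom.length_bp - m + 1, spacing):
            candidates.append((f"CP{i}", chrom.chrom_name, start))

    # one pass over every genomic window counts candidate occurrences
    def occurrence_counts(seqs: set[str]) -> dict[str, int]:
        counts = {s: 0 for s in seqs}
        for chrom in genome:
            s = chrom.sequence
            for i in range(chrom.length_bp - m + 1):
                sub = s[i : i + m]
                if sub in counts:
                    counts[sub] += 1
        return counts

    cand_seqs: list[str] = [
        genome[chrom].sequence[start : start + m] for _, chrom, start in candidates
    ]
    probe = set(cand_seqs) | {reverse_complement(s) for s in cand_seqs}
    counts = occurrence_counts(probe)

    def copies(seq: str) -> int:
        return counts.get(seq, 0) + counts.get(reverse_complement(seq), 0)

    records: list[OligoRecord] = []
    log = TruthLog()
    n_requested = len(candidates)
    per_set_index: dict[str, int] = {}
    whole = {c.chrom_name: c.sequence for c in genome}
    for probe_set, chrom, start in candidates:
        seq = whole[chrom][start : start + m]
        chosen_start = start
        if copies(seq) > 1 or "N" in seq:
            chosen_start = None
            for off in range(m, spacing, m):  # local resampling within the interval
                alt_start = start + off
                if alt_start + m > len(whole[chrom]):
                    break
                alt = whole[chrom][alt_start : alt_start + m]
                total = sum(whole[c].count(alt) + whole[c].count(reverse_complement(alt))
                            for c in whole)
                if total == 1 and "N" not in alt:
                    chosen_start, seq = alt_start, alt
                    break
            if chosen_start is None:
                achieved = len(records) / (sum(c.length_bp for c in genome) / 1000)
                raise ValueError(
                    f"single-copy density unachievable near {chrom}:{start} "
                    f"(achieved {achieved:.4f} oligos/kb of {config.oligo_density_per_kb})"
                )
        j = per_set_index.get(probe_set, 0) + 1
        per_set_index[probe_set] = j
        oligo_id = f"{probe_set}_{j:05d}"
        records.append(OligoRecord(oligo_id, probe_set, seq))
        log.oligos[oligo_id] = {"chrom": chrom, "start": chosen_start}
    assert len(records) == n_requested
    return OligoLibrary(records, library_id=f"oligos-{genome.genome_id}"), log


def diverge_genome(
    genome: Genome,
    scenario: DivergenceScenario,
    rearrangements: list[Translocation] | None = None,
    seed: int = 0,
    name_prefix: str = "t",
) -> tuple[Genome, TruthLog]:
    """Per-site independent substitution at the scenario rate, then
    optional translocations of tagged segments.

    Target chromosomes are renamed with ``name_prefix`` and their source
    chromosome recorded in the truth log.
    """
    rng = np.random.default_rng(seed)
    rearrangements = list(rearrangements or [])
    intervals: dict[str, list[tuple[int, int]]] = {}
    for r in rearrangements:
        for (a, b) in intervals.get(r.source_chrom, []):
            if r.start < b and a < r.end:
                raise ValueError(f"overlapping rearrangement intervals on {r.source_chrom}")
        intervals.setdefault(r.source_chrom, []).append((r.start, r.end))

    log = TruthLog()
    mutated: dict[str, str] = {}
    for chrom in genome:
        arr = np.frombuffer(chrom.sequence.encode("ascii"), dtype=np.uint8).copy()
        codes = _CODE[arr]
        valid = codes != 255
        hit = (rng.random(len(arr)) < scenario.subs_per_site) & valid
        n_subs = int(hit.sum())
        if n_subs:
            shift = rng.integers(1, 4, size=n_subs).astype(np.uint8)
            codes_hit = (codes[hit] + shift) % 4
            arr[hit] = _BASES[codes_hit]
        new_name = f"{name_prefix}{chrom.chrom_name}"
        mutated[new_name] = arr.tobytes().decode("ascii")
        log.chromosomes[new_name] = {
            "source": chrom.chrom_name,
            "subs_per_site": scenario.subs_per_site,
            "n_substitutions": n_subs,
            "scenario": scenario.name,
        }

    for r in rearrangements:
        src = f"{name_prefix}{r.source_chrom}"
        dst = f"{name_prefix}{r.dest_chrom}"
        segment = mutated[src][r.start : r.end]
        mutated[src] = mutated[src][: r.start] + mutated[src][r.end :]
        dest_pos = min(r.dest_pos, len(mutated[dst]))
        mutated[dst] = mutated[dst][:dest_pos] + segment + mutated[dst][dest_pos:]
        log.rearrangements.append(
            {
                "type": "translocation",
                "tag": r.tag,
                "source": {"chrom": src, "start": r.start, "end": r.end},
                "dest": {"chrom": dst, "start": dest_pos, "end": dest_pos + len(segment)},
            }
        )
        if r.tag in ("5S", "35S"):
            log.rdna[r.tag] = {"chrom": dst, "start": dest_pos, "end": dest_pos + len(segment)}

    target = Genome(
        [GenomeSequence(f"{name_prefix}{c.chrom_name}", mutated[f"{name_prefix}{c.chrom_name}"]) for c in genome],
        genome_id=f"{genome.genome_id}-{scenario.name}-seed{seed}",
    )
    return target, log


def polyploidize(
    genome: Genome,
    ploidy: Ploidy,
    per_copy_jitter_rate: float = 0.02,
    seed: int = 0,
) -> tuple[Genome, TruthLog]:
    """Expand each basic chromosome into ploidy_level jittered copies.

    Copies carry independent low-rate substitutions emulating sub-genome
    differentiation; chromosome count equals 2n.
    """
    if len(genome) != ploidy.x_basic:
        raise ValueError(
            f"genome has {len(genome)} chromosomes but basic number is x={ploidy.x_basic}"
        )
    log = TruthLog()
    copies: list[GenomeSequence] = []
    jitter = DivergenceScenario("copy-jitter", per_copy_jitter_rate)
    for c, copy_idx in [(c, i) for c in genome for i in range(1, ploidy.ploidy_level + 1)]:
        sub, _ = diverge_genome(
            Genome([c], genome_id="tmp"), jitter,
            seed=seed + 1009 * copy_idx + 9176 * genome.chrom_names.index(c.chrom_name),
            name_prefix="",
        )
        name = f"{c.chrom_name}_h{copy_idx}"
        copies.append(GenomeSequence(name, sub.chromosomes[0].sequence))
        log.chromosomes[name] = {
            "source": c.chrom_name,
            "homoeologous_group": c.chrom_name,
            "copy": copy_idx,
            "jitter_rate": per_copy_jitter_rate,
        }
    return Genome(copies, genome_id=f"{genome.genome_id}-{ploidy.two_n}x"), log


def simulate_measurements(
    true_arms: dict[str, tuple[float, float]],
    noise_sd_um: float = 0.15,
    n_cells: int = 10,
    copies_per_cell: int = 6,
    missing_copy_rate: float = 0.0,
    seed: int = 0,
) -> list[MeasurementRecord]:
    """Noisy per-cell, per-homolog arm measurements.

    Arms are truth plus independent Gaussian noise, redrawn while
    non-positive (truncation); copies drop out independently at
    missing_copy_rate (at least one copy per chromosome per cell is kept
    so every cell contributes to every chromosome); long/short ordering
    is enforced after noise, as a measurer would.
    """
    if noise_sd_um < 0:
        raise ValueError("noise_sd_um must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[MeasurementRecord] = []
    for cell in range(1, n_cells + 1):
        cell_id = f"cell{cell:02d}"
        for label, (long_true, short_true) in sorted(true_arms.items()):
            kept = [
                c for c in range(copies_per_cell)
                if rng.random() >= missing_copy_rate
            ] or [0]
            for _ in kept:
                long_um = _truncated_normal(rng, long_true, noise_sd_um)
                short_um = _truncated_normal(rng, short_true, noise_sd_um)
                if short_um > long_um:
                    long_um, short_um = short_um, long_um
                records.append(MeasurementRecord(cell_id, label, long_um, short_um))
    return records


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("could not draw a positive arm length; check noise_sd")


PRESETS = ("sorghum-like", "tripidium-like")


def generate_preset(
    preset: str, seed: int, length_scale: float = 0.1
) -> dict:
    """Generate the full input bundle for a named study scenario.

    ``sorghum-like``: reference genome + library + a moderately diverged
    diploid-style target (one copy per chromosome). ``tripidium-like``:
    a further-diverged target carrying the 5S-analog translocation from
    the chr9 analog to the chr5 analog, expanded to a hexaploid
    complement (2n=60, x=10), plus noisy arm measurements.
    ``length_scale`` shrinks the default 0.8-2.0 Mb chromosomes for quick
    runs. Returns genomes, library, measurements, truth log and
    recommended signal thresholds for the scale.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    base_lengths = tuple(
        max(int(round(x * length_scale)), 50_000)
        for x in np.linspace(2_000_000, 800_000, 10)
    )
    config = SimulationConfig(seed=seed, chrom_lengths_bp=base_lengths)
    reference, truth = simulate_reference_genome(config)
    library, lib_truth = design_oligo_library(reference, config)
    truth.oligos = lib_truth.oligos

    # desk-scale signal thresholds: fractions of the smallest probe set,
    # mirroring the candidate/confident roles of the full-scale 1000/3000
    min_set = min(library.set_sizes().values())
    thresholds = {
        "candidate_min": max(2, math.ceil(0.10 * min_set)),
        "confident_min": max(3, math.ceil(0.30 * min_set)),
    }
    # a 16-bp exact seed misses many diverged-but-retained loci (no clean
    # 16-run survives ~20% substitution); cross-species screens seed at 10
    screen_params = ScreenParams(seed_k=10)

    if preset == "sorghum-like":
        scenario = SCENARIOS["maize-sorghum"]
        target, tgt_truth = diverge_genome(reference, scenario, seed=seed + 1)
    else:
        scenario = SCENARIOS["maize-tripidium"]
        rdna_5s = truth.rdna["5S"]
        dest_pos = reference["chr5"].length_bp // 2
        trans = Translocation(
            source_chrom=rdna_5s["chrom"], start=rdna_5s["start"], end=rdna_5s["end"],
            dest_chrom="chr5", dest_pos=dest_pos, tag="5S",
        )
        diverged, tgt_truth = diverge_genome(
            reference, scenario, rearrangements=[trans], seed=seed + 1
        )
        target, poly_truth = polyploidize(
            diverged, config.ploidy, config.per_copy_jitter_rate, seed=seed + 2
        )
        tgt_truth.chromosomes.update(poly_truth.chromosomes)
    truth.chromosomes.update(tgt_truth.chromosomes)
    truth.rearrangements.extend(tgt_truth.rearrangements)
    # rDNA truth: reference coordinates, plus where each site sits on the
    # target (renamed, and relocated if a translocation moved it)
    target_rdna = {
        tag: {**entry, "chrom": f"t{entry['chrom']}"} for tag, entry in truth.rdna.items()
    }
    target_rdna.update(tgt_truth.rdna)
    truth.rdna = {"reference": dict(truth.rdna), "target": target_rdna}

    from .datasets import karyotype_true_arms

    true_arms = karyotype_true_arms()
    truth.arms = {k: {"long_um": v[0], "short_um": v[1]} for k, v in true_arms.items()}
    measurements = simulate_measurements(
        true_arms,
        noise_sd_um=config.measurement_noise_sd_um,
        n_cells=config.n_cells,
        copies_per_cell=config.ploidy.ploidy_level,
        missing_copy_rate=config.missing_copy_rate,
        seed=seed + 3,
    )
    return {
        "preset": preset,
        "config": config,
        "scenario": scenario,
        "reference": reference,
        "library": library,
        "target": target,
        "measurements": measurements,
        "truth": truth,
        "thresholds": thresholds,
        "screen_params": screen_params,
    }


def write_preset_inputs(bundle: dict, outdir: str | Path) -> dict[str, Path]:
    """Write a generated bundle to disk (FASTA/TSV/JSON); returns paths."""
    from .io_formats import write_genome_fasta, write_measurements, write_oligo_library

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "library": outdir / "library.fa",
        "target": outdir / "target.fa",
        "measurements": outdir / "measurements.tsv",
        "truth": outdir / "truth.json",
    }
    write_genome_fasta(bundle["reference"], paths["reference"])
    write_oligo_library(bundle["library"], paths["library"])
    write_genome_fasta(bundle["target"], paths["target"])
    write_measurements(bundle["measurements"], paths["measurements"])
    bundle["truth"].to_json(paths["truth"])
    return paths


def retention_fraction_at_truth(
    library: OligoLibrary,
    target: Genome,
    truth: TruthLog,
    target_truth: TruthLog,
    params: ScreenParams | None = None,
) -> float:
    """Fraction of oligos meeting the retention rule at their true locus.

    Applies the matched-bases criterion directly at the truth-log position
    of each oligo on the (unrearranged) diverged target; this is the
    rule's own retention probability, free of seeding heuristics, and is
    what the binomial closed form predicts.
    """
    params = params or ScreenParams()
    source_to_target = {
        info["source"]: name for name, info in target_truth.chromosomes.items()
    }
    retained = 0
    for oligo in library:
        entry = truth.oligos[oligo.oligo_id]
        tchrom = source_to_target[entry["chrom"]]
        start = entry["start"]
        segment = target[tchrom].sequence[start : start + oligo.length]
        matched = sum(1 for a, b in zip(oligo.sequence, segment) if a == b and a != "N")
        if matched >= params.required_matches(oligo.length):
            retained += 1
    return retained / len(library)
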