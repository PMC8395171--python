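"""Karyotype tables, centromere classification, reference naming, idiograms.

Arm measurements from metaphase cells are summarized per chromosome:
homolog copies are averaged within each cell first (cells may miss a
copy, so per-cell homolog means keep cells comparable), then means and
sample SDs are taken across cells. The arm ratio is the mean of per-cell
long/short ratios, not the ratio of mean arms — the two differ in the
second decimal and published tables are only consistent with per-cell
averaging. Centromere position follows the classical arm-ratio
convention: metacentric up to 1.7, submetacentric up to 3.0,
subtelocentric up to 7.0, telocentric beyond.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io_formats import MeasurementRecord
from .signals import SignalCall, barcode_chromosomes

#: classical arm-ratio class boundaries (upper bounds, inclusive)
DEFAULT_CLASS_BOUNDARIES = (1.7, 3.0, 7.0)
CENTROMERE_CLASSES = ("m", "sm", "st", "t")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Ploidy:
    """Somatic chromosome number and basic number, e.g. 2n=60, x=10."""

    two_n: int
    x_basic: int

    def __post_init__(self) -> None:
        if self.two_n <= 0 or self.x_basic <= 0:
            raise ValueError("chromosome numbers must be positive")
        if self.two_n % self.x_basic != 0:
            raise ValueError(f"2n={self.two_n} is not divisible by x={self.x_basic}")

    @property
    def ploidy_level(self) -> int:
        return self.two_n // self.x_basic


def classify_centromere(
    ratio: float, boundaries: tuple[float, float, float] = DEFAULT_CLASS_BOUNDARIES
) -> str:
    """Centromere class from the long/short arm ratio (boundaries inclusive)."""
    if ratio < 1:
        raise ValueError(f"arm ratio {ratio} < 1; arms must be ordered long/short")
    m_max, sm_max, st_max = boundaries
    if ratio <= m_max:
        return "m"
    if ratio <= sm_max:
        return "sm"
    if ratio <= st_max:
        return "st"
    return "t"


@dataclass(frozen=True)
class KaryotypeRow:
    """Per-chromosome summary statistics over measured cells (unrounded)."""

    chrom_label: str
    n_cells: int
    long_mean: float
    long_sd: float
    short_mean: float
    short_sd: float
    total_mean: float
    total_sd: float
    ratio_mean: float
    ratio_sd: float
    centromere_class: str


def summarize_karyotype(
    measurements: list[MeasurementRecord],
    ploidy: Ploidy | None = None,
    expected_labels: list[str] | None = None,
    boundaries: tuple[float, float, float] = DEFAULT_CLASS_BOUNDARIES,
) -> list[KaryotypeRow]:
    """Summarize arm measurements into karyotype rows.

    Per cell and chromosome label, homolog copies are averaged; per-cell
    total (long+short) and ratio (long/short) are then summarized across
    cells by mean and sample SD (SD is 0 for a single cell). Rows are
    returned in label order. ``expected_labels`` (or, with ``ploidy``, a
    check that at most x distinct labels occur) guards against typos.
    """
    if not measurements:
        raise ValueError("no measurements")
    if expected_labels is not None:
        unknown = sorted({m.chrom_label for m in measurements} - set(expected_labels))
        if unknown:
            raise ValueError(f"unknown chromosome labels {unknown}")
    labels = sorted({m.chrom_label for m in measurements})
    if ploidy is not None and len(labels) > ploidy.x_basic:
        raise ValueError(
            f"{len(labels)} distinct chromosome labels exceed basic number x={ploidy.x_basic}"
        )

    per_cell: dict[str, dict[str, list[MeasurementRecord]]] = {}
    for m in measurements:
        per_cell.setdefault(m.chrom_label, {}).setdefault(m.cell_id, []).append(m)

    def mean_sd(values: list[float]) -> tuple[float, float]:
        mu = statistics.fmean(values)
        sd = statistics.stdev(values) if len(values) > 1 else 0.0
        return mu, sd

    rows = []
    for label in labels:
        longs, shorts, totals, ratios = [], [], [], []
        for cell_id in sorted(per_cell[label]):
            copies = per_cell[label][cell_id]
            long_um = statistics.fmean(c.long_arm_um for c in copies)
            short_um = statistics.fmean(c.short_arm_um for c in copies)
            longs.append(long_um)
            shorts.append(short_um)
            totals.append(long_um + short_um)
            ratios.append(long_um / short_um)
        long_mean, long_sd = mean_sd(longs)
        short_mean, short_sd = mean_sd(shorts)
        total_mean, total_sd = mean_sd(totals)
        ratio_mean, ratio_sd = mean_sd(ratios)
        rows.append(
            KaryotypeRow(
                chrom_label=label,
                n_cells=len(longs),
                long_mean=long_mean, long_sd=long_sd,
                short_mean=short_mean, short_sd=short_sd,
                total_mean=total_mean, total_sd=total_sd,
                ratio_mean=ratio_mean, ratio_sd=ratio_sd,
                centromere_class=classify_centromere(ratio_mean, boundaries),
            )
        )
    return rows


def karyotype_table(rows: list[KaryotypeRow], ndigits: int = 2) -> pd.DataFrame:
    """Rounded (half-up) presentation table, one row per chromosome."""
    return pd.DataFrame(
        [
            {
                "chrom_label": r.chrom_label,
                "n_cells": r.n_cells,
                "long_mean": round_half_up(r.long_mean, ndigits),
                "long_sd": round_half_up(r.long_sd, ndigits),
                "short_mean": round_half_up(r.short_mean, ndigits),
                "short_sd": round_half_up(r.short_sd, ndigits),
                "total_mean": round_half_up(r.total_mean, ndigits),
                "total_sd": round_half_up(r.total_sd, ndigits),
                "ratio_mean": round_half_up(r.ratio_mean, ndigits),
                "ratio_sd": round_half_up(r.ratio_sd, ndigits),
                "centromere_class": r.centromere_class,
            }
            for r in rows
        ]
    ).set_index("chrom_label")


# ---------------------------------------------------------------------------
# Reference naming by barcode matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssignmentResult:
    """Mapping of target chromosomes onto reference numbering.

    ``mapping`` holds exact unique barcode matches; ``unassigned`` are
    targets with no match (including all-zero barcodes); ``ambiguous``
    are targets matching several reference chromosomes. ``shared`` lists
    reference chromosomes claimed by more than one target — expected for
    homoeologous groups of a polyploid, flagged rather than hidden.
    """

    mapping: dict[str, str]
    unassigned: tuple[str, ...]
    ambiguous: dict[str, tuple[str, ...]]
    shared: dict[str, tuple[str, ...]]


def assign_reference_numbers(
    target_calls: SignalCall,
    reference_calls: SignalCall,
    min_level: str = "uncertain",
) -> AssignmentResult:
    """Name target chromosomes after reference chromosomes by exact
    binary-barcode match over the shared probe rows.

    Nothing is assigned silently: no-match and multi-match targets are
    reported, as are reference numbers claimed by several targets.
    """
    probes = list(target_calls.probe_sets)
    if probes != list(reference_calls.probe_sets):
        raise ValueError("target and reference calls must share the same probe rows")
    tgt = barcode_chromosomes(target_calls, probes, min_level=min_level)
    ref = barcode_chromosomes(reference_calls, probes, min_level=min_level)
    zero = tuple([0] * len(probes))
    by_code: dict[tuple[int, ...], list[str]] = {}
    for chrom, code in ref.barcodes.items():
        by_code.setdefault(code, []).append(chrom)

    mapping: dict[str, str] = {}
    unassigned: list[str] = []
    ambiguous: dict[str, tuple[str, ...]] = {}
    for chrom, code in tgt.barcodes.items():
        if code == zero:
            unassigned.append(chrom)
            continue
        matches = sorted(by_code.get(code, []))
        if not matches:
            unassigned.append(chrom)
        elif len(matches) > 1:
            ambiguous[chrom] = tuple(matches)
        else:
            mapping[chrom] = matches[0]
    claimed: dict[str, list[str]] = {}
    for t, r in mapping.items():
        claimed.setdefault(r, []).append(t)
    shared = {r: tuple(sorted(ts)) for r, ts in claimed.items() if len(ts) > 1}
    return AssignmentResult(
        mapping=mapping,
        unassigned=tuple(sorted(unassigned)),
        ambiguous=ambiguous,
        shared=shared,
    )


# ---------------------------------------------------------------------------
# Idiogram
# ---------------------------------------------------------------------------

ANNOTATION_REGIONS = ("whole", "distal-long", "distal-short", "pericentromeric")


@dataclass(frozen=True)
class IdiogramAnnotation:
    """A probe (or marker) drawn on one chromosome of the idiogram."""

    chrom_label: str
    probe: str
    color: str
    region: str = "whole"

    def __post_init__(self) -> None:
        if self.region not in ANNOTATION_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class Idiogram:
    """Scaled schematic of the karyotype with annotation tracks.

    Bars are ordered by chromosome label, lengths proportional to mean
    total length, centromere drawn at the long/short arm boundary (short
    arm on top, following idiogram convention).
    """

    rows: list[KaryotypeRow]
    annotations: list[IdiogramAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty karyotype")
        labels = {r.chrom_label for r in self.rows}
        for ann in self.annotations:
            if ann.chrom_label not in labels:
                raise ValueError(f"annotation references missing chromosome {ann.chrom_label!r}")

    def to_dict(self) -> dict:
        return {
            "chromosomes": [
                {
                    "chrom_label": r.chrom_label,
                    "total_um": round_half_up(r.total_mean, 4),
                    "short_um": round_half_up(r.short_mean, 4),
                    "long_um": round_half_up(r.long_mean, 4),
                    "arm_ratio": round_half_up(r.ratio_mean, 4),
                    "centromere_class": r.centromere_class,
                }
                for r in self.rows
            ],
            "annotations": [
                {
                    "chrom_label": a.chrom_label,
                    "probe": a.probe,
                    "color": a.color,
                    "region": a.region,
                }
                for a in self.annotations
            ],
        }

    def to_svg(self, um_to_px: float = 60.0, bar_width: int = 26, gap: int = 30) -> str:
        """Deterministic standalone SVG of the idiogram."""
        rows = self.rows
        max_total = max(r.total_mean for r in rows)
        height = int(max_total * um_to_px) + 70
        width = len(rows) * (bar_width + gap) + gap
        parts = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
            f'viewBox="0 0 {width} {height}">',
            '<rect width="100%" height="100%" fill="white"/>',
        ]
        top_margin = 20
        for i, r in enumerate(rows):
            x = gap + i * (bar_width + gap)
            bar_h = r.total_mean * um_to_px
            short_h = r.short_mean * um_to_px
            y0 = top_margin + (max_total * um_to_px - bar_h)  # bottom-aligned
            cen_y = y0 + short_h
            parts.append(
                f'<rect x="{x}" y="{y0:.1f}" width="{bar_width}" height="{bar_h:.1f}" '
                'rx="8" fill="#d9d9d9" stroke="black"/>'
            )
            parts.append(
                f'<line x1="{x - 3}" y1="{cen_y:.1f}" x2="{x + bar_width + 3}" '
                f'y2="{cen_y:.1f}" stroke="black" stroke-width="3"/>'
            )
            for ann in [a for a in self.annotations if a.chrom_label == r.chrom_label]:
                if ann.region == "whole":
                    ay, ah = y0, bar_h
                elif ann.region == "distal-long":
                    ay, ah = y0 + bar_h - 0.25 * bar_h, 0.25 * bar_h
                elif ann.region == "distal-short":
                    ay, ah = y0, 0.25 * short_h
                else:  # pericentromeric
                    ay, ah = cen_y - 0.1 * bar_h, 0.2 * bar_h
                parts.append(
                    f'<rect x="{x + 4}" y="{ay:.1f}" width="{bar_width - 8}" '
                    f'height="{ah:.1f}" fill="{ann.color}" fill-opacity="0.65">'
                    f"<title>{ann.probe}</title></rect>"
                )
            parts.append(
                f'<text x="{x + bar_width / 2:.1f}" y="{height - 12}" font-size="12" '
                f'text-anchor="middle" font-family="sans-serif">{r.chrom_label}</text>'
            )
        parts.append("</svg>")
        return "\n".join(parts) + "\n"


def build_idiogram(
    karyotype: list[KaryotypeRow],
    annotations: list[IdiogramAnnotation] | None = None,
) -> Idiogram:
    """Assemble an idiogram, chromosomes ordered by label."""
    ordered = sorted(karyotype, key=lambda r: _label_key(r.chrom_label))
    return Idiogram(rows=ordered, annotations=list(annotations or []))


def _label_key(label: str):
    """Sort 'Chr.10' after 'Chr.9': trailing integers compare numerically."""
    digits = ""
    for ch in reversed(label):
        if ch.isdigit():
            digits = ch + digits
        else:
            break
    if digits:
        return (label[: len(label) - len(digits)], int(digits))
    return (label, -1)
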