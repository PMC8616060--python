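"""Named-region bookkeeping and feature-density arithmetic.

Covers three small but load-bearing calculations: region lengths in Mb from
genomic border coordinates, feature densities (genes/Mb, ORC sites/Mb) under
an explicit counting rule, and the eight-level RPKM expression binning used to
summarise per-tissue gene activity.

Region partition files store 1-based inclusive coordinates (the FlyBase
convention in which border positions are usually quoted); they are converted
to the package's internal 0-based half-open form on load.  Borders that have
never been determined are written as ``?`` and load as regions without an
interval rather than invented coordinates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .intervals import FormatError, GenomicInterval

__all__ = [
    "NamedRegion",
    "DensityReport",
    "ExpressionCategory",
    "region_length_mb",
    "feature_density",
    "density_ratio",
    "classify_expression",
    "expression_profile",
    "load_region_partition",
    "save_region_partition",
    "default_region_partition",
]


@dataclass(frozen=True)
class NamedRegion:
    """A named genomic region, optionally flanked by named markers.

    ``interval`` is ``None`` for regions whose border coordinates are unknown;
    such regions take part in bookkeeping but not in density arithmetic.
    """

    name: str
    interval: GenomicInterval | None
    markers: tuple[str, str] | None = None

    @property
    def length_mb(self) -> float:
        if self.interval is None:
            raise ValueError(f"region {self.name!r} has unknown coordinates")
        return region_length_mb(self.interval.start, self.interval.end)


@dataclass(frozen=True)
class DensityReport:
    """Feature count and per-Mb density for one region."""

    region: NamedRegion
    length_mb: float
    feature_count: int
    density_per_mb: float

    def __post_init__(self):
        if self.length_mb <= 0:
            raise ValueError("length_mb must be positive")
        if self.feature_count < 0:
            raise ValueError("feature_count must be non-negative")
        if abs(self.density_per_mb * self.length_mb - self.feature_count) > 0.5:
            raise ValueError("density, length and count are inconsistent")

    @property
    def display_density(self) -> float:
        """Report-style rounding: one decimal below 15, nearest integer above."""
        return round(self.density_per_mb, 1) if self.density_per_mb < 15 \
            else float(round(self.density_per_mb))

    @classmethod
    def from_counts(cls, name: str, feature_count: int, length_mb: float,
                    interval: GenomicInterval | None = None) -> "DensityReport":
        """Literature-style worked example: count and length given directly."""
        if length_mb <= 0:
            raise ValueError("length_mb must be positive")
        return cls(NamedRegion(name, interval), float(length_mb),
                   int(feature_count), feature_count / length_mb)


def region_length_mb(start: int, end: int) -> float:
    """(end - start) / 1e6 at full precision; rounding is display-only."""
    if end <= start:
        raise ValueError(f"empty or inverted region: start={start}, end={end}")
    return (end - start) / 1e6


_COUNTING_RULES = ("start_in", "midpoint_in", "any_overlap")


def feature_density(features: list[GenomicInterval], region: NamedRegion,
                    counting_rule: str = "start_in") -> DensityReport:
    """Count features in a region under a rule and report count / length_mb.

    ``start_in`` (default) counts a feature where its start coordinate lies,
    so a genome partition counts every feature exactly once; ``midpoint_in``
    uses the feature midpoint; ``any_overlap`` counts every overlapping
    feature and can exceed the other two.
    """
    if counting_rule not in _COUNTING_RULES:
        raise ValueError(f"unknown counting rule {counting_rule!r}")
    iv = region.interval
    if iv is None:
        raise ValueError(f"region {region.name!r} has unknown coordinates")
    count = 0
    for f in features:
        if f.chrom != iv.chrom:
            continue
        if counting_rule == "start_in":
            hit = iv.start <= f.start < iv.end
        elif counting_rule == "midpoint_in":
            hit = iv.start <= (f.start + f.end) // 2 < iv.end
        else:
            hit = f.start < iv.end and f.end > iv.start
        count += hit
    length = region.length_mb
    return DensityReport(region, length, count, count / length)


def density_ratio(a: DensityReport, b: DensityReport) -> float:
    """How many times denser region ``a`` is than region ``b``."""
    if b.density_per_mb <= 0:
        raise ValueError("denominator density must be positive")
    return a.density_per_mb / b.density_per_mb


class ExpressionCategory(enum.IntEnum):
    """Eight ordered RPKM activity levels (low to high)."""

    ExtremelyLowNone = 0
    VeryLow = 1
    Low = 2
    Moderate = 3
    ModerateHigh = 4
    High = 5
    VeryHigh = 6
    ExtremelyHigh = 7


#: Lower RPKM edge of each category above ExtremelyLowNone, in category order.
#: Nominal bins are 0, 1-3, 4-10, 11-25, 26-50, 51-100, 101-1000, >1000;
#: fractional values in a gap (e.g. 3.5) join the category just below the gap.
_EDGES = np.array([1.0, 4.0, 11.0, 26.0, 51.0, 101.0])
_TOP = 1000.0


def classify_expression(rpkm: float) -> ExpressionCategory:
    """Map an RPKM value to its expression category (total and monotone)."""
    rpkm = float(rpkm)
    if not np.isfinite(rpkm) or rpkm < 0:
        raise ValueError(f"rpkm must be finite and >= 0, got {rpkm}")
    if rpkm > _TOP:
        return ExpressionCategory.ExtremelyHigh
    return ExpressionCategory(int(np.searchsorted(_EDGES, rpkm, side="right")))


def expression_profile(rpkm_by_tissue, n_tissues: int = 29
                       ) -> dict[ExpressionCategory, int]:
    """Tally a gene's per-tissue RPKM vector into expression categories.

    The tallies always sum to ``n_tissues``; every category appears in the
    result, possibly with a zero count.
    """
    values = np.asarray(rpkm_by_tissue, dtype=float)
    if values.size != n_tissues:
        raise ValueError(f"expected {n_tissues} tissues, got {values.size}")
    counts = {cat: 0 for cat in ExpressionCategory}
    for v in values:
        counts[classify_expression(v)] += 1
    return counts


# -- region partition I/O ---------------------------------------------------

_PARTITION_HEADER = ["name", "chrom", "start", "end", "markers"]


def load_region_partition(path, warn=None) -> list[NamedRegion]:
    """Load a TSV region partition (1-based inclusive coordinates, ``?`` = unknown).

    Overlapping regions trigger ``warn`` (default: ``warnings.warn``) rather
    than an error — adjacent zones in a partition may legitimately abut or
    overlap by a border base.
    """
    import warnings

    if warn is None:
        warn = lambda msg: warnings.warn(msg, stacklevel=3)
    regions: list[NamedRegion] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(path, lineno, f"expected >=4 columns, got {len(fields)}")
            name, chrom, raw_start, raw_end = fields[:4]
            markers = None
            if len(fields) > 4 and fields[4] not in ("", "?"):
                parts = fields[4].split(",")
                if len(parts) == 2:
                    markers = (parts[0], parts[1])
                else:
                    raise FormatError(path, lineno, "markers must be two comma-separated names")
            if "?" in (chrom, raw_start, raw_end):
                regions.append(NamedRegion(name, None, markers))
                continue
            try:
                start_1, end_1 = int(raw_start.replace(",", "")), int(raw_end.replace(",", ""))
            except ValueError:
                raise FormatError(path, lineno, "coordinates are not integers") from None
            if end_1 < start_1:
                raise FormatError(path, lineno, f"end {end_1} before start {start_1}")
            # 1-based inclusive -> 0-based half-open
            regions.append(NamedRegion(name, GenomicInterval(chrom, start_1 - 1, end_1), markers))
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            if a.interval and b.interval and a.interval.chrom == b.interval.chrom:
                if a.interval.start < b.interval.end and b.interval.start < a.interval.end:
                    warn(f"regions {a.name!r} and {b.name!r} overlap")
    return regions


def save_region_partition(regions: list[NamedRegion], path) -> None:
    """Write regions back as TSV (inverse of :func:`load_region_partition`)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_PARTITION_HEADER) + "\n")
        for r in regions:
            markers = ",".join(r.markers) if r.markers else "?"
            if r.interval is None:
                fh.write(f"{r.name}\t?\t?\t?\t{markers}\n")
            else:
                fh.write(f"{r.name}\t{r.interval.chrom}\t{r.interval.start + 1}"
                         f"\t{r.interval.end}\t{markers}\n")


def default_region_partition() -> list[NamedRegion]:
    """The shipped partition of chromosome-3 pericentromeric heterochromatin.

    Encodes the six named zones of the heterochromatic interval with border
    coordinates where they have been determined (the eu/heterochromatin
    variability zone on 3L) and explicit unknowns elsewhere.
    """
    with resources.as_file(
        resources.files("chromstates.data") / "het_region_partition.tsv"
    ) as p:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return load_region_partition(p)
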