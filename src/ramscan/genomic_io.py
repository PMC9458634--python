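"""Readers and writers for the BED-family formats the pipeline consumes.

All coordinates are 0-based half-open (BED convention). Sources using 1-based
coordinates must be converted before they enter the system. Strand is ignored
throughout: no step of the pipeline is strand-dependent.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "PeakSet",
    "AnchorPair",
    "VariantSet",
    "BoundarySet",
    "DomainSet",
    "ParseError",
    "ValidationError",
    "read_peaks",
    "read_chrom_sizes",
    "read_intervals",
    "write_intervals",
    "read_domains",
    "write_domains",
    "read_boundaries",
    "read_pairs",
    "write_pairs",
    "read_variants",
    "write_variants",
]


class ParseError(ValueError):
    """A malformed line in an input file (message names the line number)."""


class ValidationError(ValueError):
    """Data violates an invariant (coordinates, overlap, missing chromosome)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp). Unknown-chromosome lookup is an error."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has non-positive length {length}")
        self._sizes = dict(sizes)

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} not in chrom sizes") from None

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"


@dataclass
class PeakSet:
    """Peak calls for one sample and one histone mark, sorted by (chrom, start).

    Extra narrowPeak/broadPeak columns (score, signal, summit, ...) are kept in
    ``extra`` for provenance but are never used downstream: peak density counts
    peak midpoints, not summits.
    """

    sample_id: str
    mark: str
    peaks: list[GenomicInterval]
    extra: list[tuple] | None = None

    def __post_init__(self) -> None:
        order = sorted(range(len(self.peaks)), key=lambda i: (self.peaks[i].chrom, self.peaks[i].start, self.peaks[i].end))
        self.peaks = [self.peaks[i] for i in order]
        if self.extra is not None:
            self.extra = [self.extra[i] for i in order]

    def __len__(self) -> int:
        return len(self.peaks)

    def validate_against(self, chrom_sizes: ChromSizes) -> None:
        for p in self.peaks:
            if p.end > chrom_sizes[p.chrom]:
                raise ValidationError(
                    f"peak {p.chrom}:{p.start}-{p.end} extends past chromosome end "
                    f"{chrom_sizes[p.chrom]}"
                )

    def midpoints(self, chrom: str) -> np.ndarray:
        """Sorted array of peak midpoints on one chromosome."""
        mids = np.array([p.midpoint for p in self.peaks if p.chrom == chrom], dtype=np.int64)
        mids.sort()
        return mids

    def chroms(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks})


@dataclass
class AnchorPair:
    """Two anchors (e.g. an enhancer and a promoter), optionally annotated
    with a gene id and foreground/background expression values."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    gene_id: str | None = None
    expr_foreground: float | None = None
    expr_background: float | None = None


@dataclass
class VariantSet:
    """Point variants (SNVs or indels) as (chrom, position) coordinates."""

    label: str
    variants: list[tuple[str, int]]

    def __post_init__(self) -> None:
        for chrom, pos in self.variants:
            if pos < 0:
                raise ValidationError(f"variant position {chrom}:{pos} is negative")
        self.variants = sorted(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([p for c, p in self.variants if c == chrom], dtype=np.int64)

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self.variants})


def _check_sorted_disjoint(regions: Iterable[GenomicInterval], what: str) -> None:
    prev: GenomicInterval | None = None
    for iv in regions:
        if prev is not None:
            if iv.start < prev.end:
                raise ValidationError(
                    f"{what} overlap on {iv.chrom}: "
                    f"[{prev.start},{prev.end}) and [{iv.start},{iv.end})"
                )
        prev = iv


@dataclass
class BoundarySet:
    """Per-sample boundary regions, one grid bin wide, sorted and disjoint
    per chromosome. ``step`` records the grid the boundaries were called on."""

    sample_id: str
    step: int
    regions: dict[str, list[GenomicInterval]]

    def __post_init__(self) -> None:
        for chrom, ivs in self.regions.items():
            ivs.sort(key=lambda iv: iv.start)
            _check_sorted_disjoint(ivs, "boundaries")

    def centers(self, chrom: str) -> np.ndarray:
        return np.array(
            [(iv.start + iv.end) // 2 for iv in self.regions.get(chrom, [])], dtype=np.int64
        )

    def n_boundaries(self) -> int:
        return sum(len(v) for v in self.regions.values())


@dataclass
class DomainSet:
    """Sorted non-overlapping domains (RAM / cRAM / TAD / LAD / ...) per chromosome."""

    label: str
    domains: dict[str, list[GenomicInterval]]

    def __post_init__(self) -> None:
        for chrom, ivs in self.domains.items():
            ivs.sort(key=lambda iv: iv.start)
            _check_sorted_disjoint(ivs, f"{self.label} domains")

    def all_intervals(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for chrom in sorted(self.domains):
            out.extend(self.domains[chrom])
        return out

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.all_intervals()], dtype=np.int64)

    def n_domains(self) -> int:
        return sum(len(v) for v in self.domains.values())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_FORMAT_FIELDS = {"narrowPeak": 10, "broadPeak": 9, "bed": 3}


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coords(fields: list[str], lineno: int, path) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}") from None
    try:
        return GenomicInterval(fields[0], start, end)
    except ValidationError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def read_peaks(
    path: str | Path,
    format: str = "bed",
    sample_id: str | None = None,
    mark: str = "",
) -> PeakSet:
    """Read peak calls from a BED / ENCODE narrowPeak / broadPeak file.

    narrowPeak lines must have exactly 10 tab-separated fields, broadPeak 9,
    plain BED at least 3. Coordinates are taken verbatim as 0-based half-open.
    """
    if format not in _FORMAT_FIELDS:
        raise ValueError(f"unknown peak format {format!r}; choose from {sorted(_FORMAT_FIELDS)}")
    want = _FORMAT_FIELDS[format]
    peaks: list[GenomicInterval] = []
    extra: list[tuple] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if format == "bed":
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields, got {len(fields)}")
        elif len(fields) != want:
            raise ParseError(
                f"{path}:{lineno}: {format} requires {want} fields, got {len(fields)}"
            )
        peaks.append(_parse_coords(fields, lineno, path))
        extra.append(tuple(fields[3:]))
    if sample_id is None:
        sample_id = Path(path).stem
    return PeakSet(sample_id=sample_id, mark=mark, peaks=peaks, extra=extra)


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column ``chrom length`` file (whitespace-separated)."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
        chrom = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
        if chrom in sizes:
            raise ParseError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        if length <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive length {length} for {chrom}")
        sizes[chrom] = length
    return ChromSizes(sizes)


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a plain BED3(+) file as a sorted list of intervals."""
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 fields, got {len(fields)}")
        out.append(_parse_coords(fields, lineno, path))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path, names: Iterable[str] | None = None) -> None:
    """Write intervals as BED3 (or BED4 when names are given)."""
    intervals = list(intervals)
    names_list = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names_list is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names_list[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_domains(domains: DomainSet, path: str | Path) -> None:
    """Write a DomainSet as BED4 (name column = domain label + index).

    Domains must be sorted and non-overlapping per chromosome (enforced by
    the DomainSet constructor; re-checked here so hand-built dicts fail too).
    """
    ivs = domains.all_intervals()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, lst in by_chrom.items():
        _check_sorted_disjoint(sorted(lst, key=lambda iv: iv.start), f"{domains.label} domains")
    write_intervals(ivs, path, names=[f"{domains.label}_{i + 1}" for i in range(len(ivs))])


def read_domains(path: str | Path, label: str = "domain") -> DomainSet:
    """Read a BED file of sorted non-overlapping domains."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in read_intervals(path):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return DomainSet(label=label, domains=by_chrom)


def read_boundaries(path: str | Path, step: int, sample_id: str | None = None) -> BoundarySet:
    """Read a BED file of per-sample boundary regions called at ``step``."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in read_intervals(path):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    if sample_id is None:
        sample_id = Path(path).stem
    return BoundarySet(sample_id=sample_id, step=step, regions=by_chrom)


def read_pairs(path: str | Path) -> list[AnchorPair]:
    """Read a BEDPE-like pair file.

    Columns: chrom1 start1 end1 chrom2 start2 end2 [gene expr_fg expr_bg].
    """
    pairs: list[AnchorPair] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: pair lines require >=6 fields, got {len(fields)}")
        a1 = _parse_coords(fields[0:3], lineno, path)
        a2 = _parse_coords(fields[3:6], lineno, path)
        gene = fields[6] if len(fields) > 6 and fields[6] not in (".", "") else None
        expr_fg = float(fields[7]) if len(fields) > 7 and fields[7] not in (".", "") else None
        expr_bg = float(fields[8]) if len(fields) > 8 and fields[8] not in (".", "") else None
        pairs.append(AnchorPair(a1, a2, gene, expr_fg, expr_bg))
    return pairs


def write_pairs(pairs: Iterable[AnchorPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            cols = [
                p.anchor1.chrom, str(p.anchor1.start), str(p.anchor1.end),
                p.anchor2.chrom, str(p.anchor2.start), str(p.anchor2.end),
            ]
            if p.gene_id is not None or p.expr_foreground is not None or p.expr_background is not None:
                cols.append(p.gene_id if p.gene_id is not None else ".")
                cols.append(f"{p.expr_foreground:g}" if p.expr_foreground is not None else ".")
                cols.append(f"{p.expr_background:g}" if p.expr_background is not None else ".")
            fh.write("\t".join(cols) + "\n")


def read_variants(path: str | Path, label: str = "SNV") -> VariantSet:
    """Read point variants from a BED-derived file; position = BED start."""
    variants: list[tuple[str, int]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
        try:
            pos = int(fields[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer position {fields[1]!r}") from None
        if pos < 0:
            raise ParseError(f"{path}:{lineno}: negative position {pos}")
        variants.append((fields[0], pos))
    return VariantSet(label=label, variants=variants)


def write_variants(variants: VariantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in variants.variants:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{variants.label}\n")
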