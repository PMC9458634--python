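"""Cross-sample consensus module (cRAM) boundary aggregation.

Per-sample boundary calls on a common step grid are rasterized to per-bin
occurrence fractions; bins flagged in at least 25% of the cohort become
consensus boundary bins. Nearby consensus regions (<250 kb apart) are merged,
and inter-boundary islands no longer than 250 kb are absorbed into the
flanking boundary (modules are required to exceed 250 kb), so consensus
boundaries and cRAMs still partition every chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import (
    BoundarySet,
    ChromSizes,
    DomainSet,
    GenomicInterval,
    ValidationError,
)

__all__ = [
    "OccurrenceGrid",
    "ConsensusBoundarySet",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MERGE_DIST",
    "DEFAULT_MIN_DOMAIN",
    "boundary_occurrence",
    "call_consensus",
]

DEFAULT_THRESHOLD = 0.25
DEFAULT_MERGE_DIST = 250_000
DEFAULT_MIN_DOMAIN = 250_000


@dataclass
class OccurrenceGrid:
    """Per-bin fraction of cohort samples whose boundaries cover the bin."""

    step: int
    n_samples: int
    fractions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]


@dataclass
class ConsensusBoundarySet:
    """Merged consensus boundary regions with their peak occurrence fraction."""

    cohort: str
    step: int
    regions: dict[str, list[GenomicInterval]]
    fractions: dict[str, list[float]]

    def n_boundaries(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def centers(self, chrom: str) -> np.ndarray:
        return np.array(
            [(iv.start + iv.end) // 2 for iv in self.regions.get(chrom, [])], dtype=np.int64
        )


def _bin_cell(b: int, step: int, length: int) -> tuple[int, int]:
    """Grid cell of bin b: [b*step - step/2, b*step + step/2) clipped to the chromosome."""
    half = step // 2
    return max(0, b * step - half), min(length, b * step + (step - half))


def boundary_occurrence(
    boundary_sets: list[BoundarySet],
    step: int,
    chrom_sizes: ChromSizes,
) -> OccurrenceGrid:
    """Fraction of samples flagging each grid bin as a boundary.

    A sample covers a bin when one of its boundary regions overlaps the bin's
    grid cell by at least 1 bp. The denominator is the full cohort size.
    """
    if not boundary_sets:
        raise ValidationError("empty cohort: no boundary sets")
    for bs in boundary_sets:
        if bs.step != step:
            raise ValidationError(
                f"sample {bs.sample_id} called at step {bs.step}, expected {step}"
            )
    fractions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom in chrom_sizes:
        length = chrom_sizes[chrom]
        n_bins = length // step + 1
        counts = np.zeros(n_bins, dtype=np.int64)
        half = step // 2
        for bs in boundary_sets:
            flagged = np.zeros(n_bins, dtype=bool)
            for iv in bs.regions.get(chrom, []):
                # bins whose cell [b*s - s/2, b*s + s/2) intersects [start, end)
                lo = int(np.ceil((iv.start - (step - half)) / step))
                hi = int(np.floor((iv.end - 1 + half) / step))
                lo = max(lo, 0)
                hi = min(hi, n_bins - 1)
                for b in range(lo, hi + 1):
                    cs, ce = _bin_cell(b, step, length)
                    if cs < iv.end and iv.start < ce:
                        flagged[b] = True
            counts += flagged
        fractions[chrom] = counts / len(boundary_sets)
        lengths[chrom] = length
    return OccurrenceGrid(
        step=step, n_samples=len(boundary_sets), fractions=fractions, chrom_lengths=lengths
    )


def _merge_regions(
    regions: list[list[int]], length: int, merge_dist: int, min_domain: int
) -> list[list[int]]:
    """Single-linkage merge of [start, end) regions.

    Two regions join when their gap is < merge_dist (boundary merging) or
    <= min_domain (absorbing an island too short to be a module). Chromosome-
    end segments <= min_domain are absorbed into the terminal region.
    """
    if not regions:
        return []
    merged: list[list[int]] = [list(regions[0])]
    for start, end in regions[1:]:
        gap = start - merged[-1][1]
        if gap < merge_dist or gap <= min_domain:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    if merged[0][0] > 0 and merged[0][0] <= min_domain:
        merged[0][0] = 0
    if merged[-1][1] < length and length - merged[-1][1] <= min_domain:
        merged[-1][1] = length
    return merged


def call_consensus(
    grid: OccurrenceGrid,
    threshold: float = DEFAULT_THRESHOLD,
    merge_dist: int = DEFAULT_MERGE_DIST,
    min_domain: int = DEFAULT_MIN_DOMAIN,
    cohort: str = "cohort",
) -> tuple[ConsensusBoundarySet, DomainSet]:
    """Call consensus boundaries and cRAMs from an occurrence grid.

    Three steps per chromosome: (1) bins with occurrence fraction >= threshold
    (inclusive) are consensus bins; (2) consensus regions closer than
    merge_dist are merged; (3) inter-boundary islands <= min_domain are
    absorbed into the flanking boundary. The remaining inter-boundary
    intervals are the cRAMs; boundaries and cRAMs tile each chromosome.
    Idempotent: re-running on the rasterized output reproduces it.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    regions_out: dict[str, list[GenomicInterval]] = {}
    fractions_out: dict[str, list[float]] = {}
    domains_out: dict[str, list[GenomicInterval]] = {}
    step = grid.step
    for chrom, f in grid.fractions.items():
        length = grid.chrom_lengths[chrom]
        flagged = f >= threshold - 1e-12
        # consecutive flagged bins -> contiguous regions of grid cells
        raw_regions: list[list[int]] = []
        for b in np.flatnonzero(flagged):
            cs, ce = _bin_cell(int(b), step, length)
            if raw_regions and cs <= raw_regions[-1][1]:
                raw_regions[-1][1] = ce
            else:
                raw_regions.append([cs, ce])
        merged = _merge_regions(raw_regions, length, merge_dist, min_domain)
        ivs = [GenomicInterval(chrom, s, e) for s, e in merged]
        # peak occurrence fraction over flagged bins inside each merged region
        fracs: list[float] = []
        centers = np.arange(len(f)) * step
        for s, e in merged:
            inside = flagged & (centers >= s - step) & (centers <= e + step)
            sel = [
                float(f[b])
                for b in np.flatnonzero(inside)
                if _bin_cell(int(b), step, length)[0] < e
                and _bin_cell(int(b), step, length)[1] > s
            ]
            fracs.append(max(sel) if sel else float("nan"))
        regions_out[chrom] = ivs
        fractions_out[chrom] = fracs
        crams: list[GenomicInterval] = []
        cursor = 0
        for iv in ivs:
            if iv.start > cursor:
                crams.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = iv.end
        if cursor < length:
            crams.append(GenomicInterval(chrom, cursor, length))
        domains_out[chrom] = crams
    return (
        ConsensusBoundarySet(cohort=cohort, step=step, regions=regions_out, fractions=fractions_out),
        DomainSet(label="cRAM", domains=domains_out),
    )
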