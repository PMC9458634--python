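"""Enrichment tests for domain-level observations.

Two bespoke tests: a hypergeometric upper tail for upregulated genes among
foreground-only intra-module enhancer-promoter pairs, and a pooled two-sample
proportion z-test for somatic-variant density in boundary sets (variant count
over boundary base pairs). Plus the coverage bookkeeping that feeds the
proportion test.

No continuity correction is applied in the z-test: the intended inputs are
counts in the thousands-to-millions regime; small-sample users should prefer
an exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomic_io import GenomicInterval, ValidationError, VariantSet

__all__ = [
    "HypergeomSpec",
    "ProportionSpec",
    "CoverageReport",
    "EnrichmentComparison",
    "hypergeom_upper_tail",
    "two_proportion_test",
    "variant_boundary_coverage",
    "compare_variant_enrichment",
]


@dataclass
class HypergeomSpec:
    """Population of N genes with M successes (upregulated); a sample of n
    genes contains m successes."""

    N: int
    M: int
    n: int
    m: int

    def __post_init__(self) -> None:
        ok = 0 <= self.m <= min(self.M, self.n) and self.n <= self.N and self.M <= self.N
        if not ok:
            raise ValidationError(
                f"invalid hypergeometric spec N={self.N} M={self.M} n={self.n} m={self.m}"
            )


@dataclass
class ProportionSpec:
    """Counts x over exposures n (bp) for two boundary sets."""

    x1: float
    n1: float
    x2: float
    n2: float

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0 or self.n1 <= 0 or self.n2 <= 0:
            raise ValidationError(
                f"invalid proportion spec x1={self.x1} n1={self.n1} x2={self.x2} n2={self.n2}"
            )


@dataclass
class CoverageReport:
    """How a variant set distributes over one boundary set."""

    boundary_bp: int
    genome_length: int
    n_variants_in: int
    n_variants: int

    @property
    def boundary_fraction(self) -> float:
        return self.boundary_bp / self.genome_length

    @property
    def variant_fraction(self) -> float:
        return self.n_variants_in / self.n_variants


@dataclass
class EnrichmentComparison:
    report_a: CoverageReport
    report_b: CoverageReport
    spec: ProportionSpec
    z: float
    p_value: float


def hypergeom_upper_tail(spec: HypergeomSpec) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n), computed in log space."""
    return float(stats.hypergeom.sf(spec.m - 1, spec.N, spec.M, spec.n))


def two_proportion_test(spec: ProportionSpec, sides: int = 2) -> tuple[float, float]:
    """Pooled-variance two-sample proportion z-test, no continuity correction.

    z = (x1/n1 - x2/n2) / sqrt(p̂ (1 - p̂) (1/n1 + 1/n2)) with
    p̂ = (x1 + x2)/(n1 + n2). Two-sided by default; sides=1 tests
    proportion 1 > proportion 2.
    """
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    p_pool = (spec.x1 + spec.x2) / (spec.n1 + spec.n2)
    if p_pool <= 0 or p_pool >= 1:
        raise ValidationError(f"degenerate pooled proportion {p_pool}")
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / spec.n1 + 1 / spec.n2))
    z = (spec.x1 / spec.n1 - spec.x2 / spec.n2) / se
    if sides == 2:
        p = 2 * float(stats.norm.sf(abs(z)))
    else:
        p = float(stats.norm.sf(z))
    return float(z), min(p, 1.0)


def _check_disjoint_sorted(boundaries: list[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in boundaries:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    arrays = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda v: v.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping boundaries on {chrom}: [{a.start},{a.end}) and [{b.start},{b.end})"
                )
        arrays[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    return arrays


def variant_boundary_coverage(
    variants: VariantSet,
    boundaries: list[GenomicInterval],
    genome_length: int,
) -> CoverageReport:
    """Genome fraction covered by the boundaries and the fraction of variants
    whose position falls inside them. Boundaries must be non-overlapping."""
    if len(variants) == 0:
        raise ValidationError("empty variant set: variant fraction undefined")
    if genome_length <= 0:
        raise ValidationError("genome length must be positive")
    arrays = _check_disjoint_sorted(boundaries)
    boundary_bp = sum(iv.length for iv in boundaries)
    n_in = 0
    for chrom in variants.chroms():
        if chrom not in arrays:
            continue
        starts, ends = arrays[chrom]
        pos = variants.positions(chrom)
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        n_in += int(inside.sum())
    return CoverageReport(
        boundary_bp=boundary_bp,
        genome_length=genome_length,
        n_variants_in=n_in,
        n_variants=len(variants),
    )


def compare_variant_enrichment(
    variants: VariantSet,
    boundaries_a: list[GenomicInterval],
    boundaries_b: list[GenomicInterval],
    genome_length: int,
) -> EnrichmentComparison:
    """Compare variant density (count per boundary bp) between two boundary
    sets with the pooled two-proportion z-test."""
    rep_a = variant_boundary_coverage(variants, boundaries_a, genome_length)
    rep_b = variant_boundary_coverage(variants, boundaries_b, genome_length)
    spec = ProportionSpec(
        x1=rep_a.n_variants_in, n1=rep_a.boundary_bp, x2=rep_b.n_variants_in, n2=rep_b.boundary_bp
    )
    z, p = two_proportion_test(spec)
    return EnrichmentComparison(report_a=rep_a, report_b=rep_b, spec=spec, z=z, p_value=p)
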