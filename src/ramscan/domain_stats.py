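"""Interval-level statistics on domain sets.

Covers intra-domain classification of anchor pairs (midpoint rule) and of
long intervals such as ecDNAs and super-enhancers (full-containment rule,
with a median-size filter), boundary/track overlap in both directions,
boundary recall between two calls, boundary-vs-non-boundary density contrast
by Wilcoxon rank-sum, and per-domain A/B compartment composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusBoundarySet
from .genomic_io import (
    AnchorPair,
    BoundarySet,
    DomainSet,
    GenomicInterval,
    ValidationError,
)
from .ram_caller import DensityProfile

__all__ = [
    "IntraDomainReport",
    "PairSetPartition",
    "RecallReport",
    "classify_pairs",
    "pair_set_comparison",
    "interval_intra_fraction",
    "boundary_track_overlap",
    "boundary_recall",
    "rank_sum_test",
    "density_contrast",
    "compartment_composition",
]


@dataclass
class IntraDomainReport:
    n_total: int
    n_intra: int
    n_inter: int
    labels: list[str] = field(default_factory=list)

    @property
    def fraction_intra(self) -> float | None:
        """Intra fraction, or None for an empty item list (flagged, not NaN)."""
        if self.n_total == 0:
            return None
        return self.n_intra / self.n_total


@dataclass
class PairSetPartition:
    intra_both: int
    intra_fg_only: int
    intra_bg_only: int
    inter_both: int
    labels: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.intra_both + self.intra_fg_only + self.intra_bg_only + self.inter_both


@dataclass
class RecallReport:
    n_reference: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_reference


def _domain_arrays(domains: DomainSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, ivs in domains.domains.items():
        out[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    return out


def _locate(starts: np.ndarray, ends: np.ndarray, pos: int) -> int:
    """Index of the domain containing pos, or -1."""
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i >= 0 and pos < ends[i]:
        return i
    return -1


def classify_pairs(pairs: list[AnchorPair], domains: DomainSet) -> IntraDomainReport:
    """Label each pair intra/inter: intra iff both anchor midpoints fall in
    one and the same domain interval. Cross-chromosome pairs, and pairs with
    a midpoint in a boundary/gap, are inter."""
    arrays = _domain_arrays(domains)
    labels: list[str] = []
    n_intra = 0
    for p in pairs:
        label = "inter"
        if p.anchor1.chrom == p.anchor2.chrom and p.anchor1.chrom in arrays:
            starts, ends = arrays[p.anchor1.chrom]
            i1 = _locate(starts, ends, p.anchor1.midpoint)
            i2 = _locate(starts, ends, p.anchor2.midpoint)
            if i1 >= 0 and i1 == i2:
                label = "intra"
                n_intra += 1
        labels.append(label)
    return IntraDomainReport(
        n_total=len(pairs), n_intra=n_intra, n_inter=len(pairs) - n_intra, labels=labels
    )


def pair_set_comparison(
    pairs: list[AnchorPair], domains_fg: DomainSet, domains_bg: DomainSet
) -> PairSetPartition:
    """Partition pairs by intra status in a foreground vs a background domain
    set; the intra-fg-only class feeds the hypergeometric enrichment test."""
    fg = classify_pairs(pairs, domains_fg)
    bg = classify_pairs(pairs, domains_bg)
    counts = {"intra_both": 0, "intra_fg_only": 0, "intra_bg_only": 0, "inter_both": 0}
    labels: list[str] = []
    for a, b in zip(fg.labels, bg.labels):
        if a == "intra" and b == "intra":
            key = "intra_both"
        elif a == "intra":
            key = "intra_fg_only"
        elif b == "intra":
            key = "intra_bg_only"
        else:
            key = "inter_both"
        counts[key] += 1
        labels.append(key)
    return PairSetPartition(labels=labels, **counts)


def interval_intra_fraction(
    intervals: list[GenomicInterval],
    domains: DomainSet,
    size_filter: str | int | None = "median",
) -> tuple[IntraDomainReport, float | None]:
    """Intra-domain fraction of long intervals under full containment.

    With size_filter="median" the cutoff is the median domain length and
    intervals of length >= cutoff are dropped before classification (the
    ecDNA filtering rule). An interval is intra iff [start, end) lies inside
    a single domain; an interval exactly equal to a domain is intra.
    Returns (report, applied cutoff in bp or None).
    """
    if domains.n_domains() == 0:
        raise ValidationError("empty domain set")
    if size_filter == "median":
        cutoff: float | None = float(np.median(domains.lengths()))
    elif size_filter in (None, "none"):
        cutoff = None
    elif isinstance(size_filter, (int, float)):
        cutoff = float(size_filter)
    else:
        raise ValueError(f"unknown size_filter {size_filter!r}")
    kept = intervals if cutoff is None else [iv for iv in intervals if iv.length < cutoff]
    arrays = _domain_arrays(domains)
    labels: list[str] = []
    n_intra = 0
    for iv in kept:
        label = "inter"
        if iv.chrom in arrays:
            starts, ends = arrays[iv.chrom]
            i = _locate(starts, ends, iv.start)
            if i >= 0 and iv.end <= ends[i]:
                label = "intra"
                n_intra += 1
        labels.append(label)
    report = IntraDomainReport(
        n_total=len(kept), n_intra=n_intra, n_inter=len(kept) - n_intra, labels=labels
    )
    return report, cutoff


def _merge_sorted(ivs: list[GenomicInterval]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for iv in sorted(ivs, key=lambda v: v.start):
        if merged and iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [(s, e) for s, e in merged]


def _overlap_fraction(
    queries: list[GenomicInterval], subjects: list[GenomicInterval]
) -> float:
    """Fraction of queries overlapping (>= 1 bp) the union of subjects."""
    if not queries:
        return 0.0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subjects:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = {c: _merge_sorted(v) for c, v in by_chrom.items()}
    starts = {c: np.array([s for s, _ in m], dtype=np.int64) for c, m in merged.items()}
    ends = {c: np.array([e for _, e in m], dtype=np.int64) for c, m in merged.items()}
    n_hit = 0
    for iv in queries:
        if iv.chrom not in merged:
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]
        i = int(np.searchsorted(s, iv.end, side="left")) - 1
        if i >= 0 and e[i] > iv.start:
            n_hit += 1
    return n_hit / len(queries)


def boundary_track_overlap(
    boundaries: list[GenomicInterval], track: list[GenomicInterval]
) -> tuple[float, float]:
    """(fraction of boundaries overlapping the track, fraction of track
    intervals overlapping the boundaries); overlap = >= 1 bp intersection."""
    return _overlap_fraction(boundaries, track), _overlap_fraction(track, boundaries)


def _regions_by_chrom(obj) -> dict[str, list[GenomicInterval]]:
    if isinstance(obj, (BoundarySet, ConsensusBoundarySet)):
        return obj.regions
    if isinstance(obj, DomainSet):
        return obj.domains
    if isinstance(obj, dict):
        return obj
    raise TypeError(f"cannot extract regions from {type(obj).__name__}")


def boundary_recall(reference, query, tolerance: int | None = None) -> RecallReport:
    """Fraction of reference boundaries with a query boundary center within
    ``tolerance`` bp (center-to-center; default tolerance = one step).

    Boundary positions are only defined to grid resolution, so the default
    match radius is one step of the reference call.
    """
    if tolerance is None:
        step = getattr(reference, "step", None)
        if step is None:
            raise ValueError("tolerance required when reference carries no step")
        tolerance = step
    ref_regions = _regions_by_chrom(reference)
    qry_regions = _regions_by_chrom(query)
    n_reference = 0
    n_matched = 0
    for chrom, ivs in ref_regions.items():
        ref_centers = np.array([(iv.start + iv.end) // 2 for iv in ivs], dtype=np.int64)
        n_reference += len(ref_centers)
        qry_centers = np.sort(
            np.array([(iv.start + iv.end) // 2 for iv in qry_regions.get(chrom, [])], dtype=np.int64)
        )
        if len(qry_centers) == 0:
            continue
        idx = np.searchsorted(qry_centers, ref_centers)
        for c, i in zip(ref_centers, idx):
            best = np.inf
            if i < len(qry_centers):
                best = min(best, abs(int(qry_centers[i]) - int(c)))
            if i > 0:
                best = min(best, abs(int(qry_centers[i - 1]) - int(c)))
            if best <= tolerance:
                n_matched += 1
    if n_reference == 0:
        raise ValidationError("empty reference boundary set: recall undefined")
    return RecallReport(n_reference=n_reference, n_matched=n_matched)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact enumeration for tie-free groups
    smaller than 10, otherwise midrank normal approximation with continuity
    correction. Returns (U statistic of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank-sum test requires both groups non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) < 10 and len(y) < 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _boundary_bin_mask(profile: DensityProfile, regions: list[GenomicInterval]) -> np.ndarray:
    half = profile.step // 2
    starts = profile.bin_centers - half
    ends = profile.bin_centers + (profile.step - half)
    mask = np.zeros(profile.n_bins, dtype=bool)
    for iv in regions:
        mask |= (starts < iv.end) & (ends > iv.start)
    return mask


def density_contrast(
    profiles_by_sample: dict[str, dict[str, DensityProfile]],
    boundaries: ConsensusBoundarySet,
) -> pd.DataFrame:
    """Per-sample Wilcoxon rank-sum of raw density in consensus-boundary bins
    vs non-boundary bins, pooled over chromosomes. A one-sided reading is the
    caller's job; p-values here are two-sided."""
    rows = []
    for sample_id, profiles in profiles_by_sample.items():
        in_bins: list[np.ndarray] = []
        out_bins: list[np.ndarray] = []
        for chrom, profile in profiles.items():
            if profile.step != boundaries.step:
                raise ValidationError("profile and boundaries are on different grids")
            mask = _boundary_bin_mask(profile, boundaries.regions.get(chrom, []))
            in_bins.append(profile.raw_counts[mask])
            out_bins.append(profile.raw_counts[~mask])
        x = np.concatenate(in_bins)
        y = np.concatenate(out_bins)
        if len(x) == 0 or len(y) == 0:
            raise ValidationError(f"sample {sample_id}: a contrast group is empty")
        u, p = rank_sum_test(x, y)
        rows.append(
            {
                "sample_id": sample_id,
                "n_boundary_bins": len(x),
                "n_other_bins": len(y),
                "median_boundary": float(np.median(x)),
                "median_other": float(np.median(y)),
                "statistic": u,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def compartment_composition(
    domains: DomainSet,
    labels_by_chrom: dict[str, np.ndarray],
    resolution: int = 250_000,
) -> pd.DataFrame:
    """Per-domain fraction of A and B compartment bins.

    ``labels_by_chrom[chrom][b]`` labels the bin [b*res, (b+1)*res) as "A",
    "B" or anything else (unlabeled). A bin belongs to a domain when its
    midpoint does. Unlabeled bins are excluded from the fractions and counted
    separately; domains with zero labeled bins get NaN fractions and are
    flagged for exclusion from summaries.
    """
    rows = []
    for chrom in sorted(domains.domains):
        labels = np.asarray(labels_by_chrom.get(chrom, np.array([], dtype=object)))
        mids = np.arange(len(labels)) * resolution + resolution // 2
        for iv in domains.domains[chrom]:
            inside = (mids >= iv.start) & (mids < iv.end)
            sub = labels[inside]
            n_a = int(np.sum(sub == "A"))
            n_b = int(np.sum(sub == "B"))
            n_un = int(len(sub) - n_a - n_b)
            n_lab = n_a + n_b
            rows.append(
                {
                    "chrom": chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "n_A": n_a,
                    "n_B": n_b,
                    "n_unlabeled": n_un,
                    "frac_A": n_a / n_lab if n_lab else np.nan,
                    "frac_B": n_b / n_lab if n_lab else np.nan,
                    "no_labeled_bins": n_lab == 0,
                }
            )
    return pd.DataFrame(rows)
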