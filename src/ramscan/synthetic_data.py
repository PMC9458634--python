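"""Synthetic multi-sample epigenome with a known modular ground truth.

Generates a chromosome layout of alternating modules (high active-mark peak
density) and boundary gaps (peak-poor), a cohort of per-sample peak sets
whose boundaries are partly cohort-shared and partly sample-private, and
matched downstream inputs: anchor pairs preferentially intra-module, ecDNA
intervals inside modules, point variants enriched in boundaries, and a
contact list with inflated observed counts at boundary bins.

Default geometry mirrors the scale of the real phenomenon the pipeline
targets: module lengths lognormal with median ~3 Mb (minimum 1.5 Mb),
boundary gaps with median ~750 kb, ten samples sharing 80% of boundaries,
and a module-to-boundary peak-rate ratio of 10. What the generator does NOT
emulate: read-level noise, peak-caller artifacts, copy-number variation,
centromeric deserts, and distance-dependent Hi-C decay — recovery results on
this data bound the method's behavior under the stated geometry only.

All draws are keyed on (seed, stream, index) so every artifact is
reproducible bit-for-bit from the config seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    AnchorPair,
    ChromSizes,
    GenomicInterval,
    PeakSet,
    ValidationError,
    VariantSet,
    write_intervals,
    write_pairs,
    write_variants,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "RecoveryReport",
    "simulate_layout",
    "simulate_peaks",
    "simulate_pairs",
    "simulate_ecdnas",
    "simulate_variants",
    "simulate_contacts",
    "evaluate_recovery",
    "write_fixture_dir",
]

# rng stream ids (second SeedSequence word) per artifact
_STREAM_LAYOUT = 1
_STREAM_PEAKS = 2
_STREAM_PAIRS = 3
_STREAM_ECDNA = 4
_STREAM_VARIANTS = 5
_STREAM_CONTACTS = 6


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 80_000_000, "chrS2": 80_000_000, "chrS3": 80_000_000}
    )
    n_samples: int = 10

    # layout geometry (bp)
    module_median: int = 3_000_000
    module_sigma: float = 0.45  # lognormal sigma of module lengths
    module_min: int = 1_500_000
    boundary_median: int = 750_000
    boundary_sigma: float = 0.30
    boundary_min: int = 300_000
    shared_boundary_fraction: float = 0.8

    # peak process (rates per 100 kb)
    peak_rate_module: float = 10.0
    peak_rate_boundary: float = 1.0
    peak_length_median: int = 1_000
    peak_length_sigma: float = 0.5

    # anchor pairs
    n_pairs: int = 500
    intra_prob: float = 0.95
    anchor_length: int = 2_000

    # ecDNA intervals
    n_ecdnas: int = 300
    ecdna_median: int = 800_000
    ecdna_sigma: float = 0.6

    # variants
    n_variants: int = 20_000
    variant_boundary_enrichment: float = 1.3

    # contacts
    n_contacts: int = 10_000
    contact_resolution: int = 250_000
    contact_expected: float = 10.0
    contact_boundary_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.shared_boundary_fraction <= 1):
            raise ValidationError("shared_boundary_fraction must be in [0, 1]")
        if not (0 <= self.intra_prob <= 1):
            raise ValidationError("intra_prob must be in [0, 1]")
        if self.variant_boundary_enrichment < 0:
            raise ValidationError("variant_boundary_enrichment must be >= 0")
        if self.peak_rate_module < 0 or self.peak_rate_boundary < 0:
            raise ValidationError("peak rates must be >= 0")
        for chrom, length in self.chrom_lengths.items():
            if self.module_median >= length:
                raise ValidationError(
                    f"module median {self.module_median} >= length of {chrom} ({length})"
                )

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(self.chrom_lengths)


@dataclass
class GroundTruth:
    """True layout: cohort-level modules/boundaries plus per-sample boundary
    positions (shared boundaries are identical across samples; private ones
    are re-placed per sample between the shared anchors)."""

    config: SimConfig
    modules: dict[str, list[GenomicInterval]]
    boundaries: dict[str, list[GenomicInterval]]
    shared: dict[str, list[bool]]
    sample_boundaries: list[dict[str, list[GenomicInterval]]]

    def shared_boundaries(self) -> dict[str, list[GenomicInterval]]:
        return {
            chrom: [iv for iv, s in zip(self.boundaries[chrom], self.shared[chrom]) if s]
            for chrom in self.boundaries
        }

    def sample_segments(self, sample: int, chrom: str) -> list[tuple[int, int, str]]:
        """(start, end, kind) tiling for one sample, kind in {module, boundary}."""
        length = self.config.chrom_lengths[chrom]
        segs: list[tuple[int, int, str]] = []
        cursor = 0
        for iv in self.sample_boundaries[sample][chrom]:
            if iv.start > cursor:
                segs.append((cursor, iv.start, "module"))
            segs.append((iv.start, iv.end, "boundary"))
            cursor = iv.end
        if cursor < length:
            segs.append((cursor, length, "module"))
        return segs


def _rng(config: SimConfig, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, index])


def _lognormal_at_least(rng, median: float, sigma: float, minimum: float) -> float:
    return max(minimum, rng.lognormal(np.log(median), sigma))


def simulate_layout(config: SimConfig) -> GroundTruth:
    """Draw the alternating module/boundary tiling and per-sample boundary sets."""
    rng = _rng(config, _STREAM_LAYOUT)
    modules: dict[str, list[GenomicInterval]] = {}
    boundaries: dict[str, list[GenomicInterval]] = {}
    shared: dict[str, list[bool]] = {}
    for chrom, length in config.chrom_lengths.items():
        cuts: list[tuple[int, int]] = []  # boundary segments
        cursor = _lognormal_at_least(rng, config.module_median, config.module_sigma, config.module_min)
        while True:
            b_len = _lognormal_at_least(
                rng, config.boundary_median, config.boundary_sigma, config.boundary_min
            )
            m_len = _lognormal_at_least(
                rng, config.module_median, config.module_sigma, config.module_min
            )
            if cursor + b_len + m_len > length:
                break
            cuts.append((int(cursor), int(cursor + b_len)))
            cursor += b_len + m_len
        boundaries[chrom] = [GenomicInterval(chrom, s, e) for s, e in cuts]
        shared[chrom] = [bool(rng.random() < config.shared_boundary_fraction) for _ in cuts]
        mods: list[GenomicInterval] = []
        prev = 0
        for s, e in cuts:
            mods.append(GenomicInterval(chrom, prev, s))
            prev = e
        mods.append(GenomicInterval(chrom, prev, length))
        modules[chrom] = mods

    sample_boundaries: list[dict[str, list[GenomicInterval]]] = []
    for s_idx in range(config.n_samples):
        s_rng = _rng(config, _STREAM_LAYOUT, s_idx + 1)
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for chrom, length in config.chrom_lengths.items():
            kept = [iv for iv, f in zip(boundaries[chrom], shared[chrom]) if f]
            private_lengths = [
                iv.length for iv, f in zip(boundaries[chrom], shared[chrom]) if not f
            ]
            per_chrom[chrom] = _scatter_privates(
                s_rng, chrom, length, kept, private_lengths, config
            )
        sample_boundaries.append(per_chrom)
    return GroundTruth(
        config=config,
        modules=modules,
        boundaries=boundaries,
        shared=shared,
        sample_boundaries=sample_boundaries,
    )


def _scatter_privates(rng, chrom, length, shared_ivs, private_lengths, config):
    """Per-sample boundary set: the shared boundaries at their fixed
    positions, plus the private boundary segments carved into the sample's
    modules anywhere on the chromosome (at least module_min away from other
    boundaries and the chromosome ends), so private positions are
    independent across samples."""
    placed = list(shared_ivs)
    for b_len in private_lengths:
        for _ in range(100):  # rejection-sample a legal carve position
            placed.sort(key=lambda iv: iv.start)
            modules: list[tuple[int, int]] = []
            cursor = 0
            for iv in placed:
                modules.append((cursor, iv.start))
                cursor = iv.end
            modules.append((cursor, length))
            slots = [
                (s, e)
                for s, e in modules
                if (e - s) >= 2 * config.module_min + b_len
            ]
            if not slots:
                break
            w = np.array([(e - s) - 2 * config.module_min - b_len for s, e in slots], dtype=float)
            if w.sum() <= 0:
                break
            s, e = slots[rng.choice(len(slots), p=w / w.sum())]
            pos = int(rng.uniform(s + config.module_min, e - config.module_min - b_len))
            placed.append(GenomicInterval(chrom, pos, pos + b_len))
            break
    placed.sort(key=lambda iv: iv.start)
    return placed


def simulate_peaks(truth: GroundTruth, config: SimConfig | None = None) -> list[PeakSet]:
    """One peak set per sample: a piecewise-homogeneous Poisson process on
    peak midpoints (rate peak_rate_module inside modules, peak_rate_boundary
    inside that sample's boundaries), peak intervals centered on midpoints."""
    config = config or truth.config
    out: list[PeakSet] = []
    for s_idx in range(config.n_samples):
        rng = _rng(config, _STREAM_PEAKS, s_idx)
        peaks: list[GenomicInterval] = []
        for chrom, length in config.chrom_lengths.items():
            for seg_start, seg_end, kind in truth.sample_segments(s_idx, chrom):
                rate = (
                    config.peak_rate_module if kind == "module" else config.peak_rate_boundary
                ) / 100_000.0
                n = rng.poisson((seg_end - seg_start) * rate)
                if n == 0:
                    continue
                mids = rng.uniform(seg_start, seg_end, size=n)
                lens = np.maximum(
                    150, rng.lognormal(np.log(config.peak_length_median), config.peak_length_sigma, size=n)
                )
                for m, l in zip(mids, lens):
                    start = max(0, int(m - l / 2))
                    end = min(length, int(m + l / 2))
                    if end > start:
                        peaks.append(GenomicInterval(chrom, start, end))
        out.append(PeakSet(sample_id=f"sim{s_idx:02d}", mark="H3K27ac", peaks=peaks))
    return out


def _module_weights(truth: GroundTruth, margin: int) -> tuple[list[GenomicInterval], np.ndarray]:
    mods = [iv for chrom in sorted(truth.modules) for iv in truth.modules[chrom] if iv.length > 2 * margin]
    w = np.array([iv.length - 2 * margin for iv in mods], dtype=float)
    return mods, w / w.sum()


def simulate_pairs(truth: GroundTruth, config: SimConfig | None = None) -> list[AnchorPair]:
    """Anchor pairs: with probability intra_prob both anchors fall inside one
    module of the cohort layout; otherwise they straddle one boundary."""
    config = config or truth.config
    rng = _rng(config, _STREAM_PAIRS)
    margin = config.anchor_length
    mods, w = _module_weights(truth, margin)
    all_bounds = [iv for chrom in sorted(truth.boundaries) for iv in truth.boundaries[chrom]]
    pairs: list[AnchorPair] = []
    for i in range(config.n_pairs):
        if rng.random() < config.intra_prob or not all_bounds:
            m = mods[rng.choice(len(mods), p=w)]
            lo, hi = m.start + margin, m.end - margin
            c1, c2 = sorted(rng.uniform(lo, hi, size=2))
        else:
            b = all_bounds[rng.integers(len(all_bounds))]
            reach = 1_000_000
            c1 = rng.uniform(max(0, b.start - reach), b.start - margin)
            c2 = rng.uniform(
                b.end + margin, min(config.chrom_lengths[b.chrom], b.end + reach)
            )
            m = b
        half = config.anchor_length // 2
        a1 = GenomicInterval(m.chrom, int(c1) - half, int(c1) + half)
        a2 = GenomicInterval(m.chrom, int(c2) - half, int(c2) + half)
        pairs.append(AnchorPair(a1, a2, gene_id=f"g{i + 1:04d}"))
    return pairs


def simulate_ecdnas(truth: GroundTruth, config: SimConfig | None = None) -> list[GenomicInterval]:
    """ecDNA-like intervals: with probability intra_prob fully inside a
    module, otherwise spanning a boundary."""
    config = config or truth.config
    rng = _rng(config, _STREAM_ECDNA)
    mods, w = _module_weights(truth, 0)
    all_bounds = [iv for chrom in sorted(truth.boundaries) for iv in truth.boundaries[chrom]]
    out: list[GenomicInterval] = []
    for _ in range(config.n_ecdnas):
        size = int(rng.lognormal(np.log(config.ecdna_median), config.ecdna_sigma))
        if rng.random() < config.intra_prob or not all_bounds:
            m = mods[rng.choice(len(mods), p=w)]
            size = min(size, m.length - 2)
            start = int(rng.uniform(m.start, m.end - size))
        else:
            b = all_bounds[rng.integers(len(all_bounds))]
            size = max(size, b.length + 2)
            lo = max(0, b.end + 1 - size)
            start = int(rng.uniform(lo, b.start - 1)) if b.start - 1 > lo else lo
            m = b
        end = min(config.chrom_lengths[m.chrom], start + size)
        out.append(GenomicInterval(m.chrom, start, end))
    return out


def simulate_variants(
    truth: GroundTruth,
    config: SimConfig | None = None,
    enrichment: float | None = None,
    label: str = "SNV",
    n_variants: int | None = None,
    stream_offset: int = 0,
) -> VariantSet:
    """Point variants with density enrichment * baseline inside the cohort
    boundary regions and baseline elsewhere (enrichment defaults to the
    config's variant_boundary_enrichment; 1.0 gives the uniform null)."""
    config = config or truth.config
    e = config.variant_boundary_enrichment if enrichment is None else enrichment
    if e < 0:
        raise ValidationError("enrichment must be >= 0")
    n = config.n_variants if n_variants is None else n_variants
    rng = _rng(config, _STREAM_VARIANTS, stream_offset)
    segs: list[tuple[str, int, int, float]] = []
    for chrom, length in config.chrom_lengths.items():
        cursor = 0
        for iv in truth.boundaries[chrom]:
            if iv.start > cursor:
                segs.append((chrom, cursor, iv.start, 1.0))
            segs.append((chrom, iv.start, iv.end, e))
            cursor = iv.end
        if cursor < length:
            segs.append((chrom, cursor, length, 1.0))
    weights = np.array([(s[2] - s[1]) * s[3] for s in segs], dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(n, weights)
    variants: list[tuple[str, int]] = []
    for (chrom, start, end, _), c in zip(segs, counts):
        if c:
            variants.extend((chrom, int(p)) for p in rng.uniform(start, end, size=c))
    return VariantSet(label=label, variants=variants)


def simulate_contacts(truth: GroundTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Contact list with flat expected counts and observed counts inflated by
    contact_boundary_multiplier when either endpoint bin overlaps a cohort
    boundary region."""
    config = config or truth.config
    rng = _rng(config, _STREAM_CONTACTS)
    res = config.contact_resolution
    rows = []
    chroms = sorted(config.chrom_lengths)
    n_bins = {c: config.chrom_lengths[c] // res for c in chroms}
    boundary_bins: dict[str, set[int]] = {}
    for chrom in chroms:
        bins = set()
        for iv in truth.boundaries[chrom]:
            for b in range(iv.start // res, (iv.end - 1) // res + 1):
                bins.add(b)
        boundary_bins[chrom] = bins
    weights = np.array([n_bins[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    chosen = rng.choice(len(chroms), size=config.n_contacts, p=weights)
    for ci in chosen:
        chrom = chroms[ci]
        b1, b2 = sorted(rng.integers(0, n_bins[chrom], size=2))
        mu = config.contact_expected
        if b1 in boundary_bins[chrom] or b2 in boundary_bins[chrom]:
            mu *= config.contact_boundary_multiplier
        rows.append(
            {
                "chrom": chrom,
                "bin_i": int(b1) * res,
                "bin_j": int(b2) * res,
                "observed": int(rng.poisson(mu)),
                "expected": config.contact_expected,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """How well a called consensus boundary set matches the ground truth."""

    n_shared: int
    n_shared_recovered: int
    n_called: int
    n_spurious: int

    @property
    def recall(self) -> float:
        return self.n_shared_recovered / self.n_shared

    @property
    def spurious_fraction(self) -> float:
        return self.n_spurious / self.n_called


def true_consensus(truth: GroundTruth, step: int, threshold: float = 0.25):
    """Consensus boundary regions implied by the per-sample ground truths.

    Rasterizes every sample's true boundary segments and applies the same
    occurrence threshold the caller uses. Cohort-shared boundaries are always
    in this set; sample-private boundaries enter wherever their per-sample
    placements happen to coincide in >= threshold of the cohort — by the
    consensus definition those are genuine consensus boundaries too.
    """
    from .consensus import boundary_occurrence, call_consensus
    from .genomic_io import BoundarySet

    config = truth.config
    sets = [
        BoundarySet(sample_id=f"truth{i:02d}", step=step, regions=truth.sample_boundaries[i])
        for i in range(config.n_samples)
    ]
    grid = boundary_occurrence(sets, step, config.chrom_sizes())
    cbs, _ = call_consensus(grid, threshold=threshold)
    return cbs


def evaluate_recovery(truth: GroundTruth, called, tolerance: int | None = None) -> RecoveryReport:
    """Score a called consensus boundary set against the ground truth.

    Recall: fraction of cohort-shared true boundaries with a called boundary
    center within ``tolerance`` (default one step) of their center. Spurious:
    called regions farther than ``tolerance`` (edge-to-edge) from every
    ground-truth consensus region — regions the pipeline invented rather
    than recovered.
    """
    from .domain_stats import boundary_recall

    step = getattr(called, "step", None) or 250_000
    if tolerance is None:
        tolerance = step
    shared = truth.shared_boundaries()
    rec = boundary_recall(shared, called.regions, tolerance=tolerance)
    truth_cons = true_consensus(truth, step)
    n_called = 0
    n_spurious = 0
    for chrom, regs in called.regions.items():
        true_regs = truth_cons.regions.get(chrom, [])
        for iv in regs:
            n_called += 1
            matched = any(
                t.start - tolerance <= iv.end and iv.start <= t.end + tolerance
                for t in true_regs
            )
            if not matched:
                n_spurious += 1
    return RecoveryReport(
        n_shared=rec.n_reference,
        n_shared_recovered=rec.n_matched,
        n_called=n_called,
        n_spurious=n_spurious,
    )


def write_fixture_dir(config: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Generate every artifact and write it under out_dir in plain-text
    formats (narrowPeak per sample, truth BEDs, pairs BEDPE, ecDNA BED,
    variants BED, contacts TSV, resolved config YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_layout(config)
    with open(out / "chrom.sizes", "w") as fh:
        for chrom, length in config.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    for sample_idx, ps in enumerate(simulate_peaks(truth, config)):
        with open(out / f"{ps.sample_id}.narrowPeak", "w") as fh:
            for i, p in enumerate(ps.peaks):
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i + 1}\t0\t.\t0\t-1\t-1\t{p.length // 2}\n"
                )
    truth_bounds = [iv for c in sorted(truth.boundaries) for iv in truth.boundaries[c]]
    truth_shared = [f for c in sorted(truth.boundaries) for f in truth.shared[c]]
    write_intervals(
        truth_bounds,
        out / "truth_boundaries.bed",
        names=["shared" if f else "private" for f in truth_shared],
    )
    write_intervals(
        [iv for c in sorted(truth.modules) for iv in truth.modules[c]], out / "truth_modules.bed"
    )
    write_pairs(simulate_pairs(truth, config), out / "pairs.bedpe")
    write_intervals(simulate_ecdnas(truth, config), out / "ecdna.bed")
    write_variants(simulate_variants(truth, config), out / "variants.bed")
    simulate_contacts(truth, config).to_csv(out / "contacts.tsv", sep="\t", index=False)
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: v for k, v in vars(config).items()}, fh, default_flow_style=False, sort_keys=False
        )
    return truth
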