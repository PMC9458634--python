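"""Hi-C contact statistics on plain contact lists and small dense matrices.

Implements vanilla-coverage (VC) matrix normalization, Poisson contact
significance (upper tail of observed vs VC-normalized expected, reported as
log10 p), per-locus significant-contact degree, the leading eigenvector of a
compartment correlation matrix, and A/B compartment sign assignment by
correlation with an activity track (Pol II peak density or TSS density).

Binary .hic/.cool I/O, matrix balancing beyond VC, and loop/TAD calling are
out of scope; contact lists arrive as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .genomic_io import ParseError, ValidationError

__all__ = [
    "ContactRecord",
    "CompartmentTrack",
    "DEFAULT_LOGP_CUTOFF",
    "read_contacts",
    "write_contacts",
    "vc_normalize",
    "contact_significance",
    "add_significance",
    "contact_degree",
    "first_eigenvector",
    "assign_compartments",
]

DEFAULT_LOGP_CUTOFF = -10.0

CONTACT_COLUMNS = ["chrom", "bin_i", "bin_j", "observed", "expected"]


@dataclass
class ContactRecord:
    """One contact: a pair of bins (start coordinates, bin_i <= bin_j) with
    observed and expected (VC-normalized) counts and, once computed, log10 p."""

    chrom: str
    bin_i: int
    bin_j: int
    observed: float
    expected: float
    log10_p: float | None = None


@dataclass
class CompartmentTrack:
    """Per-bin compartment eigenvector values and A/B/NA labels."""

    chrom: str
    resolution: int
    values: np.ndarray
    labels: np.ndarray  # "A", "B" or "NA"


def read_contacts(path: str | Path) -> pd.DataFrame:
    """Read a contact-list TSV (chrom, bin_i, bin_j, observed, expected
    [, log10_p]); a header line is optional."""
    first = open(path).readline().split("\t")
    header = 0 if first and first[0] == "chrom" else None
    names = None if header == 0 else CONTACT_COLUMNS + (["log10_p"] if len(first) > 5 else [])
    df = pd.read_csv(path, sep="\t", header=header, names=names)
    missing = [c for c in CONTACT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing contact columns {missing}")
    if (df["bin_i"] > df["bin_j"]).any():
        raise ValidationError(f"{path}: contact records require bin_i <= bin_j")
    return df


def write_contacts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def vc_normalize(matrix: np.ndarray) -> np.ndarray:
    """Vanilla-coverage normalization of a symmetric contact matrix.

    M'_ij = M_ij / (v_i v_j) with v the row-sum vector; rows with zero
    coverage become NaN rows/columns; the result is rescaled by one global
    constant so the grand total over unmasked entries matches the input.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("contact matrix must be square")
    if not np.allclose(m, m.T):
        raise ValidationError("contact matrix must be symmetric")
    if (m < 0).any():
        raise ValidationError("contact matrix must be non-negative")
    v = m.sum(axis=1)
    mask = v > 0
    out = np.full_like(m, np.nan)
    vv = np.outer(v[mask], v[mask])
    sub = m[np.ix_(mask, mask)] / vv
    total_in = m[np.ix_(mask, mask)].sum()
    total_out = sub.sum()
    if total_out > 0:
        sub *= total_in / total_out
    out[np.ix_(mask, mask)] = sub
    return out


def contact_significance(observed, expected):
    """log10 of the Poisson upper-tail p-value P(X >= observed), X ~ Poisson(expected).

    Computed in log space (stable far into the tail). Fractional observed
    counts (VC-normalized) are ceiled, which is the exact upper tail for an
    integer-valued variable. observed = 0 gives p = 1 (log10 p = 0).
    Accepts scalars or arrays; expected must be positive.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if (obs < 0).any():
        raise ValidationError("observed counts must be >= 0")
    if (exp <= 0).any():
        raise ValidationError("expected counts must be > 0")
    k = np.ceil(obs)
    with np.errstate(divide="ignore"):
        logp = np.atleast_1d(stats.poisson.logsf(k - 1, exp))
    # far tail: sf underflows below ~1e-308; sum the series in log space
    under = ~np.isfinite(logp) & (np.atleast_1d(k) > 0)
    if under.any():
        kk = np.atleast_1d(k)[under]
        mu = np.broadcast_to(exp, np.atleast_1d(k).shape)[under]
        j = kk[:, None] + np.arange(120)[None, :]
        terms = -mu[:, None] + j * np.log(mu[:, None]) - special.gammaln(j + 1)
        logp[under] = special.logsumexp(terms, axis=1)
    log10p = logp.reshape(np.shape(k)) / np.log(10)
    log10p = np.minimum(log10p, 0.0)
    if np.isscalar(observed) and np.isscalar(expected):
        return float(log10p)
    return log10p


def add_significance(contacts: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a contact list with a log10_p column."""
    out = contacts.copy()
    out["log10_p"] = contact_significance(out["observed"].to_numpy(), out["expected"].to_numpy())
    return out


def contact_degree(contacts: pd.DataFrame, logp_cutoff: float = DEFAULT_LOGP_CUTOFF) -> pd.Series:
    """Number of distinct significant partner bins per locus.

    A record passes when log10_p <= cutoff; it counts toward both endpoints
    (a self-contact once); duplicate records of the same pair count once.
    Returns a Series indexed by (chrom, bin), covering bins that appear in
    the contact list (degree 0 for non-significant ones).
    """
    if "log10_p" not in contacts.columns:
        raise ValidationError("contacts have no log10_p column; run add_significance first")
    degrees: dict[tuple[str, int], set[int]] = {}
    for chrom, bi, bj in zip(contacts["chrom"], contacts["bin_i"], contacts["bin_j"]):
        degrees.setdefault((chrom, int(bi)), set())
        degrees.setdefault((chrom, int(bj)), set())
    sig = contacts[contacts["log10_p"] <= logp_cutoff]
    seen: set[tuple[str, int, int]] = set()
    for chrom, bi, bj in zip(sig["chrom"], sig["bin_i"], sig["bin_j"]):
        key = (chrom, int(bi), int(bj))
        if key in seen:
            continue
        seen.add(key)
        degrees[(chrom, int(bi))].add(int(bj))
        degrees[(chrom, int(bj))].add(int(bi))
    idx = pd.MultiIndex.from_tuples(sorted(degrees), names=["chrom", "bin"])
    return pd.Series([len(degrees[k]) for k in sorted(degrees)], index=idx, name="degree")


def first_eigenvector(matrix: np.ndarray, degenerate_rtol: float = 1e-9) -> np.ndarray:
    """Unit eigenvector of the largest-magnitude eigenvalue of a symmetric
    (compartment correlation) matrix.

    Rows containing NaN are treated as masked: they are dropped before the
    decomposition and re-inserted as NaN. A degenerate leading spectrum (the
    two largest magnitudes coincide, e.g. the identity matrix) yields an
    all-NaN vector, flagging that no compartment signal exists.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("matrix must be square")
    valid = ~np.isnan(m).all(axis=1)
    sub = m[np.ix_(valid, valid)]
    if sub.shape[0] < 3:
        raise ValidationError(f"matrix has only {sub.shape[0]} unmasked rows; need >= 3")
    if np.isnan(sub).any():
        raise ValidationError("matrix has scattered NaNs outside fully masked rows")
    if not np.allclose(sub, sub.T):
        raise ValidationError("matrix must be symmetric")
    w, v = np.linalg.eigh(sub)
    mags = np.abs(w)
    order = np.argsort(mags)[::-1]
    out = np.full(m.shape[0], np.nan)
    if mags[order[0]] == 0 or (mags[order[0]] - mags[order[1]]) <= degenerate_rtol * mags[order[0]]:
        return out
    vec = v[:, order[0]]
    out[valid] = vec / np.linalg.norm(vec)
    return out


def assign_compartments(
    eigenvector: np.ndarray,
    activity: np.ndarray,
    chrom: str = "",
    resolution: int = 250_000,
) -> CompartmentTrack:
    """Orient an eigenvector by its Pearson correlation with an activity
    track and label bins: positive -> A, negative -> B, zero/NaN -> NA.

    If r(eigenvector, activity) < 0 the eigenvector is negated, so the
    output is invariant to the arbitrary global sign of the eigenvector.
    """
    e = np.asarray(eigenvector, dtype=float)
    a = np.asarray(activity, dtype=float)
    if e.shape != a.shape:
        raise ValidationError("eigenvector and activity must have equal length")
    valid = ~(np.isnan(e) | np.isnan(a))
    if valid.sum() < 2 or np.std(a[valid]) == 0:
        raise ValidationError("activity track is constant; correlation undefined")
    if np.std(e[valid]) == 0:
        raise ValidationError("eigenvector is constant; correlation undefined")
    r = float(np.corrcoef(e[valid], a[valid])[0, 1])
    oriented = e.copy()
    if r < 0:
        oriented = -oriented
    labels = np.where(
        np.isnan(oriented), "NA", np.where(oriented > 0, "A", np.where(oriented < 0, "B", "NA"))
    )
    return CompartmentTrack(chrom=chrom, resolution=resolution, values=oriented, labels=labels)
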