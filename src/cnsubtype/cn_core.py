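"""Core copy-number containers and primitives.

Profiles live on a fixed genomic bin grid (100-kbp bins by default, the
resolution of shallow-WGS read counting). Each sample carries observed and
segmented log2 ratios, discrete 5-level calls and a tumor-purity estimate.
The primitives here are the ones the subtyping pipeline is built from:
admixture inversion of log2 ratios by purity, length-weighted summarization
of segmented values over recurrent (GISTIC-style) peak regions, removal of
sex-chromosome peaks, and the genome instability index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: floor applied inside the purity-corrected log2 (keeps the log finite at
#: deep deletions in low-purity samples); 2**-10 ~ copy number 0.002
LOG2_FLOOR = 2.0 ** -10

#: default bin width in bp
DEFAULT_BIN_WIDTH = 100_000

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})

VALID_CALLS = (-2, -1, 0, 1, 2)


class CnError(ValueError):
    """Raised on invalid copy-number inputs."""


# ---------------------------------------------------------------------------
# Bin grid
# ---------------------------------------------------------------------------

@dataclass
class BinGrid:
    """Fixed genomic bin grid shared by all samples of a cohort.

    Coordinates are 1-based inclusive. Bins must be sorted by (chromosome,
    start) and non-overlapping within a chromosome. ``usable`` marks bins
    that are analyzable cohort-wide (blacklisted/low-mappability bins are
    typically masked out upstream).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.usable = np.asarray(self.usable, dtype=bool)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.usable) == n):
            raise CnError("grid arrays must have equal length")
        if n == 0 or not self.usable.any():
            raise CnError("grid must contain at least one usable bin")
        if np.any(self.end < self.start):
            raise CnError("grid bins must satisfy end >= start")
        # sorted, non-overlapping within chromosome
        for c in self.chromosomes:
            idx = np.flatnonzero(self.chrom == c)
            s, e = self.start[idx], self.end[idx]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] <= e[:-1]):
                raise CnError(f"bins on chromosome {c} overlap or are unsorted")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in grid order."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def lengths(self) -> np.ndarray:
        """Bin lengths in bp."""
        return self.end - self.start + 1

    @classmethod
    def uniform(
        cls,
        chrom_sizes: Mapping[str, int],
        bin_width: int = DEFAULT_BIN_WIDTH,
        usable: np.ndarray | None = None,
    ) -> "BinGrid":
        """Tile chromosomes with fixed-width bins (last bin may be short)."""
        chroms, starts, ends = [], [], []
        for c, size in chrom_sizes.items():
            pos = np.arange(1, size + 1, bin_width, dtype=np.int64)
            chroms.extend([c] * len(pos))
            starts.append(pos)
            ends.append(np.minimum(pos + bin_width - 1, size))
        start = np.concatenate(starts)
        end = np.concatenate(ends)
        if usable is None:
            usable = np.ones(len(start), dtype=bool)
        return cls(np.array(chroms, dtype=object), start, end, usable)

    def bins_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of bins whose MIDPOINT falls inside [start, end] on chrom."""
        mid = (self.start + self.end) / 2.0
        return np.flatnonzero((self.chrom == chrom) & (mid >= start) & (mid <= end))

    def overlapping(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices of bins overlapping [start, end] plus overlap lengths in bp."""
        on = np.flatnonzero((self.chrom == chrom) & (self.start <= end) & (self.end >= start))
        ov = np.minimum(self.end[on], end) - np.maximum(self.start[on], start) + 1
        return on, ov

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "usable": self.usable}
        )


# ---------------------------------------------------------------------------
# Per-sample profile
# ---------------------------------------------------------------------------

@dataclass
class CnProfile:
    """One sample's copy-number profile on a shared :class:`BinGrid`.

    ``log2_seg`` holds segmented log2 ratios (piecewise constant over runs of
    bins); ``call`` the discrete state in {-2,-1,0,1,2}; ``purity`` the tumor
    cell fraction in (0, 1]. ``mask`` marks bins usable for THIS sample
    (grid-usable and covered by a segment).
    """

    sample_id: str
    purity: float
    log2_seg: np.ndarray
    log2_obs: np.ndarray | None = None
    call: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise CnError(f"purity must be in (0,1], got {self.purity} for {self.sample_id}")
        self.log2_seg = np.asarray(self.log2_seg, dtype=float)
        n = len(self.log2_seg)
        if self.log2_obs is not None:
            self.log2_obs = np.asarray(self.log2_obs, dtype=float)
            if len(self.log2_obs) != n:
                raise CnError("log2_obs length mismatch")
        if self.call is not None:
            self.call = np.asarray(self.call, dtype=np.int8)
            if len(self.call) != n:
                raise CnError("call length mismatch")
            if not np.isin(self.call, VALID_CALLS).all():
                raise CnError(f"calls outside {{-2..2}} in sample {self.sample_id}")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if len(self.mask) != n:
                raise CnError("mask length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.log2_seg)

    def corrected_seg(self, floor: float = LOG2_FLOOR) -> np.ndarray:
        """Purity-corrected segmented log2 ratios (admixture inversion)."""
        return purity_correct(self.log2_seg, self.purity, floor=floor)


# ---------------------------------------------------------------------------
# Purity correction
# ---------------------------------------------------------------------------

def purity_correct(r, p: float, floor: float = LOG2_FLOOR):
    """Invert the tumor/normal admixture model on log2 ratios.

    An observed ratio mixes tumor signal with diploid normal contamination:
    2**r = p * 2**r_t + (1 - p), where r_t = log2(c/2) is the pure-tumor
    log2 and p the tumor cell fraction. Solving for r_t:

        r_t = log2(max(floor, (2**r - (1 - p)) / p))

    The floor keeps the logarithm defined when the observed ratio drops
    below the normal-contamination baseline (deep deletions at low purity).

    Parameters
    ----------
    r : float or array
        Observed log2 ratio(s).
    p : float
        Tumor purity in (0, 1]. At p=1 the function is the identity.
    """
    if not (0.0 < p <= 1.0):
        raise CnError(f"purity must be in (0,1], got {p}")
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        t = (np.exp2(r) - (1.0 - p)) / p
    out = np.log2(np.maximum(floor, t))
    return float(out) if out.ndim == 0 else out


def admix_forward(r_t, p: float):
    """Forward admixture map: pure-tumor log2 -> observed log2 at purity p."""
    if not (0.0 < p <= 1.0):
        raise CnError(f"purity must be in (0,1], got {p}")
    r_t = np.asarray(r_t, dtype=float)
    out = np.log2(p * np.exp2(r_t) + (1.0 - p))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Peak regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRegion:
    """A recurrently gained/deleted region (GISTIC-style peak).

    Coordinates are stored 1-based inclusive. ``direction`` is "gain" or
    "deletion"; ``source_cluster`` records which reference cluster the peak
    was discovered in ("CN-high" or "CN-low").
    """

    peak_id: str
    chrom: str
    start: int
    end: int
    direction: str
    source_cluster: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CnError(f"peak {self.peak_id}: end < start")
        if self.direction not in ("gain", "deletion"):
            raise CnError(f"peak {self.peak_id}: bad direction {self.direction!r}")
        if self.source_cluster not in ("CN-high", "CN-low"):
            raise CnError(f"peak {self.peak_id}: bad source_cluster {self.source_cluster!r}")


def filter_autosomal_peaks(peaks: Sequence[PeakRegion]) -> tuple[list[PeakRegion], int]:
    """Drop peaks on sex chromosomes; return (kept, n_removed).

    Classification operates on autosomal peaks only (sex-chromosome dosage
    confounds the log2 baseline between male and female patients).
    """
    kept = [p for p in peaks if p.chrom not in SEX_CHROMS]
    n_removed = len(peaks) - len(kept)
    if not kept:
        warnings.warn("all peaks were on sex chromosomes; empty peak set", stacklevel=2)
    return kept, n_removed


def summarize_peaks(
    profiles: Iterable[CnProfile],
    peaks: Sequence[PeakRegion],
    grid: BinGrid,
    apply_purity: bool = True,
) -> pd.DataFrame:
    """Mean (purity-corrected) segmented log2 per sample per peak.

    The value for (sample, peak) is the length-weighted mean of the sample's
    corrected segmented log2 over the usable bins overlapping the peak,
    weights being the bp overlap of each bin with the peak. Peaks overlapping
    no usable bin for a sample get NaN.

    Returns a samples x peaks DataFrame (columns in peak-file order).
    """
    grid_chroms = set(grid.chromosomes)
    peak_bins: list[tuple[np.ndarray, np.ndarray]] = []
    for pk in peaks:
        if pk.chrom not in grid_chroms:
            raise CnError(f"peak {pk.peak_id}: chromosome {pk.chrom} absent from grid")
        idx, ov = grid.overlapping(pk.chrom, pk.start, pk.end)
        peak_bins.append((idx, ov.astype(float)))

    rows = {}
    for prof in profiles:
        if prof.n_bins != grid.n_bins:
            raise CnError(f"profile {prof.sample_id} not on this grid")
        vals = prof.corrected_seg() if apply_purity else prof.log2_seg
        ok = grid.usable & prof.mask
        row = np.full(len(peaks), np.nan)
        for j, (idx, ov) in enumerate(peak_bins):
            use = ok[idx]
            if use.any():
                w = ov[use]
                row[j] = float(np.average(vals[idx[use]], weights=w))
        rows[prof.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=[p.peak_id for p in peaks])


# ---------------------------------------------------------------------------
# Genome instability index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GiiResult:
    sample_id: str
    gii: float  # percent of called genome altered, [0, 100]
    gii_class: str | None = None  # "low" | "high" given a cutoff


def compute_gii(profile: CnProfile, grid: BinGrid) -> GiiResult:
    """Genome instability index: percent of the called genome altered.

    GII = 100 * (bp of usable bins with call != 0) / (bp of usable bins).
    With equal-width bins this reduces to a bin-count fraction. Bins that
    are unusable (grid- or sample-level) enter neither numerator nor
    denominator.
    """
    if profile.call is None:
        raise CnError(f"sample {profile.sample_id}: no calls available for GII")
    ok = grid.usable & profile.mask
    if not ok.any():
        raise CnError(f"sample {profile.sample_id}: zero usable bins")
    lengths = grid.lengths[ok].astype(float)
    altered = lengths[profile.call[ok] != 0].sum()
    return GiiResult(profile.sample_id, 100.0 * altered / lengths.sum())


def classify_gii(result: GiiResult, cutoff: float) -> GiiResult:
    """Dichotomize a GII value at cutoff g*: gii <= g* -> low, else high."""
    return replace(result, gii_class="low" if result.gii <= cutoff else "high")
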