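"""Readers and writers for the pipeline's tab-delimited interchange formats.

Formats:

* SEG-like segments: columns ``sample, chrom, start, end, n_bins, seg_log2``,
  1-based inclusive coordinates.
* purity table: columns ``sample, purity``.
* peaks: BED (0-based half-open) with ``name`` = peak id and two extra
  columns ``direction`` (gain|deletion) and ``source_cluster``
  (CN-high|CN-low); converted to 1-based inclusive on read.
* peak matrix: TSV, rows = samples, columns = peak ids.
* centroids: TSV with columns ``peak_id, mu_GS, mu_CIN``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cn_core import BinGrid, CnError, CnProfile, PeakRegion

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_bins", "seg_log2"]


def read_purity_table(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "purity"} <= set(df.columns):
        raise CnError("purity table needs columns: sample, purity")
    return dict(zip(df["sample"].astype(str), df["purity"].astype(float)))


def read_seg(
    path,
    grid: BinGrid,
    purity: Mapping[str, float] | str | None = None,
) -> list[CnProfile]:
    """Rasterize a SEG-like segment file onto ``grid``.

    A bin belongs to the segment covering its midpoint; bins covered by no
    segment are masked unusable for that sample. Overlapping segments for
    one sample are an error.
    """
    if isinstance(purity, str):
        purity = read_purity_table(purity)
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise CnError(f"SEG file missing columns: {sorted(missing)}")
    known = set(grid.chromosomes)
    bad = set(df["chrom"].astype(str)) - known
    if bad:
        raise CnError(f"unknown chromosome(s) in SEG file: {sorted(bad)}")

    profiles = []
    for sample, seg in df.groupby("sample", sort=False):
        sample = str(sample)
        log2_seg = np.zeros(grid.n_bins)
        covered = np.zeros(grid.n_bins, dtype=bool)
        seg = seg.sort_values(["chrom", "start"])
        for _, row in seg.iterrows():
            idx = grid.bins_in(str(row["chrom"]), int(row["start"]), int(row["end"]))
            if covered[idx].any():
                raise CnError(
                    f"overlapping segments for sample {sample} at "
                    f"{row['chrom']}:{int(row['start'])}-{int(row['end'])}"
                )
            log2_seg[idx] = float(row["seg_log2"])
            covered[idx] = True
        p = 1.0 if purity is None else purity.get(sample)
        if p is None:
            raise CnError(f"no purity for sample {sample}")
        profiles.append(
            CnProfile(sample_id=sample, purity=float(p), log2_seg=log2_seg, mask=covered)
        )
    return profiles


def write_seg(profiles: Iterable[CnProfile], grid: BinGrid, path) -> None:
    """Collapse per-bin segmented values back into a SEG-like file.

    Runs of bins with identical segmented log2 (within a chromosome, over
    the sample's covered bins) become one segment.
    """
    records = []
    for prof in profiles:
        for chrom in grid.chromosomes:
            idx = np.flatnonzero((grid.chrom == chrom) & prof.mask)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(
                (np.diff(prof.log2_seg[idx]) != 0) | (np.diff(idx) != 1)
            )
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [idx.size - 1]])
            for a, b in zip(starts, ends):
                records.append(
                    (
                        prof.sample_id,
                        chrom,
                        int(grid.start[idx[a]]),
                        int(grid.end[idx[b]]),
                        int(b - a + 1),
                        float(prof.log2_seg[idx[a]]),
                    )
                )
    pd.DataFrame(records, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def write_purity_table(profiles: Iterable[CnProfile], path) -> None:
    pd.DataFrame(
        [(p.sample_id, p.purity) for p in profiles], columns=["sample", "purity"]
    ).to_csv(path, sep="\t", index=False)


def write_calls(profiles: Iterable[CnProfile], grid: BinGrid, path) -> None:
    """Per-bin 5-level calls as a bins x samples TSV (chrom/start/end first)."""
    out = grid.to_frame().drop(columns="usable")
    for p in profiles:
        if p.call is None:
            raise CnError(f"sample {p.sample_id} has no calls")
        out[p.sample_id] = p.call
    out.to_csv(path, sep="\t", index=False)


def read_calls(path, grid: BinGrid) -> pd.DataFrame:
    """Read a bins x samples call TSV back into a samples x bins DataFrame."""
    df = pd.read_csv(path, sep="\t")
    if len(df) != grid.n_bins:
        raise CnError("call table does not match grid size")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return df[samples].T.astype(np.int8)


def read_peaks_bed(path) -> list[PeakRegion]:
    """Read peaks from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "direction", "source_cluster"],
    )
    return [
        PeakRegion(
            peak_id=str(r["name"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]) + 1,
            end=int(r["end"]),
            direction=str(r["direction"]),
            source_cluster=str(r["source_cluster"]),
        )
        for _, r in df.iterrows()
    ]


def write_peaks_bed(peaks: Sequence[PeakRegion], path) -> None:
    pd.DataFrame(
        [(p.chrom, p.start - 1, p.end, p.peak_id, p.direction, p.source_cluster) for p in peaks]
    ).to_csv(path, sep="\t", index=False, header=False)


def read_peak_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_peak_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample")


def read_clinical(path) -> pd.DataFrame:
    """Clinical table: sample plus survival/covariate columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise CnError("clinical table needs a 'sample' column")
    return df.set_index("sample")


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")
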