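"""Cohort-level call regions and between-group frequency comparison.

Adjacent bins whose call pattern across the cohort is (near-)constant are
merged into regions, and per-region gain/loss frequencies are compared
between two subgroups with a chi-square statistic whose null distribution
is obtained by permuting group labels. A permutation-based FDR estimate
accompanies each region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cn_core import BinGrid, CnError


@dataclass
class RegionSet:
    """Partition of the usable genome into near-constant-signature regions.

    ``table`` has one row per region (chrom, start, end, first/last bin
    index, n_bins); ``signature`` is the samples x regions matrix of the
    per-sample modal call within each region.
    """

    table: pd.DataFrame
    signature: pd.DataFrame  # samples x regions, values in {-2..2}


def _modal_call(block: np.ndarray) -> np.ndarray:
    """Per-sample modal call over a samples x bins block (ties -> smaller)."""
    out = np.empty(block.shape[0], dtype=np.int8)
    for i, row in enumerate(block):
        vals, counts = np.unique(row, return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def regionize(calls: pd.DataFrame, grid: BinGrid, tau: float = 0.01) -> RegionSet:
    """Merge adjacent usable bins into regions of near-constant call signature.

    Greedy left-to-right scan per chromosome: a region opens at a bin with
    signature = that bin's call column; the next bin joins while the
    fraction of samples whose call differs from the signature is <= tau.
    Chromosome boundaries always split. ``calls`` is samples x bins aligned
    to the grid; unusable grid bins are skipped.
    """
    M = calls.to_numpy()
    if M.shape[1] != grid.n_bins:
        raise CnError("call matrix not aligned to grid")
    rows = []
    members = []
    for chrom in grid.chromosomes:
        idx = np.flatnonzero((grid.chrom == chrom) & grid.usable)
        if idx.size == 0:
            continue
        start = 0
        sig = M[:, idx[0]]
        for k in range(1, idx.size + 1):
            extend = k < idx.size and np.mean(M[:, idx[k]] != sig) <= tau
            if not extend:
                sel = idx[start:k]
                rows.append(
                    (chrom, int(grid.start[sel[0]]), int(grid.end[sel[-1]]),
                     int(sel[0]), int(sel[-1]), len(sel))
                )
                members.append(sel)
                if k < idx.size:
                    start = k
                    sig = M[:, idx[k]]
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "bin_first", "bin_last", "n_bins"]
    )
    table.index.name = "region"
    signature = pd.DataFrame(
        {i: _modal_call(M[:, sel]) for i, sel in enumerate(members)}, index=calls.index
    )
    return RegionSet(table, signature)


def _chi2_stats(counts: np.ndarray) -> np.ndarray:
    """Chi-square statistics for a stack of 2 x 3 tables (..., 2, 3).

    Cells with zero expected count contribute nothing (their observed count
    is necessarily zero as well when a whole category is absent).
    """
    rowsum = counts.sum(axis=-1, keepdims=True)
    colsum = counts.sum(axis=-2, keepdims=True)
    total = counts.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rowsum * colsum / total
        cell = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return cell.sum(axis=(-2, -1))


def compare_groups(
    regions: RegionSet,
    groups: pd.Series,
    B: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Permutation comparison of per-region call frequencies in two groups.

    Per region, calls are collapsed to sign (loss < 0, neutral, gain > 0)
    and the chi-square statistic of the 2-group x 3-category table is
    computed; its permutation p-value relabels samples B times,
    p = (1 + #{perm stat >= observed}) / (B + 1). The FDR column estimates,
    at each region's observed statistic t, the expected number of
    null regions reaching t (mean over permutations) divided by the number
    of observed regions reaching t, clipped to [0, 1].
    """
    if B < 100:
        raise CnError("need B >= 100 permutations")
    groups = groups.reindex(regions.signature.index).astype(str)
    if groups.isna().any():
        raise CnError("samples without a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise CnError(f"exactly two groups required, got {levels}")
    g1 = (groups == levels[0]).to_numpy()
    n1, n = int(g1.sum()), len(groups)
    if n1 < 2 or n - n1 < 2:
        raise CnError("each group needs at least two samples")

    sig = regions.signature.to_numpy()
    cat = np.sign(sig)  # -1 loss, 0 neutral, +1 gain
    R = cat.shape[1]
    onehot = np.stack([(cat == v) for v in (-1, 0, 1)], axis=0).astype(float)  # 3,S,R
    tot = onehot.sum(axis=1)  # 3,R

    def stats_for(memb: np.ndarray) -> np.ndarray:
        """memb: (B?, S) float matrix of group-1 membership -> (B?, R) stats."""
        c1 = np.einsum("bs,ksr->bkr", memb, onehot)  # B,3,R
        c2 = tot[None] - c1
        counts = np.stack([c1, c2], axis=2)  # B,3,2,R -> want (...,2,3)
        counts = counts.transpose(0, 3, 2, 1)  # B,R,2,3
        return _chi2_stats(counts)

    obs = stats_for(g1[None, :].astype(float))[0]  # (R,)

    rng = np.random.default_rng(seed)
    perm_ge = np.zeros(R)
    chunk = max(1, min(B, int(2e7 // max(1, n * R))))
    perm_stats_all = []
    done = 0
    while done < B:
        b = min(chunk, B - done)
        memb = np.zeros((b, n))
        for i in range(b):
            memb[i, rng.permutation(n)[:n1]] = 1.0
        ps = stats_for(memb)  # b,R
        perm_ge += (ps >= obs[None, :] - 1e-12).sum(axis=0)
        perm_stats_all.append(ps)
        done += b
    pvals = (1.0 + perm_ge) / (B + 1.0)

    # permutation FDR at each observed statistic, made monotone (q-value
    # style): tightening the threshold can only lower the estimate
    perm_stats = np.concatenate(perm_stats_all, axis=0)  # B,R
    sorted_perm = np.sort(perm_stats.ravel())
    sorted_obs = np.sort(obs)
    fdr = np.empty(R)
    for i, t in enumerate(obs):
        exp_null = (len(sorted_perm) - np.searchsorted(sorted_perm, t - 1e-12)) / B
        n_obs = len(sorted_obs) - np.searchsorted(sorted_obs, t - 1e-12)
        fdr[i] = min(1.0, exp_null / max(n_obs, 1))
    order = np.argsort(-obs, kind="stable")  # tightest threshold first
    fdr[order] = np.minimum.accumulate(fdr[order][::-1])[::-1]

    freq = {}
    for gi, (lab, mask) in enumerate([(levels[0], g1), (levels[1], ~g1)]):
        sub = cat[mask]
        freq[f"freq_gain_{lab}"] = (sub > 0).mean(axis=0)
        freq[f"freq_loss_{lab}"] = (sub < 0).mean(axis=0)
    out = regions.table[["chrom", "start", "end", "n_bins"]].copy()
    for k, v in freq.items():
        out[k] = v
    out["stat"] = obs
    out["p"] = pvals
    out["fdr"] = fdr
    return out


def frequency_by_bin(calls: pd.DataFrame, grid: BinGrid, groups: pd.Series) -> pd.DataFrame:
    """Per-bin gain/loss frequency per group (frequency-plot export data)."""
    out = grid.to_frame()
    M = calls.to_numpy()
    groups = groups.reindex(calls.index).astype(str)
    for g in sorted(groups.unique()):
        sel = (groups == g).to_numpy()
        out[f"freq_gain_{g}"] = (M[sel] > 0).mean(axis=0)
        out[f"freq_loss_{g}"] = (M[sel] < 0).mean(axis=0)
    return out
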