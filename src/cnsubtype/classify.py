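"""Nearest-centroid GS/CIN subtyping and the TCGA x Lauren stratification.

The genomically-stable (GS) and chromosomal-instable (CIN) centroids are the
per-peak mean log2 values over a labeled reference cohort. A new sample is
assigned to the cluster whose centroid is nearest in Euclidean distance over
the peak dimensions observed for that sample. Combining the molecular label
with the Lauren histotype (mixed mapped to diffuse, "other" excluded) yields
the four prognostic strata GS-intestinal, GS-diffuse, CIN-intestinal and
CIN-diffuse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cn_core import CnError

GS, CIN = "GS", "CIN"
LAUREN_LEVELS = ("intestinal", "diffuse", "mixed", "other")
STRATA = ("GS-intestinal", "GS-diffuse", "CIN-intestinal", "CIN-diffuse")


@dataclass(frozen=True)
class Centroids:
    """Per-cluster mean peak-level log2 vectors (aligned on peak_ids)."""

    peak_ids: list[str]
    mu_gs: np.ndarray
    mu_cin: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.peak_ids) == len(self.mu_gs) == len(self.mu_cin)):
            raise CnError("centroid vectors misaligned with peak ids")
        if not (np.isfinite(self.mu_gs).all() and np.isfinite(self.mu_cin).all()):
            raise CnError("centroids contain non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mu_GS": self.mu_gs, "mu_CIN": self.mu_cin},
            index=pd.Index(self.peak_ids, name="peak_id"),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Centroids":
        return cls(list(df.index.astype(str)), df["mu_GS"].to_numpy(), df["mu_CIN"].to_numpy())


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    label: str  # GS | CIN
    d_gs: float
    d_cin: float
    n_peaks_used: int
    tie: bool = False


def build_centroids(reference: pd.DataFrame, labels: Mapping[str, str] | pd.Series) -> Centroids:
    """Average the labeled reference cohort into GS and CIN centroids.

    Per-peak arithmetic mean within each cluster, ignoring missing entries.
    Peaks missing in more than half of either cluster's samples are dropped
    (with a warning): their means would be dominated by a handful of
    samples and the dimension would be unstable.
    """
    labels = pd.Series(labels).astype(str)
    aligned = labels.reindex(reference.index)
    if aligned.isna().any():
        raise CnError(f"unlabeled reference samples: {list(aligned.index[aligned.isna()])[:5]}")
    bad = set(aligned) - {GS, CIN}
    if bad:
        raise CnError(f"unknown reference labels: {sorted(bad)}")
    gs = reference.loc[aligned == GS]
    cin = reference.loc[aligned == CIN]
    if len(gs) == 0 or len(cin) == 0:
        raise CnError("each cluster needs at least one reference sample")
    ok = (gs.isna().mean() <= 0.5) & (cin.isna().mean() <= 0.5)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} peak(s) missing in >50% of a cluster", stacklevel=2
        )
    if not ok.any():
        raise CnError("no peak observed in enough reference samples")
    keep = reference.columns[ok]
    return Centroids(
        list(keep.astype(str)),
        gs[keep].mean(axis=0, skipna=True).to_numpy(),
        cin[keep].mean(axis=0, skipna=True).to_numpy(),
    )


def assign_subtype(sample_id: str, vector: pd.Series | np.ndarray, centroids: Centroids) -> SubtypeCall:
    """Assign one sample to GS or CIN by Euclidean distance.

    Missing peak dimensions are dropped from the sample vector AND from both
    centroids, so the two distances are computed over the identical
    dimension set. An exact tie is assigned GS with the tie flag set.
    """
    if isinstance(vector, pd.Series):
        vector = vector.reindex(centroids.peak_ids).to_numpy(dtype=float)
    else:
        vector = np.asarray(vector, dtype=float)
        if len(vector) != len(centroids.peak_ids):
            raise CnError(f"sample {sample_id}: vector not aligned to centroid peaks")
    ok = np.isfinite(vector)
    if not ok.any():
        raise CnError(f"sample {sample_id}: zero usable peak dimensions")
    d_gs = float(np.sqrt(np.sum((vector[ok] - centroids.mu_gs[ok]) ** 2)))
    d_cin = float(np.sqrt(np.sum((vector[ok] - centroids.mu_cin[ok]) ** 2)))
    tie = d_gs == d_cin
    label = GS if d_gs <= d_cin else CIN
    return SubtypeCall(sample_id, label, d_gs, d_cin, int(ok.sum()), tie)


def classify_samples(peak_matrix: pd.DataFrame, centroids: Centroids) -> pd.DataFrame:
    """Nearest-centroid calls for every row of a samples x peaks matrix."""
    calls = [assign_subtype(str(s), peak_matrix.loc[s], centroids) for s in peak_matrix.index]
    return pd.DataFrame(
        {
            "label": [c.label for c in calls],
            "d_GS": [c.d_gs for c in calls],
            "d_CIN": [c.d_cin for c in calls],
            "n_peaks_used": [c.n_peaks_used for c in calls],
            "tie_flag": [c.tie for c in calls],
        },
        index=pd.Index(peak_matrix.index, name="sample"),
    )


def stratify(
    calls: pd.DataFrame | pd.Series, lauren: Mapping[str, str] | pd.Series
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Combine GS/CIN calls with Lauren type into the four strata.

    Mixed-type tumors are grouped with diffuse (the worst differentiated
    component drives outcome); histologies outside the Lauren system
    ("other") are excluded. Returns (per-sample stratum, composition table
    with n and percent of the included total, n_excluded).
    """
    labels = calls["label"] if isinstance(calls, pd.DataFrame) else calls
    lauren = pd.Series(lauren).astype(str)
    aligned = lauren.reindex(labels.index)
    if aligned.isna().any():
        raise CnError("samples without a Lauren type")
    bad = set(aligned) - set(LAUREN_LEVELS)
    if bad:
        raise CnError(f"unknown Lauren categories: {sorted(bad)}")
    histo = aligned.replace({"mixed": "diffuse"})
    keep = histo != "other"
    n_excluded = int((~keep).sum())
    strata = (labels[keep] + "-" + histo[keep]).rename("stratum")
    if strata.empty:
        warnings.warn("no samples left after excluding 'other' histology", stacklevel=2)
    comp = composition_table(strata)
    return strata, comp, n_excluded


def composition_table(strata: pd.Series) -> pd.DataFrame:
    """n and percent per stratum (percent of the included total)."""
    n = strata.value_counts().reindex(STRATA, fill_value=0)
    total = int(n.sum())
    pct = 100.0 * n / total if total else n.astype(float)
    return pd.DataFrame({"n": n.astype(int), "percent": pct.round(1)})


def filter_cohort(clinical: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's inclusion filter to a clinical table.

    Drops tumors whose histology falls outside the Lauren system
    (``lauren == "other"``: mucinous, lymphoid-stroma and undifferentiated
    carcinomas) and tumors flagged ``insufficient_dna``. Returns the
    analyzable table plus exclusion counts.
    """
    excl = {}
    df = clinical
    if "lauren" in df.columns:
        drop = df["lauren"].astype(str) == "other"
        excl["other_histology"] = int(drop.sum())
        df = df.loc[~drop]
    if "insufficient_dna" in df.columns:
        drop = df["insufficient_dna"].astype(bool)
        excl["insufficient_dna"] = int(drop.sum())
        df = df.loc[~drop]
    excl["analyzable"] = len(df)
    return df, excl
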