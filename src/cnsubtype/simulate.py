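"""Synthetic cohort generation for end-to-end testing of the pipeline.

The generator emulates the statistical structure the analysis assumes:
binned log2 copy-number profiles arising from a tumor/normal admixture with
per-bin Gaussian noise, subgroup-specific recurrent peak events (CIN-like
tumors carry frequent gains — chromosome 8-style — and deletions, GS-like
tumors are near-diploid with an occasional chr8 gain), 5-level calls,
tumor purity drawn per sample, exponential cancer-related survival
calibrated per stratum to printed five-year rates, and Table-1-like
categorical covariates. Everything is seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cn_core import BinGrid, CnError, CnProfile, PeakRegion, DEFAULT_BIN_WIDTH
from .classify import STRATA

# five-year cancer-related survival per stratum (calibration constants)
DEFAULT_S5 = {
    "GS-intestinal": 0.614,
    "GS-diffuse": 0.565,
    "CIN-intestinal": 0.476,
    "CIN-diffuse": 0.315,
}

# observed cohort composition used as default stratum sizes
DEFAULT_N = {
    "GS-intestinal": 24,
    "GS-diffuse": 57,
    "CIN-intestinal": 142,
    "CIN-diffuse": 86,
}

# sex frequencies per stratum (male shares from the study's cohort table)
DEFAULT_COVARIATE_FREQS = {
    "sex": {
        "GS-intestinal": {"male": 9 / 24, "female": 15 / 24},
        "GS-diffuse": {"male": 23 / 57, "female": 34 / 57},
        "CIN-intestinal": {"male": 91 / 142, "female": 51 / 142},
        "CIN-diffuse": {"male": 40 / 86, "female": 46 / 86},
    }
}

# approximate hg19 chromosome sizes (Mb) for the genome-scale preset
_CHROM_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51, "X": 155,
}


def mini_grid(bin_width: int = DEFAULT_BIN_WIDTH) -> BinGrid:
    """Miniature 3-chromosome, 300-bin grid for fast tests."""
    return BinGrid.uniform({"1": 100 * bin_width, "8": 100 * bin_width, "17": 100 * bin_width},
                           bin_width)


def genome_grid(bin_width: int = DEFAULT_BIN_WIDTH) -> BinGrid:
    """Genome-scale preset (~31k bins, 22 autosomes + X)."""
    return BinGrid.uniform({c: mb * 1_000_000 for c, mb in _CHROM_MB.items()}, bin_width)


@dataclass(frozen=True)
class PeakTemplate:
    """A recurrent copy-number event and its per-subtype frequency.

    ``copy`` is the integer tumor copy state inside the event (baseline 2);
    ``f`` maps subtype (GS/CIN) to the per-sample event probability.
    """

    peak: PeakRegion
    copy: int
    f: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.f.items():
            if not (0.0 <= v <= 1.0):
                raise CnError(f"template {self.peak.peak_id}: probability {v} for {k}")


def default_templates() -> list[PeakTemplate]:
    """Default event templates on the miniature grid.

    24 one-Mb recurrent events, eight per chromosome (a scaled-down stand-in
    for a GISTIC peak catalog). CIN tumors carry frequent gains (chr8-style,
    copy 3-4, f 0.70-0.85) and deletions (17p-style, copy 1, f 0.60-0.75);
    GS tumors are near-diploid apart from chr8 gains at f = 0.3 and a 5%
    background rate elsewhere. Many moderately informative dimensions, not
    a few decisive ones, is what separates the clusters — the same geometry
    nearest-centroid assignment relies on with real peak catalogs.
    """
    plan = {  # chrom -> list of (kind, copy) in placement order
        "8": [("gain", 4), ("gain", 3), ("gain", 4), ("gain", 3),
              ("gain", 4), ("gain", 3), ("deletion", 1), ("deletion", 1)],
        "1": [("gain", 3), ("gain", 4), ("gain", 3), ("gain", 4),
              ("deletion", 1), ("deletion", 1), ("deletion", 1), ("deletion", 1)],
        "17": [("gain", 3), ("gain", 4), ("deletion", 1), ("deletion", 1),
               ("deletion", 1), ("deletion", 1), ("deletion", 1), ("deletion", 1)],
    }
    out = []
    k = 0
    for chrom, events in plan.items():
        for slot, (kind, copy) in enumerate(events):
            k += 1
            start = slot * 1_200_000 + 1  # 1-Mb peaks separated by 0.2-Mb gaps
            peak = PeakRegion(
                f"{'gain' if kind == 'gain' else 'del'}_{chrom}_{slot}",
                chrom, start, start + 1_000_000 - 1, kind,
                "CN-high" if k % 3 else "CN-low",
            )
            if kind == "gain":
                f_cin = 0.70 + 0.05 * (slot % 4)
                f_gs = 0.30 if (chrom == "8" and slot < 2) else 0.05
            else:
                f_cin = 0.60 + 0.05 * (slot % 4)
                f_gs = 0.05
            out.append(PeakTemplate(peak, copy, {"GS": f_gs, "CIN": f_cin}))
    return out


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort."""

    seed: int = 0
    n_strata: dict = field(default_factory=lambda: dict(DEFAULT_N))
    chrom_sizes: dict | None = None  # None -> miniature grid
    bin_width: int = DEFAULT_BIN_WIDTH
    templates: list = field(default_factory=default_templates)
    sigma: float = 0.15  # per-bin Gaussian noise sd on observed log2
    purity_range: tuple = (0.3, 0.9)
    s5: dict = field(default_factory=lambda: dict(DEFAULT_S5))
    censor_max_months: float = 120.0
    covariate_freqs: dict = field(default_factory=lambda: DEFAULT_COVARIATE_FREQS)
    sigma_ref: float = 0.10  # peak-level noise sd of the reference panel
    n_ref: int = 150  # reference samples per cluster
    # raw-cohort extras ahead of the inclusion filter
    n_other_histology: int = 0
    n_insufficient_dna: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise CnError("config field sigma must be >= 0")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise CnError("config field purity_range must lie in (0,1]")
        for k, v in self.s5.items():
            if not (0.0 < v < 1.0):
                raise CnError(f"config field s5[{k}] must be in (0,1)")
        for k in self.n_strata:
            if k not in STRATA:
                raise CnError(f"config field n_strata: unknown stratum {k!r}")

    def grid(self) -> BinGrid:
        if self.chrom_sizes is None:
            return mini_grid(self.bin_width)
        return BinGrid.uniform(self.chrom_sizes, self.bin_width)

    def peaks(self) -> list[PeakRegion]:
        return [t.peak for t in self.templates]


@dataclass
class SyntheticCohort:
    """A generated cohort: profiles, ground truth and clinical table."""

    config: SimConfig
    grid: BinGrid
    profiles: list
    truth: pd.DataFrame  # sample, stratum, subtype, lauren, purity
    clinical: pd.DataFrame | None = None

    @property
    def calls(self) -> pd.DataFrame:
        return pd.DataFrame(
            {p.sample_id: p.call for p in self.profiles}, dtype=np.int8
        ).T


def _call_from_copy(c: np.ndarray) -> np.ndarray:
    """5-level call from integer tumor copy (baseline 2)."""
    call = np.clip(c - 2, -2, 2)
    call[c == 1] = -1
    call[c == 0] = -2
    return call.astype(np.int8)


def mixture_log2(c, purity: float) -> np.ndarray:
    """Noiseless observed log2 of tumor copy c at the given purity."""
    return np.log2((purity * np.asarray(c, float) + 2.0 * (1.0 - purity)) / 2.0)


def simulate_profiles(config: SimConfig, rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Draw per-sample profiles (copy states, log2, calls) and truth labels."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    grid = config.grid()
    peak_bins = [
        grid.bins_in(t.peak.chrom, t.peak.start, t.peak.end) for t in config.templates
    ]
    profiles, rows = [], []
    i = 0
    for stratum in STRATA:
        n = int(config.n_strata.get(stratum, 0))
        subtype, lauren = stratum.split("-")
        for _ in range(n):
            i += 1
            sid = f"S{i:04d}"
            purity = float(rng.uniform(*config.purity_range))
            c = np.full(grid.n_bins, 2, dtype=np.int64)
            for t, bins in zip(config.templates, peak_bins):
                if rng.random() < t.f.get(subtype, 0.0):
                    c[bins] = t.copy
            seg = mixture_log2(c, purity)
            obs = seg + rng.normal(0.0, config.sigma, grid.n_bins)
            profiles.append(
                CnProfile(sid, purity, log2_seg=seg, log2_obs=obs, call=_call_from_copy(c))
            )
            rows.append((sid, stratum, subtype, lauren, purity))
    truth = pd.DataFrame(
        rows, columns=["sample", "stratum", "subtype", "lauren", "purity"]
    ).set_index("sample")
    return SyntheticCohort(config, grid, profiles, truth)


def simulate_survival(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Exponential survival calibrated to per-stratum five-year rates.

    Event hazard lambda_s = -ln(S5_s)/60 per month; independent censoring
    Uniform(0, censor_max_months). Returns time_months and event columns.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    strata = truth["stratum"]
    lam = strata.map(lambda s: -math.log(config.s5[s]) / 60.0).to_numpy(float)
    t_event = rng.exponential(1.0, len(strata)) / lam
    t_cens = rng.uniform(0.0, config.censor_max_months, len(strata))
    return pd.DataFrame(
        {
            "time_months": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        },
        index=strata.index,
    )


def simulate_covariates(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Categorical covariate draws from stratum-specific frequency tables."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    out = pd.DataFrame(index=truth.index)
    for var, per_stratum in config.covariate_freqs.items():
        vals = np.empty(len(truth), dtype=object)
        for stratum, freqs in per_stratum.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-6:
                raise CnError(f"frequencies for {var}/{stratum} sum to {tot}, not 1")
            sel = (truth["stratum"] == stratum).to_numpy()
            levels = list(freqs)
            draws = rng.choice(len(levels), size=int(sel.sum()), p=list(freqs.values()))
            vals[sel] = np.array(levels, dtype=object)[draws]
        out[var] = vals
    return out


def simulate_reference(
    config: SimConfig,
    n_ref: int | None = None,
    sigma_ref: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Labeled reference panel of peak-level log2 vectors.

    Cluster template means are the expected corrected log2 per peak,
    f * log2(copy/2); vectors are template mean + Normal(0, sigma_ref^2).
    Stands in for an external labeled reference cohort.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    n_ref = config.n_ref if n_ref is None else n_ref
    sigma_ref = config.sigma_ref if sigma_ref is None else sigma_ref
    if n_ref < 1:
        raise CnError("n_ref must be >= 1")
    peak_ids = [t.peak.peak_id for t in config.templates]
    rows, labels, ids = [], [], []
    for cluster in ("GS", "CIN"):
        # expected corrected log2 per peak: event prob * pure-tumor log2
        # (homozygous deletions floored at -10, the admixture-inversion floor)
        mu = np.array(
            [t.f.get(cluster, 0.0) * (math.log2(t.copy / 2.0) if t.copy > 0 else -10.0)
             for t in config.templates]
        )
        for i in range(n_ref):
            ids.append(f"REF_{cluster}_{i:03d}")
            labels.append(cluster)
            rows.append(mu + rng.normal(0.0, sigma_ref, len(mu)))
    ref = pd.DataFrame(rows, index=pd.Index(ids, name="sample"), columns=peak_ids)
    return ref, pd.Series(labels, index=ref.index, name="label")


def template_centroids(config: SimConfig) -> pd.DataFrame:
    """Noise-free cluster centroids implied by the templates."""
    ref, labels = simulate_reference(config, n_ref=1, sigma_ref=0.0)
    return pd.DataFrame(
        {
            "mu_GS": ref[labels == "GS"].iloc[0],
            "mu_CIN": ref[labels == "CIN"].iloc[0],
        }
    )


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Full cohort: profiles + truth + clinical (survival and covariates).

    If ``n_other_histology``/``n_insufficient_dna`` are set, that many extra
    non-analyzable samples (histology outside the Lauren system, or flagged
    as DNA failures) are appended to the clinical table so the inclusion
    filter can be exercised; they carry no profiles.
    """
    rng = np.random.default_rng(config.seed)
    cohort = simulate_profiles(config, rng)
    surv = simulate_survival(cohort.truth, config, rng)
    cov = simulate_covariates(cohort.truth, config, rng)
    clinical = pd.concat(
        [cohort.truth[["stratum", "subtype", "lauren", "purity"]], surv, cov], axis=1
    )
    clinical["insufficient_dna"] = False
    extra_rows = []
    n0 = len(clinical)
    for k in range(config.n_other_histology):
        extra_rows.append((f"X{n0 + k + 1:04d}", "other", False))
    n1 = n0 + config.n_other_histology
    for k in range(config.n_insufficient_dna):
        lauren = "intestinal" if rng.random() < 0.5 else "diffuse"
        extra_rows.append((f"X{n1 + k + 1:04d}", lauren, True))
    if extra_rows:
        extra = pd.DataFrame(
            extra_rows, columns=["sample", "lauren", "insufficient_dna"]
        ).set_index("sample")
        clinical = pd.concat([clinical, extra])
    cohort.clinical = clinical
    return cohort


def make_peak_catalog(
    grid: BinGrid,
    n_gain_high: int = 31,
    n_del_high: int = 45,
    n_gain_low: int = 13,
    n_del_low: int = 25,
    n_sex: int = 7,
    width: int = 1_000_000,
) -> list[PeakRegion]:
    """Deterministic peak catalog with the given category composition.

    Lays non-overlapping peaks of ``width`` bp across the grid's
    chromosomes round-robin; the last ``n_sex`` peaks are placed on the
    sex chromosome (which must be present in the grid).
    """
    cats = (
        [("gain", "CN-high")] * n_gain_high
        + [("deletion", "CN-high")] * n_del_high
        + [("gain", "CN-low")] * n_gain_low
        + [("deletion", "CN-low")] * n_del_low
    )
    autosomes = [c for c in grid.chromosomes if c not in ("X", "Y", "chrX", "chrY")]
    sex = [c for c in grid.chromosomes if c in ("X", "Y", "chrX", "chrY")]
    if n_sex > 0 and not sex:
        raise CnError("grid has no sex chromosome to place sex-chromosome peaks on")
    chrom_max = {c: int(grid.end[grid.chrom == c].max()) for c in grid.chromosomes}
    offsets = {c: 1 for c in grid.chromosomes}
    peaks = []
    n_auto = len(cats) - n_sex
    for i, (direction, src) in enumerate(cats):
        if i < n_auto:
            chrom = autosomes[i % len(autosomes)]
        else:
            chrom = sex[0]
        start = offsets[chrom]
        end = start + width - 1
        if end > chrom_max[chrom]:
            raise CnError(f"chromosome {chrom} too small for peak catalog")
        offsets[chrom] = end + 1 + width  # gap between consecutive peaks
        peaks.append(PeakRegion(f"peak_{i + 1:03d}", chrom, start, end, direction, src))
    return peaks
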