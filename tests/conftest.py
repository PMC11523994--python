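import numpy as np
import pandas as pd
import pytest

from cnsubtype import BinGrid, CnProfile, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def ten_bin_grid() -> BinGrid:
    """One chromosome, ten 100-kbp bins."""
    return BinGrid.uniform({"1": 1_000_000})


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (309 samples, miniature grid), seed 11."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_profile(grid: BinGrid, seg, purity=1.0, call=None, sample_id="S1", mask=None):
    seg = np.asarray(seg, dtype=float)
    return CnProfile(sample_id, purity, log2_seg=seg, call=call, mask=mask)


@pytest.fixture(scope="session")
def table1_clinical() -> pd.DataFrame:
    """Per-patient clinical table expanded from printed subgroup counts.

    Categorical counts per stratum for sex, pN stage, p53 and CDH1 IHC
    (including missing slides), as published for the 309-patient cohort.
    """
    strata = ["GS-intestinal", "GS-diffuse", "CIN-intestinal", "CIN-diffuse"]
    counts = {
        "sex": {"male": [9, 23, 91, 40], "female": [15, 34, 51, 46]},
        "pN": {"pN0": [14, 23, 44, 18], "pN1": [3, 7, 32, 16],
               "pN2": [2, 14, 39, 18], "pN3": [5, 13, 27, 34]},
        "p53_ihc": {"normal": [8, 27, 25, 24], "aberrant": [5, 7, 48, 29],
                    "missing": [11, 23, 69, 33]},
        "cdh1_ihc": {"normal": [11, 28, 71, 49], "aberrant": [3, 7, 5, 9],
                     "missing": [10, 22, 66, 28]},
    }
    n_per = [24, 57, 142, 86]
    rows = []
    for si, stratum in enumerate(strata):
        cols = {}
        for var, levels in counts.items():
            seq = []
            for level, per_stratum in levels.items():
                seq.extend([level] * per_stratum[si])
            assert len(seq) == n_per[si], (var, stratum)
            cols[var] = seq
        for i in range(n_per[si]):
            rows.append(
                {
                    "sample": f"{stratum}_{i:03d}",
                    "stratum": stratum,
                    "label": stratum.split("-")[0],
                    "lauren": stratum.split("-")[1],
                    **{var: cols[var][i] for var in counts},
                }
            )
    return pd.DataFrame(rows).set_index("sample")
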