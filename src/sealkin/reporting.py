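"""Secondary statistical checks on confirmed kin-pair tables.

A kin-pair table has one row per confirmed second-order pair with its PLOD
score, both birth years, the older animal's age at death, the birth gap,
and the mtDNA stratum ('M' = shared haplotype / maternally related,
'P' = not shared / paternally related).  The package ships the published
22-pair bearded-seal reference table (PLOD threshold 40) as a CSV fixture
so these checks run without any download.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_reference_kin_table",
    "binomial_mtdna_test",
    "chisq_sex_ratio_test",
    "birth_gap_summary",
    "same_cohort_phsp_count",
    "ggp_feasibility_flags",
]

_COLUMNS = ["plod", "birth_year_i", "age_i", "birth_year_j", "birth_gap", "mtdna", "rel_prob_hsp"]


def load_reference_kin_table() -> pd.DataFrame:
    """The shipped 22-pair reference kin table (older animal is *i*)."""
    with resources.files("sealkin.data").joinpath("kin_pair_table.csv").open() as fh:
        df = pd.read_csv(fh)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kin table missing columns {missing}")
    if (df["birth_gap"] < 0).any():
        raise ValueError("birth gaps must be non-negative (older animal first)")
    return df


def binomial_mtdna_test(n_paternal: int, n_total: int) -> float:
    """One-sided exact binomial p-value for paternal excess among HSPs.

    P(X >= n_paternal) with X ~ Binomial(n_total, 1/2): under equal male and
    female breeding shares, maternal and paternal half-sib pairs are equally
    likely, so a paternal excess signals male reproductive skew.
    """
    if not (0 <= n_paternal <= n_total):
        raise ValueError("need 0 <= n_paternal <= n_total")
    return float(stats.binom.sf(n_paternal - 1, n_total, 0.5))


def chisq_sex_ratio_test(observed: tuple, expected: tuple) -> tuple[float, float]:
    """Pearson chi-square (df=1) of observed vs expected M/P kin counts."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != (2,) or exp.shape != (2,):
        raise ValueError("observed and expected must each have two cells")
    if np.any(exp <= 0):
        raise ValueError("expected cell counts must be positive")
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def birth_gap_summary(table: pd.DataFrame) -> dict:
    """Per-stratum mean birth gaps and a Welch test of the difference.

    Larger paternal gaps suggest breeding males outlive breeding females on
    average.  With fewer than two pairs in either stratum only the means are
    returned (p-value None).
    """
    gaps_m = table.loc[table["mtdna"] == "M", "birth_gap"].to_numpy(dtype=float)
    gaps_p = table.loc[table["mtdna"] == "P", "birth_gap"].to_numpy(dtype=float)
    out = {
        "n_maternal": int(gaps_m.size),
        "n_paternal": int(gaps_p.size),
        "mean_maternal": float(gaps_m.mean()) if gaps_m.size else np.nan,
        "mean_paternal": float(gaps_p.mean()) if gaps_p.size else np.nan,
        "p_value": None,
    }
    if gaps_m.size >= 2 and gaps_p.size >= 2:
        if np.allclose(gaps_m.var(), 0) and np.allclose(gaps_p.var(), 0) and np.isclose(
            gaps_m.mean(), gaps_p.mean()
        ):
            out["p_value"] = 1.0
        else:
            out["p_value"] = float(stats.ttest_ind(gaps_p, gaps_m, equal_var=False).pvalue)
    return out


def same_cohort_phsp_count(table: pd.DataFrame) -> int:
    """Paternally related pairs born in the same year (polygyny signature)."""
    return int(((table["mtdna"] == "P") & (table["birth_gap"] == 0)).sum())


def ggp_feasibility_flags(table: pd.DataFrame, min_breeding_age: int = 5) -> pd.Series:
    """Grandparent-pair feasibility per row.

    Requires a birth gap of at least two generations and an older animal
    that lived to breeding age (lethal sampling: age_i is its age at death).
    """
    return (table["birth_gap"] >= 2 * min_breeding_age) & (table["age_i"] >= min_breeding_age)
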