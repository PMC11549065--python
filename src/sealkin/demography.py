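"""Age-structured demography for a long-lived phocid.

Survival follows a reduced additive Weibull (RAW) hazard, which produces the
"bathtub" mortality curve typical of pinnipeds: high pup mortality, low
young-adult mortality, and a senescent increase.  Cumulative survivorship to
exact age ``a`` is

    S(a) = exp(-[(eta1*a)**eta2 + (eta1*a)**(1/eta2) + eta3*a])

and the annual survival probability of age class ``a`` is
``phi_a = S(a+1)/S(a)``.

Reproduction uses a female fecundity schedule ``f_a`` (expected pups per
female per year, at most one pup) and a male maturity schedule ``m_a``
(relative male reproductive weight at age).  A post-breeding census Leslie
matrix ties the schedules together; its dominant eigenvalue is the finite
annual growth rate ``lambda``.  Ages are integer years, age class 0 is pups,
and the maximum lifespan is 40 years (age classes 0..39).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "MAX_AGE",
    "N_AGES",
    "RawSurvivalParams",
    "DEFAULT_RAW",
    "raw_survivorship",
    "annual_survival",
    "logistic_ogive",
    "knife_edge",
    "LifeHistorySchedules",
    "build_schedules",
    "leslie_matrix",
    "growth_rate",
    "stable_age_distribution",
    "PopulationTrajectory",
    "project",
    "stable_trajectory",
]

MAX_AGE = 39  #: oldest age class; animals die before reaching age 40
N_AGES = MAX_AGE + 1


@dataclass(frozen=True)
class RawSurvivalParams:
    """Parameters of the reduced additive Weibull survival model.

    eta1 : hazard scale (1/years), >= 0
    eta2 : shape (dimensionless), > 0
    eta3 : linear hazard component (1/years), >= 0
    """

    eta1: float = 0.055
    eta2: float = 2.80
    eta3: float = 0.076

    def __post_init__(self) -> None:
        if not (self.eta1 >= 0):
            raise ValueError(f"eta1 must be >= 0, got {self.eta1}")
        if not (self.eta2 > 0):
            raise ValueError(f"eta2 must be > 0, got {self.eta2}")
        if not (self.eta3 >= 0):
            raise ValueError(f"eta3 must be >= 0, got {self.eta3}")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta1, self.eta2, self.eta3], dtype=float)


#: Prior means from the phocid mortality meta-analysis used as defaults.
DEFAULT_RAW = RawSurvivalParams()


def raw_survivorship(params: RawSurvivalParams, age) -> Union[float, np.ndarray]:
    """Cumulative survivorship S(age) under the RAW model.

    S(0) = 1; negative ages raise ``ValueError``.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    x = params.eta1 * a
    hazard = x**params.eta2 + x ** (1.0 / params.eta2) + params.eta3 * a
    out = np.exp(-hazard)
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


def annual_survival(params: RawSurvivalParams, max_age: int = MAX_AGE) -> np.ndarray:
    """Annual survival phi_a = S(a+1)/S(a) for a = 0..max_age."""
    ages = np.arange(max_age + 2, dtype=float)
    S = raw_survivorship(params, ages)
    return S[1:] / S[:-1]


def logistic_ogive(
    ages: np.ndarray, midpoint: float, slope: float = 1.0, asymptote: float = 1.0
) -> np.ndarray:
    """Logistic maturity/fecundity ogive; value 0 forced at age 0 (pups)."""
    out = asymptote / (1.0 + np.exp(-(np.asarray(ages, float) - midpoint) / slope))
    out = np.asarray(out, float)
    out[np.asarray(ages) == 0] = 0.0
    return out


def knife_edge(ages: np.ndarray, age_at_maturity: int = 4, level: float = 1.0) -> np.ndarray:
    """Knife-edge schedule: 0 below ``age_at_maturity``, ``level`` at and above."""
    return np.where(np.asarray(ages) >= age_at_maturity, level, 0.0)


def _resolve_spec(spec, ages: np.ndarray, kind: str) -> np.ndarray:
    """Turn a schedule spec (name, dict, or array) into an age-indexed vector."""
    if isinstance(spec, str):
        if spec == "default":
            if kind == "fecundity":
                return logistic_ogive(ages, midpoint=5.0, slope=1.0, asymptote=0.95)
            return logistic_ogive(ages, midpoint=6.0, slope=1.0, asymptote=1.0)
        if spec == "knife_edge":
            return knife_edge(ages, age_at_maturity=4, level=1.0)
        raise ValueError(f"unknown schedule spec {spec!r}")
    if isinstance(spec, dict):
        return logistic_ogive(ages, **spec)
    arr = np.asarray(spec, dtype=float)
    if arr.shape[0] < ages.shape[0]:
        raise ValueError(
            f"{kind} table has {arr.shape[0]} entries, need {ages.shape[0]} (ages 0..{ages[-1]})"
        )
    return arr[: ages.shape[0]].copy()


@dataclass
class LifeHistorySchedules:
    """Aligned survival, fecundity, and male maturity vectors over ages 0..max_age."""

    phi: np.ndarray
    fecundity: np.ndarray
    maturity: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.fecundity = np.asarray(self.fecundity, dtype=float)
        self.maturity = np.asarray(self.maturity, dtype=float)
        n = self.phi.shape[0]
        if self.fecundity.shape[0] != n or self.maturity.shape[0] != n:
            raise ValueError("phi, fecundity and maturity must have equal length")
        for name, v in (("phi", self.phi), ("fecundity", self.fecundity), ("maturity", self.maturity)):
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")

    @property
    def max_age(self) -> int:
        return self.phi.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.phi.shape[0])

    @classmethod
    def from_raw(
        cls,
        params: RawSurvivalParams = DEFAULT_RAW,
        fecundity_spec="default",
        maturity_spec="default",
        max_age: int = MAX_AGE,
    ) -> "LifeHistorySchedules":
        ages = np.arange(max_age + 1)
        phi = annual_survival(params, max_age=max_age)[: max_age + 1].copy()
        phi[max_age] = 0.0  # lifespan cap: nobody survives past the oldest age class
        f = _resolve_spec(fecundity_spec, ages, "fecundity")
        m = _resolve_spec(maturity_spec, ages, "maturity")
        return cls(phi=phi, fecundity=f, maturity=m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "survival": self.phi,
                "fecundity": self.fecundity,
                "male_maturity": self.maturity,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeHistorySchedules":
        df = pd.read_csv(path)
        required = {"age", "survival", "fecundity", "male_maturity"}
        if not required.issubset(df.columns):
            raise ValueError(f"schedule CSV needs columns {sorted(required)}")
        df = df.sort_values("age")
        return cls(
            phi=df["survival"].to_numpy(),
            fecundity=df["fecundity"].to_numpy(),
            maturity=df["male_maturity"].to_numpy(),
        )


def build_schedules(
    params: RawSurvivalParams = DEFAULT_RAW,
    fecundity_spec="default",
    maturity_spec="default",
    max_age: int = MAX_AGE,
) -> LifeHistorySchedules:
    """Convenience wrapper around :meth:`LifeHistorySchedules.from_raw`."""
    return LifeHistorySchedules.from_raw(params, fecundity_spec, maturity_spec, max_age)


def leslie_matrix(schedules: LifeHistorySchedules) -> np.ndarray:
    """Female Leslie matrix under a post-breeding census.

    A female of age a survives with phi_a and, if she survives, produces
    0.5 * f_{a+1} daughters counted at the next census.
    """
    n = schedules.max_age + 1
    A = np.zeros((n, n))
    phi, f = schedules.phi, schedules.fecundity
    A[0, : n - 1] = 0.5 * phi[: n - 1] * f[1:n]
    idx = np.arange(n - 1)
    A[idx + 1, idx] = phi[: n - 1]
    return A


def _dominant_eig(A: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eig(A)
    k = int(np.argmax(vals.real))
    lam = vals[k]
    if abs(lam.imag) > 1e-8 * max(1.0, abs(lam.real)):
        raise ValueError("dominant eigenvalue is complex; degenerate projection matrix")
    v = vecs[:, k].real
    v = np.abs(v)
    total = v.sum()
    if lam.real <= 0 or total <= 0:
        raise ValueError("no positive dominant eigenvalue/eigenvector (reducible matrix?)")
    return float(lam.real), v / total


def growth_rate(schedules: LifeHistorySchedules) -> float:
    """Finite annual growth rate lambda (dominant Leslie eigenvalue)."""
    lam, _ = _dominant_eig(leslie_matrix(schedules))
    return lam


def stable_age_distribution(schedules: LifeHistorySchedules) -> np.ndarray:
    """Stable age proportions (sums to 1 over age classes, per sex)."""
    _, u = _dominant_eig(leslie_matrix(schedules))
    return u


@dataclass
class PopulationTrajectory:
    """Expected female/male counts per age class and year.

    ``NF[t, a]`` is the expected number of females of age ``a`` alive in
    calendar year ``start_year + t`` (post-breeding census); ``NM == NF``
    under the 50/50 sex-ratio assumption.
    """

    start_year: int
    NF: np.ndarray
    NM: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.NF = np.asarray(self.NF, dtype=float)
        self.NM = np.asarray(self.NM, dtype=float)
        if self.NF.shape != self.NM.shape:
            raise ValueError("NF and NM must have identical shape")
        if np.any(self.NF < 0) or np.any(self.NM < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_years(self) -> int:
        return self.NF.shape[0]

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)

    def index(self, year: int) -> int:
        t = int(year) - self.start_year
        if t < 0 or t >= self.n_years:
            raise KeyError(f"year {year} outside trajectory {self.start_year}..{self.years[-1]}")
        return t

    def female(self, year: int) -> np.ndarray:
        return self.NF[self.index(year)]

    def male(self, year: int) -> np.ndarray:
        return self.NM[self.index(year)]

    def total(self, year=None):
        if year is None:
            return (self.NF + self.NM).sum(axis=1)
        return float(self.NF[self.index(year)].sum() + self.NM[self.index(year)].sum())


def project(
    schedules: LifeHistorySchedules,
    n0_total: float,
    n_years: int,
    start_year: int = 0,
) -> PopulationTrajectory:
    """Project the population forward from a stable age composition.

    Aging: NF[t, a] = NF[t-1, a-1] * phi_{a-1}; recruitment:
    NF[t, 0] = 0.5 * sum_a NF[t, a] * f_a (post-breeding census, 50/50
    sex ratio at birth).
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    n = schedules.max_age + 1
    try:
        lam, u = _dominant_eig(leslie_matrix(schedules))
    except ValueError:
        # no positive stable structure (e.g. zero fecundity): start uniform
        lam, u = 0.0, np.full(n, 1.0 / n)
    NF = np.zeros((n_years + 1, n))
    NF[0] = 0.5 * n0_total * u
    phi, f = schedules.phi, schedules.fecundity
    for t in range(1, n_years + 1):
        aged = NF[t - 1, :-1] * phi[:-1]
        NF[t, 1:] = aged
        NF[t, 0] = 0.5 * float(aged @ f[1:])
    return PopulationTrajectory(start_year=start_year, NF=NF, NM=NF.copy(), lam=lam)


def stable_trajectory(
    schedules: LifeHistorySchedules,
    total_abundance: float,
    start_year: int,
    end_year: int,
    ref_year: int | None = None,
    lam_override: float | None = None,
) -> PopulationTrajectory:
    """Geometric trajectory on the stable age distribution.

    Total abundance (both sexes, all ages) equals ``total_abundance`` in
    ``ref_year`` (default: ``end_year``) and scales by ``lambda`` per year.
    ``lam_override`` pins the growth rate (e.g., 1.0 for an assumed-stable
    population) while keeping the schedule's stable age proportions.
    """
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    lam, u = _dominant_eig(leslie_matrix(schedules))
    if lam_override is not None:
        lam = float(lam_override)
    if ref_year is None:
        ref_year = end_year
    years = np.arange(start_year, end_year + 1)
    scale = total_abundance * lam ** (years - ref_year)
    NF = 0.5 * scale[:, None] * u[None, :]
    return PopulationTrajectory(start_year=start_year, NF=NF, NM=NF.copy(), lam=lam)
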