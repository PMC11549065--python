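"""Pairwise kinship probability kernels for lethally sampled animals.

Every kernel answers: given the covariates of two sampled animals (sex,
birth year, death year, mtDNA haplotype) and an expected population
trajectory, what is the probability that a particular kin relationship holds
between them?  The kernels implemented here are

* ``p_pop``   - parent-offspring (maternal or paternal, depending on the
  candidate parent's sex),
* ``p_mhsp`` / ``p_phsp`` - maternal / paternal half siblings (the shared
  parent is unobserved),
* ``p_ggp``   - grandparent-grandchild, summed over the unobserved
  intermediate parent, stratified by whether the pair shares mtDNA,
* ``p_second_order`` - the HSP+GGP mixture actually observable from a
  second-order PLOD call, discounted by the kin-calling false-negative rate.

Sampling is lethal (sampling year == death year), so a candidate parent must
have been alive in the offspring's birth year.  Persistent heterogeneity in
male breeding success enters through ``pi``, the fraction of mature males
that ever breed: conditional on one known offspring a father is a confirmed
breeder, which shrinks the competing-father pool by the factor ``pi`` and
inflates paternal half-sib probabilities by ``1/pi``.  mtDNA is inherited
maternally, so maternal half-sibs always share a haplotype, paternal ones
never do, and grandparent pairs share only along the all-female chain
(chance haplotype sharing is neglected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .demography import LifeHistorySchedules, PopulationTrajectory

__all__ = [
    "SampleRecord",
    "KinKernelContext",
    "p_pop",
    "p_mhsp",
    "p_phsp",
    "p_ggp",
    "p_second_order",
    "rel_prob_hsp",
    "evaluate_pairs",
]


@dataclass
class SampleRecord:
    """Covariates of one sampled (harvested) animal."""

    id: str
    sex: str  # 'F' or 'M'
    birth_year: int
    death_year: int
    mtdna: Optional[str] = None
    village: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.death_year < self.birth_year:
            raise ValueError(f"{self.id}: death year precedes birth year")
        if self.age > 40:
            raise ValueError(f"{self.id}: age {self.age} exceeds maximum lifespan")

    @property
    def age(self) -> int:
        """Age at death (lethal sampling: sampling year == death year)."""
        return self.death_year - self.birth_year


class KinKernelContext:
    """Demographic context shared by all kernel evaluations.

    Precomputes reproductive-output denominators per year and cumulative
    survivorship so that individual kernel calls are cheap.
    """

    def __init__(
        self,
        trajectory: PopulationTrajectory,
        schedules: LifeHistorySchedules,
        pi: float = 1.0,
        fn_rate: float = 0.0,
    ) -> None:
        if not (0.0 < pi <= 1.0):
            raise ValueError(f"pi must lie in (0, 1], got {pi}")
        if not (0.0 <= fn_rate < 1.0):
            raise ValueError(f"fn_rate must lie in [0, 1), got {fn_rate}")
        self.trajectory = trajectory
        self.schedules = schedules
        self.pi = float(pi)
        self.fn_rate = float(fn_rate)

        n = schedules.max_age + 1
        self.n_ages = n
        phi = schedules.phi
        # cumulative survivorship from birth: C[a] = prod(phi[0:a]); C[n]=0 via cap
        C = np.ones(n + 1)
        C[1:] = np.cumprod(phi)
        self.C = C
        # zero-padded schedules so age+gap lookups beyond the last class give 0
        pad = n + trajectory.n_years + 1
        self.fpad = np.zeros(pad)
        self.fpad[:n] = schedules.fecundity
        self.mpad = np.zeros(pad)
        self.mpad[:n] = schedules.maturity
        self.Cpad = np.zeros(pad + 1)
        self.Cpad[: n + 1] = C

        NF, NM = trajectory.NF, trajectory.NM
        self.denomF = NF @ schedules.fecundity  # total female reproductive output per year
        self.denomM = NM @ schedules.maturity  # total male reproductive weight per year
        self.pups = NF[:, 0] + NM[:, 0]  # total pups per year
        self._cubes: dict | None = None

    # -- helpers -----------------------------------------------------------
    def _t(self, year: int) -> int:
        return self.trajectory.index(year)

    def surv_prod(self, a: int, delta: int) -> float:
        """P(survive from age a to age a+delta)."""
        if delta == 0:
            return 1.0
        Ca = self.Cpad[a]
        if Ca <= 0:
            return 0.0
        return self.Cpad[a + delta] / Ca

    # -- vectorized year-pair matrices (used by the likelihood) ------------
    def mother_age_weights(self, t: int) -> np.ndarray:
        w = self.trajectory.NF[t] * self.schedules.fecundity
        s = w.sum()
        return w / s if s > 0 else w

    def father_age_weights(self, t: int) -> np.ndarray:
        w = self.trajectory.NM[t] * self.schedules.maturity
        s = w.sum()
        return w / s if s > 0 else w

    def hsp_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(maternal, paternal) HSP probability matrices over (t_i, t_j).

        Entry [ti, tj] is the probability that animals born in trajectory
        years ti <= tj share a mother (resp. father).  Maternal entries with
        ti == tj are 0 (one pup per female per year); paternal ones are not.
        Entries with ti > tj are 0.
        """
        T = self.trajectory.n_years
        n = self.n_ages
        ages = np.arange(n)
        deltas = np.arange(T)
        # SPf[a, d] = P(survive a -> a+d) * f_{a+d}; likewise for maturity
        surv = np.where(
            self.Cpad[ages, None] > 0,
            self.Cpad[ages[:, None] + deltas[None, :]] / np.maximum(self.Cpad[ages, None], 1e-300),
            0.0,
        )
        SPf = surv * self.fpad[ages[:, None] + deltas[None, :]]
        SPm = surv * self.mpad[ages[:, None] + deltas[None, :]]

        WF = self.trajectory.NF * self.schedules.fecundity
        rs = WF.sum(axis=1, keepdims=True)
        WF = np.divide(WF, rs, out=np.zeros_like(WF), where=rs > 0)
        WM = self.trajectory.NM * self.schedules.maturity
        rs = WM.sum(axis=1, keepdims=True)
        WM = np.divide(WM, rs, out=np.zeros_like(WM), where=rs > 0)

        Km = WF @ SPf  # [ti, delta]
        Kp = WM @ SPm
        ti_idx = np.arange(T)[:, None]
        tj_idx = np.arange(T)[None, :]
        d = tj_idx - ti_idx
        valid = d >= 0
        dF = np.where(self.denomF > 0, self.denomF, np.inf)
        dM = np.where(self.denomM > 0, self.denomM, np.inf)
        Pm = np.where(valid & (d >= 1), np.take_along_axis(Km, np.clip(d, 0, T - 1), axis=1), 0.0)
        Pm = Pm / dF[None, :]
        Pp = np.where(valid, np.take_along_axis(Kp, np.clip(d, 0, T - 1), axis=1), 0.0)
        Pp = Pp / (self.pi * dM[None, :])
        return Pm, Pp

    def ggp_cubes(self) -> dict:
        """Cumulative grandparent-chain tensors, indexed [ti, c, tj].

        ``shared``  : older female -> daughter -> grandchild (mtDNA shared)
        ``non_f``   : older female -> son -> grandchild
        ``non_m``   : older male -> either-sex child -> grandchild
        Cumulated along the intermediate birth year ``c`` so that the
        lethal-sampling constraint (grandparent alive at c, i.e. c <= death
        year) is a single prefix lookup.
        """
        if self._cubes is not None:
            return self._cubes
        T = self.trajectory.n_years
        n = self.n_ages
        f, m, C = self.fpad, self.mpad, self.Cpad

        # grandparent expected offspring of one sex born at year c
        GF = np.zeros((T, T))  # older female
        GM = np.zeros((T, T))  # older male
        for ti in range(T):
            cs = np.arange(ti + 1, T)
            alpha = cs - ti
            ok = alpha < n
            GF[ti, cs[ok]] = 0.5 * f[alpha[ok]]
            with np.errstate(invalid="ignore", divide="ignore"):
                gm = 0.5 * m[alpha[ok]] * self.pups[cs[ok]] / np.where(
                    self.denomM[cs[ok]] > 0, self.denomM[cs[ok]], np.inf
                )
            GM[ti, cs[ok]] = gm

        # intermediate parent: survive from birth to age (tj - c), then breed
        HF = np.zeros((T, T))  # intermediate female, indexed [c, tj]
        HM = np.zeros((T, T))
        for c in range(T):
            tjs = np.arange(c + 1, T)
            g = tjs - c
            ok = g < n
            with np.errstate(invalid="ignore", divide="ignore"):
                HF[c, tjs[ok]] = C[g[ok]] * f[g[ok]] / np.where(
                    self.denomF[tjs[ok]] > 0, self.denomF[tjs[ok]], np.inf
                )
                HM[c, tjs[ok]] = C[g[ok]] * m[g[ok]] / np.where(
                    self.denomM[tjs[ok]] > 0, self.denomM[tjs[ok]], np.inf
                )

        shared = np.cumsum(GF[:, :, None] * HF[None, :, :], axis=1)
        non_f = np.cumsum(GF[:, :, None] * HM[None, :, :], axis=1)
        non_m = np.cumsum(GM[:, :, None] * (HF + HM)[None, :, :], axis=1)
        self._cubes = {"shared": shared, "non_f": non_f, "non_m": non_m}
        return self._cubes


def _check_ordered(older: SampleRecord, younger: SampleRecord) -> int:
    delta = younger.birth_year - older.birth_year
    if delta < 0:
        raise ValueError("pair must be ordered by birth year (older first)")
    return delta


def p_pop(parent: SampleRecord, offspring: SampleRecord, ctx: KinKernelContext) -> float:
    """Probability that ``parent`` is the mother/father of ``offspring``.

    A randomly sampled mature male is a breeder with probability pi but each
    breeder's paternity share is 1/(pi * sum N*m), so pi cancels for POPs.
    """
    b = offspring.birth_year
    t = ctx._t(b)
    a = b - parent.birth_year
    if a < 1 or a >= ctx.n_ages:
        return 0.0
    if parent.death_year < b:  # dead before the offspring's birth/mating year
        return 0.0
    if parent.sex == "F":
        denom = ctx.denomF[t]
        return float(ctx.schedules.fecundity[a] / denom) if denom > 0 else 0.0
    denom = ctx.denomM[t]
    return float(ctx.schedules.maturity[a] / denom) if denom > 0 else 0.0


def p_mhsp(older: SampleRecord, younger: SampleRecord, ctx: KinKernelContext) -> float:
    """Probability the pair shares an (unobserved) mother.

    Zero for a same-cohort pair: a female has at most one pup per year.
    """
    delta = _check_ordered(older, younger)
    if delta == 0:
        return 0.0
    ti, tj = ctx._t(older.birth_year), ctx._t(younger.birth_year)
    if ctx.denomF[tj] <= 0:
        return 0.0
    w = ctx.mother_age_weights(ti)
    ages = np.arange(ctx.n_ages)
    surv = np.where(ctx.Cpad[ages] > 0, ctx.Cpad[ages + delta] / np.maximum(ctx.Cpad[ages], 1e-300), 0.0)
    return float((w * surv * ctx.fpad[ages + delta]).sum() / ctx.denomF[tj])


def p_phsp(older: SampleRecord, younger: SampleRecord, ctx: KinKernelContext) -> float:
    """Probability the pair shares an (unobserved) father.

    Same-cohort pairs are allowed (a male can breed with several females in
    one season).  The confirmed-breeder conditioning divides the competing
    pool by pi.
    """
    delta = _check_ordered(older, younger)
    ti, tj = ctx._t(older.birth_year), ctx._t(younger.birth_year)
    if ctx.denomM[tj] <= 0:
        return 0.0
    w = ctx.father_age_weights(ti)
    ages = np.arange(ctx.n_ages)
    surv = np.where(ctx.Cpad[ages] > 0, ctx.Cpad[ages + delta] / np.maximum(ctx.Cpad[ages], 1e-300), 0.0)
    return float((w * surv * ctx.mpad[ages + delta]).sum() / (ctx.pi * ctx.denomM[tj]))


def p_ggp(
    older: SampleRecord,
    younger: SampleRecord,
    shares_mtdna: bool,
    ctx: KinKernelContext,
) -> float:
    """Probability that ``older`` is a grandparent of ``younger``.

    Sums over the unobserved intermediate parent's sex and birth year c in
    (b_older, b_younger).  The grandparent must be alive at c (lethal
    sampling), the intermediate must survive from birth to breeding age, and
    the intermediate's share of that year's reproduction follows the same
    construction as the parent kernels.  A male grandparent can never share
    mtDNA with the grandchild; a female one shares it only through a
    daughter.  The breeder fraction pi cancels for unconditioned male links.
    """
    _check_ordered(older, younger)
    if shares_mtdna and older.sex == "M":
        return 0.0
    ti, tj = ctx._t(older.birth_year), ctx._t(younger.birth_year)
    if tj - ti < 2:
        return 0.0
    cubes = ctx.ggp_cubes()
    c_hi = min(tj - 1, ctx._t(min(older.death_year, ctx.trajectory.years[-1])))
    if c_hi <= ti:
        return 0.0
    if older.sex == "F":
        key = "shared" if shares_mtdna else "non_f"
        return float(cubes[key][ti, c_hi, tj])
    return float(cubes["non_m"][ti, c_hi, tj])


def p_second_order(
    older: SampleRecord,
    younger: SampleRecord,
    shares_mtdna: Optional[bool],
    ctx: KinKernelContext,
) -> float:
    """Probability of a second-order PLOD call (HSP+GGP mixture).

    Maternal half-sibs contribute only to the mtDNA-shared stratum, paternal
    ones only to the non-shared stratum; ``shares_mtdna=None`` (haplotype
    missing) pools both strata.  The false-negative rate discounts the whole
    mixture because the PLOD threshold acts on the pooled second-order class.
    """
    keep = 1.0 - ctx.fn_rate
    if shares_mtdna is None:
        return keep * (
            p_mhsp(older, younger, ctx)
            + p_phsp(older, younger, ctx)
            + p_ggp(older, younger, True, ctx)
            + p_ggp(older, younger, False, ctx)
        )
    if shares_mtdna:
        return keep * (p_mhsp(older, younger, ctx) + p_ggp(older, younger, True, ctx))
    return keep * (p_phsp(older, younger, ctx) + p_ggp(older, younger, False, ctx))


def rel_prob_hsp(
    older: SampleRecord,
    younger: SampleRecord,
    shares_mtdna: Optional[bool],
    ctx: KinKernelContext,
) -> float:
    """P(HSP) / (P(HSP) + P(GGP)) for an observed second-order pair.

    Returns NaN (with a warning) when both components are zero.
    """
    if shares_mtdna is None:
        hsp = p_mhsp(older, younger, ctx) + p_phsp(older, younger, ctx)
        ggp = p_ggp(older, younger, True, ctx) + p_ggp(older, younger, False, ctx)
    elif shares_mtdna:
        hsp = p_mhsp(older, younger, ctx)
        ggp = p_ggp(older, younger, True, ctx)
    else:
        hsp = p_phsp(older, younger, ctx)
        ggp = p_ggp(older, younger, False, ctx)
    if hsp + ggp <= 0:
        warnings.warn(
            f"relative HSP probability undefined for pair ({older.id}, {younger.id}): "
            "both kin probabilities are zero"
        )
        return float("nan")
    return hsp / (hsp + ggp)


def evaluate_pairs(
    pairs: list[tuple[SampleRecord, SampleRecord]],
    ctx: KinKernelContext,
) -> pd.DataFrame:
    """Long-format kernel evaluations for a list of (older, younger) pairs."""
    rows = []
    for older, younger in pairs:
        shared = (
            None
            if older.mtdna is None or younger.mtdna is None
            else older.mtdna == younger.mtdna
        )
        stratum = "U" if shared is None else ("M" if shared else "P")
        rows.extend(
            [
                (older.id, younger.id, "MHSP", stratum, p_mhsp(older, younger, ctx)),
                (older.id, younger.id, "PHSP", stratum, p_phsp(older, younger, ctx)),
                (
                    older.id,
                    younger.id,
                    "GGP",
                    stratum,
                    p_ggp(older, younger, True, ctx) + p_ggp(older, younger, False, ctx),
                ),
                (older.id, younger.id, "HSP-GGP", stratum, p_second_order(older, younger, shared, ctx)),
            ]
        )
    return pd.DataFrame(rows, columns=["older_id", "younger_id", "kin_class", "mtdna_stratum", "probability"])
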