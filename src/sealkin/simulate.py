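"""Individual-based pedigree, genotype, and harvest-sampling simulator.

The generator realizes exactly the statistical structure the CKMR kernels
assume: an age-structured population with RAW survival and one pup per
female per year, persistent heterogeneity in male breeding success (a
lifelong "breeder" flag held by a fraction ``pi`` of males, with paternity
weighted by the maturity schedule among breeders), strictly maternal mtDNA
inheritance, harvest sampling skewed towards young animals, and biallelic
SNPs with heritable null alleles transmitted Mendelian-fashion.

Harvest removal happens inside the yearly loop (sampling is lethal: a
sampled female cannot whelp in a later year), so the harvest design is part
of the simulation configuration rather than a post hoc draw.

Default settings emulate the Bering-Chukchi-Beaufort bearded seal study
system: ~3x10^5 animals, 1998-2020 harvests ramping to ~100 seals/year with
46% pups, 40 founder mtDNA haplotypes, and a 2569-locus SNP panel including
seven male-specific sexing markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .demography import (
    LifeHistorySchedules,
    stable_age_distribution,
    stable_trajectory,
)
from .genotypes import CLASS_AA, CLASS_AB, CLASS_BB, CLASS_FAIL, GenotypePanel
from .kernels import KinKernelContext, SampleRecord

__all__ = [
    "HarvestDesign",
    "study_harvest_design",
    "GenotypeDesign",
    "SimConfig",
    "Pedigree",
    "simulate_pedigree",
    "sample_harvest",
    "simulate_genotypes",
    "haplotype_sequences",
    "expected_kin_counts_analytic",
    "power_analysis",
]

_PRIORITY = {"POP": 0, "FSP": 1, "MHSP": 2, "PHSP": 2, "GGP": 3, "FTP": 4, "HTP": 5}


@dataclass
class HarvestDesign:
    """Per-year harvest sizes and the target age-class mix.

    ``age_classes`` are (lo, hi) inclusive age bounds with ``weights`` the
    share of each year's sample drawn from that class (pups, juveniles,
    older animals by default).  Within a class, animals are drawn uniformly
    from those alive, so the within-class age mix follows the population.
    """

    years: np.ndarray
    n_per_year: np.ndarray
    age_classes: tuple = ((0, 0), (1, 3), (4, 39))
    weights: tuple = (0.46, 0.193, 0.347)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.n_per_year = np.asarray(self.n_per_year, dtype=int)
        if self.years.shape != self.n_per_year.shape:
            raise ValueError("years and n_per_year must align")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("age-class weights must sum to 1")

    @property
    def total(self) -> int:
        return int(self.n_per_year.sum())


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    s = weights.sum()
    if s <= 0 or total <= 0:
        return np.zeros_like(weights, dtype=int)
    raw = total * weights / s
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def study_harvest_design(
    total: int = 1484, start_year: int = 1998, end_year: int = 2020
) -> HarvestDesign:
    """Harvest profile shaped like the Alaska biomonitoring collections:

    under 10 samples/year in the late 1990s, 80-90 by 2009, just under 100
    per year thereafter, 46% pups overall.
    """
    years = np.arange(start_year, end_year + 1)
    profile = np.interp(years, [1998, 2001, 2005, 2009, 2012, 2020], [5, 12, 45, 85, 95, 100])
    n = _largest_remainder(total, profile)
    return HarvestDesign(years=years, n_per_year=n)


@dataclass
class GenotypeDesign:
    """SNP-panel design for the genotype simulator.

    Allele frequencies mimic a post-QC kin-finding panel: visible minor
    allele frequency uniform on [minor_min, minor_max] and a modest
    heritable null-allele frequency uniform on [0, nu_max].
    """

    n_loci: int = 2562
    n_sex_linked: int = 7
    minor_min: float = 0.05
    minor_max: float = 0.5
    nu_max: float = 0.2
    fail_rate: float = 0.01


@dataclass
class SimConfig:
    """Study-system configuration for the individual-based simulator."""

    n_initial: float = 300_000
    schedules: LifeHistorySchedules = None
    pi: float = 0.34
    harvest: HarvestDesign = None
    genotypes: GenotypeDesign = field(default_factory=GenotypeDesign)
    n_haplotypes: int = 40
    burn_in: int = 45
    annual_breeder_reassignment: bool = False  # sensitivity switch; default persistent

    def __post_init__(self) -> None:
        if self.schedules is None:
            self.schedules = LifeHistorySchedules.from_raw()
        if self.harvest is None:
            self.harvest = study_harvest_design()
        if not (0 < self.pi <= 1):
            raise ValueError("pi must lie in (0, 1]")


@dataclass
class Pedigree:
    """Realized pedigree: one entry per individual ever alive."""

    birth: np.ndarray
    death: np.ndarray  # last year alive; -1 if alive at simulation end
    sex: np.ndarray  # 0 = F, 1 = M
    mother: np.ndarray  # -1 for founders
    father: np.ndarray
    breeder: np.ndarray
    hap: np.ndarray
    sampled: np.ndarray
    sample_year: np.ndarray
    start_year: int
    end_year: int
    extinct: bool = False
    shortfalls: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.birth.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "sex": np.where(self.sex == 0, "F", "M"),
                "birth_year": self.birth,
                "death_year": self.death,
                "mother": self.mother,
                "father": self.father,
                "breeder": self.breeder,
                "haplotype": self.hap,
                "sampled": self.sampled,
                "sample_year": self.sample_year,
            }
        )


class _Table:
    """Growable column store for the pedigree arrays."""

    def __init__(self) -> None:
        self.cols: dict[str, list] = {
            "birth": [], "sex": [], "mother": [], "father": [], "breeder": [], "hap": []
        }
        self.death_chunks: list = []
        self.n = 0

    def append(self, **cols) -> np.ndarray:
        m = len(next(iter(cols.values())))
        for k in self.cols:
            self.cols[k].append(np.asarray(cols[k]))
        idx = np.arange(self.n, self.n + m)
        self.n += m
        return idx

    def concat(self) -> dict:
        return {k: np.concatenate(v) if v else np.empty(0, int) for k, v in self.cols.items()}


def simulate_pedigree(config: SimConfig, seed: int = 0) -> Pedigree:
    """Run the yearly cycle: survive, whelp, assign fathers, harvest.

    Identical seeds yield byte-identical pedigrees.  If the population goes
    extinct the partial pedigree is returned with ``extinct=True``.
    """
    rng = np.random.default_rng(seed)
    sched = config.schedules
    phi, f, m = sched.phi, sched.fecundity, sched.maturity
    max_age = sched.max_age

    harvest = config.harvest
    start_year = int(harvest.years.min() - config.burn_in)
    end_year = int(harvest.years.max())
    harvest_by_year = dict(zip(harvest.years.tolist(), harvest.n_per_year.tolist()))

    hap_freqs = rng.dirichlet(np.ones(config.n_haplotypes))

    tab = _Table()
    try:
        u = stable_age_distribution(sched)
    except ValueError:
        # degenerate schedules (e.g. zero fecundity): start uniform over ages
        u = np.full(max_age + 1, 1.0 / (max_age + 1))
    counts = rng.multinomial(int(round(config.n_initial)), u)
    founders_age = np.repeat(np.arange(max_age + 1), counts)
    nfound = founders_age.size
    sex0 = (rng.random(nfound) < 0.5).astype(np.int8)
    tab.append(
        birth=start_year - founders_age,
        sex=sex0,
        mother=np.full(nfound, -1, dtype=np.int64),
        father=np.full(nfound, -1, dtype=np.int64),
        breeder=(sex0 == 1) & (rng.random(nfound) < config.pi),
        hap=rng.choice(config.n_haplotypes, size=nfound, p=hap_freqs),
    )
    alive = np.arange(nfound)
    death_chunks: list = []  # (indices, last year alive)
    sampled_chunks: list = []  # (indices, harvest year)
    shortfalls: list = []
    extinct = False

    birth_all = tab.concat()["birth"]  # refreshed after each append

    def refresh():
        nonlocal birth_all, sex_all, breeder_all, hap_all
        c = tab.concat()
        birth_all, sex_all, breeder_all, hap_all = c["birth"], c["sex"], c["breeder"], c["hap"]

    sex_all = tab.concat()["sex"]
    breeder_all = tab.concat()["breeder"]
    hap_all = tab.concat()["hap"]

    for t in range(start_year + 1, end_year + 1):
        if alive.size == 0:
            extinct = True
            break
        # survival from t-1 to t; nobody enters age max_age + 1
        age_prev = (t - 1) - birth_all[alive]
        pr = np.where(age_prev < max_age, phi[np.clip(age_prev, 0, max_age)], 0.0)
        surv = rng.random(alive.size) < pr
        death_chunks.append((alive[~surv], t - 1))
        alive = alive[surv]
        if alive.size == 0:
            extinct = True
            break

        if config.annual_breeder_reassignment:
            males = alive[sex_all[alive] == 1]
            breeder_all[males] = rng.random(males.size) < config.pi

        # births at t: mothers are females alive at t aged a whelping w.p. f_a
        age_now = t - birth_all[alive]
        females = alive[(sex_all[alive] == 0)]
        f_age = t - birth_all[females]
        whelp = rng.random(females.size) < f[np.clip(f_age, 0, max_age)]
        mothers = females[whelp]
        n_pups = mothers.size
        if n_pups > 0:
            males = alive[sex_all[alive] == 1]
            w = m[np.clip(t - birth_all[males], 0, max_age)] * breeder_all[males]
            wsum = w.sum()
            if wsum > 0:
                fathers = rng.choice(males, size=n_pups, p=w / wsum)
                psex = (rng.random(n_pups) < 0.5).astype(np.int8)
                new = tab.append(
                    birth=np.full(n_pups, t),
                    sex=psex,
                    mother=mothers,
                    father=fathers,
                    breeder=(psex == 1) & (rng.random(n_pups) < config.pi),
                    hap=hap_all[mothers],
                )
                refresh()
                alive = np.concatenate([alive, new])

        # lethal harvest at t (after the breeding pulse)
        if t in harvest_by_year and harvest_by_year[t] > 0:
            n_t = harvest_by_year[t]
            targets = _largest_remainder(n_t, np.asarray(harvest.weights))
            remove = []
            age_now = t - birth_all[alive]
            for (lo, hi), want in zip(harvest.age_classes, targets):
                cands = alive[(age_now >= lo) & (age_now <= hi)]
                if cands.size < want:
                    shortfalls.append({"year": t, "age_class": (lo, hi), "missing": int(want - cands.size)})
                    take = cands
                else:
                    take = rng.choice(cands, size=want, replace=False)
                remove.append(take)
            remove = np.concatenate(remove) if remove else np.empty(0, int)
            death_chunks.append((remove, t))
            sampled_chunks.append((remove, t))
            alive = alive[~np.isin(alive, remove)]

    cols = tab.concat()
    n = tab.n
    death_arr = np.full(n, -1, dtype=np.int64)
    for idx, y in death_chunks:
        death_arr[idx] = y
    sampled = np.zeros(n, dtype=bool)
    syear = np.full(n, -1, dtype=np.int64)
    for idx, y in sampled_chunks:
        sampled[idx] = True
        syear[idx] = y
    return Pedigree(
        birth=cols["birth"].astype(np.int64),
        death=death_arr,
        sex=cols["sex"].astype(np.int8),
        mother=cols["mother"].astype(np.int64),
        father=cols["father"].astype(np.int64),
        breeder=np.asarray(cols["breeder"], dtype=bool),
        hap=cols["hap"].astype(np.int64),
        sampled=sampled,
        sample_year=syear,
        start_year=start_year,
        end_year=end_year,
        extinct=extinct,
        shortfalls=shortfalls,
    )


def _children_index(parent: np.ndarray) -> dict:
    """Map parent id -> array of child ids (vectorized grouping)."""
    valid = parent >= 0
    kids = np.flatnonzero(valid)
    pars = parent[valid]
    order = np.argsort(pars, kind="stable")
    pars_sorted, kids_sorted = pars[order], kids[order]
    uniq, starts = np.unique(pars_sorted, return_index=True)
    out = {}
    for i, p in enumerate(uniq):
        hi = starts[i + 1] if i + 1 < uniq.size else pars_sorted.size
        out[int(p)] = kids_sorted[starts[i] : hi]
    return out


def sample_harvest(
    pedigree: Pedigree,
    design: Optional[HarvestDesign] = None,
    include_third_order: bool = True,
) -> tuple[list, pd.DataFrame]:
    """Extract harvested animals as SampleRecords with true kin annotations.

    The harvest itself was executed inside :func:`simulate_pedigree` (lethal
    sampling must remove animals from the breeding pool in-loop); this
    function builds the analysis-facing sample table and enumerates every
    true kin pair among the samples (POP, FSP, MHSP, PHSP, GGP, FTP, HTP).
    When a pair is related in more than one way the most related label wins.
    """
    S = np.flatnonzero(pedigree.sampled)
    records = [
        SampleRecord(
            id=f"S{idx}",
            sex="F" if pedigree.sex[idx] == 0 else "M",
            birth_year=int(pedigree.birth[idx]),
            death_year=int(pedigree.sample_year[idx]),
            mtdna=f"H{int(pedigree.hap[idx])}",
        )
        for idx in S
    ]
    in_sample = np.zeros(pedigree.n, dtype=bool)
    in_sample[S] = True
    mother, father = pedigree.mother, pedigree.father

    found: dict[tuple[int, int], tuple[str, int, int]] = {}

    def propose(a: int, b: int, cls: str, directed: bool = False):
        key = (min(a, b), max(a, b))
        cur = found.get(key)
        if cur is None or _PRIORITY[cls] < _PRIORITY[cur[0]]:
            found[key] = (cls, a, b) if directed else (cls, key[0], key[1])

    # POP
    for s in S:
        for par in (mother[s], father[s]):
            if par >= 0 and in_sample[par]:
                propose(int(par), int(s), "POP", directed=True)

    # siblings among samples
    def sib_groups(parent_arr):
        groups: dict[int, list] = {}
        for s in S:
            p = parent_arr[s]
            if p >= 0:
                groups.setdefault(int(p), []).append(int(s))
        return groups

    by_mother = sib_groups(mother)
    by_father = sib_groups(father)
    mpairs = set()
    for kids in by_mother.values():
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                mpairs.add((min(kids[i], kids[j]), max(kids[i], kids[j])))
    ppairs = set()
    for kids in by_father.values():
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                ppairs.add((min(kids[i], kids[j]), max(kids[i], kids[j])))
    for a, b in mpairs & ppairs:
        propose(a, b, "FSP")
    for a, b in mpairs - ppairs:
        propose(a, b, "MHSP")
    for a, b in ppairs - mpairs:
        propose(a, b, "PHSP")

    # grandparent-grandchild
    for s in S:
        for mid in (mother[s], father[s]):
            if mid < 0:
                continue
            for g in (mother[mid], father[mid]):
                if g >= 0 and in_sample[g]:
                    propose(int(g), int(s), "GGP", directed=True)

    # thiatic pairs: i is a (half-)sibling of one of j's parents
    if include_third_order:
        kids_of_mother = _children_index(mother)
        kids_of_father = _children_index(father)
        for j in S:
            for p in (mother[j], father[j]):
                if p < 0:
                    continue
                pm, pf = mother[p], father[p]
                sibs: dict[int, int] = {}  # candidate -> number of shared parents
                for gp, index in ((pm, kids_of_mother), (pf, kids_of_father)):
                    if gp < 0:
                        continue
                    for c in index.get(int(gp), ()):  # children of that grandparent
                        if c != p:
                            sibs[int(c)] = sibs.get(int(c), 0) + 1
                # a full sibling shares both parents only if counted via both
                for c, shared in sibs.items():
                    if in_sample[c] and c != j:
                        # verify actual parent sharing (the two indexes may hit
                        # the same child through different grandparents)
                        shares = int(mother[c] >= 0 and mother[c] == pm) + int(
                            father[c] >= 0 and father[c] == pf
                        )
                        if shares >= 2:
                            propose(int(c), int(j), "FTP")
                        elif shares == 1:
                            propose(int(c), int(j), "HTP")

    rows = []
    for (a, b), (cls, x, y) in found.items():
        if cls == "POP" or cls == "GGP":
            id1, id2 = x, y  # parent/grandparent first
        else:
            # order by birth year then index, matching comparison grouping
            if (pedigree.birth[a], a) <= (pedigree.birth[b], b):
                id1, id2 = a, b
            else:
                id1, id2 = b, a
        rows.append({"id1": f"S{id1}", "id2": f"S{id2}", "kin_class": cls})
    kin = pd.DataFrame(rows, columns=["id1", "id2", "kin_class"])
    return records, kin


def simulate_genotypes(
    pedigree: Pedigree,
    design: Optional[GenotypeDesign] = None,
    seed: int = 0,
    samples: Optional[np.ndarray] = None,
) -> GenotypePanel:
    """Drop founder alleles, transmit them down the pedigree, observe classes.

    Null alleles are heritable and invisible: true genotypes carrying one
    null look homozygous for the visible allele, null/null looks like a
    failed assay.  A technical failure rate adds non-heritable FAILs.
    Sex-linked loci are male-specific presence markers.
    """
    design = design or GenotypeDesign()
    rng = np.random.default_rng(seed)
    n = pedigree.n
    L = design.n_loci
    if n * L > 3e8:
        raise MemoryError("pedigree x locus allocation too large; reduce n_loci or population")

    nu = rng.uniform(0, design.nu_max, size=L)
    minor = rng.uniform(design.minor_min, design.minor_max, size=L)
    q = (1 - nu) * minor
    p = (1 - nu) * (1 - minor)
    freqs = np.stack([p, q, nu], axis=1)

    alleles = np.empty((n, L, 2), dtype=np.int8)
    order = np.argsort(pedigree.birth, kind="stable")
    cum = np.cumsum(freqs, axis=1)
    by_year: dict[int, np.ndarray] = {}
    for idx in order:
        by_year.setdefault(int(pedigree.birth[idx]), []).append(idx)
    for year in sorted(by_year):
        ids = np.asarray(by_year[year])
        is_founder = pedigree.mother[ids] < 0
        fo = ids[is_founder]
        if fo.size:
            u = rng.random((fo.size, L, 2))
            alleles[fo] = (u[:, :, :, None] > cum[None, :, None, :]).sum(axis=-1).astype(np.int8)
        ch = ids[~is_founder]
        if ch.size:
            mo = pedigree.mother[ch]
            fa = pedigree.father[ch]
            pick_m = rng.integers(0, 2, size=(ch.size, L))
            pick_f = rng.integers(0, 2, size=(ch.size, L))
            alleles[ch, :, 0] = np.take_along_axis(alleles[mo], pick_m[:, :, None], axis=2)[:, :, 0]
            alleles[ch, :, 1] = np.take_along_axis(alleles[fa], pick_f[:, :, None], axis=2)[:, :, 0]

    if samples is None:
        samples = np.flatnonzero(pedigree.sampled)
    samples = np.asarray(samples)
    a = alleles[samples]  # (N, L, 2)
    has_null = (a == 2).sum(axis=2)
    visible_min = a.min(axis=2)
    visible_max = np.where(a == 2, -1, a).max(axis=2)
    classes = np.empty((samples.size, L), dtype=np.int64)
    classes[:] = CLASS_FAIL  # null/null
    one_null = has_null == 1
    none_null = has_null == 0
    classes[one_null & (visible_max == 0)] = CLASS_AA
    classes[one_null & (visible_max == 1)] = CLASS_BB
    hom_a = none_null & (a[..., 0] == 0) & (a[..., 1] == 0)
    hom_b = none_null & (a[..., 0] == 1) & (a[..., 1] == 1)
    het = none_null & (a[..., 0] != a[..., 1])
    classes[hom_a] = CLASS_AA
    classes[hom_b] = CLASS_BB
    classes[het] = CLASS_AB
    classes[rng.random(classes.shape) < design.fail_rate] = CLASS_FAIL
    classes = classes.T  # loci x samples

    # male-specific sexing markers
    if design.n_sex_linked > 0:
        male = (pedigree.sex[samples] == 1)[None, :]
        sex_rows = np.where(male, CLASS_AA, CLASS_FAIL).repeat(design.n_sex_linked, axis=0)
        sex_rows = np.where(
            rng.random(sex_rows.shape) < design.fail_rate, CLASS_FAIL, sex_rows
        )
        classes = np.vstack([classes, sex_rows])

    loci = [f"L{i}" for i in range(L)] + [f"SEX{i}" for i in range(design.n_sex_linked)]
    sex_linked = np.zeros(L + design.n_sex_linked, dtype=bool)
    sex_linked[L:] = True
    panel = GenotypePanel(
        samples=[f"S{int(s)}" for s in samples],
        loci=loci,
        classes=classes,
        sex_linked=sex_linked,
        fail_rate=design.fail_rate,
    )
    panel.true_freqs = freqs  # autosomal truth, for calibration checks
    return panel


def haplotype_sequences(n_haplotypes: int, length: int = 200, seed: int = 0) -> dict:
    """Synthetic aligned control-region haplotypes (labels -> sequences)."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=length)
    out = {}
    for h in range(n_haplotypes):
        seq = base.copy()
        sites = rng.choice(length, size=max(2, length // 50), replace=False)
        for s in sites:
            seq[s] = rng.choice([c for c in "ACGT" if c != seq[s]])
        out[f"H{h}"] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# analytic expectations and power analysis
# ---------------------------------------------------------------------------

def _expected_composition(
    schedules: LifeHistorySchedules, design: HarvestDesign
) -> pd.DataFrame:
    """Expected number of samples per (harvest year, age) cell."""
    u = stable_age_distribution(schedules)
    rows = []
    for year, n_y in zip(design.years, design.n_per_year):
        per_class = np.asarray(design.weights) * n_y
        for (lo, hi), n_c in zip(design.age_classes, per_class):
            ages = np.arange(lo, hi + 1)
            w = u[ages]
            if w.sum() <= 0:
                continue
            w = w / w.sum()
            for a, frac in zip(ages, w):
                if frac * n_c > 0:
                    rows.append({"year": int(year), "age": int(a), "n": float(n_c * frac)})
    df = pd.DataFrame(rows)
    df["birth"] = df["year"] - df["age"]
    return df


def expected_kin_counts_analytic(
    schedules: LifeHistorySchedules,
    n_total: float,
    design: HarvestDesign,
    pi: float = 1.0,
    lam_override: float = 1.0,
    ref_year: Optional[int] = None,
    exclude_same_year_pop: bool = False,
) -> dict:
    """Expected kin-pair counts for a harvest design, no pedigree realization.

    Sums the pairwise kinship kernels over the expected covariate
    composition of the sample.  ``lam_override=1`` holds abundance constant
    over time (the power-analysis convention); pass ``None`` to let the
    schedules' own growth rate act.  ``n_total`` is the total abundance in
    ``ref_year`` (default: the last harvest year).
    """
    comp = _expected_composition(schedules, design)
    start = int(design.years.min() - schedules.max_age - 1)
    end = int(design.years.max())
    traj = stable_trajectory(
        schedules,
        n_total,
        start,
        end,
        ref_year=end if ref_year is None else int(ref_year),
        lam_override=lam_override,
    )
    ctx = KinKernelContext(traj, schedules, pi=pi)

    births = comp.groupby("birth")["n"].sum()
    b_years = births.index.to_numpy()
    b_counts = births.to_numpy()
    bt = b_years - start

    # births x death-year table for the same-year POP exclusion
    bd = comp.groupby(["birth", "year"])["n"].sum().reset_index()

    # ---- POP ----
    e_pop = 0.0
    f, mm = schedules.fecundity, schedules.maturity
    denomF = np.where(ctx.denomF > 0, ctx.denomF, np.inf)
    denomM = np.where(ctx.denomM > 0, ctx.denomM, np.inf)
    for row in comp.itertuples(index=False):
        y_p, b_p, n_p = row.year, row.birth, row.n
        # candidate offspring born b_o with 1 <= b_o - b_p <= max_age, parent alive (y_p >= b_o)
        a = b_years - b_p
        ok = (a >= 1) & (a <= schedules.max_age) & (b_years <= y_p)
        if not ok.any():
            continue
        t = bt[ok]
        p_f = f[a[ok]] / denomF[t]
        p_m = mm[a[ok]] / denomM[t]
        # per-sex parent expectation: half the cell is female, half male
        m_counts = b_counts[ok].copy()
        if exclude_same_year_pop:
            # drop offspring sampled in the same year as the parent
            excl = bd[(bd["year"] == y_p) & (bd["birth"].isin(b_years[ok]))]
            if len(excl):
                sub = {int(b): float(v) for b, v in zip(excl["birth"], excl["n"])}
                m_counts = m_counts - np.array([sub.get(int(b), 0.0) for b in b_years[ok]])
        e_pop += 0.5 * n_p * float((m_counts * (p_f + p_m)).sum())

    # ---- HSP ----
    Pm, Pp = ctx.hsp_matrices()
    M = np.outer(b_counts, b_counts)
    upper = np.triu(np.ones_like(M, dtype=bool), k=1)
    e_mhsp = float((M[upper] * Pm[np.ix_(bt, bt)][upper]).sum())
    e_phsp = float((M[upper] * Pp[np.ix_(bt, bt)][upper]).sum())
    diag = np.arange(b_counts.size)
    e_phsp += float((b_counts * (b_counts - 1) / 2.0 * Pp[bt[diag], bt[diag]]).sum())

    # ---- GGP ----
    cubes = ctx.ggp_cubes()
    e_ggp_sh = 0.0
    e_ggp_non = 0.0
    T = traj.n_years
    for row in comp.itertuples(index=False):
        ti = row.birth - start
        d_t = min(row.year - start, T - 1)
        tj_all = bt
        ok = (b_years > row.birth)
        if not ok.any():
            continue
        tj = tj_all[ok]
        c_hi = np.minimum(tj - 1, d_t)
        valid = c_hi > ti
        tj, c_hi, w = tj[valid], c_hi[valid], b_counts[ok][valid]
        if tj.size == 0:
            continue
        sh = cubes["shared"][ti, c_hi, tj]
        nf = cubes["non_f"][ti, c_hi, tj]
        nm = cubes["non_m"][ti, c_hi, tj]
        # half of the older cell is female, half male
        e_ggp_sh += 0.5 * row.n * float((w * sh).sum())
        e_ggp_non += 0.5 * row.n * float((w * nf).sum()) + 0.5 * row.n * float((w * nm).sum())

    return {
        "POP": e_pop,
        "MHSP": e_mhsp,
        "PHSP": e_phsp,
        "HSP": e_mhsp + e_phsp,
        "GGP_shared": e_ggp_sh,
        "GGP_nonshared": e_ggp_non,
        "second_order": e_mhsp + e_phsp + e_ggp_sh + e_ggp_non,
    }


def _design_records(schedules: LifeHistorySchedules, design: HarvestDesign) -> list:
    """Deterministic integer sample roster matching the expected composition."""
    comp = _expected_composition(schedules, design)
    records = []
    i = 0
    for year in sorted(comp["year"].unique()):
        sub = comp[comp["year"] == year]
        counts = _largest_remainder(int(round(sub["n"].sum())), sub["n"].to_numpy())
        for (row, k) in zip(sub.itertuples(index=False), counts):
            for j in range(int(k)):
                records.append(
                    SampleRecord(
                        id=f"D{i}",
                        sex="F" if (i % 2 == 0) else "M",
                        birth_year=int(row.birth),
                        death_year=int(row.year),
                        mtdna=None,
                    )
                )
                i += 1
    return records


def power_analysis(
    schedules: LifeHistorySchedules,
    n_total: float,
    design: HarvestDesign,
    reps: int = 20,
    seed: int = 0,
    pi: float = 1.0,
    method: str = "parametric",
    sim_config: Optional[SimConfig] = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Distribution of abundance estimates and CVs over simulated datasets.

    ``parametric`` draws kin counts group-by-group from the model's own
    Bernoulli probabilities (survival schedules treated as known) and refits
    abundance; ``pedigree`` runs the full individual-based pipeline with
    oracle kin labels.  Reps with zero observed kin are flagged
    non-estimable.
    """
    from .likelihood import CkmrModel, build_comparisons, ComparisonSet
    from dataclasses import replace as _dc_replace

    rng = np.random.default_rng(seed)
    rows = []
    defaults = dict(
        eta_free=False,
        pi_free=False,
        lambda0=1.0,
        impose_lambda0=True,  # power scenarios assume a stable population
        eta_prior=(0.055, 2.80, 0.076),
        fecundity_spec=schedules.fecundity,
        maturity_spec=schedules.maturity,
    )
    defaults.update(fit_kwargs)

    if method == "parametric":
        from .likelihood import CkmrConfig, _group_probs

        records = _design_records(schedules, design)
        comps = build_comparisons(records)
        config = CkmrConfig(
            eta_prior=tuple(defaults["eta_prior"]),
            lambda0=defaults["lambda0"],
            include_ggp=defaults.get("include_ggp", True),
            impose_lambda0=defaults["impose_lambda0"],
        )
        p_pop, p_shared, p_non, _ = _group_probs(comps, schedules, n_total, pi, config)
        have_mtdna = any(r.mtdna is not None for r in records)
        for rep in range(reps):
            k_pop = rng.binomial(comps.pop_n, np.clip(p_pop, 0, 1))
            if have_mtdna:
                k_m = rng.binomial(comps.sec_n, np.clip(p_shared, 0, 1))
                rem = np.clip(p_non / np.maximum(1 - p_shared, 1e-12), 0, 1)
                k_p = rng.binomial(comps.sec_n - k_m, rem)
                k_u = np.zeros_like(k_m)
            else:
                k_m = np.zeros_like(comps.sec_n)
                k_p = np.zeros_like(comps.sec_n)
                k_u = rng.binomial(comps.sec_n, np.clip(p_shared + p_non, 0, 1))
            comps_r = _dc_replace(comps, pop_k=k_pop, sec_k_m=k_m, sec_k_p=k_p, sec_k_u=k_u)
            n_kin = int(k_pop.sum() + k_m.sum() + k_p.sum() + k_u.sum())
            if n_kin == 0:
                rows.append({"rep": rep, "n_hat": np.nan, "cv": np.nan, "n_kin": 0, "estimable": False})
                continue
            model = CkmrModel(**defaults).fit(comps_r)
            rows.append(
                {
                    "rep": rep,
                    "n_hat": model.n_hat_,
                    "cv": model.n_hat_cv_,
                    "n_kin": n_kin,
                    "estimable": bool(model.converged_),
                }
            )
    elif method == "pedigree":
        base = sim_config or SimConfig(
            n_initial=n_total, schedules=schedules, pi=pi, harvest=design
        )
        from .kinference import annotate_kin_strata, repair_covariates

        for rep in range(reps):
            ped = simulate_pedigree(base, seed=int(rng.integers(2**31 - 1)))
            records, kin = sample_harvest(ped)
            kin = annotate_kin_strata(kin, records)
            repaired = repair_covariates(kin, records)
            comps = build_comparisons(repaired.records, kin=kin)
            n_kin = int(
                comps.pop_k.sum() + comps.sec_k_m.sum() + comps.sec_k_p.sum() + comps.sec_k_u.sum()
            )
            if n_kin == 0:
                rows.append({"rep": rep, "n_hat": np.nan, "cv": np.nan, "n_kin": 0, "estimable": False})
                continue
            model = CkmrModel(**defaults).fit(comps)
            rows.append(
                {
                    "rep": rep,
                    "n_hat": model.n_hat_,
                    "cv": model.n_hat_cv_,
                    "n_kin": n_kin,
                    "estimable": bool(model.converged_),
                }
            )
    else:
        raise ValueError("method must be 'parametric' or 'pedigree'")
    return pd.DataFrame(rows)
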