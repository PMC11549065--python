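"""Pseudo-log-odds (PLOD) kin identification from null-allele genotypes.

For a genotype pair and a kinship hypothesis K, the PLOD score is

    sum_loci log P(g_i, g_j | K) / P(g_i, g_j | UP)

where the joint probability mixes the unrelated, one-IBD-allele, and
two-IBD-allele states with the Cotterman coefficients of K:
POP (0, 1, 0); FSP (1/4, 1/2, 1/4); HSP and GGP (1/2, 1/2, 0).  The mixture
is computed on true three-allele genotypes (visible A, B and the heritable
null) and then marginalized onto the observed classes AA*, AB, BB*; loci
where either member FAILs are skipped (raw sum, no per-locus rescaling).

Second-order kin (HSP/GGP) cannot be separated from each other genetically,
and a calling threshold is needed to keep third-order kin out; the
associated false-negative rate is estimated from the theoretical HSP score
mean and the spread of the upper half of the observed kin-score
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .genotypes import CLASS_FAIL, GenotypePanel, LocusModel

__all__ = [
    "KAPPA",
    "pair_class_probs",
    "plod_tables",
    "plod",
    "expected_plod",
    "plod_variance",
    "PlodKinClassifier",
    "classify_pairs",
    "FalseNegativeEstimate",
    "false_negative_rate",
    "assign_sex",
]

#: Cotterman coefficients (kappa0, kappa1, kappa2) per kinship hypothesis.
KAPPA = {
    "UP": (1.0, 0.0, 0.0),
    "POP": (0.0, 1.0, 0.0),
    "FSP": (0.25, 0.5, 0.25),
    "HSP": (0.5, 0.5, 0.0),
    "GGP": (0.5, 0.5, 0.0),
}

# true genotypes over alleles (A=0, B=1, null=2) and their observed class
_GENOTYPES = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]
_CLASS_OF = np.array([0, 1, 2, 0, 2, 3])


def _freq_matrix(models: Sequence[LocusModel]) -> np.ndarray:
    return np.array([[m.p, m.q, m.nu] for m in models], dtype=float)


def pair_class_probs(models: Sequence[LocusModel], hypothesis: str) -> np.ndarray:
    """Joint observed-class probabilities per locus, shape (L, 4, 4).

    Entry [l, c1, c2] is P(classes c1, c2 | kinship hypothesis) at locus l,
    marginalized over true genotypes including null alleles.
    """
    k0, k1, k2 = KAPPA[hypothesis]
    v = _freq_matrix(models)  # (L, 3)
    L = v.shape[0]
    G = len(_GENOTYPES)

    # HWE probabilities of the 6 unordered genotypes
    hw = np.empty((L, G))
    for g, (x, y) in enumerate(_GENOTYPES):
        hw[:, g] = v[:, x] ** 2 if x == y else 2 * v[:, x] * v[:, y]

    # T[l, z, g] = P(random completion w makes {z, w} == genotype g)
    T = np.zeros((L, 3, G))
    for g, (x, y) in enumerate(_GENOTYPES):
        if x == y:
            T[:, x, g] += v[:, x]
        else:
            T[:, x, g] += v[:, y]
            T[:, y, g] += v[:, x]

    J0 = hw[:, :, None] * hw[:, None, :]
    J1 = np.einsum("lz,lzg,lzh->lgh", v, T, T)
    J2 = np.zeros((L, G, G))
    J2[:, np.arange(G), np.arange(G)] = hw
    J = k0 * J0 + k1 * J1 + k2 * J2

    out = np.zeros((L, 4, 4))
    for g in range(G):
        for h in range(G):
            out[:, _CLASS_OF[g], _CLASS_OF[h]] += J[:, g, h]
    return out


def plod_tables(models: Sequence[LocusModel], hypothesis: str) -> np.ndarray:
    """Per-locus log-ratio tables log[P(c1,c2|K)/P(c1,c2|UP)], shape (L,3,3)."""
    pk = pair_class_probs(models, hypothesis)[:, :3, :3]
    pu = pair_class_probs(models, "UP")[:, :3, :3]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(np.maximum(pk, 1e-300)) - np.log(np.maximum(pu, 1e-300))


def plod(
    g1: np.ndarray,
    g2: np.ndarray,
    tables: np.ndarray,
    min_shared_loci: int = 1,
) -> float:
    """PLOD score for one genotype pair; FAIL loci are skipped."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    shared = (g1 != CLASS_FAIL) & (g2 != CLASS_FAIL)
    if int(shared.sum()) < min_shared_loci:
        raise ValueError(f"only {int(shared.sum())} shared called loci (< {min_shared_loci})")
    idx = np.flatnonzero(shared)
    return float(tables[idx, g1[idx], g2[idx]].sum())


def expected_plod(models: Sequence[LocusModel], score_hypothesis: str, true_kin: str) -> float:
    """E[PLOD_{score_hypothesis}] when the pair's true kinship is ``true_kin``."""
    tables = plod_tables(models, score_hypothesis)
    pt = pair_class_probs(models, true_kin)[:, :3, :3]
    return float((pt * tables).sum())


def plod_variance(models: Sequence[LocusModel], score_hypothesis: str, true_kin: str) -> float:
    """Variance of the PLOD score under independent loci."""
    tables = plod_tables(models, score_hypothesis)
    pt = pair_class_probs(models, true_kin)[:, :3, :3]
    mu_l = (pt * tables).sum(axis=(1, 2))
    ex2 = (pt * tables**2).sum(axis=(1, 2))
    return float((ex2 - mu_l**2).sum())


@dataclass
class FalseNegativeEstimate:
    """Second-order kin false-negative probability at a calling threshold."""

    value: float
    mu_hsp: float
    sigma: float
    n_upper: int
    reliable: bool


def false_negative_rate(
    observed_scores: Sequence[float],
    models: Sequence[LocusModel],
    threshold: float,
    min_upper: int = 5,
) -> FalseNegativeEstimate:
    """FN probability that a true second-order pair scores below ``threshold``.

    The HSP score mean is theoretical (from the locus models); the standard
    deviation is estimated from the scores at or above that mean, folding the
    upper half-distribution about the mean.  Too few upper scores yields a
    wide-uncertainty flag (the variance is then likely underestimated).
    """
    mu = expected_plod(models, "HSP", "HSP")
    scores = np.asarray(list(observed_scores), dtype=float)
    upper = scores[scores >= mu]
    reliable = upper.size >= min_upper
    if upper.size == 0:
        sigma = float(np.sqrt(plod_variance(models, "HSP", "HSP")))
    else:
        sigma = float(np.sqrt(np.mean((upper - mu) ** 2)))
    if sigma <= 0:
        sigma = float(np.sqrt(max(plod_variance(models, "HSP", "HSP"), 1e-12)))
    fn = float(norm.cdf((threshold - mu) / sigma)) if np.isfinite(threshold) else 0.0
    if threshold == -np.inf:
        fn = 0.0
    return FalseNegativeEstimate(value=fn, mu_hsp=mu, sigma=sigma, n_upper=int(upper.size), reliable=reliable)


class PlodKinClassifier(BaseEstimator):
    """Kin-pair caller over a QC'd genotype panel.

    ``fit`` estimates (or adopts) the per-locus allele-frequency models and
    builds the score tables; ``predict`` scores pairs and assigns calls.
    First-order contrasts are adjudicated first (POP vs FSP by the larger
    score, ties toward POP), then the second-order threshold is applied:
    a pair is called HSP-GGP when its HSP/UP score reaches
    ``hsp_threshold`` and it was not already called first order.

    ``first_order_fraction`` sets the first-order calling threshold as a
    fraction of the theoretical expected POP score for the panel; with
    thousands of informative loci the POP/FSP and second-order score
    distributions are separated by many standard deviations, so the exact
    fraction is uncritical.
    """

    def __init__(
        self,
        hsp_threshold: float = 40.0,
        first_order_fraction: float = 0.5,
        min_shared_loci: int = 50,
    ) -> None:
        self.hsp_threshold = hsp_threshold
        self.first_order_fraction = first_order_fraction
        self.min_shared_loci = min_shared_loci

    def fit(self, X: GenotypePanel, y=None) -> "PlodKinClassifier":
        panel = X.autosomal()
        if panel.models is None or any(m is None for m in panel.models):
            panel.estimate_models()
        self.models_ = [m for m in panel.models]
        self.loci_ = list(panel.loci)
        self.samples_ = list(panel.samples)
        self.classes_matrix_ = panel.classes
        self.tables_ = {h: plod_tables(self.models_, h) for h in ("POP", "FSP", "HSP")}
        self.mu_ = {
            "POP": expected_plod(self.models_, "POP", "POP"),
            "FSP": expected_plod(self.models_, "FSP", "FSP"),
            "HSP": expected_plod(self.models_, "HSP", "HSP"),
        }
        self.first_order_threshold_ = self.first_order_fraction * self.mu_["POP"]
        return self

    def score_pairs(self, pairs: Optional[Sequence[tuple[int, int]]] = None) -> pd.DataFrame:
        """PLOD scores for index pairs (default: all unordered pairs)."""
        G = self.classes_matrix_
        N = G.shape[1]
        if pairs is None:
            iu, ju = np.triu_indices(N, k=1)
        else:
            arr = np.asarray(list(pairs), dtype=int)
            iu, ju = arr[:, 0], arr[:, 1]
        L = G.shape[0]
        # flatten each (L,3,3) table into (L,16) with FAIL (code 3) rows/cols = 0
        Gm = np.where(G == CLASS_FAIL, 3, G).astype(np.int64)
        flat = {}
        for h in ("POP", "FSP", "HSP"):
            tf = np.zeros((L, 16))
            t = self.tables_[h]
            for a in range(3):
                tf[:, 4 * a : 4 * a + 3] = t[:, a, :]
            flat[h] = tf
        out = {h: np.empty(iu.size) for h in ("POP", "FSP", "HSP")}
        shared_count = np.empty(iu.size, dtype=int)
        chunk = max(1, int(2e6 // max(L, 1)))
        for lo in range(0, iu.size, chunk):
            hi = min(lo + chunk, iu.size)
            idx = 4 * Gm[:, iu[lo:hi]] + Gm[:, ju[lo:hi]]  # (L, P)
            shared_count[lo:hi] = ((Gm[:, iu[lo:hi]] != 3) & (Gm[:, ju[lo:hi]] != 3)).sum(axis=0)
            for h in ("POP", "FSP", "HSP"):
                out[h][lo:hi] = np.take_along_axis(flat[h], idx, axis=1).sum(axis=0)
        return pd.DataFrame(
            {
                "i": iu,
                "j": ju,
                "id1": [self.samples_[a] for a in iu],
                "id2": [self.samples_[a] for a in ju],
                "plod_pop": out["POP"],
                "plod_fsp": out["FSP"],
                "plod_hsp": out["HSP"],
                "n_shared_loci": shared_count,
            }
        )

    def predict(self, pairs: Optional[Sequence[tuple[int, int]]] = None) -> pd.DataFrame:
        """Score pairs and attach calls in {UP, POP, FSP, HSP-GGP, ambiguous}."""
        df = self.score_pairs(pairs)
        call = np.full(len(df), "UP", dtype=object)
        too_few = df["n_shared_loci"].to_numpy() < self.min_shared_loci
        first = (df["plod_pop"].to_numpy() >= self.first_order_threshold_) | (
            df["plod_fsp"].to_numpy() >= self.first_order_threshold_
        )
        # ties go to the more related hypothesis (POP before FSP)
        call[first] = np.where(
            df["plod_pop"].to_numpy()[first] >= df["plod_fsp"].to_numpy()[first], "POP", "FSP"
        )
        second = ~first & (df["plod_hsp"].to_numpy() >= self.hsp_threshold)
        call[second] = "HSP-GGP"
        call[too_few] = "ambiguous"
        df["call"] = call
        df["threshold"] = self.hsp_threshold
        return df


def classify_pairs(panel: GenotypePanel, hsp_threshold: float = 40.0, **kwargs) -> pd.DataFrame:
    """Fit a :class:`PlodKinClassifier` on ``panel`` and call all pairs."""
    clf = PlodKinClassifier(hsp_threshold=hsp_threshold, **kwargs).fit(panel)
    return clf.predict()


def assign_sex(panel: GenotypePanel, sample: int | str) -> tuple[str, int, int]:
    """Genetic sex from male-specific presence markers.

    Returns (sex, n_present, n_sex_loci); sex is 'M' if a majority of the
    sex-linked loci amplified, 'F' if a majority failed, 'U' if there are no
    sex-linked loci or the vote ties.  A vote with any FAILed marker should
    be treated as lower confidence by the caller.
    """
    if isinstance(sample, str):
        sample = panel.samples.index(sample)
    sl = np.flatnonzero(panel.sex_linked)
    if sl.size == 0:
        return "U", 0, 0
    calls = panel.classes[sl, sample]
    present = int((calls != CLASS_FAIL).sum())
    absent = int((calls == CLASS_FAIL).sum())
    if present > absent:
        return "M", present, int(sl.size)
    if absent > present:
        return "F", present, int(sl.size)
    return "U", present, int(sl.size)
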