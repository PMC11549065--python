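"""Biallelic SNP genotypes with heritable null alleles.

Complexity-reduction genotyping can carry heritable null alleles (e.g.,
mutations at primer sites) that are consistently invisible to the assay.  A
locus therefore has three alleles, the visible A and B plus a null, with
frequencies ``p + q + nu = 1``, but only four observable classes:

    AA*  (true AA or A-null)     expected frequency  p^2 + 2 p nu
    AB                           expected frequency  2 p q
    BB*  (true BB or B-null)     expected frequency  q^2 + 2 q nu
    FAIL (null/null or no-call)  expected frequency  nu^2 (+ technical)

The apparent homozygote excess this creates would wreck naive kin finding;
modelling it explicitly recovers the statistical power instead.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "CLASS_AA",
    "CLASS_AB",
    "CLASS_BB",
    "CLASS_FAIL",
    "LocusModel",
    "estimate_locus_model",
    "GenotypePanel",
]

CLASS_AA = 0
CLASS_AB = 1
CLASS_BB = 2
CLASS_FAIL = 9

_VALID_CODES = frozenset({CLASS_AA, CLASS_AB, CLASS_BB, CLASS_FAIL})


@dataclass
class LocusModel:
    """Allele frequencies (p, q, nu) and observed-class probabilities."""

    p: float
    q: float
    nu: float
    fail_rate: float = 0.0  # technical (non-heritable) failure rate
    monomorphic: bool = False

    def __post_init__(self) -> None:
        total = self.p + self.q + self.nu
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"allele frequencies must sum to 1, got {total}")
        if min(self.p, self.q, self.nu) < -1e-12 or not (0 <= self.fail_rate < 1):
            raise ValueError("frequencies must be non-negative and fail_rate in [0,1)")

    def class_probs(self) -> np.ndarray:
        """Probabilities of (AA*, AB, BB*, FAIL) under HWE with nulls."""
        p, q, nu, b = self.p, self.q, self.nu, self.fail_rate
        raw = np.array([p * p + 2 * p * nu, 2 * p * q, q * q + 2 * q * nu, nu * nu])
        out = raw * (1 - b)
        out[3] = raw[3] + (1 - raw[3]) * b
        return out

    @property
    def minor_allele_freq(self) -> float:
        """Minor visible-allele frequency (MALF)."""
        return min(self.p, self.q)

    @property
    def null_allele_freq(self) -> float:
        """Null-allele frequency (NALF)."""
        return self.nu


def _moment_start(freqs: np.ndarray, fail_rate: float) -> tuple[float, float, float]:
    """Moment estimator of (p, q, nu) from observed class frequencies."""
    f_fail = max((freqs[3] - fail_rate) / (1 - fail_rate), 0.0) if fail_rate < 1 else 0.0
    nu = min(np.sqrt(f_fail), 0.999)
    vis = freqs[:3] / max(1 - fail_rate, 1e-12)
    s = vis.sum()
    if s > 0:
        vis = vis * (1 - nu * nu) / s
    diff = (vis[0] - vis[2]) / max(1 + nu, 1e-12)  # (p - q)(1 + nu) = P(AA*) - P(BB*)
    p = ((1 - nu) + diff) / 2
    q = (1 - nu) - p
    p, q = float(np.clip(p, 1e-6, 1 - 2e-6)), float(np.clip(q, 1e-6, 1 - 2e-6))
    nu = max(1.0 - p - q, 0.0)
    return p, q, nu


def estimate_locus_model(
    class_counts: Sequence[float],
    fail_rate: float = 0.0,
    polish: bool = True,
) -> LocusModel:
    """Maximum-likelihood (p, q, nu) from counts over (AA*, AB, BB*, FAIL).

    Uses a moment start (exact when class frequencies sit on the model) and
    an optional multinomial-likelihood polish.  A locus with no observed
    minor-allele signal is flagged ``monomorphic``.
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.shape != (4,) or np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("class_counts must be 4 non-negative counts with a positive total")
    freqs = counts / counts.sum()
    monomorphic = counts[1] == 0 and (counts[0] == 0 or counts[2] == 0)
    p, q, nu = _moment_start(freqs, fail_rate)

    if polish and not monomorphic:
        def nll(z):
            ez = np.exp(z - z.max())
            v = ez / ez.sum()
            m = LocusModel(v[0], v[1], v[2], fail_rate=fail_rate)
            probs = np.maximum(m.class_probs(), 1e-12)
            return -float(counts @ np.log(probs))

        z0 = np.log(np.maximum([p, q, nu], 1e-8))
        res = minimize(nll, z0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
        ez = np.exp(res.x - res.x.max())
        v = ez / ez.sum()
        p, q, nu = float(v[0]), float(v[1]), float(v[2])

    total = p + q + nu
    return LocusModel(p / total, q / total, nu / total, fail_rate=fail_rate, monomorphic=bool(monomorphic))


@dataclass
class GenotypePanel:
    """Observed genotype classes, loci x samples, with per-locus models.

    ``classes`` uses the codes 0=AA*, 1=AB, 2=BB*, 9=FAIL.  ``sex_linked``
    marks male-specific presence markers used for genetic sexing; they are
    excluded from allele-frequency estimation and PLOD scoring.
    """

    samples: list
    loci: list
    classes: np.ndarray
    sex_linked: np.ndarray = None
    models: Optional[list] = None
    fail_rate: float = 0.0

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        L, N = self.classes.shape
        if L != len(self.loci) or N != len(self.samples):
            raise ValueError("classes must be loci x samples")
        bad = ~np.isin(self.classes, list(_VALID_CODES))
        if bad.any():
            l, s = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid class code {self.classes[l, s]} at locus {self.loci[l]!r}, "
                f"sample {self.samples[s]!r}"
            )
        if self.sex_linked is None:
            self.sex_linked = np.zeros(L, dtype=bool)
        self.sex_linked = np.asarray(self.sex_linked, dtype=bool)
        if self.sex_linked.shape != (L,):
            raise ValueError("sex_linked mask must have one entry per locus")
        if L == 0 or not np.any(~self.sex_linked):
            raise ValueError("panel needs at least one autosomal locus")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def autosomal(self) -> "GenotypePanel":
        return self.subset(locus_mask=~self.sex_linked)

    def class_counts(self, locus_index: int, sample_mask: Optional[np.ndarray] = None) -> np.ndarray:
        row = self.classes[locus_index]
        if sample_mask is not None:
            row = row[sample_mask]
        return np.array(
            [(row == CLASS_AA).sum(), (row == CLASS_AB).sum(), (row == CLASS_BB).sum(), (row == CLASS_FAIL).sum()],
            dtype=float,
        )

    def estimate_models(self, sample_mask: Optional[np.ndarray] = None) -> list:
        """(Re-)estimate per-locus allele frequencies; sex-linked loci get None."""
        models = []
        for l in range(self.n_loci):
            if self.sex_linked[l]:
                models.append(None)
                continue
            models.append(
                estimate_locus_model(self.class_counts(l, sample_mask), fail_rate=self.fail_rate)
            )
        self.models = models
        return models

    def subset(
        self,
        locus_mask: Optional[np.ndarray] = None,
        sample_mask: Optional[np.ndarray] = None,
    ) -> "GenotypePanel":
        locus_mask = np.ones(self.n_loci, bool) if locus_mask is None else np.asarray(locus_mask, bool)
        sample_mask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        models = None
        if self.models is not None:
            models = [m for m, keep in zip(self.models, locus_mask) if keep]
        return GenotypePanel(
            samples=[s for s, keep in zip(self.samples, sample_mask) if keep],
            loci=[l for l, keep in zip(self.loci, locus_mask) if keep],
            classes=self.classes[np.ix_(locus_mask, sample_mask)],
            sex_linked=self.sex_linked[locus_mask],
            models=models,
            fail_rate=self.fail_rate,
        )

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, path) -> None:
        if self.models is None:
            self.estimate_models()
        df = pd.DataFrame(
            {
                "locus": self.loci,
                "p": [m.p if m else np.nan for m in self.models],
                "q": [m.q if m else np.nan for m in self.models],
                "nu": [m.nu if m else np.nan for m in self.models],
                "sex_linked": self.sex_linked.astype(int),
            }
        )
        body = pd.DataFrame(self.classes, columns=self.samples)
        pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, fail_rate: float = 0.0) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t")
        meta = ["locus", "p", "q", "nu", "sex_linked"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise ValueError(f"genotype TSV missing columns {missing}")
        sample_cols = [c for c in df.columns if c not in meta]
        if not sample_cols:
            raise ValueError("genotype TSV contains no sample columns")
        classes = df[sample_cols].to_numpy(dtype=np.int64)
        sex_linked = df["sex_linked"].to_numpy(dtype=bool)
        panel = cls(
            samples=sample_cols,
            loci=df["locus"].tolist(),
            classes=classes,
            sex_linked=sex_linked,
            fail_rate=fail_rate,
        )
        if df.loc[~sex_linked, ["p", "q", "nu"]].notna().all(axis=None):
            panel.models = [
                None if sx else LocusModel(r.p, r.q, r.nu, fail_rate=fail_rate)
                for sx, r in zip(sex_linked, df.itertuples(index=False))
            ]
        return panel
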