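"""Iterative quality control of a null-allele SNP panel.

Bad loci corrupt sample statistics and bad samples corrupt locus statistics,
so filtering proceeds by alternating rounds: loci are screened against the
currently kept samples (minor-allele frequency, null-allele frequency, and a
Hardy-Weinberg goodness-of-fit test that allows for null alleles) and
samples against the currently kept loci (heterozygosity z-score, genotype
concordance for duplicate detection).  Every round re-tests previously
rejected loci and samples against the refreshed frequency estimates, so an
item rejected because of bad companions can be re-introduced.  The loop is
deterministic for a given configuration and runs to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import CLASS_AB, CLASS_FAIL, GenotypePanel, estimate_locus_model

__all__ = ["PanelQC", "qc_panel"]


class PanelQC(BaseEstimator, TransformerMixin):
    """Panel QC as a deterministic transformer.

    Parameters
    ----------
    malf_min : loci with minor visible-allele frequency below this are dropped.
    nalf_max : loci with null-allele frequency at or above this are dropped.
    hwe_alpha : per-locus significance level of the HWE-with-nulls chi-square
        goodness-of-fit test (df = 1: four classes, one constraint, two free
        frequencies).
    hwe_method : 'per-test' (plain per-locus threshold) or 'fdr'
        (Benjamini-Hochberg across loci).
    het_z_max : samples whose heterozygote count deviates from expectation by
        more than this many standard deviations are dropped (excess suggests
        contamination, deficiency poor-quality DNA).
    dup_concordance : pairs of samples whose called-genotype concordance
        exceeds this are duplicates; the later sample is dropped.
    max_iter : safety bound on filtering rounds.
    """

    def __init__(
        self,
        malf_min: float = 0.05,
        nalf_max: float = 0.45,
        hwe_alpha: float = 0.05,
        hwe_method: str = "per-test",
        het_z_max: float = 4.0,
        dup_concordance: float = 0.95,
        max_iter: int = 25,
    ) -> None:
        self.malf_min = malf_min
        self.nalf_max = nalf_max
        self.hwe_alpha = hwe_alpha
        self.hwe_method = hwe_method
        self.het_z_max = het_z_max
        self.dup_concordance = dup_concordance
        self.max_iter = max_iter

    # -- individual screens ------------------------------------------------
    def _locus_screen(self, panel: GenotypePanel, sample_mask: np.ndarray):
        """Return (keep mask over loci, reasons dict) given kept samples."""
        L = panel.n_loci
        keep = np.ones(L, dtype=bool)
        reasons: dict[str, list] = {"malf": [], "nalf": [], "hwe": [], "monomorphic": []}
        pvals = np.full(L, np.nan)
        for l in range(L):
            if panel.sex_linked[l]:
                continue  # sexing markers are exempt from autosomal screens
            counts = panel.class_counts(l, sample_mask)
            if counts.sum() == 0:
                keep[l] = False
                reasons["monomorphic"].append(panel.loci[l])
                continue
            model = estimate_locus_model(counts, fail_rate=panel.fail_rate, polish=False)
            if model.monomorphic:
                keep[l] = False
                reasons["monomorphic"].append(panel.loci[l])
                continue
            if model.minor_allele_freq < self.malf_min:
                keep[l] = False
                reasons["malf"].append(panel.loci[l])
                continue
            if model.null_allele_freq >= self.nalf_max:
                keep[l] = False
                reasons["nalf"].append(panel.loci[l])
                continue
            def gof(mod):
                expected = mod.class_probs() * counts.sum()
                ok = expected > 0
                stat = float(((counts[ok] - expected[ok]) ** 2 / expected[ok]).sum())
                return stats.chi2.sf(stat, df=1)

            pv = gof(model)
            if pv < 0.25:
                # the chi-square is calibrated for the MLE; polish borderline loci
                pv = gof(estimate_locus_model(counts, fail_rate=panel.fail_rate, polish=True))
            pvals[l] = pv
        # HWE decision with chosen multiplicity handling
        tested = np.isfinite(pvals) & keep & ~panel.sex_linked
        if self.hwe_method == "fdr":
            idx = np.flatnonzero(tested)
            if idx.size:
                order = np.argsort(pvals[idx])
                m = idx.size
                crit = self.hwe_alpha * (np.arange(1, m + 1)) / m
                passed = pvals[idx][order] >= crit  # reject smallest p-values below BH line
                below = np.flatnonzero(~passed)
                if below.size:
                    cutoff = below.max()  # largest rank still rejected (step-up)
                    reject = order[: cutoff + 1]
                    for j in idx[reject]:
                        keep[j] = False
                        reasons["hwe"].append(panel.loci[j])
        else:
            for l in np.flatnonzero(tested):
                if pvals[l] < self.hwe_alpha:
                    keep[l] = False
                    reasons["hwe"].append(panel.loci[l])
        return keep, reasons

    def _sample_screen(self, panel: GenotypePanel, locus_mask: np.ndarray, sample_mask: np.ndarray):
        """Return (keep mask over samples, reasons) given kept loci."""
        auto = locus_mask & ~panel.sex_linked
        classes = panel.classes[auto]
        N = panel.n_samples
        keep = np.ones(N, dtype=bool)
        reasons: dict[str, list] = {"heterozygosity": [], "duplicate": []}
        models = [
            estimate_locus_model(
                panel.class_counts(l, sample_mask), fail_rate=panel.fail_rate, polish=False
            )
            for l in np.flatnonzero(auto)
        ]
        p_ab = np.array([m.class_probs()[1] for m in models])
        p_fail = np.array([m.class_probs()[3] for m in models])
        p_het_called = np.divide(p_ab, 1 - p_fail, out=np.zeros_like(p_ab), where=(1 - p_fail) > 0)
        called = classes != CLASS_FAIL
        het = classes == CLASS_AB
        for s in range(N):
            c = called[:, s]
            if c.sum() == 0:
                keep[s] = False
                reasons["heterozygosity"].append(panel.samples[s])
                continue
            mu = float(p_het_called[c].sum())
            var = float((p_het_called[c] * (1 - p_het_called[c])).sum())
            if var <= 0:
                continue
            z = (float(het[:, s].sum()) - mu) / np.sqrt(var)
            if abs(z) > self.het_z_max:
                keep[s] = False
                reasons["heterozygosity"].append(panel.samples[s])
        # duplicate screen among the samples still standing
        alive = np.flatnonzero(keep)
        sub = classes[:, alive]
        called_sub = sub != CLASS_FAIL
        for a in range(len(alive)):
            if not keep[alive[a]]:
                continue
            for b in range(a + 1, len(alive)):
                if not keep[alive[b]]:
                    continue
                both = called_sub[:, a] & called_sub[:, b]
                nb = int(both.sum())
                if nb == 0:
                    continue
                conc = float((sub[both, a] == sub[both, b]).mean())
                if conc > self.dup_concordance:
                    keep[alive[b]] = False
                    reasons["duplicate"].append((panel.samples[alive[a]], panel.samples[alive[b]]))
        return keep, reasons

    # -- the loop ----------------------------------------------------------
    def fit_transform(self, X: GenotypePanel, y=None) -> GenotypePanel:
        panel = X
        locus_mask = np.ones(panel.n_loci, dtype=bool)
        sample_mask = np.ones(panel.n_samples, dtype=bool)
        history = []
        for round_no in range(self.max_iter):
            new_locus_mask, locus_reasons = self._locus_screen(panel, sample_mask)
            new_sample_mask, sample_reasons = self._sample_screen(panel, new_locus_mask, sample_mask)
            history.append({"round": round_no, "loci": locus_reasons, "samples": sample_reasons})
            if np.array_equal(new_locus_mask, locus_mask) and np.array_equal(new_sample_mask, sample_mask):
                break
            locus_mask, sample_mask = new_locus_mask, new_sample_mask
        if not locus_mask[~panel.sex_linked].any():
            raise RuntimeError(
                "QC removed every autosomal locus; check input panel. Report: " + repr(history[-1])
            )
        self.locus_mask_ = locus_mask
        self.sample_mask_ = sample_mask
        self.report_ = {
            "rounds": history,
            "n_loci_kept": int(locus_mask.sum()),
            "n_samples_kept": int(sample_mask.sum()),
            "removed_loci": [l for l, k in zip(panel.loci, locus_mask) if not k],
            "removed_samples": [s for s, k in zip(panel.samples, sample_mask) if not k],
        }
        out = panel.subset(locus_mask=locus_mask, sample_mask=sample_mask)
        out.estimate_models()
        return out

    def fit(self, X: GenotypePanel, y=None) -> "PanelQC":
        self.fit_transform(X, y)
        return self

    def transform(self, X: GenotypePanel) -> GenotypePanel:
        return self.fit_transform(X)


def qc_panel(panel: GenotypePanel, **kwargs) -> tuple[GenotypePanel, dict]:
    """Run panel QC; returns (filtered panel, report)."""
    qc = PanelQC(**kwargs)
    out = qc.fit_transform(panel)
    return out, qc.report_
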