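"""Pair-level screening and covariate repair for called kin.

mtDNA is inherited maternally, so haplotype sharing separates maternal from
paternal half-siblings and constrains which grandparent chains are possible.
Assigned ages are treated as exact by the kinship model, so the handful of
structurally impossible called pairs (a parent harvested before the
offspring's recorded birth, a same-cohort maternal half-sib pair) are
repaired by deterministic minimal edits to the covariates, with every edit
logged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .kernels import SampleRecord

__all__ = [
    "mtdna_shared",
    "ggp_feasible",
    "annotate_kin_strata",
    "repair_covariates",
    "RepairResult",
]


def annotate_kin_strata(kin: pd.DataFrame, records) -> pd.DataFrame:
    """Attach the observed mtDNA stratum ('M'/'P'/'U') to each kin pair."""
    recs = {r.id: r for r in records}
    strata = []
    for row in kin.itertuples(index=False):
        r1, r2 = recs.get(row.id1), recs.get(row.id2)
        if r1 is None or r2 is None:
            strata.append("U")
            continue
        shared = mtdna_shared(r1.mtdna, r2.mtdna)
        strata.append("U" if shared is None else ("M" if shared else "P"))
    out = kin.copy()
    out["mtdna_stratum"] = strata
    return out

_SEQ_CHARS = set("ACGTUNRYSWKMBDHV-.")


def _looks_like_sequence(h: str) -> bool:
    u = h.upper()
    return len(u) >= 10 and set(u) <= _SEQ_CHARS


def mtdna_shared(hap_i: Optional[str], hap_j: Optional[str], ambiguous: str = "N") -> Optional[bool]:
    """True iff two animals carry the same mtDNA haplotype.

    Accepts haplotype labels (exact match) or aligned control-region
    sequences (identity after masking positions where either sequence has an
    ambiguous base).  Returns None when either haplotype is missing, in
    which case the pair is analyzed without mtDNA conditioning.
    """
    if hap_i is None or hap_j is None:
        return None
    hi, hj = str(hap_i).strip(), str(hap_j).strip()
    if _looks_like_sequence(hi) and _looks_like_sequence(hj):
        if len(hi) != len(hj):
            raise ValueError("sequences must be aligned (equal length)")
        hi, hj = hi.upper(), hj.upper()
        for a, b in zip(hi, hj):
            if a == ambiguous or b == ambiguous:
                continue
            if a != b:
                return False
        return True
    return hi == hj


def ggp_feasible(older: SampleRecord, younger: SampleRecord, min_breeding_age: int = 5) -> bool:
    """Could ``older`` be a grandparent of ``younger``?

    Requires a birth gap of at least two generations (2 x minimum breeding
    age) and, because sampling is lethal, that the older animal lived to at
    least the minimum breeding age.
    """
    delta = younger.birth_year - older.birth_year
    return delta >= 2 * min_breeding_age and older.age >= min_breeding_age


@dataclass
class RepairResult:
    records: list
    edits: list
    excluded: list


def repair_covariates(
    kin: pd.DataFrame,
    records: Sequence[SampleRecord],
    max_edit_years: int = 2,
) -> RepairResult:
    """Deterministic minimal-edit repair of age inconsistencies in called kin.

    Rules (each edit increments an age, i.e. pushes a birth year back):

    * POP with the parent harvested before the offspring's recorded birth:
      the offspring's age is increased until birth_year <= parent death year.
    * Same-cohort maternal HSP (impossible: one pup per female per year):
      the older member's age is increased by 1 to create a 1-year gap.

    Pairs needing more than ``max_edit_years`` of adjustment are flagged and
    excluded rather than silently forced.  ``kin`` needs columns
    ``id1, id2, kin_class`` (POP rows: id1 is the parent) and, for HSP rows,
    an ``mtdna_stratum`` column ('M'/'P'/'U').
    """
    recs = {r.id: r for r in records}
    edits: list[dict] = []
    excluded: list[dict] = []
    for row in kin.itertuples(index=False):
        cls = row.kin_class
        r1, r2 = recs.get(row.id1), recs.get(row.id2)
        if r1 is None or r2 is None:
            continue
        if cls == "POP":
            parent, off = r1, r2
            if parent.death_year < off.birth_year:
                shift = off.birth_year - parent.death_year
                if shift > max_edit_years:
                    excluded.append({"id1": row.id1, "id2": row.id2, "reason": f"POP needs {shift}-year edit"})
                    continue
                new = replace(off, birth_year=off.birth_year - shift)
                recs[off.id] = new
                edits.append(
                    {
                        "id": off.id,
                        "field": "birth_year",
                        "old": off.birth_year,
                        "new": new.birth_year,
                        "reason": f"POP with parent {parent.id} harvested {shift} year(s) before recorded birth",
                    }
                )
        elif cls in {"HSP", "MHSP", "PHSP", "GGP", "HSP-GGP"}:
            # the repair is driven by the *observed* mtDNA stratum: a
            # same-cohort pair sharing a haplotype is maternally impossible
            stratum = getattr(row, "mtdna_stratum", "U")
            if stratum != "M":
                continue
            older, younger = (r1, r2) if r1.birth_year <= r2.birth_year else (r2, r1)
            if older.birth_year == younger.birth_year:
                if 1 > max_edit_years:
                    excluded.append({"id1": row.id1, "id2": row.id2, "reason": "same-cohort MHSP"})
                    continue
                new = replace(older, birth_year=older.birth_year - 1)
                recs[older.id] = new
                edits.append(
                    {
                        "id": older.id,
                        "field": "birth_year",
                        "old": older.birth_year,
                        "new": new.birth_year,
                        "reason": f"same-cohort maternal HSP with {younger.id}: gap forced to 1 year",
                    }
                )
    ordered = [recs[r.id] for r in records]
    return RepairResult(records=ordered, edits=edits, excluded=excluded)
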