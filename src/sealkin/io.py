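"""File formats, run configuration, and logging helpers.

Formats are deliberately plain text: a sample covariate CSV, a genotype TSV
(loci as rows with estimated allele frequencies, then one class-code column
per sample), an mtDNA table (2-column CSV or FASTA with sample-id headers),
a kin-pair CSV, and a fit JSON.  All writers round-trip losslessly and every
run configuration is echoed into the output with a content hash so that
thresholds are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .kernels import SampleRecord

__all__ = [
    "setup_logging",
    "read_samples",
    "write_samples",
    "read_mtdna",
    "read_kin_pairs",
    "write_kin_pairs",
    "write_fit_json",
    "RunConfig",
]

log = logging.getLogger("sealkin")


def setup_logging(level: int = logging.INFO) -> None:
    """Log to stderr with ISO timestamps; result files never mix with logs."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s", "%Y-%m-%dT%H:%M:%S")
    )
    root = logging.getLogger("sealkin")
    root.handlers[:] = [handler]
    root.setLevel(level)


def read_samples(path, mtdna: Optional[dict] = None) -> list:
    """Read sample covariates; rows with irreparable fields are rejected.

    Expected columns: id, sex, birth_year, death_year, age, mtdna, village
    (birth_year or age may be blank when the other is present; death_year is
    the sampling year under lethal sampling).  Returns validated
    SampleRecords; row-level problems are logged and raised together.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "sex" not in df.columns:
        raise ValueError("sample CSV needs at least id and sex columns")
    errors = []
    records = []
    seen = set()
    for i, row in df.iterrows():
        rid = str(row["id"])
        if rid in seen:
            errors.append(f"row {i}: duplicate id {rid}")
            continue
        seen.add(rid)
        sex = str(row.get("sex", "")).strip().upper()[:1]
        death = row.get("death_year")
        birth = row.get("birth_year")
        age = row.get("age")
        if pd.isna(death):
            errors.append(f"row {i} ({rid}): missing death_year")
            continue
        death = float(death)
        if pd.isna(birth) and pd.isna(age):
            errors.append(f"row {i} ({rid}): missing both age and birth_year; not usable")
            continue
        if pd.isna(birth):
            if float(age) != int(float(age)):
                errors.append(f"row {i} ({rid}): non-integer age {age}")
                continue
            birth = death - float(age)
        hap = row.get("mtdna")
        hap = None if (hap is None or (isinstance(hap, float) and np.isnan(hap))) else str(hap)
        if mtdna is not None:
            hap = mtdna.get(rid, hap)
        village = row.get("village")
        village = None if pd.isna(village) else str(village)
        try:
            records.append(
                SampleRecord(
                    id=rid,
                    sex=sex,
                    birth_year=int(birth),
                    death_year=int(death),
                    mtdna=hap,
                    village=village,
                )
            )
        except ValueError as exc:
            errors.append(f"row {i} ({rid}): {exc}")
    for e in errors:
        log.warning("read_samples: %s", e)
    if not records:
        raise ValueError("no usable sample records; " + "; ".join(errors[:5]))
    return records


def write_samples(records, path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "sex": r.sex,
                "birth_year": r.birth_year,
                "death_year": r.death_year,
                "age": r.age,
                "mtdna": r.mtdna,
                "village": r.village,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_mtdna(path) -> dict:
    """Sample id -> haplotype (label or sequence) from CSV or FASTA."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("mtDNA CSV needs two columns: id, haplotype")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_kin_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"id1", "id2", "kin_class"}
    if not need.issubset(df.columns):
        raise ValueError(f"kin-pair CSV needs columns {sorted(need)}")
    return df


def write_kin_pairs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _settings_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_fit_json(fit, settings: dict, path) -> None:
    """Fit results plus the full configuration echo and its content hash."""
    payload = {
        "fit": fit.to_dict() if hasattr(fit, "to_dict") else dict(fit),
        "settings": settings,
        "settings_hash": _settings_hash(settings),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


@dataclass
class RunConfig:
    """Plain-text (YAML) run configuration with full echo into results."""

    seed: int = 0
    plod_threshold: float = 40.0
    malf_min: float = 0.05
    nalf_max: float = 0.45
    min_shared_loci: int = 50
    pi_free: bool = True
    lambda0: float = 1.0
    include_ggp: bool = True
    fn_rate: float = 0.0
    min_breeding_age: int = 5
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        known["extra"] = raw
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return _settings_hash(self.to_dict())
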