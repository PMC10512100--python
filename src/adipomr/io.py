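"""Readers and writers for the package's tabular file dialects.

Formats:

* phenotype TSV — one row per participant, tab-separated, missing values as
  empty fields; sex coded 0 = female, 1 = male.
* dosage file — PLINK ``--export A`` ``.raw`` dialect (space-separated header
  ``FID IID PAT MAT SEX PHENOTYPE <SNP>_<A1> ...``, dosages in {0,1,2}) or a
  plain TSV alternative (``iid`` column followed by ``<SNP>_<A1>`` columns).
* variant-weight TSV — ``variant_id effect_allele weight pvalue``.
* truth JSON — nested record of the simulation ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Column order of the phenotype TSV.
PHENOTYPE_COLUMNS = (
    ["iid", "age", "sex"]
    + [f"pc{i}" for i in range(1, 11)]
    + ["bmi", "fmi", "whr", "smoking", "diabetes", "alcohol",
       "tc", "ldl", "hdl", "tg", "sbp", "dbp",
       "time_years", "dead", "cause_icd10",
       "prev_cvd", "prev_cancer", "prev_resp"]
)


@dataclass
class DosageMatrix:
    """Allele-dosage matrix with the counted allele of each variant.

    ``frame`` is indexed by participant iid (string) with one float column per
    variant id; ``counted_allele`` maps variant id → the allele whose copies
    the dosage counts (PLINK's A1 in the ``.raw`` header).
    """

    frame: pd.DataFrame
    counted_allele: dict

    @property
    def variant_ids(self) -> list:
        return list(self.frame.columns)

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_raw(self, path: str) -> None:
        """Write in the PLINK ``--export A`` dialect."""
        header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
            f"{v}_{self.counted_allele[v]}" for v in self.frame.columns
        ]
        out = pd.DataFrame(index=self.frame.index)
        out["FID"] = self.frame.index
        out["IID"] = self.frame.index
        out["PAT"] = 0
        out["MAT"] = 0
        out["SEX"] = 0
        out["PHENOTYPE"] = -9
        body = self.frame.copy()
        body.columns = header[6:]
        out = pd.concat([out, body], axis=1)
        out.to_csv(path, sep=" ", index=False, na_rep="NA")

    def to_tsv(self, path: str) -> None:
        out = self.frame.copy()
        out.columns = [f"{v}_{self.counted_allele[v]}" for v in self.frame.columns]
        out.insert(0, "iid", self.frame.index)
        out.to_csv(path, sep="\t", index=False, na_rep="")


def _split_variant_columns(columns) -> tuple[list, dict]:
    ids, alleles = [], {}
    for col in columns:
        if "_" not in col:
            raise ValueError(
                f"dosage column {col!r} lacks the <variant>_<allele> suffix"
            )
        vid, allele = col.rsplit("_", 1)
        ids.append(vid)
        alleles[vid] = allele
    return ids, alleles


def read_raw(path: str) -> DosageMatrix:
    """Read a PLINK ``--export A`` ``.raw`` dosage file."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}
    missing = meta - set(df.columns)
    if missing:
        raise ValueError(f".raw file {path} lacks header fields {sorted(missing)}")
    variant_cols = [c for c in df.columns if c not in meta]
    ids, alleles = _split_variant_columns(variant_cols)
    frame = df[variant_cols].astype(float)
    frame.columns = ids
    frame.index = df["IID"].astype(str)
    frame.index.name = "iid"
    return DosageMatrix(frame=frame, counted_allele=alleles)


def read_dosage_tsv(path: str) -> DosageMatrix:
    """Read the plain-TSV dosage alternative (``iid`` + ``<SNP>_<A1>`` columns)."""
    df = pd.read_csv(path, sep="\t")
    if "iid" not in df.columns:
        raise ValueError(f"dosage TSV {path} lacks an 'iid' column")
    variant_cols = [c for c in df.columns if c != "iid"]
    ids, alleles = _split_variant_columns(variant_cols)
    frame = df[variant_cols].astype(float)
    frame.columns = ids
    frame.index = df["iid"].astype(str)
    frame.index.name = "iid"
    return DosageMatrix(frame=frame, counted_allele=alleles)


def read_dosages(path: str) -> DosageMatrix:
    """Dispatch on extension: ``.raw`` dialect, otherwise plain TSV."""
    if str(path).endswith(".raw"):
        return read_raw(path)
    return read_dosage_tsv(path)


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"iid": str, "cause_icd10": str}, na_values=[""],
        keep_default_na=True,
    )
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file {path} lacks columns {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="",
              columns=[c for c in PHENOTYPE_COLUMNS if c in df.columns])


def read_weights(path: str) -> pd.DataFrame:
    """Read a variant-weight TSV and validate its invariants."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "effect_allele": str})
    required = {"variant_id", "effect_allele", "weight", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weights file {path} lacks columns {sorted(missing)}")
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids in {path}: {dups[:5]}")
    bad = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    if bad.any():
        raise ValueError(f"p-values outside (0, 1] in {path}")
    return df


def write_weights(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=["variant_id", "effect_allele", "weight", "pvalue"])


def write_truth(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=_jsonable)


def read_truth(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
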