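"""Core in-memory containers for TCR-beta repertoire data.

A *clonotype* is one unique rearrangement within one sample, identified by
its CDR3 nucleotide sequence plus the TRBV and TRBJ gene calls.  A
*repertoire* is the full clonotype table of one sample, held as a pandas
DataFrame so that cohort-scale operations stay vectorised.  Clonotype
fractions are always recomputed as ``count / total_count`` so every
downstream statistic shares a single frequency definition.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
DNA_SET = frozenset("ACGT")

#: standard-table codons per amino acid (used by the simulator and for
#: translation checks; stop codons excluded)
CODONS: dict[str, tuple[str, ...]] = {}
_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
for _codon, _aa in _STANDARD_TABLE.items():
    CODONS.setdefault(_aa, ())
    CODONS[_aa] = CODONS[_aa] + (_codon,)


def translate(cdr3_nt: str) -> str:
    """Translate an in-frame CDR3 nucleotide sequence (stop codons -> ``*``)."""
    if len(cdr3_nt) % 3 != 0:
        raise ValueError(f"length {len(cdr3_nt)} is not a multiple of 3")
    return "".join(
        _STANDARD_TABLE.get(cdr3_nt[i : i + 3], "*") for i in range(0, len(cdr3_nt), 3)
    )


def is_valid_aa(seq: str) -> bool:
    return bool(seq) and all(c in AA_SET for c in seq)


class Clonotype(NamedTuple):
    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    fraction: float


REPERTOIRE_COLUMNS = ["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "count", "fraction"]
IDENTITY_KEY = ["cdr3_nt", "v_gene", "j_gene"]


@dataclasses.dataclass
class Repertoire:
    """One sample's clonotype table.

    ``df`` holds columns ``cdr3_nt, cdr3_aa, v_gene, j_gene, count,
    fraction``; the identity key (cdr3_nt, v_gene, j_gene) is unique and
    fractions are count shares of ``total_count``.
    """

    sample_id: str
    df: pd.DataFrame

    @classmethod
    def from_counts(cls, sample_id: str, df: pd.DataFrame) -> "Repertoire":
        """Build a repertoire from a count table, recomputing fractions.

        Rows sharing the identity key are collapsed by summing counts.
        """
        if df.empty:
            raise ValueError(f"{sample_id}: empty clonotype table")
        df = df[["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "count"]].copy()
        if df.duplicated(IDENTITY_KEY).any():
            df = (
                df.groupby(IDENTITY_KEY, as_index=False, sort=False)
                .agg(cdr3_aa=("cdr3_aa", "first"), count=("count", "sum"))
            )[["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "count"]]
        df["count"] = df["count"].astype(np.int64)
        total = int(df["count"].sum())
        df["fraction"] = df["count"] / total
        return cls(sample_id, df.reset_index(drop=True))

    @property
    def total_count(self) -> int:
        return int(self.df["count"].sum())

    @property
    def n_unique(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def clonotypes(self) -> Iterator[Clonotype]:
        for row in self.df.itertuples(index=False):
            yield Clonotype(
                row.cdr3_nt, row.cdr3_aa, row.v_gene, row.j_gene,
                int(row.count), float(row.fraction),
            )

    def aa_fractions(self) -> pd.Series:
        """Amino-acid-level fractions: nucleotide variants of one CDR3 aa
        within this sample are pooled by summing their fractions."""
        return self.df.groupby("cdr3_aa")["fraction"].sum()

    def validate(self) -> None:
        df = self.df
        if df.empty:
            raise ValueError(f"{self.sample_id}: empty repertoire")
        if (df["count"] < 1).any():
            raise ValueError(f"{self.sample_id}: non-positive clone count")
        if df.duplicated(IDENTITY_KEY).any():
            raise ValueError(f"{self.sample_id}: duplicate clonotype identity key")
        total = df["count"].sum()
        if not np.allclose(df["fraction"], df["count"] / total, atol=1e-12):
            raise ValueError(f"{self.sample_id}: fractions inconsistent with counts")
        if abs(df["fraction"].sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: fractions do not sum to 1")


VALID_STAGES = ("I", "II", "III", "IV", "NA")
VALID_GROUPS = ("tumor", "control")
VALID_SEX = ("male", "female", "NA")


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str
    stage: str = "NA"
    age: int = 0
    sex: str = "NA"

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"{self.sample_id}: invalid group {self.group!r}")
        if self.stage not in VALID_STAGES:
            raise ValueError(f"{self.sample_id}: invalid stage {self.stage!r}")
        if self.sex not in VALID_SEX:
            raise ValueError(f"{self.sample_id}: invalid sex {self.sex!r}")
        if (self.stage == "NA") != (self.group == "control"):
            raise ValueError(
                f"{self.sample_id}: stage must be NA exactly for controls "
                f"(group={self.group}, stage={self.stage})"
            )
        if self.age < 0:
            raise ValueError(f"{self.sample_id}: negative age")


@dataclasses.dataclass(frozen=True)
class AntigenRecord:
    """One database entry linking a CDR3 aa sequence to an epitope."""

    cdr3_aa: str
    epitope: str
    antigen_species: str
    source_db: str = ""

    def __post_init__(self) -> None:
        if not is_valid_aa(self.cdr3_aa):
            raise ValueError(f"invalid CDR3 aa sequence {self.cdr3_aa!r}")


HLA_ALLELE_RE = re.compile(r"^[A-Z]+[0-9]*\*\d{2,3}:\d{2,3}$")


@dataclasses.dataclass(frozen=True)
class HLATable:
    sample_id: str
    alleles: frozenset[str]

    def __post_init__(self) -> None:
        bad = sorted(a for a in self.alleles if not HLA_ALLELE_RE.match(a))
        if bad:
            raise ValueError(f"{self.sample_id}: malformed HLA alleles {bad}")


def meta_frame(meta: list[SampleMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        [(m.sample_id, m.group, m.stage, m.age, m.sex) for m in meta],
        columns=["sample_id", "group", "stage", "age", "sex"],
    )
    return df.set_index("sample_id")
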