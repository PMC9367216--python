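"""Readers and writers for clonotype tables and cohort side inputs.

Two tab-separated clonotype dialects are supported:

* ``airr`` — AIRR-C rearrangement TSV with columns ``junction``,
  ``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``.
* ``mixcr`` — a MiXCR-export-like TSV with columns ``cloneCount``,
  ``cloneFraction``, ``nSeqCDR3``, ``aaSeqCDR3``, ``allVHitsWithScore``,
  ``allJHitsWithScore``.

Gene calls are normalised to gene level: allele suffixes (``*00``) and
alignment-score annotations (``(1234)``) are stripped and only the best
(first-listed) hit is kept.  Records whose CDR3 amino-acid sequence
contains a stop codon (``*`` or ``_``) or any non-standard residue are
dropped with a logged count — the analysis operates on productive CDR3s.
Fractions are always recomputed from counts; a fraction column present in
the input is cross-checked at 1e-6 and mismatches are logged.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .models import (
    AntigenRecord,
    HLATable,
    Repertoire,
    SampleMeta,
    VALID_GROUPS,
    VALID_SEX,
    VALID_STAGES,
    is_valid_aa,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A table does not conform to its declared dialect."""


AIRR_COLUMNS = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count"]
MIXCR_COLUMNS = [
    "cloneCount",
    "cloneFraction",
    "nSeqCDR3",
    "aaSeqCDR3",
    "allVHitsWithScore",
    "allJHitsWithScore",
]

_SCORE_RE = re.compile(r"\([^)]*\)")


def normalize_gene(raw: str) -> str:
    """Collapse a gene call to gene level.

    Keeps the first hit of a comma-separated list, strips a trailing
    ``(score)`` annotation and an ``*allele`` suffix.  Idempotent.
    """
    g = str(raw).split(",")[0].strip()
    g = _SCORE_RE.sub("", g)
    return g.split("*")[0].strip()


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_clonotype_table(path: str | Path, dialect: str = "airr") -> Repertoire:
    """Read one sample's clonotype table into a :class:`Repertoire`.

    The sample id is the file stem.  Duplicate identity keys are summed
    with a warning; invalid amino-acid CDR3s are dropped and counted.
    """
    path = Path(path)
    if dialect == "airr":
        df = _read_tsv(path, AIRR_COLUMNS)
        tab = pd.DataFrame(
            {
                "cdr3_nt": df["junction"].astype(str).str.upper(),
                "cdr3_aa": df["junction_aa"].astype(str),
                "v_gene": df["v_call"].map(normalize_gene),
                "j_gene": df["j_call"].map(normalize_gene),
                "count": pd.to_numeric(df["duplicate_count"]),
            }
        )
        in_fraction = None
    elif dialect == "mixcr":
        df = _read_tsv(path, MIXCR_COLUMNS)
        tab = pd.DataFrame(
            {
                "cdr3_nt": df["nSeqCDR3"].astype(str).str.upper(),
                "cdr3_aa": df["aaSeqCDR3"].astype(str),
                "v_gene": df["allVHitsWithScore"].map(normalize_gene),
                "j_gene": df["allJHitsWithScore"].map(normalize_gene),
                "count": pd.to_numeric(df["cloneCount"]),
            }
        )
        in_fraction = pd.to_numeric(df["cloneFraction"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if tab.empty:
        raise FormatError(f"{path}: empty clonotype table")

    ok = tab["cdr3_aa"].map(is_valid_aa)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d record(s) with stop codons or non-standard residues",
            path.name,
            n_dropped,
        )
        tab = tab[ok]
        if in_fraction is not None:
            in_fraction = in_fraction[ok]
    if tab.empty:
        raise FormatError(f"{path}: no productive records after filtering")

    n_dup = int(tab.duplicated(["cdr3_nt", "v_gene", "j_gene"]).sum())
    if n_dup:
        logger.warning(
            "%s: %d duplicate clonotype identity key(s); counts summed", path.name, n_dup
        )
    rep = Repertoire.from_counts(path.stem, tab)
    if in_fraction is not None and n_dup == 0:
        recomputed = rep.df["fraction"].to_numpy()
        if (abs(recomputed - in_fraction.to_numpy(dtype=float)) > 1e-6).any():
            logger.warning(
                "%s: input cloneFraction differs from count-derived fractions "
                "(recomputed values are used)",
                path.name,
            )
    return rep


def write_clonotype_table(rep: Repertoire, path: str | Path, dialect: str = "airr") -> None:
    """Write a repertoire as an AIRR rearrangement TSV (round-trip safe)."""
    if dialect != "airr":
        raise ValueError(f"unsupported output dialect {dialect!r}")
    if rep.df.empty:
        raise ValueError("refusing to write an empty clonotype table")
    out = pd.DataFrame(
        {
            "junction": rep.df["cdr3_nt"],
            "junction_aa": rep.df["cdr3_aa"],
            "v_call": rep.df["v_gene"],
            "j_call": rep.df["j_gene"],
            "duplicate_count": rep.df["count"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the cohort metadata TSV (sample_id, group, stage, age, sex)."""
    df = _read_tsv(path, ["sample_id", "group"])
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"{path}: duplicate sample_id {dups}")
    errors: list[str] = []
    out: list[SampleMeta] = []
    for i, row in enumerate(df.itertuples(index=False)):
        stage = getattr(row, "stage", "NA")
        sex = getattr(row, "sex", "NA")
        age = getattr(row, "age", 0)
        stage = "NA" if pd.isna(stage) else str(stage)
        sex = "NA" if pd.isna(sex) else str(sex)
        try:
            if str(row.group) not in VALID_GROUPS:
                raise ValueError(f"invalid group {row.group!r}")
            if stage not in VALID_STAGES:
                raise ValueError(f"invalid stage {stage!r}")
            if sex not in VALID_SEX:
                raise ValueError(f"invalid sex {sex!r}")
            out.append(
                SampleMeta(
                    sample_id=str(row.sample_id),
                    group=str(row.group),
                    stage=stage,
                    age=int(age) if not pd.isna(age) else 0,
                    sex=sex,
                )
            )
        except ValueError as exc:
            errors.append(f"row {i + 2}: {exc}")
    if errors:
        raise FormatError(f"{path}: invalid metadata — " + "; ".join(errors))
    return out


def write_metadata(meta: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.group, m.stage, m.age, m.sex) for m in meta],
        columns=["sample_id", "group", "stage", "age", "sex"],
    ).to_csv(path, sep="\t", index=False)


def read_antigen_db(path: str | Path) -> list[AntigenRecord]:
    """Read an antigen-specificity database TSV.

    Columns: ``cdr3_aa``, ``epitope``, ``antigen_species``, optional
    ``source_db``.  One CDR3 may appear in several rows (one per epitope);
    all rows are retained.
    """
    df = _read_tsv(path, ["cdr3_aa", "epitope", "antigen_species"])
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AntigenRecord(
                cdr3_aa=str(row.cdr3_aa).upper(),
                epitope=str(row.epitope),
                antigen_species=str(row.antigen_species),
                source_db=str(getattr(row, "source_db", "")),
            )
        )
    return records


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a one-column CDR3 aa exclusion list (deduplicated, uppercased)."""
    df = _read_tsv(path, ["cdr3_aa"])
    return set(df["cdr3_aa"].astype(str).str.upper())


def read_hla(path: str | Path) -> list[HLATable]:
    """Read a long-format HLA table (sample_id, allele; one allele per row)."""
    df = _read_tsv(path, ["sample_id", "allele"])
    out = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        out.append(HLATable(sample_id=str(sample_id), alleles=frozenset(sub["allele"])))
    return out


def read_cohort(
    cohort_dir: str | Path, meta: list[SampleMeta], dialect: str = "airr"
) -> list[Repertoire]:
    """Load ``<cohort_dir>/<sample_id>.tsv`` for every metadata entry."""
    cohort_dir = Path(cohort_dir)
    reps = []
    for m in meta:
        reps.append(read_clonotype_table(cohort_dir / f"{m.sample_id}.tsv", dialect))
    return reps
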