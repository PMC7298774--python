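"""File formats and validated domain types for the paralog-pair analysis.

The pipeline consumes four external inputs:

* **paired CDS FASTA** — codon-aligned, gap-free coding sequences, two
  records per paralog pair, headers ``>pairID|geneID``;
* **expression TSV** — genes x samples matrix of FPKM-like values, sample
  names encoding condition metadata as ``{stress}_{time}_{rep}`` with an
  optional ``_ctrl`` suffix for control samples;
* **differential-expression TSV** — one row per gene x condition with
  log2 fold change, adjusted p-value and an expressed flag (the output a
  count-based DE caller such as edgeR would produce);
* **TF list** — plain text, one transcription-factor gene ID per line.

All readers validate into the domain dataclasses below and raise
:class:`FormatError` / :class:`ValidationError` naming the offending record.
Writers round-trip exactly (strings bitwise, floats to 6 significant digits
on disk, re-read within 1e-12 relative error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STRESSES",
    "FormatError",
    "ValidationError",
    "ParalogPair",
    "ExpressionMatrix",
    "DERecord",
    "TFList",
    "read_pair_fasta",
    "write_pair_fasta",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_de_tsv",
    "write_de_tsv",
    "read_tf_list",
    "write_tf_list",
]

#: Stress codes: drought, cold, Botrytis cinerea infection, Pieris rapae herbivory.
STRESSES: tuple[str, ...] = ("Dr", "Cd", "Bc", "Pr")

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
_VALID_NT = frozenset("ACGT")


class FormatError(ValueError):
    """Structural problem with an input file (parse-level)."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


def _check_cds(cds: str, label: str) -> None:
    bad = set(cds) - _VALID_NT
    if bad:
        raise ValidationError(
            f"{label}: non-ACGT character(s) {sorted(bad)} (ambiguity codes are rejected)"
        )
    if len(cds) % 3 != 0:
        raise ValidationError(f"{label}: length {len(cds)} is not a multiple of 3")
    for i in range(0, len(cds), 3):
        if cds[i : i + 3] in _STOP_CODONS:
            raise ValidationError(
                f"{label}: stop codon {cds[i:i+3]} at codon {i // 3 + 1}; "
                "trim terminal stops before input"
            )


@dataclass(frozen=True)
class ParalogPair:
    """A paralogous gene pair with codon-aligned, gap-free CDS.

    Sequences must be equal length, a multiple of 3, stop-free in frame 0 and
    contain only A/C/G/T. Alignment is the caller's responsibility: the two
    CDS are compared codon by codon as given.
    """

    pair_id: str
    gene_a: str
    gene_b: str
    cds_a: str
    cds_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"pair {self.pair_id}: gene_a == gene_b ({self.gene_a})")
        if len(self.cds_a) != len(self.cds_b):
            raise ValidationError(
                f"pair {self.pair_id}: unequal CDS lengths "
                f"({len(self.cds_a)} vs {len(self.cds_b)})"
            )
        _check_cds(self.cds_a, f"pair {self.pair_id} gene {self.gene_a}")
        _check_cds(self.cds_b, f"pair {self.pair_id} gene {self.gene_b}")

    @property
    def n_codons(self) -> int:
        return len(self.cds_a) // 3


@dataclass(frozen=True)
class DERecord:
    """Differential-expression call for one gene under one (stress, time) condition."""

    gene: str
    stress: str
    time_index: int
    log2fc: float
    padj: float
    expressed: bool

    def __post_init__(self) -> None:
        if self.stress not in STRESSES:
            raise ValidationError(f"gene {self.gene}: unknown stress code {self.stress!r}")
        if not (0.0 <= self.padj <= 1.0):
            raise ValidationError(f"gene {self.gene}: padj {self.padj} outside [0, 1]")
        if self.expressed and not math.isfinite(self.log2fc):
            raise ValidationError(f"gene {self.gene}: non-finite log2FC for expressed gene")

    @property
    def condition(self) -> tuple[str, int]:
        return (self.stress, self.time_index)


@dataclass(frozen=True)
class TFList:
    """Set of gene IDs annotated as transcription factors."""

    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "TFList":
        ids = list(ids)
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(g for g in ids if g in seen or seen.add(g))
            raise ValidationError(f"duplicate TF gene ID {dup!r}")
        return cls(frozenset(ids))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """FPKM-like expression values (genes x samples) plus per-sample metadata.

    ``sample_meta`` is indexed by sample ID with columns
    ``stress``, ``time_index``, ``replicate``, ``is_control``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene ID {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValidationError("sample metadata does not match matrix columns")
        for stress in self.sample_meta["stress"].unique():
            if stress not in STRESSES:
                raise ValidationError(f"unknown stress code {stress!r} in sample metadata")
        treated = self.sample_meta[~self.sample_meta["is_control"]]
        for (stress, t), grp in self.sample_meta.groupby(["stress", "time_index"]):
            if not (~grp["is_control"]).any():
                raise ValidationError(f"condition ({stress}, {t}) has no treated sample")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def treated_samples(self, stress: str | None = None, time_index: int | None = None) -> list[str]:
        """Sample IDs of treated (non-control) samples, optionally filtered."""
        meta = self.sample_meta[~self.sample_meta["is_control"]]
        if stress is not None:
            meta = meta[meta["stress"] == stress]
        if time_index is not None:
            meta = meta[meta["time_index"] == time_index]
        return list(meta.index)

    def log_values(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        """Natural-log expression, log(FPKM + 1); correlations are computed on this scale."""
        vals = self.values if samples is None else self.values[list(samples)]
        return np.log1p(vals)


# ---------------------------------------------------------------------------
# FASTA (paralog pairs)
# ---------------------------------------------------------------------------

def _parse_pair_header(header: str, path: Path) -> tuple[str, str]:
    if "|" not in header:
        raise FormatError(f"{path}: header {header!r} lacks 'pairID|geneID' convention")
    pair_id, gene_id = header.split("|", 1)
    return pair_id, gene_id


def read_pair_fasta(path: str | Path) -> list[ParalogPair]:
    """Read codon-aligned paralog pairs from FASTA (two consecutive records per pair)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise FormatError(f"{path}: odd record count ({len(records)}); pairs need two records")
    pairs: list[ParalogPair] = []
    for i in range(0, len(records), 2):
        pid_a, gene_a = _parse_pair_header(records[i].id, path)
        pid_b, gene_b = _parse_pair_header(records[i + 1].id, path)
        if pid_a != pid_b:
            raise FormatError(
                f"{path}: consecutive records {records[i].id!r} and {records[i+1].id!r} "
                "belong to different pairs"
            )
        pairs.append(
            ParalogPair(
                pair_id=pid_a,
                gene_a=gene_a,
                gene_b=gene_b,
                cds_a=str(records[i].seq).upper(),
                cds_b=str(records[i + 1].seq).upper(),
            )
        )
    return pairs


def write_pair_fasta(pairs: Iterable[ParalogPair], path: str | Path) -> None:
    records = []
    for p in pairs:
        records.append(SeqRecord(Seq(p.cds_a), id=f"{p.pair_id}|{p.gene_a}", description=""))
        records.append(SeqRecord(Seq(p.cds_b), id=f"{p.pair_id}|{p.gene_b}", description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Expression matrix TSV
# ---------------------------------------------------------------------------

def _parse_sample_name(name: str) -> dict:
    parts = name.split("_")
    is_control = parts[-1] == "ctrl"
    if is_control:
        parts = parts[:-1]
    if len(parts) != 3:
        raise FormatError(
            f"sample name {name!r} does not follow 'stress_time_rep[_ctrl]'"
        )
    stress, t, rep = parts
    if stress not in STRESSES:
        raise ValidationError(f"sample {name!r}: unknown stress code {stress!r}")
    try:
        return {
            "stress": stress,
            "time_index": int(t),
            "replicate": int(rep),
            "is_control": is_control,
        }
    except ValueError as exc:
        raise FormatError(f"sample name {name!r}: {exc}") from exc


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV; sample names encode ``stress_time_rep[_ctrl]``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.DataFrame([_parse_sample_name(c) for c in df.columns], index=df.columns)
    return ExpressionMatrix(values=df.astype(float), sample_meta=meta)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")


# ---------------------------------------------------------------------------
# DE table TSV
# ---------------------------------------------------------------------------

_DE_COLUMNS = ["gene", "stress", "time_index", "log2FC", "padj", "expressed"]


def read_de_tsv(path: str | Path) -> list[DERecord]:
    """Read a differential-expression table (gene, stress, time_index, log2FC, padj, expressed)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_DE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        expressed = str(row.expressed).strip().lower() in {"true", "1", "yes"}
        records.append(
            DERecord(
                gene=str(row.gene),
                stress=str(row.stress),
                time_index=int(row.time_index),
                log2fc=float(row.log2FC),
                padj=float(row.padj),
                expressed=expressed,
            )
        )
    return records


def write_de_tsv(records: Iterable[DERecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "stress": r.stress,
                "time_index": r.time_index,
                "log2FC": r.log2fc,
                "padj": r.padj,
                "expressed": r.expressed,
            }
            for r in records
        ],
        columns=_DE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# TF list
# ---------------------------------------------------------------------------

def read_tf_list(path: str | Path) -> TFList:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return TFList.from_iterable([ln for ln in lines if ln])


def write_tf_list(tfs: TFList, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(tfs.genes)) + "\n")
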