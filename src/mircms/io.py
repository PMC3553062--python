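"""Reading and writing the formats the pipeline touches.

All sequences are held internally in the DNA alphabet; RNA input (U) is
normalized to T on ingest so that catalog matching, substring exclusion and
degradome anchoring all operate over a single alphabet.

The two in-study reference tables (the differentially expressed miRNA table
and the novel-miRNA target table) ship as TSV fixtures inside the package,
so no network access is ever required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_RNA_TO_DNA = str.maketrans("Uu", "Tt")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (DNA alphabet; U converted to T).

    ``quality`` carries Sanger-scale Phred scores for FASTQ input and is
    ``None`` for FASTA records.
    """

    identifier: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ParseError("empty record identifier")
        if len(self.sequence) == 0:
            raise ParseError(f"record {self.identifier!r} has an empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(
                f"record {self.identifier!r} contains invalid characters {sorted(bad)}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"record {self.identifier!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.translate(_RNA_TO_DNA).upper()


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Raises :class:`ParseError` (naming the offending line where it can be
    located) for records with empty sequences or malformed headers.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    # Bio.SeqIO silently yields empty sequences for headers without a body,
    # so validate line structure ourselves while delegating parsing.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">") and line[1:].strip() == "":
                raise ParseError(f"{path}:{lineno}: FASTA header with no name")
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has no sequence body")
        # Keep the full header (id + description) so annotations like
        # "count=7" survive the round trip.
        records.append(SequenceRecord(rec.description, normalize_sequence(str(rec.seq))))
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line FASTQ (Sanger qualities) into SequenceRecords.

    Qualities are retained on the record for optional downstream filtering.
    A quality string whose length differs from the sequence is a parse error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            records.append(
                SequenceRecord(rec.id, normalize_sequence(str(rec.seq)), quals)
            )
    except ValueError as exc:  # Biopython signals length mismatch this way
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping bodies at ``width`` columns."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Packaged study tables
# ---------------------------------------------------------------------------

TABLE1_RESOURCE = "table1_de_mirnas.tsv"
TABLE2_RESOURCE = "table2_novel_targets.tsv"


@dataclass(frozen=True)
class Table1Row:
    """One differentially expressed miRNA: normalized counts in the
    maintainer-fertile (MF) and male-sterile (CMS) libraries plus the three
    test p-values and the direction of change (CMS relative to MF)."""

    uniqid: str
    sequence: str
    norm_mf: int
    norm_cms: int
    p_ac: float
    p_fisher: float
    p_chi2: float
    direction: str  # "up" | "down"


@dataclass(frozen=True)
class Table2Row:
    """One degradome-supported target of a novel candidate miRNA.

    ``mf_norm_reads`` / ``cms_norm_reads`` are normalized degradome read
    support per library; a blank cell in the source table is ``None`` (the
    library simply had no signal reported), never zero.
    """

    mirna_id: str
    transcript_id: str
    category: int
    cleavage_site: int
    mf_norm_reads: float | None
    cms_norm_reads: float | None
    annotation: str


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("mircms").joinpath("data", name)))


def load_table1(path: str | Path | None = None) -> list[Table1Row]:
    """Load the differential-expression table (packaged fixture by default)."""
    src = Path(path) if path is not None else _fixture_path(TABLE1_RESOURCE)
    df = pd.read_csv(src, sep="\t", dtype=str)
    expected = ["uniqid", "sequence", "norm_MF", "norm_CMS",
                "p_AC", "p_Fisher", "p_Chi2x2", "direction"]
    if list(df.columns) != expected:
        raise ParseError(f"{src}: expected columns {expected}, got {list(df.columns)}")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            Table1Row(
                uniqid=r.uniqid,
                sequence=normalize_sequence(r.sequence),
                norm_mf=int(r.norm_MF),
                norm_cms=int(r.norm_CMS),
                p_ac=float(r.p_AC),
                p_fisher=float(r.p_Fisher),
                p_chi2=float(r.p_Chi2x2),
                direction=r.direction,
            )
        )
    return rows


def load_table2(path: str | Path | None = None) -> list[Table2Row]:
    """Load the novel-miRNA target table (packaged fixture by default)."""
    src = Path(path) if path is not None else _fixture_path(TABLE2_RESOURCE)
    df = pd.read_csv(src, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    expected = ["mirna_id", "transcript_id", "category", "cleavage_site",
                "mf_norm_reads", "cms_norm_reads", "annotation"]
    if list(df.columns) != expected:
        raise ParseError(f"{src}: expected columns {expected}, got {list(df.columns)}")

    def _opt(v) -> float | None:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    rows = []
    for r in df.itertuples(index=False):
        row = Table2Row(
            mirna_id=r.mirna_id,
            transcript_id=r.transcript_id,
            category=int(r.category),
            cleavage_site=int(r.cleavage_site),
            mf_norm_reads=_opt(r.mf_norm_reads),
            cms_norm_reads=_opt(r.cms_norm_reads),
            annotation=r.annotation,
        )
        if row.category not in range(5):
            raise ParseError(f"{src}: category {row.category} outside 0–4")
        if row.mf_norm_reads is None and row.cms_norm_reads is None:
            raise ParseError(
                f"{src}: {row.transcript_id}: both read-support cells absent"
            )
        rows.append(row)
    return rows


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def iter_fasta_lazy(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream FASTA records without holding the whole file (genome-sized inputs)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield SequenceRecord(rec.id, normalize_sequence(str(rec.seq)))
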