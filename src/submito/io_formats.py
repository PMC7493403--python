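"""Readers and writers for the external formats the toolkit touches.

Supported formats:

* FASTA proteomes (via Biopython).
* PSI-BLAST ASCII PSSM files (``-out_ascii_pssm`` dialect): three header
  lines, then one row per residue carrying the position, the residue
  letter, 20 integer log-odds scores, 20 weighted-percentage columns and
  two trailing per-row floats.  Only the log-odds block is retained.
* Tab-separated tables with a mandatory header row: localization-tool
  vote tables, GO annotation tables, prediction output, truth labels.

All tables are strict TSV; there is no delimiter sniffing.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: residue column order of the PSI-BLAST ASCII PSSM dialect
PSSM_ALPHABET = tuple("ARNDCQEGHILKMFPSTWYV")

STANDARD_AA = frozenset(PSSM_ALPHABET)
TOLERATED_AA = STANDARD_AA | frozenset("XBZUO")

GO_ASPECTS = ("BP", "MF")
ANNOTATION_SOURCES = ("GOA_manual", "GOA_IEA", "BAR")
DEFAULT_TOOLS = ("BUSCA", "TargetP2", "MitoFates")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence, the unit flowing through every stage."""

    id: str
    sequence: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein id must be non-empty")
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise FormatError(f"{self.id}: empty sequence")
        bad = set(seq) - TOLERATED_AA
        if bad:
            raise FormatError(f"{self.id}: illegal residue letters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        nonstd = set(seq) - STANDARD_AA
        if nonstd:
            logger.warning("%s: non-standard residues %s", self.id, sorted(nonstd))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSSMProfile:
    """L x 20 integer log-odds profile paired with its sequence letters."""

    protein_id: str
    matrix: np.ndarray  # (L, 20) int
    residue_column_order: tuple[str, ...] = PSSM_ALPHABET

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[1] != 20:
            raise FormatError(f"{self.protein_id}: PSSM must be Lx20, got {m.shape}")
        object.__setattr__(self, "matrix", m.astype(np.int64))

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class GOAnnotation:
    """(protein, GO term, aspect, evidence, source) with source-quality tiers."""

    protein_id: str
    term: str
    aspect: str
    evidence: str
    source: str

    def __post_init__(self) -> None:
        if self.aspect not in GO_ASPECTS:
            raise FormatError(
                f"aspect must be one of {GO_ASPECTS}, got {self.aspect!r}"
            )
        if self.source not in ANNOTATION_SOURCES:
            raise FormatError(
                f"source must be one of {ANNOTATION_SOURCES}, got {self.source!r}"
            )
        if not (
            self.term.startswith("GO:")
            and len(self.term) == 10
            and self.term[3:].isdigit()
        ):
            raise FormatError(f"malformed GO id {self.term!r}")

    def key(self) -> tuple[str, str, str]:
        return (self.protein_id, self.term, self.aspect)


@dataclass
class ToolVoteTable:
    """Per-protein boolean mitochondrial calls from external localization tools."""

    tools: tuple[str, ...] = DEFAULT_TOOLS
    votes: dict[tuple[str, str], bool] = field(default_factory=dict)

    def add(self, protein_id: str, tool: str, is_mitochondrial: bool) -> None:
        if tool not in self.tools:
            raise FormatError(f"unknown tool {tool!r}; expected one of {self.tools}")
        key = (protein_id, tool)
        if key in self.votes:
            raise FormatError(f"duplicate vote for protein {protein_id!r}, tool {tool!r}")
        self.votes[key] = is_mitochondrial

    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.votes:
            seen.setdefault(pid)
        return list(seen)

    def votes_for(self, protein_id: str) -> dict[str, bool]:
        return {
            tool: flag
            for (pid, tool), flag in self.votes.items()
            if pid == protein_id
        }


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into protein records, order preserved.

    Raises on duplicate ids or on leading non-header content; an empty
    file yields an empty list with a warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            logger.warning("%s: empty FASTA file", path)
            return []
        if first != ">":
            raise FormatError(f"{path}: line 1: expected '>' FASTA header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord], width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

_PSSM_TITLE = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


def read_pssm(path: str | Path, record: ProteinRecord) -> PSSMProfile:
    """Parse an ASCII PSSM and verify it against the paired sequence.

    Returns only the Lx20 log-odds block; the weighted-percentage columns
    and the two trailing per-row floats are ignored.
    """
    rows: list[list[int]] = []
    letters: list[str] = []
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    data_lines = []
    for line in lines[3:]:
        parts = line.split()
        if parts and parts[0].isdigit():
            data_lines.append(parts)
    for parts in data_lines:
        pos = int(parts[0])
        if len(parts) < 42:
            raise FormatError(
                f"{path}: position {pos}: expected >= 42 fields, got {len(parts)}"
            )
        letters.append(parts[1])
        rows.append([int(v) for v in parts[2:22]])
    if len(rows) != len(record):
        raise FormatError(
            f"{path}: {len(rows)} PSSM rows but sequence {record.id!r} "
            f"has length {len(record)}"
        )
    for i, (letter, expected) in enumerate(zip(letters, record.sequence), start=1):
        if letter != expected:
            raise FormatError(
                f"{path}: position {i}: PSSM letter {letter!r} does not match "
                f"sequence letter {expected!r}"
            )
    return PSSMProfile(protein_id=record.id, matrix=np.array(rows, dtype=np.int64))


def write_pssm(path: str | Path, record: ProteinRecord, profile: PSSMProfile) -> None:
    """Emit a profile in the ASCII PSSM dialect that :func:`read_pssm` accepts.

    The percentage block is written as zeros and the two per-row floats as
    0.00 — placeholders the reader ignores.
    """
    if len(profile) != len(record):
        raise FormatError("profile/sequence length mismatch")
    header_letters = "  ".join(PSSM_ALPHABET)
    with _open_text(path, "wt") as fh:
        fh.write("\n")
        fh.write(_PSSM_TITLE + "\n")
        fh.write("            " + header_letters + "   " + header_letters + "\n")
        for i, (aa, row) in enumerate(zip(record.sequence, profile.matrix), start=1):
            scores = " ".join(f"{int(v):3d}" for v in row)
            pcts = " ".join(f"{0:3d}" for _ in range(20))
            fh.write(f"{i:5d} {aa} {scores}  {pcts}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path: str | Path, expected_cols: Sequence[str]) -> list[dict[str, str]]:
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty table (header row required)")
    header = lines[0].split("\t")
    if header != list(expected_cols):
        raise FormatError(
            f"{path}: expected header {list(expected_cols)}, got {header}"
        )
    out = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise FormatError(f"{path}: row with {len(parts)} fields: {ln!r}")
        out.append(dict(zip(header, parts)))
    return out


def read_votes(path: str | Path, tools: tuple[str, ...] = DEFAULT_TOOLS) -> ToolVoteTable:
    """Read a tool-vote table: protein_id, tool, is_mitochondrial (true/false)."""
    table = ToolVoteTable(tools=tools)
    for row in _read_tsv(path, ("protein_id", "tool", "is_mitochondrial")):
        flag_str = row["is_mitochondrial"].strip().lower()
        if flag_str not in ("true", "false", "1", "0"):
            raise FormatError(f"{path}: bad boolean {row['is_mitochondrial']!r}")
        table.add(row["protein_id"], row["tool"], flag_str in ("true", "1"))
    return table


def write_votes(path: str | Path, table: ToolVoteTable) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("protein_id\ttool\tis_mitochondrial\n")
        for (pid, tool), flag in table.votes.items():
            fh.write(f"{pid}\t{tool}\t{str(flag).lower()}\n")


def read_go_table(path: str | Path) -> list[GOAnnotation]:
    """Read GO annotations: protein_id, go_term, aspect (BP/MF), evidence, source."""
    cols = ("protein_id", "go_term", "aspect", "evidence", "source")
    return [
        GOAnnotation(
            protein_id=row["protein_id"],
            term=row["go_term"],
            aspect=row["aspect"],
            evidence=row["evidence"],
            source=row["source"],
        )
        for row in _read_tsv(path, cols)
    ]


def write_go_table(path: str | Path, annotations: Iterable[GOAnnotation]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("protein_id\tgo_term\taspect\tevidence\tsource\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.term}\t{a.aspect}\t{a.evidence}\t{a.source}\n")


PREDICTION_COLUMNS = (
    "protein_id",
    "predicted_compartment",
    "p_outer",
    "p_inner",
    "p_ims",
    "p_matrix",
)


def write_predictions(path: str | Path, results: Iterable) -> None:
    """Write prediction results (see :mod:`submito.cnn_model`) as TSV."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in results:
            probs = "\t".join(f"{p:.6f}" for p in r.probabilities)
            fh.write(f"{r.protein_id}\t{r.label.name}\t{probs}\n")


def read_predictions(path: str | Path) -> list:
    """Read back a predictions TSV written by :func:`write_predictions`."""
    from .cnn_model import CompartmentLabel, PredictionResult

    out = []
    for row in _read_tsv(path, PREDICTION_COLUMNS):
        probs = np.array(
            [float(row[c]) for c in ("p_outer", "p_inner", "p_ims", "p_matrix")]
        )
        out.append(
            PredictionResult(
                protein_id=row["protein_id"],
                probabilities=probs,
                label=CompartmentLabel[row["predicted_compartment"]],
            )
        )
    return out


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a truth-label table: protein_id, compartment (label name)."""
    return {
        row["protein_id"]: row["compartment"]
        for row in _read_tsv(path, ("protein_id", "compartment"))
    }


def write_labels(path: str | Path, labels: dict[str, str]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("protein_id\tcompartment\n")
        for pid, name in labels.items():
            fh.write(f"{pid}\t{name}\n")
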