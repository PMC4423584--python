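"""Paired-MSA construction for inter-protein covariation analysis.

Two interacting proteins (here called A and B; in the motivating system the
PhoU negative regulator and the PhoR histidine kinase) are paired per
species, joined with an artificial spacer of identical residues, aligned by
an *external* aligner (e.g. MAFFT), and re-ingested.  This module covers
everything around that external step: pairing the per-species FASTA
records, building the spacer-concatenated sequences, cleaning the returned
alignment by removing insert columns (columns where the designated
reference sequence carries a gap), and mapping alignment columns back to
per-protein residue numbers so downstream results can be reported as
"protein B residue 149 / protein A residue 147".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import ALPHABET, AMINO_ACIDS, GAP, GAP_CODE, decode_row, encode_sequence
from .exceptions import (
    DegenerateInputError,
    DuplicateIdError,
    EmptyInputError,
    FormatError,
    InconsistencyError,
    ParameterError,
)

logger = logging.getLogger(__name__)

SEGMENT_A = "A"
SEGMENT_B = "B"
SEGMENT_SPACER = "SPACER"

_ALLOWED_LETTERS = set(AMINO_ACIDS) | set("XBZUOJ") | {GAP, "."}


@dataclass(frozen=True)
class PairedRecord:
    """One species' pair of interacting-protein sequences.

    Gap characters are tolerated so that pre-aligned (e.g. synthetic)
    records can flow through the same type.
    """

    species_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if not self.species_id:
            raise FormatError("empty species identifier")
        for name, seq in (("A", self.seq_a), ("B", self.seq_b)):
            if not seq:
                raise FormatError(
                    f"record {self.species_id!r}: empty sequence for protein {name}"
                )
            bad = set(seq.upper()) - _ALLOWED_LETTERS
            if bad:
                raise FormatError(
                    f"record {self.species_id!r}: invalid residue letters "
                    f"{sorted(bad)} in protein {name}"
                )


@dataclass(frozen=True)
class ConcatenatedSet:
    """Spacer-joined A+B sequences, one per species, ready for alignment."""

    records: tuple[tuple[str, str], ...]  # (species_id, concatenated sequence)
    spacer_len: int
    spacer_char: str


@dataclass
class AlignmentMatrix:
    """An MSA over the 21-state alphabet, integer-encoded.

    ``matrix`` holds uint8 state codes (gap = 0), shape (M, L).
    ``reference_row`` designates the sequence (e.g. the E. coli pair) whose
    coordinates define insert columns and residue numbering.
    """

    matrix: np.ndarray
    row_ids: list[str]
    reference_row: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-D")
        if len(self.row_ids) != self.matrix.shape[0]:
            raise InconsistencyError(
                f"{len(self.row_ids)} row ids for {self.matrix.shape[0]} rows"
            )
        if not 0 <= self.reference_row < self.matrix.shape[0]:
            raise InconsistencyError(
                f"reference_row {self.reference_row} out of range"
            )

    @property
    def M(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def row_sequence(self, m: int) -> str:
        return decode_row(self.matrix[m])

    @classmethod
    def from_strings(
        cls,
        seqs: Sequence[str],
        row_ids: Sequence[str] | None = None,
        reference_row: int = 0,
    ) -> "AlignmentMatrix":
        if not seqs:
            raise EmptyInputError("no sequences")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if row_ids is None:
            row_ids = [f"seq{i}" for i in range(len(seqs))]
        mat = np.empty((len(seqs), len(seqs[0])), dtype=np.uint8)
        n_nonstandard = 0
        for i, s in enumerate(seqs):
            try:
                mat[i] = encode_sequence(s)
            except KeyError as exc:
                raise FormatError(
                    f"row {row_ids[i]!r}: invalid residue letter {exc.args[0]!r}"
                ) from None
            n_nonstandard += sum(1 for ch in s.upper() if ch in "XBZUOJ*")
        if n_nonstandard:
            logger.warning(
                "%d nonstandard residue letters mapped to the gap state",
                n_nonstandard,
            )
        return cls(mat, list(row_ids), reference_row)


@dataclass(frozen=True)
class PositionMap:
    """Map from alignment columns (1-based) to per-protein residue numbers.

    Built for an insert-removed alignment whose columns are, in order, the
    reference protein A residues, the artificial spacer, and the reference
    protein B residues.
    """

    len_a: int
    spacer_len: int
    len_b: int

    @property
    def L(self) -> int:
        return self.len_a + self.spacer_len + self.len_b

    def annotate(self, col: int) -> tuple[str, int | None]:
        """Return (segment, residue_number) for a 1-based column index."""
        if not 1 <= col <= self.L:
            raise InconsistencyError(f"column {col} outside 1..{self.L}")
        if col <= self.len_a:
            return SEGMENT_A, col
        if col <= self.len_a + self.spacer_len:
            return SEGMENT_SPACER, None
        return SEGMENT_B, col - self.len_a - self.spacer_len

    def column_of(self, segment: str, residue: int) -> int:
        """Inverse of :meth:`annotate` for non-spacer columns (1-based)."""
        if segment == SEGMENT_A:
            if not 1 <= residue <= self.len_a:
                raise InconsistencyError(f"A residue {residue} outside 1..{self.len_a}")
            return residue
        if segment == SEGMENT_B:
            if not 1 <= residue <= self.len_b:
                raise InconsistencyError(f"B residue {residue} outside 1..{self.len_b}")
            return self.len_a + self.spacer_len + residue
        raise InconsistencyError(f"unknown segment {segment!r}")

    def spacer_columns(self) -> list[int]:
        """1-based indices of the spacer columns."""
        return list(range(self.len_a + 1, self.len_a + self.spacer_len + 1))


# ---------------------------------------------------------------------------
# FASTA I/O and pairing
# ---------------------------------------------------------------------------

def _read_fasta_records(path) -> list[tuple[str, str]]:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    stripped = text.lstrip()
    if not stripped.startswith(">"):
        raise FormatError(f"{path} is not FASTA (no leading '>' record header)")
    try:
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
    except ValueError as exc:
        raise FormatError(f"malformed FASTA in {path}: {exc}") from exc
    return records


def read_paired_fasta(path_a, path_b) -> list[PairedRecord]:
    """Pair per-species sequences from two FASTA files by identical id.

    Only identifiers present in *both* files yield a record; output order
    follows ``path_a``.  Identifiers found in one file only are reported in
    the log, never silently matched to anything else.
    """
    recs_a = _read_fasta_records(path_a)
    recs_b = _read_fasta_records(path_b)
    by_id = {}
    for name, recs in (("A", recs_a), ("B", recs_b)):
        seen = set()
        for rid, _ in recs:
            if rid in seen:
                raise DuplicateIdError(f"duplicate identifier {rid!r} in file {name}")
            seen.add(rid)
        by_id[name] = dict(recs)
    shared = [rid for rid, _ in recs_a if rid in by_id["B"]]
    if not shared:
        raise EmptyInputError("no identifiers shared between the two FASTA files")
    only_a = set(by_id["A"]) - set(by_id["B"])
    only_b = set(by_id["B"]) - set(by_id["A"])
    if only_a or only_b:
        logger.warning(
            "unpaired identifiers dropped: %d only in A, %d only in B",
            len(only_a), len(only_b),
        )
    return [PairedRecord(rid, by_id["A"][rid], by_id["B"][rid]) for rid in shared]


def concatenate_with_spacer(
    records: Sequence[PairedRecord],
    spacer_len: int = 20,
    spacer_char: str = "A",
) -> ConcatenatedSet:
    """Join each pair as seq_a + spacer + seq_b (A first, then B).

    The spacer (by default twenty alanines) marks the protein boundary in
    the downstream alignment.
    """
    if not records:
        raise EmptyInputError("no paired records to concatenate")
    if spacer_len < 0:
        raise ParameterError(f"spacer_len must be >= 0, got {spacer_len}")
    if len(spacer_char) != 1 or spacer_char.upper() not in AMINO_ACIDS:
        raise ParameterError(f"spacer_char must be one amino-acid letter, got {spacer_char!r}")
    spacer = spacer_char * spacer_len
    joined = tuple(
        (r.species_id, r.seq_a + spacer + r.seq_b) for r in records
    )
    return ConcatenatedSet(joined, spacer_len, spacer_char)


def split_concatenated(seq: str, len_a: int, spacer_len: int) -> tuple[str, str]:
    """Recover (seq_a, seq_b) from a spacer-concatenated sequence."""
    if len(seq) < len_a + spacer_len:
        raise InconsistencyError(
            f"sequence length {len(seq)} < len_a + spacer_len = {len_a + spacer_len}"
        )
    return seq[:len_a], seq[len_a + spacer_len:]


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_alignment(path, reference_id: str | None = None) -> AlignmentMatrix:
    """Read an aligned FASTA into an :class:`AlignmentMatrix`.

    ``.`` gaps are normalised to ``-``; the reference row defaults to the
    first record unless ``reference_id`` selects another.
    """
    records = _read_fasta_records(path)
    if not records:
        raise EmptyInputError(f"no records in {path}")
    ids = [rid for rid, _ in records]
    seqs = [seq for _, seq in records]
    ref = 0
    if reference_id is not None:
        try:
            ref = ids.index(reference_id)
        except ValueError:
            raise InconsistencyError(
                f"reference id {reference_id!r} not present in {path}"
            ) from None
    return AlignmentMatrix.from_strings(seqs, ids, reference_row=ref)


# ---------------------------------------------------------------------------
# Alignment cleaning and coordinate mapping
# ---------------------------------------------------------------------------

def remove_insert_columns(aln: AlignmentMatrix) -> AlignmentMatrix:
    """Drop every column where the reference row carries a gap.

    After removal, L equals the ungapped length of the reference sequence
    and column k holds the k-th reference residue.  Idempotent.
    """
    ref = aln.matrix[aln.reference_row]
    keep = ref != GAP_CODE
    if not keep.any():
        raise DegenerateInputError("reference row is entirely gaps")
    return AlignmentMatrix(
        aln.matrix[:, keep].copy(), list(aln.row_ids), aln.reference_row
    )


def build_position_map(aln, len_a: int, spacer_len: int) -> PositionMap:
    """Tag columns of an insert-removed alignment as A / SPACER / B.

    ``aln`` may be an :class:`AlignmentMatrix` or the integer column count.
    """
    L = aln.L if hasattr(aln, "L") else int(aln)
    if len_a < 1 or spacer_len < 0:
        raise ParameterError("len_a must be >= 1 and spacer_len >= 0")
    if L < len_a + spacer_len + 1:
        raise InconsistencyError(
            f"alignment has {L} columns, fewer than len_a + spacer_len + 1 = "
            f"{len_a + spacer_len + 1}"
        )
    return PositionMap(len_a=len_a, spacer_len=spacer_len, len_b=L - len_a - spacer_len)


def alignment_from_concatenated(
    cset: ConcatenatedSet, reference_row: int = 0
) -> AlignmentMatrix:
    """Treat equal-length concatenated sequences as an alignment.

    Valid when the inputs are pre-aligned (synthetic data, or re-ingestion
    of an externally aligned file written back per species).
    """
    seqs = [seq for _, seq in cset.records]
    ids = [rid for rid, _ in cset.records]
    return AlignmentMatrix.from_strings(seqs, ids, reference_row=reference_row)
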