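"""Sequence-conservation track: MSA ingestion and per-column Shannon entropy.

Conservation is measured as Shannon entropy of each alignment column,

    H = -sum_a p(a) * log2 p(a)

over the amino acids observed in the column.  Gaps are excluded and the
probabilities renormalized over non-gap characters, so the maximum possible
entropy is log2(20) for the standard alphabet; an all-gap column yields a
missing value (NaN).  Entropy is reported per *query* position: each query
residue inherits the entropy of the alignment column it sits in, and columns
where the query is gapped map to no query position.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .core import GAP_CHARACTERS, QueryProtein

logger = logging.getLogger(__name__)

#: Maximum entropy in bits over the 20 standard amino acids.
MAX_ENTROPY_BITS = float(np.log2(20.0))

#: Default homolog panel: seven vertebrate species.
DEFAULT_SPECIES_PANEL = (
    "Bos taurus",
    "Canis lupus",
    "Gallus gallus",
    "Homo sapiens",
    "Mus musculus",
    "Takifugu rubripes",
    "Xenopus tropicalis",
)

#: Standard 12 columns of tabular BLAST output (outfmt 6).
BLAST_TABULAR_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class AlignmentError(ValueError):
    """Raised for malformed multiple sequence alignments."""


@dataclass
class MultipleAlignment:
    """An MSA of the query with its homologs.

    ``records`` are (label, aligned sequence) pairs; gap character is "-".
    """

    records: list[tuple[str, str]]
    query_index: int

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)} differ"
            )
        if not 0 <= self.query_index < len(self.records):
            raise AlignmentError("query_index outside record range")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def query_aligned(self) -> str:
        return self.records[self.query_index][1]

    def degapped_query(self) -> str:
        return "".join(c for c in self.query_aligned if c not in GAP_CHARACTERS)

    def column(self, j: int) -> list[str]:
        """Characters of 0-based column j, one per record."""
        return [seq[j] for _, seq in self.records]

    def query_column_map(self) -> np.ndarray:
        """0-based alignment column index for each query position (1..n)."""
        cols = [
            j for j, c in enumerate(self.query_aligned) if c not in GAP_CHARACTERS
        ]
        return np.asarray(cols, dtype=int)


def read_alignment(path, query_id: str, query: QueryProtein | None = None) -> MultipleAlignment:
    """Read an aligned FASTA file and locate the query record.

    If ``query`` is given, the degapped query row must equal its sequence
    exactly; the error message reports the first differing position.
    """
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentError(f"cannot read alignment {path}: {exc}") from exc
    records = [(rec.id, str(rec.seq).upper()) for rec in aln]
    matches = [i for i, (name, _) in enumerate(records) if name == query_id]
    if not matches:
        raise AlignmentError(
            f"query id {query_id!r} not found among {[n for n, _ in records]}"
        )
    msa = MultipleAlignment(records=records, query_index=matches[0])
    if query is not None:
        degapped = msa.degapped_query()
        if degapped != query.sequence:
            for pos, (a, b) in enumerate(zip(degapped, query.sequence), start=1):
                if a != b:
                    raise AlignmentError(
                        f"degapped alignment query differs from query sequence "
                        f"at position {pos}: {a!r} != {b!r}"
                    )
            raise AlignmentError(
                f"degapped alignment query length {len(degapped)} != "
                f"query length {query.length}"
            )
    return msa


def column_entropy(column: Sequence[str]) -> float:
    """Shannon entropy (bits) of one alignment column.

    Gap characters are excluded and frequencies renormalized over the
    remaining residues; an all-gap column returns NaN.  The convention
    0*log2(0) = 0 applies.
    """
    if len(column) == 0:
        raise AlignmentError("empty column")
    residues = [c for c in column if c not in GAP_CHARACTERS]
    if not residues:
        return float("nan")
    counts = np.array(list(Counter(residues).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum()) + 0.0  # +0.0 avoids -0.0


def entropy_track(msa: MultipleAlignment) -> np.ndarray:
    """Per-query-position Shannon entropy H_i in bits.

    The query is included in the column counts (it is a member of the MSA).
    """
    col_map = msa.query_column_map()
    return np.array([column_entropy(msa.column(j)) for j in col_map])


def select_homologs(
    blast_tables: Mapping[str, "pd.DataFrame | str"],
) -> list[tuple[str, str]]:
    """Pick one best hit per species from tabular BLAST results.

    Selection is by lowest E-value; ties broken by higher bit score, then
    lexicographically smallest subject accession (deterministic).  Species
    with zero hits are omitted with a warning.

    ``blast_tables`` maps species label to either a DataFrame with at least
    ``sseqid``, ``evalue``, ``bitscore`` columns, or a path to a standard
    12-column outfmt-6 file.
    """
    chosen: list[tuple[str, str]] = []
    for species, table in blast_tables.items():
        if not isinstance(table, pd.DataFrame):
            table = read_blast_tabular(table)
        if table.empty:
            warnings.warn(f"no BLAST hits for {species}; species omitted")
            logger.warning("no BLAST hits for %s; species omitted", species)
            continue
        best = table.sort_values(
            ["evalue", "bitscore", "sseqid"], ascending=[True, False, True]
        ).iloc[0]
        chosen.append((species, str(best["sseqid"])))
    return chosen


def read_blast_tabular(path) -> pd.DataFrame:
    """Read a standard 12-column tabular (outfmt 6) BLAST hit file."""
    try:
        return pd.read_csv(
            str(path), sep="\t", header=None, names=BLAST_TABULAR_COLUMNS, comment="#"
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(BLAST_TABULAR_COLUMNS))
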