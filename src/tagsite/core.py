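"""Shared domain types and the residue-numbering contract.

All per-residue vectors in this package are aligned to a :class:`QueryProtein`
and indexed 1-based, following UniProt convention.  A reported insertion site
at position *i* means "tag inserted immediately after residue *i*"; writers
state this convention in their headers.  Missing data is always an explicit
``NaN`` sentinel, never a silent zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids plus X (unknown residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: Characters treated as alignment gaps.
GAP_CHARACTERS = frozenset("-.")

#: Track names recognised by :class:`FeatureTrack`.
TRACK_NAMES = ("entropy", "secondary_structure", "rsa", "dbr_complement")


class SequenceError(ValueError):
    """Raised for malformed or illegal amino-acid sequences."""


@dataclass(frozen=True)
class QueryProtein:
    """The query sequence; anchor for all feature tracks.

    Positions are 1-based: residue ``i`` is ``sequence[i - 1]``.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError("empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in EXTENDED_ALPHABET:
                raise SequenceError(
                    f"illegal character {ch!r} at position {pos} "
                    f"(allowed: {AMINO_ACIDS} and X)"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """One-letter code at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]


def validate_sequence(raw: str, id: str = "query") -> QueryProtein:
    """Uppercase, strip and validate a raw amino-acid string.

    Raises :class:`SequenceError` naming the first offending position if a
    character outside the extended alphabet (20 standard letters plus X)
    is present, or if the input is empty after whitespace stripping.
    """
    cleaned = "".join(raw.split()).upper()
    if not cleaned:
        raise SequenceError("empty sequence input")
    return QueryProtein(id=id, sequence=cleaned)


@dataclass
class FeatureTrack:
    """A named per-residue score vector aligned to the query.

    ``values[i - 1]`` is the score at 1-based position ``i``; ``NaN`` marks
    missing data.  When ``normalized`` is set, every non-missing value must
    lie in [0, 1].
    """

    name: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.name not in TRACK_NAMES:
            raise ValueError(f"unknown track name {self.name!r}; expected one of {TRACK_NAMES}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be a 1-D vector")
        if self.normalized:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError(
                    f"normalized track {self.name!r} has values outside [0, 1]"
                )

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Weights:
    """Weights of the weighted sum score, in track order: entropy,
    secondary structure, RSA, DBR complement.

    Defaults follow the scoring function's proof-of-concept setting:
    entropy weighted 1.5, everything else 1.
    """

    entropy: float = 1.5
    secondary_structure: float = 1.0
    rsa: float = 1.0
    dbr_complement: float = 1.0

    def __post_init__(self) -> None:
        for name in ("entropy", "secondary_structure", "rsa", "dbr_complement"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name!r} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.entropy, self.secondary_structure, self.rsa, self.dbr_complement]
        )


@dataclass
class ScoreProfile:
    """Normalized feature tracks plus per-position sum and min scores.

    ``sum_score[i-1]`` is the weighted feature sum at position ``i``;
    ``min_score[i-1]`` the unweighted minimum across the four features;
    ``smoothed_min_score`` its centered moving average (window shrinks at
    the sequence edges).
    """

    query: QueryProtein
    tracks: dict[str, FeatureTrack]
    sum_score: np.ndarray
    min_score: np.ndarray
    smoothed_min_score: np.ndarray
    window: int = 7
    weights: Weights = field(default_factory=Weights)

    def __post_init__(self) -> None:
        n = self.query.length
        if set(self.tracks) != set(TRACK_NAMES):
            raise ValueError(f"profile requires exactly the tracks {TRACK_NAMES}")
        for track in self.tracks.values():
            if len(track) != n:
                raise ValueError(
                    f"track {track.name!r} has {len(track)} values for a "
                    f"{n}-residue query"
                )
            if not track.normalized:
                raise ValueError(f"track {track.name!r} is not normalized")
        for vec_name in ("sum_score", "min_score", "smoothed_min_score"):
            vec = np.asarray(getattr(self, vec_name), dtype=float)
            if vec.size != n:
                raise ValueError(f"{vec_name} length {vec.size} != query length {n}")
            setattr(self, vec_name, vec)
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")

    def feature_matrix(self) -> np.ndarray:
        """(n, 4) matrix of normalized feature values in canonical order."""
        return np.column_stack([self.tracks[name].values for name in TRACK_NAMES])

    # Lossless text serialization (17 significant digits round-trips doubles).
    def to_tsv(self) -> str:
        buf = io.StringIO()
        cols = list(TRACK_NAMES) + ["sum_score", "min_score", "smoothed_min_score"]
        buf.write("# query_id=%s window=%d\n" % (self.query.id, self.window))
        buf.write(
            "# weights=%s\n"
            % ",".join("%.17g" % w for w in self.weights.as_array())
        )
        buf.write("position\tresidue\t" + "\t".join(cols) + "\n")
        mat = np.column_stack(
            [self.feature_matrix(), self.sum_score, self.min_score, self.smoothed_min_score]
        )
        for i in range(self.query.length):
            row = "\t".join("%.17g" % v for v in mat[i])
            buf.write(f"{i + 1}\t{self.query.sequence[i]}\t{row}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "ScoreProfile":
        lines = text.splitlines()
        header = dict(
            kv.split("=", 1) for kv in lines[0].lstrip("# ").split() if "=" in kv
        )
        weights = Weights(*(float(x) for x in lines[1].split("=", 1)[1].split(",")))
        body = lines[3:]
        residues = []
        rows = []
        for line in body:
            parts = line.split("\t")
            residues.append(parts[1])
            rows.append([float(x) for x in parts[2:]])
        mat = np.array(rows)
        query = QueryProtein(id=header["query_id"], sequence="".join(residues))
        tracks = {
            name: FeatureTrack(name, mat[:, j], normalized=True)
            for j, name in enumerate(TRACK_NAMES)
        }
        return cls(
            query=query,
            tracks=tracks,
            sum_score=mat[:, 4],
            min_score=mat[:, 5],
            smoothed_min_score=mat[:, 6],
            window=int(header["window"]),
            weights=weights,
        )


@dataclass(frozen=True)
class SitePrediction:
    """A ranked candidate insertion position.

    ``score`` is the smoothed min score; ``feature_values`` the four
    normalized (unsmoothed) feature values at the position, in canonical
    track order.
    """

    position: int
    residue: str
    score: float
    rank: int
    feature_values: tuple[float, float, float, float]


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_query_fasta(path, id: str | None = None) -> QueryProtein:
    """Read the first record of a FASTA file as the query protein."""
    records = read_fasta(path)
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    rec_id, seq = records[0]
    return validate_sequence(seq, id=id or rec_id)


def write_fasta(path, records: Sequence[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def iter_positions(query: QueryProtein) -> Iterator[tuple[int, str]]:
    """Yield (1-based position, residue letter)."""
    for i, ch in enumerate(query.sequence, start=1):
        yield i, ch
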