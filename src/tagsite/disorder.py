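"""Disordered-binding-region track.

The ANCHOR2 score BR_i is the probability that residue i participates in a
protein-binding interaction while in a disordered segment.  High-BR
positions are poor tagging sites, so the feature entering the scoring
function is the complement 1 - BR.  The predictor itself is consumed as an
input track (IUPred2A text output), never reimplemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import FeatureTrack, QueryProtein


class DisorderError(ValueError):
    """Raised for malformed disordered-binding-region input."""


@dataclass
class AnchorTrack:
    """Per-residue disordered-binding probabilities BR in [0, 1]."""

    br: np.ndarray

    def __post_init__(self) -> None:
        self.br = np.asarray(self.br, dtype=float)
        if self.br.min() < 0 or self.br.max() > 1:
            raise DisorderError("BR values outside [0, 1]")


def parse_iupred2a(path, query: QueryProtein | None = None) -> AnchorTrack:
    """Parse IUPred2A text output into an :class:`AnchorTrack`.

    Two dialects are auto-detected by column count: the 4-column "long"
    output (position, residue, IUPred score, ANCHOR score) and a minimal
    2-column dialect (position, ANCHOR score).  Comment lines start with
    "#".  Positions must be contiguous from 1; residue letters (when
    present) are cross-checked against the query.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 4:
            pos, residue, _iupred, anchor = parts
        elif len(parts) == 2:
            pos, anchor = parts
            residue = None
        else:
            raise DisorderError(
                f"line {lineno}: expected 2 or 4 columns, got {len(parts)}"
            )
        try:
            pos = int(pos)
            anchor = float(anchor)
        except ValueError as exc:
            raise DisorderError(f"line {lineno}: {exc}") from exc
        if not 0 <= anchor <= 1:
            raise DisorderError(
                f"line {lineno}: ANCHOR score {anchor} outside [0, 1]"
            )
        rows.append((pos, residue, anchor))

    if not rows:
        raise DisorderError(f"no data lines in {path}")
    positions = [pos for pos, _, _ in rows]
    if positions != list(range(1, len(rows) + 1)):
        gap = next(
            (i + 1 for i, p in enumerate(positions) if p != i + 1), len(rows)
        )
        raise DisorderError(
            f"non-contiguous residue numbering near entry {gap} "
            f"(expected {gap}, found {positions[gap - 1]})"
        )
    if query is not None:
        if len(rows) != query.length:
            raise DisorderError(
                f"{len(rows)} track positions for a {query.length}-residue query"
            )
        for pos, residue, _ in rows:
            expected = query.sequence[pos - 1]
            if residue is not None and residue != expected and "X" not in (residue, expected):
                raise DisorderError(
                    f"residue mismatch at position {pos}: track has "
                    f"{residue!r}, query has {expected!r}"
                )
    return AnchorTrack(br=np.array([anchor for _, _, anchor in rows]))


def dbr_complement_track(track: AnchorTrack) -> FeatureTrack:
    """Feature value 1 - BR_i (already on the [0, 1] scale)."""
    return FeatureTrack("dbr_complement", 1.0 - track.br, normalized=True)
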