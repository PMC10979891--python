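"""Core scoring: feature normalization, sum and min scores, smoothing,
and insertion-site selection.

Four normalized per-residue features enter the score: sequence variability
(Shannon entropy over the MSA column, divided by log2(20) = 4.32), the
secondary-structure bin, relative solvent accessibility, and the complement
of the disordered-binding probability.  Two per-position summaries are
computed:

* the weighted sum score
  ``S_i = w1*(H_i/4.32) + w2*SS_i + w3*RSA_i + w4*(1-BR_i)``
  (default weights 1.5, 1, 1, 1), reported for inspection;
* the tagging score ``E_i = min(H_i/4.32, SS_i, RSA_i, 1-BR_i)`` —
  unweighted by construction — which drives ranking: a high minimum means
  every feature simultaneously favors insertion at that position.

E_i is smoothed with a centered moving average (default window 7; the
window shrinks at the sequence edges) and the highest smoothed values,
separated into distinct peaks, are reported as candidate insertion sites.
"""

from __future__ import annotations

import numpy as np

from .conservation import MAX_ENTROPY_BITS
from .core import (
    TRACK_NAMES,
    FeatureTrack,
    QueryProtein,
    ScoreProfile,
    SitePrediction,
    Weights,
)


def normalize_entropy(entropy_bits: np.ndarray) -> FeatureTrack:
    """Divide per-position entropy (bits) by log2(20), the maximum possible
    entropy over the 20 amino acids."""
    h = np.asarray(entropy_bits, dtype=float)
    return FeatureTrack("entropy", h / MAX_ENTROPY_BITS, normalized=True)


def _stack(tracks: dict[str, FeatureTrack]) -> np.ndarray:
    if set(tracks) != set(TRACK_NAMES):
        raise ValueError(f"expected exactly the tracks {TRACK_NAMES}")
    lengths = {len(t) for t in tracks.values()}
    if len(lengths) != 1:
        raise ValueError(f"track lengths differ: {sorted(lengths)}")
    for t in tracks.values():
        if not t.normalized:
            raise ValueError(f"track {t.name!r} is not normalized")
    return np.column_stack([tracks[name].values for name in TRACK_NAMES])


def sum_score(tracks: dict[str, FeatureTrack], weights: Weights | None = None) -> np.ndarray:
    """Weighted sum of the four normalized features per position.

    Positions where any feature is missing get a missing (NaN) score.
    """
    weights = weights or Weights()
    mat = _stack(tracks)
    return mat @ weights.as_array()


def min_score(tracks: dict[str, FeatureTrack]) -> np.ndarray:
    """Per-position minimum of the four normalized features (unweighted).

    Missing if any feature is missing at that position.
    """
    mat = _stack(tracks)
    out = np.min(mat, axis=1)
    out[np.isnan(mat).any(axis=1)] = np.nan
    return out


def smooth(values: np.ndarray, window: int = 7) -> np.ndarray:
    """Centered moving average over ``window`` positions.

    The window is odd; at the sequence edges it shrinks to the available
    positions (no padding).  Missing values are excluded from each local
    mean; a window containing only missing values yields missing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    values = np.asarray(values, dtype=float)
    n = values.size
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        chunk = values[lo:hi]
        good = np.isfinite(chunk)
        if good.any():
            out[i] = chunk[good].mean()
    return out


def rank_sites(
    profile: ScoreProfile, top_k: int = 5, min_separation: int = 8
) -> list[SitePrediction]:
    """Select the highest-scoring candidate insertion positions.

    Positions are ranked by smoothed min score, descending; ties break
    toward the lower (more N-terminal) position.  After a site is selected,
    positions within ``min_separation`` residues of it are suppressed so the
    reported sites are distinct peaks.  Positions with a missing score are
    never selected.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    scores = profile.smoothed_min_score
    available = np.isfinite(scores)
    sites: list[SitePrediction] = []
    mat = profile.feature_matrix()
    while len(sites) < top_k and available.any():
        candidates = np.where(available)[0]
        best = candidates[np.argmax(scores[candidates])]  # argmax: first max wins ties
        position = int(best) + 1
        sites.append(
            SitePrediction(
                position=position,
                residue=profile.query.sequence[best],
                score=float(scores[best]),
                rank=len(sites) + 1,
                feature_values=tuple(float(v) for v in mat[best]),
            )
        )
        lo = max(0, best - min_separation)
        hi = min(len(scores), best + min_separation + 1)
        available[lo:hi] = False
    return sites


def build_profile(
    query: QueryProtein,
    entropy: FeatureTrack,
    secondary_structure: FeatureTrack,
    rsa: FeatureTrack,
    dbr_complement: FeatureTrack,
    weights: Weights | None = None,
    window: int = 7,
    smooth_features_first: bool = False,
) -> ScoreProfile:
    """Assemble the four normalized tracks into a :class:`ScoreProfile`.

    By default the sliding-window average is applied to the per-position
    minimum track.  ``smooth_features_first`` instead averages each feature
    before taking the minimum (an alternative reading of window-averaging;
    off by default).

    Positions where the query residue is X are excluded from ranking
    (their min score is set missing).
    """
    weights = weights or Weights()
    tracks = {
        "entropy": entropy,
        "secondary_structure": secondary_structure,
        "rsa": rsa,
        "dbr_complement": dbr_complement,
    }
    if smooth_features_first:
        tracks = {
            name: FeatureTrack(name, smooth(t.values, window), normalized=True)
            for name, t in tracks.items()
        }
    s = sum_score(tracks, weights)
    e = min_score(tracks)
    unknown = np.array([aa == "X" for aa in query.sequence])
    e[unknown] = np.nan
    s[unknown] = np.nan
    return ScoreProfile(
        query=query,
        tracks=tracks,
        sum_score=s,
        min_score=e,
        smoothed_min_score=smooth(e, window),
        window=window,
        weights=weights,
    )
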