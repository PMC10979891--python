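"""Report writers: per-residue table, ranked sites, BED intervals, manifest.

The per-residue and site tables are 1-based and say so in their headers;
the BED output uses the standard 0-based half-open convention on protein
coordinates.  A site at position i means "tag inserted immediately after
residue i".
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SitePrediction, TRACK_NAMES
from .pipeline import RunResult

RESIDUE_COLUMNS = [
    "position", "residue", "entropy_bits", "entropy_norm", "ss_code",
    "ss_score", "sasa", "rsa", "br", "dbr_complement",
    "sum_score", "min_score", "smoothed_min_score",
]

_CONVENTION = (
    "# positions are 1-based; a site at position i means the tag is "
    "inserted immediately after residue i\n"
)


def residue_table(result: RunResult) -> pd.DataFrame:
    """One row per query residue with raw and normalized feature values."""
    profile = result.profile
    n = profile.query.length
    tracks = profile.tracks
    return pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "residue": list(profile.query.sequence),
            "entropy_bits": result.entropy_bits,
            "entropy_norm": tracks["entropy"].values,
            "ss_code": result.ss_codes,
            "ss_score": tracks["secondary_structure"].values,
            "sasa": result.sasa,
            "rsa": tracks["rsa"].values,
            "br": result.br,
            "dbr_complement": tracks["dbr_complement"].values,
            "sum_score": profile.sum_score,
            "min_score": profile.min_score,
            "smoothed_min_score": profile.smoothed_min_score,
        }
    )


def write_residue_table(result: RunResult, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_CONVENTION)
        residue_table(result).to_csv(
            fh, sep="\t", index=False, float_format="%.6f"
        )
    return path


def sites_table(sites: Sequence[SitePrediction]) -> pd.DataFrame:
    rows = []
    for site in sites:
        row = {
            "rank": site.rank,
            "position": site.position,
            "residue": site.residue,
            "score": site.score,
        }
        row.update(dict(zip(TRACK_NAMES, site.feature_values)))
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["rank", "position", "residue", "score", *TRACK_NAMES]
    )


def write_sites_table(sites: Sequence[SitePrediction], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_CONVENTION)
        sites_table(sites).to_csv(fh, sep="\t", index=False, float_format="%.6f")
    return path


def write_bed(sites: Sequence[SitePrediction], query_id: str, path) -> Path:
    """BED-style intervals on protein coordinates.

    0-based half-open: a site at 1-based position p becomes [p-1, p).
    The BED score is round(1000 * smoothed min score).
    """
    path = Path(path)
    lines = [
        "# protein-coordinate BED: 0-based half-open intervals; "
        "score = round(1000 * smoothed min score)\n"
    ]
    for site in sites:
        lines.append(
            f"{query_id}\t{site.position - 1}\t{site.position}\t"
            f"rank{site.rank}\t{round(1000 * site.score)}\n"
        )
    path.write_text("".join(lines))
    return path


def write_manifest(path, inputs: dict, config: dict) -> Path:
    """Flat key:value run manifest with input checksums and versions."""
    import tagsite

    path = Path(path)
    lines = [f"tagsite_version: {tagsite.__version__}\n"]
    for key, value in config.items():
        lines.append(f"config.{key}: {value}\n")
    for name, file_path in inputs.items():
        if file_path is None:
            continue
        file_path = Path(file_path)
        digest = hashlib.sha256(file_path.read_bytes()).hexdigest()
        lines.append(f"input.{name}: {file_path}\n")
        lines.append(f"input.{name}.sha256: {digest}\n")
    path.write_text("".join(lines))
    return path
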