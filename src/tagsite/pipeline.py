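"""Offline end-to-end pipeline: files in, ranked insertion sites out.

This is the file-based path: with a query FASTA, an aligned-FASTA MSA, a
DSSP output file (or a structure file as fallback) and an IUPred2A track
all supplied locally, the run touches no network and no external
executables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import conservation, disorder, scoring, structure
from .core import QueryProtein, ScoreProfile, SitePrediction, Weights, read_query_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """A completed scoring run: the profile, ranked sites, and the raw
    (pre-normalization) inputs needed for reporting."""

    profile: ScoreProfile
    sites: list[SitePrediction]
    entropy_bits: np.ndarray
    ss_codes: list[str]
    sasa: np.ndarray
    br: np.ndarray
    ss_source: str = "dssp"


def run_pipeline(
    query_fasta,
    msa_fasta,
    anchor_file,
    dssp_file=None,
    structure_file=None,
    query_id: str | None = None,
    chain: str | None = None,
    weights: Weights | None = None,
    window: int = 7,
    top_k: int = 5,
    min_separation: int = 8,
    smooth_features_first: bool = False,
) -> RunResult:
    """Score every position of the query and rank candidate insertion sites.

    Exactly one of ``dssp_file`` (reference path) or ``structure_file``
    (internal fallback: Shrake-Rupley SASA plus geometric secondary
    structure) must provide the structural features; if both are given the
    DSSP file takes precedence.
    """
    if dssp_file is None and structure_file is None:
        raise ValueError(
            "structural input missing: supply a DSSP output file or a "
            "PDB/mmCIF structure file"
        )
    query = read_query_fasta(query_fasta, id=query_id)
    logger.info("query %s: %d residues", query.id, query.length)

    msa = conservation.read_alignment(msa_fasta, query_id=query.id, query=query)
    entropy_bits = conservation.entropy_track(msa)
    entropy = scoring.normalize_entropy(entropy_bits)

    if dssp_file is not None:
        records = structure.parse_dssp(dssp_file)
        ss = structure.ss_track(records, query)
        sasa = structure.sasa_from_dssp(records, query)
        ss_codes = _codes_from_records(records, query)
        ss_source = "dssp"
    else:
        model = structure.parse_structure(structure_file, chain=chain)
        mapping = structure.map_structure_to_query(model, query)
        model_sasa = structure.shrake_rupley_sasa(model)
        model_codes = structure.ss_from_structure(model)
        sasa = np.full(query.length, np.nan)
        ss_codes = ["-"] * query.length
        present = mapping >= 0
        sasa[present] = model_sasa[mapping[present]]
        for qi in np.where(present)[0]:
            ss_codes[qi] = model_codes[mapping[qi]]
        ss = structure.ss_track(
            [
                structure.DsspRecord(int(qi) + 1, query.sequence[qi], ss_codes[qi], 0.0)
                for qi in np.where(present)[0]
            ],
            query,
        )
        ss_source = "internal-fallback (non-reference)"
        logger.info("no DSSP file: using internal SASA/SS fallback")
    rsa = structure.rsa_track(sasa, query)

    anchor = disorder.parse_iupred2a(anchor_file, query=query)
    dbr = disorder.dbr_complement_track(anchor)

    profile = scoring.build_profile(
        query,
        entropy,
        ss,
        rsa,
        dbr,
        weights=weights,
        window=window,
        smooth_features_first=smooth_features_first,
    )
    sites = scoring.rank_sites(profile, top_k=top_k, min_separation=min_separation)
    return RunResult(
        profile=profile,
        sites=sites,
        entropy_bits=entropy_bits,
        ss_codes=ss_codes,
        sasa=sasa,
        br=anchor.br,
        ss_source=ss_source,
    )


def _codes_from_records(records, query: QueryProtein) -> list[str]:
    codes = ["-"] * query.length
    for rec in records:
        if 1 <= rec.position <= query.length:
            codes[rec.position - 1] = rec.ss_code
    return codes
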