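"""Secondary-structure and solvent-accessibility tracks from a 3-D structure.

Two per-residue features come from structure:

* secondary structure, binned by expected sensitivity to an inserted tag —
  coil (C) scores 1, defined structure (G/H/I/E: helices and strands) scores
  0, everything else (turns, bends, bridges, polyproline II) 0.5;
* relative solvent accessibility, RSA = SASA / SA_max, the residue's solvent
  accessible surface area normalized by its theoretical maximum and clamped
  to [0, 1].

The reference path parses output of the DSSP program (which reports both the
secondary-structure code and the SASA estimate in its ACC field).  When no
DSSP file is available an internal fallback computes SASA with a
deterministic Shrake-Rupley method and assigns secondary structure with the
P-SEA geometric approximation; fallback output is labeled non-reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from Bio.Align import PairwiseAligner
from Bio.PDB.DSSP import make_dssp_dict
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _pdbx_get_structure

from .core import FeatureTrack, QueryProtein

logger = logging.getLogger(__name__)

#: Full DSSP secondary-structure alphabet (blank and "-" canonicalize to C).
DSSP_CODES = frozenset("HGIEBTSPC")

#: Secondary-structure bin scores: coil tolerant, defined structure fragile.
SS_SCORES = {
    "C": 1.0,
    "G": 0.0, "H": 0.0, "I": 0.0, "E": 0.0,
    "B": 0.5, "T": 0.5, "S": 0.5, "P": 0.5,
}


class StructureError(ValueError):
    """Raised for unreadable or inconsistent structural input."""


@dataclass
class DsspRecord:
    """One residue line of DSSP output: position, residue, SS code, SASA."""

    position: int
    amino_acid: str
    ss_code: str
    sasa: float

    def __post_init__(self) -> None:
        self.ss_code = canonicalize_ss_code(self.ss_code)
        if self.sasa < 0:
            raise StructureError(f"negative SASA at position {self.position}")


def canonicalize_ss_code(code: str) -> str:
    """Map blank / '-' to coil 'C'; reject codes outside the DSSP alphabet."""
    code = (code or " ").strip() or "C"
    if code == "-":
        code = "C"
    if code not in DSSP_CODES:
        raise StructureError(f"unknown DSSP secondary-structure code {code!r}")
    return code


@dataclass
class StructureModel:
    """Parsed atomic coordinates with per-residue metadata.

    ``plddt`` holds per-residue model confidence (0-100) when the source is
    a predicted model that stores it in the B-factor column.
    """

    atoms: "struc.AtomArray"
    sequence: str
    res_ids: np.ndarray
    chain_id: str
    plddt: np.ndarray | None = None
    source: str = "unknown"

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def parse_structure(
    path, chain: str | None = None, source: str | None = None
) -> StructureModel:
    """Parse a PDB or mmCIF file into a single-chain :class:`StructureModel`.

    For predicted models the B-factor column is interpreted as pLDDT
    (detected when all values lie in [0, 100] and the source hints at a
    predicted model, or when ``source='alphafold'`` is forced).
    A multi-chain file requires an explicit ``chain`` selector.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".cif", ".mmcif", ".pdbx"}:
            cif = CIFFile.read(str(path))
            atoms = _pdbx_get_structure(cif, model=1, extra_fields=["b_factor"])
        else:
            pdb = PDBFile.read(str(path))
            atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc

    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise StructureError(f"no protein residues in {path}")
    if not np.all(np.isfinite(atoms.coord)):
        raise StructureError(f"non-finite coordinates in {path}")

    chains = sorted(set(atoms.chain_id))
    if chain is None:
        if len(chains) > 1:
            raise StructureError(
                f"{path} has chains {chains}; pass an explicit chain selector"
            )
        chain = chains[0]
    elif chain not in chains:
        raise StructureError(f"chain {chain!r} not in {chains}")
    atoms = atoms[atoms.chain_id == chain]

    res_ids, res_names = struc.get_residues(atoms)
    sequence = "".join(_three_to_one(name) for name in res_names)

    # Per-residue B-factor (first atom of each residue); AlphaFold stores
    # pLDDT there, constant within a residue.
    starts = struc.get_residue_starts(atoms)
    b = atoms.b_factor[starts]
    plddt = None
    label = source or path.stem
    if np.all((b >= 0) & (b <= 100)) and np.any(b > 0):
        plddt = np.asarray(b, dtype=float)
    return StructureModel(
        atoms=atoms,
        sequence=sequence,
        res_ids=np.asarray(res_ids),
        chain_id=chain,
        plddt=plddt,
        source=label,
    )


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except Exception:
        return "X"


# ---------------------------------------------------------------------------
# DSSP output parsing (reference path)

def parse_dssp(path) -> list[DsspRecord]:
    """Parse a DSSP output file (classic or mmCIF dialect).

    Returns one record per residue in file order; chain-break lines are
    skipped and blank secondary structure canonicalizes to "C".
    """
    path = Path(path)
    head = path.read_text(errors="replace")[:512]
    if head.lstrip().startswith("data_"):
        return _parse_dssp_mmcif(path)
    return _parse_dssp_classic(path)


def _parse_dssp_classic(path: Path) -> list[DsspRecord]:
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:
        raise StructureError(f"cannot parse DSSP file {path}: {exc}") from exc
    if not keys:
        raise StructureError(f"no residue lines in DSSP file {path}")
    records = []
    for chain_id, res_id in keys:
        aa, ss, acc = dssp_dict[(chain_id, res_id)][:3]
        if aa == "!":
            continue  # chain break
        if aa.islower():
            aa = "C"  # disulfide-bridged cysteines are lowercased by DSSP
        records.append(
            DsspRecord(
                position=int(res_id[1]),
                amino_acid=aa,
                ss_code=ss,
                sasa=float(acc),
            )
        )
    return records


def _parse_dssp_mmcif(path: Path) -> list[DsspRecord]:
    import gemmi.cif

    block = gemmi.cif.read(str(path)).sole_block()
    seq_ids = block.find_loop("_dssp_struct_summary.label_seq_id")
    ss = block.find_loop("_dssp_struct_summary.secondary_structure")
    acc = block.find_loop("_dssp_struct_summary.accessibility")
    comp = block.find_loop("_dssp_struct_summary.label_comp_id")
    rows = list(zip(seq_ids, ss, acc, comp))
    if not rows:
        raise StructureError(f"no _dssp_struct_summary records in {path}")
    records = []
    for seq_id, code, sasa, comp_id in rows:
        if sasa in {".", "?"}:
            continue
        records.append(
            DsspRecord(
                position=int(seq_id),
                amino_acid=_three_to_one(comp_id),
                ss_code="C" if code in {".", "?"} else code,
                sasa=float(sasa),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Internal fallback: Shrake-Rupley SASA and geometric SS assignment

def shrake_rupley_sasa(
    model: StructureModel, n_points: int = 960, probe: float = 1.4
) -> np.ndarray:
    """Per-residue SASA by the Shrake-Rupley method, in squared Angstroms.

    Deterministic: test points come from a fixed Fibonacci sphere lattice
    (no RNG).  Atoms of unknown element fall back to a default van der Waals
    radius with a warning.
    """
    atoms = model.atoms
    known = np.isin(np.char.upper(atoms.element.astype("U2")), _KNOWN_ELEMENTS)
    if not known.all():
        bad = sorted(set(atoms.element[~known]))
        logger.warning(
            "unknown element(s) %s; using default van der Waals radius", bad
        )
        atoms = atoms.copy()
        atoms.element[~known] = "C"
    atom_sasa = struc.sasa(
        atoms, probe_radius=probe, point_number=n_points, vdw_radii="Single"
    )
    res_sasa = struc.apply_residue_wise(atoms, atom_sasa, np.nansum)
    return np.maximum(np.asarray(res_sasa, dtype=float), 0.0)


_KNOWN_ELEMENTS = np.array(
    ["H", "C", "N", "O", "S", "P", "SE", "F", "CL", "BR", "I"]
)


def ss_from_structure(model: StructureModel) -> list[str]:
    """Geometric (P-SEA) secondary-structure approximation — non-reference.

    Used only when no DSSP output file is supplied.  Returns DSSP-style
    codes restricted to {H, E, C}.
    """
    sse = struc.annotate_sse(model.atoms)
    mapping = {"a": "H", "b": "E", "c": "C", "": "C"}
    codes = [mapping.get(str(s), "C") for s in sse]
    if len(codes) != model.n_residues:
        # annotate_sse skips residues without complete backbones; pad as coil
        codes = codes + ["C"] * (model.n_residues - len(codes))
    return codes


# ---------------------------------------------------------------------------
# Max-SA table and track builders

def load_max_sasa_table() -> dict[str, float]:
    """Theoretical maximum solvent accessibility per residue type (A^2)."""
    table = {}
    text = (
        resources.files("tagsite").joinpath("data/max_sasa.tsv").read_text()
    )
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        table[aa] = float(value)
    if len(table) != 20 or any(v <= 0 for v in table.values()):
        raise StructureError("malformed max-SASA table")
    return table


def rsa_track(
    sasa: Sequence[float],
    query: QueryProtein,
    table: dict[str, float] | None = None,
) -> FeatureTrack:
    """RSA_i = SASA_i / SA_max(residue_i), clamped to [0, 1].

    Positions with residue X (no SA_max defined) or missing SASA are NaN.
    """
    table = table or load_max_sasa_table()
    sasa = np.asarray(sasa, dtype=float)
    if sasa.size != query.length:
        raise StructureError(
            f"SASA vector length {sasa.size} != query length {query.length}"
        )
    values = np.full(query.length, np.nan)
    for i, aa in enumerate(query.sequence):
        if aa in table and np.isfinite(sasa[i]):
            values[i] = min(sasa[i] / table[aa], 1.0)
    return FeatureTrack("rsa", values, normalized=True)


def ss_track(
    records: Sequence[DsspRecord] | Sequence[str],
    query: QueryProtein,
) -> FeatureTrack:
    """Secondary-structure feature: C -> 1, G/H/I/E -> 0, otherwise 0.5.

    Accepts DSSP records (positions in query numbering; unlisted positions
    become missing) or a plain code sequence covering every position.
    """
    values = np.full(query.length, np.nan)
    if records and isinstance(records[0], DsspRecord):
        for rec in records:
            if not 1 <= rec.position <= query.length:
                raise StructureError(
                    f"DSSP position {rec.position} outside query 1..{query.length}"
                )
            values[rec.position - 1] = SS_SCORES[rec.ss_code]
    else:
        if len(records) != query.length:
            raise StructureError(
                f"{len(records)} SS codes for a {query.length}-residue query"
            )
        for i, code in enumerate(records):
            values[i] = SS_SCORES[canonicalize_ss_code(code)]
    return FeatureTrack("secondary_structure", values, normalized=True)


def sasa_from_dssp(records: Sequence[DsspRecord], query: QueryProtein) -> np.ndarray:
    """Per-query-position SASA vector from DSSP records (NaN where absent)."""
    sasa = np.full(query.length, np.nan)
    for rec in records:
        if not 1 <= rec.position <= query.length:
            raise StructureError(
                f"DSSP position {rec.position} outside query 1..{query.length}"
            )
        if rec.amino_acid not in {"X", query.sequence[rec.position - 1]}:
            raise StructureError(
                f"DSSP residue {rec.amino_acid!r} at position {rec.position} "
                f"does not match query {query.sequence[rec.position - 1]!r}"
            )
        sasa[rec.position - 1] = rec.sasa
    return sasa


def map_structure_to_query(
    model: StructureModel, query: QueryProtein
) -> np.ndarray:
    """0-based structure-residue index for each query position, -1 if absent.

    Residues are matched by order via a global pairwise alignment; aligned
    positions must be identical (X matches anything).  Structure residues
    missing from the query raise; query positions missing from the structure
    map to -1 and later yield missing feature values.
    """
    if model.sequence == query.sequence:
        return np.arange(query.length)
    aligner = PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-1,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(query.sequence, model.sequence)[0]
    mapping = np.full(query.length, -1, dtype=int)
    for (q_start, q_end), (s_start, s_end) in zip(*aln.aligned):
        for offset in range(q_end - q_start):
            qi, si = q_start + offset, s_start + offset
            q_aa, s_aa = query.sequence[qi], model.sequence[si]
            if q_aa != s_aa and "X" not in (q_aa, s_aa):
                raise StructureError(
                    f"structure/sequence mismatch at query position {qi + 1}: "
                    f"{q_aa!r} != {s_aa!r}"
                )
            mapping[qi] = si
    return mapping
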