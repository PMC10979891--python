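"""Synthetic toy inputs with a planted best insertion site.

The generator emits internally consistent files in the same standard
formats the real pipeline reads — query FASTA, aligned FASTA MSA, classic
DSSP output, PDB structure, IUPred2A 4-column track — constructed so that a
single window of residues is simultaneously favorable in all four features:

* MSA: the eight sequences are identical to the query outside the window;
  inside it each column cycles through eight distinct residues, giving an
  analytically known column entropy of exactly 3 bits;
* DSSP: helix ("H") everywhere except coil ("C") in the window, with ACC
  equal to the residue's theoretical maximum inside (RSA = 1) and near-buried
  outside;
* ANCHOR: binding probability 0.9 everywhere except 0.05 in the window.

The planted window is therefore the unique region where the per-position
minimum feature is high, and the smoothed-minimum argmax falls on the window
center.  The structures are format- and geometry-valid but not physically
realistic.  The seed controls cosmetic identifiers and the residues outside
the window (which carry zero entropy regardless), so analytically known
values are seed-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

from .core import AMINO_ACIDS, write_fasta
from .structure import load_max_sasa_table

#: Fixed residue rotation used inside the planted window (not sampled), so
#: each window column holds 8 distinct residues: entropy = 3 bits exactly.
WINDOW_CYCLE = AMINO_ACIDS  # 20 letters; consecutive 8 are always distinct

#: Homolog labels for the toy MSA (cosmetic).
HOMOLOG_LABELS = (
    "homolog_bos_taurus",
    "homolog_canis_lupus",
    "homolog_gallus_gallus",
    "homolog_homo_sapiens",
    "homolog_mus_musculus",
    "homolog_takifugu_rubripes",
    "homolog_xenopus_tropicalis",
)

#: Normalized entropy inside the planted window: 3 bits / log2(20).
WINDOW_ENTROPY_BITS = 3.0

_DSSP_HEADER = (
    "==== Secondary Structure Definition, synthetic fixture "
    "(format-compatible output, not produced by DSSP) ====\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n"
)


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of one generated input set plus its ground truth."""

    directory: Path
    query_fasta: Path
    msa_fasta: Path
    dssp: Path
    pdb: Path
    anchor: Path
    query_id: str
    sequence: str
    peak_position: int
    window_positions: tuple[int, ...]


def make_fixture(
    out_dir,
    length: int = 60,
    peak_position: int = 30,
    seed: int = 0,
    half_width: int = 3,
) -> FixtureBundle:
    """Generate a complete toy input bundle with a planted peak.

    The favorable window spans ``peak_position +/- half_width`` clipped to
    the sequence; all five files are written under ``out_dir``.
    """
    if not 1 <= peak_position <= length:
        raise ValueError(
            f"peak_position {peak_position} outside 1..{length}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    query_id = f"synthetic{seed:04d}"

    window = [
        p
        for p in range(peak_position - half_width, peak_position + half_width + 1)
        if 1 <= p <= length
    ]
    in_window = np.zeros(length, dtype=bool)
    in_window[[p - 1 for p in window]] = True

    # Query: cycle residues inside the window (analytic entropy), random
    # elsewhere (entropy is zero there whatever the residue).
    seq = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
    for j, pos in enumerate(window):
        seq[pos - 1] = WINDOW_CYCLE[j % 20]
    sequence = "".join(seq)

    query_fasta = out_dir / "query.fasta"
    write_fasta(query_fasta, [(query_id, sequence)])

    # MSA: 8 rows; homolog r differs from the query only in the window,
    # where its residue is shifted r steps along the fixed cycle, so every
    # window column holds 8 distinct letters (H = 3 bits).
    records = [(query_id, sequence)]
    for r, label in enumerate(HOMOLOG_LABELS, start=1):
        row = list(sequence)
        for j, pos in enumerate(window):
            row[pos - 1] = WINDOW_CYCLE[(j + r) % 20]
        records.append((label, "".join(row)))
    msa_fasta = out_dir / "msa.fasta"
    write_fasta(msa_fasta, records)

    # DSSP: coil + fully exposed inside the window, helix + buried outside.
    sa_max = load_max_sasa_table()
    dssp = out_dir / "toy.dssp"
    lines = [_DSSP_HEADER]
    for i, aa in enumerate(sequence, start=1):
        if in_window[i - 1]:
            ss, acc = "C", int(round(sa_max[aa]))
        else:
            ss, acc = "H", 10
        lines.append(_dssp_line(i, aa, ss, acc))
    dssp.write_text("".join(lines))

    # Extended-backbone PDB; pLDDT-style B-factors low in the window.
    pdb = out_dir / "toy.pdb"
    _write_backbone_pdb(pdb, sequence, in_window)

    # ANCHOR track (IUPred2A long dialect): low binding probability in the
    # window, high elsewhere.
    anchor = out_dir / "anchor.iupred2a"
    anchor_lines = ["# POS\tRES\tIUPRED2\tANCHOR2\n"]
    for i, aa in enumerate(sequence, start=1):
        br = 0.05 if in_window[i - 1] else 0.90
        anchor_lines.append(f"{i}\t{aa}\t0.5000\t{br:.4f}\n")
    anchor.write_text("".join(anchor_lines))

    return FixtureBundle(
        directory=out_dir,
        query_fasta=query_fasta,
        msa_fasta=msa_fasta,
        dssp=dssp,
        pdb=pdb,
        anchor=anchor,
        query_id=query_id,
        sequence=sequence,
        peak_position=peak_position,
        window_positions=tuple(window),
    )


def _dssp_line(position: int, aa: str, ss: str, acc: int) -> str:
    """One classic-format DSSP residue line (fixed-width columns)."""
    line = [" "] * 120
    _put(line, 0, f"{position:5d}")
    _put(line, 5, f"{position:5d}")
    line[11] = "A"
    line[13] = aa
    line[16] = ss
    _put(line, 34, f"{acc:4d}")
    _put(line, 38, f"{0:7d}")
    _put(line, 46, " 0.0")
    _put(line, 50, f"{0:6d}")
    _put(line, 57, " 0.0")
    _put(line, 61, f"{0:6d}")
    _put(line, 68, " 0.0")
    _put(line, 72, f"{0:6d}")
    _put(line, 79, " 0.0")
    _put(line, 103, f"{-60.0:6.1f}")
    _put(line, 109, f"{-45.0:6.1f}")
    return "".join(line) + "\n"


def _put(line: list[str], start: int, text: str) -> None:
    line[start : start + len(text)] = list(text)


def _write_backbone_pdb(path: Path, sequence: str, in_window: np.ndarray) -> None:
    """Write an extended backbone (N, CA, C, O per residue) along the x axis."""
    n_res = len(sequence)
    atoms = struc.AtomArray(4 * n_res)
    names = ["N", "CA", "C", "O"]
    elements = ["N", "C", "C", "O"]
    offsets = np.array(
        [[0.0, 0.0, 0.0], [1.46, 0.50, 0.0], [2.48, -0.45, 0.0], [2.45, -1.68, 0.3]]
    )
    coords = np.zeros((4 * n_res, 3))
    for i, aa in enumerate(sequence):
        base = np.array([3.8 * i, 0.0, 0.0])
        coords[4 * i : 4 * i + 4] = base + offsets
        res_name = ProteinSequence.convert_letter_1to3(aa)
        for k in range(4):
            j = 4 * i + k
            atoms.chain_id[j] = "A"
            atoms.res_id[j] = i + 1
            atoms.res_name[j] = res_name
            atoms.atom_name[j] = names[k]
            atoms.element[j] = elements[k]
            atoms.hetero[j] = False
    atoms.coord = coords
    atoms.set_annotation(
        "b_factor",
        np.repeat(np.where(in_window, 40.0, 90.0), 4),
    )
    pdb_file = PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


def make_degenerate_fixtures(out_dir) -> dict[str, Path]:
    """Write small malformed inputs, one per failure path.

    Returns a mapping from failure name to file path: ragged MSA, an MSA
    with an all-gap column, an out-of-range binding probability, an unknown
    secondary-structure code, and a structure whose sequence mismatches the
    query (for a 10-residue all-alanine query).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    ragged = out_dir / "ragged_msa.fasta"
    ragged.write_text(">query\nACDEFGHIKL\n>homolog_1\nACDEFGHIK\n")
    bundle["ragged_msa"] = ragged

    all_gap = out_dir / "all_gap_column_msa.fasta"
    all_gap.write_text(">query\nAC-EFGHIKL\n>homolog_1\nAC-EFGHIKL\n")
    bundle["all_gap_column_msa"] = all_gap

    bad_br = out_dir / "bad_br.iupred2a"
    bad_br.write_text(
        "# POS\tRES\tIUPRED2\tANCHOR2\n1\tA\t0.5\t0.2\n2\tA\t0.5\t1.3\n"
    )
    bundle["br_out_of_range"] = bad_br

    bad_ss = out_dir / "bad_ss.dssp"
    bad_ss.write_text(_DSSP_HEADER + _dssp_line(1, "A", "Z", 50))
    bundle["unknown_ss_code"] = bad_ss

    mismatch = out_dir / "mismatched_structure.pdb"
    _write_backbone_pdb(
        mismatch, "AAAAGAAAAA", np.zeros(10, dtype=bool)
    )  # query is AAAAAAAAAA: G at position 5 mismatches
    bundle["mismatched_structure"] = mismatch

    return bundle
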