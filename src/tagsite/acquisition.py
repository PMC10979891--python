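"""Optional online fetchers and external-tool orchestration.

Everything here is opt-in: the default mode is strictly offline, consuming
local files only.  When enabled, fetched objects are cached to files that
the offline path consumes, keyed by accession and source; cached files are
never silently refreshed.  External tools (BLAST, an aligner, DSSP) are
invoked behind a single boundary so every stage can be bypassed by
supplying its output file directly.
"""

from __future__ import annotations

import hashlib
import logging
import re
import shutil
import subprocess
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conservation import DEFAULT_SPECIES_PANEL
from .core import Weights

logger = logging.getLogger(__name__)

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"
ALPHAFOLD_PDB_URL = (
    "https://alphafold.ebi.ac.uk/files/AF-{accession}-F1-model_v4.pdb"
)
IUPRED2A_URL = "https://iupred2a.elte.hu/iupred2a/long/{accession}"

#: UniProt accession pattern (canonical 6/10-character forms).
ACCESSION_RE = re.compile(
    r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}$"
)


class ConfigError(ValueError):
    """Raised when a pipeline configuration cannot be satisfied."""


class FetchError(RuntimeError):
    """Raised when an enabled online fetch fails."""


class ExternalToolError(RuntimeError):
    """Raised when an external tool invocation fails."""


@dataclass
class PipelineConfig:
    """Configuration of a full run, offline or fetching.

    Each stage (sequence, structure, alignment, disorder) needs either a
    local file or an enabled fetch/tool route; validation reports the first
    stage that has neither.
    """

    accession: str = ""
    species_panel: tuple[str, ...] = DEFAULT_SPECIES_PANEL
    query_fasta: str | None = None
    structure_file: str | None = None
    dssp_file: str | None = None
    msa_fasta: str | None = None
    anchor_file: str | None = None
    proteome_fastas: dict[str, str] = field(default_factory=dict)
    blast_exe: str | None = None
    aligner_exe: str | None = None
    dssp_exe: str | None = None
    fetch: bool = False
    weights: Weights = field(default_factory=Weights)
    window: int = 7
    top_k: int = 5
    min_separation: int = 8
    output_dir: str = "tagsite_out"
    cache_dir: str = ".tagsite_cache"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        weights = raw.pop("weights", None)
        cfg = cls(**raw)
        if weights is not None:
            cfg.weights = Weights(**weights)
        return cfg

    def validate(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError("window must be an odd positive integer")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        stages = {
            "sequence": self.query_fasta or (self.fetch and self.accession),
            "structure": self.dssp_file
            or self.structure_file
            or (self.fetch and self.accession),
            "alignment": self.msa_fasta
            or (self.blast_exe and self.aligner_exe and self.proteome_fastas),
            "disorder": self.anchor_file or (self.fetch and self.accession),
        }
        for stage, satisfied in stages.items():
            if not satisfied:
                raise ConfigError(
                    f"stage {stage!r} has neither a local file nor an enabled "
                    f"fetch/tool route; supply the corresponding input file "
                    f"for offline operation"
                )
        if self.accession and not ACCESSION_RE.match(self.accession):
            raise ConfigError(f"malformed accession {self.accession!r}")


def _fetch(url: str, dest: Path, retries: int = 3, backoff: float = 2.0) -> Path:
    if dest.exists():
        logger.info("cache hit: %s", dest)
        return dest
    dest.parent.mkdir(parents=True, exist_ok=True)
    last_error: Exception | None = None
    for attempt in range(retries):
        try:
            with urllib.request.urlopen(url, timeout=30) as response:
                data = response.read()
            dest.write_bytes(data)
            digest = hashlib.sha256(data).hexdigest()
            logger.info("fetched %s -> %s (sha256 %s)", url, dest, digest[:16])
            return dest
        except (urllib.error.URLError, OSError) as exc:
            last_error = exc
            logger.warning("fetch attempt %d failed for %s: %s", attempt + 1, url, exc)
            time.sleep(backoff * (attempt + 1))
    raise FetchError(f"cannot fetch {url}: {last_error}")


def fetch_uniprot_sequence(accession: str, cache_dir=".tagsite_cache") -> Path:
    """Fetch the canonical FASTA for a UniProt accession (cached)."""
    if not ACCESSION_RE.match(accession):
        raise ConfigError(f"malformed accession {accession!r}")
    dest = Path(cache_dir) / f"{accession}.fasta"
    return _fetch(UNIPROT_FASTA_URL.format(accession=accession), dest)


def fetch_alphafold_structure(accession: str, cache_dir=".tagsite_cache") -> Path:
    """Fetch the AlphaFold model PDB for a UniProt accession (cached)."""
    if not ACCESSION_RE.match(accession):
        raise ConfigError(f"malformed accession {accession!r}")
    dest = Path(cache_dir) / f"AF-{accession}.pdb"
    try:
        return _fetch(ALPHAFOLD_PDB_URL.format(accession=accession), dest)
    except FetchError as exc:
        raise FetchError(
            f"{exc}; if no predicted model exists for {accession}, supply a "
            f"local structure file instead"
        ) from exc


def fetch_iupred2a_track(accession: str, cache_dir=".tagsite_cache") -> Path:
    """Fetch the IUPred2A/ANCHOR2 text track for an accession (cached)."""
    if not ACCESSION_RE.match(accession):
        raise ConfigError(f"malformed accession {accession!r}")
    dest = Path(cache_dir) / f"{accession}.iupred2a"
    return _fetch(IUPRED2A_URL.format(accession=accession), dest)


def run_external(
    tool: str, args: list[str], outputs: list, executable: str | None = None
) -> list[Path]:
    """Run one external tool (blast / aligner / dssp) and check its outputs.

    The full command line and exit status are logged; a nonzero exit raises
    with the captured stderr.  A missing executable raises an error that
    names the file-based bypass for the stage.
    """
    exe = executable or tool
    if shutil.which(exe) is None:
        raise ExternalToolError(
            f"executable {exe!r} not found; bypass this stage by supplying "
            f"its output file directly ({_BYPASS_HINTS.get(tool, 'a local file')})"
        )
    cmd = [exe] + [str(a) for a in args]
    start = time.monotonic()
    proc = subprocess.run(cmd, capture_output=True, text=True)
    logger.info(
        "ran %s (exit %d, %.1fs)", " ".join(cmd), proc.returncode,
        time.monotonic() - start,
    )
    if proc.returncode != 0:
        raise ExternalToolError(
            f"{exe} exited {proc.returncode}: {proc.stderr.strip()[:2000]}"
        )
    paths = [Path(o) for o in outputs]
    for path in paths:
        if not path.exists() or path.stat().st_size == 0:
            raise ExternalToolError(f"{exe} did not produce {path}")
    return paths


_BYPASS_HINTS = {
    "blast": "a pre-aligned MSA via msa_fasta",
    "aligner": "a pre-aligned MSA via msa_fasta",
    "dssp": "a DSSP output file via dssp_file, or a structure file",
}
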