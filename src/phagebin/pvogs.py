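"""Per-gene hits against a viral orthologous-group profile-HMM database.

Hits come either from an external profile search engine (``hmmscan`` over
a pressed HMM database, tabular output) or from a precomputed TSV table,
so the pipeline is testable without the full pVOGs database.  A hit is
significant when its full-sequence E-value is at most 1e-10 (inclusive).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .formats_io import FormatError, HmmHit, read_hmm_tblout

DEFAULT_EVALUE_THRESHOLD = 1e-10

HIT_TSV_HEADER = "gene_id\tprofile_id\tevalue\tbitscore"


class SearchEngineError(RuntimeError):
    """The external profile search engine failed."""


@dataclass(frozen=True)
class HitTable:
    """Deduplicated profile-HMM hits plus their provenance.

    Duplicate (gene_id, profile_id) pairs keep the smallest E-value, so
    deduplication can never change which genes are significant.
    """

    hits: tuple[HmmHit, ...]
    source: str  # "external_search" | "precomputed" | "synthetic"
    db_version: str = "unversioned"

    def __post_init__(self) -> None:
        pairs = [(h.gene_id, h.profile_id) for h in self.hits]
        if len(set(pairs)) != len(pairs):
            raise ValueError("HitTable contains duplicate (gene, profile) pairs")


def deduplicate_hits(hits: Iterable[HmmHit]) -> tuple[HmmHit, ...]:
    """Keep the best (smallest-E-value) hit per (gene, profile) pair."""
    best: dict[tuple[str, str], HmmHit] = {}
    for h in hits:
        key = (h.gene_id, h.profile_id)
        if key not in best or h.evalue < best[key].evalue:
            best[key] = h
    return tuple(best[k] for k in best)  # insertion order = first-seen order


def run_profile_search(
    proteins: Mapping[str, str],
    db_path: str | Path,
    engine_cmd: str = "hmmscan --tblout {tblout} -o /dev/null {db} {query}",
    db_version: str = "unversioned",
) -> HitTable:
    """Search per-gene proteins against a pressed profile-HMM database.

    ``engine_cmd`` is a template with ``{tblout}``, ``{db}`` and
    ``{query}`` placeholders; the engine must emit target-per-line
    tabular output, which is parsed with
    :func:`phagebin.formats_io.read_hmm_tblout`.
    """
    db_path = Path(db_path)
    if not db_path.exists():
        raise FileNotFoundError(f"profile database not found: {db_path}")
    if not proteins:
        return HitTable(hits=(), source="external_search", db_version=db_version)
    exe = engine_cmd.split()[0]
    if shutil.which(exe) is None:
        raise SearchEngineError(f"search engine {exe!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "proteins.faa"
        tblout = Path(tmp) / "hits.tbl"
        with open(query, "w") as fh:
            for gene_id, aa in proteins.items():
                fh.write(f">{gene_id}\n{aa}\n")
        cmd = engine_cmd.format(tblout=tblout, db=db_path, query=query)
        proc = subprocess.run(cmd.split(), capture_output=True, text=True)
        if proc.returncode != 0:
            raise SearchEngineError(
                f"search engine failed (exit {proc.returncode}): {proc.stderr[-2000:]}"
            )
        hits = read_hmm_tblout(tblout)
    return HitTable(
        hits=deduplicate_hits(hits), source="external_search", db_version=db_version
    )


def load_precomputed_hits(path: str | Path, db_version: str = "precomputed") -> HitTable:
    """Load a precomputed hit table.

    Dialect: TSV with a header line ``gene_id  profile_id  evalue
    bitscore`` (bitscore optional per row); '#' lines are comments.
    """
    path = Path(path)
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if lineno == 1 or line.startswith("gene_id\t"):
                if line.split("\t")[:2] == ["gene_id", "profile_id"]:
                    continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                evalue = float(fields[2])
                bitscore = float(fields[3]) if len(fields) > 3 and fields[3] else 0.0
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from exc
            hits.append(HmmHit(fields[0], fields[1], evalue, bitscore))
    return HitTable(
        hits=deduplicate_hits(hits), source="precomputed", db_version=db_version
    )


def write_hit_table(table: HitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(HIT_TSV_HEADER + "\n")
        for h in table.hits:
            fh.write(f"{h.gene_id}\t{h.profile_id}\t{h.evalue:.6g}\t{h.bitscore:.2f}\n")


def significant_genes(
    table: HitTable, threshold: float = DEFAULT_EVALUE_THRESHOLD
) -> set[str]:
    """Genes with at least one hit at E-value <= threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {h.gene_id for h in table.hits if h.evalue <= threshold}
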