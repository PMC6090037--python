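"""Readers and writers for every external format the pipeline touches.

Inputs are metagenomic bins (one multi-FASTA file per bin), GenBank flat
files carrying CDS annotations of complete genomes, and tabular output of a
profile-HMM search engine (the HMMER ``--tblout`` dialect).  Output is a
directory of FASTA files for bins predicted as phage plus a tab-separated
summary.

All genomic coordinates inside the package are 1-based and inclusive on
both ends, matching the GenBank convention; every conversion happens here,
at the I/O boundary.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: file suffixes recognised as FASTA bins
DEFAULT_FASTA_EXTENSIONS = frozenset({".fa", ".fasta", ".fna"})

SUMMARY_HEADER = (
    "bin_id\tphage_probability\tlabel\tgene_density\tstrand_shift_freq\tpvogs_frac"
)


class FormatError(ValueError):
    """A file did not conform to its expected dialect."""


class EmptyInputError(FormatError):
    """An input file or directory contained no usable records."""


@dataclass(frozen=True)
class Contig:
    """One assembled sequence, uppercased, over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Bin:
    """A named set of contigs treated as one putative genome."""

    id: str
    contigs: tuple[Contig, ...]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"bin {self.id!r} has no contigs")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"bin {self.id!r} has duplicate contig ids: {dup}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)


@dataclass(frozen=True)
class HmmHit:
    """One profile-HMM match for one gene (full-sequence E-value)."""

    gene_id: str
    profile_id: str
    evalue: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not self.gene_id or not self.profile_id:
            raise ValueError("gene_id and profile_id must be nonempty")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for {self.gene_id}")


def _normalize_sequence(seq: str, record_id: str) -> str:
    """Uppercase and map every non-ACGTN character to N."""
    up = seq.upper()
    if set(up) <= DNA_ALPHABET:
        return up
    bad = sorted(set(up) - DNA_ALPHABET)
    logger.warning(
        "record %s: characters %s outside {A,C,G,T,N} replaced by N", record_id, bad
    )
    return "".join(ch if ch in DNA_ALPHABET else "N" for ch in up)


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig`, order preserved.

    Sequences are uppercased; characters outside ``{A,C,G,T,N}`` become N
    (a warning is logged).  Raises :class:`FormatError` on duplicate record
    ids and :class:`EmptyInputError` on a file without records.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        contigs.append(Contig(id=rec.id, sequence=seq))
    if not contigs:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, c.length, width):
                fh.write(c.sequence[i : i + width] + "\n")


def read_bins_dir(
    path: str | Path, extensions: Iterable[str] = DEFAULT_FASTA_EXTENSIONS
) -> list[Bin]:
    """Load every FASTA file in a directory as one :class:`Bin`.

    Bin id is the file stem; bins are returned in lexicographic order of
    their ids so downstream processing is deterministic.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"bins directory not found: {path}")
    exts = {e if e.startswith(".") else "." + e for e in extensions}
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in exts)
    if not files:
        raise EmptyInputError(
            f"{path}: no files with extensions {sorted(exts)} found"
        )
    bins = []
    for f in files:
        try:
            bins.append(Bin(id=f.stem, contigs=tuple(read_fasta(f))))
        except OSError as exc:
            raise FormatError(f"cannot read bin file {f}: {exc}") from exc
    bins.sort(key=lambda b: b.id)
    return bins


def parse_genbank_cds(path: str | Path):
    """Extract genome length and CDS calls from a GenBank flat file.

    Returns ``(genome_length, gene_calls)`` where each call is a
    :class:`~phagebin.gene_calling.GeneCall` in 1-based inclusive
    coordinates.  Compound (join) locations collapse to their outermost
    span — downstream features depend only on span, order and strand.
    Malformed CDS features are skipped with a warning; the skip count is
    logged.
    """
    from .gene_calling import GeneCall  # deferred to avoid import cycle

    path = Path(path)
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise FormatError(f"{path}: no GenBank record found")
    calls: list[GeneCall] = []
    total_length = 0
    skipped = 0
    for rec in records:
        length = len(rec.seq)
        total_length += length
        n = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            try:
                start = int(feat.location.start) + 1  # 0-based half-open -> 1-based
                end = int(feat.location.end)
                strand = "+" if (feat.location.strand or 1) >= 0 else "-"
                if len(getattr(feat.location, "parts", [feat.location])) > 1:
                    logger.debug(
                        "%s: compound location for CDS at %d..%d collapsed to outer span",
                        rec.id, start, end,
                    )
                if not (1 <= start <= end <= length):
                    raise ValueError("span outside record")
            except (TypeError, ValueError) as exc:
                skipped += 1
                logger.warning("%s: skipping malformed CDS location (%s)", rec.id, exc)
                continue
            n += 1
            calls.append(
                GeneCall(
                    gene_id=f"{rec.id}_{n}",
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    if skipped:
        logger.warning("%s: skipped %d malformed CDS feature(s)", path, skipped)
    return total_length, calls


def read_hmm_tblout(
    path: str | Path,
    gene_id_column: int = 2,
    profile_id_column: int = 0,
    evalue_column: int = 4,
    bitscore_column: int = 5,
) -> list[HmmHit]:
    """Parse target-per-line tabular profile-HMM search output.

    The defaults match ``hmmscan --tblout`` (target = profile, query =
    gene, full-sequence E-value in column 5).  For ``hmmsearch`` output
    swap ``gene_id_column=0, profile_id_column=2``.  Comment lines start
    with '#'; fields are whitespace-separated.
    """
    path = Path(path)
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            try:
                gene = fields[gene_id_column]
                profile = fields[profile_id_column]
                evalue = float(fields[evalue_column])
                bitscore = float(fields[bitscore_column])
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse hit fields ({exc})"
                ) from exc
            hits.append(HmmHit(gene, profile, evalue, bitscore))
    return hits


def write_predictions(
    bins: Sequence[Bin],
    decisions,  # Sequence[Prediction]
    vectors,  # Sequence[FeatureVector]
    out_dir: str | Path,
    overwrite: bool = False,
    source_paths: dict[str, Path] | None = None,
) -> Path:
    """Write prediction results: phage FASTAs plus a TSV summary.

    ``decisions`` and ``vectors`` are parallel to ``bins``.  Bins labelled
    phage are written as FASTA into ``out_dir/phage_bins``; the summary
    row order matches the input bin order.  Refuses a non-empty existing
    ``out_dir`` unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (use overwrite to replace)"
        )
    phage_dir = out_dir / "phage_bins"
    phage_dir.mkdir(parents=True, exist_ok=True)
    summary = out_dir / "summary.tsv"
    with open(summary, "w") as fh:
        fh.write(SUMMARY_HEADER + "\n")
        for b, d, v in zip(bins, decisions, vectors):
            fh.write(
                f"{b.id}\t{d.phage_probability:.6f}\t{d.label}\t"
                f"{v.gene_density:.6f}\t{v.strand_shift_freq:.6f}\t{v.pvogs_frac:.6f}\n"
            )
            if d.label == "phage":
                src = (source_paths or {}).get(b.id)
                dest = phage_dir / f"{b.id}.fasta"
                if src is not None:
                    shutil.copyfile(src, dest)
                else:
                    write_fasta(b.contigs, dest)
    return out_dir
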