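"""CDS prediction for bin contigs.

Two backends produce gene calls: a built-in deterministic six-frame ORF
finder (no external dependency, used throughout the test suite and for
synthetic data), and an external prokaryotic gene caller such as Prodigal
invoked through a configurable command template.  The built-in finder makes
no claim of matching Prodigal's scoring model — the classifier's features
are defined on predicted CDSs, whichever caller produced them.

Coordinates are 1-based inclusive; an ORF span includes its stop codon, so
span length is always a multiple of 3.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .formats_io import Bin, Contig, write_fasta

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 120  # bp; shorter ORFs are dominated by chance on random sequence
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GeneCallingError(RuntimeError):
    """An external gene caller failed or produced unparsable output."""


@dataclass(frozen=True)
class GeneCall:
    """One predicted CDS: contig, 1-based inclusive span, strand."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnotatedBin:
    """A bin together with its gene calls in canonical sort order.

    Genes are grouped by contig (in bin contig order) and sorted by start,
    ties broken by end then by strand with '+' before '-'.  The fixed
    tie-break makes strand-shift counting deterministic.
    """

    bin: Bin
    genes: tuple[GeneCall, ...]

    def __post_init__(self) -> None:
        contig_ids = {c.id for c in self.bin.contigs}
        for g in self.genes:
            if g.contig_id not in contig_ids:
                raise ValueError(
                    f"gene {g.gene_id} references unknown contig {g.contig_id!r}"
                )

    def genes_by_contig(self) -> dict[str, list[GeneCall]]:
        out: dict[str, list[GeneCall]] = {c.id: [] for c in self.bin.contigs}
        for g in self.genes:
            out[g.contig_id].append(g)
        return out


def sort_genes(genes: Iterable[GeneCall], contig_order: Sequence[str]) -> tuple[GeneCall, ...]:
    """Canonical gene order: contig (bin order), start, end, '+' before '-'."""
    rank = {cid: i for i, cid in enumerate(contig_order)}
    return tuple(
        sorted(
            genes,
            key=lambda g: (rank[g.contig_id], g.start, g.end, 0 if g.strand == "+" else 1),
        )
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_codes(seq_bytes: np.ndarray, frame: int) -> np.ndarray:
    """Base-4 codes of consecutive codons in one frame; codons with N get -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, base in enumerate(b"ACGT"):
        lut[base] = i
    codes = lut[seq_bytes]
    n = (len(codes) - frame) // 3
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes[frame : frame + 3 * n].reshape(n, 3).astype(np.int64)
    out = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    out[(c < 0).any(axis=1)] = -1
    return out


def _codon_set_codes(codons: Iterable[str]) -> np.ndarray:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array(
        sorted(idx[c[0]] * 16 + idx[c[1]] * 4 + idx[c[2]] for c in codons),
        dtype=np.int64,
    )


def _scan_frame(codons: np.ndarray, starts: np.ndarray, stops: np.ndarray,
                min_codons: int) -> list[tuple[int, int]]:
    """ORFs in one frame as (start_codon_idx, stop_codon_idx) pairs.

    For each in-frame stop, the ORF runs from the most upstream in-frame
    start after the previous stop to that stop (stop included).
    """
    is_stop = np.isin(codons, stops)
    stop_idx = np.nonzero(is_stop)[0]
    if stop_idx.size == 0:
        return []
    start_idx = np.nonzero(np.isin(codons, starts))[0]
    if start_idx.size == 0:
        return []
    prev_stop = np.concatenate(([-1], stop_idx[:-1]))
    # first start strictly after the previous stop
    cand = np.searchsorted(start_idx, prev_stop + 1, side="left")
    orfs = []
    for j, stop in enumerate(stop_idx):
        k = cand[j]
        if k < start_idx.size and start_idx[k] < stop:
            first = start_idx[k]
            if stop - first + 1 >= min_codons:
                orfs.append((int(first), int(stop)))
    return orfs


def call_genes_builtin(
    contig: Contig,
    min_len: int = DEFAULT_MIN_LEN,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
    stop_codons: frozenset[str] = DEFAULT_STOP_CODONS,
) -> list[GeneCall]:
    """Deterministic six-frame ORF finder.

    Scans all three frames of the forward strand and of the reverse
    complement; minus-strand spans are reported in forward coordinates.
    No overlap resolution is performed across frames.  Gene ids are
    assigned later by :func:`annotate_bin`; here they are positional.
    """
    if min_len < 60 or min_len % 3:
        raise ValueError("min_len must be >= 60 and divisible by 3")
    L = contig.length
    if L < min_len:
        return []
    min_codons = min_len // 3
    starts = _codon_set_codes(start_codons)
    stops = _codon_set_codes(stop_codons)

    calls: list[tuple[int, int, str]] = []
    fwd = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
    rev = np.frombuffer(
        reverse_complement(contig.sequence).encode("ascii"), dtype=np.uint8
    )
    for frame in range(3):
        codons = _codon_codes(fwd, frame)
        for a, b in _scan_frame(codons, starts, stops, min_codons):
            s = frame + 3 * a + 1
            e = frame + 3 * b + 3
            calls.append((s, e, "+"))
        codons = _codon_codes(rev, frame)
        for a, b in _scan_frame(codons, starts, stops, min_codons):
            # map revcomp coordinates back onto the forward strand
            rs = frame + 3 * a + 1
            re_ = frame + 3 * b + 3
            calls.append((L - re_ + 1, L - rs + 1, "-"))
    calls.sort(key=lambda t: (t[0], t[1], 0 if t[2] == "+" else 1))
    return [
        GeneCall(f"{contig.id}_orf{i + 1}", contig.id, s, e, st)
        for i, (s, e, st) in enumerate(calls)
    ]


def _parse_prodigal_gff(text: str, contig_ids: set[str]) -> list[tuple[str, int, int, str]]:
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 7 or f[2] != "CDS":
            continue
        cid, start, end, strand = f[0], int(f[3]), int(f[4]), f[6]
        if cid not in contig_ids:
            raise GeneCallingError(f"external caller reported unknown contig {cid!r}")
        rows.append((cid, start, end, strand))
    return rows


def call_genes_external(
    bin_: Bin,
    external_cmd: str = "prodigal -p meta -f gff -i {input} -o {output} -q",
) -> list[tuple[str, int, int, str]]:
    """Run an external gene caller over all contigs of a bin.

    ``external_cmd`` is a template with ``{input}`` and ``{output}``
    placeholders; the output must be GFF-like (tab-separated, CDS rows
    with 1-based inclusive coordinates), which Prodigal's ``-f gff``
    satisfies.  Returns raw ``(contig_id, start, end, strand)`` rows.
    """
    exe = external_cmd.split()[0]
    if shutil.which(exe) is None:
        raise GeneCallingError(f"external gene caller {exe!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "bin.fasta"
        out = Path(tmp) / "genes.gff"
        write_fasta(bin_.contigs, fasta)
        cmd = external_cmd.format(input=fasta, output=out)
        proc = subprocess.run(cmd.split(), capture_output=True, text=True)
        if proc.returncode != 0:
            raise GeneCallingError(
                f"external gene caller failed (exit {proc.returncode}): {proc.stderr[-2000:]}"
            )
        return _parse_prodigal_gff(out.read_text(), {c.id for c in bin_.contigs})


def annotate_bin(
    bin_: Bin,
    backend: str = "builtin",
    external_cmd: str = "prodigal -p meta -f gff -i {input} -o {output} -q",
    min_len: int = DEFAULT_MIN_LEN,
) -> AnnotatedBin:
    """Produce an :class:`AnnotatedBin` using the selected backend.

    ``backend`` is one of ``builtin``, ``external`` or ``auto`` (external
    when its executable resolves, builtin otherwise; the choice is
    logged).  Gene ids are ``<contig_id>_<ordinal>`` in canonical sort
    order.  A bin with zero genes is a valid result.
    """
    if backend == "auto":
        exe = external_cmd.split()[0]
        backend = "external" if shutil.which(exe) else "builtin"
        logger.info("gene-caller backend resolved to %s", backend)
    if backend == "builtin":
        raw = [
            (g.contig_id, g.start, g.end, g.strand)
            for c in bin_.contigs
            for g in call_genes_builtin(c, min_len=min_len)
        ]
    elif backend == "external":
        raw = call_genes_external(bin_, external_cmd)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    contig_order = [c.id for c in bin_.contigs]
    rank = {cid: i for i, cid in enumerate(contig_order)}
    raw.sort(key=lambda t: (rank[t[0]], t[1], t[2], 0 if t[3] == "+" else 1))
    per_contig: dict[str, int] = {}
    genes = []
    for cid, s, e, st in raw:
        per_contig[cid] = per_contig.get(cid, 0) + 1
        genes.append(GeneCall(f"{cid}_{per_contig[cid]}", cid, s, e, st))
    return AnnotatedBin(bin=bin_, genes=tuple(genes))


def translate_cds(call: GeneCall, contig: Contig, table: int = 11) -> str:
    """Translate one CDS to protein (bacterial table 11 by default).

    Minus-strand calls are reverse-complemented first.  The trailing stop
    is removed; internal stops and codons containing N are rendered 'X'
    (internal stops are logged).
    """
    if call.end > contig.length:
        raise ValueError(f"gene {call.gene_id}: span exceeds contig length")
    if call.length % 3:
        raise ValueError(
            f"gene {call.gene_id}: span length {call.length} not divisible by 3"
        )
    nt = contig.sequence[call.start - 1 : call.end]
    if call.strand == "-":
        nt = reverse_complement(nt)
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        logger.warning("gene %s: internal stop codon(s) rendered as X", call.gene_id)
        aa = aa.replace("*", "X")
    return aa
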