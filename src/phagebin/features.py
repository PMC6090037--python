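"""Genomic feature extraction for bin classification.

Six quantities are computed on an annotated bin; three of them carry the
class signal the classifier uses:

* **gene density** — CDS count per kbp of sequence.  Phage genomes are
  capsid-constrained and pack genes more tightly than bacteria.
* **strand-shift frequency** — number of coding-strand changes between
  neighbouring genes divided by the total CDS count.  Phages keep long
  co-oriented runs of genes; bacteria switch strands more often.
* **pVOGs fraction** — fraction of genes with at least one significant
  profile-HMM hit against a viral orthologous-group database
  (E-value <= 1e-10).

The remaining three (average gene length, average intergenic spacing, ATG
relative frequency) are retained for inspection in ``extended`` mode.

All quantities are pooled at bin level (single ratios over all contigs),
never averaged per contig.  Neighbour pairs never span a contig boundary:
contig adjacency inside a bin is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats_io import HmmHit
from .gene_calling import AnnotatedBin

SIGNIFICANCE_EVALUE = 1e-10  # inclusive bound

#: fixed feature order fed to the classifier
CORE_FEATURE_NAMES = ("gene_density", "strand_shift_freq", "pvogs_frac")
EXTENDED_FEATURE_NAMES = CORE_FEATURE_NAMES + (
    "avg_gene_length",
    "avg_spacing",
    "atg_freq",
)


class UndefinedFeatureError(ValueError):
    """A feature's defining ratio has no valid denominator."""


@dataclass(frozen=True)
class FeatureVector:
    """Per-bin genomic signature.

    ``warnings`` records degenerate conditions (e.g. ``zero_genes``) under
    which core features were pinned to 0.0 by contract rather than
    computed.  ``atg_strand`` records that ATG counting used the forward
    strand of each contig as stored.
    """

    bin_id: str
    gene_density: float
    strand_shift_freq: float
    pvogs_frac: float
    avg_gene_length: float | None = None
    avg_spacing: float | None = None
    atg_freq: float | None = None
    warnings: tuple[str, ...] = ()
    atg_strand: str = "forward"

    def core(self) -> np.ndarray:
        return np.array(
            [self.gene_density, self.strand_shift_freq, self.pvogs_frac], dtype=float
        )


def gene_density(ab: AnnotatedBin) -> float:
    """CDS count divided by bin length in kbp, pooled over contigs."""
    total = ab.bin.total_length
    if total < 1:
        raise UndefinedFeatureError("bin has zero length")
    return len(ab.genes) / (total / 1000.0)


def strand_shift_frequency(ab: AnnotatedBin) -> float:
    """Within-contig neighbour strand changes divided by total CDS count.

    Zero genes yields 0.0 (callers flag the vector).
    """
    n = len(ab.genes)
    if n == 0:
        return 0.0
    shifts = 0
    for genes in ab.genes_by_contig().values():
        for prev, nxt in zip(genes, genes[1:]):
            if prev.strand != nxt.strand:
                shifts += 1
    return shifts / n


def pvogs_fraction(
    ab: AnnotatedBin,
    hits: Iterable[HmmHit],
    threshold: float = SIGNIFICANCE_EVALUE,
) -> float:
    """Fraction of genes with >= 1 hit at E-value <= threshold (inclusive).

    A gene counts once no matter how many profiles it matches; hits whose
    gene_id is not in the bin are ignored.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(ab.genes)
    if n == 0:
        return 0.0
    gene_ids = {g.gene_id for g in ab.genes}
    significant = {
        h.gene_id for h in hits if h.evalue <= threshold and h.gene_id in gene_ids
    }
    return len(significant) / n


def avg_gene_length(ab: AnnotatedBin) -> float:
    """Mean CDS span length in bp (stop codon included in the span)."""
    if not ab.genes:
        raise UndefinedFeatureError("avg_gene_length undefined for zero genes")
    return float(np.mean([g.length for g in ab.genes]))


def avg_spacing(ab: AnnotatedBin) -> float:
    """Mean intergenic gap in bp over within-contig neighbour pairs.

    Gap = next.start - prev.end - 1; negative for overlapping genes
    (overlaps are real in phage genomes and are not clamped).
    """
    gaps = []
    for genes in ab.genes_by_contig().values():
        for prev, nxt in zip(genes, genes[1:]):
            gaps.append(nxt.start - prev.end - 1)
    if not gaps:
        raise UndefinedFeatureError(
            "avg_spacing undefined: no contig has two or more genes"
        )
    return float(np.mean(gaps))


def atg_relative_frequency(ab: AnnotatedBin) -> float:
    """Overlapping ATG count over total 3-mers, forward strand as stored.

    Windows containing N never match.  Contigs shorter than 3 bp
    contribute no windows; if none has a window, returns 0.0.
    """
    matches = 0
    windows = 0
    for c in ab.bin.contigs:
        if c.length < 3:
            continue
        windows += c.length - 2
        matches += c.sequence.count("ATG")  # non-overlapping == overlapping for ATG
    if windows == 0:
        return 0.0
    return matches / windows


def extract_features(
    ab: AnnotatedBin,
    hits: Iterable[HmmHit] = (),
    mode: str = "core3",
    threshold: float = SIGNIFICANCE_EVALUE,
) -> FeatureVector:
    """Assemble the per-bin feature vector.

    ``core3`` fills the three classifier features; ``extended6``
    additionally fills average gene length, average spacing and ATG
    frequency (left ``None`` and flagged when undefined, never silently
    zeroed).  A zero-gene bin yields the all-zero core vector with a
    ``zero_genes`` warning flag — every input bin must be classifiable.
    """
    if mode not in ("core3", "extended6"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = list(hits)
    warnings: list[str] = []
    if not ab.genes:
        warnings.append("zero_genes")
    vec = dict(
        gene_density=gene_density(ab),
        strand_shift_freq=strand_shift_frequency(ab),
        pvogs_frac=pvogs_fraction(ab, hits, threshold),
    )
    if mode == "extended6":
        try:
            vec["avg_gene_length"] = avg_gene_length(ab)
        except UndefinedFeatureError:
            warnings.append("avg_gene_length_undefined")
        try:
            vec["avg_spacing"] = avg_spacing(ab)
        except UndefinedFeatureError:
            warnings.append("avg_spacing_undefined")
        vec["atg_freq"] = atg_relative_frequency(ab)
    return FeatureVector(bin_id=ab.bin.id, warnings=tuple(warnings), **vec)


def feature_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    """Stack core feature vectors into an (n_bins, 3) matrix."""
    return np.vstack([v.core() for v in vectors]) if vectors else np.empty((0, 3))


def write_feature_tsv(vectors: Sequence[FeatureVector], path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_id\t" + "\t".join(CORE_FEATURE_NAMES) + "\n")
        for v in vectors:
            fh.write(
                f"{v.bin_id}\t{v.gene_density:.6f}\t{v.strand_shift_freq:.6f}\t"
                f"{v.pvogs_frac:.6f}\n"
            )
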