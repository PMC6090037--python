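"""Synthetic annotated genomes with controllable class-conditional features.

The generator emulates the statistical structure the classifier relies
on, not real sequence biology: a genome is a random DNA string with
planted, non-overlapping protein-coding genes whose density, coding-strand
arrangement and viral-profile hit fraction are drawn from per-class
distributions (truncated normals around the published class means).  Gene
bodies use valid start/stop codons with stop-free interiors so the
built-in ORF finder can recover them; hit E-values are two-point
(1e-20 / 1e-3), straddling the 1e-10 significance bound so the hit
fraction is exactly controllable.

What this does **not** emulate: realistic nucleotide composition, codon
usage, overlapping genes (an overlap-enabled mode exists for stress
tests) or sequence homology — conclusions from these fixtures concern the
pipeline's bookkeeping and the feature-space geometry, not real-genome
performance.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats_io import Bin, Contig, HmmHit, write_fasta
from .gene_calling import AnnotatedBin, GeneCall, reverse_complement
from .pvogs import HitTable, write_hit_table
from .simulation_benchmark import fragment_source_span

#: published training-set class means (+/- sd) for the three core features
PHAGE_PROFILE_PARAMS = dict(
    gene_density_mean=1.44, gene_density_sd=0.27,
    strand_shift_mean=0.07, strand_shift_sd=0.05,
    hit_frac_mean=0.68, hit_frac_sd=0.20,
)
BACTERIA_PROFILE_PARAMS = dict(
    gene_density_mean=0.93, gene_density_sd=0.13,
    strand_shift_mean=0.24, strand_shift_sd=0.08,
    hit_frac_mean=0.10, hit_frac_sd=0.04,
)

GENE_LEN_MIN = 120  # bp, matches the built-in finder's default min_len
GENE_LEN_MAX = 600  # bp; keeps high densities feasible on short genomes
MAX_CODING_FRACTION = 0.92

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in _STOPS
)
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ClassProfile:
    """Class-conditional feature distribution for genome generation."""

    label: str
    gene_density_mean: float
    gene_density_sd: float
    strand_shift_mean: float
    strand_shift_sd: float
    hit_frac_mean: float
    hit_frac_sd: float
    genome_length_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.gene_density_mean <= 0:
            raise ValueError("gene density mean must be positive")
        if not (0 <= self.strand_shift_mean <= 1 and 0 <= self.hit_frac_mean <= 1):
            raise ValueError("strand-shift and hit-fraction means must be in [0,1]")


#: desk-scale defaults; tailed-phage genomes are realistically 30-80 kbp,
#: the bacterial range is a compact stand-in (all three features are
#: length-normalised ratios, so genome length carries no class signal)
PHAGE_PROFILE = ClassProfile(
    label="phage", genome_length_range=(30_000, 80_000), **PHAGE_PROFILE_PARAMS
)
BACTERIA_PROFILE = ClassProfile(
    label="bacteria", genome_length_range=(80_000, 200_000), **BACTERIA_PROFILE_PARAMS
)


@dataclass(frozen=True)
class SyntheticGenome:
    """A planted genome: sequence, true gene calls, true hit table."""

    contig: Contig
    genes: tuple[GeneCall, ...]
    hits: HitTable
    label: str
    significant_ids: frozenset[str]

    def significant_spans(self) -> list[tuple[int, int, str]]:
        return [
            (g.start, g.end, g.strand)
            for g in self.genes
            if g.gene_id in self.significant_ids
        ]

    def annotated_bin(self) -> AnnotatedBin:
        """The genome as a single-contig bin with its planted annotation."""
        b = Bin(id=self.contig.id, contigs=(self.contig,))
        return AnnotatedBin(bin=b, genes=self.genes)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_genome(
    profile: ClassProfile,
    length: int,
    seed: int,
    genome_id: str | None = None,
    allow_overlap: bool = False,
) -> SyntheticGenome:
    """Generate one annotated genome from a class profile.

    Draws target density ``d`` (genes/kbp), strand-shift rate ``s`` and
    hit fraction ``p`` from the profile; plants ``floor(d*length/1000)``
    non-overlapping genes whose strands realise ``round(s*N)`` shifts and
    marks ``ceil(p*N)`` genes as significant (E = 1e-20; the rest get
    E = 1e-3).  Realised features are integer-exact functions of (N,
    shifts, n_sig).  Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    gid = genome_id or f"{profile.label}_g{seed}"
    d = _truncated_normal(rng, profile.gene_density_mean, profile.gene_density_sd,
                          0.05, 8.0)
    s = _truncated_normal(rng, profile.strand_shift_mean, profile.strand_shift_sd,
                          0.0, 1.0)
    p = _truncated_normal(rng, profile.hit_frac_mean, profile.hit_frac_sd, 0.0, 1.0)
    n_genes = int(d * length / 1000)

    budget = int(MAX_CODING_FRACTION * length)
    if n_genes * GENE_LEN_MIN > budget:
        raise ValueError(
            f"density {d:.2f}/kbp infeasible for {length} bp: "
            f"{n_genes} genes x {GENE_LEN_MIN} bp minimum exceeds "
            f"{MAX_CODING_FRACTION:.0%} of the genome"
        )
    if n_genes == 0:
        seq = "".join(rng.choice(list(_BASES), size=length))
        return SyntheticGenome(
            contig=Contig(gid, seq), genes=(), label=profile.label,
            hits=HitTable(hits=(), source="synthetic"), significant_ids=frozenset(),
        )

    # gene lengths: multiples of 3, mean capped so the total fits the budget
    upper = min(GENE_LEN_MAX, 2 * (budget // n_genes) - GENE_LEN_MIN)
    upper = max(GENE_LEN_MIN, upper - upper % 3)
    n_steps = (upper - GENE_LEN_MIN) // 3 + 1
    lengths = GENE_LEN_MIN + 3 * rng.integers(0, n_steps, size=n_genes)
    while lengths.sum() > budget:  # rare; shave the longest genes
        i = int(np.argmax(lengths))
        if lengths[i] <= GENE_LEN_MIN:
            break
        lengths[i] -= 3

    if allow_overlap:
        starts = np.sort(rng.integers(1, length - int(lengths.max()) + 1, size=n_genes))
    else:
        total_gap = length - int(lengths.sum())
        gaps = rng.multinomial(total_gap, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
        starts = np.empty(n_genes, dtype=np.int64)
        pos = 1
        for i in range(n_genes):
            pos += int(gaps[i])
            starts[i] = pos
            pos += int(lengths[i])

    # strands: first strand random, exactly round(s*N) shifts at random boundaries
    n_shifts = min(int(round(s * n_genes)), n_genes - 1)
    flip_at = set(
        rng.choice(n_genes - 1, size=n_shifts, replace=False).tolist()
    ) if n_shifts else set()
    strands = []
    cur = "+" if rng.integers(0, 2) == 0 else "-"
    for i in range(n_genes):
        strands.append(cur)
        if i in flip_at:
            cur = "+" if cur == "-" else "-"

    # sequence assembly: random intergenic bases, stop-free gene interiors
    base_arr = rng.choice(list(_BASES), size=length)
    seq = np.array(base_arr, dtype="U1")
    for st, ln, strand in zip(starts, lengths, strands):
        n_body = ln // 3 - 2
        body = "".join(rng.choice(_SENSE_CODONS, size=n_body)) if n_body > 0 else ""
        orf = "ATG" + body + str(rng.choice(_STOPS))
        if strand == "-":
            orf = reverse_complement(orf)
        seq[st - 1 : st - 1 + ln] = list(orf)
    sequence = "".join(seq)

    genes = tuple(
        GeneCall(f"{gid}_{i + 1}", gid, int(st), int(st + ln - 1), strand)
        for i, (st, ln, strand) in enumerate(zip(starts, lengths, strands))
    )
    n_sig = min(int(np.ceil(p * n_genes)), n_genes)
    sig_idx = rng.choice(n_genes, size=n_sig, replace=False)
    sig_ids = frozenset(genes[int(i)].gene_id for i in sig_idx)
    hits = HitTable(
        hits=tuple(
            HmmHit(g.gene_id, f"VOG{(i % 97) + 1:04d}",
                   1e-20 if g.gene_id in sig_ids else 1e-3, 150.0)
            for i, g in enumerate(genes)
        ),
        source="synthetic",
    )
    return SyntheticGenome(
        contig=Contig(gid, sequence), genes=genes, hits=hits,
        label=profile.label, significant_ids=sig_ids,
    )


def generate_class_pool(
    profile: ClassProfile, n: int, seed: int, id_prefix: str | None = None
) -> list[SyntheticGenome]:
    """Generate ``n`` genomes from one class profile (lengths uniform in range)."""
    ss = np.random.SeedSequence(seed).spawn(n)
    rng = np.random.default_rng(seed)
    lo, hi = profile.genome_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    prefix = id_prefix or profile.label
    return [
        generate_genome(
            profile, int(lengths[i]),
            seed=int(np.random.default_rng(ss[i]).integers(0, 2**31 - 1)),
            genome_id=f"{prefix}_{i + 1:04d}",
        )
        for i in range(n)
    ]


def simulate_fragment_hits(
    ab: AnnotatedBin,
    genomes: Mapping[str, SyntheticGenome],
    fragment_length: int,
    min_overlap: int = 60,
) -> HitTable:
    """Synthetic stand-in for a profile search over fragment gene calls.

    A called gene receives a significant hit (E = 1e-20) when, mapped back
    onto its source genome, it overlaps a planted significant gene by at
    least ``min_overlap`` bp on the same strand and in the same reading
    frame — the conditions under which the real translated protein would
    match the planted gene's profile.
    """
    rows: list[HmmHit] = []
    span_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for g in ab.genes:
        genome_id, fs, _ = fragment_source_span(g.contig_id, fragment_length)
        genome = genomes[genome_id]
        if genome_id not in span_cache:
            spans = genome.significant_spans()
            span_cache[genome_id] = (
                np.array([s for s, _, _ in spans], dtype=np.int64),
                np.array([e for _, e, _ in spans], dtype=np.int64),
                np.array([1 if st == "+" else -1 for _, _, st in spans], dtype=np.int8),
                np.arange(len(spans)),
            )
        sig_s, sig_e, sig_st, _ = span_cache[genome_id]
        if sig_s.size == 0:
            continue
        gs = fs + g.start - 1
        ge = fs + g.end - 1
        overlap = np.minimum(ge, sig_e) - np.maximum(gs, sig_s) + 1
        strand_ok = sig_st == (1 if g.strand == "+" else -1)
        # frame congruence: plus-strand frames share start mod 3, minus share end mod 3
        frame_ok = np.where(
            sig_st == 1, (sig_s - gs) % 3 == 0, (sig_e - ge) % 3 == 0
        )
        if bool(np.any((overlap >= min_overlap) & strand_ok & frame_ok)):
            rows.append(HmmHit(g.gene_id, "VOGSIM", 1e-20, 150.0))
    return HitTable(hits=tuple(rows), source="synthetic")


def write_fixture_tree(genomes: Sequence[SyntheticGenome], out_dir: str | Path) -> Path:
    """Write genomes as FASTA + gene-call TSV + hit TSV + label TSV."""
    out_dir = Path(out_dir)
    fasta_dir = out_dir / "genomes"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "gene_calls.tsv", "w") as gc, \
         open(out_dir / "labels.tsv", "w") as lab:
        gc.write("gene_id\tcontig_id\tstart\tend\tstrand\n")
        lab.write("genome_id\tlabel\n")
        all_hits: list[HmmHit] = []
        for g in genomes:
            write_fasta([g.contig], fasta_dir / f"{g.contig.id}.fasta")
            lab.write(f"{g.contig.id}\t{g.label}\n")
            for call in g.genes:
                gc.write(
                    f"{call.gene_id}\t{call.contig_id}\t{call.start}\t"
                    f"{call.end}\t{call.strand}\n"
                )
            all_hits.extend(g.hits.hits)
    write_hit_table(HitTable(hits=tuple(all_hits), source="synthetic"),
                    out_dir / "hits.tsv")
    return out_dir


def generate_toy_profile_db(
    n_profiles: int, seed: int, out_dir: str | Path,
    protein_length: int = 80, n_seqs: int = 6, mutation_rate: float = 0.08,
) -> tuple[Path, dict[str, str]]:
    """Build a tiny pressed profile-HMM database plus cognate proteins.

    Each profile is built (``hmmbuild``) from an alignment of mutated
    copies of a random master protein; the master itself is returned as
    the cognate query that should hit its own profile strongly.  Requires
    the HMMER build tools on PATH.
    """
    for tool in ("hmmbuild", "hmmpress"):
        if shutil.which(tool) is None:
            raise RuntimeError(f"required build tool {tool!r} not found on PATH")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    aas = list(_AMINO_ACIDS)
    proteins: dict[str, str] = {}
    hmm_paths = []
    for i in range(n_profiles):
        master = "".join(rng.choice(aas, size=protein_length))
        proteins[f"prot{i + 1}"] = master
        msa = out_dir / f"profile{i + 1}.afa"
        with open(msa, "w") as fh:
            for j in range(n_seqs):
                seq = list(master)
                n_mut = rng.binomial(protein_length, mutation_rate)
                for pos in rng.choice(protein_length, size=n_mut, replace=False):
                    seq[pos] = str(rng.choice(aas))
                fh.write(f">profile{i + 1}_seq{j + 1}\n{''.join(seq)}\n")
        hmm = out_dir / f"profile{i + 1}.hmm"
        subprocess.run(
            ["hmmbuild", "--amino", "-n", f"profile{i + 1}", str(hmm), str(msa)],
            check=True, capture_output=True,
        )
        hmm_paths.append(hmm)
    db = out_dir / "toydb.hmm"
    with open(db, "w") as fh:
        for h in hmm_paths:
            fh.write(h.read_text())
    subprocess.run(["hmmpress", "-f", str(db)], check=True, capture_output=True)
    return db, proteins
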