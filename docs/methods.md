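# Methods

## Model

A bin is a set of contigs treated as one putative genome. Each bin is
reduced to a three-component signature computed as *pooled* ratios over
all its contigs (never per-contig averages):

* gene density `d = N_CDS / (L / 1000)` where `L` is the bin's total
  length in bp;
* strand-shift frequency `s = (Σ within-contig neighbour pairs with
  different strands) / N_CDS`. Neighbours are consecutive genes in the
  canonical order (contig, start, end, `+` before `-`); pairs spanning
  a contig boundary are never counted, because contig adjacency inside
  a bin is arbitrary. Note the denominator is the gene count, not the
  pair count, so `k` alternating genes on one contig give `(k−1)/k`.
* pVOGs fraction `p = |{genes with ≥ 1 profile hit at E ≤ 10⁻¹⁰}| /
  N_CDS`. The bound is inclusive and uses the search engine's
  full-sequence E-value; a gene counts once however many profiles it
  matches.

Classification is a random forest of 50 CART trees (scikit-learn) with
`min_samples_leaf=2` as the leaf-pruning regulariser and all other
parameters at their defaults. Feature importances are normalised mean
impurity decrease, which approximates information-gain weighting; the
trees are CART rather than literal ID3. The phage probability of a bin
is the fraction of trees voting phage; the default decision threshold
is 0.5 and is stored in the model archive. Evaluation uses stratified
k-fold cross-validation (default k = 20) and, for simulated-bin
designs, TPR/SPC/ACC/F1 with phage as the positive class, aggregated
as mean ± sd over replicates; paired tool comparisons use the
two-sided Wilcoxon signed-rank test with zero differences discarded and
the exact null distribution for n ≤ 25 non-zero pairs.

Three further features (mean CDS length, mean intergenic gap, ATG
relative frequency) are computed in `extended6` mode for inspection
only; they carry less class information and are not fed to the
classifier. The intergenic gap `start_next − end_prev − 1` may be
negative for overlapping genes and is deliberately not clamped.
ATG frequency counts overlapping ATG windows on the forward strand of
each contig as stored (the strand choice is arbitrary for a 3-mer
statistic and is recorded on the vector); windows containing N never
match.

## Gene calling

Features are defined on predicted CDSs, not on a particular caller.
Two backends exist:

* **builtin** — a deterministic six-frame ORF finder. In every frame,
  for each in-frame stop codon, it reports the span from the most
  upstream in-frame start codon after the previous stop through that
  stop codon (stop included, so spans are multiples of 3). Defaults:
  start codons {ATG, GTG, TTG}, stops {TAA, TAG, TGA}, minimum length
  120 bp — below that, chance ORFs on random sequence dominate and
  destabilise the density features. No overlap resolution is done
  across frames. The finder makes no claim of matching Prodigal's
  scoring model; it exists so that nothing in the package requires an
  external binary, and it is strand-symmetric by construction.
* **external** — a command template (default
  `prodigal -p meta -f gff -i {input} -o {output} -q`) whose GFF-like
  output is converted to the internal 1-based inclusive coordinate
  convention. `auto` picks external when the executable resolves,
  builtin otherwise, and logs the choice. Prodigal's single-versus-
  metagenomic mode is a pass-through in the template rather than fixed
  here, since short fragments and whole genomes warrant different
  choices.

Internal coordinates are 1-based and inclusive at both ends (the
GenBank convention); compound (join) GenBank locations collapse to
their outer span, which is sufficient because all features depend only
on span, order, and strand. CDS length includes the stop codon, a ±3
bp-per-gene convention that only matters for the excluded mean-length
feature. Non-ACGT input characters normalise to N; N codons translate
to X, and ATG windows containing N never match.

## Profile hits

Real searches run `hmmscan --tblout` against a pressed profile-HMM
database and parse the target-per-line tabular output (column mapping
configurable for `hmmsearch`-style output). Duplicate (gene, profile)
rows keep the smallest E-value — a reduction that can never change
which genes are significant. A precomputed TSV path
(`gene_id  profile_id  evalue  bitscore`) makes the pipeline runnable
without the engine or the database, which is never bundled; a
three-profile toy database built at test time with `hmmbuild`/`hmmpress`
covers the engine path in integration tests.

## Simulated-bin benchmark

A simulated bin is built by excising 10 substrings of exactly the
requested length (reference lengths 2, 4, 8, 12, 16 kbp) from one
complete genome at uniformly random start positions, drawn with
replacement, so fragments may overlap; fragments are taken from the
forward strand only, since strandedness enters the features only
through gene calls. Genomes shorter than the fragment length are
excluded with a logged count. Replicated designs sample `n` genomes
per class without replacement within each replicate and independently
across replicates (the between-replicate convention is not dictated by
the protocol; independent sampling is this package's choice), with all
replicate and fragmentation seeds derived deterministically from one
master seed. The reference designs are 5 replicates of 75+75 bins and
30 replicates of 50+50.

Fragment contig ids encode their source genome and offset, which lets
the synthetic hit oracle (below) map called genes back onto the genome.

## Synthetic genomes

The generator plants what the classifier assumes: a genome of length
`L` draws a target density `d`, shift rate `s` and hit fraction `p`
from truncated normal distributions whose means/sds default to the
published per-class training-set moments (phage 1.44±0.27 genes/kbp,
0.07±0.05, 0.68±0.2; bacteria 0.93±0.13, 0.24±0.08, 0.1±0.04). It then
places `⌊d·L/1000⌋` non-overlapping genes (ATG start, stop-free
interior, random stop; lengths uniform in 120–600 bp in steps of 3,
capped so total coding stays under 92% of the genome), arranges
strands to realise exactly `round(s·N)` shifts at random boundaries,
and marks `⌈p·N⌉` genes as significant with two-point hit E-values
(1e-20 significant / 1e-3 not), straddling the 1e-10 bound. Realised
features are therefore integer-exact functions of (N, shifts, n_sig),
which the oracle tests exploit. Gene placement is non-overlapping by
default for exactly that reason; an overlap-enabled mode exists for
stress tests.

Genome length ranges default to 30–80 kbp for phage (realistic for
tailed phages) and 80–200 kbp for bacteria. The bacterial range is a
compact stand-in for megabase genomes: all three features are
length-normalised ratios and the classifier only ever sees fixed-length
fragments, so genome length carries no class signal, and the range
choice only controls simulation cost.

When fragment bins are re-annotated with the builtin finder, hits for
the called genes come from a synthetic oracle standing in for the
profile search: a called gene receives a significant hit iff, mapped
back to genome coordinates, it overlaps a planted significant gene by
≥ 60 bp on the same strand and in the same reading frame — the
conditions under which the translated protein would actually contain
the planted gene's sequence.

**What the fixtures do not emulate** — and hence what passing tests do
not show about real data: realistic nucleotide composition and codon
usage (intergenic sequence is i.i.d. uniform, so the builtin finder
also emits chance ORFs at a higher rate than a trained caller would on
real sequence; these affect both classes and are part of the pipeline's
operating conditions in the benchmark), overlapping genes, sequence
homology between genomes, chimeric bins, and the content of the real
pVOGs database. Benchmark numbers on synthetic data characterise the
pipeline's statistical machinery, not field performance; the published
full-scale results additionally depend on the frozen RefSeq genome
sets and the 2018 pVOGs snapshot, which are not bundled.

## Problem sizes and numerical choices

The default desk-scale benchmark (also what `scripts/acceptance.py`
runs) uses 200 training genomes per class, a held-out pool of 150 per
class, and 5 evaluation replicates of 75+75 bins at 8 kbp — chosen as
the smallest design that reproduces the protocol's replicate structure
with stable means. Feature-mean recovery uses 100 genomes per class.

Degenerate inputs are defined, not fatal: a zero-gene bin gets the
all-zero core vector plus a `zero_genes` warning flag (every input bin
must receive a prediction); mean gene length and spacing are undefined
without genes/pairs and raise in isolation but are flagged-`None` in
`extended6` vectors. Undefined benchmark metrics (zero denominators)
raise by default and become NaN only in fold aggregation. Gene-order
ties break by (start, end, `+` before `-`) so strand-shift counting is
deterministic. Random draws all flow from `numpy` `SeedSequence`
spawning, making every seeded entry point bitwise reproducible; model
archives carry a schema version and refuse to load on mismatch.

## Known limitations

Bins of very short contigs (≲ 2 kbp) carry few or no CDSs, degrading
all three features — the published protocol observes the same floor.
The builtin ORF finder over-calls on random-composition sequence;
training and prediction must therefore use the same gene-calling
backend, and models are not transferable between backends. Probability
calibration, alternative learners, and k-mer/GC composition features
are out of scope.
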