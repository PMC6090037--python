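"""Simulated-bin benchmarking: fragmentation, replicate designs, metrics.

A simulated bin stands in for a real metagenomic bin of known origin: a
complete genome is fragmented into 10 contigs of a fixed length (2, 4, 8,
12 or 16 kbp in the reference design) drawn at uniformly random start
positions, with replacement, so fragments may overlap.  Bins are scored
with phage as the positive class:

    TPR = TP/(TP+FN)   SPC = TN/(TN+FP)
    ACC = (TP+TN)/(TP+FP+TN+FN)   F1 = 2TP/(2TP+FP+FN)

Replicated designs (e.g. 5 replicates of 75+75 bins, or 30 of 50+50) are
aggregated as mean +/- sd per metric, and paired tool comparisons use the
two-sided Wilcoxon signed-rank test (zero differences discarded; exact
null distribution for n <= 25).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .classifier import BACTERIA, PHAGE, Prediction
from .formats_io import Bin, Contig

logger = logging.getLogger(__name__)

FRAGMENTS_PER_BIN = 10
REFERENCE_FRAGMENT_LENGTHS = (2000, 4000, 8000, 12000, 16000)

METRIC_NAMES = ("TPR", "SPC", "ACC", "F1")


class DesignError(ValueError):
    """A replicate design cannot be built from the available genomes."""


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has a zero denominator."""


@dataclass(frozen=True)
class FragmentSpec:
    n_fragments: int = FRAGMENTS_PER_BIN
    fragment_length: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 1 or self.fragment_length < 1:
            raise ValueError("n_fragments and fragment_length must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Metrics:
    TPR: float
    SPC: float
    ACC: float
    F1: float


def fragment_genome(genome: Contig, spec: FragmentSpec) -> Bin:
    """Excise ``n_fragments`` substrings of exactly ``fragment_length`` bp.

    Start positions are uniform over the genome, drawn with replacement
    (overlaps allowed); fragments are taken from the forward strand.
    Contig ids encode the source offset (``<genome>_f<i>_<start>``, start
    1-based) so synthetic hit oracles can map calls back onto the genome.
    """
    L = genome.length
    if L < spec.fragment_length:
        raise DesignError(
            f"genome {genome.id} ({L} bp) shorter than fragment length "
            f"{spec.fragment_length} bp"
        )
    rng = np.random.default_rng(spec.seed)
    starts = rng.integers(0, L - spec.fragment_length + 1, size=spec.n_fragments)
    contigs = tuple(
        Contig(
            id=f"{genome.id}_f{i + 1}_{int(s) + 1}",
            sequence=genome.sequence[int(s) : int(s) + spec.fragment_length],
        )
        for i, s in enumerate(starts)
    )
    return Bin(id=f"{genome.id}_bin", contigs=contigs)


def fragment_source_span(contig_id: str, fragment_length: int) -> tuple[str, int, int]:
    """Invert the fragment id convention: (genome_id, start, end), 1-based."""
    stem, _, start = contig_id.rpartition("_")
    genome_id, _, _ = stem.rpartition("_f")
    s = int(start)
    return genome_id, s, s + fragment_length - 1


def build_design(
    genomes: Mapping[str, Sequence[Contig]],
    spec: FragmentSpec,
    n_per_class: int,
    n_replicates: int,
    seed: int = 0,
) -> list[list[tuple[Bin, str]]]:
    """Build a replicated simulated-bin design.

    ``genomes`` maps class label (``phage``/``bacteria``) to its genome
    pool.  Per replicate, ``n_per_class`` genomes are sampled per class
    without replacement (independently across replicates), each
    fragmented into one bin.  Genomes shorter than the fragment length
    are excluded up front with a logged count.  Returns, per replicate, a
    list of ``(bin, true_label)`` pairs.  Fully determined by ``seed``.
    """
    eligible: dict[str, list[Contig]] = {}
    for label, pool in genomes.items():
        ok = [g for g in pool if g.length >= spec.fragment_length]
        excluded = len(pool) - len(ok)
        if excluded:
            logger.warning(
                "%s: excluded %d genome(s) shorter than %d bp",
                label, excluded, spec.fragment_length,
            )
        if len(ok) < n_per_class:
            raise DesignError(
                f"class {label!r} has {len(ok)} eligible genomes, "
                f"needs {n_per_class}"
            )
        eligible[label] = ok

    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    design = []
    for rep, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        replicate: list[tuple[Bin, str]] = []
        for label in sorted(eligible):
            pool = eligible[label]
            idx = rng.choice(len(pool), size=n_per_class, replace=False)
            for j in idx:
                frag_seed = int(rng.integers(0, 2**31 - 1))
                b = fragment_genome(
                    pool[int(j)],
                    FragmentSpec(spec.n_fragments, spec.fragment_length, frag_seed),
                )
                b = Bin(id=f"r{rep + 1}_{b.id}", contigs=b.contigs)
                replicate.append((b, label))
        design.append(replicate)
    return design


def score(confusion: ConfusionCounts, allow_undefined: bool = False) -> Metrics:
    """The four benchmark metrics from a confusion table (phage positive).

    A zero denominator raises :class:`UndefinedMetricError` naming the
    metric, or yields NaN when ``allow_undefined`` is set (used for
    aggregate reporting over small folds).
    """
    tp, fp, tn, fn = confusion.TP, confusion.FP, confusion.TN, confusion.FN

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            if allow_undefined:
                return math.nan
            raise UndefinedMetricError(f"{name} undefined: zero denominator")
        return num / den

    return Metrics(
        TPR=ratio(tp, tp + fn, "TPR"),
        SPC=ratio(tn, tn + fp, "SPC"),
        ACC=ratio(tp + tn, confusion.total, "ACC"),
        F1=ratio(2 * tp, 2 * tp + fp + fn, "F1"),
    )


def confusion_from_predictions(
    predictions: Iterable[Prediction], truths: Mapping[str, str]
) -> ConfusionCounts:
    """Tally a confusion table; phage is the positive class."""
    tp = fp = tn = fn = 0
    seen = set()
    for p in predictions:
        if p.bin_id not in truths:
            raise KeyError(f"prediction for unknown bin {p.bin_id!r}")
        seen.add(p.bin_id)
        truth = truths[p.bin_id]
        if truth == PHAGE:
            if p.label == PHAGE:
                tp += 1
            else:
                fn += 1
        else:
            if p.label == PHAGE:
                fp += 1
            else:
                tn += 1
    missing = set(truths) - seen
    if missing:
        raise KeyError(f"missing prediction for bin(s): {sorted(missing)[:5]}")
    return ConfusionCounts(tp, fp, tn, fn)


def evaluate_replicates(
    predictions_per_replicate: Sequence[Iterable[Prediction]],
    truths_per_replicate: Sequence[Mapping[str, str]],
) -> dict:
    """Score each replicate and aggregate as mean +/- sd per metric."""
    if len(predictions_per_replicate) != len(truths_per_replicate):
        raise ValueError("predictions and truths must have equal replicate counts")
    per_rep = [
        score(confusion_from_predictions(preds, truths))
        for preds, truths in zip(predictions_per_replicate, truths_per_replicate)
    ]
    if len(per_rep) == 1:
        logger.warning("single replicate: standard deviations reported as 0")
    agg = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_rep], dtype=float)
        agg[name] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    return {"replicates": per_rep, "aggregate": agg}


def paired_compare(series_a: Sequence[float], series_b: Sequence[float]) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired metric series.

    Zero differences are discarded; with n <= 25 non-zero untied
    differences the exact null distribution is used.  If every
    difference is zero there is nothing to test and p = 1 is reported
    with a ``no_test`` flag.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be equal-length 1-D")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n_used": 0, "no_test": True}
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", alternative="two-sided", method=method
    )
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_used": int(nonzero.size),
        "no_test": False,
    }


def featurize_synthetic_bins(
    bins: Sequence[Bin],
    genomes: Mapping[str, object],
    fragment_length: int,
    min_len: int = 120,
):
    """Annotate fragment bins with the built-in finder and featurize them.

    Hits come from the synthetic fragment-hit oracle, which plays the
    role of the profile search on fragment proteins.  Returns one
    :class:`~phagebin.features.FeatureVector` per bin.
    """
    from .features import extract_features
    from .gene_calling import annotate_bin
    from .synthetic_fixtures import simulate_fragment_hits

    vectors = []
    for b in bins:
        ab = annotate_bin(b, backend="builtin", min_len=min_len)
        ht = simulate_fragment_hits(ab, genomes, fragment_length)
        vectors.append(extract_features(ab, ht.hits))
    return vectors


def run_synthetic_benchmark(
    fragment_length: int = 8000,
    n_train_per_class: int = 200,
    n_test_pool: int = 150,
    n_per_class: int = 75,
    n_replicates: int = 5,
    seed: int = 0,
    n_trees: int = 50,
    leaf_min: int = 2,
    min_len: int = 120,
) -> dict:
    """End-to-end simulated-bin benchmark on synthetic genomes.

    Disjoint training and test genome pools are generated per class,
    fragmented into bins (10 contigs of ``fragment_length`` bp), gene-
    called, featurized and classified; test replicates are class-balanced
    samples from the held-out pool.  Returns the trained model, the
    training matrix, per-replicate metrics and their aggregate.
    """
    from .classifier import predict, train
    from .features import feature_matrix
    from .synthetic_fixtures import (
        BACTERIA_PROFILE, PHAGE_PROFILE, generate_class_pool,
    )

    seeds = np.random.SeedSequence(seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    pools = {
        "train": {
            PHAGE: generate_class_pool(PHAGE_PROFILE, n_train_per_class, sub[0],
                                       id_prefix="tr_phage"),
            BACTERIA: generate_class_pool(BACTERIA_PROFILE, n_train_per_class, sub[1],
                                          id_prefix="tr_bact"),
        },
        "test": {
            PHAGE: generate_class_pool(PHAGE_PROFILE, n_test_pool, sub[2],
                                       id_prefix="te_phage"),
            BACTERIA: generate_class_pool(BACTERIA_PROFILE, n_test_pool, sub[3],
                                          id_prefix="te_bact"),
        },
    }
    lookup = {
        g.contig.id: g
        for split in pools.values() for pool in split.values() for g in pool
    }

    # one training bin per training genome
    rng = np.random.default_rng(sub[4])
    train_bins, train_labels = [], []
    for label, pool in sorted(pools["train"].items()):
        for g in pool:
            spec = FragmentSpec(FRAGMENTS_PER_BIN, fragment_length,
                                int(rng.integers(0, 2**31 - 1)))
            train_bins.append(fragment_genome(g.contig, spec))
            train_labels.append(label)
    train_vectors = featurize_synthetic_bins(
        train_bins, lookup, fragment_length, min_len=min_len
    )
    X = feature_matrix(train_vectors)
    model = train(X, train_labels, n_trees=n_trees, seed=sub[5], leaf_min=leaf_min)

    test_genomes = {
        label: [g.contig for g in pool] for label, pool in pools["test"].items()
    }
    design = build_design(
        test_genomes,
        FragmentSpec(FRAGMENTS_PER_BIN, fragment_length, 0),
        n_per_class=n_per_class,
        n_replicates=n_replicates,
        seed=seed,
    )
    preds_per_rep, truths_per_rep = [], []
    for replicate in design:
        bins = [b for b, _ in replicate]
        truths = {b.id: label for b, label in replicate}
        vectors = featurize_synthetic_bins(bins, lookup, fragment_length,
                                           min_len=min_len)
        preds = predict(model, feature_matrix(vectors), bin_ids=[b.id for b in bins])
        preds_per_rep.append(preds)
        truths_per_rep.append(truths)
    result = evaluate_replicates(preds_per_rep, truths_per_rep)
    result.update(
        model=model,
        training_matrix=X,
        training_labels=train_labels,
        fragment_length=fragment_length,
    )
    return result
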