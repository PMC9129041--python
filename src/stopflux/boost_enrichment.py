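"""Trinucleotide deviations from mutational equilibrium and the fixation boost.

For each trinucleotide, D = (O - E)/E compares its observed frequency in a
sequence set against the mutational-null expectation built from the
GC-matched de novo mutation bin. D1 is measured in the top-20%-GC sequence
set, D2 in the bottom-20% set, and the GC-coupled fixation boost is the
second-order deviation (D1 - D2)/D2. Because the literal formula flips
orientation when D2 < 0, the difference D1 - D2 and the |D2|-denominator
variant are always co-reported, never silently substituted.

Also here: within-GC-class boost rankings and their cross-sequence-class
correlations, the sense/antisense permutation test, the focal-stop
enrichment statistic (focal usage over mean usage at downstream in-frame
positions +1..+6) and the protein-abundance expression partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._encoding import STOPS, TRINUC_INDEX, TRINUCS, revcomp
from .genome_io import GeneRecord, TrinucleotideProfile

log = logging.getLogger(__name__)

#: GC class of each trinucleotide: 100 * (#G + #C) / 3, labelled {0, 33, 66, 100}.
_GC_LABEL = {0: 0, 1: 33, 2: 66, 3: 100}
GC_CLASS = {t: _GC_LABEL[sum(b in "GC" for b in t)] for t in TRINUCS}
GC_CLASSES = (0, 33, 66, 100)


@dataclass
class BoostRecord:
    trinucleotide: str
    d1: float  # (O-E)/E in the top-20%-GC sequence set
    d2: float  # (O-E)/E in the bottom-20%-GC set
    boost: float | None  # (d1-d2)/d2, literal
    diff: float  # d1 - d2
    boost_abs: float | None  # (d1-d2)/|d2|
    gc_class: int
    sequence_class: str = "CDS"
    rank: float | None = None  # within-GC-class rank by boost


@dataclass
class EnrichmentRecord:
    stop: str
    usage_focal: float
    usage_downstream: float  # mean over downstream positions +1..+6
    enrichment: float


def deviation_D(observed: TrinucleotideProfile | np.ndarray,
                expected: TrinucleotideProfile | np.ndarray) -> dict[str, float]:
    """(O - E)/E per trinucleotide; trinucleotides with E = 0 are absent."""
    O = observed.frequencies if isinstance(observed, TrinucleotideProfile) else np.asarray(observed, float)
    E = expected.frequencies if isinstance(expected, TrinucleotideProfile) else np.asarray(expected, float)
    out = {}
    skipped = []
    for i, t in enumerate(TRINUCS):
        if E[i] > 0:
            out[t] = float((O[i] - E[i]) / E[i])
        else:
            skipped.append(t)
    if skipped:
        log.info("deviation_D skipped %d trinucleotides with zero expectation: %s",
                 len(skipped), skipped)
    return out


def boost(d1: float, d2: float) -> tuple[float | None, float, float | None]:
    """(literal boost, d1-d2, |d2|-denominator variant).

    d2 = 0 yields boost 0 when d1 = 0, else None with a warning.
    """
    diff = d1 - d2
    if d2 == 0:
        if d1 == 0:
            return 0.0, 0.0, 0.0
        warnings.warn("boost undefined: d2 = 0 with d1 != 0")
        return None, diff, None
    return diff / d2, diff, diff / abs(d2)


def boost_table(observed_top, expected_top, observed_bottom, expected_bottom,
                sequence_class: str = "CDS") -> list[BoostRecord]:
    """Per-trinucleotide D1, D2 and boost with within-GC-class ranks."""
    d1 = deviation_D(observed_top, expected_top)
    d2 = deviation_D(observed_bottom, expected_bottom)
    records = []
    for t in TRINUCS:
        if t not in d1 or t not in d2:
            continue
        b, diff, b_abs = boost(d1[t], d2[t])
        records.append(BoostRecord(t, d1[t], d2[t], b, diff, b_abs,
                                   GC_CLASS[t], sequence_class))
    # rank within GC class by literal boost (ties mid-ranked)
    for gc in GC_CLASSES:
        members = [r for r in records if r.gc_class == gc and r.boost is not None]
        ranks = pd.Series([r.boost for r in members]).rank(method="average")
        for r, rank in zip(members, ranks):
            r.rank = float(rank)
    return records


def class_rank_correlation(boosts_by_class: dict[str, list[BoostRecord]]) -> pd.DataFrame:
    """Pearson correlation of within-GC-class boost ranks between sequence classes.

    ``boosts_by_class`` maps sequence class -> BoostRecords (64 each).
    Absent boosts reduce each pair to its complete cases. Returns a long
    DataFrame with columns gc_class, class_a, class_b, r, p, n.
    """
    rows = []
    names = sorted(boosts_by_class)
    for gc in GC_CLASSES:
        vectors = {}
        for name in names:
            vectors[name] = {
                r.trinucleotide: r.rank
                for r in boosts_by_class[name]
                if r.gc_class == gc and r.rank is not None
            }
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                shared = sorted(set(vectors[a]) & set(vectors[b]))
                if len(shared) < 3:
                    continue
                va = [vectors[a][t] for t in shared]
                vb = [vectors[b][t] for t in shared]
                r, p = pearsonr(va, vb)
                rows.append({"gc_class": gc, "class_a": a, "class_b": b,
                             "r": float(r), "p": float(p), "n": len(shared)})
    return pd.DataFrame(rows)


def sense_antisense_test(boosts: dict[str, float], permutations: int = 1000,
                         seed: int = 0) -> tuple[float, float]:
    """Permutation test: are reverse-complement pairs more similar than chance?

    The statistic is the mean |boost(t) - boost(revcomp(t))| over the 32
    reverse-complement pairs. The null re-pairs trinucleotides at random
    strictly within each GC class (reverse complementation preserves GC
    class). Returns (observed statistic, p), p being the fraction of
    permutations with a statistic <= observed.
    """
    pairs = []
    seen = set()
    for t in TRINUCS:
        rc = revcomp(t)
        if t in seen or rc in seen:
            continue
        if t not in boosts or rc not in boosts:
            continue
        seen.update((t, rc))
        pairs.append((t, rc))
    if not pairs:
        raise ValueError("no reverse-complement pairs with defined boosts")
    observed = float(np.mean([abs(boosts[a] - boosts[b]) for a, b in pairs]))

    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for t in boosts:
        by_class.setdefault(GC_CLASS[t], []).append(t)
    count = 0
    for _ in range(permutations):
        stat_terms = []
        for gc, members in by_class.items():
            perm = rng.permutation(members)
            for i in range(0, len(perm) - 1, 2):
                stat_terms.append(abs(boosts[perm[i]] - boosts[perm[i + 1]]))
        if float(np.mean(stat_terms)) <= observed:
            count += 1
    return observed, count / permutations


def gc_partition_boost(sequences, mutations, reference, top: float = 0.2,
                       bottom: float = 0.2, sequence_class: str = "CDS",
                       window: int = 10000) -> list[BoostRecord]:
    """Full D1/D2/boost analysis for one sequence class.

    ``sequences`` are the class's nucleotide strings (e.g. all introns);
    they are ranked by G+C and the top/bottom fractions give the observed
    GC-rich and GC-poor trinucleotide profiles. ``mutations`` (with
    local_gc set) are ranked the same way; each tail's dinucleotide
    mutation matrix - exposure taken from its own 10 kb windows - yields a
    stationary dinucleotide distribution whose first-order Markov chain
    provides the closed-form expected trinucleotide frequencies.
    """
    from . import markov_null, mut_equilibrium
    from ._encoding import gc_fraction
    from .genome_io import trinuc_profile

    seqs = [(s, gc_fraction(s)) for s in sequences if gc_fraction(s) is not None]
    seqs.sort(key=lambda x: x[1])
    n = len(seqs)
    if n < 5:
        raise ValueError("need at least 5 sequences to take 20% tails")
    bottom_seqs = [s for s, _ in seqs[: max(1, int(n * bottom))]]
    top_seqs = [s for s, _ in seqs[n - max(1, int(n * top)):]]

    muts = sorted((m for m in mutations if m.local_gc is not None), key=lambda m: m.local_gc)
    k = len(muts)
    mut_bottom = muts[: max(1, int(k * bottom))]
    mut_top = muts[k - max(1, int(k * top)):]

    def expectation(mut_bin):
        region = mut_equilibrium._window_union(mut_bin, reference, window)
        mat = mut_equilibrium.build_dinuc_matrix(mut_bin, reference, region)
        stationary = mut_equilibrium.solve_stationary(mat.rates)
        return markov_null.closed_form_trinuc(markov_null.markov_from_dinuc(stationary))

    return boost_table(
        trinuc_profile(top_seqs), expectation(mut_top),
        trinuc_profile(bottom_seqs), expectation(mut_bottom),
        sequence_class=sequence_class,
    )


def stop_enrichment(genes: list[GeneRecord], stop: str, positions: int = 6) -> EnrichmentRecord:
    """Focal stop usage over mean downstream stop-trinucleotide usage.

    Downstream codon position +k is the k-th in-frame codon of the 3' UTR
    (the frame continuing from the terminator). Usage at a position is the
    relative frequency of ``stop`` among genes carrying any of TAA/TGA/TAG
    at that position; positions with no stop trinucleotide in a gene do not
    contribute (conditional usage, so the three usages sum to 1 per
    position).
    """
    if stop not in STOPS:
        raise ValueError(f"stop must be one of {STOPS}")
    focal_counts = {s: 0 for s in STOPS}
    down_counts = [dict.fromkeys(STOPS, 0) for _ in range(positions)]
    for g in genes:
        focal_counts[g.stop] = focal_counts.get(g.stop, 0) + 1
        for k in range(positions):
            codon = g.utr3[3 * k : 3 * k + 3]
            if codon in STOPS:
                down_counts[k][codon] += 1
    total_focal = sum(focal_counts.values())
    if total_focal == 0:
        raise ValueError("no genes with focal stops")
    usage_focal = focal_counts[stop] / total_focal
    down_usages = []
    for k in range(positions):
        total = sum(down_counts[k].values())
        if total > 0:
            down_usages.append(down_counts[k][stop] / total)
    if not down_usages:
        raise ValueError("no downstream stop trinucleotides at any position")
    usage_down = float(np.mean(down_usages))
    if usage_down == 0:
        raise ValueError(f"downstream usage of {stop} is zero; enrichment undefined")
    return EnrichmentRecord(stop=stop, usage_focal=usage_focal,
                            usage_downstream=usage_down,
                            enrichment=usage_focal / usage_down)


def expression_partition(genes: list[GeneRecord], quantile: float = 0.25):
    """(LEGs, HEGs): lowest and highest ``quantile`` of genes by abundance.

    Ties are broken by gene id so the partition is deterministic. Requires
    at least 8 genes with an abundance value.
    """
    with_ab = [g for g in genes if g.abundance is not None]
    if len(with_ab) < 8:
        raise ValueError("need at least 8 genes with abundance")
    with_ab.sort(key=lambda g: (g.abundance, g.gene_id))
    k = int(len(with_ab) * quantile)
    return with_ab[:k], with_ab[-k:]
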