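"""Mutation-rate matrices from de novo mutation tables and their equilibria.

Rates are observed changes per incidence of the source state (nucleotide or
dinucleotide) in the reference exposure region, with exact Poisson 95%
confidence intervals per cell. Stationary distributions solve the global
balance system (gain = loss per state, frequencies summing to one) by a
direct linear solve. The three-stop balance system uses substitution
controls for the six stop<->stop fluxes: TAA>TGA and TAA>TAG behave as
A>G, TGA>TAA and TAG>TAA as G>A, and the two-step TGA<->TAG exchanges as
2 x (A>G) x (G>A). Stop-to-sense mutations are ignored throughout, assumed
rare and strongly deleterious.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2

from ._encoding import BASES, BASE_INDEX, DINUCS, DINUC_INDEX, MISSING, STOPS, encode

log = logging.getLogger(__name__)


@dataclass
class MutationRecord:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    local_gc: float | None = None  # G+C over the surrounding 10 kb window

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass
class RateMatrix:
    """Counts, exposures, per-incidence rates and Poisson CIs over k states."""

    states: tuple[str, ...]
    counts: np.ndarray  # (k, k), zero diagonal
    exposure: np.ndarray  # (k,) occurrences of each state in the reference region
    rates: np.ndarray = field(init=False)
    ci95: np.ndarray = field(init=False)  # (k, k, 2) lower/upper rate bounds

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.exposure = np.asarray(self.exposure, dtype=np.int64)
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal counts must be zero")
        with np.errstate(divide="ignore", invalid="ignore"):
            self.rates = np.where(self.exposure[:, None] > 0,
                                  self.counts / self.exposure[:, None], 0.0)
        lo, hi = poisson_ci(self.counts)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.where(self.exposure[:, None] > 0, self.exposure[:, None], 1)
        self.ci95 = np.stack([lo / denom, hi / denom], axis=-1)

    def rate(self, src: str, dst: str) -> float:
        return float(self.rates[self.states.index(src), self.states.index(dst)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.states):
            for j, b in enumerate(self.states):
                if i == j:
                    continue
                rows.append(
                    {
                        "from": a, "to": b,
                        "count": int(self.counts[i, j]),
                        "exposure": int(self.exposure[i]),
                        "rate": self.rates[i, j],
                        "ci_low": self.ci95[i, j, 0],
                        "ci_high": self.ci95[i, j, 1],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class MononucleotideEquilibrium:
    nstar: np.ndarray  # 4-simplex over A,C,G,T
    gcstar: float
    m: float  # rate(GC->AT) / rate(AT->GC)
    pn: float  # 1 / (1 + m)


@dataclass
class StopCodonEquilibrium:
    taa: float
    tga: float
    tag: float
    fluxes: dict[tuple[str, str], float]
    residual: float  # max |gain - loss| over the three balance equations


def poisson_ci(counts: np.ndarray, conf: float = 0.95):
    """Exact (Garwood) Poisson interval on counts, elementwise."""
    counts = np.asarray(counts)
    alpha = 1.0 - conf
    with np.errstate(invalid="ignore"):
        lo = 0.5 * chi2.ppf(alpha / 2, 2 * counts)
        hi = 0.5 * chi2.ppf(1 - alpha / 2, 2 * (counts + 1))
    lo = np.where(counts == 0, 0.0, lo)
    return lo, hi


# ---------------------------------------------------------------------------
# mutation table ingestion


def read_mutations(path, reference: dict[str, str], window: int = 10000,
                   max_mismatch_fraction: float = 0.01) -> list[MutationRecord]:
    """Read a Chr/Pos/Ref/Alt TSV against a reference genome.

    Rows whose reference base disagrees with the FASTA are dropped (logged);
    more than ``max_mismatch_fraction`` mismatches raises, signalling an
    assembly mismatch. Non-SNV rows are dropped with a count. local_gc is
    the G+C fraction of the centred ``window`` bp, clipped at contig ends.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not set(df.columns) >= {"Chr", "Pos", "Ref", "Alt"}:
        df = pd.read_csv(path, sep="\t", header=None, names=["Chr", "Pos", "Ref", "Alt"], dtype=str)
    records = []
    mismatches = 0
    non_snv = 0
    half = window // 2
    gc_cache: dict[str, np.ndarray] = {}
    for contig, seq in reference.items():
        codes = encode(seq)
        gc_cache[contig] = np.concatenate([[0], np.cumsum((codes == 1) | (codes == 2))])
    valid_cache = {c: np.concatenate([[0], np.cumsum(encode(s) != MISSING)]) for c, s in reference.items()}

    for row in df.itertuples(index=False):
        ref, alt = str(row.Ref).upper(), str(row.Alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
            non_snv += 1
            continue
        contig = str(row.Chr)
        pos = int(row.Pos)
        if contig not in reference or not (1 <= pos <= len(reference[contig])):
            mismatches += 1
            continue
        if reference[contig][pos - 1] != ref:
            mismatches += 1
            continue
        lo = max(0, pos - 1 - half)
        hi = min(len(reference[contig]), pos - 1 + half)
        gc = gc_cache[contig][hi] - gc_cache[contig][lo]
        nv = valid_cache[contig][hi] - valid_cache[contig][lo]
        records.append(MutationRecord(contig, pos, ref, alt, local_gc=gc / nv if nv else None))

    total_snv = len(records) + mismatches
    if total_snv and mismatches / total_snv > max_mismatch_fraction:
        raise ValueError(f"{mismatches}/{total_snv} reference mismatches; assembly mismatch?")
    if mismatches or non_snv:
        log.info("read_mutations dropped %d mismatching and %d non-SNV rows", mismatches, non_snv)
    return records


def base_exposure(sequences) -> np.ndarray:
    """Occurrences of A,C,G,T over one or many sequences."""
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(4, dtype=np.int64)
    for s in sequences:
        c = encode(s)
        counts += np.bincount(c[c != MISSING], minlength=4)[:4]
    return counts


def dinuc_exposure(sequences) -> np.ndarray:
    """Occurrences of the 16 overlapping dinucleotides."""
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(16, dtype=np.int64)
    for s in sequences:
        if len(s) < 2:
            continue
        c = encode(s).astype(np.int64)
        a, b = c[:-1], c[1:]
        ok = (a != MISSING) & (b != MISSING)
        counts += np.bincount(4 * a[ok] + b[ok], minlength=16)
    return counts


def build_mono_matrix(mutations, exposure) -> RateMatrix:
    """4x4 mutation-rate matrix: counts per incidence of the reference base.

    ``exposure`` is a length-4 count vector or sequence(s) to count over.
    """
    if not isinstance(exposure, np.ndarray):
        exposure = base_exposure(exposure)
    if np.any(exposure <= 0):
        raise ValueError("exposure must be positive for all four nucleotides")
    counts = np.zeros((4, 4), dtype=np.int64)
    for m in mutations:
        counts[BASE_INDEX[m.ref], BASE_INDEX[m.alt]] += 1
    return RateMatrix(states=tuple(BASES), counts=counts, exposure=exposure)


def build_dinuc_matrix(mutations, reference: dict[str, str], exposure,
                       single_side: bool = False) -> RateMatrix:
    """16x16 dinucleotide matrix by tracing each mutation to the reference.

    A point mutation at position i contributes the left (i-1, i) and right
    (i, i+1) dinucleotide changes (both by default; ``single_side`` keeps
    only the right-hand one for sensitivity analysis). Flanks that fall off
    the contig or are ambiguous are skipped on that side.
    """
    if not isinstance(exposure, np.ndarray):
        exposure = dinuc_exposure(exposure)
    counts = np.zeros((16, 16), dtype=np.int64)
    for m in mutations:
        seq = reference[m.contig]
        i = m.position - 1
        if not single_side and i > 0 and seq[i - 1] in BASE_INDEX:
            src = DINUC_INDEX[seq[i - 1] + m.ref]
            dst = DINUC_INDEX[seq[i - 1] + m.alt]
            counts[src, dst] += 1
        if i + 1 < len(seq) and seq[i + 1] in BASE_INDEX:
            src = DINUC_INDEX[m.ref + seq[i + 1]]
            dst = DINUC_INDEX[m.alt + seq[i + 1]]
            counts[src, dst] += 1
    return RateMatrix(states=DINUCS, counts=counts, exposure=exposure)


# ---------------------------------------------------------------------------
# stationary distributions


def solve_stationary(rates: np.ndarray) -> np.ndarray:
    """Stationary distribution of a k-state rate matrix by linear solve.

    Solves gain = loss for every state with the sum-to-one constraint.
    Raises if the embedded chain is reducible, naming an absorbing class.
    """
    R = np.array(rates, dtype=float)
    np.fill_diagonal(R, 0.0)
    k = R.shape[0]
    n_comp, labels = connected_components(R > 0, directed=True, connection="strong")
    if n_comp != 1:
        classes = [np.where(labels == c)[0].tolist() for c in range(n_comp)]
        raise ValueError(f"rate matrix is reducible; strongly connected classes: {classes}")
    Q = R - np.diag(R.sum(axis=1))
    A = Q.T.copy()
    A[-1, :] = 1.0  # replace one balance equation with the sum constraint
    b = np.zeros(k)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def mono_equilibrium(matrix: RateMatrix) -> MononucleotideEquilibrium:
    """N*, GC* and the two-class GC<->AT summary from a 4x4 matrix.

    m is the per-incidence GC->AT rate over the AT->GC rate; P_n = 1/(1+m)
    is the two-class equilibrium GC content implied by those pooled rates.
    """
    nstar = solve_stationary(matrix.rates)
    gcstar = float(nstar[1] + nstar[2])
    at_idx = [BASE_INDEX["A"], BASE_INDEX["T"]]
    gc_idx = [BASE_INDEX["C"], BASE_INDEX["G"]]
    at_exp = matrix.exposure[at_idx].sum()
    gc_exp = matrix.exposure[gc_idx].sum()
    at_to_gc = matrix.counts[np.ix_(at_idx, gc_idx)].sum() / at_exp
    gc_to_at = matrix.counts[np.ix_(gc_idx, at_idx)].sum() / gc_exp
    m = gc_to_at / at_to_gc
    return MononucleotideEquilibrium(nstar=nstar, gcstar=gcstar, m=float(m), pn=float(1 / (1 + m)))


def stop_fluxes_from_mono(matrix: RateMatrix) -> dict[tuple[str, str], float]:
    """Six stop<->stop fluxes from mononucleotide substitution controls."""
    r_ag = matrix.rate("A", "G")
    r_ga = matrix.rate("G", "A")
    if r_ag == 0 or r_ga == 0:
        raise ValueError("A->G and G->A rates must be positive")
    two_step = 2.0 * r_ag * r_ga
    return {
        ("TAA", "TGA"): r_ag,
        ("TAA", "TAG"): r_ag,
        ("TGA", "TAA"): r_ga,
        ("TAG", "TAA"): r_ga,
        ("TGA", "TAG"): two_step,
        ("TAG", "TGA"): two_step,
    }


def stop_equilibrium(matrix_or_fluxes, eliminate: str = "TAG") -> StopCodonEquilibrium:
    """Solve the three-stop balance system for equilibrium TAA*/TGA*/TAG*.

    Accepts a 4x4 RateMatrix (fluxes derived via the substitution controls)
    or a prebuilt {(src, dst): rate} mapping. One stop frequency is replaced
    by 1 minus the sum of the other two and the remaining 2x2 linear system
    is solved; the result is independent of which stop is eliminated and
    satisfies each balance equation to numerical precision.
    """
    if isinstance(matrix_or_fluxes, RateMatrix):
        fluxes = stop_fluxes_from_mono(matrix_or_fluxes)
    else:
        fluxes = dict(matrix_or_fluxes)
    if eliminate not in STOPS:
        raise ValueError(f"eliminate must be one of {STOPS}")
    keep = [s for s in STOPS if s != eliminate]

    def loss(s):
        return sum(fluxes[(s, t)] for t in STOPS if t != s)

    # balance for each kept stop: f_s * loss(s) = sum_t f_t * flux(t->s),
    # with f_eliminate = 1 - sum(kept)
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for i, s in enumerate(keep):
        A[i, i] += loss(s)
        for j, t in enumerate(keep):
            A[i, j] -= fluxes[(t, s)] if t != s else 0.0
        # substitute the eliminated stop
        A[i, 0] += fluxes[(eliminate, s)]
        A[i, 1] += fluxes[(eliminate, s)]
        b[i] = fluxes[(eliminate, s)]
    x = np.linalg.solve(A, b)
    freqs = {keep[0]: x[0], keep[1]: x[1], eliminate: 1.0 - x.sum()}
    residual = max(
        abs(freqs[s] * loss(s) - sum(freqs[t] * fluxes[(t, s)] for t in STOPS if t != s))
        for s in STOPS
    )
    return StopCodonEquilibrium(taa=freqs["TAA"], tga=freqs["TGA"], tag=freqs["TAG"],
                                fluxes=fluxes, residual=residual)


def dinuc_gcstar(dinuc_stationary: np.ndarray) -> float:
    """GC* implied by a 16-dinucleotide stationary distribution."""
    gc_weight = np.array([(DINUCS[i].count("G") + DINUCS[i].count("C")) / 2 for i in range(16)])
    return float(dinuc_stationary @ gc_weight)


# ---------------------------------------------------------------------------
# local-GC binning


def window_gc_profile(seq: str, window: int = 10000) -> np.ndarray:
    """Per-position G+C fraction of the centred window, clipped at the ends.

    Uses the same window convention as read_mutations, so a mutation's
    local_gc equals this profile at its (0-based) position.
    """
    codes = encode(seq)
    half = window // 2
    gc_cum = np.concatenate([[0], np.cumsum((codes == 1) | (codes == 2))])
    ok_cum = np.concatenate([[0], np.cumsum(codes != MISSING)])
    pos = np.arange(len(seq))
    lo = np.maximum(0, pos - half)
    hi = np.minimum(len(seq), pos + half)
    nv = ok_cum[hi] - ok_cum[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(nv > 0, (gc_cum[hi] - gc_cum[lo]) / nv, np.nan)


def _gc_matched_exposure(reference, gc_profiles, gc_lo, gc_hi, dinuc: bool):
    """Exposure over all positions whose window GC lies in [gc_lo, gc_hi] -
    the opportunity set of a local-GC mutation bin. For dinucleotides each
    eligible position contributes its left and right reference pairs,
    mirroring how a point mutation contributes two dinucleotide changes."""
    k = 16 if dinuc else 4
    counts = np.zeros(k, dtype=np.int64)
    for contig, seq in reference.items():
        codes = encode(seq).astype(np.int64)
        eligible = (gc_profiles[contig] >= gc_lo) & (gc_profiles[contig] <= gc_hi)
        eligible &= codes != MISSING
        if not dinuc:
            counts += np.bincount(codes[eligible], minlength=5)[:4]
            continue
        idx = np.where(eligible)[0]
        left = idx[idx > 0]
        ok_l = codes[left - 1] != MISSING
        counts += np.bincount(4 * codes[left[ok_l] - 1] + codes[left[ok_l]], minlength=16)
        right = idx[idx < len(seq) - 1]
        ok_r = codes[right + 1] != MISSING
        counts += np.bincount(4 * codes[right[ok_r]] + codes[right[ok_r] + 1], minlength=16)
    return counts


def _window_union(mutations, reference, window: int):
    """Merged 10 kb windows around a mutation set, per contig."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    half = window // 2
    for m in mutations:
        lo = max(0, m.position - 1 - half)
        hi = min(len(reference[m.contig]), m.position - 1 + half)
        by_contig.setdefault(m.contig, []).append((lo, hi))
    seqs = []
    for contig, spans in by_contig.items():
        spans.sort()
        merged = [list(spans[0])]
        for lo, hi in spans[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        seqs.extend(reference[contig][lo:hi] for lo, hi in merged)
    return seqs


def binned_equilibria(mutations, reference: dict[str, str], bins: int = 10,
                      kind: str = "mono", window: int = 10000,
                      markov_length: int = 900, markov_n: int = 2000,
                      seed: int = 0) -> pd.DataFrame:
    """Per local-GC bin equilibrium GC* and TGA*.

    Mutations are ordered by the G+C content of their surrounding window and
    split into equal-count bins; each bin's exposure is its opportunity set -
    every reference position whose window GC falls inside the bin's local-GC
    range - so per-incidence rates stay unbiased at isochore boundaries.
    kind="mono" derives GC* from the 4x4 stationary distribution and TGA*
    from the stop balance system; kind="dinuc" derives GC* from the
    16-dinucleotide stationary distribution and TGA* from Markov-model null
    sequences built on it. Bins whose matrix is reducible are flagged with
    NaN equilibria.
    """
    from . import markov_null  # deferred: markov_null imports genome_io

    muts = [m for m in mutations if m.local_gc is not None]
    if len(muts) < bins * 100:
        raise ValueError(f"need at least {bins * 100} mutations for {bins} bins")
    muts.sort(key=lambda m: m.local_gc)
    chunks = np.array_split(np.arange(len(muts)), bins)
    gc_profiles = {c: window_gc_profile(s, window) for c, s in reference.items()}
    rows = []
    for b, idx in enumerate(chunks):
        sub = [muts[i] for i in idx]
        gcs = [m.local_gc for m in sub]
        gc_lo, gc_hi = min(gcs), max(gcs)
        row = {"bin": b, "n_mutations": len(sub), "mean_local_gc": float(np.mean(gcs))}
        try:
            if kind == "mono":
                expo = _gc_matched_exposure(reference, gc_profiles, gc_lo, gc_hi, dinuc=False)
                mat = build_mono_matrix(sub, expo)
                row["gc_star"] = mono_equilibrium(mat).gcstar
                row["tga_star"] = stop_equilibrium(mat).tga
            elif kind == "dinuc":
                expo = _gc_matched_exposure(reference, gc_profiles, gc_lo, gc_hi, dinuc=True)
                mat = build_dinuc_matrix(sub, reference, expo)
                stat = solve_stationary(mat.rates)
                row["gc_star"] = dinuc_gcstar(stat)
                model = markov_null.markov_from_dinuc(stat)
                null = markov_null.simulate_sequences(model, markov_n, markov_length, seed + b)
                row["tga_star"] = markov_null.tga_star(null)["TGA"]
            else:
                raise ValueError(f"unknown kind {kind!r}")
        except ValueError as exc:
            log.warning("bin %d equilibrium unavailable: %s", b, exc)
            row["gc_star"] = np.nan
            row["tga_star"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
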