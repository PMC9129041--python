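"""Stop-codon flux rates, pTGA and partition deviations.

Flux is the substitution rate from codon X to codon Y per incidence of X in
the ancestral sequence. Each of the two ingroup lineages of a trio
contributes one incidence of the inferred ancestral stop, and one
transition when its tip codon differs. The equilibrium statistic

    pTGA = 1 / (1 + s),    s = rate(TGA->TAA) / rate(TAA->TGA)

is the stationary TGA share of the two-state {TAA, TGA} chain implied by
the two dominant fluxes; fluxes involving TAG are excluded from it.
Transitions to non-stop codons are tabulated but never enter stop-to-stop
rate numerators.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._encoding import STOPS

log = logging.getLogger(__name__)


@dataclass
class FluxCount:
    """Ancestral-stop incidences and ancestral->derived transition counts."""

    incidences: Counter = field(default_factory=Counter)
    transitions: Counter = field(default_factory=Counter)  # (anc, derived) -> n
    skipped_unresolved: int = 0

    def rate(self, anc: str, der: str) -> float:
        n = self.incidences.get(anc, 0)
        if n == 0:
            raise ValueError(f"no incidences of ancestral {anc}")
        return self.transitions.get((anc, der), 0) / n

    def rates(self) -> dict[tuple[str, str], float]:
        """Per-incidence stop-to-stop rates (non-stop targets excluded)."""
        out = {}
        for anc in STOPS:
            if self.incidences.get(anc, 0) == 0:
                continue
            for der in STOPS:
                if der != anc:
                    out[(anc, der)] = self.rate(anc, der)
        return out

    def __add__(self, other: "FluxCount") -> "FluxCount":
        return FluxCount(
            incidences=self.incidences + other.incidences,
            transitions=self.transitions + other.transitions,
            skipped_unresolved=self.skipped_unresolved + other.skipped_unresolved,
        )


@dataclass
class FluxSummary:
    rates: dict[tuple[str, str], float]
    s: float
    ptga: float
    bootstrap_sd: float | None = None


@dataclass
class DeviationScore:
    observed: float  # pTGA of the focal partition
    expected: float  # pTGA of the reference partition
    deviation: float  # (O - E) / E


def count_stop_flux(genes) -> FluxCount:
    """Count incidences and transitions over (ancestral, tip1, tip2) triples.

    ``genes``: iterable of (ancestral stop, ingroup1 codon, ingroup2 codon).
    Genes whose ancestral stop is "unresolved" (or not a stop) are skipped
    and counted. Tip codons that are not stops are recorded as transitions
    to that codon; they stay out of stop-to-stop rates by construction.
    """
    flux = FluxCount()
    for anc, *tips in genes:
        if anc not in STOPS:
            flux.skipped_unresolved += 1
            continue
        for tip in tips:
            flux.incidences[anc] += 1
            if tip != anc:
                flux.transitions[(anc, tip)] += 1
    if flux.skipped_unresolved:
        log.info("count_stop_flux skipped %d genes with unresolved ancestral stop",
                 flux.skipped_unresolved)
    return flux


def compute_ptga(flux: FluxCount) -> FluxSummary:
    """pTGA = 1/(1+s) with s = rate(TGA->TAA)/rate(TAA->TGA).

    TAG fluxes are excluded. A zero TAA->TGA rate with nonzero reverse flux
    yields pTGA = 0 with a warning (TAA absorbs); both rates zero is an
    error (the ratio is undefined).
    """
    r_taa_tga = flux.rate("TAA", "TGA")
    r_tga_taa = flux.rate("TGA", "TAA")
    rates = flux.rates()
    if r_taa_tga == 0.0:
        if r_tga_taa == 0.0:
            raise ValueError("both TAA<->TGA rates are zero; pTGA undefined")
        warnings.warn("TAA->TGA rate is zero; pTGA = 0 (absorbing TAA)")
        return FluxSummary(rates=rates, s=np.inf, ptga=0.0)
    s = r_tga_taa / r_taa_tga
    return FluxSummary(rates=rates, s=s, ptga=1.0 / (1.0 + s))


def ptga_deviation(focal, reference) -> DeviationScore:
    """(O - E)/E with O the focal and E the reference partition's pTGA."""
    o = focal.ptga if isinstance(focal, FluxSummary) else float(focal)
    e = reference.ptga if isinstance(reference, FluxSummary) else float(reference)
    if e <= 0:
        raise ValueError("reference pTGA must be positive")
    return DeviationScore(observed=o, expected=e, deviation=(o - e) / e)


def _gene_features(genes) -> np.ndarray:
    """(n, 4) matrix: [TAA incidences, TAA->TGA events, TGA incidences, TGA->TAA events]."""
    rows = []
    for anc, *tips in genes:
        if anc not in STOPS:
            continue
        k = len(tips)
        rows.append(
            [
                k if anc == "TAA" else 0,
                sum(t == "TGA" for t in tips) if anc == "TAA" else 0,
                k if anc == "TGA" else 0,
                sum(t == "TAA" for t in tips) if anc == "TGA" else 0,
            ]
        )
    return np.array(rows, dtype=np.int64).reshape(-1, 4)


def bootstrap_sd(genes, reps: int = 10000, seed=None, batch: int = 256) -> float:
    """SD of pTGA over gene resamples (with replacement) within a partition.

    Resamples with an undefined pTGA (no TAA->TGA event, or a missing
    ancestral class) are skipped and logged; more than 50% invalid
    resamples raises (the partition is too sparse to bootstrap).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    G = _gene_features(genes)
    n = G.shape[0]
    if n == 0:
        raise ValueError("no resolved genes to bootstrap")
    rng = np.random.default_rng(seed)
    vals = []
    invalid = 0
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        idx = rng.integers(0, n, size=(b, n))
        sums = G[idx].sum(axis=1).astype(float)  # (b, 4)
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = sums[:, 1] / sums[:, 0]
            r2 = sums[:, 3] / sums[:, 2]
            ok = (sums[:, 0] > 0) & (sums[:, 2] > 0) & (r1 > 0)
            ptga = 1.0 / (1.0 + r2[ok] / r1[ok])
        invalid += int(b - ok.sum())
        vals.append(ptga)
        done += b
    if invalid > reps / 2:
        raise ValueError(f"{invalid}/{reps} bootstrap resamples had undefined pTGA")
    if invalid:
        log.info("bootstrap_sd skipped %d/%d undefined resamples", invalid, reps)
    return float(np.std(np.concatenate(vals), ddof=0))


# ---------------------------------------------------------------------------
# two-fold synonymous codon-pair flux

#: The 12 two-fold synonymous third-position pairs (AT-ending, GC-ending).
TWOFOLD_PAIRS: dict[str, tuple[str, str]] = {
    "Phe": ("TTT", "TTC"),
    "Leu": ("TTA", "TTG"),
    "Tyr": ("TAT", "TAC"),
    "His": ("CAT", "CAC"),
    "Gln": ("CAA", "CAG"),
    "Asn": ("AAT", "AAC"),
    "Lys": ("AAA", "AAG"),
    "Asp": ("GAT", "GAC"),
    "Glu": ("GAA", "GAG"),
    "Cys": ("TGT", "TGC"),
    "Ser2": ("AGT", "AGC"),
    "Arg2": ("AGA", "AGG"),
}


@dataclass
class CodonPairFlux:
    amino_acid: str
    bin_index: int
    gc_increasing_rate: float
    gc_decreasing_rate: float
    ratio: float | None  # None when the decreasing rate is zero


def twofold_flux_ratio(events, recomb_bins: int = 10):
    """GC-increasing vs GC-decreasing flux at two-fold degenerate sites.

    ``events``: iterable of (recombination rate, ancestral codon, derived
    codon), one per codon site per ingroup lineage. Sites are binned into
    ``recomb_bins`` equal-count bins of increasing recombination rate; per
    bin and amino acid the per-incidence rates of ..A->..G / ..T->..C
    (GC-increasing) and the reverse (GC-decreasing) are computed, plus a
    pooled record (amino_acid="all") per bin.
    """
    events = [e for e in events if e[0] is not None]
    if not events:
        raise ValueError("no events with a recombination rate")
    events.sort(key=lambda e: e[0])
    chunks = np.array_split(np.arange(len(events)), recomb_bins)

    at_codon = {}  # codon -> (aa, partner, is_at_ending)
    for aa, (at, gc) in TWOFOLD_PAIRS.items():
        at_codon[at] = (aa, gc, True)
        at_codon[gc] = (aa, at, False)

    out = []
    for b, idx in enumerate(chunks):
        inc = Counter()  # (aa, is_at) -> ancestral incidences
        tr = Counter()  # (aa, "up"/"down") -> synonymous switch count
        for i in idx:
            _, anc, der = events[i]
            if anc not in at_codon:
                continue
            aa, partner, is_at = at_codon[anc]
            inc[(aa, is_at)] += 1
            if der == partner:
                tr[(aa, "up" if is_at else "down")] += 1
        pooled_up = pooled_down = pooled_at = pooled_gc = 0
        for aa in TWOFOLD_PAIRS:
            n_at, n_gc = inc[(aa, True)], inc[(aa, False)]
            if n_at == 0 or n_gc == 0:
                continue
            up = tr[(aa, "up")] / n_at
            down = tr[(aa, "down")] / n_gc
            out.append(CodonPairFlux(aa, b, up, down, up / down if down > 0 else None))
            pooled_up += tr[(aa, "up")]
            pooled_down += tr[(aa, "down")]
            pooled_at += n_at
            pooled_gc += n_gc
        if pooled_at and pooled_gc:
            up = pooled_up / pooled_at
            down = pooled_down / pooled_gc
            out.append(CodonPairFlux("all", b, up, down, up / down if down > 0 else None))
    return out
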