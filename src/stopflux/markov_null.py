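"""First-order Markov null sequences from dinucleotide equilibria.

Given equilibrium dinucleotide frequencies F(ab), a null sequence starts
with a dinucleotide drawn from F and is extended one base at a time with
P(next = b | prev = a) = F(ab) / sum_b' F(ab'). Trinucleotide frequencies
of such simulants are the mutational-null expectations used by the boost
analyses; in this chain they have the closed form

    p(abc) = F(ab) * P(c | b)

which is exposed alongside the simulator (the simulation reproduces the
sampling error of the procedure; the closed form is exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._encoding import BASES, STOPS, TRINUC_INDEX, TRINUCS, decode
from .genome_io import TrinucleotideProfile


@dataclass
class MarkovModel:
    """Initial dinucleotide simplex and per-base conditional rows."""

    initial: np.ndarray  # (16,) dinucleotide frequencies
    conditional: np.ndarray  # (4, 4), rows sum to 1

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.conditional = np.asarray(self.conditional, dtype=float)
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial dinucleotide frequencies must sum to 1")
        if not np.allclose(self.conditional.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional rows must sum to 1")


@dataclass
class NullSequenceSet:
    codes: np.ndarray  # (n, length) int8
    seed: int

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]


def markov_from_dinuc(dinuc_frequencies: np.ndarray) -> MarkovModel:
    """Build the chain from a 16-dinucleotide equilibrium simplex.

    Raises if any nucleotide has zero row marginal (its conditional row
    would be undefined).
    """
    F = np.asarray(dinuc_frequencies, dtype=float)
    if F.shape != (16,):
        raise ValueError("expected 16 dinucleotide frequencies")
    if np.any(F < 0) or not np.isclose(F.sum(), 1.0):
        raise ValueError("dinucleotide frequencies must be a simplex")
    rows = F.reshape(4, 4)
    marginals = rows.sum(axis=1)
    if np.any(marginals <= 0):
        dead = [BASES[i] for i in np.where(marginals <= 0)[0]]
        raise ValueError(f"nucleotide(s) {dead} have zero marginal frequency")
    return MarkovModel(initial=F, conditional=rows / marginals[:, None])


def simulate_sequences(model: MarkovModel, n: int = 10000, length: int = 900,
                       seed: int = 0) -> NullSequenceSet:
    """Simulate n null sequences of the given length.

    Each sequence consumes its own deterministic random stream (spawned
    from the root seed), so growing n extends the set without reshuffling
    earlier sequences.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    streams = np.random.SeedSequence(seed).spawn(n)
    u = np.empty((n, length - 1))
    for i, ss in enumerate(streams):
        u[i] = np.random.default_rng(ss).random(length - 1)

    codes = np.empty((n, length), dtype=np.int8)
    cum_init = np.cumsum(model.initial)
    first = np.searchsorted(cum_init, u[:, 0] * cum_init[-1], side="right")
    first = np.minimum(first, 15)
    codes[:, 0] = first // 4
    codes[:, 1] = first % 4
    cum_cond = np.cumsum(model.conditional, axis=1)
    cum_cond[:, -1] = 1.0
    for j in range(2, length):
        prev = codes[:, j - 1].astype(np.int64)
        codes[:, j] = (u[:, j - 1, None] > cum_cond[prev]).sum(axis=1)
    return NullSequenceSet(codes=codes, seed=seed)


def null_trinuc_frequencies(null_set: NullSequenceSet) -> TrinucleotideProfile:
    """Frame-free trinucleotide profile aggregated over all simulants."""
    c = null_set.codes.astype(np.int64)
    idx = (16 * c[:, :-2] + 4 * c[:, 1:-1] + c[:, 2:]).ravel()
    return TrinucleotideProfile(counts=np.bincount(idx, minlength=64))


def tga_star(source) -> dict[str, float]:
    """Equilibrium stop shares TAA*/TGA*/TAG* among the three stops.

    ``source`` may be a NullSequenceSet, a TrinucleotideProfile or a 64-long
    frequency/count vector.
    """
    if isinstance(source, NullSequenceSet):
        freqs = null_trinuc_frequencies(source).frequencies
    elif isinstance(source, TrinucleotideProfile):
        freqs = source.frequencies
    else:
        freqs = np.asarray(source, dtype=float)
    stop_f = {s: float(freqs[TRINUC_INDEX[s]]) for s in STOPS}
    total = sum(stop_f.values())
    if total == 0:
        raise ValueError("no stop trinucleotides in source")
    return {s: f / total for s, f in stop_f.items()}


def closed_form_trinuc(model: MarkovModel) -> np.ndarray:
    """Stationary trinucleotide frequencies p(abc) = F(ab) P(c|b).

    Exact when F's left and right nucleotide marginals agree - which any
    genuine equilibrium dinucleotide composition satisfies, since both
    marginals of overlapping dinucleotides in a long sequence are the same
    base composition.
    """
    F = model.initial.reshape(4, 4)
    p = F[:, :, None] * model.conditional[None, :, :]
    return p.reshape(64)
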