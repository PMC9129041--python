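"""Maximum-likelihood ancestral states on an unrooted 3-taxon tree.

A species trio (two ingroups plus an outgroup) has a single internal node;
its marginal nucleotide posterior at each alignment column is

    P(x | column)  proportional to  pi(x) * P(x->tip1 | t1) * P(x->tip2 | t2) * P(x->tip3 | t3)

under a reversible model (JC69 or HKY85). Tips carrying a gap or N at a
column simply drop out of the product. The ancestral stop codon of a gene
is the MAP nucleotide at each of its three stop columns, accepted only when
it spells TAA/TGA/TAG and at most one sequence is gapped per stop column.

This deliberately small machinery replaces a general phylogenetics package
at three taxa; externally produced ancestral-state tables (IQ-TREE
``.state`` dialect) can be imported instead via :func:`import_state_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._encoding import BASES, MISSING, STOPS, encode

_GAPLIKE = MISSING  # encode() maps gaps, N and ambiguity codes to 4


@dataclass
class TrioAlignment:
    """Aligned trio: ingroup1, ingroup2, outgroup (equal lengths)."""

    gene_id: str
    sequences: tuple[str, str, str]
    stop_columns: tuple[int, int, int] | None = None

    def __post_init__(self):
        lens = {len(s) for s in self.sequences}
        if len(lens) != 1:
            raise ValueError(f"{self.gene_id}: aligned sequences differ in length")

    def codes(self) -> np.ndarray:
        """(3, L) int8 matrix, 4 = gap/N."""
        return np.stack([encode(s) for s in self.sequences])


@dataclass
class SubstitutionModel:
    """JC69 or HKY85 with one branch per tip from the internal node."""

    kind: str = "JC69"
    kappa: float = 1.0
    base_frequencies: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    branch_lengths: np.ndarray = field(default_factory=lambda: np.full(3, 0.1))

    def __post_init__(self):
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if not np.isclose(self.base_frequencies.sum(), 1.0):
            raise ValueError("base frequencies must sum to 1")
        if np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be non-negative")

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) in closed form, rows = ancestral state, mean rate 1."""
        return hky_transition_matrix(self.base_frequencies, self.kappa, t)


def hky_transition_matrix(pi: np.ndarray, kappa: float, t: float) -> np.ndarray:
    """Closed-form HKY85 transition probabilities (JC69 at kappa=1, pi=1/4).

    The rate matrix has q_ij = kappa*pi_j for transitions (A<->G, C<->T) and
    pi_j for transversions, scaled so the expected substitution rate is 1;
    t is then in expected substitutions per site.
    """
    pi = np.asarray(pi, dtype=float)
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    # mean rate under the unscaled matrix
    mu = 2.0 * (piA * piC + piA * piT + piC * piG + piG * piT) + 2.0 * kappa * (piA * piG + piC * piT)
    if mu <= 0:
        raise ValueError("degenerate base frequencies")
    d = t / mu  # time under the unscaled matrix

    P = np.empty((4, 4))
    e2 = np.exp(-d)
    for j in range(4):
        pj = pi[j]
        Pj = piR if j in (0, 2) else piY  # frequency of j's type (purine/pyrimidine)
        e3 = np.exp(-d * (1.0 + Pj * (kappa - 1.0)))
        for i in range(4):
            same_type = (i in (0, 2)) == (j in (0, 2))
            if i == j:
                P[i, j] = pj + pj * (1.0 / Pj - 1.0) * e2 + ((Pj - pj) / Pj) * e3
            elif same_type:
                P[i, j] = pj + pj * (1.0 / Pj - 1.0) * e2 - (pj / Pj) * e3
            else:
                P[i, j] = pj * (1.0 - e2)
    return np.clip(P, 0.0, 1.0)


@dataclass
class AncestralReconstruction:
    """Marginal posterior over the internal node, one row per column."""

    posteriors: np.ndarray  # (L, 4), rows sum to 1
    map_codes: np.ndarray  # (L,) int8

    @property
    def map_sequence(self) -> str:
        return "".join(BASES[c] for c in self.map_codes)


# ---------------------------------------------------------------------------
# model fitting


def _pattern_counts(alignments) -> np.ndarray:
    """Counts of the 64 fully resolved tip patterns over ungapped columns."""
    counts = np.zeros(64, dtype=np.int64)
    for aln in alignments:
        c = aln.codes().astype(np.int64)
        ok = (c != _GAPLIKE).all(axis=0)
        idx = 16 * c[0, ok] + 4 * c[1, ok] + c[2, ok]
        counts += np.bincount(idx, minlength=64)
    return counts


def _loglik(counts: np.ndarray, pi: np.ndarray, kappa: float, ts) -> float:
    Ps = [hky_transition_matrix(pi, kappa, t) for t in ts]
    # L(pattern abc) = sum_x pi_x P1[x,a] P2[x,b] P3[x,c]
    lik = np.einsum("x,xa,xb,xc->abc", pi, Ps[0], Ps[1], Ps[2]).reshape(64)
    lik = np.maximum(lik, 1e-300)
    return float(counts @ np.log(lik))


def fit_model(alignments, kind: str = "HKY85", max_sweeps: int = 30, tol: float = 1e-8) -> SubstitutionModel:
    """Fit branch lengths (and kappa for HKY85) by coordinate ascent.

    Base frequencies are empirical over the tip sequences. Each sweep runs a
    bounded 1-D maximisation per parameter, so the log-likelihood is
    non-decreasing across iterations.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments supplied")
    counts = _pattern_counts(alignments)
    if counts.sum() == 0:
        raise ValueError("all columns gapped; cannot fit a model")

    if kind.upper() in ("JC", "JC69"):
        kind, pi = "JC69", np.full(4, 0.25)
        fit_kappa = False
    elif kind.upper() in ("HKY", "HKY85"):
        kind = "HKY85"
        base_counts = np.zeros(4)
        for aln in alignments:
            c = aln.codes()
            base_counts += np.bincount(c[c != _GAPLIKE], minlength=4)[:4]
        pi = base_counts / base_counts.sum()
        fit_kappa = True
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    ts = [0.05, 0.05, 0.05]
    kappa = 2.0
    prev = -np.inf
    for _ in range(max_sweeps):
        for b in range(3):
            res = minimize_scalar(
                lambda t: -_loglik(counts, pi, kappa, ts[:b] + [t] + ts[b + 1 :]),
                bounds=(1e-9, 5.0),
                method="bounded",
            )
            ts[b] = float(res.x)
        if fit_kappa:
            res = minimize_scalar(
                lambda k: -_loglik(counts, pi, k, ts),
                bounds=(0.05, 100.0),
                method="bounded",
            )
            kappa = float(res.x)
        cur = _loglik(counts, pi, kappa, ts)
        if cur - prev < tol:
            break
        prev = cur
    return SubstitutionModel(kind=kind, kappa=kappa if fit_kappa else 1.0,
                             base_frequencies=pi, branch_lengths=np.array(ts))


# ---------------------------------------------------------------------------
# marginal reconstruction


def asr_marginal(alignment: TrioAlignment, model: SubstitutionModel) -> AncestralReconstruction:
    """Marginal posterior at the internal node for every alignment column.

    Columns where a tip is gapped or N use the remaining tips only; MAP ties
    break by the fixed nucleotide order A < C < G < T.
    """
    codes = alignment.codes().astype(np.int64)
    pi = model.base_frequencies
    post = np.tile(pi[None, :], (codes.shape[1], 1))
    for i in range(3):
        P = model.transition_matrix(float(model.branch_lengths[i]))
        P_aug = np.hstack([P, np.ones((4, 1))])  # column 4: missing tip
        post = post * P_aug[:, codes[i]].T
    total = post.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    post = post / total
    map_codes = post.argmax(axis=1).astype(np.int8)  # first max -> A<C<G<T
    return AncestralReconstruction(posteriors=post, map_codes=map_codes)


def ancestral_stop(reconstruction: AncestralReconstruction, alignment: TrioAlignment) -> str:
    """Ancestral stop codon at the focal stop columns, or "unresolved".

    Unresolved when the MAP codon is not a stop, or when any stop column is
    gapped in two or more of the three sequences.
    """
    if alignment.stop_columns is None:
        raise ValueError(f"{alignment.gene_id}: stop columns undefined")
    codes = alignment.codes()
    for col in alignment.stop_columns:
        if int((codes[:, col] == _GAPLIKE).sum()) >= 2:
            return "unresolved"
    codon = "".join(BASES[reconstruction.map_codes[c]] for c in alignment.stop_columns)
    return codon if codon in STOPS else "unresolved"


# ---------------------------------------------------------------------------
# state-table interchange (IQ-TREE .state dialect)

_STATE_COLUMNS = ["Node", "Site", "State", "p_A", "p_C", "p_G", "p_T"]


def export_state_table(reconstruction: AncestralReconstruction, path, node: str = "Node1") -> None:
    df = pd.DataFrame(
        {
            "Node": node,
            "Site": np.arange(1, len(reconstruction.map_codes) + 1),
            "State": list(reconstruction.map_sequence),
            "p_A": reconstruction.posteriors[:, 0],
            "p_C": reconstruction.posteriors[:, 1],
            "p_G": reconstruction.posteriors[:, 2],
            "p_T": reconstruction.posteriors[:, 3],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def import_state_table(path, node: str | None = None) -> AncestralReconstruction:
    """Read an IQ-TREE-style ancestral state table for one internal node.

    Posterior rows off unity by at most 1e-6 are renormalised; worse rows,
    or rows that do not parse, raise with their line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _STATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"state table missing columns {missing}")
    if node is None:
        node = df["Node"].iloc[0]
    sub = df[df["Node"] == node].sort_values("Site")
    probs = sub[["p_A", "p_C", "p_G", "p_T"]].to_numpy(dtype=float)
    sums = probs.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-6 + 1e-12  # epsilon guards the boundary case
    if bad.any():
        line = int(sub.index[bad][0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"state table line {line}: posteriors sum to {sums[bad][0]:.8f}")
    probs = probs / sums[:, None]
    map_codes = probs.argmax(axis=1).astype(np.int8)
    return AncestralReconstruction(posteriors=probs, map_codes=map_codes)
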