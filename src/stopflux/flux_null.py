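"""Monte-Carlo significance for a pTGA deviation between two gene groups.

The null hypothesis is genome-wide uniform flux: every gene experiences the
pooled genomic TAA->TGA and TGA->TAA per-incidence rates regardless of its
partition. Null pTGA distributions are simulated per group by Bernoulli
flux events at those rates, one pTGA per replicate; significance of the
observed deviation is the fraction of randomly paired null draws whose
deviation is at least as large, p = n/m.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .stop_flux import FluxCount

log = logging.getLogger(__name__)


@dataclass
class NullConfig:
    group_reps: int = 1000
    pair_draws: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.group_reps < 100:
            raise ValueError("group_reps must be >= 100")
        if self.pair_draws < 1000:
            raise ValueError("pair_draws must be >= 1000")


@dataclass
class DeviationTest:
    observed_deviation: float
    null_deviations: np.ndarray
    n: int  # simulants with deviation >= observed (ties counted)
    m: int  # pair draws
    p: float  # n / m


def genomic_rates(flux: FluxCount) -> tuple[float, float]:
    """Pooled per-incidence (TAA->TGA, TGA->TAA) rates over all genes."""
    for stop in ("TAA", "TGA"):
        if flux.incidences.get(stop, 0) == 0:
            raise ValueError(f"no ancestral incidences of {stop}")
    return flux.rate("TAA", "TGA"), flux.rate("TGA", "TAA")


def simulate_null_ptga(group, rates: tuple[float, float], reps: int = 1000, seed=None) -> np.ndarray:
    """Null pTGA distribution for one gene group.

    ``group`` is the list of ancestral stops (one entry per incidence, i.e.
    per scored lineage) or a (n_taa, n_tga) pair. Per replicate each TAA
    incidence fires a TAA->TGA event with the genomic rate and each TGA
    incidence the reverse; null rates are event counts over incidences.
    Replicates with zero TAA->TGA events (undefined pTGA) are redrawn and
    logged so exactly ``reps`` values return.
    """
    if isinstance(group, tuple):
        n_taa, n_tga = group
    else:
        group = list(group)
        n_taa = sum(g == "TAA" for g in group)
        n_tga = sum(g == "TGA" for g in group)
    if n_taa == 0 or n_tga == 0:
        raise ValueError("group must contain both TAA and TGA ancestral stops")
    r1, r2 = rates
    if n_taa * r1 < 1:
        warnings.warn("expected TAA->TGA events per replicate < 1; null poorly resolved")
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    filled = 0
    redrawn = 0
    while filled < reps:
        todo = reps - filled
        ev1 = rng.binomial(n_taa, r1, size=todo)
        ev2 = rng.binomial(n_tga, r2, size=todo)
        ok = ev1 > 0
        redrawn += int(todo - ok.sum())
        k = int(ok.sum())
        s = (ev2[ok] / n_tga) / (ev1[ok] / n_taa)
        out[filled : filled + k] = 1.0 / (1.0 + s)
        filled += k
    if redrawn:
        log.info("simulate_null_ptga redrew %d replicates with undefined pTGA", redrawn)
    return out


def deviation_pvalue(dist_a, dist_b, observed_deviation: float, m: int = 10000,
                     seed=None, two_sided: bool = False) -> DeviationTest:
    """p = n/m over m random (a, b) pairs with null deviation (a-b)/b.

    One-sided by default (counts null deviations >= observed, ties
    included), matching the directional GC-rich > GC-poor hypothesis;
    ``two_sided`` compares absolute deviations. Pairs with b = 0 are
    redrawn and logged.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both null distributions must be non-empty")
    rng = np.random.default_rng(seed)
    null = np.empty(m)
    filled = 0
    redrawn = 0
    while filled < m:
        todo = m - filled
        xa = a[rng.integers(0, a.size, size=todo)]
        xb = b[rng.integers(0, b.size, size=todo)]
        ok = xb != 0
        redrawn += int(todo - ok.sum())
        k = int(ok.sum())
        null[filled : filled + k] = (xa[ok] - xb[ok]) / xb[ok]
        filled += k
    if redrawn:
        log.info("deviation_pvalue redrew %d pairs with zero reference draw", redrawn)
    if two_sided:
        n = int((np.abs(null) >= abs(observed_deviation)).sum())
    else:
        n = int((null >= observed_deviation).sum())
    return DeviationTest(observed_deviation=observed_deviation, null_deviations=null,
                         n=n, m=m, p=n / m)


def run_null_test(flux_a: FluxCount, flux_b: FluxCount, observed_deviation: float,
                  config: NullConfig | None = None) -> DeviationTest:
    """Full null pipeline: pooled rates, per-group null pTGA, pair p-value.

    Group A is the focal (numerator O) partition, group B the reference E.
    """
    config = config or NullConfig()
    pooled = flux_a + flux_b
    rates = genomic_rates(pooled)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    dist_a = simulate_null_ptga(
        (flux_a.incidences["TAA"], flux_a.incidences["TGA"]), rates, config.group_reps, seeds[0]
    )
    dist_b = simulate_null_ptga(
        (flux_b.incidences["TAA"], flux_b.incidences["TGA"]), rates, config.group_reps, seeds[1]
    )
    return deviation_pvalue(dist_a, dist_b, observed_deviation, config.pair_draws, seeds[2])
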