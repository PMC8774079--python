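"""Closed-form detoxification and cross-compatibility probabilities.

Under collaborative non-self recognition, each pollen-expressed SLF
independently detoxifies (targets for degradation) any given nonself
S-RNase with a per-pair probability ``p_r``.  Pollen carrying ``n``
distinct SLF types therefore detoxifies a given S-RNase with probability

    P_n = 1 - (1 - p_r)**n

and is accepted by a heterozygous style — which deploys two S-RNases,
both of which must be detoxified — with probability ``P_n**2``.

This module houses those closed forms, estimation of ``p_r`` from
aggregated transgenic specificity calls (success = the transgene
inactivated a given S-RNase in the *Petunia* tester background), a
goodness-of-fit comparison against an expected per-pair probability, and
a Monte-Carlo validator of the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DetoxParams",
    "DetoxCountData",
    "FitResult",
    "PREstimate",
    "detox_prob_n",
    "style_acceptance",
    "percent",
    "estimate_p_r",
    "aggregate_specificity_calls",
    "goodness_of_fit",
    "simulate_acceptance",
]


@dataclass(frozen=True)
class DetoxParams:
    """Per-pair detoxification probability and number of SLF types.

    Parameters
    ----------
    p_r
        Probability that one SLF detoxifies one given nonself S-RNase.
    n
        Number of distinct SLF types carried by the pollen.
    """

    p_r: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_r <= 1.0:
            raise ValueError(f"p_r must be in [0, 1], got {self.p_r}")
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError(f"n must be a non-negative integer, got {self.n}")

    @property
    def p_n(self) -> float:
        """Probability that at least one of the n SLFs detoxifies a target."""
        return detox_prob_n(self)


@dataclass(frozen=True)
class DetoxCountData:
    """Aggregated (successes, trials) of per-pair detoxification calls."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.trials:
            raise ValueError(
                f"need 0 <= successes <= trials, got {self.successes}/{self.trials}"
            )


@dataclass(frozen=True)
class FitResult:
    """Chi-square goodness-of-fit result with an exact binomial companion.

    ``p_value`` is the chi-square p-value; ``binom_p_value`` is the exact
    two-sided binomial p-value, emitted because the chi-square
    approximation is unreliable at the small expected counts typical of
    transgenic assays.
    """

    statistic: float
    df: int
    p_value: float
    binom_p_value: float


@dataclass(frozen=True)
class PREstimate:
    """Point estimate and exact (Clopper-Pearson) confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float


def detox_prob_n(params: DetoxParams) -> float:
    """Probability P_n that pollen with n SLF types detoxifies one S-RNase.

    P_n = 1 - (1 - p_r)**n; each SLF recognises the S-RNase independently
    with probability p_r.
    """
    return 1.0 - (1.0 - params.p_r) ** params.n


def style_acceptance(params: DetoxParams, rnases_per_style: int = 2) -> float:
    """Fraction of styles accepting the pollen, unrounded.

    A heterozygous style carries ``rnases_per_style`` (default two)
    distinct S-RNases, all of which must be detoxified, so acceptance is
    ``P_n ** rnases_per_style``.
    """
    if rnases_per_style < 1:
        raise ValueError("rnases_per_style must be >= 1")
    return detox_prob_n(params) ** rnases_per_style


def percent(p: float) -> int:
    """Probability -> integer percent, rounding half up (0.725 -> 73)."""
    return int(math.floor(p * 100.0 + 0.5))


def estimate_p_r(data: DetoxCountData, ci_level: float = 0.95) -> PREstimate:
    """Estimate p_r from pooled detoxification calls.

    Point estimate is successes/trials; the interval is the exact
    Clopper-Pearson interval (inverted binomial tails), appropriate for
    the small trial counts of cross-taxon transgenic panels.
    """
    if data.trials == 0:
        raise ValueError("cannot estimate p_r from zero trials")
    bt = stats.binomtest(data.successes, data.trials)
    ci = bt.proportion_ci(confidence_level=ci_level, method="exact")
    return PREstimate(
        estimate=data.successes / data.trials,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        ci_level=ci_level,
    )


def aggregate_specificity_calls(
    specs: Iterable["DetoxSpec"], allele_universe: Sequence[str]
) -> DetoxCountData:
    """Pool per-transgene specificity calls into (successes, trials).

    Each spec is scored against every allele in the universe: a trial per
    (transgene, S-RNase) pair, a success when the allele is among the
    transgene's targets.  For the packaged cross-taxon panel against the
    two *Petunia* tester alleles this reproduces the 22/26 pooled calls.
    """
    specs = list(specs)
    universe = list(allele_universe)
    if not specs or not universe:
        raise ValueError("need at least one spec and one allele")
    successes = sum(1 for s in specs for a in universe if a in s.targets)
    return DetoxCountData(successes=successes, trials=len(specs) * len(universe))


def goodness_of_fit(data: DetoxCountData, expected_p: float) -> FitResult:
    """1-df chi-square GOF of (successes, failures) against expected_p.

    No continuity correction.  An exact two-sided binomial p-value is
    returned alongside, since expected counts near 5 are borderline for
    the chi-square approximation.
    """
    if data.trials == 0:
        raise ValueError("trials must be > 0")
    if not 0.0 < expected_p < 1.0:
        raise ValueError("expected_p must lie strictly inside (0, 1)")
    expected = np.array([data.trials * expected_p, data.trials * (1.0 - expected_p)])
    if np.any(expected == 0):
        raise ValueError("expected count of zero")
    observed = np.array([data.successes, data.trials - data.successes])
    chi2, p = stats.chisquare(observed, f_exp=expected)
    binom_p = stats.binomtest(data.successes, data.trials, expected_p).pvalue
    return FitResult(
        statistic=float(chi2), df=1, p_value=float(p), binom_p_value=float(binom_p)
    )


def simulate_acceptance(
    params: DetoxParams,
    n_pairs: int,
    seed: int,
    rnases_per_style: int = 2,
) -> float:
    """Monte-Carlo fraction of styles fully detoxified.

    For each of ``n_pairs`` simulated styles, each of its S-RNases is
    independently tested against each of the pollen's n SLFs
    (Bernoulli(p_r) per pair); the style accepts iff every S-RNase is hit
    by at least one SLF.  Validates the ``style_acceptance`` closed form.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    if params.n == 0:
        return 0.0
    hits = rng.random((n_pairs, rnases_per_style, params.n)) < params.p_r
    detoxified = hits.any(axis=2)
    return float(detoxified.all(axis=1).mean())


# imported late to avoid a cycle: si_genetics needs nothing from here at
# import time, but DetoxSpec lives there as the shared specificity type
from slocus_evo.si_genetics import DetoxSpec  # noqa: E402  (re-export)
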