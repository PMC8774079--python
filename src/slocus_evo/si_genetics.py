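"""Gametophytic SI pollination genetics under collaborative non-self recognition.

In S-RNase-based (type-1) gametophytic self-incompatibility the style
secretes the S-RNases of both maternal S-haplotypes; a haploid pollen
grain survives only if every style S-RNase is detoxified by the SLF
repertoire the pollen expresses.  The endogenous SLF repertoire of an
S-haplotype detoxifies all nonself S-RNases but never its own — that is
what makes self pollen incompatible.  A transgene adding an SLF whose
targets include the pollen's own S-RNase rescues self pollen
("competitive interaction") and converts the plant to self-compatibility.

This module predicts which pollen classes of a transgenic self-cross are
compatible, the resulting self-progeny genotype distribution, and —
inverting that prediction — infers a transgene's detoxification
specificity from observed progeny genotype counts by maximum multinomial
likelihood with an exact goodness-of-fit test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "DetoxSpec",
    "PollenClass",
    "SpecificityReport",
    "genotype_label",
    "pollen_compatible",
    "predict_breakdown",
    "predict_progeny",
    "infer_specificity",
    "segregation_test",
    "exact_multinomial_test",
    "population_cross_compatibility",
]

#: counts above which the exact multinomial test switches to Monte Carlo
_EXACT_ENUMERATION_LIMIT = 200
_MC_DRAWS = 100_000
_MC_SEED = 20211026


@dataclass(frozen=True)
class DetoxSpec:
    """Detoxification specificity of an SLF source (transgene or haplotype).

    ``targets`` is the set of S-RNase alleles the source inactivates; for
    an endogenous haplotype repertoire the haplotype's own allele is never
    a target.
    """

    source_id: str
    targets: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))


@dataclass(frozen=True)
class PollenClass:
    """One pollen genotype class: S-allele, transgene carriage, frequency."""

    s_allele: str
    carries_transgene: bool
    probability: float


@dataclass(frozen=True)
class SpecificityReport:
    """Outcome of specificity inference from progeny counts."""

    targets: FrozenSet[str]
    log_likelihood: float
    p_value: float
    fits_at_alpha: bool
    alpha: float
    candidate_log_likelihoods: Mapping[FrozenSet[str], float]


def genotype_label(a: str, b: str) -> str:
    """Canonical unordered diploid genotype label, e.g. ('S3L','S3') -> 'S3S3L'."""
    x, y = sorted((a, b))
    return f"{x}{y}"


def _check_alleles(alleles: Iterable[str], universe: Optional[Iterable[str]]) -> None:
    if universe is None:
        return
    universe = set(universe)
    unknown = [a for a in alleles if a not in universe]
    if unknown:
        raise ValueError(f"unknown S-allele name(s): {unknown}")


def pollen_compatible(
    pollen: PollenClass,
    style_alleles: Tuple[str, str],
    endogenous_specs: Optional[Mapping[str, DetoxSpec]] = None,
    transgene_spec: Optional[DetoxSpec] = None,
    allele_universe: Optional[Iterable[str]] = None,
) -> bool:
    """Is this pollen class accepted on a style of the given S-genotype?

    The pollen detoxifies a style S-RNase if it is a nonself allele (the
    endogenous repertoire covers every nonself allele unless an explicit
    per-haplotype override is supplied) or if it is among the carried
    transgene's targets.  The pollen's own S-RNase is detoxified *only*
    via the transgene.  Compatible iff every style S-RNase is detoxified.
    """
    if allele_universe is not None:
        _check_alleles([pollen.s_allele, *style_alleles], allele_universe)
    own = pollen.s_allele
    if endogenous_specs is not None and own in endogenous_specs:
        endo = endogenous_specs[own].targets
        if own in endo:
            raise ValueError(f"endogenous repertoire of {own} must not target itself")
    else:
        endo = None  # complete network: all nonself alleles
    trans = (
        transgene_spec.targets
        if (transgene_spec is not None and pollen.carries_transgene)
        else frozenset()
    )
    for rnase in style_alleles:
        nonself_hit = (rnase != own) if endo is None else (rnase in endo)
        if not (nonself_hit or rnase in trans):
            return False
    return True


def _pollen_classes(
    parent_alleles: Tuple[str, str], transgene_zygosity: str
) -> list[PollenClass]:
    if transgene_zygosity not in ("hemizygous", "homozygous"):
        raise ValueError(f"unknown transgene zygosity: {transgene_zygosity!r}")
    carrier_frac = 0.5 if transgene_zygosity == "hemizygous" else 1.0
    classes = []
    for allele in parent_alleles:
        # each S-allele is half the pollen; the transgene segregates
        # independently (unlinked single locus)
        if carrier_frac > 0:
            classes.append(PollenClass(allele, True, 0.5 * carrier_frac))
        if carrier_frac < 1:
            classes.append(PollenClass(allele, False, 0.5 * (1 - carrier_frac)))
    return classes


def predict_breakdown(
    parent_alleles: Tuple[str, str], transgene_spec: DetoxSpec
) -> bool:
    """Does the transgene break down SI (make the parent self-compatible)?

    True iff at least one transgenic pollen class is compatible on the
    parent's own style.
    """
    style = tuple(parent_alleles)
    return any(
        pollen_compatible(pc, style, transgene_spec=transgene_spec)
        for pc in _pollen_classes(parent_alleles, "hemizygous")
        if pc.carries_transgene
    )


def predict_progeny(
    parent_alleles: Tuple[str, str],
    transgene_spec: DetoxSpec,
    transgene_zygosity: str = "hemizygous",
) -> Dict[str, float]:
    """Self-progeny genotype distribution of a transgenic plant.

    Maternal gametes are the two parental alleles at 1/2 each; paternal
    contribution is the renormalised distribution of compatible pollen
    classes.  Returns probabilities over the three possible unordered
    genotypes (zero where no compatible pollen can produce the class).

    Raises
    ------
    ValueError
        If no pollen class is compatible (fully incompatible cross).
    """
    style = tuple(parent_alleles)
    compat = [
        pc
        for pc in _pollen_classes(parent_alleles, transgene_zygosity)
        if pollen_compatible(pc, style, transgene_spec=transgene_spec)
    ]
    total = sum(pc.probability for pc in compat)
    if total == 0:
        raise ValueError("fully incompatible cross: no compatible pollen class")
    labels = sorted(
        {genotype_label(a, b) for a in parent_alleles for b in parent_alleles}
    )
    probs = dict.fromkeys(labels, 0.0)
    for pc in compat:
        for maternal in parent_alleles:
            probs[genotype_label(maternal, pc.s_allele)] += (
                0.5 * pc.probability / total
            )
    return probs


def exact_multinomial_test(
    counts: Sequence[int], probs: Sequence[float], seed: int = _MC_SEED
) -> float:
    """Exact multinomial goodness-of-fit p-value.

    P-value is the total probability of outcomes no more probable than
    the observed one, by full enumeration for totals <= 200 and by
    Monte Carlo (fixed seed, 1e5 draws) above.
    """
    counts = np.asarray(counts, dtype=int)
    probs = np.asarray(probs, dtype=float)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty counts")
    if np.any(counts[probs == 0] > 0):
        return 0.0
    logp_obs = stats.multinomial.logpmf(counts, n, probs)
    if n <= _EXACT_ENUMERATION_LIMIT:
        k = len(probs)
        bars = np.array(
            list(itertools.combinations(range(n + k - 1), k - 1)), dtype=int
        ).reshape(-1, k - 1)
        # stars-and-bars decode of all compositions of n into k cells
        padded = np.hstack(
            [
                np.full((bars.shape[0], 1), -1),
                bars,
                np.full((bars.shape[0], 1), n + k - 1),
            ]
        )
        outcomes = np.diff(padded, axis=1) - 1
        lps = stats.multinomial.logpmf(outcomes, n, probs)
        total = np.exp(lps[lps <= logp_obs + 1e-9]).sum()
        return float(min(1.0, total))
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=_MC_DRAWS)
    lps = stats.multinomial.logpmf(draws, n, probs)
    return float((lps <= logp_obs + 1e-9).mean())


def infer_specificity(
    parent_alleles: Tuple[str, str],
    counts: Mapping[str, int],
    alpha: float = 0.05,
    transgene_zygosity: str = "hemizygous",
) -> SpecificityReport:
    """Infer a transgene's detoxification targets from self-progeny counts.

    Candidate target sets are the non-empty subsets of the parental
    alleles; each implies a predicted genotype distribution via
    :func:`predict_progeny`.  The maximum-multinomial-likelihood model is
    selected, ties broken toward the smaller target set (parsimony), and
    an exact multinomial goodness-of-fit p-value against the winner is
    reported; ``fits_at_alpha`` is False when even the best model is
    rejected at ``alpha``.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative progeny count")
    if sum(counts.values()) == 0:
        raise ValueError("all-zero progeny counts")
    alleles = sorted(set(parent_alleles))
    labels = sorted(
        {genotype_label(a, b) for a in parent_alleles for b in parent_alleles}
    )
    unknown = set(counts) - set(labels)
    if unknown:
        raise ValueError(f"genotype label(s) not producible by this cross: {unknown}")
    obs = np.array([counts.get(lab, 0) for lab in labels], dtype=int)

    candidates: Dict[FrozenSet[str], float] = {}
    preds: Dict[FrozenSet[str], np.ndarray] = {}
    for r in range(1, len(alleles) + 1):
        for subset in itertools.combinations(alleles, r):
            tset = frozenset(subset)
            try:
                pred = predict_progeny(
                    parent_alleles, DetoxSpec("candidate", tset), transgene_zygosity
                )
            except ValueError:
                continue
            p = np.array([pred[lab] for lab in labels])
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = float(np.where(obs > 0, obs * np.log(p), 0.0).sum())
            candidates[tset] = ll
            preds[tset] = p

    best = max(
        candidates,
        key=lambda t: (candidates[t], -len(t), tuple(sorted(t))),
    )
    p_value = (
        exact_multinomial_test(obs, preds[best])
        if np.isfinite(candidates[best])
        else 0.0
    )
    return SpecificityReport(
        targets=best,
        log_likelihood=candidates[best],
        p_value=p_value,
        fits_at_alpha=p_value >= alpha,
        alpha=alpha,
        candidate_log_likelihoods=candidates,
    )


def segregation_test(count_a: int, count_b: int, ratio: float = 0.5) -> float:
    """Two-sided exact binomial p-value for a two-class segregation ratio."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = count_a + count_b
    if n == 0:
        raise ValueError("zero total count")
    return float(stats.binomtest(count_a, n, ratio).pvalue)


def population_cross_compatibility(detox_matrix: np.ndarray) -> float:
    """Fraction of nonself pollinations accepted in a haplotype population.

    ``detox_matrix[h, a]`` says whether pollen of haplotype ``h``
    (through its full SLF repertoire) detoxifies S-RNase ``a``.  Styles
    are all heterozygous pairs {a, b}; pollen haplotypes are all h not in
    the style pair.  Exact enumeration of the fraction of (pollen, style)
    combinations where both style S-RNases are detoxified.
    """
    m = np.asarray(detox_matrix, dtype=bool)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("detox_matrix must be square")
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least 3 haplotypes for nonself heterozygous styles")
    if m.diagonal().any():
        raise ValueError("self S-RNases must never be detoxified (diagonal True)")
    # for style {a,b}: sum_h m[h,a] & m[h,b]; h in {a,b} contributes 0
    # because the diagonal is all False, so the full column dot works
    both = (m.astype(np.int64).T @ m.astype(np.int64)).astype(float)
    iu = np.triu_indices(n, k=1)
    accepted = both[iu].sum()
    total = (n * (n - 1) // 2) * (n - 2)
    return float(accepted / total)
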