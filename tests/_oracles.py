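"""Independent oracles used by the test suite.

The brute-force likelihood/posterior computation enumerates every
internal-node state assignment explicitly and never touches the pruning
code in :mod:`slocus_evo.ancestral_states` beyond the scalar transition
probability.
"""

from __future__ import annotations

import itertools
from typing import Dict, Tuple

import numpy as np

from slocus_evo.ancestral_states import F81Params, TraitTree, f81_transition


def brute_force_likelihood_and_posteriors(
    tt: TraitTree, params: F81Params
) -> Tuple[float, Dict[str, np.ndarray]]:
    """(log-likelihood, internal posteriors) by explicit enumeration.

    Sums the joint probability over all assignments of states to
    internal nodes (and to missing tips), using only scalar F81
    transition probabilities.  Exponential in tree size; for trees with
    <= 6 leaves only.
    """
    nodes = list(tt.tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    missing = [n for n in leaves if tt.tip_states[n.taxon.label] is None]
    K = tt.alphabet.size
    obs = {
        id(n): tt.alphabet.index(tt.tip_states[n.taxon.label])
        for n in leaves
        if tt.tip_states[n.taxon.label] is not None
    }
    edges = [
        (n.parent_node, n, n.edge.length or 0.0)
        for n in nodes
        if n.parent_node is not None
    ]
    total = 0.0
    post = {id(n): np.zeros(K) for n in internals}
    free = internals + missing
    for assign in itertools.product(range(K), repeat=len(free)):
        full = dict(obs)
        for n, s in zip(free, assign):
            full[id(n)] = s
        p = float(params.pi[full[id(tt.tree.seed_node)]])
        for parent, child, t in edges:
            p *= f81_transition(full[id(parent)], full[id(child)], t, params)
        total += p
        for n in internals:
            post[id(n)][full[id(n)]] += p
    posteriors = {tt.node_label(n): post[id(n)] / total for n in internals}
    return float(np.log(total)), posteriors


def enumerate_progeny_distribution(
    parent_alleles, transgene_targets, hemizygous: bool = True
) -> Dict[str, float]:
    """Progeny distribution by direct enumeration of gamete combinations.

    Walks every (maternal allele, pollen allele, transgene carriage)
    combination, applies the SI rule inline (a style S-RNase survives
    unless it is nonself to the pollen or a transgene target), and
    normalises over the surviving combinations.  Independent of
    :func:`slocus_evo.si_genetics.predict_progeny`.
    """
    targets = set(transgene_targets)
    style = tuple(parent_alleles)
    surviving = {}
    carriage = [True, False] if hemizygous else [True]
    for maternal in parent_alleles:
        for paternal in parent_alleles:
            for carries in carriage:
                detox = {a for a in style if a != paternal}
                if carries:
                    detox |= targets & set(style)
                if set(style) <= detox:
                    key = "".join(sorted((maternal, paternal)))
                    surviving[key] = surviving.get(key, 0) + 1
    total = sum(surviving.values())
    labels = {"".join(sorted((a, b))) for a in style for b in style}
    return {lab: surviving.get(lab, 0) / total for lab in labels}
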