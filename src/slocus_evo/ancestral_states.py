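"""Marginal ancestral-state reconstruction of discrete SI traits under F81.

The trait (which kind of S-locus machinery a plant family carries) is
modelled as a K-state continuous-time Markov chain of the F81 type:
every substitution draws the new state from the stationary distribution
pi, so the transition kernel for a branch of length t is

    P(i -> j | t) = exp(-mu*rho*t) * 1[i == j] + (1 - exp(-mu*rho*t)) * pi_j

with mu = 1 / (1 - sum_j pi_j**2) normalising the chain to one expected
substitution per unit of rho*t.  Branch lengths are in Myr on dated
trees; rho is a single free rate.

Likelihoods use Felsenstein's pruning algorithm with per-node scaling;
marginal posteriors per internal node come from the standard
outside (up-down) algorithm.  Missing tip observations contribute
all-ones partials.  Multifurcations are handled natively.

The default 8-state alphabet codes the SI trait repertoire: Class I/II
T2 RNases without linked F-box genes; linked Class I/II RNases and
FBA/FBK genes; linked Class III RNases and SLFs (the type-1 S-locus);
type-1 plus a type-3 locus; a type-2 locus; a type-4 locus; S-like
RNases with no linked SLFs; and absence of both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy import optimize

__all__ = [
    "DEFAULT_TRAIT_STATES",
    "TraitAlphabet",
    "F81Params",
    "TraitTree",
    "f81_matrix",
    "f81_transition",
    "tree_log_likelihood",
    "marginal_posteriors",
    "fit_and_reconstruct",
    "select_states_mppa",
]

#: the 8 SI-trait states, in fixed order (MAP ties break toward the first)
DEFAULT_TRAIT_STATES = (
    "classI_II_unlinked",
    "classI_II_linked_fbafbk",
    "type1_slocus",
    "type1_plus_type3",
    "type2_slocus",
    "type4_slocus",
    "slike_rnase_unlinked",
    "absent",
)


@dataclass(frozen=True)
class TraitAlphabet:
    """Ordered state labels of a discrete character."""

    states: Tuple[str, ...] = DEFAULT_TRAIT_STATES

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        if len(self.states) < 2:
            raise ValueError("need at least two states")

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise ValueError(f"unknown trait state {label!r}") from None


@dataclass(frozen=True)
class F81Params:
    """Stationary frequencies pi and rate scaling rho of the F81 chain."""

    pi: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("pi must sum to 1")
        if np.any(pi <= 0):
            raise ValueError("all pi entries must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "pi", pi)

    @property
    def mu(self) -> float:
        """Normaliser so rho*t counts expected substitutions."""
        return 1.0 / (1.0 - float(np.sum(self.pi**2)))


def f81_matrix(t: float, params: F81Params) -> np.ndarray:
    """Full K x K transition matrix for a branch of length t."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    decay = math.exp(-params.mu * params.rate * t)
    K = params.pi.size
    return decay * np.eye(K) + (1.0 - decay) * np.tile(params.pi, (K, 1))


def f81_transition(i: int, j: int, t: float, params: F81Params) -> float:
    """Single transition probability P(i -> j | t)."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    decay = math.exp(-params.mu * params.rate * t)
    return decay * (i == j) + (1.0 - decay) * float(params.pi[j])


class TraitTree:
    """A rooted dated tree with tip trait observations.

    Wraps a :class:`dendropy.Tree`; tips may have missing states
    (``None``).  After :func:`marginal_posteriors` each node carries a
    posterior vector in ``posteriors`` keyed by node label (internal
    nodes are auto-labelled ``N1, N2, ...`` in preorder if unlabelled).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        tip_states: Mapping[str, Optional[str]],
        alphabet: Optional[TraitAlphabet] = None,
    ) -> None:
        self.tree = tree
        if alphabet is not None:
            self.alphabet = alphabet
        else:
            observed = {s for s in tip_states.values() if s is not None}
            if observed.issubset(DEFAULT_TRAIT_STATES):
                self.alphabet = TraitAlphabet()
            else:
                self.alphabet = TraitAlphabet(tuple(sorted(observed)))
        self.tip_states: Dict[str, Optional[str]] = dict(tip_states)
        self.posteriors: Dict[str, np.ndarray] = {}
        self._label_nodes()
        self._validate()

    @classmethod
    def from_newick(
        cls,
        newick: str,
        tip_states: Mapping[str, Optional[str]],
        alphabet: Optional[TraitAlphabet] = None,
    ) -> "TraitTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree, tip_states, alphabet)

    def _label_nodes(self) -> None:
        i = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label is None:
                i += 1
                node.label = f"N{i}"

    def _validate(self) -> None:
        for leaf in self.tree.leaf_node_iter():
            name = leaf.taxon.label
            if name not in self.tip_states:
                raise ValueError(f"no trait observation for tip {name!r}")
            state = self.tip_states[name]
            if state is not None:
                self.alphabet.index(state)
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    def node_label(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def tip_partial(self, leaf: dendropy.Node) -> np.ndarray:
        state = self.tip_states[leaf.taxon.label]
        if state is None:
            return np.ones(self.alphabet.size)
        v = np.zeros(self.alphabet.size)
        v[self.alphabet.index(state)] = 1.0
        return v


def _edge_length(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def _up_pass(
    tt: TraitTree, params: F81Params
) -> Tuple[Dict[int, np.ndarray], float]:
    """Scaled conditional likelihoods per node; returns (partials, log-scale)."""
    partials: Dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tt.tree.postorder_node_iter():
        if node.is_leaf():
            partials[id(node)] = tt.tip_partial(node)
            continue
        part = np.ones(tt.alphabet.size)
        for child in node.child_nodes():
            P = f81_matrix(_edge_length(child), params)
            part = part * (P @ partials[id(child)])
        s = part.sum()
        if s <= 0:
            raise ValueError("zero likelihood: tip states inconsistent with pi")
        partials[id(node)] = part / s
        log_scale += math.log(s)
    return partials, log_scale


def tree_log_likelihood(tt: TraitTree, params: F81Params) -> float:
    """Log-likelihood of the tip data by Felsenstein pruning."""
    partials, log_scale = _up_pass(tt, params)
    root = tt.tree.seed_node
    return float(np.log(params.pi @ partials[id(root)]) + log_scale)


def marginal_posteriors(
    tt: TraitTree, params: F81Params
) -> Dict[str, np.ndarray]:
    """Per-node marginal posterior state distributions (up + down pass).

    Tips with observed states get point masses; missing tips get a
    genuine posterior.  Results are stored on ``tt.posteriors`` and
    returned keyed by node label.
    """
    partials, _ = _up_pass(tt, params)
    root = tt.tree.seed_node
    outside: Dict[int, np.ndarray] = {id(root): params.pi.copy()}
    posteriors: Dict[str, np.ndarray] = {}
    for node in tt.tree.preorder_node_iter():
        out = outside[id(node)]
        post = out * partials[id(node)]
        posteriors[tt.node_label(node)] = post / post.sum()
        children = node.child_nodes()
        if not children:
            continue
        # message each child the product of the outside weight and the
        # other children's upward messages, pushed through its branch
        msgs = []
        for child in children:
            P = f81_matrix(_edge_length(child), params)
            msgs.append(P @ partials[id(child)])
        for k, child in enumerate(children):
            others = out.copy()
            for m, msg in enumerate(msgs):
                if m != k:
                    others = others * msg
            Pk = f81_matrix(_edge_length(child), params)
            down = Pk.T @ others
            s = down.sum()
            outside[id(child)] = down / s if s > 0 else down
    tt.posteriors = posteriors
    return posteriors


def _tree_height(tt: TraitTree) -> float:
    heights = []
    for leaf in tt.tree.leaf_node_iter():
        h, node = 0.0, leaf
        while node.parent_node is not None:
            h += _edge_length(node)
            node = node.parent_node
        heights.append(h)
    return max(heights) if heights else 1.0


def _observed_pi(tt: TraitTree, pseudocount: float = 1.0) -> np.ndarray:
    counts = np.full(tt.alphabet.size, pseudocount)
    for state in tt.tip_states.values():
        if state is not None:
            counts[tt.alphabet.index(state)] += 1
    return counts / counts.sum()


@dataclass
class ReconstructionResult:
    params: F81Params
    log_likelihood: float
    posteriors: Dict[str, np.ndarray]
    map_states: Dict[str, str]
    rate_at_bound: bool = False


def fit_and_reconstruct(
    tt: TraitTree,
    pi_mode: str = "observed",
    rate_mode: str = "ml",
) -> ReconstructionResult:
    """Estimate (pi, rho), reconstruct marginal posteriors and MAP states.

    ``pi_mode='observed'`` takes tip state frequencies with pseudocount 1
    (robust for small trees); ``'ml'`` maximises the likelihood jointly
    over the simplex (softmax parametrisation) and the rate.  The rate is
    searched on [1e-6/h, 1e3/h] with h the tree height, so the bracket
    spans effectively-frozen to effectively-saturated evolution.  MAP
    ties break toward the earlier alphabet state.
    """
    if rate_mode != "ml":
        raise ValueError("only rate_mode='ml' is supported")
    observed = {s for s in tt.tip_states.values() if s is not None}
    h = _tree_height(tt)
    lo, hi = 1e-6 / h, 1e3 / h
    rate_at_bound = False

    if pi_mode == "observed":
        pi = _observed_pi(tt)
        if len(observed) < 2:
            import warnings

            warnings.warn(
                "all observed tips share one state; rate is unidentifiable, "
                "returning the lower search bound", stacklevel=2
            )
            params = F81Params(pi=pi, rate=lo)
            rate_at_bound = True
        else:
            res = optimize.minimize_scalar(
                lambda r: -tree_log_likelihood(tt, F81Params(pi=pi, rate=r)),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            params = F81Params(pi=pi, rate=float(res.x))
    elif pi_mode == "ml":
        K = tt.alphabet.size

        def unpack(theta: np.ndarray) -> F81Params:
            w = np.concatenate([[0.0], theta[:-1]])
            pi = np.exp(w - w.max())
            pi = pi / pi.sum()
            pi = np.clip(pi, 1e-9, None)
            pi = pi / pi.sum()
            return F81Params(pi=pi, rate=float(np.exp(theta[-1])))

        def nll(theta: np.ndarray) -> float:
            try:
                return -tree_log_likelihood(tt, unpack(theta))
            except (ValueError, OverflowError):
                return 1e12

        x0 = np.concatenate([np.zeros(K - 1), [math.log(1.0 / h)]])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6,
                                         "fatol": 1e-8})
        params = unpack(res.x)
    else:
        raise ValueError(f"unknown pi_mode {pi_mode!r}")

    posts = marginal_posteriors(tt, params)
    map_states = {
        label: tt.alphabet.states[int(np.argmax(v))] for label, v in posts.items()
    }
    return ReconstructionResult(
        params=params,
        log_likelihood=tree_log_likelihood(tt, params),
        posteriors=posts,
        map_states=map_states,
        rate_at_bound=rate_at_bound,
    )


def select_states_mppa(
    posteriors: Mapping[str, np.ndarray],
    alphabet: TraitAlphabet,
    threshold_fraction: float = 0.5,
) -> Dict[str, List[str]]:
    """Per-node plausible state subsets from marginal posteriors.

    A state is kept when its posterior reaches ``threshold_fraction``
    of the node's maximum posterior; the MAP state is always included,
    so the subset is never empty.  This is a thresholded simplification
    of multi-state marginal selection; downstream users who need the
    full distribution should read ``posteriors`` directly.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    out: Dict[str, List[str]] = {}
    for label, v in posteriors.items():
        cutoff = threshold_fraction * float(v.max())
        out[label] = [
            alphabet.states[k] for k in range(alphabet.size) if v[k] >= cutoff
        ]
    return out
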