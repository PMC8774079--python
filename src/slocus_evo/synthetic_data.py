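"""Simulators producing inputs with the structure the analyses assume.

Four generators, each a pure function of (config, seed):

* :func:`gen_genome` — scaffolds carrying planted type-1 S-loci (an
  S-RNase flanked by a cluster of SLF F-box genes), decoy genes beyond
  the linkage window, optional pseudogenes (injected in-frame stops),
  plus the ground truth needed for recovery tests;
* :func:`gen_detox_matrix` — Bernoulli haplotype-by-S-RNase
  detoxification matrices with the self diagonal forced off;
* :func:`gen_progeny` — multinomially sampled self-progeny genotype
  counts from the pollination model's predicted distribution;
* :func:`gen_trait_history` — forward simulation of the F81 trait chain
  down a dated tree, recording internal-node truth.

One global seed fans out to per-component child seeds through
:func:`child_seed`, so individual datasets are independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from slocus_evo.ancestral_states import F81Params, TraitTree, f81_matrix
from slocus_evo.locus_annotation import GeneClass, GeneRecord
from slocus_evo.si_genetics import DetoxSpec, predict_progeny

__all__ = [
    "GenomeSimConfig",
    "TruthRecord",
    "SyntheticGenome",
    "child_seed",
    "gen_genome",
    "gen_detox_matrix",
    "gen_progeny",
    "gen_trait_history",
    "random_coalescent_tree",
]

_NON_STOP_CODONS = np.array(
    [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
)

#: fixed offsets fanning one global seed out to the component generators
_SEED_OFFSETS = {"genome": 11, "matrix": 23, "progeny": 37, "traits": 53}


def child_seed(seed: int, component: str) -> int:
    """Derive a component-specific child seed from one global seed."""
    return (seed * 1_000_003 + _SEED_OFFSETS[component]) % (2**31 - 1)


@dataclass(frozen=True)
class GenomeSimConfig:
    """Layout of a simulated genome with planted type-1 loci.

    Defaults emulate the observed locus anatomy: an S-RNase flanked by a
    cluster of 9-37 SLFs spanning up to ~1.2 Mb, on multi-Mb scaffolds,
    with planted loci separated by more than the 3-Mb linkage window.
    """

    n_loci: int = 4
    slfs_per_locus: Tuple[int, int] = (9, 37)
    gene_len_bp: Tuple[int, int] = (900, 3000)  # CDS 0.9-3 kb
    intergenic_bp: Tuple[int, int] = (5_000, 40_000)
    scaffold_len_bp: int = 12_000_000
    n_short_scaffolds: int = 2  # below the 1-Mb filter, carrying decoys
    short_scaffold_len_bp: int = 500_000
    pseudogene_rate: float = 0.0  # per-locus probability the S-RNase is dead
    slf_pseudogene_rate: float = 0.0  # per-SLF probability of an injected stop
    n_decoy_fbox: int = 6  # F-boxes placed beyond the window from any RNase
    n_decoy_other: int = 10
    window: int = 3_000_000

    def __post_init__(self) -> None:
        if self.n_loci < 0:
            raise ValueError("n_loci must be non-negative")
        span_budget = self.slfs_per_locus[1] * (
            self.gene_len_bp[1] + self.intergenic_bp[1]
        )
        # one locus per scaffold plus decoys beyond the window must fit
        if span_budget + self.window + 200_000 > self.scaffold_len_bp:
            raise ValueError(
                "infeasible placement: locus span plus linkage window "
                "exceeds the scaffold length"
            )


@dataclass
class TruthRecord:
    """Ground truth serialised alongside every generated dataset."""

    planted_loci: List[Dict] = field(default_factory=list)
    pseudogene_ids: List[str] = field(default_factory=list)
    route_scenario: Optional[str] = None
    trait_history: Optional[Dict[str, str]] = None
    params: Dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticGenome:
    genes: List[GeneRecord]
    cds: Dict[str, str]
    scaffold_lengths: Dict[str, int]
    truth: TruthRecord

    def write_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes, key=lambda x: (x.scaffold, x.start)):
                attrs = f"ID={g.gene_id};gene_class={g.gene_class.value}"
                fh.write(
                    f"{g.scaffold}\tslocus-evo-sim\tgene\t{g.start + 1}\t"
                    f"{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    def write_cds_fasta(self, path: str) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=gene_id, description="")
            for gene_id, seq in sorted(self.cds.items())
        ]
        SeqIO.write(records, path, "fasta")


def _random_cds(rng: np.random.Generator, length_range: Tuple[int, int]) -> str:
    n_codons = int(rng.integers(length_range[0] // 3, length_range[1] // 3 + 1))
    codons = rng.choice(_NON_STOP_CODONS, size=max(2, n_codons))
    return "".join(codons)


def _pseudogenize(rng: np.random.Generator, cds: str) -> str:
    # replace one internal codon with TAA
    n_codons = len(cds) // 3
    k = int(rng.integers(1, n_codons - 1))
    return cds[: 3 * k] + "TAA" + cds[3 * (k + 1) :]


def gen_genome(config: GenomeSimConfig, seed: int) -> SyntheticGenome:
    """Simulate a genome with planted type-1 S-loci and decoys.

    One locus per long scaffold: a central S-RNase (Class III) with its
    SLF cluster, all within the linkage window of the anchor.  Decoy
    F-box genes sit beyond the window from every RNase; decoy OTHER
    genes are scattered freely; short scaffolds (below the 1-Mb filter)
    carry extra decoys.  Pseudogenes get an in-frame stop injected into
    their CDS, never silently.
    """
    rng = np.random.default_rng(seed)
    genes: List[GeneRecord] = []
    cds: Dict[str, str] = {}
    scaffold_lengths: Dict[str, int] = {}
    truth = TruthRecord(params={"seed": seed, **asdict(config)})

    def add_gene(gene_id, scaffold, start, length, gene_class, pseudo):
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _random_cds(rng, config.gene_len_bp)
        if pseudo:
            seq = _pseudogenize(rng, seq)
            truth.pseudogene_ids.append(gene_id)
        genes.append(
            GeneRecord(gene_id, scaffold, int(start), int(start + length),
                       strand, gene_class)
        )
        cds[gene_id] = seq
        return int(start + length)

    for li in range(config.n_loci):
        scaffold = f"scf{li + 1:02d}"
        scaffold_lengths[scaffold] = config.scaffold_len_bp
        n_slf = int(
            rng.integers(config.slfs_per_locus[0], config.slfs_per_locus[1] + 1)
        )
        rnase_pseudo = bool(rng.random() < config.pseudogene_rate)
        pos = int(rng.integers(50_000, 150_000))
        members = []
        # RNase goes at a random position inside the cluster
        rnase_slot = int(rng.integers(0, n_slf + 1))
        for slot in range(n_slf + 1):
            length = int(rng.integers(*config.gene_len_bp))
            if slot == rnase_slot:
                gid = f"{scaffold}_SRNase"
                gclass, pseudo = GeneClass.T2_RNASE_III, rnase_pseudo
            else:
                gid = f"{scaffold}_SLF{slot + 1:02d}"
                gclass = GeneClass.FBX_SLF
                pseudo = bool(rng.random() < config.slf_pseudogene_rate)
            end = add_gene(gid, scaffold, pos, length, gclass, pseudo)
            members.append(gid)
            pos = end + int(rng.integers(*config.intergenic_bp))
        locus_end = genes[-1].end
        all_slf_pseudo = all(
            g.gene_id in truth.pseudogene_ids
            for g in genes
            if g.scaffold == scaffold and g.gene_class is GeneClass.FBX_SLF
        )
        truth.planted_loci.append(
            {
                "scaffold": scaffold,
                "members": sorted(members),
                "type": "TYPE1_S_LIKE",
                "active": not (rnase_pseudo or all_slf_pseudo),
            }
        )
        # decoy F-boxes strictly beyond the window from the locus span
        decoy_start = locus_end + config.window + 100_000
        for d in range(config.n_decoy_fbox // max(1, config.n_loci)):
            length = int(rng.integers(*config.gene_len_bp))
            gcls = GeneClass.FBX_SLF if rng.random() < 0.5 else GeneClass.FBX_OTHER
            decoy_start = add_gene(
                f"{scaffold}_decoyF{d + 1}", scaffold, decoy_start, length,
                gcls, False,
            ) + int(rng.integers(*config.intergenic_bp))
            if decoy_start > config.scaffold_len_bp - 10_000:
                break

    for si in range(config.n_short_scaffolds):
        scaffold = f"short{si + 1:02d}"
        scaffold_lengths[scaffold] = config.short_scaffold_len_bp
        pos = int(rng.integers(10_000, 50_000))
        for d in range(2):
            length = int(rng.integers(*config.gene_len_bp))
            gcls = (
                GeneClass.T2_RNASE_III if (si + d) % 2 == 0 else GeneClass.FBX_SLF
            )
            pos = add_gene(f"{scaffold}_g{d + 1}", scaffold, pos, length,
                           gcls, False) + 20_000

    # free-floating decoys on the long scaffolds, safely beyond the
    # window from the locus (which always ends well before midpoint)
    long_scaffolds = [s for s in scaffold_lengths if s.startswith("scf")]
    for d in range(config.n_decoy_other):
        if not long_scaffolds:
            break
        scaffold = long_scaffolds[int(rng.integers(len(long_scaffolds)))]
        length = int(rng.integers(*config.gene_len_bp))
        start = int(
            rng.integers(
                config.scaffold_len_bp - 1_000_000,
                config.scaffold_len_bp - 10_000 - length,
            )
        )
        add_gene(f"decoyO{d + 1}", scaffold, start, length, GeneClass.OTHER,
                 False)

    return SyntheticGenome(genes, cds, scaffold_lengths, truth)


def gen_detox_matrix(
    n_haplotypes: int, p_r: float, seed: int
) -> np.ndarray:
    """Bernoulli(p_r) haplotype x S-RNase detoxification matrix.

    Entry [h, a]: the SLF repertoire of haplotype h detoxifies S-RNase
    a.  Off-diagonal entries are independent Bernoulli(p_r); the
    diagonal is False (a haplotype never detoxifies its own S-RNase).
    """
    if n_haplotypes < 3:
        raise ValueError("need at least 3 haplotypes")
    if not 0.0 <= p_r <= 1.0:
        raise ValueError("p_r must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = rng.random((n_haplotypes, n_haplotypes)) < p_r
    np.fill_diagonal(m, False)
    return m


def gen_progeny(
    parent_alleles: Tuple[str, str],
    transgene_spec: DetoxSpec,
    n_offspring: int,
    seed: int,
    transgene_zygosity: str = "hemizygous",
) -> Dict[str, int]:
    """Multinomial self-progeny genotype counts from the predicted law."""
    pred = predict_progeny(parent_alleles, transgene_spec, transgene_zygosity)
    labels = sorted(pred)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_offspring, [pred[l] for l in labels])
    return dict(zip(labels, (int(c) for c in draws)))


def gen_trait_history(
    tt: TraitTree, params: F81Params, seed: int
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Forward-simulate the F81 chain down the tree.

    Root state drawn from pi; each child's state drawn from the F81
    kernel row of its parent.  Returns (tip_states, internal_states),
    keyed by tip taxon label / internal node label.
    """
    rng = np.random.default_rng(seed)
    K = tt.alphabet.size
    states: Dict[int, int] = {}
    tips: Dict[str, str] = {}
    internal: Dict[str, str] = {}
    for node in tt.tree.preorder_node_iter():
        if node.parent_node is None:
            s = int(rng.choice(K, p=params.pi))
        else:
            t = node.edge.length if node.edge.length is not None else 0.0
            row = f81_matrix(t, params)[states[id(node.parent_node)]]
            s = int(rng.choice(K, p=row))
        states[id(node)] = s
        label = tt.alphabet.states[s]
        if node.is_leaf():
            tips[node.taxon.label] = label
        else:
            internal[tt.node_label(node)] = label
    return tips, internal


def random_coalescent_tree(
    n_tips: int, seed: int, height: float = 100.0
) -> dendropy.Tree:
    """Random rooted binary tree with tip labels t1..tn, ultrametric-ish.

    Built by sequential random joins with exponential waiting times
    rescaled so the root sits at ``height`` (Myr); a convenience for
    simulation studies, not a population-genetic coalescent.
    """
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    nodes = []
    depth = {}
    for i in range(n_tips):
        leaf = dendropy.Node(taxon=taxa[i])
        nodes.append(leaf)
        depth[id(leaf)] = 0.0
    t = 0.0
    while len(nodes) > 1:
        t += float(rng.exponential(1.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        depth[id(parent)] = t
        a.edge.length = t - depth[id(a)]
        b.edge.length = t - depth[id(b)]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    scale = height / depth[id(root)]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    tree.is_rooted = True
    return tree
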