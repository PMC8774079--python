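"""Annotation of type-1 S- and S-like loci from classified gene tables.

A type-1 S-locus is an S-RNase (a Class III T2-family ribonuclease) with
a linked cluster of SLF F-box genes.  Given gene features that already
carry a gene-class label (T2-RNase Class I/II/III, SLF-subfamily F-box,
other F-box, other), this module applies the genomic annotation rules:

* drop genes on scaffolds shorter than 1 Mb, the smallest linkage region
  a type-1 S-/S-like locus can occupy;
* call pseudogenes from CDS in-frame premature stop codons;
* link F-box genes to each RNase anchor within a 3-Mb window (gap
  between gene spans, boundary-inclusive), merging anchors that share a
  linked F-box into one locus;
* type each locus (type-1 S-like, Class I/II-linked, orphan RNase) and
  call it ACTIVE when it retains both an intact RNase and an intact SLF.

Coordinates are 0-based half-open internally; GFF3 I/O converts from the
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "GeneClass",
    "LocusType",
    "Activity",
    "GeneRecord",
    "Locus",
    "SpeciesProfile",
    "STOP_CODONS",
    "filter_scaffolds",
    "detect_pseudogene",
    "annotate_pseudogenes",
    "gene_gap",
    "link_genes",
    "call_loci",
    "summarize_genome",
    "read_gff3",
    "loci_table",
]

DEFAULT_WINDOW = 3_000_000  #: linkage window around an RNase anchor (bp)
DEFAULT_MIN_SCAFFOLD = 1_000_000  #: minimum scaffold length retained (bp)
DEFAULT_TPM_THRESHOLD = 1.0  #: below this TPM a gene counts as low-expressed

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GeneClass(str, Enum):
    T2_RNASE_I = "T2_RNASE_I"
    T2_RNASE_II = "T2_RNASE_II"
    T2_RNASE_III = "T2_RNASE_III"
    FBX_SLF = "FBX_SLF"
    FBX_OTHER = "FBX_OTHER"
    OTHER = "OTHER"


RNASE_CLASSES = frozenset(
    {GeneClass.T2_RNASE_I, GeneClass.T2_RNASE_II, GeneClass.T2_RNASE_III}
)
FBOX_CLASSES = frozenset({GeneClass.FBX_SLF, GeneClass.FBX_OTHER})


class LocusType(str, Enum):
    TYPE1_S = "TYPE1_S"
    TYPE1_S_LIKE = "TYPE1_S_LIKE"
    CLASSI_II_LINKED = "CLASSI_II_LINKED"
    ORPHAN_RNASE = "ORPHAN_RNASE"


class Activity(str, Enum):
    ACTIVE = "ACTIVE"
    INACTIVE = "INACTIVE"


class SIPhenotype(str, Enum):
    TYPE1_SI = "TYPE1_SI"
    TYPE2_SI = "TYPE2_SI"
    TYPE3_SI = "TYPE3_SI"
    TYPE4_SI = "TYPE4_SI"
    GSI_OTHER = "GSI_OTHER"
    SSI_OTHER = "SSI_OTHER"
    SC = "SC"
    DIOECIOUS = "DIOECIOUS"


@dataclass(frozen=True)
class GeneRecord:
    """A classified gene feature; coordinates 0-based half-open."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    gene_class: GeneClass
    pseudo: Optional[bool] = None
    expression: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class Locus:
    """A clustered RNase + F-box locus with a type and activity call."""

    locus_id: str
    scaffold: str
    span: Tuple[int, int]
    rnases: List[GeneRecord]
    fboxes: List[GeneRecord]
    locus_type: LocusType
    activity: Activity
    low_expression: bool = False  # all intact SLFs below the TPM threshold

    @property
    def members(self) -> List[GeneRecord]:
        return [*self.rnases, *self.fboxes]

    def n_intact_slfs(self) -> int:
        return sum(
            1
            for g in self.fboxes
            if g.gene_class is GeneClass.FBX_SLF and not g.pseudo
        )


@dataclass
class SpeciesProfile:
    """Per-species SI phenotype and type-1 locus inventory."""

    species: str
    si_phenotype: SIPhenotype
    wgd_events: int
    loci: List[Locus] = field(default_factory=list)
    counts: Dict[str, int] = field(default_factory=dict)


def filter_scaffolds(
    genes: Iterable[GeneRecord],
    scaffold_lengths: Mapping[str, int],
    min_len: int = DEFAULT_MIN_SCAFFOLD,
) -> List[GeneRecord]:
    """Drop genes on scaffolds shorter than ``min_len`` (boundary inclusive).

    Short scaffolds cannot demonstrate the linkage that defines a type-1
    locus, so their genes are excluded from locus calling.
    """
    genes = list(genes)
    for g in genes:
        if g.scaffold not in scaffold_lengths:
            raise ValueError(f"no declared length for scaffold {g.scaffold!r}")
    kept = [g for g in genes if scaffold_lengths[g.scaffold] >= min_len]
    dropped = len(genes) - len(kept)
    if dropped:
        warnings.warn(
            f"filter_scaffolds: removed {dropped}/{len(genes)} genes on "
            f"scaffolds < {min_len} bp",
            stacklevel=2,
        )
    return kept


def detect_pseudogene(cds: str, codon_table: str = "Standard") -> bool:
    """True iff the CDS contains an in-frame premature stop codon.

    Frame 0 of the annotated CDS is scanned; a stop in the final codon
    position is the normal terminator and does not count.  Codons
    containing N (or any non-ACGT base) are never stops.  A trailing
    partial codon is truncated with a warning.
    """
    if codon_table != "Standard":
        raise ValueError("only the standard codon table is supported")
    seq = cds.upper()
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(seq) % 3:
        warnings.warn("CDS length not a multiple of 3; truncating remainder",
                      stacklevel=2)
        seq = seq[: len(seq) - len(seq) % 3]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return any(c in STOP_CODONS for c in codons[:-1])


def annotate_pseudogenes(
    genes: Iterable[GeneRecord], cds: Mapping[str, str]
) -> List[GeneRecord]:
    """Fill each record's ``pseudo`` flag from its CDS where available."""
    out = []
    for g in genes:
        if g.gene_id in cds:
            out.append(replace(g, pseudo=detect_pseudogene(cds[g.gene_id])))
        else:
            out.append(g)
    return out


def gene_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Gap in bp between two gene spans on one scaffold (0 if overlapping)."""
    if a.scaffold != b.scaffold:
        raise ValueError("genes on different scaffolds have no defined gap")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def link_genes(
    anchor: GeneRecord,
    candidates: Iterable[GeneRecord],
    window: int = DEFAULT_WINDOW,
) -> List[GeneRecord]:
    """F-box genes linked to an RNase anchor: same scaffold, gap <= window."""
    if anchor.gene_class not in RNASE_CLASSES:
        raise ValueError(f"anchor {anchor.gene_id} is not an RNase-class gene")
    return [
        c
        for c in candidates
        if c.scaffold == anchor.scaffold and gene_gap(anchor, c) <= window
    ]


def _merge_anchor_groups(
    linked: Dict[str, List[GeneRecord]]
) -> List[List[str]]:
    """Union-find merge of anchors sharing at least one linked F-box."""
    parent = {a: a for a in linked}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_fbox: Dict[str, str] = {}
    for a, fbs in linked.items():
        for fb in fbs:
            if fb.gene_id in by_fbox:
                ra, rb = find(a), find(by_fbox[fb.gene_id])
                if ra != rb:
                    parent[ra] = rb
            else:
                by_fbox[fb.gene_id] = a
    groups: Dict[str, List[str]] = {}
    for a in linked:
        groups.setdefault(find(a), []).append(a)
    return list(groups.values())


def call_loci(
    genes: Iterable[GeneRecord],
    window: int = DEFAULT_WINDOW,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    expression_tissue: str = "stamen",
) -> List[Locus]:
    """Cluster RNase anchors with their linked F-box genes into loci.

    Every RNase-class gene anchors a candidate locus containing the
    F-box genes within the linkage window; anchors sharing a linked
    F-box are merged.  Locus typing: a Class III RNase with >= 1 linked
    SLF-subfamily F-box gives a type-1 S-like locus (promotion of one
    locus to TYPE1_S is phenotype-dependent and happens in
    :func:`summarize_genome`); a Class I/II RNase with linked F-boxes
    gives a Class I/II-linked locus; an RNase with no linked F-box is an
    orphan.  Activity requires one intact (non-pseudogene) RNase and one
    intact SLF.  Output is deterministic: loci sorted by (scaffold,
    span), members by coordinate.
    """
    genes = list(genes)
    rnases = [g for g in genes if g.gene_class in RNASE_CLASSES]
    fboxes = [g for g in genes if g.gene_class in FBOX_CLASSES]
    linked = {r.gene_id: link_genes(r, fboxes, window) for r in rnases}
    by_id = {g.gene_id: g for g in genes}

    loci: List[Locus] = []
    for group in _merge_anchor_groups(linked):
        grp_rnases = sorted((by_id[a] for a in group), key=lambda g: g.start)
        grp_fboxes = sorted(
            {fb.gene_id: fb for a in group for fb in linked[a]}.values(),
            key=lambda g: g.start,
        )
        members = [*grp_rnases, *grp_fboxes]
        span = (min(g.start for g in members), max(g.end for g in members))
        has_class3 = any(
            g.gene_class is GeneClass.T2_RNASE_III for g in grp_rnases
        )
        has_slf = any(g.gene_class is GeneClass.FBX_SLF for g in grp_fboxes)
        if not grp_fboxes:
            ltype = LocusType.ORPHAN_RNASE
        elif has_class3 and has_slf:
            ltype = LocusType.TYPE1_S_LIKE
        else:
            ltype = LocusType.CLASSI_II_LINKED
        intact_rnase = any(not g.pseudo for g in grp_rnases)
        intact_slf = any(
            not g.pseudo
            for g in grp_fboxes
            if g.gene_class is GeneClass.FBX_SLF
        )
        activity = (
            Activity.ACTIVE if intact_rnase and intact_slf else Activity.INACTIVE
        )
        intact_slfs = [
            g
            for g in grp_fboxes
            if g.gene_class is GeneClass.FBX_SLF and not g.pseudo
        ]
        low_expr = bool(intact_slfs) and all(
            g.expression is not None
            and g.expression.get(expression_tissue, float("inf")) < tpm_threshold
            for g in intact_slfs
        )
        loci.append(
            Locus(
                locus_id="",  # assigned after sorting
                scaffold=grp_rnases[0].scaffold,
                span=span,
                rnases=grp_rnases,
                fboxes=grp_fboxes,
                locus_type=ltype,
                activity=activity,
                low_expression=low_expr,
            )
        )
    loci.sort(key=lambda l: (l.scaffold, l.span))
    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"locus_{i:03d}"
    return loci


def summarize_genome(
    loci: Sequence[Locus],
    phenotype: SIPhenotype | str,
    wgd_events: int = 0,
    species: str = "unknown",
) -> SpeciesProfile:
    """Tally loci per type x activity into a species profile.

    For a species with demonstrated type-1 SI, the functional S-locus is
    the one carrying the largest intact SLF cluster; that locus is
    promoted from TYPE1_S_LIKE to TYPE1_S (ties: larger span, then
    scaffold name).
    """
    phenotype = SIPhenotype(phenotype)
    loci = [
        replace_locus(l) for l in loci
    ]  # shallow copies so promotion does not mutate inputs
    if phenotype is SIPhenotype.TYPE1_SI:
        type1 = [l for l in loci if l.locus_type is LocusType.TYPE1_S_LIKE]
        if type1:
            best = sorted(
                type1,
                key=lambda l: (
                    -l.n_intact_slfs(),
                    -(l.span[1] - l.span[0]),
                    l.scaffold,
                ),
            )[0]
            best.locus_type = LocusType.TYPE1_S
    counts: Dict[str, int] = {}
    for l in loci:
        counts[f"{l.locus_type.value}:{l.activity.value}"] = (
            counts.get(f"{l.locus_type.value}:{l.activity.value}", 0) + 1
        )
    return SpeciesProfile(
        species=species,
        si_phenotype=phenotype,
        wgd_events=wgd_events,
        loci=loci,
        counts=counts,
    )


def replace_locus(l: Locus) -> Locus:
    return Locus(
        locus_id=l.locus_id,
        scaffold=l.scaffold,
        span=l.span,
        rnases=list(l.rnases),
        fboxes=list(l.fboxes),
        locus_type=l.locus_type,
        activity=l.activity,
        low_expression=l.low_expression,
    )


# ---------------------------------------------------------------------------
# I/O


def read_gff3(
    path_or_text: str,
    expression: Optional[Mapping[str, Mapping[str, float]]] = None,
    from_string: bool = False,
) -> List[GeneRecord]:
    """Read gene features with a ``gene_class`` attribute from GFF3.

    1-based inclusive GFF3 coordinates are converted to the package's
    0-based half-open convention.  An optional ``pseudo=true`` attribute
    presets the pseudogene flag (otherwise left for CDS-based detection).
    """
    import gffutils

    db = gffutils.create_db(
        path_or_text,
        ":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    for f in db.features_of_type("gene"):
        gene_class = GeneClass(f.attributes["gene_class"][0])
        pseudo = None
        if "pseudo" in f.attributes:
            pseudo = f.attributes["pseudo"][0].lower() == "true"
        records.append(
            GeneRecord(
                gene_id=f.id,
                scaffold=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                gene_class=gene_class,
                pseudo=pseudo,
                expression=(expression or {}).get(f.id),
            )
        )
    return records


def loci_table(loci: Sequence[Locus]) -> pd.DataFrame:
    """Loci as a tidy table (one row per locus) for TSV export."""
    rows = []
    for l in loci:
        rows.append(
            {
                "locus_id": l.locus_id,
                "scaffold": l.scaffold,
                "start": l.span[0],
                "end": l.span[1],
                "locus_type": l.locus_type.value,
                "activity": l.activity.value,
                "low_expression": l.low_expression,
                "rnases": ",".join(g.gene_id for g in l.rnases),
                "fboxes": ",".join(g.gene_id for g in l.fboxes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "scaffold", "start", "end", "locus_type",
            "activity", "low_expression", "rnases", "fboxes",
        ],
    )
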