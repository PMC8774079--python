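# Methods

## Pollination model

A diploid plant with S-haplotypes (S_a, S_b) expresses both S-RNases in
the style.  Pollen is haploid: half carries S_a, half S_b.  A
single-locus transgene insertion segregates independently of the
S-locus; a hemizygous parent (the default, matching primary
transformants) transmits it to half the pollen of each S-class, a
homozygous parent to all pollen.  Pollen survives iff every style
S-RNase is detoxified by the union of

* its endogenous SLF repertoire — modelled as detoxifying **all**
  nonself S-RNases in the allele universe and never its own (the
  complete collaborative network within a species; deviations can be
  supplied as explicit per-haplotype `DetoxSpec` overrides), and
* the transgene's target set, when carried.

Self-progeny genotype probabilities are the product of maternal
segregation (½/½) and the renormalised distribution of compatible
pollen classes.  Transgene escapes are assumed absent: every self
progeny of a rescued cross carries the transgene, consistent with the
genotyping of the transgenic lines the model describes.

**Specificity inference.**  The candidate target sets are the non-empty
subsets of the parental alleles (three for a heterozygote).  Each
implies a predicted progeny distribution; the maximum multinomial
likelihood model is selected, likelihood ties broken toward the smaller
set (parsimony).  The fit is reported as an exact multinomial
goodness-of-fit p-value — total probability of outcomes no more
probable than the observed one — computed by full stars-and-bars
enumeration for totals ≤ 200 and by Monte Carlo (10⁵ draws, fixed seed
20211026) above.  `alpha` defaults to 0.05 and only drives the
`fits_at_alpha` flag, never model selection.

**Population cross-compatibility.**  Given a boolean haplotype ×
S-RNase detoxification matrix with a false diagonal, the accepted
fraction is enumerated exactly over all heterozygous style pairs {a, b}
and all pollen haplotypes h ∉ {a, b}.  For i.i.d. Bernoulli(P_R)
repertoires this converges to the closed form P_R² as the number of
haplotypes grows; the test suite checks agreement within ±0.01 at 50
haplotypes averaged over 200 seeded matrices.

## Detoxification closed forms

`P_n = 1 − (1 − P_R)^n` assumes each of the n SLF types recognises a
given S-RNase independently with the same probability P_R; style
acceptance is `P_n^r` with r = 2 S-RNases per (heterozygous) style.
Internal values are never rounded; reported percentages round half-up
to integer percent, which makes the rounded-P_n convention (0.98² →
96%) and the unrounded one (0.9775² = 0.9555 → 96%) agree at the
precision reported.  P_R is estimated as successes/trials from pooled
per-pair specificity calls with a Clopper–Pearson (exact) interval,
chosen over Wald because trial counts are small (26 in the packaged
panel).

The goodness-of-fit comparison against an expected per-pair probability
uses the standard 1-df χ² on (successes, failures) without continuity
correction, always accompanied by the exact two-sided binomial p-value:
with an expected success count of ~5 the χ² approximation is
borderline, and the exact companion is the number to trust.  For the
packaged panel against the within-species expectation 5/26 the standard
statistic is ≈ 71.6; published summaries of this comparison quote a
much smaller χ² whose exact contingency is not recoverable from the
stated counts, so only the standard computation is provided.

## Locus annotation

Inputs are gene features already classified (Class I/II/III T2 RNase,
SLF-subfamily F-box, other F-box, other) — homology search and domain
scanning are upstream of this package.  Rules:

* **Scaffold filter**: genes on scaffolds < 1 Mb are dropped
  (boundary-inclusive at exactly 1 Mb), since the smallest linkage
  region observed for these loci is about that size.
* **Pseudogenes**: an in-frame stop (TAA/TAG/TGA) strictly before the
  final codon, in frame 0 of the annotated CDS — no six-frame scan.
  Codons containing N never count as stops; a trailing partial codon is
  truncated with a warning.
* **Linkage**: an F-box is linked to an RNase anchor when the gap
  between their gene spans (0 for overlap; midpoints are not used) is
  ≤ 3 Mb, boundary-inclusive, strand ignored.  Anchors sharing a linked
  F-box merge into one locus, so no F-box belongs to two loci.
* **Typing**: Class III RNase + ≥ 1 SLF ⇒ type-1 S-like; Class I/II
  RNase + any F-box ⇒ Class I/II-linked; no linked F-box ⇒ orphan
  RNase.  Which type-1 locus is *the* S-locus is not decidable from one
  genome; when the species shows type-1 SI, the locus with the most
  intact SLFs (ties: larger span, then lexicographically smaller
  scaffold) is promoted to TYPE1_S, because the functional S-locus
  carries the largest SLF cluster.
* **Activity**: ACTIVE iff the locus retains ≥ 1 intact RNase and ≥ 1
  intact SLF.  Expression is an optional modifier: when every intact
  SLF of a locus is below 1.0 TPM in stamen (threshold and tissue
  configurable; no published numeric cutoff exists) the locus is
  flagged `low_expression` rather than reclassified, and route
  inference treats such loci as silenced duplicates.

Coordinates are 0-based half-open internally; GFF3 I/O converts from
1-based inclusive at the boundary.  Annotation is deterministic and
invariant to input order and strand flips.

## Route inference

The classifier consumes per-species inputs: SI phenotype, number of
known WGD/WGT events (taken from the literature, not inferred), the
type-1 locus inventory split into active / inactive / low-expressed,
and the S-RNase status of the remaining locus.  Rules are evaluated in
a fixed order, first match wins; the table is total (anything else is
UNCLASSIFIED with a rationale).  Notable choices:

* Duplicate loci in an SC genome are classified as loss-by-duplication
  (R1) with no regain — the mechanistically consistent reading — even
  where published species summaries label the same pattern as S-RNase
  loss; the packaged fixture keeps those labels in a
  `paper_route_label` column so the discrepancy stays visible.
* Regain route c (S-RNase reactivation) is representable but no rule
  emits it: no surveyed species shows it.  It remains reachable only by
  explicit override.
* "Silenced duplicate" means a locus with a pseudogene member or one
  whose intact SLFs all fall below the expression threshold.

The packaged `species_profiles.tsv` covers 22 species; rows whose
inventories are not fully printed in the primary sources are marked
provisional in a notes column.

## Ancestral states

F81 kernel: `P(i→j | t) = e^(−μρt)·1[i=j] + (1 − e^(−μρt))·π_j` with
`μ = 1/(1 − Σ π_j²)`, so ρt counts expected substitutions.  Branch
lengths are Myr on dated trees.  Likelihood is Felsenstein pruning with
per-node rescaling; marginal posteriors come from the outside
(up–down) algorithm, with missing tips contributing all-ones partials
and multifurcations handled natively.  Default trait alphabet: the
eight SI-machinery states from Class I/II RNases without linked F-boxes
through complete absence of the system.

Parameter fitting: π from observed tip frequencies with pseudocount 1
(default; an ML option optimises the simplex jointly with the rate via
a softmax parametrisation and Nelder–Mead).  The rate is maximised by
bounded scalar search on [10⁻⁶/h, 10³/h], h = tree height, a bracket
spanning effectively frozen to saturated evolution; if all observed
tips share one state the rate is unidentifiable and is returned at the
lower bound with a warning.  MAP ties break toward the earlier alphabet
state.  MPPA-style selection keeps every state whose posterior reaches
a configurable fraction (default 0.5) of the node's maximum — a
deliberate simplification of Brier-score subset selection; full
posteriors are always available so no downstream use is bound by it.

## Synthetic data

Generators are pure functions of (config, seed); one global seed fans
out to per-component child seeds by fixed offsets.

* **Genomes**: one planted locus per 12-Mb scaffold — an S-RNase inside
  a cluster of 9–37 SLFs (cluster size matching observed S-loci), CDS
  lengths uniform 0.9–3 kb (typical RNase/F-box range), intergenic gaps
  5–40 kb.  Decoy F-boxes are placed beyond the 3-Mb window from every
  RNase, decoy unrelated genes scattered freely, and two 0.5-Mb
  scaffolds with decoys exercise the scaffold filter.  Pseudogenes get
  one internal codon replaced by TAA.  What this does **not** emulate:
  assembly fragmentation through a locus, tandem-duplicated partial
  genes, misclassified gene classes, and sequence-level homology decay
  — so perfect planted-locus recovery demonstrates the clustering
  logic, not robustness to annotation noise in real assemblies.
* **Progeny**: multinomial draws from the predicted genotype law.
* **Trait histories**: root from π, states propagated by the F81 kernel
  along each branch, internal truth recorded.  Simulation studies in
  the test suite use 50-tip random trees of height 100 Myr with
  ρ = 0.02 (a few expected substitutions root-to-tip — a labile but not
  saturated trait), K = 3, π = (0.5, 0.3, 0.2).

## Problem sizes and verification

The test suite verifies: pruning likelihood and posteriors against
explicit enumeration on 100 random trees (≤ 6 leaves, K ≤ 8, 10⁻¹⁰
relative); Monte-Carlo style acceptance against the closed form within
4 standard errors at 10⁵ styles for P_R ∈ {0.1, 0.5, 0.85, 1.0},
n ∈ {1, 2, 5}; population cross-compatibility against P_R² within
±0.01 (50 haplotypes × 200 seeds); planted-specificity recovery ≥ 99%
over 1,000 simulated 20-offspring lines; exact planted-locus recovery
on 100 simulated genomes; and π/MAP recovery on 100 simulated 50-tip
trait histories, where MAP accuracy at internal nodes is compared to a
constant guesser that always answers the modal observed tip state.

## Known limitations

* The transgene is modelled as a single unlinked presence/absence
  locus; copy number and insertion position are ignored.
* No protein-level SLF–S-RNase interaction modelling, no tetraploid
  genetics, no evolutionary dynamics of detoxification-range narrowing.
* Endogenous repertoires are complete by assumption; partial networks
  must be specified explicitly.
* Route inference never infers WGD events and does not model dioecy.
* Locus annotation trusts the input gene classification entirely.
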