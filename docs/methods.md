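# Methods

## Scope and model

The package implements the census-style analysis of a plant phytocyanin
family: feature extraction from protein backbones, copper-ligand subfamily
assignment, six-type architecture classification, gene-duplication
detection, digital-expression rules, qRT-PCR quantification and a small
neighbor-joining phylogeny. External predictors (signal peptides, GPI
anchors, N-glycosylation, domain scans) are treated as inputs: their
outputs can be supplied in an annotation table, and lightweight heuristics
stand in for them only on synthetic data.

## Sequence-feature rules

* **PAST fraction** — share of P/A/S/T residues over an interval. It is
  reported, not gated on: the >35% AGP threshold is a guideline and the
  ALR decision below rests on glycomodules instead.
* **Pro-rich regions** — maximal chains of prolines with at most 11
  non-Pro residues between consecutive prolines; chains with fewer than
  two prolines are discarded; region bounds run from the first to the last
  Pro of the chain. The 11-residue bound is the hydroxylation-context rule
  for arabinogalactosylation.
* **Glycomodules** — (Ala/Ser/Thr)-Pro dipeptides inside a Pro-rich region
  whose Pro is *noncontiguous* (neither neighbour is a Pro; adjacent
  prolines indicate extensin-like SP₂₋₄ blocks, not AG sites), clustered
  when consecutive dipeptide starts are ≤13 positions apart (the 11-residue
  Pro rule plus the two dipeptide residues); clusters of ≥2 are reported.
  Gly counts as hydroxylation context for the Pro-rich chain but is *not*
  a glycomodule head — the two rules intentionally differ.
* **ALR call** — glycomodules are searched outside excluded intervals
  (PCLD, first 25 residues when an SP is present, last 25 when a GAS is
  present). The region is called present when qualifying glycomodules
  carry ≥3 dipeptides in total. The field does not fix this minimum; 3 was
  chosen so that a single 2-dipeptide module is insufficient but "several
  A/TP₂₋₃ motifs" qualify. The synthetic generator plants 0 or ≥6
  dipeptides, so no test or acceptance quantity is sensitive to this
  choice.

## Ligand extraction and classification

A bundled 60-residue reference PCLD (synthetic, proline-free, with
H24/C38/H52/M57 ligand columns and C13/C46 disulfide columns) anchors the
analysis. Query domains are aligned to it globally (BLOSUM62, gap open
−11, extend −1, leftmost alignment on ties); reference ligand columns map
through the alignment to the query letters, a gapped column yielding
ABSENT. Scores below 30% of the reference self-score raise a
low-confidence error. Subfamily: (H,C,H,M) → UCL, (H,C,H,Q) → SCL, all
else → ENODL. When domain intervals are not annotated, PCLDs are located
by repeated local alignment of the reference (hits ≥50% of self-score,
masked after each find, at most two domains). Multi-domain proteins take
their subfamily from the N-terminal domain. Architecture typing is the
exact six-row table above; all other flag combinations are UNCLASSIFIED.
The full multiple alignment of a real family is out of scope; the
pairwise-to-reference mapping replaces it.

## SP/GAS heuristics (synthetic data only)

SP: a ≥8-residue stretch of {A,I,L,V,F,M,W} starting within the first six
positions of the first 25 residues. GAS: a ≥10-residue hydrophobic stretch
in the last 25 residues ending within 3 of the C-terminus, plus a small
residue {S,A,G,N,C} 10–20 positions upstream of the stretch end and before
its start (the ω-site stand-in). Real analyses should supply predictor
flags via the annotation table; the heuristics exist so the generator and
classifier can agree on planted cassettes.

## Duplication rules

Ordinals (1-based rank by start per chromosome, ties by end then id) are
assigned over *all* genes so that "intervening genes" counts neighbours of
any family. Tandem: ordinal gap − 1 ≤ 5, transitive closure, singletons
dropped. Segmental: a gene belongs to a block when its midpoint lies in
it; genes across a block pair are paired when their offsets from the
respective block starts differ by ≤500 kb. Offsets-from-block-start is
this package's operationalisation of collinearity — the original
block-level tools define it only implicitly. Strand is carried but never
used; none of the rules condition on it.

## Expression and qRT-PCR

* EST specificity needs a strict majority (>1/2 of total counts) in one
  tissue; zero totals return no call rather than an error.
* MPSS tier bounds 50 and 500 are inclusive into MODERATE (reading the
  "50–500" dash as inclusive).
* Microarray normalisation divides by the grand mean and takes log2 (the
  fold-change convention); zeros are floored at half the smallest positive
  value (configurable) before division, so with no zeros the grand mean of
  2^values is exactly 1.
* Clustering uses centred-correlation distance (1 − Pearson) with average
  linkage; a zero-variance gene has no defined correlation and is assigned
  the maximal distance 2.0 to all others.
* Stress calls: fold change is the ratio of arm means on the linear scale;
  significance is a two-sided Welch t-test on log2 signals (the original
  analysis names only a p-threshold; Welch-on-logs is this package's
  documented choice). UP/DOWN requires both the fold gate (>2 / <0.5) and
  p < 0.05.
* qRT-PCR: technical replicates average on the Ct scale; quantities come
  from per-gene standard curves (Ct vs log10 amount over the 3-fold series
  10, 30, 90, 270, 810, 2430; slope −1/log10(E), so −3.3219 at 100%
  efficiency); levels are normalised by the geometric mean of four
  reference genes per (sample, biological replicate); biological
  replicates report mean ± sd. A sample with an undetected reference gene
  is flagged and excluded.

## Phylogeny

p-distance with pairwise deletion of gap columns (an optional Poisson
correction −ln(1−p) is provided; the default is uncorrected for
determinism and simplicity). Neighbor joining follows Saitou–Nei with the
Q criterion; ties break to the smallest current index pair; negative
branch-length estimates are clamped to zero and flagged. Bootstrap
resamples alignment columns with replacement and reports, for each
internal split of the full-data tree, the percentage of replicates
containing it (no majority-rule consensus is formed). Output is Newick
with supports as internal-node labels.

## Synthetic data: what it emulates, what it does not

Generators are deterministic in (spec, seed). Proteins are concatenated
cassettes — SP, proline-free linkers, the reference PCLD with
subfamily-defining ligand edits (ENODLs get a random key site substituted
or deleted), glycomodule arrays built from [AST]P-plus-spacer units, and a
GAS tail — with backgrounds free of proline and of hydrophobic runs so no
accidental feature can arise. The default family fixture plants one
protein per cell of the rice census (62 proteins: 19/1/18 type I, 3/1/4
type III, 11/1/2 type IV, 2/0/0 type V for UCL/SCL/ENODL). Genome layouts
keep planted features ≥16 gene slots apart, making rule outcomes
unambiguous. Expression data use log-normal noise (sd 0.2 on log2 by
default, 4 replicates per arm) with multiplicative planted folds (4× and
0.25×), balanced EST backgrounds that cannot reach a majority, MPSS values
sampled away from tier bounds, and Ct values that follow the stated
efficiency exactly.

Consequently a green round-trip establishes that the rules are implemented
as specified and invert the generator — not that they would reproduce a
real genome-wide census: real sequences have divergent domains, borderline
glycomodule clusters and predictor disagreements that the planted fixtures
deliberately avoid. Genome-scale discovery (BLAST/HMM searches, redundancy
removal) and real microarray/MPSS retrieval are out of scope.

## Numerical choices and degenerate inputs

1-based inclusive coordinates throughout, converters at the I/O boundary.
Non-standard residues are rejected by default or masked to X on request.
Empty FASTA, duplicate ids, inverted intervals and unknown strands are
errors; annotation rows for unknown proteins are skipped with a warning.
All-zero matrices, <2 replicates per arm, <3 dilution points and
zero-comparable-column sequence pairs are errors; an all-equal dilution
series returns slope 0 with undefined r² and a warning. Two-taxon NJ input
returns the degenerate single-branch tree.
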