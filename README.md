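# phytocyanin

Tools for genome-wide analysis of the phytocyanin (PC) gene family — the
plant-specific blue copper proteins that include uclacyanins, stellacyanins
and early-nodulin-like proteins, many of which are chimeric arabinogalactan
proteins (AGPs). The package is aimed at plant molecular biologists running
family surveys: given protein sequences (plus optional external predictor
annotations), gene coordinates, duplicated-segment tables and expression
data, it reproduces the standard census-style analysis as a tested,
reusable Python library.

## What it computes

**Sequence features.** PAST fraction (Pro+Ala+Ser+Thr content; >35% is an
AGP hallmark); Pro-rich regions (consecutive Pro at most 11 residues
apart); AG glycomodules — clusters of ≥2 (Ala/Ser/Thr)-Pro dipeptides whose
prolines are noncontiguous; and the AGP-like region (ALR) call, made
outside the folded domain, the signal peptide (SP) and the GPI ω-region.

**Subfamily and architecture.** The copper ligand set of the
plastocyanin-like domain (PCLD) is read off a global pairwise alignment to
a bundled annotated reference: (H,C,H,M) → UCL, (H,C,H,Q) → SCL, anything
lacking a key ligand → ENODL. Architecture from four elements (SP, number
of PCLDs, ALR, GPI-anchor signal GAS):

| type | SP | PCLD | ALR | GAS |
|------|----|------|-----|-----|
| I    | +  | 1    | +   | +   |
| II   | +  | 1    | +   | −   |
| III  | +  | 1    | −   | +   |
| IV   | +  | 1    | −   | −   |
| V    | −  | 1    | −   | −   |
| VI   | +  | 2    | −   | −   |

Types I and II are chimeric AGPs.

**Duplication.** Tandem groups (family genes separated by ≤5 intervening
genes, chained transitively) and segmental pairs (genes in paired collinear
blocks whose offsets from the block starts differ by ≤500 kb).

**Expression.** EST tissue specificity (strict majority rule), MPSS tiers
(<50 / 50–500 / >500 tpm), microarray normalisation (divide by the grand
mean, log2) with average-linkage correlation clustering, stress calls
(fold >2 or <0.5 with Welch p<0.05 on log2 signals), and qRT-PCR
standard-curve quantification normalised by the geometric mean of four
housekeeping genes.

**Phylogeny.** p-distances with pairwise deletion, Saitou–Nei neighbor
joining, bootstrap supports over column resampling, Newick output.

**Synthetic data.** Seeded generators for proteins with planted cassettes
(SP, PCLD with chosen ligands, glycomodule arrays, GAS tails), genome
layouts with planted tandem/segmental events, and expression bundles with
planted effects — each returning its ground truth, so every rule is tested
by round-trip.

## Worked example

```
$ python examples/classify_family.py
              UCL  SCL  ENODL  total
I              19    1     18     38
II              0    0      0      0
III             3    1      4      8
IV             11    1      2     14
V               2    0      0      2
VI              0    0      0      0
UNCLASSIFIED    0    0      0      0
total          35    3     24     62

62 phytocyanins: 38 chimeric AGPs (types I+II), 46 GPI-anchored (types I+III).
```

The fixture plants one protein per census cell (62 in total, the rice
family layout); the classifier re-derives every label from the sequence
alone — 38 type I proteins, 46 GPI-anchored, 35 UCLs / 3 SCLs / 24 ENODLs.
The other examples (`find_duplications.py`, `expression_profiles.py`,
`qpcr_quantification.py`, `build_tree.py`) each run one capability on a
small generated input and print annotated results.

## Acceptance script

`scripts/acceptance.py` regenerates the seeded 62-protein fixture, runs the
sequence-only classifier over it and writes the resulting census counts
(type I, type IV, GPI-anchored, chimeric AGPs, UCL-type chimeric AGPs) as
JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, parameter choices and limitations.
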