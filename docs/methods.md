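# Methods

## The problem

Colonic butyrate is mostly produced via butyryl-CoA:acetate CoA-transferase,
encoded by the bacterial *but* gene. Quantifying *but* abundance in fecal DNA
by qPCR gives a direct functional readout of a microbiome's butyrate
synthesis capacity, but the gene is so variable across gut butyrate
producers that no single primer pair covers them. `butqpcr` implements the
phylogeny-guided solution: group target taxa by phylogenetic proximity,
design one degenerate primer pair per group, and step down the tree whenever
a group is too variable — then quantify each group's assay by ΔCt against a
reference and compare groups nonparametrically.

## Degenerate sequence model

A degenerate oligonucleotide is a string over the 15 IUPAC nucleotide
symbols; position *i* denotes a base set `B_i ⊆ {A,C,G,T}`. Degeneracy is
`∏_i |B_i|`, the number of concrete variants in the synthesis mixture. A
pattern matches a concrete window when every window base lies in the
corresponding base set; a template `N` (masked base) matches nothing, so
masked regions can never produce phantom amplicons. Explicit expansion is
capped (default 4096 variants) to guard against pathological patterns;
everything the pipeline needs (degeneracy, Tm extremes, GC means, matching)
is computed per-position without expansion.

## Primer design

Candidates are column-wise IUPAC consensi of alignment windows. A window
fails outright if any member has a gap in it; a member `N` makes the column
`N`. Screens, with defaults:

| constraint | default | rationale |
|---|---|---|
| primer length | 18–23 nt | range spanned by the packaged panel |
| per-primer degeneracy | ≤ 256 | keeps every variant at usable concentration |
| pair degeneracy | ≤ 2048 | admits the packaged panel (max pair 1728) |
| product length | 400–800 nt | qPCR-amplifiable, spans the panel's 558–726 |
| Wallace Tm (min..max over variants) | 48–70 °C | panel spans 50–68 °C; annealing protocols near 60 °C |
| pair ΔTm (midpoints) | ≤ 8 °C | co-cycling of both primers |
| mean GC over variants | 0.30–0.70 | conventional primer design practice |
| 3' clamp | 1 concrete terminal base | extension-end fidelity; two of the packaged forward primers carry a degenerate base at the penultimate position, so the default is one |
| member coverage | 1.0 | every clade member must match at 0 mismatches |

These defaults are this package's calibration: they were chosen so that the
packaged six-cluster panel itself passes the primer-level screen, and they
are *not* presented as the settings of any external design tool. All are
configurable through `DesignConstraints`.

Ranking is deterministic: degeneracy ascending, then Wallace-Tm midpoint
proximity to the 60 °C target, then leftmost window; pairs minimize pair
degeneracy, then joint Tm proximity, then position. Product length is
measured from the forward site's 5' end to the reverse site's 5' end on the
opposite strand, inclusive, on the ungapped first member of the clade (the
reference member). Pair search first examines the top 250 ranked candidates
per orientation and falls back to a full position-indexed scan if that
window finds no feasible pair, so failure verdicts are exact.

The descent driver attempts a design on each clade root-down (preorder).
Success emits the pair and stops descending; failure recurses into the
children; failing leaves are reported undesignable. Emitted clades therefore
partition the designable leaf set. Clade alignments are re-sliced from the
global MSA (columns that are gaps in all members dropped) rather than
re-aligned, for determinism and speed. Cluster labels A, B, C… follow
emission order. Unaligned input can be aligned with the bundled `mafft`
wrapper; the design functions themselves require a pre-computed MSA.

## In-silico PCR

Binding sites are sought on both strands with a mismatch budget (default 0
for validation, 2 for the permissive off-target screen) and an exact
3'-terminal clamp of 2 positions — extension-end mismatches abolish
amplification, so they are never tolerated regardless of budget. All
forward×reverse site combinations within the product-length window are
reported, in both amplicon orientations; no "shortest product wins" rule is
applied, since qPCR interpretation belongs to the reader of the report.
Reverse-complementing a template mirrors all hits with strands swapped and
identical product lengths.

The packaged panel's expected product lengths are verified against this
length convention on synthetic templates that embed one expansion of each
primer at the printed spacing. Verification against the real NCBI accession
sequences requires network access and is left to users: the
`panel.download_manifest()` helper emits the accession list; the library
itself never touches the network.

## Quantification

Copy ratio = `E^(Ct_ref − Ct_target)` with efficiency fixed at 2.0 by
default (uncorrected ΔCt); per-assay efficiency is accepted as input but
never estimated. Technical replicates are averaged on the Ct scale
(geometric mean of ratios) after dropping replicates more than 0.5 cycles
from the replicate median (configurable). Samples lacking the chosen
reference are reported, never silently dropped. Two references are
supported: the UNC-6 spike (composition-independent) and 16S
(total bacterial load), with an optional ×4.2 copies-per-genome correction
for the 16S route. The two normalizations differ per sample by exactly
`E^(Ct_16S − Ct_spike)`, identical across clusters — the algebraic identity
behind their high observed correlation.

The recommended primer concentration interpolates log-linearly in pair
degeneracy from 200 nM (degeneracy 1, the conventional concentration) to
1 µM (degeneracy ≥ 256), rounded to 10 nM. The interpolation form is this
package's operational choice; only the endpoints and the monotone dependence
on degeneracy are externally given.

## Statistics

* **Mann–Whitney**: exact permutation null when the pooled sample is ≤ 16
  and tie-free, otherwise the continuity- and tie-corrected normal
  approximation (the `wilcox.test` convention). An independent brute-force
  enumeration oracle backs the exact branch in the tests. No multiplicity
  correction is applied by default (per-test α = 0.05).
* **Spearman** on midranks; constant inputs yield NaN with a warning.
* **Bland–Altman** on log-transformed paired values: bias ± 1.96 sd with
  t-based CI for the bias and the `sd·√(3/n)` approximation for each limit
  of agreement.
* **CLR**: counts → proportions; zeros replaced by the count-zero
  multiplicative rule with δ = 0.65 of the detection-limit proportion
  (1/total), non-zero parts rescaled multiplicatively; then
  `clr_i = ln(p_i / g(p))`. Rows sum to zero to 1e-9; zero-free rows are
  scale-invariant. All-zero samples are an error naming the sample.
* **Shapiro–Wilk** normality p-values are reported per group cell for
  information only; they gate nothing, as the group tests are nonparametric
  by design.

## Synthetic ground truth

`simulate_family` evolves a uniform-random ancestor down a tree by i.i.d.
per-site substitutions (uniform among the three alternative bases, no
indels by default). *Conserved islands* are windows assigned to a clade:
they never mutate on branches strictly inside the clade, but do mutate on
the clade's stem and above — so island content is identical within a clade
yet divergent between clades, exactly the structure that makes per-clade
primers possible and whole-tree primers impossible. The standard
`clade_family_spec(k)` construction uses an 800 nt ancestor, k clades of 3
leaves, two 30 nt islands at positions 60 and 620 (product ≈ 570 nt),
within-clade substitution probability 0.02 and between-clade 0.5.

`simulate_qpcr` draws a spike reference Ct per sample (N(22, 1)), offsets
the 16S Ct by N(−8, 1) (per-sample bacterial-load variation — this is what
keeps the two normalizations from being trivially identical), sets each
target's true Ct from the group's true copy ratio with optional per-sample
biological spread on the log2 scale, and adds N(0, 0.5) measurement noise
per technical replicate (3 by default). The study-scale preset uses
n = 60/group — the cohort sizes of the motivating study (63 vegans, 62
omnivores) rounded to a common size — with per-cluster median ratios taken
from the published summary table and biological spread 1.1 log2 cycles,
back-solved from the published IQR/median ratios under a log-normal model
(2·sinh(0.6745 σ) = IQR/median gives σ ≈ 0.6–0.8 natural-log units across
clusters and groups; 1.1 log2 cycles sits mid-range).

What the simulations do not emulate: primer-batch composition variability,
amplification-efficiency differences between degenerate variants, indels
and rate heterogeneity in gene evolution, and real fecal community
structure. Passing tests therefore demonstrate the correctness of the
algorithms and the statistical machinery under the stated model, not
wet-lab performance on real fecal DNA.

## Numerical and degenerate-input choices

0-based half-open coordinates internally, 1-based inclusive in reports.
NJ trees may carry tiny negative branch lengths; these are clamped to zero
before midpoint rooting. p-distance pairs with no comparable columns get
distance 0. Replicate sets whose members are all "outliers" fall back to
the plain median. Design output is fully deterministic (stable tie-breaks);
all generators take mandatory seeds.

## Known limitations

* Real-template validation of the packaged panel requires fetching the 36
  accession sequences (network); the repository verifies the length
  convention on synthetic layouts instead.
* The built-in NJ/p-distance path is a convenience, not a substitute for a
  proper phylogeny; trees computed with dedicated tools should be supplied
  as newick where available.
* Off-target screening is local to user-supplied templates; it does not
  replace a genome-scale specificity check.
* The descent treats multifurcations as flat sibling sets and does not use
  branch lengths; only topology guides the design.
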