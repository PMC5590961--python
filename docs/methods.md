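# Methods

## The problem

An ancient whole-genome duplication (WGD) leaves a synchronous cohort of
paralog pairs in a genome. Because synonymous (silent) substitutions
accumulate roughly clock-like, the distribution of pairwise synonymous
distances (Ks) across a species' paranome shows WGD cohorts as distinct
peaks over the quasi-continuous background of small-scale duplications
(SSDs). `paleoks` builds these paralog-age distributions from a set of
in-frame coding sequences, applies the phylogeny-based redundancy
correction that makes peak masses interpretable as event counts, and
compares paranome peaks with the Ks divergence of one-to-one orthologs
between two species to ask whether a duplication peak predates or
postdates their split.

## Pipeline

1. **Input validation** (`seqio`). One CDS per gene; length a multiple of
   3 and at least 9 nt, no ambiguity codes, no internal stops; a terminal
   stop is stripped. Ambiguous records are rejected rather than masked
   because NG86 counting is undefined on ambiguous codons; transcriptome
   ORF sets are expected to be clean.
2. **All-vs-all local alignment** (`simgraph`). Exact
   Smith–Waterman–Gotoh on peptides, BLOSUM62, affine gaps with open 11
   and extension 1 (a length-k gap costs 11 + k). Significance uses the
   Karlin–Altschul model E = K·m·n·exp(−λS) with the standard gapped
   BLOSUM62/11/1 constants λ = 0.267, K = 0.041 and raw sequence lengths;
   edge-effect corrections are deliberately omitted since only the graph
   topology at the E ≤ 1e-10 cutoff matters. The scan computes optimal
   scores for every pair with a compiled kernel and performs tracebacks
   only for pairs that can pass the cutoff, which is exact (the optimal
   score alone determines significance). Non-standard residues score −4
   (BLOSUM62's minimum) against everything.
3. **Similarity graph and families** (`simgraph`, `mcl`). Edge weight is
   min(200, −log10 E), averaged over the two directions; E = 0 maps
   to 200. Markov clustering with inflation 2.0 (the field's default),
   self-loops at each node's maximum incident weight (at least 1),
   pruning below 1e-5, convergence when the matrix changes by less than
   1e-8 (at most 200 iterations). Clusters are read off attractor
   systems; nodes attracted to several systems go to the one holding most
   of their probability mass, ties towards the lexicographically first
   cluster, so the partition is deterministic. Clustering runs per
   connected component, which is exact (expansion never crosses
   components) and fast.
4. **Codon alignment** (`codon_align`). Families are aligned at the
   protein level — pairwise by global Needleman–Wunsch–Gotoh (end gaps
   penalised), larger families by one progressive pass over a
   neighbour-joining guide tree built from Poisson-corrected p-distances,
   with mean-of-pairs profile scores — and back-translated to codons.
   No iterative refinement is attempted: Ks estimation needs homologous
   columns, not optimal alignments, and transcriptome-scale families are
   gap-light. Gap-containing columns are excluded per gene pair rather
   than alignment-wide, maximising usable sites per pair.
5. **Ks estimation** (`ks`). The default estimator is NG86:
   per-position synonymous-site fractions with stop-excluded
   denominators (so S + N = 3 × codons), difference counts averaged with
   equal weight over all minimal mutational pathways that avoid stop
   codons, and a Jukes–Cantor correction Ks = −(3/4)·ln(1 − (4/3)·pS).
   Pairs with pS ≥ 3/4 are recorded as saturated (Ks = +inf) and later
   excluded from densities; pairs with fewer than 10 aligned codons are
   flagged unreliable. A pairwise maximum-likelihood estimator under
   GY94 with F3x4 frequencies (optimising branch length, the
   transition/transversion ratio kappa and the selection ratio omega on
   the two-sequence likelihood, then decomposing the branch length by
   mutational-opportunity site proportions) is available as an
   alternative; NG86 is the default because it is exactly
   hand-verifiable and the downstream distribution analysis is
   estimator-agnostic.
6. **Redundancy correction** (`distribution`). A family of n members
   yields n(n−1)/2 pairwise estimates for only n−1 duplication events.
   Families are split into subfamilies by single-linkage connected
   components over pairs with finite Ks ≤ 5 (saturation bound); each
   subfamily gets a neighbour-joining tree on its pairwise Ks matrix
   (negative branch lengths clamped to 0), midpoint-rooted. Every
   internal node is one duplication event: its m available cross-clade
   estimates enter the distribution with weight 1/m each, so each event
   contributes exactly unit mass and a fully resolved subfamily of n
   members contributes total mass n−1. Chained pairs whose own Ks
   exceeds the bound (possible under single linkage) still count towards
   m but are excluded from densities, keeping node normalisation exact.
   NJ on the Ks matrix (rather than a likelihood tree from the
   alignments) keeps the tree self-consistent with the very distances
   being weighted; topology errors only reshuffle weights among nodes
   and cannot change a subfamily's total mass.
7. **Density and peaks** (`distribution`). Weighted Gaussian KDE on
   [0, 5] with reflection at both edges (so the curve integrates to the
   included weight); bandwidth by Silverman's rule on the weighted
   sample (effective sample size (Σw)²/Σw²), overridable. Entries with
   Ks < 0.05 are excluded: near-identical pairs are dominated by
   assembly/thresholding artefacts, not duplication events. Peaks are
   local maxima exceeding 1.5× the median density, reported with their
   half-height interval, the summed weight inside it, and the weighted
   median Ks of the entries inside it. The global KDE mode is the
   primary age estimate of a WGD cohort; interval masses of broad
   background humps overlap and are reported as-is.
8. **Orthologs** (`orthologs`). Reciprocal best hits between two
   proteomes, best by bit score (ties: lower E-value, then subject id),
   kept at ≥ 30% identity over ≥ 150 aligned columns (identity counted
   over all alignment columns, gaps included). Each pair dates the
   speciation once, so the ortholog distribution is unweighted, with the
   same saturation and near-zero exclusions as the paranome. If the
   ortholog mode is younger than both species' paranome peak modes, the
   duplication predates the split — the shared-WGD configuration.

## The synthetic-data generator

The paper-scale inputs for this kind of analysis are assembled
transcriptomes; `simulate` emulates the post-assembly state directly: a
set of gene families with known duplication histories, not reads or
assembly artefacts. Families grow on ultrametric genealogies (a strict
molecular clock; divergence split evenly across branches): a planted WGD
at a chosen Ks with per-gene retention probability, a Poisson(ssd_rate)
background of SSD copies with pair ages uniform on ssd_ks_range, and
optionally a two-species split younger than the WGD (SSDs are then added
per species below the split). Sequences evolve along the genealogy under
a GY94-style codon substitution process with uniform codon frequencies;
the rate matrix's synonymous flux is scaled so a branch of length Ks
produces, in expectation, Ks synonymous substitutions per NG86-counted
synonymous site. The truth table lists every within-family pair with its
true path Ks and the event class of its most recent common ancestor
node (WGD, SSD or SPECIATION).

Defaults: 300 base genes of 300 codons, WGD at Ks 0.8 (the regime where
an ancient gymnosperm-like WGD is still a distinct peak), retention 0.6,
ssd_rate 0.3 with ages on (0.05, 3.0), omega 0.2, kappa 2.0. ssd_rate
and retention are not observable paper quantities; they were chosen once
to give a clear burst over a visible but non-dominant background, the
regime the method targets. What the generator does **not** model:
sequencing error, assembly chimerism and isoform redundancy, gene loss
after SSD, gene conversion, rate variation among lineages or sites, and
non-uniform codon usage. Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted signals under
clock-like evolution — not robustness to assembly artefacts or rate
heterogeneity in real transcriptomes.

The estimator makes none of the simulator's parametric assumptions
(NG86 counts sites without reference to kappa or omega), so simulator →
estimator consistency is a non-circular check; residual bias of NG86
under kappa = 2 (JC correction vs. transition bias) stays within about
3% at Ks 0.8 and within the 0.07·(1+Ks) consistency band up to Ks 1.5.

## Numerical choices

- Substitution sampling uses the exact transition matrix exp(Qt) via
  eigendecomposition (Q is symmetric under uniform frequencies), per
  codon, not an event-by-event simulation.
- The Smith–Waterman kernel and Biopython's PairwiseAligner are both
  exact; tests pin them to a brute-force DP oracle and to each other.
  Gap convention everywhere: a length-k gap costs open + k·extend.
- Saturated pairs get a finite cap (max(2·ks_max, 1.2× the largest
  finite Ks in the subfamily)) only inside NJ distance matrices; they
  never enter densities.
- 1/m weights are IEEE doubles; per-node sums are exact to ~1e-12
  (m·fl(1/m) rounding), which the tests treat as exact.
- Two-member subfamilies skip midpoint re-rooting (the two-leaf tree
  already bisects the edge). Zero-diameter trees (identical sequences)
  root at a deterministic fallback edge.
- MCL readout falls back to singletons if no attractor survives pruning
  (not observed in practice, kept for safety).

## Problem sizes used in the shipped checks

End-to-end parameter-recovery checks run at 300 base genes (about 560
genes) per planted age for the single-species scenario and 150 base
genes per species for the two-species scenario, 300 codons per gene —
large enough that KDE modes are stable to well under the acceptance
tolerance of 0.1·(1+Ks), small enough to keep a full run in the
low minutes on one CPU. Unit and property checks use 9–500 codon
sequences and families of 2–20.

## Known limitations

- NG86 (and the JC correction) biases Ks upward slightly for kappa > 1
  and saturates above Ks ≈ 3–4; the Ks ≤ 5 subfamily bound removes the
  saturated regime before weighting, as the method intends.
- Identity percentages are computed over all alignment columns; tools
  that exclude gap columns will report slightly higher values.
- Midpoint rooting assumes clock-like subfamilies; strongly asymmetric
  rates could misplace the root and redistribute node weights (total
  mass is conserved regardless).
- The progressive MSA is single-pass; badly gapped real families would
  benefit from refinement that is deliberately out of scope here.
- E-values use fixed Karlin–Altschul constants with raw lengths, so they
  differ from BLAST's edge-corrected values by a modest factor; the
  cutoff is config-exposed.
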