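# Methods

## Scope and model

`introsel` implements the downstream, rule-based layer of a
multi-timescale evolutionary analysis of gene modules. It consumes the
outputs of heavy model-fitting tools rather than re-fitting them:
codon-model log-likelihoods (branch-site MA/MA1 and site models
M7/M8/M8a), per-site selection scores (BEB and M8-BEB posteriors,
MEME p-values, FUBAR posteriors, REL Bayes factors), per-gene SnIPRE
constraint values (f), per-SNP marginal probabilities of Neanderthal
ancestry, archaic (Altai Neanderthal, Denisova) genotypes, and
sweep-scan S scores. The package's own contributions are the
declaration and consensus rules, the matched-set construction, the
introgression outlier/region logic, the median-joining network, the
sweep scan, and a synthetic-cohort generator that makes all of it
testable against known truth.

## Statistical conventions

- **LRT p-values** are plain central χ² upper tails: χ²(1) for
  MA1–MA and M8a–M8, χ²(2) for M7–M8. No 50:50 boundary mixture is
  used for M8a–M8: the published p-values this package reproduces
  equal the plain χ²(1) tail of the published statistics, so the plain
  tail is the convention that reproduces them. Statistics are clamped
  at 0 (p = 1): a negative 2ΔlnL can only arise from numerical noise.
- **FDR correction** is Benjamini–Hochberg step-up, delegated to
  `statsmodels.multipletests` within each user-declared family key
  (default: one family per test × codon-frequency arm). The family
  grouping is configuration, not code: published multi-gene tables
  are often ambiguous about whether correction ran across genes,
  branches, or codon-model arms, and the right grouping depends on
  the study design.
- **Detection directionality** is encoded per method: BEB/FUBAR pass
  at score ≥ cutoff (posteriors), MEME at score ≤ cutoff (p-value),
  REL at score ≥ 50 (Bayes factor). Consensus calls never report a
  site with fewer than two supporting methods.
- **Quantiles** use linear interpolation between order statistics
  (numpy default), and outlier/region calls use strict ">" at the
  threshold. The 5th/95th percentile thresholds are empirical, from
  whatever score distribution the caller supplies.
- **Matching** uses relative deviation |c − f|/|f| ≤ 0.10 on *every*
  feature of the chosen mode. GC and CDS length are matched jointly
  (one mode), GERP alone (the other); marginal matching is available
  by calling the single-feature mode per feature. A focal feature of
  exactly 0 raises an error rather than silently matching everything.
- **Nemenyi post-hoc** (after Kruskal–Wallis) is implemented directly:
  pairwise mean-rank differences over the pooled ranking, standardized
  with the tie-corrected rank variance, referred to the studentized
  range distribution with k groups and infinite df. Tukey HSD and all
  omnibus tests come from scipy.

## Median-joining network

Sites are binary (ancestral/derived) with uniform weights. Identical
chromosome rows are collapsed; rows with any missing call are excluded
and reported, never imputed. Network construction at epsilon = 0 is a
greedy best-improvement loop: among majority medians (coordinate-wise
majority, the Hamming-space Steiner point of a triplet) of all node
triplets, add the one that most reduces the minimum-spanning
connection cost; stop when none reduces it; then iteratively prune
unobserved nodes whose removal does not raise the cost. The final edge
set is a deterministic Kruskal MST with lexicographic tie-breaks on
(weight, endpoint sequence), so output is invariant to input order.
This yields the sparsest network; alternative equal-cost links
(reticulations) are deliberately omitted. A positive epsilon admits
medians within epsilon of the current cost, giving denser candidate
sets, but 0 is the default and the tested path. On small inputs
(≤ 4 haplotypes, length ≤ 8) the greedy construction attains the
exhaustively verified Steiner-minimal cost; for larger inputs it is a
heuristic, like all median-joining implementations.

## Synthetic cohorts

The generator emulates the statistical shape of the real inputs, not
their genealogical process (no coalescent, no recombination map, no
realistic site-frequency spectrum — by design):

- **Genes**: disjoint intervals across a few chromosomes, 20–120 kb
  footprints (module genes guaranteed long enough to host planted
  signals), GC ~ U(0.35, 0.65), CDS length log-normal (median ≈ 1.5 kb),
  GERP ~ N(2, 1). Module labels split ~47:21 between M1-like and
  M2-like, matching the real module sizes.
- **SNPs**: Poisson(40)/gene, derived frequencies Beta(0.5, 2) per
  population, S ~ N(0, 1), archaic genotypes mostly homozygous
  ancestral with rare derived carriage and explicit missing calls.
- **Ancestry probabilities** follow a two-component mixture: a
  background Beta with a = 0.5 and mean 0.02 (concentrated near 0, the
  qualitative shape of genome-wide introgression maps) and a planted
  component at 0.9. The mixture shape is a modeling choice; the real
  map's empirical distribution is not claimed.
- **Planted archaic haplotype**: 20 SNPs spread across one module
  gene, made archaic-specific (Altai/Denisova homozygous derived, AFR
  frequency exactly 0, non-African frequency = carrier frequency
  0.06) and carried in full LD by a minority of non-African
  chromosomes plus both archaic rows (150 modern chromosomes, 50 per
  population). Non-carriers are fully ancestral, so the phased matrix
  collapses to two haplotypes — enough to validate carrier-sharing
  and network structure, though real loci show more haplotype
  diversity.
- **Planted sweep**: the shortest run of consecutive SNPs spanning
  ≥ 30 kb (default; must be ≥ the 25 kb reporting minimum) in a module
  gene gets S scores 1–3 units below the 5th percentile of the
  remaining distribution; the immediate chromosome-wide flanking SNPs
  are raised to at least the median so the planted run has exact,
  recoverable membership. Without this flank adjustment recovery
  would be exact only up to chance low-S neighbours.
- **LRT inputs**: null genes draw 2ΔlnL from central χ²(df),
  alternatives from noncentral χ²(df, ncp); log-likelihood baselines
  are arbitrary. Planted site evidence passes two methods exactly
  (BEB 0.97 + FUBAR 0.95, or BEB 0.97 + MEME 0.01); background sites
  pass at most one (5% single-method passes exercise the consensus
  rule). Constraint values are Beta draws at concentration 40 with
  the module mean lowered by the configured shift (default 0.2).

One root seed drives everything through named child streams in fixed
positional order, so adding a stage never perturbs earlier draws and
a fixed seed reproduces the cohort byte for byte.

What passing tests show — and do not show — about real data: the
suites demonstrate that each rule is implemented exactly (oracle
equivalence), that planted signals of the stated strength are
recovered, and that null inputs are calibrated. They do not show
robustness to LD structure, ascertainment, or frequency-spectrum
features the generator omits.

## Sizes and tolerances

Default validation sizes: 2000 genes for null LRT calibration, 1000
random vectors for the BH oracle, 500 random instances for the sweep
oracle, 450 genes for null outlier calibration, 5 seeds for
planted-signal recovery, 60/300 seeds for constraint power/null
rates, 30 instances (≤ 4 haplotypes, length ≤ 8) for the Steiner
oracle. Null-rate assertions use a three-standard-error binomial
band around the nominal rate. Floating-point comparisons in tests use
relative 1e-2 for published (rounded) table values and ~1e-8
elsewhere.

## Degenerate inputs and tie-breaks

Zero LRT statistic ⇒ p = 1. Identical groups in the three-group
comparison return omnibus p = 1 (scipy's ANOVA yields NaN on zero
total variance; this is mapped to the null answer). A gene with no
scored SNPs yields a missing introgression score, excluded downstream
rather than imputed as 0. Missing archaic genotypes make the
archaic-SNP and modern-allele rules "not callable", distinct from
negative. Single-SNP introgressed regions are emitted as degenerate
spans of 1 bp (half-open). All exported intervals are 0-based
half-open; VCF POS and codon indices are the only 1-based surfaces.

## Known limitations

- The median-joining search is exhaustive over triplets each round
  (O(n³) median candidates per iteration); fine for the ≤ dozens of
  collapsed haplotypes it is meant for, not for thousands.
- The Nemenyi implementation uses the infinite-df studentized range
  (the standard large-sample form); exact small-sample tables are not
  implemented.
- FDR family grouping must be chosen by the analyst; the package
  deliberately refuses to guess it.
- The generator's two-haplotype planted structure cannot exercise
  networks with many reticulations; unit tests cover those paths with
  hand-built inputs instead.
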