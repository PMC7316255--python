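# Methods

## Scope and model

`msaptools` implements a complete methylation-sensitive amplified
polymorphism (MSAP) analysis for clonal plant panels — here a bud-mutation
("sport") line, where dozens of varieties share one genetic background and
epigenetic differences carry most of the signal.  The pipeline runs:

1. methylation-state scoring from dual-enzyme band matrices;
2. pattern-change classification against a designated reference variety,
   with the twelve-parameter (V5–V16) epigenetic summary and group
   coefficient-of-variation analysis;
3. dominant-marker diversity and structure statistics (simple-matching
   similarity, UPGMA, principal coordinates, Shannon/Nei diversity, AMOVA
   with PhiPT, Mantel);
4. a Bayesian FST-outlier scan for loci under diversifying or purifying
   selection between mutant groups.

A synthetic-data generator with full ground truth stands in for raw band
data, which studies of this kind typically do not deposit.

## Methylation-state scoring

MSAP scores every 5'-CCGG locus twice, after EcoRI+HpaII and EcoRI+MspI
digests.  The isoschizomers respond differently to cytosine methylation,
so the joint band pattern encodes four conditions: I = (1,1) unmethylated,
II = (1,0) CHG (external-cytosine / hemi-) methylation, III = (0,1) CG
(internal-cytosine) methylation, IV = (0,0) full methylation *or* target
absence.  Any missing band propagates to a missing state; missing values
are never imputed in scoring.

**Denominator convention.** Two conventions exist for percentage profiles:
divide by observed loci (I+II+III) or by the full panel (I+II+III+IV).
Published per-variety tables for this system are internally consistent
only under the *observed* convention (each variety's total equals
I+II+III), which is therefore the default; the panel convention is
selectable.  Condition IV is uninformative on its own — hypermethylation
and fragment loss are confounded — so it enters only the panel-level
parameter V15.

**MSL/NML partition.** A locus is methylation-sensitive (MSL) when the
fraction of non-missing samples in state II or III *strictly exceeds* an
error threshold (default 0.05, interpreted as a scoring-error rate to
exceed); otherwise it is non-methylated (NML).  This follows the
conventions of the widely used R `msap` package, as does the binary
recoding: over MSL loci, II/III → 1 (methylated), I → 0, IV → missing by
default (an `iv_as_methylated` option maps it to 1); over NML loci, band
presence (I–III) → 1, IV → 0.

## Pattern-change classification

Each mutant is compared locus-by-locus with the reference.  Two
classifications are derived from the same transition:

* **Band subtypes** A1–D3: reference class A (+/+), B (+/−), C (−/+),
  D (−/−) crossed with the mutant band pattern; the (−/−)→(−/−)
  transition carries no information and has no code (15 valid codes).
* **Categories** {CG-hyper, CHG-hyper, CG-hypo, CHG-hypo}, assigned per
  transition from fixed lists.  The unmethylated→fully-methylated
  transition (I→IV) belongs to both hyper categories.  The published
  lists are asymmetric in one place — IV→I is listed only as CHG-hypo,
  not also CG-hypo — and this package reproduces the lists verbatim
  rather than symmetrising them.

**V-parameters.** V5–V8 are the per-variety category frequencies
(CHG-hyper, CG-hyper, CG-hypo, CHG-hypo) as percentages of a *fixed panel
total* T; V9 = V5+V6 and V10 = V7+V8 hold exactly because
doubly-categorised transitions increment both addends.  V11–V14 are
level fractions over the variety's observed loci V16; V15 = 100·(T−V16)/T.
With T fixed, V15 is affine-decreasing in V16, so corr(V15, V16) = −1
exactly — the motivation for using the common denominator T rather than
per-variety V16 for pattern frequencies (only the former preserves
cross-variety comparability).  T is a configuration value, defaulting to
the number of scored loci in the dataset: the effective panel behind
published group tables of this kind is generally not recoverable from the
publication (filtering steps intervene between the raw locus total and
the panel entering group statistics), so no constant is hard-coded.

Group summaries use the sample (n−1) standard deviation — the only
convention that reproduces the published group SD cells from per-variety
data — and CV = SD/mean × 100.  Parameter correlations are plain Pearson
with t-transform p-values; no multiple-testing correction by default
(matching how such matrices are reported), with Holm available as a flag.

## Diversity and structure

All statistics treat band phenotypes directly as two-state frequencies
(no dominant-marker Hardy–Weinberg back-correction, matching GenAlEx-style
binary-data treatment; a Lynch–Milligan correction is deliberately out of
scope).  Per locus with p the frequency of 1: Ne = 1/(p²+q²),
I = −p ln p − q ln q, He = 1−p²−q² (so He = 1−1/Ne identically), and PPL
is the percentage of loci with 0<p<1.  An unbiased (n/(n−1)) He variant is
available but off by default.

* **Similarity**: simple matching over loci non-missing in both samples;
  pairs with no comparable loci are NaN, never filled.
* **UPGMA**: own implementation on 1−similarity with size-weighted
  average linkage, lowest-index tie-break, heights d/2 (ultrametric),
  newick output.  Tested against SciPy average-linkage cophenetic
  distances as an independent oracle.
* **PCoA**: classical metric scaling via scikit-bio; negative-eigenvalue
  mass is reported, not dropped.
* **AMOVA**: distance-based partition on squared Euclidean distances;
  SS identities per group, variance components from expected mean squares
  with the unequal-group-size coefficient n₀; PhiPT = σ²ₐ/(σ²ₐ+σ²_w);
  permutation p-values shuffle group labels with the inclusive
  (+1)/(n+1) convention (p is never 0).  Missing cells are mean-imputed
  per locus within group because the SS identities need complete vectors;
  similarity uses pairwise deletion instead — the two choices are logged.
* **Mantel**: Pearson correlation of upper-triangle distances, one-sided
  for positive association, permuting one matrix's rows/columns jointly.

## Bayesian outlier scan

The scan re-implements the BayeScan-type model for dominant binary data
rather than wrapping the released executable: the fidelity target is
behavioural (ranking of diverged loci, FDR control), not bit-for-bit
agreement.  The model decomposes locus-by-population differentiation as
logit(F_ij) = α_i + β_j, with priors α ~ N(0,1), β ~ N(−1,1), and
p_i ~ U(0,1) for the ancestral band frequency.  Group frequencies are
Beta-distributed around p_i with precision (1−F_ij)/F_ij and counts are
binomial.

**Numerical choice.** The latent group frequency is integrated out
analytically, leaving a beta-binomial marginal likelihood.  This is exact
(identical posterior over α, β, p), removes L×J latent variables from the
chain, and mixes faster than sampling them.

A reversible-jump move toggles each α_i; because the birth proposal is
the prior, proposal and prior densities cancel and the acceptance ratio
reduces to the likelihood ratio times the prior inclusion odds.  Prior
odds default to 10:1 for neutrality.  Gaussian random walks update p
(logit scale, with Jacobian), α and β; pilot runs (default 10 × 5 000)
multiply proposal widths by 0.8/1.2 until acceptance sits in 0.25–0.45.
Default run lengths follow the published full-scale settings: burn-in
50 000, thinning 20, sample size 5 000 (so 150 000 post-pilot iterations;
the burn-in + samples×thinning bookkeeping follows BayeScan).
`ScanConfig.reduced()` (20 000 iterations) is appropriate for panels of a
few hundred loci and is what the tests and the acceptance script use.

Posterior inclusion probability P_i gives posterior odds
PO = P/(1−P) × prior-odds; log₁₀PO > 2 ("strong evidence" on Jeffreys'
scale) is reported alongside q-values — the cumulative mean of (1−P) down
the P-ranked list (mean posterior error rate of the rejection set) — with
outliers called at q ≤ FDR (default 0.05).  Both decision columns are
emitted; neither is treated as "the" rule, since published analyses
invoke both.  P is capped at the Monte-Carlo resolution (1/2S) so odds
stay finite.  The α sign (posterior mean conditional on inclusion)
separates diversifying (α > 0) from purifying/neutral loci.

## Synthetic data

The generator emulates a clonal mutation panel: reference states drawn
from a configurable distribution (default (0.614, 0.130, 0.214, 0.042)
over I–IV, whose observed-band shares match the published panel means
64.090/13.599/22.311 with a small condition-IV mass); per-group 4×4
diagonal-dominant transition matrices built from category rates (defaults
give the Color group the largest pattern-change rates, echoing the
published group ordering); a per-(locus, group) shared target state
adopted with probability `group_coherence` (default 0.2), which is what
creates *between-group* variance — purely i.i.d. per-sample transitions
would leave AMOVA and the outlier scan nothing to detect; planted outlier
loci (default 16 at full scale) with one divergent group each
(round-robin), methylated at frequency 0.5 ± divergence/2; and post-hoc
band-flip noise (default 0.01), modelling electropherogram-level scoring
error, which is the error mode the MSL threshold absorbs.  Default panel
sizes mirror the study layout (2 954 loci; groups of 51/23/17 plus the
reference).

The companion AFLP track is generated under a Balding-Nichols model:
group frequencies Beta(pθ⁻¹(1−θ), qθ⁻¹(1−θ)) around an ancestral
p ~ U(0.1, 0.9), for which the expected AMOVA among-group share equals θ
exactly — making θ a directly *planted* PhiPT.  Its random stream is
seeded independently of the methylation track, so the epigenetic–genetic
Mantel correlation is null by construction at the locus level (group
structure shared by both tracks still induces a modest positive r, as in
real panels).

What the generator does **not** emulate: fragment-length/mobility
artefacts, primer-combination batch effects, coalescent ancestry within
groups, linkage between loci, and context-dependent mutation-accumulation
dynamics.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated sampling model, not robustness to
those real-data complications.

## Problem sizes and numerical checks

Tests and the acceptance script run scaled-down instances chosen to make
Monte-Carlo checks sharp at small cost: oracle equivalence uses ≥100
random instances of ≤12 samples; PhiPT recovery uses θ = 0.15 (the
published among-group epigenetic share) over 20 seeds with 3 groups × 10
samples × 300 loci; the outlier-scan power check uses 200 neutral + 5
strongly diverged loci over 3 groups × 15 samples with the reduced
(20 000-iteration) MCMC across 10 seeds.  Permutation tests use 999
permutations at full scale and 49–199 in quick checks.  The published
outlier counts (16 outliers; 601/1147 positive/negative α split) depend
on unreleased raw data and are covered only by arithmetic consistency
checks.

Degenerate inputs are defined rather than crashed on: zero-denominator
profiles raise a dedicated error; all-missing loci are excluded and
listed; monomorphic groups yield Ne = 1, I = 0, He = 0, PPL = 0;
zero-variance parameters yield NaN correlations (flagged); a
zero-total-variance AMOVA reports PhiPT as NaN; the scan refuses
single-group input (unidentifiable).

## Known limitations

* Condition IV's ambiguity is handled by convention (missing by default),
  not resolved; bisulfite-resolution data would be required to do better.
* The scan's dominant-data likelihood uses band frequencies directly; a
  square-root dominance correction is a declared option but the band-
  phenotype convention is used throughout for consistency.
* UPGMA tie-breaking (lowest index) is deterministic but arbitrary; trees
  from tied distance matrices are reproducible, not unique.
* Hierarchical AMOVA beyond one grouping level, pairwise-population
  scans, and admixture/STRUCTURE-style inference are out of scope.
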