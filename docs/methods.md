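# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the limitations of `nodevo`. It states nothing
that the test suite or `scripts/acceptance.py` does not itself compute.

## Ortholog-set merging and representatives

Per-gene ortholog predictions are sets of species-tagged gene ids, each
containing its own query gene. Predictions sharing at least one gene
are merged transitively — the partition is the set of connected
components of the overlap graph (computed with networkx). Group ids
(`MergedOrthoGroupNNNNNN`) are assigned by sorting components on their
smallest member, so the partition and its labels are invariant to input
order; merging is idempotent.

Representative selection is two-tier. A *whole* representative must
(1) contain at least one member from each focal species and (2) equal
some single gene's predicted set exactly. Within the remaining
(fused) groups, candidates are single-gene predictions restricted to
the focal triple that meet the presence criterion; overlapping
candidates are unioned (connected components again) so subsets stay
mutually exclusive, and numbered `SubNNN` in sorted order. The
restriction-then-union rule is an interpretation: the source procedure
is under-specified on whether subsets must equal or merely contain a
restricted single-gene prediction. Union-after-restriction preserves
mutual exclusivity and reproduces identifiers of the form
`...Sub002`, so it is the default and only behavior.

## Enhancement classification

All inequalities are strict: nodule-enhanced means log2FC > +1 *and*
adjusted p < the species cutoff; root-enhanced symmetrically. Defaults
follow the study design this package models — p < 0.005 for the
three-replicate species (Ct) and p < 0.001 for the others — and are
configurable per species (`RunConfig.p_cutoffs`). Strictness matters at
the boundary: a paralog at log2FC = 0.99 with p = 0.001 is correctly
non-significant.

Paralog aggregation: one significant paralog calls the (group, species)
pair; paralogs significant in opposite tissues yield `both`; otherwise
`none`. A `both` call counts toward *each* tissue when collecting core
groups (groups enhanced in the same tissue in all three focal species);
`both_counts_for_core=False` switches to the conservative reading. The
packaged pathway table never exercises the difference.

Genome-wide legume tables are normalized before classification: genes
expressed in neither tissue get (log2FC 0, p 1); tissue-specific genes
get log2FC ±15 with missing p-values defaulting to 1. The ±15 sentinel
dwarfs any observed fold change, and the p = 1 default makes
tissue-specific genes non-significant unless the upstream analysis
supplied a p-value. That literal default is debatable — an on/off
pattern could equally be treated as significant by construction — so
`tissue_specific_significant=True` exposes the alternative (p = 0).
Legume group calls use *M. truncatula* records only; *L. japonicus*
entries contribute ortholog presence, never calls, because they carry
no expression values.

## Dissonance score and permutation test

For one group and one species pair with member fold-change vectors A
(length m) and B (length n), the dissonance is the mean absolute
pairwise difference D = Σᵢ Σⱼ |Aᵢ − Bⱼ| / (m·n); the overall score sums
D over all representative groups. D is symmetric, translation-invariant
and positively homogeneous, so the statistic measures disagreement of
nodule/root shifts, not their absolute size.

The permutation null reshuffles the pooled fold-change values across
transcripts *within each species* (group sizes preserved); both species
are reshuffled each replicate by default (`permute_both_species=False`
shuffles only the second). The permutation unit is the individual
transcript value, not the group label, matching a resampling of fold
changes; a group-label mode would be a different null and is not
implemented. The primary p-value is the inclusive fraction of
replicates with an overall score at or below the observed one; because
that estimator degenerates to 0 below the permutation resolution, the
(k+1)/(N+1) estimator is reported alongside. Default 10,000 replicates;
the generator seed is mandatory and results are bit-reproducible per
seed.

For Pearson subsets, multi-paralog groups are represented by the most
similar fold-change pair (minimum |fcₐ − fc_b|), ties broken toward the
lexicographically smallest pair for determinism. Correlations use the
sample Pearson r with the two-sided t-test p-value (scipy); a
zero-variance margin yields a flagged, undefined result.

## Codon model and scenario test

The substitution process is the Goldman–Yang codon model on the 61
sense codons of the universal code: rates between codons differing at
one nucleotide are π_target × κ^[transition] × ω^[non-synonymous], zero
otherwise. Each branch class has its own ω; κ and π are shared. Every
class generator is scaled to one expected substitution per codon, so
branch lengths are in substitutions/codon under that class's process.
Codon frequencies default to F3x4 (position-specific nucleotide
frequencies of the alignment), with an empirical-61 estimator
available; frequencies are floored at 1e-10 and renormalized so
observed codons are never likelihood-invisible.

Per-site likelihoods use Felsenstein pruning with per-node rescaling.
Transition matrices come from the symmetric eigendecomposition that
reversibility affords (π½ Q π^−½ is symmetric), giving exact
expm(Qt) at eigendecomposition cost per class, amortized over branches.
Gap/ambiguous codons are fully missing (partial vector of ones), i.e.
the likelihood sums over all 61 states.

Fitting maximizes lnL over log-transformed parameters with bounded
L-BFGS-B (ω ∈ [1e-4, 20], κ ∈ [0.1, 20], lnL tolerance 1e-6) and
multi-start (defaults κ=2, ω=0.5 and κ=4, ω=1.5). Branch lengths are
handled in three modes: `fixed` (use the input tree), `scale` (default:
fit a single ML rescaling of the input lengths under NULL), and `full`
(fit every length). The default estimates lengths once under NULL and
fixes them for SINGLE/MULTI/TWOSTEP; a single scale factor rather than
per-branch re-estimation keeps a four-scenario group fit at a few
seconds on one core while leaving the scenario contrasts — which live
in the ω parameters — unchanged in the regimes the tests cover. Each
scenario is warm-started from every fitted sub-scenario it extends
(TWOSTEP from SINGLE and MULTI, these from NULL), which both speeds
convergence and guarantees the nesting inequality
lnL(TWOSTEP) ≥ lnL(SINGLE), lnL(MULTI) ≥ lnL(NULL) by construction
(monotone line search cannot leave the optimizer below its start).
Non-convergence flags the result rather than aborting.

Branch classes are assigned from clade definitions: *a* = stem of the
NFC clade, *b*/*c* = terminal branches of the Ct/Dg taxa, *d* = stem of
the legume clade. A clade that is absent or non-monophyletic on a given
(e.g. unconstrained) tree leaves its class unavailable and the
scenarios requiring it are skipped, mirroring scenario skipping when
the required clade is missing.

Tree choice fits the one-ratio model on the constrained and
unconstrained candidates and compares them with a Kishino–Hasegawa RELL
test (bootstrap site resampling of the lnL difference, centered at
zero, two-sided); the unconstrained tree is used only when
significantly better at p < 0.05. Scenario rejection uses the
Shimodaira–Hasegawa procedure jointly over NULL and all fitted
alternatives (shared RELL replicates, per-candidate centering, max
statistic); candidates with p < α = 0.05 are rejected and the best is
never rejected. Joint inclusion of NULL in one SH family reproduces the
"did not reject the NULL" bookkeeping in a single procedure; 1,000 RELL
replicates by default. Whether the original analysis ran SH jointly or
pairwise is not documented; joint is the implemented choice (it is the
more conservative family).

Classification mirrors the two-row tabulation: among groups that
rejected NULL and retained at least one of {SINGLE, TWOSTEP}, branch
*a* categories are reject-TWOSTEP / reject-neither / reject-SINGLE;
branches *b–d* analogously over {MULTI, TWOSTEP}. Groups where a
scenario was skipped are excluded from that row.

## Synthetic data

The expression generator draws null fold changes multivariate-normal
across species (marginal sd `null_sd`, default 1.5; pairwise
correlation ρ via a one-factor model, or exact Cholesky for two
species, which also permits negative ρ). Enhanced groups (stated
fractions per tissue) add a shared shift |N(3, 1)| (negated for root),
so enhancement is concordant across species as in co-adapted pathways.
Paralogs scatter around the species value with sd 0.5. Adjusted
p-values are Uniform(0, 0.0005) for enhanced and Uniform(0.05, 1) for
null genes — enough structure to exercise threshold logic without
modeling a moderated-variance differential-expression fit. For the
dissonance acceptance experiment the null sd is 2 and ρ = 0.4 with
5,000 single-member groups.

The ortholog generator builds ground-truth families (one gene per
species, paralogs at `dup_rate`) and per-gene predictions equal to the
family, optionally contaminated with one random cross-family gene at
rate `noise` to create fusions. The codon simulator draws the root
sequence from π and evolves it down the labeled tree with the same
transition matrices the inference uses. All generators are pure
functions of (config, seed).

What the generators do *not* emulate: assembly and quantification
noise, limma's moderated variance, heavy-tailed fold-change
distributions, expression-dependent p-values, alignment error, among-
site rate variation, and selection regimes outside the branch-model
family. Passing tests therefore demonstrate correctness of the
statistics and estimators under their own assumptions, not robustness
to real-data violations of them.

## Problem sizes and test design

The statistical acceptance tests run at: 5,000 groups × 10,000
permutations (dissonance headline), 200 replicate datasets of 300
groups × 400 permutations (calibration; Kolmogorov–Smirnov distance
from uniform < 0.1), 1,000 codons × 8 taxa × 3 seeds (single-ω
recovery to within [0.15, 0.25]), and 25 replicates per generating
scenario at 600 codons on the 15-taxon tree (retention ≥ 80%, NULL
false-rejection ≤ 10%). These sizes were chosen so the full suite
completes in minutes on a single core while keeping Monte Carlo
uncertainty far from the asserted margins. Likelihood unit tests pin
the pruning algorithm to an exhaustive internal-state enumeration
oracle on 4-taxon, 3-codon instances at 1e-8.

## Known limitations

- Exact log-likelihood equality with codeml is not claimed: the
  frequency estimator, optimizer path and branch-length policy differ
  in documented ways; agreement is asserted at the level of scenario
  ranking and parameter recovery on simulated data.
- The packaged 15-taxon tree uses synthetic branch lengths on the
  family-level topology; real analyses should supply their own gene
  trees.
- The SH test's conservatism means low power to reject near-equivalent
  scenarios on short alignments; TWOSTEP, nesting all others, is
  essentially never rejected when it is fitted.
- Sites are assumed independent and classes constant within a branch;
  no branch-site or site-model variants.
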