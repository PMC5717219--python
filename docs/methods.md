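# Methods

## Model

The package models per-site bulk sequencing signals from one or more
biopsies of the same patient with a dynamic graphical model: one frame per
genomic site, two coupled hidden Markov chains, and a set of tied discrete
prevalence variables.

**Sites.** Two site types enter the model: germline heterozygous sites
(`het`), where allelic imbalance and depth changes reveal copy-number
alterations, and somatic SNV sites (`som`), where the allelic ratio reveals
the mutation's cellular prevalence. Each site carries, per biopsy m, the
allelic ratio A (fraction of reads with the alternative allele) and the
tumor/normal log2 depth ratio L.

**Hidden state.** At site t the chain state is a pair (G_t, Z_t): G_t is an
allelic copy-number genotype (n total copies, a alternative copies, all
pairs with 0 ≤ a ≤ n ≤ c_max; c_max = 5 gives 21 states, with AB = (2, 1)
the designated no-CNA state) and Z_t indexes the clone in which the event at
t arose. Per biopsy and clone, a prevalence variable takes values on a
discrete grid (default 20 equally spaced levels 0.05 … 1.00).

**Emissions.** Both observations are Gaussian around deterministic means.
With carrier prevalence p = phi_m^z, the expected allelic ratio is
(a·p + a_N·(1−p)) / (n·p + 2·(1−p)), with a_N = 1 at het sites and 0 at som
sites, and the expected log ratio is log2((n·p + 2(1−p))/2) + c_m, where c_m
is a per-biopsy offset absorbing depth and ploidy differences. Variances are
estimated per biopsy (allelic ratio: separately per site type). Two
degeneracy rules: a vanishing denominator (total deletion at p = 1) maps the
allelic ratio to 0.5 (pure mapping noise), and the average copy number is
floored at 0.01 before the log.

**Transitions.** The probability of staying in state j across a gap of h bp
is exp(−(log h)²/(2σ_j²))·(K−1)/K + 1/K — exactly 1 at h = 1, decaying to
the uniform rate 1/K, with a per-state decay variance σ_j² estimated from
data; the remaining mass spreads uniformly. The same kernel applies to both
chains. At chromosome starts the chains restart from trained priors.
Natural log is used for h; the base only rescales σ and is absorbed by
estimation.

## Prevalence bookkeeping

The decoded prevalence levels phi^1 > phi^2 > … are *carrier* fractions: the
fraction of cells in the biopsy carrying the events of clone z. Within a
biopsy the clones are assumed nested in a chain (parent events are carried
by the child too), so clone *cell* fractions are successive differences
phi^z − phi^{z+1}. A biopsy with carrier levels 0.75/0.35 therefore reports
a parent clone at 40% and a child clone at 35% of cells; the strict ordering
also breaks label switching. In the multi-biopsy tree model the clone chain
indexes tree edges and the carrier prevalence of an edge in biopsy m is the
cell-fraction sum over the subtree below it.

## Fitting

`run_themis` (or `CloneHMM(...).fit()`) orchestrates:

1. **Initialization.** Variances σ²_A = 0.01, σ²_L = 0.04, transition
   σ² = 25 (slow decay), uniform priors. The initial offset c_m is the
   median log ratio over germline sites with allelic ratio in [0.4, 0.6]
   (the putative normal cluster), unless supplied.
2. **Prevalence search.** The grid configuration maximizing the Viterbi
   path score (plus the grid prior) under the current parameters —
   exhaustive over ordered configurations when their count is small
   (C(20, 2) = 190 for two clones and one biopsy), otherwise iterated
   conditional modes from several deterministic starts. The path score
   rather than the marginal likelihood is used deliberately: decoding
   maximizes jointly over all hidden variables, and the marginal rewards
   degenerate low-prevalence configurations (see the identifiability guard
   below). Clone levels within a biopsy must be separated by at least two
   grid steps (`RunConfig.min_level_gap`): clones closer than that are
   declared indiscernible by the model, and allowing adjacent levels lets a
   spurious clone absorb segment-mean jitter, which systematically inflates
   the apparent clone count.
3. **EM.** With prevalences fixed, emission variances have closed-form
   weighted-residual updates; the transition decay variances are maximized
   per state by bounded scalar search on [1e−2, 1e4] (no closed form
   exists), accepting a new value only when it improves the expected
   transition log likelihood, which preserves EM ascent; states with fewer
   than five expected transitions keep their current (slow) decay rather
   than collapsing from stray visits, since an unvisited state's decay
   variance would otherwise be driven to the boundary and poison any later
   path through it. Start priors are normalized expected start-frame
   counts. Convergence: log-likelihood improvement below 1e−4 or 100
   iterations.
4. **Offset recalibration.** c_m is re-estimated as the mean log ratio over
   sites decoded AB; when it moves by more than 0.01 the whole fit reruns
   with the new offset (a second pass).
5. **Decoding.** Viterbi over the joint chain (ties to the lowest state
   index), maximal constant-(G, Z) runs reported as segments (1-based closed
   TSV, 0-based half-open BED).

**Identifiability guard.** At very low prevalence every genotype's expected
signals approach the normal values, so an entire genotype block can
impersonate the AB state; the marginal likelihood then *prefers* adding such
a clone (a path-multiplicity bonus), and even the path score can exploit
sub-noise mean offsets to track observation noise. A non-null (genotype,
clone) state is therefore excluded when its expected germline signals
differ from AB, in every biopsy, by less than 1.0 combined squared noise
units ((ΔA/0.05)² + (ΔL/0.2)², reference scales configurable via
`RunConfig.min_effect`). The reference scales are the package's nominal
noise levels; datasets with much tighter noise can lower them to regain
sensitivity below ~0.15 prevalence. States carried by at least ~20% of
cells are unaffected, which matches the method's stated power envelope.

**Degrees of freedom.** BIC uses k = 3M (variances) + |G| + |Z| (transition
variances) + (|G|−1) + (|Z|−1) + (|P|−1) (priors), with n the number of
site-biopsy observations. The count is reported alongside the score so
users can substitute their own.

**Clone-number selection.** Starting at 2 clones, the count increases until
the criterion deteriorates (the model after the optimum is the last one
fitted): BIC (smaller is better) on the full fit, or 3-fold chromosome
cross-validation (random seed-deterministic partition of chromosomes;
held-out chromosomes scored by the trained model's per-site Viterbi score).
The CV comparison applies the one-standard-error parsimony rule to the
paired per-fold differences: a larger model counts as an improvement only
when its mean held-out gain exceeds the standard error of that gain.
Independently trained fits differ by ~0.01 per site in their
transition-variance estimates even when the extra clone state goes unused,
and without the parsimony rule that wobble alone can add a clone.

**Multi-biopsy analysis.** Five steps: per-biopsy fits; merging of clones
from different biopsies with Jaccard similarity ≥ 0.8 over aberrant units
(identically genotyped CNA sites plus shared SNVs — the similarity metric
and threshold are this package's concrete choice, configurable); ancestry
constraints from the prevalence rule (carrier prevalences summing above 1 in
some biopsy with strict dominance wherever both clones are present) plus a
containment rule (≥ 90% of a smaller clone's events recurring identically in
a larger one implies ancestry); enumeration of all rooted trees over the
merged clones — including inferred intermediate clones carrying event sets
shared by two clones but absent elsewhere, with zero cell fraction — that
satisfy every constraint; and a joint refit per candidate tree with
edge-indexed clones and subtree-sum prevalences, keeping the
maximum-likelihood tree. Clones separated by fewer than two grid steps in a
biopsy trigger a warning (they may not be discernible).

**Single-cell classifier.** Region classes derive from a two-clone bulk
decomposition: AB segments (baseline), 1-copy parent-clone segments (clonal
LOH) and 1-copy child-clone segments (subclonal LOH). Per-segment read
counts are Poisson with rate baseline × length × relative copy (copies/2:
0.5 in LOH regions for the carrying classes, 1 otherwise); the per-cell
baseline comes from the cell's own clonal 2-copy coverage, making the
assignment scale invariant. Posterior over {normal, parent, child} with a
uniform prior by default; cells without baseline coverage are reported as
`unknown`. QC drops cells below a minimum read count (default 10,000) or
above a short-read fraction cap (default 0.3); both thresholds are
heuristics and configurable. The exact likelihood form is this package's
own surrogate for the published classifier's unavailable details; it
reproduces the expected coverage signatures (≈1.0/1.0 normal, ≈0.5/1.0
parent, ≈0.5/0.5 child in clonal/subclonal LOH).

## Synthetic patients

The simulator runs the observation model forward from an explicit truth
specification: a clone tree with per-edge CNA segments and SNV sites laid
over a synthetic genome, per-biopsy clone cell fractions, Gaussian noise on
A (clipped to [0, 1]) and L, and per-biopsy offsets. Inter-site distances
are log-uniform on 10²–10⁵ bp, giving the diverse gap spectrum that makes
distance-dependent transitions matter. Events are arranged so only one
clone's event covers any position, every clone carries at least one 1-copy
LOH event (so the single-cell region classes are populated), and all
carrier prevalences fall on the default grid.

Reference conditions (factory defaults, chosen once):

- `two_clone_spec`: 3 chromosomes × 3,300 het + 34 som sites (T ≈ 10,000),
  cell fractions 0.40/0.35 (carriers 0.75/0.35), σ_A = 0.05, σ_L = 0.2,
  c_m = 0.25.
- `three_clone_spec`: cell fractions 0.45/0.25/0.20 (carriers
  0.90/0.45/0.20), same noise.
- `multi_biopsy_spec`: three biopsies on the branching history
  A → B → CD → {C, D} with CD an unsampled intermediate (cell fraction 0
  everywhere); per-biopsy compositions {A: 0.50, B: 0.30},
  {A: 0.45, C: 0.35}, {A: 0.40, D: 0.40}; low noise (σ_A = 0.03,
  σ_L = 0.1).

What the generator does *not* emulate: read-level sampling (the observation
model is Gaussian by construction, so emission misspecification is never
tested), GC/mappability artifacts, subclonal fractions off the grid,
overlapping events from different clones, and whole-genome-amplification
bias in the single-cell counts. Passing recovery tests therefore
demonstrate correctness of inference under the model's own assumptions, not
robustness to real-data artifacts.

Test problem sizes are scaled to what the checks need: the two-clone
recovery run uses the full T ≈ 10,000 reference patient; EM-ascent checks
use ~300-site patients; clone-number selection uses 6 chromosomes × ~250
sites with three ~35-site events per chromosome, across 10 seeds (real
CNAs span many contiguous het sites, and event length is what powers both
selection criteria); the phylogeny study uses ~400 sites per chromosome
across 3 biopsies.

## Numerical choices

- All likelihood computation in log space; scaled forward/backward with
  per-frame normalization; chromosomes are independent blocks.
- The factorized transition kernel is applied in O(G·Z) per frame (diagonal
  plus uniform spill along each axis) rather than O((G·Z)²).
- Viterbi ties break to the lowest (genotype, clone) index, making decoded
  paths reproducible bit for bit.
- Emission variances are floored at 1e−8; priors at 1e−12 (renormalized).
- Kernels are numba-compiled when available, with identical pure-Python
  fallbacks.

## Known limitations

- Two clones at identical prevalence in one biopsy are unidentifiable
  (inherited model assumption); the chain ordering forces strictly distinct
  levels, and the search keeps levels at least two grid steps apart.
- Exact genotype–prevalence aliasing: at germline sites, genotype (n, a)
  carried at prevalence 2p produces the same expected allelic *and* log
  ratio as (2n−2, 2a−1) at p, so compositions sitting exactly on 2:1
  carrier ratios admit interchangeable decodes (e.g. AAB at 0.9 vs AAAB at
  0.45). Worse, every a = 1 gain state (AAB, AAAB, AAAAB) has germline
  signals that depend only on the product (n−2)·p — the whole family is
  mutually aliased across prevalence rescalings, so the prevalence of a
  gain of the reference allele is unidentifiable from germline sites alone.
  Somatic sites break these ties but are sparse. The simulator's default
  compositions avoid 2:1 carrier ratios and use identifiable event
  genotypes (gains with a ≥ 2); on real data this aliasing is an inherent
  model limit worth keeping in mind when interpreting decoded gain states.
- Within-biopsy nesting (the chain convention) is an interpretation; a
  biopsy containing genuinely sibling clones will still be decoded as a
  chain of carrier levels, and the reported cell fractions then mix the
  siblings' contributions.
- Only one CNA event per position across all clones (model assumption 5 of
  the underlying framework); regions violating it are rejected by the
  simulator and mis-decoded by the model.
- The segment count is not constrained; very noisy data can over-segment.
- Events carried by fewer than ~15% of cells sit inside the identifiability
  guard's exclusion zone at the default reference scales and are decoded as
  normal.
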