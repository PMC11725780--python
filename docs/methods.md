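# Methods

This note documents the models behind each module, the defaults and why,
what the synthetic data do and do not emulate, and the numerical choices
that matter for reproducing results.

## Synthetic study generator

The generator produces the whole observation chain with known truth.

**Pedigree and gene dropping.** The default fixture is an
eleven-individual, four-generation pedigree: six sampled burials (B1–B4,
B1s, B3s) and five unsampled relatives.  B4 is the maternal grandfather
of the full siblings B1, B2 and B3; B1s is B1's child; B3s is B2's
child.  Mitochondrial lineage mtD-1 runs down the sampled matriline;
B3s carries mtD-2 from her unsampled mother.  Birth years (436–487 CE)
and ages at death (13–28 y) are chosen so deaths of all but B4 coincide
at 500 CE, with B4 dying in 458 CE.  Founders draw Hardy–Weinberg
haplotypes at panel frequencies (Beta-distributed, truncated to
[0.01, 0.99], emulating an ascertained capture panel); meioses place
Poisson crossovers on a 22-chromosome genetic map totalling 3545 cM with
no interference.  Founder-haplotype origin labels are propagated as exact
IBD truth.

**Observation model.** Depth is Poisson per site (per-individual means;
presets cover the study's 0.01–1.2× range); each read samples one
haplotype, flips alleles with a base error (default 0.001), and
additionally miscalls reference→alternate with a deamination-like damage
rate.  The damage default (0.005) is an *effective post-trim residual*:
raw ancient-DNA terminal damage of 22–44% is largely removed by trimming
read ends before genotyping, and this pipeline operates downstream of
that step, so modelling within-read position would add nothing the
genotype-level estimators could see.  Pseudohaploid calls pick one read
uniformly per covered site.

**What the simulation does not emulate:** reference bias, contamination,
mapping artefacts, non-uniform capture efficiency, linked-read error
correlation, and ascertainment of specific 1240k sites.  Passing tests
therefore demonstrate statistical correctness of the estimators under a
clean observation model, not robustness to every artefact of real
libraries.

**Radiocarbon.** Calibration curves are synthetic stand-ins: a
terrestrial curve with smooth sinusoidal wiggles (σ = 12 14C yr) around
the 1:1 trend and a smoother marine curve offset by a 430-yr global
surface reservoir (σ = 20).  They behave like real curves (plateaus,
mild reversals) without shipping published curve files; any standard
`.14c` file can be substituted.  Simulated determinations draw
Normal(μ_mix(t), √(σ_curve² + σ_lab²)) at the tissue-formation year
(birth + tissue age; defaults: adult bone collagen forms ~14–18 y before
death, juvenile tissue ~5 y), with marine fractions per individual taken
from the diet table (0.30–0.71) and ΔR = −270 as the generating truth.
Context dates (8 by default) form up to 15 y before deposition
(short-lived plant matter and textiles).

## Kinship

**PMR.**  Mismatch fraction over shared pseudohaploid sites.  Under
Hardy–Weinberg the conditional mismatch probabilities given IBD state are
exactly (b, 3b/4, b/2) for IBD0/1/2, giving E[PMR/b] = 1 − r/2.  The
baseline b is the median PMR among designated unrelated reference pairs
(the shipped study has no unrelated sampled pairs, so simulations carry
extra unrelated reference individuals; an explicit numeric baseline is
also accepted).  Standard errors are leave-one-window-out jackknives over
10 cM map windows, robust to linkage.  Degree cutoffs sit at midpoints
between the expectations (0.625 / 0.8125 / 0.90625 / 0.953125); a call
is withheld ("undetermined") below 2,000 overlapping SNPs — the regime
in which even consistent methods become unreliable — or when ±2 SE spans
a cutoff.

**ML k-coefficients.**  Per-site genotype likelihoods are binomial in
read counts with error ε (default 0.01, absorbing base error plus
residual damage).  The pair likelihood marginalizes genotype pairs over
P(g_i, g_j | k, f), built numerically from the shared-allele
construction; (k0, k1, k2) maximize the summed log-likelihood on the
simplex by coarse grid (step 0.05) plus two zoom refinements, ties
broken toward larger k0.  Sites are thinned deterministically to at most
60k for speed.  The *degree call* compares canonical IBD profiles
(parent–offspring (0,1,0), siblings (¼,½,¼), 2nd (½,½,0), 3rd (¾,¼,0),
unrelated (1,0,0), identical (0,0,1)): the best class wins only when it
beats the runner-up by ≥ 2 log units, otherwise the call is
undetermined.  This mirrors the PMR SE gate and prevents overconfident
calls at a few thousand sites.

**Sibling vs parent–offspring.**  Windowed mismatch counts (20 cM) are
modelled as Binomial(n_w, rate) with state rates (b, 0.75b, 0.5b).  The
parent–offspring model pins every window at IBD1; the sibling model is a
3-state HMM with stationary weights (¼, ½, ¼) and window-to-window
mixing exp(−w/25 cM) (≈ the expected sibling IBD segment scale).  The
two models share the genome-wide mean and differ in the variance
profile, which is what the likelihood margin measures.  Fewer than 20
usable windows → NA.

**Consensus.**  Confidence-weighted majority over methods; undetermined
calls abstain; disagreements are flagged, never silently resolved.

Realized IBD varies between replicates (the grandparental genome share
has SD ≈ 2.3%), so single pairs near band boundaries (especially 2nd vs
3rd degree) are intermittently undetermined or miscalled even with
perfect estimation; accuracy is therefore assessed as the rate of
correct calls over the full relationship set across replicates.

## Sex and matrilines

Ry = nY/(nX+nY) with one-sided 5% normal-approximation bounds against
the published thresholds (0.016 / 0.075); Rx as the mean X/autosome
coverage ratio with a t-interval over autosomes, XX in [0.8, 1.2] and XY
in [0.3, 0.7]; both reported, conflicts undetermined.  Matriline
consistency partitions individuals by mother-edge components: all
sampled members of a component must share the mt label.

## ROH

Two-state HMM on 1 cM windows: non-autozygous emission rate is the mean
expected heterozygosity of the window's SNPs; autozygous rate is a
residual 0.002.  Transition scale 15 cM (the segment scale for recent
inbreeding loops), autozygous prior 2%.  Viterbi segments are reported
with forward–backward posteriors.  Inputs sparser than one expected het
call per window are refused.  The long-ROH sum (> 20 cM) maps to
parental-relatedness bands centred on F·L (boundaries 10 / 35 / 110 /
220 cM); sums within 5 cM of a boundary report both classes.  This
genotype HMM replaces reference-panel haplotype copying deliberately: it
needs genuinely diploid calls and is validated on synthetic diploid
data, not on 0.1× pseudohaploid data.

## f-statistics and trees

f3(O; A, B) = mean (a−o)(b−o) and f4(A,B;C,D) = mean (a−b)(c−d) over
sites with complete data; weighted delete-one-block jackknife (blocks of
5 Mb physical, or per-cM for synthetic maps; weights are block SNP
counts) gives SE and Z.  Pseudohaploid singletons contribute 0/1
frequencies; per-group heterozygosity corrections are not applied, so
outgroup-f3 values are internally comparable but not absolute drift
estimates.  Neighbor joining is the standard agglomeration with
deterministic lexicographic tie-breaks and non-negative branch clamping;
an outgroup option re-roots on the outgroup's edge.  A transversions-only
flag filters damage-sensitive sites.

## Pedigree search

Enumeration assigns each individual (sampled first, oldest first) either
founder status or an ordered parent pair drawn from existing
individuals and fresh latent individuals (budget `max_latent`, ancestor
chains capped at 3 generations above sampled nodes).  Pruning uses the
monotonicity of kinship in added ancestors (current φ is a lower bound),
exact band checks once a pair's ancestor closure is decided, parental-age
feasibility (12–50 y at a child's birth, composed across g generations
as [12g, 50g] and as ±(50−12) per shared-ancestor level for collaterals),
and a no-close-kin rule for parent couples (kinship ≤ 0.06, i.e. third
degree or more distant; consanguineous couples explode the search space
and are archaeologically unidentifiable here anyway).  Latent structures
are deduplicated by canonical relabelling.  The search is budgeted
(`cap` expansions); hitting the budget flags a partial result.

Scores add: degree-mismatch penalties (confidence-weighted, scaled by
band distance), sibling/parent–offspring HMM margins, log-probabilities
of generational gaps under Normal readings of the 95% birth intervals,
and a 0.5-point complexity penalty per latent individual (prefers the
most parsimonious of otherwise equivalent structures).  Mt-lineage
mismatch on a maternal path and infeasible generational gaps are hard
vetoes.  Ties are reported as ties; when the evidence cannot separate
"child of B2" from "child of an unsampled sibling", both candidates are
retained.

## Chronology

All years are cal BP internally (CE on output).  Single calibration
evaluates the measurement likelihood against the (mixed) curve on a
1-yr grid under a flat calendar prior; HPD by density thresholding.  The
family model's parameters are per-individual births and ages-at-death
(uniform in the osteological range), the deposition year, ΔR
(Uniform(−600, 100) — generous around any plausible Pacific-coast
value), per-date marine fractions (truncated-normal priors from the diet
table), and per-context-date inbuilt ages (Uniform(0, 20 y)).  Hard
constraints: deaths of co-deposited individuals within ±5 y of the
deposition year (a single event, with slack for osteological age error),
and ancestor–descendant birth gaps in [12g, 50g] for g meioses —
composed across unsampled generations, which is what transfers the
context-date precision to individuals like the grandfather.

Sampling is Metropolis-within-Gibbs with per-parameter Gaussian
proposals adapted to ~35% acceptance during burn-in, plus a joint
translation move of the deposition year with all member births (the ±5 y
coupling otherwise mixes poorly).  Two chains by default; split-R̂ > 1.05
on any headline parameter flags (never suppresses) the result.
Agreement indices follow the OxCal-style ratio
A = 100·∫L·p_model / ∫L·p_single per determination, with the geometric
mean reported overall.  Reported dates are medians and 95% HPDs rounded
to 10 y.

Identifiability: ΔR is informed through the marine-weighted human dates
once the terrestrial context dates anchor the deposition year; with all
marine fractions zero and no constraints the model provably reduces to
single-date calibration (tested as an oracle identity).

## Isotopes

%C4 = 100·((δ13C_en − 9.7) − (−26)) / ((−12) − (−26)), clamped to
[0, 100].  The enamel–diet spacing is 9.7‰; endpoints −26‰ (C3) and
−12‰ (C4).  %Marine is two-source mixing on δ15N between the marine
endpoint (12.7 ± 2.7‰) and a terrestrial composite (an even blend of the
terrestrial-mammal endpoint with a C3/C4 plant mix weighted by the
carbon-derived C4 fraction); endpoint uncertainties are propagated by
Monte Carlo (20k draws), and estimates are clamped to [0, 100] rather
than erroring, since measurement noise can overshoot endpoints.  The
composite weighting is configurable; point estimates should be read with
their ±SD (~20–30 percentage points).  Provenance screening is a pure
interval test against user-supplied local ranges per isotope system
(boundary values indeterminate; any nonlocal system makes the combined
call nonlocal) — no geological model is built in.

## Problem sizes

Default validation sizes are chosen for a laptop-class run: kinship recovery
uses 8–10 replicates of a 100k-SNP panel at 1.2× (≈ 50k pairwise
overlap), ROH uses 15–25 replicates of 30k SNPs, chronology recovery 10
seeds of a 13-determination model at 4–6k MCMC iterations, and the CLI
pipeline demonstration 30k SNPs with an 800k-expansion search budget.
Larger panels and replicate counts change precision, not structure.

## Known limitations

- Estimators assume Hardy–Weinberg panel frequencies supplied externally;
  no frequency estimation from the handful of samples themselves.
- The ML k-coefficient likelihood treats sites as independent; linkage
  inflates its confidence, which the likelihood-ratio gate only partly
  offsets.
- The pedigree search is exhaustive only within its latent budget and
  expansion cap; overflow returns a flagged partial candidate set.
- Single-pair degree calls near band boundaries are limited by realized
  IBD variance, not by estimator quality.
- The chronology model ignores calibration-curve covariance between
  years and treats osteological age ranges as uniform.
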