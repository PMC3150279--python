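# Methods

## Coalescent model and time scale

All simulation and estimation is on the maternal-locus scale fixed by
θ = 2Nₑμ: the pair-coalescence rate inside a population of size Nₑ is
1/Nₑ per generation, so E[T₂] = Nₑ and the expected pairwise sequence
diversity equals θ. Branch lengths and divergence times are in
generations (one year per generation by default). When comparing against
msprime in the test suite, its `ploidy=1` mode is used so both simulators
share this rate convention.

A refugium hypothesis is a rooted population tree over refugium units.
Gene trees are simulated by running an independent Kingman coalescent
within each branch, pooling surviving lineages where branches join; the
root branch extends until the grand MRCA. There is no migration between
contemporaneous branches and no within-branch size change: isolation
scenarios are encoded purely through topology, divergence times and branch
sizes. Branch Nₑ values are shares of the total: each leaf's share
defaults to its member demes' share of the sampled individuals (the
per-population diversity estimates behind the published total are not
available, making sampled share the neutral default; explicit proportions
can be supplied), and an ancestral branch carries the summed share of its
descendants, so the root always carries the full Nₑ. The three built-in
hypotheses are: panmixia (divergence 0); a southern vs north-eastern split
at 0.1 Ma; and a northern vs eastern split at 0.015 Ma nested inside the
0.1-Ma split.

## The sorting statistic

S is the minimum number of changes of the deme character on the genealogy.
On binary trees this is the classical Fitch intersection/union pass
(vectorised over the simulator's array representation). Observed trees
read from newick may contain polytomies; rather than resolving them
arbitrarily — which can understate the minimum for a hard polytomy — the
general-tree pass uses Hartigan's bottom-up rule (the states carried by
the greatest number of children form the node set; every child outside it
costs one change), which is exact on arbitrary rooted trees and reduces to
Fitch on binary ones. Both passes are checked against brute-force
enumeration of all internal state assignments.

The deme character has ten states (the sampling populations), identical
across hypotheses, so a single observed S is compared against every null.
The test is one-tailed — observed genealogies *more sorted* (smaller S)
than a model predicts reject it — with an add-one correction,
p = (1 + #{S_sim ≤ S_obs})/(n_sims + 1), and ties counted toward
rejection. A deep-coalescence (extra-lineage) count is available as a
secondary discordance measure but is not the headline statistic.

### Tip configuration of the null genealogies

The observed genealogy in this study design is a haplotype tree: one tip
per unique mitochondrial haplotype (67 tips), not one per individual (80).
Null genealogies must carry the same tip set to be comparable, so the
study-scale runs (`scripts/acceptance.py`,
`skyisland.models.TABLE1_HAPLOTYPE_SIZES`) simulate one tip per haplotype
using the per-deme haplotype counts, with the three double-counted
haplotypes shared between neighbouring demes removed from the larger
carrier (ZD, MK, CD). This choice moves each null mean by well under one
step. Simulating at the individual-level configuration
(`TABLE1_DEME_SIZES`) remains fully supported and raises every null mean
by roughly eight steps, as expected from the larger tip count.

At the study's parameter values the null means come out near 48 / 44 / 43
(panmixia / two / three refugia) with coalescent-sampling SDs near 2 —
the panmictic mean matches the published analysis closely, the structured
means sit two to three steps above it while preserving the rejection
pattern (panmixia rejected at the observed S = 40; both multi-refugium
models supported). Published SDs of 4–5 exceed pure coalescent-sampling
spread at any tip configuration; pooling runs across the Nₑ confidence
bounds (±8 %) cannot account for the difference, so the SDs are treated as
descriptive only.

## Sequence statistics

Columns containing any gap or IUPAC ambiguity are removed before
computation (complete deletion; pairwise deletion is available), and
haplotypes are exact string matches on the retained columns. Hd uses the
unbiased estimator n(1−Σp²)/(n−1); π is the mean pairwise difference per
retained site; Watterson's θ is S/a_{n−1} per locus.

Fu's F_S computes S′ = Pr(K ≥ k_obs) under the Ewens sampling distribution
with θ̂ set to the mean pairwise difference per locus; the unsigned
Stirling numbers of the first kind are generated by their recurrence
entirely in log space (log-add-exp), so samples of hundreds of sequences
are exact. F_S = ln(S′/(1−S′)) is undefined on monomorphic data and at
S′ ∈ {0, 1}, which is raised as an error rather than clamped.

Fu & Li's D uses total mutations η (per site: number of observed bases
minus one) and derived singletons η_s oriented by a designated outgroup
sequence; D* replaces derived singletons with simple singletons and needs
no outgroup. Both use the published variance weights (with the corrected
d_n term for D*). Because the statistic is slightly skewed at the neutral
null, the calibration test allows a small bias band rather than exact
centring.

The McDonald–Kreitman table classifies each ingroup-variable site as a
polymorphism and each ingroup-fixed/outgroup-different site as a fixed
difference, judging synonymy by substituting the variant base into the
majority-codon background (vertebrate mitochondrial code by default;
configurable). Degenerate margins (e.g. no fixed differences) return
P = 1 by convention; otherwise a two-sided Fisher exact P.

Φ_ST comes from AMOVA variance components computed on the matrix of
pairwise mismatch counts (used as squared Euclidean distances), truncated
at zero; the untruncated estimator is exposed for null calibration, where
it is centred at zero.

## Microsatellite statistics

Unbiased H_E = (2n/(2n−1))(1−Σp²); F_IS = 1 − H_O/H_E, undefined when
H_E = 0. Allelic richness is rarefied to the smallest per-deme gene count
among demes typed at the locus, so unequal sample sizes remain comparable.
The Hardy–Weinberg exact test shuffles gene copies into genotypes and
compares conditional genotype probabilities (2^H/Π n_g!) by Monte Carlo,
with add-one correction. Nei's (1972) standard distance averages the J
identities over loci before the log; pairwise F_ST is the Weir–Cockerham
(1984) variance-components estimator summed over loci and alleles,
truncated at zero.

The assignment test scores each genotype's log-likelihood in every deme
from allele frequencies, with zero-frequency alleles floored at 1/(2n+1)
(configurable); the exclusion null per deme is 1,000 (configurable)
genotypes drawn by gamete resampling from the deme's frequencies, and an
individual is excluded from its sampling deme below the α = 0.01 quantile.
Frequencies include the focal individual; for the deme sizes used here the
resulting conservatism is small and the realised exclusion rate stays near
the nominal α in calibration.

## Distance-based redundancy analysis

G = −½·J·D²·J (Gower centring). Pseudo-F for a predictor set with hat
matrix H of rank m is [tr(HGH)/m]/[tr((I−H)G(I−H))/(n−m−1)]; %var is
100·tr(HGH)/tr(G). Non-Euclidean matrices (Φ_ST, F_ST) are analysed on G
directly without eigenvalue correction, matching the direct
McArdle–Anderson formulation; a square-root transform of D is available as
a flag upstream of centring. Marginal P values permute rows and columns of
the distance matrix simultaneously; sequential (forward-selection) P
values permute the residual matrix under the reduced model. One-hot
variable groups (vegetation, subregion) always enter as whole sets, the
intercept is implicit in centring, and rank-deficient sets are reduced by
QR with a warning. Forward selection defaults to report-all mode (every
set eventually entered, each with its conditional P); a stopping α is
optional.

## Demography

The classic skyline estimates Nₑ = i(i−1)w/2 from each coalescent interval
(i lineages, duration w); intervals are pooled into ten composite groups
by default (balanced event counts), each pooled estimate being
Σᵢ(i)(i−1)wᵢ/(2m) for m coalescences — the constant-size MLE within the
group. The exponential-growth fit maximises the exact interval likelihood
under N(t) = N₀e^(−gt) (t into the past); N₀ has a closed-form optimum at
each g, so the fit is a bounded one-dimensional profile search
(|g| ≤ 50/tree-height by default). At g = 0 the fit reduces exactly to the
constant-size interval MLE.

The point estimator of g carries a positive skew on a single genealogy
(star-like trees push ĝ up) — the long-known upward bias of genealogical
growth estimators. For this reason the package's headline growth decision
is never the raw ĝ but the conservative replicate rule: growth is declared
only when mean g > 3·SD(g) across replicate estimates (default five,
supplied here by a parametric bootstrap over genealogies re-simulated at
the fitted parameters). Under constant size this rule declares growth in
under 5 % of trials; interval estimates use the basic (reflected)
bootstrap interval, which counters the skew.

## Synthetic data

The generator emulates the study design rather than any particular
landscape: ten demes (sample sizes 11, 14, 7, 5, 5, 7, 8, 14, 7, 2)
grouped into three subregions, a 4,029-site alignment at θ ≈ 0.004/site
under finite-sites Jukes–Cantor on simulated genealogies (infinite sites
optional), and ten diploid microsatellite loci under stepwise ±1 mutation
reflected into a nine-state allele range (so allele counts match the
published 1–9 range by construction). The per-site mutation rate is
derived from the θ target and the model's total Nₑ unless set explicitly.
Environmental tables carry the six predictor sets of the landscape
analysis; a single latent gradient, latent = effect·(subregion score) +
N(0,1), controls how strongly subregion structures the genetic distances
used in power/size tests. Coordinates cluster by subregion (a realistic
confound: the coordinate set is a geographic proxy for subregion), while
rainfall and temperature are driven by elevation and latitude plus noise.

What passing tests show — and do not show. Calibration against closed
forms (E[S] = θa_{n−1}, E[π] = θ, E[TMRCA] = 2Nₑ(1−1/n)) and agreement
with an independent simulator validate the machinery on data that satisfy
the model's assumptions exactly: no recombination, no selection, no
migration during isolation, panmixia within branches, equilibrium allele
ranges. Real mitochondrial and microsatellite data violate several of
these (most importantly migration and selection), so green tests certify
the inference given the model, not the model itself.

## Numerical choices and degenerate inputs

- Stirling/Ewens computations in log space; no overflow for n into the
  hundreds.
- Permutation and simulation p-values use add-one corrections and count
  ties conservatively toward rejection.
- Φ_ST, F_ST and Nei D are truncated at zero (negative variance
  components arise from sampling noise); Nei D with zero shared identity
  returns +inf.
- Monomorphic inputs: Hd = π = 0 and Nhap = 1 are reported; F_S, D, D*
  and F_IS raise/return undefined instead of fabricating values; the HWE
  test returns P = 1.
- Demes with fewer than two sequences are excluded from Φ_ST matrices
  with a warning path; per-deme summaries raise on n < 2.
- Gene trees are ultrametric by construction; trees read from newick are
  checked via their coalescent intervals (tolerance 10⁻⁶ relative).
- All randomness flows through numpy Generators; pipeline stages draw
  from independent spawned streams of one master seed, so reports are
  byte-identical across reruns of the same config.

## Known limitations

- No migration between refugium branches: isolation-with-migration
  histories are approximated by pure isolation.
- The exponential-growth estimator conditions on a fixed genealogy;
  genealogy uncertainty must come from replicates or bootstrap, not the
  likelihood itself.
- The skyline substitutes a stepwise fixed-genealogy estimator for a full
  Bayesian smoothing; trajectories on single genealogies are noisy by
  nature.
- dbRDA on strongly non-Euclidean distance matrices can include negative
  inertia in traces; the direct formulation keeps the permutation test
  valid but %var should be read qualitatively there.
- The McDonald–Kreitman site classification uses the majority-codon
  background and treats sites independently; densely packed codon
  variation may be classified path-dependently.
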