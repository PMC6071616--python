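# Methods

## The inference problem

Two sister species diverged from an ancestral population and may have
exchanged genes during divergence — continuously, early on, or in one or
two later contact episodes — and possibly unevenly across the genome
(a *semi-permeable* species barrier). Given coding-sequence polymorphism
from the two species plus one outgroup, the package reconstructs which of
eleven speciation scenarios best explains the data, by Approximate
Bayesian Computation (ABC) on summaries of the unfolded joint site
frequency spectrum (jSFS).

## Demographic models

All scenarios share the skeleton: an ancestral population of size
`N_A = theta_anc * N_ref` splits `T_split` generations ago into two
populations of constant sizes `N_1`, `N_2`. Migration, when present,
acts at per-direction scaled rates `M_12 = 4 N m_12` and `M_21` and is
switched on/off in epochs (backward from the present):

| model | migration epochs (backward) |
|---|---|
| SI  | off throughout |
| IM  | on throughout |
| AM  | off `[0, T_iso)`, then on |
| SC  | on `[0, T_sc)`, then off |
| PAM | off `T_iso/2`, on, off `T_iso/2`, on — migration windows equal |
| PSC | on `T_sc/2`, off, on `T_sc/2`, off — isolation windows equal |

The source description fixes the two PAM isolation windows at `T_iso/2`
but not the placement of the migration windows; we split the remaining
time `(T_split - T_iso)` into two equal windows, alternating backward
from the present, and mirror that layout for PSC. This is the symmetric
minimal completion of the verbal description; the epoch schedule is an
explicit object (`EpochSchedule`) so alternative placements are easy to
substitute, and is property-tested to tile `[0, T_split]` exactly.

Each migration model comes in a **homo** variant (one rate per
direction, shared by all loci) and a **hetero** variant: a locus is
freely introgressing with probability `p`, otherwise its rates are
multiplied by a gene-flow factor gff ~ Beta(alpha, beta) drawn once per
locus and applied to both directions. SI plus the five models × two
variants give the eleven scenarios.

## Priors and constants

Uniform priors: `theta_anc/theta_ref`, `theta_1/theta_ref`,
`theta_2/theta_ref` on 0–20; `T_split/4N_ref` on 0–25; `T_iso`, `T_sc`
uniform on `(0, T_split)` conditionally; `M` on 0–40 per direction;
`p` on 0–1; `alpha` on 0.001–10; `beta` on 0.001–5. Constants:
`N_ref = 100,000`, `mu = 2.763e-8` per bp per generation, so
`theta_ref = 4 N_ref mu ≈ 0.01105` per bp.

SNP misorientation (the outgroup carrying the derived allele, so the
site is polarized backward) is modelled post hoc: each SNP flips
`(i, j) -> (2n_1 - i, 2n_2 - j)` independently with probability `e`.
No prior for `e` is stated in the source design; we use U(0, 0.2) —
misorientation rates beyond 20% would imply an unusably distant
outgroup — and record the bound in every manifest.

## Simulation

Each locus is an independent (free inter-locus recombination) msprime
coalescent with the epoch schedule above; sizes and times are converted
to diploid individuals and generations with `N_ref`. Per-locus rates:
mutation `mu` per bp; intra-locus recombination `rho = theta` by default
(i.e. recombination rate `mu` per bp), switchable to 0.

Reference-table rows need only jSFS cell counts, so the fast path avoids
placing mutations: the branch-mode joint allele-frequency spectrum of
each tree sequence gives the expected number of infinite-sites mutations
per cell, and the realized counts are Poisson draws — exact under the
infinite-sites model. The haplotype path (used for dataset generation
and mscalc statistics) places explicit infinite-sites mutations and
discretizes their positions. In heterogeneous mode, loci are grouped by
gene-flow factor and each group simulated with its scaled migration
rates; batching identical demographies amortizes engine setup.

The masked jSFS corners ({0;0}, {2n;2n}) cannot arise in simulation
(no branch subtends all samples), and misorientation maps no legal cell
onto a corner; observed data have them removed at polarization.

## Summaries

- **jsfs4** — Wakeley–Hey classes Sf, Sx1, Sx2, Ss.
- **jsfs7** — Sf split by the species carrying the derived fixation
  (sfA, sfB); each private class split by the other species' state
  (derived absent: sxA/sxB; derived fixed: sxfA/sxfB); shared ss.
- **jsfs23** — cross-tabulation of per-species frequency categories
  {absent, singleton, doubleton, intermediate (3..2n−1 pooled), fixed}:
  5 × 5 minus the two masked corners. For n = 2 this is the full
  spectrum; for n > 2 the pooled-intermediate generalization is the
  minimal one consistent with treating singletons and doubletons as
  separate classes (a count equal to both 2 and 2n−2 is a doubleton).
  Cell names follow the printed convention (`sfB`, `ssfB_2`, `ss_1m`, …);
  the full table is in `divabc.summaries.JSFS23_NAMES` /
  `_cell_name`.
- **mscalc** — across-locus mean and SD of per-locus S, Sf, Sx1, Sx2,
  Ss, pi, Watterson's theta, Tajima's D, FST = 1 − piS/piT, div and
  netdiv (diversities per bp). SDs are population SDs (ddof = 0,
  switchable); Tajima's D on a within-species-monomorphic locus and FST
  with piT = 0 are undefined and excluded from the aggregation, with
  defined-counts reported.

Coarser jSFS schemes are exact regroupings of finer ones; this is
property-tested and exploited to simulate each reference table once on
jsfs23.

## ABC model choice

Statistics are standardized by their median absolute deviation (SD
fallback when the MAD is 0; zero-variance columns are dropped from the
distance with a warning — common for jsfs4 on small tables). The
nearest rows by Euclidean distance are retained with Epanechnikov
weights. Posterior probabilities come from one of: weighted model
frequencies in the retained set (`rejection`), a weighted multinomial
logistic regression evaluated at the observed vector (`mnlogistic`, the
deterministic default), or a single-hidden-layer neural network
(`neuralnet`, seed-controlled; hidden units and restarts configurable;
kernel weights are not applied in the network fit). Bayes factors
divide the best model's posterior probability by the second (BF_1/2)
and third (BF_1/3) best.

`ABCModelChoice(reference_table, observed).fit(...)` returns a
`ModelChoiceResults` with probabilities, retained draws, Bayes factors
and a `summary()` table. Parameter estimation is a utility on the
results object (`parameter_posterior`, weighted quantiles of the
retained draws with an optional local-linear adjustment), not part of
the headline model-choice analysis.

## Model checking

Leave-one-out cross-validation extracts pseudo-observed datasets (PODs)
from the reference table (or accepts an external labelled batch) and
classifies each against the table with that row removed. Reported per
model: the **ambiguity rate** (fraction of PODs whose best model's
posterior is below `P_min = 1/k + 1/3`), the plain **precision** and
**recall** of best-model assignments (confusion matrix included), and
the **accuracy rate** in the threshold-gated sense: among PODs assigned
with strong support, the fraction truly generated under the assigned
model, equal to 1 when no confident assignment is wrong — including
vacuously, when no POD reaches strong support. The two readings are
deliberately both surfaced: for heavily overlapping pairs (hetero nests
homo at `p -> 1`) plain per-POD precision is necessarily near 1/2 in the
equivalence region, while the threshold-gated rate measures what a
practitioner acts on: confident calls.

Goodness of fit is a posterior predictive check: parameter draws are
resampled from the retained set with the rejection weights (no
regression adjustment), datasets re-simulated, and each observed
statistic flagged if outside the simulated central 95% interval.

## Scaled-down validation experiments

`divabc.experiments` packages the two headline experiments. Sizes used
by the acceptance script: reference tables of 4,000 simulations per
model over 40 loci of 500 bp at n = 2 diploids per species, 20 PODs per
model, 1,000 nearest rows retained (12.5% of the table). The test suite
runs the same designs at 1,200 simulations per model, 25 loci, 12 PODs,
300 retained (the same fraction). Two scale choices depart from a
literal miniature of the full-scale protocol:

- the retention fraction is far looser than the full-scale protocol's
  0.1%. That fraction presumes a dense reference table (10^6 rows per
  model) whose nearest 0.1% form a tight local neighbourhood of the
  observed point. At desk-scale densities a comparably tight retention
  leaves the retained set a sparse, wide shell; its label composition
  is then dominated by sampling noise and the regression step can
  produce spuriously confident posteriors for individual PODs. A loose
  fraction keeps the posterior estimate in the regime the full-scale
  protocol actually operates in — weakly informative posteriors that
  shrink toward the prior balance when the summaries cannot separate
  the models. (Literal 0.1% retention of an 8,000-row table would also
  retain 8 rows, too few to fit any regression.)
- intra-locus recombination is off in these experiments: with `mu`
  fixed, recombination changes only the across-locus variance of global
  jSFS counts, not their means, and the rejection step is
  scale-standardized.

PODs for the homo-vs-hetero experiments are prior draws (the full-scale
protocol); PODs for the SI-vs-IM recovery experiment are conditioned to
be informative (SI: `T_split/4N_ref` ~ U(10, 25); IM: `M = 10`; both:
theta ratios ≥ 1 so datasets carry SNPs) since that experiment measures
separability of distinguishable histories, not calibration.

## What the synthetic data do and do not emulate

The generator reproduces the two study layouts (exome capture: 516/557/
512 loci at n = 2/4/8; RNA-seq: 2,147/1,842 loci at n = 2/4, with SNP
targets matching the printed totals via Watterson-linear theta
calibration), writes per-locus FASTA with a single outgroup haplotype
carrying the true ancestral allele (the derived allele at misoriented
sites), and records full ground truth. It does **not** emulate codon
structure (synthetic sites are all "eligible"; the synonymous filter is
exercised via annotations, not biology), sequencing error, coverage
variation, genotype-calling bias, paralogy, or reference-mapping bias —
so passing the full-circle tests demonstrates the correctness of the
pipeline's bookkeeping on clean data, not robustness to those artifacts.
Optional corruption knobs (missing bases, third alleles, private
outgroup mutations) exercise the documented filters at known rates.

## Numerical and degenerate-input choices

- `t_split = 0` collapses to a single panmictic population of the
  ancestral size (used by the Watterson oracle).
- Epoch boundaries are snapped to `T_split` against float drift;
  zero-length epochs are dropped (SC with `t_sc = T_split` *is* IM).
- Posterior probabilities are clipped to [0, 1] and renormalized; a
  model absent from the retained set has probability 0 with a warning.
- Rejection weights get a small positive floor so a retained set at a
  single distance still has mass; a retained set at distance 0 gets
  uniform weights.
- Tie-broken Bayes factors are flagged (`tied`); zero denominators are
  reported as infinity with a flag.
- Position discretization for sequence writing shifts colliding
  integer sites to the next free slot and errors only if a locus has
  more segregating sites than base pairs.

## Known limitations

- No population growth, bottlenecks, >2 focal populations, or
  locus-heterogeneous effective sizes (linked selection enters only
  through the gene-flow factor).
- Misorientation is modelled at the SNP level; the outgroup lineage is
  not simulated, so shared derived fixations relative to the outgroup
  ({2n;2n} sites) never arise in simulation even though real data would
  produce (and mask) them.
- The neural-network posterior is stochastic between library versions;
  the deterministic multinomial-logistic default is recommended for
  reproducible pipelines.
- VCF ingestion covers biallelic complete-call diploid sites only.
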