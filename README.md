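# divabc

Approximate Bayesian Computation (ABC) reconstruction of the divergence
history of two sister species from the coding joint site frequency
spectrum (jSFS), for population geneticists analysing exome-capture or
transcriptome data from species pairs with an outgroup.

Closely related species — the motivating system is the hybridizing
mussels *Mytilus edulis* / *M. galloprovincialis* — may have diverged in
strict isolation, with continuous gene flow, or through one or two
episodes of ancient or recent contact, with the species barrier often
*semi-permeable*: some genomic regions introgress freely while others
resist. `divabc` compares eleven such scenarios: strict isolation (SI)
plus isolation-with-migration (IM), ancient migration (AM), periodic
ancient migration (PAM), secondary contact (SC) and periodic secondary
contact (PSC), each with genome-homogeneous ("homo") or -heterogeneous
("hetero") migration, where heterogeneity means a proportion 1 − p of
loci have their effective migration rate `M = 4Nm` multiplied by a
gene-flow factor gff ~ Beta(α, β).

The method: polarize SNPs with the outgroup into derived-allele counts
per species, summarize the jSFS into 4 (Wakeley–Hey: Sf, Sx1, Sx2, Ss),
7 or 23 frequency classes (or multilocus "mscalc" statistics — means and
SDs of π, Watterson's θ, Tajima's D, FST, divergence), simulate large
reference tables under each scenario's priors with a coalescent engine
(including a SNP misorientation rate *e* that flips derived frequencies
f → 1 − f), retain the simulations nearest to the observed summary
vector, and estimate posterior model probabilities by retained-model
frequencies, multinomial logistic regression, or a neural network.
Cross-validation (accuracy and ambiguity rates against the
strong-support threshold P_min = 1/k + 1/3) and posterior-predictive
goodness-of-fit checks complete the workflow.

## Worked example

Simulate an observed dataset under a known semi-permeable
secondary-contact history, then ask which scenario explains it:

```python
import divabc as d

lay = d.SimLayout(n_loci=40, n1=2, n2=2, locus_length=500, rho_over_theta=0.0)
truth = d.ScenarioParams("SC", "hetero", theta_anc=3, theta_1=3, theta_2=3,
                         t_split=12, t_sc=3, m12=25, m21=25,
                         p=0.1, alpha=0.5, beta=3, e=0.02)
obs = d.simulate_summary(truth, lay, "jsfs23", rng=7)
print("observed jsfs4:", d.rebin(obs, "jsfs4").values.to_dict())

rt = d.build_reference_table([("SI", "none"), ("SC", "homo"), ("SC", "hetero")],
                             500, lay, "jsfs23", seed=42)
res = d.ABCModelChoice(rt, obs).fit(method="mnlogistic", n_retain=200)
print(res.summary())
```

Output:

```
observed jsfs4: {'Sf': 456, 'Sx1': 1225, 'Sx2': 2047, 'Ss': 1472}
ABC model choice
============================================
method:      mnlogistic
scheme:      jsfs23
table rows:  1500
retained:    200
--------------------------------------------
model              posterior
--------------------------------------------
SC.hetero             0.6049
SC.homo               0.2219
SI                    0.1731
--------------------------------------------
best model:  SC.hetero
BF_1/2:      2.73
BF_1/3:      3.49
```

The observed data show fixed differences (Sf = 456) *and* abundant
shared polymorphism (Ss = 1472) simultaneously — the signature of a
semi-permeable barrier — and the heterogeneous secondary-contact model
is correctly preferred, 2.7 times more probable than the runner-up
(BF_1/2 = P_best / P_second).

Real data enter through `read_locus_alignments` (per-locus FASTA for
the two species plus outgroup) → `filter_loci` (removes columns with
missing data or more than two alleles, drops loci shorter than 300 bp)
→ `polarize` → the same summaries. `generate_study_like_dataset` writes
fully ground-truthed synthetic datasets mirroring the exome-capture
(516 loci, n = 2, ~4,000 SNPs) and RNA-seq (2,147 loci, ~17,300 SNPs)
layouts. A thin CLI wraps these steps:
`divabc sfs | simulate | fit | cv | synth`.

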