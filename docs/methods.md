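# Methods

This note documents the models implemented in `ylepop`, their assumptions,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Genetics

Individuals are diploid at an autosomal target locus (the female-fertility
gene *doublesex*) with up to four allele classes: functional wild type
(`WT`), a cleavage-resistant recessive loss-of-function (`REC`), the
released dominant female-sterilising allele (`DOM_R`), and new dominant
NHEJ products (`DOM_N`).  Males additionally carry one Y allele (wild type
or the Y-linked editor), and two optional autosomal loci can be activated:
an X-shredder and a generic released construct used for SIT/RIDL
bookkeeping.  Unordered diploid pairs are stored canonically sorted; the
base three-allele model has 6 female and 12 male genotypes, and the
four-allele or multi-locus spaces follow by independent unordered
bookkeeping (e.g. 18/36 with the shredder locus).  `DOM_N` exists as a
separate class so that the dominance and production rate of NHEJ-derived
dominants can be varied in sensitivity analyses; with its production
probability at zero the model provably collapses to the three-allele space
(this is a unit test).

Germline editing acts only in editor-carrying males:

* heterozygous target (`WT` with any mutant `M`): the `WT` allele is cleaved
  with probability `cleave_het` (*C*); given cleavage it is repaired by
  homing, copying `M`, with probability 1 − `nhej_given_cleave` (1 − *j*),
  or by NHEJ, producing `DOM_N` with probability `p_dom_new` (*d*) and
  `REC` otherwise.  Gamete transmission of `M` is therefore
  0.5·(1 + *C*(1 − *j*)) in closed form.
* homozygous wild type: each allele is independently converted to an NHEJ
  product with probability `mut_wtwt` (*μ*).
* mutant/mutant targets and non-editor males segregate Mendelian, as do all
  maternal gametes (no maternal nuclease deposition).

X-shredding removes X-bearing gametes of shredder-carrying males with
probability `shred_eff` and renormalises the gamete distribution (sperm are
not limiting, so shredding biases the brood toward sons without reducing
brood size).

Baselines are derived from the engineered strain's phenotypic assays: the
dominant allele is inherited by 94.5% of offspring and ~3% of offspring
carry new target-site mutations, giving `cleave_het = 0.95` and
`nhej_given_cleave = 0.06/0.95 ≈ 0.0632` (the unique solution of
0.5·(1 + *C*(1 − *j*)) = 0.945 and 0.5·*C*·*j* = 0.030).  Because the rate
of de novo mutation in wild-type-homozygous editor males is unknown, the
model takes the conservative value `mut_wtwt = 0.945`: such males transmit
(recessive) mutations at the same rate as released males transmit the
dominant allele.  Dominance coefficients default to 1 (fully penetrant
sterility of heterozygous carriers; the ~1% incomplete penetrance observed
in crosses is ignored at baseline).

Female fertility: 0 with no functional allele (`REC/REC` and all
dominant-carrying genotypes at full dominance), 1 for `WT/WT` and `WT/REC`
(the gene is haplo-sufficient), 1 − dominance coefficient for a dominant
allele over wild type.  Male competitiveness: wild type 1; each transgenic
construct carried multiplies by its own cost factor — 1 − 0.22 for the
editor at the fitted baseline, and in the combined editor+shredder strains
the shredder construct contributes the same per-construct factor (costs
multiply).  The idealised stand-alone comparators are cost-free.

## Deterministic release model

Infinite population, discrete non-overlapping generations.  Adult abundances
are normalised so the pre-release equilibrium holds one unit of fertile
females and one of males; release rates are fractions of that male unit,
added to the adult pool at the start of each generation.  Events per
generation: (1) releases; (2) each fertile female mates exactly once, with
matings distributed across male genotypes in proportion to abundance;
(3) a mating yields a full brood with probability equal to the sire's
competitiveness weight, zero for sterile (SIT) sires, and failed matings
are not compensated — females are monandrous, so a mating wasted on a
sterile or unsuccessful male removes that female's brood; (4) offspring
follow the cross distributions above; (5) a normalised Beverton–Holt factor
*s* = 1/(1 + (*R*m − 1)·*E*) acts uniformly on all offspring, where *E* is
viable egg input relative to equilibrium and *R*m is the number of
daughters per female absent density dependence (sterile-sired eggs produce
no larvae and do not load density; doomed RIDL larvae do); (6) post-density
lethality removes construct carriers (both sexes for RIDL, females for
fs-RIDL); (7) survivors are next generation's adults.

Two analytic anchors pin this structure down.  Sustained sterile-male
releases at rate *r* give female fixed points solving
(*R*m − 1)x² − (*R*m − 1)x + *r* = 0, hence the elimination threshold
(*R*m − 1)/4 (1.25 at *R*m = 6, against 1.297 for a 36-generation
deadline); and a single release of cost-free editor males leaves the
editor-male frequency exactly at the released fraction in every later
generation.  Both are verified numerically to 1e-3 and 1e-10 respectively.

Treating reduced competitiveness as uncompensated mating failure (step 3)
rather than as re-weighted mate choice is a deliberate choice: the two are
indistinguishable in the cage trial (conditioning on a fixed pupal census
cancels the egg-pool scalar) but differ in how strongly costly males
suppress egg input in an open population, and only the uncompensated form
reproduces the strategy-comparison rates consistently across the costed and
cost-free strategies.  The same validation fixed the per-construct cost of
the shredder in the combined strains.

The minimal-release-rate solver bisects on [0, 100] to absolute tolerance
1e-4; suppression is achieved when relative fertile females touch
1 − target at any generation within the horizon (a solver flag instead
requires it at the final generation; under sustained releases the
trajectory is still declining at the deadline and the two readings agree).
An unachievable target returns infinity rather than an arbitrary rate.
Sensitivity sweeps vary one of the seven editing/phenotype parameters over
a grid with everything else at baseline, for several *R*m values, in the
four-allele space.

## Stochastic cage simulator

The laboratory protocol: 300 wild-type females, 300 wild-type males and 300
editor males found the cage; each later generation is exactly 600 pupae.
Each generation, sires are drawn in proportion to competitiveness-weighted
male counts, fertile females contribute equal expected egg numbers to a
common pool (eggs are sprayed into shared trays, so there is no per-family
bottleneck), intersex females contribute nothing, and the next generation
is one multinomial draw of 600 pupae from the expected offspring genotype
mix.  Mating, fecundity and pupal sampling are deliberately collapsed into
that single multinomial; only the ensemble variance, not the mean, depends
on this.  Adults incur no pre-mating mortality and all sampled pupae
emerge.  Pupae are classified as marker-positive (editor) vs wild-type
males and wild-type-looking vs intersex females (intersex = any dominant
allele, or no functional allele).  A cage with no fertile females or no
males terminates with an explicit extinction flag, and summaries encode the
missing generations as NaN.

Under the strain baseline the expected generation-1 relative wild-type
female count is (0.78/1.78)·0.5·(1 − 0.945) + (1/1.78)·0.5 ≈ 0.293 of the
census, i.e. 0.586 of the founding females, and the pooled dominant-allele
frequency is (0.78/1.78)·(0.945/2) ≈ 0.207; the ensemble means match these
closed forms and the published per-cage observations (57%/59%, ~22%).
Replicate *k* of an ensemble uses seed *base + k*; trajectories are
bit-identical given a seed.

## ABC inference

Rejection ABC with a single free parameter, the editor-male
competitiveness cost: uniform prior on [0, 1], 20,000 parameter draws by
default, one simulated cage per observed cage per draw, and acceptance of
the 1% of draws with the smallest equal-weight Euclidean distance between
observed and simulated summaries at exactly the observed coordinates
(cage × generation × statistic).  All other parameters stay fixed at the
assay-derived baselines.  The point estimate is the accepted-draw median
with an equal-tailed 95% interval.  An extinct simulated cage is given
infinite distance.  The defaults were chosen for stability at desk scale
and are all exposed in `ABCConfig`; the packaged empirical fixture holds
only the published per-cage numbers (generations 1 and 5 female and male
summaries; generations 1 and 3 allele frequencies), never values read off
figures.

## Synthetic data

`SyntheticSpec` wraps the cage simulator to emit observation tables in the
shared cage schema plus a ground-truth sidecar sufficient to regenerate the
dataset bit-identically, and pooled amplicon-style allele tables with
independent binomial read sampling per allele at a configured depth (no PCR
bias model).  The generator emulates census counts and pooled allele
frequencies of the cage protocol; it does not emulate phenotype
misclassification, family-size variation, stage-structured mortality or
read-level sequence errors, so tests passing on synthetic data demonstrate
correctness of the inference machinery under the model, not robustness to
those real-data complications.

## Numerical choices and problem sizes

Cross tensors are dense and cached per editing-parameter set; all dynamics
are vectorised over genotype indices.  Bisections run to 1e-4 in the rate.
The analytic sterile-male threshold is verified on an 800-generation
horizon; frequency-invariance over 50 generations to 1e-10.  The test suite
uses 200–1,000-replicate ensembles (Monte-Carlo checks use 3-standard-error
bands), a 20,000-simulation ABC fit of the empirical summaries, and a
50-repeat coverage experiment at 2,000 simulations per fit — sizes chosen
so the full suite completes in a few minutes on one CPU while keeping
Monte-Carlo error well inside the asserted bands.

## Known limitations

No spatial structure, migration, seasonality, age structure or
epidemiological layer; females mate exactly once and males are not
mating-limited; functional cleavage-resistant (R1-type) target alleles are
excluded by construction; the extended multi-locus space uses independent
unordered bookkeeping of the loci, which is sufficient for all marginal
allele and genotype dynamics reported here.
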