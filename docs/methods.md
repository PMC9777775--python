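# Methods

## Model overview

The package implements a two-modality pipeline for pairwise classification
of diagnostic groups on the Alzheimer's axis (HC < EMCI < LMCI < AD) and
for feature mining on the result:

1. **gene-eigenvalue fusion** — per-group scalar amplification of the voxel
   feature matrix by the Perron root of a gene p-value matrix;
2. **genetic weighted random forest (GWRF)** — a random-subspace CART
   ensemble refined by group-champion selection and subset crossover, with
   validation-accuracy vote weights;
3. **frequency-based selection** — features ranked by how many trees
   sampled them, refined by a nested top-j accuracy sweep;
4. **association re-analysis** — per-SNP OLS on a continuous phenotype
   built from the selected features, combined per gene with GATES and
   Bonferroni-corrected.

## Fusion

Each group's evidence is a 24 × 24 matrix `MP`: row *i* holds gene *i*'s
SNP p-values, left-aligned and zero-padded. The dimension is fixed at 24
(24 candidate genes, at most 24 SNPs each); a gene with more than 24 SNPs
contributes its 24 smallest p-values in ascending order — the over-long
case is unspecified by the zero-fill rule, and keeping the most significant
SNPs preserves the evidence the matrix is meant to summarise. SNPs within a
gene are kept in positional order when they fit.

`MP` is entrywise non-negative, so by Perron–Frobenius its maximum-modulus
eigenvalue α is real and non-negative; "the largest eigenvalue" is
therefore interpreted as maximum modulus, and α is returned as a real
scalar together with the full 24-point spectrum. `MP` is used as-is — no
symmetrisation — since the theorem needs only non-negativity. α satisfies
the classical row-sum bounds (min row sum ≤ α ≤ max row sum), which the
test suite checks against power iteration at 1e−8.

Fused datasets stack two α-scaled groups; the more advanced stage takes
label −1 (generalising AD = −1 / HC = +1 to pairs without HC). Row order is
first-listed group first, so `S_AD−HC` with ADNI-sized groups has
296 + 310 = 606 rows.

Because α scales a whole group uniformly, distinct group α's change every
feature's per-group variance. A tree can then separate groups on any
feature, which is precisely the amplification the fusion intends — but it
also means that on *synthetic* data with planted signal, fusion masks which
voxels are truly informative. Signal-recovery experiments in this package
therefore run on unscaled voxels (equivalently, equal α's), isolating the
planted effect.

## The forest

* **Split.** 6:2:2 train/validation/test, stratified by label; within each
  class the three part sizes are assigned by largest-remainder rounding, so
  each part's class count differs from the exact proportion by less than 1.
* **Subspace size.** `m = ⌊√F⌋` for `F` features — 209 at the full-scale
  F = 43,851. Floor is used: it is the rounding that reproduces the
  published subset size.
* **Trees.** CART with Gini impurity, unlimited depth, minimum leaf 1
  (scikit-learn `DecisionTreeClassifier`). Tree hyperparameters are not
  part of the method's definition; these are the defaults a practitioner
  would start from.
* **Evolution.** Per generation: a random partition into groups of
  `group_size` (default 5; a short final group is allowed), the champion of
  each group is the tree with the best validation accuracy (ties to the
  lowest tree index); champions are randomly paired (a lone champion
  self-pairs) and each pair produces children — `⌊m/2⌋` subset indices
  sampled from one parent, the rest from the other, deduplicated, refilled
  uniformly from unused features, refit on the training part — cycling over
  pairs until the population size `n` is restored. No mutation operator is
  used. `G = 0` is a no-op.
* **Weights and voting.** `W_f = ACC_f` on the validation part, not
  renormalised. The committee score is `Σ_f W_f · vote_f(x)`; the label is
  its sign; a zero score falls back to the highest-weight tree (ties to the
  lowest index); an all-zero weight vector degrades to an unweighted
  majority. The raw score doubles as the continuous output for ROC/AUC.
* **Ablations.** `use_weights=False` forces unit weights;
  `use_evolution=False` (or `G=0`) keeps the initial forest. Under a shared
  seed all four variants build bit-identical initial forests, so the
  ablation comparison isolates each ingredient.

Default hyperparameters are `n_trees = 320`, `G = 50`, `group_size = 5` —
the optimal operating point reported for the AD–HC task at full scale (the
searched ranges were 300–500 trees and 1–50 generations). The pipeline's
synthetic-scale default is 50 trees / 5 generations, sized so that a full
run and the test suite complete in minutes on one CPU.

## Selection

Importance is subset-membership frequency — how many trees of the final
forest carry the feature — with no Gini or permutation importance by
design. Candidates are the top 1000 by count (ties to the lower index).
The sweep retrains a fresh GWRF on the top-j candidates for j from the
smallest multiple of 10 strictly above m (210 at full scale) to 1000 in
steps of 10, and the best test accuracy picks the important-feature count;
accuracy ties resolve toward fewer features (parsimony). Test-part accuracy
is used for the sweep curve.

**Capacity caveat.** The frequency table of an `n`-tree forest holds
`n × m` slots. A feature absent from every subset has count 0 and can only
enter the top-1000 list through index-order tie-filling, so the ranking is
informative only when `n × m` comfortably exceeds the feature count, and
lineage collapse during evolution (all children descend from the
generation's champions) further concentrates counts on a few hundred
features. At the synthetic study scale (50 trees × m = 44 over 2000
voxels), the expected initial coverage of any fixed voxel is
1 − (1 − m/F)^n ≈ 0.67, which bounds planted-voxel recovery regardless of
signal strength; the acceptance script honestly reports the resulting
~50% top-1000 recovery. Recovery improves with more trees, but is reported
at the study's stated ensemble size rather than at one chosen to flatter
the number.

## Association

* **Phenotype.** The re-analysis uses a continuous phenotype — the mean of
  the selected fused features per participant — matching the linear
  regression framing (a binary diagnosis phenotype is a possible
  alternative, not used here).
* **Covariates.** Age, sex, education plus `k` principal components of the
  column-standardised dosage matrix (population stratification). PCA signs
  are fixed by making each component's largest-magnitude loading positive.
  `k` may be fixed or scanned over 1..20, choosing the `k` that minimises a
  candidate gene's GATES p-value (ties to the smallest k).
* **Per-SNP test.** OLS of phenotype on dosage + covariates + intercept,
  two-sided t-test on the dosage coefficient (statsmodels). A constant
  dosage column is untestable and reported as β = 0, p = 1.
* **GATES.** With the gene's p-values sorted ascending,
  `P_gene = min_j m_e · p_(j) / m_e(j)`, where
  `m_e(j) = j − Σ_i [λ_i > 1](λ_i − 1)` from the eigenvalues of the p-value
  correlation matrix of the top-j SNPs, clipped to [1, j]. The p-value
  correlation is approximated from the dosage correlation through the even
  polynomial map of the method's defining reference (applied to |r|, with
  |r| = 1 pinned to 1 so perfectly collinear SNPs give m_e = 1 and
  `P_gene = min p`). The cruder raw-dosage-correlation approximation is
  available via `pvalue_corr="genotype"`; it overstates dependence and
  measurably inflates the null rejection rate under moderate LD, which is
  why the polynomial is the default. With independent SNPs both reduce to
  the Simes statistic. Gene-level multiplicity uses Bonferroni
  (`min(1, n_genes · p)`).
* The ECS combiner is not implemented; GATES is used as the single
  gene-level combiner throughout to keep the pipeline coherent.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
the imaging or genotyping processes:

* **Groups** of configurable size (defaults 310/271/390/296 for
  HC/EMCI/LMCI/AD, totalling 1267).
* **Voxels**: standard-normal features; `n_informative_voxels` (default 40)
  receive an additive mean shift of `stage × voxel_effect` SD along
  HC→AD (stage 0..3), giving an ordered, controllable group contrast.
  δ defaults to 2.0. The voxel-value distribution after modulation is
  assumed Gaussian. Default dimension is 2000 voxels (the full-scale 43,851
  is emulated, not reproduced) nominally spread over 90 regions.
* **Dosages**: per gene, a latent AR(1) Gaussian (`ld_rho`, default 0.5)
  thresholded at Hardy–Weinberg genotype quantiles, so within-gene LD
  decays with index distance while marginal frequencies match MAFs drawn
  uniformly from `maf_range` (default [0.05, 0.5], floor at the 5% QC
  threshold). 24 genes by default with a fixed SNP-count pattern mixing
  full (24-SNP) and short rows; counts are capped at 24.
* **Genotype→imaging coupling**: causal SNPs add `snp_effect` per centred
  minor allele to the informative voxels (`snp_effect = 0` by default — the
  global null for association calibration).
* **Covariates**: age/sex/education with group-specific moments typical of
  an elderly memory-clinic cohort; non-confounding unless the
  `confounding` knob leaks age into the voxels.
* **P-value fixture**: per-gene SNP p-value lists without running a GWAS —
  Uniform(0,1) nulls with a configurable fraction drawn Beta(0.2, 1); used
  to exercise the fusion stage.

What passing tests on this generator do **not** show: realistic allele
frequency spectra or recombination, spatial voxel correlation, scanner or
site effects, non-Gaussian morphometry, or genuine gene–imaging biology.
They do show that each algorithmic component behaves as specified and that
the pipeline recovers planted signal under its own assumptions.

## Numerical and design choices

* All randomness flows from `numpy.random.Generator` seeded via
  `SeedSequence`; pipeline stages derive their seeds from the single global
  seed, and the run manifest (stage seeds + SHA-256 of artifacts, no
  timestamps) is bit-identical across reruns.
* Eigenvalues via `numpy.linalg.eigvals` (general) and `eigvalsh`
  (correlation matrices, symmetrised first). α is reported as
  `max |λ|`, exact to LAPACK precision.
* Tie-breaks: champions and prediction fallback → lowest index; sweep
  argmax → fewer features; split remainder → train part first.
* Degenerate inputs: single-class training data yields a constant tree
  (its validation weight reflects it); empty validation or test sets are
  errors; constant dosage columns are flagged untestable.
* Serialised models store per-tree subsets, decision rules and weights as
  JSON; deserialised trees predict via rule traversal and reproduce the
  original predictions exactly.

## Known limitations

* Strictly pairwise binary classification; no multiclass or online mode.
* The evolution operator has no mutation and can collapse subset diversity
  within a few generations (see the capacity caveat above).
* GATES' p-value correlation is approximated from dosages; very small
  validation sets quantise the vote weights coarsely.
* The fusion scalar is a single global amplifier per group; it does not
  model voxel-specific genetic effects.
* Problem sizes in the tests and the acceptance script (2000-voxel
  cohorts, 50-tree forests, 10-seed averages) are the package's chosen
  synthetic operating point; full-scale behaviour (43,851 voxels, 320
  trees, 50 generations) is structurally identical but not benchmarked
  here.
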