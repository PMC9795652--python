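# Methods

This note records the statistical models and procedures the package
implements, the choices made where the design was genuinely open, and what
the synthetic cohort does and does not emulate.

## Community typing

Samples are typed on the OTU table after a prevalence filter: an OTU is
kept when it has a nonzero count in at least 20% of samples (inclusive
boundary). Proportions are computed on the *unfiltered* table and the
dropped columns are simply removed, so retained values still reflect the
original composition; a config toggle re-closes them if desired.

The sample × sample similarity is the Spearman correlation of OTU
proportion profiles (average ranks for ties). "Spearman distance" is taken
as `d = 1 − ρ`, the standard correlation-to-dissimilarity map; `d` is
symmetrized against round-off and its diagonal zeroed. Samples are
clustered by Ward linkage on `d`. When the number of clusters is not fixed,
the cut is chosen to maximize the mean silhouette on the same distance over
k = 2..8; the full linkage is retained so any other cut can be taken. Mean
silhouette systematically favors merging two nearby tight clusters when all
other clusters are far away, so on strongly nested data a fixed `--k` is
the more faithful choice; the auto-k default is kept because it requires no
prior knowledge.

Cluster validity: for every within-cluster sample pair, a Spearman
correlation test; BH correction jointly across all within-cluster pairs; a
cluster is flagged valid when ≥ 95% of its pairs have adjusted p ≤ 0.05
with ρ > 0. The 95% figure is this package's operationalization of "each
cluster shows significant within-group correlations" and is configurable.
Pairwise testing (rather than sample-to-centroid) was chosen because it
needs no centroid definition on ranks.

Group separation uses one-way PERMANOVA: with `SS_T = Σ_{i<j} d²_ij / n`
and `SS_W` the analogous within-group sum, the statistic is
`F = (SS_B/(k−1)) / (SS_W/(n−k))` and `p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_perm)` under seeded label permutation. Perfect separation
(`SS_W = 0`) yields an infinite statistic and the minimal p. The
implementation is cross-checked against scikit-bio's PERMANOVA in the test
suite; it is re-implemented here because the permutation stream must be
seedable for byte-identical reruns.

Alpha diversity is the Shannon index, base 2 by default (bits), plus the
observed-feature count. Group comparisons everywhere use the tie-corrected
Kruskal–Wallis omnibus with two-sided Wilcoxon rank-sum post hocs and BH
correction across pairs; the Wilcoxon p-value is exact for tie-free groups
of ≤ 25 and a continuity-corrected normal approximation otherwise.
Statistical operations are complete-case and report per-group N; missing
metadata is never imputed.

## Beta ordination

UniFrac is computed through scikit-bio: unweighted (branch
presence/absence, presence = count > 0, no rarefaction) and weighted
(normalized by default; the non-normalized variant is a flag). PCoA is a
direct Gower double-centering of `−d²/2` followed by a symmetric
eigendecomposition: eigenvalues are reported in full, descending; axes with
eigenvalue ≤ 1e−9 (including negative ones, which arise for non-Euclidean
UniFrac matrices) are excluded from the coordinates; no Cailliez/Lingoes
correction is applied by default. Each axis's sign is fixed so its
largest-magnitude coordinate is positive, making runs comparable.

Covariate superimposition (envfit-style) regresses each covariate on the
first two axis-score columns by least squares; the arrow is the direction
cosine of the coefficient vector and R² the squared multiple correlation;
p-values come from permuting the covariate across samples (seeded).
Constant covariates are flagged and skipped. The significance filter only
sets a display flag — all covariates are retained in the output.

## Co-abundance groups

Genera are retained when their relative abundance exceeds 0.1% (strict
inequality) in at least two samples. Network edges are Kendall τ_b
correlations between genus profiles with two-sided p-values; multiplicity
is handled by Storey q-values (π₀ from the λ-grid 0.05..0.95 with a
cubic-spline smoother evaluated at the largest λ; BH fallback below 50
p-values, where the histogram is too sparse for a stable π₀). Retained
edges satisfy τ > 0 and q ≤ 0.05. The CAG partition itself uses Ward
linkage on 1 − Spearman ρ between genus profiles, cut at k = 5 by default —
the Kendall/Spearman split is deliberate fidelity to the established CAG
procedure rather than an inconsistency. Each CAG is named for its genus
with the highest cohort-mean relative abundance. Wiggum disc sizes are
over-abundance *ratios* (cluster mean ÷ cohort mean), per the more specific
figure-legend convention; absolute abundance is available by toggle.

## Dietary patterns

Correspondence analysis is the SVD of the standardized residuals
`(P − rc')/√(rc')` of the correspondence matrix; samples are rows and raw
frequencies are used. Row principal coordinates on axis 1 feed a 1-D Ward
clustering (Euclidean) into D1..Dk, labeled in order of group mean score.
The axis sign is fixed so the food with the largest column mass has a
non-negative column coordinate.

The Healthy Food Diversity index composes the number and distribution of
consumed foods through the Berry index `BI = 1 − Σ sᵢ²` of consumption
shares with a consumption-weighted mean health value `hv̄ = Σ hvᵢ sᵢ`
(health values in [0, 1]): `HFD = hv̄ × BI`, which is zero for a
single-food diet and approaches `hv̄` for a maximally diverse one. Energy
uses per-item kcal annotations; fiber is normalized to g per 1000 kcal;
macronutrient energy shares use Atwater factors 4/4/9 kcal/g.

## Transcriptional activity

RNA-level pathway abundances are divided by the matching DNA-level
abundances per (feature, sample). The zero-DNA policy is explicit: DNA = 0
with RNA = 0 is undefined and excluded; DNA = 0 with RNA > 0 is undefined
but surfaced in a side table ("RNA-only" signals are real in
pangenome-profiled data and should not be silently smoothed); an optional
pseudocount (added to both terms) is off by default.

Per-cluster over-abundance is `log2((mean_cluster + ε)/(mean_cohort + ε))`
with ε = half the smallest nonzero ratio, keeping silent features finite.
Cluster aggregation uses the mean (not median), matching the "average
RNA:DNA ratio" convention of the heatmap this feeds. A species counts as
"active" in a metabolic category within a cluster when its log2
over-abundance strictly exceeds 1 in at least ⌈m/3⌉ of the category's m
pathways. The pathway → category map (carbohydrate / amino acid / lipid /
xenobiotic) ships as a static data file and is overridable; no live
database queries are made. The KO-panel table reports cluster-mean over
cohort-mean RNA:DNA ratios for a configurable panel of ten gene families,
rows ordered by Ward clustering on 1 − Spearman ρ of their transcript
profiles.

## Sparse PLS

The two-block model maximizes cross-block covariance per component:
alternating updates `u ∝ soft(X'Yv)`, `v ∝ Y'Xu`, initialized from the
leading singular pair of `X'Y` (deterministic), with soft-thresholding
keeping the keepX largest X loadings per component, and regression-mode
deflation of both blocks by the X score. Blocks are centered and unit
scaled by default. Convergence tolerance 1e−9 with a 500-iteration cap per
component; each component's X loading is flipped so its largest-magnitude
entry is positive. With keepX = all features the first component equals
the leading singular vector of the cross-covariance (tested against that
oracle). The association heatmap scores are the low-rank loading products
weighted by the square root of each component's explained covariance;
rows/columns are ordered by complete linkage on `1 − r` (signed Pearson,
matching the cim convention; `1 − |r|` by toggle).

## Host associations

Median (0.5-quantile) regression `y ~ axis + age` per variable × axis pair
(first three axes by default), complete cases per variable. The fit and
asymptotic p-values come from statsmodels' QuantReg (iteratively reweighted
least squares with Koenker–Bassett kernel-based standard errors) — the
established Python implementation of the same estimator an LP solver would
produce; its null calibration is verified by simulation in the test suite.
Coefficients are reported raw (β), scaled to the full axis variation
(`RC_range = β·(max − min)`), and scaled to one axis standard deviation
(`RC_sd = β·sd`); both scaled forms are invariant to axis rescaling. BH is
applied across the entire variable × axis grid.

The 2 × k exact test enumerates all tables with the observed margins and
sums hypergeometric probabilities of tables no more probable than the
observed one (log-factorial arithmetic); above 10⁷ candidate tables it
switches to seeded Monte Carlo with a reported standard error. It matches
scipy's 2 × 2 hypergeometric closed form and R's `fisher.test` on reference
tables. Cramér's V uses the uncorrected chi-square:
`V = √(χ²/(n·(min(r,c) − 1)))`.

Clinical indices: HOMA-IR = glucose [mg/dl] × insulin [μU/ml] / 405, with
insulin resistance defined by HOMA-IR strictly greater than 2.5; Matsuda =
10000/√(G0·I0·Gmean·Imean) when OGTT means are available. YFAS
stratification of the obese group: ≥ 3 symptoms with diagnosis → O_DHA,
≥ 3 without → O_HA, ≤ 2 → O_LA; normal-weight participants are left
unassigned by design, and a diagnosis with < 3 symptoms is a validation
error (it violates the instrument).

## Synthetic cohort

The generator plants, with recorded ground truth, exactly the structure the
analysis stages assume. Defaults are the study conditions: 100 samples in
four clusters at proportions 0.31/0.33/0.22/0.14; normal-weight
probabilities 0.48/0.28/0.36/0.36 per cluster; 40 genera in five blocks
named Bifidobacterium, Ruminococcus, Dorea, Prevotella, Bacteroides, with
3–10 OTUs per genus; sequencing depth 5,000 reads/sample (a config knob —
kept modest so the full cohort generates in about two seconds).

Genus log-abundance for sample s in cluster c is

```
log a_gs = μ_g + δ_{g,c} + η_{b(g),c} + λ f_{b(g),s} + ε_gs ,
a'_gs = M_{c,b(g)} · exp(log a_gs)
```

- `μ_g` — baseline (sd 0.4), with a +1.8 boost for each block's canonical
  genus (so CAG naming is recoverable) and block-level mean offsets
  (Bacteroides −0.4).
- `M_{c,b}` — the block multipliers that realize the cluster phenotypes:
  C1 all 1; C2 loses the Bifidobacterium block (×0.02); C3 loses
  Bifidobacterium and over-represents Prevotella and Ruminococcus (×2);
  C4 loses Bacteroides and is enriched in Bifidobacterium (×3).
- `δ_{g,c}` — a per-(genus, cluster) fingerprint (sd 0.25). Block
  multipliers alone produce a nested two-level geometry (Bifidobacterium
  present vs absent) in sample-correlation space, which a silhouette-based
  k selection will always cut at 2 or 3; real steady states differ as full
  community profiles, and the fingerprint models that.
- `η_{b,c}` — a deterministic per-(block, cluster) response: the five block
  profiles are five icosahedral equiangular directions in the centered
   3-space of R⁴ (pairwise |cos| = 1/√5, the optimum for five lines), scaled
  to unit across-cluster variance × 0.8. This yields within-block
  co-abundance across the cohort *without adding any within-cluster sample
  noise* and without chance alignment between blocks; rows are assigned so
  each block's response reinforces its multiplier pattern.
- `λ f_{b,s}` — a per-sample, per-block latent factor (λ = 0.15) adding
  within-cluster co-abundance.
- `ε` — per-genus log-noise (sd 0.2).

Genus mass is split over its OTUs by a fixed Dirichlet(2) draw and counts
are multinomial at the configured depth. A per-cluster evenness exponent
(1.25 for C2 and C4) raises the concentration of each sample's composition
— a within-sample monotone transform, invisible to every rank-based stage —
planting the alpha-diversity ordering C1 ≈ C3 > C2 ≈ C4. The phylogeny is a
random bifurcating genus backbone with per-genus OTU subtrees (exponential
branch lengths), so genus monophyly holds by construction.

Behavior scores are `α + β·PCo2 + γ·age + noise` with PCo2 the axis-2
score of the unweighted-UniFrac PCoA of the simulated table, computed with
the same code the analysis uses; β is negative by default (−60 for TFEQ
uncontrolled eating, −50 for BITE symptoms, noise sd 0.5), sized so median
regression at n = 200 recovers it within a few percent. YFAS symptom counts
are Poisson with per-cluster rates; the diagnosis flag is only ever drawn
when symptoms ≥ 3.

The FFQ has 20 annotated items whose kcal equal the Atwater sum of their
macronutrients exactly. The three dietary archetypes sit along a single
carbohydrate-to-fat gradient (low protein/high carb; high protein/low carb,
intermediate; high fat/high protein) — with orthogonal archetype directions
the second contrast loads on CA axis 2 and an axis-1 grouping cannot see
it. Per-sample frequencies are Dirichlet perturbations (concentration 150)
of the archetype, scaled by an energy factor higher for clusters C2–C4.

Lipid panels are log-normal (noise sd 0.3) with cluster-patterned medians:
SCFAs higher in C1/C2; coprostanol, 5β-sitostanol (×4) and 5β-campestanol
higher in C3/C4; cholesterol and primary bile acids higher in C2;
secondary bile acids higher in C4.

Paired RNA/DNA tables: DNA = block-representative species abundance × a
fixed species-by-feature incidence matrix × per-feature scale; RNA = DNA ×
E(species, feature, cluster) × log-normal noise (sd 0.2). Expression
targets are specified as the desired *cluster-over-cohort ratio*; the
generator solves the unspecified clusters so the proportion-weighted mean
multiplier is exactly 1 (infeasible targets raise). A target of 4 is then
recoverable as log2 = 2 against the cohort mean — without this convention,
dividing by a cohort mean that contains the boosted cluster would shrink
every recovered ratio. Defaults plant: a KO transcribed exclusively in C1
by E. coli; secondary-bile-acid features elevated in C3/C4 (driving the
sPLS coupling with 5β-sitostanol); and a ×4 feature in C4 used by the
recovery checks. Zero-DNA entries (species absent from a sample) are kept.

### What the generator does not emulate

Real 16S data have far deeper sequencing, compositional artifacts from
amplification, phylogenetically correlated abundances, many more taxa with
long-tailed abundance distributions, and cluster structure that is rarely
as clean as planted multipliers. Passing recovery tests therefore shows the
*pipeline* is correct and calibrated under its own assumptions — not that
four clusters, five CAGs, or any particular effect will be found in a real
cohort. Calibration checks (PERMANOVA type-I error, edge FDR, null quantile
regression) are the parts that transfer most directly to real data.

## Numerical and reproducibility notes

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); a config + seed pair reproduces every output
byte-for-byte. Feature tables are features × samples on disk (the dominant
16S dialect) and samples × features in memory; the reader transposes and
logs it. Percentages are held as fractions internally. Simulation sizes in
the test suite (e.g. 500 null datasets × 199 permutations for PERMANOVA
calibration, 300 replicates × 210 hypotheses for the edge-FDR check, 100
random 8-leaf trees for the UniFrac oracle) were chosen to bound the Monte
Carlo error of each check well below its decision threshold while keeping
the default run fast on a single CPU.

## Known limitations

- Auto-k by mean silhouette underestimates k on nested cluster structure
  (see above); use `--k` when the expected number is known.
- Storey's π₀ is unstable for small p-value sets; the BH fallback is
  logged.
- Median-regression p-values are asymptotic; for n ≲ 30 they should be
  interpreted cautiously.
- Weighted UniFrac is not rarefaction-corrected; depth confounds should be
  handled upstream or by the depth toggle in the generator.
- The Fisher Monte Carlo fallback reports a standard error; for tables near
  the enumeration budget the exact path is preferred.
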