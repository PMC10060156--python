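# Methods

This note documents the statistical models behind `admixtide`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic validation does and does not
establish.

## Genotype model and conventions

Genotypes are alternate-allele dosages in {0, 1, 2, missing} on an
individuals × SNPs matrix read from EIGENSTRAT triplets. Genetic positions
are stored in Morgans throughout (the `.snp` column is read as Morgans per
the format standard); physical positions are 1-based. Pseudo-haploid
individuals — the standard representation for low-coverage ancient DNA,
one randomly sampled allele per site — carry calls in {0, 2, missing} and
contribute one allele copy to frequency estimates; diploid individuals
contribute two, and males contribute one on the X. All statistics are
unpolarized, so the ref/alt orientation of the dosage digit is immaterial.
SNPs with zero called copies in a population are dropped per statistic,
not globally, maximizing the usable sites of each analysis.

## Weighted block jackknife

Linkage makes per-SNP terms dependent, so all errors come from deleting
contiguous genetic blocks. Blocks are half-open 5 cM windows restarting at
every chromosome boundary (the final window of a chromosome may be
shorter); the X chromosome uses the same 5 cM span, with a minimum of ten
X blocks enforced before an X-mode fit is attempted. Because blocks carry
unequal SNP counts m_j, the weighted form is used: with n = Σm_j and
h_j = n/m_j, pseudovalues τ_j = h_jθ̂ − (h_j−1)θ̂₍₋ⱼ₎ give the
bias-corrected mean, and variance (1/B)Σ(τ_j − θ̃)²/(h_j − 1); the same
pseudovalue outer products give covariance matrices for statistic vectors.

## f-statistics

f2 uses the standard finite-sample correction
(p̂A − p̂B)² − p̂A(1−p̂A)/(nA−1) − p̂B(1−p̂B)/(nB−1) in allele copies and
requires ≥ 2 copies per population; a group compared with itself is
defined as exactly zero (there is no two-panel sampling to correct).
f4 = (p̂A − p̂B)(p̂C − p̂D) needs no correction when the four groups share no
individuals; overlapping groups are refused. Vectors of f4 statistics are
evaluated on a common retained-SNP set (every involved population ≥ 1
copy, configurable) so that the jointly jackknifed covariance refers to
the same sites. Numerical parity with other f-statistic implementations is
not a goal; agreement within jackknife error on simulated data is, and is
what the tests assert.

## Mixture-weight estimation

With base right R₀, the model y = Aᵀw (y_j = f4(T,R₀;R_j,R₀),
A_kj = f4(S_k,R₀;R_j,R₀)) holds exactly in expectation for a target whose
allele frequencies are a w-mixture of the sources. The solver minimizes
(y − Aᵀw)ᵀQ⁻¹(y − Aᵀw) subject to Σw = 1 via the closed-form Lagrange
solution. Q is the block-jackknife covariance of the residual vector,
which depends on w; it is refined by iterated reweighting (uniform start,
three iterations — the solution is insensitive to further iterations
because Q changes little near the optimum). Near-singular Q receives a
small ridge (10⁻⁹ × mean diagonal), recorded on the fit. The fit p-value
is the chi-square upper tail of the minimized form with
(m−1) − (k−1) degrees of freedom — equivalent asymptotics to the
rank-test formulation, chosen for transparency. Weight SEs and covariance
come from re-solving on every leave-one-block replicate (Q held fixed)
and jackknifing the replicate weights; Σw = 1 holds exactly in every
replicate. Infeasible (negative) weights are reported and flagged, never
truncated — truncation happens only in the sex-bias stage, where it is
part of the reporting convention. The choice of base right only
reparameterizes the statistics; tests verify weight invariance under
permutation of the non-base rights.

Source cycling enumerates all non-empty subsets of the candidate sources
(capped at 2¹⁰ subsets), moving the complement to the rights; the
"selected" model is the smallest feasible subset whose fit p-value clears
the threshold (default 0.05). The mixed-source grid builds a pseudo-source
with frequency π·p̂_Persian + (1−π)·p̂_Indian and conservative effective
copy counts min(n_P, n_I) — mixing at the frequency level is deterministic
and sufficient for locating the best π — and scores each two-source fit
with a Hotelling T² tail, T²·(B−q)/(q(B−1)) against F(q, B−q), where B is
the number of jackknife blocks and q the residual dimension.

## Sex-biased admixture

Solving C_A = (m+f)/2, C_X = (2f+m)/3 gives f = 3C_X − 2C_A and
m = 4C_A − 3C_X (note f + m = 2C_A, so shares normalize by 2C_A). The
Monte-Carlo procedure draws 10⁶ coefficient vectors (10⁵ in the pipeline's
fast default) from multivariate normals centred on the autosomal and X
jackknife means with their error covariances, independently for the two
chromosome sets (the cross-covariance between autosomal and X estimates is
taken as zero: they use disjoint SNPs). Covariances with a negative
eigenvalue are repaired by adding |λ_min| to the diagonal, with the
magnitude logged. Draws containing any negative coefficient are discarded
(an acceptance rate below 0.1% raises an error rather than reporting a
meaningless interval); per accepted draw the normalized shares are exact
compositions, and the report gives their mean, SD and central 95%
percentile interval, truncating interval ends (and the point estimate,
when the closed form leaves [0,1]) to the 0%/100% boundary. Percentile
intervals were chosen over mean ± 1.96 SD because the accepted-draw
distribution is asymmetric near the boundaries. The interpretation of
(f, m) as "fractions of ancestors on each side at the time of mixing"
assumes a one-pulse history; under prolonged mixture the sign of the bias
remains informative but the point estimate does not.

## Ancestry cline

Compositions with any negative mixture coefficient are excluded (flagged)
from the cline fit; the remaining points are fit by the first principal
axis through their centroid — a total-least-squares line, symmetric in
the three coordinates, so no ternary-plot drawing convention enters the
estimate. Edge intersections are computed in barycentric coordinates; an
intersection outside the simplex is clamped to the feasible segment and
flagged. Uncertainties are leave-one-individual-out jackknife SDs of the
endpoint components, with degenerate replicates dropped and counted. The
coverage filter (default > 100,000 SNPs) mirrors the practice of fitting
the line only to individuals whose per-individual coefficients are
well-determined.

## Admixture dating

Under one-pulse admixture g generations ago, recombination breaks ancestry
tracts at rate g per Morgan, so local-ancestry covariance between
positions at distance d decays as e^(−gd). With source-panel frequency
contrast w_s = p̂A − p̂B and centred genotype x_s = dosage_s/2 −
(αp̂A + (1−α)p̂B), the binned estimator C(d) = Σw₁w₂x₁x₂ / Σ(w₁w₂)² has
expectation ∝ e^(−gd) (amplitude ≈ α(1−α)/2 for diploids, shrunk further
by panel-frequency noise in the denominator — the decay *rate* is
unaffected, which is why g is invariant to rescaling the weights, a tested
property). α is taken from the autosomal mixture fit of the same cohort;
it affects the amplitude, not the rate. Pair sums are accumulated on a
0.1 cM genetic grid per chromosome and evaluated by FFT autocorrelation
per individual — algebraically identical to the binned pair sums the
estimator defines, at O(n log n) instead of the infeasible O(n²) pair
enumeration. Numerators and denominators are summed across individuals
(pooling), and per-chromosome contributions are retained for the weighted
leave-one-chromosome-out jackknife of g.

The fit C(d) = A·e^(−gd) + c uses bin weights proportional to pair counts
and an affine offset c to absorb background LD. Defaults: 0.1 cM bins, fit
range 0.45–30 cM (conventions of ancestry-LD dating tools; configurable).
For fixed g the model is linear in (A, c), so g is found by profiling: a
coarse geometric grid followed by bounded scalar minimization — no
iterative least-squares convergence failures. Estimates pinned at the
search boundary, with non-positive amplitude, or indistinguishable from
zero against their jackknife SE are flagged unreliable. Calendar
conversion is Monte-Carlo: date = sampling date − G·T with
G ~ N(ĝ, SE_g) and T ~ N(28 yr, 2 yr), both truncated at zero by
resampling; the interval therefore folds generation-time uncertainty into
the date (setting `gen_time_sd=0` gives the generations-only variant). The
sampling date is supplied by the user; radiocarbon calibration is out of
scope.

## Synthetic data

Reference allele frequencies follow the Balding–Nichols model: ancestral
p ~ U(0.05, 0.95) per SNP, population frequency ~
Beta(p(1−F)/F, (1−p)(1−F)/F) with drift F. Populations may share a
"clade" ancestor (itself drifted from p, default F = 0.05): this two-level
tree is essential, because under flat independent drift every source is
equally related to every right population, the design matrix A has
identical rows in expectation, and mixture weights are unidentifiable.
Admixed cohorts follow a one-pulse tract model per haploid genome:
Poisson(g per Morgan) breakpoints — rate (2/3)·g on X, which recombines
only in females — and i.i.d. tract sources drawn with probabilities C_A
(autosomes) or C_X (X), which makes the ancestry covariance decay exactly
e^(−gd) and the expected realized proportions equal the target
coefficients. Genotypes are sampled binomially from the tract-source
frequency; males carry one X; pseudo-haploid representation and
missingness are optional. The default map is 22 autosomes of 1.4 M plus an
X of 1.8 M with uniform recombination. Female-side and male-side source
fractions must each sum to one (each side's ancestry is a composition);
this implies the coefficient constraint Σ(f_k + m_k)/2 = 1.

What the simulator does *not* emulate: linkage disequilibrium within the
source populations (SNPs are independent given the tract), realistic
recombination-map heterogeneity, aDNA damage or contamination, genotype
error, and continuous or multi-pulse admixture. Passing the validation
suite therefore demonstrates correctness of the estimators under the
stated model, not robustness to those real-data complications; the affine
offset in the decay fit and the per-statistic SNP retention policy are the
two places where real-data deviations are partially absorbed.

### Scenario catalogue and validation problem sizes

The catalogued scenarios (`scenarios.yaml`) encode the study conditions
the package is validated on: `mtwapa-like` (C_A = 0.57/0.36/0.07,
female fractions 0.92/0.04/0.04, male 0.22/0.68/0.10, g = 30, 200
individuals, 50,000 SNPs), `two-source` (50/50, g = 30), `sex-biased`
((f, m) = (0.9, 0.1), g = 20, 150 individuals, 20,000 SNPs) and
`mixed-asian-source` (Asian side split 88/12 Persian/Indian). The
validation suite runs the weight-recovery check at the full
50,000-SNP/200-individual size; replicated checks (sex-bias interval
coverage, calendar-date coverage, p-value calibration) use 20–50
replicates at 6,000–25,000 SNPs and 30–150 individuals — sizes at which
each replicate's uncertainty intervals are wide enough that coverage is a
meaningful test while the whole suite stays desk-scale.

## Inclusion thresholds and reporting conventions

Individuals enter pooled analyses with at least 15,000 called SNPs
(configurable); the cline fit uses the > 100,000-SNP high-coverage subset.
Haplogroup labels are mapped to origin classes by a longest-prefix input
table (default: mtDNA L* and Y E1 African; Y J, G2, R1a and mtDNA
R0+16189 Southwest Asian; mtDNA M South/East Asian) — haplogroup *calling*
is out of scope, the labels are inputs. Percentages round half-up to
integers. The pipeline is a pure function of (dataset, config, seed):
reruns are byte-identical, which the suite asserts by checksum.

## Known limitations

* One-pulse admixture only; prolonged admixture biases dates old and makes
  (f, m) qualitative.
* The mixed-source grid's min(n_P, n_I) effective counts are conservative;
  p-values at the peak are approximate, the peak *location* is the
  validated quantity.
* X-mode fits rest on ~30 blocks; their covariance estimates are noisier
  than autosomal ones, which propagates into wide sex-bias intervals for
  minor sources.
* The decay amplitude is attenuated by panel-frequency noise; A and c
  should not be interpreted as unbiased mixture parameters (g is the
  estimand).
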