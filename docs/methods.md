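# Methods

This note records the models behind each stage, the defaults and why, the
numerical choices, and what the synthetic generator does and does not
emulate.

## Phenotyping and the D score

Raw measurements are germinated counts out of `n_seeds_germ` (default 50)
and shoot/root lengths in mm, under control and salt conditions across
`n_envs` environments. Relative traits are `treatment / control`; a
relative value is *missing*, never 0, when its control is 0, and
per-accession averages are taken over non-missing environments only.
Values above 1 are legitimate (mild stimulation under stress).

The composite score uses the three environment-averaged indices
(RGR-AVG, RSL-AVG, RRL-AVG). Each index is min–max normalized over the
panel (`mu`), weighted by the coefficient of variation of its membership
values (sample sd, n−1 denominator — the convention is not standardized,
so it is stated here), and summed. Consequences tested as invariants:
`D` is unchanged by any common affine rescaling of a raw index; weights
are non-negative and sum to 1; an accession at the panel maximum on every
index scores exactly 1. A degenerate index (no spread) carries no
discriminating information and is dropped with a warning, the remaining
weights renormalized; accessions with any missing index are excluded from
scoring rather than imputed, with a warning.

Grades come from 1-D agglomerative clustering (Ward linkage) on `D`, cut
at k=5 and ordered by cluster mean so grade 1 is always the most tolerant.
Ward on one dimension is deterministic and order-preserving; any method
that partitions a 1-D cloud would give similar but not identical counts,
so grade counts are a property of this choice, not of the data alone.

## Synthetic panel

Genotypes follow a Balding–Nichols structure: ancestral frequencies
uniform on (0.1, 0.9); each subpopulation draws its site frequency from
`Beta(p(1-F)/F, (1-p)(1-F)/F)` with `F = fst` (default 0.1, a typical
crop-subpopulation differentiation). Haplotypes get LD from a latent
Gaussian AR(1) along each chromosome; the correlation length is calibrated
(bivariate-normal orthant probabilities averaged over the frequency prior)
so the mean allele r² at `ld_decay_bp` (default 54,000 bp) is ~0.1. The
pairwise-r² round trip recovers the decay distance to within ~±20%; the
residual bias comes from the MAF filter truncating the frequency prior and
from weak structure-induced LD, both left uncorrected because the decay
readout, not its exact shape, is what the QTL window consumes. Calls are
coded 0/1/2 dosages of the minor (at generation) allele, −1 for missing;
sites whose realized MAF falls below `maf_min` are dropped (planted QTL
sites are kept — they are forced to be common). Positions are 1-based and
strictly increasing per chromosome, VCF convention throughout.

Planted QTLs are additive with literal per-allele effects on the relative
scale; a favored subpopulation gets favorable-allele frequency 0.60 versus
0.25 elsewhere, emulating subpopulation-biased tolerance alleles.

Phenotypes are built on the relative scale as
`R = mean + genetic + a*tau + b*c_env + d*eps`, where `tau` is a latent
tolerance shared across traits and environments, `c_env` an
accession-by-environment deviate shared across traits, and `eps`
independent noise. The weights (a, b, d) are solved per trait — pairwise
across traits, by a short fixed-point on the total variance — so that the
realized structure hits three targets: narrow-sense `h2` within trait
(default 0.5), cross-environment correlation `env_corr` (default 0.7), and
within-environment cross-trait correlation `trait_corr` (default 0.88,
set so the realized shoot–root correlation stays above 0.8 after clipping
and sampling attenuation). The germination ratio carries binomial counting
noise (counts out of 50 seeds in both arms); its delta-method variance is
folded into the solution so the realized RGR correlations stay near
target rather than being diluted. Salt germination counts are
`Binomial(n_seeds, p_control * R)` with the probability clipped to [0, 1] —
a multiplicative link chosen over a logistic one so the count model matches
the `treatment = control x tolerance` structure used for the length traits;
control germination probabilities are Beta(28, 2) (~93%), control lengths
lognormal (~33/38 mm shoot/root). With `h2 = 0` no genetic signal enters
at all, giving exact null panels for calibration tests.

What the generator does *not* emulate: real flax demography or recombination
maps, allele-frequency spectra from sequencing, imputation artifacts,
genotype-by-environment interaction of the planted effects, and selection.
Calibration and power results on it therefore show the *methods* behave
correctly under the assumed structure, not that real panels meet those
assumptions.

Defaults (desk scale): 200 accessions split (0.50, 0.20, 0.30) across
Oil/OF/Fiber (panel composition is not standardized; it is config), 15
chromosomes x 200 SNPs of 20 Mb each — a stand-in for a ~674k-marker map
that keeps the full suite in tens of seconds — missing rate 0.05,
MAF floor 0.05.

## Association models

GLM: per SNP, OLS of trait on dosage + intercept + the first `n_pcs`
(default 3) orthonormal principal components of the standardized genotype
matrix; marker tested by partial t/F; `r2_pve` is the marker's incremental
sum of squares over the total (percent). Accessions missing the trait or
the call are dropped per SNP; missing calls are mean-imputed only for
kinship and PCs, never for testing. Monomorphic-after-dropping markers are
flagged NaN, never 0. p-values are two-sided, floored at 1e-300; an exact
fit returns the floor directly.

MLM: `y = Xb + s a + u + e`, `Var(u) = sigma_g^2 K` with VanRaden kinship
`K = ZZ' / (2 sum p(1-p))`. REML is one-dimensional in
`delta = sigma_e^2/sigma_g^2` on the eigenbasis of K (Patterson–Thompson
restricted likelihood, sigma profiled out): a 41-point log-grid scan
followed by bounded scalar refinement (xatol 1e-8) over log10 delta in
[−5, 5]. Default is P3D — null-model delta reused for every marker — with
exact per-marker REML behind a flag; the two agree closely away from
pathological markers and P3D is an order of magnitude faster. Each marker
is tested by GLS after Cholesky whitening of `V = K + delta I` restricted
to the accessions observed for that marker; non-PSD kinship is clipped at
zero with a warning. The marker R² is the partial R² on the whitened data
with the whitened-intercept residual as baseline — chosen over a
likelihood-ratio pseudo-R² so that with `K = I` the MLM reproduces the GLM
exactly in p, beta *and* R², giving a sharp analytic-limit test.

Thresholds: GLM uses Bonferroni at the realized post-filter test count
(−log10(0.05/674,074) = 7.13 at full scale); the MLM cut is a fixed
config value (default 5.00) because a fixed, less stringent mixed-model
threshold is conventional where kinship already controls inflation and the
value is not derivable from the test count.

## QTL integration

Windows are closed 1-based intervals ±54 kb around each significant SNP
(left-clipped at 1). Merging is the transitive closure of overlap within a
chromosome, with touching endpoints merging — adjacent windows sharing an
LD block should unify. Retention keeps intervals with ≥2 detections
(position × trait × environment records) spanning ≥2 environments or ≥2
traits; a single position repeatedly detected across environments
qualifies, which is exactly the signature of a single-point QTL whose lead
SNP is unlinked to other assayed sites. The stricter
two-distinct-positions reading is available (`distinct_positions=True`).
Lead SNP is the member with maximum −log10(p), ties broken to the smaller
position; names are `q<FAMILY><chrom>.<rank>` with the family from the
lead SNP's trait (environment suffix stripped) and rank by start position
within family × chromosome.

## Triage and haplotypes

Gene–QTL overlap requires ≥1 shared bp (configurable to full containment).
DEG evidence is kept per list with direction; conflicts across lists are
preserved, not resolved. Annotation evidence is a case-insensitive
whole-word keyword match over homolog function text — an explicit,
configurable approximation of literature-based manual curation; the
default set covers salt/osmotic/ABA signalling and the stress-associated
transcription-factor and transporter families. The candidate flag is the
disjunction of the evidence channels, hence monotone: adding a list or a
keyword never removes a candidate.

Haplotype comparison uses the two homozygous genotype classes
(heterozygotes excluded by default — appropriate for a highly selfing
crop; configurable to keep them) and Welch's unequal-variance t-test with
Satterthwaite degrees of freedom, two-sided. No multiple-testing
correction is applied across lead SNPs; the number of comparisons is
reported instead. Monomorphic SNPs yield a flagged, not-performed
comparison rather than an error.

## Problem sizes and tolerances in the test suite

Oracle equivalences run at 20–50 accessions (regression to 1e-8, Welch to
1e-10, REML optimum to 1e-4 against a 2001-point dense grid); calibration
and power suites use 20 generator seeds of 200 × ~1000 panels, sizes at
which the statistical checks are sharp while the default suite completes
in about a minute. Type-I error is judged against the pooled binomial 95%
band and uniformity by Kolmogorov–Smirnov at alpha = 0.01; the KS check
treats pooled p-values as independent, which weak intra-panel LD violates
mildly — pooling across seeds keeps the approximation serviceable.

## Known limitations

- The LD process is stationary within chromosomes; no hotspots, no
  inversions, no variable recombination.
- P3D understates per-marker uncertainty slightly when a marker itself
  explains a large variance share; the exact flag exists for that case.
- The annotation keyword screen is a proxy; its false-positive/negative
  behavior depends entirely on the supplied keyword set and annotation
  text quality.
- Grade counts depend on the clustering choice; only the ordering
  (grade 1 most tolerant) and determinism are guaranteed.
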