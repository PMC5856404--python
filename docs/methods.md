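# Methods

`amplicall` models the computational core of a replicate-based amplicon
deep-sequencing assay for low-allele-fraction mutation detection in
cell-free DNA, together with the droplet-digital-PCR statistics used to
quantify such assays and the standard analytical-validation summaries.
This note records the models, the parameter choices and their
rationale, the numerical decisions, and what the synthetic-data stack
does and does not emulate.

## The calling model

### Observation model

At a panel position with background error rate `e` and true allele
fraction `af`, the alt-read count of one replicate library of depth `d`
is modelled as beta-binomial with mean rate

    mu = af + (1 - af) * e

and intra-class correlation (overdispersion) `rho_eff`. The
overdispersion belongs to the *error* process — PCR errors propagate
clonally within a library, while reads from true mutant molecules
sample a fixed molecule fraction and are close to binomial — so the
entry's `rho` is attenuated by the error component's share of the
mixture variance:

    rho_eff(af) = rho * e(1-e) / (mu(1-mu)),   e = (1 - af) * mean rate.

At `af = 0` this is exactly the null (`rho_eff = rho`), so threshold
calibration is unaffected; at `af >> e` the model approaches binomial.
Without this attenuation the mean-parameterized beta-binomial is highly
skewed at small `mu` and the maximum-likelihood `af` is biased upward
by tens of percent at 0.1% AF; with it, the median relative error of
the estimator at 0.1% AF and 5,000 x 8 depth is ~12%.

### Replicate integration

Replicates share one `af`; the joint MLE maximizes the summed
per-replicate log-likelihoods, and the decision statistic is
`lr = 2 (l(af_mle) - l(0))`. Zero-depth replicates are excluded from a
locus rather than failing the sample; a locus with no covered replicate
is flagged no-coverage. Overdispersion makes the statistic
concordance-aware: evidence spread evenly across replicates scores at
least as high as the same pooled count concentrated in one replicate.

Numerics: for `rho = 0` the pooled fraction is sufficient and the MLE
and LR are closed-form. Overdispersed sites use a vectorized
multiplicative grid spanning `pooled/300 .. pooled*4` (the MLE can sit
far above the naive background-subtracted start when the pooled rate
barely exceeds the null mean) followed by four zoom rounds, giving
~0.5% relative precision in `af` and ~0.01 in `lr`. Far-sub-threshold
sites (pooled binomial LRT < half the calling threshold and pooled alt
< 5) keep a single-evaluation LR at the closed-form AF; this
approximation is only ever applied to sites that cannot approach the
calling threshold.

### Background model

Per (position, substitution), fitted from a control cohort:

- **Mean rate** — the average over controls of each control's
  pooled-across-replicates error fraction, pseudocounted
  `(alt + 0.5) / (depth + 1)` per control. The pseudocount keeps clean
  positions from producing a zero-variance null in which any single alt
  read is "significant"; applying it at the per-control (not
  per-library) level keeps the inflation to ~0.5 / (pooled control
  depth), small against a 1e-4 noise floor.
- **Overdispersion** — method of moments on *raw* per-library
  fractions (the pseudocount would masquerade as binomial variance),
  decomposing the observed variance into binomial sampling
  (`mean(1/d) * m(1-m)`) and between-library components. `rho` is
  pooled across the panel by default: per-site second moments from a
  realistic cohort (tens of controls) are far too noisy, and per-site
  `rho` estimates near zero let real error bursts through calibration.
  `rho_mode="per_site"` retains the raw estimates for diagnostics.
- Sites with fewer than 3 usable controls are flagged low-confidence;
  calling there requires explicit acknowledgement
  (`allow_low_confidence=True`), otherwise candidate calls come back as
  `low_confidence_region`.

Indel nulls are estimated from the samples of the same batch with the
tested sample left out, so a genuine indel cannot mask itself; clean
loci fall back to the pseudocount floor. Oxidative-damage (8-oxoG)
artifact mode multiplies only G>T / C>A rates, leaving the other ten
substitution channels untouched.

### Threshold calibration

The LR threshold is the smallest value at which `n_sim` simulated
wild-type samples drawn from the fitted background stay within the
per-base false-call budget (default 3e-6 per base — about two false
calls per 79 samples over a 10.6 kb footprint), then a finite-simulation
safety margin (`1.25 x + 2`) is applied so the budget holds on samples
outside the calibration set. Indels are calibrated separately against
their own (much cleaner, floor-rate) null. Loosening the budget can
only lower the threshold.

### Contamination and copy number

SNP allele fractions must sit near {0, 0.5, 1} (tolerances 0.02 / 0.05);
three or more loci shifted to intermediate fractions indicate
contamination, and a genotype fingerprint contradicting a prior sample
of the same patient at three or more loci indicates a possible swap.
One or two deviating loci are reported as indeterminate rather than
forced into either bucket.

Copy number uses median-of-ratios normalization: per-amplicon reference
depths are medians over a baseline cohort (>= 5 samples) after
per-sample size normalization; a test sample's size factor is the
median depth ratio over all amplicons, which cancels library-size
effects and is robust to a single amplified gene as long as the gene
covers a minority of the panel. Gene copy number is `2 x` the
lower-median normalized ratio over the gene's amplicons (ties on even
counts resolve toward the smaller value, conservative toward CN 2);
single-amplicon genes are reported but flagged.

## Read processing

Because every template is one of a known set of short amplicons
(72-154 bp with primers), alignment reduces to anchored matching: pairs
are merged on the best ungapped overlap (>= 10 bases, >= 80% identity,
ties dropped), concordant overlap bases keep the higher quality,
discordant bases take the higher-quality base demoted to Phred 2;
merged reads are assigned to the unique amplicon whose primers match
both ends within 2 mismatches and the primers are clipped. The pileup
admits only bases at Phred >= 30 — which automatically excludes
merge-discordant bases — and keys indels by their left-normalized
representation. Read-vs-insert alignment uses an affine-gap pairwise
aligner (match 2, mismatch -3, gap open -6, extend -1); unit-cost edit
distance was rejected because it fragments long deletions into cheaper
split events. Pairs failing merge or assignment are counted in QC, not
silently dropped.

## Synthetic-data stack

The generators emulate the wet-lab study design: reference-standard
stocks with known per-variant AFs are diluted (AF scales linearly),
sampled into a fixed number of amplifiable copies (binomial), split
into replicate libraries (multinomial totals; mutant molecules follow
a multivariate hypergeometric given the totals, so copies are conserved
exactly), amplified and sequenced (per-position depth Poisson at
`reads_per_molecule x molecules`; mutant reads binomial at the molecule
fraction; errors beta-binomial from a generative background model).
Full-process plasma controls recover spike copies binomially at the
extraction efficiency and are diluted by plasma wild-type DNA, so the
expected measured AF is always below the nominal spike AF. Droplet
reactions classify mutant/wild-type/double/negative droplets from
independent Poisson occupancies with false positives added to the
mutant channel. All generators are bit-reproducible given their seed.

Default study conditions (chosen once as realistic for this assay
class): background error rates log-normal with median 1e-4 per
substitution and 0.35 decades of spread; intra-class correlation 1e-3
(a few-fold the binomial variance at depth ~2,000 — amplicon error
rates reproduce across libraries but are not violently bursty); 30
control samples; 8 replicate libraries per sample; 2 reads per
amplifiable molecule; input tiers 2,000 / 8,000 / 16,000 copies;
dilution tiers 0.06-0.08% up to 1-1.3% AF. The calibration and
acceptance studies run on a 1 kb toy panel (10 amplicons, 5 genes); a
panel-scale fixture (35 genes, 10,610 interrogated bases) exists for
structural tests. These sizes keep the full study under a minute of CPU
while leaving every rate estimate limited by the same statistics that
matter at panel scale.

What the simulator does **not** model: fragment-length differences
between sheared standards and native cfDNA (a known source of small AF
deviations between methods), PCR branching-process amplification
(amplification is a Poisson read-multiplicity per molecule; calling
operates on count ratios), sequence-context (e.g. trinucleotide) error
structure, strand asymmetry, and indel sequencing errors (the indel
null in synthetic data is clean, so indel results exercise the
machinery rather than indel-specific noise). Passing tests therefore
demonstrate the statistical machinery under the stated error model, not
performance on real libraries.

## dPCR limit of detection

Quantification inverts Poisson occupancy: `lambda = -ln(1 - k/n)`,
concentration `lambda / 0.85 nL`. The LOD combines two binomials with
`alpha = beta = 0.05`: the critical level is the 95th percentile of
`Binomial(n, fpr_lambda)` (discrete quantiles resolve upward: smallest
k with CDF >= 0.95), and the detection probability is the smallest `p`
with `CDF(critical_level; n, p) <= 0.05`, solved by bisection on exact
CDFs to 1e-9 relative tolerance (no normal approximation). LOD in
copies is `n * -ln(1 - p)`; as AF% it is taken relative to
`n * wt_lambda + lod_copies`. With no false positives this reduces to
`-ln(0.05) ~ 3.0` copies/reaction independent of droplet count. The
conventions make the round trip conservative: simulated reactions at
the LOD load are detected >= 95% of the time and wild-type-only
reactions false-call <= 5%.

## Validation statistics

Sensitivity CIs are exact Clopper-Pearson beta-quantile intervals (the
boundary cases `x = n` / `x = 0` give the closed forms
`level^(1/n)`); pooling across laboratories is `sum(x)/sum(n)` when
trial counts are available and the plain mean of percentages otherwise
(the equal-n assumption is recorded in the output). Per-base
specificity is `1 - FP / (samples x footprint bases)` with the
denominator stated explicitly in the result so alternative conventions
(e.g. three substitutions per base) are one argument away. Display
rounding is half-up at 2 decimals via decimal arithmetic on the shortest
float representation (so 89.725 displays as 89.73); computation is kept
at full precision. %CV uses the n-1 sample standard deviation.

## Known limitations

- The per-site mean-rate estimates inherit the control cohort's
  sampling noise; the calibration margin absorbs typical estimation
  error, but a position whose true rate is several-fold the fitted rate
  can still leak false calls. Deeper or larger control cohorts tighten
  this directly.
- The ultra-low-AF indel demonstration (0.02% AF at 12,450 copies) is a
  best case: with the pseudocount-floored indel null, roughly four or
  more surviving mutant molecules are needed before the LR clears the
  indel threshold.
- Pooled `rho` assumes a panel-wide overdispersion scale; a panel with
  genuinely heterogeneous burstiness would need the per-site mode plus
  a larger cohort, or an intermediate shrinkage estimator.
- CNV inference reports amplifications against a diploid baseline; it
  is not a segmentation method and does not model focal deletions.
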