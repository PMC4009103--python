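# Methods

## The pooled design and why there is no per-probe test

Each group (here a male and a female pool) contributes one array sample in
which many individuals' DNA is combined in equal mass, so a probe's β-value
estimates the group-average methylation fraction at that CpG. With a single
β per probe per group there is no per-probe variance estimate, hence no
per-probe t-test; the only available significance device is a global null
model for the difference ΔMe = β_female − β_male. That model, the threshold
it yields, and the set summaries downstream of it are what this package
implements.

## Threshold calibration

The null assumes both pools draw probe values from the same Gaussian
N(μ, σ²). One calibration repetition draws `n_points` values for each pool,
forms ΔMe by pairing the draws by index, fits a normal to the observed ΔMe
(sample mean, sample SD with denominator n − 1), and reports the central
1 − α prediction interval of that fitted normal, mean ± z_{1−α/2}·s. The
per-repetition cutoff scalar is max(|lower|, |upper|); over `n_reps`
repetitions the mean and SD of these cutoffs are aggregated, and the
recommended threshold is the mean rounded to two decimals — the precision
at which a β-scale threshold is meaningfully applied.

Closed form: with equal means and common σ, ΔMe ~ N(0, 2σ²), so the
prediction bound converges to z_{1−α/2}·√2·σ. For σ = 0.071 and α = 0.05
this is 0.1968, and the Monte Carlo mean at n_points = 10⁴ reproduces it to
well under 1%. The exact expectation of the per-repetition cutoff has two
finite-n terms the tests use as the oracle:

    E[cutoff] = z·√2σ·c₄(n) + √(2/π)·√2σ/√n

(the first from the bias of the sample SD, the second from E|mean ΔMe|,
since cutoff = z·s + |mean|). Both vanish as n grows. A corollary worth
noting: the *dispersion* of the per-repetition cutoff scales as 1/√n, so a
large reported spread around a ~0.197 cutoff implies a very small
per-repetition sample size (a ±0.067 SD corresponds to n ≈ 9); the package
therefore treats `n_points` as an explicit input, defaulting to the
retained probe count, and treats the cutoff mean — not its spread — as the
quantity of interest. σ is likewise an explicit input: the pooled design
has no replicates from which to estimate it.

Seeding: one master seed spawns an independent child stream per repetition,
so extending `n_reps` extends the sequence without reshuffling earlier
repetitions.

## Probe QC and DMP calling

A probe is retained when its detection p-value is ≤ 0.05 in **both** pools
(a probe unreliable in either pool leaves ΔMe undefined — the conservative
reading of a per-sample QC rule) and, in the autosomal mode, when it does
not sit on chrX or chrY. Filtering is idempotent and the retention report
partitions removals by reason, detection-p counted first.

Calls use a strict inequality: ΔMe > t is hypermethylated, ΔMe < −t
hypomethylated, and exactly ±t is never called. Raising t can only shrink
the call set.

The whole-genome summary compares pooled means with a two-sided Welch
(unequal-variance) t-test treating probes as observations; two identical
zero-variance pools return t = 0, p = 1 rather than an error.

### chrX hypomethylation mode

X inactivation methylates one female X chromosome, inflating female chrX
β-values, so hypermethylation calls there reflect dosage compensation
rather than sex-specific regulation. The chrX mode therefore keeps chrX
(applying the same detection-p QC), suppresses the hypermethylation
direction entirely, and reports only ΔMe < −t calls; chrY and autosomes are
out of scope for this mode.

## Region and window summaries

Manifest annotations attach each probe to zero or more (gene, region group)
pairs over six groups: TSS1500, TSS200, 5′UTR, 1st exon, gene body, 3′UTR.
The counting unit for region distributions is the **unique (probe, region
group) pair**: a probe annotated to the same group through two genes counts
once for that group; a probe spanning two groups counts in both; fractions
are over all genic pairs. Probes with no gene entry are tallied in a
separate intergenic bucket excluded from the six-group fractions. This
convention is a declared choice — pair-level counting avoids double-counting
a group while preserving genuinely multi-region probes — and other
denominators would change the printed percentages.

Genome density tables use half-open windows of 10 Mbp by default: a 1-based
position maps to 0-based window index (pos − 1) // size, so position
10,000,000 is the last base of window 0. Every window of every chromosome
present is emitted, empty ones with count 0 and missing means, which keeps
the table directly usable as a Circos track. Window counts conserve probes
by construction.

## DMG classification and list overlaps

A DMP contributes to every distinct gene symbol in its annotations; a gene
with ≥ 1 DMP is a DMG, labelled "+" when all members are hyper, "−" when
all are hypo, "mixed" otherwise — so the three statuses partition the DMG
set, and a single-DMP gene can never be mixed. Gene identity is the
case-folded symbol (the manifest dialect has no stable identifiers); a
symbol seen on two chromosomes is merged with a warning.

Overlaps with external flat gene lists are case-insensitive intersections,
reported alongside the hypergeometric expectation n·K/N for a random list
of the same size from the declared universe — an extension that turns a
qualitative "few common genes" into a number with a reference point.

## Enrichment

For each term, P(X ≥ k) with X ~ Hypergeometric(N, K, n), where the
universe N defaults to all genes on the filtered manifest — the array's
sampling frame — and terms are intersected with the universe before
testing. The tail sum is accumulated in log space (log-binomials via
gammaln, combined with logsumexp), keeping p-values accurate far below
double-precision underflow of individual factorials. BH adjustment runs
over **all** tested terms including zero-overlap ones (dropping them from
the family would overstate significance); zero-overlap terms are merely
omitted from the output rows. Only over-representation is tested.

One caution surfaced by testing: "re-adjusting" BH-adjusted p-values is not
a no-op and can shrink the rejection set; the property that actually
characterises BH adjusted values — thresholding them at α reproduces the
step-up rejection set on the raw p-values — is the one asserted.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical shape* the analysis depends on:

- a manifest over the 22 autosomes plus chrX/chrY with hg19 lengths,
  probes at sorted unique positions, 0–2 gene entries per probe
  (weights 0.25/0.65/0.10) with body-heavy region-group weights
  (0.14, 0.10, 0.12, 0.07, 0.43, 0.14 in promoter-to-3′ order);
- a bimodal baseline beta landscape: 30% low (Beta(2,18)), 40%
  intermediate (Beta(10,10)), 30% high (Beta(18,2)) — mixture mean 0.5;
- additive per-pool technical noise N(0, 0.02²) on the beta scale, clipped
  to [0,1]; clipping rather than a logit-normal model is the simplest
  mechanism consistent with the β bounds, and at this noise level it is
  rare except at the extremes;
- planted effects added to the female pool at probes whose baseline leaves
  ≥ 0.1 headroom after the shift, so the truth table's signed deltas equal
  the observed ΔMe exactly when noise is zero;
- detection p-values near zero with a 0.5% failing fraction per pool;
- gene sets drawn from the manifest's gene universe, optionally with one
  term containing exactly the planted-effect genes as an enrichment
  ground truth.

Default study conditions: 20,000 probes apportioned by chromosome length,
40 genes per chromosome, planted effects of ±0.3 (30 hyper, 25 hypo, plus
8 chrX hypomethylated probes). The ±0.3 magnitude sits comfortably above
the 0.20 threshold (3.5 noise SDs of ΔMe above it), giving sensitivity 1
and essentially zero false positives — the regime a 0.20 cutoff is designed
for; the 30/25 split makes hypermethylation the majority direction, the
qualitative pattern a female-vs-male comparison is expected to show. A
single integer seed governs all draws in a documented order (manifest:
per-chromosome positions, entry counts, gene picks, groups; pools: baseline
class, baseline value, planted selection, male noise, female noise, male
then female detection-p), so outputs are byte-reproducible.

Not emulated: individual-level variation within pools, cell-type
composition, batch/chip effects, spatial correlation of methylation along
the genome, probe cross-reactivity, and the detection-p's dependence on
signal intensity. Passing tests therefore demonstrate the *logic* of the
pipeline — thresholding, partitioning, counting, enrichment arithmetic,
reproducibility — under the stated noise model, not robustness to the
artefacts of real arrays.

## Numerical and degenerate-input choices

- Zero-σ calibration degenerates to a zero-width interval at the mean
  shift, returned rather than raised.
- Chromosome labels are normalised by stripping a `chr` prefix; unknown
  chromosomes sort after the karyotype.
- Empty call sets propagate gracefully: fractions are reported as missing,
  downstream tables are skipped in the report, and the run manifest still
  records zero counts.
- Percentages of examined probes are printed to 3 significant figures.
- Problem sizes used in the validation suite (desk scale): 10⁴ points ×
  200 repetitions for calibration checks, 10⁵ null probes for the
  false-positive check, 20,000-probe end-to-end runs — sizes at which the
  Monte Carlo errors of every asserted comparison are computed explicitly
  (3-SE bands) rather than guessed.

## Known limitations

- The Gaussian null is an approximation: real β distributions are bounded
  and bimodal, so a single global σ understates the heavy occupancy near 0
  and 1; the calibrated cutoff should be read as a convention anchored to a
  plausible σ, not a probe-level error rate.
- One threshold for all probes ignores probe-type and regional differences
  in technical variance.
- Region-distribution percentages depend on the declared pair-level
  counting convention; alternative denominators are not computed.
- Enrichment treats terms as flat sets: no ontology-graph propagation or
  parent–child conditioning, and results inherit whatever annotation
  version the supplied GMT encodes.
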