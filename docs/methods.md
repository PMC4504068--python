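# Methods

## The two-isoform deconvolution

The model assumes a single gene locus producing exactly two transcripts:
the full-length mRNA covering exons 1..n and an alternate-start variant
covering the shared 3' exons k..n, each sequenced at a uniform number of
reads per nucleotide (`a` and `b` respectively). Exon `i` of length
`len_i` then expects `a·len_i` reads if `i < k` and `(a+b)·len_i` if
`i ≥ k`. Summing raw counts over the exclusive block (`r0`) and the shared
block (`r1`) and writing `L0 = Σ len_i`, `L1 = Σ_{i≥k} len_i`:

```
F0 = r0·L0/(L0−L1),   F1 = r1 − F0·L1/L0,   R = (F1/L1)/(F0/L0)
```

Algebraically `F0/L0 = r0/(L0−L1)` estimates `a` and `F1/L1 = r1/L1 −
r0/(L0−L1)` estimates `b`, so `R` estimates `b/a` and the cancellation is
exact on noiseless counts (tested at ≤ 10⁻¹² relative error). `R` is also
the minimizer ratio of the two-parameter least-squares fit of the expected
counts when both blocks are internally consistent; the test suite checks
agreement with an independent grid-plus-Nelder-Mead least-squares oracle
at ≤ 10⁻⁶ relative on noiseless inputs.

Assumptions that matter in practice:

- **Only two isoforms.** A third transcript (or intron retention)
  redistributes coverage and biases `R`.
- **Uniform coverage.** 3' bias or positional effects violate the
  block-sum identity; at short single-end reads the approximation is
  reasonable but unverified here.
- **Raw integer counts.** RPKM or log-transformed inputs break the
  arithmetic; the count container enforces integers.

### Boundary policy

| situation | behaviour | flag |
|---|---|---|
| raw `F1 < 0` (noise, variant absent) | `F1` clipped to 0, `R = 0`; raw value kept | `F1_CLIPPED_NEGATIVE` |
| `r0 = 0`, `r1 > 0` (no full-length signal) | `R = inf` sentinel, not a numeric error | `R_UNDEFINED_ZERO_F0` |
| total gene reads < 10 | estimate still computed | `LOW_COUNTS` |

`log2 R` uses a pseudocount: `log2(R + ε)` with ε = 10⁻⁶ (configurable).
Samples with no variant have `R = 0` and would otherwise be undefined on
the log scale; ε = 10⁻⁶ places them near −20, far below any biologically
plausible ratio, so rank-based downstream tests are unaffected. Per-exon
RPKM uses the conventional `log2(RPKM + 1)`.

### Read-to-exon assignment

A primary, mapped read is assigned to the exon sharing the most aligned
bases with it (aligned blocks, so spliced alignments contribute only their
exonic segments); ties go to the lower ordinal. At 29 bp single-end reads
the choice is nearly immaterial but must be fixed for reproducibility.
Multi-exon reads count once, never fractionally. The variant's short
intronic 5' extension is deliberately excluded from `L1` and from
counting: the estimator is defined over shared exons only, and the
extension length is recorded on the model purely as documentation.

### Positivity

The binary presence call is `R ≥ 0.1` by default (the infinite-ratio
sentinel is positive). A PCR band assay has no numeric `R` equivalent, so
the threshold is a surrogate choice: 0.1 sits an order of magnitude above
the noise floor of `R` at ≥ 50× coverage (RMSE ≈ 0.01 at ρ = 1) while
still catching minor-isoform expression. It is user-configurable.

## Cohort statistics

All tests are two-sided. Unknown covariate values exclude a sample from
that test only.

- **Paired differences.** `Δ = log2 R(tumor) − log2 R(normal)` per pair;
  pairs with an undefined member (sentinel `R`) are skipped and counted.
  The headline summary reports how many pairs exceed Δ > 1.
- **Wilcoxon rank-sum** (scipy): exact permutation null when the combined
  sample is ≤ 12 and tie-free, otherwise normal approximation with tie and
  continuity corrections. Verified exhaustively against a rank-assignment
  enumeration oracle for all splits with n ≤ 10.
- **Fisher exact, 2×2 and 2×3.** Implemented by full enumeration of tables
  with the observed margins, summing the probabilities of tables no more
  probable than the observed one (log-gamma arithmetic; a 10⁻⁹ log-scale
  tolerance absorbs float ties). The available library routine for tables
  wider than 2×2 is Monte-Carlo, hence the in-house enumeration; it is
  verified against an exact rational-arithmetic oracle, and 2×2 odds
  ratios come from scipy. Grade (3 levels) uses the 2×3 form with a single
  p-value. No multiple-testing correction by default, with an optional
  Benjamini–Hochberg switch across the Fisher battery.
- **Survival** (lifelines): product-limit curves per positivity stratum
  and the two-group log-rank test; at tied times events precede
  censorings (standard convention). A cohort with no events yields flat
  curves and a flagged, undefined log-rank.

Whether the subgroup rank test consumes `R` or `log2 R` is immaterial for
positive values (ranks are invariant under monotone maps); samples with
the infinite sentinel are excluded from rank tests and counted.

## Synthetic data generator

The generator runs the coverage model forwards: expected exon counts
`a·len` / `(a+b)·len`, with `none` (rounded means), `poisson` (the default,
matching the uniform-reads assumption) or `nb` (gamma-Poisson, for
robustness checks) noise. One integer seed determines every draw.

Default gene: 15 exons × 100 bp, variant start at exon 10, so L0 = 1500,
L1 = 600.

Default cohort — 87 tumor/normal pairs shaped like a paired breast-cancer
expression study:

| parameter | default | rationale |
|---|---|---|
| full-length coverage `a` | lognormal(ln 50, 0.3), shared within a pair | ≥ 50× keeps estimator RMSE ≈ 1–3% |
| tumor ratio ρ, ER+ | lognormal(0.5, 1) (median ≈ 1.6) | variant comparable to full-length in ER+ tumors |
| tumor ratio ρ, ER− | lognormal(−1.5, 1) (median ≈ 0.22) | present but lower in ER− tumors |
| normal ratio ρ | lognormal(−4, 1) (median ≈ 0.02) | variant nearly absent in normal tissue |
| ER+ prevalence | 0.70 | typical breast-cancer cohort composition |
| Her2+ prevalence | 0.20; PR follows ER (0.8/0.2); grade (0.15, 0.45, 0.40); TP53-mut 0.30 | plausible marginals; joint structure beyond ER→PR not modelled |
| relapse-free survival | exponential, median 60 months for negatives; hazard ratio 0.5 for positives; exponential censoring, mean 120 months | a positivity-protective effect detectable at n ≈ 100 |

The tumor/normal separation implied by these choices — mean log2-ratio
difference ≈ 6.5 (ER+) and ≈ 3.6 (ER−), s.d. ≈ 2 — puts the expected
fraction of pairs with Δ > 1 at ≈ 0.96, and the measured median count
across replicates is 84–85 of 87. Positivity in the generated sample
sheet is the thresholded **true** tumor ratio, playing the role of an
assay-based call; survival is generated from that call.

What the generator does *not* emulate: sequencing error, GC/positional
bias, fragment-level sampling, a third isoform, batch effects, or
correlated censoring. Passing tests therefore demonstrate correctness of
the estimator and statistics under the stated model, not robustness to
real-data artefacts; the negative-binomial mode probes overdispersion
only.

An optional read-level mode emits each sample's counts as 29 bp single-end
reads in SAM (uniform random starts, each read fully inside its exon) so
the alignment-counting path can be tested end-to-end against the
count-table path.

## Numerical and design choices

- Exactness tests draw **integer** coverages so expected counts are exact
  integers; rounding fractional expectations would contaminate a
  machine-precision identity check.
- Exact-test sizes: enumeration Wilcoxon up to combined n = 12 (auto
  mode); Fisher enumeration is O(margin²) and desk-scale for cohorts of
  a few hundred.
- Statistical acceptance checks run at 1,000 replicates, where binomial
  noise on a 5% rate is ±1.4% (2 SE) and Monte-Carlo error on mean `R̂`
  is well under the 2% bias bound.
- Coordinates are 0-based half-open internally; GTF shifts on read.
  Transcription order defines exon ordinals, so on the minus strand
  exon 1 is genomically last.
- CLI runs log the effective config, its hash, the seed and library
  versions to `run_log.txt` for provenance.

## Known limitations

- Two isoforms only; no EM-style multi-isoform extension.
- `R` is a plug-in ratio estimator: at low coverage it is noticeably
  right-skewed, and no confidence interval is provided.
- The Fisher enumeration targets 2×2 and 2×3 tables; wider tables are out
  of scope.
- Real-annotation runs depend on the user's GTF for exon lengths; no
  annotation is bundled.
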