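# Methods

## Scope and model

`scwga` treats a single-cell WGA sequencing experiment as a comparison
between one deeply sequenced population reference and N single cells from
the same isogenic sample, jointly genotyped at biallelic diploid sites.
Under the isogenicity assumption every cell/bulk genotype discordance is a
technical artifact, which makes three quantities estimable without any
external truth set: the allelic dropout rate (ADR), the false-positive rate
(FPR), and the variant detection efficiency. All sites are modelled as
biallelic and diploid; multi-allelic records are rejected at the VCF
boundary because every estimator is defined on two-allele genotype classes
(AA / AB / BB).

### Estimators

Let `Het_p` and `Hom_p` be the reference's het and hom-ref site sets, and
let the cell's genotype at a site be its post-filter call.

* `ADR_i = |{s in Het_p : cell i called AA or BB at s}| / |Het_p,i|`.
  "Homozygous in the cell" deliberately includes both AA and BB: either
  allele can drop. The restricted form conditions `Het_p,i` on depth >= 6X
  in both reference and cell and the cell being genotyped; this removes
  sites where missing coverage, not amplification dropout, explains the
  call. The unrestricted form uses all of `Het_p` and counts an uncalled
  cell site as a dropout event — an upper bound that folds coverage loss
  into the rate. By construction unrestricted >= restricted whenever
  low-coverage sites exist.
* `FPR_i = |{s in Hom_p : cell i called AB at s, SNV}| / D_i`. The
  denominator `D_i` is the number of hom-ref bases at which cell i could
  have produced a call (depth >= 6). A joint-called VCF contains hom-ref
  records only where *some* sample is non-reference, so `D_i` cannot be
  read off the records; the simulator therefore attaches
  `hom_ref_callable_bp` to each call set, and on hand-built record-complete
  inputs the estimator falls back to counting explicit hom-ref records
  (depth >= 6 in both samples). The >= 6X restriction on the denominator is
  applied symmetrically with the ADR for coherence and is exposed via
  `min_depth`.
* Detection efficiency: a reference variant (bulk AB, and by extension
  bulk BB — the extension is flagged in the report) is detected in cell i
  when the cell call is AB or BB. Restricted denominators require cell
  depth >= 6 at the site; unrestricted denominators are all reference
  variant sites. Because AB->BB dropouts still carry the variant, a
  het-only experiment with dropout `d` and BB-bias `beta` has expected
  restricted efficiency `1 - d(1 - beta)`, which the test suite uses as a
  closed-form oracle.
* Summaries are means of per-cell rates with SEM = sd / sqrt(n_cells)
  (sample sd, ddof 1). Detection reports additionally print pooled
  aggregate counts (sum detected / sum total) because the two summaries
  differ whenever per-cell denominators differ; both are reported rather
  than adjudicated.
* Consensus mitigation: under site-independent FPs at per-base rate `p`,
  the chance the same FP is called in all of `n` cells is `p**n`. The
  recurrence analysis (fraction of event sites shared by >= 2 cells, mean
  multiplicity among shared sites) is the empirical check on that
  independence assumption.

### Site filters

Calls pass threshold filters — MQ >= 40, base-quality pass (the flag
carries a minimum base quality of 20 applied during calling), depth >= 6,
and >= 2 variant-supporting reads for non-hom_ref calls — followed by
removal of SNV calls with another SNV call within 10 bp on the same
chromosome (all cluster members are removed; keeping one would defeat the
purpose of excising FP-dense regions). hom_ref records are judged on
depth/MQ only. The >= 2-alt-read rule is applied to indels too, with a
toggle (`alt_read_filter_indels`) for fidelity studies. The cluster window
is measured between SNV start positions; the interaction with nearby indel
affected ranges is ambiguous in general and indels are left out of the
rule entirely. Threshold filters are per-site and hence idempotent and
order-independent; the cluster filter runs after them.

**Density caveat.** The cluster filter removes variant calls but not
hom_ref records. At realistic exome densities (~5.6e-4 variants/bp, the
package default) this asymmetry shifts ADR by well under one SE. On
deliberately dense desk-scale targets (e.g. 20,000 het sites in 200 kb, a
36-fold density inflation used to make estimator-recovery tests precise)
it inflates ADR by several points, because AA dropout calls survive in
cluster regions while AB/BB calls are removed. The recovery tests therefore
measure ADR and detection efficiency after threshold filters only; the
full pipeline keeps the threshold -> cluster order.

## Synthetic-data generator

The generator emulates the statistical structure of a joint-called
single-cell exome experiment; it is the package's test bed and its defaults
are the study conditions the estimators are validated under.

* **Reference**: the configured numbers of het/hom SNVs and indels are
  placed uniformly without collision on a single-contig target (default
  1 Mb, a desk-scale stand-in for a 62.3 Mb exome capture, with variant
  densities scaled proportionally: 375 het + 187 hom SNVs and 31 + 15
  indels per Mb). Reference depth is Poisson(59) floored at 6 so the bulk
  sample is fully callable, mirroring a ~59X population sequencing run.
* **Depth**: per-base cell depth is a zero-inflated, zero-truncated
  negative binomial. The covered component is gamma-Poisson with mean
  `depth_mean` (default 30X) and dispersion `alpha` (variance
  `m + alpha m^2`, default alpha = 0.6); incidental zeros are resampled so
  that the `depth_zero_fraction` point mass (default 0.04) is exactly the
  uncovered fraction — hence expected breadth = 96%, and the callable
  (>= 6X) fraction lands near the mid-80s as in real G2/M-gated data.
  `alpha = 0` is defined as deterministic constant depth, the degenerate
  perfectly-uniform profile used by the Lorenz-curve oracle. No installed
  distribution object was bypassed here: draws use `numpy.random.Generator`
  gamma/poisson primitives.
* **Dropout**: at call level — each reference-het site flips to homozygous
  in a cell with probability `d` (default 0.2152, a G2/M-like rate), to BB
  with probability `beta` (default 0.55, a slight bias toward losing the
  reference allele, plausibly from capture probes designed against the
  reference sequence) else AA. A fraction of het sites (default 0.02) are
  hotspots with dropout probability `min(1, 3d)`, shared across cells via
  a seed-derived mask; this is the simplest mechanism that yields dropout
  recurrence at the same positions in multiple cells. The default
  multiplier is a deliberately mild choice: with ~19 cells at d ~ 0.2-0.3
  even independent dropout makes shared sites common, so recurrence
  observations constrain the mechanism only weakly and the default is not
  presented as an inference.
* **False positives**: per cell, each hom-ref base yields a spurious het
  SNV call with probability `fp_rate` (default 3.2e-5, i.e. 32 errors/Mb),
  substitution class drawn from a 12-class spectrum whose default puts
  0.823 combined mass on C>T and G>A. Indel FPs are not simulated; indels
  participate in dropout and detection only.
* **Read evidence** is generated consistently with the *called* genotype:
  het calls draw alt counts Binomial(depth, 0.5) raised to a floor of
  min(2, depth), hom-alt near depth, hom-ref at most 1 alt read. The floor
  encodes that a genotype-likelihood caller only emits variant calls with
  supporting reads, so `fp_rate` and `ado_rate` parameterise rates of
  *called* events — the quantities the estimators are defined on. Without
  the floor the >= 2-alt-read filter would clip ~11% of binomial draws at
  6X and the recovered FPR would systematically undershoot the injected
  rate for reasons unrelated to the estimator.
* **Observability**: events at zero-coverage bases produce neither a call
  nor a truth row (no reads, no call); truth tables and emitted VCFs are
  therefore mutually consistent by construction, which the test suite
  asserts.
* **Determinism**: every stream derives from `SeedSequence([seed, stream_id])`
  with fixed per-purpose stream ids, so outputs are byte-identical across
  runs and per-cell streams are independent of generation order.

### What the generator does not emulate

Read-level artifacts (chimeras, alignment error, duplicate structure),
copy-number events, doublets, GC-dependent coverage, linkage between
neighbouring sites, multi-allelic sites, and real exome interval structure
(the target is one contiguous interval). Passing recovery tests therefore
demonstrates estimator correctness under the stated error model, not
robustness to every failure mode of real libraries.

## Coverage metrics

Breadth, callable fraction, mean depth and histograms are computed on
run-length-encoded depth tracks over the supplied target region (both
breadth-style and uniformity metrics use the same region; splitting them
across genome/exome would only re-create an artifact of external tooling).
The Lorenz curve sorts bases by ascending depth and plots cumulative read
fraction against cumulative base fraction; ties between equal depths
commute, so tie-breaking cannot affect the curve and is not configurable.
Curves are exact polylines over distinct depth values, thinned to <= 10,000
points with endpoints preserved; the uniformity summary is twice the area
between the diagonal and the curve (Gini-style, 0 = perfectly uniform,
an added convenience rather than a standard readout). An all-zero profile
has no defined curve and is rejected.

## Numerical and interface choices

* Positions are 1-based internally for variants (VCF convention) and
  0-based half-open for intervals (BED convention); conversions happen only
  at the I/O boundary. Indels are stored VCF-style (anchored base) and
  matched by exact (pos, ref, alt); no left-normalisation is performed
  since simulated data is born normalised.
* Per-sample MQ and base-quality pass flags travel as declared non-standard
  FORMAT fields (MQ, BQ) so a written VCF round-trips losslessly through
  cyvcf2.
* Cells with empty denominators (no qualifying sites) are excluded from
  means and logged, not imputed.
* Probability parameters are validated into [0, 1]; the FP spectrum must
  sum to 1 within 1e-9; hotspot-adjusted dropout probabilities are capped
  at 1.
* The unrestricted-ADR convention (no-call counts as dropout) is one of
  several defensible readings of "all het sites regardless of coverage";
  it is the only one under which the unrestricted rate dominates the
  restricted rate on every dataset, which is the property the report
  relies on.

## Problem sizes

Validation runs use desk-scale targets chosen to make sampling error small
relative to the effects under test: dropout and detection recovery use
5 cells x 20,000 het sites over 200 kb (20 seeds for the dropout grand
mean), FPR recovery uses 4 cells x 2 Mb of hom-ref target across 10 seeded
replicates (~225 expected FP calls per replicate), spectrum recovery uses
~10,000 injected FPs, and coverage/Lorenz checks use 0.5-1 Mb profiles.
The acceptance script reruns the same scenarios once each from a
user-supplied seed.

## Known limitations

* The FPR denominator on real (non-simulated) VCFs without depth tracks
  falls back to explicit hom-ref records, which undercounts `Hom_p`
  unless the input is record-complete; supply per-cell depth tracks or a
  precomputed callable count for absolute rates.
* ADR/FPR are defined against an isogenic reference; applying them to
  genuinely heterogeneous samples conflates biology with error.
* The call-level dropout model does not represent partial allele imbalance
  (skewed but not lost alleles), and MQ is modelled per record rather than
  per read because read-level filtering happens upstream of this package's
  scope.
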