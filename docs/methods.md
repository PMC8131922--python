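# Methods

This note documents the models, estimators and numerical choices behind
`mbrquant`, and what the synthetic benchmarks do and do not establish.

## Units and conventions

m/z in thomson (Th), retention time (RT) in minutes, ion mobility (IM) as
inverse reduced mobility 1/K0, FAIMS compensation voltage in volts.  All
intervals are closed; m/z tolerances are in ppm (default 10, config
`ppm_tolerance`).  An *ion* is the triple (peptide sequence, canonical
modification string, charge); modification strings are comma-separated
`position:deltamass` tokens sorted by position.  Natural logarithms are
used internally; reported quantities are ratios or exponentials and hence
base-free.

## Peak tracing

A query region (m/z window × RT interval, optionally × IM interval) is
quantified in five steps:

1. **Extraction** — peaks inside the m/z window and a padded RT window
   (`rt_pad`, default 0.3 min, so boundaries may extend beyond the query
   region) are collected; intensities at identical scan times are summed.
   The query RT half-width is floored at `min_rt_halfwidth` (0.1 min)
   because alignment-derived regions can be degenerate (σ = 0).
2. **Resampling** onto a uniform grid (interval = median raw spacing
   unless configured) with linear interpolation.
3. **Savitzky–Golay smoothing** (window 7, polynomial order 2) with
   polynomial fits over the edge windows.  The implementation caches the
   convolution kernel and edge hat matrix; tests verify exact agreement
   with `scipy.signal.savgol_filter(mode="interp")`.
4. **Boundaries** — the apex is the smoothed local maximum inside the
   query window nearest the hint (plateaus and ties resolve to the
   earliest RT); from the apex, boundaries descend until a local minimum
   or until intensity falls to `boundary_fraction` (1%) of the apex.
5. **Background and integration** — a straight line between the boundary
   intensities is subtracted (clipped at zero) and the area integrated by
   the trapezoid rule.  With IM bounds, scans inside the IM window are
   collapsed before integration; on the shared scan grid this equals the
   sum of per-IM-slice areas ("volume").  The reported IM center is the
   intensity-weighted mean of the contributing peaks.

The +1/+2 isotopes are traced at mono m/z + k·1.00286864/z within the
monoisotopic boundaries.  The isotope triple used for envelope scoring is
computed on one common scheme (resampled, unsmoothed, no background) so
the three values are mutually comparable; the *quantified* intensity is
the background-subtracted, smoothed mono area.  The signed mass error is
the intensity-weighted mean m/z of the in-bounds peaks vs. the query m/z.

## Normalization

Per-run multiplicative bias is estimated on MS/MS-quantified ions only
(transfers must not influence the factors they are later judged by), then
applied to all rows.  The pooled ion m/z range is split at deciles into
ten equal-population bins; per run and bin the median log-intensity offset
against the cross-run per-ion median is computed over ions seen in ≥ 2
runs, and the run factor is exp(−median over bins).  Binning keeps a few
very abundant or sparse m/z strata from dominating the factor.  A single
run, or a run sharing no ions, gets factor 1 with a warning.

## Donor selection and transfer regions

Run-pair similarity is (o·r1 + o·r2)/2, or (o·r1 + o·r2 + o·r3)/3 with
IM, where o = |shared ions| / min(|donor|, |acceptor|) and r1/r2/r3 are
Spearman correlations of RT, intensity and IM over shared ions (< 3 shared
ions ⇒ 0).  Up to `mbr_top_runs` (10) donors per acceptor with similarity
above `mbr_min_corr` (0) are used, ranked descending, ties broken by run
id.

For a donor ion at RT *t*, the RT region is `[dᵢ + m − 2σ, dᵢ + m + 2σ]`
where *dᵢ* is the nearest pairing RT at or below *t*, and m/σ are the
median and MAD of acceptor-minus-donor offsets within τ
(`mbr_rt_window`, 1 min) of *dᵢ*; the IM region is built the same way with
`mbr_im_window` (0.05).  Because the region is anchored at *dᵢ* rather
than *t*, sparse pairings (as in desk-scale studies) can leave the donor's
own aligned coordinate *t + m* outside the region; tracing therefore
covers the union of the region and a minimal window around *t + m*, with
*t + m* as the apex hint.  The RT-difference score is measured against
*t + m* (config `rt_diff_reference="donor"` switches to the raw donor RT).

Ions already identified in the acceptor (type 2) exist only to train the
discriminant, so they are transferred from the single best-correlated
donor holding the ion; unidentified ions (type 1) are attempted from every
selected donor and deduplicated afterwards (per acceptor feature location
— m/z within tolerance and overlapping RT bounds — the top composite score
survives, ties to the smallest ion key).  In FAIMS data, all tracing and
transfer stay within one compensation voltage; candidates from all
voltages are pooled for model fitting.

## Scores, decoys and transfer FDR

Each traced transfer gets: log₁₀ intensity; signed √|log₁₀ KL| of the
observed isotope proportions vs. a Poisson(λ) model truncated to
k = 0,1,2, with λ = 4.9384·10⁻⁴ · (m/z − 1.00728) · z (an averagine-style
peptide approximation; the KL is floored at 10⁻⁶ before the log so the
score stays finite — the sign is kept through the square root so the score
remains monotone in the divergence); √|ppm error|; √|RT difference|; and
√|IM difference| when IM is present.  Decoy transfers repeat the trace at
m/z + k·1.0005 Th for k = 11 down to 4, stopping at the first traceable
peak; a decoy is attempted only after a successful target trace, keeping
decoy counts matched to targets.

A Fisher discriminant w ∝ Σ⁻¹(μ₂ − μ₋₂) (pooled covariance with a
trace-proportional ridge; orientation fixed so type 2 scores higher) is
trained on type 2/−2 score vectors (≥ 20 per class) and applied to all
candidates.  Type 1/−1 composite scores feed a two-population mixture
fitted by EM:

* the **false** population is anchored on the decoy scores — by default a
  Gaussian kernel density (`kde_null=True`), optionally Gaussian moments.
  Diagnostics showed the decoy score distribution is right-skewed; a
  Gaussian fit overstates null density in the acceptance region and makes
  the FDR estimate conservative by roughly a factor two at the 5%
  operating point, while the kernel null calibrates within ~1–2 percentage
  points across seeds.
* the **true** population is a K-component Gaussian mixture (pipeline
  default K = 2, config `em_true_components`): composite scores of correct
  transfers are left-skewed and a single Gaussian under-fits the tail.
  The standalone `fit_mixture` default stays at K = 1, and without decoys
  a free two-Gaussian EM with deterministic median-split initialization is
  used.

EM is fully deterministic (no RNG), stops at relative log-likelihood
change < 10⁻⁸ or 1000 iterations, floors all standard deviations at 10⁻³
and records the (non-decreasing) likelihood path.  A BIC-style
likelihood-ratio guard collapses π_true to ~0 when the mixture does not
beat the null-only model — on data fully explained by the null the
likelihood is flat in the priors and EM would otherwise land anywhere.
The posterior p(s) = π_true f_true / (π_true f_true + π_false f_false) is
clipped to [0,1].  Global FDR above a threshold is the running mean of
1 − p in descending score order, monotonized by a cumulative minimum from
the bottom (standard q-values); acceptance at level α keeps all entries
with q ≤ α.  Filtering runs ion → peptide → protein: peptide and protein
levels collapse entries by sequence / leading protein keeping the
highest-posterior representative, and a transfer must pass all three
(defaults 1%/1%/1%).

When decoys are too few to train the discriminant or the mixture (clean,
noise-free data), the pipeline accepts all transfers with posterior 1.0
and logs a prominent warning: with no traceable decoy, the decoy-based
estimate of the false-transfer rate is zero, and no threshold can be
computed.  Real data essentially always yields decoys.

## MaxLFQ

Per protein with ≥ `min_ions` (2) distinct ions study-wide: every
experiment pair sharing ions contributes the median ion log-ratio; the
normal system A x = b (A_ii = number of partners, A_ij = −1 for sharing
pairs, b_i = Σ_j m_ij) is solved per connected component of the
sharing graph by Cholesky on A + εI, ε = 10⁻¹⁰·tr(A)/N.  A is singular up
to a constant per component (the gauge); each component's solution is
shifted so its mean log intensity equals the mean log summed-ion intensity
— the output is on the familiar summed-intensity scale and ratios are
unaffected.  Isolated experiments get their summed intensity; experiments
without ions get NaN.  Proteins split across disjoint experiment groups
carry a component-count flag, since their cross-group ratios are not
determined by the data.

## The synthetic benchmark generator

`simulate_experiment` emulates the two study designs used to validate
transfer FDR and quantification accuracy: a two-organism design (8
human-only + 8 human/yeast runs by default, 125 proteins × 16 ions, 12.5%
yeast proteins) where yeast transfers into human-only runs are
ground-truth false, and a three-species design (3+3 runs, A:B mixing
ratios 1:1 human, 2:1 yeast, 1:4 E. coli).  Per run it plants, for each
present ion, a Gaussian elution profile (σ ∈ [0.04, 0.08] min) sampled on
a 0.02-min scan grid over a 5–25 min gradient, with 0/+1/+2 isotopes at
the true ¹³C spacing 1.0033548/z Th weighted by the truncated-Poisson
envelope (the tracer uses the averaged 1.00286864 constant — the small
mismatch deliberately exercises the ppm tolerance).  Retention times pass
through a per-run monotone piecewise-linear warp (≤ 3 knots, sd 0.3 min)
plus per-ion jitter (sd 0.05 min); intensities are log-normal per ion with
per-run multiplicative noise and optional injected run scale factors.
MS/MS sampling is logistic in log intensity (max 0.97, midpoint ln 5·10⁴),
producing intensity-biased missingness.  Peptide sequences are random
amino-acid strings with masses computed from real residue masses
(pyteomics), giving realistic peptide mass-defect clusters; chemical noise
(20 000 features/run by default) is drawn from a pool of cluster-snapped
peptide-like m/z values, which is what makes shifted-m/z decoy transfers
land on traceable peaks, as in real crowded spectra.  The mass range
(800–1500 Da) and noise density were chosen so false-transfer
opportunities clearly exceed the 5% FDR working point — the regime in
which a calibration claim is testable at all.  A fixed seed reproduces the
experiment bit for bit.

What the generator does **not** model: real chromatographic peak shapes
(tailing, saturation), co-elution interference within an isotope envelope,
charge-state coupling, in-silico digestion of real proteomes, or
instrument-specific noise structure.  Passing benchmarks therefore
establish the statistical machinery (region location, decoy null,
calibration, ratio recovery) under idealized signals, not performance on
any particular instrument's data.

## Benchmark problem sizes

The calibration study runs 16 runs × ~2000 ions with ~260 000 peaks per
run (≈ 45 s on one CPU); the three-species study uses 6 runs × 480 ions;
the MaxLFQ noise bound is evaluated pooled over 200 replicate N=4, M=10
studies because a single study's median error straddles the bound
(population value ≈ 0.046).  Determinism is asserted byte-for-byte on
written reports.

## Known limitations

* Transfer FDR needs decoys: sparse or very clean data can leave the
  model untrainable (the pipeline then warns and accepts everything).
* The estimated FDR retains a mild conservative bias (observed false
  fractions sit at or below the threshold) inherited from the decoy
  null's heavier right tail.
* Nonlinear RT alignment (LOESS/splines) is out of scope; the local
  median/MAD window handles smooth monotone warps only.
* Cross-voltage transfer in FAIMS data is intentionally not performed.
* Protein inference is upstream: rows carry the protein accessions their
  PSMs supplied, and the leading protein is used for protein-level
  collapsing.
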