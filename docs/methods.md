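# Methods

This note records the models behind each stage, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Binned size statistics

The screen's raw datum is a histogram of cell counts over bin-centre
volumes (default 256 equal-width bins spanning 10–200 fL; the layout is
configurable because absolute instrument calibration varies).
Frequencies are counts normalized to the total. The summary statistics
are:

* **mean** — count-weighted mean of bin centres (exactly the mean of
  the expanded per-cell list);
* **median** — linear interpolation of cumulative count across bin
  centres, with each populated bin centre placed at its mid-count
  cumulative position (the grouped-data convention). With runs of empty
  bins adjacent to the median bin, naive interpolation can drift into
  the empty gap, so the estimate is additionally constrained to within
  half a (local) bin width of the exact per-cell median computed from
  cumulative counts. The result reproduces the brute-force expanded
  median within half a bin width on every instance, while retaining
  sub-bin resolution on smooth distributions;
* **mode** — centre of the maximum-count bin; ties break to the
  smallest volume (arbitrary but deterministic).

Replicates are summarized per replicate and then averaged (median of
each replicate's distribution, mean ± sample SD across replicates, SD 0
for a single replicate). Whether a screen should average per-replicate
medians or pool counts is an open choice; per-replicate-then-average
matches how repeated instrument runs are normally reported and keeps
the spread estimate meaningful.

## Whi/Lge classification

Percent size change is `100 * (mutant_median - wt_median) / wt_median`,
computed on replicate-averaged medians. The median, not the mode,
drives classification (the mode is reported alongside): the cutoff is
defined on median size while the mode is mainly a display statistic for
skewed distributions. For table-style reporting the *reduction*
(negated change) is rounded half-up to an integer percent.

Calls use an inclusive cutoff: change ≤ −cutoff → Whi, change ≥ +cutoff
→ Lge, else normal. The default cutoff is 20%, and `calibrate_cutoff`
reproduces how such a cutoff is derived empirically: the largest
integer c such that every benchmark small mutant is reduced by at least
c percent and every benchmark large mutant increased by at least c —
i.e. the floor of the smallest absolute benchmark change. A benchmark
strain with zero or wrong-sign change is a hard error, since it cannot
support any cutoff.

Clustering of normalized profiles uses Euclidean distance with average
linkage (neither is canonical for size profiles; Euclidean on
frequencies weights the dominant mode region most, which is what a
clustergram of size distributions is meant to show). Strains are
sorted lexicographically before linkage so leaf order is deterministic
and ties break by label.

## Growth kinetics

`estimate_doubling_time` defaults to fitting a lag-logistic model

    OD(t) = od_max / (1 + (od_max/od0 - 1) * exp(-r * max(t - lag, 0)))

by nonlinear least squares (constant-variance residuals, matching
additive plate-reader noise) and returning ln 2 / r. The classical
sliding-window procedure — steepest log2-linear window among windows
with R² ≥ 0.99, falling back to the best-R² window — is available as
`method="window"` and is exact on clean exponential segments, but on
realistic noisy saturating curves it is unreliable: with additive read
noise of 0.01 OD, early exponential windows (OD ≈ 0.05–0.3) never reach
the R² floor while saturated late windows do, so the selection lands in
the wrong phase and errors of 50–300% occur. The model fit recovers
generating doubling times within ~1% on the same curves and within
1e-4% on noise-free exponentials (the carrying-capacity bound is left
very generous so unsaturated curves degrade gracefully to an
exponential fit). A fit no better than a flat line, or a non-positive
rate, raises a "no exponential phase" error.

Time to half-max is the first linear-interpolated crossing of half the
curve's *own observed maximum* (not a fixed constant), and relative
growth rate is t_half(reference) / t_half(culture), so 1 is
wild-type-like and larger means faster.

The Start-candidate filter retains a small mutant when its doubling
time is at most (1 + max_increase/100) times its own parental wild
type's (default 10%; the boundary itself is retained). Comparison is
per parental background, since collections built in different
backgrounds have different baseline growth rates.

## Critical size at Start

An elutriation release yields ordered fractions of (time, median size,
budded/total counts). Bud counts are binomial samples, so the raw
budding index can dip; it is made monotone by pool-adjacent-violators
(isotonic) regression weighted by fraction size. The critical size is
then the linear interpolation, **on the size axis**, of the first
crossing of the threshold fraction (default 25% budded — the
operational definition of population critical size; configurable). The
estimate is therefore invariant to reindexing of fraction times. A
first fraction already above threshold ("population already budded")
and a time course that never crosses ("threshold not reached") are
errors.

At least 200 cells per fraction is the conventional floor for a stable
budding index; smaller samples trigger a warning, not an error.

## Size epistasis

With d(x, y) = 100 |x − y| / y on medians: the double mutant is
*epistatic* to the single it matches within tolerance (default 5%) when
it does not also match the other (if it matches both, the closer wins;
an exact tie is *intermediate*); it is *additive* when it deviates from
the wild type further than either single, on the same side, matching
neither; everything else — notably partial epistasis and opposite-sign
singles — is *intermediate*. The 5% default makes verbal calls like
"comparable" and "identical" testable; it is configurable.

## Enrichment statistics

ChIP replicate log2 IP/control ratios are averaged arithmetically per
probe; the enrichment cutoff is mean + k·SD (default k = 2) of the
averaged ratios, using the sample (n−1) SD, with strict inequality at
the cutoff. The realized linear fold change 2^cutoff is reported so
the conventional "≈2-fold" reading of a 2-SD cutoff can be checked on
any dataset. On a pure Gaussian background this flags the upper 2-SD
tail (≈2.3% of probes); a single extreme outlier inflates its own
cutoff and is *not* called, which is a documented property of
mean+SD thresholds. Region counts (intergenic vs ORF) come from the
probe annotation as given; no coordinate mapping is attempted.

Gene-set overlap uses the upper-tail inclusive hypergeometric
probability P(X ≥ k) (scipy's survival function, log-stable), verified
against exhaustive enumeration for every universe of size ≤ 12. Term
enrichment runs one test per term and adds Benjamini–Hochberg
adjustment across terms; raw p-values are always retained since
published screen analyses typically report them unadjusted.

## Synthetic data: what it emulates, what it does not

* **Volume distributions** are log-normal (right-skewed, positive
  support) parameterized by median and CV, binned with clipping into
  the end bins; totals equal the cell count exactly. Coulter
  histograms of budding yeast are right-skewed, and no specific
  distributional law is canonical; log-normal is the simplest choice
  with the right shape. Budded cells are *not* modelled as a second
  mode — the screen summarizes whole asynchronous populations — so
  bimodality, debris tails and coincidence artefacts of real Coulter
  data are absent. Default CV 0.35 matches typical asynchronous
  populations.
* **Screen panels** place mutants at prescribed percent effects around
  a wild type, with truth classes assigned at the generating cutoff
  (boundary effects are labelled by their intended class; at exactly
  the cutoff, sampling noise makes recovery a coin flip, which is why
  recovery tests use effects ≥ 5 points past the cutoff).
* **Growth curves** are lag + logistic with additive truncated-Gaussian
  read noise (defaults: od0 0.05, od_max 1.6, 10-min sampling for
  24 h). Diauxic shifts, evaporation and plate-position effects are not
  modelled, so passing recovery tests does not certify those.
* **Elutriation time courses** grow each cell exponentially,
  v_i(t) = v_i(0)·exp(rate·t), from a narrow initial distribution
  (CV 3% — elutriation selects a tight size window) and bud on crossing
  a personal Normal threshold. `critical_mean_fL` is defined as the
  *population* critical size at the readout fraction (default 25%
  budded): the per-cell threshold distribution is centred at
  critical_mean − Φ⁻¹(0.25)·sd so that the assay's standard readout is
  an unbiased estimate of the parameter. (Centring the per-cell
  thresholds at the parameter instead would make the 25% readout the
  25% quantile of the threshold distribution, a systematic −0.67·sd
  offset — a property of the assay definition, not an estimator
  defect.) With sd = 0 the two parameterizations coincide. Growth-rate
  variability between cells and budded-cell growth-rate changes are not
  modelled.
* **ChIP probe sets** are Normal(0, sd) background with a spiked subset
  shifted by a fixed log2 effect; array spatial artefacts and
  intensity-dependent bias are not modelled. Defaults (14400 probes,
  intergenic fraction 8300/14400, duplicate arrays, sd 0.3) mirror a
  two-colour tiling design.
* **Gene universes** realize an exact requested overlap; there is no
  annotation structure beyond membership.

All generators take a mandatory seed and never touch global random
state; identical calls are bit-identical.

## Problem sizes and tolerances in the test suite

Recovery studies run at the scales the screen itself used where those
are modest (5000-cell distributions, 3 replicates, 2000-cell
elutriations, 14400-probe arrays) and at 20–50 seeds per study, chosen
so the whole suite completes in well under a minute: classification
recovery must be 100% for effects 5+ points beyond the cutoff;
critical-size recovery must show mean |error| < 2% with every estimate
within 5%; doubling-time recovery must be within 0.1% (clean
exponential) and 5% (noisy logistic); ChIP spike-in recovery ≥ 95%
with a null call rate in [1.5%, 3.5%]. The binned-median oracle is
checked on 1000 random instances of ≤ 10 bins and ≤ 1000 cells, and
the hypergeometric tail on every universe of size ≤ 12.

## Known limitations

* The binned median is only resolved to the bin width when
  distributions are spiky; this is inherent to binned data.
* The lag-logistic growth model assumes a single exponential phase;
  multi-phase growth yields the dominant phase's rate.
* Critical-size estimation reads one threshold crossing; it does not
  fit the whole budding-vs-size curve and so does not estimate the
  threshold spread.
* The epistasis rule is a deterministic classifier on point estimates;
  it does not propagate replicate uncertainty into the call.
* Proprietary instrument binary formats are out of scope; all I/O is
  delimited text.
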