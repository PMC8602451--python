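# Methods

## Motif model

The scanner recognizes the three hydrophobic SIM core patterns
ψ-ψ-X-ψ, ψ-X-ψ-ψ and ψ-ψ-ψ, with ψ defined exhaustively as L, I or V
and X as any single residue.  Nonstandard residues (U, X, B, Z, O) are
preserved by the FASTA reader and never satisfy ψ, but do satisfy the
wildcard position — ψ is a closed set, "any amino acid" is not.
Coordinates are 0-based half-open throughout the library; reports
serialize an explicit `start_1based` column.

Because the three patterns overlap heavily (a run of n ≥ 4 hydrophobic
residues contains many satisfying windows), two counting modes exist:

* `all_matches` — every (start, pattern) window that satisfies a
  pattern, the unambiguous ground truth used for oracle testing;
* `collapsed` (default) — a greedy left-to-right non-overlapping
  subset: earliest start wins, and at equal start the 4-residue
  patterns outrank ψ-ψ-ψ (longer and more specific first); a consumed
  window blocks any overlapping later match.

Collapsed is the pipeline default because treating each overlapping
window as a separate SIM would let a single hydrophobic stretch count
several times, inflating the density statistic; de-overlapped counts
are also the only reading consistent with typical proteome-wide null
medians of a few SIMs per thousand residues.  The de-overlap rule is an
interpretation — reasonable alternatives (rightmost-wins, maximum
non-overlapping cover) differ only on pathological runs — and both
modes are exposed so users can match any external script exactly.

Each match can carry an acidic/serine flank flag: true when any residue
within 4 positions (configurable) before the start or after the end is
D, E or S.  Acidic or phosphorylatable flanks strengthen SUMO–SIM
binding; the flag is reported per motif and as a list-level fraction.

## Density statistic and list summaries

Per protein: `STAA = 1000 · sim_count / length`, computed as an exact
rational before float conversion, so equal-count/equal-length proteins
compare exactly.  Per list: the median member STAA (even n: mean of the
two central order statistics), plus the percentage of members with ≥ 1
SIM (`pct_single`) and ≥ 2 SIMs (`pct_multiple`).  "Single presence" is
read as *at least one*, which is forced by the requirement
`pct_multiple ≤ pct_single` (the multiple-SIM set is a subset of the
single-SIM set).

## Resampled null and enrichment

Null construction is a fixed five-step pipeline: (1) draw R lists of k
proteins uniformly without replacement within a list, independently
across lists, from the sampling frame (optionally length-filtered
and/or excluding the query members; both default off since uniform
sampling of the whole frame is the baseline design); (2) ROUT outlier
removal on the R list-STAA values; (3) log2 of the retained, strictly
positive values (zero-valued lists are excluded from this step with a
logged count — they remain in the linear-scale median); (4) a
D'Agostino–Pearson normality check of the log2 values, reported as QC;
(5) the null median on the linear scale of retained values.
Presence-percentage medians are computed over all R lists, since
outlier removal applies to the STAA analysis only (a flag can change
this).

Fold enrichment is the plain ratio observed-STAA / null-median-STAA.
The empirical p-value is one-sided (upper tail): the enrichment
hypothesis is directional, so "as extreme" means ≥ the observed value.
The denominator is the number of retained (post-ROUT) lists; an exceed
count of zero is reported as the strict bound `1 / n_retained` with an
explicit `is_upper_bound` flag rather than p = 0.  The operation
asserts on every call that its vectorized count equals a brute-force
Python count over the same retained vector.

Defaults follow the standard design for this analysis: R = 1000 lists,
k = query-list size, ROUT Q = 1%.

### ROUT outlier detection

No open-source implementation of ROUT exists, so the one-column case is
implemented here: a constant model is fitted by iteratively reweighted
least squares with Lorentzian weights `1/(1 + (r/RSDR)²)` initialized
at the median, where RSDR is the robust standard deviation of residuals
(the 68.27th percentile of |residuals|, corrected by N/(N−K)).  Each
residual then receives a two-sided t-distribution p-value
(df = N−1), and a Benjamini–Hochberg step-up at rate Q decides the
flags.  The exact stepwise constants of the original procedure are not
fully published; BH is the standard FDR-controlling step and the
implementation is validated by contamination simulations (5 planted
10-robust-SD outliers among 1000 normal values are all flagged with
≤ 1% false flags at Q = 1%).  A median/MAD-based detector with the same
FDR step is available (`method="mad"`) as a cross-check.  Degenerate
samples with zero robust scale flag exactly the values off the common
point.  Fewer than 10 values is an error — the robust scale is
meaningless below that.

### Normality test

The D'Agostino–Pearson omnibus statistic K2 (squared z-transformed
skewness plus squared z-transformed kurtosis, chi-squared(2) under
normality) is computed via `scipy.stats.normaltest`, with explicit
n ≥ 20 and non-degeneracy preconditions.  Note that the normality of
the *log2* null is a property of the real human proteome's STAA
distribution; synthetic proteomes with narrow length distributions
often produce a discrete-ish null whose log2 values fail the test.
That is expected and does not affect the empirical p-value, which is
distribution-free.

## Label-free differential stage

The loader accepts MaxQuant-style protein-groups TSVs (one
`LFQ intensity <sample>` column per run; decoy/contaminant/
only-by-site marks as `+`).  Filtering keeps unflagged proteins with
≥ 2 peptides and ≥ 2 valid intensities in at least one group —
one-group presence suffices because on/off proteins are precisely the
interesting ones in a pulldown comparison.  Missing values (0 or NaN)
are imputed after log2 transform from a per-sample downshifted normal
(mean − 1.8 SD, width 0.3 SD), the de-facto convention for
missing-not-at-random low-abundance dropout; both parameters are
exposed.  Median normalization (centering each sample's median on the
global median) is an explicit flag, off by default — there is no
principled automatic trigger for "when needed".  Testing is a
two-sided equal-variance Student's t-test per protein (Welch behind a
flag); classification defaults to the permissive OR rule
`|log2 diff| > 1 OR p < 0.05` with an AND variant behind a flag.  No
multiple-testing correction is applied in this stage by design.
Imputation is applied per comparison (per loaded table).

## Synthetic data

`generate_proteome` draws i.i.d. residues from a frequency table
(default: approximate reviewed-human-proteome composition; uniform and
L/I/V-free variants available) with log-normal lengths (median 375 aa,
log-sigma 0.65, floor 30 aa — matching the scale and spread of the
reviewed human proteome) and plants Poisson-distributed SIM motifs at a
per-kiloresidue rate by overwriting non-overlapping windows, recording
every planted position as ground truth.  The L/I/V-free alphabet
removes incidental matches so that recovery experiments see exactly the
planted rate.  `generate_hit_list` plants the first k proteins at
`enrichment_factor ×` the background rate.  `generate_lfq` draws
normal log2 base intensities (mean 26, SD 2 — typical LFQ scale), adds
the planted effect to group A hits, applies logistic
intensity-dependent dropout (midpoint 22, scale 1, ceiling 0.9) and
1 + Poisson peptide counts.

What the generators do *not* emulate: real domain architecture and
composition autocorrelation, shared peptides between protein groups,
correlated replicate structure, or spectral-level noise.  Passing
recovery tests therefore demonstrates the statistical machinery is
correct and calibrated, not that any particular biological list is
enriched; real-proteome conclusions require the real FASTA.

## Problem sizes and experiment conditions

The packaged experiments use a 2000-protein synthetic proteome
(calibration: k = 20, R = 500, 200 repetitions; recovery: planted
factor 4 at background 5 motifs/1000 aa, k = 59, R = 300, 20
repetitions; operating characteristics: 100 repetitions of n = 1000
samples; LFQ: 3 vs 3 with 400–500 proteins).  These sizes give stable
rates while keeping the whole suite desk-scale.  The type-I-error check
of the differential stage runs without dropout, because the nominal 5%
property belongs to the t-test on complete data; with
intensity-dependent dropout the imputation model, not the test, governs
the tail behaviour.

## Known limitations

* The de-overlap (collapse) rule is an interpretation; `all_matches`
  mode is provided for exact comparison with other scanners.
* ROUT follows the published description with a BH step; results may
  differ marginally from proprietary implementations in edge cases.
* Uniform null sampling is the designed baseline; no composition- or
  length-matched nulls are offered.
* The empirical p-value resolution is `1/R_retained`; R = 1000 cannot
  distinguish p below 0.001.
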