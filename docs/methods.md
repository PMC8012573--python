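# Methods

This note documents the statistical model, the numerical choices, the
simulator's generative assumptions, and the known limitations of the
package. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## The estimator

**Fractions.** For each sample, a strain's fraction is
`(count + pseudocount) / Σ(counts + pseudocount)` with a default
pseudocount of 0.5 (half a read), which keeps low-abundance strains finite
without materially moving well-covered ones. UPTAG and DNTAG libraries are
amplified and counted separately; under the default `mean_of_tags` policy
the two per-tag fraction vectors are averaged (each sums to 1, so the mean
does too). Per-tag estimates remain available (`uptag_only`, `dntag_only`)
for QC. Strains with fewer than `min_usc_count = 20` total tag counts in
the unsorted sample of any replicate are excluded from scoring: their
baseline fraction is too noisy to anchor the survival recurrence, and this
mirrors the attrition from a full deletion collection to the scoreable
subset seen in practice.

**Survival and generations.** The recurrences are applied exactly as
written in the package docstrings: `S_0 = 1` at the unsorted sample;
survival values above 1 (apparent enrichment beyond baseline, possible
through sampling noise or growth advantages) are retained as data and
flagged, never clipped — the fixed ceiling a = 1 lets the fit absorb them
as residuals. A zero mother-pool fraction makes survival undefined from
that round onward and the strain is flagged rather than silently patched.
The daughter-pool baseline for round 1 is the unsorted culture
(`Fy_0` = USC fraction, `Ty_0 = To_0`), since no round-0 daughter sample
exists. The age axis used for fitting is the cumulative sum of the
per-round generation estimates, which is the only monotone reading of the
model. The number of sorting rounds is arbitrary (default 4); fitting can
optionally be restricted to the first *k* rounds (`rounds_used`).

**Gompertz fit.** The model `S(G) = a·e^{−b·c^G}` with a ≡ 1 is fitted by
least squares over the transformed parameters `(log b, log(c−1))`, which
enforces b > 0, c > 1 without hard bounds. The starting point comes from
ordinary least squares on the linearization `ln(−ln S) = ln b + G·ln c`
over points with 0 < S < 1; if Levenberg–Marquardt fails from there, a
small grid of fallback starts is tried. The family's closure contains a
boundary of constant-survival curves (c → 1); its least-squares level is
the clipped mean of the data, and when that boundary beats every interior
optimum the fit is reported as `degenerate` with the boundary residual sum
of squares — such fits carry no median but remain usable wherever only an
RSS is needed. Noise-free points invert to the generating parameters to
better than 1e−6 relative error; the closed-form median
`ln(ln 2 / b)/ln c` agrees with numeric root-finding to 1e−9. When
`b ≥ ln 2` the fitted curve starts at or below 50% survival and the median
is reported as 0 with a left-censored flag.

**F-test.** Equality of a mutant's and the wild-type reference's survival
trends is tested with the extra-sum-of-squares F-test: one pooled fit with
shared (b, c) on the concatenated points against separate fits,
`F = ((RSS_pool − RSS_sep)/2)/(RSS_sep/(n − 4))`, p from F(2, n − 4).
Degenerate (boundary) fits contribute their boundary RSS; a residual sum
below numerical noise (1e−16·n) is treated as exactly zero so identical
noise-free curves give F = 0, p = 1. Under replication the headline test
pools each strain's (G, S) points across replicates against the pooled
wild-type points of all replicates — this avoids inventing a p-value
combination rule while using all the data; per-replicate medians are
reported alongside. Simulated calibration at five points per curve and
Gaussian noise σ = 0.02: type-I error ≈ 0.05 (within [0.03, 0.07] over
1000 draws), power ≈ 1.0 against a 10-fold smaller b.

**Scoring and classification.** The RLS score is the unweighted mean of
per-replicate fitted medians; a strain must fit successfully in every
replicate to be scored. Classification uses only the mean ± 1 sample-SD
rule over valid scores (long above, short below), as the screen defines
long/short lists; Benjamini–Hochberg q-values over the F-test p-values are
reported for reference but do not drive classification. Fewer than three
valid scores make the ±1 SD rule meaningless and everything is left
unclassified.

**Recovery rate.** The bead recovery rate r is user-supplied per round. A
helper (`estimate_recovery_rate`) can instead calibrate a single pooled r
by forcing the wild-type reference strains' mean fitted median to a
user-provided expected value (e.g. from a manual assay). This is explicitly
calibration against external knowledge, not inference from the count data.

## Barcode decoding

Reads are trimmed by locating the 5' adapter (substitution-only match, one
mismatch allowed by default — adapters are primer-derived and high
fidelity) and then the 3' adapter. The 3' search is anchored at the
expected tag end first so that barcodes whose suffix resembles the adapter
are not truncated, falling back to a scan that tolerates tag-length drift
from indels. Trimmed tags shorter than `tag_length − max_diff` cannot be
matched meaningfully and are counted malformed, as are reads with
non-ACGTN characters; N matches no base. Assignment computes the exact
Levenshtein distance to every library barcode of the read's tag class
(deterministic, order-independent) and accepts the unique minimizer at
distance ≤ 3 — the same "up to three differences" rule as heuristic
aligner-based decoding, but exhaustive and reproducible at 20-nt scale.
Ties are discarded as ambiguous rather than split fractionally, so counts
stay integral and conservative. Per sample,
assigned + unassigned + ambiguous + malformed equals the read total.

## The simulator

`simulate_pool` emulates the pooled experiment of the screen: a labeled
mother cohort per strain (multinomial split of `N0 = 1e7` starting cells),
four sorting rounds, `growth_gens = 4` generations of culture per round,
per-period mother survival drawn binomially with the conditional Gompertz
probability `S_i(G_end)/S_i(G_start)`, daughters accumulated as
`2^growth_gens − 1` per surviving mother (expected-value bookkeeping —
daughters only matter through the young-pool fractions), binomial bead
capture with `r_true = 0.6`, and multinomial sequencing counts at
`depth = 5e6` reads per sample (a simulator choice; real library depths
vary). True parameters are either given directly or sampled as median
lifespans uniform on 15–40 generations back-solved to b at fixed c = 1.15,
a typical range for a deletion collection. All draws flow from one seed;
an expectation mode replaces every draw by its expectation and emits exact
real-valued counts for deterministic fixtures. `simulate_reads` renders a
count table into FASTQ (tag flanked by the configured adapters, i.i.d.
per-base substitution noise) for end-to-end decoder tests.

**What the round trip shows — and a deliberate caveat.** In expectation
mode the estimated trajectories match their closed forms exactly:
`S_n = S(n·g)/S(0)` and `Gstep_n = log2(p_n · (2^g − 1))`. Two
consequences are worth understanding. First, the realized survival curve
`e^{−b(c^G−1)}` (a proper Gompertz survival with intercept 1) is *not* in
the fitted family `e^{−b·c^G}` with a ≡ 1; the intercept mismatch is tiny
pointwise (≤ e^b − 1) but, with only ~16 observed generations, it deflects
the extrapolated median of long-lived strains by up to ~13%. Second, the
generation estimate charges mortality against growth
(`log2 p_n` ≤ 0) and uses `2^g − 1` rather than `2^g`, compressing the age
axis by a few percent, most for short-lived strains. Both effects are
intrinsic to the method's equations, not to the simulator: estimated
medians are systematically a little low, while the *ranking* of strains is
preserved essentially perfectly (Spearman 1.0 in expectation mode, ≈ 0.95
at depth 5e6 with multinomial noise over 200 strains). Screens are read by
rank and by ±1 SD extremes, so this bias does not affect the screen's
calls; absolute medians should be compared against a calibrated reference,
not taken at face value. The simulator also omits real-data features —
strain-specific growth defects beyond the supplied per-strain growth
rates, label carry-over, PCR amplification bias, chimeric reads — so
passing tests demonstrate correctness of the computation and robustness to
sampling noise, not immunity to those artifacts.

## Morphology-trait association

The top and bottom `fraction = 0.10` of scored strains (ceiling of
fraction·n each; ties broken lexicographically for determinism; only
strains with valid fits are ranked) are compared per trait with a
two-sided Mann–Whitney U test: exact enumeration for groups of ≤ 20
without ties, normal approximation with tie correction otherwise.
Missing trait values are dropped pairwise, never imputed; traits with
fewer than three values in either group are skipped and listed. BH
adjustment runs over all analysed traits, significance is read at
q < 0.05. Under a permutation null the fraction of traits called at
q < 0.05 stays below 0.05 in expectation.

## Interfaces and determinism

All tabular I/O is one dialect — tab-separated, UTF-8, header row, '.'
decimal — with '#'-prefixed comment lines carrying the package version and
a hash of the analysis configuration (file paths excluded), which readers
skip. No timestamps are written, so a fixed seed makes every output
byte-identical across runs; the acceptance script verifies this for the
full simulate → decode → estimate → morph chain. Problem sizes used by the
default test suite and the acceptance script (200-strain recovery study,
1000-draw calibrations, 10,000-read decoder scan, a 16-strain end-to-end
chain at depth 8000) were chosen as the smallest scales at which each
property is statistically unambiguous.

## Known limitations

- Absolute medians inherit the downward bias discussed above; the screen's
  deliverable is the ranking and the extreme lists.
- The recovery rate r is taken as known (or externally calibrated); errors
  in r propagate multiplicatively as `(r_true/r_supplied)^n` in survival.
- No quality-score-aware matching, paired-end merging, or alignment-based
  decoding; no Kaplan–Meier/Cox machinery; no cross-replicate
  meta-analytic p-value combination.
- The ±1 SD classification is distribution-dependent: heavy-tailed score
  distributions shift both thresholds.
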