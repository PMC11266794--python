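# Methods

## Lineage-diagram division density

The diagram dialect assumed is the conventional one: vertical cell lines of
width 2 px, horizontal division bars of width > 2 px and height 2 px, and
'X' death markers composed of five elements each at most 2 px in height and
width. Parsing proceeds by (1) binarizing (Otsu threshold by default, with
a manual override; a pixel is ink iff its intensity is at or below the
threshold), (2) deleting narrow elements, (3) counting maximal horizontal
ink runs per row. A 2 px-tall bar therefore contributes to exactly two
consecutive rows; this is deliberate and matches the paired peak rows seen
at division bursts. Rows are 0-based throughout.

Two deletion rules are provided. The default erases every 8-connected
component whose bounding-box width is ≤ 2 px. On real diagrams the
vertical lines touch the bars, which makes whole subtrees single
components; the `row_runs` method handles this by instead deleting, within
each row independently, every horizontal ink run of length ≤ 2 px — a
vertical line crosses any row as a 2-px run and disappears, while bar runs
survive. The synthetic renderer keeps connectors and markers 8-disconnected
from the bars (1-px clearance; death markers as five disjoint dots), so on
fixtures both rules give identical, exact results; on scanned diagrams
`row_runs` is the recommended setting.

Row-to-hour calibration is the exact two-point line through two anchor
(row, hour) pairs; with the seam-cell anchors (448.5, 16 h) and
(684.5, 25 h) the slope is 9/236 ≈ 0.0381 h/px and row 1034 maps to
≈ 38.33 h. Anchor rows are given as the midpoint of a two-row peak to avoid
a half-row bias.

Smoothing uses an inverse-distance kernel on a window of half-width *w*
(default 10 rows, configurable, as is the exponent): k₀ = 1,
k_j = 1/|j|^α for j ≠ 0, α = 1 by default. Normalization is per *source*
row: each count V_i is distributed over its in-range neighbours with
weights k_j / Σ_{j in range} k_j. For a symmetric kernel this choice makes
Σ D_i = Σ V_i hold exactly at every boundary, which a per-target
normalizer does not; it also reproduces the expected single-spike response
(a lone count of 4 at w = 2 spreads as 0.5, 1, 1, 1, 0.5). Interior
constants are preserved. w = 0 is the identity.

## Percent-of-stage activity profiles

Stage boundaries are inputs: durations are taken from dedicated staging,
not re-inferred from locomotion (a naive activity-minimum detector is
included for convenience but is explicitly not a staging method). Cropping
restricts samples to [entry, exit] and re-origins time at entry.
Resampling evaluates the curve at t = D_j · i/100 on a 1 % grid (step
configurable) by linear interpolation, clamping to the nearest sample
beyond the endpoints; a single-sample stage is an error. Averaging is the
pointwise arithmetic mean with SD and SEM, tracking n per grid point and
excluding NaNs. The profile is exactly invariant to rescaling an
individual's time axis, which is the point of the normalization.

Whether to average on the native sampling grid or a fixed percent grid is
genuinely open; the fixed 1 % grid was chosen because it makes cohorts with
different sampling rates directly comparable and the linear-interpolation
error at 10 s sampling is negligible against measurement noise.

## Lethargus calling

Observations are 10 s pumping checks every `sampling_interval` (default
20 min) on a fixed grid; episodes are therefore interval-censored and no
smoothing between observations is attempted. Entry is the first
non-pumping observation. Bouts are maximal runs of non-pumping
observations before the L4 onset (first observation flagged as pumping
with an invaginated vulva) or, failing that, the window end. Duration is
the total count of non-pumping observations × interval, summed over bouts;
the per-longest-bout variant is reported alongside
(`longest_bout_min`) because summing versus taking the final bout is
ambiguous for fragmented animals. Fragmented means ≥ 2 bouts separated by
resumed pumping before L4. A worm with no quiescent observation, or
without L4 in the window, is censored — reported, never dropped; censored
individuals stay in the denominators of stage-transition fractions only.
Without an L4 column, a final pumping stretch reaching the window end
after quiescence is treated as presumed L4 resumption; otherwise the call
is censored.

The feeding fraction is pooled — pumping observations over all
observations in the window across every animal — not a per-animal average,
so heavily observed animals weigh more; this matches the episode-count
definition. Both the relative (ratio − 1) and absolute (percentage-point)
group differences are reported by the acceptance script since either
reading is defensible.

Discretization has one visible consequence worth flagging: a called
duration is a multiple of the interval and rounds the true episode up or
down by less than one interval, so the fraction of episodes *called*
longer than 100 min (≥ 120 min on a 20-min grid) exceeds the underlying
continuous-tail mass whenever much probability sits just below the
threshold. The simulators' ground-truth tables carry both the drawn and
the discretized values so tests can separate the two effects.

Group comparisons default to Welch's t (continuous) and Fisher's exact
test (binary); the method used is recorded in the output and degenerate
inputs (zero variance everywhere) are flagged rather than silently given a
p-value.

## Morphometrics

Volume is the exact cylinder formula V = π·L·(W/2)² (µm³); length is a
midline measurement (a polyline-length helper sums segment lengths for
segmented-line midlines), width is measured at the vulva or ~2/3 body
length and recorded as metadata, not enforced. Isomorphy is operationalized
as: no shared timepoint shows a significant group difference in the
width/length ratio after Holm adjustment across timepoints. Divergence
onset is the earliest timepoint whose volume difference is significant
(Welch t, Holm-adjusted) *and remains significant at every later measured
timepoint* — "became evident" needs an operational rule, and requiring
sustained significance makes one-timepoint flukes non-onsets; the rule and
alpha (default 0.05) are configurable. When no timepoint qualifies, the
result is an explicit null, not an error.

## Synthetic generators

The generators define the conditions under which the pipeline is
validated; they are ground-truth machines, not models of worm biology.

- **Lineage renderer**: inverts the parsing dialect with known per-row bar
  counts; random specs reject layouts whose bars would touch or whose
  division rows overlap. Connectors and markers are decorative and placed
  only where they remain 8-disconnected from bars.
- **Activity cohorts**: each individual draws its stage duration from
  Normal(8 h, cv 0.15) (redrawn while non-positive) and follows a shared
  template of percent completion plus iid Gaussian noise (default SD 0.1
  displacement units), sampled every 0.01 h (36 s). Real traces have
  autocorrelated noise and individual-specific behavioral baselines; a
  passing template-recovery test shows the resampling/averaging machinery
  is unbiased, not that real cohorts are this clean.
- **Pumping rasters**: onset ~ Normal(34 h, 1 h), left-truncated at the
  32 h window start, placing the median L3 exit at 34 h; duration is a
  mixture of a truncated Normal(85, 20) on (0, 100] min and, with weight
  `long_weight` (0.20 control), 100 min + Exponential(45 min), so the
  long-episode (> 100 min) mass equals the weight exactly. Fragmentation
  (probability 0.25 control) inserts one interior pumping observation while
  extending the quiescent stretch one grid step, keeping total quiescence —
  and hence the called duration — within one interval of the drawn value.
  No distributional forms are established for these quantities; the
  parameters are free knobs chosen to give a realistic 1–2 h lethargus with
  a heavy tail, and the comparison group (lower tail weight, lower
  fragmentation, onset one interval later) encodes the qualitative
  direction of a pheromone-exposed cohort, not an estimate of it.
- **Growth tables**: deterministic exponential length growth at 1.6 %/h
  from 600 µm at 30 h, width = 0.06 × length (isomorphic by construction),
  with independent multiplicative measurement noise (cv 0.035 — manual
  segmented-line measurement precision; the generator deliberately omits
  inter-individual size dispersion, which in real cohorts is larger and
  would demand bigger samples). At this growth rate a 2 h advance yields a
  ~10 % volume difference. `divergence_time_h` starts the advance at a
  chosen age; `None` shifts the whole trajectory.

All generators are bit-reproducible under a fixed seed and return their
ground truth alongside the data.

## Numerical and interface choices

Hours as floats everywhere; minutes only for episode durations. CSVs are
comma-separated, UTF-8, headered, '.' decimal; times written at 6 decimals
(the fixed-interval check tolerates 1e-4 h of rounding accordingly). Every
CLI command writes a JSON run log with parameters, seed and SHA-256 input
hashes. Problem sizes in the test suite and acceptance script (100
diagrams, 1000 kernel vectors, 100 cohorts of n = 50, 200 rasters, 100
growth cohorts of n = 30/group) were chosen as the smallest sizes at which
the binomial/Monte-Carlo tolerances in use are meaningful.

## Limitations

No OCR or tree-topology reconstruction from diagrams; no re-inference of
stage boundaries from locomotion; no video analysis (pumping arrives
pre-scored); no worm segmentation from micrographs; no non-cylindrical
volume model; statistics beyond two-group comparisons (and their Holm
adjustment across timepoints) are out of scope.
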