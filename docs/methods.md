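# Methods

## Data model and scope

The analysis starts from manual annotations, not audio. A *Raven Pro
selection table* (tab-delimited; columns `Selection`, `Begin Time (s)`,
`End Time (s)`, `Low Freq (Hz)`, `High Freq (Hz)`, optionally an SNR column)
supplies one row per annotated sound element. Times are absolute seconds
from the start of the recording; no frame or sample indexing is used
anywhere. Audio-level detection, spectrogram computation and vessel-traffic
extraction from AIS services are out of scope: recording-level covariates
(site, date, hour, water temperature, acoustic richness, per-category vessel
densities) enter through a plain CSV.

Parsing is strict by design: cells are converted explicitly so that a
malformed number fails with its row number, and decimal-comma exports are
rejected rather than coerced — annotation exports in the wild vary by
locale, and an explicit failure beats silent corruption.

## Sequence building

A *call sequence* is a temporally ordered run of at least three elements
from one recording. Silence is measured from the offset of one element to
the onset of the next (that is literally the silence between sounds), and a
sequence terminates when that gap reaches the threshold — 10 s by convention
for long recordings. For the 1-minute-excerpt protocol the same rule is
applied with an infinite threshold, so each excerpt yields one sequence;
under that protocol excerpts are taken from non-consecutive files precisely
so each can be treated as a different caller. Runs shorter than three
elements are discarded but logged: the pipeline's discard log is data
(`discards.csv`), and every input element ends up either in exactly one
summarized sequence or in that log.

Overlapping annotations raise an error instead of being merged: within a
single-caller sequence an overlap indicates an annotation mistake.

Individual attribution in long recordings follows the stationary-fish
argument: a non-moving caller keeps a near-constant signal-to-noise ratio,
so sequences whose median element SNRs agree within a tolerance are chained
(transitively, in time order) to one presumed individual. The tolerance
defaults to 1.0 dB; that number is a documented package choice, since the
underlying field judgement ("same SNR") was visual and unquantified. Mixed
presence/absence of SNR within one recording is refused as ambiguous
evidence rather than guessed at.

## Rhythm statistics

For onsets $t_1 < \dots < t_n$, the IOIs are the successive differences and
the CV is the sample ($n-1$) SD of the IOIs over their mean — the $n-1$ form
because per-sequence $n$ is small (typically ~20 intervals).

The *best-fitting isochronous beat* minimizes the mean normalized onset
deviation: each onset's circular distance to the nearest point of the grid
$\{\varphi + k/f\}$, divided by half the period (the largest achievable
distance), averaged over onsets. The mean, not the maximum, is reported.

Two numerical decisions matter:

* **Search band.** Any grid at an integer multiple of the true frequency
  also attains zero deviation, so an unconstrained search is ill-posed. The
  candidate grid is anchored at $f_0 = 1/\mathrm{median}(\mathrm{IOI})$
  (robust to an occasional missed or doubled element) and spans
  $\pm 50\%$ of $f_0$ in steps of `resolution_hz` (default 1 mHz, so a
  noiseless train is recovered exactly: $f_0$ itself is on the grid). Ties
  within $10^{-9}$ break toward $f_0$, then toward the lower frequency.
  Beats are never rounded internally.
* **Phase optimization.** For a fixed frequency, the mean circular distance
  as a function of the phase is piecewise linear with minima attained at the
  onset residuals (the circular-median property of the wrapped-L1 loss).
  The phase is therefore optimized *exactly* by evaluating the $n$ candidate
  residual phases — deterministic, $O(n^2)$ per frequency, and verified
  against an exhaustive dense-phase brute force in the tests. This replaces
  approximate schemes (circular-mean initialization plus local refinement)
  by a solution that provably attains the optimum.

Degenerate inputs (fewer than 3 onsets, non-increasing onsets, all onsets
effectively coincident) raise errors rather than returning sentinel values.

### Known behaviour of the beat estimator

With IOI-level jitter the onset train is a random walk around its generating
grid: onset $t_k$ drifts with SD $\sigma\sqrt{k}$, where $\sigma$ is the
IOI jitter SD. Two consequences, both verified by simulation and reported
here because they bound what parameter recovery can show:

* At the default study conditions (jitter CV 0.18, ~21 elements) the
  deviation-minimizing frequency has a per-sequence noise SD of about
  0.03 Hz around the generating beat, and in roughly 5% of sequences the
  *global* minimum of the deviation sits at a nearby rational multiple of
  the generating beat (ratios ~1.15–1.45). This is not an optimizer defect:
  at those sequences the generating beat genuinely fits worse than the
  locked frequency (checked with exact phase optimization at the true beat).
  Truth-vs-estimate correlation is therefore ~0.93 rather than arbitrarily
  close to 1, the estimate is nonetheless unbiased to within ±0.005 Hz over
  500 sequences, and the recovered between-sequence SD is inflated by a few
  percent (e.g. 0.080 → ~0.086 Hz under the pooled preset).
* Estimates are exactly translation invariant and scale covariant
  (stretching time by $c$ divides the beat by $c$ at matched resolution);
  both are tested as exact identities.

No isochrony classification threshold is imposed; the pipeline reports CV,
beat and deviation and leaves labels to the analyst. Fourier-spectrum beat
extraction and recurrence analyses are intentionally not implemented.

## Group statistics

Outlier screening is a single dataset-wide pass removing beats more than
`outlier_k` (default 3) sample SDs from the mean, computed once over the
full vector — no per-site screening, no iteration. Site contrasts are a
one-way ANOVA plus all pairwise two-sided Welch t-tests with Bonferroni
adjustment and Cohen's d (absolute mean difference over the pooled,
$n-1$-weighted SD). Welch's unequal-variance form is used for *every*
pairwise contrast: the sites were recorded with different hardware in
different years, so equal variances cannot be assumed. Welch t and the
ANOVA delegate to `scipy.stats`; both are cross-checked in the tests
against a permutation oracle, and the effect size and Bonferroni rules
against independent implementations.

`model_table.csv` joins per-sequence rhythm statistics with recording
covariates — the ready input for a downstream smooth-term regression (GAM)
of beat on season, temperature, acoustic richness and vessel densities.
That modeling step itself is out of scope.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the study's conditions:

| parameter | default | rationale |
|---|---|---|
| beat distribution, Venice preset | Normal(0.46, 0.10) Hz | reported Venice site moments |
| beat distribution, other presets | Normal(0.36, 0.08) Hz | pooled non-Venice moments; site-resolved values are not published, so all four non-Venice presets share them |
| IOI jitter CV | 0.18 | reported mean within-sequence CV |
| sequences per site | 20 | the 1-minute-excerpt protocol (20 excerpts per dataset) |
| elements per sequence | round(Normal(21, 2)), floor 3 | ~21 elements at 0.36 Hz span ~56 s, filling a 1-minute excerpt |
| element duration | 0.2 s | short pulsatile element; must stay below $T(1-3\,\mathrm{cv})$ so elements never overlap |
| element band | 100–500 Hz | nominal low-frequency band of the calls |

Jitter is injected on the IOIs (independent Normal$(T, \mathrm{cv}\,T)$
draws), not on onsets about a fixed grid: IOI-level noise is exactly what
the CV statistic measures, so the generator's jitter CV is the quantity the
pipeline should recover. Grid-anchored jitter would imply a CV of about
$\sqrt2$ times the onset jitter and is deliberately not the default. Normal
draws are resampled (true truncation, not clipping) below $0.1\,T$ for IOIs
and 0.05 Hz for beats; at default parameters these bounds sit > 4 SDs out,
so the truncation bias is negligible (< 10⁻³ relative). Random-mode control
sequences use exponential IOIs (CV → 1) shifted by the element duration.

Randomness is one explicit seed per dataset; per-sequence substreams derive
from (seed, CRC32(site name), sequence index), so adding or reordering sites
leaves every other sequence bit-identical, and identical configs produce
byte-identical output files.

What the generator does **not** emulate: overlapping choristers, missed or
spurious annotations, SNR drift of moving fish, amplitude information, or
any acoustic propagation. Recovery tests therefore validate the estimators
under the model's own assumptions; they do not certify performance on dense
chorus recordings, where segmentation and attribution are the hard part.

## Validation design

* Analytic identities (5 Hz ↔ 200 ms; translation/scale invariances;
  segmentation idempotence) are asserted exactly.
* The beat search is compared against an independent brute force over a 10×
  finer frequency grid with a dense phase grid (coarse-to-dense phase
  passes, with the discretization error bound $1/P$ guaranteeing no
  candidate is lost) on 200 generated sequences of ≤ 12 onsets.
* Parameter recovery runs at the study conditions: 80 pooled-preset
  sequences through the full pipeline (mean and SD of estimated beats),
  replicate Venice datasets (grand mean), and 500 sequences for the CV.
  Sizes were chosen so each check completes in seconds to a couple of
  minutes at desk scale while keeping Monte-Carlo error well inside the
  stated tolerances.
* Welch's test is calibrated under the null (rejection rate at
  $\alpha = 0.05$ over 1000 replicates) and checked against a permutation
  oracle on small groups.

## Limitations

* SNR-based individual attribution is a heuristic proxy; it cannot separate
  two stationary callers that happen to share an SNR, and the 1.0 dB
  tolerance is a convention, not an estimate.
* The beat estimator's rational-lock behaviour (above) means single-sequence
  beats carry ~0.03 Hz noise at default jitter; site-level conclusions
  should rest on per-site samples, as in the pipeline's aggregates.
* The between-site tests treat sequences as independent; under the 1-minute
  protocol that holds by design, but for multi-sequence long recordings the
  model table retains `individual_id` so downstream models can account for
  repeated measures.
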