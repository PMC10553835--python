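# Methods

## The dwell/exit estimator

An asynchronous, homeostatic cell population observed at an arbitrary
instant is a stationary renewal process: the probability of finding a cell
in a given cycle phase is proportional to that phase's duration
(length-biased sampling), and the elapsed time within the phase is uniform.
For a pooled set of cells followed through a short imaging window, the
average phase duration is estimated as

    T_phase = (summed observed minutes in the phase) / (observed exits from the phase).

The identity behind this is Little's law: in steady state, occupancy equals
throughput times dwell time. The estimator is consistent provided

* censored stays (window end, permanent dropout) contribute their observed
  minutes but no exit;
* cells **entering** the phase during the window are included. Omitting
  them leaves only residual dwell times — uniformly distributed fractions
  of the full duration — against a full complement of exits, which biases
  the estimate low by roughly a factor of two for phases shorter than the
  window (a regression test asserts this bias);
* the tracked pool is stationary: entries into each phase balance exits.
  See "Homeostasis in the simulator" below for why this matters.

Exits are never observable for S-phase (see reporter model), so S is
inferred from the fixed-sample S fraction `fS` (S as a fraction of the whole
cycle), pooled across germaria weighted by cell count:

    T_S = (T_G1 + T_G2 + T_M) * fS / (1 - fS),

monotone in `fS` and zero at `fS = 0`.

### Frame classification and interval bookkeeping

Each frame maps to a phase: a mitotic flag → M; GFP+RFP → G2; GFP-only →
G1; RFP-only or colorless → S. Runs of equal labels become intervals. A
transition is placed at the **midpoint** between the bounding frames, which
is unbiased when the true transition time is uniform within the frame gap;
the first and last frames bound the censored ends. Whether to count dwell
to the transition frame or the midpoint is a genuine convention choice —
both appear in practice — and only affects simulation-path results here,
because the desk-scale results take published pooled totals as direct
inputs. A label sequence violating the cyclic order G1→S→G2→M→G1
invalidates the whole track; such tracks are excluded from all summaries
with a logged count.

Colorless frames are S by default. A track that *starts* colorless carries
an ambiguity flag and its initial S interval is excluded from S dwell sums
(the history of a cell first seen colorless is unknown); the same track
still contributes fully to G1/G2/M sums. Germaria in which no G1 or G2
exit was observed are excluded by default (they typically show minimal cell
movement overall); note this selects toward active germaria.

Single-frame mitoses are handled by the same midpoint rule, so with a
20-min frame interval the M estimate is resolution-limited to roughly the
frame interval; this matches how mitosis can be scored in practice (one
frame of mitotic morphology).

### Uncertainty

The germarium is the independent sampling unit, so the bootstrap resamples
germaria with replacement (default 2.5/97.5 percentiles). Replicates with
zero pooled exits are recorded and skipped. A coverage simulation (20
synthetic experiments of 15 germaria × 40 cells) checks that the nominal
95 % interval covers the true G2 duration in ≥ 90 % of experiments.

## Reporter model

FUCCI couples a degron-linked GFP (degraded during S) and RFP (degraded at
mitotic exit and through G1): G1 cells are GFP-only, G2/M cells GFP+RFP.
Newly synthesized RFP takes time to reach detectability, so early S-phase
cells are colorless; the default onset lag is 114 min (the observed average
interval between GFP loss and RFP appearance). GFP reappears quickly at S
exit, so the default GFP lag is 0. In fixed samples a cell is EdU-positive
iff any part of the pulse (default 60 min) overlapped S-phase; colorless
cells are countable by DAPI when EdU is omitted, and the I/O layer enforces
that every cell carries at least one of the two labels.

Because a 1-h pulse also catches cells that left S within the last hour,
the EdU index exceeds the instantaneous S fraction (by ≈ pulse/cycle); both
quantities are exposed so the near-equality seen between them in slow
tissue contexts can be examined rather than assumed.

## Synthetic-data generator

`simulate_population` draws the steady state directly: phase with
probability proportional to (the cell's own) phase durations, elapsed time
uniform. Per-cell duration variability is modeled as independent gamma
draws per phase with a shared coefficient of variation `cv` (default 0,
reproducing deterministic worked examples); within-layer dispersion is not
an empirically fitted quantity, so `cv` is a simulation knob only.
Randomness flows through one named stream per germarium, so adding germaria
never perturbs existing ones; the same seed yields bit-identical output.

`simulate_imaging` samples each cell on a regular frame grid (defaults:
150-min window ≈ the typical short live session, 20-min frame interval)
strictly inside `[0, window)`. Dropout (permanent departure from the imaged
z-range) is a per-frame Bernoulli event, right-censoring the track.
Mitosis is detected as an *event*, not a point sample: a frame is flagged
mitotic if the cell is in M at the frame or if an M phase began and
completed since the previous frame. Mitotic morphology and the appearance
of two daughters make a division unambiguous in real imaging even when no
frame happens to fall inside the ~17-min M phase; without this rule, a
20-min frame interval would render ~15 % of divisions as illegal G2→G1
jumps, and excluding those tracks would preferentially discard
transition-rich tracks and bias durations high.

### Homeostasis in the simulator

At each M exit the cell divides into two G1 daughters with fresh duration
draws. By default the simulated stem pool is homeostatic: one daughter
continues the parent's track as a cycling stem cell, while the other
differentiates — it appears in the field as a new G1 track at the first
frame after division and then leaves. This mirrors a tissue whose stem-cell
count is constant because every division is, on average, balanced by one
differentiation event, and it keeps the tracked pool stationary — the
regime in which the dwell/exit estimator is consistent. Retaining both
daughters as cycling stem cells (`retain_both_daughters=True`) makes the
tracked pool grow exponentially; G1 entries then outpace exits within a
short window and the G1 estimate inflates by roughly +18 % at a 150-min
window (G2 is untouched because a newborn cannot reach G2 within 150 min).
That regime is available for studying the effect but is not the default.

### What the generator does and does not emulate

It reproduces length-biased sampling, reporter lags, frame discretization,
censoring by window end and dropout, division, EdU pulse logic, and
two-fold label dilution with heterogeneous initial labeling (multiplicative
log-normal noise of chosen CV, unit mean). It has no spatial geometry, no
cell movement between layers, no pixel-level signal model, and no
signaling-dependent regulation; phase durations are exchangeable across
cells apart from the gamma `cv`. Passing tests therefore demonstrate the
correctness of the estimators under the stated sampling model, not
robustness to segmentation error, tracking mistakes, spatially varying
cycling, or phase-correlated differentiation.

## Snapshot statistics

Phase fractions carry the standard error of a proportion
`sqrt(p(1-p)/n)`. Two proportions are compared with the "N−1" chi-squared
test: the classical Pearson 2×2 statistic multiplied by `(N−1)/N`, referred
to χ²(1); the conventional significance threshold is 0.05 and no
multiple-testing correction is applied. Degenerate margins (both groups all
success or all failure) return statistic 0, p = 1.

EdU indices from different experiments are placed on a common scale by
multiplying each stem-cell-layer index by (global control layer-1 index)/
(that experiment's control layer-1 index); escort-cell indices are never
normalized (they are zero in controls). For comparing a genotype's
per-layer EdU *pattern* to the control pattern, the genotype's overall
index (per-layer indices averaged with the normal layer-occupancy weights)
is redistributed across layers in proportion to the control indices. Two
readings of that redistribution are possible; the default (`normalized`)
rescales so the weighted average of the expected indices reproduces the
overall index, which keeps observed and expected on the same scale, while
the `literal` reading (direct multiplication by the control index) is
available behind a flag. A chi-squared statistic compares observed and
expected per layer.

## Tissue flux calculus

With `n` stem cells of cycle time `T` and a budding period `P` (default
720 min), production is `n·P/T` cells per cycle; `required_cycle_time` is
its exact inverse. The required layer-2:layer-1 cycle ratio for balanced
output is `(1/ec_to_fc_ratio)·n2/n1` (defaults: 4 × 6/8 = 3.0). The flux
report compares per-layer production against consumption (FC output for
layer 1, EC output at `ec_to_fc_ratio` times FC output for layer 2) and
interprets the residual as net inter-layer flux; production = consumption +
net flux holds by construction and is retained unrounded alongside the
reported one-decimal values. Layer-3 production is reported separately and
never folded into the layer-2 balance, because layer-3 cells divide much
more slowly and their output is unquantified. Differentiation loss per stem
cell per cycle is `F = f·p` with the wild-type baseline 0.307
(= 0.48 × 0.64) kept as a named, overridable constant.

## Label dilution

Raw intensities are normalized per germarium to the mean of its layer-3
cells (germaria lacking layer-3 cells are excluded with a warning;
normalization is idempotent). Pre-chase mean relative intensities differ by
layer (≈ 1 / 0.91 / 0.69 for layers 3/2/1), so the four-fold dilution
threshold is applied against per-layer pre-chase baselines by default — the
published per-layer counts imply layer-specific starting points — with a
single global baseline available instead. Division counts
`log2(baseline/observed)`, clipped at zero, are labeled approximate in all
outputs: initial labeling is uneven between equivalent cells and cells can
change layers during a chase, which caps the reliability of per-cell
inference.

## Numerical and reporting conventions

Durations are reported to the nearest minute, cycle ratios and cells/cycle
to one decimal, percentages to the printed precision of the matching
published value; unrounded values are always retained in JSON results.
Times are minutes from the start of imaging; CSVs are UTF-8 with "."
decimals and 0/1 booleans. Validation always fails loudly with the
offending column or cell named — nothing is silently coerced.

## Problem sizes

The test suite and acceptance script use desk-scale arithmetic for all
published-input computations, simulations of 400–3000 cells across 4–15
germaria with 150–300-min windows at 20-min frames for estimator
consistency, 8000-cell snapshots for fraction checks, 1000 random 2×2
tables for the N−1 test property, and 500–1000-cell dilution series. These
sizes give binomial/bootstrap errors comfortably inside the asserted
tolerances; the full suite runs in a few seconds.

## Known limitations

* The M-phase duration estimate is resolution-limited by the frame
  interval.
* The dwell/exit estimator assumes a stationary pool; applied to a growing
  or shrinking population it inherits the biases described above.
* S-phase duration is only as good as the snapshot S fraction fed to it and
  assumes fixed and live samples describe the same population.
* Bootstrap intervals with few germaria (< ~10) can undercover.
* The expected-EdU construction involves an interpretive choice (see
  above); both readings are implemented, and conclusions that depend on
  the choice should be checked under both.
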