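# Methods

## Kinetic model of end synapsis

Each surface-tethered DNA substrate is modeled as a three-state
continuous-time Markov chain:

- **LOW** — unpaired ends *or* the long-range complex. Both place the
  dyes outside FRET range, so they are spectroscopically one state and
  are deliberately not distinguished kinetically.
- **HIGH** — the short-range (SR) synaptic complex (E ≈ 0.5).
- **LIGATED** — the covalently joined product; spectroscopically
  identical to HIGH and absorbing.

Transitions are LOW → HIGH at rate `k_form` (s⁻¹) and HIGH → LOW at
`k_dissolve` (s⁻¹). Each formation event is independently flagged
absorbing with probability `p_ligate`, in which case the molecule
enters LIGATED directly. Ligation is a Bernoulli flag per event rather
than a separate HIGH → LIGATED rate because the assay observes only
that some high-FRET excursions persist to the end of the observation
window and others reverse; the data do not resolve a ligation rate, so
the model does not posit one.

State paths are simulated exactly (Gillespie): exponential waiting
times with the appropriate rate, thinned by the ligation coin flip.
Tests verify the first LOW dwell against its analytic mean, both dwell
families against exponential distributions by Kolmogorov–Smirnov, and
the ligated fraction against its binomial law.

### Defaults and what they mean

| parameter | default | unit | rationale |
|---|---|---|---|
| `k_form` | 1.7×10⁻³ | s⁻¹ | wild-type-scale synapsis rate |
| `k_dissolve` | 2.0×10⁻³ | s⁻¹ | ~500 s mean SR lifetime: long enough that the 5-frame detection rule misses <3% of excursions, short enough that reversible events are common |
| `p_ligate` | 0.5 | — | both phenotypes (reversal, persistence) well represented |
| `h_bleach_donor` | 5×10⁻⁴ | s⁻¹ illuminated | ~30% of molecules lose a dye within one 15-min window, typical of Cy3/Cy5 TIRF with oxygen scavenging |
| `h_bleach_acceptor` | 1×10⁻³ | s⁻¹ illuminated | Cy5 bleaches faster than Cy3 |
| `E_low` / `E_high` | 0.05 / 0.5 | — | non-zero baseline reproduces the width of the zero-FRET histogram peak; 0.5 is the apparent SR efficiency |
| `I_total` | 1000 | counts | arbitrary camera scale |
| `I_direct` | 600 | counts | direct acceptor excitation level |
| `noise_sd` | 50 (= 0.05·I_total) | counts | per-channel additive Gaussian noise; gives E-noise ≈ 0.035, i.e. the 0.25 threshold sits ≈ 7σ from both states |
| `bg_donor`, `bg_acceptor` | 100 | counts | constant channel backgrounds |

Photobleaching hazards act on *illuminated* time: the wall-clock bleach
time is the exponential draw divided by the duty factor
(exposure/frame_period, 0.5 by default), since the dyes accumulate
photodamage only while a laser is on. FRET-sensitized acceptor
bleaching under donor excitation is not modeled separately; it is
absorbed into the single effective acceptor hazard.

## Acquisition model

Defaults mirror the experimental scheme: 1 s exposures every 2 s, a
(4, 1) excitation cycle (four donor frames, one direct-acceptor frame),
15-min fields of view, three FOVs imaged back to back per replicate
(0–15, 15–30, 30–45 min), three replicates. Synapsis kinetics run from
extract addition (t = 0), so molecules in later windows may already be
synapsed or ligated at first illumination — the simulation reproduces
the experiment's time-dependent growth of the high-FRET population
across windows. The bleach clock, in contrast, starts only when a
molecule's own FOV is first illuminated.

Donor-excitation frames split `I_total` between the channels according
to the FRET efficiency; an exposure window straddling a state change or
a bleach uses the time-weighted mean emission (with 1 s exposures
against multi-minute dwells this is a second-order choice, but it must
be fixed for frame-exact tests). After donor bleach both channels fall
to background; after acceptor bleach, direct-excitation signal
disappears and all donor-excitation emission returns to the donor
channel.

## Movie rendering and localization

Movie mode renders each molecule as a pixel-integrated Gaussian PSF
(default σ = 1.1 px): donor intensity at the molecule's position in the
donor half-chip (columns [0, W/2)), acceptor intensity at the
affine-mapped position in the acceptor half. Trajectories are emitted
noiseless and background-free for rendering; all movie-mode noise
enters at the camera model (uniform background, Poisson shot noise,
Gaussian read noise, 16-bit quantization). At the defaults the peak
pixel sits ≈ 10× above the background noise (SNR ≈ 10).

Localization detects local maxima above median + 5·MAD on a lightly
smoothed average of the first donor-excitation frames, refines centers
by background-subtracted center of mass, and drops *both* members of
any spot pair closer than the minimum separation (default 4 px),
recording them for the multi-peak QC rule. Donor and acceptor spots are
paired by mutual nearest neighbor after mapping; donor spots without a
detected acceptor partner are retained with the mapped coordinate,
because the acceptor channel is legitimately dark before any FRET.
Intensities are ROI sums (5×5 px default) minus the median of a
surrounding ring times the ROI area, which cancels locally uniform
background exactly. The channel map is supplied by configuration (the
simulation knows it) or fit from fiducial pairs by least squares; no
bead-registration workflow is implemented. Coordinates are 0-based
pixel centers local to each half-chip.

A 5×5 ROI captures ≈ 95% of a σ = 1.1 px PSF; this common-mode loss
cancels in the FRET ratio and therefore in every downstream statistic.
Per-frame extraction noise at SNR 10 is ≈ 10% relative; fidelity is
asserted on the systematic (mean) agreement, and the end-to-end check
is that movie-mode and table-mode analyses of the same molecules give
statistically indistinguishable rates.

## Photobleach truncation and exclusion

Bleach steps are found by binary segmentation on the mean with an
L2 cost: a penalty-free split tree is built greedily (depth ≤ 4,
minimum segment 3 samples), then pruned by requiring each split's
squared-error gain to exceed `penalty × σ̂²` (default penalty 25, σ̂
from the MAD of first differences). Because the tree is independent of
the penalty, accepted change-point sets are nested, so increasing the
penalty can never move the truncation earlier — a property under test.
The acceptor bleach is the first accepted downward step in the
direct-excitation acceptor series whose post-step mean reaches
background (within 3σ̂); the donor bleach likewise in the
donor-excitation *total* intensity (I_D + I_A), which FRET preserves.
Trajectories are truncated before the earlier step (the bleach frame
itself is never analyzed); more than one downward step in a single
channel flags multistep bleaching.

Exclusion rules and defaults (the experimental criteria are stated
qualitatively; thresholds were fixed to pass clean simulated traces and
fail constructed violations):

- `low_snr`: mean background-subtracted total intensity / σ̂ < 3;
- `multistep_bleach`: >1 downward step in one channel;
- `non_fret_fluctuation`: coefficient of variation of the
  donor-excitation total intensity after truncation > 0.35 — FRET
  moves signal between channels but conserves the sum, so total-
  intensity swings are not FRET. Note a clean 2× step at mid-trace has
  CV = 1/3 and narrowly passes this threshold; the constructed test
  fixture uses a 3× swing;
- `multi_peak`: a competing emitter within the ROI (from localization);
- `too_short`: fewer than 10 donor-excitation or 2 direct-excitation
  frames.

On bleach-free simulations at the defaults the exclusion rate is < 5%.

## FRET, events, and the formation rate

Apparent efficiency is E = (I_A − bg_A) / ((I_A − bg_A) + (I_D − bg_D))
on donor-excitation frames, with γ = 1 (no detection-efficiency
correction; the assay's reported E ≈ 0.5 is an apparent, uncorrected
value). Non-positive denominators mask the frame; efficiencies outside
the sanity bound [−0.2, 1.2] flag the molecule. Acceptor presence is
read from the direct-excitation frames and held forward to the
interleaved donor frames.

An SR formation event is a maximal run of ≥ m (default 5) consecutive
donor-excitation frames with E > E_T (default 0.25). The event starts
at the first frame of the run, ends at the first frame back at or below
threshold, and is censored — and scored as ligated — if the run reaches
the truncation point. The original analysis applied this rule as a
manual guideline; fixing it as the literal criterion makes results
reproducible, at the cost of known, quantified deviations (excursions
shorter than ~12 s are missed; at the default `k_dissolve` this is a
<3% undercount).

A run already in progress at the first analyzed frame is flagged
`preformed` and excluded from the event count: no formation transition
was observed, and molecules imaged in the 15–30/30–45 min windows are
frequently synapsed before illumination begins. Counting such runs as
events would pair a spurious event with zero at-risk time and bias the
estimator upward; excluding them is the only reading under which the
pooled estimate converges to `k_form`.

The at-risk (observable) time counts donor-excitation frames before
truncation with the acceptor present and the molecule outside any
detected run (including preformed runs). Each donor frame represents
its share of the excitation cycle — frame_period × cycle/donor-frames
= 2.5 s by default — so qualifying frame counts convert to wall-clock
time and an eventless fully-observable 900 s trace contributes exactly
900 s. Whether in-event time should be excluded from the denominator is
not fully determined by the verbal definition ("time formation was
possible"); exclusion is the default, since formation is impossible
while formed, and a `denominator: total` switch retains in-event time
for sensitivity analysis.

The pooled rate is Σ events / Σ at-risk time. The primary 95% interval
is the t interval over replicate rates (a replicate with zero events
contributes rate 0; with < 2 replicates the interval is undefined and
omitted); the exact Garwood/Poisson interval on the pooled count is a
secondary field, and for a zero-event condition its upper bound is
−ln(0.025)/T. Fold changes are ratios of pooled rates; a zero-rate
denominator returns an infinite sentinel with the conservative Poisson
lower bound on the ratio.

All event timestamps are frame start times; the 2 s frame period is the
quantum of every reported time.

## Histograms and condition summaries

FRET histograms follow the assay's comparability convention: the bin
count is ⌊√N⌋ of the *smallest* dataset (the rounding rule is not
specified in the source convention; floor is used), all datasets share
identical edges spanning the pooled range (clipped to the sanity
bound, overridable in configuration), and counts are normalized to
fractions so each dataset sums to 1. The condition summary reproduces
the notBoxPlot layout: replicate points, mean line, and a light
rectangle spanning the replicate-based 95% t interval centered on the
mean.

## What the simulations do and do not establish

The generator emulates the study conditions — two FRET states,
reversible formation with an absorbing ligated outcome, per-dye
bleaching, the 4:1 excitation cycle, the three-window FOV structure and
replicate layout — and gives every stage a known-answer surface:
parameter recovery shows the pipeline returns `k_form` with calibrated
replicate confidence intervals under bleach censoring, and the movie
round trip shows the localization path is statistically equivalent to
the table path. It does not emulate extract autofluorescence,
spectral cross-talk, dye blinking, stage drift (a rigid-drift
correction hook exists but is off by default), EMCCD gain statistics,
or molecule-to-molecule brightness heterogeneity; passing tests
therefore validate the analysis logic, not the photophysics of any
particular instrument. Real noise magnitudes and bleach rates are not
published for the assay, so the defaults above are explicit,
configurable assumptions.

## Problem sizes

The test suite's recovery study uses the full experimental design
(3 replicates × 3 FOVs × 100 molecules) repeated 100× per condition at
the wild-type and buffer-scale rates; dwell and coverage checks use
10⁴–4×10⁴ draws; the oracle comparison uses 1000 randomized traces; the
movie round trip uses 50 molecules at SNR ≈ 10 on a 128×256 chip. The
acceptance script runs the same design once per condition plus a
50-repeat coverage study, completing in ~2 min on one CPU.

## Known limitations

- No hidden-Markov or dwell-time inference: the threshold statistic is
  the deliverable, matching the assay. SR-complex stability
  (dissolution kinetics) is out of scope.
- Event calling deviates from human judgment by construction: the rule
  is exact where the original was a guideline.
- The bleach detector assumes step-like bleaching; gradual
  photodarkening would be truncated late. Re-appearing dyes (blinking)
  are flagged as fluctuations, not rescued.
- The change-point penalty, SNR and CV thresholds are calibrated on
  simulation only; real recordings may need different settings via the
  `qc:` config block.
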