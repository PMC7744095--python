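# synapsefret

Single-molecule FRET analysis of DNA-end synapsis kinetics during
non-homologous end joining (NHEJ).

## The problem

During NHEJ, a broken DNA molecule's two ends are first tethered loosely
(the long-range, LR, complex) and then brought into close alignment by
the short-range (SR) synaptic complex, the state in which ligation
happens. In the single-molecule assay this package analyzes, a surface-
tethered linear DNA substrate carries a Cy3/Cy5 dye pair near its two
ends: unpaired ends and the LR complex show little or no FRET, while SR
complex formation (and the ligated product) produces a high apparent
FRET efficiency of E ≈ 0.5. Movies are acquired with alternating laser
excitation — four donor (532 nm) frames followed by one direct acceptor
(641 nm) frame, 1 s exposures every 2 s — across three 15-min fields of
view per replicate.

The central statistic is the **SR complex formation rate**

```
k = (number of SR formation events) / (total time formation was possible)
```

where the denominator sums, over all tracked molecules, the time during
which both dyes are photoactive and the ends are not already synapsed
or ligated. Events are called as runs of at least *m* = 5 consecutive
donor-excitation frames with apparent efficiency
E = I_A / (I_A + I_D) above a threshold E_T = 0.25. Uncertainty is
reported as the 95% t interval over replicate rates, with an exact
Poisson interval on the pooled count as a secondary check.

The package covers the whole path from raw data to that statistic:

- **simkit** — continuous-time Markov (Gillespie) simulation of
  two-state synapsis with an absorbing ligated outcome, dye
  photobleaching, intensity-trajectory emission under the alternating
  excitation cycle, and rendering of dual-half-chip TIRF movie stacks
  with ground-truth sidecars;
- **localization** — spot detection, donor/acceptor channel pairing via
  an affine chip map, and ROI intensity extraction (movie mode only);
- **trajqc** — automatic photobleach truncation (binary-segmentation
  change points) and exclusion of low-SNR, multistep-bleach,
  non-FRET-fluctuation and multi-peak molecules;
- **fretcore** — FRET computation, event calling, at-risk time, rate
  estimation, fold changes;
- **statsviz** — time-windowed FRET histograms on shared edges with
  √N-of-smallest-dataset binning, and notBoxPlot-style condition
  summaries;
- **cliio** (`io`/`config`/`pipeline`/`cli`) — CSV/TSV trajectory
  tables, strict YAML configuration, manifests, and the `synapsefret`
  command line.

## Worked example

`examples/demo.yaml` simulates two conditions whose true formation
rates differ 25-fold (1.7×10⁻³ vs 6.8×10⁻⁵ s⁻¹), then runs the full
analysis:

```sh
synapsefret run --config examples/demo.yaml --out demo_out/
```

prints (per-stage molecule counts on stderr):

```
condition wt: 360 molecules in, 358 passed QC, 252 with observable time
condition tail_truncated: 360 molecules in, 360 passed QC, 351 with observable time
wt: rate 1.624e-03 s^-1 (134 events)
tail_truncated: rate 5.469e-05 s^-1 (12 events)
```

The wt estimate 1.62×10⁻³ s⁻¹ (95% CI [1.53, 1.72]×10⁻³ from the three
replicates) recovers the simulated 1.7×10⁻³ s⁻¹; the truncated-tail
condition recovers 5.5×10⁻⁵ s⁻¹, a ~30-fold gap. Note that in the wt
condition many molecules never contribute observable time: molecules
imaged in the later 15–30 and 30–45 min windows are often already
synapsed or ligated when their field of view is first illuminated.
`demo_out/` contains the trajectory tables, QC report, event table,
`rates.json`, shared-edge FRET histograms, and the condition-summary
table and figure, plus a `manifest.json` (seed, config hash, versions)
from which the run can be reproduced exactly.

Individual stages are available as `synapsefret
simulate|localize|qc|analyze|report`, and everything is importable:

```python
import synapsefret as sf

model = sf.KineticModel(k_form=1.7e-3)
acq = sf.AcquisitionConfig(n_replicates=3, n_molecules_per_fov=100, seed=1)
trajs, truth = sf.simulate_experiment(model, acq)
```

Real recordings enter either as trajectory tables
(`synapsefret analyze --traj traj.csv ...`; columns: replicate, fov,
molecule, frame, time_s, excitation ∈ {D,A}, I_donor, I_acceptor) or as
dual-half-channel TIFF stacks via `synapsefret localize`. A best-effort
converter for the published source-data spreadsheets lives under
`contrib/`.

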