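# flagcal

Quantification of flagellar Ca²⁺ influx and intraflagellar transport
(IFT) from TIRF kymographs, plus a simulation of the ion-current model of
flagellar length control.

Flagella are a classic organelle-size problem: *Chlamydomonas* keeps its
two flagella at ~12 µm, and regrows them to the same length after
amputation.  The ion-current hypothesis proposes the length sensor is
Ca²⁺ entering through uniformly distributed membrane channels — entry
scales with length, the kinase CDPK1 reads the Ca²⁺ level and
phosphorylates the IFT kinesin, throttling the injection of IFT trains
that carry assembly precursor to the tip.  Testing that idea
experimentally means extracting, from dual-channel kymographs, the
quantities the feedback loop relates: Ca²⁺ influx events (GCaMP
channel), IFT injection intensity, train frequencies and velocities
(IFT channel), and their coupling on a seconds time scale around Ca²⁺
bursts.  This package implements that measurement pipeline, the model,
the supporting buffer chemistry and statistics, and a synthetic-data
generator with exact ground truth so every stage is testable without raw
movies.

## The core model

With F the active CDPK1 fraction and K the entry-competent kinesin
fraction,

    F = αL / (αL + K_D)
    K = 1 − F / (F + K_M)
    dL/dt = A·K·(P − 2L) − D

integrated by forward Euler (dt = 0.02 s, output every 1 s).  Lengthening
raises Ca²⁺ = αL, activates CDPK1, phosphorylates kinesin, and lowers
injection until assembly balances the constant disassembly D at a stable
set-point L*.

The measurement side follows the field's standard kymograph workflow:
Gaussian smoothing, mono-exponential photobleach correction, prominence
peak detection on the spatially summed GCaMP trace (influx intensity =
Σ event area / imaging time); oriented matched filtering plus ridge
linking for IFT trains (injection intensity = Σ anterograde trace
intensity / length / time), fragment reconnection and overlap removal;
20% scaled subtraction for spectral bleed-through; and event-triggered
five-window (5 s each) analysis around isolated Ca²⁺ bursts with paired
t tests between neighbouring windows.

## Worked example

```python
from flagcal.length_model import LengthModelParams, simulate, steady_state
from flagcal.synth import SynthConfig, make_ca_kymograph
from flagcal import kymo_ca

p = LengthModelParams()
print("steady state: %.2f um" % steady_state(p))
traj = simulate(p, 7200.0)
print("L after 2 h from zero: %.2f um" % traj.L[-1])

cfg = SynthConfig(bleach_rate=0.005)
kymo, truth = make_ca_kymograph(cfg, seed=1)
events, summary = kymo_ca.analyze(kymo)
print(len(events), "events;", summary)
print("truth influx: %.2f" % truth.summary.influx_intensity)
```

prints

```
steady state: 11.99 um
L after 2 h from zero: 11.65 um
3 events; {'influx_intensity': 368.6076, 'spike_frequency': 0.05,
           'bleach_rate': 0.005, 'n_events': 3}
truth influx: 367.51
```

The model settles at 11.99 µm and a regrowing flagellum is within 3% of
that after two hours.  The synthetic movie contained five Ca²⁺ spikes;
two pairs fell closer than the 0.5 s separation limit and merge into
single events (hence 3 events at 0.05 s⁻¹), while the influx *intensity*
— the extensive quantity the feedback model cares about — is recovered
to 0.3% of the ground truth despite photobleaching.

The same operations are scriptable from the shell:

```bash
flagcal buffer --ca-total 0.01 --egta-total 0.01 --kd-app 150e-9
# free Ca2+: 3.865491e-05 M = 38654.9 nM = 38.655 uM
flagcal simulate --duration 7200 --amputate 3600 --out traj.csv
flagcal synth dual --seed 7 --out data/   # kymographs + truth JSON
flagcal run --seed 2 --out results/       # full synthetic pipeline
```

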