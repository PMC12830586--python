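# clocksync

Cellular circadian clocks synchronize to external cues within minutes: a
glucocorticoid or growth-factor stimulus triggers CK2-mediated
phosphorylation of BMAL1 (Ser90), immediate nuclear accumulation of the
BMAL1:CLOCK transcription factor, an acute *Per2* surge, and ultimately a
phase shift of the population rhythm. `clocksync` is a reusable,
synthetic-data-testable implementation of the computational layers of that
story, for chronobiologists and quantitative cell biologists who want to
run the same analyses on their own (or simulated) data:

1. **Clock simulation** (`clocksync.models` / `simulate` / `resetting`) — a
   declarative ODE engine with a bundled 7-state reduced mammalian clock
   model carrying an explicit phosphorylated BMAL1:CLOCK species.
   Synchronization protocols multiply the phosphorylation rate constant
   k<sub>phos</sub> by a factor *f* for a duration *d* (*f* = 15, *d* = 2 h
   is the standard stimulus arm; *f* = 0 models CK2 inhibition).  Phase
   shifts Δφ of *Per2*, induction fold changes, phase response curves over
   circadian time (CT) 8–32 h, and factor × duration sweeps.
2. **Fixed-cell quantification** (`clocksync.imaging`) — nucleus
   segmentation, a 3-pixel dilation ring as the cytoplasmic compartment,
   and the nucleus-to-cytoplasm ratio Nuc/Cyto = mean nuclear / mean ring
   intensity per cell and channel.
3. **Translocation tracking** (`clocksync.tracking`) — nearest-centroid
   track linking, relative nuclear intensity (nuclear / whole-cell), and
   the positive-rate rule: a cell is a responder when its maximum
   post-stimulus fold change exceeds the 75th percentile of the
   unstimulated control.
4. **Synchrony networks** (`clocksync.synchrony`) — graphical lasso
   (ρ = 0.013) over cells' translocation series, Delaunay triangulation of
   cell positions, and the local / global correlation indices
   |E<sub>net</sub> ∩ E<sub>neigh</sub>|/|E<sub>neigh</sub>| and
   |E<sub>net</sub>|/C(n,2), with expanding-window time courses.
5. **Rhythm analysis** (`clocksync.rhythm`) — 24-h moving-average
   detrending, Lomb–Scargle periodogram (18–30 h), single-component cosinor
   y(t) = M + A·cos(2π(t−φ)/τ), and circular phase-shift comparison.
6. **Synthetic data** (`clocksync.synth`) — deterministic generators with
   ground truth for all of the above.

The `analysis/` directory holds numbered drivers (simulation → sweep → PRC
→ imaging → tracking → synchrony → rhythm) that run each stage end to end
and write tables under `results/`.

## Worked example

```bash
python analysis/01_clock_baseline.py
```

```
limit cycle period: 23.503 h (CT0 = Bmal1_mRNA peak)
Dex arm (15x, 2 h @ CT15):      Per2 shift -0.117 h, phospho FC 1.012
Dex+GO289 arm (0x, 2 h @ CT15): Per2 shift +0.028 h
CK2 inhibition suppresses the induced shift: True
```

The free-running model oscillates with a ~23.5-h period; circadian time 0
is anchored to the *Bmal1* mRNA peak.  A 15-fold increase of
k<sub>phos</sub> for 2 h at CT 15 transiently raises phosphorylated
BMAL1:CLOCK and delays the *Per2* rhythm by 0.12 h, while zeroing
k<sub>phos</sub> over the same window (CK2 inhibition) leaves only a 0.03-h
shift — the inhibitor arm suppresses the stimulus-induced resetting.  The
phase response curve (`analysis/03_phase_response_curve.py`) spans a 2.6-h
range over CT 8–32, peaking near CT 12.

On the single-cell side:

```bash
python analysis/05_translocation_positive_rate.py
```

```
treated: 200 tracks (200 full length)
control: 200 tracks (200 full length)
positive rate 80.5% (true responder fraction 80%; threshold fold change 1.249)
```

A synthetic stimulated population with a programmed 80% responder fraction,
rendered to label/intensity stacks, tracked, and pushed through the
75th-percentile rule, returns a measured positive rate of 80.5%.

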