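# biotransparency

Quantitative egg transparency from hyperspectral transmission imaging.

Marine invertebrate eggs — ascidian (sea squirt) eggs in particular — range
from nearly invisible to deeply pigmented, and that transparency matters for
predation, UV exposure and embryology. This package turns hyperspectral
image cubes of eggs in seawater into comparable transparency numbers:

* **Transmittance** per wavelength, τ(λ) = I/I₀, where I is the intensity
  through the egg and I₀ the surrounding seawater background (380–1000 nm
  sampled every 5 nm; 125 bands).
* **Bio-transparency** — the mean of τ × 100 over the visible range
  400–760 nm: a single percentage per egg.
* **Attenuation coefficient** — μ(λ) = −(1/x)·ln τ(λ), with x the egg
  thickness (equivalent-circle diameter, µm). μ removes egg size from the
  comparison: a large egg can look opaque while attenuating little per µm.

Statistics aggregate egg → individual → species (mean ± sample SD; species
spread as both variance and range of individual means), and species tables
can be joined onto an existing phylogeny as NEXUS tip annotations.

Because the raw recordings behind such surveys are rarely deposited, the
package includes a physics-based synthetic generator: pigmented attenuating
spheres rendered through chord-length Beer–Lambert optics with *analytic*
ground truth — the area-averaged disk transmittance has the closed form
T̄ = (1−R)·[1 − (1+2μr)e^(−2μr)]/(2μ²r²) — so every pipeline stage is
testable against numbers that never came from the pipeline itself.

It is for researchers measuring optical transparency of roughly spherical
specimens under a transmission microscope, and for anyone needing a tested
reference implementation of these statistics.

## Worked example

`python examples/01_simulate_and_measure.py` renders a highly transparent
200-µm egg phantom at SNR 30 and measures it end to end:

```
eggs found:          1
diameter:            199.5 um (truth 200.0 um)
bio-transparency:    89.15 % (truth 89.21 %)
visible attenuation: 0.000577 1/um (truth 0.000864 1/um)
```

The diameter and bio-transparency recover the analytic ground truth to a
fraction of a pixel / percentage point. The attenuation coefficient sits
below the generator's μ by design: the statistic treats the egg as a slab
of thickness equal to its diameter, while most light crosses shorter
chords of the sphere (see `docs/methods.md`).

`python examples/02_bt_sweep_recovery.py` sweeps ground-truth
bio-transparency across 10–90% in nine eggs and recovers each within
±0.4 points under noise. The other examples show pigment-dip detection
(two absorption bands at 500/600 nm found exactly) and phylogeny
annotation.

A thin CLI wraps the same library calls:

```sh
biotransparency simulate bt_sweep --seed 1 --noise-sd 33 --out sweep
biotransparency run config.yaml
biotransparency annotate-tree species.nwk per_species.csv --out annotated.nex
biotransparency validate sweep
```

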