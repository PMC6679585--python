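# memtopo

Does a bright spot on a membrane mean a molecule is *enriched* there, or
just that there is *more membrane* there? In polarizing *C. elegans*
zygotes, micron-scale cortical puncta labeled by the PIP₂ probe PH_PLCδ1_
(and by RHO-1, CDC-42, CSNK-1 and generic membrane markers) look like
signaling microdomains — but they are filopodia: ~100-nm membrane tubes
whose cross-section packs extra bilayer into a single diffraction-limited
spot. `memtopo` provides the computational toolkit to make and test that
argument quantitatively:

- **`memtopo.optics_sim`** — a physical image-formation model: membrane
  geometries rasterized at 5 nm/px, convolved with a Gaussian PSF
  (σ = 200 nm), block-binned to the camera pixel (155 nm), degraded with
  Poisson shot noise and Gaussian read noise. Under uniform fluorophore
  density ρ (photons/nm of membrane), a double bilayer reads 2× a single
  one, and a tube of diameter *d* ≪ σ reads
  1 + π d / (√(2π) σ) ≈ 1.6× at the peak — between single and double, with
  no enrichment at all.
- **`memtopo.quantify`** — the static measurements: straightened membrane
  band profiles, the top-3-pixel crossing metric normalized to the
  single-membrane (PM) median, two-channel relative enrichment,
  ROI colocalization scoring, structure-count time courses, and the
  asymmetry index ASI = (A − P) / [2(A + P)] ∈ [−0.5, 0.5] from cortical
  means or straightened cross-sections.
- **`memtopo.dynamics`** — the time-resolved estimators: Crocker–Grier
  puncta detection with sub-pixel Gaussian refinement, optimal
  frame-to-frame linking, velocity statistics (v_f, v_e), two-channel
  kymograph peak-to-peak lag Δτ with sub-frame interpolation,
  single-exponential FRAP fitting (τ½ = ln 2 / k), and tip-offset
  profiles.
- **`memtopo.synthetic_data`** — ground-truthed synthetic movies (motile
  tip puncta, comets with pure-delay or kinetic two-channel lag, FRAP
  bleach/recovery) so every estimator is validated by parameter recovery.
- **`memtopo.io` / `memtopo.pipeline` / `memtopo.cli`** — TIFF + JSON
  sidecar I/O, a validated YAML run configuration, and the `memtopo`
  command-line entry point.

## Worked example

Simulate the reference cortex scene — a single bilayer, a pseudocleavage
furrow double membrane, and a 100-nm filopodial tube tangent to the
membrane — then quantify it exactly like an experimental image:

```python
import numpy as np
from memtopo import optics_sim, quantify

scene, ann = optics_sim.filopodium_furrow_scene()
cfg = optics_sim.OpticsConfig(seed=7)          # sigma 200 nm, 155 nm px
sim = optics_sim.simulate_membrane_image(scene, cfg)

img = sim.channel(0)
path = quantify.MembranePath(np.asarray(ann["path_px"]))
crossings = [quantify.Crossing(label=c["label"],
                               center_px=c["center_px"] - ann["path_offset_px"])
             for c in ann["crossings"]]
records = quantify.enrichment_table(img, path, crossings,
                                    cytoplasm_background=float(np.median(img[:3])))
for label in ("PM", "Filo", "Furrow"):
    vals = [r.normalized for r in records if r.label == label]
    print(label, round(float(np.median(vals)), 2))
```

prints

```
PM 1.0
Filo 1.42
Furrow 1.97
```

i.e. with *uniform* membrane labeling, the furrow's double bilayer scores
twice the single membrane and the filopodium scores ~1.4× — topology alone
reproduces the apparent "enrichment" ordering PM < Filo < Furrow. The
whole pipeline (scene → enrichment → movie → tracking → lag → FRAP) runs
from one config:

```sh
memtopo run --config run.yaml
```

and writes tidy CSVs plus a seeded, byte-reproducible `summary.json`.

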