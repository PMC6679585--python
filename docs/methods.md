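# Methods

## The image-formation model

The central question the package answers is geometric: how bright should a
membrane feature appear in a fluorescence microscope if the fluorophore
density on the membrane is perfectly uniform? The forward model treats
membrane as a one-dimensional emitter in the imaging plane with line
density ρ (photons per nm per channel) and proceeds in four stages.

1. **Rasterization** (default 5 nm/px). Polylines are drawn with an integer
   line algorithm on pixel centers (0-based, origin top-left, y downward),
   circles with the midpoint algorithm. Each primitive deposits
   ρ × (length / n lit pixels) per pixel, so its photon budget is exactly
   ρ × membrane length regardless of orientation — a midpoint circle lights
   ~10% fewer pixels than circumference/raster, and a uniform per-pixel
   deposit would silently shrink a tube's photon budget by the same amount.
   Segments are half-open (the shared vertex belongs to the next segment):
   a 1 µm axis-aligned line at 5 nm lights exactly 200 pixels. Overlapping
   primitives sum. The uniform background (photons per raster pixel) is
   added **before** blurring.
2. **PSF convolution**: isotropic Gaussian, σ = 200 nm by default,
   reflective padding. The blur parameter is a σ, not a FWHM — the same
   convention as ImageJ's Gaussian Blur, and the value that places a
   100-nm tube strictly between single- and double-membrane brightness, as
   observed. It is a config field (`psf_sigma_nm`).
3. **Camera binning**: block *sum* over the integer factor
   `out_px_nm / raster_nm` (155/5 = 31), which conserves photons to float
   precision; the downstream metric is self-normalized, so no rescale is
   applied. Edge rows that do not fill a camera pixel are trimmed with a
   warning.
4. **Noise**: counts ~ Poisson(gain·λ)/gain + N(0, `read_noise_sd`),
   clipped at zero; defaults gain = 1 photon/count and read SD = 5 counts.
   Both are configurable because camera gain and the exact read-noise
   figure vary between setups. Identical seeds give identical images.

Closed forms used as oracles: an infinite line of density ρ blurred with σ
peaks at ρ/(√(2π)σ); a point-like source of S photons at S/(2πσ²). A tube
of diameter d ≪ σ adjacent to a membrane line therefore predicts a peak
ratio 1 + πd/(√(2π)σ) ≈ 1.63 for d = 100 nm, σ = 200 nm. The finite tube
size and its 50-nm offset from the line lower the simulated value to ≈1.59
(within 3% of the closed form); after camera binning and the 3-px band
averaging of the top-3 metric the *measured* Filo/PM ratio is ≈1.42. The
reference scene (`filopodium_furrow_scene`) places the filopodium tangent
to the membrane; a gap of tens of nm would further lower the ratio.

The furrow double membrane uses a 50-nm inter-bilayer gap by default
(apposed membranes, gap ≪ σ), giving Furrow/PM ≈ 1.99; the ratio tends to
exactly 2 as the gap goes to 0, by linearity.

**Quantification geometry.** Scene coordinates are laid out on camera-pixel
centers so the membrane runs along a camera row; quantification windows
stay > 3σ away from canvas borders. A 12.4 × 3.1 µm canvas (80 × 20 camera
px) is enough to hold four single-membrane windows, one filopodium and one
furrow window with those margins — larger canvases change nothing but run
time, which matters for the 1 nm/px brute-force oracle used to validate
raster-resolution convergence (agreement is ≤ 0.1%, far inside the 3%
test band).

## Static quantifications

- **Profiles**: images are pre-smoothed (Gaussian σ = 1 px), the path
  resampled at unit speed (1 px), and a band of 3 px (profiles), 20 px
  (display) or 50 px (cross-section ASI) sampled along the local normal by
  bilinear interpolation and averaged. Chip background (median outside the
  embryo) is subtracted before mean-normalization; an all-background
  profile is flagged degenerate rather than normalized.
- **Top-3 crossing metric**: sum of the three largest
  cytoplasm-background-subtracted samples in a ±5 px window around each
  annotated crossing (not necessarily contiguous; ties are order-invariant;
  negatives clip to 0). Normalization is per embryo to the median of
  single-membrane (PM) crossings — for simulated images all single-membrane
  peaks play that role. The metric is invariant to matched constant offsets
  and scales linearly with gain.
- **Colocalization**: the protocol being automated is manual ("is this
  reference structure labeled in the other channel?"), so the package
  defines the criterion: a structure is positive when the test-channel ROI
  maximum exceeds the membrane background (median outside all ROIs) by
  k × 1.4826 × MAD, k = 3 by default. The MAD is scaled to a robust σ so k
  reads in Gaussian sigmas; with raw MAD the same k would sit at ≈2σ and
  pure Poisson noise would score ~40% of ROIs positive, which no usable
  criterion can mean. At k = 3σ the noise-only false-positive fraction is
  <10% and fully co-labeled structures at SNR 5 score >90%. Fewer than 30
  ROIs warns; zero is an error.
- **ASI**: (A − P)/[2(A + P)], bounded in [−0.5, 0.5], 0 when symmetric.
  For cross-sections, a 50-px band around the closed contour is
  straightened and the normalized cytoplasmic profile *across* the band,
  scaled at each arclength position to the band's cytoplasm-proximal edge,
  is subtracted before averaging anterior and posterior thirds of the
  circumference (contour vertex 0 = anterior pole). The width-wise
  reference matters: subtracting a single arclength curve over-subtracts
  wherever the band extends past the embryo edge and biases ASI away
  from 0. Negative residuals clip to 0; a profile with no membrane signal
  above the scaled reference raises instead of returning a number.
- **Bootstrap CIs**: 95% percentile bootstrap of class medians, 10,000
  resamples, seeded.

## Dynamics estimators

- **Detection** (Crocker–Grier): band-pass = Gaussian(σ = 1 px) smoothing
  minus boxcar mean over the feature diameter (7 px default); candidate
  local maxima above median + 5 robust σ (1.4826 × MAD) of the filtered
  frame; sub-pixel refinement by least-squares 2-D Gaussian + offset in a
  diameter-sized window, falling back to the pixel maximum when the fit
  diverges. The 5σ robust threshold keeps the blank-frame false-positive
  rate below 0.05/frame while detecting SNR-5 spots; localization RMS error
  is ≈0.1 px at SNR 10.
- **Linking**: per-frame optimal assignment (Hungarian algorithm on squared
  displacement) with a no-link alternative priced at max_disp² (5 px
  default), so the solution minimizes total squared displacement among
  links within the capture radius; unmatched detections seed new tracks;
  `memory_frames` lets a track survive missed detections. Equal-cost
  ambiguities resolve deterministically (tracks are offered in id order).
- **Velocities**: per-track speed is the mean per-step speed, not net
  displacement over duration, over tracks of ≥5 detections; v_f is the
  mean ± s.d. over tracks, v_e the mean of per-embryo means. Because step
  speed is a magnitude, localization noise biases it upward when the
  per-frame displacement is comparable to the ≈0.1–0.2 px localization
  error; sampling should be matched to motion (e.g. 4 s intervals at
  0.05 µm/s, 1 s at 0.5 µm/s), which keeps recovery within 10% across the
  0.05–0.5 µm/s range.
- **Kymograph lag**: per spatial position, both channels' temporal traces
  must peak away from the trace boundary and rise ≥3 MAD above their
  median; traces are aligned on the channel-A peak frame, averaged across
  ≥10 positions, and Δτ is the difference of quadratically interpolated
  peak times. Sub-frame interpolation is essential at 2 s/frame, where raw
  argmax would quantize a 9.3 s delay to 8 or 10 s. Aligned raw traces are
  averaged without per-position normalization. For a pure delay the two
  averaged traces are congruent, so peak-shape bias cancels; the estimator
  is antisymmetric under channel swap.
- **FRAP**: intensities normalized to the prebleach mean (20 frames by
  default; no second normalization for acquisition bleaching — the
  generator does not model it and the fit would absorb it into the
  plateau); post-bleach points fit to I(t) = C + A(1 − e^(−k(t−t₀))) with
  t₀ the first post-bleach frame; τ½ = ln 2/k; mobile fraction
  A/(1 − C). Fits with k ≤ 0 or recovered amplitude <1% of prebleach raise;
  τ½ < 2 frame intervals is flagged under-sampled (at 0.5 s intervals a
  0.84 s half-time is in this regime yet still recovers within ~5% on
  clean box-averaged curves because the plateau constrains the fit).
- **Tip offsets**: per-filopodium 3-px profiles starting at the tip
  punctum, mean-normalized, averaged over the common length; the peak
  offset uses the same quadratic sub-sample interpolation.

## The synthetic-data generator

Surface movies are rendered directly at camera resolution (0.155 µm/px,
spot σ = 1.0 px ≈ diffraction) — the dynamics estimators need sub-pixel
ground truth, not a physically resolved membrane, and the 5-nm simulator is
reserved for the topology analysis. Defaults mirror the imaging conditions
the analyses assume: 2 s frame interval for surface movies, 0.5 s and 20
prebleach frames for FRAP with a 6.2 × 6.2 µm bleach box (40 × 40 px),
background 100 photons/px, SNR (spot peak over √background) = 5, read
noise SD 2 counts. Structure kinds: static spots, motile tip puncta,
uniform filopodium segments, and comets (head spot plus exponential tail,
decay length one third of the structure length). Channel 1 of a structure
follows its lag mode: synchronous, a pure time shift Δ (channel B rendered
at t − Δ), or kinetic — channel-A occupancy convolved with a normalized
exponential kernel of half-life τ½, which produces a lag that grows
monotonically with τ½ but is not a pure shift, exactly the slow-turnover
probe phenomenology. FRAP fields recover as
I(t) = I₀ + (I_pre − I₀)·f_mobile·(1 − 2^(−t/τ½)).

What the generator does **not** emulate: cortical flow advection, embryo
curvature and shape, acquisition photobleaching, probe diffusion during
FRAP (recovery is spatially uniform inside the box), camera fixed-pattern
noise, and structure birth/death. Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to every confounder of real embryo movies.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng(seed)`; seeds are
  mandatory in movie specs and recorded in every sidecar and summary.
- Quadratic peak interpolation falls back to the discrete maximum at trace
  boundaries or non-concave neighborhoods.
- Assignment costs beyond the capture radius are priced prohibitively
  rather than removed, keeping the cost matrix square and the solution
  deterministic.
- Degenerate inputs raise typed errors rather than returning numbers:
  all-background profiles, zero PM medians, A + P = 0, all-zero count
  series, flat FRAP curves, open contours for cross-section ASI, comet
  kymographs with fewer than 10 interior-peak positions.
- Problem sizes in the test suite (128-px fields, tens of frames, a
  12.4 µm scene canvas, a single 1 nm/px oracle render) are chosen so the
  full suite completes in a few minutes while every statistical tolerance
  retains comfortable margin.

## Known limitations

- The PSF is a 2-D Gaussian: no z-sectioning, vectorial/Airy structure or
  spectral bleed-through; the topology argument is made in a single
  imaging plane, matching how the cross-section data are quantified.
- The colocalization criterion is a formalization of a manual protocol;
  its absolute fractions depend on k and the ROI radius, though the >90%
  co-labeling conclusion is robust across reasonable settings.
- FRAP fitting assumes a single well in the bleach box and one exponential;
  reaction–diffusion recovery shapes are out of scope.
- Linking has no motion model; at high density and speed (displacement
  approaching the inter-particle distance) identity swaps are possible, as
  with any nearest-neighbour-class linker.
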