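# Methods

`memroll` quantifies how annexins reshape model membranes: a curvature-
inducing annexin (e.g. ANXA4) rolls a supported membrane patch up from its
free edges, while crosslinking annexins (A1, A2, A6) glue the patch to the
underlying membrane and hinder rolling and unrolling.  The package covers
the four quantitative analyses of such experiments — rolling energetics,
rolling/unrolling kinetics, AFM lattice/domain analysis, and membrane
curvature mapping — together with synthetic-data generators that stand in
for the microscopy, AFM and simulation raw data.

## Rolling energetics (`memroll.energetics`)

The rolled patch is modelled as an Archimedean spiral
`r(θ) = r0 + (b/2π) θ` of pitch `b` (the interlayer spacing of the roll).
Per unit roll width, the energy difference between the rolled and flat
state after membrane arclength `L` has rolled is

    ΔE(L) = ∫₀ᴸ [ (k_c/2)((1/r(s) − c0)² − c0²) + w_ad ] ds ,

the Helfrich bending energy of the rolled membrane (local curvature `1/r`,
spontaneous curvature `c0`) measured against the flat, curvature-frustrated
state, plus the adhesion energy density `w_ad` forfeited by lifting
membrane off the support.  The equilibrium rolled length `L*` minimises
`ΔE`; because the integrand changes sign exactly where
`|1/r − c0| = √(c0² − 2 w_ad/k_c)`, `L*` is computed from the closed-form
marginal radius and the exact spiral arclength map (the thin-pitch
approximation `L ≈ π(r² − r0²)/b` is kept as a documented fast path and
agrees to ≪1% at `b = 2.1 nm`).  A dense-grid minimisation of the
tabulated `ΔE` serves as the normative oracle in the tests.

Parameters (SI units):

| parameter | meaning | default |
| --- | --- | --- |
| `k_c` | bending modulus | 1.0e-19 J (`results` preset) / 4.0e-20 J (`methods` preset) |
| `c0`  | spontaneous curvature from one-sided annexin binding | 3.33e7 m⁻¹ |
| `w_ad`| patch–support adhesion energy density | 1.0e-5 J m⁻² |
| `b`   | roll-spiral pitch | 2.1 nm |
| `r0`  | innermost roll radius | `1/c0` |

Design choices where the physics left latitude:

* **Adhesion magnitude.** One published source prints the reference
  adhesion with a positive exponent (1.0e+5 J/m²), which exceeds membrane
  bond energies by ~10 orders of magnitude and the maximal curvature gain
  `(k_c/2)c0² ≈ 5.5e-5 J/m²`; it is read as a sign typo and 1.0e-5 J/m² is
  used.  The field is plain configuration, so either value can be set.
* **Two bending-modulus presets.** The literature on this system quotes
  both 1.0e-19 J and 4.0e-20 J; both ship as named presets and the default
  is `results` (the preset under which the published parameter sweeps are
  presented).  At the reference adhesion, `L*` ≈ 149 µm (`results`) or
  ≈ 19 µm (`methods`).
* **Inner radius.** `r0 = 1/c0` places the innermost turn at the
  spontaneous radius (zero local frustration).  For the `c0` sweep the
  default convention lets `r0` follow the reduced `c0`
  (`r0 = 1/(c0·fraction)`); a fixed-`r0` convention is selectable.
* **Adhesion acts only between patch and support.**  No wrap-to-wrap
  adhesion gain inside the roll is included; crosslinking is modelled
  purely as the energy cost of detaching the patch from the primary
  membrane.
* **Pitch convention.** `b` is the radial advance per full turn (pitch per
  2π), not per radian.
* **Sweeps.** `sweep_adhesion` scales `w_ad` multiplicatively;
  `sweep_spontaneous_curvature` scales `c0` by fractions ≤ 1.  The
  critical factor at which `L*` reaches the 1 µm optical resolution limit
  is refined by bisection between bracketing sweep points and reported as
  `nan` when the sweep does not bracket the crossing.  With the defaults,
  the adhesion sweep crosses 1 µm at a factor ≈ 5.2 (`results`) / ≈ 2.1
  (`methods`), and the `c0` sweep at a reduction of ≈ 57% (`results`) /
  ≈ 32% (`methods`).  These land on either side of the published
  factor-level landmarks (~3.5 and ~50%); since the exact functional form
  of the original model is not public, agreement is treated as a
  factor-level calibration, not an identity.

The model is quasi-static: no rolling dynamics, membrane tension, thermal
fluctuations or edge line energy.

## Rolling and unrolling kinetics (`memroll.kinetics`)

Rolling removes membrane-dye signal, so the rolled area is quantified from
frame differences of a time-lapse stack:

1. each frame is median-filtered (3×3).  The median filter is
   edge-preserving, so the moving patch boundary survives while isolated
   pixel noise is strongly suppressed;
2. consecutive filtered frames are differenced (`previous − current`);
3. the loss map is binarized.  The automatic cutoff is
   `mean + 5·SD` of the signed difference image's border margin (10 px).
   Five rather than three SDs because losses are counted over the whole
   frame across hundreds of frame pairs: at 3 SD the expected number of
   false pixels per movie rivals the true rolled area, while at 5 SD it is
   ≪ 1 pixel.  An absolute intensity cutoff can be supplied instead;
4. a pixel is counted at most once over the movie (membrane can only roll
   once), which removes double counts when the bright roll rim passes;
5. incremental area = count × pixel area; cumulative area is its running
   sum, guaranteed non-decreasing.

The cumulative trace is fitted with the three-parameter logistic
`A / (1 + exp(−(t − t0)/τ))` by trust-region least squares, initialised
from trace quantiles (`A = max`, `t0` = half-max crossing,
`τ = (t80 − t20)/2.2`).  The **onset time** is defined as the first time
the measured cumulative area exceeds 5% of the fitted amplitude (the
threshold is configurable).  Degenerate traces and non-convergent fits
raise `LogisticFitError` carrying diagnostics rather than returning a
silent default.

Unrolling is quantified as the per-frame patch area (pixels above a
cutoff; Otsu's threshold of the first frame by default) relative to the
maximally rolled first frame, truncated at 80 s.  Edge localization uses
per-channel line profiles (averaged across a configurable width, min–max
normalized); the peak is the largest interior local maximum after 3-point
smoothing, so protein/dye peak offsets quantify edge colocalization.
Group comparisons use Welch's unequal-variance t test with
Welch–Satterthwaite degrees of freedom (two-sided).

No image registration is performed — supported patches do not drift — but
a phase-correlation drift check warns when the first-to-last frame shift
exceeds 2 px.  (On rolling movies the patch itself changes shape, which
can trip this check; the warning is informational.)  One region of
interest per run; patches are not detected or tracked automatically.

## AFM lattice and domains (`memroll.afm`)

Annexin trimers close-pack into two-dimensional crystals; the lattice
period (row spacing, ~9 nm for trimer arrays) is measured from the 2D
power spectrum of a height scan:

* per-scanline polynomial flattening (order 0–2) removes offset, tilt or
  bow; a Hann window precedes the FFT;
* the first-order Bragg ring is located within the trimer band
  (periods 3–30 nm) on the radially averaged spectrum *after subtracting
  its smooth background* (15-bin median filter), so broadband domain
  texture cannot pose as a lattice;
* discrete peaks in the ring annulus must exceed the radial background at
  that radius both by 5× the annulus median absolute deviation and
  four-fold (on a 3×3-smoothed spectrum); crystallinity requires ≥ 4 such
  peaks, otherwise the period is reported as `nan` with the flag false;
* the period is `2π/|q|` averaged over all detected first-order peaks
  (sub-bin refined by intensity-weighted centroids); the hexagonal lattice
  constant `a = 2d/√3` is reported alongside for transparency.

Height domains (e.g. a GFP-tagged species riding ~2.7 nm above an
untagged one) are segmented by a two-component Gaussian mixture of the
plane-flattened heights, initialised from Otsu's split so the mixture
cannot spend both components on one structured mode.  Bimodality requires
Ashman's `D = √2|μ₁−μ₂|/√(σ₁²+σ₂²) ≥ 2` and both weights above 2%;
otherwise `SegmentationError` is raised with the height histogram
attached.  The threshold is the decision boundary of the fitted mixture
(falling back to Otsu when the fit fails); area fractions are percentages
of the analyzed (optionally masked) area and always sum to 100.

Out of scope: tip deconvolution, force curves, scan-to-scan drift
correction.

## Membrane curvature mapping (`memroll.curvature`)

Lipid-particle frames (x, y periodic, z free; leaflet-labelled) are
reduced to the bilayer midplane by binning each leaflet onto a square grid
and averaging the two leaflet mean heights per cell.  Cells missing a
leaflet are filled by periodic neighbour interpolation and flagged; when
more than 20% of cells miss a leaflet, `ResolutionError` advises a larger
cell.  Mean curvature is evaluated in the Monge gauge,

    H = [(1 + h_x²) h_yy − 2 h_x h_y h_xy + (1 + h_y²) h_xx]
        / (2 (1 + h_x² + h_y²)^{3/2}) ,

with periodic central differences.  A periodic Gaussian smooth (σ = 1 grid
cell by default; the scale is in cells, so hold it fixed in physical units
when comparing grids) suppresses binning noise before differentiation and
is disabled for the analytic oracle tests.  Sign convention: the normal
points along +z (the protein-bound side); a bowl opening towards +z has
positive H.

The footprint statistic is the arithmetic mean of `H` (not `|H|`; both are
emitted) over an explicitly supplied region, averaged across frames, with
the sample SD across frames; replicas aggregate as the mean of replica
means with the sample SD across replica means.  The region is supplied by
the caller — protein coordinates are out of scope, so contacts are not
inferred.  All lipid particles of a leaflet define the surface; per-atom
selections can be emulated by filtering the input frame.

Published trajectory-scale curvature values (e.g. 0.0083 ± 0.0014 nm⁻¹
under an ANXA6 dimer) require microsecond all-atom trajectories that are
not redistributable; they are context for the synthetic scales used here,
not quantities this package can regenerate.  The curvature machinery is
instead validated against closed-form surfaces: spherical caps
(`|H| = 1/R` to < 2% for R = 50–200 nm), Gaussian dimples (pointwise
closed-form agreement to < 1% at 0.5 nm cells with smoothing off — checked
away from the dimple's H zero crossing at `r = σ√2`, where relative error
is ill-defined), and hand-checkable replica arithmetic.

## Synthetic data (`memroll.synthetic`)

Each generator emits a `SyntheticTruth` record sufficient to regenerate
the dataset bit-exactly from its seed; all randomness flows from the seed
argument, with no global state.

* **Rolling movies.**  A bright patch (disc or polygon) on a dark
  background is consumed by erosion fronts seeded on the patch edge
  (circular-arc erosion; one seed for unidirectional, ≥ 2 for
  multidirectional rolling).  Cumulative consumed area follows
  `A/(1 + exp(−(t − t0)/τ))` with `t0` chosen so the logistic's 5%-of-A
  crossing equals the requested onset, *gated at the onset*: frames before
  the onset are exactly static and consumption starts there at the
  logistic's current value, a short burst standing in for the unresolved
  early tail.  (An ungated logistic would nibble visibly before the
  onset; a clamped-and-rescaled one is no longer a logistic and biases the
  fitted τ by ~10%.  The gated form keeps pre-onset frames static while
  the fitted τ stays within ~2.5% of truth.)  A bright 2-pixel rim leads
  each front, emulating the rolled membrane; corrugation/puckering is not
  modelled.  Defaults mirror the experimental setting — 0.32 µm/px and
  10 fps — at a 160² px field rather than a full 2048² camera frame.
  Gaussian noise is specified relative to the patch–background contrast
  (0.9), so `noise_sigma = 0.2` corresponds to SNR 5.
* **Unrolling movies.**  A disc whose area grows linearly,
  `A(t) = A₀(1 + g·t)`; `g = 0` emulates a fully crosslinked roll.
* **AFM images.**  Gaussian bumps (height 0.8 nm, σ = 0.22·spacing) on a
  hexagonal lattice of given row spacing and rotation inside the low
  domain; the high domain rides a 2.7 nm step (the GFP differential) with
  smooth texture and occupies exactly the requested area fraction
  (smoothed-noise field thresholded at the matching quantile); 0.2 nm
  roughness everywhere, optional tilt plane.
* **Membrane frames.**  Two leaflets at ±thickness/2 around an analytic
  midplane (flat, spherical cap continued flat beyond its rim, or Gaussian
  dimple `z = −A·exp(−r²/2σ²)`), uniform in x, y, with Gaussian z-noise on
  the 0.2 nm lipid-protrusion scale; generation fails for surfaces with
  `|∇f| > 1` (outside the Monge regime).

What the generators do **not** emulate — optical PSF and shot noise,
patch-shape irregularity, drift, protein binding kinetics, calcium
dependence, lattice defects and grain boundaries, lipid chemistry — bounds
what passing tests show: the closed-loop tests demonstrate that each
analysis stage recovers the truth of data obeying its model assumptions at
realistic noise, not that the stages are robust to every artefact of real
recordings.

## Problem sizes and tolerances

The test suite runs at desk scale by choice: 96–160 px movie fields with
the frame interval scaled as τ/25 (≈ 250–400 frames per movie), 512–1024 px
AFM scans (≈ 256 nm fields, matching high-resolution scan sizes), and
10³–10⁵-particle membrane frames.  Parameter-recovery tolerances: fitted τ
within 3% (noiseless pipeline) and < 5% median over 50 movies at SNR 5;
final cumulative area within 3%; AFM period within one frequency bin
(`Δf = 1/(N·px)`) across spacings 6–12 nm, pixel sizes 0.25–1 nm and
arbitrary rotation/tilt; domain fractions within 1 percentage point;
curvature oracles as listed above.  Dense-grid energy minimisation
(2×10⁵–10⁶ points over 0–1 mm) agrees with the closed-form rolled length
within one grid step across 100 random parameter sets within ×/÷10 of the
reference values.
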