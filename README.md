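# memroll

Quantitative analysis of annexin-driven membrane remodelling in model
membrane systems.  Annexins are Ca²⁺-dependent membrane-binding proteins
central to plasma membrane repair: curvature-inducing members (ANXA4/A5)
roll supported membrane patches up from their free edges, while
crosslinking members (ANXA1/A2/A6) glue membranes together and hinder
rolling and unrolling.  `memroll` implements the four analyses used to
quantify this interplay, for biophysicists working with membrane patches,
supported bilayers, AFM scans and bilayer simulations:

* **Rolling energetics** — a spiral Helfrich model of the equilibrium
  rolled length.  The roll is an Archimedean spiral `r(θ) = r0 + (b/2π)θ`
  and the energy per unit roll width after arclength `L` has rolled is

      ΔE(L) = ∫₀ᴸ [ (k_c/2)((1/r(s) − c0)² − c0²) + w_ad ] ds ,

  with bending modulus `k_c`, spontaneous curvature `c0`, adhesion energy
  `w_ad` and pitch `b`; the rolled length `L*` minimises `ΔE`.  Parameter
  sweeps locate the adhesion factor or `c0` reduction at which rolling
  drops below the 1 µm optical resolution limit.
* **Rolling/unrolling kinetics** — incremental rolled area from frame
  differencing of time-lapse stacks, logistic fits
  `A/(1 + exp(−(t − t0)/τ))` for the rolling time constant τ and onset
  time, relative-area unrolling traces, edge line profiles, and Welch's
  t test.
* **AFM lattice & domains** — 2D-FFT lattice period of close-packed
  annexin-trimer crystals (~9 nm row spacing) and low/high height-domain
  area fractions where a GFP tag provides a ~2.7 nm height differential.
* **Curvature mapping** — bilayer midplane reconstruction from
  leaflet-labelled particle coordinates and Monge-gauge mean curvature
  `H`, averaged under a protein footprint across frames and replicas.
* **Synthetic data** — generators for all of the above, each paired with
  a ground-truth record, so the entire pipeline is testable without any
  experimental download.

See `docs/methods.md` for the model details, conventions and tolerances.

## Worked example

```python
import numpy as np
import memroll as m

# --- rolling energetics at the reference parameterisation ---------------
p = m.reference_params("results")   # k_c=1e-19 J, c0=3.33e7 /m, w_ad=1e-5 J/m^2
print(f"L* = {m.rolled_length(p)*1e6:.0f} um")
sweep = m.sweep_adhesion(p, np.linspace(1, 10, 19))
print(f"adhesion factor at 1 um limit: {sweep.critical_factor:.2f}")

# --- closed loop: synthetic rolling movie -> logistic tau ---------------
stack, truth = m.gen_rolling_movie(tau=10.0, onset=20.0, seed=5,
                                   noise_sigma=0.2, size_px=128,
                                   shape=9.0, frame_interval=0.4)
trace = m.incremental_rolled_area(stack)
fit = m.fit_logistic(trace)
print(f"tau = {fit.tau:.2f} s, onset = {fit.onset_time:.1f} s, "
      f"A = {fit.amplitude:.0f} um^2 (true {truth.parameters['amplitude_um2']:.0f})")

# --- AFM: trimer lattice period and domain fractions --------------------
hmap, _ = m.gen_afm_image(spacing=9.08, pixel_size=0.5, size_px=512,
                          seed=7, domain_fraction_high=30.0)
res = m.lattice_period(hmap)
labels, fr = m.segment_height_domains(hmap)
print(f"period = {res.period:.2f} nm, domains low/high = "
      f"{fr.low_fraction:.1f}%/{fr.high_fraction:.1f}%")
```

Output:

```
L* = 149 um
adhesion factor at 1 um limit: 5.22
tau = 9.81 s, onset = 20.4 s, A = 254 um^2 (true 254)
period = 9.08 nm, domains low/high = 70.0%/30.0%
```

The rolled length of ~149 µm says that at the reference parameters an
entire patch rolls up completely; raising the adhesion ~5-fold (modelling
crosslinking) suppresses rolling below the optical resolution limit.  The
movie loop recovers the generator's time constant within ~2% at SNR 5, and
the AFM loop recovers the trimer row spacing to the frequency-bin limit
and the domain composition to a fraction of a percentage point.

A command-line interface mirrors the library
(`memroll roll-model | roll-trace | roll-fit | unroll-trace | profile |
afm-period | afm-domains | midplane | curvature | footprint-h |
generate`); every analysis subcommand reads standard formats (multi-page
TIFF, CSV/text matrices, text particle frames, YAML parameters) and
writes CSV/JSON plus optional PNG plots.

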