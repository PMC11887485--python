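# nanosar

Analysis pipeline for **ssDNA-wrapped single-walled carbon nanotube
(SWCNT) optical sensors** of catecholamine-like analytes. The package
covers the computational side of a structure–activity screening study:

* **Screening** — near-infrared plate-reader spectra → blank-subtracted,
  integrated, dopamine-normalized responses ΔF/F = (F − F₀)/F₀ and the
  four response categories (I ≥ 1.00, II 0.75–1.00, III 0.15–0.50,
  IV < 0.10 relative to dopamine = 1.00).
* **Structure–activity statistics** — Pearson correlations of responses
  against molecular descriptors (Hammett σ, e_HOMO, reduction potential
  E°) and unpaired *t* tests between analyte groups (e.g. positively
  charged vs neutral).
* **pH modelling** — Henderson–Hasselbalch microspecies fractions,
  f(BH⁺) = 1/(1 + 10^(pH − pKa)), under an independent-site
  approximation, overlaid against ΔF(pH) profiles.
* **MD binding metrics** — for trajectories of analytes around a
  (9,4)-SWCNT wrapped by (GT)₆ ssDNA:
  buried contact areas s = (s_A + s_B − s_AB)/2 from Shrake–Rupley SASA;
  cylindrical surface distances d = r − r_SWNT; percentage of bound
  frames (contact > 1 Å²); binding-event segmentation (contact > 30 Å²,
  amine COM < 10.5 Å) and residence times
  τ_R = Σᵢ tᵢnᵢ / Σⱼ nⱼ = 1/k_off; aryl stacking distances; polar-group
  distance distributions within 10 Å with areas under the curve below
  4 Å; g(r); geometric hydrogen bonds; and an operationalized
  binding-mode classifier (stacking on DNA / on the nanotube /
  insertion / mixtures).
* **Synthetic data** — seeded generators for all of the above: emission
  spectra with prescribed ΔF/F, triplicate screening plates, and a
  cylinder-world trajectory simulator whose binding/unbinding follows a
  continuous-time Markov chain with known rates, so every estimator can
  be validated against ground truth.

## Worked example

```python
import numpy as np
from nanosar import metrics as M
from nanosar.synthetic import KineticParams, build_world, simulate_trajectory

world = build_world(seed=1)                      # (9,4) tube + 3 DNA strands
kin = KineticParams.two_state(k_on=0.04, k_off=0.04, dt=1.0,
                              n_frames=9000, seed=2)
bundle, truth = simulate_trajectory(world, kin)  # 6 analyte molecules

series = M.contact_series(bundle, "conjugate", n_sphere_points=128)
events = M.segment_binding_events(series)
res = M.residence_time(events)
_, bound_pct = M.bound_fraction(series)

print(f"radius  {M.swcnt_cylinder(bundle).radius:.3f} A")
print(f"tau_R   {res.tau_R:.1f} frames over {res.n_events} events")
print(f"% bound {bound_pct:.1f}")
```

Output:

```
radius  4.517 A
tau_R   23.9 frames over 1097 events
% bound 48.7
```

The fitted radius matches the (9,4) closed form
a·√(n² + nm + m²)/(2π) = 4.517 Å; the residence time recovers the
simulator's mean dwell 1/k_off = 25 frames, and the bound percentage
recovers the stationary occupancy k_on/(k_on + k_off) = 50 %.

A CLI mirrors the library:
`nanosar screen`, `nanosar correlate`, `nanosar phmodel`,
`nanosar traj`, and `nanosar simulate {traj,screen}` (see `--help`).

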