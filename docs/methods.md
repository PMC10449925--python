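# Methods

This note records the models implemented in `proteinglue`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Sequence propensity (P_HAP)

Hexapeptide windows are enumerated per chain (width 6 by default,
configurable); windows never cross chain boundaries, but all chains of a
multi-chain protein pool into one denominator. The HAP cutoff is
**inclusive** (energy ≤ −23 kcal/mol), and so is the solidification
threshold (P_HAP ≥ 16.77%): the packaged survey places its boundary protein
(thyroglobulin) exactly at 16.77% with an observed "yes", so the inclusive
convention is the only one that keeps the survey internally consistent.

External energy tables are validated row-by-row against the sequence
(window string must match the substring); missing windows warn and, by
default, shrink the P_HAP denominator to the loaded windows (a strict mode
requires full coverage). This tolerates database exports that skip
unscoreable segments. Note the published per-protein P_HAP values imply a
windowing/denominator convention that cannot be verified without the
original database export; the packaged survey therefore stores the printed
percentages themselves, and the survey classifier consumes those, never
surrogate output.

**Surrogate energy.** `E = c0 + c_h·mean(KD) + c_b·mean(Pβ)` over the
window, with the Kyte–Doolittle hydropathy and Chou–Fasman β-propensity
scales shipped as data files (citations in the file headers) and default
coefficients (−10, −2, −5). These place poly-serine at −12.15 kcal/mol
(benign) and poly-valine at −26.9 kcal/mol (amyloidogenic), straddling the
−23 cutoff with margin. The surrogate is deterministic and is *only* a
stand-in scorer for offline work; it makes no claim to reproduce
steric-zipper database energies. Unknown residues (including "X") are
rejected, never imputed.

## Curing-front model

State: water concentration c(r, t) on a uniform 1D grid with an
irreversible boolean solid mask. Phase dichotomy: diffusivity D₁ where the
mask is liquid, D₂ where solid; the mask latches wherever c ≥ C_c
(the "≥" branch of the piecewise law). Solidification is never undone by
later dilution.

Discretisation: conservative finite volume. Face diffusivities are
**harmonic means** of the adjacent cells' phase diffusivities, which keeps
the flux continuous across the solid/liquid interface. Geometries:

- `radial` (default): axisymmetric disk of radius 3 mm (the 6 mm round
  glass sheet), Dirichlet c = c_boundary at the rim over a half cell,
  zero-flux at r = 0. The thin sandwiched glue layer justifies dropping the
  axial dimension; the observed pattern is a rim ring.
- `planar`: Dirichlet at x = 0, zero-flux at the far end; used as the
  semi-infinite proxy for validation.

Time integration is explicit with dt = safety·dr²/(2·max(D₁,D₂)),
safety = 0.4; `step` refuses a larger dt. The scheme's interior mass change
per step equals the boundary influx to round-off (bookkeeping exposed via
`total_mass` and `boundary_influx`), values obey the discrete maximum
principle, and refinement studies show first-order-or-better convergence of
the ring width.

**Front observables.** `ring_width` is the width of the contiguous solid
region attached to the wetted boundary (cell-resolution, matching the
fluorescence-image measurement of a growing ring); `front_position`
linearly interpolates the c = C_c level set for smooth diagnostics. In the
single-diffusivity planar limit the solver matches
`c(x,t) = c_b + (c₀−c_b)·erf(x/2√(Dt))` to ~7·10⁻⁶ of the concentration
span on a 400-cell grid, and the interpolated front grows as √t
(R² > 0.999 after a 20% transient) with slope matching
`2√(D)·erf⁻¹((C_c−c_b)/(c₀−c_b))`.

**Defaults.** C_c = 38.9 mol/L ↔ 70% water by volume; the pure-water
molarity constant is 55.56 mol/L (1000 g/L ÷ 18.0 g/mol), the round-number
convention that reproduces the 38.9 calibration at three significant
figures. c_init = 11.1 mol/L (20% water in the 80%-stabilizer
formulation). D₁ = 1·10⁻¹⁰ and D₂ = 5·10⁻¹⁰ m²/s are order-of-magnitude
choices for water in a concentrated polymer phase, with D₂ > D₁ because
solidification creates interconnected water-filled pores that speed
diffusion; measured values for a given formulation should replace them.
Because D₁/D₂ are not published, simulated ring widths are validated by
the analytic oracle and qualitative front behaviour, not against measured
ring-width curves. A 2D mode for irregular droplet shapes was considered
and deliberately left out; the radial/planar pair covers the disk
experiment and the validation limit with one code path.

## Trajectory metrics

Inputs are multi-frame XYZ files (comment line: `time=<ns> box=<nm,nm,nm>`)
plus a roster CSV tagging every atom with residue and group
(`protein`/`water`/`surface`) — a deliberately simple text convention for
desk-scale scripted trajectories; frames are assumed whole, with an
optional orthorhombic minimum-image mode.

- **Contact time**: first frame at which the minimum residue–surface atom
  distance is strictly < 0.35 nm (one water diameter); "never" if no frame
  qualifies. The interface is all surface-group atoms.
- **Surface water**: the plane is the maximal surface-atom coordinate along
  the normal (default z); water oxygens with height in [0, 0.35 nm) are
  binned on a 2D grid; zero bins are the dry patches.
- **Hydrogen bonds**: donor–acceptor distance ≤ 0.35 nm and H–D–A angle
  ≤ 30° — the common MD-analysis geometric convention, since no criterion
  is standard across engines.
- **SASA**: Shrake–Rupley with a Fibonacci point lattice (default 256
  points/atom, probe 0.14 nm) over shipped Bondi vdW radii; converges to
  the closed-form sphere area for isolated atoms and is additive at large
  separation.
- **Shear strength**: τ = F/A with mandatory unit tags; kJ/mol/nm forces
  are divided by Avogadro's number and 10⁻⁹ m. No attempt is made to infer
  an effective contact area: a pull trace plus the true bonded area are the
  caller's inputs. (A published molar breaking force of order
  10³ kJ/mol/nm corresponds to ~10⁻⁹ N; the stress depends entirely on the
  area it is divided by, which is why the tags are mandatory.)
- **Hydrophobicity index**: Kyte–Doolittle by default (the field's default
  "hydrophobicity index"); isoleucine is the scale maximum, arginine the
  minimum.

## Solution-state analytics

- **Guinier**: fit ln I vs q², Rg = √(−3·slope); the fit is iterated,
  trimming to q·Rg ≤ 1.3 until the retained set is stable. Non-negative
  slopes and windows with < 3 points are errors, not numbers.
- **Kratky**: y = I·q²; flag "peaked-globular" when the interior maximum
  (outside the last quarter of points) exceeds the tail mean by 1.5×, else
  "plateau-unfolded"; degenerate tails are "inconclusive". This mirrors the
  visual judgement usually applied to Kratky plots and is declared a
  heuristic.
- **Viscometry**: Einstein law η/η₀ = 1 + 2.5φ with φ = v̄c
  (v̄ = 0.73 mL/g, typical protein partial specific volume) has *no free
  parameter*; its R² is computed on relative viscosity. Huggins law
  η_sp/c = [η] + k_H[η]²c is fitted linearly in the reduced-viscosity
  representation; a zero-variance reduced viscosity (exact hard-sphere
  data, where the Huggins form is degenerate) reports R² = 0. The verdict
  goes to the model leading by more than the tie band (0.05); if both R²
  sit below 0.5 the call is inconclusive. Computing each R² in its own
  representation avoids the nesting problem (Huggins contains Einstein as
  a special case) that would otherwise make exact spherical data a tie.
- **Bragg**: d = λ/(2 sin θ), λ = 0.154 nm (Cu target). The 19.2° β-sheet
  interchain peak gives 0.46 nm; the 23.9° peak computes to 0.372 nm even
  though it is sometimes annotated 0.35 nm — the function reports the
  computed value.

## Synthetic-data generators

All generators are deterministic functions of (parameters, seed), use one
`numpy` Generator per invocation, record the seed in their truth output,
and emit machine-readable truth files so round-trip tests read truth rather
than re-deriving it.

- **Sequences**: one poly-valine run at the sequence start, length chosen
  so that *exactly* `round(f·n_windows)` windows score ≤ −23 under the
  surrogate; the hydrophilic alphabet (S,N,G,D,K,Q,E,R,H,T,P) is chosen so
  no window with fewer than five valines can cross the cutoff. Realized
  fractions are re-scored, never assumed, and land within 0.5/n_windows of
  the target. This scripts composition, not realistic protein statistics.
- **Energy tables**: exactly `round(target·n)` windows drawn without
  replacement get energies in [−30, −23.5]; the rest in [−20, −5].
- **Trajectories**: a 7×7 silica-like slab at z = 0, one pseudo-atom per
  residue placed above slab columns, oxygen-only waters. Scenarios script
  geometry directly: scheduled residues drop from 1.2 nm to 0.30 nm at
  their contact frame; hydration sweeps place the scripted number of waters
  at 0.2 nm. No forces, no dynamics — the generators exist to give the
  metrics exact, known answers.
- **Scattering**: I(q) = exp(−q²Rg²/3) on 50 points inside q·Rg ≤ 1.3,
  multiplicative lognormal noise of given CV (default grid stays in the
  Guinier regime by construction).
- **Viscosity**: series from the pinned Einstein or Huggins forms
  (defaults: η₀ = 1.2 mPa·s, c = 0.02–0.10 g/mL over 8 points,
  [η] = 8 mL/g and k_H = 0.4 for chains, v̄ = 0.73 mL/g for spheres),
  multiplicative Gaussian noise CV 0.01. These defaults were fixed by a
  design simulation (recovery ≥ 95% over 200 seeded replicates) before the
  tests were frozen. The concentration range keeps the reduced-viscosity
  noise amplification (σ/c) bounded, which is what a careful viscometry
  design would do.

Passing round-trip tests on these generators demonstrates that the metrics
and fitters are correct on data whose ground truth is known exactly; it
does not demonstrate robustness to the messiness of real SAXS backgrounds,
real trajectories (periodic wrapping, hydrogen networks) or polydisperse
samples.

## Problem sizes

Default runs are desk-scale by design: diffusion validations use 200–400
cells (seconds), the randomized property sweep uses 100 configurations of
24–64 cells, oracle-equivalence frames stay ≤ 200 atoms, and the
stochastic studies use 200 viscometry replicates and 100 scattering seeds.

## Known limitations

- The surrogate scorer ranks windows sensibly but is not a steric-zipper
  energy; published per-protein P_HAP values cannot be regenerated from
  sequence without the external database.
- The curing model is single-species (water); stabilizer counter-diffusion,
  curing stresses and 3D droplet shapes are out of scope.
- The trajectory toolkit analyses trajectories, it does not create
  physically realistic ones; binding free energies and secondary-structure
  assignment are out of scope.
- The Kratky shape call and the viscometry tie band are heuristics with
  documented defaults, not statistical tests.
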