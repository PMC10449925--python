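# Units and indexing conventions

Enforced by the readers and constructors; stated once here.

- Lengths: nm in trajectories and scattering (q in nm⁻¹); m in the curing
  model (grid, ring width).
- Times: ns in trajectories; s in the curing model.
- Concentrations: mol/L (water); g/mL (solute in viscometry).
- Energies: kcal/mol (segment energies); forces tagged N or kJ/mol/nm;
  areas tagged m², cm² or nm²; stresses in Pa.
- Angles: degrees (2θ in diffraction, hydrogen-bond angle cutoffs).
- Viscosities: mPa·s.
- Residue positions are 1-based within a chain; chain indices are 0-based.
- Window starts are 1-based; a window of width w at start s covers
  residues [s, s+w−1] of its chain and never crosses chains.
- Trajectory group tags form the closed set {protein, water, surface};
  water oxygens are atoms in group `water` whose name starts with "O".
- Percent quantities (P_HAP, swelling ratio) are reported on the 0–100
  scale; fractions on 0–1. Constructors reject out-of-range values.
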