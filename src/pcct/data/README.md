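# Packaged data tables

All tables here are **synthetic** plain-text stand-ins so the package runs
fully offline:

- `matten_<material>_synthetic.txt` — mass attenuation mu/rho (cm^2/g) on a
  1 keV grid from 10 to 150 keV, from a two-term parametric model
  (photoelectric ~ E^-3 + Klein-Nishina Compton shape) least-squares fitted
  to approximate anchor values at 30/60/100 keV. The material density is
  recorded in the header.
- `spectrum_120kvp_synthetic.txt` — a 120 kVp source spectrum on a 1 keV grid
  from 12 to 120 keV: Kramers-law bremsstrahlung filtered by 0.8 mm Be,
  1.0 mm Al and 0.11 mm Cu.
- `detector_constants.yaml` — default CdTe fluorescence energies, K-edges and
  branch-probability parameters for the parametric detector response.

Regenerate with `python scripts/make_data_tables.py` from the repo root.
These curves are simulator inputs, not reference physics data.
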