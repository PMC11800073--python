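# Default CdTe sensor constants for the parametric charge-splitting response.
# Fluorescence energies are the Cd and Te K-alpha values; K-edges gate which
# incident energies can produce fluorescence at all.  Branch-probability
# parameters are plausible defaults for a ~2 mm CdTe sensor and are fully
# configurable; they are inputs to the simulator, not ground truth.
fluorescence:
  cd_k_alpha_kev: 23.2
  te_k_alpha_kev: 27.5
k_edges:
  cd_kev: 26.7
  te_kev: 31.8
branch_probabilities:
  # free penetration grows smoothly with energy: p_pen(E) = base + gain * ((E - e0) / span)^2
  penetration_base: 0.01
  penetration_gain: 0.30
  penetration_e0_kev: 12.0
  penetration_span_kev: 108.0
  # above the K-edges a fixed share of detected photons excites fluorescence;
  # of those, `lost` leave the pixel and `reabsorbed` deposit fully.
  fluorescence_lost: 0.15
  fluorescence_reabsorbed: 0.25
energy_blur_sigma_kev: 2.0
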