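"""Image quality of a stiff-lesion phantom vs filter dimensionality.

Reconstructs the 12 kPa spherical-lesion phantom (2 m/s in a 1 m/s
background) from one 25-dB noise realization, without filtering and with
2-D, 3-D and 4-D directional filters, then reports lesion CNR and
within-lesion percent bias.  CNR rises steeply once backward-traveling
reflected waves are removed; higher filter dimensionality also strips
noise and out-of-plane wave components.

Runtime: a couple of minutes at the desk grid.
"""

from shearwave import FilterSpec, add_awgn, presets, simulate_displacements
from shearwave.quality import evaluate_experiment

phantom = presets.lesion_phantom(12.0)
field = simulate_displacements(phantom, presets.excitation(1), presets.desk_grid(), seed=0)
noisy = add_awgn(field, snr_db=presets.SNR_DB, seed=0)

specs = [None, FilterSpec(2), FilterSpec(3), FilterSpec(4)]
df = evaluate_experiment([noisy], specs, "image2d", phantom)
print(df[["filter_dim", "cnr", "bias_mean", "bias_median", "bias_iqr"]].to_string(index=False))
print("\nfilter_dim 0 = unfiltered. Expect CNR to increase and the bias "
      "spread (IQR) to collapse once directional filtering removes the "
      "reflected-wave artifact.")
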