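"""Extract the four per-channel EEG feature types from synthetic epochs.

Generates band-limited multichannel signals whose spectral content
depends on the class (class 1 carries an alpha-band tone, class 2 a
beta-band tone), then extracts band power (PSD), differential entropy
(DE), Higuchi fractal dimension (FD) and mean absolute value (MAV) —
10 values per channel each — and shows that the alpha-band PSD feature
separates the classes.
"""

import numpy as np

from dasrc import FeatureConfig, featurize_domain, generate_class_signals

epochs = generate_class_signals(
    n_epochs=40,
    channels=4,
    sampling_rate=128.0,
    class_band_map={1: (8.0, 13.0), 2: (13.0, 30.0)},
    noise_sd=0.5,
    seed=0,
)

for feature in ("psd", "de", "fd", "mav"):
    dom = featurize_domain(epochs, FeatureConfig(feature))
    print(f"{feature}: feature matrix {dom.X.shape[0]} x {dom.X.shape[1]} "
          f"(10 per channel x 4 channels)")

psd = featurize_domain(epochs, FeatureConfig("psd"))
# channel-major layout: channel 0's ten values are rows 0..9; alpha-band
# power of the two half-windows sits at rows 2 and 7
alpha = psd.X[[2, 7]].mean(axis=0)
for c in (1, 2):
    print(f"class {c}: mean alpha-band power {alpha[psd.labels == c].mean():.3f}")
# The alpha-tone class shows clearly higher alpha-band power.
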