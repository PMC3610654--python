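"""How correlations between kinetic parameters change noise suppression.

Builds extrinsic covariance matrices over (k_R, k_P, gamma_R, gamma_P) with
the same per-parameter variances but different correlation structures — the
independent (diagonal) reference, the favourable sign pattern for the
transcriptional circuit (transcription/translation correlated, the two
degradation rates correlated, everything else anti-correlated), its
opposite, and random correlation matrices projected to validity with
Higham's nearest-correlation algorithm — and screens the autoregulatory
circuit under each.
"""

import warnings

import numpy as np

from totalnoise import covariance_screen

grid = np.logspace(-4, -2, 7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # sign flips during projection are benign here
    scr = covariance_screen("transcriptional", grid, n_matrices=3,
                            sds=0.15, seed=7, hill=2)

print("correlation structure                min CV^2_r over the sweep")
for label in sorted(scr.results):
    print(f"  {label:35s} {scr.results[label].min_cv2r():8.3f}")
print("\nspread of CV^2_r across the random matrices, per strength:")
print(scr.spread.to_string(index=False))
print("\nThe favourable pattern beats independent parameters; the opposite "
      "pattern is worst — correlations matter when no single parameter "
      "dominates the extrinsic variance.")
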