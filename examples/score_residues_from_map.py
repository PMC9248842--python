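"""Estimate residue-type probabilities from a density map.

Synthesizes a 2.5 A map from an ideal helical model with side chains,
then runs the baseline density-correlation scorer on the backbone alone
and compares its top-1 calls with the true sequence.
"""

import numpy as np

import registercheck as rc
from registercheck.alphabet import AA_ORDER
from registercheck.density_scorer import score_backbone

rng = np.random.default_rng(3)
sequence = rc.random_sequence(rng, 40)
model = rc.build_helix_model(sequence)
volume = rc.synthesize_map(model, resolution=2.5, voxel=1.0)

profile = score_backbone(model.backbone_dicts(), volume, resolution=2.5)
predicted = "".join(AA_ORDER[i] for i in profile.probabilities.argmax(axis=1))
accuracy = np.mean([p == t for p, t in zip(predicted, sequence)])

print(f"true sequence:      {sequence}")
print(f"top-1 prediction:   {predicted}")
print(f"top-1 accuracy:     {accuracy:.0%}")

# The scorer sees only backbone coordinates and density.  At 2.5 A it
# recovers ~85-90% of types; confusions stay within similar-shape groups
# (e.g. D/N/L or T/V), which is why downstream assignment works on whole
# fragments rather than single residues.
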