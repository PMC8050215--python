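"""Feature-based decoding vs emotion-content bias baseline.

Choices here are driven by feature differences whose readout is projected
orthogonal to the class-mean structure, so a preference for (say) happy
faces carries no information.  The bias baseline predicts from training-set
expression preferences with the same folding.
"""

import gazedecode as gd

s = gd.bias_dissociation_study(seed=8, n_participants=4, n_identities=12,
                               n_repeats=12)
for i, (f, b) in enumerate(zip(s["feature_accuracy"], s["bias_accuracy"])):
    print(f"participant {i}: features {f:.3f} vs emotion bias {b:.3f}")
print(f"feature decoding wins in {s['fraction_feature_wins']:.0%} of "
      f"participants (features {s['feature_mean']:.3f} vs bias "
      f"{s['bias_mean']:.3f} on average)")
print("Bias accuracy hovers near 0.5 because the simulated choices carry no "
      "emotion-content signal; the image features still predict them.")
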