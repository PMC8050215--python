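"""Extract Fourier and HOG features from synthetic face stimuli.

Renders a small stimulus set, extracts both feature families from one face,
and forms the right-minus-left trial difference the decoder consumes.
"""

import numpy as np

import gazedecode as gd

faces = gd.generate_faces(n_identities=3, seed=1)
print(f"rendered {len(faces)} stimuli "
      f"({sorted({im.expression for im in faces})} x 3 identities)")

happy = next(im for im in faces if im.expression == "happy")
angry = next(im for im in faces if im.expression == "angry")

fourier = gd.fourier_features(happy)
hog = gd.hog_features(happy, gd.HOGSpec(cell_size_px=10))
print(f"Fourier features: {len(fourier)} (24 SF bands x 16 orientation bands)")
print(f"HOG features:     {len(hog)} (276 in-aperture cells x 9 orientations)")

# a trial: happy left, angry right, observer looked right
td = gd.trial_difference(gd.fourier_features(happy), gd.fourier_features(angry),
                         chosen_side="right", condition=("happy", "angry"))
print(f"trial difference: length {len(td.diff.values)}, label {td.label} "
      f"(1 = right chosen), largest |difference| = "
      f"{np.abs(td.diff.values).max():.1f}")
print("The difference vector is what the decoder sees: positive entries mean "
      "the right face has more contrast energy in that band.")
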