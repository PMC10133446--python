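"""Build the jnd-scaled feature ladders behind each experiment's singletons.

Brightness steps are 5% of the spectral centroid per jnd; roughness steps
are 0.10 of modulation depth per jnd.  Additive ladders step linearly from
the base; compound ladders step multiplicatively.
"""

import timbrecapture as tc

ladders = {
    "brightness, additive x{1,2,5,10} from 512 Hz":
        tc.FeatureLadder("brightness_sc", 512.0, 0.05, (1, 2, 5, 10), "additive"),
    "roughness, additive x{1,2,5,10} from depth 0":
        tc.FeatureLadder("roughness_depth", 0.0, 0.10, (1, 2, 5, 10), "additive"),
    "brightness, compound x{2,5} from 512 Hz":
        tc.FeatureLadder("brightness_sc", 512.0, 0.05, (2, 5), "compound"),
    "brightness, compound x{-4,-2,2,4} around 631 Hz":
        tc.FeatureLadder("brightness_sc", 631.0, 0.05, (-4, -2, 2, 4), "compound"),
}

for label, ladder in ladders.items():
    exact = ", ".join(f"{v:.2f}" for v in tc.build_ladder(ladder))
    rounded = tc.rounded_ladder(ladder)
    print(f"{label}\n  exact: [{exact}]\n  reported: {rounded}")

print(
    "\nThe reported values are what a participant hears as 1, 2, 5 or 10 "
    "just-noticeable differences away from the distractor."
)
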