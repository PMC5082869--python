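"""Three-phase RMS demodulation on synthetic grid-modulated frames.

Builds three frames of a scene modulated by a shifted illumination grid
(phases 0, 2pi/3, 4pi/3) with an out-of-focus layer whose modulation is
attenuated, demodulates them, and prints how well the sectioned image
recovers the in-focus plane while rejecting the defocused one.
"""

import numpy as np

from pseudohe import PhantomSpec, generate_phantom, rms_demodulate
from pseudohe.phantom import modulated_frames

spec = PhantomSpec(image_shape=(256, 256), n_nuclei=60, n_lumina=1,
                   n_rows=1, n_cols=1, overlap_px=0, rng_seed=42)
scene = generate_phantom(spec)
in_focus = scene.e_truth
defocus = 0.4 * np.roll(scene.e_truth, 40, axis=0)  # displaced blurred-ish layer
attenuation = 0.12  # grid contrast surviving at the layer's defocus

frames = modulated_frames(in_focus, spec, defocus=defocus,
                          attenuation=attenuation)
out = rms_demodulate(frames)

m = spec.modulation_depth
recovered = out.sectioned / m
print(f"modulation depth m = {m}, layer attenuation a = {attenuation}")
print(f"widefield mean (in-focus + layer): {out.widefield.mean():.4f}")
print(f"sectioned/m mean (in-focus + a*layer): {recovered.mean():.4f}")
print(f"in-focus plane mean: {in_focus.mean():.4f}, layer mean: {defocus.mean():.4f}")
err = np.abs(recovered - (in_focus + attenuation * defocus)).max()
print(f"max deviation from the closed-form prediction: {err:.2e}")
print()
print("The widefield image carries the full defocused layer; the sectioned")
print("image carries it scaled by its grid-contrast attenuation — that is")
print("the optical sectioning the three-phase demodulation buys.")
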