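"""Render the unit colors of the virtual-H&E mapping.

Builds single-pixel stain inputs, applies the RGB remapping, and prints the
resulting colors: zero stain is paper-white, a saturated DRAQ5 (nuclear)
pixel renders the hematoxylin-like blue-purple, a saturated eosin pixel
renders pink, and a doubly saturated pixel darkens with its green plane
clipped at zero.
"""

import numpy as np

from pseudohe import map_rgb

cases = {
    "background (D5=0, E=0)": (0.0, 0.0),
    "pure nuclear (D5=1, E=0)": (1.0, 0.0),
    "pure eosin   (D5=0, E=1)": (0.0, 1.0),
    "double stain (D5=1, E=1)": (1.0, 1.0),
}

for name, (d5, e) in cases.items():
    rgb = map_rgb(np.array([[d5]]), np.array([[e]])).rgb[0, 0]
    print(f"{name}: RGB = ({rgb[0]:.2f}, {rgb[1]:.2f}, {rgb[2]:.2f})")

print()
print("The unit colors are the rendered appearance of each saturated stain;")
print("intermediate intensities interpolate linearly toward white, which is")
print("why unstained background renders as blank slide.")
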