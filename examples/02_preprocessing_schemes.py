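"""Apply the three chamber pre-processing schemes to one capture.

Crop keeps only the ROI pixels; the alpha mask (AM) multiplies the image by
0.5 everywhere except the ROI; CEAM additionally concatenates a 75-row strip
from the adjacent capture area along the shared edge before masking.
"""

import numpy as np

from patchtest import PhantomConfig, generate_cohort
from patchtest.preprocess import apply_alpha_mask, apply_ceam, crop_roi

cohort = generate_cohort(PhantomConfig(n_patients=1, chambers_per_area=6, seed=0))
area1, area2 = cohort.captures
annotation = area1.annotations[4]  # a chamber in the bottom row of area 1
image = area1.images.color
adjacent = area2.images.color

crop = crop_roi(image, annotation.bbox)
am = apply_alpha_mask(image, annotation.bbox)
ceam = apply_ceam(image, annotation.bbox, adjacent, area_index=1)

print(f"source image:      {image.shape[0]}x{image.shape[1]}")
print(f"crop output:       {crop.image.shape[0]}x{crop.image.shape[1]}  (ROI only)")
print(f"alpha-mask output: {am.image.shape[0]}x{am.image.shape[1]}  (full frame, context dimmed)")
print(f"CEAM output:       {ceam.image.shape[0]}x{ceam.image.shape[1]}  (75 context rows appended)")

inside = am.image[annotation.bbox.y0:annotation.bbox.y1, annotation.bbox.x0:annotation.bbox.x1]
source = image[annotation.bbox.y0:annotation.bbox.y1, annotation.bbox.x0:annotation.bbox.x1]
outside_ratio = am.image[0, 0].astype(float) / np.maximum(image[0, 0].astype(float), 1)
print(f"ROI pixels unchanged by AM: {np.array_equal(inside, source)}")
print(f"background scaling at corner pixel: {outside_ratio.round(2)}  (alpha = 0.5)")
print()
print("CEAM keeps the whole frame plus the neighboring area's edge rows, so a")
print("classifier can see reactions spilling over from adjacent chambers.")
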