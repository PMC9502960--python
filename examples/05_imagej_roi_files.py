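"""Reading and writing ImageJ .roi files and .zip bundles.

Annotations drawn with ImageJ's ROI tools can be loaded directly; the
package writes the same binary format back (sub-pixel polygon records,
composite records for multi-ring lesions).
"""

import io

import numpy as np

from chorioconcord import (
    RegionOfInterest,
    polygon_area_px,
    read_imagej_roi,
    read_roi_zip,
    write_imagej_roi,
    write_roi_zip,
)

# a single-ring lesion outline
ring = np.array([(100.5, 80.25), (220, 90), (240, 200), (150, 260), (90, 180)])
roi = RegionOfInterest([ring])
data = write_imagej_roi(roi)
print(f"single-ring ROI -> {len(data)} bytes, magic {data[:4]!r}")
back = read_imagej_roi(data)
print(f"round-trip vertex error: {np.abs(back.rings[0] - ring).max():.2e} px")

# a multifocal lesion: two disjoint rings in one composite record
th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
spots = [
    np.column_stack([cx + 20 * np.cos(th), 150 + 20 * np.sin(th)]) for cx in (300, 400)
]
multi = RegionOfInterest(spots)
back2 = read_imagej_roi(write_imagej_roi(multi))
print(
    f"composite ROI: {len(back2.rings)} rings, total area "
    f"{polygon_area_px(back2):.1f} px^2 (two 20 px-radius spots ~ {2*np.pi*400:.1f})"
)

# a .zip bundle, as ImageJ's ROI manager saves them
buf = io.BytesIO()
write_roi_zip([roi, multi], buf, names=["lesion.roi", "spots.roi"])
buf.seek(0)
bundle = read_roi_zip(buf)
print(f"zip bundle: {len(bundle)} ROIs in archive order")
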