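"""Render a synthetic field of view, segment it, and gate the nuclei.

Nuclei are drawn as uniform ellipses in the H2B-GFP channel with exact
ground-truth label masks; segmentation (Gaussian smooth, Otsu, watershed)
recovers them, areas are converted to um^2 with the pixel calibration,
and the filter stack applies the border / area / BFP-infection / size
gates.
"""

from optenrich import EffectModel, FilterConfig, apply_filters, build_library
from optenrich import render_field, segment_nuclei
from optenrich.imaging import layout_cells
from optenrich.library import default_efficacies, simulate_population

lib = build_library(10, 0, 10, 5, seed=0)
effects = EffectModel(sgrna_efficacy=default_efficacies(lib, seed=0))
cells = simulate_population(lib, effects, 50, 0.95, seed=3)
placed = layout_cells(cells, (1536, 1536), seed=3)
field = render_field(placed, (1536, 1536), noise=(60.0, True), seed=3)

labels, measurements = segment_nuclei(
    field.channels["gfp"], field.pixel_size,
    channels={"bfp": field.channels["bfp"]},
)
print(f"rendered {len(field.truth)} nuclei, segmented {len(measurements)}")

res = apply_filters(measurements, FilterConfig(size_threshold=1000.0))
print(f"selected (area > 1,000 um^2): {len(res.selected)}, "
      f"analyzed negatives: {len(res.negatives)}, "
      f"rejected: {len(res.rejected)}")
areas = sorted(m.area for m in measurements)
print(f"area range: {areas[0]:.0f}-{areas[-1]:.0f} um^2 "
      "(most wild-type nuclei sit far below the screening threshold)")
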