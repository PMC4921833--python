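"""Per-cell nuclear vs cytosolic nascent-RNA quantification.

Simulates four 3-channel imaging fields (nuclei / troponin-I marker /
EU-RNA), segments nuclei and cell territories, gates cardiomyocytes on
cytosolic marker overlap, and measures background-subtracted EU intensity
separately in the nucleus and the cytosol of every cell.
"""

import pandas as pd

from cardioquant import (
    ImageSimConfig,
    quantify_field,
    simulate_image_fields,
    summarize_condition,
)

cfg = ImageSimConfig(seed=7)
fields, truth = simulate_image_fields(cfg, n_fields=4)
print(f"simulated {len(fields)} fields, {len(truth)} cells "
      f"({int(truth.marker_positive.sum())} marker-positive)")

tables = []
for fld in fields:
    seg, cells = quantify_field(fld)
    print(f"  {fld.field_id}: {len(seg.cell_ids)} cells segmented "
          f"({int(cells.is_cardiomyocyte.sum())} cardiomyocytes)")
    cells["condition"] = "demo"
    tables.append(cells)
cells = pd.concat(tables, ignore_index=True)

summary = summarize_condition(cells).iloc[0]
print(f"\nover {summary.n_cardiomyocytes} cardiomyocytes "
      "(marker-positive, not edge-touching):")
print(f"  mean nuclear EU   {summary.mean_nuclear_eu:7.1f}  "
      f"(generator contrast {cfg.nuclear_eu - cfg.eu_background:.0f})")
print(f"  mean cytosolic EU {summary.mean_cytosolic_eu:7.1f}  "
      f"(generator contrast {cfg.cytosolic_eu - cfg.eu_background:.0f})")
print(f"  mean cell area    {summary.mean_cell_area:7.1f} px "
      f"(ground truth {truth[truth.marker_positive].cell_area_px.mean():.1f})")
print("\nEU intensities are medians-of-background subtracted; nuclear and "
      "cytosolic values come from disjoint masks that partition each cell.")
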