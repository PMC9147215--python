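"""Generate a synthetic patient panel and inspect its structure.

Real metabolic-panel records are protected health information, so the
package ships a generator that reproduces the *shape* of such data: ~42
irregularly spaced blood draws over ~a year, nine cross-correlated indices,
a few missing cells and occasional outliers.
"""

import numpy as np

from panelcast import SyntheticConfig, generate_panel, write_panel_csv

panel = generate_panel(SyntheticConfig(seed=7))

print(f"visits:        {panel.n_visits}")
print(f"span (days):   {panel.span_days:.0f}")
print(f"indices:       {', '.join(panel.index_names)}")
print(f"missing cells: {int(panel.missing_mask.sum())}")
gaps = np.diff(panel.day_offsets)
print(f"visit gaps:    min {gaps.min():.0f} d, median {np.median(gaps):.0f} d, "
      f"max {gaps.max():.0f} d")

write_panel_csv(panel, "panel.csv")
print("wrote panel.csv (ISO dates, one column per index, blank = missing)")
# The gap statistics show the irregular sampling the preprocessing stage
# must bridge before any recurrent model can be trained.
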