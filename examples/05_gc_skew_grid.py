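"""Strand-faceted GC-skew / GC-fraction enrichment of R-loop windows.

The genome is tiled into 50 bp windows; GC skew (G - C)/(G + C) is expressed
on the transcribed (sense) strand. R-loop windows (observed) are compared to
the rest of the genome (expected) on a binned (skew, GC) grid per facet.
"""

import numpy as np

from rloopm5c import (SimulationParams, build_obs_exp_grid, simulate_dataset,
                      windowed_gc_stats)

ds = simulate_dataset(SimulationParams(seed=1))
windows = windowed_gc_stats(ds.genome, 50, ds.transcripts, ds.rloops)

defined = windows.gc_skew.notna()
obs = windows[windows.in_rloop & defined]
exp = windows[~windows.in_rloop & defined]
print(f"{len(windows)} windows; {len(obs)} in R-loops")
print(f"mean sense-strand skew: R-loop {obs.gc_skew.mean():+.3f} "
      f"vs rest {exp.gc_skew.mean():+.3f}")
print(f"mean GC fraction:       R-loop {obs.gc_fraction.mean():.3f} "
      f"vs rest {exp.gc_fraction.mean():.3f}")
# Planted R-loops carry sense skew +0.4 at GC 0.6 on a 0.45-GC background;
# both excesses are recovered from sequence alone.

grids = build_obs_exp_grid(windows, skew_bin_width=0.1, gc_bin_width=0.05)
for facet, g in grids.items():
    ratio = g.ratio
    i, j = np.unravel_index(np.nanargmax(ratio), ratio.shape)
    print(f"facet {facet!r}: strongest enrichment ratio "
          f"{np.nanmax(ratio):.1f} at skew "
          f"[{g.skew_edges[i]:+.1f},{g.skew_edges[i+1]:+.1f}) x GC "
          f"[{g.gc_edges[j]:.2f},{g.gc_edges[j+1]:.2f})")
# On both transcribed-strand facets the high-skew, high-GC cells are
# enriched — positive skew means G-rich on the strand that becomes the RNA.
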