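"""Generate a synthetic four-condition bisulfite + DRIP-seq dataset.

Builds a 100 kb genome with 40 transcripts, 20 GC-skewed R-loop regions,
200 TRDMT1-dependent and 200 independent m5C sites, then prints the truth
table structure. Every downstream stage can be checked against this truth.
"""

from rloopm5c import SimulationParams, simulate_dataset, write_dataset

ds = simulate_dataset(SimulationParams(seed=1))
paths = write_dataset(ds, "scratch/example_data")

print(f"genome: {sum(ds.genome.length(c) for c in ds.genome):,} bp "
      f"over {len(ds.genome)} chromosomes")
print(f"transcripts: {len(ds.transcripts)}, R-loop regions: {len(ds.rloops)}")
print(f"planted sites: {len(ds.truth)} "
      f"({int(ds.truth.dependent.sum())} dependent, "
      f"{int((~ds.truth.dependent).sum())} independent)")
dep = ds.truth[ds.truth.dependent]
print(f"dependent sites in R-loops: {dep.in_rloop.mean():.1%} "
      f"(co-localization parameter {ds.params.colocalization})")
print(f"files written: {sorted(p.name for p in paths.values())}")
# The truth table stores per-condition methylation levels, so calling,
# classification and overlap results can all be scored against it.
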