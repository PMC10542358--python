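"""R-loop overlap enrichment of dependent m5C sites.

Peaks surviving RNaseH treatment are artifacts and are subtracted; the
remaining RNaseH-sensitive peaks are high-confidence R-loops. Site classes
are then compared to the unmethylated-C background with Fisher's exact test.
"""

from rloopm5c import (SimulationParams, dataset_config, run_pipeline,
                      simulate_dataset, subtract_rnaseh, write_dataset)

ds = simulate_dataset(SimulationParams(seed=1))

sensitive = subtract_rnaseh(ds.drip_untreated, ds.drip_rnaseh,
                            removal_overlap_frac=0.5)
print(f"{len(ds.drip_untreated)} untreated peaks -> {len(sensitive)} "
      f"RNaseH-sensitive (the {len(ds.drip_rnaseh)} artifact peaks removed)")

paths = write_dataset(ds, "scratch/example_data")
result = run_pipeline(dataset_config(paths, seed=1), "scratch/example_out")
cols = ["class", "n_total", "n_in_rloop", "fraction_in_rloop",
        "background_fraction", "odds_ratio", "p_value"]
print(result.enrichment[cols].to_string(index=False))
# Dependent sites sit in R-loops far above the unmethylated-C background
# (odds ratio >> 1, tiny p), while independent sites do not — the planted
# co-localization recovered from raw counts alone.
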