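# rloopm5c

Genome-scale analysis of TRDMT1-dependent RNA 5-methylcytosine (m5C) in
R-loops, as a tested, reusable Python library.

## The scientific problem

TRDMT1 (DNMT2) writes m5C on RNA, and this modification is stimulated by DNA
damage. R-loops — three-stranded structures in which a nascent RNA hybridizes
with the template DNA strand — form preferentially where the transcribed
(sense) strand is G-rich, because the G-rich RNA : C-rich template hybrid is
thermodynamically stable. The question this pipeline addresses: do
TRDMT1-dependent m5C sites preferentially occur inside R-loops, in G-rich,
GC-skewed sequence contexts?

The analysis chain:

1. **Bisulfite m5C calling.** Bisulfite converts unmethylated C to U (read
   as T); m5C resists. At a site with coverage *n* and *u* unconverted reads,
   the evidence for methylation is the one-sided exact binomial tail
   P(X ≥ u | n, ε), where ε is the non-conversion error estimated from an
   unmethylated spike-in RNA (ε = Σu / Σn over spike-in cytosines, with a
   Clopper–Pearson 95 % CI). Benjamini–Hochberg correction across sites;
   *best* sites have coverage > 25 reads and methylation > 10 % (strict).
2. **TRDMT1-dependence.** A WT-called site is dependent when its
   pseudocount-adjusted methylation fold WT/KO ≥ 2 within the matching
   damage condition; the same rule on +damage/−damage flags damage
   induction.
3. **R-loop overlap.** DRIP-seq peaks surviving RNaseH pre-treatment are
   artifacts and are subtracted; a site is "in an R-loop" when its position
   falls in a remaining peak. Site classes are compared to the
   unmethylated-C background by Fisher's exact test on the 2×2 in/out table.
4. **GC skew.** The genome is tiled into 50 bp windows; GC skew
   (G−C)/(G+C) and GC fraction (G+C)/50 are expressed on the transcribed
   strand, and observed (R-loop) vs expected (rest of genome) window counts
   are binned on a (skew, GC) grid per strand facet. Positional G frequency
   is profiled around top- vs bottom-methylated sites.

A fully specified synthetic-data generator (`rloopm5c.simulate`) produces
genome, transcripts, GC-skewed R-loop regions, planted m5C sites, bisulfite
counts for all four conditions (WT/KO × ±damage), spike-in counts and DRIP
peak sets ± RNaseH — with a truth table, so every stage is testable without
external downloads.

## Worked example

```python
from rloopm5c import (SimulationParams, simulate_dataset, write_dataset,
                      dataset_config, run_pipeline)

ds = simulate_dataset(SimulationParams(seed=1))   # 100 kb, 4 conditions
paths = write_dataset(ds, "scratch/example_data")
result = run_pipeline(dataset_config(paths, seed=1), "scratch/example_out")
print(result.enrichment[["class", "n_total", "n_in_rloop",
                         "fraction_in_rloop", "odds_ratio", "p_value"]])
```

prints (abridged):

```
             class  n_total  n_in_rloop  fraction_in_rloop  odds_ratio       p_value
         dependent      222         167           0.752252   38.624209 4.560860e-127
  best10_dependent       23          19           0.826087   60.422603  2.580505e-18
       independent      179          11           0.061453    0.832893  6.607749e-01
```

222 of the 400 planted sites are recovered as TRDMT1-dependent after calling
and WT/KO classification; 75 % of them (83 % of the best 10 %) fall inside
RNaseH-sensitive R-loop peaks versus 7 % of unmethylated background
cytosines — the planted co-localization (0.8) recovered from raw counts
alone, while independent sites show no enrichment. The `examples/` directory
has one narrative script per capability (simulation, calling,
classification, overlap, GC-skew grid, sequence context).

A thin CLI mirrors the stages:

```bash
rloopm5c simulate --seed 1 --out-dir data
rloopm5c run-all --simulate-first --seed 1 --out-dir run1
rloopm5c call --counts data/counts_WT_dmg.tsv --spikein data/spikein.tsv --out calls.tsv
```

## Layout

- `src/rloopm5c/core.py` — interval/genome types, FASTA/BED/TSV I/O
- `src/rloopm5c/simulate.py` — synthetic-data generator with truth table
- `src/rloopm5c/calling.py` — spike-in calibration and m5C calling
- `src/rloopm5c/dependence.py` — WT/KO fold classification
- `src/rloopm5c/overlap.py` — RNaseH filtering, containment, Fisher enrichment
- `src/rloopm5c/features.py` — windowed GC stats, grids, contexts
- `src/rloopm5c/pipeline.py`, `cli.py`, `config.py` — orchestration
- `docs/methods.md` — model assumptions, parameter defaults, limitations
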