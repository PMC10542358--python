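"""Synthetic dataset generator with a known truth table.

Emulates the four-condition RNA bisulfite-sequencing design (WT and TRDMT1 KO
cells, each with and without oxidative damage) together with DRIP-seq peak
sets with and without RNaseH pre-treatment, on a small synthetic genome:

* i.i.d. background sequence at a stated GC fraction;
* non-overlapping stranded transcripts;
* R-loop-prone regions inside transcripts, rewritten so the transcribed
  (sense) strand is GC-rich with a positive GC skew — the sequence signature
  that favours DNA:RNA hybrid formation;
* planted m5C sites on transcript-strand cytosines: TRDMT1-dependent sites
  (methylation collapses in the KO) co-localized with R-loop regions at a
  configurable probability, TRDMT1-independent sites with equal levels in WT
  and KO, and an optional G-rich ±5 nt sequence context around dependent
  sites;
* per-cytosine bisulfite counts: coverage ~ negative binomial, unconverted
  reads ~ Binomial(n, m + (1 - m) * eps) where m is the true methylation
  level and eps the non-conversion error, calibrated on an unmethylated
  spike-in RNA;
* DRIP peaks: the untreated set is the R-loop regions (with optional boundary
  jitter) plus RNaseH-insensitive artifact peaks; the RNaseH-treated set
  contains the artifact peaks only.

Every emitted file is byte-identical across runs at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CONDITIONS,
    GenomeSequence,
    Interval,
    PipelineError,
    reverse_complement,
    write_bed,
    write_fasta,
    write_table,
)
from .config import PipelineConfig

#: The unmethylated spike-in RNA used to calibrate bisulfite non-conversion,
#: written as DNA (U -> T). 50 nt, 5 cytosines.
SPIKEIN_SEQUENCE = "TTAATTGGTGTGACTAATCGAAGTTGATACATCGACGTTATGGTGATGAT"
SPIKEIN_CHROM = "spikein"

BASES = np.frombuffer(b"ACGT", dtype="S1")

TRUTH_COLUMNS = [
    "chrom", "pos", "strand",
    "level_WT_nodmg", "level_WT_dmg", "level_KO_nodmg", "level_KO_dmg",
    "dependent", "damage_induced", "in_rloop", "context_class",
]


@dataclass
class SimulationParams:
    """All knobs of the generator; defaults are the standard study conditions."""

    # genome
    n_chroms: int = 2
    chrom_length: int = 50_000
    gc_fraction: float = 0.45

    # transcripts
    n_transcripts: int = 40
    transcript_length: int = 2_000

    # R-loop regions (targets expressed on the transcribed / sense strand)
    n_rloops: int = 20
    rloop_length: int = 400
    rloop_gc: float = 0.60
    rloop_skew: float = 0.40

    # planted m5C sites
    n_dependent: int = 200
    n_independent: int = 200
    colocalization: float = 0.8       # P(dependent site lies in an R-loop region)
    frac_damage_induced: float = 0.7  # of dependent sites; rest constitutive
    level_basal: float = 0.02
    level_induced: float = 0.30
    level_independent: float = 0.20
    grich_context: bool = True        # dependent sites get G-rich +-5 nt flanks
    grich_prob: float = 0.60
    grich_halfwidth: int = 5

    # bisulfite counts
    coverage_mean: float = 50.0
    coverage_dispersion: float = 0.1  # var = mean + dispersion * mean^2; 0 = Poisson
    nonconversion: float = 0.005
    spikein_coverage_mean: float = 2_000.0

    # DRIP peaks
    n_artifact_peaks: int = 10
    artifact_peak_length: int = 400
    peak_jitter: int = 20

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "rloop_gc", "colocalization", "frac_damage_induced",
                     "level_basal", "level_induced", "level_independent", "grich_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise PipelineError(f"{name} must be in [0, 1], got {v}")
        if not (0 <= self.nonconversion <= 0.05):
            raise PipelineError("nonconversion must be in [0, 0.05]")
        if self.coverage_mean <= 0:
            raise PipelineError("coverage_mean must be > 0")
        if abs(self.rloop_skew) > 1:
            raise PipelineError("rloop_skew must be in [-1, 1]")
        # nonzero skew needs G or C bases to carry it
        if self.rloop_gc == 0 and self.rloop_skew != 0:
            raise PipelineError("rloop_gc and rloop_skew jointly infeasible")
        if self.coverage_dispersion < 0:
            raise PipelineError("coverage_dispersion must be >= 0")


@dataclass
class SyntheticDataset:
    """Everything the generator produced, plus the truth table."""

    genome: GenomeSequence
    transcripts: list[Interval]
    rloops: list[Interval]
    truth: pd.DataFrame
    counts: dict[str, pd.DataFrame]     # condition -> count table
    spikein: pd.DataFrame
    drip_untreated: list[Interval]
    drip_rnaseh: list[Interval]
    params: SimulationParams


def _base_probs(gc: float, skew: float = 0.0) -> np.ndarray:
    """Per-base probabilities (A, C, G, T) for a target GC fraction and skew.

    skew = (pG - pC) / (pG + pC); A and T are symmetric.
    """
    p_g = gc * (1 + skew) / 2
    p_c = gc * (1 - skew) / 2
    p_at = (1 - gc) / 2
    return np.array([p_at, p_c, p_g, p_at])


def _random_seq(rng: np.random.Generator, length: int, gc: float, skew: float = 0.0) -> str:
    idx = rng.choice(4, size=length, p=_base_probs(gc, skew))
    return BASES[idx].tobytes().decode()


def simulate_genome(params: SimulationParams,
                    rng: np.random.Generator | None = None
                    ) -> tuple[GenomeSequence, list[Interval]]:
    """I.i.d. genome at the stated GC fraction plus non-overlapping transcripts.

    Transcripts are placed per chromosome by distributing the free space among
    the gaps between them (multinomial stick-breaking), so placement always
    succeeds when the lengths fit; each transcript gets a random fixed strand.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    per_chrom = np.full(params.n_chroms, params.n_transcripts // max(params.n_chroms, 1))
    per_chrom[: params.n_transcripts % max(params.n_chroms, 1)] += 1

    seqs: dict[str, str] = {}
    transcripts: list[Interval] = []
    for ci in range(params.n_chroms):
        chrom = f"chr{ci + 1}"
        seqs[chrom] = _random_seq(rng, params.chrom_length, params.gc_fraction)
        k = int(per_chrom[ci])
        if k == 0:
            continue
        occupied = k * params.transcript_length
        free = params.chrom_length - occupied
        if free < 0:
            raise PipelineError(
                f"cannot place {k} transcripts of {params.transcript_length} bp "
                f"on a {params.chrom_length} bp chromosome"
            )
        gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for ti in range(k):
            pos += int(gaps[ti])
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                Interval(chrom, pos, pos + params.transcript_length, strand,
                         f"tx{len(transcripts) + 1}")
            )
            pos += params.transcript_length
    return GenomeSequence(seqs), transcripts


def plant_rloop_regions(genome: GenomeSequence, transcripts: list[Interval],
                        params: SimulationParams,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[Interval], GenomeSequence]:
    """Rewrite R-loop-prone regions inside transcripts and return them.

    Within each region the sequence is resampled so that, read on the
    transcript (sense) strand, it has the target GC fraction and GC skew
    (G over C). Regions inherit the transcript strand.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if params.n_rloops == 0:
        return [], genome
    if not transcripts:
        raise PipelineError("cannot plant R-loop regions without transcripts")
    eligible = [t for t in transcripts if len(t) >= params.rloop_length]
    if len(eligible) < params.n_rloops:
        raise PipelineError(
            f"only {len(eligible)} transcripts can hold a {params.rloop_length} bp region"
        )
    hosts = rng.choice(len(eligible), size=params.n_rloops, replace=False)
    seqs = {c: bytearray(genome[c], "ascii") for c in genome}
    rloops: list[Interval] = []
    for ri, hi in enumerate(sorted(int(h) for h in hosts)):
        tx = eligible[hi]
        offset = int(rng.integers(0, len(tx) - params.rloop_length + 1))
        start = tx.start + offset
        end = start + params.rloop_length
        sense = _random_seq(rng, params.rloop_length, params.rloop_gc, params.rloop_skew)
        plus = sense if tx.strand == "+" else reverse_complement(sense)
        seqs[tx.chrom][start:end] = plus.encode()
        rloops.append(Interval(tx.chrom, start, end, tx.strand, f"rloop{ri + 1}"))
    new_genome = GenomeSequence({c: bytes(s).decode() for c, s in seqs.items()})
    return rloops, new_genome


def _sense_c_positions(genome: GenomeSequence, tx: Interval) -> np.ndarray:
    """Plus-strand coordinates whose transcript-strand (sense) base is C."""
    seq = np.frombuffer(genome.fetch(tx).encode(), dtype="S1")
    target = b"C" if tx.strand == "+" else b"G"
    return tx.start + np.flatnonzero(seq == target)


def plant_m5c_sites(genome: GenomeSequence, transcripts: list[Interval],
                    rloops: list[Interval], params: SimulationParams,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, GenomeSequence]:
    """Choose site positions and true per-condition methylation levels.

    Dependent sites are forced inside an R-loop region with probability
    ``colocalization`` and otherwise placed uniformly over all transcript
    cytosines (so colocalization 0 is uniform placement); independent sites
    are uniform over all transcript cytosines. For G-rich contexts, the ±grich_halfwidth sense-strand flanks
    are resampled with elevated G probability (the planted site C itself is
    never touched).

    Returns the truth table and the (possibly rewritten) genome.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    by_tx: list[tuple[Interval, np.ndarray]] = []
    rl_by_chrom: dict[str, list[Interval]] = {}
    for r in rloops:
        rl_by_chrom.setdefault(r.chrom, []).append(r)

    all_pos: list[tuple[str, int, str, bool]] = []  # chrom, pos, strand, in_rloop
    for tx in transcripts:
        for pos in _sense_c_positions(genome, tx):
            pos = int(pos)
            in_rl = any(r.start <= pos < r.end for r in rl_by_chrom.get(tx.chrom, []))
            all_pos.append((tx.chrom, pos, tx.strand, in_rl))
    if not all_pos:
        raise PipelineError("no transcript-strand cytosines available")
    pos_df = pd.DataFrame(all_pos, columns=["chrom", "pos", "strand", "in_rloop"])

    in_idx = pos_df.index[pos_df["in_rloop"]].to_numpy()
    out_idx = pos_df.index[~pos_df["in_rloop"]].to_numpy()
    n_total = params.n_dependent + params.n_independent
    if n_total > len(pos_df):
        raise PipelineError(
            f"requested {n_total} sites but only {len(pos_df)} cytosines available"
        )

    chosen: list[int] = []
    taken = np.zeros(len(pos_df), dtype=bool)

    def _draw(pool: np.ndarray) -> int:
        avail = pool[~taken[pool]]
        if len(avail) == 0:
            raise PipelineError("ran out of cytosine positions during planting")
        i = int(avail[rng.integers(0, len(avail))])
        taken[i] = True
        return i

    all_idx = pos_df.index.to_numpy()
    dep_rows, indep_rows = [], []
    for _ in range(params.n_dependent):
        # with probability `colocalization` force an R-loop cytosine,
        # otherwise place uniformly over all transcript cytosines
        use_rloop = rng.random() < params.colocalization and len(in_idx) > 0
        dep_rows.append(_draw(in_idx if use_rloop else all_idx))
    for _ in range(params.n_independent):
        indep_rows.append(_draw(all_idx))

    records = []
    for i in dep_rows:
        row = pos_df.loc[i]
        induced = bool(rng.random() < params.frac_damage_induced)
        wt_nodmg = params.level_basal if induced else params.level_induced
        records.append((row.chrom, row.pos, row.strand,
                        wt_nodmg, params.level_induced,
                        params.level_basal, params.level_basal,
                        True, induced, bool(row.in_rloop),
                        "G-rich" if params.grich_context else "neutral"))
    for i in indep_rows:
        row = pos_df.loc[i]
        lv = params.level_independent
        records.append((row.chrom, row.pos, row.strand, lv, lv, lv, lv,
                        False, False, bool(row.in_rloop), "neutral"))
    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # resample G-rich flanks on the sense strand around G-rich sites
    seqs = {c: bytearray(genome[c], "ascii") for c in genome}
    k = params.grich_halfwidth
    planted_positions = set(zip(truth["chrom"], truth["pos"]))
    for rec in truth.itertuples():
        if rec.context_class != "G-rich":
            continue
        chrom_len = genome.length(rec.chrom)
        for off in range(-k, k + 1):
            if off == 0:
                continue
            # offset is along the sense strand; map to plus-strand coordinate
            p = rec.pos + off if rec.strand == "+" else rec.pos - off
            if not (0 <= p < chrom_len):
                continue
            if (rec.chrom, p) in planted_positions:
                continue  # never overwrite another planted site's C
            sense_base = BASES[int(rng.choice(4, p=_grich_probs(params)))].decode()
            seqs[rec.chrom][p:p + 1] = (
                sense_base if rec.strand == "+" else reverse_complement(sense_base)
            ).encode()
    new_genome = GenomeSequence({c: bytes(s).decode() for c, s in seqs.items()})
    return truth, new_genome


def _grich_probs(params: SimulationParams) -> np.ndarray:
    """Flank base probabilities for the G-rich context class (sense strand)."""
    p_g = params.grich_prob
    rest = (1 - p_g) / 3
    return np.array([rest, rest, p_g, rest])


def _nb_coverage(rng: np.random.Generator, mean: float, dispersion: float,
                 size: int) -> np.ndarray:
    """Negative-binomial coverage (var = mean + dispersion * mean^2); Poisson at 0."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_bisulfite_counts(genome: GenomeSequence, transcripts: list[Interval],
                              truth: pd.DataFrame, params: SimulationParams,
                              rng: np.random.Generator | None = None
                              ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-cytosine count tables for the four conditions plus the spike-in.

    Every transcript-strand cytosine gets a row (unplanted sites have true
    level 0); unconverted reads ~ Binomial(n, m + (1 - m) * eps).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 3)
    rows = []
    for tx in transcripts:
        for pos in _sense_c_positions(genome, tx):
            rows.append((tx.chrom, int(pos), tx.strand))
    base = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    base = base.drop_duplicates(["chrom", "pos", "strand"])
    base = base.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    eps = params.nonconversion
    counts: dict[str, pd.DataFrame] = {}
    for cond in CONDITIONS:
        level = pd.Series(0.0, index=pd.MultiIndex.from_frame(base[["chrom", "pos"]]))
        if len(truth):
            planted = truth.set_index(["chrom", "pos"])[f"level_{cond}"].astype(float)
            level.loc[planted.index.intersection(level.index)] = planted
        m = level.to_numpy()
        n = _nb_coverage(rng, params.coverage_mean, params.coverage_dispersion, len(base))
        p_unconv = m + (1 - m) * eps
        u = rng.binomial(n, p_unconv)
        df = base.copy()
        df["n_unconverted"] = u
        df["n_converted"] = n - u
        counts[cond] = df

    c_pos = [i for i, b in enumerate(SPIKEIN_SEQUENCE) if b == "C"]
    n_sp = _nb_coverage(rng, params.spikein_coverage_mean, params.coverage_dispersion,
                        len(c_pos))
    u_sp = rng.binomial(n_sp, eps)
    spikein = pd.DataFrame({
        "chrom": SPIKEIN_CHROM,
        "pos": c_pos,
        "strand": "+",
        "n_unconverted": u_sp,
        "n_converted": n_sp - u_sp,
    })
    return counts, spikein


def simulate_drip_peaks(genome: GenomeSequence, rloops: list[Interval],
                        params: SimulationParams,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[Interval], list[Interval]]:
    """Untreated and RNaseH-treated DRIP peak sets.

    Untreated = R-loop regions (boundaries jittered by up to ``peak_jitter``)
    plus artifact peaks placed uniformly outside R-loops; RNaseH-treated =
    the artifact peaks only (genuine hybrids are destroyed by RNaseH).
    DRIP peaks are unstranded.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 4)
    untreated: list[Interval] = []
    for i, r in enumerate(rloops):
        j1 = int(rng.integers(-params.peak_jitter, params.peak_jitter + 1)) if params.peak_jitter else 0
        j2 = int(rng.integers(-params.peak_jitter, params.peak_jitter + 1)) if params.peak_jitter else 0
        start = max(0, r.start + j1)
        end = min(genome.length(r.chrom), r.end + j2)
        if end <= start:
            start, end = r.start, r.end
        untreated.append(Interval(r.chrom, start, end, ".", f"peak{i + 1}"))

    artifacts: list[Interval] = []
    chroms = genome.chroms()
    tries = 0
    while len(artifacts) < params.n_artifact_peaks:
        tries += 1
        if tries > 10_000:
            raise PipelineError("cannot place artifact peaks clear of R-loop regions")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, genome.length(chrom) - params.artifact_peak_length))
        end = start + params.artifact_peak_length
        clash = any(r.chrom == chrom and start < r.end and r.start < end
                    for r in rloops + artifacts)
        if not clash:
            artifacts.append(Interval(chrom, start, end, ".",
                                      f"artifact{len(artifacts) + 1}"))
    return untreated + artifacts, list(artifacts)


def simulate_dataset(params: SimulationParams | None = None) -> SyntheticDataset:
    """Run the whole generator with a single seed; fully deterministic."""
    params = params or SimulationParams()
    genome, transcripts = simulate_genome(params)
    rloops, genome = plant_rloop_regions(genome, transcripts, params)
    truth, genome = plant_m5c_sites(genome, transcripts, rloops, params)
    counts, spikein = simulate_bisulfite_counts(genome, transcripts, truth, params)
    untreated, rnaseh = simulate_drip_peaks(genome, rloops, params)
    return SyntheticDataset(genome, transcripts, rloops, truth, counts, spikein,
                            untreated, rnaseh, params)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact of the dataset to ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    write_fasta(ds.genome, paths["genome"])
    paths["transcripts"] = out / "transcripts.bed"
    write_bed(ds.transcripts, paths["transcripts"])
    paths["rloops_truth"] = out / "rloop_truth.bed"
    write_bed(ds.rloops, paths["rloops_truth"])
    paths["truth"] = out / "truth.tsv"
    write_table(ds.truth, paths["truth"],
                ["truth table: positions are 0-based; levels are true methylation fractions"])
    for cond, df in ds.counts.items():
        paths[f"counts_{cond}"] = out / f"counts_{cond}.tsv"
        write_table(df, paths[f"counts_{cond}"],
                    [f"bisulfite counts, condition {cond}; pos is 0-based"])
    paths["spikein"] = out / "spikein.tsv"
    write_table(ds.spikein, paths["spikein"],
                ["unmethylated spike-in counts for non-conversion calibration"])
    paths["drip_untreated"] = out / "drip_untreated.bed"
    write_bed(ds.drip_untreated, paths["drip_untreated"])
    paths["drip_rnaseh"] = out / "drip_rnaseh.bed"
    write_bed(ds.drip_rnaseh, paths["drip_rnaseh"])

    with open(out / "params.txt", "w") as fh:
        for f in fields(ds.params):
            fh.write(f"{f.name} = {getattr(ds.params, f.name)}\n")
    paths["params"] = out / "params.txt"
    return paths


def dataset_config(paths: dict[str, Path], **overrides) -> PipelineConfig:
    """Build a PipelineConfig pointing at a written dataset."""
    cfg = PipelineConfig(
        genome_fasta=str(paths["genome"]),
        transcripts_bed=str(paths["transcripts"]),
        counts_wt_nodmg=str(paths["counts_WT_nodmg"]),
        counts_wt_dmg=str(paths["counts_WT_dmg"]),
        counts_ko_nodmg=str(paths["counts_KO_nodmg"]),
        counts_ko_dmg=str(paths["counts_KO_dmg"]),
        spikein_counts=str(paths["spikein"]),
        drip_untreated_bed=str(paths["drip_untreated"]),
        drip_rnaseh_bed=str(paths["drip_rnaseh"]),
    )
    from .config import replace
    return replace(cfg, **overrides)
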