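"""Synthetic small-RNA datasets with planted ground truth.

The generator produces everything the screening pipeline consumes — a
curated miRNA dictionary (guide + passenger strands, family structure via a
shared seed region), spike-in oligos, negative-binomial replicate counts per
genotype x stage, adapter-trimmed reads with planted isoform structure and
spike miscalls, a piRNA panel with a genomically contiguous downregulated
block, and an mRNA fold-change table with seed-target-driven repression —
together with a :class:`TruthTable` recording exactly what was planted, so
every downstream stage can be validated against known answers.

The noise model is the one the analysis assumes: counts are negative
binomial with var = mu + alpha*mu^2, replicates independent, library depths
log-normally jittered, mutant means multiplied by the planted (linear) fold
change.  A fixed seed fully determines every output.

The default isoform-fraction vector places no mass on 5'-trimmed or
3'-trim-4 classes: the 19-nt-prefix abundance counter is structurally blind
to those species (a 5' trim changes the prefix; an 18-nt read is shorter
than the prefix), so the default emulates the read population that counter
can see, keeping emitted reads and recounted reads in exact agreement.
Profiling-oriented simulations pass an explicit all-14-class vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    WT,
    MUTANT,
    CountMatrix,
    MirnaDictionary,
    MirnaEntry,
    SeqRead,
    make_library_meta,
)
from .isoforms import ISOFORM_CLASSES, isoform_sequence

RNA = "ACGU"

#: Default isoform fractions: realistic mass on full-length, minor 3' trims
#: and short tails; zero on classes invisible to 19-nt-prefix counting.
DEFAULT_ISOFORM_FRACS: dict[str, float] = {
    "FL": 0.82,
    "3t1": 0.10,
    "3t2": 0.025,
    "3t3": 0.006,
    "3t4": 0.0,
    "5t1": 0.0,
    "5t2": 0.0,
    "+A": 0.02,
    "+AA": 0.003,
    "+U": 0.015,
    "+UU": 0.005,
    "+UUU": 0.002,
    "+AU": 0.002,
    "+UA": 0.002,
}

#: Planted spike miscall rates (apparent isoform fractions of a pure
#: full-length oligo), of the magnitude seen in real libraries.
DEFAULT_SPIKE_MISCALLS: dict[str, float] = {
    "+A": 0.001,
    "+U": 0.0005,
    "3t1": 0.005,
    "3t2": 0.001,
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic dataset; the seed fully determines outputs."""

    n_families: int = 30
    family_sizes: tuple[int, ...] | None = None  # default: one 8-member family + singletons
    mature_length: int = 22
    stages: tuple[str, ...] = ("L1",)
    n_replicates: int = 2
    depth: float = 1e6  # expected miRNA-matching reads per library
    depth_sd: float = 0.15  # lognormal sd of library depth factors
    dispersion: float = 0.05
    mean_log_mu: float = 5.5  # baseline-abundance lognormal (log scale)
    mean_log_sd: float = 1.0
    frac_sensitive: float = 0.1
    sensitive_fold_range: tuple[float, float] = (2.0, 8.0)  # log-uniform
    passenger_fc_range: tuple[float, float] = (0.9, 1.1)
    isoform_fracs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOFORM_FRACS)
    )
    n_spikes: int = 2
    spike_proportion: float = 0.01  # spike reads as fraction of miRNA reads
    spike_miscalls: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPIKE_MISCALLS)
    )
    # piRNA panel
    n_pirnas: int = 60
    pirna_length: int = 21
    pirna_chrom: str = "chrIV"
    pirna_spacing: int = 2000
    pirna_blocks: tuple[tuple[int, int, float], ...] = ((20, 8, -2.0),)  # (start_idx, size, log2fc)
    pirna_mean_log_mu: float = 4.0
    pirna_mean_log_sd: float = 0.8
    # mRNA table
    n_genes: int = 2000
    n_targets: int = 200
    conserved_fraction: float = 0.4
    mrna_target_effect: float = -0.5  # log2, predicted targets
    mrna_conserved_effect: float = -0.8  # log2, conserved-site targets
    mrna_noise_sd: float = 0.3
    utr_log_mean: float = 6.2  # lognormal 3'-UTR lengths, median ~ 490 nt
    utr_log_sd: float = 0.6
    mrna_reads_log_mu: float = 6.0
    mrna_reads_log_sd: float = 1.5
    # plumbing
    plant_identical_guides: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.mature_length < 20:
            raise ValueError(
                "mature length < 20 nt: 19-nt prefix counting would be ill-posed"
            )
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        total = sum(self.isoform_fracs.get(c, 0.0) for c in ISOFORM_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isoform fractions must sum to 1 (got {total})")
        lo, hi = self.sensitive_fold_range
        if lo <= 1.0:
            raise ValueError("planted sensitive fold changes must exceed 1")
        for i, (s1, n1, _) in enumerate(self.pirna_blocks):
            if s1 + n1 > self.n_pirnas:
                raise ValueError("piRNA block extends past the panel")
            for s2, n2, _ in self.pirna_blocks[i + 1:]:
                if s1 < s2 + n2 and s2 < s1 + n1:
                    raise ValueError("overlapping piRNA block intervals")

    def resolved_family_sizes(self) -> tuple[int, ...]:
        if self.family_sizes is not None:
            return self.family_sizes
        return (8,) + (1,) * (self.n_families - 1)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class TruthTable:
    """What was planted: per-guide fold changes and flags, per-passenger fold
    changes, baseline means, dispersions, the piRNA block, spike miscalls."""

    fold: pd.DataFrame  # feature x stage, linear fold change (mutant / WT)
    sensitive: pd.DataFrame  # guide x stage, bool
    baseline: pd.Series  # feature -> expected WT count at depth factor 1
    dispersion: pd.Series  # feature -> NB dispersion
    pirna_blocks: list[dict]  # chrom/start/end/log2fc per planted block
    spike_miscalls: dict[str, float]

    def validate(self) -> None:
        for stage in self.sensitive.columns:
            sens = self.sensitive[stage]
            guides = sens.index[sens]
            if (self.fold.loc[guides, stage] <= 1.0).any():
                raise ValueError("planted fold change for sensitive guides must be > 1")
        passengers = [n for n in self.fold.index if n.endswith("*")]
        pf = self.fold.loc[passengers]
        if ((pf < 0.8) | (pf > 1.25)).any().any():
            raise ValueError("passenger planted fold changes must lie in [0.8, 1.25]")
        for blk in self.pirna_blocks:
            if blk["end"] <= blk["start"]:
                raise ValueError("piRNA block interval must be a forward range")

    def sensitive_guides(self, stage: str) -> list[str]:
        sens = self.sensitive[stage]
        return list(sens.index[sens])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA[i] for i in rng.integers(0, 4, size=length))


def make_mirna_dictionary(config: SimConfig) -> MirnaDictionary:
    """Generate guide + passenger entries per locus with family seed sharing.

    Family members share nucleotides 2-8 (the seed region) and diverge
    elsewhere; all 19-nt prefixes are unique by rejection sampling unless
    identical guides are explicitly planted (``plant_identical_guides``
    appends copies of the first guide under new names, to exercise merging).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.mature_length
    entries: list[MirnaEntry] = []
    seen_prefixes: set[str] = set()

    def fresh(seq_maker) -> str:
        for _ in range(1000):
            seq = seq_maker()
            if seq[:19] not in seen_prefixes:
                seen_prefixes.add(seq[:19])
                return seq
        raise RuntimeError("could not draw a collision-free sequence")

    for fam_idx, size in enumerate(config.resolved_family_sizes(), start=1):
        seed_region = _random_seq(rng, 7)  # shared nt 2-8
        family = f"fam-{fam_idx}"
        for mem in range(1, size + 1):
            locus = f"locus-{fam_idx}.{mem}"
            guide_seq = fresh(
                lambda: _random_seq(rng, 1) + seed_region + _random_seq(rng, L - 8)
            )
            entries.append(
                MirnaEntry(f"mir-{fam_idx}.{mem}", guide_seq, "guide", family, locus)
            )
            passenger_seq = fresh(lambda: _random_seq(rng, L))
            entries.append(
                MirnaEntry(f"mir-{fam_idx}.{mem}*", passenger_seq, "passenger", family, locus)
            )
    first_guide = entries[0]
    for k in range(config.plant_identical_guides):
        entries.append(
            MirnaEntry(
                f"{first_guide.name}-copy{k + 1}",
                first_guide.sequence,
                "guide",
                first_guide.family,
                first_guide.locus,
            )
        )
    return MirnaDictionary.from_entries(entries)


def make_spikes(config: SimConfig, dictionary: MirnaDictionary) -> MirnaDictionary:
    """Synthetic spike-in oligos with prefixes disjoint from the dictionary."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    taken = {e.sequence[:19] for e in dictionary.entries}
    entries = []
    while len(entries) < config.n_spikes:
        seq = _random_seq(rng, config.mature_length)
        if seq[:19] not in taken:
            taken.add(seq[:19])
            entries.append(
                MirnaEntry(f"spike-{len(entries) + 1}", seq, "guide", "spike", "")
            )
    return MirnaDictionary.from_entries(entries)


def make_truth(dictionary: MirnaDictionary, config: SimConfig) -> TruthTable:
    """Plant the ground truth: sensitive guides, fold changes, baselines."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    guides = [e.name for e in dictionary.guides()]
    passengers = [e.name for e in dictionary.entries if e.role == "passenger"]
    features = guides + passengers
    stages = list(config.stages)

    n_sens = int(round(config.frac_sensitive * len(guides)))
    sens_guides = list(rng.choice(guides, size=n_sens, replace=False))
    sensitive = pd.DataFrame(False, index=guides, columns=stages)
    fold = pd.DataFrame(1.0, index=features, columns=stages)
    lo, hi = config.sensitive_fold_range
    for stage in stages:
        sensitive.loc[sens_guides, stage] = True
        fold.loc[sens_guides, stage] = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=n_sens)
        )
        plo, phi = config.passenger_fc_range
        fold.loc[passengers, stage] = rng.uniform(plo, phi, size=len(passengers))

    raw = np.exp(rng.normal(config.mean_log_mu, config.mean_log_sd, size=len(features)))
    baseline = pd.Series(raw * config.depth / raw.sum(), index=features)
    dispersion = pd.Series(config.dispersion, index=features)

    blocks = []
    for start_idx, size, log2fc in config.pirna_blocks:
        blocks.append(
            {
                "chrom": config.pirna_chrom,
                "start": start_idx * config.pirna_spacing,
                "end": (start_idx + size - 1) * config.pirna_spacing + config.pirna_length,
                "start_idx": start_idx,
                "size": size,
                "log2fc": log2fc,
            }
        )
    truth = TruthTable(fold, sensitive, baseline, dispersion,
                       blocks, dict(config.spike_miscalls))
    truth.validate()
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with var = mu + alpha*mu^2; Poisson in the alpha->0 limit."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    dictionary: MirnaDictionary, truth: TruthTable, config: SimConfig
) -> CountMatrix:
    """NB replicate counts per genotype x stage for every dictionary feature."""
    config.validate()
    if (truth.baseline <= 0).any():
        raise ValueError("baseline means must be > 0")
    if config.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 15485863]))
    features = list(truth.baseline.index)
    genotypes, stages, reps = [], [], []
    for stage in config.stages:
        for genotype in (WT, MUTANT):
            for rep in range(1, config.n_replicates + 1):
                genotypes.append(genotype)
                stages.append(stage)
                reps.append(rep)
    meta = make_library_meta(genotypes, stages, reps)
    depth_factors = np.exp(rng.normal(0.0, config.depth_sd, size=len(meta)))
    data = {}
    base = truth.baseline.to_numpy()
    alpha = config.dispersion
    for j, lib in enumerate(meta.index):
        stage = meta.loc[lib, "stage"]
        fold = truth.fold[stage].reindex(features).to_numpy()
        mu = base * depth_factors[j]
        if meta.loc[lib, "genotype"] == MUTANT:
            mu = mu * fold
        data[lib] = _nb_draw(rng, mu, alpha)
    counts = pd.DataFrame(data, index=features)
    return CountMatrix(counts, meta, "miRNA")


def emit_reads(
    counts: CountMatrix,
    truth: TruthTable,
    dictionary: MirnaDictionary,
    config: SimConfig,
    spikes: MirnaDictionary | None = None,
) -> dict[str, list[SeqRead]]:
    """Split each count across isoform classes and emit per-library reads.

    Reads come out as DNA (T alphabet), already adapter-trimmed, with all
    bases at Q40.  Spike reads are appended at ``spike_proportion`` of the
    library's miRNA total, with the planted per-class miscall rates.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 32452843]))
    fracs = np.array([config.isoform_fracs.get(c, 0.0) for c in ISOFORM_CLASSES])
    seqs = dictionary.sequences
    miscall = np.array([truth.spike_miscalls.get(c, 0.0) for c in ISOFORM_CLASSES])
    spike_probs = miscall.copy()
    spike_probs[0] = 1.0 - miscall[1:].sum()  # FL gets the remainder

    def to_read(rna: str) -> SeqRead:
        dna = rna.replace("U", "T")
        return SeqRead(dna, (40,) * len(dna))

    libraries: dict[str, list[SeqRead]] = {}
    for lib in counts.counts.columns:
        out: list[SeqRead] = []
        col = counts.counts[lib]
        for name, c in col.items():
            if c == 0:
                continue
            mature = seqs[name]
            split = rng.multinomial(int(c), fracs)
            for cls, k in zip(ISOFORM_CLASSES, split):
                if k:
                    out.extend([to_read(isoform_sequence(mature, cls))] * int(k))
        if spikes is not None and spikes.entries:
            n_spike = int(round(config.spike_proportion * int(col.sum())))
            per_spike = np.full(len(spikes.entries), n_spike // len(spikes.entries))
            per_spike[: n_spike % len(spikes.entries)] += 1
            for entry, ns in zip(spikes.entries, per_spike):
                split = rng.multinomial(int(ns), spike_probs)
                for cls, k in zip(ISOFORM_CLASSES, split):
                    if k:
                        out.extend([to_read(isoform_sequence(entry.sequence, cls))] * int(k))
        order = rng.permutation(len(out))
        libraries[lib] = [out[i] for i in order]
    return libraries


def write_fastq(reads: list[SeqRead], path, prefix: str = "read") -> None:
    """Write simulated reads as FASTQ (four plain lines per record)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            qual = "".join(chr(q + 33) for q in (read.quality or (40,) * len(read.sequence)))
            fh.write(f"@{prefix}_{i}\n{read.sequence}\n+\n{qual}\n")


def simulate_pirna_counts(
    config: SimConfig, truth: TruthTable
) -> tuple[CountMatrix, pd.DataFrame]:
    """piRNA panel counts plus genomic records (BED-ready, 0-based half-open).

    piRNAs inside a planted block get the block's (negative) log2 fold
    change in the mutant; all others are unchanged.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 49979687]))
    n = config.n_pirnas
    names = [f"21ur-{i + 1}" for i in range(n)]
    starts = np.arange(n) * config.pirna_spacing
    records = pd.DataFrame(
        {
            "name": names,
            "chrom": config.pirna_chrom,
            "start": starts,
            "end": starts + config.pirna_length,
            "strand": "+",
            "sequence": [_random_seq(rng, config.pirna_length) for _ in range(n)],
        }
    )
    if records["sequence"].duplicated().any():  # vanishingly unlikely at 21 nt
        raise RuntimeError("duplicate piRNA sequences drawn")
    log2fc = np.zeros(n)
    for start_idx, size, blk_log2fc in config.pirna_blocks:
        log2fc[start_idx: start_idx + size] = blk_log2fc
    base = np.exp(rng.normal(config.pirna_mean_log_mu, config.pirna_mean_log_sd, size=n))
    genotypes, stages, reps = [], [], []
    stage = config.stages[0]
    for genotype in (WT, MUTANT):
        for rep in range(1, config.n_replicates + 1):
            genotypes.append(genotype)
            stages.append(stage)
            reps.append(rep)
    meta = make_library_meta(genotypes, stages, reps)
    data = {}
    for lib in meta.index:
        mu = base * (2.0 ** log2fc) if meta.loc[lib, "genotype"] == MUTANT else base
        data[lib] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(data, index=names)
    return CountMatrix(counts, meta, "piRNA"), records


def simulate_mrna_table(truth: TruthTable, config: SimConfig) -> pd.DataFrame:
    """Gene-level fold-change table with 3'-UTR lengths and target flags.

    Predicted targets get the planted mean log2 fold change (conserved-site
    targets a stronger one); nontargets centre at zero.  3'-UTR lengths are
    log-normal; WT raw read counts are included for the 50-read filter.
    """
    config.validate()
    if config.mrna_target_effect > 0 or config.mrna_conserved_effect > 0:
        raise ValueError("planted repression effects must be <= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 86028121]))
    n = config.n_genes
    genes = [f"gene-{i + 1}" for i in range(n)]
    predicted = np.zeros(n, dtype=bool)
    target_idx = rng.choice(n, size=config.n_targets, replace=False)
    predicted[target_idx] = True
    conserved = np.zeros(n, dtype=bool)
    n_cons = int(round(config.conserved_fraction * config.n_targets))
    conserved[rng.choice(target_idx, size=n_cons, replace=False)] = True
    effect = np.where(
        conserved, config.mrna_conserved_effect,
        np.where(predicted, config.mrna_target_effect, 0.0),
    )
    log2fc = effect + rng.normal(0.0, config.mrna_noise_sd, size=n)
    utr = np.exp(rng.normal(config.utr_log_mean, config.utr_log_sd, size=n))
    wt_reads = np.exp(
        rng.normal(config.mrna_reads_log_mu, config.mrna_reads_log_sd, size=n)
    ).astype(np.int64)
    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "wt_reads": wt_reads,
            "utr_length": np.round(utr).astype(np.int64),
            "predicted_target": predicted,
            "conserved_target": conserved,
        }
    )


def simulate_dataset(config: SimConfig) -> dict:
    """Convenience bundle: dictionary, spikes, truth, and counts in one call."""
    dictionary = make_mirna_dictionary(config)
    spikes = make_spikes(config, dictionary)
    truth = make_truth(dictionary, config)
    counts = simulate_counts(dictionary, truth, config)
    return {
        "dictionary": dictionary,
        "spikes": spikes,
        "truth": truth,
        "counts": counts,
    }
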