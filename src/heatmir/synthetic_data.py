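"""Self-contained synthetic study generator.

Emulates the data layout of a two-genotype (heat-tolerant NH vs heat-sensitive
SH), two-condition (mild AP vs extreme JP heat), three-replicate pollen
small-RNA experiment: a toy genome with planted miRNA precursor hairpins
(some arranged in sub-50-kb clusters), per-sample small-RNA libraries with a
24-nt-peaked length distribution and per-length first-base biases,
negative-binomial miRNA counts with planted fold changes, transcripts
carrying miRNA binding sites, pooled degradome libraries whose tags pile up
at the position paired with miRNA nucleotide 10, and a two-group hormone
table.

Every stage of the analysis pipeline can be exercised against the ground
truth recorded here.  All randomness flows from ``SyntheticConfig.seed``;
the same seed reproduces byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio

DNA = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")
MAX_READ_LENGTH = 25

GROUPS = ("AP_NH", "AP_SH", "JP_NH", "JP_SH")
N_REPLICATES = 3
DEGRADOME_LIBRARIES = ("P_NH", "P_SH")

#: Fraction-of-library length weights peaked at 24 nt, the modal length of
#: plant pollen sRNA libraries (21 nt is the second mode among miRNAs).
DEFAULT_LENGTH_WEIGHTS = {
    18: 0.04, 19: 0.05, 20: 0.07, 21: 0.20,
    22: 0.08, 23: 0.08, 24: 0.40, 25: 0.08,
}

#: Per-length first-base preference: G-start at the length extremes,
#: U-start for 19-22 nt, C-start for 23-24 nt.
DEFAULT_FIRST_BASE_BIAS = {
    18: {"A": 0.15, "C": 0.15, "G": 0.55, "T": 0.15},
    19: {"A": 0.15, "C": 0.15, "G": 0.10, "T": 0.60},
    20: {"A": 0.15, "C": 0.15, "G": 0.10, "T": 0.60},
    21: {"A": 0.15, "C": 0.15, "G": 0.10, "T": 0.60},
    22: {"A": 0.15, "C": 0.15, "G": 0.10, "T": 0.60},
    23: {"A": 0.20, "C": 0.45, "G": 0.15, "T": 0.20},
    24: {"A": 0.20, "C": 0.45, "G": 0.15, "T": 0.20},
    25: {"A": 0.07, "C": 0.07, "G": 0.79, "T": 0.07},
}

#: About a third of the miRNAs carry a planted four-fold change, matching
#: the differential fraction seen in pollen heat-stress libraries; effects
#: are split between the mild (AP) and extreme (JP) genotype contrasts.
DEFAULT_FOLD_CHANGES = {
    "syn-miR001": (2.0, "JP_SH_vs_JP_NH"),
    "syn-miR002": (2.0, "JP_SH_vs_JP_NH"),
    "syn-miR003": (-2.0, "JP_SH_vs_JP_NH"),
    "syn-miR004": (-2.0, "JP_SH_vs_JP_NH"),
    "syn-miR005": (2.0, "AP_SH_vs_AP_NH"),
    "syn-miR006": (2.0, "AP_SH_vs_AP_NH"),
    "syn-miR007": (-2.0, "AP_SH_vs_AP_NH"),
    "syn-miR008": (-2.0, "AP_SH_vs_AP_NH"),
}

DEFAULT_TARGETS = {"syn-miR001": "G0001.1", "syn-miR002": "G0002.1"}

#: analyte -> ({group: mean}, sd, n per group); auxin and JA elevated and
#: MeJA depleted in the heat-sensitive genotype, six replicates each.
DEFAULT_HORMONES = {
    "IAA": ({"NH": 1.0, "SH": 1.8}, 0.15, 6),
    "JA": ({"NH": 1.0, "SH": 1.6}, 0.15, 6),
    "MeJA": ({"NH": 1.0, "SH": 0.6}, 0.10, 6),
}


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig cannot produce a consistent study."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 400_000
    n_precursors: int = 24
    cluster_fraction: float = 0.5
    mature_length_weights: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    first_base_bias: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FIRST_BASE_BIAS.items()})
    library_depth: int = 50_000
    background_fraction: float = 0.3
    planted_fold_changes: dict = field(default_factory=lambda: dict(DEFAULT_FOLD_CHANGES))
    dispersion: float = 0.05
    n_transcripts: int = 30
    planted_targets: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    degradome_depth: int = 5_000
    slice_signal_fraction: float = 0.8
    hormone_effects: dict = field(default_factory=lambda: {k: (dict(v[0]), v[1], v[2]) for k, v in DEFAULT_HORMONES.items()})
    max_cluster_gap: int = 50_000

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_r{i}" for g in GROUPS for i in range(1, N_REPLICATES + 1)]

    @property
    def n_samples(self) -> int:
        return len(GROUPS) * N_REPLICATES

    def validate(self) -> None:
        if abs(sum(self.mature_length_weights.values()) - 1.0) > 1e-9:
            raise ConfigurationError("mature_length_weights must sum to 1")
        for length, bias in self.first_base_bias.items():
            if abs(sum(bias.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"first_base_bias[{length}] must sum to 1")
        for name, frac in [
            ("cluster_fraction", self.cluster_fraction),
            ("background_fraction", self.background_fraction),
            ("slice_signal_fraction", self.slice_signal_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name, count in [
            ("n_chromosomes", self.n_chromosomes),
            ("chromosome_length", self.chromosome_length),
            ("n_precursors", self.n_precursors),
            ("library_depth", self.library_depth),
            ("n_transcripts", self.n_transcripts),
            ("degradome_depth", self.degradome_depth),
        ]:
            if count < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")

    def _rng(self, stage: int) -> np.random.Generator:
        # independent, reproducible stream per generation stage
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class SyntheticGenome:
    chromosomes: dict  # name -> DNA sequence
    loci: pd.DataFrame  # precursor locus table, 1-based inclusive
    precursors: dict  # precursor_id -> (sequence, dot_bracket, mature_start, mature_end)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, n)])


def _draw_length(rng: np.random.Generator, weights: dict) -> int:
    lengths = sorted(weights)
    probs = np.array([weights[l] for l in lengths], dtype=float)
    return int(rng.choice(lengths, p=probs / probs.sum()))


def _draw_first_base(rng: np.random.Generator, bias: dict, length: int) -> str:
    table = bias.get(length)
    if table is None:
        return DNA[rng.integers(0, 4)]
    bases = sorted(table)
    probs = np.array([table[b] for b in bases], dtype=float)
    return str(rng.choice(bases, p=probs / probs.sum()))


def _hairpin_dot_bracket(mature_len: int, loop_len: int) -> str:
    # [mature][loop][revcomp(mature)] pairs mature i with star end-i
    return "(" * mature_len + "." * loop_len + ")" * mature_len


def generate_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Build chromosomes with planted precursor hairpins.

    Each precursor is ``mature + loop + reverse-complement(mature)`` so the
    hairpin has a fully paired stem of >= 16 bp by construction.  A
    ``cluster_fraction`` share of the precursors is laid out in runs with
    successive end-to-start gaps below ``max_cluster_gap``; all other
    precursors (and the clusters themselves) are separated by larger gaps.
    """
    config.validate()
    rng = config._rng(1)

    # design precursor sequences
    precursor_rows = []
    precursors = {}
    for i in range(config.n_precursors):
        mature_len = _draw_length(rng, config.mature_length_weights)
        first = _draw_first_base(rng, config.first_base_bias, mature_len)
        mature = first + _random_seq(rng, mature_len - 1)
        loop_len = max(int(rng.integers(14, 21)), 52 - 2 * mature_len)
        loop = _random_seq(rng, loop_len)
        precursor = mature + loop + revcomp(mature)
        pid = f"syn-MIR{i + 1:03d}"
        precursors[pid] = {
            "sequence": precursor,
            "dot_bracket": _hairpin_dot_bracket(mature_len, loop_len),
            "mature_start": 1,
            "mature_end": mature_len,
            "mature_sequence": mature,
            "mirna": f"syn-miR{i + 1:03d}",
            "arm": "5p",
        }

    # group into placement units: clusters of 2-4 and singletons
    n_clustered = int(round(config.cluster_fraction * config.n_precursors))
    if n_clustered == 1:
        n_clustered = 2 if config.n_precursors >= 2 else 0
    ids = list(precursors)
    units: list[list[str]] = []
    i = 0
    while i < n_clustered:
        size = int(rng.integers(2, 5))
        size = min(size, n_clustered - i)
        if size == 1:  # never leave a dangling singleton inside the clustered share
            units[-1].append(ids[i])
            i += 1
            continue
        units.append(ids[i : i + size])
        i += size
    for pid in ids[n_clustered:]:
        units.append([pid])

    # place units across chromosomes with > max_gap between units and
    # < max_gap inside clusters
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    rows = []
    chrom_idx = 0
    cursor = int(rng.integers(1_000, 5_000))
    cluster_counter = 0
    for unit in units:
        while True:
            if chrom_idx >= len(chrom_names):
                raise ConfigurationError(
                    "total locus length exceeds chromosome capacity; "
                    "increase chromosome_length or n_chromosomes"
                )
            span = sum(len(precursors[p]["sequence"]) for p in unit) + 45_000 * (len(unit) - 1)
            if cursor + span < config.chromosome_length - 1_000:
                break
            chrom_idx += 1
            cursor = int(rng.integers(1_000, 5_000))
        cluster_id = ""
        if len(unit) > 1:
            cluster_counter += 1
            cluster_id = f"planted_cluster_{cluster_counter}"
        for j, pid in enumerate(unit):
            info = precursors[pid]
            plen = len(info["sequence"])
            start = cursor + 1  # 1-based inclusive
            end = start + plen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            mlen = info["mature_end"] - info["mature_start"] + 1
            if strand == "+":
                m_start, m_end = start, start + mlen - 1
            else:
                m_start, m_end = end - mlen + 1, end
            rows.append(
                {
                    "precursor_id": pid,
                    "mirna": info["mirna"],
                    "chromosome": chrom_names[chrom_idx],
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "mature_start": m_start,
                    "mature_end": m_end,
                    "mature_sequence": info["mature_sequence"],
                    "arm": info["arm"],
                    "cluster_id": cluster_id,
                }
            )
            if j < len(unit) - 1:
                gap = int(rng.integers(500, min(40_000, config.max_cluster_gap - 5_000)))
            else:
                gap = config.max_cluster_gap + 5_000 + int(rng.integers(0, 20_000))
            cursor = end + gap

    loci = pd.DataFrame(
        rows,
        columns=[
            "precursor_id", "mirna", "chromosome", "start", "end", "strand",
            "mature_start", "mature_end", "mature_sequence", "arm", "cluster_id",
        ],
    )

    # background chromosomes, then splice the precursors in
    chromosomes = {}
    for name in chrom_names:
        chromosomes[name] = _random_seq(rng, config.chromosome_length)
    for _, row in loci.iterrows():
        seq = precursors[row["precursor_id"]]["sequence"]
        if row["strand"] == "-":
            seq = revcomp(seq)
        chrom = chromosomes[row["chromosome"]]
        s0 = row["start"] - 1
        chromosomes[row["chromosome"]] = chrom[:s0] + seq + chrom[s0 + len(seq):]

    return SyntheticGenome(chromosomes=chromosomes, loci=loci, precursors=precursors)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def expected_group_means(config: SyntheticConfig, base_means: pd.Series) -> pd.DataFrame:
    """Per-group expected counts after applying the planted fold changes.

    A fold change ``(lfc, "X_vs_Y")`` multiplies group X's mean by 2**lfc,
    leaving Y (and all other groups) at baseline.
    """
    means = pd.DataFrame({g: base_means for g in GROUPS})
    for mirna, (lfc, contrast) in config.planted_fold_changes.items():
        if mirna not in means.index:
            continue
        top, _, bottom = contrast.partition("_vs_")
        if top not in means.columns or bottom not in means.columns:
            raise ConfigurationError(f"unknown contrast {contrast!r}")
        means.loc[mirna, top] = means.loc[mirna, top] * 2.0 ** lfc
    return means


@dataclass
class SyntheticReads:
    reads: dict  # sample -> list of (read_id, sequence, count)
    counts: pd.DataFrame  # miRNA x sample count matrix (mature reads only)
    base_means: pd.Series


def generate_reads(config: SyntheticConfig, genome: SyntheticGenome) -> SyntheticReads:
    """Per-sample collapsed read sets.

    Mature-arm reads follow negative-binomial counts around group means with
    planted fold changes; background reads are random genome windows with
    the configured length distribution and first-base bias.
    """
    config.validate()
    rng = config._rng(2)
    mirnas = list(genome.loci["mirna"]) if len(genome.loci) else []
    mature_seqs = dict(zip(genome.loci["mirna"], genome.loci["mature_sequence"])) if mirnas else {}
    mature_set = set(mature_seqs.values())

    n_mature_total = int(round((1.0 - config.background_fraction) * config.library_depth))
    if mirnas and n_mature_total > 0:
        raw = pd.Series(rng.lognormal(mean=np.log(100.0), sigma=1.0, size=len(mirnas)), index=mirnas)
        # planted differential miRNAs are at least median-abundant, matching
        # the moderate-to-high expression of DEMs in real pollen libraries
        planted = [m for m in config.planted_fold_changes if m in raw.index]
        raw[planted] = np.maximum(raw[planted], 100.0)
        base_means = raw * (n_mature_total / raw.sum())
    else:
        base_means = pd.Series(0.0, index=mirnas, dtype=float)
    group_means = expected_group_means(config, base_means) if mirnas else pd.DataFrame(index=mirnas)

    counts = pd.DataFrame(0, index=mirnas, columns=config.sample_names, dtype=int)
    reads = {}
    chrom_names = list(genome.chromosomes)
    lengths = sorted(config.mature_length_weights)
    probs = np.array([config.mature_length_weights[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()

    for sample in config.sample_names:
        group = sample.rsplit("_r", 1)[0]
        sample_reads = []
        if mirnas and n_mature_total > 0:
            mu = group_means[group].to_numpy()
            c = _nb_draw(rng, mu, config.dispersion)
            counts[sample] = c
            for name, n in zip(mirnas, c):
                if n > 0:
                    sample_reads.append((name, mature_seqs[name], int(n)))
        n_background = max(config.library_depth - int(counts[sample].sum()), 0)
        if chrom_names and n_background > 0:
            bg_lengths = rng.choice(lengths, size=n_background, p=probs)
            chrom_idx = rng.integers(0, len(chrom_names), size=n_background)
            max_start = max(config.chromosome_length - MAX_READ_LENGTH, 1)
            positions = rng.integers(0, max_start, size=n_background)
            flip = rng.random(n_background) < 0.5
            firsts = np.empty(n_background, dtype="U1")
            for length in set(int(l) for l in bg_lengths):
                mask = bg_lengths == length
                table = config.first_base_bias.get(length)
                if table is None:
                    firsts[mask] = np.array(list(DNA))[rng.integers(0, 4, int(mask.sum()))]
                else:
                    bases = sorted(table)
                    p = np.array([table[b] for b in bases], dtype=float)
                    firsts[mask] = rng.choice(bases, size=int(mask.sum()), p=p / p.sum())
            collapsed: dict[str, int] = {}
            for length, ci, pos, rc, first in zip(bg_lengths, chrom_idx, positions, flip, firsts):
                window = genome.chromosomes[chrom_names[ci]][pos : pos + int(length)]
                if rc:
                    window = revcomp(window)
                window = first + window[1:]
                if window in mature_set:
                    continue  # background must not reproduce a mature arm
                collapsed[window] = collapsed.get(window, 0) + 1
            for k, (seq, n) in enumerate(sorted(collapsed.items())):
                sample_reads.append((f"bg{k:06d}", seq, n))
        reads[sample] = sample_reads

    return SyntheticReads(reads=reads, counts=counts, base_means=base_means)


@dataclass
class SyntheticTranscripts:
    sequences: dict  # transcript_id -> sequence
    table: pd.DataFrame  # transcript_id, gene_id, length, planted miRNA/site
    gene_map: pd.DataFrame  # transcript_id -> gene_id


def generate_transcripts(config: SyntheticConfig, genome: SyntheticGenome) -> SyntheticTranscripts:
    """Random transcripts; planted targets carry the exact antisense site.

    For a planted pair the transcript contains ``revcomp(mature)`` at a
    recorded position; the expected cleavage position (paired with miRNA
    nucleotide 10) is ``site_start + len(miRNA) - 10`` (1-based).
    """
    config.validate()
    rng = config._rng(3)
    mature_seqs = dict(zip(genome.loci["mirna"], genome.loci["mature_sequence"])) if len(genome.loci) else {}
    for mirna in config.planted_targets:
        if mirna not in mature_seqs:
            raise ConfigurationError(f"planted target references unknown miRNA {mirna!r}")

    target_of = {tid: mirna for mirna, tid in config.planted_targets.items()}
    sequences = {}
    rows = []
    for i in range(config.n_transcripts):
        tid = f"G{i + 1:04d}.1"
        gene = tid.rsplit(".", 1)[0]
        length = int(rng.integers(500, 1501))
        seq = _random_seq(rng, length)
        planted_mirna = target_of.get(tid, "")
        site_start = 0
        slice_pos = 0
        if planted_mirna:
            mature = mature_seqs[planted_mirna]
            site = revcomp(mature)
            s0 = int(rng.integers(100, length - len(site) - 100))
            seq = seq[:s0] + site + seq[s0 + len(site):]
            site_start = s0 + 1  # 1-based
            slice_pos = site_start + len(mature) - 10  # paired with miRNA nt 10
        sequences[tid] = seq
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": gene,
                "length": length,
                "planted_mirna": planted_mirna,
                "site_start": site_start,
                "slice_position": slice_pos,
            }
        )
    table = pd.DataFrame(rows)
    gene_map = table[["transcript_id", "gene_id"]].copy()
    return SyntheticTranscripts(sequences=sequences, table=table, gene_map=gene_map)


def generate_degradome(config: SyntheticConfig, transcripts: SyntheticTranscripts) -> dict:
    """Pooled degradome tag libraries (one per genotype pool).

    ``slice_signal_fraction`` of a planted transcript's tags start exactly at
    the planted slice position; the rest (and all tags of unplanted
    transcripts) start uniformly along the transcript.  Tags are 20 nt
    (clipped at the 3' end, minimum 15 nt).
    """
    config.validate()
    rng = config._rng(4)
    table = transcripts.table
    planted = table[table["planted_mirna"] != ""] if len(table) else table
    if len(planted):
        for _, row in planted.iterrows():
            if row["site_start"] <= 0:
                raise ConfigurationError(
                    f"planted target {row['transcript_id']} lacks a binding site"
                )

    tids = list(transcripts.sequences)
    libraries = {}
    for lib in DEGRADOME_LIBRARIES:
        collapsed: dict[str, int] = {}
        if tids and config.degradome_depth > 0:
            # planted transcripts get a fixed half of the library so the
            # signal does not drown at small depths
            planted_ids = list(planted["transcript_id"]) if len(planted) else []
            n_planted_total = config.degradome_depth // 2 if planted_ids else 0
            per_planted = n_planted_total // max(len(planted_ids), 1) if planted_ids else 0
            n_rest = config.degradome_depth - per_planted * len(planted_ids)
            alloc = {tid: 0 for tid in tids}
            for tid in planted_ids:
                alloc[tid] += per_planted
            other = rng.multinomial(n_rest, np.full(len(tids), 1.0 / len(tids)))
            for tid, n in zip(tids, other):
                alloc[tid] += int(n)
            for tid in tids:
                seq = transcripts.sequences[tid]
                length = len(seq)
                n_tags = alloc[tid]
                if n_tags == 0:
                    continue
                row = table[table["transcript_id"] == tid].iloc[0]
                n_slice = 0
                if row["planted_mirna"]:
                    n_slice = int(round(config.slice_signal_fraction * n_tags))
                    p0 = int(row["slice_position"]) - 1
                    tag = seq[p0 : p0 + 20]
                    if len(tag) >= 15 and n_slice > 0:
                        collapsed[tag] = collapsed.get(tag, 0) + n_slice
                max_start = length - 15
                if max_start >= 0 and n_tags - n_slice > 0:
                    starts = rng.integers(0, max_start + 1, size=n_tags - n_slice)
                    for p0 in starts:
                        tag = seq[int(p0) : int(p0) + 20]
                        collapsed[tag] = collapsed.get(tag, 0) + 1
        libraries[lib] = [
            (f"tag{k:06d}", seq, n) for k, (seq, n) in enumerate(sorted(collapsed.items()))
        ]
    return libraries


def generate_hormones(config: SyntheticConfig) -> pd.DataFrame:
    """Tidy hormone measurement table: analyte, group, replicate, value."""
    config.validate()
    rng = config._rng(5)
    rows = []
    for analyte in sorted(config.hormone_effects):
        means, sd, n = config.hormone_effects[analyte]
        for group in sorted(means):
            values = rng.normal(means[group], sd, size=n)
            for i, v in enumerate(values, start=1):
                rows.append({"analyte": analyte, "group": group, "replicate": i, "value": float(v)})
    return pd.DataFrame(rows)


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    genome: SyntheticGenome
    reads: SyntheticReads
    transcripts: SyntheticTranscripts
    degradome: dict
    hormones: pd.DataFrame


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Run every generator stage and return the full in-memory study."""
    config = config or SyntheticConfig()
    genome = generate_genome(config)
    reads = generate_reads(config, genome)
    transcripts = generate_transcripts(config, genome)
    degradome = generate_degradome(config, transcripts)
    hormones = generate_hormones(config)
    return SyntheticStudy(config, genome, reads, transcripts, degradome, hormones)


def design_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for sample in config.sample_names:
        group, rep = sample.rsplit("_r", 1)
        rows.append({"sample": sample, "group": group, "replicate": int(rep)})
    return pd.DataFrame(rows)


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the whole study as plain-text files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_fasta(out / "genome.fa", study.genome.chromosomes)
    hio.write_tsv(study.genome.loci, out / "precursor_loci.tsv")
    hio.loci_to_bed(study.genome.loci).to_csv(
        out / "precursor_loci.bed", sep="\t", index=False, header=False
    )
    for sample, reads in study.reads.reads.items():
        hio.write_count_fasta(out / f"reads_{sample}.fa", reads)
        hio.write_fastq(out / f"reads_{sample}.fastq", reads)
    hio.write_tsv(study.reads.counts.rename_axis("mirna").reset_index(), out / "mirna_counts.tsv")
    hio.write_tsv(design_table(study.config), out / "design.tsv")
    hio.write_fasta(out / "transcripts.fa", study.transcripts.sequences)
    _write_transcript_gff3(study.transcripts, out / "transcripts.gff3")
    hio.write_tsv(study.transcripts.gene_map, out / "gene_map.tsv")
    for lib, tags in study.degradome.items():
        hio.write_count_fasta(out / f"degradome_{lib}.fa", tags)
    hio.write_tsv(study.hormones, out / "hormones.tsv")
    with open(out / "config.txt", "w") as fh:
        for key, value in vars(study.config).items():
            fh.write(f"{key}: {value!r}\n")


def _write_transcript_gff3(transcripts: SyntheticTranscripts, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in transcripts.table.iterrows():
            tid, gene, length = row["transcript_id"], row["gene_id"], row["length"]
            fh.write(f"{tid}\theatmir\tgene\t1\t{length}\t.\t+\t.\tID={gene}\n")
            fh.write(f"{tid}\theatmir\tmRNA\t1\t{length}\t.\t+\t.\tID={tid};Parent={gene}\n")
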