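"""Seeded desk-scale synthetic metagenome communities.

Emulates the statistical structure a differential-coverage binner relies
on: (1) each genome is drawn from an order-3 Markov chain with its own
Dirichlet-sampled transition rows, so genomes carry distinct
tetranucleotide signatures; (2) each genome receives a log-normal
abundance in every sample, with genome-by-sample effects scaled by the
``profile_separation`` preset, so genomes have distinct coverage
profiles across >= 3 samples; (3) genomes are fragmented into
log-normal-length contigs; (4) error-free single-end reads are placed
uniformly per contig with Poisson counts proportional to abundance x
depth, and emitted as sorted, indexed BAMs.

A genome's expected depth in a sample is its abundance times
``depth_factor``, so ``depth_factor`` is the read depth of a genome at
unit abundance. Everything is driven by one integer seed; the same
config and seed give byte-identical FASTA/TSV outputs and identical BAM
records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

_BASES = "ACGT"
SEPARATION_SIGMA = {"low": 0.25, "medium": 0.75, "high": 1.5}
_BASE_ABUNDANCE_SIGMA = 0.6  # log-sd of a genome's community-wide abundance
_DIRICHLET_CONC = 6.0  # concentration of per-context transition rows


@dataclass
class SimulationConfig:
    n_genomes: int = 10
    genome_length_range: tuple = (100_000, 200_000)
    n_samples: int = 3
    profile_separation: str = "high"
    depth_factor: float = 20.0
    contig_length_mu: float = 8.2  # log-normal, median ~3.6 kbp
    contig_length_sigma: float = 0.55
    read_length: int = 100
    seed: int = 42

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 (differential coverage needs it)")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be positive")
        lo, hi = self.genome_length_range
        if lo < 1 or hi < lo:
            raise ValueError("bad genome_length_range")
        if self.read_length < 1 or self.depth_factor <= 0:
            raise ValueError("read_length and depth_factor must be positive")
        if self.profile_separation not in SEPARATION_SIGMA:
            raise ValueError(
                f"profile_separation must be one of {sorted(SEPARATION_SIGMA)}"
            )
        if np.exp(self.contig_length_mu) > lo:
            raise ValueError("typical contig length exceeds the shortest genome")


@dataclass
class SyntheticTruth:
    """Generator outputs: file paths plus in-memory truth and expectations."""

    fasta: Path
    bams: list
    truth_tsv: Path
    truth: pd.DataFrame  # contig_id, verified_bin_id (source genome), length
    expected_coverage: pd.DataFrame  # contig_id x sample expected mean depth
    config: SimulationConfig


def _markov_genome(rng: np.random.Generator, length: int) -> str:
    """One genome from an order-3 Markov chain with Dirichlet-drawn rows."""
    base_weights = rng.dirichlet(np.full(4, 5.0))
    rows = rng.dirichlet(_DIRICHLET_CONC * 4 * base_weights, size=64)
    cum = np.cumsum(rows, axis=1)
    seq = np.empty(length, dtype=np.int64)
    seq[:3] = rng.integers(0, 4, size=3)
    ctx = int(seq[0] * 16 + seq[1] * 4 + seq[2])
    u = rng.random(length)
    for i in range(3, length):
        row = cum[ctx]
        b = int(u[i] > row[0]) + int(u[i] > row[1]) + int(u[i] > row[2])
        seq[i] = b
        ctx = (ctx * 4) % 64 + b
    return "".join(_BASES[b] for b in seq)


def _fragment(rng: np.random.Generator, length: int, mu: float, sigma: float):
    """Cut [0, length) into contig intervals with log-normal lengths."""
    cuts = []
    start = 0
    while start < length:
        clen = max(1, int(round(rng.lognormal(mu, sigma))))
        clen = min(clen, length - start)
        cuts.append((start, start + clen))
        start += clen
    return cuts


def write_fixture_bams(placements: dict, contigs: dict, out_dir: str | Path) -> dict:
    """Write one sorted+indexed BAM per sample from explicit read placements.

    *placements* maps sample name -> list of (contig_id, start) pairs
    with an implied full-length, error-free, forward-strand read;
    *contigs* maps contig id -> (sequence, read_length source). Here the
    read length is recovered from the placement tuple when present:
    entries may be (contig_id, start) or (contig_id, start, read_len).
    All reads are primary, MAPQ 60, full-match CIGAR.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = sorted(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cid, "LN": len(contigs[cid])} for cid in ids],
    }
    tid = {cid: i for i, cid in enumerate(ids)}
    paths = {}
    for sample in sorted(placements):
        unsorted = out_dir / f"{sample}.unsorted.bam"
        final = out_dir / f"{sample}.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
            for n, placement in enumerate(placements[sample]):
                cid, start, rlen = (
                    placement if len(placement) == 3 else (*placement, None)
                )
                seq = contigs[cid]
                if rlen is None:
                    rlen = min(100, len(seq))
                if start < 0 or start + rlen > len(seq):
                    raise ValueError(
                        f"read at {cid}:{start}+{rlen} exceeds contig bounds"
                    )
                a = pysam.AlignedSegment()
                a.query_name = f"{sample}.{n}"
                a.flag = 0
                a.reference_id = tid[cid]
                a.reference_start = start
                a.mapping_quality = 60
                a.cigartuples = [(0, rlen)]
                a.query_sequence = seq[start : start + rlen]
                bam.write(a)
        pysam.sort("-o", str(final), str(unsorted))
        unsorted.unlink()
        pysam.index(str(final))
        paths[sample] = final
    return paths


def simulate_community(config: SimulationConfig, out_dir: str | Path) -> SyntheticTruth:
    """Generate a full community: FASTA, per-sample BAMs, truth, expectations."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    genome_seeds, abund_seed, read_seed = root.spawn(3)
    genome_rngs = [np.random.default_rng(s) for s in genome_seeds.spawn(config.n_genomes)]
    abund_rng = np.random.default_rng(abund_seed)
    read_rng = np.random.default_rng(read_seed)

    # genomes and contigs
    genome_names = [f"g{g + 1:02d}" for g in range(config.n_genomes)]
    contig_seqs: dict = {}
    contig_genome: dict = {}
    for name, rng in zip(genome_names, genome_rngs):
        glen = int(rng.integers(config.genome_length_range[0], config.genome_length_range[1] + 1))
        genome = _markov_genome(rng, glen)
        for start, end in _fragment(
            rng, glen, config.contig_length_mu, config.contig_length_sigma
        ):
            cid = f"ctg_{len(contig_seqs) + 1:05d}"
            contig_seqs[cid] = genome[start:end]
            contig_genome[cid] = name

    # per-sample abundances: log-normal genome base level plus
    # genome-by-sample effects scaled by the separation preset
    sigma = SEPARATION_SIGMA[config.profile_separation]
    base = abund_rng.normal(0.0, _BASE_ABUNDANCE_SIGMA, size=config.n_genomes)
    effects = abund_rng.normal(0.0, 1.0, size=(config.n_genomes, config.n_samples))
    abundance = np.exp(base[:, None] + sigma * effects)

    sample_names = [f"sample{s + 1}" for s in range(config.n_samples)]
    genome_idx = {name: g for g, name in enumerate(genome_names)}
    contig_ids = list(contig_seqs)

    expected = np.zeros((len(contig_ids), config.n_samples))
    placements: dict = {s: [] for s in sample_names}
    for i, cid in enumerate(contig_ids):
        seq = contig_seqs[cid]
        g = genome_idx[contig_genome[cid]]
        for s, sample in enumerate(sample_names):
            depth = abundance[g, s] * config.depth_factor
            if len(seq) < config.read_length:
                continue
            expected[i, s] = depth
            lam = depth * len(seq) / config.read_length
            count = int(read_rng.poisson(lam))
            if count:
                starts = read_rng.integers(
                    0, len(seq) - config.read_length + 1, size=count
                )
                placements[sample].extend(
                    (cid, int(p), config.read_length) for p in sorted(starts)
                )

    # outputs
    fasta = out_dir / "contigs.fa"
    with fasta.open("w") as fh:
        for cid in contig_ids:
            fh.write(f">{cid}\n{contig_seqs[cid]}\n")
    bam_paths = write_fixture_bams(placements, contig_seqs, out_dir)

    truth = pd.DataFrame(
        {
            "contig_id": contig_ids,
            "verified_bin_id": [contig_genome[c] for c in contig_ids],
            "length": [len(contig_seqs[c]) for c in contig_ids],
        }
    )
    truth_tsv = out_dir / "truth.tsv"
    truth[["contig_id", "verified_bin_id"]].to_csv(
        truth_tsv, sep="\t", header=False, index=False
    )
    expected_df = pd.DataFrame(expected, index=contig_ids, columns=sample_names)
    expected_df.to_csv(out_dir / "expected_coverage.tsv", sep="\t")
    (out_dir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=list) + "\n"
    )
    return SyntheticTruth(
        fasta=fasta,
        bams=[bam_paths[s] for s in sample_names],
        truth_tsv=truth_tsv,
        truth=truth,
        expected_coverage=expected_df,
        config=config,
    )


def simulate_marker_table(
    truth: pd.DataFrame, n_markers: int = 20, seed: int = 0
) -> tuple[list, list]:
    """Single-copy marker hits consistent with a truth table.

    Each source genome carries each of *n_markers* markers exactly once,
    on a contig chosen with probability proportional to length — the
    pattern real single-copy marker sets produce on a perfect assembly.
    Returns (hit rows, marker set).
    """
    rng = np.random.default_rng(seed)
    marker_set = [f"m{k + 1:03d}" for k in range(n_markers)]
    rows = []
    for _genome, grp in truth.groupby("verified_bin_id", sort=True):
        weights = grp["length"].to_numpy(dtype=float)
        weights /= weights.sum()
        for marker in marker_set:
            cid = grp["contig_id"].to_numpy()[rng.choice(len(grp), p=weights)]
            rows.append((cid, marker))
    return rows, marker_set
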