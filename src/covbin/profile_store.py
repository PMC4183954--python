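"""Parse stage: contig/coverage/composition profiling and the profile database.

Reads a contig FASTA plus one sorted+indexed BAM per related sample,
computes per-sample mean read depth and canonical tetranucleotide
frequency profiles for every retained contig, and persists everything in
a single HDF5 file (the *profile store*) that the later stages mutate in
place.

Tetranucleotide profiles use 136 canonical classes: the 256 4-mers
collapsed by summing each tetramer with its reverse complement (16
palindromes plus 120 complementary pairs), so a contig and its reverse
complement have identical composition vectors.
"""

from __future__ import annotations

import json
import logging
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

N_TETRAMER_CLASSES = 136
_BASES = "ACGT"

# ---------------------------------------------------------------------------
# canonical tetramer classes


@lru_cache(maxsize=1)
def canonical_tetramer_classes() -> tuple[tuple[str, ...], dict[str, int]]:
    """Return the 136 canonical tetramer class labels and the 256->class map.

    A tetramer and its reverse complement belong to the same class; the
    class label is the lexicographically smaller of the pair, and classes
    are ordered lexicographically by label.
    """
    labels = set()
    for i in range(256):
        t = "".join(_BASES[(i >> (2 * k)) & 3] for k in (3, 2, 1, 0))
        rc = str(Seq(t).reverse_complement())
        labels.add(min(t, rc))
    ordered = tuple(sorted(labels))
    index = {label: k for k, label in enumerate(ordered)}
    mapping = {}
    for i in range(256):
        t = "".join(_BASES[(i >> (2 * k)) & 3] for k in (3, 2, 1, 0))
        rc = str(Seq(t).reverse_complement())
        mapping[t] = index[min(t, rc)]
    return ordered, mapping


@lru_cache(maxsize=1)
def _class_lookup() -> np.ndarray:
    """Map tetramer code (base-4 integer, AAAA=0..TTTT=255) -> class index."""
    _, mapping = canonical_tetramer_classes()
    lut = np.empty(256, dtype=np.int64)
    for t, cls in mapping.items():
        code = 0
        for ch in t:
            code = code * 4 + _BASES.index(ch)
        lut[code] = cls
    return lut


@lru_cache(maxsize=1)
def _base_codes() -> np.ndarray:
    """ASCII byte -> base code (A=0,C=1,G=2,T=3, N=-1, other=-2)."""
    codes = np.full(256, -2, dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[ord(b)] = i
        codes[ord(b.lower())] = i
    codes[ord("N")] = -1
    codes[ord("n")] = -1
    return codes


def count_tetranucleotides(sequence: str) -> np.ndarray:
    """Canonical tetramer frequency vector (length 136) of *sequence*.

    A 1 bp sliding window counts every 4-mer; windows containing N are
    skipped; counts of reverse-complement pairs are summed and the vector
    is normalised by the number of valid windows (all-zero if there is
    none).

    Raises ValueError on characters outside {A,C,G,T,N} (case-insensitive).
    """
    enc = _base_codes()[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(enc == -2)[0]
    if bad.size:
        ch = sequence[bad[0]]
        raise ValueError(f"non-nucleotide character {ch!r} in sequence")
    freqs = np.zeros(N_TETRAMER_CLASSES, dtype=np.float64)
    if enc.size < 4:
        return freqs
    codes = (
        64 * enc[:-3] + 16 * enc[1:-2] + 4 * enc[2:-1] + enc[3:]
    )
    valid = (enc[:-3] >= 0) & (enc[1:-2] >= 0) & (enc[2:-1] >= 0) & (enc[3:] >= 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return freqs
    cls = _class_lookup()[codes[valid]]
    counts = np.bincount(cls, minlength=N_TETRAMER_CLASSES).astype(np.float64)
    return counts / n_valid


# ---------------------------------------------------------------------------
# coverage


def _usable(read: pysam.AlignedSegment, mapq_min: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and read.mapping_quality >= mapq_min
    )


def contig_mean_depth(
    bam: str | Path | pysam.AlignmentFile,
    contig_id: str,
    contig_length: int,
    mapq_min: int = 0,
) -> float:
    """Mean per-base aligned depth of *contig_id* in one BAM.

    Depth is the sum over reference positions of aligned-base counts
    divided by the contig length; only CIGAR match/mismatch blocks of
    primary, non-duplicate, non-supplementary alignments with mapping
    quality >= *mapq_min* contribute. Insertions and clips add nothing.
    """
    own = not isinstance(bam, pysam.AlignmentFile)
    handle = pysam.AlignmentFile(str(bam), "rb") if own else bam
    try:
        if not handle.has_index():
            raise FileNotFoundError(f"BAM {handle.filename!r} has no index")
        if contig_id not in handle.references:
            raise KeyError(f"contig {contig_id!r} absent from BAM header")
        total = 0
        for read in handle.fetch(contig_id):
            if not _usable(read, mapq_min):
                continue
            for start, end in read.get_blocks():
                total += end - start
        return total / contig_length
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# the profile store


class ProfileStore:
    """Single-file profile database for one assembly.

    Holds the contig table (ids, lengths, GC), the coverage matrix (one
    column per sample, CLI order), the canonical tetramer matrix, and —
    once the later stages have run — transformed coordinates, composition
    PCA scores, bin assignments and the refine journal. All sections are
    row-aligned on contig id and round-trip bit-exactly through HDF5.
    """

    def __init__(
        self,
        contig_ids: np.ndarray,
        lengths: np.ndarray,
        gc: np.ndarray,
        sample_names: list[str],
        coverage: np.ndarray,
        kmers: np.ndarray,
        path: str | Path | None = None,
        meta: dict | None = None,
    ):
        self.path = Path(path) if path is not None else None
        self.contig_ids = np.asarray(contig_ids, dtype=object)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.gc = np.asarray(gc, dtype=np.float64)
        self.sample_names = list(sample_names)
        self.coverage = np.asarray(coverage, dtype=np.float64)
        self.kmers = np.asarray(kmers, dtype=np.float64)
        self.transformed: np.ndarray | None = None
        self.zero_coverage_flags: np.ndarray | None = None
        self.tf_scores: np.ndarray | None = None
        self.pca_loadings: np.ndarray | None = None
        self.bins = np.zeros(len(self.contig_ids), dtype=np.int64)
        self.meta = dict(meta or {})
        self.journal: list[dict] = []
        self._validate()

    def _validate(self) -> None:
        n = len(self.contig_ids)
        if len(set(self.contig_ids)) != n:
            raise ValueError("contig ids are not unique")
        if np.any(self.lengths < 1):
            raise ValueError("contig lengths must be >= 1")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc must lie in [0, 1]")
        if self.coverage.shape != (n, len(self.sample_names)):
            raise ValueError("coverage matrix shape mismatch")
        if np.any(self.coverage < 0):
            raise ValueError("coverage must be non-negative")
        if self.kmers.shape != (n, N_TETRAMER_CLASSES):
            raise ValueError("tetramer matrix must have 136 columns")

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def index_of(self, contig_id: str) -> int:
        idx = np.nonzero(self.contig_ids == contig_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown contig {contig_id!r}")
        return int(idx[0])

    # -- persistence

    def save(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path is not None else self.path
        if path is None:
            raise ValueError("no output path given")
        self.path = path
        str_dt = h5py.string_dtype(encoding="utf-8")
        with h5py.File(path, "w") as fh:
            g = fh.create_group("contigs")
            g.create_dataset("ids", data=np.asarray(self.contig_ids, dtype=str_dt))
            g.create_dataset("lengths", data=self.lengths)
            g.create_dataset("gc", data=self.gc)
            fh.create_dataset("coverage", data=self.coverage)
            fh.create_dataset("kmers", data=self.kmers)
            if self.transformed is not None:
                fh.create_dataset("transformed", data=self.transformed)
                fh.create_dataset("zero_coverage", data=self.zero_coverage_flags)
            if self.tf_scores is not None:
                fh.create_dataset("tf_scores", data=self.tf_scores)
            if self.pca_loadings is not None:
                fh.create_dataset("pca_loadings", data=self.pca_loadings)
            fh.create_dataset("bins", data=self.bins)
            m = fh.create_group("meta")
            m.attrs["sample_names"] = json.dumps(self.sample_names)
            m.attrs["params"] = json.dumps(self.meta, sort_keys=True)
            m.attrs["journal"] = json.dumps(self.journal)
            m.attrs["version"] = __import__("covbin").__version__
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProfileStore":
        with h5py.File(path, "r") as fh:
            ids = np.array(
                [s.decode() if isinstance(s, bytes) else s for s in fh["contigs/ids"][:]],
                dtype=object,
            )
            sample_names = json.loads(fh["meta"].attrs["sample_names"])
            store = cls(
                contig_ids=ids,
                lengths=fh["contigs/lengths"][:],
                gc=fh["contigs/gc"][:],
                sample_names=sample_names,
                coverage=fh["coverage"][:],
                kmers=fh["kmers"][:],
                path=path,
                meta=json.loads(fh["meta"].attrs["params"]),
            )
            if "transformed" in fh:
                store.transformed = fh["transformed"][:]
                store.zero_coverage_flags = fh["zero_coverage"][:].astype(bool)
            if "tf_scores" in fh:
                store.tf_scores = fh["tf_scores"][:]
            if "pca_loadings" in fh:
                store.pca_loadings = fh["pca_loadings"][:]
            store.bins = fh["bins"][:]
            store.journal = json.loads(fh["meta"].attrs["journal"])
        return store


def _gc_fraction(sequence: str) -> float:
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in _BASES)
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def build_profile_store(
    fasta: str | Path,
    bam_list: list[str | Path],
    min_contig_len: int = 500,
    out_path: str | Path | None = None,
    mapq_min: int = 0,
) -> ProfileStore:
    """Parse stage: build (and optionally save) the profile store.

    Contigs shorter than *min_contig_len* (default 500 bp, the standard
    assembly filter) are dropped. Each BAM becomes one coverage column,
    in the order given — the transform depends on this order. Fewer than
    three samples triggers a warning because the downstream coverage
    transform requires at least three related samples.
    """
    if not bam_list:
        raise ValueError("at least one BAM is required")
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise ValueError(f"FASTA {fasta} is empty")
    if len(bam_list) < 3:
        logger.warning(
            "only %d samples given; the coverage transform requires >= 3",
            len(bam_list),
        )

    kept = [r for r in records if len(r.seq) >= min_contig_len]
    logger.info(
        "retained %d/%d contigs (min length %d bp)",
        len(kept), len(records), min_contig_len,
    )
    if not kept:
        raise ValueError("no contigs pass the minimum length filter")

    ids = np.array([r.id for r in kept], dtype=object)
    lengths = np.array([len(r.seq) for r in kept], dtype=np.int64)
    gc = np.array([_gc_fraction(str(r.seq)) for r in kept], dtype=np.float64)
    fasta_len = {r.id: len(r.seq) for r in kept}

    coverage = np.zeros((len(kept), len(bam_list)), dtype=np.float64)
    sample_names = []
    for j, bam_path in enumerate(bam_list):
        with pysam.AlignmentFile(str(bam_path), "rb") as bam:
            header = dict(zip(bam.references, bam.lengths))
            missing = [
                f"{cid} (len {l})"
                for cid, l in fasta_len.items()
                if header.get(cid) != l
            ]
            if missing:
                raise ValueError(
                    f"BAM {bam_path} header inconsistent with FASTA for: "
                    + ", ".join(missing[:10])
                )
            sample_names.append(Path(bam_path).stem)
            for i, cid in enumerate(ids):
                coverage[i, j] = contig_mean_depth(
                    bam, cid, int(lengths[i]), mapq_min=mapq_min
                )

    kmers = np.vstack([count_tetranucleotides(str(r.seq)) for r in kept])
    store = ProfileStore(
        contig_ids=ids,
        lengths=lengths,
        gc=gc,
        sample_names=sample_names,
        coverage=coverage,
        kmers=kmers,
        path=out_path,
        meta={"min_contig_len": min_contig_len, "mapq_min": mapq_min},
    )
    if out_path is not None:
        store.save(out_path)
    return store
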