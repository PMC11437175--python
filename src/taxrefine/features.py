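"""Per-contig feature table: projected TNFs plus multi-sample abundances.

Each contig contributes one row of ``103 + Ns + 1`` values:

* 103 tetranucleotide-frequency dimensions, obtained by projecting the
  centred tetramer frequency vector through the fixed orthonormal kernel
  and then z-scaling each dimension across contigs;
* ``Ns`` per-sample abundances, normalised within sample and then across
  samples so each row sums to one;
* one sample-relative total abundance, taken before the across-sample
  normalisation and passed through untransformed.

Depths arrive as a TSV (``contigname`` column then one column per sample),
typically produced upstream by a coverage extractor from sorted BAM files;
computing coverage from alignments is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .kernel import N_TETRAMERS, TNF_DIM, projection_kernel

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG_LENGTH = 2000

# ASCII -> base code lookup; -1 marks anything outside ACGT/acgt (all IUPAC
# ambiguity codes are treated as ambiguous).
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def count_tetramers(sequence: str, contig_id: str | None = None) -> np.ndarray:
    """Count tetramer occurrences in a sliding window of step 1.

    Windows containing any character outside {A, C, G, T} (case-insensitive)
    are skipped. Sequences shorter than 4 bp yield all-zero counts.

    Returns a vector of 256 nonnegative integers in lexicographic tetramer
    order.
    """
    if len(sequence) == 0:
        raise ValueError(f"empty sequence for contig {contig_id!r}")
    if len(sequence) < 4:
        return np.zeros(N_TETRAMERS, dtype=np.int64)
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    idx = ((c0 * 4 + c1) * 4 + c2) * 4 + c3
    return np.bincount(idx[valid], minlength=N_TETRAMERS).astype(np.int64)


def project_tnf(counts: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Project raw tetramer counts into the 103-dimensional kernel space.

    Counts are normalised to frequencies, centred by subtracting the
    uniform frequency 1/256, and multiplied by the kernel. An all-zero
    count vector (no unambiguous window) maps to the zero vector.
    """
    if kernel is None:
        kernel = projection_kernel()
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum(axis=-1, keepdims=True)
    if counts.ndim == 1:
        if total == 0:
            return np.zeros(TNF_DIM)
        return (counts / total - 1.0 / N_TETRAMERS) @ kernel
    freqs = np.divide(counts, total, out=np.zeros_like(counts), where=total > 0)
    freqs = np.where(total > 0, freqs - 1.0 / N_TETRAMERS, 0.0)
    return freqs @ kernel


def zscale_columns(matrix: np.ndarray) -> np.ndarray:
    """Z-scale each column across contigs (population standard deviation).

    Zero-variance columns — including every column when there is a single
    contig — are set to zero.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0)
    out = np.zeros_like(matrix)
    nz = std > 0
    out[:, nz] = (matrix[:, nz] - mean[nz]) / std[nz]
    return out


@dataclass(frozen=True)
class AbundanceMatrix:
    """Row-normalised per-sample abundances plus sample-relative totals."""

    per_sample: np.ndarray  # Nc x Ns, rows sum to 1 where total > 0
    total: np.ndarray  # Nc, taken before across-sample normalisation
    sample_ids: tuple[str, ...]


def normalize_abundances(
    depths: np.ndarray,
    sample_totals: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
    contig_ids: Sequence[str] | None = None,
) -> AbundanceMatrix:
    """Normalise a contig-by-sample depth table into abundance features.

    Step 1 divides each sample column by that sample's total mapped reads
    (``sample_totals``; when absent, the per-sample column sum of depths is
    used as a proxy with the same relative scaling). Step 2 records each
    contig's row sum as its sample-relative total abundance. Step 3
    normalises each row with positive total to sum to one; all-zero rows
    stay zero.
    """
    depths = np.asarray(depths, dtype=np.float64)
    if depths.ndim != 2:
        raise ValueError("depths must be a 2-D contig x sample array")
    n_contigs, n_samples = depths.shape
    if np.any(depths < 0):
        c, s = np.argwhere(depths < 0)[0]
        cname = contig_ids[c] if contig_ids is not None else f"row {c}"
        sname = sample_ids[s] if sample_ids is not None else f"column {s}"
        raise ValueError(f"negative depth for contig {cname!r} in sample {sname!r}")
    if sample_totals is None:
        sample_totals = depths.sum(axis=0)
        sample_totals[sample_totals == 0] = 1.0
    sample_totals = np.asarray(sample_totals, dtype=np.float64)
    if sample_totals.shape != (n_samples,) or np.any(sample_totals <= 0):
        raise ValueError("sample_totals must be strictly positive, one per sample")
    within = depths / sample_totals
    total = within.sum(axis=1)
    per_sample = np.divide(
        within, total[:, None], out=np.zeros_like(within), where=total[:, None] > 0
    )
    if sample_ids is None:
        sample_ids = tuple(f"sample{i + 1}" for i in range(n_samples))
    return AbundanceMatrix(per_sample=per_sample, total=total, sample_ids=tuple(sample_ids))


@dataclass(frozen=True)
class FeatureMatrix:
    """The Nc x (103 + Ns + 1) feature table with block boundaries."""

    values: np.ndarray
    contig_ids: tuple[str, ...]
    n_samples: int
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        expected = TNF_DIM + self.n_samples + 1
        if self.values.shape != (len(self.contig_ids), expected):
            raise ValueError(
                f"feature table shape {self.values.shape} does not match "
                f"{len(self.contig_ids)} contigs x (103 + {self.n_samples} + 1)"
            )

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)

    @property
    def tnf(self) -> np.ndarray:
        return self.values[:, :TNF_DIM]

    @property
    def abundance(self) -> np.ndarray:
        return self.values[:, TNF_DIM : TNF_DIM + self.n_samples]

    @property
    def total_abundance(self) -> np.ndarray:
        return self.values[:, -1]

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"tnf{i}" for i in range(TNF_DIM)]
            + [f"abund_{s}" for s in (self.sample_ids or range(self.n_samples))]
            + ["total_abundance"]
        )
        return pd.DataFrame(self.values, index=list(self.contig_ids), columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("contigname").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        n_samples = frame.shape[1] - TNF_DIM - 1
        sample_ids = tuple(
            c.removeprefix("abund_") for c in frame.columns[TNF_DIM : TNF_DIM + n_samples]
        )
        return cls(
            values=frame.to_numpy(dtype=np.float64),
            contig_ids=tuple(str(i) for i in frame.index),
            n_samples=n_samples,
            sample_ids=sample_ids,
        )


def assemble_features(
    tnf_z: np.ndarray,
    abundances: AbundanceMatrix,
    contig_ids: Sequence[str],
) -> FeatureMatrix:
    """Concatenate [z-scaled TNF | per-sample abundance | total] blocks."""
    tnf_z = np.asarray(tnf_z, dtype=np.float64)
    if tnf_z.shape[0] != abundances.per_sample.shape[0] or tnf_z.shape[0] != len(contig_ids):
        raise ValueError(
            f"row-count mismatch: {tnf_z.shape[0]} TNF rows, "
            f"{abundances.per_sample.shape[0]} abundance rows, {len(contig_ids)} contig ids"
        )
    values = np.hstack([tnf_z, abundances.per_sample, abundances.total[:, None]])
    return FeatureMatrix(
        values=values,
        contig_ids=tuple(contig_ids),
        n_samples=abundances.per_sample.shape[1],
        sample_ids=abundances.sample_ids,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (contig id, sequence) pairs; the id is the first header token."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_depths(path: str | Path) -> pd.DataFrame:
    """Read the depth TSV: `contigname` index, one column per sample."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.map(str)
    return frame


def compute_features(
    fasta_path: str | Path,
    depths_path: str | Path,
    min_contig_length: int = DEFAULT_MIN_CONTIG_LENGTH,
    sample_reads_path: str | Path | None = None,
) -> FeatureMatrix:
    """Full feature pipeline from a contig FASTA and a depth TSV.

    Contigs shorter than ``min_contig_length`` are dropped (with a logged
    count). Every kept contig must have a row in the depth table.
    ``sample_reads_path`` optionally points to a two-column TSV of
    per-sample total mapped reads used for the within-sample normalisation.
    """
    records = read_fasta(fasta_path)
    if not records:
        raise ValueError(f"no contigs in {fasta_path}")
    kept = [(cid, seq) for cid, seq in records if len(seq) >= min_contig_length]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("dropped %d contigs shorter than %d bp", n_dropped, min_contig_length)
    if not kept:
        raise ValueError(f"no contigs of length >= {min_contig_length} bp in {fasta_path}")
    contig_ids = [cid for cid, _ in kept]
    if len(set(contig_ids)) != len(contig_ids):
        raise ValueError(f"duplicate contig ids in {fasta_path}")

    depth_frame = read_depths(depths_path)
    missing = [cid for cid in contig_ids if cid not in depth_frame.index]
    if missing:
        raise ValueError(f"contigs missing from depth table: {missing[:5]}")
    depths = depth_frame.loc[contig_ids].to_numpy(dtype=np.float64)

    sample_totals = None
    if sample_reads_path is not None:
        totals_frame = pd.read_csv(sample_reads_path, sep="\t", index_col=0)
        sample_totals = (
            totals_frame.iloc[:, 0].reindex(depth_frame.columns).to_numpy(dtype=np.float64)
        )
        if np.any(~np.isfinite(sample_totals)):
            raise ValueError("sample read totals do not cover every depth column")

    counts = np.stack([count_tetramers(seq, cid) for cid, seq in kept])
    tnf = project_tnf(counts)
    tnf_z = zscale_columns(tnf)
    abund = normalize_abundances(
        depths,
        sample_totals=sample_totals,
        sample_ids=list(depth_frame.columns),
        contig_ids=contig_ids,
    )
    return assemble_features(tnf_z, abund, contig_ids)
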