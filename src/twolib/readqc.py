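"""Raw-read filtering, brute-force mapping and per-gene counting.

Three read-level filters are applied in a fixed order: (1) the read
contains the adaptor literal as a substring, (2) unknown bases (N) make
up more than ``max_n_frac`` of the read, (3) bases at or below Phred
``lowq_threshold`` make up more than ``lowq_frac`` of the read. Both
"more than" comparisons are strict, so a read sitting exactly on a
boundary is kept. Each removed read is attributed to the first rule it
trips.

Mapping is a deliberately simple mismatch-bounded exact scan: every
clean read is compared against every position of every reference gene
on both strands, with Hamming distance up to ``max_mismatches``
(default 2, the conventional short-read setting). Reads hitting exactly
one gene are unique and contribute to that gene's count and coverage
mask; reads hitting several genes are tallied as multi-mapped and
excluded from unique counts. There is no indexing, gapped alignment or
quality trimming: this is a reference-counting stand-in, not an aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ParseError",
    "ReadRecord",
    "FilterReport",
    "LibraryCounts",
    "read_fastq",
    "filter_reads",
    "map_reads",
    "coverage_ratio",
    "remove_bacterial_genes",
]

logger = logging.getLogger("twolib")

_CODE = np.full(256, 4, dtype=np.uint8)  # anything unexpected behaves like N
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_COMPLEMENT = {65: 84, 84: 65, 67: 71, 71: 67, 78: 78}  # A<->T, C<->G, N->N


class ParseError(ValueError):
    """Raised for malformed read records, naming the offending record."""


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.sequence) != len(self.qualities):
            raise ParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if (self.qualities < 0).any():
            raise ParseError(f"read {self.read_id!r}: negative Phred quality")


@dataclass
class FilterReport:
    """Tallies of the three-rule raw-read filter."""

    n_raw: int = 0
    n_adaptor_removed: int = 0
    n_highN_removed: int = 0
    n_lowq_removed: int = 0

    @property
    def n_clean(self) -> int:
        return (self.n_raw - self.n_adaptor_removed
                - self.n_highN_removed - self.n_lowq_removed)

    def as_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_adaptor_removed": self.n_adaptor_removed,
            "n_highN_removed": self.n_highN_removed,
            "n_lowq_removed": self.n_lowq_removed,
            "n_clean": self.n_clean,
        }


@dataclass
class LibraryCounts:
    """Per-gene unique-read counts plus library size for one condition.

    ``library_size`` is the number of clean reads entering the mapper
    (the pre-mapping total), which is the N that normalises RPKM and the
    two-library test. ``coverage_mask`` holds one boolean array per gene
    marking bases covered by uniquely mapped reads.
    """

    sample_id: str
    counts: pd.Series
    library_size: int
    coverage_mask: dict[str, np.ndarray] = field(default_factory=dict)
    n_multi_mapped: int = 0

    def to_frame(self, lengths: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.counts.index, "count": self.counts.to_numpy()})
        if self.coverage_mask:
            df["covered_bases"] = [
                int(self.coverage_mask[g].sum()) if g in self.coverage_mask else 0
                for g in df["gene_id"]
            ]
        if lengths is not None:
            df["length_bp"] = lengths.reindex(df["gene_id"]).to_numpy()
        return df


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a Sanger (Phred+33) FASTQ file into ReadRecords."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            ReadRecord(rec.id, str(rec.seq).upper(),
                       np.asarray(rec.letter_annotations["phred_quality"], dtype=int))
        )
    return records


def filter_reads(
    reads: Iterable[ReadRecord],
    adaptor: str,
    max_n_frac: float = 0.10,
    lowq_threshold: int = 5,
    lowq_frac: float = 0.50,
) -> tuple[list[ReadRecord], FilterReport]:
    """Apply the three raw-read filters; returns (clean reads, report)."""
    if not adaptor:
        raise ValueError("adaptor must be a non-empty string")
    if not (0.0 <= max_n_frac <= 1.0 and 0.0 <= lowq_frac <= 1.0):
        raise ValueError("filter fractions must lie in [0, 1]")
    report = FilterReport()
    clean: list[ReadRecord] = []
    for read in reads:
        report.n_raw += 1
        n = len(read.sequence)
        if adaptor in read.sequence:
            report.n_adaptor_removed += 1
        elif read.sequence.count("N") > max_n_frac * n:
            report.n_highN_removed += 1
        elif int((read.qualities <= lowq_threshold).sum()) > lowq_frac * n:
            report.n_lowq_removed += 1
        else:
            clean.append(read)
    return clean, report


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _revcomp(seq: str) -> str:
    return seq.encode().translate(bytes(_COMPLEMENT.get(i, 78) for i in range(256)))[::-1].decode()


def map_reads(
    reads: Iterable[ReadRecord],
    sequences: dict[str, str],
    max_mismatches: int = 2,
) -> LibraryCounts:
    """Exhaustively map clean reads against every gene on both strands.

    A read "hits" a gene if some offset on either strand has at most
    ``max_mismatches`` mismatching bases (N never matches a real base).
    Unique hits increment the gene's count and mark covered bases at the
    best-scoring offset; multi-gene hits are counted as multi-mapped.
    """
    if not sequences:
        raise ValueError("reference is empty")
    reads = list(reads)
    gene_ids = list(sequences)
    windows = {}
    for g in gene_ids:
        arr = _encode(sequences[g])
        windows[g] = arr
    counts = pd.Series(0, index=gene_ids, dtype=int, name="count")
    masks = {g: np.zeros(len(sequences[g]), dtype=bool) for g in gene_ids}
    n_multi = 0

    for read in reads:
        k = len(read.sequence)
        fwd = _encode(read.sequence)
        rev = _encode(_revcomp(read.sequence))
        hits: list[tuple[str, int]] = []  # (gene, best offset)
        for g in gene_ids:
            arr = windows[g]
            if len(arr) < k:
                continue
            win = sliding_window_view(arr, k)
            best_off, best_mm = -1, max_mismatches + 1
            for query in (fwd, rev):
                mm = (win != query).sum(axis=1)
                off = int(mm.argmin())
                if mm[off] < best_mm:
                    best_mm, best_off = int(mm[off]), off
            if best_mm <= max_mismatches:
                hits.append((g, best_off))
        if len(hits) == 1:
            g, off = hits[0]
            counts[g] += 1
            masks[g][off:off + k] = True
        elif len(hits) > 1:
            n_multi += 1

    return LibraryCounts(
        sample_id="mapped",
        counts=counts,
        library_size=len(reads),
        coverage_mask=masks,
        n_multi_mapped=n_multi,
    )


def coverage_ratio(mask: np.ndarray) -> float:
    """Fraction of a gene's bases covered by uniquely mapped reads."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty coverage mask")
    return float(mask.sum()) / mask.size


def remove_bacterial_genes(counts: LibraryCounts, bacterial_ids: set[str]) -> LibraryCounts:
    """Drop contaminant genes from the count table.

    The library size is deliberately left unchanged: N is the clean-read
    total of the library, not the sum of retained counts.
    """
    keep = [g for g in counts.counts.index if g not in bacterial_ids]
    if not keep:
        logger.warning("remove_bacterial_genes: every gene was flagged bacterial; "
                       "count table for %s is now empty", counts.sample_id)
    return LibraryCounts(
        sample_id=counts.sample_id,
        counts=counts.counts.loc[keep],
        library_size=counts.library_size,
        coverage_mask={g: m for g, m in counts.coverage_mask.items() if g in keep},
        n_multi_mapped=counts.n_multi_mapped,
    )
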