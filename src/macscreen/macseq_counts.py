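"""Plate-multiplexed 3' RNA-seq read processing.

Read 1 carries the well barcode at positions 1-10 and the UMI at positions
11-20 (1-based, inclusive); demultiplexing requires an exact barcode match
(edit distance 0) and every base of the barcode+UMI span at quality >= 20.
Read 2 is trimmed 15 bp from the 5' end to remove primer bias, truncated to
35 bases, and assigned to the unique gene whose transcript contains it as an
exact substring (reads matching zero or more than one gene are discarded).
PCR duplicates are removed by exact UMI identity per (well, gene); the result
is a genes x wells matrix of unique-molecule counts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "BC_START",
    "BC_STOP",
    "UMI_START",
    "UMI_STOP",
    "TRIM5",
    "KEEP",
    "MIN_QUAL",
    "RejectionStats",
    "demultiplex",
    "trim_read2",
    "assign_gene",
    "count_umis",
    "normalize_library_size",
    "process_fastq_pair",
    "write_matrix",
]

# defaults mirroring the demultiplexer settings used for this assay:
# bcStart=1, bcStop=10, bcEdit=0, umiStart=11, umiStop=20, keep=35, minQual=20
BC_START, BC_STOP = 1, 10
UMI_START, UMI_STOP = 11, 20
TRIM5 = 15
KEEP = 35
MIN_QUAL = 20
_MIN_MATCH = 20  # shortest trimmed read accepted for gene assignment


@dataclass
class RejectionStats:
    """Per-read accounting; assigned + rejections == total read pairs."""

    assigned: int = 0
    rejected_length: int = 0
    rejected_quality: int = 0
    rejected_barcode: int = 0
    unmapped: int = 0  # assigned to a well but no unique gene match

    @property
    def total(self) -> int:
        return (
            self.assigned
            + self.rejected_length
            + self.rejected_quality
            + self.rejected_barcode
        )


def _quals(qual: str, offset: int = 33) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - offset


def demultiplex(
    r1_seq: str,
    r1_qual: str,
    barcode_table: dict[str, str],
    min_qual: int = MIN_QUAL,
    bc_start: int = BC_START,
    bc_stop: int = BC_STOP,
    umi_start: int = UMI_START,
    umi_stop: int = UMI_STOP,
) -> tuple[str, str] | str:
    """Assign a read pair to a well by its R1 barcode.

    Returns ``(well_id, umi)`` on success or a rejection reason string:
    ``"too_short"`` (R1 does not cover the barcode+UMI span),
    ``"low_quality"`` (any base in the span below ``min_qual``) or
    ``"barcode_mismatch"`` (no exact match in the table).
    Positions are 1-based inclusive, matching the assay's convention.
    """
    span_end = max(bc_stop, umi_stop)
    if len(r1_seq) < span_end:
        return "too_short"
    q = _quals(r1_qual[:span_end])
    if (q < min_qual).any():
        return "low_quality"
    barcode = r1_seq[bc_start - 1 : bc_stop]
    well = barcode_table.get(barcode)
    if well is None:
        return "barcode_mismatch"
    return well, r1_seq[umi_start - 1 : umi_stop]


def trim_read2(r2_seq: str, trim5: int = TRIM5, keep: int = KEEP) -> str | None:
    """Remove the 5' primer pad then truncate; None if too short to map."""
    if len(r2_seq) < trim5 + _MIN_MATCH:
        return None
    return r2_seq[trim5 : trim5 + keep]


def assign_gene(trimmed: str, reference: dict[str, str]) -> str | None:
    """Gene whose transcript contains the read as an exact substring.

    Ambiguous (>= 2 genes) and unmapped (0 genes) reads return ``None`` —
    the unique-best-location contract.
    """
    if not reference:
        raise ValueError("empty reference")
    hits = [g for g, tx in reference.items() if trimmed in tx]
    return hits[0] if len(hits) == 1 else None


def count_umis(assignments: pd.DataFrame) -> pd.DataFrame:
    """Genes x wells matrix of distinct-UMI counts.

    ``assignments`` has columns well, gene, umi; duplicates of the same
    (well, gene, umi) triple collapse to one molecule (exact UMI identity,
    no near-duplicate merging).
    """
    if len(assignments) == 0:
        return pd.DataFrame()
    dedup = assignments.drop_duplicates(["well", "gene", "umi"])
    mat = (
        dedup.groupby(["gene", "well"]).size().unstack(fill_value=0).sort_index()
    )
    return mat.sort_index(axis=1)


def normalize_library_size(
    matrix: pd.DataFrame, scale: float = 1e6, log: bool = True
) -> pd.DataFrame:
    """Counts-per-million normalization with optional log1p.

    Wells with zero library size are dropped with a warning attribute
    (``result.attrs["dropped_wells"]``).
    """
    libsize = matrix.sum(axis=0)
    zero = libsize[libsize == 0].index.tolist()
    kept = matrix.drop(columns=zero)
    cpm = kept / kept.sum(axis=0) * scale
    out = np.log1p(cpm) if log else cpm
    out.attrs["dropped_wells"] = zero
    return out


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a genes x wells count matrix as CSV or MatrixMarket.

    A ``.mtx`` path gets the triplet file plus ``<stem>.genes.txt`` and
    ``<stem>.wells.txt`` sidecars; anything else is written as CSV.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy import io as sio
        from scipy.sparse import csr_matrix

        sio.mmwrite(path, csr_matrix(matrix.to_numpy()))
        path.with_suffix(".genes.txt").write_text("\n".join(matrix.index) + "\n")
        path.with_suffix(".wells.txt").write_text("\n".join(matrix.columns) + "\n")
    else:
        matrix.rename_axis("gene").to_csv(path)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def process_fastq_pair(
    r1_path,
    r2_path,
    barcode_table: dict[str, str],
    reference: dict[str, str],
    min_qual: int = MIN_QUAL,
    trim5: int = TRIM5,
    keep: int = KEEP,
) -> tuple[pd.DataFrame, RejectionStats]:
    """End-to-end: paired FASTQ -> UMI-deduplicated genes x wells counts.

    Returns the count matrix and the per-read rejection accounting.  Reads
    that demultiplex but fail gene assignment (length, unmapped or
    ambiguous) still count as assigned wells in the accounting, tracked
    separately as ``unmapped``.
    """
    stats = RejectionStats()
    triples: list[tuple[str, str, str]] = []
    memo: dict[str, str | None] = {}  # PCR duplicates share inserts
    with _open_maybe_gzip(r1_path) as f1, _open_maybe_gzip(r2_path) as f2:
        for (_, s1, q1), (_, s2, _q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            res = demultiplex(s1, q1, barcode_table, min_qual=min_qual)
            if isinstance(res, str):
                if res == "too_short":
                    stats.rejected_length += 1
                elif res == "low_quality":
                    stats.rejected_quality += 1
                else:
                    stats.rejected_barcode += 1
                continue
            stats.assigned += 1
            well, umi = res
            trimmed = trim_read2(s2, trim5=trim5, keep=keep)
            if trimmed is None:
                gene = None
            elif trimmed in memo:
                gene = memo[trimmed]
            else:
                gene = memo[trimmed] = assign_gene(trimmed, reference)
            if gene is None:
                stats.unmapped += 1
                continue
            triples.append((well, gene, umi))
    matrix = count_umis(pd.DataFrame(triples, columns=["well", "gene", "umi"]))
    return matrix, stats
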