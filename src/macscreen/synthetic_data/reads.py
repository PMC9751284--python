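"""Synthetic plate-multiplexed 3' RNA-seq (MAC-seq style) read generation.

Read 1 carries the identity of the molecule: a 10-nt well barcode at
positions 1-10 followed by a 10-nt UMI at positions 11-20.  Read 2 carries a
15-nt primer pad (removed by trimming downstream) followed by transcript
sequence.  Every molecule of a (well, gene) pair receives a distinct UMI, and
``dup_factor`` identical copies of each molecule emulate PCR duplication, so
that UMI deduplication recovers the molecule table exactly.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateLayout",
    "make_layout",
    "make_reference",
    "write_macseq_fastq",
    "PRIMER_PAD",
]

_BASES = np.array(list("ACGT"))
PRIMER_PAD = "AAGCAGTGGTATCAA"  # 15 nt, template-switch-primer-like
R2_INSERT_LEN = 35


@dataclass(frozen=True)
class PlateLayout:
    """Well annotations for one 96-well plate.

    ``wells`` has columns well, row, column, compound_id, dose, replicate,
    barcode (10-nt, unique within the plate).
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        bc = self.wells["barcode"]
        if bc.duplicated().any():
            raise ValueError("barcodes must be unique within a plate")
        if (bc.str.len() != 10).any():
            raise ValueError("barcodes must be 10 nt")
        if (self.wells["row"].max() > 7) or (self.wells["column"].max() > 11):
            raise ValueError("wells must fit a 96-well plate (8 rows x 12 columns)")

    @property
    def barcode_table(self) -> dict[str, str]:
        """barcode -> well id."""
        return dict(zip(self.wells["barcode"], self.wells["well"]))


def _index_to_seq(idx: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(out)


def make_layout(
    compounds: list[str],
    replicates: int = 1,
    dose: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> PlateLayout:
    """Assign compounds x replicates to wells with random distinct barcodes."""
    n = len(compounds) * replicates
    if n > 96:
        raise ValueError("more wells than a 96-well plate holds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    barcodes: set[str] = set()
    while len(barcodes) < n:
        barcodes.add("".join(rng.choice(_BASES, 10)))
    bc_list = sorted(barcodes)
    rng.shuffle(bc_list)
    rows = []
    k = 0
    for comp in compounds:
        for rep in range(1, replicates + 1):
            r, c = divmod(k, 12)
            rows.append(
                {
                    "well": f"{'ABCDEFGH'[r]}{c + 1:02d}",
                    "row": r,
                    "column": c,
                    "compound_id": comp,
                    "dose": dose,
                    "replicate": rep,
                    "barcode": bc_list[k],
                }
            )
            k += 1
    return PlateLayout(pd.DataFrame(rows))


def make_reference(
    n_genes: int = 20,
    length: int = 200,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Random toy transcriptome; gene id -> transcript sequence (>= 50 nt)."""
    if length < 50:
        raise ValueError("transcripts must be >= 50 nt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {
        f"gene{i:04d}": "".join(rng.choice(_BASES, length)) for i in range(n_genes)
    }


def write_macseq_fastq(
    molecules: pd.DataFrame,
    layout: PlateLayout,
    reference: dict[str, str],
    r1_path,
    r2_path,
    dup_factor: int = 1,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    quality_char: str = "I",
) -> int:
    """Write paired gzip FASTQ for a molecule table.

    ``molecules`` has columns well, gene, count (molecules of that gene in
    that well).  Each molecule receives a distinct 10-nt UMI within its
    (well, gene) pair and is written ``dup_factor`` times; substitution
    errors at ``error_rate`` are injected into the transcript-derived part of
    R2 only (barcode and UMI stay exact).  Returns the number of read pairs
    written.
    """
    if dup_factor < 1:
        raise ValueError("dup_factor must be >= 1")
    wells = set(layout.wells["well"])
    missing = set(molecules["well"]) - wells
    if missing:
        raise ValueError(f"wells without barcode in layout: {sorted(missing)}")
    short = [g for g in set(molecules["gene"]) if len(reference.get(g, "")) < 50]
    if short:
        raise ValueError(f"transcripts shorter than 50 nt (or absent): {sorted(short)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    well_to_bc = {w: b for b, w in layout.barcode_table.items()}

    def _gz_writer(path):
        # mtime pinned so identical inputs give byte-identical files
        raw = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        return io.TextIOWrapper(raw)

    n_written = 0
    with _gz_writer(r1_path) as f1, _gz_writer(r2_path) as f2:
        ordered = molecules.sort_values(["well", "gene"])
        for well, gene, n_mol in zip(
            ordered["well"], ordered["gene"], ordered["count"]
        ):
            bc = well_to_bc[well]
            tx = reference[gene]
            max_start = len(tx) - R2_INSERT_LEN
            for m in range(int(n_mol)):
                umi = _index_to_seq(m, 10)
                start = int(rng.integers(0, max_start + 1))
                insert = tx[start : start + R2_INSERT_LEN]
                r1 = bc + umi
                for _ in range(dup_factor):
                    r2 = PRIMER_PAD + insert
                    if error_rate > 0:
                        r2 = _inject_errors(r2, len(PRIMER_PAD), error_rate, rng)
                    rid = f"read{n_written}:{well}:{gene}:{m}"
                    f1.write(f"@{rid}\n{r1}\n+\n{quality_char * len(r1)}\n")
                    f2.write(f"@{rid}\n{r2}\n+\n{quality_char * len(r2)}\n")
                    n_written += 1
    return n_written


def _inject_errors(seq: str, start: int, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    hit = hit[hit >= start]
    for i in hit:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return "".join(arr)
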