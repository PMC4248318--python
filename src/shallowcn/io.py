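"""Readers and writers for the standard formats the pipeline touches.

FASTA via pyfaidx, SAM/BAM via pysam, BED / bedGraph / wiggle / TSV via
plain parsing.  Bin tables are written 1-based inclusive (genome-browser
convention); everything is 0-based half-open in memory.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .bins import BinGrid
from .counts import AlignedRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_track",
    "read_alignments",
    "read_position_table",
    "write_position_table",
    "write_profile",
    "MISSING",
]

MISSING = "NA"


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """All records of a (possibly line-wrapped) FASTA as name -> sequence."""
    with Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | os.PathLike, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """3+ column BED (0-based half-open); track/browser/comment lines skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(
    path: str | os.PathLike,
    regions: Iterable[tuple[str, int, int] | tuple[str, int, int, str]],
) -> None:
    with open(path, "w") as fh:
        for rec in regions:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_track(path: str | os.PathLike) -> Iterator[tuple[str, int, int, float]]:
    """Yield (chrom, start, end, value) from bedGraph or wiggle text.

    Supports 4-column bedGraph plus fixedStep / variableStep wiggle blocks;
    wiggle coordinates are 1-based and converted to 0-based half-open.
    """
    mode = "bedgraph"
    chrom, step, span, pos = None, 1, 1, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                mode, chrom = "fixed", kv["chrom"]
                pos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
                continue
            fields = line.split()
            if mode == "fixed":
                yield chrom, pos, pos + span, float(fields[0])
                pos += step
            elif mode == "variable":
                start = int(fields[0]) - 1
                yield chrom, start, start + span, float(fields[1])
            else:
                yield fields[0], int(fields[1]), int(fields[2]), float(fields[3])


def read_alignments(path: str | os.PathLike) -> Iterator[AlignedRead]:
    """Stream reads from SAM/BAM (by extension) or a plain position table."""
    path = str(path)
    if path.endswith((".sam", ".bam", ".cram")):
        mode = "rb" if path.endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for rec in fh:
                yield AlignedRead(
                    chrom=rec.reference_name if not rec.is_unmapped else "*",
                    pos=rec.reference_start if not rec.is_unmapped else -1,
                    mapq=rec.mapping_quality,
                    is_duplicate=rec.is_duplicate,
                    is_unmapped=rec.is_unmapped,
                )
    else:
        yield from read_position_table(path)


def read_position_table(path: str | os.PathLike) -> Iterator[AlignedRead]:
    """TSV with columns chrom, pos, mapq, is_duplicate (fixture format)."""
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        yield AlignedRead(
            chrom=str(row.chrom),
            pos=int(row.pos),
            mapq=int(row.mapq),
            is_duplicate=bool(row.is_duplicate),
        )


def write_position_table(path: str | os.PathLike, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def _fmt(values: np.ndarray, log2: bool) -> list[str]:
    out = []
    for v in values:
        if not np.isfinite(v) or (log2 and v <= 0):
            out.append(MISSING)
        else:
            out.append(f"{np.log2(v):.6g}" if log2 else f"{v:.6g}")
    return out


def write_profile(
    path: str | os.PathLike,
    grid: BinGrid,
    columns: dict[str, np.ndarray],
    fmt: str = "tsv",
    log2: bool = False,
    sample_id: str = "sample",
) -> None:
    """Export a per-bin profile as TSV, SEG, or IGV text.

    TSV carries every supplied column (linear or log2 per the flag); SEG and
    IGV carry the single ``normalized`` column on the log2 scale, the
    convention of viewers and segmenters.  Masked bins are written as the
    missing-value sentinel, never as 0.
    """
    start1 = grid.start + 1  # 1-based inclusive in all text output
    if fmt == "tsv":
        df = pd.DataFrame({"chrom": grid.chrom, "start": start1, "end": grid.end})
        for name, vals in columns.items():
            df[name] = _fmt(np.asarray(vals, dtype=float), log2)
        df.to_csv(path, sep="\t", index=False)
    elif fmt in ("seg", "igv"):
        if "normalized" not in columns:
            raise ValueError(f"{fmt} export needs a 'normalized' column")
        vals = _fmt(np.asarray(columns["normalized"], dtype=float), log2=True)
        with open(path, "w") as fh:
            if fmt == "seg":
                fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
                for i in range(grid.n_bins):
                    fh.write(
                        f"{sample_id}\t{grid.chrom[i]}\t{start1[i]}\t"
                        f"{grid.end[i]}\t1\t{vals[i]}\n"
                    )
            else:
                fh.write("#type=COPY_NUMBER\n")
                fh.write(f"Chromosome\tStart\tEnd\tFeature\t{sample_id}\n")
                for i in range(grid.n_bins):
                    fh.write(
                        f"{grid.chrom[i]}\t{start1[i]}\t{grid.end[i]}\t"
                        f"bin{i}\t{vals[i]}\n"
                    )
    else:
        raise ValueError(f"unknown export format {fmt!r}")
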