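"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA and FASTQ go through Biopython; annotation is accepted as GFF3
(``gene`` records, converted from 1-based closed to 0-based half-open) or
as a 5-column TSV.  Tracks are written as bedgraph, intervals as BED.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .genome_model import GeneAnnotation


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines ok) -> {name: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence); Phred qualities are ignored."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs with constant placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_gff3_genes(path: str | Path) -> GeneAnnotation:
    """Parse ``gene``-type GFF3 records; 1-based closed -> 0-based half-open."""
    ids, chroms, starts, ends, strands = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            ids.append(attrs.get("ID", f"{parts[0]}:{parts[3]}-{parts[4]}"))
            chroms.append(parts[0])
            starts.append(int(parts[3]) - 1)
            ends.append(int(parts[4]))
            strands.append(parts[6])
    return GeneAnnotation(ids, chroms, np.array(starts), np.array(ends), strands)


def write_gff3_genes(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, c, s, e, strand in zip(
            annotation.gene_ids,
            annotation.chroms,
            annotation.starts,
            annotation.ends,
            annotation.strands,
        ):
            fh.write(f"{c}\t.\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gid}\n")


def read_gene_table(path: str | Path) -> GeneAnnotation:
    """5-column TSV fallback: gene_id, chrom, start, end, strand (0-based)."""
    ids, chroms, starts, ends, strands = [], [], [], [], []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "gene_id":
                continue
            ids.append(row[0])
            chroms.append(row[1])
            starts.append(int(row[2]))
            ends.append(int(row[3]))
            strands.append(row[4] if len(row) > 4 else ".")
    return GeneAnnotation(ids, chroms, np.array(starts), np.array(ends), strands)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Dispatch on extension: .gff/.gff3 -> GFF3, otherwise gene TSV."""
    p = Path(path)
    if p.suffix.lower() in {".gff", ".gff3"}:
        return read_gff3_genes(p)
    return read_gene_table(p)


def write_gatc_sites(sites: dict[str, np.ndarray], path: str | Path) -> None:
    """Site table cache: TSV (chrom, position)."""
    with open(path, "w") as fh:
        fh.write("chrom\tposition\n")
        for chrom, pos in sites.items():
            for p in pos:
                fh.write(f"{chrom}\t{int(p)}\n")


def read_gatc_sites(path: str | Path) -> dict[str, np.ndarray]:
    sites: dict[str, list[int]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, pos = line.split("\t")
            sites.setdefault(chrom, []).append(int(pos))
    return {c: np.asarray(v, dtype=np.int64) for c, v in sites.items()}


def write_count_table(
    chroms: list[str],
    intervals: np.ndarray,
    counts: np.ndarray,
    path: str | Path,
) -> None:
    """Fragment/bin counts as TSV (chrom, start, end, count)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcount\n")
        for c, (s, e), n in zip(chroms, intervals, counts):
            fh.write(f"{c}\t{int(s)}\t{int(e)}\t{int(n)}\n")


def read_count_table(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read TSV (chrom, start, end, count) -> (chroms, intervals, counts)."""
    chroms, starts, ends, counts = [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            c, s, e, n = line.rstrip("\n").split("\t")
            chroms.append(c)
            starts.append(int(s))
            ends.append(int(e))
            counts.append(int(n))
    intervals = np.stack(
        [np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)], axis=1
    )
    return chroms, intervals, np.asarray(counts, dtype=np.int64)


def write_bedgraph(
    chroms: list[str],
    intervals: Iterable[tuple[int, int]],
    values: np.ndarray,
    path: str | Path,
    name: str | None = None,
) -> None:
    """Track as bedgraph (chrom, start, end, value) for browser views."""
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        for c, (s, e), v in zip(chroms, intervals, values):
            fh.write(f"{c}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def write_bed(
    chroms: list[str],
    intervals: Iterable[tuple[int, int]],
    path: str | Path,
    names: Iterable[str] | None = None,
) -> None:
    """Intervals as BED3/BED4."""
    with open(path, "w") as fh:
        if names is None:
            for c, (s, e) in zip(chroms, intervals):
                fh.write(f"{c}\t{int(s)}\t{int(e)}\n")
        else:
            for c, (s, e), n in zip(chroms, intervals, names):
                fh.write(f"{c}\t{int(s)}\t{int(e)}\t{n}\n")
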