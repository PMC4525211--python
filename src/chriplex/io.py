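"""Readers and writers for the plain-text formats the pipeline speaks.

Internally everything is 0-based half-open; GTF's 1-based closed
convention is converted exactly here and nowhere else. TSV tables carry a
header line; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from chriplex.annotation import Annotation, TranscriptModel
from chriplex.peaks import GeneSet, Peak

FASTA_WIDTH = 60

_GTF_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')
_GTF_ATTR_PLAIN = re.compile(r"(\w+)=([^;]+)")


# ---------------------------------------------------------------- FASTA


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


# ------------------------------------------------------------------ GTF


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs = dict(_GTF_ATTR_QUOTED.findall(raw))
    if not attrs:  # tolerate the key=value dialect
        attrs = {k: v.strip() for k, v in _GTF_ATTR_PLAIN.findall(raw)}
    return attrs


def read_gtf(path: str | Path) -> Annotation:
    """Parse exon features of a GTF into transcript models."""
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr_raw = fields[:9]
            if feature != "exon":
                continue
            start_i, end_i = int(start), int(end)
            if start_i < 1 or end_i < start_i:
                raise ValueError(
                    f"{path}:{lineno}: bad 1-based closed interval {start}-{end}"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_gtf_attributes(attr_raw)
            tid = attrs.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}:{lineno}: exon lacks transcript_id")
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("biotype", "other"),
                    "exons": [],
                },
            )
            rec["exons"].append((start_i - 1, end_i))  # to 0-based half-open
    transcripts = []
    for tid, rec in exons.items():
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                biotype=rec["biotype"],
            )
        )
    return Annotation(transcripts)


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in annotation:
            for start, end in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'biotype "{tx.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            "chriplex",
                            "exon",
                            str(start + 1),  # to 1-based closed
                            str(end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ------------------------------------------------------------------ BED


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6+1: the 7th column is the absolute summit coordinate."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(int(p.score)),
                        "+",
                        str(p.summit),
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path, sample: str = "peak") -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: bad interval {start}-{end}")
            name = fields[3] if len(fields) > 3 else f"peak{lineno}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            summit = int(fields[6]) if len(fields) > 6 else (start + end) // 2
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    sample=sample,
                    score=score,
                    name=name,
                )
            )
    return peaks


# ------------------------------------------------------------------ TSV


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame = frame.set_index(frame.columns[0])
    return frame


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_gene_list(path: str | Path) -> set[str]:
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split("\t")[0])
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ------------------------------------------------------------------ GMT


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, desc, genes")
            sets.append(GeneSet(name=fields[0], genes=frozenset(fields[2:])))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "."] + sorted(s.genes)) + "\n")
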