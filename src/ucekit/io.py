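"""Readers and writers for the on-disk formats the pipeline exchanges.

FASTA goes through Biopython; BED6 and the gene-model subset of GFF3 are
column formats handled directly so that parse -> write -> parse is the
identity on the data model. All interval formats are 0-based half-open on
disk exactly as in memory (GFF3 columns are converted from its 1-based
inclusive convention at the boundary).
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AnnotationSet, Gene, GenomicInterval, Transcript

log = logging.getLogger(__name__)


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}.

    Soft-masked (lowercase) bases are uppercased; a flag is logged so run
    manifests can record it.
    """
    seqs: dict[str, str] = {}
    had_lower = False
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if not s.isupper():
            had_lower = True
        seqs[rec.id] = s.upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    if had_lower:
        log.info("lowercase (soft-masked) bases uppercased in %s", path)
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# -- BED6 -------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            out.append(GenomicInterval(fields[0], start, end, name))
    return out


def write_bed(path: str | Path, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.length}\t+\n")


# -- GFF3 gene models -------------------------------------------------------


def read_gff3(path: str | Path) -> AnnotationSet:
    """Parse gene/mRNA/exon/ncRNA features into an AnnotationSet.

    Exon attributes may carry ``constitutive=0|1``; exons without the tag
    default to constitutive.
    """
    genes: dict[str, Gene] = {}
    declared_spans: dict[str, tuple[int, int]] = {}
    transcripts: dict[str, tuple[str, Transcript]] = {}  # tid -> (gene id, obj)
    constitutive: dict[tuple[str, int, int], bool] = {}
    ncrnas: list[GenomicInterval] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line has {len(cols)} columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = cols
            start, end = int(start1) - 1, int(end1)
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = Gene(gid, chrom, strand, [])
                declared_spans[gid] = (start, end)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attr["ID"], attr["Parent"]
                transcripts[tid] = (parent, Transcript(tid, []))
            elif ftype == "exon":
                parent = attr["Parent"]
                if parent not in transcripts:
                    raise ValueError(f"{path}:{lineno}: exon with unknown Parent {parent}")
                transcripts[parent][1].exons.append((start, end))
                constitutive[(chrom, start, end)] = attr.get("constitutive", "1") == "1"
            elif ftype in ("ncRNA", "tRNA", "rRNA", "snoRNA", "miRNA"):
                ncrnas.append(GenomicInterval(chrom, start, end, attr.get("ID", "")))

    for tid, (gid, tr) in transcripts.items():
        tr.exons.sort()
        if gid not in genes:
            raise ValueError(f"transcript {tid} references unknown gene {gid}")
        genes[gid].transcripts.append(tr)

    for g in genes.values():
        lo, hi = declared_spans[g.id]
        for t in g.transcripts:
            for s, e in t.exons:
                if s < lo or e > hi:
                    raise ValueError(
                        f"{path}: exon {g.chrom}:{s}-{e} outside gene {g.id} span"
                    )
    return AnnotationSet(list(genes.values()), sorted(ncrnas), constitutive)


def write_gff3(path: str | Path, ann: AnnotationSet) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(ann.genes, key=lambda g: (g.chrom, g.span)):
            lo, hi = g.span
            fh.write(
                f"{g.chrom}\tucekit\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                fh.write(
                    f"{g.chrom}\tucekit\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.id};Parent={g.id}\n"
                )
                for s, e in t.exons:
                    const = ann.constitutive.get((g.chrom, s, e), True)
                    fh.write(
                        f"{g.chrom}\tucekit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={t.id};constitutive={1 if const else 0}\n"
                    )
        for nc in ann.ncrnas:
            fh.write(
                f"{nc.chrom}\tucekit\tncRNA\t{nc.start + 1}\t{nc.end}\t.\t+\t.\t"
                f"ID={nc.name or 'ncRNA'}\n"
            )
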