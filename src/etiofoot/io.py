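"""Readers and writers for the standard formats the pipeline consumes.

FASTA goes through Biopython; MEME-minimal motif files are parsed with
``Bio.motifs``; bedGraph/BED/TSV go through pandas. GFF3 covers the
single-isoform gene models this package works with (gene / five_prime_UTR /
CDS / three_prime_UTR features, one mRNA per gene).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CutProfile, DHSCollection, GeneAnnotation, GeneModel, GenomeSequence


# -------------------------------------------------------------- FASTA

def write_fasta(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(genome.chroms.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> GenomeSequence:
    return GenomeSequence(
        {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    )


# -------------------------------------------------------------- GFF3

_FEATURE_FIELDS = {
    "five_prime_UTR": "five_utr",
    "CDS": "cds",
    "intron": "introns",
    "three_prime_UTR": "three_utr",
}


def write_gff3(annotation: GeneAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        # GFF3 is 1-based inclusive
        def row(ftype, s, e, parent=None):
            attr = f"ID={g.gene_id}" if ftype == "gene" else f"Parent={parent}"
            if ftype == "mRNA":
                attr = f"ID={g.gene_id}.t1;Parent={g.gene_id}"
            return "\t".join(
                [g.chrom, "etiofoot", ftype, str(s + 1), str(e), ".", g.strand, ".", attr]
            )

        lines.append(row("gene", g.start, g.end))
        lines.append(row("mRNA", g.start, g.end))
        for ftype, field in _FEATURE_FIELDS.items():
            for s, e in getattr(g, field):
                lines.append(row(ftype, s, e, parent=f"{g.gene_id}.t1"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path, promoter_length: int = 2000) -> GeneAnnotation:
    genes: dict[str, GeneModel] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = line.split("\t")
        s, e = int(start) - 1, int(end)
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            gid = fields["ID"]
            genes[gid] = GeneModel(gid, chrom, strand, s, e)
        elif ftype in _FEATURE_FIELDS:
            gid = fields["Parent"].split(".t1")[0]
            getattr(genes[gid], _FEATURE_FIELDS[ftype]).append((s, e))
    for g in genes.values():
        for field in _FEATURE_FIELDS.values():
            getattr(g, field).sort()
    return GeneAnnotation(list(genes.values()), promoter_length=promoter_length)


# -------------------------------------------------------------- bedGraph

def write_bedgraph_pair(profile: CutProfile, prefix) -> tuple[Path, Path]:
    """Write one bedGraph per strand (single-base intervals, zeros omitted)."""
    paths = []
    for strand, tag in (("+", "fwd"), ("-", "rev")):
        rows = []
        for chrom in profile.chroms():
            arr = profile.counts[chrom][strand]
            idx = np.nonzero(arr)[0]
            for i in idx:
                rows.append((chrom, int(i), int(i) + 1, int(arr[i])))
        path = Path(f"{prefix}.{tag}.bedgraph")
        pd.DataFrame(rows, columns=["chrom", "start", "end", "count"]).to_csv(
            path, sep="\t", header=False, index=False
        )
        paths.append(path)
    return tuple(paths)


def read_bedgraph_pair(fwd_path, rev_path, chrom_lengths: dict[str, int],
                       label: str = "sample", **meta) -> CutProfile:
    counts = {
        c: {"+": np.zeros(n, dtype=np.int64), "-": np.zeros(n, dtype=np.int64)}
        for c, n in chrom_lengths.items()
    }
    for path, strand in ((fwd_path, "+"), (rev_path, "-")):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "count"])
        for chrom, s, e, v in df.itertuples(index=False):
            counts[chrom][strand][s:e] += int(v)
    return CutProfile(label, counts, **meta)


# -------------------------------------------------------------- BED

def write_bed(records, path, extra_cols=()) -> None:
    """records: iterable of (chrom, start, end, *extras)."""
    cols = ["chrom", "start", "end", *extra_cols]
    pd.DataFrame(list(records), columns=cols).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed_collection(path, label: str) -> DHSCollection:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return DHSCollection.from_records(label, df.itertuples(index=False))


# -------------------------------------------------------------- MEME

def write_meme(pwms, path, background=None) -> None:
    """Write a MEME-minimal motif file from a list of PWM objects."""
    bg = background if background is not None else [0.25] * 4
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", bg)), "",
    ]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 100000 E= 0"
        )
        for col in pwm.probs.T:
            lines.append(" ".join(f"{p:.6f}" for p in col))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path):
    """Parse a MEME-minimal file into (motif_id, prob matrix 4 x w) pairs."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        pwm = np.array([[m.pwm[b][i] for i in range(m.length)] for b in "ACGT"])
        out.append((m.name, pwm))
    return out


# -------------------------------------------------------------- TSV / JSON

def write_group_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame(sorted(mapping.items()), columns=["motif_id", "group"]).to_csv(
        path, sep="\t", index=False
    )


def read_group_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["motif_id"], df["group"]))


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
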