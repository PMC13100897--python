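"""Readers and writers for the plain-text formats the pipeline touches.

Interval formats (bedGraph, BED) are 0-based half-open; gene midpoints in
TSVs are 1-based integers. Codon alignments are paired FASTA files holding
exactly two equal-length records whose length is divisible by 3.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synth import ChromosomeRecord, Karyotype

BEDGRAPH_COLS = ["chrom", "start", "end", "depth"]


def write_bedgraph(track: pd.DataFrame, path, value_col: str = "depth") -> None:
    df = track[["chrom", "start", "end", value_col]]
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path, value_col: str = "depth") -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", value_col],
        comment="#",
    )
    if df.empty:
        raise ValueError(f"empty bedGraph: {path}")
    return df


def write_chrom_sizes(karyotype: Karyotype, path) -> None:
    with open(path, "w") as fh:
        for rec in karyotype:
            fh.write(f"{rec.id}\t{rec.length}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                if lineno == 1:  # tolerate a header line
                    continue
                raise ValueError(f"{path}:{lineno}: length {parts[1]!r} is not an integer")
    return sizes


def write_gene_table(genes: pd.DataFrame, path) -> None:
    """Gene table TSV; midpoints are written as 1-based integer positions."""
    df = genes.copy()
    df["midpoint"] = df["midpoint"].round().astype(int).clip(lower=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_paired_fasta(gene_id: str, seq1: str, seq2: str, path,
                       names: tuple[str, str] = ("Rty", "Sti")) -> None:
    records = [
        SeqRecord(Seq(seq1), id=f"{names[0]}_{gene_id}", description=""),
        SeqRecord(Seq(seq2), id=f"{names[1]}_{gene_id}", description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_paired_fasta(path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(
            f"{path}: paired codon alignment must contain exactly 2 records, "
            f"found {len(records)}"
        )
    s1, s2 = str(records[0].seq).upper(), str(records[1].seq).upper()
    if len(s1) != len(s2):
        raise ValueError(f"{path}: records differ in length ({len(s1)} vs {len(s2)})")
    if len(s1) % 3:
        raise ValueError(f"{path}: alignment length {len(s1)} not divisible by 3")
    return s1, s2


def write_newick_lines(trees: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for nwk in trees:
            fh.write(nwk.rstrip("\n") + "\n")


def read_newick_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_par_bed(pars, path) -> None:
    with open(path, "w") as fh:
        for p in pars:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tPAR_{p.side}\n")


def read_karyotype_table(path) -> Karyotype:
    """Karyotype from a TSV with columns chrom, length and optional chrom_class."""
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns:  # headerless two-column fallback
        sizes = read_chrom_sizes(path)
        recs = sorted(sizes.items(), key=lambda kv: -kv[1])
        return Karyotype(tuple(ChromosomeRecord(c, l) for c, l in recs))
    recs = []
    for _, row in df.sort_values("length", ascending=False).iterrows():
        recs.append(
            ChromosomeRecord(
                str(row["chrom"]), int(row["length"]),
                str(row.get("chrom_class", "autosome")),
            )
        )
    return Karyotype(tuple(recs))
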