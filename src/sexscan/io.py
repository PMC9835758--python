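"""Flat-file helpers: GFF3 gene models, BED intervals, BedGraph tracks.

All in-memory coordinates are 0-based half-open; conversion to the 1-based
closed GFF3 convention (and back) happens only here.
"""
from __future__ import annotations

import os

import pandas as pd

from .assembly import Assembly


def write_gff3_genes(genes: pd.DataFrame, assembly: Assembly,
                     path: str | os.PathLike) -> None:
    """Write gene intervals (0-based half-open in memory) as GFF3 gene lines."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in assembly.names:
            fh.write(f"##sequence-region {name} 1 {assembly.length(name)}\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['scaffold']}\tsexscan\tgene\t{int(g['start']) + 1}\t"
                f"{int(g['end'])}\t.\t{g.get('strand', '+')}\t.\t"
                f"ID={g['gene_id']}\n")


def read_gff3_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene-type GFF3 records into a 0-based half-open DataFrame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            rows.append((gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end",
                                       "strand"])


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["scaffold", "start", "end"]
    extra = [c for c in ("name", "score", "strand") if c in df.columns]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["scaffold", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]]
    return df


def write_bedgraph(df: pd.DataFrame, value_column: str,
                   path: str | os.PathLike) -> None:
    out = df[["scaffold", "start", "end", value_column]].copy()
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format="%.6g")


def read_bedgraph(path: str | os.PathLike, value_column: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["scaffold", "start", "end", value_column])
    return df
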