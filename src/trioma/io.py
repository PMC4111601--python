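"""Readers and writers for the plain-text formats the pipeline consumes.

Tab-delimited expression/annotation/target tables with a header row, GFF3,
BED6/BED12 and GMT.  Genomic coordinates are converted to 0-based half-open
on the way in (GFF3 is 1-based inclusive; BED is already 0-based).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .data import (
    Channel,
    ExpressionMatrix,
    GeneModel,
    GeneSetCollection,
    LncLocus,
    ProbeAnnotation,
    TargetTable,
)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_gene_models",
    "read_lnc_bed",
    "read_gmt",
    "read_target_table",
    "read_probe_annotation",
]


def read_expression_table(path: str | Path, channel: Channel | str) -> ExpressionMatrix:
    """Read a probe x sample intensity table (first column = probe id)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty expression table: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"expression table needs a probe column and >=1 sample: {path}")
    probe_col = df.columns[0]
    dupes = df[probe_col][df[probe_col].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate probe id(s) in {path}: {dupes}")
    df = df.set_index(probe_col)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric cell in {path} at probe {row!r}, column {col!r}")
        df[col] = coerced.astype(float)
    df.index.name = "probe_id"
    return ExpressionMatrix(channel=Channel(channel), data=df)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Inverse of :func:`read_expression_table` (modulo float formatting)."""
    out = matrix.data.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene models


def _parse_gff3_attrs(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _gff3_gene_models(path: Path) -> list[GeneModel]:
    # one transcript per gene assumed: gene/mRNA span interchangeable
    spans: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    utr3: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attr = fields[:9]
            if strand not in ("+", "-"):
                raise ValueError(f"unknown strand {strand!r} in {path}")
            iv = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
            attrs = _parse_gff3_attrs(attr)
            if ftype in ("gene", "mRNA", "transcript"):
                gid = attrs.get("ID") or attrs.get("Parent")
                if gid is None:
                    raise ValueError(f"{ftype} without ID in {path}")
                rec = spans.setdefault(
                    gid, {"chrom": chrom, "strand": strand, "iv": iv, "symbol": gid}
                )
                rec["iv"] = (min(rec["iv"][0], iv[0]), max(rec["iv"][1], iv[1]))
                if "Name" in attrs and ftype == "gene":
                    rec["symbol"] = attrs["Name"]
            elif ftype == "exon":
                parent = attrs.get("Parent")
                exons.setdefault(parent, []).append(iv)
            elif ftype == "three_prime_UTR":
                utr3[attrs.get("Parent")] = iv
    models = []
    for gid, rec in spans.items():
        models.append(
            GeneModel(
                gene_id=gid,
                symbol=rec["symbol"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=rec["iv"][0],
                end=rec["iv"][1],
                exons=tuple(exons.get(gid, ())),
                utr3=utr3.get(gid),
            )
        )
    return models


def _bed12_gene_models(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line with {len(f)} fields in {path}")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"unknown strand {strand!r} in {path}")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            models.append(
                GeneModel(
                    gene_id=name,
                    symbol=name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
    return models


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read coding gene models from GFF3 or BED12 (by file extension)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _gff3_gene_models(path)
    return _bed12_gene_models(path)


def read_lnc_bed(path: str | Path) -> list[LncLocus]:
    """Read lncRNA loci from BED6 (score column optionally flags ultraconserved)."""
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"BED6 line with {len(f)} fields in {path}")
            loci.append(
                LncLocus(
                    lnc_id=f[3],
                    chrom=f[0],
                    strand=f[5],
                    start=int(f[1]),
                    end=int(f[2]),
                    ultraconserved=f[4] not in ("0", ".", ""),
                )
            )
    return loci


# ---------------------------------------------------------------------------
# gene sets / targets / annotation


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {i} has fewer than 3 fields in {path}")
            name, _desc, *members = fields
            sets[name] = {m for m in members if m}
    return GeneSetCollection(sets, universe=universe)


def read_target_table(path: str | Path) -> TargetTable:
    """Read a miRNA->gene target table with columns (mirna, gene, evidence, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    required = ["mirna", "gene", "evidence", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"target table {path} missing column(s): {missing}")
    return TargetTable(df[required])


def read_probe_annotation(path: str | Path, channel: Channel | str) -> list[ProbeAnnotation]:
    """Read a probe annotation table with columns (probe_id, transcript, gene)."""
    channel = Channel(channel)
    out = []
    seen = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pid = row["probe_id"]
            if pid in seen:
                raise ValueError(f"duplicate probe id {pid!r} in {path}")
            seen.add(pid)
            out.append(
                ProbeAnnotation(
                    probe_id=pid,
                    transcript=row.get("transcript", ""),
                    gene=row.get("gene", "") or "",
                    channel=channel,
                )
            )
    return out
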