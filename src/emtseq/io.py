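"""Readers and writers for the plain-text formats used throughout the pipeline.

Formats: count tables as TSV (first column ``gene_id``, one column per
sample), gene sets as GMT, peak intervals as BED3/BED4 (0-based half-open),
transcript models as refFlat (11 tab-separated columns), DEG programs as
two-column TSV, and YAML configuration / group maps.

Report writers prepend ``#``-prefixed provenance headers; the matching
readers skip them.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .peaks import GeneModel, Peak

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_group_map",
    "write_group_map",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_refflat",
    "write_refflat",
    "read_deg_program",
    "write_deg_program",
    "read_config",
    "write_table",
    "file_sha256",
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene × sample integer count table (genes in rows)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene_id"
    return df.astype(int)


def write_counts_tsv(path: str | Path, counts: pd.DataFrame) -> None:
    counts = counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(path, sep="\t")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a sample→group mapping (YAML: ``sample_id: group_label``)."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"group map {path} must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def write_group_map(path: str | Path, groups: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(groups), fh, sort_keys=False)


def read_gmt(path: str | Path) -> list[tuple[str, str, set[str]]]:
    """Read GMT lines as (set_name, description, member genes)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            out.append((parts[0], parts[1], set(g for g in parts[2:] if g)))
    return out


def write_gmt(
    path: str | Path, sets: Iterable[tuple[str, str, Iterable[str]]]
) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_bed(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            if start >= end:
                raise ValueError(f"{path}:{ln}: empty interval {start}>={end}")
            peaks.append(Peak(chrom=chrom, start=start, end=end, name=name))
    return peaks


def write_bed(path: str | Path, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fields = [p.chrom, str(p.start), str(p.end)]
            if p.name is not None:
                fields.append(p.name)
            fh.write("\t".join(fields) + "\n")


def read_refflat(path: str | Path) -> list[GeneModel]:
    """Read refFlat transcript models (geneName, name, chrom, strand,
    txStart, txEnd used; CDS/exon columns ignored)."""
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: refFlat needs >=6 columns")
            gene, _tx, chrom, strand, tx_start, tx_end = parts[:6]
            if strand not in "+-":
                raise ValueError(f"{path}:{ln}: bad strand {strand!r}")
            models.append(
                GeneModel(
                    gene_name=gene,
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(tx_start),
                    tx_end=int(tx_end),
                )
            )
    return models


def write_refflat(path: str | Path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.gene_name,
                        m.gene_name,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(m.tx_start),
                        str(m.tx_end),
                        "1",
                        f"{m.tx_start},",
                        f"{m.tx_end},",
                    ]
                )
                + "\n"
            )


def read_deg_program(path: str | Path) -> tuple[set[str], set[str]]:
    """Read a two-column (gene_id, direction) table into (up, down) sets."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["gene_id", "direction"],
                     header=0, dtype=str)
    up = set(df.loc[df["direction"] == "up", "gene_id"])
    down = set(df.loc[df["direction"] == "down", "gene_id"])
    return up, down


def write_deg_program(
    path: str | Path, up: Iterable[str], down: Iterable[str],
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tdirection\n")
        for g in sorted(up):
            fh.write(f"{g}\tup\n")
        for g in sorted(down):
            fh.write(f"{g}\tdown\n")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_table(
    path: str | Path, df: pd.DataFrame, header_lines: Sequence[str] = ()
) -> None:
    """Write a TSV report with ``#`` provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                  lineterminator="\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
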