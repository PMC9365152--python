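"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: genomic intervals on disk are BED-style 0-based half-open;
SNV positions in mutation tables are 1-based (VCF convention) and
converted to the 0-based grid internally by the burden module.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import TrackProfile, WindowGrid

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "cohort"]
_BASES = {"A", "C", "G", "T"}
SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(sizes.items()).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph track: chrom, start, end, value (0-based half-open)."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def aggregate_bigwig(path: str | Path, grid: WindowGrid) -> np.ndarray:
    """Per-window mean signal from a bigWig file (requires pyBigWig).

    Uncovered bases count as 0, consistent with
    :func:`regmut.grid.aggregate_track`.
    """
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    try:
        out = np.zeros(len(grid))
        for i, (c, s, e) in enumerate(zip(grid.chroms, grid.starts, grid.ends)):
            v = bw.stats(str(c), int(s), int(e), type="sum", exact=True)[0]
            out[i] = (v or 0.0) / grid.window_size
        return out
    finally:
        bw.close()


def write_windows_bed(grid: WindowGrid, path: str | Path) -> None:
    """Emit the grid as BED4 with name = chrom:start-end."""
    pd.DataFrame(
        {
            "chrom": grid.chroms,
            "start": grid.starts,
            "end": grid.ends,
            "name": grid.labels(),
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def write_grid(grid: WindowGrid, path: str | Path) -> None:
    grid.to_frame().to_csv(path, sep="\t", index=False)


def read_grid(path: str | Path, window_size: int | None = None) -> WindowGrid:
    df = pd.read_csv(path, sep="\t")
    if window_size is None:
        window_size = int((df["end"] - df["start"]).iloc[0])
    mapp = df["mappability"].to_numpy() if "mappability" in df else None
    return WindowGrid(
        df["chrom"].astype(str).to_numpy(dtype=object),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        window_size,
        mapp,
    )


def read_mappability(path: str | Path) -> pd.DataFrame:
    """Per-window mappability TSV: chrom, start, score."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "start", "score"}.issubset(df.columns):
        raise ValueError("mappability table needs columns chrom, start, score")
    return df


def write_track_matrix(
    X: pd.DataFrame, meta: pd.DataFrame, prefix: str | Path
) -> tuple[Path, Path]:
    """Window x track matrix plus companion metadata table."""
    prefix = Path(prefix)
    mat = prefix.with_suffix(".tsv")
    metap = prefix.parent / (prefix.name + ".meta.tsv")
    X.to_csv(mat, sep="\t", index=False)
    meta.to_csv(metap, sep="\t", index=False)
    return mat, metap


def read_track_matrix(prefix: str | Path) -> list[TrackProfile]:
    prefix = Path(prefix)
    X = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = pd.read_csv(
        prefix.parent / (prefix.name + ".meta.tsv"), sep="\t", keep_default_na=False
    )
    tracks = []
    for row in meta.itertuples(index=False):
        tracks.append(
            TrackProfile(
                track_id=row.track_id,
                feature_class=row.feature_class,
                tissue=row.tissue,
                values=X[row.track_id].to_numpy(),
                rt_phase=row.rt_phase or None,
            )
        )
    return tracks


def read_mutations(path: str | Path, drop_invalid: bool = True) -> pd.DataFrame:
    """Somatic SNV table: chrom, pos (1-based), ref, alt, sample_id, cohort.

    Indels (multi-base alleles) and sex-chromosome variants are rejected
    at parse time; only single-base substitutions on autosomes enter the
    analysis.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns {sorted(missing)}")
    return _clean_mutations(df, drop_invalid=drop_invalid)


def _clean_mutations(df: pd.DataFrame, drop_invalid: bool = True) -> pd.DataFrame:
    df = df.copy()
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    snv = (
        df["ref"].isin(_BASES)
        & df["alt"].isin(_BASES)
        & (df["ref"] != df["alt"])
        & ~df["chrom"].isin(SEX_CHROMS)
    )
    n_bad = int((~snv).sum())
    if n_bad:
        if not drop_invalid:
            raise ValueError(f"{n_bad} records are not autosomal SNVs")
        logger.info("dropped %d non-SNV or sex-chromosome records", n_bad)
    out = df.loc[snv, MUTATION_COLUMNS + [c for c in df.columns if c not in MUTATION_COLUMNS]]
    return out.reset_index(drop=True)


def read_mutations_vcf(
    path: str | Path, sample_to_cohort: dict[str, str]
) -> pd.DataFrame:
    """Minimal VCF reader: one record per SNV, sample taken from the ID
    column or a single-sample header, cohort from ``sample_to_cohort``."""
    rows = []
    with open(path) as fh:
        sample = None
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) > 9:
                    sample = cols[9]
                continue
            f = line.rstrip("\n").split("\t")
            sid = sample or f[2]
            rows.append((f[0], int(f[1]), f[3], f[4], sid))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample_id"])
    df["cohort"] = df["sample_id"].map(sample_to_cohort)
    if df["cohort"].isna().any():
        unknown = sorted(df.loc[df["cohort"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without cohort mapping: {unknown}")
    return _clean_mutations(df)


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_signature_probabilities(path: str | Path) -> pd.DataFrame:
    """Per-SNV signature probabilities: key columns (chrom, pos, sample_id)
    plus one column per signature; probabilities sum to 1 per row."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    key = {"chrom", "pos", "sample_id"}
    if not key.issubset(df.columns):
        raise ValueError("probability table needs columns chrom, pos, sample_id")
    sig_cols = [c for c in df.columns if c not in key]
    total = df[sig_cols].to_numpy().sum(axis=1)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ValueError("signature probabilities must sum to 1 per SNV")
    return df


def read_class_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping signature id to aetiology class."""
    df = pd.read_csv(path, sep="\t", header=None, names=["signature", "sig_class"])
    return dict(zip(df["signature"], df["sig_class"]))


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """BED6 gene annotations; the name field carries the gene id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    return df[["gene_id", "chrom", "start", "end"]]


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out["score"] = 0
    out["strand"] = "."
    out[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line (e.g. a known cancer-gene list)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
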