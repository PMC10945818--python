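"""Readers and writers for the pipeline's file formats.

Fixed TSV dialect throughout: tab-separated, header row, UTF-8, '.'
decimal, empty string = missing.  Tracks are 4-column BED (0-based
half-open, label in column 4); genes travel as a minimal GTF; gene sets as
GMT.  Reports and manifests are JSON with sorted keys so identical runs
produce identical bytes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationTrack
from .glmm import KinshipMatrix
from .mstarr import MstarrData
from .qc import MethylationCounts

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, na_rep="")


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=True,
                       na_values=[""], **kw)


# -- counts -----------------------------------------------------------------


def write_counts(counts: MethylationCounts, meth_path, total_path) -> None:
    for mat, path in ((counts.meth, meth_path), (counts.total, total_path)):
        df = pd.DataFrame(mat, index=counts.site_ids, columns=counts.sample_ids)
        df.index.name = "site_id"
        df.to_csv(path, sep="\t")


def read_counts(meth_path, total_path) -> MethylationCounts:
    meth = pd.read_csv(meth_path, sep="\t", index_col="site_id")
    total = pd.read_csv(total_path, sep="\t", index_col="site_id")
    if list(meth.index) != list(total.index) or list(meth.columns) != list(
        total.columns
    ):
        raise ValueError("meth and total matrices disagree on sites or samples")
    return MethylationCounts(
        site_ids=list(meth.index),
        sample_ids=list(meth.columns),
        meth=meth.to_numpy(dtype=np.int64),
        total=total.to_numpy(dtype=np.int64),
    )


# -- kinship ----------------------------------------------------------------


def write_kinship(k: KinshipMatrix, path) -> None:
    df = k.to_frame()
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    if list(df.index) != list(df.columns):
        raise ValueError("kinship rows and columns disagree")
    return KinshipMatrix(individual_ids=list(df.index), K=df.to_numpy(float))


# -- BED tracks -------------------------------------------------------------


def write_bed(track: AnnotationTrack, path) -> None:
    track.intervals[["chrom", "start", "end", "label"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path, name: str) -> AnnotationTrack:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            label = parts[3] if len(parts) > 3 else name
            rows.append((chrom, start, end, label))
    return AnnotationTrack(
        name=name,
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]),
    )


# -- GTF genes --------------------------------------------------------------


def write_gtf(gene_intervals: pd.DataFrame, path) -> None:
    """Minimal GTF: one 'gene' feature per gene (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in gene_intervals.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tbioembed\tgene\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )


def read_gtf_genes(path) -> pd.DataFrame:
    """Parse gene features from a GTF; malformed rows skipped with warning."""
    rows, n_bad = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                if len(parts) < 9:
                    n_bad += 1
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                n_bad += 1
                continue
            gene_id = None
            for field in parts[8].split(";"):
                field = field.strip()
                if field.startswith("gene_id"):
                    gene_id = field.split(" ", 1)[1].strip().strip('"')
            if gene_id is None:
                n_bad += 1
                continue
            rows.append((gene_id, parts[0], start, end))
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed GTF rows in {path}")
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


# -- GMT gene sets ----------------------------------------------------------


def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out


# -- mSTARR counts ----------------------------------------------------------


def write_mstarr(data: MstarrData, path) -> None:
    write_tsv(data.counts, path)


def read_mstarr(path) -> MstarrData:
    return MstarrData(counts=read_tsv(path))


# -- JSON -------------------------------------------------------------------


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, (set, tuple)):
        return sorted(x) if isinstance(x, set) else list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
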