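"""Regulatory-activity calling from paired DNA/RNA reporter-assay counts.

mSTARR-seq transfects a library of genomic fragments, each in a fully CpG
methylated and a fully unmethylated state, into cells where fragments with
enhancer-like activity drive their own transcription.  Per 500-bp window
and replicate, the data are a DNA (input plasmid) count and an RNA
(transcript) count in each condition.

Calling proceeds on size-factor-normalised log2(RNA/DNA) ratios:

1. a window is *active* in a condition when a one-sample t-test of that
   condition's replicate log-ratios against the genome-wide median
   log-ratio (the plasmid self-transcription background) passes a
   Benjamini-Hochberg FDR across windows;
2. among windows active in either condition (*regulatory* windows),
   *methylation dependence* is a Welch t-test of methylated vs
   unmethylated log-ratios, again BH-corrected; the direction of the mean
   difference classifies the window as repressed or enhanced by
   methylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import bh_fdr
from .enrichment import fisher_or, EnrichmentResult

METH, UNMETH = "methylated", "unmethylated"
PSEUDOCOUNT = 0.5


@dataclass
class MstarrData:
    """Replicate x condition DNA and RNA counts for 500-bp windows.

    ``counts`` is a tidy frame: window_id, condition, replicate, dna, rna.
    Window ids are "chrom:start-end" with 0-based half-open coordinates.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"window_id", "condition", "replicate", "dna", "rna"}
        if not req.issubset(self.counts.columns):
            raise ValueError(f"mSTARR counts need columns {req}")
        bad = set(self.counts["condition"]) - {METH, UNMETH}
        if bad:
            raise ValueError(f"unknown conditions {bad}")
        if (self.counts[["dna", "rna"]] < 0).any().any():
            raise ValueError("counts must be non-negative")
        reps = self.counts.groupby(["window_id", "condition"])["replicate"].nunique()
        if (reps < 2).any():
            raise ValueError("need >= 2 replicates per window x condition")

    @property
    def window_ids(self) -> list[str]:
        return list(dict.fromkeys(self.counts["window_id"]))

    def window_bounds(self) -> pd.DataFrame:
        rows = []
        for wid in self.window_ids:
            chrom, _, span = wid.partition(":")
            start, _, end = span.partition("-")
            rows.append((wid, chrom, int(start), int(end)))
        return pd.DataFrame(rows, columns=["window_id", "chrom", "start", "end"])


def _median_ratio_size_factors(mat: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (windows x libraries).

    Each library's factor is the median, over windows, of its pseudocounted
    count divided by the across-library geometric mean for that window;
    factors are rescaled to geometric mean 1.  Robust to a minority of
    strongly active windows, which would skew total-count factors.
    """
    logc = np.log(mat.to_numpy(dtype=float) + PSEUDOCOUNT)
    ref = logc.mean(axis=1, keepdims=True)
    log_sf = np.median(logc - ref, axis=0)
    log_sf = log_sf - log_sf.mean()
    sf = pd.Series(np.exp(log_sf), index=mat.columns)
    if not np.all(np.isfinite(sf)) or (sf <= 0).any():
        raise ValueError("degenerate library size factors")
    return sf


def normalize_log_ratios(data: MstarrData) -> pd.DataFrame:
    """Per replicate x condition x window log2 RNA/DNA ratio.

    Counts are normalised by per-library size factors before the ratio:
    ``log2((rna + 0.5)/sf_rna) - log2((dna + 0.5)/sf_dna)``.  Size factors
    are median-of-ratios within each assay (DNA libraries against DNA
    libraries, RNA against RNA), so a minority of highly active windows
    cannot shift the normalisation of the rest.
    """
    df = data.counts.copy()
    if (df.groupby(["condition", "replicate"])[["dna", "rna"]].sum() == 0).any().any():
        raise ValueError("zero library size in a condition x replicate")
    df["_lib"] = df["condition"].astype(str) + "/" + df["replicate"].astype(str)
    dna_mat = df.pivot_table(index="window_id", columns="_lib", values="dna",
                             sort=False)
    rna_mat = df.pivot_table(index="window_id", columns="_lib", values="rna",
                             sort=False)
    sf_dna = _median_ratio_size_factors(dna_mat)
    sf_rna = _median_ratio_size_factors(rna_mat)
    key = df["_lib"].to_numpy()
    df["log_ratio"] = np.log2(
        (df["rna"] + PSEUDOCOUNT) / sf_rna[key].to_numpy()
    ) - np.log2((df["dna"] + PSEUDOCOUNT) / sf_dna[key].to_numpy())
    return df[["window_id", "condition", "replicate", "log_ratio"]]


def call_windows(data: MstarrData, alpha_fdr: float = 0.10) -> pd.DataFrame:
    """Activity and methylation-dependence calls for every window.

    Returns one row per window: window_id, active_meth, active_unmeth,
    q_activity_meth, q_activity_unmeth, regulatory, methylation_dependent,
    q_dependence, direction ('repressed_by_methylation',
    'enhanced_by_methylation', or 'none'), skipped (zero-variance flag).
    """
    lr = normalize_log_ratios(data)
    baseline = float(lr["log_ratio"].median())

    wide = lr.pivot_table(
        index="window_id",
        columns=["condition", "replicate"],
        values="log_ratio",
        sort=False,
    )
    windows = list(wide.index)
    per_cond = {
        cond: wide[cond].to_numpy(dtype=float) for cond in (METH, UNMETH)
    }

    n_w = len(windows)
    out = pd.DataFrame({"window_id": windows})
    skipped = np.zeros(n_w, dtype=bool)
    for cond in (METH, UNMETH):
        vals = per_cond[cond]
        sd = np.nanstd(vals, axis=1, ddof=1)
        zero_var = sd == 0
        skipped |= zero_var
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_1samp(
                vals, popmean=baseline, axis=1, nan_policy="omit"
            )
        p = np.asarray(p, dtype=float)
        p[zero_var] = np.nan
        q = bh_fdr(p)
        out[f"q_activity_{cond}"] = q
        out[f"active_{cond}"] = (q <= alpha_fdr) & ~np.isnan(q)

    out["regulatory"] = out[f"active_{METH}"] | out[f"active_{UNMETH}"]
    out["skipped"] = skipped

    # dependence: Welch t between conditions, tested among regulatory windows
    meth_vals = per_cond[METH]
    unmeth_vals = per_cond[UNMETH]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_dep, p_dep = stats.ttest_ind(
            meth_vals, unmeth_vals, axis=1, equal_var=False, nan_policy="omit"
        )
    p_dep = np.asarray(p_dep, dtype=float)
    p_dep[~out["regulatory"].to_numpy()] = np.nan
    p_dep[skipped] = np.nan
    q_dep = bh_fdr(p_dep)
    out["q_dependence"] = q_dep
    out["methylation_dependent"] = (q_dep <= alpha_fdr) & ~np.isnan(q_dep)

    mean_diff = np.nanmean(meth_vals, axis=1) - np.nanmean(unmeth_vals, axis=1)
    direction = np.where(
        out["methylation_dependent"],
        np.where(mean_diff < 0, "repressed_by_methylation", "enhanced_by_methylation"),
        "none",
    )
    out["direction"] = direction
    return out


def map_sites_to_windows(
    site_ids: list[str], window_bounds: pd.DataFrame
) -> dict[str, str | None]:
    """Assign each CpG site (1-based position) to its containing window.

    Windows are 0-based half-open, so a site at 1-based position 500 falls
    in [0, 500) but not [500, 1000).
    """
    from .enrichment import site_positions

    pos = site_positions(site_ids)
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("start") for c, g in window_bounds.groupby("chrom")
    }
    assign: dict[str, str | None] = {}
    for sid, chrom, p1 in pos.itertuples(index=False):
        p0 = p1 - 1
        assign[sid] = None
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        idx = np.searchsorted(grp["start"].to_numpy(), p0, side="right") - 1
        if idx >= 0:
            row = grp.iloc[idx]
            if row["start"] <= p0 < row["end"]:
                assign[sid] = row["window_id"]
    return assign


def regulatory_overlap_enrichment(
    window_calls: pd.DataFrame,
    site_results: pd.DataFrame,
    window_bounds: pd.DataFrame,
    fdr_grid: list[float] = (0.05, 0.10, 0.20),
) -> pd.DataFrame:
    """Enrichment of predictor-associated CpGs in regulatory windows.

    For each discovery FDR threshold, Fisher tests of (significant sites in
    regulatory windows vs all in-window tested sites) and the same
    restricted to methylation-dependent windows.  ``site_results`` is one
    row per site with columns (site_id, q).
    """
    assign = map_sites_to_windows(list(site_results["site_id"]), window_bounds)
    sr = site_results.copy()
    sr["window_id"] = sr["site_id"].map(assign)
    sr = sr[sr["window_id"].notna()]
    calls = window_calls.set_index("window_id")
    rows = []
    for kind in ("regulatory", "methylation_dependent"):
        in_kind = sr["window_id"].map(calls[kind]).fillna(False).astype(bool)
        for thr in fdr_grid:
            sig = sr["q"] <= thr
            a = int((sig & in_kind).sum())
            b = int((sig & ~in_kind).sum())
            c = int((~sig & in_kind).sum())
            d = int((~sig & ~in_kind).sum())
            res: EnrichmentResult = fisher_or((a, b, c, d), category=kind)
            rows.append(
                {
                    "window_class": kind,
                    "fdr_threshold": thr,
                    "a": a, "b": b, "c": c, "d": d,
                    "log2_or": res.log2_or,
                    "p": res.p,
                    "defined": res.defined,
                }
            )
    return pd.DataFrame(rows)
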