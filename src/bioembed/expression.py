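"""Linking CpG-level methylation effects to gene-level expression effects.

CpG sites are mapped to gene bodies (GTF-style 1-based inclusive
intervals); the distance of predictor-associated sites to
predictor-associated genes is compared to background with a two-sample
Kolmogorov-Smirnov test; and the signs of methylation and expression
effects for the same gene are crossed in a Fisher's exact test, the
expectation under a repressive model of gene-body-adjacent methylation
being anti-concordance (methylation up, expression down).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import fisher_or, site_positions, EnrichmentResult


def map_sites_to_genes(
    site_ids: list[str], gene_intervals: pd.DataFrame
) -> pd.DataFrame:
    """Assign sites to every gene body containing them.

    ``gene_intervals`` has columns (gene_id, chrom, start, end), 1-based
    inclusive.  Returns one row per (site, gene) assignment with a
    ``multi_gene`` flag on sites contained in more than one gene.
    """
    req = {"gene_id", "chrom", "start", "end"}
    if not req.issubset(gene_intervals.columns):
        raise ValueError(f"gene intervals need columns {req}")
    pos = site_positions(site_ids)
    rows = []
    by_chrom = dict(tuple(gene_intervals.groupby("chrom")))
    for sid, chrom, p1 in pos.itertuples(index=False):
        genes = by_chrom.get(chrom)
        if genes is None:
            continue
        hit = genes[(genes["start"] <= p1) & (p1 <= genes["end"])]
        for g in hit["gene_id"]:
            rows.append((sid, g))
    out = pd.DataFrame(rows, columns=["site_id", "gene_id"])
    counts = out.groupby("site_id")["gene_id"].transform("size")
    out["multi_gene"] = counts > 1
    return out


def distance_to_genes(
    site_ids: list[str], gene_intervals: pd.DataFrame, genes: set[str]
) -> pd.Series:
    """bp distance of each site to the nearest gene body in ``genes``.

    Zero when the site lies inside a gene body; strand is ignored.
    """
    sub = gene_intervals[gene_intervals["gene_id"].isin(genes)]
    pos = site_positions(site_ids)
    by_chrom = dict(tuple(sub.groupby("chrom")))
    dists = []
    for sid, chrom, p1 in pos.itertuples(index=False):
        genes_c = by_chrom.get(chrom)
        if genes_c is None or genes_c.empty:
            dists.append(np.inf)
            continue
        start = genes_c["start"].to_numpy()
        end = genes_c["end"].to_numpy()
        d = np.where(
            (start <= p1) & (p1 <= end),
            0,
            np.minimum(np.abs(start - p1), np.abs(p1 - end)),
        )
        dists.append(int(d.min()))
    return pd.Series(dists, index=site_ids, name="distance_bp")


def ks_distance_test(
    distances_hits: np.ndarray, distances_background: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS test: D = sup |F_hits - F_background|, asymptotic p."""
    a = np.asarray(distances_hits, dtype=float)
    b = np.asarray(distances_background, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distance samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def summarize_gene_methylation(
    site_effects: pd.DataFrame,
    assignments: pd.DataFrame,
    rule: str = "top_site",
) -> pd.Series:
    """Per-gene summary sign of methylation effects.

    ``site_effects`` has one row per site (site_id, beta, p).  Default rule
    takes the sign of the most significant site in the gene body;
    ``rule='mean_sign'`` averages the signs of all assigned sites instead.
    """
    merged = assignments.merge(site_effects, on="site_id")
    if rule == "top_site":
        idx = merged.groupby("gene_id")["p"].idxmin()
        signs = np.sign(merged.loc[idx].set_index("gene_id")["beta"])
    elif rule == "mean_sign":
        signs = np.sign(
            merged.groupby("gene_id")["beta"].apply(lambda b: np.sign(b).mean())
        )
    else:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    return signs


def sign_concordance(
    site_effects: pd.DataFrame,
    expression_effects: pd.DataFrame,
    assignments: pd.DataFrame,
    rule: str = "top_site",
    site_sig: pd.Series | None = None,
    expr_sig_q: float = 0.10,
) -> dict:
    """Cross gene-level methylation and expression effect signs.

    Returns the 2x2 sign table and its Fisher test (negative log2 OR =
    anti-concordance), the concordant fraction, and the fold-enrichment
    (relative risk) of expression-significant genes among genes containing
    a significant CpG, with its own Fisher p.

    ``expression_effects``: one row per gene (gene_id, beta_expr, se, q).
    ``site_sig``: optional boolean per site marking predictor-significant
    CpGs for the fold-enrichment; defaults to p-based top decile.
    """
    meth_sign = summarize_gene_methylation(site_effects, assignments, rule=rule)
    expr = expression_effects.set_index("gene_id")
    shared = meth_sign.index.intersection(expr.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 genes shared between methylation and expression")
    ms = meth_sign.loc[shared]
    es = np.sign(expr.loc[shared, "beta_expr"])

    pp = int(((ms > 0) & (es > 0)).sum())
    pn = int(((ms > 0) & (es <= 0)).sum())
    np_ = int(((ms <= 0) & (es > 0)).sum())
    nn = int(((ms <= 0) & (es <= 0)).sum())
    table_fet: EnrichmentResult = fisher_or((pp, pn, np_, nn), category="sign")
    concordant = (pp + nn) / len(shared)

    # fold-enrichment of expression-significant genes among genes with a
    # significant CpG (relative risk), with FET p
    if site_sig is None:
        cut = site_effects["p"].quantile(0.1)
        site_sig = site_effects.set_index("site_id")["p"] <= cut
    sig_sites = set(site_sig[site_sig].index)
    genes_with_sig = set(
        assignments.loc[assignments["site_id"].isin(sig_sites), "gene_id"]
    )
    expr_sig = set(expr.index[expr["q"] <= expr_sig_q])
    universe = set(shared)
    g_sig = universe & genes_with_sig
    g_not = universe - genes_with_sig
    a = len(g_sig & expr_sig)
    b = len(g_sig - expr_sig)
    c = len(g_not & expr_sig)
    d = len(g_not - expr_sig)
    with np.errstate(divide="ignore", invalid="ignore"):
        risk_sig = a / (a + b) if (a + b) else np.nan
        risk_not = c / (c + d) if (c + d) else np.nan
        fold = risk_sig / risk_not if risk_not else np.nan
    fold_fet = fisher_or((a, b, c, d), category="fold")

    return {
        "n_genes": int(len(shared)),
        "sign_table": (pp, pn, np_, nn),
        "sign_fet": table_fet,
        "concordant_fraction": float(concordant),
        "fold_enrichment": float(fold) if fold == fold else np.nan,
        "fold_fet": fold_fet,
    }
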