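"""Genomic-context annotation and enrichment statistics for CpG site sets.

Differentially methylated sites are compared against the full tested site
set (the background) with Fisher's exact tests: per genomic compartment
(promoter, CpG island, shore, enhancer, gene body, unannotated), per
chromatin state, between predictors (overlap and directional concordance),
and per gene set (hypergeometric with Bonferroni correction).

Coordinate conventions: CpG site ids carry 1-based positions; annotation
tracks are BED-style 0-based half-open.  The conversion lives in one place
(:func:`site_overlaps_interval` / the interval lookup), so a site at
1-based position 100 overlaps the half-open interval [99, 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

COMPARTMENT_PRIORITY = (
    "promoter",
    "cpg_island",
    "shore",
    "enhancer",
    "gene_body",
)
UNANNOTATED = "unannotated"


@dataclass
class AnnotationTrack:
    """Named set of labelled genomic intervals (0-based, half-open)."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "label"}
        if not req.issubset(self.intervals.columns):
            raise ValueError(f"track {self.name!r} missing columns {req}")
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            raise ValueError(
                f"track {self.name!r}: start >= end at rows {list(self.intervals.index[bad])}"
            )

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            out[str(chrom)] = IntervalTree.from_tuples(
                (int(s), int(e), lab)
                for s, e, lab in zip(grp["start"], grp["end"], grp["label"])
            )
        return out


@dataclass
class EnrichmentResult:
    """2x2 Fisher's exact test with the sample (cross-product) odds ratio.

    The table is (a, b; c, d) = (hits in category, hits outside,
    non-hit background in category, non-hit background outside).  When a
    zero cell makes the cross-product ratio incomputable the result is
    flagged ``defined=False`` rather than patched with a continuity
    correction, mirroring how overlap tests report inestimable ratios.
    """

    category: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = field(init=False)
    log2_or: float = field(init=False)
    p: float = field(init=False)
    defined: bool = field(init=False)

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("counts must be non-negative")
        table = [[self.a, self.b], [self.c, self.d]]
        self.p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        if self.b * self.c > 0 and self.a * self.d > 0:
            self.odds_ratio = (self.a * self.d) / (self.b * self.c)
            self.log2_or = float(np.log2(self.odds_ratio))
            self.defined = True
        else:
            self.odds_ratio = np.nan
            self.log2_or = np.nan
            self.defined = False


def fisher_or(
    table: tuple[int, int, int, int], category: str = ""
) -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table (a, b, c, d), row-major."""
    a, b, c, d = table
    return EnrichmentResult(category=category, a=a, b=b, c=c, d=d)


def site_positions(site_ids: list[str]) -> pd.DataFrame:
    """Split "chrom_pos" ids (1-based pos) into a (site_id, chrom, pos) frame."""
    rows = []
    for sid in site_ids:
        chrom, _, pos = sid.rpartition("_")
        rows.append((sid, chrom, int(pos)))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos"])


def annotate_sites(
    site_ids: list[str],
    compartment_tracks: dict[str, AnnotationTrack],
    chromatin_track: AnnotationTrack | None = None,
) -> pd.DataFrame:
    """Assign each site a compartment label and (optionally) a chromatin state.

    Compartments are made exclusive by a fixed priority:
    promoter > cpg_island > shore > enhancer > gene_body > unannotated.
    Chromatin state comes from direct overlap with the (partition)
    segmentation track.  A site on a chromosome absent from every track is
    labelled unannotated with a warning.
    """
    pos = site_positions(site_ids)
    trees = {
        name: track.trees() for name, track in compartment_tracks.items()
    }
    chrom_trees = chromatin_track.trees() if chromatin_track is not None else {}
    known_chroms = set().union(*(t.keys() for t in trees.values())) | set(
        chrom_trees.keys()
    )

    labels, states = [], []
    n_unknown_chrom = 0
    for sid, chrom, p1 in pos.itertuples(index=False):
        start0 = p1 - 1  # 1-based position -> 0-based point
        if chrom not in known_chroms:
            n_unknown_chrom += 1
            labels.append(UNANNOTATED)
            states.append(None)
            continue
        label = UNANNOTATED
        for name in COMPARTMENT_PRIORITY:
            tree = trees.get(name, {}).get(chrom)
            if tree is not None and tree.overlaps_point(start0):
                label = name
                break
        labels.append(label)
        state = None
        ctree = chrom_trees.get(chrom)
        if ctree is not None:
            hits = ctree[start0]
            if hits:
                state = sorted(iv.data for iv in hits)[0]
        states.append(state)
    if n_unknown_chrom:
        warnings.warn(
            f"{n_unknown_chrom} sites on chromosomes absent from all tracks; "
            "labelled unannotated"
        )
    out = pos.copy()
    out["compartment"] = labels
    out["chromatin_state"] = states
    return out


def compartment_enrichment(
    hit_sites: set[str] | list[str],
    background_sites: list[str],
    labels: pd.Series | dict[str, str],
) -> list[EnrichmentResult]:
    """One Fisher's exact test per category, hits vs background minus hits.

    ``labels`` maps site_id -> category over the background universe.
    """
    hit_sites = set(hit_sites)
    bg = list(background_sites)
    if not hit_sites <= set(bg):
        raise ValueError("hit sites must be a subset of the background")
    lab = labels if isinstance(labels, dict) else labels.to_dict()
    from collections import Counter

    bg_counts = Counter(lab[s] for s in bg)
    hit_counts = Counter(lab[s] for s in hit_sites)
    n_hits, n_nonhit = len(hit_sites), len(bg) - len(hit_sites)
    results = []
    for cat in sorted(bg_counts):
        a = hit_counts.get(cat, 0)
        b = n_hits - a
        c = bg_counts[cat] - a
        d = n_nonhit - c
        results.append(EnrichmentResult(category=cat, a=a, b=b, c=c, d=d))
    return results


def overlap_and_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    primary_fdr: float = 0.10,
    secondary_fdr: float = 0.20,
) -> dict:
    """Cross-predictor overlap with directional concordance.

    Each input frame has one row per site with columns (site_id, beta, q).
    A site is in the overlap when it passes the primary FDR for one
    predictor and the (looser) secondary FDR for the other, in either
    direction.  Returns the overlap set, an enrichment Fisher test of the
    overlap against independence, the fraction of overlap sites whose
    effects share a sign, and a Fisher test on the 2x2 sign table.
    """
    a = results_a.set_index("site_id")
    b = results_b.set_index("site_id")
    if set(a.index) != set(b.index):
        raise ValueError("result tables cover different site universes")
    b = b.loc[a.index]

    sig_a1 = a["q"] <= primary_fdr
    sig_b1 = b["q"] <= primary_fdr
    sig_a2 = a["q"] <= secondary_fdr
    sig_b2 = b["q"] <= secondary_fdr
    overlap_mask = (sig_a1 & sig_b2) | (sig_b1 & sig_a2)
    overlap = set(a.index[overlap_mask])

    # enrichment of joint significance against independence, at primary FDR
    n = len(a.index)
    both = int((sig_a1 & sig_b1).sum())
    only_a = int((sig_a1 & ~sig_b1).sum())
    only_b = int((~sig_a1 & sig_b1).sum())
    neither = n - both - only_a - only_b
    overlap_fet = fisher_or((both, only_a, only_b, neither), category="overlap")

    if overlap:
        sa = np.sign(a.loc[list(overlap), "beta"])
        sb = np.sign(b.loc[list(overlap), "beta"])
        concordance = float((sa == sb).mean())
        pp = int(((sa > 0) & (sb > 0)).sum())
        pn = int(((sa > 0) & (sb <= 0)).sum())
        np_ = int(((sa <= 0) & (sb > 0)).sum())
        nn = int(((sa <= 0) & (sb <= 0)).sum())
        sign_fet = fisher_or((pp, pn, np_, nn), category="sign")
    else:
        concordance = np.nan
        sign_fet = fisher_or((0, 0, 0, 0), category="sign")

    return {
        "overlap_sites": overlap,
        "n_overlap": len(overlap),
        "overlap_fet": overlap_fet,
        "concordance": concordance,
        "sign_fet": sign_fet,
    }


def effect_size_correlation(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    site_set: set[str] | list[str],
) -> tuple[float, float]:
    """Pearson correlation of standardized effects (z) over a site set."""
    site_set = list(site_set)
    if len(site_set) < 3:
        raise ValueError("need at least 3 sites")
    za = results_a.set_index("site_id").loc[site_set, "z"].to_numpy(float)
    zb = results_b.set_index("site_id").loc[site_set, "z"].to_numpy(float)
    if np.std(za) == 0 or np.std(zb) == 0:
        raise ValueError("zero variance in effect sizes")
    r, p = stats.pearsonr(za, zb)
    return float(r), float(p)


def gene_set_enrichment(
    hit_genes: set[str] | list[str],
    background_genes: set[str] | list[str],
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    Gene sets are intersected with the background before testing; the
    Bonferroni multiplier is the number of sets tested.
    """
    bg = set(background_genes)
    if not bg:
        raise ValueError("empty background gene universe")
    hits = set(hit_genes)
    if not hits <= bg:
        raise ValueError("hit genes must be a subset of the background")
    n_sets = len(gene_sets)
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & bg
        k = len(hits & genes)
        # P(X >= k) for X ~ Hypergeom(N=|bg|, K=|set|, n=|hits|)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(genes), len(hits)))
        rows.append(
            {
                "gene_set": name,
                "n_set": len(genes),
                "n_hit_in_set": k,
                "p": p,
                "p_bonferroni": min(1.0, p * n_sets),
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
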