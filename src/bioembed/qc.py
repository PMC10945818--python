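"""Site-level quality control for CpG count matrices.

Reduced-representation bisulfite sequencing yields, per CpG site and
sample, a methylated read count and a total read count.  Sites that are
poorly covered, invariant, or constitutively hypo-/hyper-methylated carry
no usable signal for association scans and are removed before modelling.
Rules are applied in a fixed order (coverage -> invariance -> mean bounds)
so the attrition accounting is reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SITE_ID_RE = re.compile(r"^(?P<chrom>[\w.]+)_(?P<pos>\d+)$")


@dataclass
class MethylationCounts:
    """Paired site x sample matrices of methylated and total read counts.

    Site ids are "chrom_pos" strings with 1-based positions
    (e.g. ``chr12_111013997``).
    """

    site_ids: list[str]
    sample_ids: list[str]
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        n_sites, n_samples = self.meth.shape
        if self.total.shape != (n_sites, n_samples):
            raise ValueError("meth and total shapes differ")
        if len(self.site_ids) != n_sites or len(self.sample_ids) != n_samples:
            raise ValueError("id lists inconsistent with matrix dimensions")
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.meth > self.total):
            raise ValueError("methylated count exceeds total count")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def positions(self) -> pd.DataFrame:
        """Parse site ids into (chrom, pos); pos is 1-based."""
        rows = []
        for sid in self.site_ids:
            m = _SITE_ID_RE.match(sid)
            if m is None:
                raise ValueError(f"malformed site id {sid!r}")
            rows.append((sid, m["chrom"], int(m["pos"])))
        return pd.DataFrame(rows, columns=["site_id", "chrom", "pos"])

    def subset_sites(self, mask: np.ndarray) -> "MethylationCounts":
        idx = np.flatnonzero(mask)
        return MethylationCounts(
            site_ids=[self.site_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            meth=self.meth[idx],
            total=self.total[idx],
        )

    def reorder_samples(self, order: list[int]) -> "MethylationCounts":
        return MethylationCounts(
            site_ids=list(self.site_ids),
            sample_ids=[self.sample_ids[i] for i in order],
            meth=self.meth[:, order],
            total=self.total[:, order],
        )


@dataclass
class FilterReport:
    """Per-rule attrition, in order of application."""

    n_input: int
    removed_low_coverage: int = 0
    removed_invariant: int = 0
    removed_hypomethylated: int = 0
    removed_hypermethylated: int = 0
    n_retained: int = 0
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_low_coverage": self.removed_low_coverage,
            "removed_invariant": self.removed_invariant,
            "removed_hypomethylated": self.removed_hypomethylated,
            "removed_hypermethylated": self.removed_hypermethylated,
            "n_retained": self.n_retained,
            "params": self.params,
        }


def methylation_fraction(counts: MethylationCounts) -> np.ndarray:
    """meth/total per site x sample; NaN where total == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = counts.meth / counts.total.astype(float)
    frac[counts.total == 0] = np.nan
    return frac


def filter_sites(
    counts: MethylationCounts,
    min_cov: int = 5,
    min_fraction_samples: float = 0.5,
    hypo_cut: float = 0.10,
    hyper_cut: float = 0.90,
) -> tuple[MethylationCounts, FilterReport]:
    """Restrict to the analyzable site set.

    Retains sites with coverage >= ``min_cov`` in at least
    ``min_fraction_samples`` of samples, with nonzero variance of the
    methylation fraction, and with mean fraction strictly inside
    ``(hypo_cut, hyper_cut)``.  Rules apply in that order; the report
    attributes each removed site to the first rule it fails.
    """
    if not (0 <= hypo_cut < hyper_cut <= 1):
        raise ValueError("require 0 <= hypo_cut < hyper_cut <= 1")
    report = FilterReport(
        n_input=counts.n_sites,
        params={
            "min_cov": min_cov,
            "min_fraction_samples": min_fraction_samples,
            "hypo_cut": hypo_cut,
            "hyper_cut": hyper_cut,
        },
    )
    frac = methylation_fraction(counts)

    covered = (counts.total >= min_cov).mean(axis=1) >= min_fraction_samples
    report.removed_low_coverage = int((~covered).sum())

    with np.errstate(invalid="ignore"):
        var = np.nanvar(frac, axis=1)
        mean = np.nanmean(frac, axis=1)
    var = np.where(np.isnan(var), 0.0, var)
    variant = var > 0
    report.removed_invariant = int((covered & ~variant).sum())

    keep_so_far = covered & variant
    hypo = mean <= hypo_cut
    hyper = mean >= hyper_cut
    report.removed_hypomethylated = int((keep_so_far & hypo).sum())
    report.removed_hypermethylated = int((keep_so_far & ~hypo & hyper).sum())

    keep = keep_so_far & ~hypo & ~hyper
    report.n_retained = int(keep.sum())
    if report.n_retained == 0:
        raise ValueError(
            f"no sites survive filtering; attrition: {report.to_dict()}"
        )
    return counts.subset_sites(keep), report
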