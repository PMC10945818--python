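"""Shared fixtures: small pedigrees, kinship matrices and count fixtures.

Everything is generated programmatically at collection time; no data files.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from bioembed.glmm import KinshipMatrix
from bioembed.qc import MethylationCounts


@pytest.fixture(scope="session")
def trio_kinship() -> KinshipMatrix:
    """Father, mother, two full-sib offspring."""
    ids = ["fa", "mo", "c1", "c2"]
    K = np.array(
        [
            [1.0, 0.0, 0.5, 0.5],
            [0.0, 1.0, 0.5, 0.5],
            [0.5, 0.5, 1.0, 0.5],
            [0.5, 0.5, 0.5, 1.0],
        ]
    )
    return KinshipMatrix(individual_ids=ids, K=K)


@pytest.fixture(scope="session")
def family_kinship_60() -> KinshipMatrix:
    """60 individuals in 15 unrelated families of 4 (parents + 2 sibs)."""
    n = 60
    K = np.eye(n)
    block = np.array(
        [
            [1.0, 0.0, 0.5, 0.5],
            [0.0, 1.0, 0.5, 0.5],
            [0.5, 0.5, 1.0, 0.5],
            [0.5, 0.5, 0.5, 1.0],
        ]
    )
    for i in range(0, n, 4):
        K[i : i + 4, i : i + 4] = block
    ids = [f"i{j:02d}" for j in range(n)]
    return KinshipMatrix(individual_ids=ids, K=K)


@pytest.fixture()
def toy_counts() -> MethylationCounts:
    """10 sites x 4 samples with known QC failures.

    Sites 0-1 all-zero (invariant/hypo), site 2 all-one (hyper), site 3
    low-coverage, sites 4-9 clean intermediate -> defaults retain 6.
    """
    rng = np.random.default_rng(0)
    n_samples = 4
    total = np.full((10, n_samples), 20, dtype=int)
    meth = np.zeros((10, n_samples), dtype=int)
    meth[2] = total[2]
    total[3] = 2  # below min_cov everywhere
    meth[3] = 1
    for s in range(4, 10):
        meth[s] = rng.binomial(20, 0.5, size=n_samples)
        # guard against accidental invariance in the tiny fixture
        meth[s, 0] = 8
        meth[s, 1] = 12
    site_ids = [f"chr1_{1000 + 10 * i}" for i in range(10)]
    return MethylationCounts(
        site_ids=site_ids,
        sample_ids=[f"s{j}" for j in range(n_samples)],
        meth=meth,
        total=total,
    )


@pytest.fixture(scope="session")
def small_cohort_frame() -> pd.DataFrame:
    """Eight-individual life-history table exercising every adversity rule."""
    rows = []
    for i in range(8):
        rows.append(
            {
                "individual_id": f"b{i}",
                "sex": "female" if i % 2 else "male",
                "birthdate": date(1990, 1, 1 + i).isoformat(),
                "mother_id": f"m{i}",
                "maternal_ordinal_rank_at_birth": i + 1,  # ranks 1..8
                "group_size_at_birth": 10 * (i + 1),  # 10..80
                "rainfall_first_year_mm": [150, 200, 250, 199, 300, 400, 500, 100][i],
                "mother_death_date": ""
                if i != 1
                else date(1993, 6, 1).isoformat(),
                "sibling_birthdates": ""
                if i != 2
                else date(1991, 1, 1).isoformat(),
            }
        )
    return pd.DataFrame(rows)
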