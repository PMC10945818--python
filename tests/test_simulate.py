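"""Generators: pedigree kinship identities, cohort prevalences,
methylation model fidelity, annotation geometry, determinism."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from bioembed.lifehistory import records_from_frame, score_cohort
from bioembed.simulate import (
    simulate_annotations,
    simulate_cohort,
    simulate_expression,
    simulate_methylation,
    simulate_mstarr,
    simulate_pedigree,
    simulate_samples,
)

SHIFT = date(1992, 1, 1)


def kinship_path_oracle(sires, dams, i, j, memo=None):
    """Numerator relationship by recursive path counting."""
    if memo is None:
        memo = {}
    if i > j:
        i, j = j, i
    if (i, j) in memo:
        return memo[(i, j)]
    if i == j:
        s, d = sires[i], dams[i]
        val = 1.0 + (
            0.5 * kinship_path_oracle(sires, dams, s, d, memo)
            if s >= 0 and d >= 0
            else 0.0
        )
    else:
        # j is the younger individual (higher index)
        s, d = sires[j], dams[j]
        val = 0.0
        if s >= 0:
            val += 0.5 * kinship_path_oracle(sires, dams, i, s, memo)
        if d >= 0:
            val += 0.5 * kinship_path_oracle(sires, dams, i, d, memo)
    memo[(i, j)] = val
    return val


class TestPedigree:
    def test_pedigree_identities(self):
        ped, kin = simulate_pedigree(n_founders=10, n_generations=3, seed=1)
        ids = kin.individual_ids
        pos = {x: k for k, x in enumerate(ids)}
        K = kin.K
        founders = ped[ped["sire"] == ""]["individual_id"]
        fi = [pos[f] for f in founders]
        off = np.array(K[np.ix_(fi, fi)])
        assert np.allclose(np.diag(off), 1.0)
        assert np.allclose(off - np.diag(np.diag(off)), 0.0)
        # parent-offspring entries = 0.5 for non-inbred parents
        for row in ped[ped["sire"] != ""].itertuples():
            i, s = pos[row.individual_id], pos[row.sire]
            if K[s, s] == 1.0 and K[pos[row.sire], pos[row.dam]] == 0.0:
                assert K[i, s] == pytest.approx(0.5)

    def test_full_sibs_half(self):
        ped, kin = simulate_pedigree(n_founders=6, n_generations=2, seed=2)
        pos = {x: k for k, x in enumerate(kin.individual_ids)}
        kids = ped[ped["sire"] != ""]
        by_parents = kids.groupby(["sire", "dam"])["individual_id"].apply(list)
        for sibs in by_parents:
            for a in sibs:
                for b in sibs:
                    if a != b:
                        assert kin.K[pos[a], pos[b]] == pytest.approx(0.5)

    def test_matches_path_counting_oracle(self):
        ped, kin = simulate_pedigree(n_founders=6, n_generations=3, seed=3)
        ids = kin.individual_ids
        pos = {x: k for k, x in enumerate(ids)}
        sires = [pos[s] if s else -1 for s in ped["sire"]]
        dams = [pos[d] if d else -1 for d in ped["dam"]]
        n = len(ids)
        memo = {}
        for i in range(n):
            for j in range(i, n):
                assert kin.K[i, j] == pytest.approx(
                    kinship_path_oracle(sires, dams, i, j, memo), abs=1e-12
                )

    @pytest.mark.parametrize("seed", range(12))
    def test_psd_across_seeds(self, seed):
        _, kin = simulate_pedigree(n_founders=8, n_generations=3, seed=seed)
        assert np.linalg.eigvalsh(kin.K)[0] >= -1e-8

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_pedigree(n_founders=1)
        with pytest.raises(ValueError):
            simulate_pedigree(n_founders=5, offspring_rate=0)


class TestCohort:
    def test_realized_prevalences(self):
        cohort = simulate_cohort(n_individuals=400, shift_date=SHIFT, seed=4)
        profiles = score_cohort(records_from_frame(cohort.fillna("")), SHIFT)
        for comp in (
            "drought", "maternal_loss", "close_sibling",
            "low_maternal_rank", "large_group",
        ):
            assert abs(profiles[comp].mean() - 0.25) < 0.06

    def test_habitat_fraction(self):
        cohort = simulate_cohort(
            n_individuals=200, fraction_low_habitat=0.2, shift_date=SHIFT, seed=5
        )
        profiles = score_cohort(records_from_frame(cohort.fillna("")), SHIFT)
        assert profiles["habitat_low_quality_at_birth"].mean() == pytest.approx(
            0.2, abs=0.01
        )

    def test_exposures_near_independent(self):
        cohort = simulate_cohort(n_individuals=500, shift_date=SHIFT, seed=6)
        profiles = score_cohort(records_from_frame(cohort.fillna("")), SHIFT)
        comps = [
            "drought", "maternal_loss", "close_sibling",
            "low_maternal_rank", "large_group",
        ]
        mat = profiles[comps].astype(float).corr().to_numpy()
        off = mat[~np.eye(5, dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.15

    def test_cumulative_independent_of_habitat(self):
        """Wilcoxon of cumulative score by habitat non-significant in
        >= 18/20 seeded null cohorts."""
        nonsig = 0
        for seed in range(20):
            cohort = simulate_cohort(n_individuals=150, shift_date=SHIFT, seed=seed)
            profiles = score_cohort(records_from_frame(cohort.fillna("")), SHIFT)
            low = profiles[profiles["habitat_low_quality_at_birth"] == 1][
                "cumulative"
            ].dropna().astype(int)
            high = profiles[profiles["habitat_low_quality_at_birth"] == 0][
                "cumulative"
            ].dropna().astype(int)
            p = stats.mannwhitneyu(low, high).pvalue
            if p > 0.05:
                nonsig += 1
        assert nonsig >= 18

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(adversity_prevalences={"drought": 1.5})

    def test_repeat_sampling_bookkeeping(self):
        cohort = simulate_cohort(n_individuals=100, shift_date=SHIFT, seed=7)
        samples, ranks = simulate_samples(cohort, shift_date=SHIFT, seed=7)
        per_ind = samples.groupby("individual_id").size()
        assert (per_ind >= 1).all() and (per_ind <= 3).all()
        assert len(samples) >= 100


class TestMethylation:
    def test_null_site_means_match_baseline(self):
        n_samples = 40
        preds = pd.DataFrame({"x": np.zeros(n_samples)})
        counts, truth = simulate_methylation(
            np.eye(n_samples), preds, n_sites=400,
            sigma2_g=0.0, sigma2_e=0.0, seed=8,
        )
        frac = counts.meth.sum(axis=1) / counts.total.sum(axis=1)
        p = expit(truth.table["baseline_logit"].to_numpy())
        se = np.sqrt(p * (1 - p) / counts.total.sum(axis=1))
        assert (np.abs(frac - p) < 4 * se + 1e-3).mean() > 0.98

    def test_kinship_correlation_increases_with_relatedness(self):
        """Latent g makes sample pairs' fractions covary by kinship bin."""
        n = 40
        K = np.eye(n)
        for i in range(0, n, 2):
            K[i, i + 1] = K[i + 1, i] = 0.5
        preds = pd.DataFrame({"x": np.zeros(n)})
        counts, truth = simulate_methylation(
            K, preds, n_sites=1500, sigma2_g=1.0, sigma2_e=0.0,
            baseline_weights=(0.0, 1.0, 0.0), seed=9,
        )
        frac = counts.meth / np.maximum(counts.total, 1)
        dev = frac - frac.mean(axis=1, keepdims=True)
        related, unrelated = [], []
        for i in range(0, n, 2):
            related.append(np.mean(dev[:, i] * dev[:, i + 1]))
            j = (i + 2) % n
            unrelated.append(np.mean(dev[:, i] * dev[:, j]))
        assert np.mean(related) > np.mean(unrelated)

    def test_truth_table_records_planted_effects(self):
        n = 30
        preds = pd.DataFrame({"habitat_low": np.repeat([1.0, 0.0], 15)})
        counts, truth = simulate_methylation(
            np.eye(n), preds, n_sites=100,
            causal_effects={"habitat_low": (10, 0.8)}, seed=10,
        )
        t = truth.table
        assert (t["habitat_low"] != 0).sum() == 10
        assert set(t.loc[t["habitat_low"] != 0, "habitat_low"]) == {0.8}
        assert t["causal"].sum() == 10

    def test_non_psd_kinship_rejected(self):
        preds = pd.DataFrame({"x": np.zeros(4)})
        with pytest.raises(ValueError):
            simulate_methylation(-np.eye(4), preds, n_sites=5, seed=0)


class TestAnnotations:
    def test_chromatin_states_tile_exactly(self):
        lengths = {"chr1": 100_000, "chr2": 50_000}
        _, chromatin, _ = simulate_annotations(chrom_lengths=lengths, seed=11)
        for chrom, length in lengths.items():
            ivs = chromatin.intervals[
                chromatin.intervals["chrom"] == chrom
            ].sort_values("start")
            assert ivs["start"].iloc[0] == 0
            assert ivs["end"].iloc[-1] == length
            assert (ivs["end"].to_numpy()[:-1] == ivs["start"].to_numpy()[1:]).all()

    def test_shores_flank_islands(self):
        tracks, _, _ = simulate_annotations(
            chrom_lengths={"chr1": 200_000}, seed=12
        )
        islands = tracks["cpg_island"].intervals
        shores = tracks["shore"].intervals
        shore_set = set(zip(shores["start"], shores["end"]))
        for isl in islands.itertuples(index=False):
            left = (max(0, isl.start - 2000), isl.start)
            right = (isl.end, min(200_000, isl.end + 2000))
            if left[0] < left[1]:
                assert left in shore_set
            if right[0] < right[1]:
                assert right in shore_set

    def test_density_targets_roughly_met(self):
        fracs = []
        length = 300_000
        for seed in range(10):
            tracks, _, _ = simulate_annotations(
                chrom_lengths={"chr1": length},
                densities={"enhancer": 0.05},
                seed=seed,
            )
            ivs = tracks["enhancer"].intervals
            covered = np.zeros(length, dtype=bool)
            for r in ivs.itertuples(index=False):
                covered[r.start : r.end] = True
            fracs.append(covered.mean())
        assert abs(np.mean(fracs) - 0.05) < 0.02


class TestDeterminism:
    def test_bit_identical_regeneration(self):
        """Same (seed, params) -> identical outputs for every generator."""
        for maker in (
            lambda s: simulate_pedigree(8, 3, seed=s)[1].K,
            lambda s: simulate_cohort(50, SHIFT, seed=s).to_csv(),
            lambda s: simulate_mstarr(100, 10, seed=s)[0].counts.to_csv(),
        ):
            a, b = maker(13), maker(13)
            if isinstance(a, np.ndarray):
                assert np.array_equal(a, b)
            else:
                assert a == b

    def test_substreams_independent(self):
        """Running one generator does not perturb another's draws."""
        c1 = simulate_cohort(30, SHIFT, seed=14)
        simulate_mstarr(50, 5, seed=14)
        c2 = simulate_cohort(30, SHIFT, seed=14)
        assert c1.equals(c2)
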