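"""Synthetic data generators with planted, recorded truth.

Every input the pipeline consumes can be generated here: a random-mating
pedigree and its relatedness matrix, a life-history cohort spanning the
habitat shift, per-CpG methylated/total count matrices drawn from the same
binomial mixed model the scan assumes, annotation tracks and gene models,
reporter-assay (mSTARR) window counts, and gene-level expression effects.
Each generator records what it planted in a :class:`TruthTable`, so
recovery tests can compare estimates against known effects.

All randomness flows through one seed with named substreams per generator
(``numpy.random.SeedSequence`` spawn keys), so enabling one generator never
perturbs another's draws, and regeneration from (seed, parameters) is
bit-identical.

Default scale emulates the study conditions at desk size: tens of
individuals, ~80 samples with a minority born before the habitat shift and
a subset of individuals sampled repeatedly, bimodal baseline methylation,
negative-binomial coverage around 30x, and kinship-structured logit-scale
random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .glmm import KinshipMatrix
from .qc import MethylationCounts
from .mstarr import MstarrData, METH, UNMETH
from .enrichment import AnnotationTrack

# substream ids: one per generator so streams never interleave
_STREAMS = {
    "pedigree": 1,
    "cohort": 2,
    "samples": 3,
    "methylation": 4,
    "annotations": 5,
    "mstarr": 6,
    "expression": 7,
    "gene_sets": 8,
}

DEFAULT_CHROM_LENGTHS = {"chr1": 5_000_000, "chr2": 3_000_000}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass
class TruthTable:
    """Planted truth for one generated dataset."""

    table: pd.DataFrame
    params: dict = field(default_factory=dict)
    seed: int = 0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _negbin(rng, mean, dispersion, size):
    """NB draws with Var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


# ---------------------------------------------------------------------------
# pedigree and kinship


def simulate_pedigree(
    n_founders: int = 20,
    n_generations: int = 3,
    offspring_rate: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, KinshipMatrix]:
    """Random-mating pedigree and its numerator relationship matrix.

    Each generation pairs random sires and dams from the previous
    generation; the expected number of offspring per pair is Poisson with
    mean ``2 * offspring_rate``.  The relatedness matrix is twice the
    kinship coefficient, computed by the recursive tabular method
    (founders unrelated and non-inbred).
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 1 or offspring_rate <= 0:
        raise ValueError("degenerate pedigree parameters")
    rng = _rng(seed, "pedigree")
    sires: list[int] = []
    dams: list[int] = []
    sexes: list[str] = []
    gen_of: list[int] = []
    for _ in range(n_founders):
        sires.append(-1)
        dams.append(-1)
        sexes.append("male" if rng.random() < 0.5 else "female")
        gen_of.append(0)
    prev = list(range(n_founders))
    for gen in range(1, n_generations):
        males = [i for i in prev if sexes[i] == "male"]
        females = [i for i in prev if sexes[i] == "female"]
        if not males or not females:
            break
        n_pairs = max(1, min(len(males), len(females)))
        ms = rng.permutation(males)[:n_pairs]
        fs = rng.permutation(females)[:n_pairs]
        cur = []
        for s, d in zip(ms, fs):
            for _ in range(rng.poisson(2 * offspring_rate)):
                sires.append(int(s))
                dams.append(int(d))
                sexes.append("male" if rng.random() < 0.5 else "female")
                gen_of.append(gen)
                cur.append(len(sires) - 1)
        prev = cur if cur else prev

    n = len(sires)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[j, s]
            if d >= 0:
                aij += 0.5 * A[j, d]
            A[i, j] = A[j, i] = aij
    ids = [f"ind{i:03d}" for i in range(n)]
    ped = pd.DataFrame(
        {
            "individual_id": ids,
            "sire": [ids[s] if s >= 0 else "" for s in sires],
            "dam": [ids[d] if d >= 0 else "" for d in dams],
            "sex": sexes,
            "generation": gen_of,
        }
    )
    return ped, KinshipMatrix(individual_ids=ids, K=A)


# ---------------------------------------------------------------------------
# life-history cohort and samples


def simulate_cohort(
    n_individuals: int = 60,
    shift_date: date = date(1992, 1, 1),
    adversity_prevalences: dict[str, float] | None = None,
    fraction_low_habitat: float = 0.25,
    seed: int = 0,
    individual_ids: list[str] | None = None,
    sexes: list[str] | None = None,
) -> pd.DataFrame:
    """Life-history table with near-independent adversity exposures.

    Drought, maternal-loss and close-sibling prevalences are freely
    settable; the low-maternal-rank and large-group flags are produced
    downstream by the empirical quartile rule, which pins their prevalence
    near 25% (the generator draws continuous rank/size values).  Exposures
    are drawn independently of the birth cohort, so cumulative adversity
    does not differ between habitats except by sampling noise.
    """
    prev = {"drought": 0.25, "maternal_loss": 0.25, "close_sibling": 0.25}
    if adversity_prevalences:
        for k, v in adversity_prevalences.items():
            if not 0 <= v <= 1:
                raise ValueError(f"prevalence for {k} outside [0, 1]")
            if k in prev:
                prev[k] = v
            elif k not in ("low_maternal_rank", "large_group"):
                raise KeyError(f"unknown adversity component {k!r}")
    rng = _rng(seed, "cohort")
    if individual_ids is None:
        individual_ids = [f"ind{i:03d}" for i in range(n_individuals)]
    if len(individual_ids) != n_individuals:
        raise ValueError("individual_ids length mismatch")

    n_low = int(round(fraction_low_habitat * n_individuals))
    rows = []
    for i, ind in enumerate(individual_ids):
        born_low = i < n_low
        if born_low:
            offset = rng.integers(1, int(12 * 365.25))
            birth = shift_date - timedelta(days=int(offset))
        else:
            offset = rng.integers(0, int(12 * 365.25))
            birth = shift_date + timedelta(days=int(offset))
        drought = rng.random() < prev["drought"]
        rainfall = rng.uniform(60, 199) if drought else rng.uniform(201, 600)
        mloss = rng.random() < prev["maternal_loss"]
        death = (
            (birth + timedelta(days=int(rng.uniform(30, 4 * 365))))
            if mloss
            else None
        )
        sib = rng.random() < prev["close_sibling"]
        if sib:
            sib_dates = [birth + timedelta(days=int(rng.uniform(200, 500)))]
        elif rng.random() < 0.7:
            sib_dates = [birth + timedelta(days=int(rng.uniform(600, 1200)))]
        else:
            sib_dates = []
        rows.append(
            {
                "individual_id": ind,
                "sex": (
                    sexes[i]
                    if sexes is not None
                    else ("male" if rng.random() < 0.5 else "female")
                ),
                "birthdate": birth.isoformat(),
                "mother_id": f"mom_{ind}",
                "maternal_ordinal_rank_at_birth": int(rng.integers(1, 21)),
                "group_size_at_birth": int(rng.integers(20, 101)),
                "rainfall_first_year_mm": round(float(rainfall), 1),
                "mother_death_date": death.isoformat() if death else "",
                "sibling_birthdates": ";".join(d.isoformat() for d in sib_dates),
            }
        )
    return pd.DataFrame(rows)


def simulate_samples(
    cohort: pd.DataFrame,
    shift_date: date = date(1992, 1, 1),
    repeat_fraction: float = 0.15,
    n_batches: int = 3,
    missing_rank_rate: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample table plus monthly dominance ranks.

    A ``repeat_fraction`` of individuals contribute 2-3 longitudinal
    samples.  Each sampled month gets an ordinal rank except a
    ``missing_rank_rate`` fraction of male sample-months (observation
    gaps), which are simply absent from the rank table.
    """
    rng = _rng(seed, "samples")
    rows, rank_rows = [], []
    k = 0
    for row in cohort.itertuples():
        birth = date.fromisoformat(row.birthdate)
        n_rep = 1
        if rng.random() < repeat_fraction:
            n_rep = int(rng.integers(2, 4))
        ages = np.sort(rng.uniform(4.0, 20.0, size=n_rep))
        for age in ages:
            cdate = birth + timedelta(days=int(age * 365.25))
            sid = f"samp{k:04d}"
            k += 1
            rows.append(
                {
                    "sample_id": sid,
                    "individual_id": row.individual_id,
                    "collection_date": cdate.isoformat(),
                    "batch": f"b{int(rng.integers(n_batches))}",
                    "conversion_rate": round(float(rng.uniform(0.985, 0.999)), 4),
                    "mean_depth": round(float(rng.uniform(20, 40)), 1),
                }
            )
            missing = row.sex == "male" and rng.random() < missing_rank_rate
            if not missing:
                rank_rows.append(
                    {
                        "individual_id": row.individual_id,
                        "year_month": f"{cdate.year:04d}-{cdate.month:02d}",
                        "ordinal_rank": int(rng.integers(1, 21)),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(rank_rows)


# ---------------------------------------------------------------------------
# methylation counts


def simulate_methylation(
    kinship_samples: np.ndarray,
    predictors: pd.DataFrame,
    n_sites: int = 5000,
    causal_effects: dict[str, tuple[int, float]] | None = None,
    sigma2_g: float = 0.3,
    sigma2_e: float = 0.2,
    mean_coverage: float = 30.0,
    coverage_dispersion: float = 0.1,
    baseline_weights: tuple[float, float, float] = (0.35, 0.30, 0.35),
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[MethylationCounts, TruthTable]:
    """Per-CpG counts from the binomial mixed model the scan assumes.

    Per site, the latent logit is a bimodal baseline (hypomethylated mode
    N(-3, 0.5), intermediate N(0, 1), hypermethylated mode N(+3, 0.5),
    mixed with ``baseline_weights``) plus planted fixed effects, a
    kinship-correlated random effect g ~ MVN(0, sigma2_g K) and residual
    noise e ~ N(0, sigma2_e I).  Coverage is negative-binomial per
    site x sample; methylated counts are binomial.

    ``causal_effects`` maps a predictor column name to (n_causal, beta):
    that many randomly chosen sites receive logit effect ``beta`` for the
    column (columns of ``predictors`` are numeric; nested designs are
    expressed by passing the nested column, e.g. adversity x low-habitat).

    Returns counts plus a truth table with one row per site: baseline
    logit, per-predictor true beta, and the variance components.
    """
    rng = _rng(seed, "methylation")
    K = np.asarray(kinship_samples, dtype=float)
    n_samples = K.shape[0]
    if predictors.shape[0] != n_samples:
        raise ValueError("predictors rows must match kinship dimension")
    eigmin = float(np.linalg.eigvalsh(K)[0])
    if eigmin < -1e-8:
        raise ValueError("kinship matrix not PSD")
    L = np.linalg.cholesky(K + 1e-9 * np.eye(n_samples))

    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    site_ids = _draw_site_ids(rng, n_sites, chrom_lengths)

    w = np.asarray(baseline_weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=n_sites, p=w)
    baseline = np.where(
        comp == 0,
        rng.normal(-3.0, 0.5, n_sites),
        np.where(
            comp == 1, rng.normal(0.0, 1.0, n_sites), rng.normal(3.0, 0.5, n_sites)
        ),
    )

    betas = pd.DataFrame(
        0.0, index=site_ids, columns=list(predictors.columns)
    )
    causal_effects = causal_effects or {}
    for term, (n_causal, beta) in causal_effects.items():
        if term not in predictors.columns:
            raise KeyError(f"unknown predictor column {term!r}")
        chosen = rng.choice(n_sites, size=n_causal, replace=False)
        # scalar effect, or a sequence cycled across the causal sites
        vals = np.resize(np.atleast_1d(np.asarray(beta, dtype=float)), n_causal)
        betas.iloc[chosen, betas.columns.get_loc(term)] = vals

    Xp = predictors.to_numpy(dtype=float)
    eta = (
        baseline[:, None]
        + betas.to_numpy() @ Xp.T
        + np.sqrt(sigma2_g) * (rng.standard_normal((n_sites, n_samples)) @ L.T)
        + np.sqrt(sigma2_e) * rng.standard_normal((n_sites, n_samples))
    )
    total = _negbin(rng, mean_coverage, coverage_dispersion, (n_sites, n_samples))
    meth = rng.binomial(total, _sigmoid(eta))

    sample_ids = (
        list(predictors.index.astype(str))
        if predictors.index.nlevels == 1
        else [f"s{i}" for i in range(n_samples)]
    )
    counts = MethylationCounts(
        site_ids=site_ids, sample_ids=sample_ids, meth=meth, total=total
    )
    truth = betas.copy()
    truth.insert(0, "baseline_logit", baseline)
    truth["causal"] = (betas != 0).any(axis=1).astype(int)
    truth["sigma2_g"] = sigma2_g
    truth["sigma2_e"] = sigma2_e
    truth.index.name = "site_id"
    table = truth.reset_index()
    params = {
        "n_sites": n_sites,
        "sigma2_g": sigma2_g,
        "sigma2_e": sigma2_e,
        "mean_coverage": mean_coverage,
        "coverage_dispersion": coverage_dispersion,
        "causal_effects": {
            k: [int(v[0]), np.atleast_1d(v[1]).tolist()]
            for k, v in causal_effects.items()
        },
    }
    return counts, TruthTable(table=table, params=params, seed=seed)


def _draw_site_ids(rng, n_sites, chrom_lengths) -> list[str]:
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    assign = rng.choice(len(chroms), size=n_sites, p=probs)
    ids = set()
    out = []
    for a in assign:
        while True:
            pos = int(rng.integers(1, chrom_lengths[chroms[a]] + 1))
            sid = f"{chroms[a]}_{pos}"
            if sid not in ids:
                ids.add(sid)
                out.append(sid)
                break
    return sorted(out, key=lambda s: (s.rpartition("_")[0], int(s.rpartition("_")[2])))


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    chrom_lengths: dict[str, int] | None = None,
    densities: dict[str, float] | None = None,
    n_states: int = 15,
    seed: int = 0,
) -> tuple[dict[str, AnnotationTrack], AnnotationTrack, pd.DataFrame]:
    """Compartment tracks, a chromatin-state partition, and gene models.

    Returns (compartment_tracks, chromatin_track, gene_intervals).  The
    chromatin segmentation tiles each chromosome exactly; CpG-island shores
    flank each island by 2 kb; compartment genome fractions follow
    ``densities`` (defaults: promoter 2%, island 2%, enhancer 3%, gene
    body 35%).  Gene intervals are returned 1-based inclusive.
    """
    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    dens = {"promoter": 0.02, "cpg_island": 0.02, "enhancer": 0.03, "gene_body": 0.35}
    if densities:
        dens.update(densities)
    if any(not 0 < v < 1 for v in dens.values()):
        raise ValueError("densities must lie in (0, 1)")
    rng = _rng(seed, "annotations")

    state_rows = []
    for chrom, length in chrom_lengths.items():
        pos = 0
        while pos < length:
            seg = int(min(rng.integers(1000, 20000), length - pos))
            state = int(rng.integers(1, n_states + 1))
            state_rows.append((chrom, pos, pos + seg, f"state_{state:02d}"))
            pos += seg
    chromatin = AnnotationTrack(
        name="chromatin_15state",
        intervals=pd.DataFrame(
            state_rows, columns=["chrom", "start", "end", "label"]
        ),
    )

    def _scatter(name, frac, min_len, max_len):
        rows = []
        for chrom, length in chrom_lengths.items():
            target = frac * length
            covered = 0
            while covered < target:
                ln = int(rng.integers(min_len, max_len + 1))
                start = int(rng.integers(0, max(1, length - ln)))
                end = min(start + ln, length)
                rows.append((chrom, start, end, name))
                covered += end - start
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

    islands = _scatter("cpg_island", dens["cpg_island"], 300, 2000)
    shore_rows = []
    for chrom, start, end, _ in islands.itertuples(index=False):
        length = chrom_lengths[chrom]
        left = (max(0, start - 2000), start)
        right = (end, min(length, end + 2000))
        if left[0] < left[1]:
            shore_rows.append((chrom, *left, "shore"))
        if right[0] < right[1]:
            shore_rows.append((chrom, *right, "shore"))
    shores = pd.DataFrame(shore_rows, columns=["chrom", "start", "end", "label"])

    promoters = _scatter("promoter", dens["promoter"], 500, 2000)
    enhancers = _scatter("enhancer", dens["enhancer"], 200, 1500)
    genes = _scatter("gene_body", dens["gene_body"], 5000, 50000)
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    genes["label"] = [f"gene{i:04d}" for i in range(len(genes))]

    tracks = {
        "promoter": AnnotationTrack(name="promoter", intervals=promoters),
        "cpg_island": AnnotationTrack(name="cpg_island", intervals=islands),
        "shore": AnnotationTrack(name="shore", intervals=shores),
        "enhancer": AnnotationTrack(name="enhancer", intervals=enhancers),
        "gene_body": AnnotationTrack(
            name="gene_body",
            intervals=genes.assign(label="gene_body"),
        ),
    }
    gene_intervals = pd.DataFrame(
        {
            "gene_id": genes["label"],
            "chrom": genes["chrom"],
            "start": genes["start"] + 1,  # to 1-based inclusive
            "end": genes["end"],
        }
    )
    return tracks, chromatin, gene_intervals


# ---------------------------------------------------------------------------
# mSTARR windows


def simulate_mstarr(
    n_windows: int = 1000,
    n_active: int = 50,
    n_replicates: int = 6,
    unmeth_multiplier: float = 8.0,
    meth_multiplier: float = 1.0,
    dna_mean: float = 100.0,
    dispersion: float = 0.1,
    chrom: str = "chr1",
    seed: int = 0,
) -> tuple[MstarrData, TruthTable]:
    """Reporter-assay counts for 500-bp windows with planted activity.

    Inactive windows transcribe at the plasmid background rate (RNA mean =
    DNA mean x background).  Active windows multiply that rate by
    ``unmeth_multiplier`` in the unmethylated condition and
    ``meth_multiplier`` in the methylated condition, so the planted
    direction is repression-by-methylation whenever the unmethylated
    multiplier exceeds the methylated one.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = _rng(seed, "mstarr")
    active = np.zeros(n_windows, dtype=bool)
    active[rng.choice(n_windows, size=n_active, replace=False)] = True
    background = 0.1  # basal RNA/DNA rate for the plasmid library

    rows = []
    wids = [f"{chrom}:{i * 500}-{(i + 1) * 500}" for i in range(n_windows)]
    for i, wid in enumerate(wids):
        for cond, mult in ((METH, meth_multiplier), (UNMETH, unmeth_multiplier)):
            m = mult if active[i] else 1.0
            for rep in range(n_replicates):
                dna = _negbin(rng, dna_mean, dispersion, None)
                rna = _negbin(rng, dna_mean * background * m, dispersion, None)
                rows.append((wid, cond, rep, int(dna), int(rna)))
    counts = pd.DataFrame(
        rows, columns=["window_id", "condition", "replicate", "dna", "rna"]
    )
    dependent = active & (unmeth_multiplier != meth_multiplier)
    direction = np.where(
        dependent,
        np.where(
            unmeth_multiplier > meth_multiplier,
            "repressed_by_methylation",
            "enhanced_by_methylation",
        ),
        "none",
    )
    truth = pd.DataFrame(
        {
            "window_id": wids,
            "active": active.astype(int),
            "dependent": dependent.astype(int),
            "direction": direction,
        }
    )
    params = {
        "n_windows": n_windows,
        "n_active": n_active,
        "n_replicates": n_replicates,
        "unmeth_multiplier": unmeth_multiplier,
        "meth_multiplier": meth_multiplier,
        "dna_mean": dna_mean,
        "dispersion": dispersion,
    }
    return MstarrData(counts=counts), TruthTable(table=truth, params=params, seed=seed)


# ---------------------------------------------------------------------------
# expression effects


def simulate_expression(
    gene_intervals: pd.DataFrame,
    site_truth: pd.DataFrame,
    effect_term: str,
    anti_concordance_rate: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Gene-level expression effects opposing planted methylation effects.

    Genes whose body contains a causal CpG (for ``effect_term``) receive an
    expression effect whose sign opposes the methylation effect with
    probability ``anti_concordance_rate``; other genes get null effects.
    ``site_truth`` is the methylation truth table (site_id + per-term
    betas).
    """
    from .expression import map_sites_to_genes

    rng = _rng(seed, "expression")
    causal = site_truth[site_truth[effect_term] != 0]
    assign = map_sites_to_genes(list(causal["site_id"]), gene_intervals)
    meth_sign = (
        assign.merge(causal[["site_id", effect_term]], on="site_id")
        .groupby("gene_id")[effect_term]
        .apply(lambda b: float(np.sign(b.mean())))
    )
    rows = []
    truth_rows = []
    for g in gene_intervals["gene_id"]:
        if g in meth_sign.index and meth_sign[g] != 0:
            opposite = rng.random() < anti_concordance_rate
            sign = -meth_sign[g] if opposite else meth_sign[g]
            beta = sign * abs(rng.normal(1.0, 0.2))
            q = float(rng.uniform(0.0, 0.05))
            causal_flag = 1
        else:
            beta = rng.normal(0.0, 0.1)
            q = float(rng.uniform(0.2, 1.0))
            causal_flag = 0
        rows.append(
            {
                "gene_id": g,
                "beta_expr": float(beta),
                "se": 0.2,
                "q": q,
                "expressed": 1,
            }
        )
        truth_rows.append({"gene_id": g, "causal": causal_flag})
    effects = pd.DataFrame(rows)
    truth = TruthTable(
        table=pd.DataFrame(truth_rows),
        params={"anti_concordance_rate": anti_concordance_rate,
                "effect_term": effect_term},
        seed=seed,
    )
    return effects, truth


def simulate_gene_sets(
    genes: list[str], n_sets: int = 10, set_size: int = 30, seed: int = 0
) -> dict[str, set[str]]:
    """Random gene sets over a gene universe (GMT-style)."""
    rng = _rng(seed, "gene_sets")
    genes = list(genes)
    return {
        f"SET_{i:02d}": set(
            rng.choice(genes, size=min(set_size, len(genes)), replace=False)
        )
        for i in range(n_sets)
    }
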