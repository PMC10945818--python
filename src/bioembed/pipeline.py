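"""End-to-end pipeline: simulate -> QC -> scans -> enrichment -> prediction
-> reporter-assay calls -> expression concordance.

Every stage writes its outputs before the next begins; a JSON manifest
records the seed, a hash of the configuration, and per-stage row counts.
Reruns with an identical configuration produce byte-identical files.  The
genome scan caches its results keyed on the scan-relevant configuration,
so threshold-only changes (FDR cutoffs are applied downstream of the scan)
reuse the fitted site results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from . import enrichment as enr
from . import expression as expr
from . import lifehistory as lh
from . import mstarr as ms
from . import predict as pred
from . import qc as qcmod
from . import simulate as sim
from .glmm import ModelSpec, scan

STAGES = (
    "simulate",
    "qc",
    "adversity",
    "scan",
    "enrich",
    "predict",
    "mstarr",
    "concordance",
)


@dataclass
class RunConfig:
    """All knobs for one pipeline run."""

    outdir: str = "results"
    seed: int = 0
    # simulation scale (kept minutes-scale; generators accept larger)
    n_individuals: int = 60
    fraction_low_habitat: float = 0.25
    n_sites: int = 400
    n_mstarr_windows: int = 1000
    n_gene_sets: int = 10
    shift_date: str = "1992-01-01"
    sigma2_g: float = 0.3
    sigma2_e: float = 0.2
    mean_coverage: float = 30.0
    # planted effects: habitat cohort effect + adversity nested in low habitat
    habitat_effect: float = 0.8
    habitat_n_causal: int = 40
    adversity_low_effect: float = 0.5
    adversity_low_n_causal: int = 20
    # QC
    min_cov: int = 5
    min_fraction_samples: float = 0.5
    hypo_cut: float = 0.10
    hyper_cut: float = 0.90
    # models and thresholds
    model_ids: tuple[int, ...] = (1, 2, 3)
    primary_fdr: float = 0.10
    secondary_fdr: float = 0.20
    # elastic net
    en_mixing: float = 0.5
    en_penalties: int = 50
    en_inner_folds: int = 5
    # mSTARR
    mstarr_alpha_fdr: float = 0.10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for thr in (self.primary_fdr, self.secondary_fdr):
            if not 0 < thr < 1:
                raise ValueError("FDR thresholds must lie in (0, 1)")
        if self.primary_fdr > self.secondary_fdr:
            raise ValueError("primary FDR must be <= secondary FDR")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def scan_hash(self) -> str:
        """Hash over scan-relevant fields only (thresholds excluded)."""
        d = asdict(self)
        for k in ("primary_fdr", "secondary_fdr", "mstarr_alpha_fdr",
                  "log_level", "outdir"):
            d.pop(k)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_dataset(config: RunConfig) -> dict:
    """Load and cross-validate the simulated input bundle from disk."""
    out = Path(config.outdir)
    inp = out / "inputs"
    bundle = {
        "life_history": bio.read_tsv(inp / "life_history.tsv"),
        "samples": bio.read_tsv(inp / "samples.tsv"),
        "ranks": bio.read_tsv(inp / "ranks_by_month.tsv"),
        "kinship": bio.read_kinship(inp / "kinship.tsv"),
        "counts": bio.read_counts(inp / "meth.tsv", inp / "total.tsv"),
        "mstarr": bio.read_mstarr(inp / "mstarr_counts.tsv"),
        "genes": bio.read_gtf_genes(inp / "genes.gtf"),
        "gene_sets": bio.read_gmt(inp / "gene_sets.gmt"),
        "expression": bio.read_tsv(inp / "expression_effects.tsv"),
    }
    inds = set(bundle["life_history"]["individual_id"])
    kin_ids = set(bundle["kinship"].individual_ids)
    missing = inds - kin_ids
    if missing:
        raise ValueError(f"individuals missing from kinship: {sorted(missing)}")
    samp_inds = set(bundle["samples"]["individual_id"])
    unknown = samp_inds - inds
    if unknown:
        raise ValueError(f"samples reference unknown individuals: {sorted(unknown)}")
    if set(bundle["counts"].sample_ids) != set(bundle["samples"]["sample_id"]):
        raise ValueError("count matrix samples disagree with sample table")
    return bundle


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages (default: all) and write a manifest."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out = Path(config.outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": asdict(config),
        "stages": {},
    }
    try:
        for stage in STAGES:
            if stage in stages:
                counts = _STAGE_FUNCS[stage](config)
                manifest["stages"][stage] = {"status": "ok", **counts}
                _write_manifest(out, manifest)
    except Exception as exc:  # partial outputs retained for inspection
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest(out, manifest)
        raise
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    bio.write_json(manifest, out / "manifest.json")


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig) -> dict:
    out = Path(config.outdir) / "inputs"
    shift = date.fromisoformat(config.shift_date)
    seed = config.seed

    # grow founders until the pedigree covers the cohort (pedigree sets
    # relatedness, the cohort sets life history; sexes reused for coherence)
    n_founders = max(10, config.n_individuals // 3)
    for _ in range(8):
        ped, kin = sim.simulate_pedigree(
            n_founders=n_founders, n_generations=3, seed=seed
        )
        if len(kin.individual_ids) >= config.n_individuals:
            break
        n_founders *= 2
    else:
        raise ValueError("pedigree smaller than requested cohort")
    # most recent pedigree members: descendants carry the family structure
    ids = kin.individual_ids[-config.n_individuals :]
    sexes = list(ped.set_index("individual_id").loc[ids, "sex"])
    sub = ped.set_index("individual_id").index.get_indexer(ids)
    kin_sub = sim.KinshipMatrix(
        individual_ids=ids, K=kin.K[np.ix_(sub, sub)]
    )
    cohort = sim.simulate_cohort(
        n_individuals=config.n_individuals,
        shift_date=shift,
        fraction_low_habitat=config.fraction_low_habitat,
        seed=seed,
        individual_ids=ids,
        sexes=sexes,
    )
    samples, ranks = sim.simulate_samples(cohort, shift_date=shift, seed=seed)

    # covariates needed to express the planted (nested) effects
    records = lh.records_from_frame(cohort)
    profiles = lh.score_cohort(records, shift)
    covariates = lh.build_sample_covariates(samples, records, ranks, shift)
    covariates = covariates.merge(
        profiles.drop(columns="habitat_low_quality_at_birth"),
        on="individual_id",
    )
    low = covariates["habitat_low_quality_at_birth"].to_numpy(float)
    cum = covariates["cumulative"].astype(float).fillna(0.0).to_numpy()
    predictors = pd.DataFrame(
        {
            "habitat_low": low,
            "adversity_low": cum * low,
        },
        index=covariates["sample_id"],
    )
    K_samples = sim.np.asarray(
        sim.KinshipMatrix(
            individual_ids=kin_sub.individual_ids, K=kin_sub.K
        ).K
    )
    from .glmm import expand_kinship

    K_exp = expand_kinship(kin_sub, list(covariates["individual_id"]))
    counts, meth_truth = sim.simulate_methylation(
        K_exp,
        predictors,
        n_sites=config.n_sites,
        causal_effects={
            "habitat_low": (config.habitat_n_causal, config.habitat_effect),
            "adversity_low": (
                config.adversity_low_n_causal,
                config.adversity_low_effect,
            ),
        },
        sigma2_g=config.sigma2_g,
        sigma2_e=config.sigma2_e,
        mean_coverage=config.mean_coverage,
        seed=seed,
    )
    tracks, chromatin, genes = sim.simulate_annotations(seed=seed)
    mstarr_data, mstarr_truth = sim.simulate_mstarr(
        n_windows=config.n_mstarr_windows, seed=seed
    )
    expr_effects, expr_truth = sim.simulate_expression(
        genes, meth_truth.table, effect_term="adversity_low", seed=seed
    )
    gene_sets = sim.simulate_gene_sets(
        list(genes["gene_id"]), n_sets=config.n_gene_sets, seed=seed
    )

    bio.write_tsv(cohort, out / "life_history.tsv")
    bio.write_tsv(samples, out / "samples.tsv")
    bio.write_tsv(ranks, out / "ranks_by_month.tsv")
    bio.write_kinship(kin_sub, out / "kinship.tsv")
    bio.write_counts(counts, out / "meth.tsv", out / "total.tsv")
    for name, track in tracks.items():
        bio.write_bed(track, out / f"track_{name}.bed")
    bio.write_bed(chromatin, out / "track_chromatin.bed")
    bio.write_gtf(genes, out / "genes.gtf")
    bio.write_mstarr(mstarr_data, out / "mstarr_counts.tsv")
    bio.write_tsv(expr_effects, out / "expression_effects.tsv")
    bio.write_gmt(gene_sets, out / "gene_sets.gmt")
    bio.write_tsv(meth_truth.table, out / "truth_methylation.tsv")
    bio.write_tsv(mstarr_truth.table, out / "truth_mstarr.tsv")
    bio.write_tsv(expr_truth.table, out / "truth_expression.tsv")
    bio.write_json(
        {
            "seed": seed,
            "methylation": meth_truth.params,
            "mstarr": mstarr_truth.params,
            "expression": expr_truth.params,
        },
        out / "truth_params.json",
    )
    bio.write_tsv(covariates, out / "covariates.tsv")
    return {
        "n_individuals": len(cohort),
        "n_samples": len(samples),
        "n_sites": counts.n_sites,
        "n_windows": config.n_mstarr_windows,
    }


def _stage_qc(config: RunConfig) -> dict:
    out = Path(config.outdir)
    counts = bio.read_counts(out / "inputs/meth.tsv", out / "inputs/total.tsv")
    filtered, report = qcmod.filter_sites(
        counts,
        min_cov=config.min_cov,
        min_fraction_samples=config.min_fraction_samples,
        hypo_cut=config.hypo_cut,
        hyper_cut=config.hyper_cut,
    )
    bio.write_counts(filtered, out / "meth_filtered.tsv", out / "total_filtered.tsv")
    bio.write_json(report.to_dict(), out / "filter_report.json")
    return {"n_input": report.n_input, "n_retained": report.n_retained}


def _stage_adversity(config: RunConfig) -> dict:
    out = Path(config.outdir)
    shift = date.fromisoformat(config.shift_date)
    cohort = bio.read_tsv(out / "inputs/life_history.tsv").fillna("")
    records = lh.records_from_frame(cohort)
    profiles = lh.score_cohort(records, shift)
    bio.write_tsv(profiles, out / "adversity_profiles.tsv")
    return {"n_individuals": len(profiles)}


def _covariates(config: RunConfig) -> pd.DataFrame:
    out = Path(config.outdir)
    return bio.read_tsv(out / "inputs/covariates.tsv")


def _stage_scan(config: RunConfig) -> dict:
    out = Path(config.outdir)
    cache_key = {"scan_hash": config.scan_hash()}
    cache_path = out / "scan_cache.json"
    if cache_path.exists():
        cached = bio.read_json(cache_path)
        if cached == cache_key and all(
            (out / f"scan_model{m}.tsv").exists() for m in config.model_ids
        ):
            return {
                "cached": True,
                **{
                    f"model{m}_rows": len(bio.read_tsv(out / f"scan_model{m}.tsv"))
                    for m in config.model_ids
                },
            }
    counts = bio.read_counts(out / "meth_filtered.tsv", out / "total_filtered.tsv")
    covariates = _covariates(config)
    kinship = bio.read_kinship(out / "inputs/kinship.tsv")
    info = {}
    for m in config.model_ids:
        res = scan(counts, ModelSpec(model_id=m), covariates, kinship)
        bio.write_tsv(res, out / f"scan_model{m}.tsv")
        info[f"model{m}_rows"] = len(res)
    bio.write_json(cache_key, cache_path)
    return {"cached": False, **info}


def _term_results(config: RunConfig, model_id: int, term: str) -> pd.DataFrame:
    out = Path(config.outdir)
    res = bio.read_tsv(out / f"scan_model{model_id}.tsv")
    sub = res[(res["term"] == term) & res["converged"]]
    return sub[["site_id", "beta", "se", "z", "p", "q"]].reset_index(drop=True)


def _stage_enrich(config: RunConfig) -> dict:
    out = Path(config.outdir)
    model = 2 if 2 in config.model_ids else config.model_ids[0]
    habitat = _term_results(config, model, "habitat_low")
    background = list(habitat["site_id"])
    tracks = {
        name: bio.read_bed(out / f"inputs/track_{name}.bed", name)
        for name in ("promoter", "cpg_island", "shore", "enhancer", "gene_body")
    }
    chromatin = bio.read_bed(out / "inputs/track_chromatin.bed", "chromatin")
    ann = enr.annotate_sites(background, tracks, chromatin)
    bio.write_tsv(ann, out / "site_annotations.tsv")

    hits = set(habitat.loc[habitat["q"] <= config.primary_fdr, "site_id"])
    rows = []
    comp = enr.compartment_enrichment(
        hits, background, ann.set_index("site_id")["compartment"]
    )
    state = enr.compartment_enrichment(
        hits, background, ann.set_index("site_id")["chromatin_state"].fillna("none")
    )
    for res in comp + state:
        rows.append(
            {
                "category": res.category,
                "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                "log2_or": res.log2_or,
                "p": res.p,
                "defined": res.defined,
            }
        )
    bio.write_tsv(pd.DataFrame(rows), out / "enrichment_compartments.tsv")

    overlap_summary = {}
    if model == 2:
        adv = _term_results(config, 2, "adversity_low")
        shared = set(habitat["site_id"]) & set(adv["site_id"])
        ha = habitat[habitat["site_id"].isin(shared)]
        ad = adv[adv["site_id"].isin(shared)]
        ov = enr.overlap_and_concordance(
            ha, ad, config.primary_fdr, config.secondary_fdr
        )
        overlap_summary = {
            "n_overlap": ov["n_overlap"],
            "concordance": ov["concordance"],
            "overlap_log2_or": ov["overlap_fet"].log2_or,
            "overlap_p": ov["overlap_fet"].p,
        }
        bio.write_json(overlap_summary, out / "overlap_concordance.json")

    genes = bio.read_gtf_genes(out / "inputs/genes.gtf")
    gene_sets = bio.read_gmt(out / "inputs/gene_sets.gmt")
    assign = expr.map_sites_to_genes(background, genes)
    hit_genes = set(assign.loc[assign["site_id"].isin(hits), "gene_id"])
    bg_genes = set(assign["gene_id"])
    if bg_genes:
        gse = enr.gene_set_enrichment(hit_genes, bg_genes, gene_sets)
        bio.write_tsv(gse, out / "gene_set_enrichment.tsv")
    return {
        "n_hits": len(hits),
        "n_background": len(background),
        **overlap_summary,
    }


def _stage_predict(config: RunConfig) -> dict:
    out = Path(config.outdir)
    counts = bio.read_counts(out / "meth_filtered.tsv", out / "total_filtered.tsv")
    covariates = _covariates(config).set_index("sample_id")
    covariates = covariates.loc[counts.sample_ids]
    frac = qcmod.methylation_fraction(counts)
    labels = np.where(
        covariates["habitat_low_quality_at_birth"].to_numpy() == 1, "low", "high"
    )
    preds = pred.loo_elastic_net(
        frac,
        labels,
        sample_ids=counts.sample_ids,
        mixing=config.en_mixing,
        n_penalties=config.en_penalties,
        inner_folds=config.en_inner_folds,
        seed=config.seed,
    )
    bio.write_tsv(preds, out / "habitat_predictions.tsv")
    auc, curve = pred.roc_auc(preds["score"], preds["true_label"])
    bio.write_tsv(curve, out / "roc_curve.tsv")

    lowmask = preds["true_label"] == "low"
    result = {"auc": auc, "n_low": int(lowmask.sum())}
    if lowmask.sum() >= 3:
        lowpred = preds[lowmask].reset_index(drop=True)
        cov_low = covariates.loc[lowpred["sample_id"]]
        days = cov_low["days_since_habitat_shift"].to_numpy(float)
        # cumulative time in the low-quality habitat = age until the shift
        age_days = cov_low["age_at_sampling"].to_numpy(float) * 365.25
        cum_low = np.minimum(age_days, age_days - days)
        try:
            att = pred.attenuation_test(
                lowpred, days, cum_low, age=cov_low["age_at_sampling"].to_numpy()
            )
            result["attenuation"] = {
                k: {"slope": v.slope, "se": v.se, "p": v.p} for k, v in att.items()
            }
        except ValueError:
            result["attenuation"] = None
    bio.write_json(result, out / "prediction_summary.json")
    return {"auc": auc, "n_samples": len(preds)}


def _stage_mstarr(config: RunConfig) -> dict:
    out = Path(config.outdir)
    data = bio.read_mstarr(out / "inputs/mstarr_counts.tsv")
    calls = ms.call_windows(data, alpha_fdr=config.mstarr_alpha_fdr)
    bio.write_tsv(calls, out / "mstarr_calls.tsv")
    model = 2 if 2 in config.model_ids else config.model_ids[0]
    site_res = _term_results(config, model, "habitat_low")
    overlap = ms.regulatory_overlap_enrichment(
        calls,
        site_res,
        data.window_bounds(),
        fdr_grid=[0.05, config.primary_fdr, config.secondary_fdr],
    )
    bio.write_tsv(overlap, out / "mstarr_overlap_enrichment.tsv")
    return {
        "n_windows": len(calls),
        "n_regulatory": int(calls["regulatory"].sum()),
        "n_dependent": int(calls["methylation_dependent"].sum()),
    }


def _stage_concordance(config: RunConfig) -> dict:
    out = Path(config.outdir)
    model = 2 if 2 in config.model_ids else config.model_ids[0]
    site_res = _term_results(config, model, "adversity_low" if model == 2 else "habitat_low")
    genes = bio.read_gtf_genes(out / "inputs/genes.gtf")
    effects = bio.read_tsv(out / "inputs/expression_effects.tsv")
    assign = expr.map_sites_to_genes(list(site_res["site_id"]), genes)

    sig_genes = set(
        assign.loc[
            assign["site_id"].isin(
                set(site_res.loc[site_res["q"] <= config.secondary_fdr, "site_id"])
            ),
            "gene_id",
        ]
    )
    report: dict = {}
    if sig_genes:
        d_hits = expr.distance_to_genes(
            list(site_res.loc[site_res["q"] <= config.secondary_fdr, "site_id"]),
            genes,
            sig_genes,
        )
        d_bg = expr.distance_to_genes(list(site_res["site_id"]), genes, sig_genes)
        finite_h = d_hits[np.isfinite(d_hits)]
        finite_b = d_bg[np.isfinite(d_bg)]
        if len(finite_h) and len(finite_b):
            D, p = expr.ks_distance_test(finite_h, finite_b)
            report["ks"] = {"D": D, "p": p}
    try:
        conc = expr.sign_concordance(
            site_res.rename(columns={"p": "p"}),
            effects,
            assign,
            site_sig=(site_res.set_index("site_id")["q"] <= config.secondary_fdr),
        )
        report["sign_concordance"] = {
            "n_genes": conc["n_genes"],
            "concordant_fraction": conc["concordant_fraction"],
            "log2_or": conc["sign_fet"].log2_or,
            "p": conc["sign_fet"].p,
            "fold_enrichment": conc["fold_enrichment"],
        }
    except ValueError as exc:
        report["sign_concordance"] = {"error": str(exc)}
    bio.write_json(report, out / "concordance_report.json")
    n_genes = report.get("sign_concordance", {}).get("n_genes", 0)
    return {"n_genes": n_genes if isinstance(n_genes, int) else 0}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "adversity": _stage_adversity,
    "scan": _stage_scan,
    "enrich": _stage_enrich,
    "predict": _stage_predict,
    "mstarr": _stage_mstarr,
    "concordance": _stage_concordance,
}
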