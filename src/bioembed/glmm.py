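"""Per-CpG binomial mixed models with a genetic-relatedness random effect.

The counts at one site are modelled as

    m_i ~ Binomial(r_i, pi_i),   logit(pi_i) = x_i' beta + u_i,
    u ~ MVN(0, sigma2_g * K + sigma2_e * I),

where ``K`` is the kinship (genetic relatedness) matrix expanded to sample
level, ``sigma2_g`` captures genetic / pedigree-structured variation on the
logit scale and ``sigma2_e`` captures residual, sample-specific
overdispersion.  Narrow-sense heritability of the latent methylation level
is ``h2 = sigma2_g / (sigma2_g + sigma2_e)``.

Inference uses a Laplace approximation to the marginal likelihood: for a
candidate variance pair the fixed effects and random effects are jointly
maximised by Newton's method, and the two variance components are then
optimised by Nelder-Mead on the log scale.  Wald tests per focal term use
``Var(beta) = (X' V^-1 X)^-1`` with ``V = W^-1 + Sigma`` evaluated at the
optimum.  With both variance components fixed at zero the model collapses
to an ordinary binomial GLM fitted by iteratively reweighted least squares.

The genome scan API mirrors the three nested designs used in the study:

* Model 1 — habitat quality at birth + cumulative early adversity + age +
  sex-nested dominance rank + technical covariates (samples with missing
  rank excluded);
* Model 2 — as Model 1 but cumulative adversity nested within habitat
  quality (missing-rank samples retained);
* Model 3 — as Model 2 but each of the five adversity components nested
  within habitat quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

VAR_FLOOR = 1e-6
VAR_CEIL = 50.0

ADVERSITY_COMPONENTS = (
    "drought",
    "maternal_loss",
    "close_sibling",
    "low_maternal_rank",
    "large_group",
)


# ---------------------------------------------------------------------------
# kinship


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix over individuals (diagonal >= 1)."""

    individual_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.individual_ids)
        if self.K.shape != (n, n):
            raise ValueError("kinship matrix shape inconsistent with ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        if np.any(np.diag(self.K) < 1 - 1e-8):
            raise ValueError("kinship diagonal entries must be >= 1")
        if np.any(self.K < -1e-10):
            raise ValueError("kinship entries must be non-negative")
        eigmin = float(np.linalg.eigvalsh(self.K)[0])
        if eigmin < -1e-8:
            raise ValueError(f"kinship matrix not PSD (eigmin={eigmin:.3g})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.K, index=self.individual_ids, columns=self.individual_ids
        )


def expand_kinship(
    kinship: KinshipMatrix, sample_to_individual: list[str]
) -> np.ndarray:
    """Expand an individual-level kinship matrix to sample level.

    Repeated samples from one individual share that individual's row and
    column, so they get its diagonal value for their mutual relatedness.
    """
    pos = {ind: i for i, ind in enumerate(kinship.individual_ids)}
    try:
        idx = np.array([pos[s] for s in sample_to_individual])
    except KeyError as exc:
        raise KeyError(f"sample maps to unknown individual {exc}") from None
    return kinship.K[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# design construction


@dataclass
class ModelSpec:
    """One of the three nested fixed-effect designs (model_id 1, 2, or 3)."""

    model_id: int

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")

    @property
    def focal_terms(self) -> list[str]:
        if self.model_id == 1:
            return [
                "habitat_low",
                "cumulative",
                "age",
                "female_rank",
                "male_rank",
            ]
        if self.model_id == 2:
            return [
                "habitat_low",
                "adversity_low",
                "adversity_high",
                "age",
                "female_rank",
                "male_rank",
            ]
        terms = ["habitat_low"]
        for comp in ADVERSITY_COMPONENTS:
            terms += [f"{comp}_low", f"{comp}_high"]
        terms += ["age", "female_rank", "male_rank"]
        return terms


@dataclass
class DesignInfo:
    """Design matrix plus bookkeeping from :func:`build_design`."""

    X: pd.DataFrame
    focal_terms: list[str]
    dropped_samples: list[str]
    dropped_columns: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)


def build_design(spec: ModelSpec, covariates: pd.DataFrame) -> DesignInfo:
    """Build the fixed-effect design for one model.

    ``covariates`` holds one row per sample (indexed or keyed by
    ``sample_id``) with the merged sample covariates and adversity profile:
    habitat_low_quality_at_birth, cumulative, the five component flags,
    age_at_sampling, rank_at_sampling, sex, batch, conversion_rate,
    mean_depth.

    Nested terms are coded as value x group indicator (e.g.
    ``adversity_low = cumulative * 1[habitat == low]``); rank is nested in
    sex and no sex main effect is included.  Model 1 drops samples with a
    missing rank; Models 2-3 keep them, mean-imputing rank within sex.
    Samples with a missing adversity score are dropped for every model.
    Aliased (zero or linearly dependent) columns are dropped with a
    warning; focal terms among them are simply absent from the result.
    """
    cov = covariates.copy()
    if "sample_id" in cov.columns:
        cov = cov.set_index("sample_id")

    dropped_samples: list[str] = []
    need_score = (
        ["cumulative"] if spec.model_id in (1, 2) else list(ADVERSITY_COMPONENTS)
    )
    bad = cov[need_score].isna().any(axis=1)
    if bad.any():
        dropped_samples += list(cov.index[bad])
        cov = cov[~bad]

    rank = pd.to_numeric(cov["rank_at_sampling"], errors="coerce").astype(float)
    if spec.model_id == 1:
        missing_rank = rank.isna()
        if missing_rank.any():
            dropped_samples += list(cov.index[missing_rank])
            cov = cov[~missing_rank]
            rank = rank[~missing_rank]
    else:
        for sex in ("female", "male"):
            m = (cov["sex"] == sex) & rank.isna()
            if m.any():
                fill = rank[(cov["sex"] == sex) & ~rank.isna()].mean()
                rank[m] = 0.0 if np.isnan(fill) else fill

    low = cov["habitat_low_quality_at_birth"].astype(float)
    high = 1.0 - low
    X = pd.DataFrame(index=cov.index)
    X["intercept"] = 1.0
    X["habitat_low"] = low
    if spec.model_id == 1:
        X["cumulative"] = cov["cumulative"].astype(float)
    elif spec.model_id == 2:
        X["adversity_low"] = cov["cumulative"].astype(float) * low
        X["adversity_high"] = cov["cumulative"].astype(float) * high
    else:
        for comp in ADVERSITY_COMPONENTS:
            X[f"{comp}_low"] = cov[comp].astype(float) * low
            X[f"{comp}_high"] = cov[comp].astype(float) * high
    X["age"] = cov["age_at_sampling"].astype(float)
    X["female_rank"] = rank.to_numpy() * (cov["sex"] == "female").to_numpy()
    X["male_rank"] = rank.to_numpy() * (cov["sex"] == "male").to_numpy()

    # technical covariates: batch one-hot (reference level dropped) + scalars
    if "batch" in cov.columns:
        batches = sorted(map(str, cov["batch"].unique()))
        for b in batches[1:]:
            X[f"batch_{b}"] = (cov["batch"].astype(str) == b).astype(float)
    for tech in ("conversion_rate", "mean_depth"):
        if tech in cov.columns:
            X[tech] = cov[tech].astype(float)

    X, dropped_columns = _drop_aliased(X)
    if "intercept" not in X.columns:
        raise ValueError("design degenerate: intercept aliased away")
    focal = [t for t in spec.focal_terms if t in X.columns]
    return DesignInfo(
        X=X,
        focal_terms=focal,
        dropped_samples=dropped_samples,
        dropped_columns=dropped_columns,
    )


def _drop_aliased(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop constant-zero and linearly dependent columns (QR pivoting)."""
    dropped = [c for c in X.columns if c != "intercept" and (X[c] == 0).all()]
    X = X.drop(columns=dropped)
    A = X.to_numpy(dtype=float)
    # scale columns so pivoting is not driven by units
    scale = np.abs(A).max(axis=0)
    scale[scale == 0] = 1.0
    _, R = np.linalg.qr(A / scale)
    diag = np.abs(np.diag(R))
    rank = int((diag > 1e-8 * max(diag.max(), 1.0)).sum())
    if rank < A.shape[1]:
        keep_idx: list[int] = []
        for j in range(A.shape[1]):
            cand = A[:, keep_idx + [j]]
            if np.linalg.matrix_rank(cand / scale[keep_idx + [j]]) > len(keep_idx):
                keep_idx.append(j)
        dep = [X.columns[j] for j in range(A.shape[1]) if j not in keep_idx]
        dropped += dep
        X = X.iloc[:, keep_idx]
    if dropped:
        warnings.warn(f"dropped aliased design columns: {dropped}", stacklevel=3)
    return X, dropped


# ---------------------------------------------------------------------------
# model / results objects


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class BinomialMixedModel:
    """Binomial mixed model for one CpG site.

    Parameters
    ----------
    meth, total
        Methylated and total read counts per sample.  Samples with zero
        total count are dropped.
    exog
        Fixed-effect design matrix (DataFrame or array; must include an
        intercept column if one is wanted).
    kinship
        Sample-level relatedness matrix (symmetric PSD).  ``None`` means
        the identity.
    """

    def __init__(
        self,
        meth: np.ndarray,
        total: np.ndarray,
        exog: pd.DataFrame | np.ndarray,
        kinship: np.ndarray | None = None,
    ) -> None:
        meth = np.asarray(meth, dtype=float)
        total = np.asarray(total, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{j}" for j in range(X.shape[1])]
        if meth.shape != total.shape or X.shape[0] != meth.shape[0]:
            raise ValueError("inconsistent dimensions")
        if np.any(meth > total) or np.any(meth < 0):
            raise ValueError("require 0 <= meth <= total")
        keep = total > 0
        self.meth = meth[keep]
        self.total = total[keep]
        self.X = X[keep]
        self.nobs = int(keep.sum())
        if self.nobs <= self.X.shape[1]:
            raise ValueError("fewer covered samples than design columns")
        if kinship is None:
            self.K = np.eye(self.nobs)
        else:
            K = np.asarray(kinship, dtype=float)
            if K.shape[0] != meth.shape[0]:
                raise ValueError("kinship dimension mismatch")
            self.K = K[np.ix_(keep, keep)]
            eigmin = float(np.linalg.eigvalsh(self.K)[0])
            if eigmin < -1e-8:
                raise ValueError("kinship matrix not PSD")
        # eigendecomposition reused across variance-component evaluations
        lam, U = np.linalg.eigh(self.K)
        self._lam = np.clip(lam, 0.0, None)
        self._U = U

    # -- likelihood machinery -------------------------------------------

    def _penalized_loglik(self, beta, b, Sigma_inv):
        eta = self.X @ beta + b
        ll = float(np.sum(self.meth * eta - self.total * np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(b @ (Sigma_inv @ b))

    def _inner_newton(self, Sigma_inv, beta0, b0, tol=1e-8, maxiter=50):
        """Joint Newton maximisation of the penalized log-likelihood."""
        n, p = self.nobs, self.X.shape[1]
        beta, b = beta0.copy(), b0.copy()
        f = self._penalized_loglik(beta, b, Sigma_inv)
        W = None
        for _ in range(maxiter):
            eta = self.X @ beta + b
            pi = _sigmoid(eta)
            W = np.clip(self.total * pi * (1.0 - pi), 1e-10, None)
            resid = self.meth - self.total * pi
            g = np.concatenate([self.X.T @ resid, resid - Sigma_inv @ b])
            H = np.empty((p + n, p + n))
            XtW = self.X.T * W
            H[:p, :p] = XtW @ self.X
            H[:p, p:] = XtW
            H[p:, :p] = XtW.T
            H[p:, p:] = Sigma_inv + np.diag(W)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                step = np.linalg.solve(H, g)
            t = 1.0
            for _ in range(30):
                beta_new = beta + t * step[:p]
                b_new = b + t * step[p:]
                f_new = self._penalized_loglik(beta_new, b_new, Sigma_inv)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            moved = f_new - f
            beta, b, f = beta_new, b_new, f_new
            if abs(moved) < tol * (1.0 + abs(f)):
                return beta, b, f, W, True
        return beta, b, f, W, False

    def _laplace_negloglik(self, sg2, se2, state):
        d = sg2 * self._lam + se2
        Sigma_inv = (self._U / d) @ self._U.T
        beta, b, f, W, ok = self._inner_newton(Sigma_inv, state["beta"], state["b"])
        if ok:
            state["beta"], state["b"] = beta, b
        A = Sigma_inv + np.diag(W)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        ll = f - 0.5 * float(np.sum(np.log(d))) - 0.5 * logdet_A
        return -ll

    # -- public API ------------------------------------------------------

    def fit(
        self,
        fix_sigma_g: float | None = None,
        fix_sigma_e: float | None = None,
        start_var: float = 0.1,
        maxiter: int = 100,
        tol: float = 1e-6,
    ) -> "BinomialMixedModelResults":
        """Fit by Laplace approximation.

        ``fix_sigma_g`` / ``fix_sigma_e`` pin a variance component instead
        of estimating it; fixing both at zero reduces the fit to a plain
        binomial GLM (exact IRLS path).
        """
        p = self.X.shape[1]
        if fix_sigma_g == 0.0 and fix_sigma_e == 0.0:
            return self._fit_glm(maxiter=maxiter, tol=tol)

        state = {"beta": np.zeros(p), "b": np.zeros(self.nobs)}
        # crude starting beta from the marginal logit of the pooled fraction
        pbar = np.clip(self.meth.sum() / self.total.sum(), 1e-4, 1 - 1e-4)
        if "intercept" in self.exog_names:
            state["beta"][self.exog_names.index("intercept")] = np.log(
                pbar / (1 - pbar)
            )

        free: list[str] = []
        if fix_sigma_g is None:
            free.append("g")
        if fix_sigma_e is None:
            free.append("e")

        def unpack(theta):
            vals = dict(
                zip(
                    free,
                    np.exp(np.clip(theta, np.log(VAR_FLOOR), np.log(VAR_CEIL))),
                )
            )
            sg2 = vals.get("g", max(fix_sigma_g or 0.0, 1e-12))
            se2 = vals.get("e", max(fix_sigma_e or 0.0, 1e-12))
            return sg2, se2

        converged = True
        if free:
            def obj(theta):
                sg2, se2 = unpack(theta)
                return self._laplace_negloglik(sg2, se2, state)

            x0 = np.full(len(free), np.log(start_var))
            # log-variance accuracy of ~1e-3 is far below the statistical
            # noise in the variance components; fatol is on the loglik scale
            res = optimize.minimize(
                obj,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-2, "fatol": 1e-4, "maxiter": maxiter * 2},
            )
            sg2, se2 = unpack(res.x)
            # a flat final simplex (e.g. the sg2/se2 ridge when kinship is
            # near-identity) is a converged fit even if xatol never trips
            fvals = res.final_simplex[1]
            converged = bool(res.success) or float(
                np.max(fvals) - np.min(fvals)
            ) < 5e-3
        else:
            sg2, se2 = max(fix_sigma_g, 1e-12), max(fix_sigma_e, 1e-12)

        d = sg2 * self._lam + se2
        Sigma_inv = (self._U / d) @ self._U.T
        beta, b, f, W, ok = self._inner_newton(Sigma_inv, state["beta"], state["b"])
        converged = converged and ok
        neg_ll = self._laplace_negloglik(sg2, se2, {"beta": beta, "b": b})

        # Wald covariance of beta: (X' V^-1 X)^-1, V = W^-1 + Sigma
        Sigma = (self._U * d) @ self._U.T
        V = Sigma + np.diag(1.0 / W)
        Vinv_X = np.linalg.solve(V, self.X)
        cov_beta = np.linalg.inv(self.X.T @ Vinv_X)
        return BinomialMixedModelResults(
            model=self,
            params=beta,
            cov_params=cov_beta,
            random_effects=b,
            sigma2_g=float(sg2),
            sigma2_e=float(se2),
            loglike=-float(neg_ll),
            converged=converged,
        )

    def _fit_glm(self, maxiter=100, tol=1e-6):
        """Plain binomial GLM via IRLS (no random effects)."""
        n, p = self.nobs, self.X.shape[1]
        beta = np.zeros(p)
        pbar = np.clip(self.meth.sum() / self.total.sum(), 1e-4, 1 - 1e-4)
        if "intercept" in self.exog_names:
            beta[self.exog_names.index("intercept")] = np.log(pbar / (1 - pbar))
        converged = False
        for _ in range(maxiter):
            eta = self.X @ beta
            pi = _sigmoid(eta)
            W = np.clip(self.total * pi * (1.0 - pi), 1e-10, None)
            g = self.X.T @ (self.meth - self.total * pi)
            H = (self.X.T * W) @ self.X
            step = np.linalg.solve(H, g)
            beta = beta + step
            if np.max(np.abs(step)) < tol * 1e-2:
                converged = True
                break
        eta = self.X @ beta
        pi = _sigmoid(eta)
        W = np.clip(self.total * pi * (1.0 - pi), 1e-10, None)
        cov_beta = np.linalg.inv((self.X.T * W) @ self.X)
        ll = float(np.sum(self.meth * eta - self.total * np.logaddexp(0.0, eta)))
        return BinomialMixedModelResults(
            model=self,
            params=beta,
            cov_params=cov_beta,
            random_effects=np.zeros(n),
            sigma2_g=0.0,
            sigma2_e=0.0,
            loglike=ll,
            converged=converged,
        )


class BinomialMixedModelResults:
    """Estimates, uncertainties and variance components from one site fit."""

    def __init__(
        self,
        model: BinomialMixedModel,
        params: np.ndarray,
        cov_params: np.ndarray,
        random_effects: np.ndarray,
        sigma2_g: float,
        sigma2_e: float,
        loglike: float,
        converged: bool,
    ) -> None:
        self.model = model
        self.params = pd.Series(params, index=model.exog_names)
        self._cov = cov_params
        self.random_effects = random_effects
        self.sigma2_g = sigma2_g
        self.sigma2_e = sigma2_e
        self.loglike = loglike
        self.converged = converged

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._cov)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return float(self.sigma2_g / tot) if tot > 0 else 0.0

    def summary(self) -> str:
        lines = [
            "Binomial mixed model (Laplace)",
            f"  nobs: {self.model.nobs}   converged: {self.converged}",
            f"  sigma2_g: {self.sigma2_g:.4f}   sigma2_e: {self.sigma2_e:.4f}"
            f"   h2: {self.h2:.3f}   loglik: {self.loglike:.2f}",
            f"  {'term':<18}{'beta':>10}{'se':>10}{'z':>9}{'P>|z|':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<18}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.zvalues[name]:>9.3f}{self.pvalues[name]:>10.3g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface used by the genome scan


def standardized_effect(beta: float, se: float) -> float:
    """Effect size in SE units (z = beta / se)."""
    if se <= 0:
        raise ValueError("se must be positive")
    return beta / se


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p passes through as NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        _, qv, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = qv
    return q


def fit_site(
    meth: np.ndarray,
    total: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    K_samples: np.ndarray | None,
    **fit_kwargs,
) -> BinomialMixedModelResults:
    """Fit one site, dropping zero-coverage samples (done by the model)."""
    return BinomialMixedModel(meth, total, X, kinship=K_samples).fit(**fit_kwargs)


def scan(
    counts,
    spec: ModelSpec,
    covariates: pd.DataFrame,
    kinship: KinshipMatrix,
    progress: bool = False,
) -> pd.DataFrame:
    """Genome scan: one binomial mixed model per site.

    Returns a tidy frame with one row per site x focal term:
    site_id, term, beta, se, z, p, q, sigma2_g, sigma2_e, h2, converged.
    q-values are Benjamini-Hochberg within each focal term, computed over
    converged sites only.
    """
    design = build_design(spec, covariates)
    cov = covariates.copy()
    if "sample_id" in cov.columns:
        cov = cov.set_index("sample_id")
    sample_ids = design.sample_ids
    col_idx = [counts.sample_ids.index(s) for s in sample_ids]
    sample_to_ind = [cov.loc[s, "individual_id"] for s in sample_ids]
    K_samples = expand_kinship(kinship, sample_to_ind)

    rows = []
    X = design.X
    for i, site in enumerate(counts.site_ids):
        m = counts.meth[i, col_idx]
        r = counts.total[i, col_idx]
        try:
            res = fit_site(m, r, X, K_samples)
        except (ValueError, np.linalg.LinAlgError):
            for term in design.focal_terms:
                rows.append((site, term, np.nan, np.nan, np.nan, np.nan,
                             np.nan, np.nan, np.nan, False))
            continue
        for term in design.focal_terms:
            beta = float(res.params[term])
            se = float(res.bse[term])
            rows.append(
                (
                    site,
                    term,
                    beta,
                    se,
                    standardized_effect(beta, se) if se > 0 else np.nan,
                    float(res.pvalues[term]),
                    res.sigma2_g,
                    res.sigma2_e,
                    res.h2,
                    res.converged,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "site_id", "term", "beta", "se", "z", "p",
            "sigma2_g", "sigma2_e", "h2", "converged",
        ],
    )
    out["q"] = np.nan
    for term in out["term"].unique():
        mask = (out["term"] == term) & out["converged"]
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out[
        ["site_id", "term", "beta", "se", "z", "p", "q",
         "sigma2_g", "sigma2_e", "h2", "converged"]
    ]
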