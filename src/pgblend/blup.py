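"""REML estimation and BLUP prediction with known heteroscedastic residual weights.

Two model families are provided:

* :func:`fit_single_kernel` — ``y = 1*mu + Z g + e`` with ``Var(g) = K sigma2_g``
  and ``Var(e) = sigma2_e * diag(se^2)``; used for A-BLUP, G-BLUP and
  blended K-BLUP (same code path, label only).
* :func:`fit_two_kernel` — ``y = 1*mu + Z m + Z a + e`` with independent
  ``Var(m) = Gs sigma2_m`` and ``Var(a) = A sigma2_a``; the blended model's
  reparameterization with ``g = m + a`` and implied weight
  ``w = sigma2_a / (sigma2_a + sigma2_m)``.

The residual contract is ``Var(e_i) = sigma2_e * se_i^2``: squared standard
errors act as known relative weights with one free residual scale.  Passing
``fixed_r=True`` pins ``sigma2_e = 1`` so the residual covariance is exactly
``diag(se^2)``.

Restricted log-likelihoods keep all constants
(``-2ll = (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py``) so values are
comparable across kinship matrices and between the two parameterizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .kinship import GenotypeMatrix
from .relmat import RelationshipMatrix, check_alignment

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))

MIN_PHENOTYPED = 10


class ModelError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    """Line-level adjusted means (BLUEs) with their standard errors."""

    line_ids: list[str]
    blues: np.ndarray
    ses: np.ndarray
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.line_ids = [str(i) for i in self.line_ids]
        self.blues = np.asarray(self.blues, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if not (len(self.line_ids) == len(self.blues) == len(self.ses)):
            raise ModelError("phenotype columns have unequal lengths")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ModelError("duplicate line ids in phenotype table")
        if not np.all(self.ses > 0):
            raise ModelError("every standard error must be positive")
        if np.isnan(self.blues).any():
            raise ModelError("missing BLUEs are not allowed; drop those lines")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def subset(self, ids: list[str]) -> "PhenotypeTable":
        index = {i: k for k, i in enumerate(self.line_ids)}
        idx = [index[i] for i in ids]
        return PhenotypeTable(list(ids), self.blues[idx], self.ses[idx], self.trait)

    def drop(self, ids: set[str]) -> "PhenotypeTable":
        keep = [i for i in self.line_ids if i not in ids]
        return self.subset(keep)


def read_phenotypes(path: str, trait: str | None = None) -> PhenotypeTable:
    """Read a TSV with columns ``line_id, trait, blue, se``; one trait selected."""
    frame = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    required = {"line_id", "trait", "blue", "se"}
    if not required.issubset(frame.columns):
        raise ModelError(f"phenotype file must have columns {sorted(required)}")
    traits = frame["trait"].unique()
    if trait is None:
        if len(traits) > 1:
            raise ModelError(f"file holds several traits {list(traits)}; pick one")
        trait = str(traits[0])
    sub = frame[frame["trait"] == trait]
    if sub.empty:
        raise ModelError(f"trait {trait!r} not present; available: {list(traits)}")
    if sub["line_id"].duplicated().any():
        raise ModelError(f"duplicate line records for trait {trait!r}")
    return PhenotypeTable(
        list(sub["line_id"]), sub["blue"].to_numpy(), sub["se"].to_numpy(), trait
    )


def write_phenotypes(pheno: PhenotypeTable, path: str) -> None:
    pd.DataFrame(
        {
            "line_id": pheno.line_ids,
            "trait": pheno.trait,
            "blue": pheno.blues,
            "se": pheno.ses,
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    sigma2_m: float | None = None
    sigma2_a: float | None = None

    @property
    def w_implied(self) -> float | None:
        if self.sigma2_m is None or self.sigma2_a is None:
            return None
        tot = self.sigma2_m + self.sigma2_a
        if tot <= 0:
            raise ModelError("total additive variance is zero; weight undefined")
        return self.sigma2_a / tot


@dataclass
class BlupFit:
    mu: float
    gebv: dict[str, float]
    vc: VarianceComponents
    reml_loglik: float
    converged: bool
    model_tag: str
    boundary: bool = False
    n_phenotyped: int = 0
    gebv_m: dict[str, float] = field(default_factory=dict)
    gebv_a: dict[str, float] = field(default_factory=dict)

    def predictions(self, ids: list[str]) -> np.ndarray:
        return np.array([self.gebv[i] for i in ids])


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability of line means, ``sigma2_g / (sigma2_g + sigma2_e)``."""
    tot = vc.sigma2_g + vc.sigma2_e
    if tot <= 0:
        raise ModelError("both variance components are zero; h2 undefined")
    return vc.sigma2_g / tot


def ml_weight_from_agblup(fit: BlupFit) -> float:
    """Likelihood-implied pedigree weight of a two-kernel fit."""
    w = fit.vc.w_implied
    if w is None:
        raise ModelError("fit has no genomic/polygenic split; run fit_two_kernel")
    return w


def _check_pheno_in_kinship(pheno: PhenotypeTable, ids: list[str]) -> None:
    missing = [i for i in pheno.line_ids if i not in set(ids)]
    if missing:
        raise ModelError(f"phenotyped lines absent from kinship matrix: {missing[:10]}")
    if pheno.n < MIN_PHENOTYPED:
        raise ModelError(f"need at least {MIN_PHENOTYPED} phenotyped lines, got {pheno.n}")


def fit_single_kernel(
    pheno: PhenotypeTable,
    K: RelationshipMatrix,
    fixed_r: bool = False,
    components: tuple[float, float] | None = None,
    model_tag: str | None = None,
    ratio_bounds: tuple[float, float] = (1e-8, 1e8),
) -> BlupFit:
    """REML fit of the single-kinship mixed model and BLUP for every K id.

    The restricted likelihood is profiled on the variance ratio
    ``gamma = sigma2_g / sigma2_e`` after one eigendecomposition of the
    weighted kinship, then maximized by bounded scalar search.  With
    ``components=(sigma2_g, sigma2_e)`` no estimation is performed (used by
    equivalence oracles).  ``fixed_r=True`` pins ``sigma2_e = 1``.
    """
    _check_pheno_in_kinship(pheno, K.ids)
    train_ids = pheno.line_ids
    y = pheno.blues
    d = pheno.ses**2
    n = pheno.n

    k_tt = K.restrict(train_ids).values
    dm12 = 1.0 / np.sqrt(d)
    s = k_tt * dm12[:, None] * dm12[None, :]
    lam, u = np.linalg.eigh(s)
    lam = np.clip(lam, 0.0, None)
    ystar = u.T @ (dm12 * y)
    xstar = u.T @ dm12  # design is a column of ones
    logdet_d = float(np.sum(np.log(d)))

    def profile(gamma: float) -> tuple[float, float, float]:
        """Return (-2 restricted ll, mu_hat, sigma2_e_hat) at variance ratio gamma."""
        v = gamma * lam + 1.0
        xvx = np.sum(xstar**2 / v)
        mu_hat = np.sum(xstar * ystar / v) / xvx
        resid = ystar - xstar * mu_hat
        q = float(np.sum(resid**2 / v))
        s2e = q / (n - 1)
        neg2ll = (
            (n - 1) * LOG2PI
            + float(np.sum(np.log(v)))
            + (n - 1) * np.log(s2e)
            + logdet_d
            + np.log(xvx / s2e)
            + (n - 1)
        )
        return neg2ll, float(mu_hat), float(s2e)

    def fixed_neg2ll(s2g: float, s2e: float) -> tuple[float, float]:
        v = s2g * lam + s2e
        xvx = np.sum(xstar**2 / v)
        mu_hat = np.sum(xstar * ystar / v) / xvx
        resid = ystar - xstar * mu_hat
        q = float(np.sum(resid**2 / v))
        neg2ll = (
            (n - 1) * LOG2PI
            + float(np.sum(np.log(v)))
            + logdet_d
            + np.log(xvx)
            + q
        )
        return neg2ll, float(mu_hat)

    converged = True
    boundary = False
    if components is not None:
        s2g, s2e = components
        neg2ll, mu_hat = fixed_neg2ll(s2g, s2e)
    elif fixed_r:
        var_y = float(np.var(y)) or 1.0
        res = minimize_scalar(
            lambda t: fixed_neg2ll(np.exp(t), 1.0)[0],
            bounds=(np.log(1e-10 * var_y), np.log(1e6 * var_y)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        s2g, s2e = float(np.exp(res.x)), 1.0
        neg2ll, mu_hat = fixed_neg2ll(s2g, s2e)
        converged = bool(res.success)
        boundary = bool(res.x < np.log(1e-10 * var_y) + 1e-6)
    else:
        lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
        res = minimize_scalar(
            lambda t: profile(np.exp(t))[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = float(np.exp(res.x))
        neg2ll, mu_hat, s2e = profile(gamma)
        s2g = gamma * s2e
        converged = bool(res.success)
        boundary = bool(res.x < lo + 1e-6 or res.x > hi - 1e-6)
    if boundary:
        logger.warning("single-kernel REML hit a variance boundary")

    # BLUP for every id in K via the joint covariance:
    # g_hat = sigma2_g * K[:, T] V^-1 (y - mu), V = sigma2_g K_TT + sigma2_e D
    v_rot = s2g * lam + s2e
    vinv_resid = dm12 * (u @ ((ystar - xstar * mu_hat) / v_rot))
    k_cols = K.values[:, [K._index[i] for i in train_ids]]
    g_all = s2g * (k_cols @ vinv_resid)
    gebv = {i: float(g) for i, g in zip(K.ids, g_all)}

    return BlupFit(
        mu=mu_hat,
        gebv=gebv,
        vc=VarianceComponents(sigma2_g=float(s2g), sigma2_e=float(s2e)),
        reml_loglik=-0.5 * float(neg2ll),
        converged=converged,
        model_tag=model_tag or f"K-BLUP({K.kind})",
        boundary=boundary,
        n_phenotyped=n,
    )


def fit_two_kernel(
    pheno: PhenotypeTable,
    A: RelationshipMatrix,
    Gs: RelationshipMatrix,
    fixed_r: bool = False,
    components: tuple[float, float, float] | None = None,
    max_iter: int = 400,
) -> BlupFit:
    """REML fit of the two-kinship model (pedigree + genomic random effects).

    Maximizes the restricted likelihood over ``(sigma2_m, sigma2_a,
    sigma2_e)`` on the log scale with a Nelder-Mead simplex (derivative-free;
    each evaluation is one Cholesky of the phenotyped-block covariance).
    Variances are floored at ``1e-10 * var(y)``; estimates at the floor are
    flagged as boundary fits.  ``components=(sigma2_m, sigma2_a, sigma2_e)``
    skips estimation.
    """
    check_alignment(A, Gs)
    _check_pheno_in_kinship(pheno, Gs.ids)
    ids = Gs.ids
    train_ids = pheno.line_ids
    y = pheno.blues
    d = pheno.ses**2
    n = pheno.n

    a_full = A.aligned_values(ids)
    g_full = Gs.values
    tr_idx = [Gs._index[i] for i in train_ids]
    a_tt = a_full[np.ix_(tr_idx, tr_idx)]
    g_tt = g_full[np.ix_(tr_idx, tr_idx)]
    x = np.ones(n)

    def neg2ll(theta: np.ndarray) -> float:
        s2m, s2a, s2e = theta
        v = s2m * g_tt + s2a * a_tt + s2e * np.diag(d)
        try:
            chol = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(chol))))
        viy = np.linalg.solve(chol.T, np.linalg.solve(chol, y))
        vix = np.linalg.solve(chol.T, np.linalg.solve(chol, x))
        xvx = float(x @ vix)
        mu_hat = float(x @ viy) / xvx
        ypy = float(y @ viy) - xvx * mu_hat**2
        return (n - 1) * LOG2PI + logdet_v + np.log(xvx) + ypy

    var_y = float(np.var(y)) or 1.0
    floor = 1e-10 * var_y
    converged = True
    if components is not None:
        s2m, s2a, s2e = components
    else:
        mean_d = float(np.mean(d))
        theta0 = np.log([0.3 * var_y, 0.3 * var_y, 0.4 * var_y / mean_d])
        res = minimize(
            lambda t: neg2ll(np.exp(t))
            if not fixed_r
            else neg2ll(np.array([np.exp(t[0]), np.exp(t[1]), 1.0])),
            theta0 if not fixed_r else theta0[:2],
            method="Nelder-Mead",
            options={
                "maxiter": max_iter * 3,
                "xatol": 1e-9,
                "fatol": 1e-10,
                "adaptive": True,
            },
        )
        converged = bool(res.success)
        if not converged:
            logger.warning("two-kernel REML did not converge: %s", res.message)
        est = np.exp(res.x)
        if fixed_r:
            s2m, s2a, s2e = float(est[0]), float(est[1]), 1.0
        else:
            s2m, s2a, s2e = (float(v) for v in est)
    s2m, s2a = max(s2m, floor), max(s2a, floor)
    boundary = s2m <= floor * 1.01 or s2a <= floor * 1.01
    if boundary:
        logger.warning("two-kernel REML variance at its boundary floor")

    final = float(neg2ll(np.array([s2m, s2a, s2e])))
    v = s2m * g_tt + s2a * a_tt + s2e * np.diag(d)
    chol = np.linalg.cholesky(v)
    viy = np.linalg.solve(chol.T, np.linalg.solve(chol, y))
    vix = np.linalg.solve(chol.T, np.linalg.solve(chol, x))
    mu_hat = float(x @ viy) / float(x @ vix)
    vinv_resid = np.linalg.solve(chol.T, np.linalg.solve(chol, y - mu_hat))

    m_all = s2m * (g_full[:, tr_idx] @ vinv_resid)
    a_all = s2a * (a_full[:, tr_idx] @ vinv_resid)
    g_all = m_all + a_all

    return BlupFit(
        mu=mu_hat,
        gebv={i: float(g) for i, g in zip(ids, g_all)},
        vc=VarianceComponents(
            sigma2_g=s2m + s2a, sigma2_e=float(s2e), sigma2_m=s2m, sigma2_a=s2a
        ),
        reml_loglik=-0.5 * final,
        converged=converged,
        model_tag="AG-BLUP",
        boundary=boundary,
        n_phenotyped=n,
        gebv_m={i: float(g) for i, g in zip(ids, m_all)},
        gebv_a={i: float(g) for i, g in zip(ids, a_all)},
    )


def snp_blup_oracle(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    components: tuple[float, float],
    fixed_r: bool = False,
) -> tuple[float, dict[str, float]]:
    """Ridge-type marker-effect BLUP; independent oracle for G-BLUP.

    Solves the (1 + m) mixed-model equations for the intercept and marker
    effects with effect variance ``sigma2_g / (2 sum p(1-p))`` under residual
    covariance ``sigma2_e * diag(se^2)``, then maps effects back to per-line
    predictions ``W beta_hat``.  Must agree with
    :func:`fit_single_kernel` on the unscaled VanRaden G at the same fixed
    variance components.
    """
    if geno.has_missing():
        raise ModelError("genotypes must be complete for SNP-BLUP")
    index = {i: k for k, i in enumerate(geno.line_ids)}
    missing = [i for i in pheno.line_ids if i not in index]
    if missing:
        raise ModelError(f"phenotyped lines without genotypes: {missing[:10]}")
    s2g, s2e = components
    p = geno.allele_freqs()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    s2b = s2g / denom
    w_all = geno.dosages - 2.0 * p
    rows = [index[i] for i in pheno.line_ids]
    w = w_all[rows]
    n, m = w.shape
    rinv = 1.0 / (s2e * pheno.ses**2)

    if s2b == 0.0:  # no marker variance: GLS mean, zero effects
        mu_hat = float(np.sum(rinv * pheno.blues) / np.sum(rinv))
        return mu_hat, {i: 0.0 for i in geno.line_ids}

    # mixed-model equations for (mu, beta)
    c = np.empty((m + 1, m + 1))
    c[0, 0] = np.sum(rinv)
    c[0, 1:] = rinv @ w
    c[1:, 0] = c[0, 1:]
    c[1:, 1:] = (w.T * rinv) @ w + np.eye(m) / s2b
    rhs = np.concatenate(([np.sum(rinv * pheno.blues)], w.T @ (rinv * pheno.blues)))
    sol = np.linalg.solve(c, rhs)
    mu_hat, beta = float(sol[0]), sol[1:]
    preds = w_all @ beta
    return mu_hat, {i: float(v) for i, v in zip(geno.line_ids, preds)}


def write_fit(fit: BlupFit, json_path: str, gebv_path: str) -> None:
    import json

    payload = {
        "model_tag": fit.model_tag,
        "mu": fit.mu,
        "sigma2_g": fit.vc.sigma2_g,
        "sigma2_e": fit.vc.sigma2_e,
        "sigma2_m": fit.vc.sigma2_m,
        "sigma2_a": fit.vc.sigma2_a,
        "w_implied": fit.vc.w_implied,
        "h2": heritability(fit.vc),
        "reml_loglik": float(fit.reml_loglik),
        "converged": bool(fit.converged),
        "boundary": bool(fit.boundary),
        "n_phenotyped": fit.n_phenotyped,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    pd.DataFrame(
        {"line_id": list(fit.gebv), "gebv": list(fit.gebv.values())}
    ).to_csv(gebv_path, sep="\t", index=False)
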