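"""Joint (integrated) likelihood for detection and density parameters.

A single likelihood couples two processes that conventional distance
sampling estimates in separate stages:

* a Poisson count model for the number of pellet groups per transect and
  distance interval, with a log link, habitat covariates, and a normal
  random intercept b_s shared by the transects of each wadi system; and
* a global half-normal (or hazard-rate) detection function that thins the
  latent pellet groups by distance.

For transect i (length L_i, covariates x_i) in system s, the expected count
in distance interval k is

    lambda_ik(b_s) = 2 L_i * exp(beta_0 + x_i' beta + b_s) * I_k(sigma_det),

where I_k = int over interval k of g(y; sigma_det) dy.  Counts are Poisson
given b_s; the marginal likelihood integrates each system's contribution
over b_s ~ N(0, sigma_b^2) by adaptive Gauss–Hermite quadrature (mode and
curvature found per system by Newton steps, which are closed-form here
because the conditional log-likelihood in b is N b - M e^b plus the prior).

Maximization is by quasi-Newton on the transformed parameter vector
theta = (beta, log sigma_b, log sigma_det), with multi-start jitter to
guard against the flat ridges that small random-effect variances produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

from .detection import DetectionModel, bin_probabilities
from .survey_data import DEFAULT_CUTPOINTS, SPECIES

__all__ = ["ModelSpec", "FittedModel", "build_model_data", "integrated_loglik",
           "fit", "aicc", "predict_density"]

_LOG_SIGMA_B_FLOOR = np.log(1e-4)


@dataclass(frozen=True)
class ModelSpec:
    """A density formula: covariate subset plus optional two-way interactions.

    ``species`` selects the response ("oryx", "gazelle", or "combined", the
    latter stacking both species and allowing a ``species`` indicator term).
    ``terms`` are main-effect predictor names; ``interactions`` are pairs of
    included main effects.  The wadi-system random intercept and the
    detection scale are always part of the model.
    """

    species: str = "oryx"
    terms: tuple = ()
    interactions: tuple = ()
    detection_form: str = "half_normal"

    def __post_init__(self):
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ValueError(
                    f"interaction {a}:{b} requires both main effects in terms")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model spec")

    @property
    def name(self) -> str:
        parts = ["1"] + list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]
        return f"{self.species}~" + "+".join(parts)

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.terms) + len(self.interactions)

    @property
    def k(self) -> int:
        # intercept + fixed terms + sigma_b + sigma_det
        return self.n_fixed + 2


@dataclass
class ModelData:
    """Design matrices and binned counts arranged for likelihood evaluation."""

    counts: np.ndarray        # (n_rows, K)
    X: np.ndarray             # (n_rows, p) including intercept column
    exposure: np.ndarray      # (n_rows,) 2 * L_i in meters
    system_idx: np.ndarray    # (n_rows,) 0..S-1
    n_systems: int
    cutpoints: tuple
    colnames: list
    transect_ids: list

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]


def build_model_data(binned: pd.DataFrame, transects: pd.DataFrame,
                     covariates: pd.DataFrame, spec: ModelSpec,
                     cutpoints=DEFAULT_CUTPOINTS,
                     standardize: bool = False) -> ModelData:
    """Assemble counts, design matrix and groupings for a model spec.

    For single-species specs each transect contributes one row; for
    "combined" each transect contributes one row per species and the
    reserved predictor name ``species`` codes gazelle = 1.  Covariates
    enter on their raw scales by default; ``standardize=True`` z-scores
    continuous predictors (indicator terms are left alone), which changes
    coefficient scales but not fit or ranking.
    """
    cov = covariates.set_index("transect_id")
    if standardize:
        cov = cov.copy()
        for c in cov.columns:
            if c in ("habitat_type",):
                continue
            sd = cov[c].std(ddof=0)
            if sd > 0:
                cov[c] = (cov[c] - cov[c].mean()) / sd
    tr = transects.set_index("transect_id")
    bin_cols = [c for c in binned.columns if c.startswith("bin_")]
    species_list = list(SPECIES) if spec.species == "combined" else [spec.species]
    rows, Xr, expo, sysid, tids = [], [], [], [], []
    systems = {ws: i for i, ws in enumerate(pd.unique(transects["wadi_system"]))}
    b_idx = binned.set_index(["transect_id", "species"])
    for tid in transects["transect_id"]:
        for sp in species_list:
            rows.append(b_idx.loc[(tid, sp), bin_cols].to_numpy(float))
            x = [1.0]
            vals = {}
            for t in spec.terms:
                if t == "species":
                    vals[t] = 1.0 if sp == "gazelle" else 0.0
                else:
                    vals[t] = float(cov.loc[tid, t])
                x.append(vals[t])
            for a, b in spec.interactions:
                x.append(vals[a] * vals[b])
            Xr.append(x)
            expo.append(2.0 * float(tr.loc[tid, "length_m"]))
            sysid.append(systems[tr.loc[tid, "wadi_system"]])
            tids.append(tid)
    colnames = (["intercept"] + list(spec.terms)
                + [f"{a}:{b}" for a, b in spec.interactions])
    return ModelData(counts=np.asarray(rows, float), X=np.asarray(Xr, float),
                     exposure=np.asarray(expo, float),
                     system_idx=np.asarray(sysid, int), n_systems=len(systems),
                     cutpoints=tuple(cutpoints), colnames=colnames,
                     transect_ids=tids)


def _bin_integrals(sigma_det: float, cutpoints, form: str) -> np.ndarray:
    """I_k = integral of g over interval k, in meters."""
    model = DetectionModel(form=form, sigma=sigma_det,
                           b=2.5 if form == "hazard_rate" else None,
                           cutpoints=tuple(cutpoints))
    w = cutpoints[-1]
    return bin_probabilities(model) * w


def _system_stats(data: ModelData, beta: np.ndarray, sigma_det: float,
                  form: str):
    """Per-system sufficient statistics for the random-effect integral.

    Conditional on b, the system log-likelihood is C + N b - M e^b with
    N = total count, M = sum of lambda at b = 0, and C collecting the
    b-free Poisson terms.
    """
    I_k = _bin_integrals(sigma_det, data.cutpoints, form)
    eta = data.X @ beta
    if np.any(~np.isfinite(eta)):
        bad = data.transect_ids[int(np.argmax(~np.isfinite(eta)))]
        raise FloatingPointError(f"non-finite linear predictor at transect {bad}")
    A = data.exposure[:, None] * I_k[None, :]          # (n_rows, K)
    log_lam0 = eta[:, None] + np.log(A)
    row_N = data.counts.sum(axis=1)
    row_M = np.exp(eta) * A.sum(axis=1)
    row_C = (data.counts * log_lam0).sum(axis=1) - special.gammaln(
        data.counts + 1.0).sum(axis=1)
    S = data.n_systems
    N = np.bincount(data.system_idx, weights=row_N, minlength=S)
    M = np.bincount(data.system_idx, weights=row_M, minlength=S)
    C = np.bincount(data.system_idx, weights=row_C, minlength=S)
    return N, M, C


def integrated_loglik(data: ModelData, theta: np.ndarray, *,
                      form: str = "half_normal", n_nodes: int = 15,
                      sigma_det_fixed: float | None = None) -> float:
    """Marginal log-likelihood at theta = (beta, log sigma_b, log sigma_det).

    When ``sigma_det_fixed`` is given the detection scale is dropped from
    theta (theta = (beta, log sigma_b)) and held at the supplied value, so
    the model reduces to a Poisson mixed model with a detection offset.
    """
    theta = np.asarray(theta, float)
    if sigma_det_fixed is None:
        beta, log_sb, log_sd = theta[:-2], theta[-2], theta[-1]
        sigma_det = float(np.exp(log_sd))
    else:
        beta, log_sb = theta[:-1], theta[-1]
        sigma_det = float(sigma_det_fixed)
    sigma_b = float(np.exp(log_sb))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        N, M, C = _system_stats(data, beta, sigma_det, form)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(C))):
        return -np.inf

    # Newton for the mode of H(b) = N b - M e^b - b^2/(2 s^2), per system.
    sb2 = sigma_b ** 2
    b = np.zeros_like(N)
    for _ in range(100):
        Me = M * np.exp(b)
        grad = N - Me - b / sb2
        hess = -Me - 1.0 / sb2
        step = grad / hess
        # dampen to keep e^b finite on early steps
        step = np.clip(step, -5.0, 5.0)
        b -= step
        if np.max(np.abs(grad)) < 1e-10:
            break
    Me = M * np.exp(b)
    curv = Me + 1.0 / sb2                      # -H''(b_hat)
    scale = 1.0 / np.sqrt(curv)

    x, wq = hermgauss(n_nodes)
    nodes = b[:, None] + np.sqrt(2.0) * scale[:, None] * x[None, :]
    H = (N[:, None] * nodes - M[:, None] * np.exp(nodes)
         - nodes ** 2 / (2.0 * sb2))
    Hmax = H.max(axis=1, keepdims=True)
    integral = np.log(np.sum(wq[None, :] * np.exp(H - Hmax + x[None, :] ** 2),
                             axis=1)) + Hmax[:, 0]
    integral += np.log(np.sqrt(2.0) * scale)
    # normal density constant for b
    const = -0.5 * np.log(2.0 * np.pi * sb2)
    return float(np.sum(C + integral + const))


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction.

    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class FittedModel:
    """A converged integrated-likelihood fit with its information-criterion bookkeeping."""

    spec: ModelSpec
    data: ModelData
    theta: np.ndarray
    loglik: float
    k: int
    n_effective: int
    aicc: float
    vcov: np.ndarray | None
    converged: bool
    sigma_det_fixed: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        p = self.spec.n_fixed
        return self.theta[:p]

    @property
    def sigma_b(self) -> float:
        p = self.spec.n_fixed
        return float(np.exp(self.theta[p]))

    @property
    def sigma_det(self) -> float:
        if self.sigma_det_fixed is not None:
            return float(self.sigma_det_fixed)
        return float(np.exp(self.theta[-1]))

    @property
    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        d = np.diag(self.vcov)
        return np.where(d > 0, np.sqrt(np.maximum(d, 0.0)), np.nan)

    def coef_table(self) -> pd.DataFrame:
        names = list(self.data.colnames) + ["log_sigma_b"]
        if self.sigma_det_fixed is None:
            names.append("log_sigma_det")
        se = self.se
        return pd.DataFrame({
            "term": names,
            "estimate": self.theta,
            "se": se if se is not None else np.full(len(names), np.nan),
        })

    def to_report(self) -> dict:
        tab = self.coef_table()
        return {
            "model": self.spec.name,
            "k": self.k,
            "n_effective": self.n_effective,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "sigma_b": self.sigma_b,
            "sigma_det": self.sigma_det,
            "converged": self.converged,
            "coefficients": {r["term"]: {"estimate": float(r["estimate"]),
                                         "se": None if np.isnan(r["se"]) else float(r["se"])}
                             for _, r in tab.iterrows()},
            "diagnostics": self.diagnostics,
        }


def _numeric_hessian(f, theta, rel_step=1e-4):
    p = len(theta)
    h = rel_step * (1.0 + np.abs(theta))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit(data: ModelData, spec: ModelSpec, *, n_nodes: int = 15,
        n_starts: int = 5, seed: int = 0, sigma_det_fixed: float | None = None,
        n_convention: str = "transects", gtol: float = 1e-8) -> FittedModel:
    """Maximize the integrated likelihood for one model spec.

    Uses L-BFGS-B on the transformed parameters from ``n_starts`` jittered
    starting points (deterministic given ``seed``); the best-likelihood
    optimum wins, ties broken by the smallest parameter norm.  The
    covariance matrix is the inverse of the observed (numerically
    differentiated) information; a singular Hessian leaves ``vcov`` None
    with a diagnostic rather than failing.

    ``n_convention`` sets the AICc sample size: "transects" (one unit per
    modeled row group, i.e. transects, or transect × species rows for
    combined fits) or "bins" (rows × intervals).
    """
    total = data.counts.sum()
    if total <= 0:
        raise ValueError("all counts zero: detection scale not estimable")
    if data.n_rows < 2:
        raise ValueError("need at least 2 transects")

    p = spec.n_fixed
    w = data.cutpoints[-1]
    free_det = sigma_det_fixed is None
    dim = p + 1 + (1 if free_det else 0)

    # moment-matched intercept start: mean count vs exposure * naive I
    sd0 = w / 2.0
    I0 = _bin_integrals(sigma_det_fixed if not free_det else sd0,
                        data.cutpoints, spec.detection_form).sum()
    b0 = np.log(max(total, 1.0) / (data.exposure.sum() * I0))
    start = np.zeros(dim)
    start[0] = b0
    start[p] = np.log(0.5)          # log sigma_b
    if free_det:
        start[-1] = np.log(sd0)     # log sigma_det

    lb = np.full(dim, -np.inf)
    ub = np.full(dim, np.inf)
    lb[p] = _LOG_SIGMA_B_FLOOR
    ub[p] = np.log(10.0)
    if free_det:
        lb[-1] = np.log(0.01 * w)
        ub[-1] = np.log(100.0 * w)

    def nll(theta):
        try:
            ll = integrated_loglik(data, theta, form=spec.detection_form,
                                   n_nodes=n_nodes,
                                   sigma_det_fixed=sigma_det_fixed)
        except FloatingPointError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    candidates = []
    for s in range(n_starts):
        x0 = start.copy()
        if s > 0:
            x0 = x0 + rng.normal(0.0, 0.5, size=dim)
            x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=list(zip(lb, ub)),
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": gtol})
        candidates.append(res)
    best = min(candidates,
               key=lambda r: (r.fun, float(np.linalg.norm(r.x))))
    converged = bool(best.success and np.isfinite(best.fun))
    theta = best.x
    ll = -best.fun

    H = _numeric_hessian(nll, theta)
    vcov = None
    diag = {"grad_norm": float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan,
            "n_starts": n_starts}
    boundary_sb = bool(theta[p] <= _LOG_SIGMA_B_FLOOR + 1e-6)
    diag["sigma_b_boundary"] = boundary_sb
    try:
        cond = np.linalg.cond(H)
        diag["hessian_condition"] = float(cond)
        if np.isfinite(cond) and cond < 1e12:
            vcov = np.linalg.inv(H)
            if np.any(np.diag(vcov) <= 0):
                vcov = None
                diag["hessian_not_pd"] = True
    except np.linalg.LinAlgError:
        diag["hessian_singular"] = True

    if n_convention == "transects":
        n_eff = data.n_rows
    elif n_convention == "bins":
        n_eff = data.n_rows * data.counts.shape[1]
    else:
        raise ValueError(f"unknown n_convention {n_convention!r}")
    k = spec.k - (1 if not free_det else 0)
    aicc_val = aicc(ll, k, n_eff) if converged else float("nan")
    return FittedModel(spec=spec, data=data, theta=theta, loglik=ll, k=k,
                       n_effective=n_eff, aicc=aicc_val, vcov=vcov,
                       converged=converged, sigma_det_fixed=sigma_det_fixed,
                       diagnostics=diag)


def predict_density(fitted: FittedModel, covariates: pd.DataFrame, *,
                    marginal: bool = True) -> pd.DataFrame:
    """Predicted pellet-group density (per m^2) per transect.

    ``marginal=True`` averages over the random effect using the lognormal
    mean correction exp(sigma_b^2 / 2); ``marginal=False`` conditions on
    b = 0 (the typical system).  A delta-method SE on the log scale is
    attached when the fit has a covariance matrix.
    """
    cov = covariates.set_index("transect_id")
    spec = fitted.spec
    rows = []
    for tid in cov.index:
        x = [1.0]
        vals = {}
        for t in spec.terms:
            if t == "species":
                raise ValueError("per-species prediction requires explicit species rows")
            if t not in cov.columns:
                raise KeyError(f"missing covariate {t!r} for prediction")
            vals[t] = float(cov.loc[tid, t])
            x.append(vals[t])
        for a, b in spec.interactions:
            x.append(vals[a] * vals[b])
        x = np.asarray(x)
        eta = float(x @ fitted.beta)
        if marginal:
            eta += 0.5 * fitted.sigma_b ** 2
        se_log = np.nan
        if fitted.vcov is not None:
            p = spec.n_fixed
            se_log = float(np.sqrt(x @ fitted.vcov[:p, :p] @ x))
        rows.append({"transect_id": tid, "density_per_m2": float(np.exp(eta)),
                     "se_log": se_log})
    return pd.DataFrame(rows)


def wald_ci(fitted: FittedModel, level: float = 0.95) -> pd.DataFrame:
    """Wald confidence intervals on the working (transformed) scale."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    tab = fitted.coef_table()
    tab["lo"] = tab["estimate"] - z * tab["se"]
    tab["hi"] = tab["estimate"] + z * tab["se"]
    return tab
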