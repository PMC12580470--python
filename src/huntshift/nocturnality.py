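"""Beta-binomial regression of nocturnality on disturbance covariates.

Each camera x hunting-effort cell contributes a row: the number of a
species' independent events recorded at night (between evening nautical-dusk
onset and morning nautical-dawn end) out of the cell's total events. The
night count is modelled as beta-binomial,

    n_night ~ BetaBinomial(n_total, alpha = mu * phi, beta = (1 - mu) * phi),
    logit(mu) = X beta,

the mean-precision parameterization: mu is the expected night share (the
nocturnality index; 0.5 = equal day/night activity) and phi > 0 the
precision, accommodating overdispersion relative to a binomial.

The design crosses hunting effort (treatment-coded, reference = high) and
camera placement (reference = trail) with each continuous disturbance
covariate — distance to the hunting-zone border, recreation RAI at the
paired trail camera, and a species-appropriate visibility layer — including
all two- and three-way interactions. Continuous covariates are z-scored with
stored constants; optional per-species transforms (log1p, quadratic) are
applied before scaling.

Estimation is by (optionally ridge-penalized) maximum likelihood with
standard errors from the inverse observed information; a random-walk
Metropolis sampler over the matching posterior (N(0, 2.5^2) priors on scaled
coefficients, half-normal on phi) is available for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from . import sun
from .events import EffortCalendar, annotate_effort

logger = logging.getLogger(__name__)

EFFORT_LEVELS = ("high", "medium", "low")  # first = reference
PLACEMENT_LEVELS = ("trail", "forest")

#: default species -> visibility layer (cm) mapping, by typical eye height
DEFAULT_VISIBILITY_LAYER = {
    "red_deer": "vis140",
    "roe_deer": "vis70",
    "wild_boar": "vis70",
    "red_fox": "vis50",
    "lynx": "vis50",
}


def aggregate_day_night(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    calendar: EffortCalendar,
    recreation_rai: pd.DataFrame | None = None,
    lat: float = sun.DEFAULT_LAT,
    lon: float = sun.DEFAULT_LON,
) -> pd.DataFrame:
    """Count night/day events per camera x effort stratum.

    ``events`` are independent events of one species with ``camera_id`` and
    ``event_time``. Night classification uses nautical twilight via
    :func:`huntshift.sun.is_night`. ``recreation_rai`` (per camera-period,
    trail cameras) is pooled over the two high-effort seasons
    (events-weighted) and joined through the paired trail camera. Rows with
    zero total events never arise (cells without events simply don't appear);
    cells for cameras missing from the deployment table are dropped and
    logged.
    """
    ev = events if "effort" in events.columns else annotate_effort(events, calendar)
    ev = ev.copy()
    ev["night"] = [bool(sun.is_night(t, lat, lon)) for t in ev["event_time"]]
    agg = (
        ev.groupby(["camera_id", "effort"])["night"]
        .agg(n_night="sum", n_total="size")
        .reset_index()
    )
    agg["n_day"] = agg["n_total"] - agg["n_night"]

    dep = deployments[
        ["camera_id", "location_id", "placement", "dist_hunting_zone_m",
         "vis50", "vis70", "vis140"]
    ]
    out = agg.merge(dep, on="camera_id", how="left")
    n_orphan = out["placement"].isna().sum()
    if n_orphan:
        logger.warning("%d camera cell(s) missing from deployments dropped", n_orphan)
        out = out[out["placement"].notna()]

    if recreation_rai is not None:
        rec = recreation_rai.merge(
            deployments[["camera_id", "location_id"]], on="camera_id", how="left"
        )
        pooled = (
            rec.groupby(["location_id", "effort"])
            .apply(
                lambda g: 100.0 * g["n_events"].sum() / g["n_active_days"].sum()
                if g["n_active_days"].sum() > 0 else np.nan,
                include_groups=False,
            )
            .rename("recreation_rai")
            .reset_index()
        )
        out = out.merge(pooled, on=["location_id", "effort"], how="left")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class SpeciesFormula:
    """Covariates and optional pre-scaling transforms for one species.

    ``transforms`` maps a covariate to a list drawn from
    {"log1p", "quadratic"}: log1p replaces the covariate; quadratic adds a
    squared copy as an extra base covariate (both z-scored afterwards).
    """

    covariates: tuple[str, ...] = ("dist_hunting_zone_m", "recreation_rai", "visibility")
    transforms: dict[str, list[str]] = field(default_factory=dict)


def build_design(
    rows: pd.DataFrame,
    formula: SpeciesFormula | None = None,
    scaling: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, dict[str, tuple[float, float]]]:
    """Expand rows into the full factorial design.

    Returns ``(X, n_night, n_total, scaling)``. Treatment coding uses
    effort reference "high" and placement reference "trail". Each continuous
    covariate is z-scored with constants taken from ``scaling`` when given
    (prediction grids) or estimated and returned. Constant covariates are
    dropped with a warning; a rank-deficient result is reported.
    """
    formula = formula or SpeciesFormula()
    efforts = [e for e in EFFORT_LEVELS if e in set(rows["effort"])]
    if len(efforts) < 1:
        raise ValueError("no effort levels present")
    cat_cols: dict[str, np.ndarray] = {}
    for lev in efforts[1:]:
        cat_cols[f"effort[{lev}]"] = (rows["effort"] == lev).to_numpy(float)
    if set(rows["placement"]) - {"trail"}:
        cat_cols["placement[forest]"] = (rows["placement"] == "forest").to_numpy(float)

    # transformed continuous covariates
    cont: dict[str, np.ndarray] = {}
    for name in formula.covariates:
        x = rows[name].to_numpy(float)
        tfs = formula.transforms.get(name, [])
        base = np.log1p(x) if "log1p" in tfs else x
        cont[name] = base
        if "quadratic" in tfs:
            cont[f"{name}^2"] = base**2

    scale_out: dict[str, tuple[float, float]] = {}
    for name, x in list(cont.items()):
        if scaling is not None and name in scaling:
            m, s = scaling[name]
        else:
            m, s = float(np.mean(x)), float(np.std(x, ddof=0))
        if s <= 0:
            logger.warning("covariate %s is constant; dropped", name)
            del cont[name]
            continue
        scale_out[name] = (m, s)
        cont[name] = (x - m) / s

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(rows))}
    cols.update(cat_cols)
    eff_names = [c for c in cat_cols if c.startswith("effort[")]
    plc_names = [c for c in cat_cols if c.startswith("placement[")]
    for e in eff_names:
        for p in plc_names:
            cols[f"{e}:{p}"] = cat_cols[e] * cat_cols[p]
    for name, x in cont.items():
        cols[name] = x
        for e in eff_names:
            cols[f"{e}:{name}"] = cat_cols[e] * x
        for p in plc_names:
            cols[f"{p}:{name}"] = cat_cols[p] * x
        for e in eff_names:
            for p in plc_names:
                cols[f"{e}:{p}:{name}"] = cat_cols[e] * cat_cols[p] * x

    X = pd.DataFrame(cols, index=rows.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        logger.warning("design is rank deficient: rank %d < %d columns", rank, X.shape[1])
    n_night = rows["n_night"].to_numpy(float)
    n_total = (rows["n_night"] + rows["n_day"]).to_numpy(float) if "n_day" in rows else rows[
        "n_total"
    ].to_numpy(float)
    return X, n_night, n_total, scale_out


# ---------------------------------------------------------------------------
# likelihood


def betabinom_loglik(
    beta: np.ndarray, phi: float, X: np.ndarray, n_night: np.ndarray, n_total: np.ndarray
) -> float:
    """Beta-binomial log-likelihood, mean-precision form, via log-gamma.

    Stable for counts up to at least 1e5 per row. Raises on non-finite
    contributions, naming the offending row.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    mu = expit(np.asarray(X) @ beta)
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    a = mu * phi
    b = (1.0 - mu) * phi
    k, n = n_night, n_total
    ll = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite log-likelihood contribution at row {bad}")
    return float(ll.sum())


def betabinom_logpmf_vector(n: int, mu: float, phi: float) -> np.ndarray:
    """log pmf over 0..n for one (n, mu, phi); used for quantile residuals."""
    ks = np.arange(n + 1, dtype=float)
    a, b = mu * phi, (1 - mu) * phi
    return (
        gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)
        + gammaln(ks + a) + gammaln(n - ks + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


@dataclass
class NocturnalityFit:
    coef: pd.Series
    se: pd.Series
    phi: float
    phi_se: float
    loglik: float
    converged: bool
    gradient_norm: float
    scaling: dict[str, tuple[float, float]]
    cov: np.ndarray
    method: str = "ml"
    n_obs: int = 0

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame(
            {
                "estimate": self.coef,
                "se": self.se,
                "ci_low": self.coef - 1.96 * self.se,
                "ci_high": self.coef + 1.96 * self.se,
                "z": z,
            }
        )


def _num_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = len(x)
    H = np.empty((p, p))
    hs = eps * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = hs[i]
            ej = np.zeros(p); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


def fit_betabinom(
    X: pd.DataFrame,
    n_night: np.ndarray,
    n_total: np.ndarray,
    method: str = "ml",
    penalty_sd: float = 2.5,
    scaling: dict[str, tuple[float, float]] | None = None,
    init: np.ndarray | None = None,
) -> NocturnalityFit:
    """Maximize the beta-binomial likelihood (``method="ml"``) or the ridge
    posterior with N(0, penalty_sd^2) priors on coefficients (``"map"``).

    Optimizes over (beta, log phi) with L-BFGS-B; standard errors from the
    inverse observed information at the optimum. Non-convergence is flagged
    but partial results are returned with a warning.
    """
    Xa = X.to_numpy(float)
    names = list(X.columns)
    p = Xa.shape[1]
    pen = 0.0 if method == "ml" else 1.0 / (2.0 * penalty_sd**2)

    def negll(theta: np.ndarray) -> float:
        beta, logphi = theta[:p], theta[p]
        phi = np.exp(np.clip(logphi, -20, 20))
        try:
            ll = betabinom_loglik(beta, phi, Xa, n_night, n_total)
        except FloatingPointError:
            return 1e12
        return -(ll - pen * float(beta @ beta))

    x0 = np.zeros(p + 1) if init is None else np.asarray(init, float)
    if init is None:
        x0[p] = np.log(10.0)
    res = minimize(negll, x0, method="L-BFGS-B", options={"maxiter": 2000, "maxfun": 20000})
    theta = res.x
    grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.nan
    if not res.success:
        logger.warning("beta-binomial fit did not converge: %s", res.message)

    H = _num_hessian(negll, theta)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        se_all = np.sqrt(diag)
    except np.linalg.LinAlgError:
        cov = np.full((p + 1, p + 1), np.nan)
        se_all = np.full(p + 1, np.nan)
    phi = float(np.exp(theta[p]))
    return NocturnalityFit(
        coef=pd.Series(theta[:p], index=names),
        se=pd.Series(se_all[:p], index=names),
        phi=phi,
        phi_se=float(se_all[p] * phi),  # delta method from log phi
        loglik=float(-negll(theta) - (0.0 if method == "ml" else -pen * theta[:p] @ theta[:p])),
        converged=bool(res.success),
        gradient_norm=grad_norm,
        scaling=scaling or {},
        cov=cov,
        method=method,
        n_obs=len(n_total),
    )


def predict_nocturnality(
    fit: NocturnalityFit, X_grid: pd.DataFrame, ci_level: float = 0.95
) -> pd.DataFrame:
    """Predicted night share over a covariate grid with normal-approximation
    intervals on the linear predictor. Warns when grid columns are missing or
    covariates sit far outside the training range.
    """
    unknown = set(X_grid.columns) - set(fit.coef.index)
    if unknown:
        raise ValueError(f"unknown coefficient name(s): {sorted(unknown)}")
    X = X_grid.reindex(columns=fit.coef.index, fill_value=0.0).to_numpy(float)
    big = np.abs(X[:, 1:]).max(initial=0.0)
    if big > 3.0:
        logger.warning("prediction grid extends %.1f SDs beyond the training mean", big)
    lp = X @ fit.coef.to_numpy()
    V = fit.cov[: len(fit.coef), : len(fit.coef)]
    se_lp = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, V, X), 0.0))
    from scipy.stats import norm

    zq = norm.ppf(0.5 + ci_level / 2.0)
    return pd.DataFrame(
        {
            "linpred": lp,
            "night_share": expit(lp),
            "ci_low": expit(lp - zq * se_lp),
            "ci_high": expit(lp + zq * se_lp),
        },
        index=X_grid.index,
    )


def quantile_residuals(
    fit: NocturnalityFit, X: pd.DataFrame, n_night: np.ndarray, n_total: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Randomized quantile residuals (uninterpreted export)."""
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    mu = expit(X.to_numpy(float) @ fit.coef.to_numpy())
    out = np.empty(len(n_total))
    for i, (k, n, m) in enumerate(zip(n_night.astype(int), n_total.astype(int), mu)):
        pmf = np.exp(betabinom_logpmf_vector(n, m, fit.phi))
        cdf = np.cumsum(pmf)
        lo = cdf[k - 1] if k > 0 else 0.0
        hi = cdf[k]
        u = rng.uniform(lo, min(hi, 1.0))
        out[i] = norm.ppf(np.clip(u, 1e-10, 1 - 1e-10))
    return out


def sample_posterior(
    X: pd.DataFrame,
    n_night: np.ndarray,
    n_total: np.ndarray,
    n_samples: int = 2000,
    burn: int = 1000,
    step_scale: float = 0.05,
    prior_sd: float = 2.5,
    phi_prior_sd: float = 50.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Random-walk Metropolis over (beta, log phi).

    Priors: N(0, prior_sd^2) on each scaled coefficient, half-normal
    (sd ``phi_prior_sd``) on phi. A comparison route to the ML/MAP point
    fits, not the primary estimator.
    """
    rng = np.random.default_rng(seed)
    Xa = X.to_numpy(float)
    p = Xa.shape[1]

    def logpost(theta):
        beta, logphi = theta[:p], theta[p]
        phi = np.exp(np.clip(logphi, -20, 20))
        try:
            ll = betabinom_loglik(beta, phi, Xa, n_night, n_total)
        except FloatingPointError:
            return -np.inf
        lp = -0.5 * float(beta @ beta) / prior_sd**2
        # half-normal on phi with the log-phi Jacobian
        lp += -0.5 * (phi / phi_prior_sd) ** 2 + np.log(phi)
        return ll + lp

    theta = np.zeros(p + 1)
    theta[p] = np.log(10.0)
    cur = logpost(theta)
    draws = np.empty((n_samples, p + 1))
    kept = 0
    total = burn + n_samples
    for it in range(total):
        prop = theta + rng.normal(scale=step_scale, size=p + 1)
        lp = logpost(prop)
        if np.log(rng.uniform()) < lp - cur:
            theta, cur = prop, lp
        if it >= burn:
            draws[kept] = theta
            kept += 1
    cols = list(X.columns) + ["log_phi"]
    return pd.DataFrame(draws, columns=cols)
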