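"""Differentially retained introns by beta regression.

IR ratios are proportions in [0, 1], so group differences are modelled with a
beta likelihood: y ~ Beta(mu*phi, (1-mu)*phi) with logit(mu) = beta0 +
beta1*group and a constant precision phi. Inference on the group coefficient
is a Wald test from the observed information. An intron is called
differentially retained when the raw-group-mean difference
delta_ir = mean(IR_cancer) - mean(IR_normal) exceeds 0.1 in magnitude and the
Benjamini-Hochberg adjusted Wald p-value is below 0.05.

Boundary observations (0 or 1, where the beta density is undefined) are
pulled inside the unit interval with the standard proportion squeeze
(y*(n-1) + 0.5)/n before fitting; delta_ir is always computed on the raw
ratios.

Also provided: the Audic-Claverie test for comparing a count between two
libraries of known sizes, the appropriate choice when only a couple of
replicates per condition exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .filters import CohortMatrix


@dataclass
class BetaRegFit:
    intron_id: str
    beta0: float
    beta1: float
    phi: float
    se_beta1: float
    loglik: float
    converged: bool


@dataclass
class DiffIRResult:
    intron_id: str
    mean_ir_normal: float
    mean_ir_cancer: float
    delta_ir: float
    p: float
    q: float
    significant: bool
    direction: str  # up / down / ns


def squeeze_boundary(y, n: int):
    """Shrink proportions off the {0, 1} boundary: (y*(n-1) + 0.5)/n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    out = (y * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out


def beta_loglik(y, group, beta0: float, beta1: float, phi: float) -> float:
    """Sum of log beta densities under the logit-mean / constant-phi model."""
    y = np.asarray(y, float)
    group = np.asarray(group, float)
    if y.shape != group.shape:
        raise ValueError("y and group must have equal length")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly inside (0, 1); squeeze first")
    mu = special.expit(beta0 + beta1 * group)
    a, b = mu * phi, (1 - mu) * phi
    return float(np.sum((a - 1) * np.log(y) + (b - 1) * np.log1p(-y) - special.betaln(a, b)))


def _negloglik_and_grad(params: np.ndarray, y: np.ndarray, g: np.ndarray):
    beta0, beta1, log_phi = params
    phi = np.exp(log_phi)
    eta = beta0 + beta1 * g
    mu = special.expit(eta)
    a, b = mu * phi, (1 - mu) * phi
    log_y, log_1my = np.log(y), np.log1p(-y)
    ll = np.sum((a - 1) * log_y + (b - 1) * log_1my - special.betaln(a, b))
    # score: d ll / d mu_i = phi * (y*_i - mu*_i) with digamma-centred residual
    ystar = log_y - log_1my
    mustar = special.digamma(a) - special.digamma(b)
    dmu = phi * (ystar - mustar) * mu * (1 - mu)
    d_beta0 = np.sum(dmu)
    d_beta1 = np.sum(dmu * g)
    d_phi = np.sum(
        mu * (log_y - special.digamma(a)) + (1 - mu) * (log_1my - special.digamma(b)) + special.digamma(phi)
    )
    return -ll, -np.array([d_beta0, d_beta1, d_phi * phi])  # chain rule for log-phi


def _observed_information(params: np.ndarray, y: np.ndarray, g: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Numerical Hessian of the negative log-likelihood from the analytic gradient."""
    k = len(params)
    H = np.zeros((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps * max(1.0, abs(params[j]))
        _, gp = _negloglik_and_grad(params + step, y, g)
        _, gm = _negloglik_and_grad(params - step, y, g)
        H[:, j] = (gp - gm) / (2 * step[j])
    return (H + H.T) / 2


def fit_beta_regression(y, group, intron_id: str = "", squeeze: bool = True) -> BetaRegFit:
    """Maximum-likelihood beta regression of proportions on a binary group.

    Starts from moment estimates (logit of group means; phi from the pooled
    variance), optimizes by BFGS with the analytic score, and restarts once
    from a perturbed start on failure. ``se_beta1`` comes from the inverse
    observed information.
    """
    y = np.asarray(y, float)
    g = np.asarray(group, float)
    if squeeze:
        y = squeeze_boundary(y, len(y))
    m0 = float(np.mean(y[g == 0])) if np.any(g == 0) else float(np.mean(y))
    m1 = float(np.mean(y[g == 1])) if np.any(g == 1) else m0
    m0, m1 = np.clip([m0, m1], 1e-4, 1 - 1e-4)
    mbar, v = float(np.mean(y)), float(np.var(y))
    phi0 = max(mbar * (1 - mbar) / max(v, 1e-8) - 1, 1.0)
    start = np.array([special.logit(m0), special.logit(m1) - special.logit(m0), np.log(phi0)])

    def _ok(res) -> bool:
        # BFGS often reports "precision loss" at a point whose score is
        # already ~1e-6; judge convergence by the gradient norm itself
        return bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-4

    best = None
    for x0 in (start, start + np.array([0.1, -0.1, 0.5])):
        res = optimize.minimize(
            _negloglik_and_grad, x0, args=(y, g), jac=True, method="BFGS",
            options={"gtol": 1e-6, "maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
        if _ok(res):
            best = res
            break
    beta0, beta1, log_phi = best.x
    phi = float(np.exp(log_phi))
    converged = _ok(best)
    se_beta1 = np.nan
    if converged:
        H = _observed_information(best.x, y, g)
        try:
            cov = np.linalg.inv(H)
            var = cov[1, 1]
            if var > 0:
                se_beta1 = float(np.sqrt(var))
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    return BetaRegFit(
        intron_id=intron_id,
        beta0=float(beta0),
        beta1=float(beta1),
        phi=phi,
        se_beta1=se_beta1,
        loglik=float(-best.fun),
        converged=converged,
    )


def wald_test(fit: BetaRegFit) -> float:
    """Two-sided normal p-value for beta1 / se(beta1); 1 if the fit failed."""
    if not fit.converged or not np.isfinite(fit.se_beta1):
        warnings.warn(f"{fit.intron_id or 'fit'}: non-converged fit, reporting p = 1")
        return 1.0
    z = fit.beta1 / fit.se_beta1
    return float(2 * stats.norm.sf(abs(z)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dir(
    fits: list[BetaRegFit],
    cohort: CohortMatrix,
    normal_label: str = "normal",
    cancer_label: str = "cancer",
    delta_threshold: float = 0.1,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Assemble differential-retention calls from per-intron fits.

    delta_ir is the difference of raw group means of IR ratios; an intron is
    significant when |delta_ir| > delta_threshold and BH q < q_threshold.
    """
    normal_cols = cohort.groups[cohort.groups == normal_label].index
    cancer_cols = cohort.groups[cohort.groups == cancer_label].index
    ids = [f.intron_id for f in fits]
    ir = cohort.ir_ratio.loc[ids]
    mean_n = ir[normal_cols].mean(axis=1)
    mean_c = ir[cancer_cols].mean(axis=1)
    p = np.array([wald_test(f) for f in fits])
    q = bh_adjust(p)
    delta = (mean_c - mean_n).to_numpy()
    sig = (np.abs(delta) > delta_threshold) & (q < q_threshold)
    direction = np.where(~sig, "ns", np.where(delta > 0, "up", "down"))
    return pd.DataFrame(
        {
            "intron_id": ids,
            "mean_ir_normal": mean_n.to_numpy(),
            "mean_ir_cancer": mean_c.to_numpy(),
            "delta_ir": delta,
            "beta1": [f.beta1 for f in fits],
            "se": [f.se_beta1 for f in fits],
            "p": p,
            "q": q,
            "significant": sig,
            "direction": direction,
        }
    ).set_index("intron_id")


def run_differential_ir(
    cohort: CohortMatrix,
    mask: pd.DataFrame | None = None,
    normal_label: str = "normal",
    cancer_label: str = "cancer",
    delta_threshold: float = 0.1,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fit beta regression on every mask-passing intron and call dIRs."""
    ids = list(mask[mask["pass_all"]].index) if mask is not None else list(cohort.intron_ids)
    g = (cohort.groups == cancer_label).astype(float).to_numpy()
    fits = []
    for intron_id in ids:
        y = cohort.ir_ratio.loc[intron_id].to_numpy(float)
        fits.append(fit_beta_regression(y, g, intron_id=intron_id))
    return call_dir(fits, cohort, normal_label, cancer_label, delta_threshold, q_threshold)


def audic_claverie_test(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts x, y from libraries N1, N2.

    Under the null, given x, the second count follows
    P(Y=y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)); the reported
    p-value doubles the smaller exact tail (capped at 1). All tail mass is
    summed in log space.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    log_r = np.log(N2) - np.log(N1)
    log_1pr = np.logaddexp(0.0, log_r)

    def log_pmf(ks: np.ndarray) -> np.ndarray:
        return (
            ks * log_r
            + special.gammaln(x + ks + 1)
            - special.gammaln(x + 1)
            - special.gammaln(ks + 1)
            - (x + ks + 1) * log_1pr
        )

    ks = np.arange(0, y + 1)
    lower = float(np.exp(special.logsumexp(log_pmf(ks))))
    upper = 1.0 - float(np.exp(special.logsumexp(log_pmf(ks[:-1])))) if y > 0 else 1.0
    return float(min(1.0, 2 * min(lower, upper)))
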