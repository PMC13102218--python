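"""Recovery metrics: RMSE, finite-population corrections, correlations.

Item-side accuracy is summarized by the root mean squared error between the
true and estimated discriminations (on the classic *a* scale), optionally
multiplied by a small-*J* finite-population correction and/or standardized
by the observed range of the estimates.  Person-side accuracy uses the RMSE
between true and EAP-estimated thetas with an FPC reflecting the sampling
fraction n/N_pop, plus the Pearson correlation as an ordinal-fidelity
measure.  Correlations are averaged across replications on the Fisher-z
scale and back-transformed.

Both FPC factors default to their square-root forms, sqrt(J/(J-1)) and
sqrt(1 - n/N_pop) — the conventional definitions, which keep the corrected
quantity on the RMSE scale; ``sqrt=False`` selects the raw ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class EvaluationCriteria:
    """Interpretation thresholds for the recovery summaries.

    ``rmse_reference = 0.30`` marks "sufficient accuracy" for theta: if
    estimation errors are N(0, 0.30^2), about 68.27% of them fall within
    +/-0.30 (one error SD).  The agreement bands for the mean correlation
    follow Cohen's guidelines.
    """

    rmse_reference: float = 0.30
    high_cut: float = 0.70
    low_cut: float = 0.50


@dataclass(frozen=True)
class ReplicationMetrics:
    """All per-replication recovery summaries for one fitted sample."""

    rmse_a: float
    fpc_a: float
    rmse_a_fpc: float
    rmse_a_std: float
    rmse_a_std_fpc: float
    rmse_theta: float
    fpc_theta: float
    rmse_theta_fpc: float
    r: float
    converged: bool
    n_warnings: int


def _check_paired(x: np.ndarray, y: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"{what}: vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    return x, y


def rmse_a(a_hat, a_true) -> float:
    """Root mean squared error of the discrimination estimates over J items."""
    a_hat, a_true = _check_paired(a_hat, a_true, "rmse_a")
    return float(np.sqrt(np.mean((a_hat - a_true) ** 2)))


def fpc_a(J: int, sqrt: bool = True) -> float:
    """Small-J finite-population correction, sqrt(J/(J-1)) by default."""
    if J < 2:
        raise ValueError(f"fpc_a needs J >= 2, got {J}")
    ratio = J / (J - 1)
    return float(np.sqrt(ratio)) if sqrt else float(ratio)


def rmse_a_standardized(rmse: float, a_hat) -> float:
    """RMSE divided by the observed range of the estimated discriminations."""
    a_hat = np.asarray(a_hat, dtype=float)
    rng = float(a_hat.max() - a_hat.min())
    if rng <= 0:
        raise ValueError("standardized RMSE undefined: estimated discriminations have zero range")
    return float(rmse) / rng


def rmse_theta(theta_hat, theta_true) -> float:
    """Root mean squared error of the latent-trait estimates over n respondents."""
    theta_hat, theta_true = _check_paired(theta_hat, theta_true, "rmse_theta")
    return float(np.sqrt(np.mean((theta_hat - theta_true) ** 2)))


def fpc_theta(n: int, N_pop: int, sqrt: bool = True) -> float:
    """Finite-population correction for sampling n of N_pop, sqrt(1 - n/N_pop)."""
    if not 1 <= n <= N_pop:
        raise ValueError(f"fpc_theta needs 1 <= n <= N_pop, got n={n}, N_pop={N_pop}")
    frac = 1.0 - n / N_pop
    return float(np.sqrt(frac)) if sqrt else float(frac)


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x, y = _check_paired(x, y, "pearson_r")
    if x.size < 3:
        raise ValueError(f"pearson_r needs n >= 3, got {x.size}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("pearson_r undefined for a constant vector")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return max(-1.0, min(1.0, r))


def fisher_mean_r(rs) -> float:
    """Average correlations on the Fisher-z scale: tanh(mean(artanh(r)))."""
    rs = np.asarray(rs, dtype=float)
    if rs.size < 1:
        raise ValueError("fisher_mean_r needs at least one correlation")
    if (np.abs(rs) >= 1).any():
        raise ValueError("fisher_mean_r undefined for |r| = 1 (infinite z)")
    return float(np.tanh(np.mean(np.arctanh(rs))))


def classify_agreement(r_bar: float, criteria: EvaluationCriteria = EvaluationCriteria()) -> str:
    """Cohen-style band: > 0.70 high, 0.50-0.70 moderate, < 0.50 low.

    "Above 0.70" is read strictly, so exactly 0.70 (and exactly 0.50) fall
    in the moderate band.
    """
    if not -1.0 <= r_bar <= 1.0:
        raise ValueError(f"correlation out of range: {r_bar}")
    if r_bar > criteria.high_cut:
        return "high"
    if r_bar >= criteria.low_cut:
        return "moderate"
    return "low"


def normal_band_probability(z: float = 1.0) -> float:
    """P(-z < Z < z) for Z ~ N(0,1); z = 1 gives 0.6827.

    This is the coverage argument behind the RMSE = 0.30 reference point:
    if theta errors are centered normal with SD 0.30, about 68.27% of them
    fall within +/-0.30.
    """
    return float(norm.cdf(z) - norm.cdf(-z))


def compute_replication_metrics(
    a_true,
    a_hat,
    theta_true,
    theta_hat,
    N_pop: int,
    converged: bool = True,
    n_warnings: int = 0,
    sqrt_fpc: bool = True,
) -> ReplicationMetrics:
    """Assemble every per-replication metric from true and estimated values."""
    a_true = np.asarray(a_true, dtype=float)
    J = a_true.shape[0]
    n = np.asarray(theta_true).shape[0]
    ra = rmse_a(a_hat, a_true)
    fa = fpc_a(J, sqrt=sqrt_fpc)
    ra_std = rmse_a_standardized(ra, a_hat)
    rt = rmse_theta(theta_hat, theta_true)
    ft = fpc_theta(n, N_pop, sqrt=sqrt_fpc)
    return ReplicationMetrics(
        rmse_a=ra,
        fpc_a=fa,
        rmse_a_fpc=ra * fa,
        rmse_a_std=ra_std,
        rmse_a_std_fpc=ra_std * fa,
        rmse_theta=rt,
        fpc_theta=ft,
        rmse_theta_fpc=rt * ft,
        r=pearson_r(theta_true, theta_hat),
        converged=converged,
        n_warnings=n_warnings,
    )
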