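"""Marginal maximum likelihood EM fitting of the GRM, and EAP trait scoring.

The latent trait is integrated out over a fixed quadrature grid (equally
spaced nodes with renormalized standard-normal weights; the latent
distribution is held at N(0,1) for identification, matching the generating
prior).  Each EM cycle is:

* **E-step** — for every respondent, the posterior mass over nodes given the
  current item parameters; accumulated into per-item expected response
  counts ``r[j, q, k]`` (expected number of responses in category *k* at
  node *q*).
* **M-step** — per item, maximize the expected complete-data log-likelihood
  over the internal slope and intercepts.  Items are independent, so the J
  per-item problems are solved as one block L-BFGS-B call on the stacked
  parameter vector with analytic gradients (same maximizer, one optimizer
  call per cycle).

The per-item parametrization is ``(log a1, d_1, log(-gaps of d))``: the
intercepts are forced strictly descending — equivalently the implied
category locations strictly ascending — by construction, so no ordering
constraint is ever violated during optimization.

Cycles stop when the largest absolute change over all (a1, d) parameters
falls below ``tol``, or at ``max_cycles`` (then ``converged=False`` on the
returned model — not an exception).  The marginal log-likelihood trace is
recorded every cycle and is nondecreasing, the standard EM ascent property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .grm_model import DEFAULT_D, boundary_probs, probs_from_boundaries

#: Intercepts beyond this magnitude indicate an effectively unobserved
#: category boundary; they are clipped and a warning recorded.
MAX_ABS_INTERCEPT = 30.0

#: Minimum respondents for a meaningful marginal fit.
MIN_SAMPLE_SIZE = 50

_LOG_A1_BOUNDS = (np.log(1e-3), np.log(1e3))
_D1_BOUNDS = (-MAX_ABS_INTERCEPT, MAX_ABS_INTERCEPT)
_LOG_GAP_BOUNDS = (np.log(1e-6), np.log(2 * MAX_ABS_INTERCEPT))


class DegenerateItemError(ValueError):
    """An item whose observed responses all fall in a single category."""


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed theta grid with a discrete standard-normal prior."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if (np.diff(nodes) <= 0).any():
            raise ValueError("quadrature nodes must be strictly ascending")
        if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
            raise ValueError("quadrature weights must be nonnegative and sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def size(self) -> int:
        return self.nodes.shape[0]


def make_quadrature(n_points: int = 61, half_width: float = 6.0) -> QuadratureGrid:
    """Equally spaced nodes on [-half_width, half_width], N(0,1) weights."""
    if n_points < 11:
        raise ValueError(f"need at least 11 quadrature points, got {n_points}")
    if half_width <= 0:
        raise ValueError(f"half_width must be positive, got {half_width}")
    nodes = np.linspace(-half_width, half_width, n_points)
    weights = norm.pdf(nodes)
    weights /= weights.sum()
    return QuadratureGrid(nodes=nodes, weights=weights)


@dataclass
class FittedModel:
    """One replication's estimates and EM diagnostics.

    ``a1_hat`` are internal slopes (coefficient of theta in the boundary
    logit).  ``a_hat`` is the classic discrimination scale on which recovery
    is evaluated: equal to ``a1_hat`` under the default unrescaled-slope
    convention, or ``a1_hat / D`` when fitting data generated with the
    rescaled convention.  ``b_hat = -d_hat / a1_hat`` are the implied
    ascending category locations on the model's own theta-location scale
    (under the default convention these estimate ``D * b`` of the
    generating bank).
    """

    a1_hat: np.ndarray
    d_hat: np.ndarray
    D: float
    theta_eap: np.ndarray
    theta_psd: np.ndarray
    loglik_trace: np.ndarray
    n_cycles: int
    converged: bool
    slope_rescaled: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def a_hat(self) -> np.ndarray:
        return self.a1_hat / self.D if self.slope_rescaled else self.a1_hat

    @property
    def b_hat(self) -> np.ndarray:
        return -self.d_hat / self.a1_hat[:, None]

    @property
    def J(self) -> int:
        return self.a1_hat.shape[0]

    @property
    def K(self) -> int:
        return self.d_hat.shape[1] + 1


# ---------------------------------------------------------------------------
# Parameter packing: per item x = (log a1, d_1, log g_2 .. log g_{K-1}) with
# d_k = d_1 - sum_{m<=k} g_m, guaranteeing d strictly descending.
# ---------------------------------------------------------------------------

def _pack(a1: np.ndarray, d: np.ndarray) -> np.ndarray:
    gaps = d[:, :-1] - d[:, 1:]
    x = np.empty((d.shape[0], d.shape[1] + 1))
    x[:, 0] = np.log(a1)
    x[:, 1] = d[:, 0]
    if d.shape[1] > 1:
        x[:, 2:] = np.log(np.maximum(gaps, 1e-6))
    return x


def _unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a1 = np.exp(x[:, 0])
    Km1 = x.shape[1] - 1
    d = np.empty((x.shape[0], Km1))
    d[:, 0] = x[:, 1]
    if Km1 > 1:
        d[:, 1:] = x[:, 1, None] - np.cumsum(np.exp(x[:, 2:]), axis=1)
    return a1, d


def _expected_neg_loglik_and_grad(
    x_flat: np.ndarray, r: np.ndarray, nodes: np.ndarray
) -> tuple[float, np.ndarray]:
    """Block objective for the M-step: -sum_j,q,k r[j,q,k] log P[j,q,k].

    Separable across items; gradient derived through the boundary logits
    eta[j,q,m] = a1_j * node_q + d_{jm}:

        dF/d eta_m = W_m * (G_m - G_{m+1}),   W = P*(1-P*),  G_k = r_k / P_k.
    """
    J, Q, K = r.shape
    x = x_flat.reshape(J, K)
    a1, d = _unpack(x)
    pstar = boundary_probs(nodes, a1, d)            # (J, Q, K-1)
    # keep saturated boundaries off exact 0/1 so G = r/P and W stay finite
    # even when the line search probes extreme slopes/intercepts
    np.clip(pstar, 1e-12, 1.0 - 1e-12, out=pstar)
    probs = probs_from_boundaries(pstar)            # (J, Q, K)
    np.clip(probs, 1e-12, None, out=probs)
    f = -np.sum(r * np.log(probs))

    G = r / probs                                   # (J, Q, K)
    W = pstar * (1.0 - pstar)                       # (J, Q, K-1)
    dF_deta = W * (G[:, :, :-1] - G[:, :, 1:])      # (J, Q, K-1)
    dF_dd = dF_deta.sum(axis=1)                     # (J, K-1)
    dF_da1 = np.einsum("jqm,q->j", dF_deta, nodes)  # (J,)

    grad = np.empty_like(x)
    grad[:, 0] = a1 * dF_da1
    # d_k = d_1 - cumulative gaps: d_1 enters every d_k, gap g_t enters d_k for k > t.
    suffix = np.cumsum(dF_dd[:, ::-1], axis=1)[:, ::-1]   # sum_{k>=t} dF/dd_k
    grad[:, 1] = suffix[:, 0]
    if K > 2:
        grad[:, 2:] = -np.exp(x[:, 2:]) * suffix[:, 1:]
    return f, grad.ravel()


def _start_values(
    responses: np.ndarray, K: int, a1_start: float
) -> tuple[np.ndarray, np.ndarray]:
    """Slopes at classic a = 1; intercepts from observed cumulative proportions."""
    n, J = responses.shape
    a1 = np.full(J, a1_start)
    d = np.empty((J, K - 1))
    eps = 1.0 / (2.0 * n)
    for j in range(J):
        counts = np.bincount(responses[:, j], minlength=K)
        p_at_least = 1.0 - np.cumsum(counts)[:-1] / n      # P(X >= k), k = 1..K-1
        p_at_least = np.clip(p_at_least, eps, 1.0 - eps)
        dj = np.log(p_at_least / (1.0 - p_at_least))
        # enforce strict descent for the gap parametrization
        for k in range(1, K - 1):
            dj[k] = min(dj[k], dj[k - 1] - 1e-3)
        d[j] = dj
    return a1, d


def _pattern_loglik(responses: np.ndarray, a1: np.ndarray, d: np.ndarray,
                    nodes: np.ndarray) -> np.ndarray:
    """Log-likelihood of each response pattern at each node, shape (n, Q)."""
    logP = np.log(probs_from_boundaries(boundary_probs(nodes, a1, d)))  # (J, Q, K)
    n = responses.shape[0]
    L = np.zeros((n, logP.shape[1]))
    for j in range(logP.shape[0]):
        L += logP[j][:, responses[:, j]].T
    return L


def em_fit(
    responses: np.ndarray,
    K: int,
    quad: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_cycles: int = 500,
    D: float = DEFAULT_D,
    slope_rescaled: bool = False,
) -> FittedModel:
    """Fit a unidimensional GRM by marginal maximum likelihood EM.

    Parameters
    ----------
    responses
        ``(n, J)`` integer matrix with entries in ``0..K-1``.
    K
        Number of response categories (constant across items).
    quad
        Theta quadrature; defaults to 61 nodes on [-6, 6].
    tol
        Convergence threshold on the max absolute change of any (a1, d)
        parameter between cycles.
    max_cycles
        Cycle cap; hitting it returns ``converged=False``.

    Raises
    ------
    DegenerateItemError
        If any item's responses are constant (its slope is unidentified).
    """
    responses = np.asarray(responses)
    if responses.ndim != 2:
        raise ValueError("responses must be a 2-D respondent-by-item matrix")
    n, J = responses.shape
    if n < MIN_SAMPLE_SIZE:
        raise ValueError(f"need at least {MIN_SAMPLE_SIZE} respondents, got {n}")
    if K < 2:
        raise ValueError(f"need K >= 2 categories, got {K}")
    if responses.min() < 0 or responses.max() > K - 1:
        raise ValueError(f"responses must lie in 0..{K - 1}")
    responses = np.ascontiguousarray(responses, dtype=np.int64)

    warnings: list[str] = []
    for j in range(J):
        counts = np.bincount(responses[:, j], minlength=K)
        if (counts > 0).sum() < 2:
            raise DegenerateItemError(
                f"item {j}: all responses in category {int(responses[0, j])}"
            )
        if (counts == 0).any():
            missing = np.where(counts == 0)[0].tolist()
            warnings.append(f"item {j}: unobserved categories {missing}")

    if quad is None:
        quad = make_quadrature()
    nodes, logw = quad.nodes, np.log(quad.weights)
    Q = quad.size

    a1, d = _start_values(responses, K, a1_start=D if slope_rescaled else 1.0)
    x = _pack(a1, d)
    bounds = [(_LOG_A1_BOUNDS[0], _LOG_A1_BOUNDS[1]), _D1_BOUNDS] + \
             [_LOG_GAP_BOUNDS] * (K - 2)
    bounds_flat = bounds * J

    trace: list[float] = []
    converged = False
    n_cycles = 0
    # per-category respondent masks, reused every E-step
    masks = [[responses[:, j] == k for k in range(K)] for j in range(J)]

    for cycle in range(1, max_cycles + 1):
        n_cycles = cycle
        # E-step: posterior over nodes, marginal loglik, expected counts
        L = _pattern_loglik(responses, a1, d, nodes)          # (n, Q)
        M = L + logw[None, :]
        trace.append(float(logsumexp(M, axis=1).sum()))
        mx = M.max(axis=1, keepdims=True)
        post = np.exp(M - mx)
        post /= post.sum(axis=1, keepdims=True)               # (n, Q)

        r = np.zeros((J, Q, K))
        for j in range(J):
            for k, mask in enumerate(masks[j]):
                if mask.any():
                    r[j, :, k] = post[mask].sum(axis=0)

        # M-step: block quasi-Newton with analytic gradients
        res = minimize(
            _expected_neg_loglik_and_grad,
            x.ravel(),
            args=(r, nodes),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds_flat,
            options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-7},
        )
        x_new = res.x.reshape(J, K)
        a1_new, d_new = _unpack(x_new)

        delta = max(np.abs(a1_new - a1).max(), np.abs(d_new - d).max())
        a1, d, x = a1_new, d_new, x_new
        if delta < tol:
            converged = True
            break

    if np.abs(d).max() > MAX_ABS_INTERCEPT + 1e-9:
        d = np.clip(d, -MAX_ABS_INTERCEPT, MAX_ABS_INTERCEPT)
        warnings.append("intercepts clipped to |d| <= 30")

    theta_eap, theta_psd = eap_scores(responses, a1, d, quad)
    return FittedModel(
        a1_hat=a1,
        d_hat=d,
        D=D,
        theta_eap=theta_eap,
        theta_psd=theta_psd,
        loglik_trace=np.asarray(trace),
        n_cycles=n_cycles,
        converged=converged,
        slope_rescaled=slope_rescaled,
        warnings=warnings,
    )


def eap_scores(
    responses: np.ndarray,
    a1: np.ndarray,
    d: np.ndarray,
    quad: QuadratureGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected-a-posteriori theta estimates and posterior SDs.

    For respondent *i* with pattern likelihood :math:`L_i(\\theta_q)` and
    prior weights :math:`w_q`,

    .. math:: \\hat\\theta_i = \\frac{\\sum_q \\theta_q w_q L_i(\\theta_q)}
                                    {\\sum_q w_q L_i(\\theta_q)},

    and the posterior SD is computed under the same discrete posterior.
    Pattern likelihoods are evaluated in log space, so posterior mass never
    underflows to zero for any finite pattern.
    """
    if quad is None:
        quad = make_quadrature()
    responses = np.ascontiguousarray(np.asarray(responses), dtype=np.int64)
    a1 = np.asarray(a1, dtype=float)
    d = np.asarray(d, dtype=float)
    L = _pattern_loglik(responses, a1, d, quad.nodes)         # (n, Q)
    M = L + np.log(quad.weights)[None, :]
    post = np.exp(M - M.max(axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)
    eap = post @ quad.nodes
    second = post @ quad.nodes**2
    psd = np.sqrt(np.maximum(second - eap**2, 0.0))
    return eap, psd
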