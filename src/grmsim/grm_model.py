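"""Samejima's graded response model (GRM): probabilities and response generation.

The GRM describes ordinal item responses through boundary ("operating
characteristic") curves.  For item *j* with discrimination :math:`a_j` and
ascending category locations :math:`b_{j1} \\le \\dots \\le b_{j,K-1}`, the
probability of responding in category *k* **or above** is logistic,

.. math::

    P^*_{jk}(\\theta) = \\mathrm{logit}^{-1}\\bigl(D a_j (\\theta - b_{jk})\\bigr)
                      = \\mathrm{logit}^{-1}(a^{(1)}_j \\theta + d_{jk}),

with the scaling constant :math:`D` (1.701 aligns the logistic with the
normal ogive), internal slope :math:`a^{(1)}_j = D a_j` and intercept
:math:`d_{jk} = -D a_j b_{jk}`.  Category probabilities are adjacent
differences :math:`P_{jk} = P^*_{jk} - P^*_{j,k+1}` with
:math:`P^*_{j0} \\equiv 1` and :math:`P^*_{jK} \\equiv 0`.

Categories are coded 0-based throughout (``0 .. K-1``); any 1-based external
data must be shifted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

#: Default logistic-to-normal-ogive scaling constant.
DEFAULT_D: float = 1.701

#: Probabilities are clipped here before logs to avoid -inf likelihoods.
PROB_FLOOR: float = 1e-300


@dataclass(frozen=True)
class ItemBank:
    """True item parameters for a set of *J* graded items with *K* categories.

    Parameters
    ----------
    a
        Discriminations on the classic IRT scale, shape ``(J,)``, positive.
    b
        Category locations in theta units, shape ``(J, K-1)``, each row
        ascending.  ``b[j, k]`` is the theta at which the probability of
        responding in category ``k+1`` or above equals one half.
    D
        Scaling constant used to construct the intercepts.
    slope_rescaled
        Convention switch for the slope the response model receives.  With
        the default ``False``, the logit of boundary *k* is
        ``a * theta + d_k = a * (theta - D * b_k)`` — the slope enters
        unrescaled and the scaling constant effectively stretches the
        thresholds (this is what common IRT simulators do when handed
        ``(a, d)`` directly, and is the convention under which the reference
        recovery levels are obtained).  With ``True``, the logit is
        ``D * a * (theta - b_k)``: the boundary sits exactly at
        ``theta = b_k`` and ``D`` acts as a pure slope rescaling.

    The intercepts ``d = -D * a[:, None] * b`` are derived on construction
    under either convention.
    """

    a: np.ndarray
    b: np.ndarray
    D: float = DEFAULT_D
    slope_rescaled: bool = False
    d: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        b = np.atleast_2d(np.asarray(self.b, dtype=float))
        if a.ndim != 1 or b.ndim != 2 or b.shape[0] != a.shape[0]:
            raise ValueError(
                f"shape mismatch: a has {a.shape}, b has {b.shape}; "
                "expected (J,) and (J, K-1)"
            )
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("item parameters must be finite")
        if (a <= 0).any():
            raise ValueError("discriminations must be positive")
        if self.D <= 0:
            raise ValueError(f"scaling constant D must be positive, got {self.D}")
        if (np.diff(b, axis=1) < 0).any():
            bad = np.where((np.diff(b, axis=1) < 0).any(axis=1))[0]
            raise ValueError(f"category locations must be ascending; items {bad.tolist()} are not")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "d", -self.D * a[:, None] * b)

    @property
    def J(self) -> int:
        """Number of items."""
        return self.a.shape[0]

    @property
    def K(self) -> int:
        """Number of response categories per item."""
        return self.b.shape[1] + 1

    @property
    def a1(self) -> np.ndarray:
        """Internal slopes (the coefficient of theta in the boundary logit)."""
        return self.D * self.a if self.slope_rescaled else self.a.copy()

    @classmethod
    def from_intercepts(
        cls, a: np.ndarray, d: np.ndarray, D: float = DEFAULT_D,
        slope_rescaled: bool = False,
    ) -> "ItemBank":
        """Build a bank from classic slopes and intercepts, recovering b = -d/(D a)."""
        a = np.atleast_1d(np.asarray(a, dtype=float))
        d = np.atleast_2d(np.asarray(d, dtype=float))
        b = -d / (D * a[:, None])
        return cls(a=a, b=b, D=D, slope_rescaled=slope_rescaled)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: columns ``item, a, b_1..b_{K-1}, d_1..d_{K-1}``."""
        Km1 = self.K - 1
        data: dict[str, np.ndarray] = {"item": np.arange(self.J)}
        data["a"] = self.a
        for k in range(Km1):
            data[f"b_{k + 1}"] = self.b[:, k]
        for k in range(Km1):
            data[f"d_{k + 1}"] = self.d[:, k]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, D: float = DEFAULT_D, slope_rescaled: bool = False) -> "ItemBank":
        """Read a bank from the CSV schema written by :meth:`to_csv`.

        The ``b`` columns are authoritative; ``d`` columns, if present, are
        checked against ``-D a b`` and rejected on disagreement (mixed
        conventions are a common silent error in IRT file exchange).
        """
        df = pd.read_csv(path)
        if "a" not in df.columns:
            raise ValueError("item bank CSV must have an 'a' column")
        b_cols = sorted((c for c in df.columns if c.startswith("b_")), key=lambda c: int(c[2:]))
        if not b_cols:
            raise ValueError("item bank CSV must have b_1..b_{K-1} columns")
        bank = cls(a=df["a"].to_numpy(), b=df[b_cols].to_numpy(), D=D,
                   slope_rescaled=slope_rescaled)
        d_cols = sorted((c for c in df.columns if c.startswith("d_")), key=lambda c: int(c[2:]))
        if d_cols:
            d_file = df[d_cols].to_numpy()
            if not np.allclose(d_file, bank.d, atol=1e-8):
                raise ValueError(
                    "d columns disagree with -D*a*b; check the scaling constant or the file"
                )
        return bank


def cumulative_prob(theta, a, b_k, D: float = DEFAULT_D):
    """Boundary probability P* of responding in a given category or above.

    ``logit P* = D * a * (theta - b_k)``; strictly increasing in ``theta``
    and strictly decreasing in the location ``b_k``.
    """
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.isfinite(a) and np.isfinite(b_k) and np.isfinite(D)):
        raise ValueError("cumulative_prob requires finite inputs")
    if a <= 0 or D <= 0:
        raise ValueError("cumulative_prob requires a > 0 and D > 0")
    return expit(D * a * (theta - b_k))


def boundary_probs(theta, a1, d):
    """All boundary probabilities from internal slopes and intercepts.

    Parameters
    ----------
    theta : array, shape (T,)
    a1 : array, shape (J,)
        Internal slopes (``D * a``).
    d : array, shape (J, K-1)
        Intercepts, each row strictly descending for ascending locations.

    Returns
    -------
    array, shape (J, T, K-1)
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    a1 = np.asarray(a1, dtype=float)
    d = np.asarray(d, dtype=float)
    return expit(a1[:, None, None] * theta[None, :, None] + d[:, None, :])


def probs_from_boundaries(pstar: np.ndarray) -> np.ndarray:
    """Adjacent differences of boundary curves -> category probabilities.

    ``pstar`` has shape ``(..., K-1)``; the result has shape ``(..., K)`` and
    sums to 1 along the last axis.  Values are floored at ``PROB_FLOOR``.
    """
    shape = pstar.shape[:-1]
    K = pstar.shape[-1] + 1
    probs = np.empty(shape + (K,), dtype=float)
    probs[..., 0] = 1.0 - pstar[..., 0]
    if K > 2:
        probs[..., 1:-1] = pstar[..., :-1] - pstar[..., 1:]
    probs[..., -1] = pstar[..., -1]
    np.clip(probs, PROB_FLOOR, None, out=probs)
    return probs


def category_probs(
    theta, a, b, D: float = DEFAULT_D, slope_rescaled: bool = False
) -> np.ndarray:
    """Category probabilities for one item at one or many theta values.

    Adjacent differences of the boundary curves under the given slope
    convention (see :class:`ItemBank`); with ``slope_rescaled=True`` the
    boundary curves equal :func:`cumulative_prob` at the same ``(a, b, D)``.

    Parameters
    ----------
    theta : scalar or array, shape (T,)
    a : float
        Discrimination on the classic scale.
    b : array, shape (K-1,)
        Ascending category locations.

    Returns
    -------
    array, shape (K,) for scalar theta, else (T, K); nonnegative, sums to 1.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if (np.diff(b) < 0).any():
        raise ValueError(f"category locations must be ascending, got {b}")
    scalar = np.isscalar(theta) or np.asarray(theta).ndim == 0
    a1 = D * a if slope_rescaled else a
    d = -D * a * b
    pstar = boundary_probs(theta, np.array([a1]), d[None, :])[0]  # (T, K-1)
    probs = probs_from_boundaries(pstar)
    return probs[0] if scalar else probs


def simulate_responses(thetas, bank: ItemBank, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical GRM response per (respondent, item).

    Uses the inverse-CDF trick on the boundary curves: with ``u ~ U(0,1)``,
    the response is the number of boundaries whose P* exceeds ``u`` (valid
    because P* is nonincreasing across boundaries).

    Returns an ``(len(thetas), J)`` integer matrix with entries in ``0..K-1``.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    if thetas.size == 0:
        raise ValueError("simulate_responses requires at least one theta")
    pstar = boundary_probs(thetas, bank.a1, bank.d)  # (J, n, K-1)
    u = rng.random(size=(thetas.shape[0], bank.J))
    responses = (u.T[:, :, None] < pstar).sum(axis=2)  # (J, n)
    return np.ascontiguousarray(responses.T, dtype=np.int64)
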