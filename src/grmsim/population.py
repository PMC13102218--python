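"""Condition-level truth: item banks, finite latent-trait populations, samples.

A simulation *condition* is a cell of the design grid (sample size ``n``,
item count ``J``, category count ``K``).  For each condition one finite
population is built: ``N_pop = ceil(n / 0.001)`` latent traits drawn from
N(0, 1) together with a single item bank (``a ~ U(0.5, 2.5)``; ``K - 1``
locations per item ``~ U(-2, 2)`` sorted ascending; intercepts
``d = -D a b`` with ``D = 1.701``).  Replications then draw samples of size
``n`` without replacement from that fixed population — the sampling fraction
is 0.001, which is what makes the finite-population correction of the
theta-RMSE meaningful — and generate fresh responses for the sampled
respondents.

Seeding is hierarchical: every random stream is keyed by
``(base_seed, n, J, K[, replication])`` through ``numpy``'s
``SeedSequence``, so results are reproducible regardless of the order in
which conditions or replications execute.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil

import numpy as np
import pandas as pd

from .grm_model import DEFAULT_D, ItemBank, simulate_responses

#: Finite-population sampling fraction n / N_pop (exact rational to keep
#: ceil(n / fraction) free of binary-float artefacts).
SAMPLING_FRACTION = Fraction(1, 1000)

# Design grid of the reference Monte Carlo study.
GRID_N_VALUES: tuple[int, ...] = tuple(range(500, 1501, 100))
GRID_J_VALUES: tuple[int, ...] = tuple(range(5, 51, 5))
GRID_K_VALUES: tuple[int, ...] = (4, 5, 6, 7)
GRID_REPLICATIONS: int = 100
GRID_BASE_SEED: int = 123


def population_size(n: int) -> int:
    """N_pop = ceil(n / sampling fraction); e.g. n = 500 -> 500,000."""
    return ceil(n / SAMPLING_FRACTION)


@dataclass(frozen=True)
class Condition:
    """One cell of the design grid plus its replication count and seed."""

    n: int
    J: int
    K: int
    R: int = GRID_REPLICATIONS
    base_seed: int = GRID_BASE_SEED

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be positive, got n={self.n}")
        if self.J < 2:
            raise ValueError(f"need at least 2 items, got J={self.J}")
        if self.K < 2:
            raise ValueError(f"need at least 2 response categories, got K={self.K}")
        if self.R < 1:
            raise ValueError(f"replication count must be >= 1, got R={self.R}")

    @property
    def N_pop(self) -> int:
        return population_size(self.n)

    def seed_sequence(self, *extra: int) -> np.random.SeedSequence:
        """Collision-resistant child seed keyed by the condition (and extras)."""
        return np.random.SeedSequence((self.base_seed, self.n, self.J, self.K, *extra))

    def rng(self, *extra: int) -> np.random.Generator:
        return np.random.default_rng(self.seed_sequence(*extra))


@dataclass(frozen=True)
class Population:
    """The fixed truth of one condition: theta pool plus item bank.

    Only the ``N_pop`` latent traits are materialized (about 12 MB at the
    largest grid cell); responses are generated per drawn sample, never for
    the whole population.
    """

    thetas: np.ndarray
    bank: ItemBank
    condition: Condition

    @property
    def N_pop(self) -> int:
        return self.thetas.shape[0]


@dataclass(frozen=True)
class SampleData:
    """One replication's draw: indices into the population, true thetas, responses."""

    indices: np.ndarray
    theta_true: np.ndarray
    responses: np.ndarray

    @property
    def n(self) -> int:
        return self.responses.shape[0]


def generate_item_bank(
    J: int, K: int, rng: np.random.Generator, D: float = DEFAULT_D,
    slope_rescaled: bool = False,
) -> ItemBank:
    """Draw a true item bank: a ~ U(0.5, 2.5); sorted locations ~ U(-2, 2)."""
    if J < 2 or K < 2:
        raise ValueError(f"item bank needs J >= 2 and K >= 2, got J={J}, K={K}")
    a = rng.uniform(0.5, 2.5, size=J)
    b = np.sort(rng.uniform(-2.0, 2.0, size=(J, K - 1)), axis=1)
    return ItemBank(a=a, b=b, D=D, slope_rescaled=slope_rescaled)


def generate_population(
    condition: Condition, rng: np.random.Generator | None = None, D: float = DEFAULT_D,
    slope_rescaled: bool = False,
) -> Population:
    """Build the condition's fixed population (item bank first, then thetas).

    With ``rng=None`` the stream is derived from the condition's hierarchical
    seed, so the same condition always yields a bit-identical population.
    """
    if rng is None:
        rng = condition.rng()
    bank = generate_item_bank(condition.J, condition.K, rng, D=D,
                              slope_rescaled=slope_rescaled)
    thetas = rng.standard_normal(condition.N_pop)
    return Population(thetas=thetas, bank=bank, condition=condition)


def draw_sample(pop: Population, rng: np.random.Generator) -> SampleData:
    """Draw ``n`` respondents without replacement and generate their responses."""
    n = pop.condition.n
    if n > pop.N_pop:
        raise ValueError(f"cannot draw n={n} from a population of {pop.N_pop}")
    indices = rng.choice(pop.N_pop, size=n, replace=False)
    theta_true = pop.thetas[indices]
    responses = simulate_responses(theta_true, pop.bank, rng)
    return SampleData(indices=indices, theta_true=theta_true, responses=responses)


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Sample files carry a '#'-prefixed JSON header recording
# the condition and seed lineage; theta pools are one column of floats.
# ---------------------------------------------------------------------------

def write_sample_csv(path, sample: SampleData, condition: Condition, replication: int) -> None:
    meta = {
        "n": condition.n,
        "J": condition.J,
        "K": condition.K,
        "replication": replication,
        "seed_lineage": [condition.base_seed, condition.n, condition.J, condition.K, replication],
    }
    df = pd.DataFrame(sample.responses, columns=[f"item_{j}" for j in range(condition.J)])
    df.insert(0, "theta_true", sample.theta_true)
    df.insert(0, "pop_index", sample.indices)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False)


def read_sample_csv(path) -> tuple[SampleData, dict]:
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        body = fh.read() if first.startswith("#") else first + fh.read()
    df = pd.read_csv(io.StringIO(body))
    item_cols = [c for c in df.columns if c.startswith("item_")]
    sample = SampleData(
        indices=df["pop_index"].to_numpy(dtype=np.int64),
        theta_true=df["theta_true"].to_numpy(dtype=float),
        responses=df[item_cols].to_numpy(dtype=np.int64),
    )
    return sample, meta


def write_theta_csv(path, pop: Population) -> None:
    c = pop.condition
    meta = {"n": c.n, "J": c.J, "K": c.K, "N_pop": pop.N_pop, "base_seed": c.base_seed}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("theta\n")
        np.savetxt(fh, pop.thetas, fmt="%.17g")


def read_theta_csv(path) -> np.ndarray:
    return np.loadtxt(path, comments="#", skiprows=2)
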