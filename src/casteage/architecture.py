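"""Mutational architecture: pleiotropic structure of mutational effects.

A gene regulatory network controls ``4k`` trait values — two castes
(queen, worker) times two traits (survival, fecundity) times ``k`` age
classes.  Antagonistic pleiotropy between trait values is encoded as a
``4k x 4k`` partial-correlation matrix ``P`` whose off-diagonal structure
depends on the scenario:

``baseline``
    no pleiotropy; ``P`` is the identity.
``WCWT`` (within-caste, within-trait)
    a mutation on a trait at age ``a`` carries a correlated effect on the
    same trait in the same caste ``delay`` age classes later.
``WCBT`` (within-caste, between-trait)
    queen fecundity at age ``a`` is coupled to queen survival at age
    ``a + delay``.
``BCWT`` (between-caste, within-trait)
    queen survival at age ``a`` is coupled to worker survival at the same
    age.
``BCBT`` (between-caste, between-trait)
    queen fecundity at age ``a`` is coupled to worker survival at the same
    age.

Workers are sterile, so no scenario attaches pleiotropic effects to the
worker-fecundity block.

``P`` is converted to a mutational covariance ``Sigma`` through the
Gaussian-graphical-model identity between partial correlations and the
precision matrix, with a nearest-correlation (Higham-style) repair when
the banded structures are indefinite.  Mutations are single draws from a
``4k``-dimensional multivariate normal with mean ``b`` (biased downward)
in every coordinate and covariance ``Sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCENARIOS",
    "CASTES",
    "TRAITS",
    "BLOCK_ORDER",
    "ConfigurationError",
    "RepairError",
    "TraitIndexLayout",
    "RepairInfo",
    "MutationArchitecture",
    "build_partial_correlation",
    "nearest_correlation",
    "partial_to_covariance",
    "sample_mutation",
    "export_matrix_csv",
]

SCENARIOS = ("baseline", "WCWT", "WCBT", "BCWT", "BCBT")
CASTES = ("queen", "worker")
TRAITS = ("survival", "fecundity")

#: Fixed flat layout: four contiguous blocks of length k each.
BLOCK_ORDER = (
    ("queen", "survival"),
    ("queen", "fecundity"),
    ("worker", "survival"),
    ("worker", "fecundity"),
)


class ConfigurationError(ValueError):
    """Invalid simulation or architecture configuration."""


class RepairError(RuntimeError):
    """Positive-definiteness repair failed to converge."""


@dataclass(frozen=True)
class TraitIndexLayout:
    """Bijection between (caste, trait, age) and a flat index in [0, 4k).

    Ages are 1-based (age classes ``1..k``); flat indices are 0-based.
    Block order is queen survival, queen fecundity, worker survival,
    worker fecundity.
    """

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")

    @property
    def n(self) -> int:
        return 4 * self.k

    def block_index(self, caste: str, trait: str) -> int:
        try:
            return BLOCK_ORDER.index((caste, trait))
        except ValueError:
            raise ConfigurationError(f"unknown caste/trait: {caste!r}/{trait!r}") from None

    def block_start(self, caste: str, trait: str) -> int:
        return self.block_index(caste, trait) * self.k

    def block_slice(self, caste: str, trait: str) -> slice:
        start = self.block_start(caste, trait)
        return slice(start, start + self.k)

    def index(self, caste: str, trait: str, age: int) -> int:
        if not 1 <= age <= self.k:
            raise ConfigurationError(f"age {age} outside [1, {self.k}]")
        return self.block_start(caste, trait) + age - 1

    def decode(self, flat: int) -> tuple[str, str, int]:
        if not 0 <= flat < self.n:
            raise ConfigurationError(f"flat index {flat} outside [0, {self.n})")
        caste, trait = BLOCK_ORDER[flat // self.k]
        return caste, trait, flat % self.k + 1

    def labels(self) -> list[str]:
        """Flat-index labels like ``Q_surv_a1`` for CSV headers."""
        short = {("queen", "survival"): "Q_surv", ("queen", "fecundity"): "Q_fec",
                 ("worker", "survival"): "W_surv", ("worker", "fecundity"): "W_fec"}
        return [f"{short[(c, t)]}_a{a}" for (c, t) in BLOCK_ORDER for a in range(1, self.k + 1)]


def _validate_scenario_args(scenario: str, k: int, rho: float, delay: int) -> None:
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError(f"rho must lie in [-1, 1], got {rho}")
    if delay < 1:
        raise ConfigurationError(f"delay must be >= 1, got {delay}")
    if k <= delay:
        raise ConfigurationError(
            f"k must exceed delay (k={k}, delay={delay}): no insertable positions"
        )


def build_partial_correlation(scenario: str, k: int, rho: float, delay: int) -> np.ndarray:
    """Build the scenario's 4k x 4k partial-correlation matrix.

    Delayed effects sit ``delay`` columns to the right of the diagonal of
    the affected submatrix — absent for the last ``delay`` age classes,
    where the effect would act beyond the maximum age — and are mirrored
    below the diagonal so that ``P`` is symmetric.  The worker-fecundity
    block never carries off-diagonal entries (workers are sterile).
    """
    _validate_scenario_args(scenario, k, rho, delay)
    layout = TraitIndexLayout(k)
    P = np.eye(layout.n)
    ages = np.arange(1, k - delay + 1)  # ages with a within-horizon delayed partner

    def couple(caste_i, trait_i, age_i, caste_j, trait_j, age_j):
        i = layout.block_start(caste_i, trait_i) + age_i - 1
        j = layout.block_start(caste_j, trait_j) + age_j - 1
        P[i, j] = rho
        P[j, i] = rho

    if scenario == "baseline":
        pass
    elif scenario == "WCWT":
        # Delayed same-trait effects in every block except worker fecundity.
        for caste, trait in (("queen", "survival"), ("queen", "fecundity"),
                             ("worker", "survival")):
            for a in ages:
                couple(caste, trait, a, caste, trait, a + delay)
    elif scenario == "WCBT":
        for a in ages:
            couple("queen", "fecundity", a, "queen", "survival", a + delay)
    elif scenario == "BCWT":
        for a in range(1, k + 1):
            couple("queen", "survival", a, "worker", "survival", a)
    elif scenario == "BCBT":
        for a in range(1, k + 1):
            couple("queen", "fecundity", a, "worker", "survival", a)
    return P


@dataclass
class RepairInfo:
    """Record of the positive-definiteness repair applied to a matrix."""

    fired: bool = False
    iterations: int = 0
    frobenius_distance: float = 0.0


def nearest_correlation(mat: np.ndarray, eps: float = 1e-8,
                        max_iter: int = 100) -> tuple[np.ndarray, RepairInfo]:
    """Project a symmetric unit-diagonal matrix onto the PD correlation cone.

    Alternating projections with Dykstra correction: clip eigenvalues at
    ``eps``, restore the unit diagonal, iterate.  A matrix whose smallest
    eigenvalue already meets ``eps`` is returned unchanged (idempotence).
    """
    mat = np.asarray(mat, dtype=float)
    w = np.linalg.eigvalsh(mat)
    if w[0] >= eps - 1e-15:
        return mat, RepairInfo(fired=False)

    Y = mat.copy()
    dS = np.zeros_like(mat)
    info = RepairInfo(fired=True)
    for it in range(1, max_iter + 1):
        R = Y - dS
        w, V = np.linalg.eigh(R)
        X = (V * np.clip(w, eps, None)) @ V.T
        X = (X + X.T) / 2.0
        dS = X - R
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        wy = np.linalg.eigvalsh(Y)
        if wy[0] >= eps * 0.5:
            info.iterations = it
            info.frobenius_distance = float(np.linalg.norm(Y - mat))
            return Y, info
    raise RepairError(
        f"nearest-correlation projection did not converge in {max_iter} iterations"
    )


def partial_to_covariance(P: np.ndarray, sigma: float,
                          return_info: bool = False):
    """Convert a partial-correlation matrix to a mutational covariance.

    Uses the Gaussian-graphical-model identity: build a precision-like
    matrix ``Omega`` with unit diagonal and off-diagonal ``-P_ij``, repair
    it to positive definiteness if needed, invert, rescale the inverse to
    unit diagonal, and scale by ``sigma**2``.  The covariance diagonal is
    therefore exactly ``sigma**2``; off-diagonal marginal correlations
    carry the sign of the partial correlations but generally smaller
    magnitude, and can deviate further when the repair fires.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ConfigurationError("P must be square")
    if not np.allclose(P, P.T, atol=1e-12):
        raise ConfigurationError("P must be symmetric")
    if not np.allclose(np.diag(P), 1.0, atol=1e-12):
        raise ConfigurationError("P must have a unit diagonal")
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be > 0, got {sigma}")

    omega = -P.copy()
    np.fill_diagonal(omega, 1.0)
    omega, info = nearest_correlation(omega)
    cov = np.linalg.inv(omega)
    cov = (cov + cov.T) / 2.0
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    Sigma = sigma ** 2 * corr
    if return_info:
        return Sigma, info
    return Sigma


@dataclass
class MutationArchitecture:
    """Scenario identity plus the derived mutation sampling distribution.

    ``b`` is the mean mutational effect size (the downward mutation bias,
    applied to every coordinate), ``sigma`` the per-coordinate standard
    deviation, ``rho`` the partial correlation of the scenario's
    antagonistic couplings, and ``delay`` the age-class offset of delayed
    effects.
    """

    scenario: str
    k: int = 20
    rho: float = -0.8
    delay: int = 5
    b: float = -0.2
    sigma: float = 0.4
    P: np.ndarray = field(init=False, repr=False)
    Sigma: np.ndarray = field(init=False, repr=False)
    mean_vector: np.ndarray = field(init=False, repr=False)
    repair: RepairInfo = field(init=False, repr=False)
    _chol: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.P = build_partial_correlation(self.scenario, self.k, self.rho, self.delay)
        self.Sigma, self.repair = partial_to_covariance(self.P, self.sigma,
                                                        return_info=True)
        self.mean_vector = np.full(4 * self.k, self.b)
        try:
            self._chol = np.linalg.cholesky(self.Sigma)
        except np.linalg.LinAlgError:
            # PSD but numerically singular: tiny diagonal jitter.
            jitter = 1e-12 * self.sigma ** 2
            self._chol = np.linalg.cholesky(
                self.Sigma + jitter * np.eye(4 * self.k)
            )

    @property
    def layout(self) -> TraitIndexLayout:
        return TraitIndexLayout(self.k)


def sample_mutation(architecture: MutationArchitecture,
                    rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Draw mutational effect vectors: MVN(mean = b, cov = Sigma).

    Returns shape ``(4k,)`` for ``size=None`` else ``(size, 4k)``.
    """
    n = 4 * architecture.k
    if size is None:
        z = rng.standard_normal(n)
        return architecture.mean_vector + architecture._chol @ z
    z = rng.standard_normal((size, n))
    return architecture.mean_vector + z @ architecture._chol.T


def export_matrix_csv(matrix: np.ndarray, layout: TraitIndexLayout, path) -> None:
    """Write a dense 4k x 4k matrix as CSV with flat-index labels."""
    labels = layout.labels()
    header = ",".join(labels)
    np.savetxt(path, matrix, delimiter=",", header=header, comments="")
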