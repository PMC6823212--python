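"""Synthetic hierarchical datasets with known truth.

Two canonical study designs are provided, mirroring the conditions under
which the sampler's recovery behaviour is characterised:

* ``simulation1_design`` — a two-dimensional 30-item test taken by 2,000
  students in 10 equal schools, one person covariate and one school
  covariate, every coefficient random across schools.
* ``simulation2_design`` — a four-dimensional test with N in
  {1000, 2000, 3000} students and K in {40, 100, 200} items split evenly
  over four subtests, same structural layout.

Every stochastic component (item bank, covariates, coefficients, abilities,
responses) consumes an independent child stream spawned from the master
seed, so regenerating one component leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import truncated_normal
from .model import (
    HierarchicalDataset,
    ItemParameters,
    ModelError,
    ModelSpec,
    apply_identification_constraints,
    full_random_spec,
    response_probability,
)

# Canonical true item parameters of the two-dimensional 30-item reference
# design (items 1-2 are the identification anchors; columns a_k1, a_k2, b_k).
REFERENCE_ITEMS_2D = np.array([
    [1.000, 0.000, 0.000],
    [0.000, 1.000, 0.000],
    [0.914, 0.686, -1.182],
    [1.102, 1.468, 0.441],
    [2.055, 1.428, -1.197],
    [2.291, 1.146, -2.536],
    [2.131, 0.758, 1.782],
    [1.027, 1.720, 0.152],
    [0.569, 1.119, 0.964],
    [0.578, 2.129, 1.462],
    [0.795, 1.445, 0.619],
    [2.279, 1.148, -2.020],
    [0.714, 2.225, 0.602],
    [2.200, 1.465, 0.127],
    [1.565, 0.728, -0.587],
    [2.419, 2.408, -0.218],
    [1.561, 1.398, 0.830],
    [2.457, 2.111, 1.558],
    [0.714, 0.918, 1.504],
    [2.447, 1.704, 0.126],
    [1.588, 2.170, -0.760],
    [1.724, 1.590, 0.769],
    [2.273, 0.948, 0.265],
    [1.228, 2.782, -1.398],
    [0.687, 2.261, 1.802],
    [1.665, 0.572, 0.033],
    [2.383, 1.871, 1.307],
    [1.778, 2.326, -0.871],
    [1.522, 2.909, 0.241],
    [1.173, 1.703, 0.397],
])

# Structural truths of the two-dimensional design: per dimension the flat
# fixed-effect vector (gamma_00q, gamma_01q, gamma_10q, gamma_11q).
SIM1_GAMMA = [
    np.array([1.000, 0.300, 0.500, 0.350]),
    np.array([-0.350, 0.300, 0.500, -1.000]),
]
SIM1_SIGMA_E = np.array([[0.300, 0.075], [0.075, 0.500]])
SIM1_TAU = 0.100  # level-3 variance of each random coefficient; covariances 0

# Four-dimensional design truths: same fixed-effect vector on every dimension,
# level-2 variances rising across dimensions with common covariance 0.075.
SIM2_GAMMA_PER_DIM = np.array([1.000, 0.300, 0.500, 0.350])
SIM2_SIGMA_E_DIAG = np.array([0.300, 0.500, 0.750, 1.000])
SIM2_SIGMA_E_OFFDIAG = 0.075


@dataclass
class TruthBundle:
    """Generating values for one synthetic dataset."""

    items: ItemParameters
    spec: ModelSpec
    gamma: list[np.ndarray]       # per dimension, flat masked coefficients
    Sigma_e: np.ndarray
    T: list[np.ndarray]           # per dimension, r_q x r_q
    beta: np.ndarray              # (J, h+1, Q) realized school coefficients
    theta: np.ndarray             # (n, Q) realized abilities
    label: str = ""

    def structural_flat(self) -> dict[str, float]:
        """Flat name -> true value table for all structural parameters."""
        out: dict[str, float] = {}
        for q in range(self.spec.n_dim):
            for name, val in zip(self.spec.gamma_names(q), self.gamma[q]):
                out[name] = float(val)
        Q = self.Sigma_e.shape[0]
        for q1 in range(Q):
            for q2 in range(Q):
                out[f"sigma_e{q1 + 1}{q2 + 1}"] = float(self.Sigma_e[q1, q2])
        for q in range(self.spec.n_dim):
            names = self.spec.tau_names(q)
            for name, val in zip(names, self.T[q].ravel()):
                out[name] = float(val)
        return out


def _rngs(seed, n: int) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def generate_item_bank(
    K: int, Q: int, seed, *, disc_mean: float = 1.5, disc_sd: float = 1.0
) -> ItemParameters:
    """Draw a K-item bank: free loadings from N(disc_mean, disc_sd^2)
    truncated to (0, inf), difficulties from N(0, 1), first Q items anchored.
    """
    if K <= Q:
        raise ModelError(f"need K > Q items, got K={K}, Q={Q}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = truncated_normal(rng, disc_mean, disc_sd, lower=0.0, size=(K, Q))
    b = rng.standard_normal(K)
    items = ItemParameters(a, b)
    return apply_identification_constraints(items, Q)


def generate_covariates(
    n: int,
    J: int,
    h: int,
    s: int,
    seed,
    *,
    n_j: list[int] | None = None,
    person_mean: float = 0.25,
    school_mean: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Person and school design matrices with leading constant columns.

    Person covariates are i.i.d. N(person_mean, 1); school covariates i.i.d.
    N(school_mean, 1).  Persons are allocated equally over schools unless an
    explicit per-school size list is given.
    """
    if n_j is None:
        if n % J != 0:
            raise ModelError(
                f"n={n} not divisible by J={J}; pass an explicit n_j allocation"
            )
        n_j = [n // J] * J
    if sum(n_j) != n:
        raise ModelError(f"school sizes {n_j} sum to {sum(n_j)}, expected n={n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = np.ones((n, h + 1))
    if h:
        X[:, 1:] = rng.normal(person_mean, 1.0, size=(n, h))
    W = np.ones((J, s + 1))
    if s:
        W[:, 1:] = rng.normal(school_mean, 1.0, size=(J, s))
    school_index = np.repeat(np.arange(J), n_j)
    return X, W, school_index


def generate_regression_coefficients(
    gamma: list[np.ndarray],
    T: list[np.ndarray],
    school_design: np.ndarray,
    spec: ModelSpec,
    seed,
) -> np.ndarray:
    """Realize per-school coefficients beta (J, h+1, Q).

    Each coefficient's mean is the masked school-design regression on its
    fixed effects; random coefficients add a multivariate-normal residual
    with covariance T_q (jointly over that dimension's random coefficients).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    J = school_design.shape[0]
    P, Q = spec.random.shape
    beta = np.zeros((J, P, Q))
    for q in range(Q):
        g = np.asarray(gamma[q], dtype=float)
        pos = 0
        means = np.zeros((J, P))
        for p in range(P):
            cols = np.flatnonzero(spec.school_mask[p, :, q])
            means[:, p] = school_design[:, cols] @ g[pos:pos + len(cols)]
            pos += len(cols)
        if pos != len(g):
            raise ModelError(
                f"gamma for dimension {q} has length {len(g)}, expected {pos}"
            )
        beta[:, :, q] = means
        ridx = spec.random_idx(q)
        if len(ridx):
            Tq = np.asarray(T[q], dtype=float)
            if Tq.shape != (len(ridx), len(ridx)):
                raise ModelError(f"T[{q}] must be {len(ridx)}x{len(ridx)}")
            eig = np.linalg.eigvalsh(Tq)
            if eig.min() < -1e-10:
                raise ModelError(f"T[{q}] is not positive semidefinite")
            if np.abs(Tq).max() > 0:
                L = np.linalg.cholesky(Tq + 1e-12 * np.eye(len(ridx)))
                u = rng.standard_normal((J, len(ridx))) @ L.T
                beta[:, ridx, q] += u
    return beta


def generate_abilities(
    person_design: np.ndarray,
    school_index: np.ndarray,
    beta: np.ndarray,
    Sigma_e: np.ndarray,
    seed,
) -> np.ndarray:
    """theta_ij = (X_ij beta_j1, ..., X_ij beta_jQ) + e_ij, e ~ N(0, Sigma_e)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    Sigma_e = np.asarray(Sigma_e, dtype=float)
    n = person_design.shape[0]
    Q = Sigma_e.shape[0]
    if beta.shape[1] != person_design.shape[1]:
        raise ModelError("beta and person_design column counts differ")
    # mean[i, q] = X_i . beta[school_i, :, q]
    mean = np.einsum("ip,ipq->iq", person_design, beta[school_index])
    if np.allclose(Sigma_e, 0.0):
        return mean
    L = np.linalg.cholesky(Sigma_e)
    return mean + rng.standard_normal((n, Q)) @ L.T


def generate_responses(theta: np.ndarray, items: ItemParameters, seed) -> np.ndarray:
    """Bernoulli responses with probit success probability Phi(eta_ijk)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eta = theta @ items.discriminations.T - items.difficulties
    p = response_probability(eta)
    return (rng.random(eta.shape) < p).astype(np.int8)


def _assemble(
    items: ItemParameters,
    spec: ModelSpec,
    gamma: list[np.ndarray],
    Sigma_e: np.ndarray,
    T: list[np.ndarray],
    n: int,
    J: int,
    h: int,
    s: int,
    seed,
    label: str,
) -> tuple[HierarchicalDataset, TruthBundle]:
    r_cov, r_coef, r_theta, r_resp = _rngs(seed, 4)
    X, W, school_index = generate_covariates(n, J, h, s, r_cov)
    beta = generate_regression_coefficients(gamma, T, W, spec, r_coef)
    theta = generate_abilities(X, school_index, beta, Sigma_e, r_theta)
    Y = generate_responses(theta, items, r_resp)
    data = HierarchicalDataset(Y, school_index, X, W)
    truth = TruthBundle(items, spec, [np.asarray(g) for g in gamma],
                        np.asarray(Sigma_e), [np.asarray(t) for t in T],
                        beta, theta, label=label)
    return data, truth


def simulation1_design(
    seed, *, n_j: int = 200, J: int = 10, redraw_items: bool = False
) -> tuple[HierarchicalDataset, TruthBundle]:
    """The two-dimensional reference recovery design.

    K=30 items, Q=2 dimensions, J schools of n_j students (defaults 10 x 200),
    one person covariate ~ N(0.25, 1) and one school covariate ~ N(0.5, 1);
    both the intercept and the slope are random across schools with level-3
    variance 0.100 and zero covariance; level-2 residual covariance
    [[0.300, 0.075], [0.075, 0.500]].  Item truths default to the canonical
    printed bank; ``redraw_items=True`` draws a fresh bank from the same
    distributions instead.
    """
    master = np.random.SeedSequence(seed)
    item_ss, rest_ss = master.spawn(2)
    if redraw_items:
        items = generate_item_bank(30, 2, np.random.default_rng(item_ss))
    else:
        items = ItemParameters(
            REFERENCE_ITEMS_2D[:, :2].copy(),
            REFERENCE_ITEMS_2D[:, 2].copy(),
        )
        items = apply_identification_constraints(items, 2)
    spec = full_random_spec(2, n_person_cols=2, n_school_cols=2)
    T = [SIM1_TAU * np.eye(2), SIM1_TAU * np.eye(2)]
    return _assemble(
        items, spec, [g.copy() for g in SIM1_GAMMA], SIM1_SIGMA_E.copy(), T,
        n=n_j * J, J=J, h=1, s=1, seed=rest_ss, label=f"sim1(J={J},n_j={n_j})",
    )


def simulation2_design(
    N: int, K: int, seed, *, J: int = 10
) -> tuple[HierarchicalDataset, TruthBundle]:
    """The four-dimensional design over the (persons x items) grid.

    Q=4 dimensions, N persons equally distributed over J=10 schools, K items
    (split evenly into four subtests, e.g. 10/25/50 per subtest for
    K=40/100/200).  Item truths are drawn from the same distributions as the
    two-dimensional design; structural truths: fixed effects
    (1.000, 0.300, 0.500, 0.350) on every dimension, level-2 variances
    (0.300, 0.500, 0.750, 1.000) with covariance 0.075, level-3 variances
    0.1 with covariance 0.
    """
    if N % J != 0:
        raise ModelError(f"N={N} must divide equally over J={J} schools")
    master = np.random.SeedSequence(seed)
    item_ss, rest_ss = master.spawn(2)
    items = generate_item_bank(K, 4, np.random.default_rng(item_ss))
    spec = full_random_spec(4, n_person_cols=2, n_school_cols=2)
    Q = 4
    Sigma_e = np.full((Q, Q), SIM2_SIGMA_E_OFFDIAG)
    np.fill_diagonal(Sigma_e, SIM2_SIGMA_E_DIAG)
    gamma = [SIM2_GAMMA_PER_DIM.copy() for _ in range(Q)]
    T = [SIM1_TAU * np.eye(2) for _ in range(Q)]
    return _assemble(
        items, spec, gamma, Sigma_e, T,
        n=N, J=J, h=1, s=1, seed=rest_ss, label=f"sim2(N={N},K={K})",
    )
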