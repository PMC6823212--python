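"""Seven-step data-augmentation Gibbs sampler for the three-level
multidimensional normal-ogive IRT model.

Every full conditional is conjugate, so the sampler cycles plain draws:

1. latent continuous scores Z_ijk (truncated normal, sign tied to Y_ijk);
2. abilities theta_ijq, one dimension at a time, combining the measurement
   likelihood with the conditional structural prior given the other
   dimensions;
3. free item parameters (a_k, b_k) from a multivariate normal truncated to
   positive discriminations (one coordinate-wise truncated sweep per
   iteration, itself a valid Gibbs kernel);
4. random school coefficients beta_jq (normal, precision form);
   fixed person-level coefficients pooled across schools (flat prior);
5. fixed effects gamma_q regressing random coefficients on school
   covariates (flat prior, optional uniform box);
6. level-2 residual covariance Sigma_e (inverse-Wishart);
7. level-3 covariances T_q per dimension (inverse-Wishart, block-diagonal
   across dimensions).

Anchored item parameters never move; the identification constraints are the
ones applied by :func:`mlmirt.model.apply_identification_constraints`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import invwishart

from .distributions import truncated_normal
from .model import (
    HierarchicalDataset,
    ItemParameters,
    ModelError,
    ModelSpec,
    PriorSpec,
)

_JITTER = 1e-8


@dataclass
class ChainConfig:
    """MCMC run configuration.

    ``iterations`` counts total sweeps per chain; the first ``burn_in`` are
    discarded.  ``z_thin`` controls how often a full augmented-score snapshot
    (needed for the marginalized DIC) is stored: every ``z_thin``-th kept
    draw.  ``overdispersed_starts`` offsets each chain's initial values by a
    chain-indexed factor, for convergence diagnostics.
    """

    iterations: int = 20000
    burn_in: int = 5000
    chains: int = 1
    seed: int = 0
    z_thin: int = 20
    store_augmented: bool = False
    store_abilities: bool = False
    store_coefficients: bool = False
    overdispersed_starts: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ModelError("need 0 <= burn_in < iterations")
        if self.z_thin < 1:
            raise ModelError("z_thin must be >= 1")


@dataclass
class Snapshot:
    """One thinned draw of everything the marginalized deviance needs."""

    Z: np.ndarray
    gamma: list[np.ndarray]
    a: np.ndarray
    b: np.ndarray
    Sigma_e: np.ndarray
    T: list[np.ndarray]


@dataclass
class PosteriorDraws:
    """Stored post-burn-in draws, leading axis (chain, kept iteration)."""

    gamma: np.ndarray                 # (C, M, G)
    gamma_names: list[str]
    sigma_e: np.ndarray               # (C, M, Q, Q)
    T: list[np.ndarray]               # per q: (C, M, r_q, r_q)
    tau_names: list[str]
    a: np.ndarray                     # (C, M, K, Q)
    b: np.ndarray                     # (C, M, K)
    spec: ModelSpec
    snapshots: list[Snapshot] = field(default_factory=list)
    theta: np.ndarray | None = None   # (C, M, n, Q) when stored
    beta: np.ndarray | None = None    # (C, M, J, P, Q) when stored

    @property
    def n_chains(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_kept(self) -> int:
        return self.gamma.shape[1]

    def structural_draws(self) -> dict[str, np.ndarray]:
        """Name -> (chains, kept) draw matrix for every structural parameter."""
        out: dict[str, np.ndarray] = {}
        for i, name in enumerate(self.gamma_names):
            out[name] = self.gamma[:, :, i]
        Q = self.sigma_e.shape[-1]
        for q1 in range(Q):
            for q2 in range(Q):
                out[f"sigma_e{q1 + 1}{q2 + 1}"] = self.sigma_e[:, :, q1, q2]
        pos = 0
        for q in range(self.spec.n_dim):
            r = self.spec.r_q(q)
            names = self.tau_names[pos:pos + r * r]
            flat = self.T[q].reshape(self.n_chains, self.n_kept, r * r)
            for i, name in enumerate(names):
                out[name] = flat[:, :, i]
            pos += r * r
        return out

    def item_draws(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        K, Q = self.a.shape[2], self.a.shape[3]
        for k in range(K):
            for q in range(Q):
                out[f"a_{k + 1}_{q + 1}"] = self.a[:, :, k, q]
            out[f"b_{k + 1}"] = self.b[:, :, k]
        return out


# ---------------------------------------------------------------------------
# per-fit precomputed layout
# ---------------------------------------------------------------------------

class _Layout:
    """Index bookkeeping derived from (dataset, spec), fixed for a fit."""

    def __init__(self, data: HierarchicalDataset, spec: ModelSpec):
        if spec.n_coef != data.n_person_cols:
            raise ModelError("spec and person_design disagree on h+1")
        if spec.school_mask.shape[1] != data.n_school_cols:
            raise ModelError("spec and school_design disagree on s+1")
        self.data = data
        self.spec = spec
        self.J = data.n_schools
        self.n = data.n_persons
        self.P = spec.n_coef
        self.Q = spec.n_dim
        self.school_rows = [
            np.flatnonzero(data.school_index == j) for j in range(self.J)
        ]
        # gamma slot layout per dimension: p-major over masked school columns
        self.slots: list[list[slice]] = []
        self.gamma_len: list[int] = []
        for q in range(self.Q):
            pos = 0
            sl = []
            for p in range(self.P):
                w = int(spec.school_mask[p, :, q].sum())
                sl.append(slice(pos, pos + w))
                pos += w
            self.slots.append(sl)
            self.gamma_len.append(pos)
        # per dimension: school-design matrix mapping the random part of
        # gamma_q onto the prior means of the random coefficients
        self.rand_gamma_idx: list[np.ndarray] = []
        self.Wall: list[np.ndarray] = []     # (J, r_q, g_rand)
        for q in range(self.Q):
            ridx = spec.random_idx(q)
            cols = []
            for p in ridx:
                cols.extend(range(self.slots[q][p].start, self.slots[q][p].stop))
            self.rand_gamma_idx.append(np.array(cols, dtype=int))
            W = np.zeros((self.J, len(ridx), len(cols)))
            pos = 0
            for r, p in enumerate(ridx):
                ccols = np.flatnonzero(spec.school_mask[p, :, q])
                W[:, r, pos:pos + len(ccols)] = data.school_design[:, ccols]
                pos += len(ccols)
            self.Wall.append(W)
        # per dimension: pooled design for the fixed person-level coefficients
        # (column = person covariate p interacted with masked school column c)
        self.fixed_gamma_idx: list[np.ndarray] = []
        self.Gfix: list[np.ndarray] = []     # (n, g_fixed)
        for q in range(self.Q):
            fidx = spec.fixed_idx(q)
            cols = []
            blocks = []
            for p in fidx:
                ccols = np.flatnonzero(spec.school_mask[p, :, q])
                cols.extend(range(self.slots[q][p].start, self.slots[q][p].stop))
                blocks.append(
                    data.person_design[:, [p]]
                    * data.school_design[np.ix_(data.school_index, ccols)]
                )
            self.fixed_gamma_idx.append(np.array(cols, dtype=int))
            self.Gfix.append(
                np.hstack(blocks) if blocks else np.zeros((self.n, 0))
            )
        # random-coefficient cross products per (school, dimension)
        self.XtX_rand: list[list[np.ndarray]] = []
        for q in range(self.Q):
            ridx = spec.random_idx(q)
            per_school = []
            for j in range(self.J):
                Xr = data.person_design[np.ix_(self.school_rows[j], ridx)]
                per_school.append(Xr.T @ Xr)
            self.XtX_rand.append(per_school)

    def beta_from_gamma(self, gamma: list[np.ndarray]) -> np.ndarray:
        """Deterministic coefficient means w_j' gamma, all (J, P, Q)."""
        beta = np.zeros((self.J, self.P, self.Q))
        for q in range(self.Q):
            for p in range(self.P):
                ccols = np.flatnonzero(self.spec.school_mask[p, :, q])
                beta[:, p, q] = (
                    self.data.school_design[:, ccols] @ gamma[q][self.slots[q][p]]
                )
        return beta


def conditional_variances(Sigma_e: np.ndarray) -> np.ndarray:
    """sigma_q^2 = Sigma_qq - Sigma_{q,-q} Sigma_{-q,-q}^{-1} Sigma_{-q,q}."""
    Q = Sigma_e.shape[0]
    if Q == 1:
        return np.array([Sigma_e[0, 0]])
    prec = np.linalg.inv(Sigma_e)
    return 1.0 / np.diag(prec)


def _chol_spd(M: np.ndarray) -> np.ndarray:
    """Cholesky with one scale-aware jitter retry, then a hard error."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        eps = _JITTER * max(1.0, float(np.mean(np.abs(np.diag(M)))))
        try:
            return np.linalg.cholesky(M + eps * np.eye(M.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"matrix not positive definite after jitter: {exc}")


def _spd_inverse(M: np.ndarray) -> np.ndarray:
    L = _chol_spd(M)
    return cho_solve((L, True), np.eye(M.shape[0]))


def _mvn_draw(rng, mean: np.ndarray, prec: np.ndarray) -> np.ndarray:
    """One draw from N(mean, prec^{-1}) via the precision Cholesky."""
    L = _chol_spd(prec)
    z = rng.standard_normal(mean.shape[0])
    return mean + solve_triangular(L.T, z, lower=False)


# ---------------------------------------------------------------------------
# the seven steps
# ---------------------------------------------------------------------------

def sample_augmented_scores(
    Y: np.ndarray, theta: np.ndarray, items: ItemParameters, rng
) -> np.ndarray:
    """Step 1: Z_ijk ~ N(eta_ijk, 1) truncated to agree in sign with Y_ijk."""
    eta = theta @ items.discriminations.T - items.difficulties
    pos = Y == 1
    lower = np.where(pos, 0.0, -np.inf)
    upper = np.where(pos, np.inf, 0.0)
    return truncated_normal(rng, eta, 1.0, lower=lower, upper=upper)


def sample_abilities(
    Z: np.ndarray,
    items: ItemParameters,
    mu_struct: np.ndarray,
    Sigma_e: np.ndarray,
    theta: np.ndarray,
    rng,
) -> np.ndarray:
    """Step 2: cycle dimensions, drawing theta_.q given the others.

    ``mu_struct`` holds the structural means X_ij beta_jq (n, Q); the
    conditional prior of dimension q given the rest is derived from Sigma_e,
    and combined with the measurement pseudo-observation
    theta~_q = (a_q'a_q)^{-1} a_q'(Z + b - theta_{-q} A_{-q}').
    """
    A = items.discriminations
    b = items.difficulties
    Q = A.shape[1]
    theta = theta.copy()
    for q in range(Q):
        aq = A[:, q]
        denom = float(aq @ aq)
        if denom <= 0:
            raise ModelError(f"dimension {q} has no nonzero loadings")
        v = 1.0 / denom
        pred_minus = theta @ A.T - np.outer(theta[:, q], aq)
        theta_tilde = ((Z + b - pred_minus) @ aq) / denom
        if Q == 1:
            mu = mu_struct[:, 0]
            var_q = float(Sigma_e[0, 0])
        else:
            other = [i for i in range(Q) if i != q]
            S_oo = Sigma_e[np.ix_(other, other)]
            S_qo = Sigma_e[q, other]
            w = np.linalg.solve(S_oo, S_qo)
            mu = mu_struct[:, q] + (theta[:, other] - mu_struct[:, other]) @ w
            var_q = float(Sigma_e[q, q] - w @ S_qo)
        post_var = v * var_q / (v + var_q)
        post_mean = (theta_tilde * var_q + mu * v) / (v + var_q)
        theta[:, q] = post_mean + np.sqrt(post_var) * rng.standard_normal(len(mu))
    return theta


def sample_item_parameters(
    Z: np.ndarray,
    theta: np.ndarray,
    items: ItemParameters,
    priors: PriorSpec,
    rng,
) -> ItemParameters:
    """Step 3: free xi_k = (a_k, b_k) from the conjugate normal truncated to
    positive discriminations; anchors untouched.

    The positive-orthant truncation is handled with one coordinate-wise
    truncated-normal sweep (vectorized across items) starting from the
    current values, which leaves the target conditional invariant.
    """
    items = items.copy()
    K, Q = items.discriminations.shape
    free = ~items.anchor_mask
    if not free.any():
        return items
    H = np.hstack([theta, -np.ones((theta.shape[0], 1))])
    HtH = H.T @ H
    prior_prec = np.diag(
        [1.0 / priors.var_a] * Q + [1.0 / priors.var_b]
    )
    prior_mean = np.array([priors.mu_a] * Q + [priors.mu_b])
    P = HtH + prior_prec
    rhs = H.T @ Z[:, free] + (prior_prec @ prior_mean)[:, None]
    cP, low = cho_factor(P)
    means = cho_solve((cP, low), rhs).T          # (K_free, Q+1)
    x = np.hstack([
        items.discriminations[free], items.difficulties[free, None]
    ])
    cond_sd = 1.0 / np.sqrt(np.diag(P))
    for c in range(Q + 1):
        dev = (x - means) @ P[:, c] - (x[:, c] - means[:, c]) * P[c, c]
        cmean = means[:, c] - dev / P[c, c]
        if c < Q:
            x[:, c] = truncated_normal(rng, cmean, cond_sd[c], lower=0.0)
        else:
            x[:, c] = cmean + cond_sd[c] * rng.standard_normal(len(cmean))
    items.discriminations[free] = x[:, :Q]
    items.difficulties[free] = x[:, Q]
    return items


def sample_level2_coefficients(
    theta: np.ndarray,
    lay: _Layout,
    beta: np.ndarray,
    gamma: list[np.ndarray],
    sigma_cond: np.ndarray,
    T: list[np.ndarray],
    rng,
) -> np.ndarray:
    """Step 4: per school and dimension, draw the random-coefficient
    subvector from the precision-form conjugate normal

        N((X'X/s^2 + T^{-1})^{-1}(X'theta*/s^2 + T^{-1} w_j gamma), ...)

    where theta* is the dimension's ability column residualized against the
    fixed coefficients' contribution.
    """
    beta = beta.copy()
    X = lay.data.person_design
    for q in range(lay.Q):
        ridx = lay.spec.random_idx(q)
        if len(ridx) == 0:
            continue
        fidx = lay.spec.fixed_idx(q)
        Tinv = _spd_inverse(T[q])
        s2 = sigma_cond[q]
        g_rand = gamma[q][lay.rand_gamma_idx[q]]
        prior_means = lay.Wall[q] @ g_rand          # (J, r_q)
        for j in range(lay.J):
            rows = lay.school_rows[j]
            resid = theta[rows, q]
            if len(fidx):
                resid = resid - X[np.ix_(rows, fidx)] @ beta[j, fidx, q]
            Xr = X[np.ix_(rows, ridx)]
            prec = lay.XtX_rand[q][j] / s2 + Tinv
            rhs = Xr.T @ resid / s2 + Tinv @ prior_means[j]
            L = _chol_spd(prec)
            mean = cho_solve((L, True), rhs)
            beta[j, ridx, q] = mean + solve_triangular(
                L.T, rng.standard_normal(len(ridx)), lower=False
            )
    return beta


def sample_global_coefficients(
    theta: np.ndarray,
    lay: _Layout,
    beta: np.ndarray,
    gamma: list[np.ndarray],
    sigma_cond: np.ndarray,
    priors: PriorSpec,
    rng,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Fixed person-level coefficients, pooled across schools (flat prior).

    Each dimension's fixed coefficients (and their school-covariate
    regressions) form one pooled normal regression of the ability column --
    residualized against the random coefficients -- on the interaction
    design person-column x masked-school-column.
    """
    beta = beta.copy()
    gamma = [g.copy() for g in gamma]
    X = lay.data.person_design
    for q in range(lay.Q):
        fcols = lay.fixed_gamma_idx[q]
        if len(fcols) == 0:
            continue
        ridx = lay.spec.random_idx(q)
        resid = theta[:, q].copy()
        if len(ridx):
            contrib = np.einsum(
                "ip,ip->i",
                X[:, ridx],
                beta[np.ix_(lay.data.school_index, ridx)][:, :, q],
            )
            resid -= contrib
        G = lay.Gfix[q]
        GtG = G.T @ G
        if np.linalg.matrix_rank(GtG) < GtG.shape[0]:
            raise ModelError(
                f"pooled fixed-coefficient design is rank deficient (dim {q})"
            )
        s2 = sigma_cond[q]
        draw = _gamma_normal_draw(
            rng, GtG / s2, G.T @ resid / s2, priors.gamma_bound
        )
        gamma[q][fcols] = draw
        # propagate the new global values into the per-school coefficients
        fidx = lay.spec.fixed_idx(q)
        for p in fidx:
            ccols = np.flatnonzero(lay.spec.school_mask[p, :, q])
            beta[:, p, q] = lay.data.school_design[:, ccols] @ gamma[q][lay.slots[q][p]]
    return beta, gamma


def _gamma_normal_draw(rng, prec, rhs, bound: float | None) -> np.ndarray:
    """Draw from N(prec^{-1} rhs, prec^{-1}), optionally confined to a box.

    The box prior uses rejection from the unconstrained normal; if 100 tries
    all fall outside, two coordinate-wise truncated Gibbs sweeps from the
    clipped mean are used instead (also an exact kernel for the truncated
    target).
    """
    L = _chol_spd(prec)
    mean = cho_solve((L, True), rhs)
    if bound is None:
        return mean + solve_triangular(L.T, rng.standard_normal(len(mean)), lower=False)
    for _ in range(100):
        draw = mean + solve_triangular(L.T, rng.standard_normal(len(mean)), lower=False)
        if np.all(np.abs(draw) <= bound):
            return draw
    x = np.clip(mean, -bound, bound)
    P = prec
    for _ in range(2):
        for c in range(len(x)):
            dev = P[c] @ (x - mean) - P[c, c] * (x[c] - mean[c])
            cmean = mean[c] - dev / P[c, c]
            csd = 1.0 / np.sqrt(P[c, c])
            x[c] = truncated_normal(rng, cmean, csd, lower=-bound, upper=bound)
    return x


def sample_fixed_effects(
    lay: _Layout,
    beta: np.ndarray,
    gamma: list[np.ndarray],
    T: list[np.ndarray],
    priors: PriorSpec,
    rng,
) -> list[np.ndarray]:
    """Step 5: gamma_q for the random coefficients, regressing beta_jq on the
    school design through T_q (flat prior, optional uniform box)."""
    gamma = [g.copy() for g in gamma]
    for q in range(lay.Q):
        cols = lay.rand_gamma_idx[q]
        if len(cols) == 0:
            continue
        ridx = lay.spec.random_idx(q)
        Tinv = _spd_inverse(T[q])
        W = lay.Wall[q]                          # (J, r, g)
        prec = np.einsum("jrg,rs,jsh->gh", W, Tinv, W)
        rhs = np.einsum("jrg,rs,js->g", W, Tinv, beta[:, ridx, q])
        if lay.J < prec.shape[0] // max(1, len(ridx)):
            raise ModelError(
                f"too few schools to identify the fixed effects on dimension {q}"
            )
        try:
            gamma[q][cols] = _gamma_normal_draw(rng, prec, rhs, priors.gamma_bound)
        except ModelError:
            raise ModelError(
                f"singular fixed-effect normal equations on dimension {q}"
            )
    return gamma


def sample_level2_covariance(
    theta: np.ndarray,
    mu_struct: np.ndarray,
    priors: PriorSpec,
    rng,
) -> np.ndarray:
    """Step 6: Sigma_e ~ IW(v0 + n, S + Sigma0), S the residual outer-product
    sum over all persons.

    With ``priors.diagonal_sigma_e`` the residuals are modelled independent
    across dimensions and each variance gets its own univariate
    inverse-Wishart (= inverse-gamma) draw.
    """
    Q = theta.shape[1]
    resid = theta - mu_struct
    v0 = priors.v0 if priors.v0 is not None else Q + 2
    if priors.diagonal_sigma_e:
        out = np.zeros((Q, Q))
        for q in range(Q):
            s_qq = float(resid[:, q] @ resid[:, q])
            out[q, q] = invwishart.rvs(
                df=v0 + theta.shape[0], scale=s_qq + priors.Sigma0_scale,
                random_state=rng,
            )
        return out
    S = resid.T @ resid
    scale = S + priors.Sigma0_scale * np.eye(Q)
    return invwishart.rvs(df=v0 + theta.shape[0], scale=scale, random_state=rng).reshape(Q, Q)


def sample_level3_covariance(
    lay: _Layout,
    beta: np.ndarray,
    gamma: list[np.ndarray],
    priors: PriorSpec,
    rng,
) -> list[np.ndarray]:
    """Step 7: per dimension, T_q ~ IW(v1 + J, S1 + Sigma1) over that
    dimension's random coefficients (block-diagonal across dimensions)."""
    out = []
    for q in range(lay.Q):
        ridx = lay.spec.random_idx(q)
        r = len(ridx)
        if r == 0:
            out.append(np.zeros((0, 0)))
            continue
        prior_means = lay.Wall[q] @ gamma[q][lay.rand_gamma_idx[q]]
        dev = beta[:, ridx, q] - prior_means
        S1 = dev.T @ dev
        if priors.improper_T:
            v1, Sigma1 = 0, np.zeros((r, r))
            if lay.J <= r + 1:
                raise ModelError(
                    f"improper level-3 prior needs J > r_q + 1 (J={lay.J}, r_q={r})"
                )
        else:
            v1 = priors.v1 if priors.v1 is not None else r + 2
            Sigma1 = priors.Sigma1_scale * np.eye(r)
        scale = S1 + Sigma1
        # scale-relative jitter: the chain may visit |correlation| ~ 1 under
        # the improper prior, where the scale matrix degenerates numerically
        scale += _JITTER * max(1e-4, float(np.trace(scale)) / r) * np.eye(r)
        out.append(
            invwishart.rvs(df=v1 + lay.J, scale=scale, random_state=rng).reshape(r, r)
        )
    return out


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

def _initial_state(lay: _Layout, config: ChainConfig, chain: int):
    """Default starts: theta=0, free a=1, b=0, gamma=0, beta=w gamma,
    Sigma_e=I, T=0.1 I; overdispersed chains scale/offset by chain index."""
    K = lay.data.n_items
    Q = lay.Q
    a = np.ones((K, Q))
    b = np.zeros(K)
    items = ItemParameters(a, b)
    from .model import apply_identification_constraints

    items = apply_identification_constraints(items, Q)
    gamma = [np.zeros(lay.gamma_len[q]) for q in range(Q)]
    scale = 1.0
    if config.overdispersed_starts and chain > 0:
        offset = 0.4 * ((chain + 1) // 2) * (-1 if chain % 2 == 0 else 1)
        for g in gamma:
            g += offset
        scale = 1.0 + 0.25 * chain
    theta = np.zeros((lay.n, Q))
    beta = lay.beta_from_gamma(gamma)
    Sigma_e = scale * np.eye(Q)
    T = [
        scale * 0.1 * np.eye(lay.spec.r_q(q)) if lay.spec.r_q(q) else np.zeros((0, 0))
        for q in range(Q)
    ]
    return theta, items, beta, gamma, Sigma_e, T


def _mu_struct(lay: _Layout, beta: np.ndarray) -> np.ndarray:
    return np.einsum(
        "ip,ipq->iq", lay.data.person_design, beta[lay.data.school_index]
    )


def run_chain(
    dataset: HierarchicalDataset,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    config: ChainConfig | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return post-burn-in draws.

    Reproducible: the draw sequence is fully determined by
    ``(config.seed, chain index)``.
    """
    priors = priors or PriorSpec()
    config = config or ChainConfig()
    lay = _Layout(dataset, spec)
    Q, K = lay.Q, dataset.n_items
    kept = config.iterations - config.burn_in
    C = config.chains
    G = sum(lay.gamma_len)
    gamma_names = [n for q in range(Q) for n in spec.gamma_names(q)]
    tau_names = [n for q in range(Q) for n in spec.tau_names(q)]

    gam = np.empty((C, kept, G))
    sig = np.empty((C, kept, Q, Q))
    Ts = [np.empty((C, kept, spec.r_q(q), spec.r_q(q))) for q in range(Q)]
    a_d = np.empty((C, kept, K, Q))
    b_d = np.empty((C, kept, K))
    th_d = np.empty((C, kept, lay.n, Q)) if config.store_abilities else None
    be_d = (
        np.empty((C, kept, lay.J, lay.P, Q)) if config.store_coefficients else None
    )
    snapshots: list[Snapshot] = []

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(C)
    Y = dataset.responses

    for c in range(C):
        rng = np.random.default_rng(chain_seeds[c])
        theta, items, beta, gamma, Sigma_e, T = _initial_state(lay, config, c)
        for it in range(config.iterations):
            Z = sample_augmented_scores(Y, theta, items, rng)
            mu = _mu_struct(lay, beta)
            theta = sample_abilities(Z, items, mu, Sigma_e, theta, rng)
            items = sample_item_parameters(Z, theta, items, priors, rng)
            sigma_cond = conditional_variances(Sigma_e)
            beta = sample_level2_coefficients(
                theta, lay, beta, gamma, sigma_cond, T, rng
            )
            if any(len(lay.fixed_gamma_idx[q]) for q in range(Q)):
                beta, gamma = sample_global_coefficients(
                    theta, lay, beta, gamma, sigma_cond, priors, rng
                )
            gamma = sample_fixed_effects(lay, beta, gamma, T, priors, rng)
            mu = _mu_struct(lay, beta)
            Sigma_e = sample_level2_covariance(theta, mu, priors, rng)
            T = sample_level3_covariance(lay, beta, gamma, priors, rng)

            k = it - config.burn_in
            if k < 0:
                continue
            gam[c, k] = np.concatenate(gamma) if G else np.zeros(0)
            sig[c, k] = Sigma_e
            for q in range(Q):
                Ts[q][c, k] = T[q]
            a_d[c, k] = items.discriminations
            b_d[c, k] = items.difficulties
            if th_d is not None:
                th_d[c, k] = theta
            if be_d is not None:
                be_d[c, k] = beta
            if config.store_augmented and c == 0 and k % config.z_thin == 0:
                snapshots.append(
                    Snapshot(
                        Z.copy(),
                        [g.copy() for g in gamma],
                        items.discriminations.copy(),
                        items.difficulties.copy(),
                        Sigma_e.copy(),
                        [t.copy() for t in T],
                    )
                )

    return PosteriorDraws(
        gamma=gam,
        gamma_names=gamma_names,
        sigma_e=sig,
        T=Ts,
        tau_names=tau_names,
        a=a_d,
        b=b_d,
        spec=spec,
        snapshots=snapshots,
        theta=th_d,
        beta=be_d,
    )
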