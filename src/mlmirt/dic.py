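"""Top-level marginalized deviance information criterion.

The deviance is defined on the augmented-data likelihood p(Z | Omega_1)
with Omega_1 = (item parameters, Sigma_e, T): the mid-level random effects
-- abilities theta and school coefficients beta -- are integrated out
analytically, leaving a multivariate normal for the stacked scores of each
school.  Within a school, persons share the random-coefficient residuals, so
the covariance is a person-block-diagonal part A Sigma_e A' + I_K plus a
low-rank coupling M_j blockdiag(T_q) M_j'; it is evaluated with
Woodbury/matrix-determinant-lemma updates rather than by materializing the
(n_j K) x (n_j K) matrix.

pD and the DIC follow the usual plug-in estimator along the joint chain:
D_bar averages the deviance over stored (Z, Omega_1, gamma) snapshots, D_hat
replaces gamma by its posterior mean, pD = D_bar - D_hat, DIC = D_bar + pD.
Smaller DIC is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .model import HierarchicalDataset, ModelError, ModelSpec, PriorSpec
from .sampler import ChainConfig, PosteriorDraws, Snapshot, _Layout, run_chain

_LOG2PI = np.log(2.0 * np.pi)
_JITTER = 1e-8


@dataclass
class DicResult:
    """DIC = mean deviance + effective number of parameters."""

    label: str
    dic: float
    p_d: float
    mean_deviance: float

    def row(self) -> dict:
        return {"model": self.label, "pD": self.p_d,
                "mean_deviance": self.mean_deviance, "dic": self.dic}


def marginal_augmented_loglik(
    Z: np.ndarray,
    gamma: list[np.ndarray],
    a: np.ndarray,
    b: np.ndarray,
    Sigma_e: np.ndarray,
    T: list[np.ndarray],
    dataset: HierarchicalDataset,
    spec: ModelSpec,
) -> float:
    """Log density of the stacked augmented scores with theta and the random
    school coefficients integrated out.

    Per school j the scores are N(mean_j, C_j) with
    mean_ijk = sum_q a_kq (X_ij w_j gamma)_q - b_k and
    C_j = blockdiag_i(A Sigma_e A' + I_K) + M_j blockdiag_q(T_q) M_j'.
    """
    lay = _layout_cache(dataset, spec)
    A = np.asarray(a, dtype=float)
    K, Q = A.shape
    Sigma_e = np.asarray(Sigma_e, dtype=float)
    _require_spd(Sigma_e, "Sigma_e")
    # the +I_K makes the person block well conditioned (eigenvalues >= 1)
    D = A @ Sigma_e @ A.T + np.eye(K)
    cD = cho_factor(D)
    logdet_D = 2.0 * np.sum(np.log(np.diag(cD[0])))

    beta_mean = lay.beta_from_gamma([np.asarray(g, dtype=float) for g in gamma])
    mu_theta = np.einsum(
        "ip,ipq->iq", dataset.person_design, beta_mean[dataset.school_index]
    )
    mean_Z = mu_theta @ A.T - b
    resid = Z - mean_Z

    # random-effect coupling layout
    ridx = [spec.random_idx(q) for q in range(Q)]
    sizes = [len(r) for r in ridx]
    R = sum(sizes)
    T_blocks = [np.asarray(T[q], dtype=float) for q in range(Q)]
    use_coupling = R > 0 and any(np.abs(t).max() > 0 for t in T_blocks if t.size)
    if use_coupling:
        for q, t in enumerate(T_blocks):
            if t.size:
                _require_spd(t, f"T[{q}]")
        T_full = np.zeros((R, R))
        pos = 0
        for q, t in enumerate(T_blocks):
            r = sizes[q]
            T_full[pos:pos + r, pos:pos + r] = t
            pos += r
        cT = cho_factor(T_full)
        T_inv = cho_solve(cT, np.eye(R))
        logdet_T = 2.0 * np.sum(np.log(np.diag(cT[0])))

    total = 0.0
    X = dataset.person_design
    for j in range(dataset.n_schools):
        rows = lay.school_rows[j]
        nj = len(rows)
        Rj = resid[rows]                       # (nj, K)
        DinvR = cho_solve(cD, Rj.T).T          # (nj, K)
        quad = float(np.sum(Rj * DinvR))
        logdet = nj * logdet_D
        if use_coupling:
            # M_i columns: for dim q, coefficient p in ridx[q]:
            # column = a_.q * X_i[p]  -> M stacked over persons
            M = np.empty((nj, K, R))
            pos = 0
            for q in range(Q):
                for p in ridx[q]:
                    M[:, :, pos] = X[rows, p][:, None] * A[None, :, q]
                    pos += 1
            Mf = M.reshape(nj * K, R)
            DinvM = cho_solve(cD, M.transpose(1, 0, 2).reshape(K, nj * R))
            DinvM = DinvM.reshape(K, nj, R).transpose(1, 0, 2).reshape(nj * K, R)
            core = T_inv + Mf.T @ DinvM
            cC = cho_factor(core)
            u = Mf.T @ DinvR.reshape(nj * K)
            quad -= float(u @ cho_solve(cC, u))
            logdet += logdet_T + 2.0 * np.sum(np.log(np.diag(cC[0])))
        total += -0.5 * (nj * K * _LOG2PI + logdet + quad)
    return float(total)


_layout_memo: dict[tuple, _Layout] = {}


def _layout_cache(dataset: HierarchicalDataset, spec: ModelSpec) -> _Layout:
    key = (id(dataset), id(spec))
    lay = _layout_memo.get(key)
    if lay is None:
        lay = _Layout(dataset, spec)
        _layout_memo.clear()
        _layout_memo[key] = lay
    return lay


def _require_spd(M: np.ndarray, name: str) -> None:
    if M.size and np.linalg.eigvalsh(M).min() <= 0:
        raise ModelError(f"{name} must be symmetric positive definite")


def _snapshot_deviance(
    snap: Snapshot,
    gamma: list[np.ndarray],
    dataset: HierarchicalDataset,
    spec: ModelSpec,
) -> float:
    return -2.0 * marginal_augmented_loglik(
        snap.Z, gamma, snap.a, snap.b, snap.Sigma_e, snap.T, dataset, spec
    )


def compute_dic(
    draws: PosteriorDraws,
    dataset: HierarchicalDataset,
    spec: ModelSpec,
    label: str | None = None,
) -> DicResult:
    """DIC from the stored thinned (Z, Omega_1, gamma) snapshots."""
    snaps = draws.snapshots
    if len(snaps) < 10:
        raise ModelError(
            f"need >= 10 stored augmented snapshots for the DIC, have {len(snaps)}"
        )
    # posterior-mean gamma over all kept draws, re-split per dimension
    gbar_flat = draws.gamma.mean(axis=(0, 1))
    gamma_bar: list[np.ndarray] = []
    pos = 0
    for q in range(spec.n_dim):
        g_len = len(snaps[0].gamma[q])
        gamma_bar.append(gbar_flat[pos:pos + g_len])
        pos += g_len
    d_bar = float(np.mean([
        _snapshot_deviance(s, s.gamma, dataset, spec) for s in snaps
    ]))
    d_hat = float(np.mean([
        _snapshot_deviance(s, gamma_bar, dataset, spec) for s in snaps
    ]))
    p_d = d_bar - d_hat
    return DicResult(label or spec.label, dic=d_bar + p_d, p_d=p_d,
                     mean_deviance=d_bar)


def compare_models(
    dataset: HierarchicalDataset,
    specs: list[ModelSpec],
    priors: PriorSpec | None = None,
    config: ChainConfig | None = None,
) -> list[DicResult]:
    """Fit each candidate structure, compute its DIC, and rank ascending
    (smallest DIC preferred)."""
    if len(specs) < 1:
        raise ModelError("need at least one candidate spec")
    import dataclasses

    config = config or ChainConfig()
    if not config.store_augmented:
        config = dataclasses.replace(config, store_augmented=True)
    results = []
    for spec in specs:
        try:
            draws = run_chain(dataset, spec, priors, config)
            results.append(compute_dic(draws, dataset, spec))
        except ModelError as exc:
            raise ModelError(f"fit failed for spec {spec.label!r}: {exc}")
    return sorted(results, key=lambda r: r.dic)


def dic_table(results: list[DicResult]) -> pd.DataFrame:
    """Small report table (model, pD, mean deviance, DIC), ascending DIC."""
    return pd.DataFrame([r.row() for r in results])
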