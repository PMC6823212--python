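"""Posterior summaries (EAP, HPDI, potential-scale-reduction) and the
replication harness producing bias/RMSE recovery tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelError
from .sampler import ChainConfig, PosteriorDraws, run_chain


def eap(draws) -> float:
    """Expected a posteriori estimate: the mean of the post-burn-in draws."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ModelError("cannot summarize an empty draw sequence")
    return float(draws.mean())


def hpdi(draws, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(level * M) sorted draws.

    Empirical (no density smoothing); equivariant under monotone affine
    transforms of the draws.
    """
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    M = draws.size
    if M < 20:
        raise ModelError(f"need at least 20 draws for an HPDI, got {M}")
    m = int(np.ceil(level * M))
    widths = draws[m - 1:] - draws[: M - m + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + m - 1])


def brooks_gelman_ratio(chains) -> float:
    """Potential-scale-reduction ratio from >= 2 equal-length chains.

    sqrt of (weighted within + between variance) / within; approaches 1
    from below as the chains mix over a common stationary distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ModelError("need >= 2 equal-length chains")
    m, n = chains.shape
    if n < 2:
        raise ModelError("chains too short")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    V_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(V_hat / W))


def bias_rmse(estimates, truth: float) -> tuple[float, float]:
    """bias = mean(est - truth); rmse = sqrt(mean((est - truth)^2))."""
    estimates = np.asarray(estimates, dtype=float).ravel()
    if estimates.size == 0:
        raise ModelError("need at least one replication estimate")
    err = estimates - truth
    return float(err.mean()), float(np.sqrt((err ** 2).mean()))


@dataclass
class RecoveryReport:
    """Per-parameter recovery table across replications."""

    table: pd.DataFrame          # parameter, true, eap, bias, rmse
    replications: int
    failures: int
    label: str = ""

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def subset(self, prefix: str) -> pd.DataFrame:
        return self.table[self.table["parameter"].str.startswith(prefix)]


def summarize_structural(
    draws: PosteriorDraws, level: float = 0.95
) -> pd.DataFrame:
    """EAP and HPDI for every structural parameter, chains pooled."""
    rows = []
    for name, mat in draws.structural_draws().items():
        flat = mat.ravel()
        lo, hi = hpdi(flat, level)
        rows.append({"parameter": name, "eap": eap(flat), "hpdi_lower": lo,
                     "hpdi_upper": hi})
    return pd.DataFrame(rows)


def replicate_recovery(
    design,
    replications: int,
    config: ChainConfig,
    priors=None,
    *,
    parameters: list[str] | None = None,
    label: str = "",
) -> RecoveryReport:
    """Fit ``replications`` independently generated datasets and aggregate
    per-parameter bias and RMSE of the EAP estimates.

    ``design`` is a callable ``seed -> (dataset, truth_bundle)``; replicate r
    uses ``config.seed + r`` for both generation and fitting, so individual
    replicates can be re-run independently.  Failed fits are excluded with a
    warning and counted in ``failures``.
    """
    import dataclasses

    estimates: dict[str, list[float]] = {}
    truths: dict[str, float] = {}
    failures = 0
    done = 0
    for r in range(replications):
        seed = config.seed + r
        try:
            dataset, truth = design(seed)
            cfg = dataclasses.replace(config, seed=seed)
            draws = run_chain(dataset, truth.spec, priors, cfg)
        except ModelError as exc:
            warnings.warn(f"replication {r} failed and was excluded: {exc}")
            failures += 1
            continue
        flat_truth = truth.structural_flat()
        if parameters is None:
            wanted = list(flat_truth)
        else:
            wanted = parameters
        structural = draws.structural_draws()
        for name in wanted:
            estimates.setdefault(name, []).append(eap(structural[name]))
            truths[name] = flat_truth[name]
        done += 1
    if done == 0:
        raise ModelError("every replication failed")
    rows = []
    for name, est in estimates.items():
        bias, rmse = bias_rmse(est, truths[name])
        rows.append({
            "parameter": name, "true": truths[name],
            "eap": float(np.mean(est)), "bias": bias, "rmse": rmse,
        })
    return RecoveryReport(pd.DataFrame(rows), done, failures, label=label)


def convergence_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Potential-scale-reduction ratio for every structural parameter."""
    if draws.n_chains < 2:
        raise ModelError("convergence diagnostics need >= 2 chains")
    rows = [
        {"parameter": name, "rhat": brooks_gelman_ratio(mat)}
        for name, mat in draws.structural_draws().items()
    ]
    return pd.DataFrame(rows)
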