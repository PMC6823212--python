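"""File formats and run configuration.

Datasets travel as three CSV files: wide responses
(person_id, school_id, item_1..item_K), person covariates keyed by
person_id, and school covariates keyed by school_id.  Draws are written in
tidy long format (chain, iteration, parameter, value) with a JSON sidecar
holding the shape metadata needed for a lossless round-trip; augmented
snapshots (for DIC recomputation) go to a companion long-format CSV.
Readers validate and reject rather than silently coerce.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    HierarchicalDataset,
    ModelError,
    ModelSpec,
    PriorSpec,
    build_model_spec,
)
from .sampler import ChainConfig, PosteriorDraws, Snapshot


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: HierarchicalDataset,
    responses_path,
    person_cov_path,
    school_cov_path,
) -> None:
    n, K = dataset.responses.shape
    resp = pd.DataFrame(
        dataset.responses, columns=[f"item_{k + 1}" for k in range(K)]
    )
    resp.insert(0, "school_id", dataset.school_index)
    resp.insert(0, "person_id", np.arange(n))
    resp.to_csv(responses_path, index=False)

    h = dataset.person_design.shape[1] - 1
    pcov = pd.DataFrame(
        dataset.person_design[:, 1:], columns=[f"x{i + 1}" for i in range(h)]
    )
    pcov.insert(0, "person_id", np.arange(n))
    pcov.to_csv(person_cov_path, index=False)

    s = dataset.school_design.shape[1] - 1
    scov = pd.DataFrame(
        dataset.school_design[:, 1:], columns=[f"w{i + 1}" for i in range(s)]
    )
    scov.insert(0, "school_id", np.arange(dataset.n_schools))
    scov.to_csv(school_cov_path, index=False)


def read_dataset(
    responses_path, person_cov_path, school_cov_path
) -> HierarchicalDataset:
    """Read and validate the three-file CSV dataset format."""
    resp = pd.read_csv(responses_path)
    for col in ("person_id", "school_id"):
        if col not in resp.columns:
            raise ModelError(f"responses file lacks required column {col!r}")
    item_cols = [c for c in resp.columns if c.startswith("item_")]
    if not item_cols:
        raise ModelError("responses file has no item_* columns")
    if resp[item_cols].isna().any().any():
        bad = resp.index[resp[item_cols].isna().any(axis=1)].tolist()[:10]
        raise ModelError(f"missing response cells in rows {bad}")
    vals = resp[item_cols].to_numpy()
    offending = np.argwhere(~np.isin(vals, [0, 1]))
    if len(offending):
        r, c = offending[0]
        raise ModelError(
            f"non-binary response {vals[r, c]!r} at row {r}, {item_cols[c]}"
        )

    pcov = pd.read_csv(person_cov_path)
    if "person_id" not in pcov.columns:
        raise ModelError("person covariate file lacks person_id")
    if pcov.isna().any().any():
        raise ModelError("missing cells in person covariate file")
    pcov = pcov.set_index("person_id")
    try:
        pcov = pcov.loc[resp["person_id"]]
    except KeyError as exc:
        raise ModelError(f"person covariate table misses ids: {exc}")

    scov = pd.read_csv(school_cov_path)
    if "school_id" not in scov.columns:
        raise ModelError("school covariate file lacks school_id")
    if scov.isna().any().any():
        raise ModelError("missing cells in school covariate file")
    scov = scov.sort_values("school_id")
    school_ids = scov["school_id"].to_numpy()
    unknown = set(resp["school_id"]) - set(school_ids)
    if unknown:
        raise ModelError(f"unknown school key(s) in responses: {sorted(unknown)}")
    id_to_pos = {sid: i for i, sid in enumerate(school_ids)}
    school_index = resp["school_id"].map(id_to_pos).to_numpy()

    n = len(resp)
    person_design = np.column_stack([np.ones(n), pcov.to_numpy(dtype=float)])
    school_design = np.column_stack([
        np.ones(len(scov)), scov.drop(columns="school_id").to_numpy(dtype=float)
    ])
    return HierarchicalDataset(
        vals.astype(np.int8), school_index, person_design, school_design
    )


# ---------------------------------------------------------------------------
# draws
# ---------------------------------------------------------------------------

def write_draws(draws: PosteriorDraws, path, *, include_snapshots: bool = False) -> None:
    """Tidy long format plus a JSON metadata sidecar (lossless round-trip)."""
    path = Path(path)
    records = []
    series = {**draws.structural_draws(), **draws.item_draws()}
    for name, mat in series.items():
        C, M = mat.shape
        for c in range(C):
            records.append(pd.DataFrame({
                "chain": c,
                "iteration": np.arange(M),
                "parameter": name,
                "value": mat[c],
            }))
    # %.17g guarantees a lossless double round-trip
    pd.concat(records, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = {
        "chains": draws.n_chains,
        "kept": draws.n_kept,
        "K": draws.a.shape[2],
        "Q": draws.a.shape[3],
        "gamma_names": draws.gamma_names,
        "tau_names": draws.tau_names,
        "random": draws.spec.random.tolist(),
        "school_mask": draws.spec.school_mask.tolist(),
        "label": draws.spec.label,
        "n_snapshots": len(draws.snapshots) if include_snapshots else 0,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    if include_snapshots and draws.snapshots:
        _write_snapshots(draws.snapshots, path.with_suffix(path.suffix + ".snapshots.csv"))


def _snapshot_fields(snap: Snapshot):
    yield "Z", snap.Z
    for q, g in enumerate(snap.gamma):
        yield f"gamma{q}", g
    yield "a", snap.a
    yield "b", snap.b
    yield "Sigma_e", snap.Sigma_e
    for q, t in enumerate(snap.T):
        yield f"T{q}", t


def _write_snapshots(snapshots: list[Snapshot], path) -> None:
    frames = []
    shapes = {name: arr.shape for name, arr in _snapshot_fields(snapshots[0])}
    for m, snap in enumerate(snapshots):
        for name, arr in _snapshot_fields(snap):
            frames.append(pd.DataFrame({
                "snapshot": m,
                "field": name,
                "index": np.arange(arr.size),
                "value": np.asarray(arr, dtype=float).ravel(),
            }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )
    Path(str(path) + ".shapes.json").write_text(
        json.dumps({k: list(v) for k, v in shapes.items()})
    )


def _read_snapshots(path) -> list[Snapshot]:
    df = pd.read_csv(path, float_precision="round_trip")
    shapes = json.loads(Path(str(path) + ".shapes.json").read_text())
    out = []
    for m, grp in df.groupby("snapshot"):
        fields = {}
        for name, sub in grp.groupby("field"):
            arr = sub.sort_values("index")["value"].to_numpy()
            fields[name] = arr.reshape(shapes[name])
        n_gam = sum(1 for k in fields if k.startswith("gamma"))
        n_T = sum(1 for k in fields if k.startswith("T"))
        out.append(Snapshot(
            Z=fields["Z"],
            gamma=[fields[f"gamma{q}"] for q in range(n_gam)],
            a=fields["a"],
            b=fields["b"],
            Sigma_e=fields["Sigma_e"],
            T=[fields[f"T{q}"] for q in range(n_T)],
        ))
    return out


def read_draws(path) -> PosteriorDraws:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    if df[["chain", "iteration", "parameter", "value"]].isna().any().any():
        raise ModelError(f"truncated or malformed draws file {path}")
    C, M, K, Q = meta["chains"], meta["kept"], meta["K"], meta["Q"]
    spec = ModelSpec(
        np.array(meta["random"], dtype=bool),
        np.array(meta["school_mask"], dtype=bool),
        label=meta["label"],
    )
    wide = df.pivot_table(
        index=["chain", "iteration"], columns="parameter", values="value",
        sort=False,
    )

    def series(name):
        return wide[name].to_numpy().reshape(C, M)

    gamma = np.stack([series(n) for n in meta["gamma_names"]], axis=-1) \
        if meta["gamma_names"] else np.zeros((C, M, 0))
    sigma = np.empty((C, M, Q, Q))
    for q1 in range(Q):
        for q2 in range(Q):
            sigma[:, :, q1, q2] = series(f"sigma_e{q1 + 1}{q2 + 1}")
    Ts = []
    pos = 0
    for q in range(Q):
        r = spec.r_q(q)
        block = np.empty((C, M, r, r))
        for i, name in enumerate(meta["tau_names"][pos:pos + r * r]):
            block[:, :, i // r, i % r] = series(name)
        pos += r * r
        Ts.append(block)
    a = np.empty((C, M, K, Q))
    b = np.empty((C, M, K))
    for k in range(K):
        for q in range(Q):
            a[:, :, k, q] = series(f"a_{k + 1}_{q + 1}")
        b[:, :, k] = series(f"b_{k + 1}")
    snaps_path = path.with_suffix(path.suffix + ".snapshots.csv")
    snapshots = _read_snapshots(snaps_path) if snaps_path.exists() else []
    return PosteriorDraws(
        gamma=gamma, gamma_names=meta["gamma_names"], sigma_e=sigma, T=Ts,
        tau_names=meta["tau_names"], a=a, b=b, spec=spec, snapshots=snapshots,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CHAIN_KEYS = {"iterations", "burn_in", "chains", "seed", "z_thin",
               "store_augmented", "store_abilities", "store_coefficients",
               "overdispersed_starts"}
_PRIOR_KEYS = {"mu_a", "var_a", "mu_b", "var_b", "gamma_bound", "v0",
               "Sigma0_scale", "v1", "Sigma1_scale", "improper_T",
               "diagonal_sigma_e"}
_TOP_KEYS = {"model", "priors", "chain"}
_MODEL_KEYS = {"variant", "Q", "n_person_cols", "n_school_cols", "random",
               "school_mask", "label"}


def load_run_config(path) -> tuple[ModelSpec | None, PriorSpec, ChainConfig]:
    """Load a YAML/JSON run configuration with defaults applied.

    An empty file yields all defaults and ``spec=None`` (interpreted by
    callers as: every coefficient random with all school covariates, built
    once the data dimensions are known).  Unknown keys are rejected.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ModelError("run config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ModelError(f"unknown config section(s): {sorted(unknown)}")

    chain_raw = raw.get("chain", {}) or {}
    bad = set(chain_raw) - _CHAIN_KEYS
    if bad:
        raise ModelError(f"unknown chain key(s): {sorted(bad)}")
    config = ChainConfig(**chain_raw)

    prior_raw = raw.get("priors", {}) or {}
    bad = set(prior_raw) - _PRIOR_KEYS
    if bad:
        raise ModelError(f"unknown prior key(s): {sorted(bad)}")
    priors = PriorSpec(**prior_raw)

    model_raw = raw.get("model", {}) or {}
    bad = set(model_raw) - _MODEL_KEYS
    if bad:
        raise ModelError(f"unknown model key(s): {sorted(bad)}")
    spec = None
    if model_raw:
        if "variant" in model_raw:
            if "Q" not in model_raw:
                raise ModelError("a named variant requires the Q key")
            spec = build_model_spec(
                model_raw["variant"], Q=int(model_raw["Q"]),
                n_person_cols=int(model_raw.get("n_person_cols", 3)),
                n_school_cols=int(model_raw.get("n_school_cols", 3)),
                label=model_raw.get("label"),
            )
        else:
            spec = ModelSpec(
                np.array(model_raw["random"], dtype=bool),
                np.array(model_raw["school_mask"], dtype=bool),
                label=model_raw.get("label", "custom"),
            )
    return spec, priors, config


def write_manifest(path, *, seed, config_digest_source: str = "") -> None:
    """Reproducibility manifest: seed, config hash, library versions."""
    import scipy

    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            config_digest_source.encode()
        ).hexdigest(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
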