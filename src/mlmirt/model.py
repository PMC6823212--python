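"""Core model layer: data containers, the probit measurement model and the
two structural regression layers of the three-level multidimensional IRT model.

The measurement model is a within-item multidimensional two-parameter
normal-ogive model: person (i, j) answers item k correctly with probability

    P(Y_ijk = 1) = Phi(eta_ijk),    eta_ijk = sum_q a_kq * theta_ijq - b_k,

where Phi is the standard-normal CDF, a_kq >= 0 are discriminations and b_k
is the difficulty.  Abilities theta_ij (Q-vector) are regressed on person
covariates with school-specific coefficients (level 2), and those
coefficients are in turn regressed on school covariates (level 3).  The
latent scale is identified by anchoring the first Q items: item k <= Q has
a_kk = 1, a_kq = 0 (q != k) and b_k = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc, ndtri  # noqa: F401  (ndtri re-exported for samplers)


class ModelError(ValueError):
    """Structured error for invalid model inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ItemParameters:
    """Discriminations (K x Q), difficulties (K,) and the anchor mask.

    Anchor items pin the latent scale: for k < Q (0-based), a_kq = 1 if
    k == q else 0 and b_k = 0.  Anchored entries never change during
    sampling; all free discriminations are kept strictly positive.
    """

    discriminations: np.ndarray
    difficulties: np.ndarray
    anchor_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.discriminations = np.asarray(self.discriminations, dtype=float)
        self.difficulties = np.asarray(self.difficulties, dtype=float)
        if self.discriminations.ndim != 2:
            raise ModelError("discriminations must be a K x Q matrix")
        K = self.discriminations.shape[0]
        if self.difficulties.shape != (K,):
            raise ModelError(
                f"difficulties must have length K={K}, got {self.difficulties.shape}"
            )
        if self.anchor_mask is None:
            self.anchor_mask = np.zeros(K, dtype=bool)
        else:
            self.anchor_mask = np.asarray(self.anchor_mask, dtype=bool)
            if self.anchor_mask.shape != (K,):
                raise ModelError("anchor_mask must have length K")

    @property
    def n_items(self) -> int:
        return self.discriminations.shape[0]

    @property
    def n_dim(self) -> int:
        return self.discriminations.shape[1]

    def copy(self) -> "ItemParameters":
        return ItemParameters(
            self.discriminations.copy(),
            self.difficulties.copy(),
            self.anchor_mask.copy(),
        )


@dataclass
class HierarchicalDataset:
    """Binary responses with the person- and school-level design matrices.

    ``person_design`` is n x (h+1) with a leading constant column;
    ``school_design`` is J x (s+1) with a leading constant column;
    ``school_index`` maps each person row to a school in 0..J-1.
    """

    responses: np.ndarray
    school_index: np.ndarray
    person_design: np.ndarray
    school_design: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        self.school_index = np.asarray(self.school_index, dtype=int)
        self.person_design = np.asarray(self.person_design, dtype=float)
        self.school_design = np.asarray(self.school_design, dtype=float)
        n, K = self.responses.shape
        vals = np.unique(self.responses)
        if not np.all(np.isin(vals, [0, 1])):
            raise ModelError(
                f"responses must contain only 0/1; found values {vals[:5]}"
            )
        if self.school_index.shape != (n,):
            raise ModelError("school_index must have one entry per person")
        J = self.school_design.shape[0]
        if self.school_index.min() < 0 or self.school_index.max() >= J:
            raise ModelError("school_index out of range for school_design")
        counts = np.bincount(self.school_index, minlength=J)
        if (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            raise ModelError(f"school {empty} has no persons")
        if self.person_design.shape[0] != n:
            raise ModelError("person_design must have one row per person")
        if not np.allclose(self.person_design[:, 0], 1.0):
            raise ModelError("person_design must carry a leading constant column")
        if not np.allclose(self.school_design[:, 0], 1.0):
            raise ModelError("school_design must carry a leading constant column")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_schools(self) -> int:
        return self.school_design.shape[0]

    @property
    def n_person_cols(self) -> int:
        """h + 1: person design columns including the constant."""
        return self.person_design.shape[1]

    @property
    def n_school_cols(self) -> int:
        """s + 1: school design columns including the constant."""
        return self.school_design.shape[1]

    def school_sizes(self) -> np.ndarray:
        return np.bincount(self.school_index, minlength=self.n_schools)


@dataclass
class ModelSpec:
    """Which person-level coefficients are random and which school covariates
    predict each of them.

    ``random``: bool (h+1, Q); entry (p, q) is True when coefficient beta_pjq
    carries a school residual u_pjq.
    ``school_mask``: bool (h+1, s+1, Q); entry (p, c, q) is True when school
    design column c predicts beta_pjq.  Column 0 (the constant) is always on,
    so a fixed coefficient with an otherwise empty mask reduces to a single
    global parameter.
    """

    random: np.ndarray
    school_mask: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.random = np.asarray(self.random, dtype=bool)
        self.school_mask = np.asarray(self.school_mask, dtype=bool)
        if self.random.ndim != 2:
            raise ModelError("random flags must be (h+1, Q)")
        P, Q = self.random.shape
        if (
            self.school_mask.ndim != 3
            or self.school_mask.shape[0] != P
            or self.school_mask.shape[2] != Q
        ):
            raise ModelError("school_mask must be (h+1, s+1, Q)")
        if not self.school_mask[:, 0, :].all():
            raise ModelError("the constant school column must predict every coefficient")

    @property
    def n_coef(self) -> int:
        return self.random.shape[0]

    @property
    def n_dim(self) -> int:
        return self.random.shape[1]

    def r_q(self, q: int) -> int:
        """Number of random coefficients on dimension q."""
        return int(self.random[:, q].sum())

    def random_idx(self, q: int) -> np.ndarray:
        return np.flatnonzero(self.random[:, q])

    def fixed_idx(self, q: int) -> np.ndarray:
        return np.flatnonzero(~self.random[:, q])

    def gamma_names(self, q: int) -> list[str]:
        """Flat fixed-effect names for dimension q, paper-style gamma_{pcq}."""
        names = []
        for p in range(self.n_coef):
            for c in np.flatnonzero(self.school_mask[p, :, q]):
                names.append(f"gamma_{p}{c}{q + 1}")
        return names

    def tau_names(self, q: int) -> list[str]:
        """Level-3 covariance entry names for dimension q, tau_{p1 p2 q}."""
        idx = self.random_idx(q)
        return [f"tau_{p1}{p2}{q + 1}" for p1 in idx for p2 in idx]


@dataclass
class PriorSpec:
    """Priors for one fit.

    Item parameters get independent normal priors, discriminations truncated
    to (0, inf).  Fixed effects are flat by default; ``gamma_bound`` enables a
    uniform box prior U(-bound, bound).  Both covariance levels use
    inverse-Wishart priors; ``improper_T=True`` uses p(T_q) proportional to 1,
    read as v1 = 0 with a zero scale matrix.
    """

    mu_a: float = 0.0
    var_a: float = 100.0
    mu_b: float = 0.0
    var_b: float = 100.0
    gamma_bound: float | None = None
    v0: int | None = None          # defaults to Q + 2 at fit time
    Sigma0_scale: float = 1.0      # Sigma0 = scale * I_Q
    v1: int | None = None          # defaults to r_q + 2 at fit time
    Sigma1_scale: float = 1.0      # Sigma1 = scale * I_{r_q}
    improper_T: bool = False
    diagonal_sigma_e: bool = False  # constrain level-2 residuals independent

    def __post_init__(self) -> None:
        if self.var_a <= 0 or self.var_b <= 0:
            raise ModelError("prior variances must be positive")
        if self.gamma_bound is not None and self.gamma_bound <= 0:
            raise ModelError("gamma_bound must be positive")


# ---------------------------------------------------------------------------
# measurement-model operations
# ---------------------------------------------------------------------------

def linear_predictor(theta_row: np.ndarray, a: np.ndarray, b: float) -> float:
    """eta = sum_q a_q * theta_q - b for one person/item pair."""
    theta_row = np.asarray(theta_row, dtype=float)
    a = np.asarray(a, dtype=float)
    if theta_row.shape != a.shape:
        raise ModelError(
            f"ability ({theta_row.shape}) and discrimination ({a.shape}) "
            "dimensions do not match"
        )
    return float(a @ theta_row - b)


def response_probability(eta):
    """Standard-normal CDF of the linear predictor.

    Computed through the complementary error function, which is accurate in
    both tails (Phi(eta) = erfc(-eta/sqrt(2)) / 2).
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ModelError("linear predictor must be finite")
    out = 0.5 * erfc(-eta / np.sqrt(2.0))
    return float(out) if out.ndim == 0 else out


def apply_identification_constraints(
    items: ItemParameters, Q: int | None = None, anchors: list[int] | None = None
) -> ItemParameters:
    """Anchor Q items to the identity loading pattern with zero difficulty.

    By default the anchors are the first Q items in input order; an explicit
    ``anchors`` list (one item per dimension, in dimension order) overrides
    that.  Idempotent.
    """
    out = items.copy()
    K, nQ = out.discriminations.shape
    Q = nQ if Q is None else Q
    if Q != nQ:
        raise ModelError(f"Q={Q} does not match loading matrix with {nQ} columns")
    if K < Q:
        raise ModelError(f"need at least Q={Q} items to anchor, have K={K}")
    if anchors is None:
        anchors = list(range(Q))
    if len(anchors) != Q:
        raise ModelError(f"need exactly one anchor item per dimension ({Q})")
    if len(set(anchors)) != len(anchors):
        raise ModelError(f"duplicated anchor item in {anchors}")
    out.anchor_mask[:] = False
    for q, k in enumerate(anchors):
        out.discriminations[k, :] = 0.0
        out.discriminations[k, q] = 1.0
        out.difficulties[k] = 0.0
        out.anchor_mask[k] = True
    return out


def conditional_ability_prior(
    q: int,
    theta_row: np.ndarray,
    mean_row: np.ndarray,
    Sigma_e: np.ndarray,
) -> tuple[float, float]:
    """Conditional prior of theta_q given the other dimensions.

    ``mean_row`` holds the structural means X_ij beta_jq for every dimension.
    Returns (mu_q + S_q,-q S_-q,-q^{-1} (theta_-q - mu_-q),
             S_qq - S_q,-q S_-q,-q^{-1} S_-q,q).
    """
    Sigma_e = np.asarray(Sigma_e, dtype=float)
    theta_row = np.asarray(theta_row, dtype=float)
    mean_row = np.asarray(mean_row, dtype=float)
    Q = Sigma_e.shape[0]
    if Q == 1:
        return float(mean_row[0]), float(Sigma_e[0, 0])
    other = [i for i in range(Q) if i != q]
    S_oo = Sigma_e[np.ix_(other, other)]
    S_qo = Sigma_e[q, other]
    try:
        w = np.linalg.solve(S_oo, S_qo)
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"singular cross-dimension covariance block: {exc}")
    mean = mean_row[q] + w @ (theta_row[other] - mean_row[other])
    var = Sigma_e[q, q] - w @ S_qo
    if var <= 0:
        raise ModelError("conditional ability variance is not positive")
    return float(mean), float(var)


# ---------------------------------------------------------------------------
# structural model variants
# ---------------------------------------------------------------------------

_VARIANTS = ("model1", "model2", "model3")


def build_model_spec(
    variant: str | None = None,
    *,
    Q: int,
    n_person_cols: int = 3,
    n_school_cols: int = 3,
    random: np.ndarray | None = None,
    school_mask: np.ndarray | None = None,
    label: str | None = None,
) -> ModelSpec:
    """Build a ModelSpec from a named structural variant or explicit masks.

    The named variants encode the three candidate structures compared in the
    application (person covariates SES and gender; school covariates
    satisfaction and climate):

    * ``model1`` — random intercept only, no school covariates, both person
      slopes fixed.
    * ``model2`` — intercept predicted by both school covariates and random;
      SES slope random without school covariates; gender slope fixed.
    * ``model3`` — as model2 but the gender slope is random too.
    """
    if variant is None:
        if random is None or school_mask is None:
            raise ModelError("either a variant name or explicit masks are required")
        return ModelSpec(random, school_mask, label=label or "custom")
    if variant not in _VARIANTS:
        raise ModelError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")
    if n_person_cols != 3 or n_school_cols != 3:
        raise ModelError(
            "named variants require two person covariates and two school covariates"
        )
    P, C = n_person_cols, n_school_cols
    rand = np.zeros((P, Q), dtype=bool)
    mask = np.zeros((P, C, Q), dtype=bool)
    mask[:, 0, :] = True
    rand[0, :] = True                      # intercept always random
    if variant in ("model2", "model3"):
        mask[0, 1:, :] = True              # school covariates on the intercept
        rand[1, :] = True                  # SES slope random
    if variant == "model3":
        rand[2, :] = True                  # gender slope random too
    return ModelSpec(rand, mask, label=label or variant)


def full_random_spec(Q: int, n_person_cols: int, n_school_cols: int) -> ModelSpec:
    """Every coefficient random, every school covariate predicting each one.

    This is the structure of both simulation designs (e.g. the two-level
    model beta_hjq = gamma_h0q + gamma_h1q w_j + u_hjq).
    """
    P, C = n_person_cols, n_school_cols
    return ModelSpec(
        np.ones((P, Q), dtype=bool),
        np.ones((P, C, Q), dtype=bool),
        label="full-random",
    )


def all_fixed_spec(Q: int, n_person_cols: int, n_school_cols: int = 1) -> ModelSpec:
    """Degenerate spec: no random coefficients (single-level latent regression)."""
    P, C = n_person_cols, n_school_cols
    mask = np.zeros((P, C, Q), dtype=bool)
    mask[:, 0, :] = True
    return ModelSpec(np.zeros((P, Q), dtype=bool), mask, label="all-fixed")
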