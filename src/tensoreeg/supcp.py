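"""Supervised canonical polyadic (SupCP) factorization fitted by EM.

Model: for participant i with feature tensor X_i (modes d_1 x ... x d_K)
and supervision row y_i (class indicator + covariates),

    X_i = sum_r u_ir (v^1_r o v^2_r o ... o v^K_r) + E_i,
    u_i  = y_i B + f_i,     f_i ~ N(0, Sigma_f),   E_i ~ N(0, sigma^2 I),

with Sigma_f diagonal.  Marginalizing the latent scores u_i gives a
Gaussian on the vectorized tensor with mean W B' y_i and covariance
W Sigma_f W' + sigma^2 I, where W is the Khatri-Rao product of the mode
loading matrices; all linear algebra below exploits that structure
(R x R solves instead of D x D).  EM alternates the conditional
moments of U with closed-form updates of the loadings, the regression
coefficients B, Sigma_f and sigma^2, so the observed-data log-likelihood
is non-decreasing.  Scale indeterminacy is resolved by unit-norm loading
columns, with magnitude absorbed into the scores (and hence B, Sigma_f),
which leaves the likelihood unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from tensoreeg.tensor import FeatureTensor, SupervisionMatrix

_SF_FLOOR = 1e-12


@dataclass
class SupCPModel:
    """Fitted SupCP parameters and conditional score estimates."""

    rank: int
    factor_matrices: list[np.ndarray]  # one (d_k, R) loading matrix per mode
    coeff_matrix: np.ndarray  # B, (q, R)
    score_var: np.ndarray  # diagonal of Sigma_f, (R,)
    noise_var: float  # sigma^2
    scores: np.ndarray  # E[U | X, Y], (n, R)
    loglik_trace: np.ndarray
    axis_names: tuple[str, ...] = ()
    axis_labels: dict = field(default_factory=dict)
    column_names: list[str] = field(default_factory=list)

    @property
    def mode_dims(self) -> tuple[int, ...]:
        return tuple(v.shape[0] for v in self.factor_matrices)

    def gram(self) -> np.ndarray:
        """W'W as the Hadamard product of the per-mode Gram matrices."""
        g = np.ones((self.rank, self.rank))
        for v in self.factor_matrices:
            g *= v.T @ v
        return g

    def low_rank(self, scores: np.ndarray | None = None) -> np.ndarray:
        """Rank-R reconstruction sum_r u_r (v1_r o ... o vK_r)."""
        u = self.scores if scores is None else scores
        return cp_reconstruct(u, self.factor_matrices)

    def permuted(self, perm: np.ndarray) -> "SupCPModel":
        """Jointly reorder factors (likelihood-invariant)."""
        perm = np.asarray(perm)
        return SupCPModel(
            rank=self.rank,
            factor_matrices=[v[:, perm] for v in self.factor_matrices],
            coeff_matrix=self.coeff_matrix[:, perm],
            score_var=self.score_var[perm],
            noise_var=self.noise_var,
            scores=self.scores[:, perm],
            loglik_trace=self.loglik_trace,
            axis_names=self.axis_names,
            axis_labels=self.axis_labels,
            column_names=list(self.column_names),
        )


def cp_reconstruct(u: np.ndarray, factors: list[np.ndarray]) -> np.ndarray:
    """Dense tensor from CP factors: out[i, a, b, ...] = sum_r u[i,r] prod V[., r]."""
    n, r = u.shape
    t = u
    # t: (n, [assembled modes...], R) grown one mode at a time
    t = t[:, None, :] * factors[0][None, :, :]
    for v in factors[1:]:
        t = t[..., None, :] * v[(None,) * (t.ndim - 1) + (slice(None), slice(None))]
    return t.sum(axis=-1)


def _mode_contract(t: np.ndarray, v: np.ndarray, axis: int) -> np.ndarray:
    """Contract axis `axis` of t (..., R) with v (d, R), columnwise in R."""
    letters = [chr(ord("a") + i) for i in range(t.ndim - 1)] + ["r"]
    sub_t = "".join(letters)
    sub_v = letters[axis] + "r"
    sub_out = "".join(l for i, l in enumerate(letters) if i != axis)
    return np.einsum(f"{sub_t},{sub_v}->{sub_out}", t, v)


def _contract_data(x: np.ndarray, factors: list[np.ndarray]) -> np.ndarray:
    """XW: (n, R) with XW[i, r] = <vec(X_i), w_r>."""
    t = np.tensordot(x, factors[0], axes=([1], [0]))  # (n, d2.., R)
    # after each contraction the next tensor mode is again at axis 1
    for v in factors[1:]:
        t = _mode_contract(t, v, 1)
    return t


def _as_array_and_meta(x) -> tuple[np.ndarray, tuple, dict]:
    if isinstance(x, FeatureTensor):
        return x.array, x.axis_names, x.axis_labels
    return np.asarray(x, dtype=float), (), {}


def _as_supervision(y, n: int) -> tuple[np.ndarray, list[str]]:
    if y is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(y, SupervisionMatrix):
        return y.Y, list(y.column_names)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    return y, [f"y{i}" for i in range(y.shape[1])]


def fit_supcp(
    X,
    Y=None,
    R: int = 30,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    n_starts: int = 1,
) -> SupCPModel:
    """Fit the SupCP model by EM.

    Parameters
    ----------
    X : FeatureTensor or ndarray, shape (n, d_1, ..., d_K)
    Y : SupervisionMatrix, ndarray or None (None fits a lone intercept,
        i.e. unsupervised probabilistic CP)
    R : rank (number of latent factors); must not exceed prod(d_k)
    tol : stop when the relative log-likelihood change drops below tol
    max_iter : iteration cap
    seed : seeds the random orthonormal loading initialization
    n_starts : independent EM runs from different seeded initializations;
        the fit with the highest final log-likelihood is returned (EM on
        CP structure can stall in local optima)

    Raises ``ValueError`` for infeasible rank and ``FloatingPointError``
    (with the iteration index) if the log-likelihood becomes non-finite.
    """
    if n_starts > 1:
        fits = [
            fit_supcp(X, Y, R=R, tol=tol, max_iter=max_iter,
                      seed=seed + 1009 * j, n_starts=1)
            for j in range(n_starts)
        ]
        return max(fits, key=lambda m: m.loglik_trace[-1])
    x, axis_names, axis_labels = _as_array_and_meta(X)
    if x.ndim < 3:
        raise ValueError("X must have at least two non-participant modes")
    n = x.shape[0]
    dims = x.shape[1:]
    d_total = int(np.prod(dims))
    if R < 1 or R > d_total:
        raise ValueError(f"rank {R} infeasible for modes {dims} (D={d_total})")
    y, column_names = _as_supervision(Y, n)
    if y.shape[0] != n:
        raise ValueError("supervision rows must align with the participant mode")

    rng = np.random.default_rng(seed)
    factors = []
    for d in dims:
        a = rng.standard_normal((d, R))
        if R <= d:
            a = np.linalg.qr(a)[0]
        else:
            a /= np.linalg.norm(a, axis=0, keepdims=True)
        factors.append(a)
    q = y.shape[1]
    b = np.zeros((q, R))
    sf = np.ones(R)
    s2 = max(float(np.var(x)), 1e-8) / 2.0
    x_sq = float(np.sum(x**2))
    yty = y.T @ y
    trace = []

    for it in range(max_iter):
        # ----- E-step
        wtw = np.ones((R, R))
        for v in factors:
            wtw *= v.T @ v
        xw = _contract_data(x, factors)
        prec = wtw / s2 + np.diag(1.0 / sf)
        cf = linalg.cho_factor(prec)
        sigma_u = linalg.cho_solve(cf, np.eye(R))
        yb = y @ b
        eu = (xw / s2 + yb / sf[None, :]) @ sigma_u
        eutu = eu.T @ eu + n * sigma_u

        # ----- observed-data log-likelihood under current parameters
        logdet = d_total * np.log(s2) + np.sum(np.log(sf)) + 2 * np.sum(
            np.log(np.diag(cf[0]))
        )
        q_mat = xw - yb @ wtw  # rows W'(x_i - W B'y_i)
        rss = x_sq - 2 * np.sum(yb * xw) + np.sum(wtw * (yb.T @ yb))
        quad = rss / s2 - np.sum(q_mat * linalg.cho_solve(cf, q_mat.T).T) / s2**2
        ll = -0.5 * (n * d_total * np.log(2 * np.pi) + n * logdet + quad)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1e-12):
            break

        # ----- M-step (conditional closed-form block updates)
        g = np.tensordot(eu, x, axes=(0, 0))  # (R, d1, ..., dK)
        g = np.moveaxis(g, 0, -1)  # (d1, ..., dK, R)
        grams = [v.T @ v for v in factors]
        for k in range(len(dims)):
            t = g
            for j in range(len(dims) - 1, -1, -1):
                if j == k:
                    continue
                t = _mode_contract(t, factors[j], j)
            gamma = eutu.copy()
            for j in range(len(dims)):
                if j != k:
                    gamma *= grams[j]
            factors[k] = np.linalg.solve(gamma.T, t.T).T
            grams[k] = factors[k].T @ factors[k]

        b = np.linalg.lstsq(y, eu, rcond=None)[0]
        resid = eu - y @ b
        sf = np.maximum(np.mean(resid**2, axis=0) + np.diag(sigma_u), _SF_FLOOR)

        wtw = np.ones((R, R))
        for gm in grams:
            wtw *= gm
        xw = _contract_data(x, factors)
        s2 = (x_sq - 2 * np.sum(eu * xw) + np.sum(wtw * eutu)) / (n * d_total)
        s2 = max(s2, 1e-12)

        # ----- unit-norm loading columns; magnitude into scores (B, Sigma_f)
        scale = np.ones(R)
        for k, v in enumerate(factors):
            norms = np.maximum(np.linalg.norm(v, axis=0), 1e-300)
            factors[k] = v / norms
            grams[k] = factors[k].T @ factors[k]
            scale *= norms
        b *= scale[None, :]
        sf = np.maximum(sf * scale**2, _SF_FLOOR)

    # final E-step so scores match the returned parameters
    wtw = np.ones((R, R))
    for v in factors:
        wtw *= v.T @ v
    xw = _contract_data(x, factors)
    prec = wtw / s2 + np.diag(1.0 / sf)
    sigma_u = linalg.cho_solve(linalg.cho_factor(prec), np.eye(R))
    eu = (xw / s2 + (y @ b) / sf[None, :]) @ sigma_u

    return SupCPModel(
        rank=R,
        factor_matrices=factors,
        coeff_matrix=b,
        score_var=sf,
        noise_var=float(s2),
        scores=eu,
        loglik_trace=np.asarray(trace),
        axis_names=axis_names,
        axis_labels=axis_labels,
        column_names=column_names,
    )


def marginal_log_likelihood(model: SupCPModel, x_i: np.ndarray, y_i: np.ndarray) -> float:
    """Log density of one participant's tensor under the marginal Gaussian.

    The latent scores are integrated out: vec(X_i) ~ N(W B'y_i,
    W Sigma_f W' + sigma^2 I).  Evaluated through the Woodbury identity so
    only R x R systems are solved.
    """
    x_i = np.asarray(x_i, dtype=float)
    if x_i.shape != model.mode_dims:
        raise ValueError(f"slice shape {x_i.shape} does not match model modes {model.mode_dims}")
    y_i = np.atleast_1d(np.asarray(y_i, dtype=float))
    if y_i.shape[0] != model.coeff_matrix.shape[0]:
        raise ValueError("supervision row length does not match the coefficient matrix")
    r = model.rank
    s2 = model.noise_var
    sf = model.score_var
    d_total = int(np.prod(model.mode_dims))
    wtw = model.gram()
    xw = _contract_data(x_i[None], model.factor_matrices)[0]
    mu_scores = y_i @ model.coeff_matrix  # prior mean of u_i
    prec = wtw / s2 + np.diag(1.0 / sf)
    cf = linalg.cho_factor(prec)
    logdet = d_total * np.log(s2) + np.sum(np.log(sf)) + 2 * np.sum(np.log(np.diag(cf[0])))
    q_vec = xw - wtw @ mu_scores
    rss = float(x_i.ravel() @ x_i.ravel()) - 2 * float(mu_scores @ xw) + float(
        mu_scores @ wtw @ mu_scores
    )
    quad = rss / s2 - float(q_vec @ linalg.cho_solve(cf, q_vec)) / s2**2
    return float(-0.5 * (d_total * np.log(2 * np.pi) + logdet + quad))


@dataclass
class LatentFactorReport:
    """Per-factor association with an outcome, ranked by |r|."""

    factor_index: np.ndarray  # original factor positions, ranked
    r: np.ndarray  # association (Pearson / point-biserial) per ranked factor
    p: np.ndarray
    retained: np.ndarray  # boolean, |r| > threshold
    threshold: float
    participant_weights: np.ndarray  # (n, R), ranked column order
    mode_weights: list[np.ndarray]  # per mode, (d_k, R), ranked column order
    flags: list[str]

    @property
    def retained_weights(self) -> np.ndarray:
        return self.participant_weights[:, self.retained]


def extract_factor_report(
    model: SupCPModel,
    outcome: np.ndarray,
    threshold: float = 0.2,
) -> LatentFactorReport:
    """Rank latent factors by |association| with an outcome.

    ``outcome`` may be continuous (age) or binary (group); the association
    is the Pearson correlation of the participant score column with the
    outcome (point-biserial for a 0/1 outcome).  Factors with |r| above
    the threshold (default 0.2) form the retained set.  Constant score
    columns get association 0 and a flag.
    """
    outcome = np.asarray(outcome, dtype=float).ravel()
    u = model.scores
    if u.shape[0] != outcome.shape[0]:
        raise ValueError("outcome length must match the participant mode")
    rs = np.zeros(model.rank)
    ps = np.ones(model.rank)
    flags = []
    for j in range(model.rank):
        col = u[:, j]
        if np.std(col) == 0 or np.std(outcome) == 0:
            flags.append(f"factor {j}: constant weights; association set to 0")
            continue
        rs[j], ps[j] = stats.pearsonr(col, outcome)
    order = np.argsort(-np.abs(rs), kind="stable")
    return LatentFactorReport(
        factor_index=order,
        r=rs[order],
        p=ps[order],
        retained=np.abs(rs[order]) > threshold,
        threshold=threshold,
        participant_weights=u[:, order],
        mode_weights=[v[:, order] for v in model.factor_matrices],
        flags=flags,
    )


def factor_congruence(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute column congruence after greedy factor matching.

    Columns of ``b`` are matched to columns of ``a`` by maximal |cosine|;
    returns (mean matched |cosine|, permutation applied to b's columns).
    Used to compare a fitted loading matrix with ground truth up to the
    CP sign/permutation indeterminacy.
    """
    a = a / np.maximum(np.linalg.norm(a, axis=0, keepdims=True), 1e-300)
    b = b / np.maximum(np.linalg.norm(b, axis=0, keepdims=True), 1e-300)
    c = np.abs(a.T @ b)
    perm = np.full(a.shape[1], -1)
    used = set()
    for _ in range(a.shape[1]):
        i, j = np.unravel_index(np.argmax(c), c.shape)
        perm[i] = j
        used.add(j)
        c[i, :] = -1
        c[:, j] = -1
    a2 = a
    b2 = b[:, perm]
    cong = np.abs(np.sum(a2 * b2, axis=0))
    return float(np.mean(cong)), perm
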