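"""Stochastic variational inference for a Gaussian mixture over 2-D samples.

The generative story: a sample ``s`` comes from a K-component Gaussian
mixture whose parameters are themselves latent,

    weights        alpha ~ Dirichlet(D)
    means          mu_k ~ Normal(N1_k, diag(N2_k^2))
    precisions     Lambda_k ~ Wishart(W1_k, W2_k)

with priors Normal(0, 1) per coordinate on the means, Wishart(3, I/3) on the
precisions, and a symmetric Dirichlet on the weights.  Training minimizes the
negative Monte-Carlo evidence lower bound

    loss = -( (1/L) sum_l mean_i log p(s_i | theta_l)  -  kld_scale * KL(q || p) )

where theta_l are L reparameterized draws of (alpha, mu, Lambda) and the KL
term is the sum of closed-form Gaussian, Wishart and Dirichlet divergences.
Gradients flow through the draws (location-scale means, Bartlett precision
factors, normalized-Gamma weights, each with a moment-matched log-normal
surrogate where the exact path is not differentiable) into the unconstrained
parameterization of the variational state and, when the inputs are raw
21-frame windows, into the attention block as well.

Positivity and positive-definiteness are structural: positive scalars live on
a log scale, Dirichlet concentrations behind a softplus, and the Wishart
scale behind its Cholesky factor, so no projection step is ever needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import special as sp
from scipy.linalg import solve_triangular

from . import _tape as T
from ._tape import Var
from .trajectory_features import (
    FEATURE_DIM,
    WINDOW_LEN,
    AttentionParams,
    FeatureVector,
    FeatureWindow,
    attention_forward_batch,
    attention_graph,
    window_array,
)

DIM = FEATURE_DIM  # the mixture lives in the 2-D attended feature space
LOG_2PI = float(np.log(2.0 * np.pi))

SEVERITY_ORDER = ("normal", "transition", "falling")

# basis matrices used to assemble 2x2 lower-triangular factors on the tape
_E00 = np.array([[1.0, 0.0], [0.0, 0.0]])
_E10 = np.array([[0.0, 0.0], [1.0, 0.0]])
_E11 = np.array([[0.0, 0.0], [0.0, 1.0]])

ATTENTION_KEYS = ("gate_weights", "gate_bias", "projection")


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    # exact inverse up to float rounding: softplus(log(expm1(y))) == y
    y = np.asarray(y, dtype=float)
    return np.where(y > 30.0, y, np.log(np.expm1(np.minimum(y, 30.0))))


# ---------------------------------------------------------------------------
# specifications


@dataclass
class PriorSpec:
    """Prior p(z) over mixture parameters (may be per-cluster for the
    empirical-Bayes refresh mode; defaults are shared across clusters)."""

    mean_loc: np.ndarray  # (DIM,) or (K, DIM)
    mean_scale: np.ndarray  # std devs, same shapes
    wishart_df: np.ndarray  # scalar or (K,)
    wishart_scale: np.ndarray  # (DIM, DIM) or (K, DIM, DIM)
    dirichlet_conc: np.ndarray  # (K,)

    def __post_init__(self):
        self.mean_loc = np.asarray(self.mean_loc, dtype=float)
        self.mean_scale = np.asarray(self.mean_scale, dtype=float)
        self.wishart_df = np.asarray(self.wishart_df, dtype=float)
        self.wishart_scale = np.asarray(self.wishart_scale, dtype=float)
        self.dirichlet_conc = np.asarray(self.dirichlet_conc, dtype=float)
        if np.any(self.wishart_df <= DIM - 1):
            raise ValueError("invalid distribution: Wishart df must exceed dim - 1")
        if np.any(self.dirichlet_conc <= 0) or np.any(self.mean_scale <= 0):
            raise ValueError("invalid distribution")

    @property
    def K(self) -> int:
        return int(self.dirichlet_conc.shape[0])

    @classmethod
    def default(cls, K: int, dirichlet_interpretation: str = "2/K") -> "PriorSpec":
        """Normal(0,1) means, Wishart(3, I/3) precisions, symmetric Dirichlet.

        The Dirichlet concentration is 2/K per component by default (a weakly
        informative symmetric choice); ``"2K"`` selects the literal reading
        with concentration 2K.
        """
        if dirichlet_interpretation == "2/K":
            conc = 2.0 / K
        elif dirichlet_interpretation == "2K":
            conc = 2.0 * K
        else:
            raise ValueError("dirichlet_interpretation must be '2/K' or '2K'")
        return cls(
            mean_loc=np.zeros(DIM),
            mean_scale=np.ones(DIM),
            wishart_df=np.asarray(3.0),
            wishart_scale=np.eye(DIM) / 3.0,
            dirichlet_conc=np.full(K, conc),
        )


@dataclass
class GMMParams:
    """A concrete mixture: the point the posterior / maps are evaluated at."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, DIM)
    covariances: np.ndarray  # (K, DIM, DIM)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float).reshape(-1, DIM)
        self.covariances = np.asarray(self.covariances, dtype=float).reshape(
            -1, DIM, DIM
        )
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("invalid distribution: weights must sum to 1")

    @property
    def K(self) -> int:
        return int(self.weights.shape[0])

    def component_cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.covariances)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate component") from exc


@dataclass
class FitConfig:
    """Training settings for :func:`svi_fit`.

    ``kld_scale="auto"`` charges the KL term once per dataset (1/N per
    sample), the usual stochastic-variational scaling; a float pins it.

    The attention block trains at ``step_size * attention_step_scale``:
    a likelihood objective with a learnable feature map has a scale
    degeneracy (collapsing the map inflates the density), so the feature
    extractor must move much more slowly than the mixture it feeds.
    """

    K: int = 3
    covariance_mode: str = "full"  # "full" | "diagonal"
    L: int = 10
    batch_size: int = 64
    step_size: float = 1e-2
    momentum: float = 0.9
    steps: int = 2000
    kld_scale: Union[str, float] = "auto"
    dirichlet_interpretation: str = "2/K"
    train_attention: bool = True
    attention_step_scale: float = 1e-3
    clip_grad_norm: float = 10.0  # per-tensor cap; 0 disables
    init: str = "data"  # "data" (k-means) | "prior"
    empirical_bayes_every: int = 0  # refresh p(z) from q(z) every n steps; 0 = off
    seed: Optional[int] = None

    def __post_init__(self):
        if self.covariance_mode not in ("full", "diagonal"):
            raise ValueError("covariance_mode must be 'full' or 'diagonal'")

    @classmethod
    def from_json(cls, path) -> "FitConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# variational state

_SCHEMA_VERSION = 1


@dataclass
class VariationalState:
    """All trainable quantities, stored unconstrained.

    raw keys: ``n1`` (K,2), ``log_n2`` (K,2), ``w1_raw`` (K,),
    ``lw_log_diag`` (K,2), ``lw_off`` (K,) [full mode only], ``d_raw`` (K,),
    plus the attention parameters ``gate_weights``/``gate_bias``/``projection``.
    The natural parameters N1, N2, W1, W2, D are derived properties.
    """

    K: int
    covariance_mode: str
    raw: Dict[str, np.ndarray]

    def __post_init__(self):
        self.raw = {k: np.asarray(v, dtype=float) for k, v in self.raw.items()}
        for v in self.raw.values():
            if not np.all(np.isfinite(v)):
                raise ValueError("invalid distribution: non-finite state")

    # derived natural parameters -----------------------------------------
    @property
    def N1(self) -> np.ndarray:
        return self.raw["n1"]

    @property
    def N2(self) -> np.ndarray:
        return np.exp(self.raw["log_n2"])

    @property
    def W1(self) -> np.ndarray:
        return (DIM - 1) + np.exp(self.raw["w1_raw"])

    @property
    def chol_W2(self) -> np.ndarray:
        L = np.zeros((self.K, DIM, DIM))
        diag = np.exp(self.raw["lw_log_diag"])
        L[:, 0, 0] = diag[:, 0]
        L[:, 1, 1] = diag[:, 1]
        if self.covariance_mode == "full":
            L[:, 1, 0] = self.raw["lw_off"]
        return L

    @property
    def W2(self) -> np.ndarray:
        L = self.chol_W2
        return L @ np.swapaxes(L, -1, -2)

    @property
    def D(self) -> np.ndarray:
        return _softplus(self.raw["d_raw"])

    @property
    def attention(self) -> AttentionParams:
        return AttentionParams(
            self.raw["gate_weights"], self.raw["gate_bias"], self.raw["projection"]
        )

    # construction -------------------------------------------------------
    @classmethod
    def from_prior(
        cls,
        prior: PriorSpec,
        covariance_mode: str = "full",
        attention: Optional[AttentionParams] = None,
    ) -> "VariationalState":
        """Start the variational state exactly at the prior (KL = 0)."""
        K = prior.K
        attention = attention or AttentionParams.default()
        loc = np.broadcast_to(prior.mean_loc, (K, DIM)).copy()
        scale = np.broadcast_to(prior.mean_scale, (K, DIM)).copy()
        df = np.broadcast_to(prior.wishart_df, (K,)).copy()
        Vw = np.broadcast_to(prior.wishart_scale, (K, DIM, DIM)).copy()
        Lw = np.linalg.cholesky(Vw)
        raw = {
            "n1": loc,
            "log_n2": np.log(scale),
            "w1_raw": np.log(df - (DIM - 1)),
            "lw_log_diag": np.log(np.stack([Lw[:, 0, 0], Lw[:, 1, 1]], axis=1)),
            "d_raw": _softplus_inv(prior.dirichlet_conc.copy()),
            "gate_weights": attention.gate_weights.copy(),
            "gate_bias": attention.gate_bias.copy(),
            "projection": attention.projection.copy(),
        }
        if covariance_mode == "full":
            raw["lw_off"] = Lw[:, 1, 0].copy()
        return cls(K=K, covariance_mode=covariance_mode, raw=raw)

    # serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": _SCHEMA_VERSION,
            "K": self.K,
            "covariance_mode": self.covariance_mode,
            "raw": {k: v.tolist() for k, v in self.raw.items()},
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "VariationalState":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        if doc.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError("incompatible model: unknown schema version")
        return cls(
            K=doc["K"],
            covariance_mode=doc["covariance_mode"],
            raw={k: np.array(v, dtype=float) for k, v in doc["raw"].items()},
        )


# ---------------------------------------------------------------------------
# mixture density and posterior (Eq. 4 / Eq. 5 style quantities)


def _coerce_points(s) -> Tuple[np.ndarray, bool]:
    if isinstance(s, FeatureVector):
        return s.s[None, :], True
    if isinstance(s, (list, tuple)) and len(s) and isinstance(s[0], FeatureVector):
        return np.stack([p.s for p in s]), False
    arr = np.asarray(s, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2 and arr.shape[1] == DIM:
        return arr, False
    if hasattr(s, "__iter__"):
        pts = np.stack([p.s if isinstance(p, FeatureVector) else np.asarray(p) for p in s])
        return pts, False
    raise ValueError(f"cannot interpret points of shape {arr.shape}")


def _component_logpdf(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """Per-component Gaussian log-densities, shape (n, K)."""
    chols = params.component_cholesky()
    n = X.shape[0]
    out = np.empty((n, params.K))
    for k in range(params.K):
        Lk = chols[k]
        diff = X - params.means[k]
        sol = solve_triangular(Lk, diff.T, lower=True)
        quad = np.sum(sol * sol, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(Lk)))
        out[:, k] = -0.5 * (DIM * LOG_2PI + logdet + quad)
    return out


def gmm_log_likelihood(s, params: GMMParams):
    """Log of the weighted sum of component densities (log-sum-exp stable)."""
    X, single = _coerce_points(s)
    logcomp = _component_logpdf(X, params) + np.log(params.weights)
    out = sp.logsumexp(logcomp, axis=1)
    return float(out[0]) if single else out


def posterior_responsibility(s, params: GMMParams):
    """Posterior cluster probabilities r_k = alpha_k N_k / sum_j alpha_j N_j."""
    X, single = _coerce_points(s)
    logcomp = _component_logpdf(X, params) + np.log(params.weights)
    lse = sp.logsumexp(logcomp, axis=1, keepdims=True)
    if not np.all(np.isfinite(lse)):
        raise ValueError("point outside support")
    r = np.exp(logcomp - lse)
    return r[0] if single else r


def expected_gmm(state: VariationalState) -> GMMParams:
    """Point summary of q(z): mean weights, mean locations, mean precisions.

    mu_k = N1_k, Sigma_k = (W1_k W2_k)^{-1} (inverse of the Wishart mean),
    alpha_k = D_k / sum(D).  Diagonal mode zeroes the off-diagonals.
    """
    D = state.D
    weights = D / D.sum()
    precision = state.W1[:, None, None] * state.W2
    if state.covariance_mode == "diagonal":
        precision = precision * np.eye(DIM)
    cov = np.linalg.inv(precision)
    cov = 0.5 * (cov + np.swapaxes(cov, -1, -2))
    return GMMParams(weights=weights, means=state.N1.copy(), covariances=cov)


# ---------------------------------------------------------------------------
# reparameterized sampling


def _draw_noise(rng: np.random.Generator, L: int, K: int) -> Dict[str, np.ndarray]:
    """All stochastic inputs for L mixture draws, in a fixed order."""
    return {
        "eps_mu": rng.standard_normal((L, K, DIM)),
        "chi_u": rng.standard_normal((L, K, DIM)),
        "bartlett_off": rng.standard_normal((L, K)),
        "gamma_u": rng.standard_normal((L, K)),
    }


def _chol_w2_graph(raw: Dict[str, Var], mode: str, K: int) -> Var:
    ld0 = T.vexp(T.vtake(raw["lw_log_diag"], (slice(None), 0)))
    ld1 = T.vexp(T.vtake(raw["lw_log_diag"], (slice(None), 1)))
    Lw = T.add(
        T.mul(T.vreshape(ld0, (K, 1, 1)), _E00),
        T.mul(T.vreshape(ld1, (K, 1, 1)), _E11),
    )
    if mode == "full":
        Lw = T.add(Lw, T.mul(T.vreshape(raw["lw_off"], (K, 1, 1)), _E10))
    return Lw


def _chi2_surrogate(a: Var, u: np.ndarray) -> Var:
    """Moment-matched log-normal stand-in for a chi-square(a) draw.

    mean a and variance 2a are matched exactly; the path is differentiable
    in the degrees of freedom, which an exact chi-square draw is not.
    """
    s2 = T.vlog(T.add(1.0, T.div(2.0, a)))
    s = T.vsqrt(s2)
    return T.mul(a, T.vexp(T.sub(T.mul(s, u), T.mul(0.5, s2))))


def _sample_graph(
    raw: Dict[str, Var],
    mode: str,
    K: int,
    L: int,
    noise: Dict[str, np.ndarray],
) -> Tuple[Var, Var, Var, Var]:
    """Tape graph for L reparameterized draws of (weights, means, precisions).

    Returns (weights (L,K), means (L,K,DIM), M (L,K,DIM,DIM), logdet (L,K))
    with precision Lambda = M M^T and M lower-triangular.
    """
    N2 = T.vexp(raw["log_n2"])
    mu = T.add(raw["n1"], T.mul(N2, noise["eps_mu"]))  # (L,K,DIM)

    W1 = T.add(float(DIM - 1), T.vexp(raw["w1_raw"]))  # (K,)
    c0 = _chi2_surrogate(W1, noise["chi_u"][..., 0])  # (L,K)
    c1 = _chi2_surrogate(T.sub(W1, 1.0), noise["chi_u"][..., 1])
    A = T.add(
        T.mul(T.vreshape(T.vsqrt(c0), (L, K, 1, 1)), _E00),
        T.mul(T.vreshape(T.vsqrt(c1), (L, K, 1, 1)), _E11),
    )
    if mode == "full":
        A = T.add(A, noise["bartlett_off"][..., None, None] * _E10)
    Lw = _chol_w2_graph(raw, mode, K)  # (K,DIM,DIM)
    M = T.matmul(Lw, A)  # broadcast -> (L,K,DIM,DIM), lower-triangular
    # diag(M) = diag(Lw) * diag(A), both triangular, so the log-determinant
    # of Lambda = M M^T is a cheap sum of logs.
    logdet = T.add(
        T.mul(2.0, T.vsum(raw["lw_log_diag"], axis=1)),
        T.add(T.vlog(c0), T.vlog(c1)),
    )  # (L,K)

    Dc = T.vsoftplus(raw["d_raw"])  # (K,)
    s2 = T.vlog(T.add(1.0, T.div(1.0, Dc)))
    g = T.vexp(
        T.add(T.sub(T.vlog(Dc), T.mul(0.5, s2)), T.mul(T.vsqrt(s2), noise["gamma_u"]))
    )  # (L,K): moment-matched Gamma(D_k, 1) surrogate
    w = T.div(g, T.vsum(g, axis=1, keepdims=True))
    return w, mu, M, logdet


def sample_gmm_params(
    state: VariationalState, L: int, seed: Union[int, np.random.Generator] = 0
) -> List[GMMParams]:
    """L reparameterized mixture draws from q(z); deterministic given seed."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = _draw_noise(rng, L, state.K)
    raw = {k: Var(v) for k, v in state.raw.items()}
    w, mu, M, _ = _sample_graph(raw, state.covariance_mode, state.K, L, noise)
    precisions = M.v @ np.swapaxes(M.v, -1, -2)
    covs = np.linalg.inv(precisions)
    covs = 0.5 * (covs + np.swapaxes(covs, -1, -2))
    return [
        GMMParams(weights=w.v[l], means=mu.v[l], covariances=covs[l]) for l in range(L)
    ]


# ---------------------------------------------------------------------------
# KL divergence between variational state and prior


def _multigammaln2(a: Var) -> Var:
    return T.add(
        0.5 * np.log(np.pi), T.add(T.vgammaln(a), T.vgammaln(T.sub(a, 0.5)))
    )


def _multidigamma2(a: Var) -> Var:
    return T.add(T.vdigamma(a), T.vdigamma(T.sub(a, 0.5)))


def _kld_graph(raw: Dict[str, Var], prior: PriorSpec, mode: str, K: int) -> Var:
    # Gaussian term: q = N(N1, diag(N2^2)) against p = N(m0, diag(s0^2))
    m0 = np.broadcast_to(prior.mean_loc, (K, DIM))
    s0 = np.broadcast_to(prior.mean_scale, (K, DIM))
    N1, logN2 = raw["n1"], raw["log_n2"]
    N2 = T.vexp(logN2)
    diff = T.sub(N1, m0)
    mean_kl = T.vsum(
        T.add(
            T.sub(np.log(s0), logN2),
            T.sub(
                T.div(T.add(T.vsquare(N2), T.vsquare(diff)), 2.0 * s0 ** 2),
                0.5,
            ),
        )
    )

    # Wishart term: q = W(W1, W2) against p = W(nu0, V0)
    nu0 = np.broadcast_to(prior.wishart_df, (K,)).astype(float)
    V0 = np.broadcast_to(prior.wishart_scale, (K, DIM, DIM))
    V0_inv = np.linalg.inv(V0)
    _, logdet_V0 = np.linalg.slogdet(V0)
    W1 = T.add(float(DIM - 1), T.vexp(raw["w1_raw"]))  # (K,)
    Lw = _chol_w2_graph(raw, mode, K)
    W2 = T.matmul(Lw, T.vswapaxes(Lw, -1, -2))
    logdet_W2 = T.mul(2.0, T.vsum(raw["lw_log_diag"], axis=1))  # (K,)
    trace = T.vsum(T.mul(V0_inv, W2), axis=(1, 2))  # tr(V0^{-1} W2), symmetric
    half_q = T.mul(0.5, W1)
    half_p = 0.5 * nu0
    lg_p = sp.multigammaln(half_p, DIM) if np.ndim(half_p) == 0 else np.array(
        [sp.multigammaln(h, DIM) for h in half_p]
    )
    wish_kl = T.vsum(
        T.add(
            T.add(
                T.mul(-0.5 * nu0, T.sub(logdet_W2, logdet_V0)),
                T.mul(half_q, T.sub(trace, float(DIM))),
            ),
            T.add(
                T.sub(lg_p, _multigammaln2(half_q)),
                T.mul(T.sub(half_q, half_p), _multidigamma2(half_q)),
            ),
        )
    )

    # Dirichlet term
    Dp = prior.dirichlet_conc
    Dq = T.vsoftplus(raw["d_raw"])
    Sq = T.vsum(Dq)
    dir_kl = T.add(
        T.sub(T.vgammaln(Sq), float(sp.gammaln(Dp.sum()))),
        T.add(
            T.vsum(T.sub(sp.gammaln(Dp), T.vgammaln(Dq))),
            T.vsum(T.mul(T.sub(Dq, Dp), T.sub(T.vdigamma(Dq), T.vdigamma(Sq)))),
        ),
    )
    return T.add(mean_kl, T.add(wish_kl, dir_kl))


def kld_variational_prior(state: VariationalState, prior: PriorSpec) -> float:
    """Closed-form KL(q(z) || p(z)), summed over clusters; always >= 0."""
    if prior.K != state.K:
        raise ValueError("invalid distribution: prior/state cluster mismatch")
    raw = {k: Var(v) for k, v in state.raw.items()}
    return float(_kld_graph(raw, prior, state.covariance_mode, state.K).v)


# ---------------------------------------------------------------------------
# loss


def _loss_graph(
    S: Var,
    raw: Dict[str, Var],
    prior: PriorSpec,
    mode: str,
    K: int,
    L: int,
    noise: Dict[str, np.ndarray],
    kld_scale: float,
) -> Tuple[Var, Var, Var]:
    """Negative Monte-Carlo ELBO on the tape; returns (loss, mc_term, kld)."""
    w, mu, M, logdet = _sample_graph(raw, mode, K, L, noise)
    B = S.shape[0]
    d = T.sub(T.vreshape(S, (1, B, 1, DIM)), T.vreshape(mu, (L, 1, K, DIM)))
    v = T.matmul(T.vreshape(d, (L, B, K, 1, DIM)), T.vreshape(M, (L, 1, K, DIM, DIM)))
    quad = T.vsum(T.vsquare(v), axis=(-1, -2))  # (L,B,K): (s-mu)^T Lambda (s-mu)
    logcomp = T.add(
        T.sub(
            T.add(T.vreshape(T.vlog(w), (L, 1, K)), T.mul(0.5, T.vreshape(logdet, (L, 1, K)))),
            0.5 * DIM * LOG_2PI,
        ),
        T.mul(-0.5, quad),
    )
    mc = T.vmean(T.vlogsumexp(logcomp, axis=-1))
    kld = _kld_graph(raw, prior, mode, K)
    loss = T.sub(T.mul(kld_scale, kld), mc)
    return loss, mc, kld


def svi_loss(
    batch,
    state: VariationalState,
    prior: Optional[PriorSpec] = None,
    L: int = 10,
    seed: Union[int, np.random.Generator] = 0,
    kld_scale: float = 1.0,
) -> float:
    """The training loss on one batch:

        loss = -( (1/L) sum_l mean_i log p(s_i | theta_l) - kld_scale * KL )

    Since the KL term is nonnegative, the loss is bounded below by the
    negative Monte-Carlo likelihood term.
    """
    X, _ = _coerce_points(batch)
    if X.shape[0] == 0:
        raise ValueError("empty input")
    prior = prior or PriorSpec.default(state.K)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = _draw_noise(rng, L, state.K)
    raw = {k: Var(v) for k, v in state.raw.items()}
    loss, _, _ = _loss_graph(
        Var(X), raw, prior, state.covariance_mode, state.K, L, noise, kld_scale
    )
    return float(loss.v)


# ---------------------------------------------------------------------------
# training


@dataclass
class FitResult:
    state: VariationalState
    loss_trace: np.ndarray
    prior: PriorSpec


def _coerce_training_data(data) -> Tuple[np.ndarray, bool]:
    """Accept FeatureWindow sequences / (N,21,4) tensors (attention trained)
    or FeatureVector sequences / (N,2) arrays (attention bypassed)."""
    if isinstance(data, np.ndarray):
        if data.ndim == 3 and data.shape[1:] == (WINDOW_LEN, 4):
            return data.astype(float), True
        if data.ndim == 2 and data.shape[1] == DIM:
            return data.astype(float), False
        raise ValueError(f"cannot interpret training data of shape {data.shape}")
    seq = list(data)
    if len(seq) == 0:
        raise ValueError("empty input")
    if isinstance(seq[0], FeatureWindow):
        return window_array(seq), True
    X, _ = _coerce_points(seq)
    return X, False


def _init_state_from_data(
    X: np.ndarray,
    windows_mode: bool,
    cfg: FitConfig,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> VariationalState:
    """K-means initialization in the (initial) feature space.

    Cluster centers seed N1, per-cluster sample covariances seed W2 (through
    W2 = Sigma^{-1}/W1 so the Wishart mean matches), and cluster fractions
    seed D.  The mean-location scale N2 starts small so early mean draws stay
    near their centers.
    """
    from sklearn.cluster import KMeans

    attention = AttentionParams.default(rng if windows_mode else None)
    feats = attention_forward_batch(X, attention) if windows_mode else X
    sub = feats
    if sub.shape[0] > 4096:
        sub = sub[rng.choice(sub.shape[0], 4096, replace=False)]
    km = KMeans(
        n_clusters=cfg.K, n_init=4, random_state=int(rng.integers(2**31 - 1))
    ).fit(sub)
    order = np.lexsort(km.cluster_centers_.T[::-1])
    centers = km.cluster_centers_[order]

    # hard assignment of the subsample for per-cluster scatter
    d2 = ((sub[:, None, :] - centers[None]) ** 2).sum(-1)
    assign = d2.argmin(axis=1)
    covs = np.empty((cfg.K, DIM, DIM))
    fracs = np.empty(cfg.K)
    global_cov = np.cov(sub.T) + 1e-4 * np.eye(DIM)
    for k in range(cfg.K):
        pts = sub[assign == k]
        fracs[k] = max(len(pts), 1) / len(sub)
        if len(pts) < DIM + 2:
            covs[k] = global_cov
        else:
            covs[k] = np.cov(pts.T) + 1e-5 * np.eye(DIM)
    if cfg.covariance_mode == "diagonal":
        covs = covs * np.eye(DIM)

    W1_init = 3.0
    W2 = np.linalg.inv(covs) / W1_init
    Lw = np.linalg.cholesky(W2)
    n2 = np.maximum(0.05 * np.sqrt(np.diag(global_cov)), 1e-3)
    raw = {
        "n1": centers,
        "log_n2": np.log(np.broadcast_to(n2, (cfg.K, DIM)).copy()),
        "w1_raw": np.full(cfg.K, np.log(W1_init - (DIM - 1))),
        "lw_log_diag": np.log(np.stack([Lw[:, 0, 0], Lw[:, 1, 1]], axis=1)),
        "d_raw": _softplus_inv(np.maximum(cfg.K * fracs, 0.2)),
        "gate_weights": attention.gate_weights,
        "gate_bias": attention.gate_bias,
        "projection": attention.projection,
    }
    if cfg.covariance_mode == "full":
        raw["lw_off"] = Lw[:, 1, 0].copy()
    return VariationalState(K=cfg.K, covariance_mode=cfg.covariance_mode, raw=raw)


def _empirical_bayes_prior(state: VariationalState) -> PriorSpec:
    """Refresh p(z) from the current variational summary (optional mode)."""
    return PriorSpec(
        mean_loc=state.N1.copy(),
        mean_scale=np.maximum(state.N2, 1e-3),
        wishart_df=state.W1.copy(),
        wishart_scale=state.W2.copy(),
        dirichlet_conc=state.D.copy(),
    )


def svi_fit(
    data,
    config: Optional[FitConfig] = None,
    prior: Optional[PriorSpec] = None,
    seed: int = 0,
) -> FitResult:
    """Mini-batch gradient training of the variational state (and, for window
    inputs, the attention block) by momentum SGD on :func:`svi_loss`.

    Deterministic given ``seed``: batches, Monte-Carlo draws and the k-means
    initialization all derive from one generator.
    """
    cfg = config or FitConfig()
    if cfg.K not in (2, 3):
        import warnings

        warnings.warn(f"K={cfg.K} is outside the studied range {{2, 3}}")
    X, windows_mode = _coerce_training_data(data)
    N = X.shape[0]
    rng = np.random.default_rng(seed)
    prior = prior or PriorSpec.default(cfg.K, cfg.dirichlet_interpretation)
    if prior.K != cfg.K:
        raise ValueError("invalid distribution: prior K does not match config K")

    if cfg.init == "prior":
        state = VariationalState.from_prior(prior, cfg.covariance_mode)
    else:
        state = _init_state_from_data(X, windows_mode, cfg, prior, rng)
    raw = {k: v.copy() for k, v in state.raw.items()}

    kscale = 1.0 / N if cfg.kld_scale == "auto" else float(cfg.kld_scale)
    train_keys = [k for k in raw if k not in ATTENTION_KEYS]
    if windows_mode and cfg.train_attention:
        train_keys += list(ATTENTION_KEYS)
    vel = {k: np.zeros_like(raw[k]) for k in train_keys}

    batch = min(cfg.batch_size, N)
    trace = np.empty(cfg.steps)
    for step in range(cfg.steps):
        if cfg.empirical_bayes_every and step and step % cfg.empirical_bayes_every == 0:
            prior = _empirical_bayes_prior(
                VariationalState(cfg.K, cfg.covariance_mode, raw)
            )
        idx = rng.integers(0, N, size=batch)
        noise = _draw_noise(rng, cfg.L, cfg.K)
        vars_ = {k: Var(v) for k, v in raw.items()}
        if windows_mode:
            S = attention_graph(
                Var(X[idx]),
                vars_["gate_weights"],
                vars_["gate_bias"],
                vars_["projection"],
            )
        else:
            S = Var(X[idx])
        loss, _, _ = _loss_graph(
            S, vars_, prior, cfg.covariance_mode, cfg.K, cfg.L, noise, kscale
        )
        if not np.isfinite(loss.v):
            raise ValueError(f"training diverged at step {step}")
        T.backward(loss)
        for k in train_keys:
            g = vars_[k].grad
            if g is None:
                continue
            if cfg.clip_grad_norm > 0:
                gnorm = float(np.linalg.norm(g))
                if gnorm > cfg.clip_grad_norm:
                    g = g * (cfg.clip_grad_norm / gnorm)
            lr = cfg.step_size * (
                cfg.attention_step_scale if k in ATTENTION_KEYS else 1.0
            )
            vel[k] = cfg.momentum * vel[k] - lr * g
            raw[k] = raw[k] + vel[k]
        trace[step] = loss.v

    final = VariationalState(K=cfg.K, covariance_mode=cfg.covariance_mode, raw=raw)
    return FitResult(state=final, loss_trace=trace, prior=prior)


# ---------------------------------------------------------------------------
# post-hoc cluster labeling


def assign_cluster_labels(
    params: GMMParams,
    points,
    tags: Sequence[str],
    severity: Sequence[str] = SEVERITY_ORDER,
) -> Dict[int, str]:
    """Majority vote of labeled points per cluster; ties go to the more
    severe label; clusters that captured no points default to the most
    severe tag seen (a cautious fallback)."""
    X, _ = _coerce_points(points)
    tags = list(tags)
    if len(tags) != X.shape[0]:
        raise ValueError("misaligned streams")
    rank = {t: i for i, t in enumerate(severity)}
    r = posterior_responsibility(X, params)
    hard = r.argmax(axis=1)
    out: Dict[int, str] = {}
    seen = sorted(set(tags), key=lambda t: rank.get(t, -1))
    fallback = seen[-1] if seen else severity[0]
    for k in range(params.K):
        members = [tags[i] for i in range(len(tags)) if hard[i] == k]
        if not members:
            out[k] = fallback
            continue
        counts: Dict[str, int] = {}
        for t in members:
            counts[t] = counts.get(t, 0) + 1
        best = max(counts.values())
        winners = [t for t, c in counts.items() if c == best]
        out[k] = max(winners, key=lambda t: rank.get(t, -1))
    return out
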