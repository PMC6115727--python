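"""Bayesian robust PCA by Gibbs sampling.

Decomposes an observed matrix ``Y`` (genes x samples) into

    Y = L + S + E,   L = D (Z Lambda) W,   S = B o X,

where ``L`` is low rank (at most ``K``), ``S`` is sparse with binary support
``B``, and ``E`` is Gaussian noise with a per-sample precision.  The
hierarchical priors are

    d_k   ~ N(0, I_P / P)                (columns of D, P x K)
    w_n   ~ N(0, I_K / K)                (columns of W, K x N)
    l_kk  ~ N(0, 1/tau),   tau   ~ Gamma(a0, b0)
    z_kk  ~ Bern(p_k),     p_k   ~ Beta(alpha0, beta0)
    b_pn  ~ Bern(pi_pn),   pi_pn ~ Beta(.)  (Markov regime, see below)
    x_pn  ~ N(0, 1/nu),    nu    ~ Gamma(c0, d0)
    e_pn  ~ N(0, 1/gamma_n), gamma_n ~ Gamma(e0, f0)

The sparsity prior is Markov across neighbouring *sample columns*: the Beta
hyperparameters of ``pi_pn`` depend on whether gene ``p`` is currently active
in the neighbouring samples (score ``0.5 b_pn + 0.25 (b_p,n-1 + b_p,n+1)``,
with the boundary columns using their single neighbour twice).  A score of
at least 0.5 selects the (alphaH, betaH) regime, otherwise (alphaL, betaL).
With the default hyperparameters the high-score regime has prior mean 0.01
and the low-score regime 0.99; ``swap_markov_regimes`` exchanges the two
(see the methods note for why both orientations are offered).

All full conditionals follow from conjugacy; the derivation of each update
is stated in a comment next to it.  The (z_k, lambda_k) and (b_pn, x_pn)
pairs are sampled blockwise (the continuous variable integrated out of the
binary draw) which mixes far better when the spike is strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .datatypes import ExpressionMatrix

PREC_FLOOR = 1e-12
PROB_CLAMP = 1e-12

HIGH = "HIGH"
LOW = "LOW"


@dataclass
class BRPCAHyperparams:
    """Hyperparameters and run settings of the sampler.

    ``for_shape`` fills in the standard defaults, which scale with the data
    shape: ``alpha0 = 1/K``, ``beta0 = (K-1)/K``, ``alphaH = 0.01 P``,
    ``betaH = 0.99 P``, ``alphaL = 0.99 P``, ``betaL = 0.01 P`` and flat
    ``Gamma(1e-6, 1e-6)`` priors on every precision.
    """

    K: int
    a0: float = 1e-6
    b0: float = 1e-6
    c0: float = 1e-6
    d0: float = 1e-6
    e0: float = 1e-6
    f0: float = 1e-6
    alpha0: float = 1.0
    beta0: float = 1.0
    alphaH: float = 1.0
    betaH: float = 1.0
    alphaL: float = 1.0
    betaL: float = 1.0
    n_burn: int = 200
    n_collect: int = 100
    init_nu: float = 1e-6
    init_gamma: float = 1.0
    seed: int = 0
    swap_markov_regimes: bool = False

    @classmethod
    def for_shape(cls, P: int, N: int, K: int = 30, **overrides) -> "BRPCAHyperparams":
        K = int(min(K, P, N))
        hp = cls(
            K=K,
            alpha0=1.0 / K,
            beta0=(K - 1.0) / K if K > 1 else 1.0,
            alphaH=0.01 * P,
            betaH=0.99 * P,
            alphaL=0.99 * P,
            betaL=0.01 * P,
        )
        return replace(hp, **overrides)

    def validate(self, P: int, N: int) -> None:
        pos = ("a0", "b0", "c0", "d0", "e0", "f0", "alpha0", "beta0",
               "alphaH", "betaH", "alphaL", "betaL", "init_nu", "init_gamma")
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")
        if self.K < 1 or self.K > min(P, N):
            raise ValueError(f"K={self.K} must satisfy 1 <= K <= min(P, N) = {min(P, N)}")
        if self.n_burn < 0:
            raise ValueError("n_burn must be >= 0")
        if self.n_collect < 1:
            raise ValueError("n_collect must be >= 1")


@dataclass
class BRPCAState:
    """One Gibbs state: every latent variable of the model."""

    D: np.ndarray          # P x K
    W: np.ndarray          # K x N
    lam: np.ndarray        # K diagonal entries of Lambda
    z: np.ndarray          # K binary
    pk: np.ndarray         # K in [0, 1]
    B: np.ndarray          # P x N binary (stored as float 0/1)
    X: np.ndarray          # P x N
    pi: np.ndarray         # P x N in [0, 1]
    tau: float
    nu: float
    gamma: np.ndarray      # N positive

    def low_rank(self) -> np.ndarray:
        return (self.D * (self.z * self.lam)) @ self.W

    def sparse(self) -> np.ndarray:
        return self.B * self.X

    def copy(self) -> "BRPCAState":
        return BRPCAState(
            D=self.D.copy(), W=self.W.copy(), lam=self.lam.copy(), z=self.z.copy(),
            pk=self.pk.copy(), B=self.B.copy(), X=self.X.copy(), pi=self.pi.copy(),
            tau=self.tau, nu=self.nu, gamma=self.gamma.copy(),
        )


@dataclass
class BRPCADecomposition:
    """Posterior-mean decomposition ``Y = L_hat + S_hat + E_hat``.

    ``E_hat`` is defined as the residual ``Y - L_hat - S_hat`` so the
    additivity holds exactly.  ``rank_estimate`` is the posterior mean of
    ``sum_k z_kk`` and ``sparsity_fraction`` the posterior mean of the
    fraction of active entries of ``B``.
    """

    L_hat: np.ndarray
    S_hat: np.ndarray
    E_hat: np.ndarray
    B_mean: np.ndarray
    rank_estimate: float
    sparsity_fraction: float
    n_samples_used: int
    hyperparams: BRPCAHyperparams = field(repr=False, default=None)  # type: ignore[assignment]


def _as_values(Y) -> np.ndarray:
    if isinstance(Y, ExpressionMatrix):
        return Y.values
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D matrix")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    return Y


def markov_scores(B: np.ndarray) -> np.ndarray:
    """Neighbour-activity score ``0.5 b_pi + 0.25 (b_p,i-1 + b_p,i+1)`` for
    every entry, with column 1 using column 2 twice and column N using
    column N-1 twice (no left/right neighbour at the boundary)."""
    B = np.asarray(B, dtype=float)
    N = B.shape[1]
    if N < 2:
        raise ValueError("Markov sparsity prior is undefined for a single sample column")
    left = np.concatenate(([1], np.arange(N - 1)))
    right = np.concatenate((np.arange(1, N), [N - 2]))
    return 0.5 * B + 0.25 * (B[:, left] + B[:, right])


def markov_pi_regime(B: np.ndarray, p: int, i: int) -> str:
    """Regime of the Beta prior on ``pi_pi``: ``"HIGH"`` iff the neighbour
    score is at least 0.5 (see :func:`markov_scores`)."""
    B = np.asarray(B)
    P, N = B.shape
    if not (0 <= p < P and 0 <= i < N):
        raise IndexError(f"index ({p}, {i}) out of range for {P} x {N} support matrix")
    return HIGH if markov_scores(B)[p, i] >= 0.5 else LOW


def _regime_params(hp: BRPCAHyperparams, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    high = scores >= 0.5
    aH, bH, aL, bL = hp.alphaH, hp.betaH, hp.alphaL, hp.betaL
    if hp.swap_markov_regimes:
        aH, bH, aL, bL = aL, bL, aH, bH
    alpha = np.where(high, aH, aL)
    beta = np.where(high, bH, bL)
    return alpha, beta


def init_state(Y, hp: BRPCAHyperparams, rng: np.random.Generator) -> BRPCAState:
    """Initial state: factor matrices from their priors, empty sparse part,
    all rank components switched on, precisions at their configured
    starting values."""
    Yv = _as_values(Y)
    P, N = Yv.shape
    K = hp.K
    B = np.zeros((P, N))
    state = BRPCAState(
        D=rng.standard_normal((P, K)) / np.sqrt(P),
        W=rng.standard_normal((K, N)) / np.sqrt(K),
        lam=np.zeros(K),
        z=np.ones(K),
        pk=np.full(K, hp.alpha0 / (hp.alpha0 + hp.beta0)),
        B=B,
        X=np.zeros((P, N)),
        pi=np.empty((P, N)),
        tau=1.0,
        nu=hp.init_nu,
        gamma=np.full(N, hp.init_gamma),
    )
    alpha, beta = _regime_params(hp, markov_scores(B))
    state.pi = alpha / (alpha + beta)
    return state


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise FloatingPointError(f"non-finite values in Gibbs update of {name}")


def gibbs_step(state: BRPCAState, Y, hp: BRPCAHyperparams, rng: np.random.Generator) -> BRPCAState:
    """One full Gibbs sweep: every latent variable is resampled once from
    its full conditional.  Returns a new state; the input is not modified."""
    Yv = _as_values(Y)
    P, N = Yv.shape
    K = hp.K
    st = state.copy()

    gamma = st.gamma                      # N
    M = Yv - st.B * st.X                  # data minus sparse part
    a = st.z * st.lam                     # effective factor scales
    L = (st.D * a) @ st.W

    # --- D columns.  Row-wise normal-normal conjugacy: for each gene p,
    #     d_pk | rest ~ N(m, 1/phi) with phi = P + a_k^2 sum_n gamma_n w_kn^2
    #     and m = (a_k / phi) sum_n gamma_n w_kn R_pn, R = M - L + a_k d_k w_k.
    for k in range(K):
        w = st.W[k]
        gw = gamma * w
        if a[k] == 0.0:
            d_new = rng.standard_normal(P) / np.sqrt(P)
            st.D[:, k] = d_new
            continue
        Rk = M - L + np.outer(a[k] * st.D[:, k], w)
        phi = P + a[k] ** 2 * (gw @ w)
        mean = (a[k] / phi) * (Rk @ gw)
        d_new = mean + rng.standard_normal(P) / np.sqrt(phi)
        L += np.outer(a[k] * (d_new - st.D[:, k]), w)
        st.D[:, k] = d_new
    _check_finite("D", st.D)

    # --- W columns.  With A = D diag(a), w_n | rest ~ N(mu, Sigma) where
    #     Sigma^-1 = K I + gamma_n A'A and mu = gamma_n Sigma A' M[:, n].
    A = st.D * a
    G = A.T @ A
    AtM = A.T @ M
    eyeK = np.eye(K)
    for n in range(N):
        prec = K * eyeK + gamma[n] * G
        cf = np.linalg.cholesky(prec)
        mu = np.linalg.solve(prec, gamma[n] * AtM[:, n])
        st.W[:, n] = mu + np.linalg.solve(cf.T, rng.standard_normal(K))
    _check_finite("W", st.W)
    L = A @ st.W

    # --- (z_k, lambda_k) blocks.  lambda_k is integrated out of the z_k
    #     draw: with s_k = |d_k|^2 sum_n gamma_n w_kn^2 and
    #     c_k = d_k' (R_k * gamma) w_k, the marginal likelihood ratio of
    #     z_k = 1 vs 0 is sqrt(tau/(tau+s_k)) exp(c_k^2 / (2 (tau+s_k))).
    #     Then lambda_k | z_k=1 ~ N(c_k/(tau+s_k), 1/(tau+s_k)), and from
    #     its prior when z_k = 0.
    for k in range(K):
        d = st.D[:, k]
        w = st.W[k]
        Rk = M - L + np.outer(a[k] * d, w)
        gw2 = gamma * w
        s = (d @ d) * (gw2 @ w)
        c = d @ (Rk @ gw2)
        post_prec = st.tau + s
        log_odds = (np.log(st.pk[k] / (1.0 - st.pk[k]))
                    + 0.5 * np.log(st.tau / post_prec)
                    + 0.5 * c * c / post_prec)
        z_new = 1.0 if rng.random() < expit(log_odds) else 0.0
        if z_new:
            lam_new = c / post_prec + rng.standard_normal() / np.sqrt(post_prec)
        else:
            lam_new = rng.standard_normal() / np.sqrt(st.tau)
        a_new = z_new * lam_new
        if a_new != a[k]:
            L += np.outer((a_new - a[k]) * d, w)
        st.z[k], st.lam[k], a[k] = z_new, lam_new, a_new
    _check_finite("lambda", st.lam)

    # --- p_k | z_k ~ Beta(alpha0 + z_k, beta0 + 1 - z_k)  (beta-Bernoulli).
    st.pk = rng.beta(hp.alpha0 + st.z, hp.beta0 + 1.0 - st.z)
    st.pk = np.clip(st.pk, PROB_CLAMP, 1.0 - PROB_CLAMP)

    # --- tau | lambda ~ Gamma(a0 + K/2, b0 + sum lambda^2 / 2).
    st.tau = max(rng.gamma(hp.a0 + 0.5 * K, 1.0 / (hp.b0 + 0.5 * st.lam @ st.lam)), PREC_FLOOR)

    # --- (B, X) blocks.  x_pn is integrated out of the b_pn draw: the
    #     residual Q = Y - L is N(0, 1/nu + 1/gamma_n) under b = 1 and
    #     N(0, 1/gamma_n) under b = 0, giving the collapsed log ratio
    #     0.5 log(nu/(gamma+nu)) + 0.5 Q^2 gamma^2/(gamma+nu).
    #     Then x | b=1 ~ N(Q gamma/(gamma+nu), 1/(gamma+nu)); x | b=0 from
    #     its prior.
    Q = Yv - L
    g = gamma[None, :]
    pi = np.clip(st.pi, PROB_CLAMP, 1.0 - PROB_CLAMP)
    log_odds = (np.log(pi / (1.0 - pi))
                + 0.5 * np.log(st.nu / (g + st.nu))
                + 0.5 * Q * Q * g * g / (g + st.nu))
    st.B = (rng.random((P, N)) < expit(log_odds)).astype(float)
    zmat = rng.standard_normal((P, N))
    post_mean = Q * g / (g + st.nu)
    post_sd = 1.0 / np.sqrt(g + st.nu)
    prior_sd = 1.0 / np.sqrt(st.nu)
    st.X = np.where(st.B == 1.0, post_mean + post_sd * zmat, prior_sd * zmat)
    _check_finite("X", st.X)
    S = st.B * st.X

    # --- pi | B ~ Beta(alpha_r + b, beta_r + 1 - b), the regime r taken
    #     from the neighbour score of the freshly sampled support B.
    alpha, beta = _regime_params(hp, markov_scores(st.B))
    st.pi = np.clip(rng.beta(alpha + st.B, beta + 1.0 - st.B), PROB_CLAMP, 1.0 - PROB_CLAMP)
    _check_finite("pi", st.pi)

    # --- nu | X ~ Gamma(c0 + PN/2, d0 + sum x^2 / 2).
    st.nu = max(rng.gamma(hp.c0 + 0.5 * P * N, 1.0 / (hp.d0 + 0.5 * np.sum(st.X * st.X))), PREC_FLOOR)

    # --- gamma_n | E ~ Gamma(e0 + P/2, f0 + sum_p E_pn^2 / 2), E = Y - L - S.
    E = Yv - L - S
    st.gamma = np.maximum(
        rng.gamma(hp.e0 + 0.5 * P, 1.0 / (hp.f0 + 0.5 * np.sum(E * E, axis=0))), PREC_FLOOR
    )
    _check_finite("gamma", st.gamma)
    return st


def decompose(Y, hp: BRPCAHyperparams) -> BRPCADecomposition:
    """Run the Gibbs sampler (``n_burn`` burn-in plus ``n_collect``
    collection sweeps) and average ``L`` and ``S`` over the collection
    phase.  Bit-reproducible for a fixed ``hp.seed``."""
    Yv = _as_values(Y)
    P, N = Yv.shape
    hp.validate(P, N)
    rng = np.random.default_rng(hp.seed)
    state = init_state(Yv, hp, rng)
    for _ in range(hp.n_burn):
        state = gibbs_step(state, Yv, hp, rng)
    L_acc = np.zeros_like(Yv)
    S_acc = np.zeros_like(Yv)
    B_acc = np.zeros_like(Yv)
    rank_acc = 0.0
    for _ in range(hp.n_collect):
        state = gibbs_step(state, Yv, hp, rng)
        L_acc += state.low_rank()
        S_acc += state.sparse()
        B_acc += state.B
        rank_acc += float(np.sum(state.z))
    L_hat = L_acc / hp.n_collect
    S_hat = S_acc / hp.n_collect
    B_mean = B_acc / hp.n_collect
    return BRPCADecomposition(
        L_hat=L_hat,
        S_hat=S_hat,
        E_hat=Yv - L_hat - S_hat,
        B_mean=B_mean,
        rank_estimate=rank_acc / hp.n_collect,
        sparsity_fraction=float(np.mean(B_mean)),
        n_samples_used=hp.n_collect,
        hyperparams=hp,
    )
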