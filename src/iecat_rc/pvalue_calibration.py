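"""Saddlepoint and efficient-resampling calibration of score-test p-values.

The normal approximation to the score statistic S = sum_i G~_i (Y_i - mu_i)
breaks down when the case-control ratio is unbalanced (skewed S) or the
minor-allele count is low (discrete S). Two remedies are implemented:

Saddlepoint approximation (SPA)
    Uses the full cumulant-generating function of S under the null,

        K(t) = sum_i log(1 - mu_i + mu_i e^{G~_i t}) - t sum_i G~_i mu_i,

    solving K'(t^) = s and applying the Lugannani-Rice / Barndorff-Nielsen
    tail formula  Pr(S < s) ~ Phi(w + log(v/w)/w)  with
    w = sgn(t^) sqrt(2 (t^ s - K(t^)))  and  v = t^ sqrt(K''(t^)).
    The reported p-value is two-sided: the sum of the upper tail at |s| and
    the lower tail at -|s|, each with its own saddlepoint. Near s = 0
    (|w| < 1e-4) the formula divides by ~0 and the normal approximation is
    returned instead, flagged as a fallback.

Efficient resampling (ER)
    For minor-allele count below a threshold (default 10) the p-value is
    computed exactly by enumerating the case-control assignments of the m
    minor-allele carriers. Writing D for the number of cases among carriers,

        Pr(Q >= Q^) = sum_d Pr(Q >= Q^ | D=d) Pr(D=d),

    where Pr(D=d) is the Poisson-binomial law of the carrier case count with
    the null fitted probabilities mu_i; summing the conditional enumeration
    over d is identical to enumerating all 2^m carrier phenotype
    configurations under the product-Bernoulli(mu_i) measure, which is how it
    is evaluated (exactly for 2^m <= enum_limit, by sampling otherwise).
    Q is the carrier-restricted score sum_{carriers} G~_i (y_i - mu_i); the
    tail is two-sided in |Q| and includes the observed configuration, so
    p > 0 always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .score_test import NullModel, adjust_genotype

__all__ = [
    "CGFContext",
    "SPAResult",
    "ERResult",
    "cgf",
    "cgf_d1",
    "cgf_d2",
    "solve_saddlepoint",
    "spa_pvalue",
    "spa_pvalue_batch",
    "er_pvalue",
]

OMEGA_FALLBACK = 1e-4
_EXP_CLIP = 700.0


@dataclass
class CGFContext:
    """Inputs of the CGF of the score: adjusted genotypes, null probabilities, observed score."""

    G_hat: np.ndarray
    mu_hat: np.ndarray
    s: float

    def __post_init__(self) -> None:
        self.G_hat = np.asarray(self.G_hat, dtype=float)
        self.mu_hat = np.asarray(self.mu_hat, dtype=float)
        if self.G_hat.shape != self.mu_hat.shape:
            raise ValueError("G_hat and mu_hat lengths differ")


@dataclass
class SPAResult:
    t_hat: float
    omega: float
    nu: float
    p_value: float
    fallback_used: bool


@dataclass
class ERResult:
    m: int
    Q_hat: float
    p_value: float
    method: str


# ---------------------------------------------------------------------------
# CGF evaluation (overflow-safe; works on (n,) with scalar t or (n, k) with
# a length-k t vector broadcast across columns)
# ---------------------------------------------------------------------------


def _prep(g, mu, t):
    g = np.asarray(g, dtype=float)
    mu = np.asarray(mu, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if g.ndim == 2:
        mu = mu[:, None] if mu.ndim == 1 else mu
        t_b = t_arr[None, :]
    else:
        t_b = t_arr
    return g, mu, t_b


def _expm1_terms(g, mu, t):
    """mu * expm1(g t) — the shared kernel of K and its derivatives.

    ``1 - mu + mu e^{gt} = 1 + mu*expm1(gt)``, which is branch-free and
    stable over the clipped range (expm1 never underflows to a harmful 0
    for negative arguments and stays below float max at +700).
    """
    g, mu, t_b = _prep(g, mu, t)
    x = np.clip(g * t_b, -_EXP_CLIP, _EXP_CLIP)
    return g, np.broadcast_to(mu, x.shape), np.expm1(x) * np.broadcast_to(mu, x.shape)


def _k(g, mu, t):
    g_b, mu_b, me = _expm1_terms(g, mu, t)
    return np.log1p(me).sum(axis=0) - np.asarray(t, dtype=float) * (g_b * mu_b).sum(axis=0)


def _pi(g, mu, t):
    """mu e^{gt} / (1 - mu + mu e^{gt}), stable both directions."""
    g_b, mu_b, me = _expm1_terms(g, mu, t)
    return (mu_b + me) / (1.0 + me)


def _k1(g, mu, t):
    g_b, mu_b, me = _expm1_terms(g, mu, t)
    return (g_b * ((mu_b + me) / (1.0 + me))).sum(axis=0) - (g_b * mu_b).sum(axis=0)


def _k2(g, mu, t):
    return _k1_k2(g, mu, t)[1]


def _k1_k2(g, mu, t):
    """K' and K'' from a single exponential evaluation (solver hot path)."""
    g_b, mu_b, me = _expm1_terms(g, mu, t)
    pi = (mu_b + me) / (1.0 + me)
    gpi = g_b * pi
    return gpi.sum(axis=0) - (g_b * mu_b).sum(axis=0), (g_b * gpi * (1.0 - pi)).sum(axis=0)


def _k_k2(g, mu, t):
    """K and K'' from a single exponential evaluation (tail hot path)."""
    g_b, mu_b, me = _expm1_terms(g, mu, t)
    pi = (mu_b + me) / (1.0 + me)
    kt = np.log1p(me).sum(axis=0) - np.asarray(t, dtype=float) * (g_b * mu_b).sum(axis=0)
    return kt, (g_b * g_b * pi * (1.0 - pi)).sum(axis=0)


def _var_at_origin(gmat, mu):
    """K''(0) = sum g^2 mu (1-mu) without an exponential evaluation."""
    v = mu * (1.0 - mu)
    return (gmat * gmat * (v[:, None] if gmat.ndim == 2 else v)).sum(axis=0)


def cgf(ctx: CGFContext, t: float) -> float:
    """K(t), the estimated cumulant-generating function of the score."""
    return float(_k(ctx.G_hat, ctx.mu_hat, float(t)))


def cgf_d1(ctx: CGFContext, t: float) -> float:
    """K'(t)."""
    return float(_k1(ctx.G_hat, ctx.mu_hat, float(t)))


def cgf_d2(ctx: CGFContext, t: float) -> float:
    """K''(t) (always >= 0: K is convex)."""
    return float(_k2(ctx.G_hat, ctx.mu_hat, float(t)))


# ---------------------------------------------------------------------------
# saddlepoint solver
# ---------------------------------------------------------------------------


def _score_range(g: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    mean = float((g * mu).sum())
    smax = float(g[g > 0].sum()) - mean
    smin = float(g[g < 0].sum()) - mean
    return smin, smax


def solve_saddlepoint(ctx: CGFContext, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Root of K'(t) = s by safeguarded Newton with bisection fallback.

    Requires s strictly inside the attainable score range; the returned root
    satisfies |K'(t^) - s| < tol * max(1, |s|) and has the sign of s.
    """
    s = float(ctx.s)
    if s == 0.0:
        return 0.0
    smin, smax = _score_range(ctx.G_hat, ctx.mu_hat)
    if not (smin < s < smax):
        raise ValueError(f"score {s} outside attainable open range ({smin}, {smax})")
    t_hat, converged = _newton_batch(
        ctx.G_hat[:, None], ctx.mu_hat, np.array([s]), tol=tol, max_iter=max_iter
    )
    if not converged[0]:  # pragma: no cover - bisection safeguard converges in practice
        raise RuntimeError("saddlepoint iteration failed to converge")
    return float(t_hat[0])


def _newton_batch(
    gmat: np.ndarray,
    mu: np.ndarray,
    s: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized safeguarded Newton for K'(t)=s, one column per target.

    K' is strictly increasing (K is convex), so a bracket [lo, hi] around the
    root is first found by geometric expansion away from the origin and then
    shrunk; Newton steps landing outside the bracket fall back to bisection.
    """
    k = gmat.shape[1]
    t0 = s / np.maximum(_var_at_origin(gmat, mu), 1e-300)
    sgn = np.where(s < 0, -1.0, 1.0)
    outer = sgn * np.maximum(2.0 * np.abs(t0), 1e-2)
    for _ in range(120):
        not_past = sgn * (_k1(gmat, mu, outer) - s) < 0.0
        if not not_past.any():
            break
        outer = np.where(not_past, outer * 2.0, outer)
    lo = np.minimum(0.0, outer)
    hi = np.maximum(0.0, outer)
    t = np.clip(t0, lo, hi)
    converged = np.zeros(k, dtype=bool)
    active = np.arange(k)
    for _ in range(max_iter):
        ga = gmat[:, active]
        f, d2 = _k1_k2(ga, mu, t[active])
        f = f - s[active]
        below = f < 0  # K' increasing: root above t
        lo[active] = np.where(below, t[active], lo[active])
        hi[active] = np.where(below, hi[active], t[active])
        done = np.abs(f) < tol * np.maximum(1.0, np.abs(s[active]))
        converged[active[done]] = True
        if done.all():
            break
        sub = active[~done]
        t_new = t[sub] - f[~done] / np.maximum(d2[~done], 1e-300)
        bad = ~np.isfinite(t_new) | (t_new <= lo[sub]) | (t_new >= hi[sub])
        t_new = np.where(bad, 0.5 * (lo[sub] + hi[sub]), t_new)
        t[sub] = t_new
        active = sub
    return t, converged


def _lr_tail(omega: np.ndarray, nu: np.ndarray, lower: bool) -> np.ndarray:
    """Lugannani-Rice tail from (omega, nu): Phi-based CDF approximation."""
    z = omega + np.log(np.abs(nu / omega)) / omega
    return stats.norm.cdf(z) if lower else stats.norm.sf(z)


def spa_pvalue(ctx: CGFContext) -> SPAResult:
    """Two-sided saddlepoint p-value for the observed score ``ctx.s``."""
    p, fallback, t_hat, omega, nu = _spa_batch_core(
        ctx.G_hat[:, None], ctx.mu_hat, np.array([float(ctx.s)])
    )
    return SPAResult(float(t_hat[0]), float(omega[0]), float(nu[0]), float(p[0]), bool(fallback[0]))


def spa_pvalue_batch(
    gmat: np.ndarray, mu: np.ndarray, s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided SPA p-values for many variants sharing mu.

    ``gmat`` is (n, k) adjusted genotypes, ``s`` the length-k observed
    scores. Returns (p_values, fallback_flags).
    """
    p, fallback, *_ = _spa_batch_core(np.asarray(gmat, float), np.asarray(mu, float), np.asarray(s, float))
    return p, fallback


def _one_tail(gmat, mu, s, lower: bool):
    """Saddlepoint tail at s (lower: Pr(S<=s)-ish; upper: Pr(S>=s))."""
    t_hat, conv = _newton_batch(gmat, mu, s)
    kt, k2t = _k_k2(gmat, mu, t_hat)
    arg = np.maximum(t_hat * s - kt, 0.0)
    omega = np.sign(t_hat) * np.sqrt(2.0 * arg)
    nu = t_hat * np.sqrt(np.maximum(k2t, 0.0))
    ok = conv & (np.abs(omega) >= OMEGA_FALLBACK) & (nu != 0.0)
    tail = np.full(s.shape, np.nan)
    if ok.any():
        tail[ok] = _lr_tail(omega[ok], nu[ok], lower)
    return tail, ok, t_hat, omega, nu


def _spa_batch_core(gmat, mu, s):
    k = len(s)
    var0 = _var_at_origin(gmat, mu)
    sd = np.sqrt(np.maximum(var0, 1e-300))
    p_norm = 2.0 * stats.norm.sf(np.abs(s) / sd)

    s_abs = np.abs(s)
    mu_c = mu[:, None]
    mean = (gmat * mu_c).sum(axis=0)
    smax = np.where(gmat > 0, gmat, 0.0).sum(axis=0) - mean
    smin = np.where(gmat < 0, gmat, 0.0).sum(axis=0) - mean
    scale = np.maximum(1.0, np.maximum(np.abs(smax), np.abs(smin)))
    margin = 1e-7 * scale
    # probability of the all-extreme configurations (the boundary atoms)
    logp_hi = np.where(gmat > 0, np.log(mu_c), np.where(gmat < 0, np.log1p(-mu_c), 0.0)).sum(
        axis=0
    )
    logp_lo = np.where(gmat < 0, np.log(mu_c), np.where(gmat > 0, np.log1p(-mu_c), 0.0)).sum(
        axis=0
    )

    p = np.empty(k)
    fallback = np.zeros(k, dtype=bool)
    t_all = np.zeros(k)
    om_all = np.zeros(k)
    nu_all = np.zeros(k)

    zero = s_abs <= margin * 1e-6
    # upper tail Pr(S >= |s|)
    up = np.zeros(k)
    up_at_edge = (~zero) & (s_abs >= smax - margin)
    up[up_at_edge & (s_abs <= smax + margin)] = np.exp(logp_hi[up_at_edge & (s_abs <= smax + margin)])
    ok_u = np.ones(k, dtype=bool)
    inner_u = (~zero) & (~up_at_edge)
    if inner_u.any():
        tail, ok, t_u, om_u, nu_u = _one_tail(gmat[:, inner_u], mu, s_abs[inner_u], lower=False)
        idx = np.flatnonzero(inner_u)
        up[idx] = tail
        ok_u[idx] = ok
        t_all[idx] = t_u
        om_all[idx] = om_u
        nu_all[idx] = nu_u
    # lower tail Pr(S <= -|s|)
    dn = np.zeros(k)
    dn_at_edge = (~zero) & (-s_abs <= smin + margin)
    dn[dn_at_edge & (-s_abs >= smin - margin)] = np.exp(logp_lo[dn_at_edge & (-s_abs >= smin - margin)])
    ok_d = np.ones(k, dtype=bool)
    inner_d = (~zero) & (~dn_at_edge)
    if inner_d.any():
        tail, ok, *_ = _one_tail(gmat[:, inner_d], mu, -s_abs[inner_d], lower=True)
        idx = np.flatnonzero(inner_d)
        dn[idx] = tail
        ok_d[idx] = ok

    ok = ok_u & ok_d & ~zero
    p[ok] = np.clip(up[ok] + dn[ok], 0.0, 1.0)
    bad = ~ok & ~zero
    p[bad] = p_norm[bad]
    fallback[bad] = True
    # s == 0: both tails are 1/2; report p = 1 via the normal fallback
    p[zero] = 1.0
    fallback[zero] = True
    # edge tails have no saddlepoint; flag them so t_hat/omega are not trusted
    fallback[ok & (up_at_edge | dn_at_edge)] = True
    return p, fallback, t_all, om_all, nu_all


# ---------------------------------------------------------------------------
# efficient resampling
# ---------------------------------------------------------------------------


def er_pvalue(
    Y: np.ndarray,
    G: np.ndarray,
    null: NullModel,
    enum_limit: int = 100_000,
    n_samples: int = 10_000,
    rng: np.random.Generator | int | None = None,
    G_tilde: np.ndarray | None = None,
) -> ERResult:
    """Exact (or sampled) carrier-enumeration p-value for a low-MAC variant.

    Carriers are subjects with G >= 1; homozygous carriers enter through
    their adjusted genotype value, so G = 2 is handled exactly. With no
    carriers the p-value is 1.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    gt = adjust_genotype(G, null) if G_tilde is None else np.asarray(G_tilde, dtype=float)
    carriers = np.flatnonzero(G >= 1)
    m = len(carriers)
    if m == 0:
        return ERResult(0, 0.0, 1.0, "exact_enumeration")
    w = gt[carriers]
    mu_c = null.mu_hat[carriers]
    q_hat = float(w @ (Y[carriers] - mu_c))
    offset = float(w @ mu_c)
    if 2**m <= enum_limit:
        # all carrier phenotype configurations, product-Bernoulli weighted
        configs = ((np.arange(2**m)[:, None] >> np.arange(m)[None, :]) & 1).astype(float)
        q = configs @ w - offset
        logp = configs @ np.log(mu_c) + (1.0 - configs) @ np.log1p(-mu_c)
        probs = np.exp(logp)
        p = float(probs[np.abs(q) >= abs(q_hat) - 1e-12].sum())
        return ERResult(m, q_hat, min(p, 1.0), "exact_enumeration")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    draws = rng.random((n_samples, m)) < mu_c
    q = draws @ w - offset
    exceed = int((np.abs(q) >= abs(q_hat) - 1e-12).sum())
    p = (exceed + 1.0) / (n_samples + 1.0)  # observed outcome included in its tail
    return ERResult(m, q_hat, p, "conditional_sampling")
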