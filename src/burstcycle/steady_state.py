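"""Steady-state (age-independent) mRNA count distributions.

The two-state telegraph model of transcription,

    G* <-> G  (switching rates sigma1 on, sigma0 off),
    G -> G + M  (rate rho),   M -> 0  (rate d),

has an exact stationary count distribution expressed through Kummer's
confluent hypergeometric function.  Its bursty limit (sigma0 >> sigma1)
is a negative binomial NB(f, (1+b)^-1) with burst frequency f = sigma1
and mean burst size b = rho/sigma0; its constitutive limit
(sigma1 >> sigma0) is Poisson.  All rates are normalised by the
degradation rate, i.e. d = 1 throughout this module.

This module evaluates those distributions stably in log-space, supports
zero inflation of the observed counts and k-fold self-convolution for
multi-copy genes (2 copies in G1, 4 in G2/M), and provides a brute-force
oracle that extracts the stationary distribution from the truncated
master-equation generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson

__all__ = [
    "SteadyStateParams",
    "BurstParams",
    "Pmf",
    "poisson_pmf",
    "nb_pmf",
    "telegraph_pmf",
    "cme_oracle_pmf",
    "zero_inflate",
    "convolve_copies",
    "burst_params",
]

#: truncation tolerance: a pmf vector must carry at least 1 - EPS_TRUNC mass
EPS_TRUNC = 1e-8
#: hard ceiling on the truncation count
M_MAX_CAP = 5000


@dataclass(frozen=True)
class SteadyStateParams:
    """Telegraph-model rates normalised by the degradation rate.

    sigma0 : off-switching rate, sigma1 : on-switching rate,
    rho : transcription rate while active, p0 : optional zero-inflation
    probability (fraction of observed zeros that are non-biological).
    """

    sigma0: float
    sigma1: float
    rho: float
    p0: float | None = None

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.sigma1 < 0 or self.rho < 0:
            raise ValueError("sigma0, sigma1 and rho must be non-negative")
        if self.p0 is not None and not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")


@dataclass(frozen=True)
class BurstParams:
    """Burst frequency f and mean burst size b (per allele)."""

    f: float
    b: float

    def __post_init__(self) -> None:
        if self.f < 0 or self.b < 0:
            raise ValueError("f and b must be non-negative")


@dataclass
class Pmf:
    """A truncated count distribution on m = 0..m_max.

    ``kind`` tags distributions with known closed-form convolutions
    ("poisson" with args (rho,), "nb" with args (f, p)); generic vectors
    are tagged "generic".
    """

    probs: np.ndarray
    kind: str = "generic"
    args: tuple = ()

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size == 0:
            raise ValueError("probs must be a non-empty 1-d vector")
        if np.any(self.probs < -1e-12):
            raise ValueError("pmf entries must be non-negative")
        self.probs = np.clip(self.probs, 0.0, None)

    @property
    def m_max(self) -> int:
        return self.probs.size - 1

    def mean(self) -> float:
        return float(np.arange(self.probs.size) @ self.probs)

    def var(self) -> float:
        m = np.arange(self.probs.size)
        mu = self.mean()
        return float((m - mu) ** 2 @ self.probs)

    def total_mass(self) -> float:
        return float(self.probs.sum())


def _check_mass(p: np.ndarray, eps: float = EPS_TRUNC) -> None:
    s = p.sum()
    if not (1.0 - eps <= s <= 1.0 + 1e-12):
        raise ValueError(
            f"truncated pmf carries mass {s:.12g}; raise m_max (cap {M_MAX_CAP})"
        )


def poisson_pmf(rho: float, m_max: int | None = None) -> Pmf:
    """Poisson(rho) counts, the constitutive-expression limit."""
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if m_max is None:
        m_max = _adaptive_m_max(rho, rho)
    p = poisson.pmf(np.arange(m_max + 1), rho)
    _check_mass(p)
    return Pmf(p, kind="poisson", args=(rho,))


def nb_pmf(f: float, b: float, m_max: int | None = None) -> Pmf:
    """Bursty-limit counts NB(m; f, (1+b)^-1); mean f*b, variance f*b*(1+b)."""
    if f < 0 or b < 0:
        raise ValueError("f and b must be non-negative")
    if b == 0 or f == 0:
        size = 1 if m_max is None else m_max + 1
        p = np.zeros(size)
        p[0] = 1.0
        return Pmf(p, kind="nb", args=(f, 1.0))
    p_nb = 1.0 / (1.0 + b)
    if m_max is None:
        m_max = _adaptive_m_max(f * b, f * b * (1.0 + b))
    p = nbinom.pmf(np.arange(m_max + 1), f, p_nb)
    _check_mass(p)
    return Pmf(p, kind="nb", args=(f, p_nb))


def _adaptive_m_max(mean: float, var: float) -> int:
    """Smallest truncation comfortably holding 1 - EPS_TRUNC of the mass."""
    m = int(np.ceil(mean + 12.0 * np.sqrt(max(var, 1.0)) + 30.0))
    return min(max(m, 10), M_MAX_CAP)


def _log_kummer_series(a: float, b: float, x: float) -> float:
    """log 1F1(a, b, x) for a, b, x >= 0 via the all-positive-term series."""
    if x == 0.0 or a == 0.0:
        return 0.0
    # terms t_k = (a)_k x^k / ((b)_k k!); ratio t_{k+1}/t_k = x(a+k)/((b+k)(k+1))
    # series effectively converges once k >> x
    n_terms = int(np.ceil(x + 12.0 * np.sqrt(x + 1.0) + 60.0))
    k = np.arange(n_terms)
    log_t = (
        gammaln(a + k)
        - gammaln(a)
        - gammaln(b + k)
        + gammaln(b)
        + k * np.log(x)
        - gammaln(k + 1.0)
    )
    return float(logsumexp(log_t))


def telegraph_logpmf(params: SteadyStateParams, m: np.ndarray) -> np.ndarray:
    """Log stationary probability of the telegraph model at counts ``m``.

    Evaluated via Kummer's transformation 1F1(a, c, -rho) =
    e^{-rho} 1F1(c - a, c, rho), whose series has positive terms only, so
    the whole computation stays in log-space without cancellation.  Falls
    back to mpmath if the float path produces a non-finite value.
    """
    s0, s1, rho = params.sigma0, params.sigma1, params.rho
    m = np.asarray(m, dtype=float)
    if rho == 0.0:
        return np.where(m == 0, 0.0, -np.inf)
    c = s0 + s1
    mf = m.ravel()
    log_poch = (gammaln(s1 + mf) - gammaln(s1)) - (gammaln(c + mf) - gammaln(c))
    n_terms = int(np.ceil(rho + 12.0 * np.sqrt(rho + 1.0) + 60.0))
    k = np.arange(n_terms)
    # series of 1F1(sigma0, c + m, rho): all terms positive
    log_t = (
        (gammaln(s0 + k) - gammaln(s0) + k * np.log(rho) - gammaln(k + 1.0))[None, :]
        - gammaln(c + mf[:, None] + k[None, :])
        + gammaln(c + mf)[:, None]
    )
    log_kummer = logsumexp(log_t, axis=1)
    out = mf * np.log(rho) - gammaln(mf + 1.0) + log_poch - rho + log_kummer
    bad = ~np.isfinite(out)
    if np.any(bad):
        for i in np.nonzero(bad)[0]:
            out[i] = _telegraph_logpmf_mp(s0, s1, rho, int(mf[i]))
    return out.reshape(m.shape)


def _telegraph_logpmf_mp(s0: float, s1: float, rho: float, m: int) -> float:
    """Arbitrary-precision fallback for a single count."""
    import mpmath as mp

    with mp.workdps(50):
        c = mp.mpf(s0) + mp.mpf(s1)
        val = (
            mp.power(rho, m) / mp.factorial(m)
            * mp.rf(mp.mpf(s1), m) / mp.rf(c, m)
            * mp.hyp1f1(mp.mpf(s1) + m, c + m, -mp.mpf(rho))
        )
        if val <= 0:
            raise FloatingPointError(
                f"telegraph pmf evaluation failed at m={m} (params {s0}, {s1}, {rho})"
            )
        return float(mp.log(val))


def telegraph_pmf(params: SteadyStateParams, m_max: int | None = None) -> Pmf:
    """Exact stationary telegraph-model pmf, truncated adaptively."""
    s0, s1, rho = params.sigma0, params.sigma1, params.rho
    mean = rho * s1 / (s0 + s1) if (s0 + s1) > 0 else rho
    # stationary variance of the telegraph model
    if (s0 + s1) > 0:
        var = mean + mean * rho * s0 / ((s0 + s1) * (1.0 + s0 + s1))
    else:
        var = mean
    adaptive = m_max is None
    if adaptive:
        m_max = _adaptive_m_max(mean, var)
    while True:
        p = np.exp(telegraph_logpmf(params, np.arange(m_max + 1)))
        if p.sum() >= 1.0 - EPS_TRUNC or not adaptive or m_max >= M_MAX_CAP:
            break
        m_max = min(2 * m_max, M_MAX_CAP)
    _check_mass(p)
    return Pmf(p)


def cme_oracle_pmf(params: SteadyStateParams, m_max: int) -> Pmf:
    """Stationary distribution from the truncated master-equation generator.

    States are (gene state, m) for m = 0..m_max; the null-space of the
    truncated generator is solved directly and marginalised over the gene
    state.  Serves purely as an independent test oracle for
    :func:`telegraph_pmf`.
    """
    s0, s1, rho = params.sigma0, params.sigma1, params.rho
    n = m_max + 1
    dim = 2 * n  # index g * n + m, g = 0 inactive, 1 active

    rows, cols, vals = [], [], []

    def add(i: int, j: int, rate: float) -> None:
        rows.append(j)
        cols.append(i)
        vals.append(rate)
        rows.append(i)
        cols.append(i)
        vals.append(-rate)

    for m in range(n):
        add(0 * n + m, 1 * n + m, s1)  # activation
        add(1 * n + m, 0 * n + m, s0)  # inactivation
        if m + 1 < n:
            add(1 * n + m, 1 * n + m + 1, rho)  # transcription (active only)
        for g in (0, 1):
            if m >= 1:
                add(g * n + m, g * n + m - 1, m * 1.0)  # degradation, d = 1

    gen = sparse.csr_matrix((vals, (rows, cols)), shape=(dim, dim))
    # replace the last balance equation by the normalisation constraint
    a = gen.tolil()
    a[dim - 1, :] = 1.0
    rhs = np.zeros(dim)
    rhs[dim - 1] = 1.0
    try:
        pi = spsolve(a.tocsr(), rhs)
    except Exception as exc:  # pragma: no cover - singular generator
        raise np.linalg.LinAlgError(
            f"truncated generator solve failed: {exc}"
        ) from exc
    if not np.all(np.isfinite(pi)):
        raise np.linalg.LinAlgError("truncated generator is ill-conditioned")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    marg = pi[:n] + pi[n:]
    if marg[-1] > 1e-10:
        raise ValueError(
            f"boundary mass {marg[-1]:.3g} at m_max={m_max}; increase truncation"
        )
    return Pmf(marg)


def zero_inflate(pmf: Pmf, p0: float) -> Pmf:
    """Mix a point mass at zero into a count distribution.

    P_ZI(0) = p0 + (1-p0) P(0), P_ZI(m>=1) = (1-p0) P(m).
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    p = (1.0 - p0) * pmf.probs
    p = p.copy()
    p[0] += p0
    return Pmf(p)


def convolve_copies(pmf: Pmf, k: int) -> Pmf:
    """k-fold self-convolution: total counts from k independent gene copies.

    Closed forms are used for tagged Poisson / NB inputs
    (Pois(rho)*...*Pois(rho) = Pois(k rho); NB(f,p)*... = NB(k f, p));
    generic vectors are convolved by direct summation.
    """
    if k < 1 or int(k) != k:
        raise ValueError("k must be a positive integer")
    k = int(k)
    if k == 1:
        return pmf
    if pmf.kind == "poisson":
        (rho,) = pmf.args
        return poisson_pmf(k * rho)
    if pmf.kind == "nb":
        f, p_nb = pmf.args
        b = (1.0 - p_nb) / p_nb
        return nb_pmf(k * f, b)
    out = pmf.probs
    for _ in range(k - 1):
        out = np.convolve(out, pmf.probs)
    m_max = min(out.size - 1, M_MAX_CAP)
    out = out[: m_max + 1]
    _check_mass(out)
    return Pmf(out)


def burst_params(params: SteadyStateParams | BurstParams) -> BurstParams:
    """Burst frequency and size implied by telegraph rates: f = sigma1, b = rho/sigma0."""
    if isinstance(params, BurstParams):
        return params
    if params.sigma0 == 0:
        raise ZeroDivisionError("burst size is undefined for sigma0 = 0")
    return BurstParams(f=params.sigma1, b=params.rho / params.sigma0)


def total_variation(p: Pmf | np.ndarray, q: Pmf | np.ndarray) -> float:
    """Total-variation distance between two truncated pmfs."""
    pa = p.probs if isinstance(p, Pmf) else np.asarray(p, dtype=float)
    qa = q.probs if isinstance(q, Pmf) else np.asarray(q, dtype=float)
    n = max(pa.size, qa.size)
    pa = np.pad(pa, (0, n - pa.size))
    qa = np.pad(qa, (0, n - qa.size))
    return 0.5 * float(np.abs(pa - qa).sum())
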