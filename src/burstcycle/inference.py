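"""Maximum-likelihood fitting, BIC model selection and profile-likelihood
confidence intervals for the steady-state and age-dependent model families.

Optimisation is carried out on transformed coordinates (log for rates,
logit for probabilities, linear for the age-scaling exponents) inside the
bounded search boxes; a global differential-evolution stage is followed
by local quasi-Newton (L-BFGS-B) refinement, repeated from several random
initialisations, and the best likelihood wins.  The Poisson family is
solved in closed form (the MLE is the sample mean).

Confidence intervals follow the profile-likelihood construction: the
target quantity is stepped outward from its MLE, the nuisance parameters
are re-optimised at each step, and the crossing of the chi-square
threshold is refined by bisection.  Derived quantities (burst-parameter
ratios within one fit or across the joint likelihood of two phase fits)
are handled by the prediction-profile variant, where the constraint is
imposed by eliminating one coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import differential_evolution, minimize
from scipy.special import expit, gammaln, logit
from scipy.stats import chi2, nbinom, poisson

from .age_model import AgeModelParams, default_boundaries, solve_moments
from .steady_state import Pmf, SteadyStateParams, telegraph_logpmf, zero_inflate

__all__ = [
    "STEADY_FAMILIES",
    "ModelSpec",
    "AgeModelSpec",
    "OptimizerConfig",
    "FitResult",
    "ConfidenceInterval",
    "negloglik_steady",
    "negloglik_age",
    "fit_mle",
    "fit_steady_models",
    "fit_age_model",
    "bic",
    "select_model",
    "profile_ci",
    "prediction_profile_ci",
    "steady_ratio_ci",
]

#: penalty returned for non-finite likelihoods, shaped so the global
#: optimiser is pushed back toward the centre of the box
PENALTY = 1e10

# transformed-space search boxes, as used in the original analysis
STEADY_FAMILIES: dict[str, list[tuple[str, str, float, float]]] = {
    "Poisson": [("rho", "log", -9.0, 7.0)],
    "ZIP": [("rho", "log", -9.0, 7.0), ("p0", "logit", -30.0, 30.0)],
    "NB": [("f", "log", -10.0, 10.0), ("p", "logit", -30.0, 30.0)],
    "ZINB": [
        ("f", "log", -10.0, 10.0),
        ("p", "logit", -30.0, 30.0),
        ("p0", "logit", -30.0, 30.0),
    ],
    "Telegraph": [
        ("sigma0", "log", -9.0, 7.0),
        ("sigma1", "log", -9.0, 7.0),
        ("rho", "log", -9.0, 7.0),
    ],
    "ZITelegraph": [
        ("sigma0", "log", -9.0, 7.0),
        ("sigma1", "log", -9.0, 7.0),
        ("rho", "log", -9.0, 7.0),
        ("p0", "logit", -30.0, 30.0),
    ],
}

MODEL_LADDER = ["Poisson", "ZIP", "NB", "ZINB", "Telegraph", "ZITelegraph"]


def _to_natural(kind: str, z: float) -> float:
    if kind == "log":
        return float(np.exp(z))
    if kind == "logit":
        return float(expit(z))
    return float(z)


def _to_trans(kind: str, x: float) -> float:
    if kind == "log":
        return float(np.log(x))
    if kind == "logit":
        return float(logit(x))
    return float(x)


@dataclass(frozen=True)
class ModelSpec:
    """A steady-state model family with its copy number and search box."""

    family: str
    n_copies: int = 1
    zi_post_convolution: bool = True

    def __post_init__(self) -> None:
        if self.family not in STEADY_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")

    @property
    def param_names(self) -> list[str]:
        return [t[0] for t in STEADY_FAMILIES[self.family]]

    @property
    def transforms(self) -> list[tuple[str, str, float, float]]:
        return STEADY_FAMILIES[self.family]

    @property
    def k(self) -> int:
        return len(self.param_names)

    def bounds_trans(self) -> list[tuple[float, float]]:
        return [(lo, hi) for _, _, lo, hi in self.transforms]

    def to_natural(self, z: np.ndarray) -> dict[str, float]:
        return {
            name: _to_natural(kind, zi)
            for (name, kind, _, _), zi in zip(self.transforms, z)
        }

    def to_trans(self, params: dict[str, float]) -> np.ndarray:
        return np.array(
            [_to_trans(kind, params[name]) for name, kind, _, _ in self.transforms]
        )

    def prepare(self, counts: np.ndarray):
        return _UniqueCounts.from_counts(counts)

    def nll(self, params: dict[str, float], prepared: "_UniqueCounts") -> float:
        return _negloglik_steady_unique(self, params, prepared)


@dataclass
class _UniqueCounts:
    values: np.ndarray
    weights: np.ndarray
    n: int
    m_max: int

    @classmethod
    def from_counts(cls, counts) -> "_UniqueCounts":
        counts = np.asarray(counts)
        if counts.size and (np.any(counts < 0) or np.any(counts != np.floor(counts))):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(np.int64)
        values, weights = np.unique(counts, return_counts=True)
        m_max = int(values.max()) if values.size else 0
        return cls(values, weights.astype(float), int(counts.size), m_max)


def _steady_total_logpmf(spec: ModelSpec, params: dict[str, float], m_max: int) -> np.ndarray:
    """Log pmf of the total (multi-copy, optionally zero-inflated) count
    distribution on 0..m_max."""
    fam = spec.family
    k = spec.n_copies
    p0 = params.get("p0", 0.0)
    m = np.arange(m_max + 1)

    zi_pre = (p0 > 0.0) and not spec.zi_post_convolution
    if fam in ("Poisson", "ZIP") and not zi_pre:
        logp = poisson.logpmf(m, k * params["rho"])
    elif fam in ("NB", "ZINB") and not zi_pre:
        logp = nbinom.logpmf(m, k * params["f"], params["p"])
    else:
        # generic path: build the allele pmf, (optionally) zero-inflate it,
        # convolve k-fold
        if fam in ("Telegraph", "ZITelegraph"):
            allele = np.exp(
                telegraph_logpmf(
                    SteadyStateParams(params["sigma0"], params["sigma1"], params["rho"]),
                    np.arange(m_max + 1),
                )
            )
        elif fam in ("Poisson", "ZIP"):
            allele = poisson.pmf(m, params["rho"])
        else:
            allele = nbinom.pmf(m, params["f"], params["p"])
        if zi_pre:
            allele = zero_inflate(Pmf(allele), p0).probs
            p0 = 0.0  # consumed
        total = allele
        for _ in range(k - 1):
            total = np.convolve(total, allele)[: m_max + 1]
        with np.errstate(divide="ignore"):
            logp = np.log(total)

    if p0 > 0.0 and spec.zi_post_convolution:
        with np.errstate(divide="ignore"):
            out = np.log1p(-p0) + logp
        out[0] = np.logaddexp(np.log(p0), out[0])
        logp = out
    return logp


def _negloglik_steady_unique(
    spec: ModelSpec, params: dict[str, float], uc: _UniqueCounts
) -> float:
    if uc.n == 0:
        return 0.0
    logp = _steady_total_logpmf(spec, params, uc.m_max)
    ll = logp[uc.values] @ uc.weights
    return float(-ll)


def negloglik_steady(spec: ModelSpec, params: dict[str, float], counts) -> float:
    """-log L of a steady-state family: the observation model is the
    n_copies-fold self-convolution of the allele distribution (with zero
    inflation applied to the total observed count)."""
    return _negloglik_steady_unique(spec, params, _UniqueCounts.from_counts(counts))


# ---------------------------------------------------------------------------
# age-dependent likelihood


@dataclass(frozen=True)
class AgeModelSpec:
    """The age-dependent bursty family: free parameters f1, f2, rho1, rho2
    (log scale) and beta1..beta4 (linear); d, T and the segment boundaries
    are fixed inputs."""

    d: float
    T: float = 13.25
    boundaries: tuple[float, float, float] = field(default_factory=default_boundaries)
    variant: str = "size"

    family: str = "AgeDependent"

    @property
    def param_names(self) -> list[str]:
        return ["f1", "f2", "rho1", "rho2", "beta1", "beta2", "beta3", "beta4"]

    @property
    def transforms(self) -> list[tuple[str, str, float, float]]:
        rates = [(n, "log", -7.0, 7.0) for n in ("f1", "f2", "rho1", "rho2")]
        betas = [(f"beta{i}", "linear", -100.0, 100.0) for i in range(1, 5)]
        return rates + betas

    @property
    def k(self) -> int:
        return 8

    def bounds_trans(self) -> list[tuple[float, float]]:
        return [(lo, hi) for _, _, lo, hi in self.transforms]

    def to_natural(self, z: np.ndarray) -> dict[str, float]:
        return {
            name: _to_natural(kind, zi)
            for (name, kind, _, _), zi in zip(self.transforms, z)
        }

    def to_trans(self, params: dict[str, float]) -> np.ndarray:
        return np.array(
            [_to_trans(kind, params[name]) for name, kind, _, _ in self.transforms]
        )

    def make_params(self, params: dict[str, float]) -> AgeModelParams:
        tg1, tr, ts = self.boundaries
        return AgeModelParams(
            f1=params["f1"],
            f2=params["f2"],
            rho1=params["rho1"],
            rho2=params["rho2"],
            betas=(params["beta1"], params["beta2"], params["beta3"], params["beta4"]),
            d=self.d,
            T=self.T,
            theta_g1=tg1,
            theta_r=tr,
            theta_s=ts,
            variant=self.variant,
        )

    def prepare(self, data: tuple) -> "_AgeData":
        theta, counts = data
        return _AgeData.from_cells(theta, counts)

    def nll(self, params: dict[str, float], prepared: "_AgeData") -> float:
        return _negloglik_age_prepared(self.make_params(params), prepared)


@dataclass
class _AgeData:
    """(theta, count) pairs deduplicated for fast repeated likelihoods."""

    bins: np.ndarray  # unique theta bins present
    pair_bin: np.ndarray  # index into bins per unique pair
    pair_count: np.ndarray
    pair_weight: np.ndarray
    n: int
    _seg_cache: dict = field(default_factory=dict)

    @classmethod
    def from_cells(cls, theta, counts) -> "_AgeData":
        theta = np.round(np.asarray(theta, dtype=float), 2)
        counts = np.asarray(counts)
        if counts.size and (np.any(counts < 0) or np.any(counts != np.floor(counts))):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(np.int64)
        if theta.shape != counts.shape:
            raise ValueError("theta and counts must align")
        bins, bin_idx = np.unique(theta, return_inverse=True)
        key = bin_idx * (counts.max() + 1 if counts.size else 1) + counts
        _, first, weight = np.unique(key, return_index=True, return_counts=True)
        return cls(
            bins=bins,
            pair_bin=bin_idx[first],
            pair_count=counts[first],
            pair_weight=weight.astype(float),
            n=int(counts.size),
        )


def _nb_logpmf(m, r, p):
    return (
        gammaln(m + r) - gammaln(r) - gammaln(m + 1.0)
        + r * np.log(p) + m * np.log1p(-p)
    )


def _poisson_logpmf(m, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mu > 0, m * np.log(mu) - mu - gammaln(m + 1.0), np.where(m == 0, 0.0, -np.inf))
    return out


def _negloglik_age_prepared(params: AgeModelParams, ad: _AgeData) -> float:
    if ad.n == 0:
        return 0.0
    key = (params.theta_g1, params.theta_r, params.theta_s)
    seg_idx = ad._seg_cache.get(key)
    if seg_idx is None:
        seg_idx = np.asarray(params.segment_of(ad.bins))
        ad._seg_cache[key] = seg_idx
    try:
        traj = solve_moments(params, ad.bins, seg_idx)
    except (ArithmeticError, FloatingPointError, OverflowError):
        return np.inf
    mean, var = traj.mean, traj.variance
    if not np.all(np.isfinite(var)):
        return np.inf
    m = ad.pair_count
    mu = mean[ad.pair_bin]
    v = var[ad.pair_bin]
    nb_sel = v > mu
    logp = np.empty(m.shape, dtype=float)
    if nb_sel.all():
        r = mu**2 / (v - mu)
        logp = _nb_logpmf(m, r, mu / v)
    else:
        if nb_sel.any():
            mus, vs = mu[nb_sel], v[nb_sel]
            logp[nb_sel] = _nb_logpmf(m[nb_sel], mus**2 / (vs - mus), mus / vs)
        po = ~nb_sel
        logp[po] = _poisson_logpmf(m[po], mu[po])
    ll = logp @ ad.pair_weight
    return float(-ll)


def negloglik_age(params: AgeModelParams, theta, counts) -> float:
    """-log L of the age-dependent model: the count of each cell is scored
    under the moment-matched NB at that cell's age bin."""
    return _negloglik_age_prepared(params, _AgeData.from_cells(theta, counts))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class OptimizerConfig:
    """Budgets for the global + local optimisation stages.

    n_restarts defaults to 5 for steady-state families and 10 for the
    age-dependent family when left as None.
    """

    n_restarts: int | None = None
    use_de: bool = True
    de_maxiter: int = 40
    de_popsize: int = 12
    de_tol: float = 0.01
    polish_maxiter: int = 300
    seed: int = 0
    inits: list[dict] = field(default_factory=list)


@dataclass
class FitResult:
    spec: object
    params: dict[str, float]
    x_trans: np.ndarray
    loglik: float
    n: int
    k: int
    bic: float
    restarts_used: int
    seed: int
    success: bool = True

    @property
    def family(self) -> str:
        return self.spec.family


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, -2 log L + k log n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * np.log(n)


def _make_objective(spec, prepared):
    bounds = np.asarray(spec.bounds_trans())
    center = bounds.mean(axis=1)

    def obj(z: np.ndarray) -> float:
        params = spec.to_natural(z)
        try:
            val = spec.nll(params, prepared)
        except (ValueError, ArithmeticError, FloatingPointError):
            val = np.inf
        if not np.isfinite(val):
            return PENALTY + float(np.sum((z - center) ** 2))
        return val

    return obj


def fit_mle(spec, data, config: OptimizerConfig | None = None) -> FitResult:
    """Best-of-restarts MLE for a steady-state or age-dependent spec.

    ``data`` is a count vector for steady-state specs and a
    ``(theta, counts)`` pair for :class:`AgeModelSpec`.
    """
    config = config or OptimizerConfig()
    prepared = spec.prepare(data)
    n = prepared.n
    if n == 0:
        raise ValueError("cannot fit an empty dataset")

    if spec.family == "Poisson":
        # closed form: the per-copy MLE is the sample mean / n_copies
        mean = (prepared.values @ prepared.weights) / n
        lo, hi = np.exp(-9.0), np.exp(7.0)
        rho = float(np.clip(mean / spec.n_copies, lo, hi))
        params = {"rho": rho}
        ll = -spec.nll(params, prepared)
        return FitResult(
            spec, params, spec.to_trans(params), ll, n, spec.k,
            bic(ll, spec.k, n), 0, config.seed,
        )

    obj = _make_objective(spec, prepared)
    bounds = spec.bounds_trans()
    restarts = config.n_restarts
    if restarts is None:
        restarts = 10 if spec.family == "AgeDependent" else 5

    best_z, best_val = None, np.inf
    inits = [spec.to_trans(p) for p in config.inits]
    for r in range(restarts):
        rs = (config.seed + r) % (2**31 - 1)
        rng = np.random.default_rng(rs)
        if config.use_de:
            de = differential_evolution(
                obj,
                bounds,
                seed=rs,
                maxiter=config.de_maxiter,
                popsize=config.de_popsize,
                tol=config.de_tol,
                polish=False,
            )
            z0 = de.x
        elif inits:
            base = inits[r % len(inits)]
            jitter = 0.0 if r < len(inits) else 0.5
            z0 = np.clip(
                base + jitter * rng.standard_normal(len(base)),
                [b[0] for b in bounds],
                [b[1] for b in bounds],
            )
        else:
            z0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(
            obj, z0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.polish_maxiter},
        )
        val = min(res.fun, obj(z0))
        z = res.x if res.fun <= obj(z0) else z0
        if val < best_val:
            best_val, best_z = val, z

    success = best_val < PENALTY
    params = spec.to_natural(best_z)
    ll = -best_val
    return FitResult(
        spec, params, best_z, ll, n, spec.k, bic(ll, spec.k, n),
        restarts, config.seed, success,
    )


def fit_steady_models(
    counts,
    n_copies: int,
    config: OptimizerConfig | None = None,
    families: list[str] | None = None,
) -> dict[str, FitResult]:
    """Fit the six steady-state families (ladder order) to one phase's counts."""
    families = families or MODEL_LADDER
    out = {}
    base = config or OptimizerConfig()
    for i, fam in enumerate(families):
        cfg = replace(base, seed=(base.seed + 1000 * i) % (2**31 - 1))
        out[fam] = fit_mle(ModelSpec(fam, n_copies=n_copies), counts, cfg)
    return out


def select_model(fits: dict[str, FitResult], delta: float = 10.0) -> FitResult:
    """BIC ladder: walk from the simplest family, advancing only while some
    more complex family improves BIC by more than ``delta``."""
    ladder = [f for f in MODEL_LADDER if f in fits]
    if not ladder:
        raise ValueError("no fits supplied")
    for fam in MODEL_LADDER:
        if fam in fits and fits[fam] is None:
            raise ValueError(f"missing fit for {fam}")
    i = 0
    while i < len(ladder) - 1:
        cur = fits[ladder[i]].bic
        if all(cur - fits[f].bic <= delta for f in ladder[i + 1 :]):
            break
        i += 1
    return fits[ladder[i]]


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


@dataclass
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    target: str
    lower_at_bound: bool = False
    upper_at_bound: bool = False


def _scan_direction(
    profile_nll,
    z_hat: float,
    nll_min: float,
    threshold: float,
    z_lo: float,
    z_hi: float,
    direction: int,
    rel_tol: float = 1e-4,
    grow: float = 1.5,
    max_steps: int = 200,
) -> tuple[float, bool]:
    """Step z away from the MLE until the profile crosses the threshold;
    bisect the crossing.  Returns (limit, hit_bound)."""
    step = max(0.02 * abs(z_hat), 0.02)
    inside_z, z = z_hat, z_hat
    for _ in range(max_steps):
        z = z + direction * step
        hit = False
        if z <= z_lo:
            z, hit = z_lo, True
        if z >= z_hi:
            z, hit = z_hi, True
        val = profile_nll(z)
        if val > nll_min + threshold:
            lo, hi = (inside_z, z) if direction > 0 else (z, inside_z)
            # bisection to relative tolerance on z
            for _ in range(100):
                if hi - lo <= rel_tol * max(abs(z_hat), 1e-12):
                    break
                mid = 0.5 * (lo + hi)
                if (profile_nll(mid) > nll_min + threshold) == (direction > 0):
                    hi = mid
                else:
                    lo = mid
            return (lo if direction > 0 else hi), False
        inside_z = z
        if hit:
            return z, True
        step *= grow
    return z, True


def _profile_engine(
    profile_nll, z_hat: float, nll_min: float, alpha: float,
    z_lo: float, z_hi: float, target: str,
) -> ConfidenceInterval:
    threshold = 0.5 * chi2.ppf(1.0 - alpha, df=1)
    if threshold <= 0.0:
        return ConfidenceInterval(z_hat, z_hat, 1.0 - alpha, target)
    up, up_bound = _scan_direction(profile_nll, z_hat, nll_min, threshold, z_lo, z_hi, +1)
    lo, lo_bound = _scan_direction(profile_nll, z_hat, nll_min, threshold, z_lo, z_hi, -1)
    return ConfidenceInterval(lo, up, 1.0 - alpha, target, lo_bound, up_bound)


def _nuisance_profiler(spec, prepared, x_hat: np.ndarray, fixed_index: int):
    """Profile nll over all coordinates except ``fixed_index``, warm-started
    from the previous optimum."""
    obj_full = _make_objective(spec, prepared)
    bounds = spec.bounds_trans()
    free = [i for i in range(len(bounds)) if i != fixed_index]
    state = {"psi": x_hat[free].copy()}

    def profile_nll_trans(z_trans: float) -> float:
        if not free:
            x = x_hat.copy()
            x[fixed_index] = z_trans
            return obj_full(x)

        def obj_psi(psi):
            x = x_hat.copy()
            x[free] = psi
            x[fixed_index] = z_trans
            return obj_full(x)

        res = minimize(
            obj_psi, state["psi"], method="L-BFGS-B",
            bounds=[bounds[i] for i in free], options={"maxiter": 200},
        )
        if np.isfinite(res.fun):
            state["psi"] = res.x
        return float(res.fun)

    return profile_nll_trans


def profile_ci(
    spec, data, fit: FitResult, target: str, alpha: float = 0.05
) -> ConfidenceInterval:
    """Profile-likelihood CI for a single model parameter (natural scale)."""
    names = spec.param_names
    if target not in names:
        raise ValueError(f"unknown parameter {target!r}")
    idx = names.index(target)
    kind, lo_t, hi_t = spec.transforms[idx][1], *spec.transforms[idx][2:]
    prepared = spec.prepare(data)
    profiler = _nuisance_profiler(spec, prepared, fit.x_trans.copy(), idx)

    def profile_nll(z_nat: float) -> float:
        return profiler(_to_trans(kind, z_nat))

    z_hat = fit.params[target]
    nll_min = -fit.loglik
    z_lo, z_hi = _to_natural(kind, lo_t), _to_natural(kind, hi_t)
    return _profile_engine(profile_nll, z_hat, nll_min, alpha, z_lo, z_hi, target)


def prediction_profile_ci(
    nll_joint,
    x_hat: np.ndarray,
    bounds: list[tuple[float, float]],
    eliminate_index: int,
    solve_eliminated,
    z_hat: float,
    alpha: float = 0.05,
    z_bounds: tuple[float, float] = (1e-12, 1e12),
    target: str = "derived",
) -> ConfidenceInterval:
    """CI for a derived quantity z = g(xi) via the prediction profile
    likelihood.

    The constraint g(xi) = z is imposed by eliminating one transformed
    coordinate: ``solve_eliminated(z, x)`` must return the value of
    coordinate ``eliminate_index`` that makes the constraint hold given
    the remaining coordinates of ``x``.  ``nll_joint`` maps a full
    transformed vector to the joint negative log-likelihood.
    """
    free = [i for i in range(len(bounds)) if i != eliminate_index]
    lo_e, hi_e = bounds[eliminate_index]
    center = np.mean(bounds, axis=1)
    state = {"psi": x_hat[free].copy()}

    def constrained_nll(z: float, psi: np.ndarray) -> float:
        x = x_hat.copy()
        x[free] = psi
        e = solve_eliminated(z, x)
        if not np.isfinite(e) or e < lo_e or e > hi_e:
            return PENALTY + float((e - center[eliminate_index]) ** 2 if np.isfinite(e) else PENALTY)
        x[eliminate_index] = e
        return nll_joint(x)

    def profile_nll(z: float) -> float:
        res = minimize(
            lambda psi: constrained_nll(z, psi),
            state["psi"],
            method="L-BFGS-B",
            bounds=[bounds[i] for i in free],
            options={"maxiter": 200},
        )
        if np.isfinite(res.fun):
            state["psi"] = res.x
        return float(res.fun)

    nll_min = profile_nll(z_hat)
    return _profile_engine(profile_nll, z_hat, nll_min, alpha, *z_bounds, target)


def steady_ratio_ci(
    fit_g1: FitResult,
    fit_g2m: FitResult,
    counts_g1,
    counts_g2m,
    which: str = "f",
    alpha: float = 0.05,
) -> ConfidenceInterval:
    """Joint-likelihood prediction-profile CI for the steady-state NB
    burst-parameter ratio between G2/M and G1.

    ``which="f"`` targets Q_f = f_G2M/f_G1; ``which="b"`` targets
    Q_b = b_G2M/b_G1 with b = (1-p)/p.  The joint likelihood is the
    product of the two phase likelihoods; the constraint is imposed by
    eliminating the G2/M coordinate.
    """
    for fit in (fit_g1, fit_g2m):
        if fit.family != "NB":
            raise ValueError("steady_ratio_ci supports the NB family")
    spec1, spec2 = fit_g1.spec, fit_g2m.spec
    prep1, prep2 = spec1.prepare(counts_g1), spec2.prepare(counts_g2m)
    obj1, obj2 = _make_objective(spec1, prep1), _make_objective(spec2, prep2)
    k1 = len(spec1.param_names)

    def nll_joint(x: np.ndarray) -> float:
        return obj1(x[:k1]) + obj2(x[k1:])

    x_hat = np.concatenate([fit_g1.x_trans, fit_g2m.x_trans])
    bounds = spec1.bounds_trans() + spec2.bounds_trans()
    if which == "f":
        i_g1 = spec1.param_names.index("f")
        elim = k1 + spec2.param_names.index("f")
        z_hat = fit_g2m.params["f"] / fit_g1.params["f"]
        solve = lambda z, x: np.log(z) + x[i_g1]  # log f_G2M = log z + log f_G1
        target = "Q_f"
    elif which == "b":
        i_p1 = spec1.param_names.index("p")
        elim = k1 + spec2.param_names.index("p")
        b1_hat = (1.0 - fit_g1.params["p"]) / fit_g1.params["p"]
        b2_hat = (1.0 - fit_g2m.params["p"]) / fit_g2m.params["p"]
        z_hat = b2_hat / b1_hat
        # logit p = -log b, so the eliminated coordinate is -log(z * b_G1)
        solve = lambda z, x: -(np.log(z) - x[i_p1])
        target = "Q_b"
    else:
        raise ValueError("which must be 'f' or 'b'")
    return prediction_profile_ci(
        nll_joint, x_hat, bounds, elim, solve, z_hat,
        alpha=alpha, z_bounds=(1e-8, 1e8), target=target,
    )


# ---------------------------------------------------------------------------
# age-model fitting with data-informed initialisation


def _trend_init(spec: AgeModelSpec, theta, counts) -> dict[str, float]:
    """Moment/trend-based starting point: per-segment log-linear slopes of
    the binned means give the betas; quasi-steady moment relations split
    the production into f and rho."""
    theta = np.round(np.asarray(theta, dtype=float), 2)
    counts = np.asarray(counts, dtype=float)
    tg1, tr, ts = spec.boundaries
    edges = np.array([0.0, tg1, tr, ts, 1.0])
    dT = spec.d * spec.T
    bins = np.unique(theta)
    bin_mean = np.array([counts[theta == b].mean() for b in bins])
    bin_var = np.array([counts[theta == b].var() for b in bins])

    betas, prods, rhos = [], [], []
    for seg in range(4):
        sel = (bins >= edges[seg]) & (bins < edges[seg + 1]) & (bin_mean > 0)
        copies = 2 if seg < 2 else 4
        if sel.sum() >= 3:
            x, y = bins[sel], np.log(bin_mean[sel])
            beta = float(np.polyfit(x, y, 1)[0])
        else:
            beta = 0.0
        beta = float(np.clip(beta, -50.0, 50.0))
        betas.append(beta)
        if sel.any():
            mid = bins[sel][len(bins[sel]) // 2]
            m_mid = bin_mean[bins == mid][0]
            # quasi-steady: m ~ copies f rho T e^{beta theta} / (beta + dT)
            prod = m_mid * (beta + dT) / (copies * spec.T * np.exp(beta * mid))
            prods.append(max(prod, 1e-3))
            fano = bin_var[bins == mid][0] / max(m_mid, 1e-9)
            rhos.append(max((fano - 1.0) / np.exp(beta * mid), 1e-2))
        else:
            prods.append(1e-2)
            rhos.append(0.5)

    rho1 = float(np.clip(np.mean(rhos[:2]), np.exp(-7), np.exp(7)))
    rho2 = float(np.clip(np.mean(rhos[2:]), np.exp(-7), np.exp(7)))
    f1 = float(np.clip(np.mean(prods[:2]) / rho1, np.exp(-7), np.exp(7)))
    f2 = float(np.clip(np.mean(prods[2:]) / rho2, np.exp(-7), np.exp(7)))
    return {
        "f1": f1, "f2": f2, "rho1": rho1, "rho2": rho2,
        "beta1": betas[0], "beta2": betas[1], "beta3": betas[2], "beta4": betas[3],
    }


def fit_age_model(
    theta,
    counts,
    d: float,
    T: float = 13.25,
    boundaries: tuple[float, float, float] | None = None,
    variant: str = "size",
    config: OptimizerConfig | None = None,
) -> FitResult:
    """Fit the age-dependent bursty model to one gene's (theta, count) data.

    By default the optimiser starts from a moment/trend-based initial
    point plus jittered restarts, which is fast and reliable when the
    model matches the data; set ``config.use_de=True`` for the full
    global-search strategy.
    """
    spec = AgeModelSpec(
        d=d, T=T, boundaries=tuple(boundaries or default_boundaries()), variant=variant
    )
    if config is None:
        config = OptimizerConfig(n_restarts=3, use_de=False)
    if not config.inits and not config.use_de:
        config = replace(config, inits=[_trend_init(spec, theta, counts)])
    return fit_mle(spec, (np.asarray(theta), np.asarray(counts)), config)
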