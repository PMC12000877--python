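"""Piecewise cell-age-dependent bursty transcription model.

A gene is transcribed in instantaneous bursts (geometric burst sizes) from
each allele; the cell progresses through the cycle with normalised age
theta = t/T in [0, 1).  Burst frequency is f1 before DNA replication
(theta < theta_r) and f2 after; the mean burst size scales exponentially
with age, b(theta) = rho_seg * exp(beta_seg * theta), with a separate
scale rho (rho1 pre-, rho2 post-replication) and exponent beta per
segment: G1 [0, theta_g1), early S [theta_g1, theta_r), late S
[theta_r, theta_s), G2/M [theta_s, 1).  Gene copy number is 2 before and
4 after replication; at division mRNA is binomially partitioned with
probability 1/2.

The first two moments of the total count obey linear ODEs with
exponential forcing in each segment,

    d<m>/dtheta   = c_i e^{beta_i theta} - dT <m>,
    dvar/dtheta   = -2 dT var + c_i e^{beta_i theta} (1 + 2 rho_i e^{beta_i theta})
                    + dT <m>(theta),

with c_i = (copies) f rho T, continuity at the three interior boundaries
and the division conditions <m>(0) = <m>(1)/2,
var(0) = (var(1) + <m>(1))/4.  These are solved in closed form per
segment (sums of c * theta^k * e^{s theta} terms, with the analytic
resonant limit when a forcing exponent collides with the homogeneous
decay rate), and the cyclo-stationary initial condition follows from an
affine fixed point because the whole system is linear.

The count distribution at any age is approximated by a negative binomial
matched to the exact mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import nbinom, poisson

__all__ = [
    "AgeModelParams",
    "MomentTrajectory",
    "AgeDistribution",
    "CountDistribution",
    "THETA_GRID",
    "default_boundaries",
    "production_rate",
    "burst_size_at_age",
    "solve_mean_trajectory",
    "solve_variance_trajectory",
    "solve_moments",
    "nb_at_age",
    "phase_averaged_burst_size",
    "division_boundary_map",
]

#: the 100 age bins of the processed data
THETA_GRID = np.round(np.arange(100) * 0.01, 2)

#: |forcing exponent - homogeneous exponent| below which the resonant
#: (theta * exp) analytic limit is used
RESONANCE_TOL = 1e-9

# The G1/S and S/G2 transitions sit at raw DeepCycle ages 0.26-0.27 and
# 0.63-0.64; after truncating theta <= 0.09 and rescaling to [0, 0.99]
# the midpoints land at the values below.  Replication is placed halfway
# through the S phase.
_RAW_G1S = 0.265
_RAW_SG2 = 0.635


def _rescale_raw_age(theta: float) -> float:
    return (theta - 0.1) * 0.99 / 0.89


def default_boundaries() -> tuple[float, float, float]:
    """(theta_g1, theta_r, theta_s) on the truncated/rescaled age axis."""
    tg1 = _rescale_raw_age(_RAW_G1S)
    ts = _rescale_raw_age(_RAW_SG2)
    return tg1, 0.5 * (tg1 + ts), ts


@dataclass(frozen=True)
class AgeModelParams:
    """Rate parameters of the age-dependent bursty model.

    f1, f2 : burst frequencies pre/post replication (1/h)
    rho1, rho2 : burst-size scales pre/post replication (molecules)
    betas : age-scaling exponents (beta1..beta4) of the four segments
    d : mRNA degradation rate (1/h); T : cell-cycle duration (h)
    variant : "size" scales the burst size with age (default);
        "frequency" scales the burst frequency instead, with constant
        burst size rho per segment group.
    """

    f1: float
    f2: float
    rho1: float
    rho2: float
    betas: tuple[float, float, float, float]
    d: float
    T: float = 13.25
    theta_g1: float = field(default_factory=lambda: default_boundaries()[0])
    theta_r: float = field(default_factory=lambda: default_boundaries()[1])
    theta_s: float = field(default_factory=lambda: default_boundaries()[2])
    variant: str = "size"

    def __post_init__(self) -> None:
        if min(self.f1, self.f2, self.rho1, self.rho2) < 0:
            raise ValueError("f and rho parameters must be non-negative")
        if self.d <= 0 or self.T <= 0:
            raise ValueError("d and T must be positive")
        if not 0.0 < self.theta_g1 < self.theta_r < self.theta_s < 1.0:
            raise ValueError("boundaries must satisfy 0 < theta_g1 < theta_r < theta_s < 1")
        if self.variant not in ("size", "frequency"):
            raise ValueError("variant must be 'size' or 'frequency'")
        if len(self.betas) != 4:
            raise ValueError("betas must have four entries")

    @property
    def dT(self) -> float:
        return self.d * self.T

    def segment_edges(self) -> np.ndarray:
        return np.array([0.0, self.theta_g1, self.theta_r, self.theta_s, 1.0])

    def segment_of(self, theta: np.ndarray | float) -> np.ndarray | int:
        """0-based segment index; half-open intervals [. , .)."""
        th = np.asarray(theta)
        if np.any(th < 0) or np.any(th >= 1):
            raise ValueError("theta must lie in [0, 1)")
        idx = np.searchsorted(self.segment_edges()[1:4], th, side="right")
        return idx if th.ndim else int(idx)

    def segment_rates(self, seg: int) -> tuple[float, float, float, int]:
        """(f, rho, beta, copies) for segment seg."""
        if seg < 2:
            return (self.f1, self.rho1, self.betas[seg], 2)
        return (self.f2, self.rho2, self.betas[seg], 4)


@dataclass
class AgeDistribution:
    """Normalised weights g(theta) over a set of age bins."""

    theta: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.theta.shape != self.weights.shape:
            raise ValueError("theta and weights must have equal shapes")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_cells(cls, theta: np.ndarray, grid: np.ndarray | None = None) -> "AgeDistribution":
        """Empirical age histogram of a set of cells."""
        theta = np.asarray(theta, dtype=float)
        bins, counts = np.unique(np.round(theta, 2), return_counts=True)
        return cls(bins, counts / counts.sum())


@dataclass
class MomentTrajectory:
    """Cyclo-stationary mean and variance on an age grid."""

    theta: np.ndarray
    mean: np.ndarray
    variance: np.ndarray | None
    segment_index: np.ndarray


def production_rate(theta: float, params: AgeModelParams) -> float:
    """Effective per-allele production rate mu(theta) = f * b(theta)."""
    seg = params.segment_of(float(theta))
    f, rho, beta, _ = params.segment_rates(seg)
    return f * rho * float(np.exp(beta * theta))


def burst_size_at_age(theta: float, params: AgeModelParams) -> float:
    """Mean burst size at a given age (constant per segment group in the
    frequency-scaling variant)."""
    seg = params.segment_of(float(theta))
    _, rho, beta, _ = params.segment_rates(seg)
    if params.variant == "frequency":
        return rho
    return rho * float(np.exp(beta * theta))


# ---------------------------------------------------------------------------
# closed-form linear ODE machinery.  Within a segment starting at theta0
# the solution is a sum of terms c * u^k * exp(s * u) in the local
# coordinate u = theta - theta0, which keeps all exponents bounded.


def _particular_terms(c: float, s: float, k: int, a: float) -> list[tuple[float, float, int]]:
    """Particular solution of y' = -a y + c u^k e^{s u} (k in {0, 1})."""
    if abs(s + a) < RESONANCE_TOL:
        if k == 0:
            return [(c, s, 1)]
        raise ArithmeticError("unsupported resonant forcing of degree >= 1")
    if k == 0:
        return [(c / (s + a), s, 0)]
    if k == 1:
        return [(c / (s + a), s, 1), (-c / (s + a) ** 2, s, 0)]
    raise ArithmeticError("forcing terms of degree > 1 are not required")


def _eval_terms(
    terms: list[tuple[float, float, int]], theta: np.ndarray, theta0: float
) -> np.ndarray:
    u = np.atleast_1d(np.asarray(theta, dtype=float)) - theta0
    out = np.zeros_like(u)
    for c, s, k in terms:
        out += c * u**k * np.exp(s * u)
    return out


def _segment_solution(
    y0: float,
    a: float,
    forcings: list[tuple[float, float, int]],
) -> list[tuple[float, float, int]]:
    """Terms (local coordinates) of the solution with value y0 at u = 0."""
    terms: list[tuple[float, float, int]] = []
    for c, s, k in forcings:
        terms.extend(_particular_terms(c, s, k, a))
    part0 = sum(c for c, _, k in terms if k == 0)
    terms.append((y0 - part0, -a, 0))
    return terms


def _mean_forcings(params: AgeModelParams, seg: int, theta0: float) -> list[tuple[float, float, int]]:
    f, rho, beta, copies = params.segment_rates(seg)
    return [(copies * f * rho * params.T * np.exp(beta * theta0), beta, 0)]


def _variance_forcings(
    params: AgeModelParams,
    seg: int,
    theta0: float,
    mean_terms: list[tuple[float, float, int]],
) -> list[tuple[float, float, int]]:
    f, rho, beta, copies = params.segment_rates(seg)
    T, dT = params.T, params.dT
    out: list[tuple[float, float, int]] = []
    if params.variant == "size":
        # burst size b = rho e^{beta theta}: E[r] and E[r^2] contributions
        out.append((copies * f * rho * T * np.exp(beta * theta0), beta, 0))
        out.append((2.0 * copies * f * rho**2 * T * np.exp(2.0 * beta * theta0), 2.0 * beta, 0))
    else:
        # burst frequency f e^{beta theta}, constant size rho
        out.append((copies * f * rho * (1.0 + 2.0 * rho) * T * np.exp(beta * theta0), beta, 0))
    out.extend((dT * c, s, k) for c, s, k in mean_terms)
    return out


def _propagate_cycle(
    params: AgeModelParams,
    a: float,
    forcings_of_seg,
    y_birth: float,
) -> tuple[list[list[tuple[float, float, int]]], float]:
    """Solve segment by segment from a birth value; return per-segment
    terms (in segment-local coordinates) and the end-of-cycle value."""
    edges = params.segment_edges()
    all_terms = []
    y = y_birth
    for seg in range(4):
        terms = _segment_solution(y, a, forcings_of_seg(seg, edges[seg]))
        all_terms.append(terms)
        y = float(_eval_terms(terms, np.array([edges[seg + 1]]), edges[seg])[0])
    return all_terms, y


def _cyclostationary_birth(end_at_zero: float, homog: float, divide) -> float:
    """Affine fixed point y0 = divide(homog * y0 + end_at_zero)."""
    # divide is linear: divide(x) = q * x + r with q = divide(1) - divide(0)
    r = divide(0.0)
    q = divide(1.0) - r
    denom = 1.0 - q * homog
    if denom <= 0:
        raise ArithmeticError("cycle map has no stable fixed point")
    return (q * end_at_zero + r) / denom


def solve_mean_trajectory(
    params: AgeModelParams,
    grid: np.ndarray | None = None,
    seg_idx: np.ndarray | None = None,
) -> MomentTrajectory:
    """Cyclo-stationary mean count <m>(theta) on the age grid."""
    grid = THETA_GRID if grid is None else np.asarray(grid, dtype=float)
    a = params.dT
    edges = params.segment_edges()
    forcings = lambda s, t0: _mean_forcings(params, s, t0)
    _, end0 = _propagate_cycle(params, a, forcings, 0.0)
    homog = np.exp(-a)  # whole-cycle homogeneous decay factor
    m0 = _cyclostationary_birth(end0, homog, lambda x: 0.5 * x)
    terms, _ = _propagate_cycle(params, a, forcings, m0)
    if seg_idx is None:
        seg_idx = np.asarray(params.segment_of(grid))
    mean = np.empty_like(grid)
    for seg in range(4):
        sel = seg_idx == seg
        if np.any(sel):
            mean[sel] = _eval_terms(terms[seg], grid[sel], edges[seg])
    if not np.all(np.isfinite(mean)):
        raise ArithmeticError("non-finite mean trajectory")
    traj = MomentTrajectory(grid, mean, None, seg_idx)
    traj._mean_terms = terms  # cached for the variance pass
    traj._mean_end = float(_eval_terms(terms[3], np.array([1.0]), edges[3])[0])
    return traj


def solve_variance_trajectory(
    params: AgeModelParams,
    mean_traj: MomentTrajectory,
    grid: np.ndarray | None = None,
) -> MomentTrajectory:
    """Cyclo-stationary variance added onto a solved mean trajectory."""
    grid = mean_traj.theta if grid is None else np.asarray(grid, dtype=float)
    mean_terms = getattr(mean_traj, "_mean_terms", None)
    if mean_terms is None:
        raise ValueError("mean trajectory must come from solve_mean_trajectory")
    a2 = 2.0 * params.dT
    edges = params.segment_edges()
    forcings = lambda s, t0: _variance_forcings(params, s, t0, mean_terms[s])
    _, end0 = _propagate_cycle(params, a2, forcings, 0.0)
    homog = np.exp(-a2)
    m_end = mean_traj._mean_end
    v0 = _cyclostationary_birth(end0, homog, lambda x: 0.25 * (x + m_end))
    terms, _ = _propagate_cycle(params, a2, forcings, v0)
    seg_idx = mean_traj.segment_index
    var = np.empty_like(grid)
    for seg in range(4):
        sel = seg_idx == seg
        if np.any(sel):
            var[sel] = _eval_terms(terms[seg], grid[sel], edges[seg])
    if not np.all(np.isfinite(var)):
        raise ArithmeticError("non-finite variance trajectory")
    if np.any(var < -1e-6 * np.maximum(mean_traj.mean, 1.0)):
        raise ArithmeticError("negative variance: moment solver failure")
    var = np.clip(var, 0.0, None)
    out = MomentTrajectory(grid, mean_traj.mean, var, seg_idx)
    out._mean_terms = mean_terms
    out._mean_end = m_end
    out._var_terms = terms
    return out


def solve_moments(
    params: AgeModelParams,
    grid: np.ndarray | None = None,
    seg_idx: np.ndarray | None = None,
) -> MomentTrajectory:
    """Convenience: mean and variance in one call."""
    return solve_variance_trajectory(params, solve_mean_trajectory(params, grid, seg_idx))


@dataclass(frozen=True)
class CountDistribution:
    """Moment-matched count law at one age: NB(r, p), or Poisson when the
    variance does not exceed the mean."""

    mean: float
    r: float | None
    p: float | None

    @property
    def is_poisson(self) -> bool:
        return self.r is None

    def logpmf(self, m: np.ndarray) -> np.ndarray:
        if self.is_poisson:
            return poisson.logpmf(m, self.mean)
        return nbinom.logpmf(m, self.r, self.p)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.is_poisson:
            return rng.poisson(self.mean, size=size)
        return rng.negative_binomial(self.r, self.p, size=size)


def nb_at_age(mean: float, variance: float) -> CountDistribution:
    """Negative binomial matched to (mean, variance); Poisson fallback for
    sub-Poissonian moment pairs, which can arise transiently during
    optimisation."""
    if mean < 0 or variance < 0:
        raise ValueError("moments must be non-negative")
    if variance <= mean or mean == 0.0:
        return CountDistribution(mean=mean, r=None, p=None)
    r = mean**2 / (variance - mean)
    p = mean / variance
    return CountDistribution(mean=mean, r=r, p=p)


def phase_averaged_burst_size(rho: float, beta: float, g: AgeDistribution) -> float:
    """Burst size averaged over the cells of a phase:
    b_phase = rho * sum_theta g(theta) e^{beta theta}."""
    return float(rho * np.sum(g.weights * np.exp(beta * g.theta)))


def division_boundary_map(mean_end: float, var_end: float) -> tuple[float, float]:
    """Moments just after binomial halving at division."""
    if mean_end < 0 or var_end < 0:
        raise ValueError("moments must be non-negative")
    return 0.5 * mean_end, 0.25 * (var_end + mean_end)
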