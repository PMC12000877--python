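"""Synthetic age-annotated count datasets with known ground truth.

The generator emulates the processed single-cell product the pipeline
consumes: ~5294 cells on the 0.01 age grid with phase counts of order
941 (G1) / 2240 (S) / 2113 (G2/M), per-gene counts drawn from the
age-dependent bursty model's moment-matched negative binomial, a per-gene
degradation-rate table (log-normal around a 7.1 h median half-life), and
an optional per-cell Beta-distributed capture efficiency applied as
binomial thinning.

An exact stochastic simulation (instantaneous geometric bursts, linear
degradation, copy-number doubling at replication, binomial partitioning
at division) provides an independent oracle for the moment ODEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .age_model import (
    AgeDistribution,
    AgeModelParams,
    THETA_GRID,
    default_boundaries,
    nb_at_age,
    phase_averaged_burst_size,
    solve_moments,
)
from .data import AgeAnnotatedCounts, phase_of_theta

__all__ = [
    "CaptureModel",
    "CohortConfig",
    "SyntheticDataset",
    "sample_age_distribution",
    "generate_gene_params",
    "simulate_counts",
    "ssa_simulate",
    "binomial_downsample",
    "generate_dataset",
]

#: median mRNA half-life (hours) used for the degradation-rate fixture
MEDIAN_HALF_LIFE_H = 7.1

AGE_MODES = ("uniform", "exponential_growth", "empirical_histogram")


@dataclass(frozen=True)
class CaptureModel:
    """Per-cell capture efficiency p ~ Beta(beta_a, beta_b)."""

    beta_a: float = 30.0
    beta_b: float = 70.0

    def __post_init__(self) -> None:
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.beta_a / (self.beta_a + self.beta_b)

    @property
    def cv(self) -> float:
        a, b = self.beta_a, self.beta_b
        return float(np.sqrt(b / (a * (a + b + 1.0))))


def _age_weights(mode: str, grid: np.ndarray, histogram: np.ndarray | None) -> np.ndarray:
    if mode == "uniform":
        w = np.ones_like(grid)
    elif mode == "exponential_growth":
        # steady exponential growth: newborn cells are twice as frequent
        # as cells about to divide
        w = 2.0 ** (1.0 - grid)
    elif mode == "empirical_histogram":
        if histogram is None:
            raise ValueError("empirical_histogram mode needs a histogram")
        w = np.asarray(histogram, dtype=float)
        if w.shape != grid.shape:
            raise ValueError("histogram must match the age grid")
    else:
        raise ValueError(f"unknown age-distribution mode {mode!r}")
    return w / w.sum()


def sample_age_distribution(
    n_cells: int,
    mode: str = "exponential_growth",
    seed: int = 0,
    histogram: np.ndarray | None = None,
    grid: np.ndarray = THETA_GRID,
) -> np.ndarray:
    """Draw per-cell age bins from the chosen population age structure."""
    rng = np.random.default_rng(seed)
    w = _age_weights(mode, np.asarray(grid, dtype=float), histogram)
    return rng.choice(grid, size=n_cells, p=w)


@dataclass
class CohortConfig:
    """Shape and ground-truth structure of a synthetic study."""

    n_genes: int = 200
    n_cells: int = 5294
    phase_counts: tuple[int, int, int] = (941, 2240, 2113)
    age_mode: str = "exponential_growth"
    age_histogram: np.ndarray | None = None
    q_f: float | None = None  # constrain every gene's f2/f1
    q_b: float | None = None  # constrain every gene's phase-averaged size ratio
    f1_range: tuple[float, float] = (0.2, 2.0)
    rho1_range: tuple[float, float] = (1.0, 4.0)
    beta_ranges: tuple = (
        (0.05, 0.7),
        (-0.7, -0.05),
        (0.05, 0.7),
        (0.05, 0.7),
    )
    half_life_median_h: float = MEDIAN_HALF_LIFE_H
    half_life_sigma: float = 0.4
    missing_rate_frac: float = 0.0
    T: float = 13.25
    boundaries: tuple[float, float, float] = field(default_factory=default_boundaries)
    variant: str = "size"
    capture: CaptureModel | None = None
    emit_raw_ages: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.phase_counts) != self.n_cells:
            raise ValueError("phase counts must sum to n_cells")
        if self.age_mode not in AGE_MODES:
            raise ValueError(f"unknown age mode {self.age_mode!r}")


def _phase_age_bins(boundaries, grid=THETA_GRID):
    tg1, _, ts = boundaries
    return (grid[grid < tg1], grid[(grid >= tg1) & (grid < ts)], grid[grid >= ts])


def generate_gene_params(
    config: CohortConfig, seed: int | None = None
) -> tuple[list[AgeModelParams], pd.DataFrame]:
    """Draw per-gene rate parameters (and degradation rates) from the
    cohort priors; optional exact constraints pin each gene's burst
    frequency ratio f2/f1 and phase-averaged burst-size ratio."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tg1, tr, ts = config.boundaries
    grid_w = _age_weights(config.age_mode, THETA_GRID, config.age_histogram)
    g1_bins, _, g2m_bins = _phase_age_bins(config.boundaries)
    g_g1 = AgeDistribution(g1_bins, grid_w[THETA_GRID < tg1] / grid_w[THETA_GRID < tg1].sum())
    g_g2m = AgeDistribution(g2m_bins, grid_w[THETA_GRID >= ts] / grid_w[THETA_GRID >= ts].sum())

    rows, params = [], []
    for i in range(config.n_genes):
        f1 = float(np.exp(rng.uniform(*np.log(config.f1_range))))
        rho1 = float(np.exp(rng.uniform(*np.log(config.rho1_range))))
        betas = tuple(float(rng.uniform(lo, hi)) for lo, hi in config.beta_ranges)
        # unconstrained draws centre the burst-frequency ratio near 0.5
        # (frequency roughly halves after replication) and the burst-size
        # ratio near 1, the structure observed in cycling transcriptomes
        if config.q_f is not None:
            f2 = config.q_f * f1
        else:
            f2 = float(f1 * np.exp(rng.normal(np.log(0.5), 0.4)))
        # phase-averaged burst sizes fix rho2 given a target Q_b
        b_g1_unit = phase_averaged_burst_size(1.0, betas[0], g_g1)
        b_g2m_unit = phase_averaged_burst_size(1.0, betas[3], g_g2m)
        q_b_draw = config.q_b if config.q_b is not None else float(np.exp(rng.normal(0.0, 0.4)))
        rho2 = q_b_draw * rho1 * b_g1_unit / b_g2m_unit
        d = float(
            (np.log(2.0) / config.half_life_median_h)
            * np.exp(rng.normal(0.0, config.half_life_sigma))
        )
        p = AgeModelParams(
            f1=f1, f2=f2, rho1=rho1, rho2=rho2, betas=betas, d=d, T=config.T,
            theta_g1=tg1, theta_r=tr, theta_s=ts, variant=config.variant,
        )
        params.append(p)
        rows.append(
            dict(
                gene_id=f"g{i:04d}", f1=f1, f2=f2, rho1=rho1, rho2=rho2,
                beta1=betas[0], beta2=betas[1], beta3=betas[2], beta4=betas[3],
                d=d,
                q_f_true=f2 / f1,
                q_b_true=(rho2 * b_g2m_unit) / (rho1 * b_g1_unit),
            )
        )
    return params, pd.DataFrame(rows)


def simulate_counts(
    params: AgeModelParams, theta: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Draw one count per cell from the moment-matched NB at its age bin."""
    rng = np.random.default_rng(seed)
    theta = np.round(np.asarray(theta, dtype=float), 2)
    bins = np.unique(theta)
    traj = solve_moments(params, bins)
    out = np.empty(theta.size, dtype=np.int64)
    for b, mu, v in zip(bins, traj.mean, traj.variance):
        sel = theta == b
        out[sel] = nb_at_age(mu, v).rvs(int(sel.sum()), rng)
    return out


def binomial_downsample(
    counts: np.ndarray, capture: CaptureModel = CaptureModel(), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Thin a cell x gene count matrix with one capture efficiency per cell.

    Returns (observed counts, per-cell capture efficiencies).
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    one_d = counts.ndim == 1
    mat = counts[:, None] if one_d else counts
    p = rng.beta(capture.beta_a, capture.beta_b, size=mat.shape[0])
    out = rng.binomial(mat, p[:, None])
    return (out[:, 0] if one_d else out), p


# ---------------------------------------------------------------------------
# exact stochastic simulation oracle


@njit(cache=True)
def _ssa_core(
    seed, thetas, T, d, f1, f2, rho1, rho2, b1, b2, b3, b4,
    tg1, tr, ts, freq_variant, warmup, cap,
):  # pragma: no cover - exercised through ssa_simulate
    np.random.seed(seed)
    n = thetas.shape[0]
    out = np.empty(n, dtype=np.int64)
    edges = np.array([0.0, tg1, tr, ts, 1.0])
    betas = np.array([b1, b2, b3, b4])
    for i in range(n):
        target = thetas[i]
        m = 0
        for gen in range(warmup + 1):
            end_theta = 1.0 if gen < warmup else target
            th = 0.0
            while th < end_theta - 1e-12:
                # locate segment
                seg = 0
                for j in range(1, 4):
                    if th >= edges[j] - 1e-12:
                        seg = j
                seg_end = edges[seg + 1]
                if seg_end > end_theta:
                    seg_end = end_theta
                if seg < 2:
                    f, rho, copies = f1, rho1, 2.0
                else:
                    f, rho, copies = f2, rho2, 4.0
                beta = betas[seg]
                # upper bound on the burst propensity over the segment
                # (time-dependent only in the frequency-scaling variant)
                if freq_variant:
                    e0 = np.exp(beta * th)
                    e1 = np.exp(beta * seg_end)
                    fmax = f * (e0 if e0 > e1 else e1)
                else:
                    fmax = f
                rate = (copies * fmax + m * d) * T  # per unit theta
                if rate <= 0.0:
                    th = seg_end
                    continue
                dt = np.random.exponential(1.0 / rate)
                if th + dt >= seg_end:
                    th = seg_end
                    continue
                th = th + dt
                u = np.random.random() * rate
                if u < copies * fmax * T:
                    # candidate burst; thinning for the time-varying rate
                    accept = True
                    if freq_variant:
                        accept = np.random.random() < np.exp(beta * th) * f / fmax
                        b_now = rho
                    else:
                        b_now = rho * np.exp(beta * th)
                    if accept and b_now > 0.0:
                        r = np.random.geometric(1.0 / (1.0 + b_now)) - 1
                        m += r
                else:
                    m -= 1
                if m > cap:
                    return out[:0]  # runaway population
            if gen < warmup:
                m = np.random.binomial(m, 0.5)
        out[i] = m
    return out


def ssa_simulate(
    params: AgeModelParams,
    n_cells: int,
    seed: int = 0,
    theta: np.ndarray | None = None,
    warmup_generations: int = 10,
    population_cap: int = 10_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact stochastic simulation of the age-dependent bursty model.

    Each of ``n_cells`` lineages is evolved from zero molecules through
    ``warmup_generations`` full cycles (binomial halving at each division)
    to reach cyclo-stationarity, then observed at its assigned age.
    Returns (theta, counts).
    """
    rng = np.random.default_rng(seed)
    if theta is None:
        theta = rng.uniform(0.0, 1.0, size=n_cells)
    theta = np.asarray(theta, dtype=float)
    if theta.size != n_cells:
        raise ValueError("theta must have one entry per cell")
    b1, b2, b3, b4 = params.betas
    counts = _ssa_core(
        int(rng.integers(0, 2**31 - 1)),
        theta,
        params.T, params.d,
        params.f1, params.f2, params.rho1, params.rho2,
        b1, b2, b3, b4,
        params.theta_g1, params.theta_r, params.theta_s,
        params.variant == "frequency",
        warmup_generations,
        population_cap,
    )
    if counts.size == 0:
        raise RuntimeError("SSA population exceeded the runaway cap")
    return theta, counts


# ---------------------------------------------------------------------------
# full datasets


@dataclass
class SyntheticDataset:
    data: AgeAnnotatedCounts
    params: list[AgeModelParams]
    truth: pd.DataFrame
    rates: pd.DataFrame
    capture_p: np.ndarray | None
    true_counts: np.ndarray
    config: CohortConfig


def _sample_phase_ages(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Ages drawn phase by phase so the phase totals are hit exactly."""
    w = _age_weights(config.age_mode, THETA_GRID, config.age_histogram)
    phase_bins = _phase_age_bins(config.boundaries)
    thetas = []
    for n_phase, bins in zip(config.phase_counts, phase_bins):
        wp = w[np.isin(THETA_GRID, bins)]
        thetas.append(rng.choice(bins, size=n_phase, p=wp / wp.sum()))
    return np.sort(np.concatenate(thetas))


def generate_dataset(config: CohortConfig) -> SyntheticDataset:
    """Generate a complete age-annotated study with ground-truth tables."""
    rng = np.random.default_rng(config.seed)
    theta = _sample_phase_ages(config, rng)
    tg1, _, ts = config.boundaries
    phase = phase_of_theta(theta, tg1, ts)

    params, truth = generate_gene_params(config, seed=int(rng.integers(2**31 - 1)))
    counts = np.empty((theta.size, config.n_genes), dtype=np.int64)
    for j, p in enumerate(params):
        counts[:, j] = simulate_counts(p, theta, seed=int(rng.integers(2**31 - 1)))

    capture_p = None
    true_counts = counts
    if config.capture is not None:
        counts, capture_p = binomial_downsample(
            counts, config.capture, seed=int(rng.integers(2**31 - 1))
        )

    rates = truth[["gene_id", "d"]].rename(columns={"d": "rate_per_hour"})
    if config.missing_rate_frac > 0:
        drop = rng.random(config.n_genes) < config.missing_rate_frac
        rates = rates.loc[~drop].reset_index(drop=True)

    if config.emit_raw_ages:
        theta_out = np.round(np.round((theta * 0.89 / 0.99 + 0.1) * 100) / 100, 2)
    else:
        theta_out = theta
    data = AgeAnnotatedCounts(
        counts=counts,
        theta=theta_out,
        phase=phase,
        gene_ids=truth["gene_id"].to_numpy(),
    )
    return SyntheticDataset(data, params, truth, rates, capture_p, true_counts, config)
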