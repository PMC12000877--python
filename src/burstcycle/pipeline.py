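"""End-to-end analysis: age preprocessing, gene filters, per-gene fitting,
burst-parameter ratio estimation and the capture-noise robustness experiment.

The canonical flow for the age-dependent path is

    preprocess_ages -> expression_filter -> (i) degradation rate present
    -> (ii) non-negative mean/age correlation in G1 and G2/M
    -> age-model MLE -> (iii) fitted trend agrees in sign with the data
    -> (iv) non-negative R^2 of mean and variance -> Q_f, Q_b

Q_f = f2/f1 is the ratio of per-allele burst frequencies between G2/M and
G1; Q_b is the ratio of the phase-averaged burst sizes
rho * sum_theta g(theta) e^{beta theta} using each phase's empirical cell
age histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .age_model import (
    AgeDistribution,
    AgeModelParams,
    default_boundaries,
    phase_averaged_burst_size,
    solve_moments,
)
from .data import PHASES, AgeAnnotatedCounts
from .inference import (
    AgeModelSpec,
    ConfidenceInterval,
    FitResult,
    ModelSpec,
    OptimizerConfig,
    _make_objective,
    fit_age_model,
    fit_mle,
    fit_steady_models,
    prediction_profile_ci,
    select_model,
)
from .steady_state import burst_params, SteadyStateParams

__all__ = [
    "AgeAnnotatedCounts",
    "GeneResult",
    "RatioEstimate",
    "TrendFit",
    "preprocess_ages",
    "expression_filter",
    "mean_ratio_lambda",
    "binned_stats",
    "fit_exp_trend",
    "gene_filters_age",
    "compute_q_ratios",
    "run_age_study",
    "run_steady_study",
    "downsampling_experiment",
    "summarize_transcriptome",
    "DownsamplingConfig",
]

#: the age range removed as possibly misclassified newborn cells
LOW_AGE_CUT = 0.09

FILTER_STEPS = (
    "low_expression",
    "no_degradation_rate",
    "negative_data_trend",
    "fit_trend_mismatch",
    "negative_r2",
    "pass",
)


def preprocess_ages(data: AgeAnnotatedCounts, lower_cut: float = LOW_AGE_CUT) -> AgeAnnotatedCounts:
    """Drop cells in the [0, lower_cut] age range and affinely rescale the
    remaining ages back onto the full [0, 0.99] grid."""
    keep = data.theta > lower_cut + 1e-9
    sub = data.subset_cells(keep)
    theta = np.round((sub.theta - 0.1) * 0.99 / 0.89, 10)
    theta = np.round(np.round(theta * 100) / 100, 2)
    return AgeAnnotatedCounts(
        counts=sub.counts,
        theta=theta,
        phase=sub.phase,
        gene_ids=sub.gene_ids,
        cell_ids=sub.cell_ids,
    )


def expression_filter(data: AgeAnnotatedCounts, threshold: float = 1.0) -> np.ndarray:
    """Keep genes whose mean count is at least ``threshold`` in every phase
    (strictly-below-threshold means are filtered, the boundary is kept)."""
    masks = [data.phase_mask(p) for p in PHASES]
    if any(not m.any() for m in masks):
        raise ValueError("every phase must contain at least one cell")
    keep = np.ones(data.n_genes, dtype=bool)
    for m in masks:
        keep &= data.counts[m].mean(axis=0) >= threshold
    return keep


def mean_ratio_lambda(data: AgeAnnotatedCounts, gene_id) -> float:
    """Lambda = <m_G2/M> / <m_G1>, the dosage-compensation summary."""
    c = data.gene_counts(gene_id)
    g1 = c[data.phase_mask("G1")].mean()
    g2m = c[data.phase_mask("G2/M")].mean()
    if g1 == 0:
        return np.nan
    return float(g2m / g1)


def binned_stats(theta: np.ndarray, counts: np.ndarray) -> pd.DataFrame:
    """Per-age-bin sample mean and variance of one gene's counts."""
    df = pd.DataFrame({"theta": np.round(theta, 2), "count": counts})
    g = df.groupby("theta")["count"]
    out = pd.DataFrame({"mean": g.mean(), "var": g.var(ddof=0), "n": g.size()})
    return out.reset_index()


@dataclass
class TrendFit:
    k: float
    beta: float
    correlation: float


def fit_exp_trend(theta: np.ndarray, means: np.ndarray) -> TrendFit:
    """Non-linear least squares of k * exp(beta * theta) to binned means,
    initialised from a log-linear regression."""
    theta = np.asarray(theta, dtype=float)
    means = np.asarray(means, dtype=float)
    pos = means > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 bins with positive mean")
    slope, intercept = np.polyfit(theta[pos], np.log(means[pos]), 1)
    try:
        popt, _ = curve_fit(
            lambda t, k, b: k * np.exp(b * t),
            theta, means, p0=[np.exp(intercept), slope], maxfev=10000,
        )
        k, beta = float(popt[0]), float(popt[1])
    except RuntimeError:
        k, beta = float(np.exp(intercept)), float(slope)
    pred = k * np.exp(beta * theta)
    if np.std(pred) == 0 or np.std(means) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(pred, means)[0, 1])
    return TrendFit(k=k, beta=beta, correlation=corr)


def _phase_bin_corr(stats: pd.DataFrame, lo: float, hi: float) -> float:
    """Pearson correlation of binned mean vs age within [lo, hi)."""
    sel = (stats["theta"] >= lo) & (stats["theta"] < hi)
    sub = stats.loc[sel]
    if len(sub) < 2 or sub["mean"].std() == 0:
        return 0.0
    return float(np.corrcoef(sub["theta"], sub["mean"])[0, 1])


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def gene_filters_age(
    data: AgeAnnotatedCounts,
    gene_id,
    has_rate: bool,
    fit: FitResult | None = None,
    boundaries: tuple[float, float, float] | None = None,
) -> str:
    """Verdict of the four-step filter cascade for the age-dependent model.

    Steps (i) and (ii) are pre-fit (pass ``fit=None`` to evaluate only
    those); steps (iii) and (iv) require the fitted model.
    """
    tg1, _, ts = boundaries or default_boundaries()
    if not has_rate:
        return "no_degradation_rate"
    counts = data.gene_counts(gene_id)
    stats = binned_stats(data.theta, counts)
    corr_g1 = _phase_bin_corr(stats, 0.0, tg1)
    corr_g2m = _phase_bin_corr(stats, ts, 1.0)
    if corr_g1 < 0 or corr_g2m < 0:
        return "negative_data_trend"
    if fit is None:
        return "pass"

    spec: AgeModelSpec = fit.spec
    params = spec.make_params(fit.params)
    bins = stats["theta"].to_numpy()
    traj = solve_moments(params, bins)
    pred = pd.DataFrame({"theta": bins, "mean": traj.mean})
    fit_g1 = _phase_bin_corr(pred, 0.0, tg1)
    fit_g2m = _phase_bin_corr(pred, ts, 1.0)
    if (np.sign(fit_g1) != np.sign(corr_g1) and corr_g1 != 0) or (
        np.sign(fit_g2m) != np.sign(corr_g2m) and corr_g2m != 0
    ):
        return "fit_trend_mismatch"
    r2_mean = _r_squared(stats["mean"].to_numpy(), traj.mean)
    r2_var = _r_squared(stats["var"].to_numpy(), traj.variance)
    if r2_mean < 0 or r2_var < 0:
        return "negative_r2"
    return "pass"


@dataclass
class RatioEstimate:
    """Per-gene burst-parameter ratios between G2/M and G1."""

    q_f: float
    q_b: float
    b_g1: float
    b_g2m: float
    ci_f: ConfidenceInterval | None = None
    ci_b: ConfidenceInterval | None = None


def _phase_age_distributions(
    data: AgeAnnotatedCounts, boundaries
) -> tuple[AgeDistribution, AgeDistribution]:
    tg1, _, ts = boundaries
    g1 = data.theta[data.theta < tg1]
    g2m = data.theta[data.theta >= ts]
    return AgeDistribution.from_cells(g1), AgeDistribution.from_cells(g2m)


def compute_q_ratios(
    fit: FitResult,
    g_g1: AgeDistribution,
    g_g2m: AgeDistribution,
    data: tuple | None = None,
    with_ci: bool = False,
    alpha: float = 0.05,
) -> RatioEstimate:
    """Q_f = f2/f1 and Q_b from phase-averaged burst sizes, with optional
    prediction-profile confidence intervals."""
    p = fit.params
    if p["f1"] == 0 or p["rho1"] == 0:
        raise ZeroDivisionError("undefined ratio: zero pre-replication parameter")
    b_g1 = phase_averaged_burst_size(p["rho1"], p["beta1"], g_g1)
    b_g2m = phase_averaged_burst_size(p["rho2"], p["beta4"], g_g2m)
    q_f = p["f2"] / p["f1"]
    q_b = b_g2m / b_g1
    ci_f = ci_b = None
    if with_ci:
        if data is None:
            raise ValueError("with_ci requires the (theta, counts) data")
        spec: AgeModelSpec = fit.spec
        prepared = spec.prepare(data)
        nll = _make_objective(spec, prepared)
        names = spec.param_names
        bounds = spec.bounds_trans()
        i_f1, i_f2 = names.index("f1"), names.index("f2")
        i_r1, i_r2 = names.index("rho1"), names.index("rho2")
        i_b1, i_b4 = names.index("beta1"), names.index("beta4")
        ci_f = prediction_profile_ci(
            nll, fit.x_trans.copy(), bounds, eliminate_index=i_f2,
            solve_eliminated=lambda z, x: np.log(z) + x[i_f1],
            z_hat=q_f, alpha=alpha, z_bounds=(1e-8, 1e8), target="Q_f",
        )

        def solve_rho2(z: float, x: np.ndarray) -> float:
            a1 = np.log(np.sum(g_g1.weights * np.exp(x[i_b1] * g_g1.theta)))
            a4 = np.log(np.sum(g_g2m.weights * np.exp(x[i_b4] * g_g2m.theta)))
            return np.log(z) + x[i_r1] + a1 - a4

        ci_b = prediction_profile_ci(
            nll, fit.x_trans.copy(), bounds, eliminate_index=i_r2,
            solve_eliminated=solve_rho2,
            z_hat=q_b, alpha=alpha, z_bounds=(1e-8, 1e8), target="Q_b",
        )
    return RatioEstimate(q_f=q_f, q_b=q_b, b_g1=b_g1, b_g2m=b_g2m, ci_f=ci_f, ci_b=ci_b)


@dataclass
class GeneResult:
    gene_id: str
    status: str
    lam: float = np.nan
    q_f: float = np.nan
    q_b: float = np.nan
    b_g1: float = np.nan
    b_g2m: float = np.nan
    loglik: float = np.nan
    r2_mean: float = np.nan
    r2_var: float = np.nan
    fit: FitResult | None = None


def run_age_study(
    data: AgeAnnotatedCounts,
    rates: pd.DataFrame,
    boundaries: tuple[float, float, float] | None = None,
    T: float = 13.25,
    variant: str = "size",
    optimizer: OptimizerConfig | None = None,
    with_ci: bool = False,
    preprocess: bool = False,
) -> pd.DataFrame:
    """Fit the age-dependent model across the expression-filtered
    transcriptome and estimate per-gene burst-parameter ratios.

    ``rates`` maps gene_id -> rate_per_hour; genes without a rate are
    removed at filter step (i).  Returns one row per input gene with the
    filter verdict and, for passing genes, Q_f, Q_b and fit diagnostics.
    """
    if preprocess:
        data = preprocess_ages(data)
    boundaries = tuple(boundaries or default_boundaries())
    rate_map = dict(zip(rates["gene_id"], rates["rate_per_hour"]))
    expr_keep = expression_filter(data)
    g_g1, g_g2m = _phase_age_distributions(data, boundaries)

    rows = []
    for j, gene in enumerate(data.gene_ids):
        if not expr_keep[j]:
            rows.append(GeneResult(gene, "low_expression"))
            continue
        lam = mean_ratio_lambda(data, gene)
        d = rate_map.get(gene)
        verdict = gene_filters_age(data, gene, has_rate=d is not None, boundaries=boundaries)
        if verdict != "pass":
            rows.append(GeneResult(gene, verdict, lam=lam))
            continue
        counts = data.gene_counts(gene)
        cfg = optimizer
        if cfg is not None:
            cfg = replace(cfg, seed=(cfg.seed + j) % (2**31 - 1))
        fit = fit_age_model(
            data.theta, counts, d=float(d), T=T,
            boundaries=boundaries, variant=variant, config=cfg,
        )
        verdict = gene_filters_age(
            data, gene, has_rate=True, fit=fit, boundaries=boundaries
        )
        if verdict != "pass":
            rows.append(GeneResult(gene, verdict, lam=lam, fit=fit))
            continue
        ratios = compute_q_ratios(
            fit, g_g1, g_g2m,
            data=(data.theta, counts) if with_ci else None, with_ci=with_ci,
        )
        stats = binned_stats(data.theta, counts)
        traj = solve_moments(fit.spec.make_params(fit.params), stats["theta"].to_numpy())
        rows.append(
            GeneResult(
                gene, "pass", lam=lam,
                q_f=ratios.q_f, q_b=ratios.q_b,
                b_g1=ratios.b_g1, b_g2m=ratios.b_g2m,
                loglik=fit.loglik,
                r2_mean=_r_squared(stats["mean"].to_numpy(), traj.mean),
                r2_var=_r_squared(stats["var"].to_numpy(), traj.variance),
                fit=fit,
            )
        )
    df = pd.DataFrame(
        [
            dict(
                gene_id=r.gene_id, status=r.status, lam=r.lam,
                q_f=r.q_f, q_b=r.q_b, b_g1=r.b_g1, b_g2m=r.b_g2m,
                loglik=r.loglik, r2_mean=r.r2_mean, r2_var=r.r2_var,
            )
            for r in rows
        ]
    )
    df.attrs["fits"] = {r.gene_id: r.fit for r in rows if r.fit is not None}
    return df


def run_steady_study(
    data: AgeAnnotatedCounts,
    families: list[str] | None = None,
    optimizer: OptimizerConfig | None = None,
    select: bool = True,
) -> pd.DataFrame:
    """Fit steady-state families per gene in G1 (2 copies) and G2/M
    (4 copies), BIC-select, and form per-copy burst-parameter ratios.

    Restricting ``families`` (e.g. to ["NB"]) skips selection and fits a
    single family, which is the dominant outcome for bursty genes.
    """
    expr_keep = expression_filter(data)
    masks = {"G1": data.phase_mask("G1"), "G2/M": data.phase_mask("G2/M")}
    copies = {"G1": 2, "G2/M": 4}
    rows = []
    for j, gene in enumerate(data.gene_ids):
        if not expr_keep[j]:
            rows.append(dict(gene_id=gene, status="low_expression"))
            continue
        lam = mean_ratio_lambda(data, gene)
        row = dict(gene_id=gene, status="pass", lam=lam)
        bursty = True
        for phase, mask in masks.items():
            counts = data.counts[mask, j]
            cfg = optimizer
            if cfg is not None:
                cfg = replace(cfg, seed=(cfg.seed + 7919 * j) % (2**31 - 1))
            if families is not None and len(families) == 1 and not select:
                fit = fit_mle(ModelSpec(families[0], n_copies=copies[phase]), counts, cfg)
            else:
                fits = fit_steady_models(counts, copies[phase], cfg, families)
                fit = select_model(fits)
            row[f"family_{phase}"] = fit.family
            fb = _steady_burst_params(fit)
            if fb is None:
                bursty = False
            else:
                row[f"f_{phase}"], row[f"b_{phase}"] = fb
        if not bursty:
            row["status"] = "non_bursty"
        else:
            row["q_f"] = row["f_G2/M"] / row["f_G1"]
            row["q_b"] = row["b_G2/M"] / row["b_G1"]
        rows.append(row)
    return pd.DataFrame(rows)


def _steady_burst_params(fit: FitResult) -> tuple[float, float] | None:
    fam = fit.family
    if fam in ("Poisson", "ZIP"):
        return None
    p = fit.params
    if fam in ("NB", "ZINB"):
        b = (1.0 - p["p"]) / p["p"]
        return p["f"], b
    bp = burst_params(SteadyStateParams(p["sigma0"], p["sigma1"], p["rho"]))
    return bp.f, bp.b


@dataclass
class DownsamplingConfig:
    """Scaled-down replica of the binomial-capture robustness experiment."""

    n_genes: int = 200
    n_replicates: int = 100
    capture: object | None = None  # CaptureModel; None = perfect capture
    percentile_box: tuple[float, float] = (5.0, 95.0)
    rescale_by_capture: bool = True
    seed: int = 0
    optimizer: OptimizerConfig | None = None


def downsampling_experiment(
    cohort: pd.DataFrame,
    params_by_gene: dict[str, AgeModelParams],
    theta: np.ndarray,
    config: DownsamplingConfig,
) -> pd.DataFrame:
    """Assess the bias that finite mRNA capture induces in the burst
    ratios: sample genes from the central (Q_f, Q_b) percentile box,
    rescale burst sizes by 1/<p>, simulate true counts, thin them
    binomially with per-cell Beta capture efficiencies, refit, and report
    per-gene medians and interquartile ranges over replicates.
    """
    from .synthetic import binomial_downsample, simulate_counts

    rng = np.random.default_rng(config.seed)
    ok = cohort.dropna(subset=["q_f", "q_b"])
    lo, hi = config.percentile_box
    qf_lo, qf_hi = np.percentile(ok["q_f"], [lo, hi])
    qb_lo, qb_hi = np.percentile(ok["q_b"], [lo, hi])
    box = ok[
        ok["q_f"].between(qf_lo, qf_hi) & ok["q_b"].between(qb_lo, qb_hi)
    ]
    if len(box) < config.n_genes:
        raise ValueError(
            f"cohort has {len(box)} genes in the percentile box; "
            f"{config.n_genes} requested"
        )
    chosen = box.sample(n=config.n_genes, random_state=int(rng.integers(2**31 - 1)))

    p_mean = config.capture.mean if config.capture is not None else 1.0
    rows = []
    for _, rec in chosen.iterrows():
        gene = rec["gene_id"]
        base = params_by_gene[gene]
        sim_params = replace(
            base,
            rho1=base.rho1 / p_mean if config.rescale_by_capture else base.rho1,
            rho2=base.rho2 / p_mean if config.rescale_by_capture else base.rho2,
        )
        qf_est, qb_est = [], []
        for _ in range(config.n_replicates):
            y = simulate_counts(sim_params, theta, seed=int(rng.integers(2**31 - 1)))
            if config.capture is not None:
                x, _ = binomial_downsample(y, config.capture, seed=int(rng.integers(2**31 - 1)))
            else:
                x = y
            cfg = config.optimizer
            if cfg is not None:
                cfg = replace(cfg, seed=int(rng.integers(2**31 - 1)))
            fit = fit_age_model(
                theta, x, d=base.d, T=base.T,
                boundaries=(base.theta_g1, base.theta_r, base.theta_s),
                variant=base.variant, config=cfg,
            )
            qf_est.append(fit.params["f2"] / fit.params["f1"])
            g_g1 = AgeDistribution.from_cells(theta[theta < base.theta_g1])
            g_g2m = AgeDistribution.from_cells(theta[theta >= base.theta_s])
            b1 = phase_averaged_burst_size(fit.params["rho1"], fit.params["beta1"], g_g1)
            b4 = phase_averaged_burst_size(fit.params["rho2"], fit.params["beta4"], g_g2m)
            qb_est.append(b4 / b1)
        rows.append(
            dict(
                gene_id=gene,
                q_f_true=rec["q_f"], q_b_true=rec["q_b"],
                q_f_median=float(np.median(qf_est)),
                q_f_q1=float(np.percentile(qf_est, 25)),
                q_f_q3=float(np.percentile(qf_est, 75)),
                q_b_median=float(np.median(qb_est)),
                q_b_q1=float(np.percentile(qb_est, 25)),
                q_b_q3=float(np.percentile(qb_est, 75)),
            )
        )
    return pd.DataFrame(rows)


def summarize_transcriptome(results: pd.DataFrame) -> dict:
    """Cohort medians/quartiles of Lambda, Q_f and Q_b, the (Q_f, Q_b)
    correlation, and the per-filter attrition bookkeeping."""
    ok = results[results["status"] == "pass"]
    if len(ok) < 2:
        raise ValueError("need at least 2 passing genes to summarise")

    def quartiles(x):
        x = x.dropna()
        return dict(
            median=float(x.median()),
            q1=float(x.quantile(0.25)),
            q3=float(x.quantile(0.75)),
        )

    attrition = {step: int((results["status"] == step).sum()) for step in FILTER_STEPS}
    if len(ok) > 1 and ok["q_f"].std() > 0 and ok["q_b"].std() > 0:
        corr = float(np.corrcoef(ok["q_f"], ok["q_b"])[0, 1])
    else:
        corr = np.nan
    return dict(
        n_genes=int(len(results)),
        n_pass=int(len(ok)),
        lam=quartiles(results.loc[results["status"] != "low_expression", "lam"]),
        q_f=quartiles(ok["q_f"]),
        q_b=quartiles(ok["q_b"]),
        qf_qb_correlation=corr,
        attrition=attrition,
    )
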