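# burstcycle

Cell-cycle-resolved inference of transcriptional bursting from
age-annotated single-cell RNA-seq counts.

## The problem

Genes are transcribed in random bursts characterised by two parameters:
the **burst frequency** *f* (how often bursts fire per allele) and the
**burst size** *b* (mean mRNA made per burst). How these change when a
cell replicates its DNA — from 2 gene copies in G1 to 4 in G2/M — is the
question this package addresses. Naive fitting of snapshot count
distributions conflates three effects: intrinsic burst noise, extrinsic
noise from the coupling of transcription to cell age within a phase, and
technical noise from the finite mRNA capture efficiency of sequencing.

`burstcycle` implements a mechanistic inference framework for UMI count
matrices in which every cell carries a cell-age label θ ∈ [0, 1) (binned
at 0.01; θ = 0 at birth, θ = 1 at division) and a phase label
(G1 / S / G2/M), as produced by deep-learning cell-cycle staging of
mESC scRNA-seq data. It estimates, per gene, the per-allele ratios

- **Q_f = f_G2/M / f_G1** — burst-frequency ratio across replication,
- **Q_b = b_G2/M / b_G1** — burst-size ratio (phase-averaged),

together with profile-likelihood confidence intervals, and quantifies the
robustness of these ratios to capture noise.

## Models

**Age-independent (steady-state) family.** Per allele, the telegraph
model G* ⇌ G, G → G + M (rate ρ), M → ∅ (rate d), whose stationary pmf is

P(m) = (ρ/d)^m / m! · (σ₁/d)_m / ((σ₁/d + σ₀/d))_m · ₁F₁(σ₁/d + m, σ₁/d + σ₀/d + m, −ρ/d),

with the NB(f, (1+b)⁻¹) bursty limit (f = σ₁, b = ρ/σ₀) and the Poisson
constitutive limit, each with an optional zero-inflated variant. The
observed count is the k-fold self-convolution of the allele distribution
(k = 2 in G1, k = 4 in G2/M). Model choice per gene and phase uses a BIC
ladder from simplest to most complex, advancing only on strong evidence
(ΔBIC > 10).

**Age-dependent bursty model.** Bursts of geometric size with mean
b(θ) = ρ·e^{βθ} fire at frequency f₁ before and f₂ after DNA replication
(at θ_r, mid-S); ρ takes pre/post-replication values ρ₁, ρ₂ and β is
piecewise constant over G1 / early S / late S / G2/M. The first two
moments of the total count obey linear ODEs with exponential forcing,
solved in closed form per segment with continuity at the phase
boundaries and the binomial-partitioning division condition
⟨m⟩(0) = ⟨m⟩(1)/2, σ²(0) = (σ²(1) + ⟨m⟩(1))/4. The count law at age θ is
the negative binomial matched to ⟨m⟩(θ), σ²(θ), which makes the
likelihood of the full age-resolved dataset tractable.

Because the real sequencing study is not redistributable, a first-class
synthetic-data module generates age-annotated cohorts from the
age-dependent model (with exact ground truth, Beta-distributed per-cell
capture efficiencies, and an exact stochastic-simulation oracle), so the
entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
from burstcycle import CohortConfig, generate_dataset
from burstcycle.pipeline import run_age_study, summarize_transcriptome

# a synthetic 20-gene study: burst frequency halves after replication
# (Q_f = 0.5) while the phase-averaged burst size is unchanged (Q_b = 1)
config = CohortConfig(n_genes=20, q_f=0.5, q_b=1.0, seed=11, emit_raw_ages=True)
study = generate_dataset(config)

results = run_age_study(study.data, study.rates, preprocess=True)
summary = summarize_transcriptome(results)
print("genes passing all filters:", summary["n_pass"], "of", summary["n_genes"])
print("median Lambda (G2/M vs G1 mean ratio):", round(summary["lam"]["median"], 2))
print("median Q_f:", round(summary["q_f"]["median"], 2),
      " IQR:", (round(summary["q_f"]["q1"], 2), round(summary["q_f"]["q3"], 2)))
print("median Q_b:", round(summary["q_b"]["median"], 2),
      " IQR:", (round(summary["q_b"]["q1"], 2), round(summary["q_b"]["q3"], 2)))
```

prints

```
genes passing all filters: 20 of 20
median Lambda (G2/M vs G1 mean ratio): 1.58
median Q_f: 0.5  IQR: (0.45, 0.54)
median Q_b: 1.02  IQR: (0.95, 1.06)
```

The mean-count ratio Λ ≈ 1.6 sits between 1 (perfect dosage
compensation) and 2 (no compensation): halving the burst frequency only
partially offsets the doubled gene dosage. The estimated ratio medians
recover the generating truth (Q_f = 0.5, Q_b = 1.0).

## The analysis

The numbered drivers under `analysis/` run the full study on a synthetic
cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py      # 5294-cell, 200-gene cohort + truth tables
python analysis/02_steady_state_fits.py    # six-model BIC ladder per phase
python analysis/03_age_model_fits.py       # age-dependent fits, filters, Q_f/Q_b, CIs
python analysis/04_capture_robustness.py   # binomial capture-noise experiment
```

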