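# jiatraj

Multivariate clustering of disease-activity trajectories in juvenile
idiopathic arthritis (JIA).

JIA is a heterogeneous childhood-onset arthritis whose activity is usually
summarised by the clinical Juvenile Arthritis Disease Activity Score with a
ten-joint cap (cJADAS-10): the sum of the active joint count capped at 10
(AJC), the physician's global assessment (PGA, 0–10 cm VAS) and the
patient/parent global evaluation of wellbeing (PGE, 0–10 cm VAS).  The three
components do not always move together — a substantial minority of children
report persistently poor wellbeing while their joint counts and physician
scores improve.  `jiatraj` implements the analysis pipeline for finding such
subgroups in inception-cohort data:

* **Latent profile analysis (LPA)** of the three components at first
  presentation: a K-class mixture with a Poisson density for AJC and normal
  densities for PGA/PGE, K chosen by BIC over 1–10 classes.
* **Multivariate group-based trajectory modelling (GBTM)** over three years
  of follow-up: a latent class growth model in which group *g* follows
  polynomial trajectories η_jg(t) (order 1–3) for each outcome *j*, with

  - AJC ~ ZIP(λ = exp(η), ρ_g) — zero-inflated Poisson, intercept-only
    structural-zero probability per group,
  - PGA, PGE ~ censored normal (Tobit) on [0, 10] cm with a residual SD
    shared across groups,

  fitted by maximum likelihood (multi-start EM) with missing visits and
  components simply omitted from the likelihood (missing at random; no
  imputation).
* **Model adequacy and selection**: models are excluded if any group holds
  <1% of the cohort, any group's average posterior probability (APP) is
  below 0.70, or relative entropy is below 0.5; survivors are ranked by
  BIC = −2 log L + k ln N, with near-ties reported rather than auto-resolved.
* **Noise sensitivity**: observed outcome values are replaced at increasing
  fractions (1–25%) by draws from ZIP(λ=2, ρ=0.4) / censored-normal noise,
  the model is refitted, and stability is quantified by the adjusted Rand
  index and group-survival tables.
* **Characterisation**: per-group median (IQR) and n (%) summaries,
  Kruskal–Wallis and χ²/Fisher tests, and the baseline-cluster ×
  trajectory-group mapping matrix.

Because the motivating registry data are access-restricted, the package
ships a **synthetic cohort generator** that emulates its structure — 1184
individuals, visits at 0, 0.5, 1, 2, 3 years with availability
96/77/94/87/80%, six trajectory groups with shares
0.32/0.20/0.16/0.10/0.14/0.08 and group-associated covariates — providing
ground truth for every stage.  See `docs/methods.md` for the model details
and what the synthetic defaults do and do not emulate.

## Worked example

```python
import jiatraj as jt

cfg = jt.paper_default_config(n_individuals=400, seed=1)
cohort, truth = jt.generate_cohort(cfg)

fit = jt.fit_gbtm(cohort, jt.TrajectorySpec(n_groups=6, polynomial_order=3),
                  n_starts=2, seed=1)
print("group shares:", fit.params.pi.round(3))
print("entropy:", round(fit.entropy, 3), " APP:", fit.app.round(3))
```

prints (groups in ascending baseline-severity order):

```
group shares: [0.358 0.189 0.132 0.086 0.163 0.071]
entropy: 0.907  APP: [0.914 0.864 0.995 0.94  0.959 0.995]
```

The fitted shares sit close to the generating ones (0.32/0.20/…);
relative entropy 0.91 and per-group APP ≥ 0.86 indicate a cleanly
classified solution that passes all three adequacy filters.  The same
pipeline is available from the shell:

```bash
jiatraj generate --n 400 --seed 1 --out cohort.csv --truth truth.csv
jiatraj fit-gbtm --cohort cohort.csv --groups 6 --order 3 --starts 2 \
        --seed 1 --out fit.json
jiatraj select --cohort cohort.csv --orders 1,2,3 --kmax 6 --out report.json
jiatraj noise-scan --cohort cohort.csv --fit fit.json --out stability.json
```

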