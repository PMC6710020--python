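# netcoevolve

Stochastic actor-oriented models (SAOMs) for the co-evolution of school
friendship networks and adolescent drinking, with multi-school
meta-analysis and ego–alter selection tables.

## The problem

In longitudinal school cohorts, pupils nominate up to ten friends each
year and report their drinking frequency (never / rarely / monthly /
weekly+), alongside parental-control and secrecy scores.  Similar
drinking among friends can arise from *selection* (befriending pupils who
drink like you) or *influence* (adjusting drinking toward your friends').
SAOMs separate the two by modelling the panel as a continuous-time chain
of elementary decisions ("microsteps"): at exponentially distributed
opportunities an actor either toggles one outgoing tie or moves one
behaviour by ±1, choosing among candidate states by a multinomial logit
over an objective function

&nbsp;&nbsp;&nbsp;&nbsp; f_i(x, z) = Σ_k θ_k s_ik(x, z),

whose statistics s_ik include outdegree, reciprocity, transitive
triplets, indegree popularity (√), covariate homophily, ego / alter /
similarity terms for each behaviour (sim_ij = 1 − |z_i − z_j| / range),
and influence terms (total and average similarity, cross-behaviour
"effect-from" terms).  Parameters θ and per-period change rates λ are
estimated per school by **unconditional method of moments** with
Robbins–Monro stochastic approximation; per-school estimates are pooled
by **Paule–Mandel random-effects meta-analysis** and regressed on school
context (gender status, drinking prevalence); the fitted selection
parameters are turned into **ego–alter selection tables** — odds ratios
of a tie by sender and receiver category relative to a mean-level dyad —
that expose asymmetries such as opportunity hoarding.

Because no cohort data are deposited, the package ships a first-class
synthetic-study generator that emulates the target design: 22 schools
(9 coeducational, 8 girls, 5 boys) of 60–210 pupils over 5 annual waves,
weekly drinking rising from ≈5% to ≈40%, tertiled control/secrecy and
~12% wave-level absence, with known ground-truth parameters and
school-context offsets.

## Worked example

```python
import numpy as np
from netcoevolve import (SynthConfig, generate_study, ModelSpec,
                         estimate_school, EstimationOptions,
                         meta_analyse_fits)

cfg = SynthConfig(n_coed=2, n_girls=1, n_boys=1, size_range=(30, 40),
                  waves=3, seed=3)
panels, truths, metadata = generate_study(cfg)

fits, specs = [], []
for panel in panels:
    spec = ModelSpec.from_panel(panel)
    fit = estimate_school(panel, spec, EstimationOptions(n3=500), seed=7)
    fits.append(fit); specs.append(spec)
    est, se = fit.get("alc_sim", spec)
    print(f"{panel.school_id}: alcohol-similarity {est:+.2f} (se {se:.2f})")

result = meta_analyse_fits(fits, specs, metadata, ["alc_sim", "alc_totsim"],
                           require_converged=False)
pe = result.pooled["alc_sim"]
print(f"pooled alcohol-similarity {pe.estimate:+.2f} "
      f"({pe.ci_low:+.2f}, {pe.ci_high:+.2f})")
```

prints, for one run:

```
s00_coed: alcohol-similarity -0.10 (se 13.90)
s01_coed: alcohol-similarity -0.62 (se 1.15)
s02_girls: alcohol-similarity +1.15 (se 4.69)
s03_boys: alcohol-similarity -2.16 (se 4.11)
pooled alcohol-similarity -0.63 (-2.73, +1.47)
```

Each per-school line is the estimated log-odds contribution of alcohol
similarity to tie formation (positive: pupils prefer friends who drink
like themselves).  At 30–40 pupils and three waves the single-school
estimates are very noisy — similarity selection is weakly identified in
small networks, which the large standard errors report honestly — and
the last line is their inverse-variance pooled value with a 95%
confidence interval; the full 22-school design narrows it substantially.  The full pipeline (synthesis → estimation → GOF →
meta-analysis → selection tables) is also scriptable:

```bash
netcoevolve run --config examples/config.yaml --seed 1 --out runs/demo
```

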