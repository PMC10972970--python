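# tavi-cea

Lifetime cost-effectiveness of transcatheter aortic valve implantation
(TAVI) with a self-expandable valve versus surgical replacement (SAVR) in
severe aortic-stenosis patients at **low surgical risk**, analysed from the
French collective (all-payer, direct-cost) perspective.

The package implements a decision-analytic **Markov cohort model** for
health economists and HTA analysts: two-year clinical event rates,
utilities and costs enter as published numbers, and the model projects
per-strategy life years (LY), quality-adjusted life years (QALYs) and
costs over the cohort's remaining lifetime.

## Model in brief

* Three primary health states — *alive, no stroke*, *alive, post-stroke*,
  *dead* — with nested substates for incident adverse events (MI,
  pacemaker implantation, bleeding, AKI, vascular complication, AF, valve
  rehospitalization, reintervention). Cycle length 1 month.
* Cycles 1–24 run "along the trial": cumulative incidences at 30 days /
  12 months / 24 months are converted to per-cycle probabilities under a
  piecewise-constant hazard,
  `q = 1 − ((1 − p_b)/(1 − p_a))^(1/n)`.
* Beyond 24 months, mortality continues from sex-specific Gompertz
  lifetables calibrated so that remaining life expectancy at age 74 equals
  the published 13.0 y (men) / 15.8 y (women); stroke continues at the
  pooled year-2 trial rate. Male and female sub-cohorts (35.3% female,
  start age 73.9 y) are traced separately and aggregated.
* Outcomes: discounted (2.5%/yr) costs and QALYs per arm, the incremental
  cost-effectiveness ratio `ICER = ΔC/ΔE`, net monetary benefit
  `NMB = λ·ΔE − ΔC` at willingness-to-pay λ = €50,000/QALY, plus scenario,
  one-way (tornado) and probabilistic sensitivity analyses (10,000 joint
  parameter draws, CE plane and CEAC).

## Worked example

```bash
python analysis/01_base_case.py        # base case -> results/
```

prints (packaged inputs, lifetime horizon, 2.5%/yr discounting):

```
TAVI : 9.33 QALYs (11.29 LY), EUR 48,256 discounted
SAVR : 9.20 QALYs (11.19 LY), EUR 47,390 discounted
Delta: EUR 866 for 0.1307 QALYs (0.1017 LY) -> ICER 6,628 EUR/QALY
Max incremental cost staying cost-effective at EUR 50,000/QALY: EUR 6,536
```

i.e. TAVI gains ≈0.13 QALYs at ≈€870 extra lifetime cost — roughly €6,600
per QALY gained, far below the €50,000 threshold, with ≈€6,500 of headroom
in incremental cost before that would change.

The other drivers follow the same pattern and write delimited tables (and
figures) under `results/`:

```bash
python analysis/02_scenarios.py        # named scenario registry (horizons,
                                       # long-term mortality RRs, utilities)
python analysis/03_deterministic_sa.py # one-way sensitivity + tornado
python analysis/04_psa.py              # 10,000-draw PSA, CE plane, CEAC
python analysis/05_validate.py         # survival vs lifetable anchors,
                                       # structural invariants (exit code)
```

Or from Python:

```python
from tavi_cea import run_base_case
res = run_base_case()
print(res.cea.icer, res.cea.delta_qaly)
```

Inputs live in one YAML file (`src/tavi_cea/data/default_inputs.yaml`,
sections `cohort` / `events` / `costs` / `utilities` / `settings`); pass an
edited copy via `--config` or `load_inputs(path)`. A real lifetable can
replace the calibrated synthetic one via `settings.lifetable_file`
(columns `sex,age,q_annual`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch by running the full
pipeline on the packaged inputs — the base-case ICER (per QALY and per
LY), TAVI survival and quality-adjusted survival (discounted and
undiscounted), the incremental lifetime cost, the €50,000/QALY threshold
cost, and the ICERs of the 2-year-horizon and differential long-term
mortality scenarios — and writes them as JSON.

See `docs/methods.md` for the model's assumptions, parameter conventions,
the synthetic-lifetable construction, and known limitations.
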