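# copdce

A hybrid decision-tree / Markov cohort cost-effectiveness model for inhaled
COPD therapy, built for health economists comparing single-inhaler triple
therapy (FF/UMEC/VI) against dual therapy (FF/VI or UMEC/VI) from a UK
health-service perspective.

The model has two phases. Year 1 is a decision tree costed directly from
52-week trial outputs per arm (exacerbation rates, pneumonia, mortality,
discontinuation, EQ-5D trajectory). Years 2–35 are an annual-cycle Markov
cohort over six living states — three FEV₁ severity grades (moderate
50–<80 %, severe 30–<50 %, very severe <30 % predicted) × recent-exacerbation
history — plus death. State mortality is `1 − (1 − q_age)^RR` with severity
relative risks applied to non-COPD background mortality; progression is
worsening-only; exacerbation risk rises with severity and with recent
history. Outputs are discounted (3.5 %/yr) life-years, QALYs and costs by
category, pairwise increments with ICERs (ΔC/ΔE) or dominance verdicts,
±20 % one-way sensitivity (tornado), Table-3-style scenario analyses, and a
Cholesky-correlated probabilistic sensitivity analysis summarised as
cost-effectiveness acceptability curves, `P(λ·ΔQALY − Δcost > 0)`.

Published point estimates (unit costs, utilities, disutilities, mortality
relative risks) are bundled; the unpublished inputs (risk-equation
probability table, per-arm trial outputs, pneumonia unit costs, life table)
ship as clearly-marked synthetic stand-ins so the full pipeline runs
end-to-end out of the box — see `docs/methods.md` for exactly what the
stand-ins do and do not represent.

## Worked example

```python
import copdce

params = copdce.base_case_bundle()          # or copdce.load_parameters("cfg.yaml")
results, comparisons = copdce.run_comparison(params)
for label, r in results.items():
    print(f"{label:11s} LY={r.lys:.3f} QALY={r.qalys:.3f} cost={r.total_cost:.0f}")
for label, cr in comparisons.items():
    print(f"vs {label}: dQALY={cr.delta_qaly:.3f} dCost={cr.delta_cost:.0f} "
          f"ICER={cr.icer_label()}")
```

prints

```
FF/UMEC/VI  LY=8.286 QALY=6.031 cost=24505
FF/VI       LY=8.160 QALY=5.898 cost=23223
UMEC/VI     LY=8.195 QALY=5.943 cost=23941
vs FF/VI: dQALY=0.133 dCost=1282 ICER=9635
vs UMEC/VI: dQALY=0.088 dCost=564 ICER=6417
```

i.e. on the bundled inputs triple therapy gains 0.133 discounted QALYs over
FF/VI at an extra £1282 lifetime cost — £9635 per QALY gained, well under
the conventional £20 000/QALY willingness-to-pay threshold. Costs are GBP at
2018 prices; LYs/QALYs are discounted lifetime totals per patient.

The same pipeline is scriptable from the shell:

```sh
copdce generate config.yaml --seed 0        # synthetic config (YAML)
copdce run-base config.yaml --out-dir out   # per-arm results + increments
copdce owsa config.yaml --out-dir out       # tornado table
copdce psa config.yaml --draws 10000 --seed 7 --out-dir out   # cloud + CEAC
copdce scenarios config.yaml --out-dir out  # scenario suite
```

Each command writes CSVs plus a JSON manifest (config digest, seed, package
version, file list).

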