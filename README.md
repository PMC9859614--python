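# fuzzycad

A fuzzy rule-based expert system for grading the anatomical lesion of the
coronary arteries in patients with coronary artery disease (CAD), with a
reusable Mamdani-style inference engine, the complete clinical knowledge
base, a least-squares tuning procedure and a seeded synthetic cohort
generator, so the whole system is testable with no external data.

## The problem and the model

Clinicians grade coronary-artery lesions from angiographic findings that are
naturally fuzzy: scores such as "presence of atherosclerotic plaques in the
diagonal/LAD basin" do not map crisply onto clinical forms of CAD. The
system encodes this expertise as four linguistic variables:

| factor | meaning | range |
|---|---|---|
| X1 | presence of a/p on the territory of DG or LAD LCA | 1.83–2.76 |
| X2 | presence of HSS on the territory of DG or LAD LCA | 1.74–3.0 |
| X3 | presence of HSS in the trunk of the RCA | 1.0–2.35 |
| X4 | absence of HSS CA | 2.07–4.67 |

(a/p — atherosclerotic plaques; HSS — hemodynamically significant stenosis;
DG/LAD/RCA/LCA — diagonal branch, left anterior descending, right and left
coronary arteries.)

Each factor carries five terms — L (low), LA (lower than average),
A (average), HA (higher than average), H (high) — formalised by published
piecewise-linear membership functions μ̃ʲ(xᵢ) ∈ [0, 1]. Fourteen if-then
rules map term combinations to the four clinical forms of CAD:
I — NSTEMI, II — UAP (unstable angina), III — STEMI, IV — StAP (stable
angina). Inference is classical Mamdani min/max composition,

    μ_d(x) = max over rules r of class d of [ w_r · min_i μ^{A_{r,i}}(x_i) ],

with a product / probabilistic-sum alternative, and the decision is the
class of maximal membership, μ_{d₀}(x) = max_d μ_d(x). For tuning, terms
are re-parametrised as bell curves μ(x) = 1 / (1 + ((x − b)/c)²) and the
peak coordinates b, spreads c and rule weights w are fitted by bounded
least squares, Σ_l ‖F(x̂_l) − ŷ_l‖² → min.

## Worked example

```python
from fuzzycad import (PatientRecord, build_default_knowledge_base,
                      classify_patient)

kb = build_default_knowledge_base()
patient = PatientRecord.from_values(2.15, 2.50, 1.00, 2.50, id="uap-means")
res = classify_patient(patient, kb)
print({c.name: round(v, 4) for c, v in res.memberships.items()})
print(res.decision.name, res.decision.clinical_name, round(res.margin, 3))
```

prints

```
{'I': 0.3325, 'II': 0.7, 'III': 0.0, 'IV': 0.405}
II UAP 0.295
```

The patient's factor vector is the UAP group's mean profile. Fuzzifying it
and composing all fourteen rules with min/max gives class memberships
0.3325 / 0.7 / 0 / 0.405: the class-II membership is highest (its binding
rule is (LA, HA, L, LA), whose weakest antecedent is μ_HA(X2) = 0.7), so
the decision is UAP with a margin of 0.295 over the runner-up. Class III
is exactly zero because every STEMI rule requires X3 = HA, and
μ_HA(1.0) = 0.

The same pipeline is available from the shell:

```sh
fuzzycad classify --in patients.csv --out results.csv
fuzzycad simulate --seed 42 --out cohort.csv
fuzzycad validate-kb --report diagnostics.json
fuzzycad tune --train cohort.csv --what b,c,w --seed 1 \
              --out tuned_kb.json --report tuning.json
fuzzycad report --in cohort.csv --out agreement.json
```

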