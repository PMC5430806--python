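# motenet

Pipeline for studying how a mother's position in a camp's proximity
network relates to her reproductive success and health, in small mobile
forager populations instrumented with wearable proximity sensors
("motes"). Every person in a camp wears a sensor that broadcasts its id
every two minutes; any sensor within ~3 m logs the detection. Over a
5–9-day deployment this yields a complete record of close-range contacts,
from which per-camp weighted social networks are built and related to
reproductive histories and medical-survey outcomes.

The package is aimed at human behavioural ecologists and social-network
epidemiologists: it implements the full measurement-and-inference chain
as an importable library, and ships a synthetic deployment generator with
*planted* effects so the chain's statistical behaviour (bias, interval
coverage, type-I error, mediation signatures) can be audited without
field data.

## The pipeline

1. **Ingest** (`motenet.ingest`) — parse directed ping logs
   (`emitter,receiver,timestamp`), apply sensor-swap corrections, keep the
   half-open daytime window [05:00, 20:00), collapse reciprocal
   detections to one event per unordered dyad per 2-minute slot, and
   compute each dyad's daytime co-presence hours from camp entry/exit
   records.
2. **Networks** (`motenet.netbuild`) — edge weight = dyad-slot events per
   shared daytime hour (a *rate*, so late arrivals are not penalized);
   nodes restricted to ages ≥ 12. For degree only, edges must exceed 1%
   of the camp's total tie weight (strict inequality).
3. **Centrality** (`motenet.centrality`) — degree, strength, eigenvector
   centrality (power iteration, max-normalized), betweenness and
   closeness with geodesic distance d = 1/w; each standardized within
   camp (z-scores, sample SD).
4. **Fertility** (`motenet.fitness`) — living offspring y regressed on
   age with a Poisson GLM, log μ = a + b·age + c·age²; the quantity
   analysed downstream is the response residual y − μ̂ ("0 = age-typical
   number of living offspring"). Score equations make the residuals
   exactly orthogonal to age and age².
5. **Models** (`motenet.models`) — OLS with camp fixed effects;
   continuous predictors standardized over two standard deviations so
   coefficients are comparable with binary controls; centrality × age
   interactions pruned when p > 0.05; joint
   degree + betweenness + closeness models guarded by variance-inflation
   factors (flag above 2.5); sickness models (0–2 reported instances)
   with age/settled/mobility/belongings controls and a
   number-of-dependents term whose inclusion operationalizes a mediation
   check by coefficient attenuation.
6. **Simulator** (`motenet.simulate`) — multi-camp populations with
   households, kin ties and lognormal gregariousness; per-slot Bernoulli
   contacts with probability
   `base_rate · household_boost^[same hh] · kin_boost^[kin] · g_i · g_j`;
   planted centrality→fertility, centrality×age, closeness→sickness and
   dependents→sickness effects expressed per two SD of the *realized*
   camp-standardized centrality, so the downstream OLS estimand equals
   the planted value exactly.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/04_sickness_mediation.py` simulates 20 camps in which
betweenness raises fertility and each living dependent raises the
sickness rate — with *no direct* betweenness→sickness effect — and prints:

```
192 mothers; mean sickness instances 0.93 (capped at 2)

betweenness -> sickness, dependents NOT controlled: beta=+0.426 (significant: True)
betweenness -> sickness, dependents controlled   : beta=+0.050 (significant: False)
proportional attenuation: 88%
dependents term beta=+0.849, p=0.0000
```

Read: a naive model shows a significant betweenness–sickness association
(+0.426 per two SD of betweenness), but once the number of dependents is
controlled the coefficient collapses by 88% and loses significance — the
association runs through family size, which is precisely the planted
structure. `examples/03_fertility_models.py` does the same for the
fertility suite (planted closeness effect of +1.0 recovered at +1.55 with
CI [+0.72, +2.37] in a single 70-mother study), and prints the joint
model with its VIFs.

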