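"""Fit the fertility model suite on a study with a planted closeness effect.

Plants a +1.0 (per two SD of camp-standardized closeness) effect on
mothers' expected living offspring, then runs the estimation chain: the
quadratic Poisson age curve, response residuals, single-centrality OLS
models with interaction pruning, and the VIF-guarded joint model.
"""

from motenet import SimConfig, simulate_study
from motenet.centrality import MEASURES
from motenet.models import (fit_fertility_with_pruning, fit_joint_model)

cfg = SimConfig(n_camps=8, camp_size_range=(20, 30), seed=3,
                beta_centrality_fertility=1.0, fertility_measure="closeness")
study = simulate_study(cfg)
m = study.mothers
print(f"{len(m)} mothers in {m['camp'].nunique()} camps; "
      f"age curve (log scale): {study.age_fit.coef.round(4)}")
print(f"residuals span {m['residual'].min():.2f} .. "
      f"{m['residual'].max():.2f} offspring (0 = age-typical)\n")

print("single-centrality models (standardized beta, p, 95% CI):")
for measure in MEASURES:
    res = fit_fertility_with_pruning(m, measure)
    lo, hi = res.ci(measure)
    tag = "interaction kept" if res.interaction_retained else "pruned"
    print(f"  {measure:<12} beta={res.beta(measure):+.3f}  "
          f"p={res.p(measure):.4f}  CI [{lo:+.2f}, {hi:+.2f}]  "
          f"adjR2={res.adj_r2:.2f}  ({tag})")

joint = fit_joint_model(m)     # vif_mode="warn" logs any breach
print("\njoint degree + betweenness + closeness model:")
for measure in ("degree", "betweenness", "closeness"):
    print(f"  {measure:<12} beta={joint.beta(measure):+.3f}  "
          f"p={joint.p(measure):.4f}  VIF={joint.vif[measure]:.2f}")
print("A VIF above 2.5 flags predictors too collinear to separate — in")
print("dense camps degree and closeness often track each other, which is")
print("exactly why the joint model is VIF-guarded (abort mode refuses).")
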