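"""Fit the nested mixed model for total recumbency and reduce it stepwise.

Treatment enters as an ordered factor coded by orthogonal polynomial
contrasts (linear/quadratic/cubic), with rank status and the rank x
treatment interaction; random intercepts nest the experimental condition
in the horse in the group.  Backward reduction drops terms with p > 0.1,
respecting marginality.
"""

from equirest import SimConfig, estimate_response_scale, stepwise_reduce
from equirest.models import default_model_specs
from equirest.pipeline import simulate_true_metrics

metrics = simulate_true_metrics(SimConfig(seed=3))
spec = next(s for s in default_model_specs() if s.outcome == "duration_min_total")
fit = stepwise_reduce(spec, metrics)

print(f"outcome: {spec.outcome} ({spec.family}, poly order {spec.poly_order})")
print(f"dropped during reduction: {fit.path or 'nothing'}")
print("\nretained terms (Wald F against residual df):")
print(fit.stats_frame().round(4).to_string(index=False))
print("\nresponse-scale estimates (95% CI):")
print(estimate_response_scale(fit).round(1).to_string(index=False))
print("\nthe interaction means low-ranking horses keep gaining recumbency as "
      "the littered area grows beyond the legal minimum.")
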