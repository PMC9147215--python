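"""The two design variants: input stacking and multi-step horizons.

Input stacking (stack number S) concatenates S consecutive 9-vectors into
each input token, feeding the recurrence more history per step and training
against per-step sequence targets.  The multi-step design (horizon L)
predicts the next L vectors jointly.  Each has its own loss tolerance
(0.05 stacked, 1 multi-step).
"""

from panelcast import (
    SyntheticConfig, TrainConfig, WindowSpec,
    evaluate_model, fit_design, generate_panel, preprocess_panel,
)
from panelcast.training import standardized_pairs

panel = generate_panel(SyntheticConfig(seed=7))
split, stats, _ = preprocess_panel(panel)

stacked_cfg = TrainConfig(epsilon=0.05, epochs=60, seed=7)
stacked = fit_design(split, stats, WindowSpec(T=2, S=3), stacked_cfg)
_, tp = standardized_pairs(split, stats, WindowSpec(T=2, S=3))
rep = evaluate_model(stacked.model, tp, stats)
print(f"stacked  (T=2, S=3): final train loss {stacked.final_train_loss:.4f}, "
      f"mean rel L1 {rep.aggregate['mean_rel_l1']:.4f}")

multi_cfg = TrainConfig(epsilon=1.0, epochs=60, seed=7)
multi = fit_design(split, stats, WindowSpec(T=1, L=3), multi_cfg)
_, tp = standardized_pairs(split, stats, WindowSpec(T=1, L=3))
pooled = evaluate_model(multi.model, tp, stats)
print(f"multistep (T=1, L=3): mean rel L1 pooled over horizons "
      f"{pooled.aggregate['mean_rel_l1']:.4f}")
for h, r in evaluate_model(multi.model, tp, stats, per_horizon=True).items():
    print(f"  horizon {h} ({h * 0.5:.1f} d ahead): mean rel L1 "
          f"{r.aggregate['mean_rel_l1']:.4f}")
# Error grows with the horizon: each extra half-day of lookahead compounds
# the uncertainty of the underlying dynamics.
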