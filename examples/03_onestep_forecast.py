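"""Train the one-step forecaster on a synthetic patient and evaluate it.

The model sees T=2 consecutive standardized 9-vectors and predicts the
next one (about 12 hours ahead on the 0.5-day grid).  Training follows the
tolerance-checkpoint protocol: every epoch whose training loss drops below
epsilon = 0.01 is snapshotted, and the snapshot with the best test loss is
kept.  Metrics are computed per index after mapping predictions back to
laboratory units.
"""

from panelcast import (
    SyntheticConfig, TrainConfig, WindowSpec,
    evaluate_model, fit_design, generate_panel, preprocess_panel,
)
from panelcast.training import standardized_pairs

panel = generate_panel(SyntheticConfig(seed=7))
split, stats, _ = preprocess_panel(panel)

cfg = TrainConfig(epsilon=0.01, epochs=120, seed=7)
result = fit_design(split, stats, WindowSpec(T=2), cfg)
print(f"tolerance reached at epoch {result.epochs_to_tolerance}; "
      f"selected checkpoint from epoch {result.selected_epoch} "
      f"({result.checkpoints_evaluated} evaluated)")

_, test_pairs = standardized_pairs(split, stats, WindowSpec(T=2))
report = evaluate_model(result.model, test_pairs, stats)
print(report.to_text())
# rel_l1 is the mean absolute error relative to the observed value (the
# MAPE); rel_linf its worst case; NSE = 1 means a perfect fit, 0 no better
# than predicting the training mean.
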