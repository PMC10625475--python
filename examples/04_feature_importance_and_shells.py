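"""Permutation feature importance and per-shell ablation on synthetic data.

Plants affinity signal in specific columns of a multi-shelled-style feature
table, then shows that permutation importance recovers the drivers and that
the ablation harness identifies the signal-bearing distance shell.
"""
import numpy as np
import pandas as pd

from msecif import (GBTConfig, per_shell_ablation, permutation_importance,
                    shell_scheme, train)

rng = np.random.default_rng(3)
scheme = shell_scheme(threshold=6.0, step=2.0)
bounds = [f"{b:g}" for b in scheme.bounds]
pairs = ["N;3;2;1;0-O;2;1;1;0", "C;4;3;1;0-C;4;1;3;0"]
columns = [f"{p}-{b}" for p in pairs for b in ("2.5", "4.5", "6.0")]
features = pd.DataFrame(rng.poisson(1.5, size=(300, 6)), columns=columns)

driver = "N;3;2;1;0-O;2;1;1;0-4.5"
pk = 1.4 * features[driver] + rng.normal(0, 0.4, 300)

config = GBTConfig(n_stages=150, max_depth=3, learning_rate=0.1,
                   subsample_fraction=1.0, max_features_rule="all", seed=0)
model = train(features, pk, config)

importance = permutation_importance(model, features, pk, n_repeats=30, seed=0)
print("permutation importance (mean score drop over 30 shuffles):")
print(importance.round(3).sort_values("importance_mean",
                                      ascending=False).to_string())
print(f"-> top feature is the planted driver: "
      f"{importance['importance_mean'].idxmax() == driver}")

ablation = per_shell_ablation(features, pk, scheme, config,
                              n_folds=3, n_trials=1)
print("\nper-shell ablation (CV metrics of models seeing one shell only):")
print(ablation.round(3).to_string())
print("-> the 4.5 A shell carries the signal, so its band scores highest")
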