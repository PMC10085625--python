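"""Why the zero-inflated layer matters when many patients are risk-free.

Generates two-status data (a latent at-risk indicator gates mortality),
fits the plain and zero-inflated models on a training half, and compares
their discrimination on the held-out half.
"""

import warnings

from hcam import ScenarioSpec, fit, generate, metrics, split_train_test

warnings.filterwarnings("ignore")

spec = ScenarioSpec(scenario="ZIB", H=80, n_h=30, theta=-2.0, seed=11)
data, truth = generate(spec)
train, test = split_train_test(data, truth["split_rng"])
print(f"event rate {data.y.mean():.3f} (excess zeros from the risk-free group)")

for model in ("hcam", "zib"):
    res = fit(train, model=model, K_grid=(0, 2), selection="aic")
    rep = metrics(truth, res, test=test, threshold=train.y.mean())
    print(f"{model:5s} held-out AUC={rep.auc:.3f} (95% CI {rep.auc_ci[0]:.3f}-"
          f"{rep.auc_ci[1]:.3f})  accuracy={rep.accuracy:.3f}  F1={rep.f1:.3f}")

print("\nThe zero-inflated model separates 'no risk of death' from 'at risk")
print("but survived', recovering the mortality coefficients and improving")
print("held-out discrimination when zeros are inflated.")
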