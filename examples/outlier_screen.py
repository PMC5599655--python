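"""Two-stage screening: jackknife Mahalanobis candidates, then hard rules.

A participant is excluded only when they are both statistically extreme
(leave-one-out Mahalanobis distance above the alpha-level control limit)
and in violation of a hard rule (seasonal delta-amplitude or task-timing
bound), or when an experimenter error was recorded."""

import numpy as np

from calmflow import jackknife_mahalanobis, jackknife_ucl

rng = np.random.default_rng(0)
features = rng.normal(size=(12, 3))   # 12 participants, 3 band features
features[4] += 8.0                    # one grossly deviant participant

report = jackknife_mahalanobis(features, alpha=0.05)
print(f"UCL at (n=12, p=3, alpha=0.05): {jackknife_ucl(12, 3):.2f}")
for line in report.log_lines():
    print(line)
# Distances are on the same scale as the control limit (~4 at n=12, p=3);
# only the planted participant should exceed it.
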