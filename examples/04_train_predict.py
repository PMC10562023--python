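"""Train the multi-branch CNN to predict GPR and evaluate it.

Uses a reduced-scale synthetic cohort (32 plans) with the standard 200-epoch
protocol on a single train/test split; the full study (96 plans, five seeds,
model comparison) is what the test suite and acceptance script run.
"""

import numpy as np
from scipy import stats

from vmatqa import TrainConfig, desk_scale_kwargs, generate_dataset, train_single_split

dataset = generate_dataset(32, **desk_scale_kwargs(seed=6))
measured, predicted, log = train_single_split(
    dataset, variant="model1", cfg=TrainConfig(epochs=200, seed=0)
)

print(f"trained on {dataset.n} plans; adopted epoch {log.best_epoch} "
      f"(val loss {log.val_loss[log.best_epoch]:.2e})")
i22 = 4  # 2%/2mm
mae = np.abs(measured[:, i22] - predicted[:, i22]).mean()
r = stats.pearsonr(measured[:, i22], predicted[:, i22]).statistic
print(f"held-out 2%/2mm: MAE = {mae:.2f}%  Pearson r = {r:+.2f}")
for m, p in zip(measured[:3, i22], predicted[:3, i22]):
    print(f"  measured {m:6.2f}%  predicted {p:6.2f}%")
# MAE says how far predictions sit from gamma-measured GPR; r says whether
# the model ranks hard plans below easy ones (the clinically useful part).
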