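"""Seeded random hyperparameter search over the study's ranges.

Samples network configurations (hidden units, dropout, L2, FC stack,
batch size, optimizer) from the documented grid and scores each by mean
5-fold validation accuracy on a small synthetic two-class problem.
"""

import numpy as np

from subtremor import (ModelConfig, SearchSpace, TrainConfig, holdout_split,
                       hyperparameter_search, make_folds,
                       recordings_to_dataset, train_cv)
from subtremor.simdata import generate_dataset

recordings = generate_dataset(n_per_class=12, seed=0)
dataset = recordings_to_dataset(recordings, labels=[1, 2])
trainval, _ = holdout_split(dataset, n_test_per_class=2, seed=0)
plan = make_folds(trainval, k=5, seed=0)


def objective(cfg: dict) -> float:
    model_cfg = ModelConfig(n_classes=2, hidden_units=cfg["hidden_units"],
                            fc_widths=cfg["fc_widths"], dropout=cfg["dropout"])
    train_cfg = TrainConfig(optimizer=cfg["optimizer"],
                            batch_size=cfg["batch_size"], l2=cfg["l2"],
                            max_epochs=10, patience=4, seed=0)
    return float(np.mean(train_cv(trainval, plan, model_cfg, train_cfg)["val_acc"]))


result = hyperparameter_search(SearchSpace(), objective, budget=3, seed=0)
for trial in result["trials"]:
    print(f"trial {trial['trial']}: score {trial['score']:.3f}  {trial['config']}")
print(f"best: {result['best']} (mean validation accuracy "
      f"{result['best_score']:.3f})")
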