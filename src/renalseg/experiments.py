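"""Self-contained, CPU-sized experiments used for acceptance checking.

These reproduce the training/evaluation protocol shape (80/20 split, cascade
of a coarse and a fine stage, HEC scoring) on synthetic cohorts small enough
to run in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .model import DualPathAttentionUNet, NetworkConfig
from .phantoms import generate_case, sample_cohort_specs
from .training import TrainConfig, evaluate_run, split_cases, train


def untrained_checkpoint(config: NetworkConfig, stats: dict, seed: int) -> dict:
    """A checkpoint-shaped dict around freshly initialized weights."""
    model = DualPathAttentionUNet(config, rng=np.random.default_rng(seed))
    return {"state": model.state_dict(), "config": config.to_dict(),
            "stats": stats, "k": config.in_channels, "stage": "untrained",
            "best_epoch": 0}


def run_scaled_experiment(seed: int = 123, n_cases: int = 20,
                          test_fraction: float = 0.2, epochs: int = 10,
                          steps_per_epoch: int = 25, depth: int = 3,
                          base_width: int = 8, k: int = 3,
                          block_type: str = "resconv",
                          compare_untrained: bool = True) -> dict:
    """Generate a cohort, train both cascade stages briefly, and score HECs.

    Returns a dict with the trained cascade's mean HEC metrics
    (``trained_mean``), the untrained-network baseline (``untrained_mean``,
    when requested), the split sizes and the epochs actually run.
    """
    specs = sample_cohort_specs(n_cases, seed=seed)
    cases = {f"case_{i:05d}": generate_case(s, case_id=f"case_{i:05d}")
             for i, s in enumerate(specs)}
    train_ids, test_ids = split_cases(sorted(cases), test_fraction, seed=seed)
    train_cases = [cases[c] for c in train_ids]
    test_cases = [cases[c] for c in test_ids]

    coarse_cfg = NetworkConfig(in_channels=k, num_classes=2, depth=depth,
                               base_width=base_width, block_type=block_type)
    fine_cfg = NetworkConfig(in_channels=k, num_classes=4, depth=depth,
                             base_width=base_width, block_type=block_type)
    coarse_tc = TrainConfig(max_epochs=epochs, patience=epochs, batch_size=4,
                            steps_per_epoch=steps_per_epoch, seed=seed)
    # the fine stage fights extreme class imbalance (lesions are a tiny voxel
    # fraction): give it more steps and a higher learning rate
    fine_tc = TrainConfig(max_epochs=epochs, patience=epochs, batch_size=4,
                          steps_per_epoch=int(steps_per_epoch * 1.6),
                          learning_rate=2e-3, seed=seed)
    coarse_ckpt, coarse_hist = train(coarse_cfg, train_cases, coarse_tc,
                                     stage="coarse")
    fine_ckpt, fine_hist = train(fine_cfg, train_cases, fine_tc, stage="fine")

    report = evaluate_run(coarse_ckpt, fine_ckpt, test_cases, "kits21")
    out = {
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "coarse_epochs": len(coarse_hist),
        "fine_epochs": len(fine_hist),
        "trained_mean": report.mean,
        "per_case": report.per_case,
    }
    if compare_untrained:
        u_coarse = untrained_checkpoint(coarse_cfg, coarse_ckpt["stats"], seed + 7)
        u_fine = untrained_checkpoint(fine_cfg, fine_ckpt["stats"], seed + 8)
        out["untrained_mean"] = evaluate_run(u_coarse, u_fine, test_cases,
                                             "kits21").mean
    return out
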