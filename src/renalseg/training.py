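"""Training loop for either cascade stage.

Defaults follow the reported schedule — up to 100 epochs with early stopping
after 30 consecutive epochs without improvement of the monitored metric
(mean foreground smoothed Dice) — scaled down per run config for CPU-sized
fixtures.  Loss is voxelwise cross-entropy + soft Dice, optimized with Adam.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from .cascade import (DEFAULT_MARGIN, NetworkPredictor, crop, extract_roi,
                      run_cascade)
from .metrics import DiceReport, dice_report, smoothed_dice
from .model import DualPathAttentionUNet, NetworkConfig
from .nn import tensor as T
from .slicing import make_stacks
from .volume_io import (DEFAULT_WINDOW, LabelVolume, NormalizationStats,
                        compute_cohort_foreground_stats, normalize)


@dataclass
class TrainConfig:
    max_epochs: int = 100
    patience: int = 30
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0
    loss_name: str = "ce_dice"
    monitor: str = "foreground_dice"
    val_fraction: float = 0.0        # 0 -> monitor on the training stacks
    steps_per_epoch: int | None = None
    foreground_ratio: float = 0.7    # fraction of samples with foreground centers
    class_weighting: bool = True     # tempered inverse-frequency CE weights
    min_delta: float = 1e-5
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.loss_name not in nn.LOSSES:
            raise ValueError(f"unknown loss {self.loss_name!r}")


def split_cases(case_ids, fraction: float, seed: int) -> tuple[list, list]:
    """Reproducible disjoint train/test split; test size = round(fraction*n)."""
    ids = list(case_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 cases to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = int(round(fraction * len(ids)))
    n_test = min(max(n_test, 1), len(ids) - 1)
    test = [ids[i] for i in sorted(order[:n_test])]
    train = [ids[i] for i in sorted(order[n_test:])]
    return train, test


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement.

    Improvement means exceeding the best value so far by at least
    ``min_delta``.  The first observed value initializes the best.
    """

    def __init__(self, patience: int, min_delta: float = 1e-5):
        self.patience = int(patience)
        self.min_delta = float(min_delta)
        self.best: float | None = None
        self.best_epoch = 0
        self.stale = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record an epoch's monitor value; return True to stop now."""
        if self.best is None or value > self.best + self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def run_schedule(monitor_fn, max_epochs: int, patience: int,
                 min_delta: float = 1e-5) -> tuple[int, int]:
    """Drive the stopping rule with ``monitor_fn(epoch) -> float``.

    Returns (epochs_run, best_epoch); epochs are 1-based.
    """
    stopper = EarlyStopping(patience, min_delta)
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        if stopper.update(float(monitor_fn(epoch)), epoch):
            break
    return epoch, stopper.best_epoch


# ---------------------------------------------------------------------------
# sample preparation

@dataclass
class StageSamples:
    """Flattened 2.5D training samples for one cascade stage.

    ``priority_idx`` holds the slices oversampled during training: slices
    containing the rarest class group — lesion labels (>= 2) when any exist,
    otherwise any foreground.  ``rest_idx`` is its complement.
    """

    stacks: np.ndarray        # (n, k, H, W) normalized intensities
    targets: np.ndarray       # (n, H, W) int
    stats: NormalizationStats
    foreground_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    priority_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    rest_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __post_init__(self):
        fg = np.array([t.any() for t in self.targets])
        lesion = np.array([(t >= 2).any() for t in self.targets])
        self.foreground_idx = np.nonzero(fg)[0]
        prio = lesion if lesion.any() else fg
        self.priority_idx = np.nonzero(prio)[0]
        self.rest_idx = np.nonzero(~prio)[0]


def _pad_to_shape(data: np.ndarray, target_h: int, target_w: int,
                  is_label: bool = False) -> np.ndarray:
    """Pad (trailing) the in-plane extent; edge values for intensities,
    background zeros for labels."""
    _, h, w = data.shape
    ph, pw = target_h - h, target_w - w
    if not (ph or pw):
        return data
    mode = "constant" if is_label else "edge"
    return np.pad(data, ((0, 0), (0, ph), (0, pw)), mode=mode)


def prepare_stage_samples(cases, stage: str, k: int, net_config: NetworkConfig,
                          window=DEFAULT_WINDOW, margin=DEFAULT_MARGIN,
                          stats: NormalizationStats | None = None) -> StageSamples:
    """Build normalized stacks/targets for ``stage`` in {"coarse", "fine"}.

    Coarse: whole slices, labels collapsed to kidney-vs-background.
    Fine: ground-truth-derived ROI crops at native labels, padded to the
    network's downsampling divisor.
    """
    if stage not in ("coarse", "fine"):
        raise ValueError(f"stage must be 'coarse' or 'fine', got {stage!r}")
    if stats is None:
        stats = compute_cohort_foreground_stats(cases, window=window)
    div = net_config.divisor
    prepared = []
    for volume, label in cases:
        vol = normalize(volume, stats)
        lab = label
        if stage == "coarse":
            binary = (label.data > 0).astype(np.int16)
            lab = LabelVolume(binary, vocabulary=label.vocabulary,
                              spacing=label.spacing, affine=label.affine,
                              case_id=label.case_id)
        else:
            box = extract_roi(label.data, margin=margin)
            vol = crop(vol, box)
            lab = crop(label, box)
        prepared.append((vol, lab))
    # fine-stage crops differ per case: pad everything to one common,
    # divisor-aligned in-plane extent so samples can be batched together
    target_h = max(v.data.shape[1] for v, _ in prepared)
    target_w = max(v.data.shape[2] for v, _ in prepared)
    target_h += (-target_h) % div
    target_w += (-target_w) % div
    all_stacks: list[np.ndarray] = []
    all_targets: list[np.ndarray] = []
    for vol, lab in prepared:
        vol = replace(vol, data=_pad_to_shape(vol.data, target_h, target_w))
        lab = replace(lab, data=_pad_to_shape(lab.data, target_h, target_w,
                                              is_label=True))
        for stack, target in make_stacks(vol, lab, k=k):
            all_stacks.append(stack.channels)
            all_targets.append(target.mask)
    return StageSamples(stacks=np.stack(all_stacks),
                        targets=np.stack(all_targets).astype(np.int64),
                        stats=stats)


def _sample_batch(samples: StageSamples, batch_size: int, fg_ratio: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_prio = int(round(batch_size * fg_ratio))
    idx = []
    if samples.priority_idx.size:
        idx.append(rng.choice(samples.priority_idx, size=min(n_prio, batch_size)))
    n_rest = batch_size - sum(len(i) for i in idx)
    if n_rest > 0:
        pool = samples.rest_idx if samples.rest_idx.size else \
            np.arange(len(samples.targets))
        idx.append(rng.choice(pool, size=n_rest))
    sel = np.concatenate(idx)
    return samples.stacks[sel], samples.targets[sel]


def _monitor_foreground_dice(model: DualPathAttentionUNet,
                             samples: StageSamples, max_slices: int = 32,
                             batch_size: int = 8) -> float:
    """Mean per-foreground-class smoothed Dice over a capped slice sample.

    Pooled over the monitored slices; averaged across the foreground classes
    actually present so lesion classes weigh as much as the organ class.
    """
    idx = samples.priority_idx if samples.priority_idx.size \
        else np.arange(min(len(samples.targets), max_slices))
    if idx.size > max_slices:
        idx = idx[np.linspace(0, idx.size - 1, max_slices).astype(int)]
    preds = []
    for i in range(0, idx.size, batch_size):
        sel = idx[i:i + batch_size]
        preds.append(model.predict_batch(samples.stacks[sel]))
    pred = np.concatenate(preds)
    targ = samples.targets[idx]
    scores = []
    for c in range(1, model.config.num_classes):
        if (targ == c).any():
            scores.append(smoothed_dice(pred == c, targ == c))
    if not scores:  # all-background monitor set
        scores.append(smoothed_dice(pred > 0, targ > 0))
    return float(np.mean(scores))


class DivergenceError(RuntimeError):
    pass


def train(net_config: NetworkConfig, cases, tc: TrainConfig, stage: str = "coarse",
          margin=DEFAULT_MARGIN, samples: StageSamples | None = None
          ) -> tuple[dict, list[dict]]:
    """Train one cascade stage; returns (checkpoint, history).

    The checkpoint dict holds the best-epoch weights, the network config, the
    frozen normalization stats and the stage/k metadata; ``history`` has one
    row per epoch with loss and monitor values.
    """
    if not cases and samples is None:
        raise ValueError("need at least one training case")
    rng = np.random.default_rng(tc.seed)
    if samples is None:
        samples = prepare_stage_samples(cases, stage, k=net_config.in_channels,
                                        net_config=net_config, window=tc.window,
                                        margin=margin)
    model = DualPathAttentionUNet(net_config, rng=np.random.default_rng(tc.seed + 1))
    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    loss_fn = nn.LOSSES[tc.loss_name]
    weights = None
    if tc.class_weighting and tc.loss_name in ("ce", "ce_dice"):
        weights = nn.balanced_class_weights(samples.targets, net_config.num_classes)
    n = len(samples.targets)
    steps = tc.steps_per_epoch or max(1, int(np.ceil(n / tc.batch_size)))
    stopper = EarlyStopping(tc.patience, tc.min_delta)
    history: list[dict] = []
    best_state = model.state_dict()
    for epoch in range(1, tc.max_epochs + 1):
        model.train()
        epoch_loss = 0.0
        for _ in range(steps):
            xb, yb = _sample_batch(samples, tc.batch_size, tc.foreground_ratio, rng)
            opt.zero_grad()
            if weights is None:
                loss = loss_fn(model(T.Tensor(xb)), yb)
            else:
                loss = loss_fn(model(T.Tensor(xb)), yb, class_weights=weights)
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)!r}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        monitor = _monitor_foreground_dice(model, samples)
        history.append({"epoch": epoch, "loss": epoch_loss / steps,
                        "monitor": monitor,
                        "stale_epochs": stopper.stale})
        stop = stopper.update(monitor, epoch)
        if stopper.best_epoch == epoch:  # set only when this epoch improved
            best_state = model.state_dict()
        if stop:
            break
    checkpoint = {
        "state": best_state,
        "config": net_config.to_dict(),
        "stats": asdict(samples.stats),
        "stage": stage,
        "k": net_config.in_channels,
        "best_epoch": stopper.best_epoch,
    }
    return checkpoint, history


# ---------------------------------------------------------------------------
# checkpoint (de)serialization: single .npz with JSON metadata embedded

def save_checkpoint(checkpoint: dict, path: str) -> None:
    meta = {k: v for k, v in checkpoint.items() if k != "state"}
    arrays = {f"param/{name}": arr for name, arr in checkpoint["state"].items()}
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> dict:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        state = {name[len("param/"):]: data[name]
                 for name in data.files if name.startswith("param/")}
    meta["state"] = state
    return meta


def predictor_from_checkpoint(checkpoint: dict, vocabulary: str,
                              batch_size: int = 8) -> NetworkPredictor:
    config = NetworkConfig.from_dict(checkpoint["config"])
    model = DualPathAttentionUNet(config)
    model.load_state_dict(checkpoint["state"])
    model.eval()
    stats = NormalizationStats(**checkpoint["stats"])
    return NetworkPredictor(model, stats, k=checkpoint["k"],
                            vocabulary=vocabulary, batch_size=batch_size)


def evaluate_run(coarse_ckpt: dict, fine_ckpt: dict, test_cases, vocabulary: str,
                 margin=DEFAULT_MARGIN, tolerance: float = 2.0,
                 coarse_predictor=None, fine_predictor=None) -> DiceReport:
    """Run the cascade on every test case and score all HECs.

    Oracle predictors may be passed explicitly (for plumbing tests); otherwise
    they are rebuilt from the checkpoints.
    """
    if coarse_predictor is None:
        coarse_predictor = predictor_from_checkpoint(coarse_ckpt, vocabulary)
    if fine_predictor is None:
        fine_predictor = predictor_from_checkpoint(fine_ckpt, vocabulary)
    scored = {}
    for i, (volume, label) in enumerate(test_cases):
        case_id = volume.case_id or f"case_{i:05d}"
        pred, _ = run_cascade(volume, coarse_predictor, fine_predictor, margin=margin)
        scored[case_id] = (label, pred)
    return dice_report(scored, vocabulary=vocabulary, tolerance=tolerance)
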