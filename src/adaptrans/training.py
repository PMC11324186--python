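"""Fitting protocol: MSE loss, adaptive-moment optimization, early stopping,
clip-level data splits, cross-validation, and teacher-parameter recovery.

The protocol mirrors standard practice for these encoding models: constant
learning rate 1e-3, batch size 1 (small sets) or 16 (large sets), no explicit
regularization (weight decay 0), validation after every epoch with the best
checkpoint kept, and stopping after 50 epochs without validation improvement.
Filter parameters (w, a_on, a_off), when present, are optimized jointly with
the backbone by the same gradient steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from ._autodiff import AdamW, Tensor
from .metrics import evaluate_predictions, psth

__all__ = [
    "FitProtocol",
    "SplitSpec",
    "FitResult",
    "split_clips",
    "fit",
    "cross_validate",
    "recover_parameters",
]


@dataclass
class FitProtocol:
    """Optimization hyperparameters."""

    learning_rate: float = 1e-3
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 0.0
    batch_size: int = 1
    patience: int = 50
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class SplitSpec:
    """Clip-level split specification.

    Either fractional (train/val/test fractions; floor rounding for val and
    test, remainder to train) or explicit fixed clip-id lists.
    """

    train: float = 0.70
    val: float = 0.10
    test: float = 0.20
    fixed_test_ids: list | None = None
    val_fraction_of_trainval: float = 0.20
    n_repeats: int = 10

    def __post_init__(self):
        if self.fixed_test_ids is None and abs(self.train + self.val + self.test - 1) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_clips(recording_set, spec: SplitSpec, seed: int):
    """Disjoint, exhaustive clip-level partition, deterministic given seed.

    Fractional mode shuffles clips and assigns floor(val), floor(test) clips
    to validation/test and the remainder to training.  Fixed-list mode pins
    the test clips and splits the rest into train/val.
    """
    clips = list(recording_set)
    rng = np.random.default_rng(seed)
    if spec.fixed_test_ids is not None:
        test = [c for c in clips if c.clip_id in set(spec.fixed_test_ids)]
        rest = [c for c in clips if c.clip_id not in set(spec.fixed_test_ids)]
        if len(test) != len(spec.fixed_test_ids):
            raise ValueError("fixed test ids not all present in the recording set")
        order = rng.permutation(len(rest))
        n_val = int(np.floor(spec.val_fraction_of_trainval * len(rest)))
        val = [rest[i] for i in order[:n_val]]
        train = [rest[i] for i in order[n_val:]]
        return train, val, test
    if len(clips) < 3:
        raise ValueError("need at least 3 clips for a fractional split")
    order = rng.permutation(len(clips))
    # floor rounding, remainder to train — but never an empty val/test set
    n_val = max(int(np.floor(spec.val * len(clips))), 1)
    n_test = max(int(np.floor(spec.test * len(clips))), 1)
    val = [clips[i] for i in order[:n_val]]
    test = [clips[i] for i in order[n_val:n_val + n_test]]
    train = [clips[i] for i in order[n_val + n_test:]]
    return train, val, test


@dataclass
class FitResult:
    """Best checkpoint plus training history."""

    model: object
    best_val_loss: float
    best_epoch: int
    n_epochs: int
    history: list = field(default_factory=list)  # (epoch, train_loss, val_loss, saved)

    def history_jsonl(self, path):
        import json

        with open(path, "w") as fh:
            for epoch, tr, va, saved in self.history:
                fh.write(json.dumps({"epoch": epoch, "train_loss": tr,
                                     "val_loss": va, "checkpoint": saved}) + "\n")


def _targets(clips, n_outputs):
    """Per-clip training targets: PSTH, tiled across output units."""
    out = []
    for c in clips:
        r = psth(c.trials)
        out.append(np.tile(r, (n_outputs, 1)))
    return out


def _clip_loss(model, clip, target, training):
    pred = model.forward(clip.stimulus, training=training)
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def _validation_loss(model, clips, targets):
    """Per-bin mean squared error over the concatenated validation bins."""
    total, n = 0.0, 0
    for clip, target in zip(clips, targets):
        pred = model.forward(clip.stimulus, training=False).data
        total += float(((pred - target) ** 2).sum())
        n += target.size
    return total / n


def fit(model, protocol: FitProtocol, train_clips, val_clips,
        verbose=False) -> FitResult:
    """Gradient fitting with per-epoch validation and early stopping.

    Every epoch performs MSE gradient steps over the training clips (batched
    by gradient accumulation); the model with the lowest validation loss so
    far is checkpointed, and fitting stops after ``patience`` epochs without
    improvement (or at ``max_epochs``).  The returned model carries the best
    checkpoint.
    """
    if not train_clips or not val_clips:
        raise ValueError("need non-empty training and validation sets")
    N = model.config.n_outputs
    train_targets = _targets(train_clips, N)
    val_targets = _targets(val_clips, N)
    params = model.parameters()
    opt = AdamW(params, lr=protocol.learning_rate, betas=protocol.betas,
                weight_decay=protocol.weight_decay)
    rng = np.random.default_rng(protocol.seed)
    best_val = np.inf
    best_state = model.clone_state()
    best_epoch = 0
    history = []
    epochs_since_best = 0
    for epoch in range(1, protocol.max_epochs + 1):
        order = rng.permutation(len(train_clips))
        epoch_loss = 0.0
        for start in range(0, len(order), protocol.batch_size):
            batch = order[start:start + protocol.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for i in batch:
                loss = _clip_loss(model, train_clips[i], train_targets[i],
                                  training=True)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, clip "
                        f"{train_clips[i].clip_id}: {loss.data}")
                # scale so the accumulated gradient is the batch-mean gradient
                loss.backward(np.full_like(loss.data, 1.0 / len(batch)))
                batch_loss += float(loss.data)
            opt.step()
            epoch_loss += batch_loss
        epoch_loss /= len(order)
        val_loss = _validation_loss(model, val_clips, val_targets)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        saved = val_loss < best_val
        if saved:
            best_val = val_loss
            best_state = model.clone_state()
            best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        history.append((epoch, epoch_loss, val_loss, saved))
        if verbose and (epoch % 25 == 0 or saved):
            print(f"epoch {epoch:4d}  train {epoch_loss:.3e}  val {val_loss:.3e}"
                  f"{'  *' if saved else ''}")
        if epochs_since_best >= protocol.patience:
            break
    model.load_state_arrays(best_state)
    return FitResult(model=model, best_val_loss=best_val, best_epoch=best_epoch,
                     n_epochs=len(history), history=history)


def evaluate(model, clips) -> dict:
    """Scalar metrics of a fitted model on a clip set (concatenated bins)."""
    preds = []
    for c in clips:
        p = model.predict(c.stimulus)
        preds.append(p if p.ndim == 1 else p[0])
    return evaluate_predictions(clips, preds)


def cross_validate(recording_set, config, protocol: FitProtocol,
                   split_spec: SplitSpec, model_factory=None) -> dict:
    """Fit once per split re-randomization and average the test metrics.

    Returns per-split records plus a mean record.  ``model_factory`` may be
    supplied to customize construction (defaults to ``build_model``).
    """
    from .models import build_model

    factory = model_factory or build_model
    records = []
    for i in range(split_spec.n_repeats):
        seed = protocol.seed + i
        train, val, test = split_clips(recording_set, split_spec, seed)
        model = factory(config, rng=seed)
        proto = FitProtocol(learning_rate=protocol.learning_rate,
                            betas=protocol.betas,
                            weight_decay=protocol.weight_decay,
                            batch_size=protocol.batch_size,
                            patience=protocol.patience,
                            max_epochs=protocol.max_epochs, seed=seed)
        try:
            result = fit(model, proto, train, val)
        except RuntimeError as err:
            raise RuntimeError(f"fit failed on split {i}: {err}") from err
        rec = evaluate(result.model, test)
        rec["split"] = i
        records.append(rec)
    mean = {k: float(np.nanmean([r[k] for r in records]))
            for k in ("cc_raw", "cc_norm", "cc_max")}
    return {"splits": records, "mean": mean}


def recover_parameters(teacher_spec, model) -> dict:
    """Compare fitted filter parameters against a teacher's ground truth.

    Reports per-band |w_hat - w|, their median, and rank correlations between
    fitted and true time constants for both polarities.
    """
    layer = getattr(model, "prefilter_layer", None)
    if layer is None:
        raise ValueError("model was not fitted with a learnable paired prefilter")
    fitted = layer.current_params
    true = teacher_spec.params
    w_err = np.abs(fitted.w - true.w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant sequences -> NaN rho
        rho_on = spearmanr(fitted.tau_on, true.tau_on).statistic
        rho_off = spearmanr(fitted.tau_off, true.tau_off).statistic
        rho_w = spearmanr(fitted.w, true.w).statistic
    return {
        "w_abs_error": w_err,
        "w_median_abs_error": float(np.median(w_err)),
        "w_rank_correlation": float(rho_w),
        "tau_on_rank_correlation": float(rho_on),
        "tau_off_rank_correlation": float(rho_off),
        "fitted": fitted,
        "true": true,
    }
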