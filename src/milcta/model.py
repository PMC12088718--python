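"""Attention-based multi-instance learning classifier.

A patient's CMR slices are grouped into bags of 36 processed slices; the bag
inherits the patient's weak binary label (stenosis ≥50% in the artery).  Each
slice is embedded by a shared convolutional encoder, the in-bag position is
injected with sinusoidal positional encoding, one multi-head self-attention
block contextualizes the instances, and gated attention pooling produces a
bag probability together with per-slice attention scores that sum to one.
Patient-level probability is the maximum over the patient's bag
probabilities; per-case attention is renormalized over original slices.

:class:`MILAttentionClassifier` follows the sklearn estimator contract
(``fit``/``predict_proba``/``get_params``), treating one bag as one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import Adam, MILNet, bce_with_logits, sinusoidal_positional_encoding
from .cohort import Bag


class ConfigurationError(ValueError):
    """Raised for invalid model/training configuration."""


@dataclass
class BagArray:
    """A bag materialized to pixels: the unit sample the model consumes."""

    patient_id: str
    bag_index: int
    x: np.ndarray  # (bag_size, H, W) float32 in [0, 1]
    label: int
    entries: list = field(default_factory=list)
    replicated_flags: list = field(default_factory=list)


@dataclass
class BagPrediction:
    bag_prob: float
    attention: np.ndarray  # (bag_size,) non-negative, sums to 1

    def __post_init__(self) -> None:
        self.attention = np.asarray(self.attention, dtype=float)
        if not (0.0 <= self.bag_prob <= 1.0):
            raise ValueError("bag_prob must lie in [0, 1]")
        if abs(self.attention.sum() - 1.0) > 1e-5 or (self.attention < -1e-9).any():
            raise ValueError("attention must be non-negative and sum to 1")


@dataclass
class CasePrediction:
    patient_id: str
    patient_prob: float
    slice_ids: list
    case_attention: np.ndarray  # over original slices, sums to 1
    contributing_bag_index: int
    bag_predictions: list[BagPrediction] = field(default_factory=list)


def materialize_bags(bags: list[Bag], slice_arrays: dict) -> list[BagArray]:
    """Resolve bag slice references against a slice_id → array mapping."""
    out = []
    for bag in bags:
        x = np.stack([np.asarray(slice_arrays[sid], dtype=np.float32) for sid in bag.entries])
        out.append(
            BagArray(
                patient_id=bag.patient_id,
                bag_index=bag.bag_index,
                x=x,
                label=bag.label,
                entries=list(bag.entries),
                replicated_flags=list(bag.replicated_flags),
            )
        )
    return out


def compute_class_weights(labels) -> dict[int, float]:
    """Balanced inverse-frequency weights w_c = N / (2·N_c)."""
    y = np.asarray(labels, dtype=int)
    n = len(y)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == n:
        raise ValueError("class weighting requires both classes present")
    return {0: n / (2.0 * (n - n_pos)), 1: n / (2.0 * n_pos)}


def add_positional_encoding(features: np.ndarray, mode: str = "sinusoidal") -> np.ndarray:
    """Add the sinusoidal position signal to (N, D) or (B, N, D) features."""
    if mode == "none":
        return np.asarray(features)
    if mode != "sinusoidal":
        raise ConfigurationError(f"unknown positional encoding {mode!r}")
    feats = np.asarray(features)
    n, d = feats.shape[-2], feats.shape[-1]
    return feats + sinusoidal_positional_encoding(n, d)


def augment_bag(
    x: np.ndarray,
    zoom_range: float = 0.1,
    shift_range: float = 0.1,
    rng: np.random.Generator | None = None,
    rotation_range: float = 0.0,
) -> np.ndarray:
    """Per-slice random zoom and shift, zero-filled; slice order is preserved.

    Rotation is deliberately unsupported: it would scramble what the
    positional encoding represents.  Requesting it is a hard error.
    """
    if rotation_range != 0.0:
        raise ConfigurationError("rotation augmentation is not supported (positional encoding)")
    if zoom_range == 0.0 and shift_range == 0.0:
        return np.asarray(x)
    rng = rng or np.random.default_rng()
    x = np.asarray(x)
    out = np.empty_like(x)
    n, h, w = x.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    for i in range(n):
        z = rng.uniform(1.0 - zoom_range, 1.0 + zoom_range) if zoom_range > 0 else 1.0
        shift = (
            rng.uniform(-shift_range, shift_range, size=2) * np.array([h, w]) if shift_range > 0 else np.zeros(2)
        )
        matrix = np.array([[1.0 / z, 0.0], [0.0, 1.0 / z]])
        offset = center - center / z - shift / z
        out[i] = ndimage.affine_transform(x[i], matrix, offset=offset, order=1, mode="constant", cval=0.0)
    return out


class MILAttentionClassifier(ClassifierMixin, BaseEstimator):
    """Weakly supervised bag classifier with interpretable attention.

    Samples are bags of ``bag_size`` slices; ``fit`` accepts either a list of
    :class:`BagArray` (labels and patient identity carried along) or a raw
    array of shape (n_bags, bag_size, H, W) with a label vector ``y``.
    Training uses class-weighted binary cross-entropy, ADAM, learning-rate
    reduction on validation plateau and early stopping with best-weight
    restoration, mirroring the reference training protocol.

    Parameters follow the published configuration where one was stated
    (four attention heads, dropout 0.2, L2 1e-4, lr 1e-4, patience 7,
    plateau factor 0.2 / patience 5, zoom/shift-only augmentation).
    """

    def __init__(
        self,
        backbone: str = "small_cnn",
        embed_dim: int = 128,
        n_heads: int = 4,
        attn_dim: int = 64,
        dropout: float = 0.2,
        context_dropout: float = 0.5,
        l2: float = 1e-4,
        frozen_layers: int | None = None,
        bag_size: int = 36,
        positional_encoding: str = "sinusoidal",
        gated_pool: bool = True,
        small_cnn_channels: tuple = (8, 16, 32, 64),
        vgg_width_scale: float = 1.0,
        lr: float = 1e-4,
        max_epochs: int = 30,
        batch_bags: int = 8,
        early_stop_patience: int = 7,
        plateau_factor: float = 0.2,
        plateau_patience: int = 5,
        min_delta: float = 0.0,
        class_weighting: bool = True,
        pretrain: str = "shapes",
        pretrain_images: int = 2000,
        pretrain_epochs: int = 6,
        pretrain_lr: float = 3e-3,
        augment: bool = True,
        zoom_range: float = 0.1,
        shift_range: float = 0.1,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.backbone = backbone
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.attn_dim = attn_dim
        self.dropout = dropout
        self.context_dropout = context_dropout
        self.l2 = l2
        self.frozen_layers = frozen_layers
        self.bag_size = bag_size
        self.positional_encoding = positional_encoding
        self.gated_pool = gated_pool
        self.small_cnn_channels = small_cnn_channels
        self.vgg_width_scale = vgg_width_scale
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_bags = batch_bags
        self.early_stop_patience = early_stop_patience
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.min_delta = min_delta
        self.class_weighting = class_weighting
        self.pretrain = pretrain
        self.pretrain_images = pretrain_images
        self.pretrain_epochs = pretrain_epochs
        self.pretrain_lr = pretrain_lr
        self.augment = augment
        self.zoom_range = zoom_range
        self.shift_range = shift_range
        self.random_state = random_state
        self.verbose = verbose

    # -- input plumbing ----------------------------------------------------
    @staticmethod
    def _coerce(X, y=None):
        """Return (stack (n,36,H,W), labels, patient_ids or None)."""
        if len(X) == 0:
            raise ValueError("no bags provided")
        if isinstance(X[0], BagArray):
            stack = np.stack([b.x for b in X]).astype(np.float32)
            labels = np.array([b.label for b in X], dtype=int) if y is None else np.asarray(y, dtype=int)
            pids = [b.patient_id for b in X]
            return stack, labels, pids
        stack = np.asarray(X, dtype=np.float32)
        if stack.ndim == 3:
            stack = stack[None]
        labels = None if y is None else np.asarray(y, dtype=int)
        return stack, labels, None

    def _validate_config(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} must be divisible by n_heads {self.n_heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.positional_encoding not in ("sinusoidal", "none"):
            raise ConfigurationError("positional_encoding must be 'sinusoidal' or 'none'")

    def _build_net(self, input_size, rng) -> MILNet:
        frozen = self.frozen_layers
        if frozen is None:
            frozen = 15 if self.backbone == "vgg16_style" else 0
        return MILNet(
            backbone=self.backbone,
            input_size=input_size,
            bag_size=self.bag_size,
            embed_dim=self.embed_dim,
            n_heads=self.n_heads,
            attn_dim=self.attn_dim,
            dropout=self.dropout,
            positional_encoding=self.positional_encoding,
            rng=rng,
            frozen_layers=frozen,
            small_cnn_channels=tuple(self.small_cnn_channels),
            vgg_width_scale=self.vgg_width_scale,
            gated_pool=self.gated_pool,
            context_dropout=self.context_dropout,
        )

    # -- training ----------------------------------------------------------
    def fit(self, X, y=None, X_val=None, y_val=None):
        """Train on bags; early stopping needs a validation set.

        When both sides carry patient identity, overlapping patients between
        training and validation raise a leakage error.
        """
        self._validate_config()
        Xs, ys, pids = self._coerce(X, y)
        if ys is None:
            raise ValueError("labels are required to fit")
        val = None
        if X_val is not None:
            Xv, yv, pids_v = self._coerce(X_val, y_val)
            if yv is None:
                raise ValueError("validation labels are required")
            if pids is not None and pids_v is not None:
                overlap = set(pids) & set(pids_v)
                if overlap:
                    raise ValueError(f"patient leakage between train and val: {sorted(overlap)[:5]}")
            val = (Xv, yv)

        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(0, 2**31 - 1, 5)
        init_rng, shuffle_rng, aug_rng, drop_rng, pre_rng = [np.random.default_rng(s) for s in seeds]
        self.net_ = self._build_net(Xs.shape[-2:], init_rng)
        if self.pretrain == "shapes" and self.backbone == "small_cnn":
            from .pretraining import pretrain_encoder

            self.pretext_losses_ = pretrain_encoder(
                self.net_.encoder,
                embed_dim=self.embed_dim,
                input_size=tuple(Xs.shape[-2:]),
                rng=pre_rng,
                n_images=self.pretrain_images,
                epochs=self.pretrain_epochs,
                lr=self.pretrain_lr,
                l2=self.l2,
            )
        elif self.pretrain not in ("shapes", "none"):
            raise ConfigurationError("pretrain must be 'shapes' or 'none'")
        opt = Adam(self.net_.parameters(), lr=self.lr, l2=self.l2)

        if self.class_weighting:
            cw = compute_class_weights(ys)
            sample_w = np.array([cw[int(t)] for t in ys])
        else:
            sample_w = np.ones(len(ys))

        history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
        best_val, best_state = np.inf, None
        plateau_counter = stop_counter = 0
        n = len(Xs)
        for epoch in range(1, self.max_epochs + 1):
            order = shuffle_rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, self.batch_bags):
                idx = order[start : start + self.batch_bags]
                xb = Xs[idx]
                if self.augment and (self.zoom_range > 0 or self.shift_range > 0):
                    xb = np.stack(
                        [augment_bag(b, self.zoom_range, self.shift_range, rng=aug_rng) for b in xb]
                    )
                logits, _ = self.net_.forward(xb, train=True, rng=drop_rng)
                loss = bce_with_logits(logits, ys[idx], sample_w[idx])
                self.net_.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                weights.append(len(idx))
            train_loss = float(np.average(losses, weights=weights))
            val_loss = self._eval_loss(*val) if val is not None else np.nan
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            history["lr"].append(opt.lr)
            if self.verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}  lr {opt.lr:.2e}")
            if val is not None:
                if val_loss < best_val - self.min_delta:
                    best_val = val_loss
                    best_state = self.net_.state_arrays()
                    plateau_counter = stop_counter = 0
                else:
                    plateau_counter += 1
                    stop_counter += 1
                    if plateau_counter >= self.plateau_patience:
                        opt.lr *= self.plateau_factor
                        plateau_counter = 0
                    if stop_counter >= self.early_stop_patience:
                        break
        if best_state is not None:
            self.net_.load_state_arrays(best_state)
        self.history_ = history
        self.classes_ = np.array([0, 1])
        self.n_epochs_ = len(history["epoch"])
        return self

    def _eval_loss(self, Xv: np.ndarray, yv: np.ndarray) -> float:
        losses, weights = [], []
        for start in range(0, len(Xv), self.batch_bags):
            xb = Xv[start : start + self.batch_bags]
            logits, _ = self.net_.forward(xb, train=False)
            loss = bce_with_logits(logits, yv[start : start + self.batch_bags])
            losses.append(float(loss.data))
            weights.append(len(xb))
        return float(np.average(losses, weights=weights))

    # -- inference ---------------------------------------------------------
    def _forward_eval(self, stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        probs, attns = [], []
        for start in range(0, len(stack), max(1, self.batch_bags)):
            logits, attn = self.net_.forward(stack[start : start + self.batch_bags], train=False)
            probs.append(1.0 / (1.0 + np.exp(-logits.data)))
            attns.append(attn.data)
        return np.concatenate(probs), np.concatenate(attns)

    def predict_bag(self, bag) -> BagPrediction:
        """Probability and attention scores for one bag."""
        stack, _, _ = self._coerce([bag] if isinstance(bag, BagArray) else bag)
        probs, attns = self._forward_eval(stack)
        return BagPrediction(bag_prob=float(probs[0]), attention=attns[0])

    def predict_proba(self, X) -> np.ndarray:
        stack, _, _ = self._coerce(X)
        probs, _ = self._forward_eval(stack)
        return np.column_stack([1.0 - probs, probs])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_patient(self, bags: list[BagArray]) -> CasePrediction:
        """Patient-level prediction: max over bag probabilities.

        Case attention assigns each original slice the maximum attention it
        received over all its occurrences (replicated entries included), then
        renormalizes to sum to one — replication never inflates a slice.
        """
        if not bags:
            raise ValueError("predict_patient requires at least one bag")
        pid = bags[0].patient_id
        stack = np.stack([b.x for b in bags]).astype(np.float32)
        probs, attns = self._forward_eval(stack)
        best = int(np.argmax(probs))
        slice_scores: dict = {}
        for bag, attn in zip(bags, attns):
            for sid, a in zip(bag.entries, attn):
                slice_scores[sid] = max(slice_scores.get(sid, 0.0), float(a))
        slice_ids = sorted(slice_scores)
        scores = np.array([slice_scores[s] for s in slice_ids], dtype=float)
        total = scores.sum()
        scores = scores / total if total > 0 else np.full(len(scores), 1.0 / len(scores))
        bag_preds = [BagPrediction(float(p), a) for p, a in zip(probs, attns)]
        return CasePrediction(
            patient_id=pid,
            patient_prob=float(probs.max()),
            slice_ids=slice_ids,
            case_attention=scores,
            contributing_bag_index=bags[best].bag_index,
            bag_predictions=bag_preds,
        )

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Write a single-file checkpoint: estimator params, training
        history and all network parameter arrays."""
        import json

        if not hasattr(self, "net_"):
            raise ValueError("cannot save an unfitted model")
        arrays = {f"param_{i}": a for i, a in enumerate(self.net_.state_arrays())}
        meta = {
            "params": self.get_params(),
            "history": getattr(self, "history_", {}),
            "input_size": list(self.net_.input_size),
        }
        np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "MILAttentionClassifier":
        """Restore a checkpoint written by :meth:`save`."""
        import json

        archive = np.load(path)
        meta = json.loads(archive["__meta__"].tobytes().decode())
        params = meta["params"]
        for key in ("small_cnn_channels", "windows"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        clf = cls(**params)
        clf._validate_config()
        clf.net_ = clf._build_net(tuple(meta["input_size"]), np.random.default_rng(0))
        n = len([k for k in archive.files if k.startswith("param_")])
        clf.net_.load_state_arrays([archive[f"param_{i}"] for i in range(n)])
        clf.history_ = meta["history"]
        clf.classes_ = np.array([0, 1])
        clf.n_epochs_ = len(clf.history_.get("epoch", []))
        return clf
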