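"""Temporally convolved feed-forward velocity decoder with ReFIT retraining.

The decoder maps a window of the three most recent 50-ms spike-band-power
bins across all channels to instantaneous finger-group velocities:

* a time-feature layer contracts the 3 bins into 16 learned features per
  channel, with weights shared across channels (a length-3 temporal
  convolution);
* the flattened features pass through four fully connected layers, with a
  ReLU after every layer except the last, and batch normalization plus 50%
  dropout regularizing each intermediate output;
* the final linear layer has no bias and the final batch normalization is
  variance-only (it never subtracts a mean and has no bias parameter), so
  the network cannot cheaply produce a velocity offset -- any non-zero
  output mean must be earned by the preceding blocks and is penalized by
  the MSE loss during training.

The raw output is z-scored with empirical statistics computed on the
training set and multiplied by a per-DOF gain (plus a global speed scale)
to obtain velocities in ROM-units/s.  Supervised training minimizes MSE
with Adam from a Kaiming initialization.  After a closed-loop block, ReFIT
retraining relabels each decoded velocity by assuming the user always
intended motion toward the target: magnitudes are kept, signs are flipped
on away-from-target bins, and bins already inside the target are labeled
zero; the network is then updated for 500 Adam iterations at lr 1e-4 with
weight decay 1e-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._nn import Adam, BatchNorm, Dropout, Linear, ReLU, TemporalConv, mse_loss_and_grad

__all__ = [
    "DecoderConfig",
    "TrainingSet",
    "Decoder",
    "refit_relabel",
]

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class DecoderConfig:
    """Architecture and output-scaling hyperparameters.

    ``hidden_widths`` are the widths of the four fully connected layers; the
    last entry must equal ``dof``.  ``n_time_bins`` is fixed at 3 by the
    input contract (three most-recent 50-ms bins).
    """

    n_channels: int
    dof: int
    n_time_bins: int = 3
    n_time_features: int = 16
    hidden_widths: tuple[int, ...] | None = None
    dropout_rate: float = 0.5
    speed_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_time_bins != 3:
            raise ValueError("n_time_bins is fixed at 3")
        if self.n_channels < 1 or self.dof < 1:
            raise ValueError("n_channels and dof must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        widths = self.hidden_widths
        if widths is None:
            widths = (256, 256, 256, self.dof)
            object.__setattr__(self, "hidden_widths", widths)
        if len(widths) != 4 or any(w < 1 for w in widths):
            raise ValueError("hidden_widths must be a 4-tuple of positive integers")
        if widths[-1] != self.dof:
            raise ValueError(
                f"last hidden width ({widths[-1]}) must equal dof ({self.dof})"
            )


@dataclass
class TrainingSet:
    """Aligned (SBP window, velocity label) pairs.

    ``windows``: (n, n_channels, 3); ``targets``: (n, dof) in ROM-units/s;
    ``provenance``: per-sample origin, ``open_loop`` or ``refit_relabel``.
    """

    windows: np.ndarray
    targets: np.ndarray
    provenance: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[2] != 3:
            raise ValueError("windows must be (n, n_channels, 3)")
        if len(self.windows) != len(self.targets):
            raise ValueError("windows and targets must have the same length")
        if np.any(~np.isfinite(self.targets)):
            raise ValueError("targets contain missing values")
        if self.provenance is None:
            self.provenance = np.full(len(self.targets), "open_loop")

    def __len__(self) -> int:
        return len(self.targets)


class Decoder:
    """The decoder network together with its output normalization and gains.

    Construction performs Kaiming initialization from ``seed``; the output
    statistics stay unset (identity) until :meth:`train_supervised` runs.
    """

    def __init__(self, config: DecoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.tconv = TemporalConv(rng, c.n_time_bins, c.n_time_features)
        flat = c.n_channels * c.n_time_features
        widths = c.hidden_widths
        self.relu0 = ReLU()
        self.bn0 = BatchNorm(flat)
        self.drop0 = Dropout(c.dropout_rate)
        self.hidden: list[tuple] = []
        n_in = flat
        for w in widths[:-1]:
            self.hidden.append(
                (Linear(rng, n_in, w), ReLU(), BatchNorm(w), Dropout(c.dropout_rate))
            )
            n_in = w
        self.final = Linear(rng, n_in, widths[-1], bias=False)
        self.final_bn = BatchNorm(widths[-1], apply_mean=False, learn_bias=False)
        # output normalization + gain; identity until fitted
        self.output_mean = np.zeros(c.dof)
        self.output_sd = np.ones(c.dof)
        self.gains = np.ones(c.dof)
        self._fitted_stats = False

    # ------------------------------------------------------------------ layers
    def _layers(self):
        yield self.tconv
        yield self.relu0
        yield self.bn0
        yield self.drop0
        for lin, relu, bn, drop in self.hidden:
            yield lin
            yield relu
            yield bn
            yield drop
        yield self.final
        yield self.final_bn

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.parameters())
        return out

    # ----------------------------------------------------------------- forward
    def forward(
        self, windows: np.ndarray, mode: str = "inference", rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Raw network output (before normalization/gain) for SBP windows.

        ``windows`` is (n_channels, 3) or (batch, n_channels, 3).  In
        inference mode dropout is disabled and batch normalization uses
        running statistics; the result is a pure function of the input.
        """
        x = np.asarray(windows, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != (self.config.n_channels, self.config.n_time_bins):
            raise ValueError(
                f"window shape {x.shape[1:]} != "
                f"({self.config.n_channels}, {self.config.n_time_bins})"
            )
        if mode not in ("train", "inference"):
            raise ValueError("mode must be 'train' or 'inference'")
        train = mode == "train"
        if train and rng is None:
            raise ValueError("train mode requires an rng for dropout")

        h = self.tconv.forward(x) if train else self.tconv.infer(x)
        h = self.relu0.forward(h) if train else self.relu0.infer(h)
        h = h.reshape(h.shape[0], -1)
        self._flat_shape = (x.shape[0], self.config.n_channels, self.config.n_time_features)
        h = self.bn0.forward(h) if train else self.bn0.infer(h)
        h = self.drop0.forward(h, rng) if train else self.drop0.infer(h)
        for lin, relu, bn, drop in self.hidden:
            h = lin.forward(h) if train else lin.infer(h)
            h = relu.forward(h) if train else relu.infer(h)
            h = bn.forward(h) if train else bn.infer(h)
            h = drop.forward(h, rng) if train else drop.infer(h)
        h = self.final.forward(h) if train else self.final.infer(h)
        h = self.final_bn.forward(h) if train else self.final_bn.infer(h)
        return h[0] if single else h

    def _backward(self, grad: np.ndarray) -> None:
        g = self.final_bn.backward(grad)
        g = self.final.backward(g)
        for lin, relu, bn, drop in reversed(self.hidden):
            g = drop.backward(g)
            g = bn.backward(g)
            g = relu.backward(g)
            g = lin.backward(g)
        g = self.drop0.backward(g)
        g = self.bn0.backward(g)
        g = g.reshape(self._flat_shape)
        g = self.relu0.backward(g)
        self.tconv.backward(g)

    def _grads(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(gr for _, gr in layer.params_grads())
        return out

    # ------------------------------------------------------- normalization/gain
    def apply_normalization_and_gain(self, raw_v: np.ndarray) -> np.ndarray:
        """ROM-units/s velocities: gains * (raw - mean)/sd * speed_scale."""
        if not self._fitted_stats:
            raise RuntimeError(
                "output normalization statistics are unset; train the decoder first"
            )
        raw_v = np.asarray(raw_v, dtype=float)
        return self.gains * (raw_v - self.output_mean) / self.output_sd * self.config.speed_scale

    def decode(self, window: np.ndarray) -> np.ndarray:
        """Inference forward pass followed by normalization and gain."""
        return self.apply_normalization_and_gain(self.forward(window, "inference"))

    # ---------------------------------------------------------------- training
    def _fit(
        self,
        training_set: TrainingSet,
        *,
        n_steps: int,
        by_epochs: bool,
        learning_rate: float,
        batch_size: int,
        weight_decay: float,
        seed: int,
    ) -> list[float]:
        rng = np.random.default_rng(seed)
        x = training_set.windows
        t = np.asarray(training_set.targets, dtype=float)
        # standardize labels per DOF so the mean-free network output contract
        # (zero mean, unit variance if ideally trained) matches the targets
        t_mean = t.mean(axis=0)
        t_sd = t.std(axis=0)
        t_sd_safe = np.where(t_sd > 0, t_sd, 1.0)
        t_std = (t - t_mean) / t_sd_safe

        n = len(x)
        params = self.parameters()
        opt = Adam(params, lr=learning_rate, weight_decay=weight_decay)
        losses: list[float] = []

        def one_step(idx: np.ndarray) -> None:
            pred = self.forward(x[idx], "train", rng)
            loss, grad = mse_loss_and_grad(pred, t_std[idx])
            self._backward(grad)
            opt.step(self._grads())
            losses.append(loss)

        if by_epochs:
            for _ in range(n_steps):
                order = rng.permutation(n)
                for start in range(0, n, batch_size):
                    idx = order[start : start + batch_size]
                    if len(idx) < 2:  # batchnorm needs >= 2 samples
                        continue
                    one_step(idx)
        else:
            order = rng.permutation(n)
            pos = 0
            for _ in range(n_steps):
                if pos + batch_size > n:
                    order = rng.permutation(n)
                    pos = 0
                idx = order[pos : pos + batch_size]
                pos += batch_size
                if len(idx) < 2:
                    continue
                one_step(idx)

        # empirical output statistics on the training set (inference mode)
        raw = self.forward(x, "inference")
        self.output_mean = raw.mean(axis=0)
        sd = raw.std(axis=0)
        self.output_sd = np.where(sd > 0, sd, 1.0)
        # empirically tuned gain: restore the training-label velocity scale
        self.gains = t_sd_safe.copy()
        self._fitted_stats = True
        return losses

    def train_supervised(
        self,
        training_set: TrainingSet,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        seed: int = 0,
    ) -> list[float]:
        """Supervised MSE/Adam training; returns the per-batch loss curve."""
        if len(training_set) == 0:
            raise ValueError("training_set is empty")
        return self._fit(
            training_set,
            n_steps=epochs,
            by_epochs=True,
            learning_rate=learning_rate,
            batch_size=batch_size,
            weight_decay=0.0,
            seed=seed,
        )

    def refit_update(
        self,
        relabeled_set: TrainingSet,
        seed: int = 0,
        n_iterations: int = 500,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-2,
        batch_size: int = 64,
    ) -> list[float]:
        """ReFIT parameter update: 500 Adam iterations, lr 1e-4, wd 1e-2.

        Starts from the parameters used during the online session (i.e. the
        current ones) and recomputes the output statistics afterwards.
        """
        if not self._fitted_stats:
            raise RuntimeError("refit_update requires a previously trained decoder")
        if len(relabeled_set) == 0:
            raise ValueError("relabeled_set is empty")
        return self._fit(
            relabeled_set,
            n_steps=n_iterations,
            by_epochs=False,
            learning_rate=learning_rate,
            batch_size=batch_size,
            weight_decay=weight_decay,
            seed=seed,
        )

    # ------------------------------------------------------------ serialization
    def save(self, path) -> None:
        arrays = {"version": np.array(SERIALIZATION_VERSION)}
        cfg = self.config
        arrays["config"] = np.array(
            [
                cfg.n_channels,
                cfg.dof,
                cfg.n_time_bins,
                cfg.n_time_features,
                *cfg.hidden_widths,
            ],
            dtype=int,
        )
        arrays["config_float"] = np.array([cfg.dropout_rate, cfg.speed_scale])
        for i, layer in enumerate(self._layers()):
            for j, p in enumerate(layer.parameters()):
                arrays[f"p_{i}_{j}"] = p
            if isinstance(layer, BatchNorm):
                arrays[f"rm_{i}"] = layer.running_mean
                arrays[f"rv_{i}"] = layer.running_var
        arrays["output_mean"] = self.output_mean
        arrays["output_sd"] = self.output_sd
        arrays["gains"] = self.gains
        arrays["fitted"] = np.array(int(self._fitted_stats))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Decoder":
        data = np.load(path, allow_pickle=False)
        if int(data["version"]) != SERIALIZATION_VERSION:
            raise ValueError(f"unsupported decoder file version {int(data['version'])}")
        ci = data["config"]
        cf = data["config_float"]
        config = DecoderConfig(
            n_channels=int(ci[0]),
            dof=int(ci[1]),
            n_time_bins=int(ci[2]),
            n_time_features=int(ci[3]),
            hidden_widths=tuple(int(w) for w in ci[4:8]),
            dropout_rate=float(cf[0]),
            speed_scale=float(cf[1]),
        )
        dec = cls(config, seed=0)
        for i, layer in enumerate(dec._layers()):
            for j, p in enumerate(layer.parameters()):
                p[...] = data[f"p_{i}_{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = data[f"rm_{i}"]
                layer.running_var[...] = data[f"rv_{i}"]
        dec.output_mean = data["output_mean"]
        dec.output_sd = data["output_sd"]
        dec.gains = data["gains"]
        dec._fitted_stats = bool(int(data["fitted"]))
        return dec


def windows_from_sbp(sbp: np.ndarray, n_time_bins: int = 3) -> np.ndarray:
    """Rolling 3-bin windows from an (n_bins, n_channels) SBP stream.

    The first bins are edge-padded with the stream's first bin, matching how
    the closed-loop engine primes its window at trial start.  Output shape is
    (n_bins, n_channels, n_time_bins), most recent bin last.
    """
    sbp = np.asarray(sbp, dtype=float)
    n = len(sbp)
    out = np.empty((n, sbp.shape[1], n_time_bins))
    for k in range(n):
        for t in range(n_time_bins):
            src = max(0, k - (n_time_bins - 1 - t))
            out[k, :, t] = sbp[src]
    return out


def refit_relabel(
    trial_records: Sequence,
    zero_inside: bool = True,
    mode: str = "per_axis",
    vector_groups: Sequence[Sequence[int]] | None = None,
) -> TrainingSet:
    """Intention relabeling of closed-loop trials for ReFIT retraining.

    Per bin and per DOF the label equals the decoded velocity when it points
    toward the target and its sign is inverted when it points away; the
    magnitude is never changed.  Bins where a DOF is already inside its
    target are labeled zero velocity (``zero_inside=False`` disables this).

    ``mode='vector'`` instead rotates the decoded velocity of each axis
    group in ``vector_groups`` (e.g. the thumb's two axes) to point at the
    target while keeping the group's joint magnitude.
    """
    if mode not in ("per_axis", "vector"):
        raise ValueError("mode must be 'per_axis' or 'vector'")
    windows_all, labels_all = [], []
    for rec in trial_records:
        if rec.decoded_velocities is None or len(rec.decoded_velocities) == 0:
            raise ValueError("trial record lacks decoded velocities")
        if rec.sbp is None:
            raise ValueError("trial record lacks SBP data needed for retraining")
        decoded = np.asarray(rec.decoded_velocities, dtype=float)
        # position at the start of each bin is the state the velocity acted from
        pos = np.asarray(rec.positions, dtype=float)[: len(decoded)]
        centers = np.asarray(rec.target_set.centers, dtype=float)
        half_w = rec.target_set.width / 2.0
        err = centers[None, :] - pos
        inside = np.abs(err) <= half_w

        if mode == "per_axis":
            toward = np.sign(err)
            labels = np.abs(decoded) * toward
        else:
            labels = decoded.copy()
            groups = vector_groups or [tuple(range(decoded.shape[1]))]
            for axes in groups:
                axes = list(axes)
                e = err[:, axes]
                norm_e = np.linalg.norm(e, axis=1, keepdims=True)
                unit = np.divide(e, norm_e, out=np.zeros_like(e), where=norm_e > 0)
                mag = np.linalg.norm(decoded[:, axes], axis=1, keepdims=True)
                labels[:, axes] = mag * unit
        if zero_inside:
            labels = np.where(inside, 0.0, labels)
        windows_all.append(windows_from_sbp(np.asarray(rec.sbp, dtype=float)))
        labels_all.append(labels)
    if not windows_all:
        raise ValueError("no trial records supplied")
    return TrainingSet(
        windows=np.concatenate(windows_all),
        targets=np.concatenate(labels_all),
        provenance=np.full(sum(len(l) for l in labels_all), "refit_relabel"),
    )
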