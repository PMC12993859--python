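"""Autoencoder early-warning tier: reconstruction-error anomaly screening.

A fixed 64-32-64 dense encoder-decoder is trained to reconstruct healthy
(control-treatment) growth-trajectory windows of one feature.  At
inference, a window whose per-window mean squared reconstruction error
strictly exceeds tau = multiplier x (mean training reconstruction error at
the final epoch) is flagged anomalous.  Sweeping window lengths and
features yields net detection rates — the fraction of treated trajectories
flagged minus the fraction of held-out healthy trajectories flagged —
which identify when and with which index a depletion becomes detectable.

The model interface follows the fit/results convention: a
:class:`TrajectoryAnomalyAE` is configured, ``fit`` returns an
:class:`AEDetectorResults` that carries the weights, the threshold, the
training-error diagnostics and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, mse, relu

__all__ = ["AEConfig", "TrajectoryAnomalyAE", "AEDetectorResults", "window_sweep"]

HIDDEN_WIDTHS = (64, 32, 64)  # fixed encoder-decoder widths, independent of window length


@dataclass(frozen=True)
class AEConfig:
    """Training configuration for the anomaly autoencoder.

    ``train_cap`` caps training at the first ``n`` healthy windows in
    ascending plant-id order (destructive sampling shrinks the pool at long
    window lengths, so "as many as available" applies below the cap).
    """

    epochs: int = 100
    learning_rate: float = 1e-3
    threshold_multiplier: float = 1.5
    train_cap: int = 40
    batch_size: int | None = None  # None = full batch (the pool is <= train_cap)
    seed: int = 0


class TrajectoryAnomalyAE:
    """64-32-64 autoencoder over fixed-length single-feature windows.

    Each window is one vector of length L; hidden layers use ReLU, the
    output layer is linear, and inputs are min-max normalized per time
    point with statistics fit on the training windows.
    """

    def __init__(self, window_length: int, config: AEConfig | None = None):
        if window_length < 2:
            raise ValueError("window length must be >= 2")
        self.window_length = window_length
        self.config = config or AEConfig()

    def _init_params(self, rng: np.random.Generator) -> list[Tensor]:
        dims = [self.window_length, *HIDDEN_WIDTHS, self.window_length]
        params = []
        for fan_in, fan_out in zip(dims, dims[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            params.append(Tensor(rng.uniform(-bound, bound, (fan_in, fan_out)),
                                 requires_grad=True))
            params.append(Tensor(np.zeros(fan_out), requires_grad=True))
        return params

    @staticmethod
    def _forward(params: list[Tensor], x: Tensor) -> Tensor:
        h = x
        n_layers = len(params) // 2
        for i in range(n_layers):
            h = h @ params[2 * i] + params[2 * i + 1]
            if i < n_layers - 1:
                h = relu(h)
        return h

    def fit(self, windows: np.ndarray, plant_ids=None) -> "AEDetectorResults":
        """Train on healthy windows; returns results with the detection threshold.

        ``windows`` is (n, L).  When ``plant_ids`` is given, the pool is
        sorted by ascending plant id before the first-``train_cap`` windows
        are taken (a deterministic stand-in for acquisition order).
        """
        windows = np.asarray(windows, dtype=np.float64)
        if windows.ndim != 2 or windows.shape[0] == 0:
            raise ValueError("need a non-empty (n, L) array of windows")
        if windows.shape[1] != self.window_length:
            raise ValueError(
                f"window length {windows.shape[1]} != model length {self.window_length}"
            )
        if np.isnan(windows).any():
            raise ValueError("windows contain missing values")
        if plant_ids is not None:
            order = np.argsort(np.asarray(plant_ids, dtype=object))
            windows = windows[order]
        train = windows[: self.config.train_cap]
        if len(train) < 2:
            raise ValueError("need at least 2 training windows")

        lo = train.min(axis=0)
        span = train.max(axis=0) - lo
        span[span == 0] = 1.0  # constant dimensions normalize to 0

        rng = np.random.default_rng(self.config.seed)
        params = self._init_params(rng)
        opt = Adam(params, lr=self.config.learning_rate)
        x_all = (train - lo) / span
        n = len(x_all)
        bs = self.config.batch_size or n
        loss_curve = []
        for _ in range(self.config.epochs):
            perm = rng.permutation(n) if bs < n else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                xb = x_all[perm[start:start + bs]]
                x = Tensor(xb)
                loss = mse(self._forward(params, x), xb)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(xb)
            loss_curve.append(epoch_loss / n)

        recon = self._forward(params, Tensor(x_all)).data
        train_errors = ((x_all - recon) ** 2).mean(axis=1)
        tau = self.config.threshold_multiplier * float(train_errors.mean())
        return AEDetectorResults(
            model=self, params=params, norm_lo=lo, norm_span=span,
            threshold=tau, train_errors=train_errors,
            loss_curve=np.asarray(loss_curve), n_train=n,
        )


@dataclass
class AEDetectorResults:
    """Fitted autoencoder, its normalization, and the detection threshold."""

    model: TrajectoryAnomalyAE
    params: list[Tensor]
    norm_lo: np.ndarray
    norm_span: np.ndarray
    threshold: float
    train_errors: np.ndarray
    loss_curve: np.ndarray
    n_train: int

    def reconstruction_error(self, windows: np.ndarray) -> np.ndarray:
        """Per-window mean squared error between normalized input and output."""
        windows = np.atleast_2d(np.asarray(windows, dtype=np.float64))
        if windows.shape[1] != self.model.window_length:
            raise ValueError(
                f"window length {windows.shape[1]} != model length {self.model.window_length}"
            )
        x = (windows - self.norm_lo) / self.norm_span
        recon = TrajectoryAnomalyAE._forward(self.params, Tensor(x)).data
        return ((x - recon) ** 2).mean(axis=1)

    def detect(self, windows: np.ndarray) -> np.ndarray:
        """True where the reconstruction error strictly exceeds the threshold."""
        return self.reconstruction_error(windows) > self.threshold

    def summary(self) -> str:
        lines = [
            "Trajectory anomaly autoencoder (64-32-64)",
            f"  window length        : {self.model.window_length}",
            f"  training windows     : {self.n_train}",
            f"  epochs / lr          : {self.model.config.epochs} / {self.model.config.learning_rate}",
            f"  final training loss  : {self.loss_curve[-1]:.3e}",
            f"  mean training error  : {self.train_errors.mean():.3e}",
            f"  threshold (x{self.model.config.threshold_multiplier:g})     : {self.threshold:.3e}",
        ]
        return "\n".join(lines)


def window_sweep(
    trajectories,
    features: list[str],
    lengths=range(6, 23),
    start_dat: int = 4,
    control: str = "T1",
    treated: list[str] | None = None,
    config: AEConfig | None = None,
) -> pd.DataFrame:
    """Net detection rate over (feature, window length, treated group).

    For each combination: fit on the first ``train_cap`` control windows,
    compute the false detection rate on the held-out control windows and
    the true detection rate on each treated group's windows, and report
    net = true - false.  Raises if a combination leaves no held-out
    control windows.
    """
    config = config or AEConfig()
    rows = []
    for feature in features:
        for length in lengths:
            vals, pids, treats = trajectories.windows(feature, int(length), start_dat)
            treats = np.asarray(treats, dtype=object)
            is_control = treats == control
            ctrl_vals = vals[is_control]
            ctrl_pids = [p for p, c in zip(pids, is_control) if c]
            if len(ctrl_vals) == 0:
                raise ValueError(f"no {control} windows for {feature} at L={length}")
            order = np.argsort(np.asarray(ctrl_pids, dtype=object))
            ctrl_vals = ctrl_vals[order]
            n_train = min(config.train_cap, len(ctrl_vals))
            held_out = ctrl_vals[n_train:]
            if len(held_out) == 0:
                raise ValueError(
                    f"no held-out {control} windows for {feature} at L={length}; "
                    "false detection rate undefined"
                )
            ae = TrajectoryAnomalyAE(int(length), config)
            res = ae.fit(ctrl_vals[:n_train])
            false_rate = float(res.detect(held_out).mean())
            groups = treated or sorted(set(treats) - {control})
            for grp in groups:
                grp_vals = vals[treats == grp]
                if len(grp_vals) == 0:
                    continue
                true_rate = float(res.detect(grp_vals).mean())
                rows.append({
                    "feature": feature, "window_length": int(length),
                    "treated": grp, "true_rate": true_rate,
                    "false_rate": false_rate, "net_rate": true_rate - false_rate,
                    "n_train": int(res.n_train), "n_test_healthy": int(len(held_out)),
                    "n_test_treated": int(len(grp_vals)),
                })
    return pd.DataFrame(rows)
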