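"""Supervised spike inference trained on the synthetic corpus.

A windowed regressor maps a local fluorescence window (±window_s around
each sample) to the ground-truth spike density smoothed with a Gaussian
kernel (default 10 ms SD).  The regressor is a small multilayer perceptron
over the raw window samples — deliberately compact so it trains on a CPU
in minutes.  Continuous density predictions are discretized into spike
times by greedy matching pursuit with the same Gaussian kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.neural_network import MLPRegressor

from .cell import FluorescenceTrace, SpikeTrain
from .metrics import bin_spikes


@dataclass
class TrainConfig:
    window_s: float = 0.064        # half-window around each sample
    kernel_sd_s: float = 0.010     # target smoothing kernel SD
    hidden: tuple = (96, 48)
    max_samples: int = 120_000     # training windows after subsampling
    holdout_frac: float = 0.2
    max_iter: int = 40
    stride: int = 2                # take every k-th sample of each trace
    min_spikes: int = 10


@dataclass
class TrainedModel:
    """Fitted regressor plus the manifest needed to retrain it."""

    regressor: MLPRegressor
    rate: float
    config: TrainConfig
    manifest: dict = field(default_factory=dict)

    def save(self, path):
        """Persist weights and manifest to an .npz file."""
        reg = self.regressor
        arrays = {}
        for i, (W, b) in enumerate(zip(reg.coefs_, reg.intercepts_)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        arrays["meta"] = np.frombuffer(json.dumps({
            "rate": self.rate, "hidden": list(self.config.hidden),
            "window_s": self.config.window_s,
            "kernel_sd_s": self.config.kernel_sd_s,
            "manifest": self.manifest}).encode(), dtype=np.uint8)
        np.savez(path, **arrays)


class _MLPForward:
    """Predict-only forward pass over saved MLP weights (ReLU hidden
    layers, identity output) — lets saved models be used without
    refitting."""

    def __init__(self, weights, biases):
        self.weights = weights
        self.biases = biases

    def predict(self, X):
        a = np.asarray(X, dtype=float)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()


def load_model(path) -> TrainedModel:
    """Load a model saved by :meth:`TrainedModel.save`."""
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        n_layers = len(meta["hidden"]) + 1
        weights = [f[f"W{i}"] for i in range(n_layers)]
        biases = [f[f"b{i}"] for i in range(n_layers)]
    config = TrainConfig(window_s=meta["window_s"],
                         kernel_sd_s=meta["kernel_sd_s"],
                         hidden=tuple(meta["hidden"]))
    return TrainedModel(regressor=_MLPForward(weights, biases),
                        rate=meta["rate"], config=config,
                        manifest=meta["manifest"])


def _windows(dff: np.ndarray, half: int) -> np.ndarray:
    pad = np.pad(dff, half, mode="edge")
    return np.lib.stride_tricks.sliding_window_view(pad, 2 * half + 1)


def _targets(spikes: SpikeTrain, n: int, rate: float,
             kernel_sd_s: float) -> np.ndarray:
    binned = bin_spikes(spikes, n, rate)
    return gaussian_filter1d(binned, kernel_sd_s * rate)


def train(corpus, config: TrainConfig | None = None,
          seed: int = 0) -> TrainedModel:
    """Train the windowed regressor on (trace, spikes) pairs.

    Deterministic given ``seed`` up to floating-point reduction order.
    Returns a model whose manifest records the split, the loss curve and
    the held-out loss; retraining from the manifest reproduces it.
    """
    config = config or TrainConfig()
    corpus = list(corpus)
    total_spikes = sum(len(s) for _, s in corpus)
    if total_spikes < config.min_spikes:
        raise ValueError(f"corpus has {total_spikes} spikes; "
                         f"need >= {config.min_spikes}")
    rate = corpus[0][0].rate
    half = int(round(config.window_s * rate))
    rng = np.random.default_rng(seed)
    n_hold = max(1, int(round(config.holdout_frac * len(corpus))))
    order = rng.permutation(len(corpus))
    hold_idx = set(order[:n_hold].tolist())
    X_tr, y_tr, X_ho, y_ho = [], [], [], []
    for i, (trace, spikes) in enumerate(corpus):
        if abs(trace.rate - rate) > 1e-6:
            raise ValueError("corpus traces must share one sampling rate")
        Xi = _windows(trace.dff, half)[::config.stride]
        yi = _targets(spikes, trace.dff.size, rate,
                      config.kernel_sd_s)[::config.stride]
        (X_ho if i in hold_idx else X_tr).append(Xi)
        (y_ho if i in hold_idx else y_tr).append(yi)
    X = np.concatenate(X_tr)
    y = np.concatenate(y_tr)
    if X.shape[0] > config.max_samples:
        keep = rng.choice(X.shape[0], config.max_samples, replace=False)
        keep.sort()
        X, y = X[keep], y[keep]
    reg = MLPRegressor(hidden_layer_sizes=config.hidden,
                       max_iter=config.max_iter, random_state=seed,
                       early_stopping=False, n_iter_no_change=config.max_iter)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # convergence warning at max_iter
        reg.fit(X, y)
    Xh = np.concatenate(X_ho)
    yh = np.concatenate(y_ho)
    ph = reg.predict(Xh)
    held_loss = float(np.mean((ph - yh) ** 2))
    r = float(np.corrcoef(ph, yh)[0, 1]) if np.std(ph) > 0 else 0.0
    manifest = {"seed": seed, "n_traces": len(corpus),
                "holdout_indices": sorted(int(order[k]) for k in
                                          range(n_hold)),
                "kernel_sd_s": config.kernel_sd_s,
                "loss_curve": list(map(float, reg.loss_curve_)),
                "held_out_mse": held_loss, "held_out_r": r,
                "n_train_windows": int(X.shape[0])}
    return TrainedModel(regressor=reg, rate=rate, config=config,
                        manifest=manifest)


def predict(model: TrainedModel, trace: FluorescenceTrace,
            resample: bool = False) -> np.ndarray:
    """Per-bin nonnegative spike-density prediction for a trace."""
    if abs(trace.rate - model.rate) > 1e-6:
        if not resample:
            raise ValueError(
                f"trace rate {trace.rate} != training rate {model.rate}; "
                "pass resample=True to interpolate")
        n_new = int(round(trace.duration * model.rate))
        t_new = np.arange(n_new) / model.rate
        dff = np.interp(t_new, trace.t, trace.dff)
        trace = FluorescenceTrace(t=t_new, dff=dff, rate=model.rate)
    half = int(round(model.config.window_s * model.rate))
    X = _windows(trace.dff, half)
    out = model.regressor.predict(X)
    return np.clip(out, 0.0, None)


def discretize(density: np.ndarray, kernel_width: float,
               rate: float) -> SpikeTrain:
    """Greedy matching-pursuit conversion of a density into spike times.

    Repeatedly places a unit Gaussian kernel (SD ``kernel_width`` seconds)
    at the maximum of the matched-filter response while at least half a
    kernel of residual mass remains; returns the placed centers.
    """
    density = np.asarray(density, dtype=float)
    if (density < 0).any():
        raise ValueError("density must be nonnegative")
    n = density.size
    sd = kernel_width * rate
    half = int(np.ceil(4 * sd))
    tt = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (tt / sd) ** 2)
    kernel /= kernel.sum()             # unit mass per spike
    k_energy = float(kernel @ kernel)
    resid = density.copy()
    used = np.zeros(n, dtype=bool)
    times = []
    for _ in range(10 * n):
        if resid.sum() < 0.5:
            break
        score = np.convolve(resid, kernel[::-1], mode="same")
        score[used] = -np.inf      # one spike per bin
        i = int(np.argmax(score))
        # stop when the best-fitting kernel amplitude drops below half a
        # kernel — same half-kernel rule as the global mass criterion
        if not np.isfinite(score[i]) or score[i] / k_energy < 0.5:
            break
        lo, hi = max(0, i - half), min(n, i + half + 1)
        resid[lo:hi] -= kernel[half - (i - lo): half + (hi - i)]
        np.clip(resid, 0.0, None, out=resid)
        used[i] = True
        times.append((i + 0.5) / rate)
    return SpikeTrain(np.sort(np.array(times)))
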