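"""Workload prediction and adaptive intervention.

A Matern-3/2 Gaussian-process regressor maps three per-trial features
(normalized task duration, 15-22 Hz beta-band power variance, gaze
entropy) onto 0-100 workload scores.  Predictions above 68/100 switch on
three interventions -- a 20% higher confirmation threshold, a 0.4 m/s
virtual-hand speed cap, and 2.5 N/mm stabilizing stiffness -- released
with hysteresis below 63.  The module also computes the weighted
task-complexity score C.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .eeg import band_power_series
from .streams import SampleStream

LOAD_THRESHOLD_ON = 68.0
LOAD_THRESHOLD_OFF = 63.0
BASE_VMAX = 0.5           # m/s
ADAPTED_VMAX = 0.4        # 80% of baseline
ADAPTED_STIFFNESS = 2.5   # N/mm
ADAPTED_MULTIPLIER = 1.2
COMPLEXITY_WEIGHTS = (0.5, 0.3, 0.2)
DX_MAX = 1.8              # m


def matern32(r: np.ndarray | float, sigma2: float = 1.0,
             length_scale: float = 1.0) -> np.ndarray | float:
    """Matern-3/2 covariance: sigma2 * (1 + sqrt3 r/l) exp(-sqrt3 r/l)."""
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    r = np.asarray(r, float)
    if (r < 0).any():
        raise ValueError("distances must be non-negative")
    s = math.sqrt(3.0) * r / length_scale
    out = sigma2 * (1.0 + s) * np.exp(-s)
    return float(out) if out.ndim == 0 else out


@dataclass
class LoadFeatures:
    norm_duration: float
    beta_var: float
    gaze_entropy: float

    def to_array(self) -> np.ndarray:
        return np.array([self.norm_duration, self.beta_var, self.gaze_entropy])


def beta_band_variance(stream: SampleStream, band: tuple[float, float] = (15.0, 22.0),
                       window: float = 2.0, hop: float = 1.0) -> float:
    """Variance of the 15-22 Hz band power over 2-s sliding windows."""
    _, powers = band_power_series(stream.values, stream.rate, band=band,
                                  window=window, hop=hop)
    return float(np.var(powers))


class GPRModel:
    """Exact GP regression with a Matern-3/2 kernel on standardized inputs."""

    def __init__(self) -> None:
        self._gpr: GaussianProcessRegressor | None = None
        self.x_mean: np.ndarray | None = None
        self.x_sd: np.ndarray | None = None
        self.r2: float | None = None

    # -- fitting -------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, noise: float | str = "fit",
            n_restarts: int = 2, seed: int = 0) -> "GPRModel":
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float)
        if len(X) < 5:
            raise ValueError("need at least 5 training pairs")
        self.x_mean = X.mean(axis=0)
        self.x_sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self.x_mean) / self.x_sd
        kernel = ConstantKernel(1.0, (1e-3, 1e4)) * Matern(1.0, (1e-2, 1e3), nu=1.5)
        if noise == "fit":
            kernel = kernel + WhiteKernel(1.0, (1e-10, 1e4))
            alpha = 1e-10
        else:
            alpha = float(noise)
        self._gpr = GaussianProcessRegressor(
            kernel=kernel, alpha=alpha, normalize_y=True,
            n_restarts_optimizer=n_restarts, random_state=seed)
        self._gpr.fit(Xs, y)
        self._y_orig = y.copy()
        pred = self._gpr.predict(Xs)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r2 = None if ss_tot == 0 else 1.0 - float(((y - pred) ** 2).sum()) / ss_tot
        return self

    # -- fitted hyperparameters ---------------------------------------------

    def _kernel_parts(self):
        k = self._gpr.kernel_
        white = None
        prod = k
        if hasattr(k, "k2") and isinstance(k.k2, WhiteKernel):
            prod, white = k.k1, k.k2
        return prod, white

    @property
    def sigma2(self) -> float:
        prod, _ = self._kernel_parts()
        return float(prod.k1.constant_value)

    @property
    def length_scale(self) -> float:
        """Isotropic length-scale in standardized input units."""
        prod, _ = self._kernel_parts()
        return float(prod.k2.length_scale)

    @property
    def noise_var(self) -> float:
        _, white = self._kernel_parts()
        return 0.0 if white is None else float(white.noise_level)

    # -- prediction ----------------------------------------------------------

    def predict(self, X: np.ndarray, clamp: bool = False,
                ) -> tuple[np.ndarray, np.ndarray]:
        if self._gpr is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, float))
        Xs = (X - self.x_mean) / self.x_sd
        mean, sd = self._gpr.predict(Xs, return_std=True)
        if clamp:
            mean = np.clip(mean, 0.0, 100.0)
        return mean, sd

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        if self._gpr is None:
            raise RuntimeError("model is not fitted")
        payload = {
            "sigma2": self.sigma2,
            "length_scale": self.length_scale,
            "noise_var": self.noise_var,
            "alpha": self._gpr.alpha,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "X_train_std": self._gpr.X_train_.tolist(),
            "y_train": self._y_orig.tolist(),
            "r2": self.r2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "GPRModel":
        with open(path) as fh:
            p = json.load(fh)
        model = cls()
        model.x_mean = np.asarray(p["x_mean"])
        model.x_sd = np.asarray(p["x_sd"])
        model.r2 = p["r2"]
        kernel = (ConstantKernel(p["sigma2"], "fixed")
                  * Matern(p["length_scale"], "fixed", nu=1.5)
                  + WhiteKernel(max(p["noise_var"], 1e-12), "fixed"))
        model._gpr = GaussianProcessRegressor(kernel=kernel, alpha=p["alpha"],
                                              normalize_y=True, optimizer=None)
        y = np.asarray(p["y_train"])
        model._gpr.fit(np.asarray(p["X_train_std"]), y)
        model._y_orig = y
        return model


def gpr_fit(X, y, **kwargs) -> GPRModel:
    return GPRModel().fit(np.asarray(X, float), np.asarray(y, float), **kwargs)


def gpr_predict(model: GPRModel, x, clamp: bool = True):
    mean, sd = model.predict(np.atleast_2d(np.asarray(x, float)), clamp=clamp)
    return float(mean[0]), float(sd[0])


@dataclass(frozen=True)
class AdaptationState:
    active: bool = False
    threshold_multiplier: float = 1.0
    vmax: float = BASE_VMAX
    stiffness: float = 0.0


ADAPTED = AdaptationState(True, ADAPTED_MULTIPLIER, ADAPTED_VMAX, ADAPTED_STIFFNESS)
RELAXED = AdaptationState()


def adapt(predicted_load: float, previous: AdaptationState | None = None,
          on: float = LOAD_THRESHOLD_ON, off: float = LOAD_THRESHOLD_OFF,
          ) -> AdaptationState:
    """Hysteresis rule: engage above ``on``, release below ``off``."""
    if not 0.0 <= predicted_load <= 100.0:
        raise ValueError(f"predicted load {predicted_load} outside [0, 100]")
    previous = previous or RELAXED
    if predicted_load > on:
        return replace(ADAPTED)
    if predicted_load < off:
        return replace(RELAXED)
    return replace(previous)


def complexity(dx: float, h_g: float, n_d: float,
               dx_max: float = DX_MAX, hg_max: float = math.log(64),
               nd_max: float = 5.0,
               weights: tuple[float, float, float] = COMPLEXITY_WEIGHTS,
               normalized: bool = True) -> float:
    """Weighted task-complexity score C.

    With ``normalized=True`` (default) each term is scaled to [0, 1] by its
    maximum before weighting, so C itself lies in [0, 1]; the raw
    unnormalized weighted sum is available with ``normalized=False``.
    """
    if not 0.0 <= dx <= dx_max + 1e-9:
        raise ValueError(f"target displacement {dx} outside [0, {dx_max}]")
    if n_d < 0:
        raise ValueError("distractor count must be non-negative")
    w1, w2, w3 = weights
    if not normalized:
        return w1 * dx + w2 * h_g + w3 * n_d
    if dx_max <= 0 or hg_max <= 0 or nd_max <= 0:
        raise ValueError("normalization maxima must be positive")
    terms = (np.clip(dx / dx_max, 0, 1), np.clip(h_g / hg_max, 0, 1),
             np.clip(n_d / nd_max, 0, 1))
    return float(w1 * terms[0] + w2 * terms[1] + w3 * terms[2])
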