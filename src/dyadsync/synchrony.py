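"""Windowed cross-lagged synchrony of motion energy series.

The synchrony of two movement streams is measured by sliding a fixed-length
window along both series, Pearson-correlating one window against the other
at a grid of temporal offsets (lags), and mapping each correlation r to
``|atanh(r)|`` (absolute Fisher Z). Interpersonal synchrony correlates the
participant's stream against the administrator's (60 s windows, +-5 s lags,
30 s steps); intrapersonal head-body coordination uses the same machinery on
one person's head vs body streams (30 s windows, +-5 s lags, 15 s steps).

A chance-level baseline is obtained from pseudodyads: role-preserving
pairings of a participant series with an administrator series from a
*different* dyad, re-scored with identical settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motion_energy import MotionEnergySeries

#: r is clipped to this magnitude before atanh so entries stay finite.
R_CAP = 1.0 - 1e-7


@dataclass(frozen=True)
class PreprocessConfig:
    """Scaling/smoothing applied to raw motion energy before correlation.

    ``sd_scale`` divides the series by its own standard deviation, removing
    camera/room-specific amplitude units; ``smooth_sec`` is the length of a
    centered moving-average window in seconds (edges shrink symmetrically).
    """

    sd_scale: bool = True
    smooth_sec: float = 0.5

    def __post_init__(self) -> None:
        if self.smooth_sec < 0:
            raise ValueError("smooth_sec must be >= 0")


@dataclass(frozen=True)
class CrossCorrConfig:
    """Grid geometry of the windowed cross-lagged correlation.

    All extents are in seconds and converted to samples by round(sec * fps).
    The lag grid runs from -max_lag_sec to +max_lag_sec in steps of
    ``lag_increment_sec``.
    """

    fps: float
    window_sec: float = 60.0
    max_lag_sec: float = 5.0
    step_sec: float = 30.0
    lag_increment_sec: float = 1.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.window_sec <= 0 or self.step_sec <= 0 or self.lag_increment_sec <= 0:
            raise ValueError("window, step and lag increment must be positive")
        if self.max_lag_sec < 0:
            raise ValueError("max lag must be >= 0")
        if self.window_samples <= 2:
            raise ValueError("window must span more than 2 samples")

    @property
    def window_samples(self) -> int:
        return round(self.window_sec * self.fps)

    @property
    def step_samples(self) -> int:
        return round(self.step_sec * self.fps)

    @property
    def lag_grid_sec(self) -> np.ndarray:
        n = int(math.floor(self.max_lag_sec / self.lag_increment_sec + 1e-9))
        return np.arange(-n, n + 1) * self.lag_increment_sec

    @property
    def lag_grid_samples(self) -> np.ndarray:
        return np.array([round(l * self.fps) for l in self.lag_grid_sec], dtype=int)


def interpersonal_config(fps: float, **kw) -> CrossCorrConfig:
    """60 s windows, +-5 s lags, 30 s steps."""
    return CrossCorrConfig(fps=fps, window_sec=60.0, max_lag_sec=5.0, step_sec=30.0, **kw)


def intrapersonal_config(fps: float, **kw) -> CrossCorrConfig:
    """30 s windows, +-5 s lags, 15 s steps."""
    return CrossCorrConfig(fps=fps, window_sec=30.0, max_lag_sec=5.0, step_sec=15.0, **kw)


@dataclass
class CrossCorrMatrix:
    """Windows x lags grid of absolute Fisher-Z synchrony values.

    Entries are >= 0; NaN marks windows where a correlation is undefined
    (zero variance, i.e. no movement within the window).
    """

    values: np.ndarray  # (n_windows, n_lags)
    window_starts_sec: np.ndarray
    lags_sec: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts_sec = np.asarray(self.window_starts_sec, dtype=float)
        self.lags_sec = np.asarray(self.lags_sec, dtype=float)
        if self.values.shape != (len(self.window_starts_sec), len(self.lags_sec)):
            raise ValueError("matrix shape disagrees with its axes")

    @property
    def entries(self) -> np.ndarray:
        """All non-missing entries pooled across windows and lags."""
        flat = self.values.ravel()
        return flat[np.isfinite(flat)]

    def mean(self) -> float:
        ent = self.entries
        return float(ent.mean()) if ent.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (window_start, lag, value) table."""
        w, l = np.meshgrid(self.window_starts_sec, self.lags_sec, indexing="ij")
        return pd.DataFrame(
            {"window_start": w.ravel(), "lag": l.ravel(), "value": self.values.ravel()}
        )


def preprocess_series(
    series: MotionEnergySeries | np.ndarray,
    cfg: PreprocessConfig = PreprocessConfig(),
    fps: float | None = None,
) -> np.ndarray:
    """SD-scale and moving-average smooth a motion energy series.

    The moving average is centered with shrinking edges: near the series
    boundaries the window is truncated to the available samples, so the
    output length equals the input length.
    """
    if isinstance(series, MotionEnergySeries):
        x = series.values.astype(float)
        fps = series.fps
    else:
        x = np.asarray(series, dtype=float)
        if fps is None:
            raise ValueError("fps required when passing a bare array")
    if cfg.sd_scale:
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if sd == 0.0:
            raise ZeroVarianceError("cannot SD-scale a zero-variance series")
        x = x / sd
    w = round(cfg.smooth_sec * fps)
    if w > 1:
        kernel = np.ones(w)
        x = np.convolve(x, kernel, mode="same") / np.convolve(
            np.ones_like(x), kernel, mode="same"
        )
    return x


class ZeroVarianceError(ValueError):
    """Raised when a degenerate (constant) series cannot be processed."""


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, NaN when either window has zero variance."""
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return float("nan")
    return float(a @ b) / denom


def _abs_fisher_z(r: float) -> float:
    if math.isnan(r):
        return float("nan")
    return abs(math.atanh(max(-R_CAP, min(R_CAP, r))))


def windowed_crosslag(
    a: np.ndarray, b: np.ndarray, cfg: CrossCorrConfig
) -> CrossCorrMatrix:
    """Windowed cross-lagged |Fisher Z| synchrony of two equal-length series.

    For window start t (samples, stepping by the step size) and lag l
    (samples) the entry is ``|atanh(Pearson(a[t:t+w], b[t+l:t+l+w]))|``.
    Only window starts for which *every* lag in the grid stays inside both
    series are used, so no partial windows enter the grid.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    n = len(a)
    w = cfg.window_samples
    lags = cfg.lag_grid_samples
    max_lag = int(lags.max()) if len(lags) else 0
    t0 = max(0, -int(lags.min()))
    t_max = n - w - max_lag
    if t_max < t0:
        raise ValueError(
            f"series of {n} samples too short for a {w}-sample window at +-{max_lag} lag"
        )
    starts = np.arange(t0, t_max + 1, cfg.step_samples)
    values = np.empty((len(starts), len(lags)))
    for i, t in enumerate(starts):
        wa = a[t : t + w]
        for j, l in enumerate(lags):
            values[i, j] = _abs_fisher_z(_pearson(wa, b[t + l : t + l + w]))
    return CrossCorrMatrix(values, starts / cfg.fps, cfg.lag_grid_sec)


def intrapersonal_coordination(
    head: np.ndarray, body: np.ndarray, fps: float, **kw
) -> CrossCorrMatrix:
    """Head-body coordination of one interactant (30 s / +-5 s / 15 s grid)."""
    return windowed_crosslag(head, body, intrapersonal_config(fps, **kw))


# ---------------------------------------------------------------------------
# Pseudodyad surrogate null


@dataclass
class PseudodyadSet:
    """Role-preserving surrogate pairings used as the chance-level null."""

    pairings: list[tuple[str, str]]  # (participant dyad id, administrator dyad id)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.pairings)


def generate_pseudodyads(
    participant_ids: Sequence[str],
    administrator_ids: Sequence[str] | None = None,
    n: int | None = 500,
    seed: int | None = None,
) -> PseudodyadSet:
    """Sample pairings of a participant with a foreign dyad's administrator.

    Pairings where both series come from the same genuine dyad are excluded.
    Sampling is without replacement of *pairings* (individuals recur);
    ``n=None`` returns every non-genuine pairing (exhaustive mode).
    """
    participant_ids = list(participant_ids)
    if administrator_ids is None:
        administrator_ids = participant_ids
    administrator_ids = list(administrator_ids)
    if len(participant_ids) < 2:
        raise ValueError("need at least 2 dyads to form pseudodyads")
    candidates = [
        (p, a) for p in participant_ids for a in administrator_ids if p != a
    ]
    if n is None:
        return PseudodyadSet(candidates, seed)
    if n > len(candidates):
        raise ValueError(
            f"requested {n} pseudodyads but only {len(candidates)} non-genuine "
            "pairings exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return PseudodyadSet([candidates[i] for i in idx], seed)


def pseudosynchrony_comparison(
    real_matrices: Mapping[str, CrossCorrMatrix] | Sequence[CrossCorrMatrix],
    pseudo_matrices: Mapping[str, CrossCorrMatrix] | Sequence[CrossCorrMatrix],
):
    """Welch comparison of per-dyad mean synchrony, real vs pseudodyads.

    Returns a :class:`dyadsync.posthoc.WelchResult`; a significant positive t
    indicates above-chance interpersonal synchrony.
    """
    from .posthoc import welch_t_from_raw

    def _means(ms) -> np.ndarray:
        vals = ms.values() if isinstance(ms, Mapping) else ms
        return np.array([m.mean() for m in vals], dtype=float)

    real = _means(real_matrices)
    pseudo = _means(pseudo_matrices)
    if len(real) < 2 or len(pseudo) < 2:
        raise ValueError("need at least 2 dyads per side for the comparison")
    return welch_t_from_raw(real, pseudo)
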