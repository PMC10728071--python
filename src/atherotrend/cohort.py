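"""Synthetic longitudinal imaging cohorts.

Generates measurement tables (and optional image stacks) with exactly the
statistical structure the state-space model assumes: per-diet-group latent
signal-area trajectories :math:`A_{t,f}` following a second-order random
walk driven by innovations :math:`\\mu_{t,f} \\sim N(0, \\sigma_2)`, observed
per mouse through multiplicative log-normal noise

.. math::

    Y \\sim \\mathrm{LogNormal}(\\log A_{t,f} - \\sigma_1^2/2,\\ \\sigma_1),

so that :math:`E[Y] = A_{t,f}` exactly.  The default configuration emulates
a four-diet mouse atherosclerosis study (high-cholesterol diet control plus
three natto-supplemented diets) with 6/6/6/3 mice per group imaged weekly
over weeks 0-10, latent areas rising from near zero to order hundreds of
pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MEASUREMENT_COLUMNS = ("mouse_id", "group", "week", "signal_area")

DEFAULT_GROUPS = ("HCD", "HCD+HVK", "HCD+LVK", "HCD+NN")
DEFAULT_N_MICE = (6, 6, 6, 3)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    Parameters
    ----------
    n_weeks : int
        Number of weekly observation time points T (weeks 0 .. T-1).
    groups : sequence of str
        Ordered diet-group labels; the first group is the control
        (food index f = 1).
    n_mice : sequence of int
        Mice per group, aligned with ``groups``.
    sigma_obs : float
        Observation noise scale sigma_1 on the log scale (dimensionless).
    sigma_state : float
        Innovation scale sigma_2 of the latent trend, in pixel-area units.
    seed : int
        Master seed; per-group and per-image streams are derived from it.
    image_shape : (int, int), optional
        If set, synthetic images of this shape can be rendered.
    scale_min, scale_max : int
        Fixed color-scale bounds (counts) used when rendering images.
    max_redraws : int
        Cap on rejection redraws per group when enforcing positive latents.
    """

    n_weeks: int = 11
    groups: Sequence[str] = DEFAULT_GROUPS
    n_mice: Sequence[int] = DEFAULT_N_MICE
    sigma_obs: float = 0.3
    sigma_state: float = 30.0
    seed: int = 0
    image_shape: Optional[tuple] = None
    scale_min: int = 337
    scale_max: int = 1020
    max_redraws: int = 1000

    def __post_init__(self):
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be >= 2")
        if len(self.groups) < 1:
            raise ValueError("at least one group required")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if len(self.n_mice) != len(self.groups):
            raise ValueError("n_mice must align with groups")
        if any(int(n) < 1 for n in self.n_mice):
            raise ValueError("all group sizes must be >= 1")
        if not self.sigma_obs > 0:
            raise ValueError("sigma_obs must be > 0")
        if self.sigma_state < 0:
            raise ValueError("sigma_state must be >= 0")
        if self.image_shape is not None:
            r, c = self.image_shape
            if r < 1 or c < 1:
                raise ValueError("image_shape entries must be positive")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class LatentTrajectory:
    """Latent per-group trajectories A [T x F] and their innovations mu."""

    A: np.ndarray
    mu: np.ndarray
    groups: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.A.shape != self.mu.shape:
            raise ValueError("A and mu must share a shape")
        if not np.allclose(self.A, latent_from_innovations(self.mu),
                           rtol=1e-10, atol=1e-8):
            raise ValueError("A does not satisfy the trend recursion for mu")


def latent_from_innovations(mu: np.ndarray) -> np.ndarray:
    """Latent trajectory A from trend innovations mu.

    Implements the second-order random walk
    ``A_t = 2 A_{t-1} - A_{t-2} + mu_t`` with the convention
    ``A_0 = A_{-1} = 0`` (so A_1 = mu_1 and A_2 = 2 mu_1 + mu_2), which is
    equivalent to a double cumulative sum of the innovations along time.
    Columns are independent groups.

    Parameters
    ----------
    mu : array, shape (T,) or (T, F)

    Returns
    -------
    array of the same shape.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.ndim not in (1, 2):
        raise ValueError("mu must be 1-D or 2-D (time x group)")
    if mu.size and not np.all(np.isfinite(mu)):
        raise ValueError("mu contains non-finite entries")
    return np.cumsum(np.cumsum(mu, axis=0), axis=0)


def innovations_from_latent(A: np.ndarray) -> np.ndarray:
    """Invert :func:`latent_from_innovations` (second difference with A_0 = A_{-1} = 0)."""
    A = np.asarray(A, dtype=float)
    if A.ndim not in (1, 2):
        raise ValueError("A must be 1-D or 2-D (time x group)")
    if A.size and not np.all(np.isfinite(A)):
        raise ValueError("A contains non-finite entries")
    pad = np.zeros((2,) + A.shape[1:], dtype=float)
    Ap = np.concatenate([pad, A], axis=0)
    return np.diff(Ap, n=2, axis=0)


def _group_rng(seed: int, f: int, stream: int = 0) -> np.random.Generator:
    # keyed streams: one master seed, fixed per-(purpose, group) offsets
    return np.random.default_rng([seed, stream, f])


def draw_innovations(config: CohortConfig, f: int) -> np.ndarray:
    """Draw one group's innovation column mu ~ N(0, sigma_state), rejecting
    any draw whose implied latent trajectory is not strictly positive.

    Rejection keeps the generative model inside the support of the
    log-normal observation likelihood (which needs log A).
    """
    if config.sigma_state == 0:
        raise ValueError(
            "sigma_state = 0 cannot produce a strictly positive latent "
            "trajectory; supply true_mu explicitly")
    rng = _group_rng(config.seed, f, stream=1)
    for _ in range(config.max_redraws):
        mu = rng.normal(0.0, config.sigma_state, size=config.n_weeks)
        if np.all(latent_from_innovations(mu) > 0):
            return mu
    raise RuntimeError(
        f"could not draw a positive latent trajectory for group "
        f"{config.groups[f]!r} in {config.max_redraws} attempts; "
        f"sigma_state={config.sigma_state} is likely too large relative to "
        f"the trend scale")


def simulate_cohort(config: CohortConfig,
                    true_mu: Optional[np.ndarray] = None,
                    ) -> tuple[LatentTrajectory, pd.DataFrame]:
    """Simulate latent trajectories and per-mouse weekly measurements.

    Parameters
    ----------
    config : CohortConfig
    true_mu : array (T, F), optional
        Innovations to use instead of drawing them; the implied latent
        trajectory must be strictly positive.

    Returns
    -------
    (LatentTrajectory, DataFrame)
        The ground truth and a long-format table with columns
        ``mouse_id, group, week, signal_area``.  Fully reproducible from
        ``config.seed``.
    """
    T, F = config.n_weeks, config.n_groups
    if true_mu is not None:
        mu = np.asarray(true_mu, dtype=float)
        if mu.shape != (T, F):
            raise ValueError(f"true_mu must have shape {(T, F)}")
        A = latent_from_innovations(mu)
        if not np.all(A > 0):
            raise ValueError("true_mu implies a non-positive latent area")
    else:
        mu = np.column_stack([draw_innovations(config, f) for f in range(F)])
        A = latent_from_innovations(mu)

    s1 = config.sigma_obs
    rows = []
    for f, (label, n) in enumerate(zip(config.groups, config.n_mice)):
        rng = _group_rng(config.seed, f, stream=2)
        # E[Y] = A exactly: location log A - sigma1^2 / 2
        z = rng.standard_normal((T, int(n)))
        y = A[:, f:f + 1] * np.exp(s1 * z - 0.5 * s1 * s1)
        for i in range(int(n)):
            mouse = f"{label}_m{i + 1}"
            for t in range(T):
                rows.append((mouse, label, t, y[t, i]))
    table = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    return LatentTrajectory(A=A, mu=mu, groups=tuple(config.groups)), table


def example_true_latents(n_weeks: int = 11, groups: Sequence[str] = DEFAULT_GROUPS,
                         ) -> np.ndarray:
    """Smooth reference trajectories shaped like the magnitudes a
    high-cholesterol-diet study reports: the control, low-K2 and plain natto
    groups reach ~100 px by week 5 and ~300 px by week 10, the high-K2
    group ~75 and ~200.  Returned as the innovation matrix mu whose double
    cumulative sum is the trajectory (piecewise-linear ramps, strictly
    positive).
    """
    week = np.arange(n_weeks, dtype=float)
    targets = {"fast": (100.0, 300.0), "slow": (75.0, 200.0)}
    cols = []
    for g in groups:
        lo, hi = targets["slow"] if "HVK" in g else targets["fast"]
        a = np.interp(week, [0, 5, 10], [2.0, lo, hi])
        cols.append(a)
    A = np.column_stack(cols)
    return innovations_from_latent(A)


# ---------------------------------------------------------------------------
# measurement-table I/O

def write_measurements(table: pd.DataFrame, path) -> None:
    """Write the long-format measurement table as UTF-8 CSV."""
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    table.loc[:, list(MEASUREMENT_COLUMNS)].to_csv(
        path, index=False, float_format="%.10g")


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV (``mouse_id,group,week,signal_area``)."""
    table = pd.read_csv(path, dtype={"mouse_id": str, "group": str})
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    table["week"] = table["week"].astype(int)
    table["signal_area"] = table["signal_area"].astype(float)
    return table


# ---------------------------------------------------------------------------
# synthetic image rendering

@dataclass
class SyntheticImageSet:
    """Stack of rendered grayscale frames with one shared ROI mask.

    ``targets[i]`` is the exact number of supra-threshold ROI pixels in
    ``images[i]``; the quantification stage must recover it exactly.
    """

    images: np.ndarray          # (N, H, W) uint16
    roi_mask: np.ndarray        # (H, W) bool
    targets: np.ndarray         # (N,) int
    index: pd.DataFrame         # mouse_id, group, week, signal_area, target


def default_roi_mask(image_shape: tuple) -> np.ndarray:
    """Centered rectangular ROI covering ~1/4 of the frame (a stand-in for
    a manually traced thoracic-aorta outline)."""
    h, w = image_shape
    mask = np.zeros((h, w), dtype=bool)
    mask[h // 4: h - h // 4, w // 4: w - w // 4] = True
    return mask


def render_synthetic_images(measurements: pd.DataFrame, config: CohortConfig,
                            roi_mask: Optional[np.ndarray] = None,
                            ) -> SyntheticImageSet:
    """Render one grayscale frame per measurement row.

    Each frame contains exactly ``round(signal_area)`` ROI pixels with
    intensity strictly above ``scale_min``; every other pixel (ROI or
    background) carries noise at or below ``scale_min``, emulating the
    fixed color-scale convention under which the scale floor is background.
    """
    if config.image_shape is None:
        raise ValueError("config.image_shape must be set to render images")
    shape = tuple(config.image_shape)
    if roi_mask is None:
        roi_mask = default_roi_mask(shape)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != shape:
        raise ValueError("roi_mask shape must match image_shape")
    roi_idx = np.flatnonzero(roi_mask.ravel())
    n_roi = roi_idx.size

    lo, hi = config.scale_min, config.scale_max
    images = np.empty((len(measurements), *shape), dtype=np.uint16)
    targets = np.empty(len(measurements), dtype=int)
    for i, (_, row) in enumerate(measurements.iterrows()):
        target = int(round(float(row["signal_area"])))
        if target < 0:
            raise ValueError(f"row {i}: negative signal_area")
        if target > n_roi:
            raise ValueError(
                f"row {i}: target area {target} exceeds ROI size {n_roi}")
        rng = np.random.default_rng([config.seed, 3, i])
        flat = rng.integers(0, lo + 1, size=shape[0] * shape[1])
        hot = rng.choice(roi_idx, size=target, replace=False)
        flat[hot] = rng.integers(lo + 1, hi + 1, size=target)
        images[i] = flat.reshape(shape).astype(np.uint16)
        targets[i] = target

    index = measurements.reset_index(drop=True).copy()
    index["target"] = targets
    return SyntheticImageSet(images=images, roi_mask=roi_mask,
                             targets=targets, index=index)
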