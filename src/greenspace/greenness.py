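"""Annual NDVI phenology metrics: maximum NDVI (MXN) and time-integrated NDVI (TIN).

The input is a per-pixel time series of NDVI values on a 0-100 percent
scale, typically one value per period (e.g. monthly composites) over one
year. Two summaries are computed per pixel:

* **MXN** — the maximum of the series: the densest greenness reached at
  any point in the year.
* **TIN** — the average greenness *in excess of the dormant-season
  baseline* over the growing season: a seasonality-aware measure that
  rewards a long, productive growing season rather than a single green
  peak.

The TIN here is defined operationally as follows (all constants are
exposed on :class:`PhenologyConfig`):

1. Smooth the series with a circular moving average (window 3) — the year
   is treated as periodic.
2. ``baseline`` = minimum of the smoothed series; ``amplitude`` = smoothed
   maximum minus baseline. Zero amplitude (flat series) gives TIN = 0 and
   an empty season.
3. The growing season is the longest contiguous circular run of periods
   whose smoothed value reaches ``baseline + onset_fraction * amplitude``
   (onset fraction 0.10); ties are broken toward the earlier run. Run
   endpoints whose *raw* value is still below the threshold are trimmed,
   so smoothing cannot leak dormant periods into the season.
4. TIN = mean over the season of (raw NDVI - baseline), floored at 0.

This keeps TIN on the same 0-100 scale as MXN and guarantees
``0 <= TIN <= MXN <= 100`` pixelwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import RasterGrid

__all__ = [
    "PhenologyConfig",
    "NDVIStack",
    "GreennessRaster",
    "compute_mxn",
    "compute_tin",
    "compute_greenness",
]


@dataclass(frozen=True)
class PhenologyConfig:
    """Tunable constants of the TIN definition.

    smooth_window : odd moving-average window (periods), default 3.
    onset_fraction : fraction of amplitude above baseline that marks the
        growing season, default 0.10.
    """

    smooth_window: int = 3
    onset_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        if not 0.0 < self.onset_fraction < 1.0:
            raise ValueError("onset_fraction must be in (0, 1)")


@dataclass
class NDVIStack:
    """A T-period NDVI raster time series on a fixed grid.

    ``values`` has shape (T, n_rows, n_cols); NaN marks nodata. All
    non-nodata values must lie in [0, 100].
    """

    grid: RasterGrid
    periods: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (T, rows, cols) array")
        t, r, c = self.values.shape
        if t < 4:
            raise ValueError("an NDVI stack needs at least 4 periods")
        if len(self.periods) != t:
            raise ValueError("period labels do not match the number of bands")
        if (r, c) != self.grid.shape:
            raise ValueError("values shape does not match the grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("NDVI values must lie in [0, 100]")

    @property
    def n_periods(self) -> int:
        return self.values.shape[0]


@dataclass
class GreennessRaster:
    """Per-pixel MXN/TIN bands plus diagnostic season indices.

    ``season_start``/``season_end`` hold period indices (inclusive,
    circular) of the growing season; -1 marks pixels with no season
    (nodata or zero amplitude).
    """

    grid: RasterGrid
    mxn: np.ndarray
    tin: np.ndarray
    season_start: np.ndarray
    season_end: np.ndarray
    config: PhenologyConfig = field(default_factory=PhenologyConfig)


def _circular_smooth(x: np.ndarray, window: int, axis: int = 0) -> np.ndarray:
    """Moving average with periodic (wrap-around) boundary handling."""
    if window == 1:
        return np.asarray(x, dtype=float)
    half = window // 2
    out = np.zeros_like(x, dtype=float)
    for k in range(-half, half + 1):
        out += np.roll(x, -k, axis=axis)
    return out / window


def _longest_circular_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest circular run of True; earliest start wins ties."""
    t = mask.size
    if mask.all():
        return 0, t
    if not mask.any():
        return -1, 0
    doubled = np.concatenate([mask, mask])
    # run_from[i] = length of consecutive True starting at i in doubled
    run_from = np.zeros(2 * t, dtype=int)
    for i in range(2 * t - 1, -1, -1):
        if doubled[i]:
            run_from[i] = 1 + (run_from[i + 1] if i + 1 < 2 * t else 0)
    lengths = np.minimum(run_from[:t], t)
    start = int(np.argmax(lengths))
    return start, int(lengths[start])


def compute_mxn(series: np.ndarray) -> float:
    """Maximum over non-nodata periods; NaN if every period is nodata."""
    series = np.asarray(series, dtype=float)
    if not np.isfinite(series).any():
        return float("nan")
    return float(np.nanmax(series))


def compute_tin(
    series: np.ndarray, config: PhenologyConfig | None = None
) -> tuple[float, int, int]:
    """Time-integrated NDVI of one pixel series.

    Returns ``(tin, season_start, season_end)`` with season indices into
    the original series (inclusive, possibly wrapping past the year end);
    ``(-1, -1)`` marks an empty season. Fewer than 4 valid periods gives
    ``(nan, -1, -1)``.
    """
    config = config or PhenologyConfig()
    series = np.asarray(series, dtype=float)
    valid = np.isfinite(series)
    if valid.sum() < 4:
        return float("nan"), -1, -1
    idx = np.flatnonzero(valid)
    raw = series[valid]

    smoothed = _circular_smooth(raw, config.smooth_window)
    baseline = float(smoothed.min())
    amplitude = float(smoothed.max()) - baseline
    if amplitude <= 0:
        return 0.0, -1, -1
    threshold = baseline + config.onset_fraction * amplitude

    start, length = _longest_circular_run(smoothed >= threshold)
    t = raw.size
    # trim endpoints whose raw value has not yet reached the threshold
    while length > 0 and raw[start % t] < threshold:
        start += 1
        length -= 1
    while length > 0 and raw[(start + length - 1) % t] < threshold:
        length -= 1
    if length == 0:
        return 0.0, -1, -1
    season = raw[(start + np.arange(length)) % t]
    tin = max(0.0, float(np.mean(season - baseline)))
    s = int(idx[start % t])
    e = int(idx[(start + length - 1) % t])
    return tin, s, e


def _greenness_dense(values: np.ndarray, config: PhenologyConfig):
    """Vectorized MXN/TIN over an all-valid (T, rows, cols) block."""
    t, nr, nc = values.shape
    mxn = values.max(axis=0)

    smoothed = _circular_smooth(values, config.smooth_window, axis=0)
    baseline = smoothed.min(axis=0)
    amplitude = smoothed.max(axis=0) - baseline
    threshold = baseline + config.onset_fraction * amplitude
    mask = smoothed >= threshold[None]

    # longest circular run per pixel: run_from on the doubled mask
    doubled = np.concatenate([mask, mask], axis=0)
    run_from = np.zeros((2 * t, nr, nc), dtype=np.int32)
    for i in range(2 * t - 1, -1, -1):
        nxt = run_from[i + 1] if i + 1 < 2 * t else 0
        run_from[i] = np.where(doubled[i], 1 + nxt, 0)
    lengths = np.minimum(run_from[:t], t)
    start = lengths.argmax(axis=0).astype(np.int64)
    length = np.take_along_axis(lengths, start[None], axis=0)[0].astype(np.int64)
    all_true = mask.all(axis=0)
    start[all_true] = 0
    length[all_true] = t

    flatv = values.reshape(t, -1)
    cols = np.arange(flatv.shape[1])
    startf = start.ravel()
    lengthf = length.ravel()
    thrf = threshold.ravel()
    for _ in range(t):  # trim front
        front = flatv[startf % t, cols]
        bad = (lengthf > 0) & (front < thrf)
        if not bad.any():
            break
        startf[bad] += 1
        lengthf[bad] -= 1
    for _ in range(t):  # trim back
        back = flatv[(startf + np.maximum(lengthf, 1) - 1) % t, cols]
        bad = (lengthf > 0) & (back < thrf)
        if not bad.any():
            break
        lengthf[bad] -= 1

    total = np.zeros(flatv.shape[1])
    for k in range(t):
        inside = k < lengthf
        if not inside.any():
            break
        total[inside] += flatv[(startf[inside] + k) % t, cols[inside]]
    tin = total / np.where(lengthf > 0, lengthf, 1) - baseline.ravel()
    tin = np.maximum(tin, 0.0)

    empty = (lengthf == 0) | (amplitude.ravel() <= 0)
    tin[empty] = 0.0
    startf = startf % t
    endf = (startf + lengthf - 1) % t
    startf = np.where(empty, -1, startf)
    endf = np.where(empty, -1, endf)
    return (
        mxn,
        tin.reshape(nr, nc),
        startf.reshape(nr, nc).astype(np.int32),
        endf.reshape(nr, nc).astype(np.int32),
    )


def compute_greenness(
    stack: NDVIStack, config: PhenologyConfig | None = None
) -> GreennessRaster:
    """Apply :func:`compute_mxn` / :func:`compute_tin` to every pixel.

    Pixels with every period valid go through a vectorized path; pixels
    containing nodata fall back to the per-pixel routines. Pixels with
    fewer than 4 valid periods propagate nodata (NaN) in both bands.
    """
    config = config or PhenologyConfig()
    values = stack.values
    t, nr, nc = values.shape

    finite = np.isfinite(values)
    dense = finite.all(axis=0)

    mxn = np.full((nr, nc), np.nan)
    tin = np.full((nr, nc), np.nan)
    s0 = np.full((nr, nc), -1, dtype=np.int32)
    s1 = np.full((nr, nc), -1, dtype=np.int32)

    if dense.any():
        dm, dt, ds, de = _greenness_dense(values[:, dense].reshape(t, -1, 1), config)
        mxn[dense] = dm[:, 0]
        tin[dense] = dt[:, 0]
        s0[dense] = ds[:, 0]
        s1[dense] = de[:, 0]

    sparse = ~dense & finite.any(axis=0)
    for r, c in zip(*np.nonzero(sparse)):
        series = values[:, r, c]
        mxn[r, c] = compute_mxn(series)
        tv, ss, se = compute_tin(series, config)
        tin[r, c] = tv
        s0[r, c] = ss
        s1[r, c] = se

    return GreennessRaster(
        grid=stack.grid, mxn=mxn, tin=tin, season_start=s0, season_end=s1, config=config
    )
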