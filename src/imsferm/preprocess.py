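"""Raw GC-IMS spectra to an aligned cube and a non-negative unfolded matrix.

The chain mirrors standard GC-IMS chemometric preprocessing:

1. retention-direction binning (mean of consecutive spectra) for data
   reduction,
2. reactant-ion-peak (RIP) detection and normalization of the drift axis to
   RIP-relative units,
3. cubic-spline resampling onto a shared uniform RIPrel grid,
4. cropping to the informative window (1.03-2.0 RIPrel, 150-600 s),
5. baseline correction along both axes,
6. averaging of duplicate measurements per sample,
7. stacking into a samples x retention x drift cube and row-wise unfolding
   into the S x (R*D) matrix consumed by PCA and NNMF.

Intensities are clipped at zero after baseline correction so the unfolded
matrix satisfies the non-negativity NNMF requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import minimum_filter1d, uniform_filter1d

__all__ = [
    "GCIMSSpectrum",
    "SpectrumCube",
    "UnfoldedMatrix",
    "AxisMap",
    "PreprocessConfig",
    "bin_retention",
    "detect_rip",
    "normalize_and_resample",
    "default_drift_grid",
    "crop",
    "baseline_correct",
    "average_duplicates",
    "unfold",
    "refold",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

# Informative spectral window (RIPrel drift, retention seconds).
DRIFT_CROP = (1.03, 2.0)
RETENTION_CROP = (150.0, 600.0)
# Default uniform RIPrel grid: 531 drift points across the cropped window.
DEFAULT_DRIFT_POINTS = 531


def _strictly_increasing(axis: np.ndarray) -> bool:
    return bool(np.all(np.diff(axis) > 0))


@dataclass
class GCIMSSpectrum:
    """One GC-IMS measurement: an intensity matrix over retention x drift.

    ``retention_axis`` is in seconds; ``drift_axis`` in milliseconds for raw
    spectra or RIP-relative units after normalization (``drift_units``).
    """

    sample_id: str
    replicate_id: str
    intensity: np.ndarray
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    class_label: str | None = None
    drift_units: str = "ms"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.retention_axis = np.asarray(self.retention_axis, dtype=float)
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D matrix")
        r, d = self.intensity.shape
        if self.retention_axis.shape != (r,) or self.drift_axis.shape != (d,):
            raise ValueError(
                "axis lengths must match intensity dimensions: "
                f"{self.intensity.shape} vs ({self.retention_axis.size},"
                f" {self.drift_axis.size})"
            )
        if np.isnan(self.intensity).any():
            raise ValueError("intensity contains missing values")
        for name, axis in (
            ("retention_axis", self.retention_axis),
            ("drift_axis", self.drift_axis),
        ):
            if not _strictly_increasing(axis):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class SpectrumCube:
    """Aligned stack of preprocessed spectra on shared axes (S x R x D)."""

    intensity: np.ndarray
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    sample_ids: list[str]
    class_labels: list[str | None]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("cube intensity must be S x R x D")
        s, r, d = self.intensity.shape
        if len(self.sample_ids) != s or len(self.class_labels) != s:
            raise ValueError("label lengths must match sample count")
        if self.retention_axis.size != r or self.drift_axis.size != d:
            raise ValueError("axis lengths must match cube dimensions")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


@dataclass(frozen=True)
class AxisMap:
    """Bijection between unfolded column index and (retention, drift) index.

    Columns are retention-major: column ``c`` maps to
    ``(c // n_drift, c % n_drift)``.
    """

    n_retention: int
    n_drift: int

    def to_indices(self, column: int) -> tuple[int, int]:
        if not 0 <= column < self.n_retention * self.n_drift:
            raise IndexError(f"column {column} out of range")
        return divmod(column, self.n_drift)

    def to_column(self, retention_index: int, drift_index: int) -> int:
        if not (0 <= retention_index < self.n_retention
                and 0 <= drift_index < self.n_drift):
            raise IndexError("index out of range")
        return retention_index * self.n_drift + drift_index


@dataclass
class UnfoldedMatrix:
    """Non-negative S x (R*D) matrix with the axis map needed to refold."""

    values: np.ndarray
    axis_map: AxisMap
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    sample_ids: list[str]
    class_labels: list[str | None]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("unfolded matrix must be 2-D")
        expected = self.axis_map.n_retention * self.axis_map.n_drift
        if self.values.shape[1] != expected:
            raise ValueError("column count must equal R*D")
        if (self.values < 0).any():
            raise ValueError("unfolded matrix must be non-negative")


def bin_retention(spec: GCIMSSpectrum, factor: int = 5) -> GCIMSSpectrum:
    """Average every ``factor`` consecutive retention rows (data reduction).

    A trailing partial bin is kept and averaged over its actual row count.
    The drift axis is unchanged; the binned retention axis is the mean of
    each bin's retention times.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    r = spec.intensity.shape[0]
    if factor > r:
        raise ValueError(f"factor {factor} exceeds retention rows {r}")
    if factor == 1:
        return spec
    edges = np.arange(0, r + factor, factor)
    edges[-1] = min(edges[-1], r)
    edges = np.unique(edges)
    rows = [spec.intensity[a:b].mean(axis=0) for a, b in zip(edges, edges[1:])]
    axis = [spec.retention_axis[a:b].mean() for a, b in zip(edges, edges[1:])]
    return replace(
        spec,
        intensity=np.vstack(rows),
        retention_axis=np.asarray(axis),
    )


def detect_rip(spec: GCIMSSpectrum, analyte_exclusion: int = 5) -> float:
    """Drift time of the reactant ion peak.

    The RIP is located as the argmax of the median drift profile over the 20%
    of retention rows with the lowest analyte signal, where depletion of the
    reactant ions is weakest.  Analyte signal per row is the total intensity
    outside a small window (+/- ``analyte_exclusion`` grid steps) around the
    provisional RIP column (global drift-profile argmax).
    """
    if spec.intensity.shape[0] < 1:
        raise ValueError("spectrum must have at least one retention row")
    profile = np.median(spec.intensity, axis=0)
    span = profile.max() - profile.min()
    if not span > 1e-12 * max(abs(profile.max()), 1.0):
        raise ValueError("flat spectrum: no unique RIP maximum")
    candidate = int(np.argmax(profile))
    lo = max(candidate - analyte_exclusion, 0)
    hi = min(candidate + analyte_exclusion + 1, spec.intensity.shape[1])
    analyte = spec.intensity.sum(axis=1) - spec.intensity[:, lo:hi].sum(axis=1)
    n_quiet = max(1, int(np.ceil(0.2 * spec.intensity.shape[0])))
    quiet_rows = np.argsort(analyte, kind="stable")[:n_quiet]
    quiet_profile = np.median(spec.intensity[quiet_rows], axis=0)
    return float(spec.drift_axis[int(np.argmax(quiet_profile))])


def default_drift_grid(
    lo: float = DRIFT_CROP[0],
    hi: float = DRIFT_CROP[1],
    n_points: int = DEFAULT_DRIFT_POINTS,
) -> np.ndarray:
    """Uniform RIPrel drift grid; 531 points across 1.03-2.0 by default."""
    return np.linspace(lo, hi, n_points)


def normalize_and_resample(
    spec: GCIMSSpectrum, rip: float, grid: np.ndarray
) -> GCIMSSpectrum:
    """Normalize the drift axis to RIPrel and resample onto a uniform grid.

    Each retention row is interpolated by a cubic spline over the RIPrel
    source axis ``drift_axis / rip``; grid points outside the source range
    are set to zero.  The grid must not extend beyond the source range by
    more than one grid step.
    """
    if not rip > 0:
        raise ValueError("rip must be strictly positive")
    grid = np.asarray(grid, dtype=float)
    if not _strictly_increasing(grid):
        raise ValueError("grid must be strictly increasing")
    source = spec.drift_axis / rip
    step = np.median(np.diff(grid))
    if grid[0] < source[0] - step or grid[-1] > source[-1] + step:
        raise ValueError(
            "grid extends beyond the source RIPrel range by more than one step"
        )
    inside = (grid >= source[0]) & (grid <= source[-1])
    out = np.zeros((spec.intensity.shape[0], grid.size))
    for i, row in enumerate(spec.intensity):
        spline = CubicSpline(source, row, extrapolate=False)
        out[i, inside] = spline(grid[inside])
    return replace(
        spec,
        intensity=out,
        drift_axis=grid.copy(),
        drift_units="riprel",
        metadata={**spec.metadata, "rip_drift_time": rip},
    )


def crop(
    spec: GCIMSSpectrum,
    drift_bounds: tuple[float, float] = DRIFT_CROP,
    retention_bounds: tuple[float, float] = RETENTION_CROP,
) -> GCIMSSpectrum:
    """Restrict to the informative window (inclusive bounds)."""
    if spec.drift_units != "riprel":
        raise ValueError("crop expects a RIPrel drift axis")
    dmask = (spec.drift_axis >= drift_bounds[0]) & (
        spec.drift_axis <= drift_bounds[1]
    )
    rmask = (spec.retention_axis >= retention_bounds[0]) & (
        spec.retention_axis <= retention_bounds[1]
    )
    if not dmask.any() or not rmask.any():
        raise ValueError("cropping produced an empty spectrum")
    return replace(
        spec,
        intensity=spec.intensity[np.ix_(rmask, dmask)],
        retention_axis=spec.retention_axis[rmask],
        drift_axis=spec.drift_axis[dmask],
    )


def _baseline_1d(rows: np.ndarray, window: int) -> np.ndarray:
    """Rolling-minimum baseline smoothed by a moving average, per row."""
    floor = minimum_filter1d(rows, size=window, axis=-1, mode="nearest")
    return uniform_filter1d(floor, size=window, axis=-1, mode="nearest")


def baseline_correct(
    spec: GCIMSSpectrum, window_fraction: float = 0.10
) -> GCIMSSpectrum:
    """Subtract a rolling-minimum baseline along drift, then retention.

    The window is ``window_fraction`` of the axis length (>= 3 points);
    negatives are clipped to zero, preserving the non-negativity required by
    the factorization downstream.
    """
    out = spec.intensity.copy()
    for axis in (1, 0):
        n = out.shape[axis]
        window = int(round(window_fraction * n))
        if window < 3:
            raise ValueError(
                f"baseline window of {window} points (< 3) along axis {axis};"
                " spectrum too small for the requested window fraction"
            )
        moved = np.moveaxis(out, axis, -1)
        moved -= _baseline_1d(moved, window)
        out = np.moveaxis(moved, -1, axis)
    return replace(spec, intensity=np.clip(out, 0.0, None))


def average_duplicates(specs: Sequence[GCIMSSpectrum]) -> list[GCIMSSpectrum]:
    """Average replicate measurements per sample (elementwise mean).

    Spectra are grouped by ``sample_id``; all replicates of a sample must be
    on identical axes.  Samples with a single replicate pass through with a
    logged warning.
    """
    groups: dict[str, list[GCIMSSpectrum]] = {}
    order: list[str] = []
    for spec in specs:
        if spec.sample_id not in groups:
            order.append(spec.sample_id)
        groups.setdefault(spec.sample_id, []).append(spec)
    averaged = []
    for sample_id in order:
        reps = groups[sample_id]
        first = reps[0]
        for rep in reps[1:]:
            if not (
                np.array_equal(rep.retention_axis, first.retention_axis)
                and np.array_equal(rep.drift_axis, first.drift_axis)
            ):
                raise ValueError(
                    f"replicates of sample {sample_id!r} are on different axes"
                )
        if len(reps) == 1:
            logger.warning(
                "sample %s has a single replicate; passing through", sample_id
            )
        mean = np.mean([rep.intensity for rep in reps], axis=0)
        merged_meta: dict = {}
        for rep in reps:
            merged_meta.update(rep.metadata)
        merged_meta["n_replicates"] = len(reps)
        averaged.append(
            replace(first, intensity=mean, replicate_id="mean",
                    metadata=merged_meta)
        )
    return averaged


def unfold(cube: SpectrumCube) -> UnfoldedMatrix:
    """Unfold the cube row-wise into S x (R*D); columns retention-major."""
    s, r, d = cube.shape
    values = cube.intensity.reshape(s, r * d)
    return UnfoldedMatrix(
        values=values,
        axis_map=AxisMap(n_retention=r, n_drift=d),
        retention_axis=cube.retention_axis,
        drift_axis=cube.drift_axis,
        sample_ids=list(cube.sample_ids),
        class_labels=list(cube.class_labels),
    )


def refold(row_vector: np.ndarray, axis_map: AxisMap) -> np.ndarray:
    """Refold an unfolded row back into an R x D matrix (exact inverse)."""
    row_vector = np.asarray(row_vector)
    expected = axis_map.n_retention * axis_map.n_drift
    if row_vector.size != expected:
        raise ValueError(
            f"vector length {row_vector.size} != R*D = {expected}"
        )
    return row_vector.reshape(axis_map.n_retention, axis_map.n_drift)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing chain parameters."""

    bin_factor: int = 5
    drift_bounds: tuple[float, float] = DRIFT_CROP
    retention_bounds: tuple[float, float] = RETENTION_CROP
    n_drift_points: int = DEFAULT_DRIFT_POINTS
    baseline_window_fraction: float = 0.10


def preprocess_pipeline(
    raw_specs: Sequence[GCIMSSpectrum],
    config: PreprocessConfig | None = None,
) -> tuple[SpectrumCube, UnfoldedMatrix]:
    """Full chain: bin -> RIP-normalize -> crop -> baseline -> average -> unfold."""
    config = config or PreprocessConfig()
    if len({s.sample_id for s in raw_specs}) < 2:
        raise ValueError("preprocessing requires at least 2 samples")
    grid = default_drift_grid(
        config.drift_bounds[0], config.drift_bounds[1], config.n_drift_points
    )
    processed = []
    for spec in raw_specs:
        binned = bin_retention(spec, config.bin_factor)
        rip = detect_rip(binned)
        aligned = normalize_and_resample(binned, rip, grid)
        cropped = crop(aligned, config.drift_bounds, config.retention_bounds)
        corrected = baseline_correct(cropped, config.baseline_window_fraction)
        processed.append(corrected)
    logger.info(
        "preprocessed %d raw spectra to %s grids",
        len(processed),
        processed[0].shape,
    )
    averaged = average_duplicates(processed)
    first = averaged[0]
    for spec in averaged[1:]:
        if spec.shape != first.shape:
            raise ValueError("averaged spectra disagree in shape")
    cube = SpectrumCube(
        intensity=np.stack([s.intensity for s in averaged]),
        retention_axis=first.retention_axis,
        drift_axis=first.drift_axis,
        sample_ids=[s.sample_id for s in averaged],
        class_labels=[s.class_label for s in averaged],
    )
    logger.info("cube shape %s", cube.shape)
    return cube, unfold(cube)
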