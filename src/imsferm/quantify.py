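"""Peak detection, plateau-based volume integration and microbe-VOC screens.

Quantification in GC-IMS fingerprinting is semi-quantitative: a 2-D peak's
volume is the summed intensity above the "plateau" formed by the local
minimum ring around it.  Here the footprint is grown from the apex by a
flood fill that follows non-increasing intensity outward; the first cells
where intensity rises again (or the floor is reached) form the boundary
ring, whose median intensity defines the plateau.  The raw volume is the sum
of (intensity - plateau) over footprint cells above the plateau, which makes
the measure invariant to a constant pedestal and exactly linear in intensity
scale.  Volumes are normalized to the cell count of a pre-selected
per-compound window so differently sized integration windows stay
comparable.

Peaks are annotated against a compound library (retention start + drift
position) by one-to-one nearest assignment within tolerances; fold changes
between sample groups and a Pearson correlation screen against per-sample
microbial presence complete the semi-quantitative picture.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .preprocess import SpectrumCube
from .simulate import COMPOUND_TABLE, _DEFAULT_DT_SIGMA_RIPREL, \
    _DEFAULT_RT_SIGMA_S, _RT_CENTER_OFFSET_S

__all__ = [
    "PeakRegion",
    "CompoundLibrary",
    "default_library",
    "find_peaks_2d",
    "integrate_peak",
    "normalize_volume",
    "annotate",
    "fold_change",
    "PresenceFlag",
    "correlate_microbes",
    "volume_table",
    "sample_volume_table",
    "class_mean_spectra",
]

logger = logging.getLogger(__name__)

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class PeakRegion:
    """An integrated 2-D peak."""

    apex: tuple[int, int]            # (retention index, drift index)
    footprint: set[tuple[int, int]]
    plateau_level: float
    raw_volume: float
    normalized_volume: float | None = None
    compound: str | None = None

    def __post_init__(self) -> None:
        if self.raw_volume < 0:
            raise ValueError("raw_volume must be >= 0")
        if self.apex not in self.footprint:
            raise ValueError("apex must lie inside the footprint")


@dataclass
class CompoundLibrary:
    """Per-compound positions, integration windows and annotations.

    Columns: name, rt_center_s, drift_riprel, window_rt_halfwidth_s,
    window_dt_halfwidth, descriptor.  Drift positions not measured on this
    instrument are synthetic fixture values.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "name", "rt_center_s", "drift_riprel",
            "window_rt_halfwidth_s", "window_dt_halfwidth",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"library is missing columns {sorted(missing)}")
        if self.table["name"].duplicated().any():
            raise ValueError("compound names must be unique")

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def row(self, name: str) -> pd.Series:
        hit = self.table[self.table["name"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CompoundLibrary":
        return cls(pd.read_csv(path))


def default_library(window_sigmas: float = 3.0) -> CompoundLibrary:
    """Library built from the packaged position fixture with +/-3-sigma windows."""
    rows = [
        {
            "name": name,
            "rt_center_s": rt_start + _RT_CENTER_OFFSET_S,
            "drift_riprel": drift,
            "window_rt_halfwidth_s": window_sigmas * _DEFAULT_RT_SIGMA_S,
            "window_dt_halfwidth": window_sigmas * _DEFAULT_DT_SIGMA_RIPREL,
            "descriptor": descriptor,
        }
        for name, (rt_start, drift, descriptor) in COMPOUND_TABLE.items()
    ]
    return CompoundLibrary(pd.DataFrame(rows))


def find_peaks_2d(
    spectrum: np.ndarray, min_intensity_frac: float = 0.02
) -> list[tuple[int, int]]:
    """Apexes: cells strictly greater than all 8 neighbours and above
    ``min_intensity_frac`` of the global maximum, sorted by intensity
    descending."""
    spectrum = np.asarray(spectrum, float)
    if spectrum.size == 0 or spectrum.max() <= 0:
        return []
    ring = np.ones((3, 3), dtype=bool)
    ring[1, 1] = False
    neighbour_max = maximum_filter(
        spectrum, footprint=ring, mode="constant", cval=-np.inf
    )
    mask = (spectrum > neighbour_max) & (
        spectrum >= min_intensity_frac * spectrum.max()
    )
    apexes = list(zip(*np.nonzero(mask)))
    apexes.sort(key=lambda rc: -spectrum[rc])
    return [(int(r), int(c)) for r, c in apexes]


def integrate_peak(
    spectrum: np.ndarray,
    apex: tuple[int, int],
    floor: float = 0.0,
    bounds: tuple[int, int, int, int] | None = None,
) -> PeakRegion:
    """Plateau-based 2-D integration by steepest-descent flood fill.

    Cells are collected outward from the apex while intensity is
    non-increasing; the first cells where it rises again, or cells at or
    below ``floor``, form the boundary ring.  The plateau is the median
    boundary intensity; the raw volume is the intensity above the plateau
    summed over footprint cells.  ``bounds`` (r_lo, r_hi, d_lo, d_hi,
    half-open) confines the fill to a window; window and grid edges
    contribute the edge cell's own intensity to the boundary ring.
    """
    spectrum = np.asarray(spectrum, float)
    r0, d0 = apex
    nr, nd = spectrum.shape
    if bounds is None:
        bounds = (0, nr, 0, nd)
    r_lo, r_hi, d_lo, d_hi = bounds
    if not (r_lo <= r0 < r_hi and d_lo <= d0 < d_hi):
        raise ValueError("apex outside the integration bounds")
    apex_value = spectrum[r0, d0]
    # numerically-equal cells (saturated plateau tops, interpolation noise)
    # count as non-increasing, so the footprint is stable under roundoff
    rise_tol = 1e-9 * abs(apex_value)
    for dr, dc in _NEIGHBOURS:
        rr, cc = r0 + dr, d0 + dc
        if r_lo <= rr < r_hi and d_lo <= cc < d_hi:
            if spectrum[rr, cc] > apex_value + rise_tol:
                raise ValueError("apex is not a local maximum")
    region: set[tuple[int, int]] = {(r0, d0)}
    boundary_values: list[float] = []
    queue: deque[tuple[int, int]] = deque([(r0, d0)])
    while queue:
        r, c = queue.popleft()
        value = spectrum[r, c]
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if not (r_lo <= rr < r_hi and d_lo <= cc < d_hi):
                boundary_values.append(value)  # truncated at the window edge
                continue
            if (rr, cc) in region:
                continue
            nb = spectrum[rr, cc]
            if nb > value + rise_tol:
                boundary_values.append(nb)  # intensity rises: boundary ring
            elif nb <= floor + rise_tol:
                boundary_values.append(nb)  # floor reached
            else:
                region.add((rr, cc))
                queue.append((rr, cc))
    plateau = float(np.median(boundary_values)) if boundary_values else floor
    plateau = min(plateau, apex_value)
    footprint = {cell for cell in region if spectrum[cell] > plateau}
    footprint.add((r0, d0))
    raw_volume = float(
        sum(max(spectrum[cell] - plateau, 0.0) for cell in footprint)
    )
    return PeakRegion(
        apex=(r0, d0),
        footprint=footprint,
        plateau_level=plateau,
        raw_volume=raw_volume,
    )


def normalize_volume(region: PeakRegion, window_cells: int) -> float:
    """Raw volume divided by the pre-selected window's cell count."""
    if window_cells < 1:
        raise ValueError("window must contain at least one cell")
    region.normalized_volume = region.raw_volume / window_cells
    return region.normalized_volume


def annotate(
    apex_positions: list[tuple[float, float]],
    library: CompoundLibrary,
    rt_tol: float = 5.0,
    dt_tol: float = 0.01,
) -> list[str]:
    """Assign compounds to apexes one-to-one by increasing distance.

    ``apex_positions`` are (retention s, drift RIPrel).  Distances are
    normalized by the tolerances; an apex with no library entry within both
    tolerances, or whose nearest entries are taken by closer apexes, is
    labelled ``"unknown"``.
    """
    names = library.names
    candidates = []
    for i, (rt, dt) in enumerate(apex_positions):
        for name in names:
            row = library.row(name)
            drt = abs(rt - row["rt_center_s"])
            ddt = abs(dt - row["drift_riprel"])
            if drt <= rt_tol and ddt <= dt_tol:
                dist = np.hypot(drt / rt_tol, ddt / dt_tol)
                candidates.append((dist, i, name))
    candidates.sort(key=lambda t: t[0])
    assigned: list[str] = ["unknown"] * len(apex_positions)
    used: set[str] = set()
    for _, i, name in candidates:
        if assigned[i] != "unknown" or name in used:
            continue
        assigned[i] = name
        used.add(name)
    return assigned


@dataclass(frozen=True)
class PresenceFlag:
    """Fold change degenerates to presence/absence when one side is zero."""

    present_in: str


def fold_change(
    volumes_a, volumes_b, compound: str | None = None
) -> float | PresenceFlag:
    """Ratio a / b of a compound's volumes in two groups.

    Accepts scalars or per-compound mappings (then ``compound`` selects the
    entry).  A zero denominator or numerator is flagged as presence/absence
    rather than returned as a ratio.
    """
    if compound is not None:
        volumes_a = volumes_a[compound]
        volumes_b = volumes_b[compound]
    a, b = float(volumes_a), float(volumes_b)
    if a < 0 or b < 0:
        raise ValueError("volumes must be non-negative")
    if b == 0 and a == 0:
        raise ValueError("compound absent from both groups")
    if b == 0:
        return PresenceFlag(present_in="a")
    if a == 0:
        return PresenceFlag(present_in="b")
    return a / b


def _window_indices(
    axis: np.ndarray, center: float, halfwidth: float
) -> tuple[int, int]:
    lo = int(np.searchsorted(axis, center - halfwidth, side="left"))
    hi = int(np.searchsorted(axis, center + halfwidth, side="right"))
    return lo, hi


def _hill_climb(
    spectrum: np.ndarray, cell: tuple[int, int],
    bounds: tuple[int, int, int, int],
) -> tuple[int, int]:
    """Walk uphill to the nearest 8-neighbour local maximum within bounds."""
    r_lo, r_hi, d_lo, d_hi = bounds
    r, c = cell
    tol = 1e-9 * abs(spectrum[r, c])
    while True:
        best = (r, c)
        best_val = spectrum[r, c]
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if r_lo <= rr < r_hi and d_lo <= cc < d_hi:
                if spectrum[rr, cc] > best_val + tol:
                    best, best_val = (rr, cc), spectrum[rr, cc]
        if best == (r, c):
            return best
        r, c = best


def _integrate_window(
    spectrum: np.ndarray,
    retention_axis: np.ndarray,
    drift_axis: np.ndarray,
    row: pd.Series,
    min_intensity: float,
) -> float:
    """Normalized volume of one library compound on one spectrum (0 if absent)."""
    r_lo, r_hi = _window_indices(
        retention_axis, row["rt_center_s"], row["window_rt_halfwidth_s"]
    )
    d_lo, d_hi = _window_indices(
        drift_axis, row["drift_riprel"], row["window_dt_halfwidth"]
    )
    if r_hi - r_lo < 1 or d_hi - d_lo < 1:
        return 0.0
    window = spectrum[r_lo:r_hi, d_lo:d_hi]
    cells = window.size
    if window.max() <= min_intensity:
        return 0.0
    local = np.unravel_index(int(np.argmax(window)), window.shape)
    apex = _hill_climb(
        spectrum, (r_lo + local[0], d_lo + local[1]),
        (r_lo, r_hi, d_lo, d_hi),
    )
    region = integrate_peak(spectrum, apex, bounds=(r_lo, r_hi, d_lo, d_hi))
    return region.raw_volume / cells


def volume_table(
    spectra: dict[str, np.ndarray],
    retention_axis: np.ndarray,
    drift_axis: np.ndarray,
    library: CompoundLibrary,
    min_intensity_frac: float = 0.02,
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Normalized volumes (rows = spectra, columns = compounds).

    ``spectra`` maps a row name (a sample or a component) to its 2-D
    spectrum.  A compound with no signal above ``min_intensity_frac`` of the
    spectrum's maximum inside its window gets volume 0; compounds that are
    zero across all rows are dropped (logged).
    """
    rows = {}
    for name, spectrum in spectra.items():
        spectrum = np.asarray(spectrum, float)
        threshold = min_intensity_frac * max(spectrum.max(), 0.0)
        rows[name] = {
            compound: _integrate_window(
                spectrum, retention_axis, drift_axis,
                library.row(compound), threshold,
            )
            for compound in library.names
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[library.names]
    if drop_empty:
        empty = table.columns[(table == 0).all(axis=0)]
        if len(empty):
            logger.info(
                "dropping all-zero compound columns: %s", list(empty)
            )
            table = table.drop(columns=empty)
    return table


def sample_volume_table(
    cube: SpectrumCube, library: CompoundLibrary, **kwargs
) -> pd.DataFrame:
    """Per-sample normalized volumes from a preprocessed cube."""
    spectra = {
        sid: cube.intensity[i] for i, sid in enumerate(cube.sample_ids)
    }
    return volume_table(
        spectra, cube.retention_axis, cube.drift_axis, library, **kwargs
    )


def class_mean_spectra(cube: SpectrumCube) -> dict[str, np.ndarray]:
    """Mean preprocessed spectrum per class label."""
    labels = np.asarray([str(lab) for lab in cube.class_labels])
    return {
        cls: cube.intensity[labels == cls].mean(axis=0)
        for cls in sorted(set(labels.tolist()))
    }


def correlate_microbes(
    volumes: pd.DataFrame,
    microbes: pd.DataFrame,
    threshold: float = 0.85,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pearson correlation of compound volumes against microbial presence.

    Rows of both tables are samples (shared index); returns the compound x
    microbe correlation matrix and the pairs with |r| > threshold.  Constant
    vectors have undefined correlation and are reported as missing (NaN),
    never flagged.
    """
    shared = volumes.index.intersection(microbes.index)
    if len(shared) < 3:
        raise ValueError("correlation requires at least 3 shared samples")
    v = volumes.loc[shared]
    m = microbes.loc[shared]
    corr = pd.DataFrame(
        index=v.columns, columns=m.columns, dtype=float
    )
    for compound in v.columns:
        x = v[compound].to_numpy(float)
        for microbe in m.columns:
            y = m[microbe].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                corr.loc[compound, microbe] = np.nan
                continue
            corr.loc[compound, microbe] = float(np.corrcoef(x, y)[0, 1])
    flagged = [
        (compound, microbe, float(corr.loc[compound, microbe]))
        for compound in corr.index
        for microbe in corr.columns
        if np.isfinite(corr.loc[compound, microbe])
        and abs(corr.loc[compound, microbe]) > threshold
    ]
    return corr, flagged
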