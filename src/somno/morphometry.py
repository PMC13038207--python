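"""Landmark-anchored morphometry of PDF-immunoreactive axonal terminals.

Small ventrolateral clock neurons (s-LNvs) remodel their dorsal axonal
terminals daily: extended and branched in the morning, retracted at night.
This module quantifies that plasticity from fluorescence maxima ("foci"):
each focus is expressed in an anatomical coordinate frame anchored at the
primary axonal branching point (origin) with +y pointing toward a second,
dorsal landmark.  Terminal extension is summarised by per-axis dispersion
histograms and by the percentage of foci in the distal region ("area 2"),
defined radially as Euclidean distance from the origin beyond a configured
boundary.

Landmarks are inputs (manual annotation or generator-provided); they are
not inferred from the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .io_formats import logger
from .sleep import GroupComparison, _percent_change


@dataclass
class FociSet:
    """Fluorescence maxima of one brain in the anatomical (um) frame.

    ``foci_um`` has the origin at the primary branching point and +y toward
    the dorsal reference landmark.
    """

    brain_id: str
    genotype: str
    timepoint: str  # e.g. "ZT1-3" or "ZT13-15"
    foci_um: np.ndarray  # (n, 2)
    intensities: np.ndarray | None = None
    x_sign_arbitrary: bool = False

    def __post_init__(self) -> None:
        self.foci_um = np.asarray(self.foci_um, dtype=float).reshape(-1, 2)

    @property
    def n_foci(self) -> int:
        return int(self.foci_um.shape[0])


@dataclass
class MorphometryResult:
    """Dispersion histograms and the distal-region percentage for one brain."""

    brain_id: str
    n_foci: int
    percent_area2: float  # NaN when n_foci == 0
    dispersion_x: np.ndarray = field(default=None)  # type: ignore[assignment]
    dispersion_y: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_edges_x: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_edges_y: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Focus detection
# ---------------------------------------------------------------------------

def detect_foci(
    image: np.ndarray,
    smooth_sigma_px: float = 1.0,
    min_distance_px: int = 3,
    threshold_k: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect fluorescence maxima on a 2-D grayscale image.

    The image is Gaussian-smoothed, then local maxima separated by at least
    ``min_distance_px`` and brighter than mean + threshold_k * SD of the
    smoothed image are kept.  Returns ``(coords_xy, intensities)`` where
    coordinates are (x=col, y=row) pixels, sorted lexicographically for
    determinism (ties at min-distance conflicts resolve to the
    lexicographically smallest pixel).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_foci expects a 2-D grayscale image")
    if not np.isfinite(image).all() or (image < 0).any():
        raise ValueError("image must be finite and non-negative")
    smoothed = gaussian(image, sigma=smooth_sigma_px, preserve_range=True)
    if np.ptp(smoothed) == 0:
        logger.warning("constant image: no foci detectable")
        return np.empty((0, 2)), np.empty(0)
    threshold = smoothed.mean() + threshold_k * smoothed.std()
    peaks_rc = peak_local_max(
        smoothed, min_distance=min_distance_px, threshold_abs=threshold
    )
    if peaks_rc.size == 0:
        return np.empty((0, 2)), np.empty(0)
    # lexicographic (row, col) order -> deterministic output
    order = np.lexsort((peaks_rc[:, 1], peaks_rc[:, 0]))
    peaks_rc = peaks_rc[order]
    coords_xy = peaks_rc[:, ::-1].astype(float)  # (x=col, y=row)
    intensities = smoothed[peaks_rc[:, 0], peaks_rc[:, 1]]
    return coords_xy, intensities


# ---------------------------------------------------------------------------
# Anatomical frame
# ---------------------------------------------------------------------------

def to_anatomical(
    foci_px: np.ndarray,
    origin_px: tuple[float, float],
    dorsal_ref_px: tuple[float, float],
    um_per_px: float,
    brain_id: str = "",
    genotype: str = "",
    timepoint: str = "",
    intensities: np.ndarray | None = None,
) -> FociSet:
    """Map pixel foci into the branch-point-anchored anatomical frame.

    Rigid transform (translation + rotation + isotropic scale to um): the
    origin maps to (0, 0) and the dorsal reference to (0, +d) with d > 0.
    The +x direction is chosen toward the side of the foci centroid; if the
    centroid lies on the dorsal axis the choice is arbitrary and flagged.
    The result is therefore independent of the image's pixel-axis
    convention and of any rigid motion applied jointly to foci and
    landmarks.
    """
    origin = np.asarray(origin_px, dtype=float)
    dorsal = np.asarray(dorsal_ref_px, dtype=float)
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    axis = dorsal - origin
    norm = np.hypot(*axis)
    if norm == 0:
        raise ValueError("origin and dorsal reference landmarks coincide")
    u_y = axis / norm
    u_x = np.array([u_y[1], -u_y[0]])  # one of the two perpendiculars

    foci = np.asarray(foci_px, dtype=float).reshape(-1, 2) - origin
    y = foci @ u_y
    x = foci @ u_x
    x_sign_arbitrary = False
    cx = x.mean() if x.size else 0.0
    if np.isclose(cx, 0.0):
        x_sign_arbitrary = bool(x.size)
        if x_sign_arbitrary:
            logger.warning("foci centroid on dorsal axis: +x sign arbitrary")
    elif cx < 0:
        x = -x
    out = np.column_stack([x, y]) * um_per_px
    return FociSet(
        brain_id=brain_id,
        genotype=genotype,
        timepoint=timepoint,
        foci_um=out,
        intensities=None if intensities is None else np.asarray(intensities, float),
        x_sign_arbitrary=x_sign_arbitrary,
    )


# ---------------------------------------------------------------------------
# Dispersion and the distal region
# ---------------------------------------------------------------------------

def dispersion_profiles(fociset: FociSet, bin_um: float = 5.0) -> MorphometryResult:
    """Per-axis percentage histograms of foci positions.

    Bins tile a symmetric range (multiples of ``bin_um`` around 0) covering
    every focus; each histogram sums to 100.
    """
    if fociset.n_foci < 1:
        raise ValueError("dispersion_profiles needs at least one focus")
    xy = fociset.foci_um

    def _hist(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        half = max(1, int(np.ceil((np.abs(vals).max() + 1e-12) / bin_um)))
        edges = np.arange(-half, half + 1) * bin_um
        counts, _ = np.histogram(vals, bins=edges)
        return 100.0 * counts / vals.size, edges

    hx, ex = _hist(xy[:, 0])
    hy, ey = _hist(xy[:, 1])
    return MorphometryResult(
        brain_id=fociset.brain_id,
        n_foci=fociset.n_foci,
        percent_area2=float("nan"),
        dispersion_x=hx,
        dispersion_y=hy,
        bin_edges_x=ex,
        bin_edges_y=ey,
    )


def area2_percentage(fociset: FociSet, r_boundary_um: float) -> float:
    """Percent of foci in the distal region, beyond ``r_boundary_um`` from the origin.

    Returns NaN (with a log message) for an empty foci set.  The boundary is
    a required configuration parameter.
    """
    if r_boundary_um <= 0:
        raise ValueError("r_boundary_um must be positive")
    if fociset.n_foci == 0:
        logger.warning("brain %s: no foci, distal percentage undefined", fociset.brain_id)
        return float("nan")
    r = np.hypot(fociset.foci_um[:, 0], fociset.foci_um[:, 1])
    return float(100.0 * np.count_nonzero(r > r_boundary_um) / fociset.n_foci)


def analyze_brain(
    fociset: FociSet, r_boundary_um: float, bin_um: float = 5.0
) -> MorphometryResult:
    """Dispersion profiles plus the distal-region percentage for one brain."""
    res = dispersion_profiles(fociset, bin_um=bin_um)
    res.percent_area2 = area2_percentage(fociset, r_boundary_um)
    return res


def compare_area2(
    group_a: list[float], group_b: list[float], metric: str = "percent_area2"
) -> GroupComparison:
    """Two-tailed unpaired t test on per-brain distal-region percentages."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 brains per group")
    degenerate = bool(np.allclose(a, a[0]) and np.allclose(b, b[0]))
    if degenerate and np.isclose(a[0], b[0]):
        statistic, p = 0.0, 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        metric=metric,
        case_mean=float(a.mean()),
        control_mean=float(b.mean()),
        test="t_unpaired",
        statistic=statistic,
        p_raw=p,
        p_bonferroni=p,
        n_tests=1,
        percent_change=_percent_change(float(a.mean()), float(b.mean())),
        degenerate=degenerate,
    )
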