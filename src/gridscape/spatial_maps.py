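"""Firing-field analytics: rate maps, spatial autocorrelograms and gridness.

A neuron's trajectory-aligned response is binned into a rate map (mean
rectified activity per spatial bin, unvisited bins masked), the rate map is
autocorrelated over spatial lags with a Pearson coefficient per lag computed
on the overlapping visited pixels, and hexagonal symmetry is quantified by the
gridness score

    HGS = min[cor(r, r60), cor(r, r120)] - max[cor(r, r30), cor(r, r90), cor(r, r150)]

where ``r`` is the annulus-masked autocorrelogram and ``r_phi`` its rotation
by ``phi`` degrees. Positive HGS indicates six-fold (hexagonal) symmetry;
square lattices score negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import (EmptyInputError, InsufficientSamplingError,
                     InvalidShapeError, UndefinedEllipseError)
from .geometry import Environment, compartment_of
from .trajectory import Trajectory

MIN_OVERLAP_PIXELS = 20
HGS_ANGLES_ON = (60, 120)
HGS_ANGLES_OFF = (30, 90, 150)


# ---------------------------------------------------------------------------
# Rate maps
# ---------------------------------------------------------------------------

@dataclass
class RateMap:
    """Mean-activity grid. ``grid[iy, ix]``; unvisited bins are NaN."""

    grid: np.ndarray
    occupancy: np.ndarray
    bin_size: float
    extent: tuple[float, float, float, float]   # xmin, ymin, xmax, ymax

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy > 0

    def to_csv(self, path) -> None:
        np.savetxt(path, self.grid, delimiter=",")


def firing_field_map(traj: Trajectory, response: np.ndarray,
                     threshold_quantile: float = 0.8) -> np.ndarray:
    """Trajectory points where the response exceeds its given quantile."""
    response = np.asarray(response)
    if response.size == 0:
        raise EmptyInputError("empty response array")
    if len(response) != len(traj):
        raise ValueError("response and trajectory lengths differ")
    eps = np.quantile(response, threshold_quantile)
    return traj.pos[response > eps]


def rate_map(traj: Trajectory, response: np.ndarray, bin_size: float = 0.03,
             smoothing_sigma: float = 1.0,
             extent: tuple[float, float, float, float] | None = None,
             rectify: bool = True) -> RateMap:
    """Bin mean (rectified) activity on a spatial grid and smooth it.

    ``smoothing_sigma`` is in bins; smoothing is mask-normalized so unvisited
    bins neither leak into nor dilute visited ones. Unvisited bins stay NaN.
    """
    if bin_size <= 0:
        raise InvalidShapeError("bin_size must be positive")
    x, y = traj.x, traj.y
    r = np.asarray(response, dtype=float)
    if len(r) != len(traj):
        raise ValueError("response and trajectory lengths differ")
    if rectify:
        r = np.clip(r, 0.0, None)
    if extent is None:
        extent = (x.min(), y.min(), x.max(), y.max())
    xmin, ymin, xmax, ymax = extent
    nx = max(2, int(np.ceil((xmax - xmin) / bin_size - 1e-9)))
    ny = max(2, int(np.ceil((ymax - ymin) / bin_size - 1e-9)))
    if nx < 2 and ny < 2:
        raise InvalidShapeError("trajectory covers fewer than 2 bins")
    xe = xmin + np.arange(nx + 1) * bin_size
    ye = ymin + np.arange(ny + 1) * bin_size
    counts, _, _ = np.histogram2d(y, x, bins=[ye, xe])
    sums, _, _ = np.histogram2d(y, x, bins=[ye, xe], weights=r)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    visited = counts > 0
    if smoothing_sigma > 0:
        filled = np.where(visited, mean, 0.0)
        sm = ndimage.gaussian_filter(filled, smoothing_sigma)
        norm = ndimage.gaussian_filter(visited.astype(float), smoothing_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(visited, sm / norm, np.nan)
    else:
        mean = np.where(visited, mean, np.nan)
    return RateMap(grid=mean, occupancy=counts, bin_size=bin_size,
                   extent=(xmin, ymin, xmin + nx * bin_size, ymin + ny * bin_size))


# ---------------------------------------------------------------------------
# Autocorrelogram
# ---------------------------------------------------------------------------

@dataclass
class Autocorrelogram:
    """2-D spatial autocorrelation over lags; invalid lags are NaN.

    ``r`` is a square array of odd side with zero lag at the center;
    ``bin_size`` carries the spatial scale of one lag step.
    """

    r: np.ndarray
    n_pixels_used: np.ndarray
    bin_size: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.r.shape[0] // 2, self.r.shape[1] // 2)

    @property
    def max_lag_bins(self) -> int:
        return self.r.shape[0] // 2


def autocorrelogram(rmap: RateMap, max_lag: float | None = None) -> Autocorrelogram:
    """Pearson autocorrelation of the rate map at every spatial lag.

    At each lag the correlation runs over the pixels where both the map and
    its shifted copy are visited; lags with fewer than
    ``MIN_OVERLAP_PIXELS`` overlapping pixels are masked. A constant map has
    undefined correlation everywhere except zero lag; a fully masked result
    is returned with a warning.
    """
    visited = rmap.visited
    if visited.sum() < 2:
        raise InsufficientSamplingError("rate map has fewer than 2 visited bins")
    lam = np.where(visited, np.nan_to_num(rmap.grid), 0.0)
    v = visited.astype(float)

    def xcorr(a, b):
        return signal.fftconvolve(a, b[::-1, ::-1], mode="full")

    n = xcorr(v, v)
    s1 = xcorr(lam, v)
    s2 = xcorr(v, lam)
    s11 = xcorr(lam * lam, v)
    s22 = xcorr(v, lam * lam)
    s12 = xcorr(lam, lam)
    n = np.round(n)
    num = n * s12 - s1 * s2
    var1 = n * s11 - s1 ** 2
    var2 = n * s22 - s2 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(np.clip(var1, 0, None) * np.clip(var2, 0, None))
    bad = (n < MIN_OVERLAP_PIXELS) | (var1 <= 1e-12 * np.maximum(n, 1) ** 2) \
        | (var2 <= 1e-12 * np.maximum(n, 1) ** 2)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    # zero lag is 1 by definition whenever the map is non-degenerate
    cy, cx = visited.shape[0] - 1, visited.shape[1] - 1
    if np.isfinite(r[cy, cx]) or visited.sum() >= MIN_OVERLAP_PIXELS:
        if not np.isfinite(r[cy, cx]):
            warnings.warn("degenerate (constant) rate map: autocorrelogram undefined")
            r[cy, cx] = 1.0

    # crop to a centered square of half-width L
    L = min(cy, cx)
    if max_lag is not None:
        L = min(L, int(round(max_lag / rmap.bin_size)))
    r = r[cy - L:cy + L + 1, cx - L:cx + L + 1]
    n = n[cy - L:cy + L + 1, cx - L:cx + L + 1]
    return Autocorrelogram(r=r, n_pixels_used=n.astype(int), bin_size=rmap.bin_size)


# ---------------------------------------------------------------------------
# Gridness
# ---------------------------------------------------------------------------

def _radial_profile(ac: Autocorrelogram) -> tuple[np.ndarray, np.ndarray]:
    cy, cx = ac.center
    yy, xx = np.indices(ac.r.shape)
    rad = np.hypot(yy - cy, xx - cx)
    rbins = np.arange(0, ac.max_lag_bins + 1)
    prof = np.full(len(rbins), np.nan)
    idx = rad.round().astype(int)
    for k in rbins:
        vals = ac.r[(idx == k) & np.isfinite(ac.r)]
        if vals.size:
            prof[k] = vals.mean()
    return rbins, prof


def _covered_radius(ac: Autocorrelogram, min_coverage: float = 0.9) -> int:
    """Largest radius whose full circle of lags is (mostly) valid.

    On maps with anisotropic valid regions (e.g. half-arena rate maps), lags
    beyond this radius exist only along the long axis; letting the mask reach
    them makes small rotations overlap more than 60/90-degree ones and biases
    the gridness score negative.
    """
    cy, cx = ac.center
    yy, xx = np.indices(ac.r.shape)
    rad = np.round(np.hypot(yy - cy, xx - cx)).astype(int)
    finite = np.isfinite(ac.r)
    L = ac.max_lag_bins
    out = 1
    for k in range(1, L + 1):
        ring = rad == k
        if ring.sum() == 0 or finite[ring].mean() < min_coverage:
            break
        out = k
    return out


def _annulus_radii(ac: Autocorrelogram) -> tuple[float, float]:
    """Inner/outer mask radii (bins): first radial minimum to 1.5x the peak ring,
    capped at the fully-covered radius."""
    rbins, prof = _radial_profile(ac)
    L = _covered_radius(ac)
    r_in = None
    for k in range(1, L - 1):
        if np.isfinite(prof[k - 1:k + 2]).all() and prof[k] <= prof[k - 1] and prof[k] <= prof[k + 1]:
            r_in = float(k)
            break
    if r_in is None or r_in >= 0.8 * L:
        return 0.2 * L, 0.8 * L
    seg = np.nan_to_num(prof[int(r_in):L + 1], nan=-np.inf)
    r_peak = r_in + int(np.argmax(seg))
    # keep the first peak ring plus margin; including further rings dilutes the
    # rotation contrast (ideal-lattice oracle: hex > 1 requires a tight outer)
    r_out = min(1.5 * r_peak, float(L))
    if r_out <= r_in + 2:
        return 0.2 * L, 0.8 * L
    return r_in, r_out


def _masked_rotation_corr(ac: Autocorrelogram, angles_deg,
                          radii: tuple[float, float] | None = None) -> dict[int, float]:
    """Pearson correlation between the annulus-masked map and its rotations."""
    if radii is None:
        radii = _annulus_radii(ac)
    r_in, r_out = radii
    cy, cx = ac.center
    yy, xx = np.indices(ac.r.shape)
    rad = np.hypot(yy - cy, xx - cx)
    annulus = (rad >= r_in) & (rad <= r_out)
    base = ac.r
    valid = np.isfinite(base)
    filled = np.where(valid, base, 0.0)
    vmask = valid.astype(float)
    out: dict[int, float] = {}
    for ang in angles_deg:
        # cubic interpolation for the map (bilinear attenuates fine rings and
        # biases the rotation correlations), linear for the validity mask
        rot = ndimage.rotate(filled, ang, reshape=False, order=3, mode="constant", cval=0.0)
        rotm = ndimage.rotate(vmask, ang, reshape=False, order=1, mode="constant", cval=0.0)
        joint = annulus & valid & (rotm > 0.99)
        a, b = base[joint], rot[joint]
        if a.size < MIN_OVERLAP_PIXELS or a.std() < 1e-12 or b.std() < 1e-12:
            out[ang] = np.nan
            continue
        out[ang] = float(np.corrcoef(a, b)[0, 1])
    return out


def hgs(ac: Autocorrelogram, radii: tuple[float, float] | None = None) -> float:
    """Hexagonal gridness score of an autocorrelogram (range [-2, 2])."""
    cors = _masked_rotation_corr(ac, HGS_ANGLES_ON + HGS_ANGLES_OFF, radii)
    on = [cors[a] for a in HGS_ANGLES_ON]
    off = [cors[a] for a in HGS_ANGLES_OFF]
    if not (np.all(np.isfinite(on)) and np.all(np.isfinite(off))):
        return np.nan
    return float(min(on) - max(off))


# ---------------------------------------------------------------------------
# Compound-arena and symmetry analytics
# ---------------------------------------------------------------------------

def local_global_hgs(env: Environment, traj: Trajectory, response: np.ndarray,
                     bin_size: float = 0.03, smoothing_sigma: float = 1.0,
                     min_samples: int = 100) -> tuple[float, float]:
    """(local, global) HGS for a two-compartment connected arena.

    Global: HGS of the whole-arena rate map. Local: mean of the HGS of the
    two per-compartment rate maps (corridor samples excluded).
    """
    comp = compartment_of(env, traj.x)
    local_scores = []
    for side in (-1, 1):
        sel = comp == side
        if sel.sum() < min_samples:
            raise InsufficientSamplingError(f"compartment {side} has {int(sel.sum())} samples")
        sub = Trajectory(t=traj.t[sel], pos=traj.pos[sel], heading=traj.heading[sel],
                         speed=traj.speed[sel], dt=traj.dt)
        rm = rate_map(sub, np.asarray(response)[sel], bin_size, smoothing_sigma)
        local_scores.append(hgs(autocorrelogram(rm)))
    rm_all = rate_map(traj, response, bin_size, smoothing_sigma)
    return float(np.mean(local_scores)), hgs(autocorrelogram(rm_all))


def _ring_peaks(ac: Autocorrelogram, max_peaks: int = 6) -> np.ndarray:
    """Coordinates (dx, dy in bins) of the central ring peaks, nearest first."""
    r_in, r_out = _annulus_radii(ac)
    cy, cx = ac.center
    yy, xx = np.indices(ac.r.shape)
    rad = np.hypot(yy - cy, xx - cx)
    finite = np.isfinite(ac.r)
    filled = np.where(finite, ac.r, -np.inf)
    localmax = ndimage.maximum_filter(filled, size=3) == filled
    cand = localmax & finite & (rad >= max(r_in, 2)) & (rad <= r_out) & (filled > 0)
    ys, xs = np.nonzero(cand)
    if ys.size == 0:
        return np.empty((0, 2))
    order = np.argsort(rad[ys, xs])
    pts = np.column_stack([xs - cx, ys - cy]).astype(float)[order]
    # suppress near-duplicate maxima (plateaus) within 2 bins
    keep: list[np.ndarray] = []
    for p in pts:
        if all(np.hypot(*(p - q)) > 2 for q in keep):
            keep.append(p)
        if len(keep) == max_peaks:
            break
    return np.array(keep)


def ellipticity(ac: Autocorrelogram) -> float:
    """Major/minor axis ratio of the ellipse through the central-ring peaks.

    The autocorrelogram is symmetric under point reflection, so each detected
    peak contributes its antipode as well; at least 3 distinct peaks are
    required.
    """
    from skimage.measure import EllipseModel

    peaks = _ring_peaks(ac)
    if len(peaks) < 3:
        raise UndefinedEllipseError(f"only {len(peaks)} ring peaks found")
    pts = np.vstack([peaks, -peaks])
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise UndefinedEllipseError("ellipse fit failed")
    lo, hi = sorted(np.abs(model.axis_lengths))
    if lo < 1e-9:
        raise UndefinedEllipseError("degenerate ellipse")
    return float(hi / lo)


def half_map_similarity(rmap: RateMap, axis: str = "vertical",
                        split: float | None = None) -> float:
    """Pearson correlation between the two halves of a rate map.

    ``axis="vertical"`` cuts with a vertical line (left vs right half),
    ``"horizontal"`` with a horizontal line. The second half is reflected
    onto the first's frame; the correlation runs over jointly visited bins.
    Returns NaN (with a warning) when either half has no variance.
    """
    grid, occ = rmap.grid, rmap.occupancy
    if axis == "horizontal":
        grid, occ = grid.T, occ.T
        lo = rmap.extent[1]
    elif axis == "vertical":
        lo = rmap.extent[0]
    else:
        raise ValueError("axis must be 'vertical' or 'horizontal'")
    ncols = grid.shape[1]
    cut = ncols // 2 if split is None else int(round((split - lo) / rmap.bin_size))
    cut = int(np.clip(cut, 1, ncols - 1))
    left, occ_l = grid[:, :cut], occ[:, :cut]
    right, occ_r = grid[:, cut:][:, ::-1], occ[:, cut:][:, ::-1]  # reflect onto left frame
    w = min(left.shape[1], right.shape[1])
    left, occ_l = left[:, -w:], occ_l[:, -w:]
    right, occ_r = right[:, -w:], occ_r[:, -w:]
    joint = (occ_l > 0) & (occ_r > 0) & np.isfinite(left) & np.isfinite(right)
    if joint.sum() == 0:
        raise InsufficientSamplingError("no jointly visited bins across the two halves")
    a, b = left[joint], right[joint]
    if a.std() < 1e-12 or b.std() < 1e-12:
        warnings.warn("constant half-map: similarity undefined")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def autocorr_similarity(a: "Autocorrelogram", b: "Autocorrelogram") -> float:
    """Pearson correlation between two autocorrelograms over common lags.

    Compares the *spatial structure* of two firing patterns (spacing,
    orientation, regularity) independent of spatial phase — the natural way
    to ask whether two halves of an arena carry the same grid pattern.
    """
    L = min(a.max_lag_bins, b.max_lag_bins)
    ca = a.r[a.center[0] - L:a.center[0] + L + 1, a.center[1] - L:a.center[1] + L + 1]
    cb = b.r[b.center[0] - L:b.center[0] + L + 1, b.center[1] - L:b.center[1] + L + 1]
    both = np.isfinite(ca) & np.isfinite(cb)
    if both.sum() < MIN_OVERLAP_PIXELS:
        raise InsufficientSamplingError("too few common lags between autocorrelograms")
    return float(np.corrcoef(ca[both], cb[both])[0, 1])


@dataclass
class GridnessReport:
    """Per-neuron gridness summary."""

    hgs: float
    hgs_local: float | None = None
    hgs_global: float | None = None
    ellipticity: float | None = None
    half_similarity: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Synthetic lattice fixtures (validation oracles)
# ---------------------------------------------------------------------------

def synthetic_lattice_map(kind: str = "hex", spacing: float = 0.3,
                          side: float = 1.8, bin_size: float = 0.03,
                          angle: float = 0.0, noise: float = 0.0,
                          stretch_x: float = 1.0,
                          seed: int = 0) -> RateMap:
    """Ideal lattice of Gaussian bumps as a RateMap (for validating gridness).

    ``kind``: "hex" (triangular lattice), "square", or "ring" (rotationally
    symmetric concentric rings). ``noise`` adds i.i.d. Gaussian noise of that
    standard deviation relative to the unit bump amplitude.
    """
    n = int(round(side / bin_size))
    xs = (np.arange(n) + 0.5) * bin_size
    X, Y = np.meshgrid(xs, xs)
    cx = cy = side / 2
    if kind == "ring":
        rad = np.hypot(X - cx, Y - cy)
        grid = 0.5 + 0.5 * np.cos(2 * np.pi * rad / spacing)
    else:
        if kind == "hex":
            basis = np.array([[1.0, 0.0], [0.5, np.sqrt(3) / 2]]) * spacing
        elif kind == "square":
            basis = np.array([[1.0, 0.0], [0.0, 1.0]]) * spacing
        else:
            raise ValueError(f"unknown lattice kind {kind!r}")
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        basis = basis @ rot.T
        basis[:, 0] *= stretch_x
        reach = int(np.ceil(1.5 * side / spacing)) + 1
        grid = np.zeros_like(X)
        sig = spacing / 6
        for i in range(-reach, reach + 1):
            for j in range(-reach, reach + 1):
                px, py = cx + i * basis[0, 0] + j * basis[1, 0], cy + i * basis[0, 1] + j * basis[1, 1]
                if -spacing <= px <= side + spacing and -spacing <= py <= side + spacing:
                    grid += np.exp(-((X - px) ** 2 + (Y - py) ** 2) / (2 * sig ** 2))
    if noise > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0, noise, grid.shape)
    occ = np.ones_like(grid)
    return RateMap(grid=grid, occupancy=occ, bin_size=bin_size,
                   extent=(0.0, 0.0, side, side))
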