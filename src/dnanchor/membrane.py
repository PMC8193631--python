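"""Bilayer perturbation metrics.

The bilayer is tracked through one glycerol-backbone C2 atom per lipid.
Three quantities are computed:

* the instantaneous **midplane**, the midpoint of the two leaflets'
  mean C2 z positions (leaflets partitioned by the sign of z after
  centering on the global C2 mean);
* the **local membrane thickness** near the DNA, the distance between
  the per-leaflet C2 density peaks accumulated from C2 atoms whose
  minimum lateral (xy, minimum-image) distance to any DNA atom is
  within a cutoff (15 Å by default), with a "bulk" profile from the
  remaining lipids for comparison;
* the **water penetration count**, the number of water oxygens within a
  half-width (10 Å by default) of the instantaneous midplane, averaged
  after an equilibration discard, with an SD over 2 ns block means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dnanchor.io_model import Selection, TrajectorySet

__all__ = [
    "MembraneProfile",
    "WaterCountSeries",
    "LocalThicknessResult",
    "midplane",
    "midplane_series",
    "local_thickness",
    "water_midplane_count",
]


@dataclass
class MembraneProfile:
    """Per-leaflet C2 density along z (midplane-relative) with peaks."""

    z_grid: np.ndarray  # bin centers, Å
    density_upper: np.ndarray  # mean counts per bin per frame
    density_lower: np.ndarray
    peak_upper: float  # Å
    peak_lower: float  # Å
    region: str  # "near_dna" or "bulk"

    def __post_init__(self) -> None:
        if not self.peak_upper > self.peak_lower:
            raise ValueError("peak_upper must exceed peak_lower")

    @property
    def thickness(self) -> float:
        return self.peak_upper - self.peak_lower


@dataclass
class LocalThicknessResult:
    near_dna: MembraneProfile
    bulk: MembraneProfile | None


@dataclass
class WaterCountSeries:
    """Per-frame water counts near the midplane with summary statistics."""

    times: np.ndarray  # ns
    counts: np.ndarray  # integers
    mean: float  # over frames after discard
    sd_block: float  # SD over block means (2 ns blocks by default)

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def _leaflet_masks(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = z.mean()
    upper = z > center
    lower = ~upper
    if not upper.any() or not lower.any():
        raise ValueError("all C2 atoms fall in one leaflet; cannot split bilayer")
    return upper, lower


def midplane(traj: TrajectorySet, c2_sel: Selection, frame: int = 0) -> float:
    """Midplane z (Å) of one frame: midpoint of the leaflet mean C2 z's."""
    z = traj.coords[frame, c2_sel.array, 2]
    upper, lower = _leaflet_masks(z)
    return 0.5 * (float(z[upper].mean()) + float(z[lower].mean()))


def midplane_series(traj: TrajectorySet, c2_sel: Selection) -> np.ndarray:
    """Instantaneous midplane z for every frame (vectorized).

    The leaflet partition (sign of z after centering) is recomputed per
    frame, so slow membrane drift is tracked.
    """
    z = traj.coords[:, c2_sel.array, 2]  # (n_frames, n_c2)
    center = z.mean(axis=1, keepdims=True)
    upper = z > center
    n_up = upper.sum(axis=1)
    if np.any(n_up == 0) or np.any(n_up == z.shape[1]):
        raise ValueError("all C2 atoms fall in one leaflet in some frame")
    sum_up = np.where(upper, z, 0.0).sum(axis=1)
    sum_lo = np.where(upper, 0.0, z).sum(axis=1)
    return 0.5 * (sum_up / n_up + sum_lo / (z.shape[1] - n_up))


def _min_lateral_distance(
    c2_xy: np.ndarray, dna_xy: np.ndarray, box_xy: np.ndarray
) -> np.ndarray:
    """Minimum-image xy distance from each C2 atom to the nearest DNA atom."""
    d = c2_xy[:, None, :] - dna_xy[None, :, :]
    d -= box_xy * np.round(d / box_xy)
    return np.sqrt((d**2).sum(axis=2)).min(axis=1)


def _pick_peak(
    grid: np.ndarray, density: np.ndarray, leaflet_mean: float, smooth_bins: int
) -> float:
    """Density peak: argmax after a moving-average smoothing.

    Smoothed ties (a spike narrower than the kernel produces several
    equal smoothed bins) are broken by the raw density, then by the bin
    center closest to the leaflet mean z."""
    raw = density
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        density = np.convolve(density, kernel, mode="same")
    candidates = np.flatnonzero(np.isclose(density, density.max()))
    if candidates.size > 1:
        raw_best = raw[candidates].max()
        candidates = candidates[np.isclose(raw[candidates], raw_best)]
    if candidates.size > 1:
        pick = candidates[np.argmin(np.abs(grid[candidates] - leaflet_mean))]
    else:
        pick = candidates[0]
    return float(grid[pick])


def local_thickness(
    traj: TrajectorySet,
    c2_sel: Selection,
    dna_sel: Selection,
    cutoff: float = 15.0,
    bin_width: float = 0.5,
    discard_ns: float = 200.0,
    smooth_bins: int = 3,
    include_bulk: bool = True,
) -> LocalThicknessResult:
    """Local membrane thickness near the DNA from C2 density peaks.

    Per analyzed frame, C2 atoms within ``cutoff`` of the DNA (minimum
    lateral xy distance to any DNA atom, minimum-image convention) are
    accumulated into per-leaflet histograms of z relative to the
    instantaneous midplane; the thickness is the distance between the
    two leaflet density peaks of the frame-averaged histogram.  A bulk
    profile from the beyond-cutoff C2 atoms is returned alongside.

    Frames before ``discard_ns`` are excluded.  It is an error if more
    than half of the analyzed frames have no near-DNA C2 atom.
    """
    frames = np.flatnonzero(traj.times >= discard_ns)
    if frames.size == 0:
        raise ValueError("no frames remain after the equilibration discard")
    c2 = c2_sel.array
    dna = dna_sel.array
    mid = midplane_series(traj, c2_sel)

    near_z: list[np.ndarray] = []
    bulk_z: list[np.ndarray] = []
    n_empty = 0
    for f in frames:
        xy = traj.coords[f, c2, :2]
        dna_xy = traj.coords[f, dna, :2]
        dmin = _min_lateral_distance(xy, dna_xy, traj.boxes[f, :2])
        near = dmin <= cutoff
        rel = traj.coords[f, c2, 2] - mid[f]
        if not near.any():
            n_empty += 1
        else:
            near_z.append(rel[near])
        if include_bulk and (~near).any():
            bulk_z.append(rel[~near])
    if n_empty > 0.5 * frames.size:
        raise ValueError(
            f"no C2 atoms within {cutoff} Å of the DNA in {n_empty} of "
            f"{frames.size} frames"
        )

    def build(z_lists: list[np.ndarray], region: str) -> MembraneProfile:
        allz = np.concatenate(z_lists)
        lo = np.floor(allz.min() / bin_width) * bin_width - bin_width
        hi = np.ceil(allz.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        grid = 0.5 * (edges[:-1] + edges[1:])
        up = allz[allz > 0]
        down = allz[allz <= 0]
        if up.size == 0 or down.size == 0:
            raise ValueError(f"{region}: C2 atoms present in only one leaflet")
        dens_up = np.histogram(up, bins=edges)[0] / frames.size
        dens_lo = np.histogram(down, bins=edges)[0] / frames.size
        peak_up = _pick_peak(grid, dens_up, float(up.mean()), smooth_bins)
        peak_lo = _pick_peak(grid, dens_lo, float(down.mean()), smooth_bins)
        return MembraneProfile(
            z_grid=grid,
            density_upper=dens_up,
            density_lower=dens_lo,
            peak_upper=peak_up,
            peak_lower=peak_lo,
            region=region,
        )

    near_profile = build(near_z, "near_dna")
    bulk_profile = build(bulk_z, "bulk") if include_bulk and bulk_z else None
    return LocalThicknessResult(near_dna=near_profile, bulk=bulk_profile)


def water_midplane_count(
    traj: TrajectorySet,
    water_sel: Selection,
    c2_sel: Selection,
    half_width: float = 10.0,
    discard_ns: float = 200.0,
    sd_block_ns: float = 2.0,
) -> WaterCountSeries:
    """Count water oxygens within ``half_width`` of the midplane per frame.

    The midplane is the instantaneous one; the mean is over frames at or
    after ``discard_ns`` and the quoted SD is the population SD over
    consecutive ``sd_block_ns`` block means of the same frames.
    """
    mid = midplane_series(traj, c2_sel)
    wz = traj.coords[:, water_sel.array, 2]
    counts = (np.abs(wz - mid[:, None]) < half_width).sum(axis=1)

    keep = traj.times >= discard_ns
    if not keep.any():
        raise ValueError("no frames remain after the equilibration discard")
    kept_t = traj.times[keep]
    kept_c = counts[keep]
    mean = float(kept_c.mean())

    t0 = kept_t[0]
    block_idx = np.floor((kept_t - t0) / sd_block_ns + 1e-9).astype(int)
    sums = np.bincount(block_idx, weights=kept_c)
    ns = np.bincount(block_idx)
    means = sums[ns > 0] / ns[ns > 0]
    ns = ns[ns > 0]
    # drop a trailing partial block when more than one block exists
    if means.size > 1 and ns[-1] < ns[:-1].max():
        means = means[:-1]
    sd = float(means.std()) if means.size > 1 else 0.0
    return WaterCountSeries(times=traj.times.copy(), counts=counts, mean=mean, sd_block=sd)
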