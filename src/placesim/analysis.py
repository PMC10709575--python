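"""Place-field quantification: rate maps, field geometry, rotation/remap.

A rate map is the standard occupancy-normalized spatial firing map:
spike counts per 2-D bin divided by dwell time, masked where occupancy is
below a minimum.  Field extraction takes the connected region above half
the peak rate containing the peak bin; rotation and remapping experiments
compare maps by Pearson correlation and field-centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class RateMap:
    """Occupancy-normalized spatial firing map on an n×n grid."""

    occupancy_s: np.ndarray        # (n, n), row = x bin, col = y bin
    spike_counts: np.ndarray
    rate_hz: np.ndarray            # masked (NaN) where occupancy < min
    edges: np.ndarray              # bin edges, shared by both axes
    min_occupancy_s: float

    @property
    def n_bins(self) -> int:
        return self.occupancy_s.shape[0]

    def bin_centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2


def rate_map(result, n_bins: int = 20, min_occupancy_s: float = 0.2,
             side_length: float = 1.0,
             smooth_sigma_bins: float = 0.0) -> RateMap:
    """Build the rate map of a session result.

    Spikes are attributed to the trajectory sample nearest in time; each
    trajectory sample contributes one environment step of dwell time.
    With ``smooth_sigma_bins`` > 0 the spike and occupancy maps are
    Gaussian-smoothed before division (common practice for sparse maps).
    """
    edges = np.linspace(0.0, side_length, n_bins + 1)
    xy = result.traj_xy
    occ_counts, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges, edges])
    occupancy = occ_counts * result.dt_env_s
    sp = result.spike_positions()
    counts, _, _ = np.histogram2d(sp[:, 0], sp[:, 1], bins=[edges, edges])
    occ_eff, cnt_eff = occupancy, counts
    if smooth_sigma_bins > 0:
        occ_eff = ndimage.gaussian_filter(occupancy, smooth_sigma_bins)
        cnt_eff = ndimage.gaussian_filter(counts, smooth_sigma_bins)
    rate = np.full_like(occupancy, np.nan)
    ok = occ_eff >= min_occupancy_s
    rate[ok] = cnt_eff[ok] / occ_eff[ok]
    return RateMap(occupancy, counts, rate, edges, min_occupancy_s)


def field_centroid_and_size(rmap: RateMap, threshold_fraction: float = 0.5):
    """Centroid (arena coords) and bin area of the place field.

    The field is the connected bin region at or above
    ``threshold_fraction`` of the peak rate that contains the peak bin.
    Raises on an all-zero or fully masked map.
    """
    rate = np.where(np.isnan(rmap.rate_hz), 0.0, rmap.rate_hz)
    peak = rate.max()
    if peak <= 0:
        raise ValueError("rate map has no firing; no field to extract")
    mask = rate >= threshold_fraction * peak
    labels, _ = ndimage.label(mask)
    peak_bin = np.unravel_index(np.argmax(rate), rate.shape)
    region = labels == labels[peak_bin]
    centers = rmap.bin_centers()
    w = rate * region
    cx = float((w.sum(axis=1) * centers).sum() / w.sum())
    cy = float((w.sum(axis=0) * centers).sum() / w.sum())
    return np.array([cx, cy]), int(region.sum())


def _rotate_map(m: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a map counterclockwise about the grid center.

    The grid convention is row = x bin, column = y bin, matching the
    arena's rotation convention (positive angle = counterclockwise).
    """
    if angle % 90 == 0:
        return np.rot90(m, k=int(angle // 90) % 4, axes=(0, 1)).copy()
    filled = np.where(np.isfinite(m), m, 0.0)
    return ndimage.rotate(filled, angle, axes=(0, 1), reshape=False, order=1,
                          mode="constant", cval=np.nan)


def rotation_test(map_before: RateMap, map_after: RateMap,
                  angle: float) -> float:
    """Pearson correlation of ``map_after`` with ``map_before`` rotated.

    Only bins unmasked in both maps enter the correlation.
    """
    if map_before.rate_hz.shape != map_after.rate_hz.shape:
        raise ValueError("rate maps must share the bin grid")
    rb = _rotate_map(map_before.rate_hz, angle)
    ra = map_after.rate_hz
    ok = np.isfinite(rb) & np.isfinite(ra)
    if ok.sum() < 3:
        raise ValueError("too few overlapping unmasked bins")
    a, b = ra[ok], rb[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate (constant) rate map")
    return float(np.corrcoef(a, b)[0, 1])


def remap_test(map_a: RateMap, map_b: RateMap) -> float:
    """Euclidean distance between the two maps' field centroids."""
    ca, _ = field_centroid_and_size(map_a)
    cb, _ = field_centroid_and_size(map_b)
    return float(np.linalg.norm(ca - cb))


def export_rate_map(rmap: RateMap, path) -> None:
    np.savetxt(path, rmap.rate_hz, delimiter=",")


def summary(rmap: RateMap) -> dict:
    centroid, area = field_centroid_and_size(rmap)
    return {
        "peak_rate_hz": float(np.nanmax(rmap.rate_hz)),
        "field_centroid": centroid.tolist(),
        "field_area_bins": area,
    }
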