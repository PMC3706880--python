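"""Per-component features: smoothness ratio curves, mask overlap, temporal noise.

Four features drive the classification:

* **Ratio curves** — for each component map, the 3D discrete Fourier
  transform is taken and, for a sweep of spectral radii r (in cycles/mm),
  the ratio R(r) = L(r)/H(r) of summed spectral magnitude strictly inside
  the sphere of radius r (low frequencies, L) to the magnitude outside
  (high frequencies, H) is computed.  Smooth maps concentrate magnitude at
  low frequencies and produce uniformly higher curves than "spotty" ones.
* **Edge / CSF overlap** — contiguous suprathreshold clusters of the
  thresholded map are extracted; the activity is the summed full volume of
  every cluster touching the mask, normalized by the mask volume, and the
  overlap fraction is the share of suprathreshold voxels lying inside the
  mask.
* **Temporal frequency noise (TFN)** — the summed power of the component's
  spectrum at frequencies at or above a cutoff (default 0.08 Hz, the
  dominant frequency of the hemodynamic response) up to Nyquist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from sock.ica_io import ICADecomposition, SockInputError

#: Cap applied to a ratio whose high-frequency sum is (numerically) zero:
#: constant maps must sort as maximally smooth rather than overflow.
RATIO_CAP = 1e12

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class RatioCurveSet:
    """Low/high spatial-frequency ratio curves for all components.

    ``radii`` is strictly increasing (cycles/mm); ``curves`` has one row
    per component, each non-negative and non-decreasing along the radii.
    """

    radii: np.ndarray
    curves: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if np.any(np.diff(self.radii) <= 0):
            raise SockInputError("radii must be strictly increasing")
        if self.curves.shape[1] != self.radii.shape[0]:
            raise SockInputError(
                f"curves have {self.curves.shape[1]} radii columns, expected {len(self.radii)}"
            )

    @property
    def n_components(self) -> int:
        return self.curves.shape[0]


@dataclass
class OverlapFeature:
    """Cluster-overlap feature against one mask (edge or CSF).

    ``activity`` is the summed volume of suprathreshold clusters touching
    the mask, divided by the mask volume (can exceed 1: clusters count in
    full).  ``overlap_fraction`` is the share of suprathreshold voxels
    inside the mask, in [0, 1].
    """

    activity: float
    overlap_fraction: float
    n_clusters_overlapping: int


@dataclass
class TFNFeature:
    """High-frequency share of a component's temporal power spectrum."""

    tfn: float
    total_power: float
    cutoff_hz: float
    nyquist_hz: float


def spectral_radius_grid(grid_shape, voxel_size_mm, n_radii: int) -> np.ndarray:
    """Radius sweep from the smallest nonzero frequency step to the largest
    spectral radius whose sphere is inscribed in the sampled frequency box."""
    steps = [1.0 / (n * d) for n, d in zip(grid_shape, voxel_size_mm)]
    max_freqs = [
        np.abs(np.fft.fftfreq(n, d=d)).max() for n, d in zip(grid_shape, voxel_size_mm)
    ]
    return np.linspace(min(steps), min(max_freqs), n_radii)


def spectral_partition(
    volume: np.ndarray, voxel_size_mm, radii: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split the DFT magnitude of a volume at each radius of a sweep.

    Returns ``(low, high)`` where ``low[j]`` sums |DFT| over spatial
    frequencies with magnitude strictly below ``radii[j]`` (cycles/mm) and
    ``high[j]`` sums the rest; ``low + high`` equals the total magnitude
    at every radius.
    """
    volume = np.asarray(volume, dtype=float)
    freqs = np.meshgrid(
        *[np.fft.fftfreq(n, d=d) for n, d in zip(volume.shape, voxel_size_mm)],
        indexing="ij",
    )
    dist = np.sqrt(sum(f**2 for f in freqs)).ravel()
    # voxel with |k| = dist contributes to low(r_j) iff r_j > dist
    first_bin = np.searchsorted(radii, dist, side="right")
    mag = np.abs(np.fft.fftn(volume)).ravel()
    n_radii = len(radii)
    low = np.cumsum(np.bincount(first_bin, weights=mag, minlength=n_radii + 1))[:n_radii]
    return low, mag.sum() - low


def compute_ratio_curves(
    decomposition: ICADecomposition, n_radii: int = 20
) -> RatioCurveSet:
    """Ratio of low to high spatial-frequency magnitude per component.

    For each component map S, compute F = DFT3(S) and, at each radius r of
    the sweep, L(r) = sum of |F| at spatial frequencies with magnitude
    strictly below r (the zero-frequency bin always belongs to L) and
    H(r) = sum of |F| at or beyond r.  The curve value is
    min(L / max(H, eps), cap), so a constant map yields the capped maximum
    at every radius and an all-zero map yields zeros (with a warning).

    Spatial frequencies are physical (cycles/mm), so anisotropic voxels
    are handled; the sweep has ``n_radii`` evenly spaced values.
    """
    if n_radii < 2:
        raise SockInputError(f"n_radii must be >= 2, got {n_radii}")
    maps = decomposition.unthresholded_maps
    if not np.isfinite(maps).all():
        raise SockInputError("component maps contain non-finite voxels")

    grid_shape = decomposition.grid_shape
    radii = spectral_radius_grid(grid_shape, decomposition.voxel_size_mm, n_radii)

    n = decomposition.n_components
    curves = np.zeros((n, n_radii))
    for i in range(n):
        vol = maps[..., i]
        if not vol.any():
            warnings.warn(f"component {i} is identically zero; ratio curve set to 0")
            continue
        low, high = spectral_partition(vol, decomposition.voxel_size_mm, radii)
        curves[i] = np.minimum(low / np.maximum(high, 1e-30), RATIO_CAP)
    return RatioCurveSet(radii=radii, curves=curves)


def label_clusters(active: np.ndarray, connectivity: int = 26):
    """Connected-component labeling of a binary volume.

    Returns ``(labels, n_clusters)`` with labels 1..n; connectivity is one
    of 6 (faces), 18 (faces+edges) or 26 (faces+edges+corners).
    """
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise SockInputError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    structure = ndimage.generate_binary_structure(3, rank)
    return ndimage.label(active, structure=structure)


def compute_overlap_feature(
    thresholded_map: np.ndarray, mask: np.ndarray, connectivity: int = 26
) -> OverlapFeature:
    """Overlap of suprathreshold clusters with a binary mask.

    A cluster "overlaps" if at least one of its voxels lies in the mask;
    its full volume then counts toward the activity.  A map with no
    suprathreshold voxels yields all-zero fields.
    """
    thresholded_map = np.asarray(thresholded_map)
    mask = np.asarray(mask).astype(bool)
    if thresholded_map.shape != mask.shape:
        raise SockInputError(
            f"map grid {thresholded_map.shape} does not match mask grid {mask.shape}"
        )
    if not mask.any():
        raise SockInputError("overlap mask is empty")

    active = thresholded_map != 0
    n_active = int(active.sum())
    if n_active == 0:
        return OverlapFeature(activity=0.0, overlap_fraction=0.0, n_clusters_overlapping=0)

    labels, _ = label_clusters(active, connectivity)
    overlapping_ids = np.unique(labels[mask & active])
    overlapping_ids = overlapping_ids[overlapping_ids > 0]
    cluster_sizes = np.bincount(labels.ravel())
    activity = float(cluster_sizes[overlapping_ids].sum()) / float(mask.sum())
    fraction = float((active & mask).sum()) / float(n_active)
    return OverlapFeature(
        activity=activity,
        overlap_fraction=fraction,
        n_clusters_overlapping=int(len(overlapping_ids)),
    )


def spectrum_frequencies(n_bins: int, tr_seconds: float) -> np.ndarray:
    """Frequency of each spectrum bin: f_k = k / (2 * F * TR), k = 1..F.

    MELODIC spectra exclude the DC bin; the last bin lands exactly on the
    Nyquist frequency 1/(2*TR).
    """
    return np.arange(1, n_bins + 1) / (2.0 * n_bins * tr_seconds)


def compute_tfn(
    power_spectrum: np.ndarray, tr_seconds: float, cutoff_hz: float = 0.08
) -> TFNFeature:
    """Summed spectral power at frequencies >= ``cutoff_hz`` up to Nyquist."""
    ps = np.asarray(power_spectrum, dtype=float)
    if np.any(ps < 0):
        raise SockInputError("power spectrum contains negative values")
    if not tr_seconds > 0:
        raise SockInputError(f"tr_seconds must be positive, got {tr_seconds}")
    nyquist = 1.0 / (2.0 * tr_seconds)
    total = float(ps.sum())
    if cutoff_hz >= nyquist:
        warnings.warn(
            f"TFN cutoff {cutoff_hz} Hz is at or above Nyquist {nyquist} Hz; TFN is 0"
        )
        tfn = 0.0
    else:
        freqs = spectrum_frequencies(len(ps), tr_seconds)
        tfn = float(ps[freqs >= cutoff_hz].sum())
    return TFNFeature(tfn=tfn, total_power=total, cutoff_hz=cutoff_hz, nyquist_hz=nyquist)
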