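"""Phantom ICA decompositions with ground-truth artifact classes.

Five component classes emulate the signatures the classifier targets:

* ``neuronal`` — a wide Gaussian blob deep inside the brain with a
  low-frequency time course; the only class that should survive.
* ``spotty`` — unsmoothed salt-and-pepper noise (machine/undetermined
  noise); rejected for being spatially unsmooth.
* ``edge`` — activation concentrated in the brain-boundary band (gross
  head motion); rejected by the edge-overlap hard rule.
* ``csf`` — a blob confined to the ventricle region (physiological
  noise); rejected by the CSF-overlap hard rule.
* ``hf_smooth`` — a moderately smooth blob whose time course carries its
  power above 0.08 Hz; rejected as subsmooth with high temporal
  frequency noise.

Maps are built so that the class-defining property holds by construction
(e.g. edge components place the majority of their suprathreshold voxels in
the edge band); thresholded maps keep voxels with |z| >= 2.3 after
standardization, mimicking mixture-model thresholding.  Spectra are raw
periodograms of the generated time courses, binned like MELODIC's
(bins 1..T/2 spanning (0, Nyquist]).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from sock.classify import ARTIFACT, UNLIKELY_ARTIFACT
from sock.ica_io import ICADecomposition, MaskSet, SockInputError, save_nifti
from sock.masks import Ellipsoid, derive_edge_mask

CLASS_NAMES = ("neuronal", "spotty", "edge", "csf", "hf_smooth")

#: Per-class (blob/background smoothing sigma in voxels, blob amplitude).
#: Amplitudes keep the structured signal dominant over the smoothed
#: background so that thresholding isolates the intended support; sigmas
#: order the classes on the smoothness axis (neuronal > csf/edge > hf >
#: spotty) with gaps wide enough for the nested 2-means to find.
_CLASS_SHAPE = {
    "neuronal": (2.0, 6.0),
    "csf": (1.2, 15.0),
    "hf_smooth": (0.6, 25.0),
    "edge": (0.8, 5.0),
}

#: Blobs are flattened along z like the brain, so their suprathreshold
#: core stays clear of the boundary band on the thin axis.
_BLOB_Z_FACTOR = 0.6

_BACKGROUND_SCALE = 0.3
_LOW_BAND_HZ = (0.01, 0.06)
_HIGH_BAND_HZ = (0.10, 0.25)


@dataclass
class PhantomSpec:
    """Parameters of a phantom decomposition.

    Defaults give a 32 x 32 x 16 grid of 3 mm voxels, TR = 2 s, 200
    timepoints and three components per class (15 total) — a desk-scale
    stand-in for a short resting-state run.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 2.0
    n_timepoints: int = 200
    class_counts: dict = field(
        default_factory=lambda: {name: 3 for name in CLASS_NAMES}
    )
    z_threshold: float = 2.3
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(CLASS_NAMES)
        if unknown:
            raise SockInputError(f"unknown phantom classes {sorted(unknown)}")
        if any(c < 1 for c in self.class_counts.values()):
            raise SockInputError("each enabled phantom class needs at least one component")
        if self.n_components < 6:
            raise SockInputError(
                f"phantom needs >= 6 components for the nested smoothness split, "
                f"got {self.n_components}"
            )

    @property
    def n_components(self) -> int:
        return sum(self.class_counts.values())


def _brain_geometry(spec: PhantomSpec):
    shape = np.asarray(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    brain_axes = shape * 0.41  # ellipsoid nearly filling the grid
    csf_axes = shape * np.array([0.10, 0.10, 0.14])
    return center, brain_axes, csf_axes


def _gaussian_blob(grid_shape, center, sigma) -> np.ndarray:
    sigmas = (sigma, sigma, sigma * _BLOB_Z_FACTOR)
    coords = np.indices(grid_shape, dtype=float)
    d2 = sum(((coords[i] - center[i]) / sigmas[i]) ** 2 for i in range(3))
    return np.exp(-d2 / 2.0)


def _background(rng, grid_shape, sigma) -> np.ndarray:
    noise = rng.standard_normal(grid_shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma)
    noise -= noise.mean()
    return noise / noise.std()


def _band_limited_course(rng, n_timepoints, tr, band_hz) -> np.ndarray:
    """Gaussian process with power confined to a temporal frequency band."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    spectrum = np.fft.rfft(rng.standard_normal(n_timepoints))
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    spectrum[~keep] = 0.0
    course = np.fft.irfft(spectrum, n=n_timepoints)
    return course / course.std()


def _blob_center(rng, center, brain_axes, index, n_in_class, offset=0.0):
    """Place a blob on a mid-depth ring, evenly spread with a little jitter."""
    angle = 2.0 * np.pi * (index / max(n_in_class, 1)) + offset + rng.uniform(-0.2, 0.2)
    # mid-depth: clear of the central ventricle region and the edge band
    radius = 0.60
    return (
        center[0] + radius * brain_axes[0] * np.cos(angle),
        center[1] + radius * brain_axes[1] * np.sin(angle),
        center[2] + rng.uniform(-1.0, 1.0),
    )


def generate_phantom(spec: PhantomSpec | None = None):
    """Build a phantom decomposition, its masks, and ground-truth labels.

    Returns ``(decomposition, masks, truth)`` where ``truth`` is a
    DataFrame with one row per component: 1-based index, class name, and
    the verdict the classifier should reach.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    center, brain_axes, csf_axes = _brain_geometry(spec)

    brain = Ellipsoid(tuple(center), tuple(brain_axes)).rasterize(spec.grid_shape)
    edge = derive_edge_mask(brain, thickness=1)
    csf = Ellipsoid(tuple(center), tuple(csf_axes)).rasterize(spec.grid_shape) & brain
    masks = MaskSet(brain=brain, edge=edge, csf=csf)

    edge_template = ndimage.gaussian_filter(edge.astype(float), _CLASS_SHAPE["edge"][0])
    edge_template /= edge_template.max()

    maps, courses, classes = [], [], []
    for name in CLASS_NAMES:
        count = spec.class_counts.get(name, 0)
        for j in range(count):
            if name == "spotty":
                vol = rng.standard_normal(spec.grid_shape)
            elif name == "edge":
                sigma, amp = _CLASS_SHAPE["edge"]
                vol = amp * edge_template + _BACKGROUND_SCALE * _background(rng, spec.grid_shape, sigma)
            elif name == "csf":
                sigma, amp = _CLASS_SHAPE["csf"]
                blob = _gaussian_blob(spec.grid_shape, center, sigma)
                vol = amp * blob + _BACKGROUND_SCALE * _background(rng, spec.grid_shape, sigma)
            else:  # neuronal, hf_smooth: off-center blobs at class smoothness
                sigma, amp = _CLASS_SHAPE[name]
                offset = 0.0 if name == "neuronal" else np.pi / 3.0
                c = _blob_center(rng, center, brain_axes, j, count, offset)
                blob = _gaussian_blob(spec.grid_shape, c, sigma)
                vol = amp * blob + _BACKGROUND_SCALE * _background(rng, spec.grid_shape, sigma)

            band = _HIGH_BAND_HZ if name == "hf_smooth" else _LOW_BAND_HZ
            courses.append(_band_limited_course(rng, spec.n_timepoints, spec.tr_seconds, band))
            maps.append(vol)
            classes.append(name)

    unthresh = np.stack(
        [(m - m.mean()) / m.std() for m in maps], axis=-1
    )
    thresh = np.where(np.abs(unthresh) >= spec.z_threshold, unthresh, 0.0)
    time_courses = np.stack(courses, axis=-1)

    # raw periodogram on MELODIC-style bins 1..T/2 (DC dropped, last = Nyquist)
    n_bins = spec.n_timepoints // 2
    spectra = np.abs(np.fft.rfft(time_courses, axis=0))[1 : n_bins + 1] ** 2

    decomposition = ICADecomposition(
        unthresholded_maps=unthresh,
        thresholded_maps=thresh,
        tr_seconds=spec.tr_seconds,
        voxel_size_mm=spec.voxel_size_mm,
        time_courses=time_courses,
        power_spectra=spectra,
    )
    truth = pd.DataFrame(
        {
            "component": np.arange(1, len(classes) + 1),
            "klass": classes,
            "verdict": [
                UNLIKELY_ARTIFACT if k == "neuronal" else ARTIFACT for k in classes
            ],
        }
    )
    return decomposition, masks, truth


def write_phantom_melodic_dir(phantom, path: str) -> None:
    """Write a phantom as the MELODIC-style directory ``read_melodic_dir``
    consumes, plus mask images and a ground-truth TSV."""
    decomposition, masks, truth = phantom
    os.makedirs(os.path.join(path, "stats"), exist_ok=True)
    vx = decomposition.voxel_size_mm

    save_nifti(decomposition.unthresholded_maps, vx, os.path.join(path, "melodic_IC.nii.gz"))
    for i in range(decomposition.n_components):
        save_nifti(
            decomposition.thresholded_maps[..., i],
            vx,
            os.path.join(path, "stats", f"thresh_zstat{i + 1}.nii.gz"),
        )
    np.savetxt(os.path.join(path, "melodic_mix"), decomposition.time_courses, fmt="%.10g")
    np.savetxt(os.path.join(path, "melodic_FTmix"), decomposition.power_spectra, fmt="%.10g")
    save_nifti(masks.brain.astype(np.uint8), vx, os.path.join(path, "brain_mask.nii.gz"))
    save_nifti(masks.edge.astype(np.uint8), vx, os.path.join(path, "edge_mask.nii.gz"))
    save_nifti(masks.csf.astype(np.uint8), vx, os.path.join(path, "csf_mask.nii.gz"))
    truth.to_csv(os.path.join(path, "ground_truth.tsv"), sep="\t", index=False)
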