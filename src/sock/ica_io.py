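"""Reading MELODIC-style ICA decompositions and masks; writing reports.

A MELODIC output directory contains a 4D image of unthresholded component
z-maps, per-component mixture-model-thresholded z-maps, a plain-text mixing
matrix (timepoints x components) and plain-text power spectra
(frequency bins x components).  This module parses that layout into the
package's in-memory model and serializes classification reports as a TSV
table plus a JSON summary.
"""

from __future__ import annotations

import glob
import json
import os
import re
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


class SockInputError(ValueError):
    """Raised for malformed or inconsistent decomposition inputs."""


@dataclass
class ICADecomposition:
    """A spatial-ICA decomposition of a 4D fMRI run.

    Attributes
    ----------
    unthresholded_maps : ndarray, shape (X, Y, Z, N)
        Raw component z-maps, all spatial frequency modes retained.
    thresholded_maps : ndarray, shape (X, Y, Z, N)
        Component z-maps zeroed outside suprathreshold voxels.  Signed
        z-values are retained; any nonzero voxel counts as suprathreshold.
    time_courses : ndarray, shape (T, N) or None
        Component time courses (mixing-matrix columns).  Optional.
    power_spectra : ndarray, shape (F, N)
        Non-negative temporal power spectra of the time courses.  Bin k
        (1-based) maps to frequency k / (2 * F * TR); may be empty
        (shape ``(0, N)``) when the temporal feature is disabled.
    tr_seconds : float
        Repetition time in seconds; sets the Nyquist frequency 1/(2*TR).
    voxel_size_mm : tuple of 3 floats
        Voxel dimensions, used to express spatial frequencies in cycles/mm.
    """

    unthresholded_maps: np.ndarray
    thresholded_maps: np.ndarray
    tr_seconds: float
    voxel_size_mm: tuple[float, float, float]
    time_courses: np.ndarray | None = None
    power_spectra: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.unthresholded_maps = np.asarray(self.unthresholded_maps, dtype=float)
        self.thresholded_maps = np.asarray(self.thresholded_maps, dtype=float)
        if self.unthresholded_maps.ndim != 4:
            raise SockInputError(
                f"component maps must be 4D (X,Y,Z,N); got shape {self.unthresholded_maps.shape}"
            )
        if self.thresholded_maps.shape != self.unthresholded_maps.shape:
            raise SockInputError(
                "thresholded and unthresholded maps disagree: "
                f"{self.thresholded_maps.shape} vs {self.unthresholded_maps.shape}"
            )
        if self.power_spectra is None:
            self.power_spectra = np.zeros((0, self.n_components))
        self.power_spectra = np.asarray(self.power_spectra, dtype=float)
        if self.power_spectra.shape[1] != self.n_components:
            raise SockInputError(
                f"power spectra have {self.power_spectra.shape[1]} columns "
                f"but there are {self.n_components} component maps"
            )
        if self.time_courses is not None:
            self.time_courses = np.asarray(self.time_courses, dtype=float)
            if self.time_courses.shape[1] != self.n_components:
                raise SockInputError(
                    f"mixing matrix has {self.time_courses.shape[1]} columns "
                    f"but there are {self.n_components} component maps"
                )
        if not self.tr_seconds > 0:
            raise SockInputError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise SockInputError(f"voxel_size_mm must be 3 positive reals, got {self.voxel_size_mm}")

    @property
    def n_components(self) -> int:
        return self.unthresholded_maps.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.unthresholded_maps.shape[:3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class MaskSet:
    """Binary brain, edge and CSF masks on the decomposition grid.

    The edge mask covers the brain boundary band (motion artifact localizes
    there); the CSF mask covers the lateral-ventricle region (physiological
    artifact localizes there).
    """

    brain: np.ndarray
    edge: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.brain = np.asarray(self.brain).astype(bool)
        self.edge = np.asarray(self.edge).astype(bool)
        self.csf = np.asarray(self.csf).astype(bool)
        if not (self.brain.shape == self.edge.shape == self.csf.shape):
            raise SockInputError(
                "mask grids disagree: "
                f"brain {self.brain.shape}, edge {self.edge.shape}, csf {self.csf.shape}"
            )

    @property
    def edge_volume(self) -> int:
        return int(self.edge.sum())

    @property
    def csf_volume(self) -> int:
        return int(self.csf.sum())


def _find_image(directory: str, stem: str) -> str | None:
    for ext in (".nii.gz", ".nii"):
        candidate = os.path.join(directory, stem + ext)
        if os.path.exists(candidate):
            return candidate
    return None


def _load_thresholded(path: str, n_components: int, grid_shape) -> np.ndarray:
    """Locate thresholded maps: either per-component stats/thresh_zstat<i>
    files or a single 4D image alongside the component image."""
    stats_files = sorted(
        glob.glob(os.path.join(path, "stats", "thresh_zstat*.nii*")),
        key=lambda f: int(re.search(r"thresh_zstat(\d+)", f).group(1)),
    )
    if stats_files:
        if len(stats_files) != n_components:
            raise SockInputError(
                f"found {len(stats_files)} thresholded maps for {n_components} components"
            )
        vols = [np.asarray(nib.load(f).dataobj, dtype=float) for f in stats_files]
        return np.stack(vols, axis=-1)
    four_d = _find_image(path, "melodic_IC_thr")
    if four_d is not None:
        data = np.asarray(nib.load(four_d).dataobj, dtype=float)
        if data.ndim != 4 or data.shape[3] != n_components:
            raise SockInputError(
                f"4D thresholded image {four_d} has shape {data.shape}, "
                f"expected (*, *, *, {n_components})"
            )
        return data
    raise SockInputError(
        f"no thresholded maps found under {path} "
        "(looked for stats/thresh_zstat*.nii[.gz] and melodic_IC_thr.nii[.gz])"
    )


def read_melodic_dir(
    path: str,
    tr_seconds: float,
    *,
    require_spectra: bool = True,
    component_image: str = "melodic_IC",
    mix_file: str = "melodic_mix",
    spectra_file: str = "melodic_FTmix",
) -> ICADecomposition:
    """Read a MELODIC-style ICA output directory.

    Parameters
    ----------
    path : str
        Directory containing the decomposition.
    tr_seconds : float
        Repetition time; required because the spectra frequency axis
        depends on it and plain-text spectra carry no units.
    require_spectra : bool
        If False, a missing spectra file yields empty ``power_spectra``
        (the temporal-frequency feature must then be disabled downstream).

    Raises
    ------
    SockInputError
        Missing 4D component image, missing spectra (when required), or a
        column-count mismatch between maps and matrices.
    """
    ic_path = _find_image(path, component_image)
    if ic_path is None:
        raise SockInputError(f"missing 4D component image {component_image}.nii[.gz] in {path}")
    img = nib.load(ic_path)
    unthresh = np.asarray(img.dataobj, dtype=float)
    if unthresh.ndim != 4:
        raise SockInputError(f"{ic_path} is {unthresh.ndim}D; expected a 4D component image")
    n = unthresh.shape[3]
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])

    thresh = _load_thresholded(path, n, unthresh.shape[:3])

    mix_path = os.path.join(path, mix_file)
    time_courses = None
    if os.path.exists(mix_path):
        time_courses = np.loadtxt(mix_path, ndmin=2)
        if time_courses.shape[1] != n:
            raise SockInputError(
                f"mixing matrix {mix_path} has {time_courses.shape[1]} columns "
                f"but the component image has {n} maps"
            )

    spectra_path = os.path.join(path, spectra_file)
    if os.path.exists(spectra_path):
        spectra = np.loadtxt(spectra_path, ndmin=2)
        if spectra.shape[1] != n:
            raise SockInputError(
                f"power spectra {spectra_path} have {spectra.shape[1]} columns "
                f"but the component image has {n} maps"
            )
    elif require_spectra:
        raise SockInputError(
            f"missing power spectra file {spectra_file} in {path}; "
            "supply it or disable the temporal-frequency feature"
        )
    else:
        spectra = np.zeros((0, n))

    return ICADecomposition(
        unthresholded_maps=unthresh,
        thresholded_maps=thresh,
        tr_seconds=tr_seconds,
        voxel_size_mm=voxel_size,
        time_courses=time_courses,
        power_spectra=spectra,
    )


def read_masks(
    edge_path: str,
    csf_path: str,
    decomposition: ICADecomposition,
    *,
    brain_path: str | None = None,
) -> MaskSet:
    """Load edge and CSF mask images onto the decomposition grid.

    Any nonzero voxel is a member.  A brain mask is optional; when absent
    the union of edge and CSF is used as a stand-in (the classifier itself
    only consumes edge and CSF).
    """
    def _load(p: str, name: str) -> np.ndarray:
        data = np.asarray(nib.load(p).dataobj, dtype=float)
        if data.shape != decomposition.grid_shape:
            raise SockInputError(
                f"{name} mask grid {data.shape} does not match "
                f"decomposition grid {decomposition.grid_shape}"
            )
        return data != 0

    edge = _load(edge_path, "edge")
    csf = _load(csf_path, "CSF")
    if brain_path is not None:
        brain = _load(brain_path, "brain")
    else:
        brain = edge | csf
    if not edge.any():
        raise SockInputError(f"edge mask {edge_path} is empty")
    if not csf.any():
        raise SockInputError(f"CSF mask {csf_path} is empty")
    return MaskSet(brain=brain, edge=edge, csf=csf)


_REPORT_COLUMNS = [
    "component",
    "smoothness",
    "edge_activity",
    "edge_label",
    "edge_fraction",
    "csf_activity",
    "csf_label",
    "csf_fraction",
    "tfn",
    "tfn_label",
    "verdict",
    "triggered_rules",
]


def write_report(report, path: str) -> None:
    """Write a classification report as TSV plus a JSON summary.

    ``path`` names the TSV file; the summary (verdict counts, rule firing
    counts) goes to the same stem with a ``_summary.json`` suffix.
    """
    import pandas as pd

    table = report.table.copy()
    table["triggered_rules"] = [
        ",".join(rules) for rules in table["triggered_rules"]
    ]
    table = table[[c for c in _REPORT_COLUMNS if c in table.columns]]
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    summary_path = _summary_path(path)
    with open(summary_path, "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str):
    """Read back a report written by :func:`write_report`."""
    import pandas as pd

    from sock.classify import ClassificationReport

    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    table["triggered_rules"] = [
        r.split(",") if r else [] for r in table["triggered_rules"].astype(str)
    ]
    with open(_summary_path(path)) as fh:
        summary = json.load(fh)
    return ClassificationReport(table=table, summary=summary)


def _summary_path(tsv_path: str) -> str:
    stem, _ = os.path.splitext(tsv_path)
    return stem + "_summary.json"


def save_nifti(data: np.ndarray, voxel_size_mm, path: str) -> None:
    """Write an array as NIfTI with a diagonal affine from the voxel size."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)
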