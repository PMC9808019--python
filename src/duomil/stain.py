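"""Macenko stain normalisation in optical-density space.

H&E colour formation is modelled by Beer–Lambert: each pixel's optical
density (OD) is a non-negative combination of two stain vectors,
``od = M @ c`` with ``M`` a 3x2 matrix of unit OD columns (haematoxylin,
eosin) and ``c`` the per-pixel stain concentrations. The stain basis of an
image is estimated from the extremes of its OD point cloud projected onto
the best-fit plane (top-2 singular directions); normalisation re-renders the
image's concentrations in a fixed reference basis, removing scanner- and
lab-specific colour variation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np


class StainEstimationError(ValueError):
    """Raised when an image has no usable stain signal."""


@dataclass(frozen=True)
class StainNormConfig:
    """Estimation constants of the Macenko procedure.

    io_white
        Transmitted-light white point (uint8 scale).
    od_min
        OD magnitude below which pixels count as background and are excluded
        from basis estimation.
    angle_percentile
        Robust extreme of the projection-angle distribution: the stain
        directions are taken at this percentile and its complement.
    conc_percentile
        Percentile of per-stain concentration used as the robust maximum.
    min_tissue_pixels
        Minimum number of above-``od_min`` pixels required for estimation.
    """

    io_white: float = 255.0
    od_min: float = 0.15
    angle_percentile: float = 1.0
    conc_percentile: float = 99.0
    min_tissue_pixels: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.angle_percentile < 50):
            raise ValueError("angle_percentile must be in (0, 50)")
        if self.od_min <= 0:
            raise ValueError("od_min must be positive")


@dataclass(frozen=True)
class StainProfile:
    """A 3x2 unit-column stain matrix (H then E) plus concentration maxima."""

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray = field(
        default_factory=lambda: np.ones(2)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=np.float64)
        if m.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        if np.any(m < -1e-9):
            raise ValueError("stain matrix entries must be non-negative")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit vectors")
        object.__setattr__(self, "stain_matrix", m)
        object.__setattr__(
            self,
            "max_concentrations",
            np.asarray(self.max_concentrations, dtype=np.float64).reshape(2),
        )

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "StainProfile":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            stain_matrix=np.array(payload["stain_matrix"]),
            max_concentrations=np.array(payload["max_concentrations"]),
        )


def _unit_columns(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=0, keepdims=True)


#: Reference stain basis used when none is supplied: the classical H&E OD
#: vectors (haematoxylin first), with concentration maxima fixed once from
#: the synthetic generator's canonical rendering regime.
REFERENCE_PROFILE = StainProfile(
    stain_matrix=_unit_columns(
        np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]])
    ),
    max_concentrations=np.array([1.2, 0.9]),
)


def rgb_to_od(pixels: np.ndarray, io_white: float = 255.0) -> np.ndarray:
    """Optical density per channel: ``-log10(max(I, 1) / Io)``."""
    arr = np.maximum(np.asarray(pixels, dtype=np.float64), 1.0)
    return -np.log10(arr / io_white)


def od_to_rgb(od: np.ndarray, io_white: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped and quantised to uint8."""
    rgb = io_white * np.power(10.0, -np.asarray(od, dtype=np.float64))
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def estimate_stain_profile(
    patch: np.ndarray,
    config: StainNormConfig = StainNormConfig(),
    max_pixels: int = 20000,
    rng: np.random.Generator | None = None,
) -> StainProfile:
    """Estimate an image's two-stain basis with Macenko's procedure.

    Steps: drop low-OD (background) pixels; find the best-fit plane of the
    OD cloud via the top-2 right singular vectors; project onto the plane;
    take the directions at the extreme percentiles of the projection angle;
    order columns haematoxylin-then-eosin (larger blue-channel OD first).
    Concentration maxima are the ``conc_percentile`` percentile of each
    stain's unmixed concentration.

    ``max_pixels`` caps the number of tissue pixels entering the SVD and
    percentiles (deterministic subsample unless ``rng`` is given); this is a
    runtime knob, not a statistical parameter.
    """
    od = rgb_to_od(patch, config.io_white).reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) > config.od_min]
    if tissue.shape[0] < config.min_tissue_pixels:
        raise StainEstimationError("no stainable tissue")
    if tissue.shape[0] > max_pixels:
        if rng is None:
            idx = np.linspace(0, tissue.shape[0] - 1, max_pixels).astype(int)
        else:
            idx = rng.choice(tissue.shape[0], size=max_pixels, replace=False)
        tissue = tissue[idx]

    # Macenko operates on raw (uncentred) OD
    _, s, vt = np.linalg.svd(tissue, full_matrices=False)
    if s[1] <= 0.01 * max(s[0], 1e-300):
        raise StainEstimationError("degenerate single-stain image")
    plane = vt[:2]  # rows: the two principal OD directions
    # orient the first axis so projections are mostly positive
    if np.sum(tissue @ plane[0]) < 0:
        plane = plane.copy()
        plane[0] = -plane[0]

    proj = tissue @ plane.T  # N x 2 coordinates in the plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, config.angle_percentile)
    hi = np.percentile(phi, 100.0 - config.angle_percentile)
    # a one-stain OD cloud spans essentially no angle in the plane
    if abs(hi - lo) < np.deg2rad(1.0):
        raise StainEstimationError("degenerate single-stain image")
    v_lo = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v_hi = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]

    columns = []
    for v in (v_lo, v_hi):
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)  # stain ODs are physically non-negative
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            raise StainEstimationError("degenerate stain direction")
        columns.append(v / norm)
    m = np.column_stack(columns)
    # haematoxylin = column with the larger blue-channel OD component
    if m[2, 0] < m[2, 1]:
        m = m[:, ::-1]

    conc = _unmix(tissue, m)
    max_conc = np.percentile(conc, config.conc_percentile, axis=0)
    max_conc = np.maximum(max_conc, 1e-8)
    return StainProfile(stain_matrix=m, max_concentrations=max_conc)


def _unmix(od_flat: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Least-squares concentrations for flattened OD rows, clipped at 0."""
    pinv = np.linalg.pinv(stain_matrix)  # 2 x 3
    return np.clip(od_flat @ pinv.T, 0.0, None)


def concentrations(patch: np.ndarray, profile: StainProfile,
                   io_white: float = 255.0) -> np.ndarray:
    """Per-pixel (H, E) concentrations; shape ``patch.shape[:-1] + (2,)``."""
    od = rgb_to_od(patch, io_white)
    flat = _unmix(od.reshape(-1, 3), profile.stain_matrix)
    return flat.reshape(od.shape[:-1] + (2,))


def estimate_slide_profile(
    reader,
    config: StainNormConfig = StainNormConfig(),
    max_pixels: int = 100000,
) -> StainProfile:
    """Estimate one stain basis for a whole slide.

    Pixels are subsampled on a regular grid across the full slide and fed to
    :func:`estimate_stain_profile`. Normalising every tile of a slide with
    the slide's own profile applies a single linear map per slide, which
    preserves the between-tile contrast (e.g. a lesion's elevated
    haematoxylin) that per-patch renormalisation would equalise away.
    """
    w, h = reader.dims
    image = reader.read_region(0, 0, w, h)
    step = max(1, int(np.sqrt(w * h / max_pixels)))
    sample = image[::step, ::step]
    return estimate_stain_profile(sample, config, max_pixels=max_pixels)


def normalize_patch(
    patch: np.ndarray,
    reference: StainProfile = REFERENCE_PROFILE,
    config: StainNormConfig = StainNormConfig(),
    source_profile: StainProfile | None = None,
    rescale_concentrations: bool = True,
) -> np.ndarray:
    """Re-render a patch in the reference stain basis.

    The patch's own basis is estimated (unless ``source_profile`` is given,
    e.g. a per-slide estimate), concentrations are unmixed, optionally
    rescaled so the robust per-stain maxima match the reference's, and
    re-rendered through the reference stain matrix.

    ``rescale_concentrations=False`` applies basis correction only. That is
    the right choice when the profile is shared across a whole slide in a
    weakly supervised setting: a slide's robust concentration maxima are
    shifted by disease itself (dense nuclei raise the haematoxylin
    percentile), so rescaling by them imprints slide-level label
    information onto every patch.
    """
    src = source_profile or estimate_stain_profile(patch, config)
    c = concentrations(patch, src, config.io_white)
    if rescale_concentrations:
        c = c * (reference.max_concentrations / src.max_concentrations)
    od_new = c @ reference.stain_matrix.T
    return od_to_rgb(od_new, config.io_white)
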