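"""Partial-volume-correction algorithms.

Implements the five corrections compared in the evaluation:

* ``none``       — plain ROI means (no correction)
* ``meltzer2c``  — 2-compartment: divide by the PSF-smoothed brain mask
* ``mg3c``       — 3-compartment (Mueller-Gartner): subtract spread white
  matter signal (estimated on an eroded WM mask), divide by smoothed GM
* ``vc``         — van Cittert iterative deconvolution (no segmentation)
* ``gtm``        — geometric transfer matrix: solve the linear inter-region
  spill system for regional means (no corrected image)
* ``rbv``        — region-based voxelwise: rescale voxels by the ratio of a
  GTM-derived piecewise-constant image to its blurred version

All methods operate on a single common grid; convolutions go through
:func:`pvceval.phantom.convolve_volume` (FFT, zero padding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from pvceval.phantom import (
    ActivityVolume,
    LabelVolume,
    PSFModel,
    convolve_volume,
)

__all__ = [
    "GtmModel",
    "PvcResult",
    "build_gtm",
    "erode_mask",
    "plain_roi_means",
    "pvc_gtm",
    "pvc_meltzer",
    "pvc_muller_gartner",
    "pvc_rbv",
    "pvc_van_cittert",
]

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class GtmModel:
    """Geometric transfer matrix over an ordered region list.

    ``transfer_matrix[i, j]`` is the mean, over region i, of the blurred
    indicator of region j — the fraction of region j's activity observed in
    region i.  All non-background labels are included in the model.
    """

    region_names: list[str]
    transfer_matrix: np.ndarray
    condition_number: float
    voxel_size_mm: float
    grid: tuple[int, int, int]


@dataclass
class PvcResult:
    """Outcome of one correction: optional corrected image, regional values,
    and method-specific diagnostics."""

    method: str
    regional_values: dict[str, float]
    corrected_image: ActivityVolume | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.regional_values.items() if not np.isfinite(v)}
        if bad:
            raise ValueError(f"non-finite regional values: {bad}")


def _check_grids(*arrays) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"mismatched grids: {sorted(shapes)}")


def _masked_roi_means(
    values: np.ndarray, valid: np.ndarray, labels: LabelVolume | None
) -> dict[str, float]:
    """ROI means restricted to valid voxels; empty valid-intersection ROIs
    are skipped rather than reported as NaN."""
    if labels is None:
        return {}
    out: dict[str, float] = {}
    for name, code in labels.label_map.items():
        if name == "background":
            continue
        sel = (labels.labels == code) & valid
        if sel.any():
            out[name] = float(values[sel].mean())
    return out


def plain_roi_means(pet: ActivityVolume, labels: LabelVolume) -> PvcResult:
    """Method ``none``: uncorrected ROI means."""
    _check_grids(pet.values, labels.labels)
    valid = np.ones(pet.values.shape, dtype=bool)
    return PvcResult(
        method="none",
        regional_values=_masked_roi_means(pet.values, valid, labels),
        corrected_image=ActivityVolume(pet.values.copy(), pet.voxel_size_mm),
    )


def erode_mask(mask: np.ndarray, n_shells: int) -> np.ndarray:
    """``n_shells`` applications of 6-connected morphological erosion."""
    if n_shells < 0:
        raise ValueError("n_shells must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if n_shells == 0:
        return mask.copy()
    eroded = ndimage.binary_erosion(
        mask, structure=_STRUCT_6, iterations=n_shells, border_value=0
    )
    if not eroded.any():
        raise ValueError(f"erosion by {n_shells} shells emptied the mask")
    return eroded


def _smooth_mask(mask: np.ndarray, psf: PSFModel, voxel_size_mm: float) -> np.ndarray:
    if psf.is_delta:
        return mask.astype(float)
    return convolve_volume(mask.astype(float), psf.kernel(voxel_size_mm))


def pvc_meltzer(
    pet: ActivityVolume,
    brain_mask: np.ndarray,
    psf: PSFModel,
    mask_threshold: float = 0.5,
    labels: LabelVolume | None = None,
) -> PvcResult:
    """2-compartment correction: pet / (brain_mask ⊗ psf) where the
    smoothed mask exceeds ``mask_threshold``.

    ``brain_mask`` should be the union of GM and WM (CSF and background
    excluded).  Voxels below the threshold are invalid and excluded from
    the regional means; their count is reported in the diagnostics.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    _check_grids(pet.values, brain_mask)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    smoothed = _smooth_mask(brain_mask, psf, pet.voxel_size_mm)
    valid = smoothed >= mask_threshold
    corrected = np.zeros_like(pet.values)
    corrected[valid] = pet.values[valid] / smoothed[valid]
    return PvcResult(
        method="meltzer2c",
        regional_values=_masked_roi_means(corrected, valid, labels),
        corrected_image=ActivityVolume(corrected, pet.voxel_size_mm),
        diagnostics={
            "mask_threshold": mask_threshold,
            "excluded_voxels": int(np.sum(~valid)),
            "valid_voxels": int(np.sum(valid)),
        },
    )


def pvc_muller_gartner(
    pet: ActivityVolume,
    gm_mask: np.ndarray,
    wm_mask: np.ndarray,
    psf: PSFModel,
    wm_erosion_shells: int = 2,
    gm_threshold: float = 0.3,
    labels: LabelVolume | None = None,
) -> PvcResult:
    """3-compartment correction: subtract the spread white-matter signal
    (mean of the image over an eroded WM mask), divide by the smoothed GM
    mask, assume CSF activity is zero.

    Negative corrected voxels are floored at 0 and counted.  Regional means
    are computed over valid GM voxels only.
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    _check_grids(pet.values, gm_mask, wm_mask)
    if (gm_mask & wm_mask).any():
        raise ValueError("gm_mask and wm_mask must be disjoint")
    if not gm_mask.any():
        raise ValueError("GM mask is empty")
    eroded_wm = erode_mask(wm_mask, wm_erosion_shells)  # raises if emptied
    wm_estimate = float(pet.values[eroded_wm].mean())

    smoothed_gm = _smooth_mask(gm_mask, psf, pet.voxel_size_mm)
    smoothed_wm = _smooth_mask(wm_mask, psf, pet.voxel_size_mm)
    valid = gm_mask & (smoothed_gm >= gm_threshold)
    corrected = np.zeros_like(pet.values)
    numer = pet.values - wm_estimate * smoothed_wm
    corrected[valid] = numer[valid] / smoothed_gm[valid]
    n_negative = int(np.sum(corrected[valid] < 0))
    np.clip(corrected, 0.0, None, out=corrected)
    return PvcResult(
        method="mg3c",
        regional_values=_masked_roi_means(corrected, valid, labels),
        corrected_image=ActivityVolume(corrected, pet.voxel_size_mm),
        diagnostics={
            "wm_estimate": wm_estimate,
            "wm_erosion_shells": wm_erosion_shells,
            "gm_threshold": gm_threshold,
            "excluded_voxels": int(np.sum(gm_mask & ~valid)),
            "negative_voxels_floored": n_negative,
        },
    )


def pvc_van_cittert(
    pet: ActivityVolume,
    psf: PSFModel,
    alpha: float = 1.5,
    n_iterations: int = 30,
    rel_tol: float = 1e-4,
    labels: LabelVolume | None = None,
) -> PvcResult:
    """Classical van Cittert deconvolution with a nonnegativity clamp.

    Iterates ``f_{k+1} = clamp(f_k + alpha * (pet - psf ⊗ f_k))`` from
    ``f_0 = pet`` and stops after ``n_iterations`` or when the relative
    change of the residual norm drops below ``rel_tol``.
    """
    if not 0.0 < alpha <= 2.0:
        raise ValueError("alpha must lie in (0, 2]")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    f = pet.values.copy()
    residual_norms: list[float] = []
    kernel = None if psf.is_delta else psf.kernel(pet.voxel_size_mm)
    for k in range(n_iterations):
        reblurred = f if kernel is None else convolve_volume(f, kernel)
        residual = pet.values - reblurred
        norm = float(np.linalg.norm(residual))
        if not np.isfinite(norm):
            raise FloatingPointError(f"non-finite residual at iteration {k}")
        residual_norms.append(norm)
        if norm == 0.0:
            break
        f = f + alpha * residual
        np.clip(f, 0.0, None, out=f)
        if len(residual_norms) >= 2:
            prev = residual_norms[-2]
            if prev > 0 and abs(prev - norm) / prev < rel_tol:
                break
    valid = np.ones(f.shape, dtype=bool)
    return PvcResult(
        method="vc",
        regional_values=_masked_roi_means(f, valid, labels),
        corrected_image=ActivityVolume(f, pet.voxel_size_mm),
        diagnostics={
            "alpha": alpha,
            "iterations": len(residual_norms),
            "residual_norms": residual_norms,
        },
    )


def build_gtm(
    labels: LabelVolume,
    psf: PSFModel,
    condition_cap: float = 1e6,
) -> GtmModel:
    """Geometric transfer matrix over all non-background labels present.

    ``W[i, j]`` = mean over region i of the blurred indicator of region j.
    Raises when the matrix condition number exceeds ``condition_cap``.
    """
    names = [n for n in labels.names_present() if n != "background"]
    masks = {n: labels.mask(n) for n in names}
    empty = [n for n, m in masks.items() if not m.any()]
    if empty:
        raise ValueError(f"empty regions in GTM model: {empty}")
    n = len(names)
    w = np.empty((n, n), dtype=float)
    for j, src in enumerate(names):
        blurred = _smooth_mask(masks[src], psf, labels.voxel_size_mm)
        for i, obs in enumerate(names):
            w[i, j] = float(blurred[masks[obs]].mean())
    cond = float(np.linalg.cond(w))
    if cond > condition_cap:
        raise ValueError(
            f"GTM condition number {cond:.3g} exceeds cap {condition_cap:.3g}; "
            "consider merging small or thin regions"
        )
    return GtmModel(
        region_names=names,
        transfer_matrix=w,
        condition_number=cond,
        voxel_size_mm=labels.voxel_size_mm,
        grid=labels.grid,
    )


def pvc_gtm(pet: ActivityVolume, gtm: GtmModel, labels: LabelVolume) -> PvcResult:
    """Solve the GTM system for regional values (least squares).

    Returns regional values only; GTM produces no corrected image.
    """
    _check_grids(pet.values, labels.labels)
    if gtm.grid != labels.grid:
        raise ValueError("GTM was built on a different grid")
    observed = np.array(
        [float(pet.values[labels.mask(name)].mean()) for name in gtm.region_names]
    )
    solution, _, _, _ = np.linalg.lstsq(gtm.transfer_matrix, observed, rcond=None)
    return PvcResult(
        method="gtm",
        regional_values={n: float(v) for n, v in zip(gtm.region_names, solution)},
        corrected_image=None,
        diagnostics={
            "condition_number": gtm.condition_number,
            "observed_means": {n: float(v) for n, v in zip(gtm.region_names, observed)},
        },
    )


def pvc_rbv(
    pet: ActivityVolume,
    labels: LabelVolume,
    psf: PSFModel,
    gtm_values: dict[str, float],
    denominator_threshold: float = 1e-3,
    max_invalid_fraction: float = 0.25,
) -> PvcResult:
    """Region-based voxelwise correction applied after GTM.

    Builds the synthetic piecewise-constant image from ``gtm_values``
    (background fixed at 0), and rescales: ``pet * s / (s ⊗ psf)`` where
    the blurred synthetic image exceeds ``denominator_threshold`` times its
    maximum.  Regional values are ROI means of the corrected image over
    valid voxels.
    """
    _check_grids(pet.values, labels.labels)
    missing = [
        n for n in labels.names_present() if n != "background" and n not in gtm_values
    ]
    if missing:
        raise ValueError(f"gtm_values missing regions: {missing}")
    lut = np.zeros(max(labels.label_map.values()) + 1, dtype=float)
    for name, code in labels.label_map.items():
        lut[code] = gtm_values.get(name, 0.0)
    if "background" in labels.label_map:
        lut[labels.label_map["background"]] = 0.0
    synthetic = lut[labels.labels]
    blurred = (
        synthetic.copy() if psf.is_delta
        else convolve_volume(synthetic, psf.kernel(labels.voxel_size_mm))
    )
    floor = denominator_threshold * float(blurred.max())
    valid = blurred > floor
    head = labels.labels != labels.label_map.get("background", -1)
    invalid_fraction = float(np.sum(head & ~valid)) / max(int(head.sum()), 1)
    if invalid_fraction > max_invalid_fraction:
        raise ValueError(
            f"{invalid_fraction:.1%} of head voxels have near-zero RBV denominator"
        )
    corrected = np.zeros_like(pet.values)
    corrected[valid] = pet.values[valid] * synthetic[valid] / blurred[valid]
    n_negative = int(np.sum(corrected < 0))
    np.clip(corrected, 0.0, None, out=corrected)
    return PvcResult(
        method="rbv",
        regional_values=_masked_roi_means(corrected, valid, labels),
        corrected_image=ActivityVolume(corrected, pet.voxel_size_mm),
        diagnostics={
            "invalid_fraction": invalid_fraction,
            "denominator_threshold": denominator_threshold,
            "negative_voxels_floored": n_negative,
        },
    )
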