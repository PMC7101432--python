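"""PET volumes, SUV calibration and metabolically active tumor volume (MATV) delineation.

Two delineation strategies are provided: a fixed threshold at a fraction of
SUVmax (the widely used 41% rule) and a fuzzy Gaussian-mixture segmenter that
adaptively separates tumor uptake from background by EM with soft memberships.
Both return binary masks restricted to a user-supplied search box and keep only
the connected component anchored at the hottest voxel (fixed threshold) or the
largest component (fuzzy), using 26-connectivity throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage, stats

__all__ = [
    "PETVolume",
    "TumorMask",
    "Box",
    "compute_suv",
    "segment_fixed_fraction",
    "segment_fuzzy_adaptive",
    "compare_matv",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
]

#: 3D structuring element connecting all 26 neighbours.
CONN26 = np.ones((3, 3, 3), dtype=bool)

# A box is a half-open voxel-index bound per axis: ((i0,i1),(j0,j1),(k0,k1)).
Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(int(a), int(b)) for a, b in box)  # type: ignore[return-value]


@dataclass
class PETVolume:
    """A 3D PET grid with voxel spacing in mm.

    ``values`` holds either raw activity concentration (Bq/ml) or SUV;
    ``calibrated`` records which.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    calibrated: bool = False
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("PETVolume.values must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PETVolume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class TumorMask:
    """Binary segmentation aligned to a :class:`PETVolume`.

    ``provenance`` tags how the mask was obtained: ``fixed_fraction``,
    ``fuzzy_adaptive`` or ``ground_truth``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = "ground_truth"
    degenerate: bool = False
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("TumorMask.data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        """Mask volume in ml (= cm^3)."""
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0


def compute_suv(volume: PETVolume, injected_dose_bq: float, body_weight_kg: float) -> PETVolume:
    """Convert an activity-concentration volume (Bq/ml) to body-weight SUV.

    SUV = activity[Bq/ml] * body_weight[g] / injected_dose[Bq]; decay
    correction of the dose is assumed to have been applied upstream.
    """
    if injected_dose_bq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if volume.calibrated:
        raise ValueError("volume is already in SUV units")
    suv = volume.values * (body_weight_kg * 1000.0) / injected_dose_bq
    return PETVolume(suv, volume.spacing, calibrated=True, patient_id=volume.patient_id)


def _component_of(binary: np.ndarray, anchor: tuple[int, ...]) -> np.ndarray:
    labels, _ = ndimage.label(binary, structure=CONN26)
    return labels == labels[anchor]


def segment_fixed_fraction(
    vol: PETVolume, search_box: Box, fraction: float = 0.41
) -> TumorMask:
    """Threshold at ``fraction`` of the SUVmax inside ``search_box``.

    The mask is the 26-connected component, containing the box's maximum
    voxel, of the set {voxels >= fraction * SUVmax}. Ties for the maximum are
    broken at the lowest linear (row-major) index. A constant box is flagged
    degenerate and returns the whole box with a warning.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    sl = _box_slices(search_box)
    sub = vol.values[sl]
    if sub.size == 0:
        raise ValueError("empty search box")
    full = np.zeros(vol.values.shape, dtype=bool)
    if np.ptp(sub) == 0:
        warnings.warn("constant search box: fixed-fraction segmentation degenerate")
        full[sl] = True
        return TumorMask(full, vol.spacing, "fixed_fraction", degenerate=True,
                         patient_id=vol.patient_id)
    argmax = np.unravel_index(int(np.argmax(sub)), sub.shape)
    binary = sub >= fraction * sub[argmax]
    full[sl] = _component_of(binary, argmax)
    return TumorMask(full, vol.spacing, "fixed_fraction", patient_id=vol.patient_id)


def _fuzzy_gmm_1d(
    x: np.ndarray, n_classes: int, rng: np.random.Generator,
    max_iter: int = 300, tol: float = 1e-8, max_restarts: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded EM for a 1D Gaussian mixture; returns (weights, means, sds, resp).

    Restarts with jittered initialisation when a class collapses to zero
    variance or zero weight; errors after ``max_restarts`` failures.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    # variance floor at 1.5% of the intensity range: a class narrower than
    # the effective intensity resolution (e.g. exactly-constant background)
    # is not meaningful and would drag the decision boundary onto it
    floor = max(1e-12, (0.015 * float(np.ptp(x))) ** 2)
    rng_range = float(np.ptp(x))
    for restart in range(max_restarts + 1):
        # means spread over the intensity range (data quantiles collapse when
        # one class dominates the box, e.g. mostly-background boxes)
        mu = x.min() + rng_range * np.linspace(0, 1, n_classes + 2)[1:-1]
        if restart > 0:
            mu = mu + rng.normal(0, 0.1 * (rng_range + 1e-12), size=n_classes)
        var = np.full(n_classes, max(np.var(x) / n_classes, floor))
        w = np.full(n_classes, 1.0 / n_classes)
        ok = True
        prev_ll = -np.inf
        for _ in range(max_iter):
            logp = (
                np.log(w)[None, :]
                - 0.5 * np.log(2 * np.pi * var)[None, :]
                - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
            )
            m = logp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
            resp = np.exp(logp - lse[:, None])
            ll = float(lse.sum())
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                ok = False
                break
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            # zero within-class variance (e.g. perfectly separated data) is
            # absorbed by the resolution floor rather than treated as failure
            var = np.maximum(var, floor)
            if abs(ll - prev_ll) < tol * (1 + abs(ll)):
                break
            prev_ll = ll
        if ok and np.min(np.diff(np.sort(mu))) < 1e-6 * (rng_range + 1e-12):
            ok = False  # classes collapsed onto one mode
        if ok:
            return w, mu, np.sqrt(var), resp
    raise RuntimeError("fuzzy mixture EM failed to converge after restarts")


def segment_fuzzy_adaptive(
    vol: PETVolume, search_box: Box, n_classes: int = 2, seed: int = 0
) -> TumorMask:
    """Fuzzy Gaussian-mixture delineation inside ``search_box``.

    An EM-fitted mixture of ``n_classes`` (2 or 3) Gaussians over the box SUVs
    yields soft class memberships; tumor voxels are those whose membership in
    the highest-mean class (union of the two highest for ``n_classes=3``)
    exceeds 0.5. The largest 26-connected component is kept. This is a
    documented stand-in for the published FLAB delineation algorithm: a fuzzy
    adaptive mixture segmenter, not a reimplementation of FLAB itself.
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    sl = _box_slices(search_box)
    sub = vol.values[sl]
    if sub.size < 50:
        raise ValueError("search box must contain at least 50 voxels")
    rng = np.random.default_rng(seed)
    _, mu, _, resp = _fuzzy_gmm_1d(sub.ravel(), n_classes, rng)
    order = np.argsort(mu)
    hot = order[-1:] if n_classes == 2 else order[-2:]
    member = resp[:, hot].sum(axis=1).reshape(sub.shape) > 0.5
    if not member.any():
        raise RuntimeError("fuzzy segmentation produced an empty mask")
    labels, nlab = ndimage.label(member, structure=CONN26)
    sizes = ndimage.sum_labels(member, labels, index=np.arange(1, nlab + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    full = np.zeros(vol.values.shape, dtype=bool)
    full[sl] = keep
    return TumorMask(full, vol.spacing, "fuzzy_adaptive", patient_id=vol.patient_id)


def compare_matv(
    masks_a: list[TumorMask], masks_b: list[TumorMask]
) -> tuple[float, float, float]:
    """Paired comparison of MATVs (cm^3) from two segmentations.

    Returns (mean_cm3_a, mean_cm3_b, p) with p from a two-sided Wilcoxon
    signed-rank test on the paired volumes (exact distribution for n <= 15
    when no paired difference is zero). Pairing is positional and checked
    against patient ids when present.
    """
    if len(masks_a) != len(masks_b):
        raise ValueError("paired mask lists must have equal length")
    if len(masks_a) < 5:
        raise ValueError("need at least 5 pairs")
    for a, b in zip(masks_a, masks_b):
        if a.patient_id is not None and b.patient_id is not None and a.patient_id != b.patient_id:
            raise ValueError(f"patient pairing mismatch: {a.patient_id} vs {b.patient_id}")
    va = np.array([m.volume_ml for m in masks_a])
    vb = np.array([m.volume_ml for m in masks_b])
    d = va - vb
    if np.all(d == 0):
        return float(va.mean()), float(vb.mean()), 1.0
    method = "exact" if (len(d) <= 15 and not np.any(d == 0)) else "auto"
    res = stats.wilcoxon(va, vb, alternative="two-sided", method=method)
    return float(va.mean()), float(vb.mean()), float(res.pvalue)


# ---------------------------------------------------------------- NIfTI IO

def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(vol: PETVolume, path: str) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing)), path)


def write_mask(mask: TumorMask, path: str) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing)), path)


def read_volume(path: str, calibrated: bool = False, patient_id: str | None = None) -> PETVolume:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PETVolume(np.asarray(img.dataobj, dtype=float), spacing,
                     calibrated=calibrated, patient_id=patient_id)


def read_mask(path: str, provenance: str = "ground_truth", patient_id: str | None = None) -> TumorMask:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TumorMask(np.asarray(img.dataobj) > 0, spacing, provenance, patient_id=patient_id)
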