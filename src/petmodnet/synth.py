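"""Synthetic desk-scale radiogenomic cohort with known ground truth.

Three generators, all pure functions of their spec and a seed:

* PET phantoms — radially perturbed ellipsoids with Gaussian uptake lumps,
  blurred by the reconstruction point-spread function (5 mm FWHM default)
  and corrupted by zero-truncated Gaussian noise. The pre-blur tumor support
  is returned as the ground-truth mask.
* cohorts — per-patient phantom specs drawn from stated ranges (default 45
  patients, heterogeneous sizes, shapes and uptake patterns).
* expression arrays — paired tumor/normal raw one-color intensities in which
  planted gene modules have leaf-specific tumor log2 offsets driven by step
  functions (regulator trees) of the cohort's normalized radiomic features:
  exactly the generative assumption of the module-network model, so
  parameter-recovery tests are well posed. Raw foregrounds are built as
  2^signal plus additive Gaussian background so the normexp correction has
  real work to do.

A small synthetic pathway database generator (24 top-level pathways by
default) and a probe annotation builder support offline end-to-end runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .diffexpr import RawArraySet
from .imaging import PETVolume, TumorMask, write_mask, write_volume
from .modnet import RegulatorTree, Split
from .pathways import PathwayDB

__all__ = [
    "PhantomSpec",
    "PlantSpec",
    "make_tumor_phantom",
    "make_cohort",
    "plant_expression",
    "random_regulator_matrix",
    "make_pathway_db",
    "make_annotation",
    "write_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one tumor phantom.

    Units: mm for lengths, SUV for uptake. ``lumpiness`` is
    (number of Gaussian blobs, amplitude in SUV); ``boundary_perturbation``
    is the amplitude (mm) of a smooth random radial field added to the
    ellipsoid boundary; ``psf_fwhm`` models the reconstruction post-filter.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    base_radius: float = 20.0
    eccentricity: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lumpiness: tuple[int, float] = (0, 0.0)
    boundary_perturbation: float = 0.0
    background_suv: float = 1.0
    tumor_base_suv: float = 8.0
    psf_fwhm: float = 5.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_base_suv <= self.background_suv:
            raise ValueError("tumor_base_suv must exceed background_suv")
        if self.background_suv < 0 or self.noise_sd < 0 or self.psf_fwhm < 0:
            raise ValueError("SUVs, noise and PSF width must be non-negative")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")


def _radial_perturbation(u: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random radial field on unit directions: a few random plane-wave
    harmonics of the direction vector, scaled to RMS ~= amplitude."""
    if amplitude == 0:
        return np.zeros(u.shape[:-1])
    n_waves = 6
    w = rng.normal(size=(n_waves, 3))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    freq = rng.uniform(1.5, 4.0, size=n_waves)
    phase = rng.uniform(0, 2 * np.pi, size=n_waves)
    coef = rng.normal(size=n_waves)
    coef /= np.sqrt((coef**2).sum() / 2.0)  # unit RMS of the cosine sum
    out = np.zeros(u.shape[:-1])
    for k in range(n_waves):
        out += coef[k] * np.cos(freq[k] * (u @ w[k]) * np.pi + phase[k])
    return amplitude * out / np.sqrt(n_waves)


def make_tumor_phantom(spec: PhantomSpec) -> tuple[PETVolume, TumorMask]:
    """Generate one phantom volume and its ground-truth mask.

    The volume is the Gaussian-blurred (``psf_fwhm``) sum of background,
    tumor-interior uptake and lumps, plus i.i.d. Gaussian noise truncated at
    zero. The mask is the pre-blur tumor support. Identical specs (including
    the seed) give bit-identical output; a tumor touching the grid boundary
    raises, since shape features would be truncated.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * d for n, d in zip(shape, spacing)], indexing="ij"),
        axis=-1,
    ) - center
    ecc = np.asarray(spec.eccentricity, dtype=float)
    y = coords / ecc
    rho = np.linalg.norm(y, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(rho[..., None] > 0, y / np.maximum(rho, 1e-12)[..., None], 0.0)
    pert = _radial_perturbation(u, spec.boundary_perturbation, rng)
    mask = rho <= spec.base_radius + pert
    if not mask.any():
        raise ValueError("phantom mask is empty; enlarge base_radius or grid")
    for ax in range(3):
        sl = [slice(None)] * 3
        for side in (0, -1):
            sl[ax] = side  # type: ignore[call-overload]
            if mask[tuple(sl)].any():
                raise ValueError("tumor touches the grid boundary; enlarge the grid")

    uptake = np.full(shape, spec.background_suv, dtype=float)
    uptake[mask] = spec.tumor_base_suv
    n_lumps, lump_amp = int(spec.lumpiness[0]), float(spec.lumpiness[1])
    if n_lumps > 0 and lump_amp > 0:
        tumor_vox = np.argwhere(mask)
        lump_field = np.zeros(shape)
        for _ in range(n_lumps):
            c = tumor_vox[rng.integers(len(tumor_vox))] * spacing
            sigma_mm = spec.base_radius * rng.uniform(0.15, 0.35)
            amp = lump_amp * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            d2 = ((coords + center - c) ** 2).sum(axis=-1)
            lump_field += amp * np.exp(-0.5 * d2 / sigma_mm**2)
        uptake[mask] = np.maximum(uptake[mask] + lump_field[mask], 0.0)

    sigma_vox = spec.psf_fwhm * _FWHM_TO_SIGMA / spacing
    blurred = ndimage.gaussian_filter(uptake, sigma=sigma_vox) if spec.psf_fwhm > 0 else uptake
    if spec.noise_sd > 0:
        blurred = blurred + rng.normal(0.0, spec.noise_sd, size=shape)
    values = np.maximum(blurred, 0.0)
    pid = f"P{spec.seed:04d}"
    return (
        PETVolume(values, tuple(spacing), calibrated=True, patient_id=pid),
        TumorMask(mask, tuple(spacing), "ground_truth", patient_id=pid),
    )


#: Default per-phantom parameter ranges for cohort sampling. Radii spanning
#: 12-28 mm give MATVs covering well over a 3-fold range; lump counts and
#: amplitudes span homogeneous to strongly heterogeneous uptake.
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "base_radius": (12.0, 28.0),
    "eccentricity": (0.7, 1.3),
    "n_lumps": (0, 6),
    "lump_amplitude": (0.0, 4.0),
    "boundary_perturbation": (0.0, 4.0),
    "tumor_base_suv": (5.0, 12.0),
    "noise_sd": (0.1, 0.3),
}


def make_cohort(
    n_patients: int = 45,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> tuple[list[PETVolume], list[TumorMask], list[PhantomSpec]]:
    """Draw ``n_patients`` phantom specs from ``ranges`` and generate them."""
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    r = dict(DEFAULT_COHORT_RANGES)
    if ranges:
        r.update(ranges)
    rng = np.random.default_rng(seed)
    volumes, masks, specs = [], [], []
    for i in range(n_patients):
        spec = PhantomSpec(
            grid_shape=grid_shape,
            spacing=spacing,
            base_radius=float(rng.uniform(*r["base_radius"])),
            eccentricity=tuple(rng.uniform(*r["eccentricity"], size=3)),
            lumpiness=(int(rng.integers(r["n_lumps"][0], r["n_lumps"][1] + 1)),
                       float(rng.uniform(*r["lump_amplitude"]))),
            boundary_perturbation=float(rng.uniform(*r["boundary_perturbation"])),
            tumor_base_suv=float(rng.uniform(*r["tumor_base_suv"])),
            noise_sd=float(rng.uniform(*r["noise_sd"])),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, mask = make_tumor_phantom(spec)
        vol.patient_id = mask.patient_id = f"P{i:03d}"
        volumes.append(vol)
        masks.append(mask)
        specs.append(spec)
    return volumes, masks, specs


# ------------------------------------------------------------- expression

@dataclass(frozen=True)
class PlantSpec:
    """Planted module structure for the expression generator.

    ``planted_trees`` pairs each module's regulator tree with its leaf mean
    log2 tumor offsets (one per leaf, tree leaf order). The default leaf
    offsets (3, 1) keep every planted probe's mean paired log2 difference
    above the fold-change filter while leaving a 2-unit between-leaf
    contrast for the module learner. ``replicate_multiplicity`` duplicates
    every probe with independent noise to exercise replicate averaging.
    """

    planted_trees: tuple[tuple[RegulatorTree, tuple[float, ...]], ...]
    probes_per_module: int = 100
    n_null_probes: int = 200
    probe_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    array_background_mean: float = 50.0
    array_background_sd: float = 8.0
    replicate_multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.probes_per_module < 1:
            raise ValueError("probes_per_module must be >= 1")
        if self.replicate_multiplicity < 1:
            raise ValueError("replicate_multiplicity must be >= 1")
        for tree, means in self.planted_trees:
            if tree.depth > 2:
                raise ValueError("planted tree depth must be <= 2")
            if len(means) != tree.n_leaves:
                raise ValueError("one leaf mean required per tree leaf")
            if not all(np.isfinite(means)):
                raise ValueError("leaf means must be finite")

    @property
    def n_modules(self) -> int:
        return len(self.planted_trees)


def plant_expression(
    features: pd.DataFrame,
    plant: PlantSpec,
    seed: int = 0,
) -> tuple[RawArraySet, RawArraySet, dict]:
    """Generate paired tumor/normal raw arrays with planted module structure.

    ``features`` is the normalized (0-1) patients x features table whose
    columns include every planted regulator. For probe g of module m and
    patient p in leaf l of that module's tree, the tumor log2 signal is
    baseline_g + mu_{m,l} + noise and the normal signal baseline_g + noise;
    null probes carry no offset. Raw foreground = 2^signal plus additive
    Gaussian background; the background channel is an independent draw from
    the same background distribution. Returns (tumor set, normal set,
    ground truth dict with the true assignment and trees).
    """
    fvals = features.to_numpy(dtype=float)
    if np.isnan(fvals).any() or fvals.min() < 0 or fvals.max() > 1:
        raise ValueError("features must be normalized to [0, 1]")
    for tree, _ in plant.planted_trees:
        for f in tree.features:
            if f not in features.columns:
                raise ValueError(f"planted regulator {f!r} missing from feature table")
    rng = np.random.default_rng(seed)
    patients = [str(p) for p in features.index]
    n_pat = len(patients)

    probe_ids: list[str] = []
    offsets: list[np.ndarray] = []  # per unique probe: per-patient tumor offset
    truth_assign: dict[str, int] = {}
    for m, (tree, means) in enumerate(plant.planted_trees, start=1):
        leaves = tree.leaf_sets(features)
        for leaf in leaves:
            if len(leaf) == 0:
                raise ValueError(f"planted tree of module {m} has an empty leaf")
        per_patient = np.zeros(n_pat)
        for mu, leaf in zip(means, leaves):
            per_patient[leaf] = mu
        for g in range(plant.probes_per_module):
            pid = f"M{m:02d}_G{g:03d}"
            probe_ids.append(pid)
            offsets.append(per_patient)
            truth_assign[pid] = m
    for g in range(plant.n_null_probes):
        pid = f"NULL_G{g:04d}"
        probe_ids.append(pid)
        offsets.append(np.zeros(n_pat))
        truth_assign[pid] = 0

    n_probes = len(probe_ids)
    baseline = rng.normal(plant.baseline_mean, plant.baseline_sd, size=n_probes)
    offset_mat = np.stack(offsets)  # probes x patients

    def build(kind: str) -> RawArraySet:
        rep = plant.replicate_multiplicity
        rows = n_probes * rep
        signal_mean = baseline[:, None] + (offset_mat if kind == "tumor" else 0.0)
        signal = np.repeat(signal_mean, rep, axis=0) + rng.normal(
            0.0, plant.probe_sd, size=(rows, n_pat)
        )
        bg_true = rng.normal(plant.array_background_mean, plant.array_background_sd,
                             size=(rows, n_pat))
        fg = np.power(2.0, signal) + bg_true
        bg_obs = rng.normal(plant.array_background_mean, plant.array_background_sd,
                            size=(rows, n_pat))
        if (fg <= 0).any() or (bg_obs <= 0).any():
            raise RuntimeError("generated non-positive raw intensity; raise bg_mean/bg_sd ratio")
        arrays = [f"{p}_{kind[0].upper()}" for p in patients]
        index = pd.Index(np.repeat(probe_ids, rep), name="probe_id")
        samples = pd.DataFrame(
            {"patient_id": patients, "tissue": kind}, index=pd.Index(arrays, name="array_id")
        )
        return RawArraySet(
            pd.DataFrame(fg, index=index, columns=arrays),
            pd.DataFrame(np.abs(bg_obs) + 1e-9, index=index, columns=arrays),
            samples,
        )

    tumor = build("tumor")
    normal = build("normal")
    truth = {
        "assignment": truth_assign,
        "trees": [
            {"module": m + 1, "tree": tree.to_dict(), "leaf_means": list(means)}
            for m, (tree, means) in enumerate(plant.planted_trees)
        ],
        "baseline_log2": {p: float(b) for p, b in zip(probe_ids, baseline)},
        "seed": int(seed),
    }
    return tumor, normal, truth


def combine_arrays(tumor: RawArraySet, normal: RawArraySet) -> RawArraySet:
    """Merge the tumor and normal halves of a paired design into one set."""
    fg = pd.concat([tumor.foreground, normal.foreground], axis=1)
    bg = pd.concat([tumor.background, normal.background], axis=1)
    samples = pd.concat([tumor.samples, normal.samples])
    return RawArraySet(fg, bg, samples)


def random_regulator_matrix(
    n_patients: int, feature_names: list[str], seed: int = 0
) -> pd.DataFrame:
    """Uniform random feature table, min-max rescaled to span [0, 1] exactly."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=(n_patients, len(feature_names)))
    x = (x - x.min(axis=0)) / (x.max(axis=0) - x.min(axis=0))
    return pd.DataFrame(
        x, index=[f"P{i:03d}" for i in range(n_patients)], columns=feature_names
    )


# ---------------------------------------------------------- pathway world

#: Names for the default 24 top-level pathway universe.
TOP_LEVEL_NAMES = tuple(f"TOP_{i:02d}" for i in range(1, 25))


def make_pathway_db(
    n_top: int = 24,
    pathways_per_top: int = 3,
    genes_per_pathway: int = 12,
    seed: int = 0,
) -> PathwayDB:
    """Synthetic pathway database with a flat two-level hierarchy.

    Gene symbols are unique to their top-level family (GENE_<top>_<k>), so a
    module drawing its genes from one family is enriched only there.
    """
    rng = np.random.default_rng(seed)
    gene_sets: dict[str, frozenset[str]] = {}
    hierarchy: dict[str, str] = {}
    for t in range(1, n_top + 1):
        top = f"TOP_{t:02d}"
        pool = [f"GENE_T{t:02d}_{k:03d}" for k in range(pathways_per_top * genes_per_pathway)]
        for j in range(1, pathways_per_top + 1):
            name = f"PATH_T{t:02d}_{j}"
            genes = rng.choice(pool, size=genes_per_pathway, replace=False)
            gene_sets[name] = frozenset(genes)
            hierarchy[name] = top
    return PathwayDB(gene_sets, hierarchy)


def make_annotation(
    probe_ids: list[str],
    truth_assignment: dict[str, int],
    db: PathwayDB,
    module_family: dict[int, str],
    family_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe -> gene annotation in which each planted module's probes draw
    ``family_fraction`` of their genes from one top-level family's pathways
    and the rest (plus all null probes) from the whole database."""
    rng = np.random.default_rng(seed)
    by_top: dict[str, list[str]] = {}
    for pw, top in db.hierarchy.items():
        by_top.setdefault(top, []).extend(sorted(db.gene_sets[pw]))
    all_genes = sorted(db.genes)
    rows = []
    for pid in probe_ids:
        m = truth_assignment.get(pid, 0)
        if m in module_family and rng.uniform() < family_fraction:
            gene = str(rng.choice(by_top[module_family[m]]))
        else:
            gene = str(rng.choice(all_genes))
        rows.append({"probe_id": pid, "gene": gene})
    return pd.DataFrame(rows)


def simulate_radiogenomic_study(
    n_patients: int = 12,
    n_modules: int = 2,
    probes_per_module: int = 30,
    n_null_probes: int = 540,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    family_fraction: float = 0.8,
) -> dict:
    """Generate a complete in-memory desk-scale study with ground truth.

    Phantom cohort -> ground-truth-box segmentation inputs -> normalized
    radiomic features -> planted paired expression -> pathway database and
    probe annotation in which each planted module draws ``family_fraction``
    of its genes from one top-level pathway family. Returns a dict with all
    intermediate objects plus the planted truth (assignment, trees, the
    module -> top-level family map).
    """
    from .radiomics import extract_cohort_features, normalize_cohort_features

    rng = np.random.default_rng(seed)
    volumes, masks, _ = make_cohort(n_patients, seed=int(rng.integers(2**31 - 1)),
                                    grid_shape=grid_shape)
    features = normalize_cohort_features(extract_cohort_features(volumes, masks))
    feat_names = list(features.columns)
    trees = []
    for m in range(n_modules):
        # space planted regulators across feature categories (adjacent
        # columns are strongly correlated intensity variants)
        feat = feat_names[(m * 9) % len(feat_names)]
        # median split guarantees both leaves are populated
        t = float(np.median(features[feat].to_numpy()))
        trees.append((RegulatorTree(Split(feat, t)), (3.0, 1.0) if m % 2 == 0 else (1.0, 3.0)))
    plant = PlantSpec(
        planted_trees=tuple(trees),
        probes_per_module=probes_per_module,
        n_null_probes=n_null_probes,
    )
    tumor, normal, truth = plant_expression(features, plant, seed=int(rng.integers(2**31 - 1)))
    raw = combine_arrays(tumor, normal)
    db = make_pathway_db(seed=int(rng.integers(2**31 - 1)))
    family = {m + 1: f"TOP_{(m % 24) + 1:02d}" for m in range(n_modules)}
    probe_ids = list(dict.fromkeys(raw.foreground.index))
    annotation = make_annotation(
        probe_ids, truth["assignment"], db, family,
        family_fraction=family_fraction, seed=int(rng.integers(2**31 - 1)),
    )
    return {
        "volumes": volumes,
        "masks": masks,
        "features": features,
        "raw_arrays": raw,
        "truth": truth,
        "pathway_db": db,
        "annotation": annotation,
        "module_family": family,
        "plant": plant,
    }


# -------------------------------------------------------------- file dump

def write_cohort(
    outdir: str,
    volumes: list[PETVolume],
    masks: list[TumorMask],
    dose_bq: float = 350e6,
    weight_kg: float = 70.0,
) -> str:
    """Write NIfTI volumes/masks plus a manifest TSV; returns manifest path.

    The manifest carries patient_id, dose_Bq, weight_kg, volume/mask paths
    and the half-open search-box bounds (ground-truth bounding box plus a
    2-voxel margin) used by the segmenters.
    """
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for vol, mask in zip(volumes, masks, strict=True):
        pid = vol.patient_id or "P"
        vpath = os.path.join(outdir, f"{pid}_suv.nii.gz")
        mpath = os.path.join(outdir, f"{pid}_truth.nii.gz")
        write_volume(vol, vpath)
        write_mask(mask, mpath)
        nz = np.argwhere(mask.data)
        lo = np.maximum(nz.min(axis=0) - 2, 0)
        hi = np.minimum(nz.max(axis=0) + 3, mask.data.shape)
        rows.append(
            {
                "patient_id": pid,
                "dose_Bq": dose_bq,
                "weight_kg": weight_kg,
                "volume_path": os.path.basename(vpath),
                "mask_path": os.path.basename(mpath),
                "box_i0": lo[0], "box_i1": hi[0],
                "box_j0": lo[1], "box_j1": hi[1],
                "box_k0": lo[2], "box_k1": hi[2],
            }
        )
    manifest = os.path.join(outdir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
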