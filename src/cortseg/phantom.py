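"""Seeded synthetic two-contrast brain phantoms with typed lesions.

The generator emulates the statistical structure of a multi-site MS cohort
without any clinical data: a nested-shell "brain" (an ellipsoidal cortex
ribbon wrapped around a white-matter core) into which ellipsoidal lesions
are placed -- white-matter lesions (WMLs) strictly inside the core,
cortical lesions (CLs) seeded in the ribbon (they may extend into adjacent
WM, as leukocortical lesions do).  Contrast follows the clinical picture:
WMLs are strongly hyperintense in the FLAIR-like channel while CLs barely
differ from cortex there; in the MP2RAGE-like channel the CL contrast is
the larger of the two.  Per-lesion volumes are drawn from a log-normal
truncated below at the 3-voxel minimum lesion size; per-subject lesion
counts vary across a cohort, giving burdens that span a wide range.

No MR physics is simulated (no bias field, no partial volume); noise is
additive Gaussian per channel.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes_io import CL, WML, ImageVolume, LabelVolume, SubjectCase

#: minimum lesion size in voxels; smaller candidates are resampled.
MIN_LESION_VOXELS = 3

_TYPE_LABEL = {"WML": WML, "CL": CL}


class PlacementError(RuntimeError):
    """Raised when lesion placement is infeasible under the configuration."""


def _default_tissue_intensities() -> Dict[str, Dict[str, float]]:
    # Arbitrary units. FLAIR: WML strongly hyperintense (+60 vs WM), CL barely
    # above cortex (+12). MP2RAGE-like (UNI): CL clearly hypointense vs cortex
    # (-40), WML moderately hypointense vs WM (-30).
    return {
        "FLAIR": {"background": 10.0, "wm": 100.0, "cortex": 110.0,
                  "wml": 160.0, "cl": 122.0},
        "MP2RAGE": {"background": 10.0, "wm": 140.0, "cortex": 100.0,
                    "wml": 110.0, "cl": 60.0},
    }


@dataclasses.dataclass
class PhantomConfig:
    """Configuration of one synthetic subject.

    ``n_wml``/``n_cl`` are exact per-subject lesion counts (cohort-level
    variability is injected by :func:`make_cohort`).  ``size_distribution``
    maps lesion type to log-normal parameters ``(median_voxels, sigma_log)``;
    draws are truncated below at 3 voxels.  Intensities are per-contrast
    tissue means; see :func:`_default_tissue_intensities`.
    """

    dims: Tuple[int, int, int] = (96, 96, 96)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_wml: int = 8
    n_cl: int = 3
    size_distribution: Dict[str, Tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"WML": (25.0, 1.0), "CL": (12.0, 0.8)})
    tissue_intensities: Dict[str, Dict[str, float]] = dataclasses.field(
        default_factory=_default_tissue_intensities)
    noise_sigma: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"FLAIR": 4.0, "MP2RAGE": 4.0})
    cortex_thickness: float = 3.0
    brain_fraction: float = 0.45
    max_attempts: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.dims) < 32:
            raise ValueError(f"dims {self.dims}: each axis must be >= 32 to hold the geometry")
        ti = self.tissue_intensities
        if abs(ti["FLAIR"]["cl"] - ti["FLAIR"]["cortex"]) >= abs(
                ti["FLAIR"]["wml"] - ti["FLAIR"]["wm"]):
            raise ValueError("CL contrast in FLAIR must be smaller than WML contrast")
        if abs(ti["MP2RAGE"]["cl"] - ti["MP2RAGE"]["cortex"]) <= abs(
                ti["FLAIR"]["cl"] - ti["FLAIR"]["cortex"]):
            raise ValueError("CL contrast must be larger in MP2RAGE than in FLAIR")


@dataclasses.dataclass
class LesionGeometry:
    """One placed ellipsoid: center, semi-axes (voxels) and type tag."""

    center: Tuple[float, float, float]
    radii: Tuple[float, float, float]
    lesion_type: str
    voxels: np.ndarray  # (n, 3) int indices actually rendered


@dataclasses.dataclass
class PhantomTruth:
    """A generated subject together with its exact lesion-level ground truth."""

    case: SubjectCase
    components: List["LesionGeometry"]
    geometry_log: pd.DataFrame

    def render_labels(self) -> np.ndarray:
        """Re-render the label grid from the component voxel lists."""
        lab = np.zeros(self.case.shape, dtype=np.uint8)
        for comp in self.components:
            vx = comp.voxels
            lab[vx[:, 0], vx[:, 1], vx[:, 2]] = _TYPE_LABEL[comp.lesion_type]
        return lab


def _ellipsoid_mask(dims, center, radii) -> np.ndarray:
    grids = np.ogrid[: dims[0], : dims[1], : dims[2]]
    acc = np.zeros(dims, dtype=np.float32)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def brain_regions(config: PhantomConfig):
    """Return (brain, wm_core, cortex_ribbon) boolean masks."""
    dims = config.dims
    center = tuple((d - 1) / 2.0 for d in dims)
    outer = tuple(config.brain_fraction * d for d in dims)
    inner = tuple(max(4.0, r - config.cortex_thickness) for r in outer)
    brain = _ellipsoid_mask(dims, center, outer)
    wm = _ellipsoid_mask(dims, center, inner)
    cortex = brain & ~wm
    return brain, wm, cortex


def _draw_volume(rng: np.random.Generator, median: float, sigma: float,
                 cap: float) -> float:
    # log-normal truncated below at the minimum size (resampling) and capped.
    for _ in range(1000):
        v = float(np.exp(np.log(median) + sigma * rng.standard_normal()))
        if MIN_LESION_VOXELS <= v <= cap:
            return v
    raise PlacementError("could not draw a lesion volume within [3, cap]")


def sample_lesion_geometry(rng: np.random.Generator, lesion_type: str,
                           region: np.ndarray,
                           size_params: Tuple[float, float] = (25.0, 1.0),
                           max_attempts: int = 200) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
    """Draw an ellipsoid (center, radii) for one lesion inside ``region``.

    The center is a uniformly drawn region voxel; semi-axes are derived from
    a truncated log-normal volume draw with mild random anisotropy.  The
    discretized ellipsoid always has volume >= 3 voxels.  Raises
    :class:`PlacementError` if the region is empty or smaller than the
    minimum lesion.
    """
    idx = np.argwhere(region)
    if len(idx) == 0:
        raise PlacementError(f"empty placement region for {lesion_type}")
    if len(idx) < MIN_LESION_VOXELS:
        raise PlacementError(
            f"region of {len(idx)} voxels cannot host a >= {MIN_LESION_VOXELS}-voxel lesion")
    cap = max(float(len(idx)), MIN_LESION_VOXELS + 1.0)
    target = _draw_volume(rng, size_params[0], size_params[1], cap)
    center = tuple(float(c) for c in idx[rng.integers(len(idx))])
    # semi-axes from volume: V = 4/3 pi a b c, anisotropy factors of product 1
    aniso = np.exp(rng.uniform(-0.3, 0.3, size=3))
    aniso /= aniso.prod() ** (1.0 / 3.0)
    r0 = (3.0 * target / (4.0 * np.pi)) ** (1.0 / 3.0)
    radii = tuple(float(max(0.8, r0 * a)) for a in aniso)
    return center, radii


def _try_place(rng, lesion_type, allowed, must_touch, occupied_dilated, dims,
               size_params, max_attempts):
    """Rejection-sample one lesion; returns its voxel index array."""
    struct = np.ones((3, 3, 3), dtype=bool)
    last_reason = "no attempt made"
    for _ in range(max_attempts):
        try:
            center, radii = sample_lesion_geometry(rng, lesion_type, allowed,
                                                   size_params, max_attempts)
        except PlacementError as e:
            raise PlacementError(f"{lesion_type}: {e}") from e
        mask = _ellipsoid_mask(dims, center, radii) & allowed
        n = int(mask.sum())
        if n < MIN_LESION_VOXELS:
            last_reason = f"candidate shrank below {MIN_LESION_VOXELS} voxels after clipping"
            continue
        lab, ncomp = ndimage.label(mask, structure=struct)
        if ncomp != 1:
            last_reason = "candidate disconnected after clipping to its region"
            continue
        if must_touch is not None and not (mask & must_touch).any():
            last_reason = "cortical candidate does not touch the cortex ribbon"
            continue
        if (mask & occupied_dilated).any():
            last_reason = "candidate touches an already placed lesion"
            continue
        return np.argwhere(mask), center, radii
    raise PlacementError(
        f"could not place a {lesion_type} after {max_attempts} attempts: {last_reason}")


def generate_phantom(config: PhantomConfig, subject_id: str = "phantom",
                     site: str = "site1") -> PhantomTruth:
    """Generate one synthetic subject. Deterministic given ``config.seed``.

    Lesions of the same type never touch (26-neighbourhood separation is
    enforced between all lesions), so the ground truth contains exactly
    ``n_wml`` label-1 and ``n_cl`` label-2 connected components under any
    standard connectivity.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    dims = tuple(config.dims)
    brain, wm, cortex = brain_regions(config)

    struct = np.ones((3, 3, 3), dtype=bool)
    occupied = np.zeros(dims, dtype=bool)
    components: List[LesionGeometry] = []
    rows = []
    plan = [("WML", wm, None)] * config.n_wml + [("CL", brain, cortex)] * config.n_cl
    for lesion_type, allowed, must_touch in plan:
        occupied_dil = ndimage.binary_dilation(occupied, structure=struct) if occupied.any() \
            else occupied
        # CLs may extend into WM but must avoid existing lesions and stay in brain
        vox, center, radii = _try_place(
            rng, lesion_type, allowed & ~occupied_dil, must_touch, occupied_dil,
            dims, config.size_distribution[lesion_type], config.max_attempts)
        occupied[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        components.append(LesionGeometry(center=center, radii=radii,
                                         lesion_type=lesion_type, voxels=vox))
        rows.append(dict(lesion_type=lesion_type, cx=center[0], cy=center[1],
                         cz=center[2], rx=radii[0], ry=radii[1], rz=radii[2],
                         n_voxels=len(vox)))

    labels = np.zeros(dims, dtype=np.uint8)
    for comp in components:
        vx = comp.voxels
        labels[vx[:, 0], vx[:, 1], vx[:, 2]] = _TYPE_LABEL[comp.lesion_type]

    channels = {}
    for contrast in ("FLAIR", "MP2RAGE"):
        ti = config.tissue_intensities[contrast]
        img = np.full(dims, ti["background"], dtype=np.float32)
        img[wm] = ti["wm"]
        img[cortex] = ti["cortex"]
        img[labels == WML] = ti["wml"]
        img[labels == CL] = ti["cl"]
        img += config.noise_sigma[contrast] * rng.standard_normal(dims).astype(np.float32)
        channels[contrast] = img

    affine = np.diag(list(config.spacing) + [1.0])
    case = SubjectCase(
        subject_id=subject_id,
        flair=ImageVolume(channels["FLAIR"], config.spacing, affine, "FLAIR"),
        mp2rage=ImageVolume(channels["MP2RAGE"], config.spacing, affine, "MP2RAGE"),
        gt=LabelVolume(labels, config.spacing, affine),
        site=site,
    )
    geometry_log = pd.DataFrame(rows)
    return PhantomTruth(case=case, components=components, geometry_log=geometry_log)


def make_cohort(n_subjects: int, config_template: Optional[PhantomConfig] = None,
                master_seed: int = 0, site: str = "site1",
                id_prefix: str = "sub") -> List[PhantomTruth]:
    """Generate a cohort with per-subject seeds and variable lesion burden.

    Subject seeds are spawned deterministically from ``master_seed``.  Lesion
    counts are drawn per subject (Poisson around the template's counts; at
    least one WML so every case is trainable), mimicking the wide per-patient
    spread of lesion burden seen clinically.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    template = config_template or PhantomConfig()
    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        n_wml = max(1, int(rng.poisson(template.n_wml)))
        n_cl = int(rng.poisson(template.n_cl))
        cfg = dataclasses.replace(template, n_wml=n_wml, n_cl=n_cl, seed=sub_seed)
        cohort.append(generate_phantom(cfg, subject_id=f"{id_prefix}{i:03d}", site=site))
    return cohort


def cohort_manifest(cohort: List[PhantomTruth]) -> pd.DataFrame:
    """Per-subject summary table (id, site, lesion counts, total volumes)."""
    rows = []
    for truth in cohort:
        case = truth.case
        vox_ul = case.flair.voxel_volume_ul
        n_wml = sum(1 for c in truth.components if c.lesion_type == "WML")
        n_cl = sum(1 for c in truth.components if c.lesion_type == "CL")
        wml_ul = sum(len(c.voxels) for c in truth.components if c.lesion_type == "WML") * vox_ul
        cl_ul = sum(len(c.voxels) for c in truth.components if c.lesion_type == "CL") * vox_ul
        rows.append(dict(subject_id=case.subject_id, site=case.site, n_wml=n_wml,
                         n_cl=n_cl, wml_volume_ul=wml_ul, cl_volume_ul=cl_ul))
    return pd.DataFrame(rows)


def write_cohort(cohort: List[PhantomTruth], outdir) -> pd.DataFrame:
    """Write per-subject NIfTI triplets plus a manifest CSV; returns the manifest."""
    import os

    from .volumes_io import save_image, save_mask

    os.makedirs(outdir, exist_ok=True)
    for truth in cohort:
        case = truth.case
        sid = case.subject_id
        save_image(case.flair, os.path.join(outdir, f"{sid}_flair.nii.gz"))
        save_image(case.mp2rage, os.path.join(outdir, f"{sid}_mp2rage.nii.gz"))
        save_mask(case.gt, case.flair, os.path.join(outdir, f"{sid}_gt.nii.gz"))
    manifest = cohort_manifest(cohort)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest


def load_cohort(manifest_path) -> List[SubjectCase]:
    """Load the cases referenced by a cohort manifest written by write_cohort."""
    import os

    from .volumes_io import load_case

    manifest = pd.read_csv(manifest_path)
    root = os.path.dirname(os.path.abspath(manifest_path))
    cases = []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        cases.append(load_case(
            os.path.join(root, f"{sid}_flair.nii.gz"),
            os.path.join(root, f"{sid}_mp2rage.nii.gz"),
            os.path.join(root, f"{sid}_gt.nii.gz"),
            subject_id=sid, site=str(row["site"])))
    return cases
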