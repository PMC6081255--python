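"""Synthetic basilar-artery plaque cohort generator.

Produces 2D cross-sectional plaque "studies" (T1, T2, CE-T1 intensity grids
plus lumen / outer-wall / plaque / reference-muscle / grey-matter masks and a
clinical covariate row) with the group structure the downstream analysis
assumes: a symptomatic group with higher intraplaque-haemorrhage prevalence,
larger minimal luminal area, stronger contrast enhancement and rougher plaque
texture than the asymptomatic group.

The generator draws one analysed slice per patient on a 64x64 grid at 0.3 mm
in-plane spacing and 2 mm slice thickness.  The vessel is a pair of
concentric ellipses (lumen inside outer wall); the plaque annulus is filled
with a base intensity plus spatially correlated Gaussian noise whose
correlation length is the texture-heterogeneity knob (rougher = shorter
correlation = higher co-occurrence entropy after discretisation).  CE-T1
plaque intensities are affinely rescaled so that the grey-matter-normalised
enhancement-ratio formula recovers the drawn per-patient value.

All randomness flows through one :class:`numpy.random.Generator` derived from
the spec seed; identical specs yield bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter

__all__ = [
    "CohortSpec",
    "RoiImage",
    "PlaqueStudy",
    "generate_cohort",
    "render_plaque_image",
    "perturb_segmentation",
    "write_cohort",
    "read_cohort",
]

SEQUENCES = ("T1", "T2", "CE_T1")
MASK_NAMES = ("lumen", "outer_wall", "plaque_roi", "muscle_ref", "grey_matter_ref")

_EIGHT_CONN = np.ones((3, 3), dtype=int)


class GeometryError(ValueError):
    """Vessel geometry does not fit the image grid."""


@dataclass(frozen=True)
class RoiImage:
    """A 2D intensity grid with its physical pixel geometry."""

    data: np.ndarray
    pixel_spacing: float
    slice_thickness: float

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def shape(self):
        return self.data.shape


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters.

    Group-indexed pairs are ordered (symptomatic, asymptomatic).  Defaults
    reproduce the published cohort structure: 61 vs 35 patients, IPH
    prevalence 19/61 vs 1/35, MLA 3.78+-2.80 vs 2.39+-1.46 mm^2 (drawn from
    a positive gamma matched on mean/SD), enhancement ratio 24.20+-29.46 vs
    3.38+-21.91 %, plaque burden ~83-85 %, stenosis ~54 %, and a rougher
    texture in the symptomatic group.
    """

    n_symptomatic: int = 61
    n_asymptomatic: int = 35
    iph_prevalence_by_group: Tuple[float, float] = (19 / 61, 1 / 35)
    mla_mean_sd_by_group: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (3.78, 2.80),
        (2.39, 1.46),
    )
    enhancement_mean_sd_by_group: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (24.20, 29.46),
        (3.38, 21.91),
    )
    texture_heterogeneity_by_group: Tuple[float, float] = (0.55, 0.4)
    # Haemorrhage is a lesion-level finding over the whole slice stack; only
    # this fraction of IPH-positive lesions shows the blob on the single
    # analysed slice (the rest is visible to the clinical read only).
    iph_on_analysed_slice_prob: float = 1.0
    texture_heterogeneity_sd: float = 0.25  # per-patient spread around the group value
    intensity_gain_sd: float = 0.25  # log-SD of the per-patient, per-sequence receive gain
    plaque_burden_mean_sd_by_group: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (83.24, 9.71),
        (85.04, 7.51),
    )
    stenosis_mean_sd_by_group: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (53.69, 15.19),
        (53.76, 16.73),
    )
    age_mean_sd_by_group: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (61.68, 10.75),
        (62.14, 8.92),
    )
    covariate_prevalence_by_group: Tuple[Dict[str, float], Dict[str, float]] = (
        {
            "sex_male": 46 / 61,
            "smoking": 23 / 61,
            "diabetes": 23 / 61,
            "hypertension": 48 / 61,
            "hyperlipidaemia": 23 / 61,
        },
        {
            "sex_male": 18 / 35,
            "smoking": 4 / 35,
            "diabetes": 11 / 35,
            "hypertension": 30 / 35,
            "hyperlipidaemia": 11 / 35,
        },
    )
    pixel_spacing: float = 0.3
    slice_thickness: float = 2.0
    grid_size: int = 64
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "CohortSpec":
        """Load a spec from a JSON or YAML mapping of field overrides."""
        import json

        from pathlib import Path as _Path

        text = _Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown cohort-spec fields: {sorted(unknown)}")

        def _tuplify(v):
            return tuple(_tuplify(x) for x in v) if isinstance(v, list) else v

        return cls(**{k: _tuplify(v) for k, v in data.items()})

    def __post_init__(self) -> None:
        if self.n_symptomatic <= 0 or self.n_asymptomatic <= 0:
            raise ValueError("group counts must be positive")
        for p in self.iph_prevalence_by_group:
            if not 0.0 <= p <= 1.0:
                raise ValueError("IPH prevalence must lie in [0, 1]")
        for pair_set in (
            self.mla_mean_sd_by_group,
            self.enhancement_mean_sd_by_group,
            self.plaque_burden_mean_sd_by_group,
            self.stenosis_mean_sd_by_group,
            self.age_mean_sd_by_group,
        ):
            for _, sd in pair_set:
                if sd < 0:
                    raise ValueError("standard deviations must be non-negative")
        for h in self.texture_heterogeneity_by_group:
            if h < 0:
                raise ValueError("texture heterogeneity must be non-negative")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")
        if self.grid_size < 32:
            raise ValueError("grid too small for the vessel geometry")


@dataclass
class PlaqueStudy:
    """One patient's analysed slice: images, masks, covariates and label."""

    patient_id: str
    images: Dict[str, RoiImage]
    masks: Dict[str, np.ndarray]
    covariates: Dict[str, float]
    label: str  # "acute_subacute_symptomatic" | "asymptomatic"
    pixel_spacing: float
    slice_thickness: float
    reference_lumen_area: float  # mm^2, proximal normal-appearing lumen
    iph_lesion: bool = False  # haemorrhage anywhere in the stack (clinical read)

    def validate(self) -> None:
        shape = self.masks["lumen"].shape
        for name in MASK_NAMES:
            if self.masks[name].shape != shape:
                raise ValueError("masks do not share the image grid")
        lumen = self.masks["lumen"]
        outer = self.masks["outer_wall"]
        if (lumen & ~outer).any():
            raise ValueError("lumen must lie inside the outer wall")
        if ((self.masks["muscle_ref"] | self.masks["grey_matter_ref"]) & outer).any():
            raise ValueError("reference ROIs must be disjoint from the vessel")
        if not (outer & ~lumen).any():
            raise ValueError("plaque ROI is empty")


# ---------------------------------------------------------------------------
# Geometry and rendering
# ---------------------------------------------------------------------------


def _ellipse_mask(
    shape: Tuple[int, int],
    centre: Tuple[float, float],
    semi_axes: Tuple[float, float],
    angle: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - centre[0]
    dc = cc - centre[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _texture_field(shape: Tuple[int, int], heterogeneity: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially correlated noise.

    Correlation length shrinks as heterogeneity grows, so rougher groups get
    higher co-occurrence entropy after range discretisation; zero
    heterogeneity returns an all-zero field (constant plaque).
    """
    if heterogeneity <= 0:
        return np.zeros(shape)
    sigma = 2.5 / (0.5 + heterogeneity)
    w = min(0.9, 0.6 * heterogeneity)
    smooth = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    smooth /= smooth.std()
    f = (1.0 - w) * smooth + w * rng.standard_normal(shape)
    return f / f.std()


# Fixed reference-ROI placement (vessel is centred, references sit in corners).
_MUSCLE_SLICE = (slice(50, 55), slice(5, 10))
# 13x13 px at 0.3 mm -> 15.2 mm^2, the grey-matter reference patch.
_GM_SLICE = (slice(47, 60), slice(47, 60))

_T1_PLAQUE_BASE = 100.0
_T2_PLAQUE_BASE = 110.0
_MUSCLE_BASE = {"T1": 90.0, "T2": 80.0, "CE_T1": 92.0}
_GM_BASE = {"T1": 100.0, "T2": 120.0, "CE_T1": 106.0}
_NOISE_AMPLITUDE = 0.08  # plaque texture amplitude relative to base signal


def render_plaque_image(
    shape: Tuple[int, int],
    masks: Dict[str, np.ndarray],
    contrast: str,
    heterogeneity: float,
    rng: np.random.Generator,
    iph: bool = False,
    iph_pixels: np.ndarray | None = None,
    pixel_spacing: float = 0.3,
    slice_thickness: float = 2.0,
) -> RoiImage:
    """Render one contrast of the slice from its masks.

    The plaque annulus receives base signal plus the heterogeneity-scaled
    correlated noise field; on pre-contrast T1 an optional haemorrhage blob
    is painted at 1.6-2.2x the muscle reference mean.  CE-T1 is rescaled by
    the caller to hit the drawn enhancement ratio.
    """
    if contrast not in SEQUENCES:
        raise ValueError(f"unknown contrast {contrast!r}")
    img = 60.0 + gaussian_filter(rng.standard_normal(shape), 1.5, mode="wrap") * 3.0

    muscle = masks["muscle_ref"]
    gm = masks["grey_matter_ref"]
    img[muscle] = _MUSCLE_BASE[contrast] + rng.standard_normal(muscle.sum()) * 1.0
    img[gm] = _GM_BASE[contrast] + rng.standard_normal(gm.sum()) * 1.0

    plaque = masks["plaque_roi"]
    base = _T2_PLAQUE_BASE if contrast == "T2" else _T1_PLAQUE_BASE
    field = _texture_field(shape, heterogeneity, rng)
    img[plaque] = base * (1.0 + _NOISE_AMPLITUDE * field[plaque])

    img[masks["lumen"]] = 30.0 + rng.standard_normal(masks["lumen"].sum()) * 1.5

    if iph and contrast == "T1":
        if iph_pixels is None:
            raise ValueError("iph_pixels required when painting a haemorrhage")
        muscle_mean = float(img[muscle].mean())
        img[iph_pixels] = muscle_mean * rng.uniform(1.6, 2.2, int(iph_pixels.sum()))
    return RoiImage(img, pixel_spacing, slice_thickness)


def _draw_geometry(
    spec: CohortSpec, lumen_area_mm2: float, burden_pct: float, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    g = spec.grid_size
    s = spec.pixel_spacing
    lumen_px = lumen_area_mm2 / s**2
    outer_px = lumen_px / (1.0 - burden_pct / 100.0)

    centre = (g / 2 + rng.uniform(-2, 2), g / 2 + rng.uniform(-2, 2))
    q = rng.uniform(0.75, 1.0)  # ellipse aspect ratio
    angle = rng.uniform(0.0, np.pi)
    a_l = np.sqrt(lumen_px / (np.pi * q))
    scale = np.sqrt(outer_px / lumen_px)
    a_o = a_l * scale

    if a_o >= g / 2 - 14:  # keep clear of the reference patches
        raise GeometryError("vessel does not fit the grid")

    shape = (g, g)
    outer = _ellipse_mask(shape, centre, (a_o, q * a_o), angle)
    lumen = _ellipse_mask(shape, centre, (a_l, q * a_l), angle) & outer
    if not lumen.any():  # sub-pixel lumen: keep the centre pixel patent
        lumen = np.zeros(shape, dtype=bool)
        lumen[int(round(centre[0])), int(round(centre[1]))] = True
        lumen &= outer
    plaque = outer & ~lumen
    if plaque.sum() < 10:  # too thin for texture matrices
        raise GeometryError("degenerate plaque annulus")

    masks = {name: np.zeros(shape, dtype=bool) for name in MASK_NAMES}
    masks["lumen"] = lumen
    masks["outer_wall"] = outer
    masks["plaque_roi"] = plaque
    masks["muscle_ref"][_MUSCLE_SLICE] = True
    masks["grey_matter_ref"][_GM_SLICE] = True
    if ((masks["muscle_ref"] | masks["grey_matter_ref"]) & outer).any():
        raise GeometryError("vessel overlaps a reference ROI")
    return masks


def _choose_iph_pixels(plaque: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A compact 3-8 pixel blob inside the plaque annulus."""
    n_target = int(rng.integers(3, 9))
    rows, cols = np.nonzero(plaque)
    seed_idx = int(rng.integers(len(rows)))
    d2 = (rows - rows[seed_idx]) ** 2 + (cols - cols[seed_idx]) ** 2
    order = np.argsort(d2, kind="stable")[:n_target]
    blob = np.zeros(plaque.shape, dtype=bool)
    blob[rows[order], cols[order]] = True
    return blob


def _gamma_params(mean: float, sd: float) -> Tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def _render_study(
    spec: CohortSpec, patient_id: str, group: int, rng: np.random.Generator
) -> PlaqueStudy:
    label = "acute_subacute_symptomatic" if group == 0 else "asymptomatic"
    mla_mean, mla_sd = spec.mla_mean_sd_by_group[group]
    bmean, bsd = spec.plaque_burden_mean_sd_by_group[group]
    masks = None
    for _ in range(50):  # redraw when the joint (MLA, burden) tail overflows the grid
        if mla_sd > 0:
            k, theta = _gamma_params(mla_mean, mla_sd)
            mla = float(max(rng.gamma(k, theta), 0.27))
        else:
            mla = mla_mean
        burden = float(np.clip(rng.normal(bmean, bsd), 55.0, 95.0))
        try:
            masks = _draw_geometry(spec, mla, burden, rng)
            break
        except GeometryError:
            continue
    if masks is None:
        raise GeometryError("could not fit a vessel into the grid")
    emean, esd = spec.enhancement_mean_sd_by_group[group]
    enh = float(np.clip(rng.normal(emean, esd), -60.0, 200.0))
    smean, ssd = spec.stenosis_mean_sd_by_group[group]
    sten = float(np.clip(rng.normal(smean, ssd), 5.0, 90.0))
    h_group = spec.texture_heterogeneity_by_group[group]
    if spec.texture_heterogeneity_sd > 0 and h_group > 0:
        h = float(max(rng.normal(h_group, spec.texture_heterogeneity_sd), 0.02))
    else:
        h = h_group
    iph_lesion = bool(rng.random() < spec.iph_prevalence_by_group[group])
    if iph_lesion and spec.iph_on_analysed_slice_prob < 1.0:
        iph = bool(rng.random() < spec.iph_on_analysed_slice_prob)
    else:
        iph = iph_lesion
    iph_pixels = _choose_iph_pixels(masks["plaque_roi"], rng) if iph else None

    # T2 texture is rendered with a group-independent heterogeneity so the
    # texture signal lives in T1/CE-T1, mirroring the uninformative T2 arm.
    h_t2 = float(np.mean(spec.texture_heterogeneity_by_group))
    if spec.texture_heterogeneity_sd > 0:
        h_t2 = float(max(rng.normal(h_t2, spec.texture_heterogeneity_sd), 0.02))
    images: Dict[str, RoiImage] = {}
    for seq in SEQUENCES:
        images[seq] = render_plaque_image(
            (spec.grid_size, spec.grid_size),
            masks,
            seq,
            h_t2 if seq == "T2" else h,
            rng,
            iph=iph and seq == "T1",
            iph_pixels=iph_pixels,
            pixel_spacing=spec.pixel_spacing,
            slice_thickness=spec.slice_thickness,
        )

    # Rescale CE-T1 plaque signal so the grey-matter-normalised enhancement
    # formula recovers the drawn value exactly on the ROI means.
    pm = masks["plaque_roi"]
    gm = masks["grey_matter_ref"]
    t1 = images["T1"].data
    ce = images["CE_T1"].data
    target = (1.0 + enh / 100.0) * (t1[pm].mean() / t1[gm].mean()) * ce[gm].mean()
    # Additive uptake: enhancement raises the plaque mean while the noise
    # floor stays unscaled, so absolute CE-T1 texture amplitude carries no
    # direct enhancement signal (the normalised ratio does).
    delta = target - ce[pm].mean()
    shifted = ce[pm] + delta
    if shifted.min() > 1.0:
        ce[pm] = shifted  # zero-mean patch keeps the ROI mean exactly on target
    else:  # extreme negative enhancement draw: fall back to pure scaling
        ce[pm] *= target / ce[pm].mean()

    # Per-sequence global receive-gain factor (coil positioning varies between
    # patients): scales absolute intensities, leaving ratio-normalised
    # quantities (enhancement ratio, IPH rule, discretised textures) intact.
    for seq in SEQUENCES:
        arr = images[seq].data
        arr *= float(np.exp(rng.normal(0.0, spec.intensity_gain_sd)))

    age_mean, age_sd = spec.age_mean_sd_by_group[group]
    covs: Dict[str, float] = {"age": float(rng.normal(age_mean, age_sd))}
    for name, prob in spec.covariate_prevalence_by_group[group].items():
        covs[name] = float(rng.random() < prob)

    ref_area = mla / (1.0 - sten / 100.0) ** 2
    study = PlaqueStudy(
        patient_id=patient_id,
        images=images,
        masks=masks,
        covariates=covs,
        label=label,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        reference_lumen_area=ref_area,
        iph_lesion=iph_lesion,
    )
    study.validate()
    return study


def generate_cohort(spec: CohortSpec) -> List[PlaqueStudy]:
    """Generate the full synthetic cohort, symptomatic patients first."""
    rng = np.random.default_rng(spec.seed)
    studies: List[PlaqueStudy] = []
    for i in range(spec.n_symptomatic):
        studies.append(_render_study(spec, f"sym{i:03d}", 0, rng))
    for i in range(spec.n_asymptomatic):
        studies.append(_render_study(spec, f"asym{i:03d}", 1, rng))
    return studies


# ---------------------------------------------------------------------------
# Second-reader perturbation
# ---------------------------------------------------------------------------


def _jitter_mask(mask: np.ndarray, jitter_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Level-set boundary jitter: signed distance + correlated noise."""
    if jitter_scale == 0:
        return mask.copy()
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    sdf = inside - outside
    u = gaussian_filter(rng.standard_normal(mask.shape), 2.0, mode="wrap")
    u /= u.std()
    new = (sdf + jitter_scale * u) > 0
    if not new.any():
        return mask.copy()
    # Keep the largest component and fill holes to preserve topology.
    comp, n = ndimage.label(new, structure=_EIGHT_CONN)
    if n > 1:
        sizes = np.bincount(comp.ravel())[1:]
        new = comp == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(new)


def perturb_segmentation(study: PlaqueStudy, jitter_scale: float, seed: int) -> PlaqueStudy:
    """Emulate a second reader by jittering the lumen/outer-wall boundaries.

    jitter_scale is in pixels (0 returns an identical copy); the lumen is
    forced to stay strictly inside the perturbed outer wall so the plaque
    annulus never vanishes.
    """
    if jitter_scale < 0:
        raise ValueError("jitter_scale must be non-negative")
    rng = np.random.default_rng(seed)
    outer = _jitter_mask(study.masks["outer_wall"], jitter_scale, rng)
    lumen = _jitter_mask(study.masks["lumen"], jitter_scale, rng)
    interior = ndimage.binary_erosion(outer)
    lumen = lumen & interior
    if not lumen.any():
        lumen = study.masks["lumen"] & interior
    if not lumen.any():
        inside = ndimage.distance_transform_edt(outer)
        lumen = np.zeros_like(outer)
        lumen[np.unravel_index(int(np.argmax(inside)), outer.shape)] = True
    plaque = outer & ~lumen

    masks = dict(study.masks)
    masks["outer_wall"] = outer
    masks["lumen"] = lumen
    masks["plaque_roi"] = plaque
    twin = dataclasses.replace(study, masks=masks)
    twin.validate()
    return twin


# ---------------------------------------------------------------------------
# NIfTI / manifest round-trip
# ---------------------------------------------------------------------------


def _affine(spacing: float, thickness: float) -> np.ndarray:
    return np.diag([spacing, spacing, thickness, 1.0])


def write_cohort(studies: List[PlaqueStudy], out_dir: str | Path) -> Path:
    """Write per-study NIfTI images/masks and a cohort manifest CSV.

    Returns the manifest path.  Exclusion bookkeeping columns are left empty
    (synthetic patients all pass screening).
    """
    import nibabel as nib
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for st in studies:
        pdir = out_dir / st.patient_id
        pdir.mkdir(exist_ok=True)
        aff = _affine(st.pixel_spacing, st.slice_thickness)
        paths: Dict[str, str] = {}
        for seq, img in st.images.items():
            p = pdir / f"{seq}.nii"
            nib.save(nib.Nifti1Image(img.data[:, :, None].astype(np.float32), aff), p)
            paths[f"image_{seq}"] = str(p.relative_to(out_dir))
        for name, m in st.masks.items():
            p = pdir / f"mask_{name}.nii"
            nib.save(nib.Nifti1Image(m[:, :, None].astype(np.uint8), aff), p)
            paths[f"mask_{name}"] = str(p.relative_to(out_dir))
        rows.append(
            {
                "patient_id": st.patient_id,
                "label": st.label,
                "exclusion_reason": "",
                "pixel_spacing": st.pixel_spacing,
                "slice_thickness": st.slice_thickness,
                "reference_lumen_area": st.reference_lumen_area,
                "iph_lesion": int(st.iph_lesion),
                **st.covariates,
                **paths,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> List[PlaqueStudy]:
    """Load a cohort previously written by :func:`write_cohort`."""
    import nibabel as nib
    import pandas as pd

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False)
    cov_names = ["age", "sex_male", "smoking", "diabetes", "hypertension", "hyperlipidaemia"]
    studies = []
    for _, row in df.iterrows():
        spacing = float(row["pixel_spacing"])
        thickness = float(row["slice_thickness"])
        images = {}
        for seq in SEQUENCES:
            arr = np.asarray(nib.load(root / row[f"image_{seq}"]).dataobj)[:, :, 0]
            images[seq] = RoiImage(arr.astype(float), spacing, thickness)
        masks = {
            name: np.asarray(nib.load(root / row[f"mask_{name}"]).dataobj)[:, :, 0] > 0
            for name in MASK_NAMES
        }
        studies.append(
            PlaqueStudy(
                patient_id=str(row["patient_id"]),
                images=images,
                masks=masks,
                covariates={k: float(row[k]) for k in cov_names if k in row},
                label=str(row["label"]),
                pixel_spacing=spacing,
                slice_thickness=thickness,
                reference_lumen_area=float(row["reference_lumen_area"]),
                iph_lesion=bool(int(row["iph_lesion"])) if "iph_lesion" in row else False,
            )
        )
    return studies
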