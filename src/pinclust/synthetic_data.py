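"""Seeded synthetic confocal stacks and immunogold point fields.

Both generators emit ground truth alongside the data so every downstream
stage can be validated without original micrographs.

Confocal stacks
---------------
A stack contains one or more planar membrane sheets (slabs a few voxels
thick, normal to one of the principal axes) at a baseline intensity.  Each
sheet carries a Poisson-distributed number of diffraction-limited clusters,
modelled as isotropic 2D Gaussian spots in the sheet plane (FWHM =
``cluster_diameter_um``) extruded through the slab.  The whole volume is
blurred with an anisotropic Gaussian PSF (axial sigma larger than lateral,
emulating the optical z-elongation) and then corrupted with additive
Gaussian and/or scaled-Poisson noise.

Immunogold fields
-----------------
A rectangular membrane sheet is populated by a Thomas-type cluster process:
Poisson parents (optionally with an exponential density gradient away from
the apical edge) each emit a Poisson number of labels scattered with an
isotropic Gaussian, plus homogeneous scattered singles.  Each label is then
displaced uniformly within a disc (the epitope-to-gold distance, 20 nm by
default) and retained with the labeling efficiency.  The truth table
records, per generated label, its pre-displacement position, parent, and
its *configuration class*: the scattered/doublet/cluster class obtained by
applying the 55-nm linkage rule to the complete, undisplaced, unthinned
label configuration.  Recovery experiments therefore measure exactly the
effect of displacement and partial labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datatypes import AXES, DEFAULT_VOXEL_SIZE_XYZ_UM, CellAxis, ImageStack, ParticleSet
from .particle_analysis import DEFAULT_DMAX_NM, link_particles

GOLD_LABEL_DISPLACEMENT_NM = 20.0  # upper bound of the epitope-to-gold distance


# ---------------------------------------------------------------------------
# confocal stack simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneFace:
    """One planar membrane sheet inside the simulated volume."""

    normal_axis: str  # "z" | "y" | "x"
    index: int  # voxel index of the sheet along the normal
    cluster_density_per_um2: float
    thickness_vox: int = 2
    polarity_label: str = "unspecified"
    #: optional in-plane extent in µm: ((u_min, u_max), (v_min, v_max)) where
    #: (u, v) are the two non-normal axes in (z, y, x) order; None = full plane
    extent_um: Optional[tuple[tuple[float, float], tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.normal_axis not in AXES:
            raise ValueError(f"normal_axis must be one of {AXES}")
        if self.cluster_density_per_um2 < 0:
            raise ValueError("cluster density must be >= 0")
        if self.thickness_vox < 1:
            raise ValueError("face thickness must be >= 1 voxel")


@dataclass(frozen=True)
class StackSimParams:
    """Study conditions for one simulated confocal stack.

    Defaults mirror the acquisition geometry of the quantified data: voxel
    size 0.089/0.089/0.313 µm (x/y/z), an anisotropic PSF with the axial
    sigma exceeding the lateral one, spot FWHM in the middle of the
    0.44–0.80 µm retained size-class range, and spot amplitude five times
    the additive noise sigma.
    """

    shape_zyx: tuple[int, int, int] = (16, 128, 128)
    voxel_size_xyz_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_XYZ_UM
    membrane_faces: tuple[MembraneFace, ...] = ()
    cluster_diameter_um: float = 0.65
    spot_amplitude: float = 5.0
    membrane_background: float = 1.0
    psf_sigma_lateral_um: float = 0.11
    psf_sigma_axial_um: float = 0.30
    noise_sigma: float = 1.0
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables shot noise
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape_zyx):
            raise ValueError("grid must be at least 16 voxels per axis")
        if any(v <= 0 for v in self.voxel_size_xyz_um):
            raise ValueError("voxel sizes must be positive")
        for name in ("cluster_diameter_um", "spot_amplitude", "membrane_background",
                     "psf_sigma_lateral_um", "psf_sigma_axial_um", "noise_sigma", "poisson_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lateral = min(self.voxel_size_xyz_um[0], self.voxel_size_xyz_um[1])
        if self.cluster_diameter_um < lateral:
            raise ValueError(
                f"cluster_diameter_um={self.cluster_diameter_um} is below one lateral voxel "
                f"({lateral} µm); such spots are undetectable"
            )

    @property
    def voxel_size_zyx_um(self) -> tuple[float, float, float]:
        vx, vy, vz = self.voxel_size_xyz_um
        return (vz, vy, vx)


@dataclass(frozen=True)
class StackTruth:
    """Planted ground truth for one simulated stack."""

    #: per face: list of planted spot centres, each a (z, y, x) position in µm
    planted_centers_um: tuple[tuple[tuple[float, float, float], ...], ...]
    face_areas_um2: tuple[float, ...]
    params: StackSimParams

    @property
    def planted_counts(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.planted_centers_um)


def simulate_membrane_stack(params: StackSimParams) -> tuple[ImageStack, StackTruth]:
    """Generate one membrane stack plus its planted-cluster truth.

    Identical parameters and seed produce bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    vol = np.zeros(params.shape_zyx, dtype=float)
    voxel_zyx = np.asarray(params.voxel_size_zyx_um)

    sigma_spot_um = params.cluster_diameter_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    all_centers: list[tuple[tuple[float, float, float], ...]] = []
    areas: list[float] = []

    for face in params.membrane_faces:
        ax = AXES.index(face.normal_axis)
        in_plane = [i for i in range(3) if i != ax]
        extents = []
        for k, axi in enumerate(in_plane):
            full = (0.0, params.shape_zyx[axi] * voxel_zyx[axi])
            if face.extent_um is not None:
                lo, hi = face.extent_um[k]
                extents.append((max(lo, full[0]), min(hi, full[1])))
            else:
                extents.append(full)
        (u0, u1), (v0, v1) = extents
        area = (u1 - u0) * (v1 - v0)
        areas.append(area)

        # slab occupancy along the normal
        i0 = max(face.index, 0)
        i1 = min(face.index + face.thickness_vox, params.shape_zyx[ax])
        if i1 <= i0:
            raise ValueError(f"face slab [{face.index}, {face.index + face.thickness_vox}) outside the grid")

        n_spots = int(rng.poisson(face.cluster_density_per_um2 * area))
        centers_uv = np.column_stack(
            [rng.uniform(u0, u1, size=n_spots), rng.uniform(v0, v1, size=n_spots)]
        )

        # render the in-plane spot image once, add it across the slab
        shape_uv = (params.shape_zyx[in_plane[0]], params.shape_zyx[in_plane[1]])
        sheet = np.zeros(shape_uv, dtype=float)
        umask_lo = int(np.floor(u0 / voxel_zyx[in_plane[0]]))
        umask_hi = int(np.ceil(u1 / voxel_zyx[in_plane[0]]))
        vmask_lo = int(np.floor(v0 / voxel_zyx[in_plane[1]]))
        vmask_hi = int(np.ceil(v1 / voxel_zyx[in_plane[1]]))
        sheet[umask_lo:umask_hi, vmask_lo:vmask_hi] += params.membrane_background
        for cu, cv in centers_uv:
            _add_gaussian_spot(
                sheet,
                (cu, cv),
                sigma_spot_um,
                params.spot_amplitude,
                (voxel_zyx[in_plane[0]], voxel_zyx[in_plane[1]]),
            )

        slicer: list = [slice(None)] * 3
        slicer[ax] = slice(i0, i1)
        vol[tuple(slicer)] += sheet[None, :, :] if ax == 0 else (
            sheet[:, None, :] if ax == 1 else sheet[:, :, None]
        )

        normal_um = (face.index + 0.5 * face.thickness_vox) * voxel_zyx[ax]
        centers_zyx = []
        for cu, cv in centers_uv:
            pos = [0.0, 0.0, 0.0]
            pos[ax] = float(normal_um)
            pos[in_plane[0]] = float(cu)
            pos[in_plane[1]] = float(cv)
            centers_zyx.append(tuple(pos))
        all_centers.append(tuple(centers_zyx))

    # anisotropic PSF blur (instrument frame: axial = z)
    sigmas_vox = (
        params.psf_sigma_axial_um / voxel_zyx[0],
        params.psf_sigma_lateral_um / voxel_zyx[1],
        params.psf_sigma_lateral_um / voxel_zyx[2],
    )
    if any(s > 0 for s in sigmas_vox):
        vol = gaussian_filter(vol, sigma=sigmas_vox)

    if params.poisson_scale > 0:
        vol = rng.poisson(vol * params.poisson_scale).astype(float) / params.poisson_scale
    if params.noise_sigma > 0:
        vol = vol + rng.normal(0.0, params.noise_sigma, size=vol.shape)
    vol = np.clip(vol, 0.0, None)

    stack = ImageStack(data=vol, voxel_size_zyx_um=tuple(voxel_zyx))
    truth = StackTruth(
        planted_centers_um=tuple(all_centers),
        face_areas_um2=tuple(areas),
        params=params,
    )
    return stack, truth


def _add_gaussian_spot(
    sheet: np.ndarray,
    center_um: tuple[float, float],
    sigma_um: float,
    amplitude: float,
    pixel_um: tuple[float, float],
) -> None:
    """Add one isotropic Gaussian spot to a 2D sheet, over a ±4σ window."""
    cu, cv = center_um
    pu, pv = pixel_um
    ru = max(1, int(np.ceil(4 * sigma_um / pu)))
    rv = max(1, int(np.ceil(4 * sigma_um / pv)))
    iu, iv = int(round(cu / pu)), int(round(cv / pv))
    u_lo, u_hi = max(iu - ru, 0), min(iu + ru + 1, sheet.shape[0])
    v_lo, v_hi = max(iv - rv, 0), min(iv + rv + 1, sheet.shape[1])
    if u_hi <= u_lo or v_hi <= v_lo:
        return
    uu = (np.arange(u_lo, u_hi) + 0.5) * pu - cu
    vv = (np.arange(v_lo, v_hi) + 0.5) * pv - cv
    g = np.exp(-(uu[:, None] ** 2 + vv[None, :] ** 2) / (2.0 * sigma_um**2))
    sheet[u_lo:u_hi, v_lo:v_hi] += amplitude * g


# ---------------------------------------------------------------------------
# immunogold field simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSimParams:
    """Study conditions for one simulated immunogold label field.

    Coordinates are nm; the field is ``[0, w] x [0, h]`` µm with the apical
    edge at ``y = 0`` and the basal edge at ``y = h``.
    """

    field_size_um: tuple[float, float] = (10.0, 10.0)
    parent_intensity_per_um2: float = 0.5
    offspring_mean: float = 4.0
    offspring_sigma_nm: float = 15.0
    gradient_decay_um: float = np.inf  # exponential decay from the apical edge; inf = uniform
    scattered_intensity_per_um2: float = 1.3
    label_displacement_max_nm: float = GOLD_LABEL_DISPLACEMENT_NM
    labeling_efficiency: float = 0.8
    linkage_dmax_nm: float = DEFAULT_DMAX_NM  # rule used for configuration truth classes
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size_um
        if w <= 0 or h <= 0:
            raise ValueError("field size must be positive")
        for name in ("parent_intensity_per_um2", "offspring_mean", "offspring_sigma_nm",
                     "scattered_intensity_per_um2", "label_displacement_max_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ValueError("labeling_efficiency must be in [0, 1]")
        if self.gradient_decay_um <= 0:
            raise ValueError("gradient_decay_um must be positive (use inf for uniform)")


@dataclass(frozen=True)
class FieldTruth:
    """Per-label generative truth for one simulated field.

    ``labels`` has one row per generated label (retained or not) with its
    pre-displacement position, parent id (-1 for scattered singles), the
    configuration class, the final position and the retention flag.
    """

    parents_xy_nm: np.ndarray
    labels: pd.DataFrame
    class_fractions: dict  # over the full configuration, percentages
    retained_class_fractions: Optional[dict]  # over retained labels only
    band_counts: dict  # retained labels per apical/central/basal band
    params: FieldSimParams


def simulate_particle_field(params: FieldSimParams) -> tuple[ParticleSet, FieldTruth]:
    """Generate one immunogold label field plus its generative truth."""
    rng = np.random.default_rng(params.seed)
    w_nm, h_nm = params.field_size_um[0] * 1000.0, params.field_size_um[1] * 1000.0

    # Parents: inhomogeneous Poisson by thinning, sampled on a margin-extended
    # window so clusters straddling the field edge are not depleted
    # (plus-sampling).  The apical gradient applies inside the field only;
    # the margin band beyond the apical edge keeps the edge intensity.
    margin = 3.0 * params.offspring_sigma_nm
    area_ext_um2 = ((w_nm + 2 * margin) / 1000.0) * ((h_nm + 2 * margin) / 1000.0)
    n_parents = int(rng.poisson(params.parent_intensity_per_um2 * area_ext_um2))
    px = rng.uniform(-margin, w_nm + margin, size=n_parents)
    py = rng.uniform(-margin, h_nm + margin, size=n_parents)
    if np.isfinite(params.gradient_decay_um):
        decay_nm = params.gradient_decay_um * 1000.0
        accept = rng.uniform(size=n_parents) < np.exp(-np.maximum(py, 0.0) / decay_nm)
        px, py = px[accept], py[accept]
    parents = np.column_stack([px, py]) if len(px) else np.empty((0, 2))

    # Offspring labels
    pre_xy: list[tuple[float, float]] = []
    parent_of: list[int] = []
    counts = rng.poisson(params.offspring_mean, size=len(parents))
    for i, (pxy, k) in enumerate(zip(parents, counts)):
        offs = pxy + rng.normal(0.0, params.offspring_sigma_nm, size=(k, 2))
        for o in offs:
            pre_xy.append((float(o[0]), float(o[1])))
            parent_of.append(i)

    # Scattered singles, homogeneous over the field
    area_um2 = params.field_size_um[0] * params.field_size_um[1]
    n_scatter = int(rng.poisson(params.scattered_intensity_per_um2 * area_um2))
    sx = rng.uniform(0.0, w_nm, size=n_scatter)
    sy = rng.uniform(0.0, h_nm, size=n_scatter)
    for x, y in zip(sx, sy):
        pre_xy.append((float(x), float(y)))
        parent_of.append(-1)

    pre = np.asarray(pre_xy, dtype=float).reshape(-1, 2)
    n = len(pre)

    # Configuration truth: linkage classes of the complete, undisplaced,
    # unthinned label configuration.
    config_classes = _linkage_classes(pre, params.linkage_dmax_nm)

    # Displacement uniform in a disc, then Bernoulli retention, then clipping
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    radius = params.label_displacement_max_nm * np.sqrt(rng.uniform(size=n))
    final = pre + np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    retained = rng.uniform(size=n) < params.labeling_efficiency
    inside = (
        (final[:, 0] >= 0.0) & (final[:, 0] <= w_nm) & (final[:, 1] >= 0.0) & (final[:, 1] <= h_nm)
    )
    kept = retained & inside

    labels_df = pd.DataFrame(
        {
            "pre_x_nm": pre[:, 0],
            "pre_y_nm": pre[:, 1],
            "parent_id": np.asarray(parent_of, dtype=int),
            "config_class": config_classes,
            "final_x_nm": np.where(kept, final[:, 0], np.nan),
            "final_y_nm": np.where(kept, final[:, 1], np.nan),
            "retained": kept,
        }
    )

    from shapely.geometry import Polygon

    region = Polygon([(0.0, 0.0), (w_nm, 0.0), (w_nm, h_nm), (0.0, h_nm)])
    axis = CellAxis(direction=(0.0, 1.0), apical_edge_nm=0.0, basal_edge_nm=h_nm)
    particles = ParticleSet(xy_nm=final[kept], region=region, axis=axis, source="frl")

    fractions = _class_percentages(config_classes)
    retained_fractions = _class_percentages(config_classes[kept]) if kept.any() else None

    band_nm = 2000.0
    d = final[kept][:, 1] if kept.any() else np.empty(0)
    band_counts = {
        "apical": int(np.count_nonzero(d <= band_nm)),
        "central": int(np.count_nonzero(np.abs(d - h_nm / 2) <= band_nm / 2)),
        "basal": int(np.count_nonzero((h_nm - d) <= band_nm)),
    }

    truth = FieldTruth(
        parents_xy_nm=parents,
        labels=labels_df,
        class_fractions=fractions,
        retained_class_fractions=retained_fractions,
        band_counts=band_counts,
        params=params,
    )
    return particles, truth


def _linkage_classes(xy_nm: np.ndarray, dmax_nm: float) -> np.ndarray:
    if len(xy_nm) == 0:
        return np.empty(0, dtype=object)
    groups = link_particles(ParticleSet(xy_nm=xy_nm), dmax_nm=dmax_nm)
    classes = np.empty(len(xy_nm), dtype=object)
    for g in groups:
        for m in g.members:
            classes[m] = g.group_class
    return classes


def _class_percentages(classes: np.ndarray) -> dict:
    n = len(classes)
    if n == 0:
        return {"scattered": np.nan, "doublet": np.nan, "cluster": np.nan}
    return {c: 100.0 * float(np.count_nonzero(classes == c)) / n for c in ("scattered", "doublet", "cluster")}


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------

def polar_marker_field_params(seed: int = 0) -> FieldSimParams:
    """Strongly clustered field emulating an apical polar-cargo membrane.

    Parent and scattered intensities are set so that roughly 55% of labels
    belong to clusters (>= 3 linked particles) before displacement and
    thinning, with a total label density of a few per µm² over a
    10 µm x 10 µm sheet.  The mean cluster occupancy of 6 reflects the large
    polar-domain clusters seen by replica labeling and keeps observed
    clusters above the 3-particle definition after partial labeling.
    """
    return FieldSimParams(
        field_size_um=(10.0, 10.0),
        parent_intensity_per_um2=0.35,
        offspring_mean=6.0,
        offspring_sigma_nm=15.0,
        gradient_decay_um=np.inf,
        scattered_intensity_per_um2=1.65,
        label_displacement_max_nm=GOLD_LABEL_DISPLACEMENT_NM,
        labeling_efficiency=0.8,
        seed=seed,
    )


def nonpolar_marker_field_params(seed: int = 0) -> FieldSimParams:
    """Mostly scattered field emulating a uniformly distributed membrane marker.

    Calibrated for a clustered-label share of about 3% and a label density
    near 2.4 per µm².
    """
    return FieldSimParams(
        field_size_um=(10.0, 10.0),
        parent_intensity_per_um2=0.03,
        offspring_mean=3.0,
        offspring_sigma_nm=15.0,
        gradient_decay_um=np.inf,
        scattered_intensity_per_um2=2.3,
        label_displacement_max_nm=GOLD_LABEL_DISPLACEMENT_NM,
        labeling_efficiency=0.8,
        seed=seed,
    )


def single_face_stack_params(
    cluster_density_per_um2: float,
    seed: int = 0,
    shape_zyx: tuple[int, int, int] = (16, 192, 192),
) -> StackSimParams:
    """Stack with one full-extent membrane sheet normal to z, mid-volume.

    The en-face projection of this sheet is the standard input for confocal
    density-recovery experiments.
    """
    face = MembraneFace(
        normal_axis="z",
        index=shape_zyx[0] // 2,
        cluster_density_per_um2=cluster_density_per_um2,
        thickness_vox=2,
    )
    return StackSimParams(shape_zyx=shape_zyx, membrane_faces=(face,), seed=seed)
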