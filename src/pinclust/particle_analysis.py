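"""Distance-based clustering statistics for immunogold particle patterns.

Particles (gold-label centroids, nm coordinates) are grouped by single
linkage: two particles belong to the same group whenever a chain of
centre-to-centre distances of at most ``dmax`` (55 nm by default, inclusive
at the threshold) connects them.  Groups of one, two, and three-or-more
particles are called scattered, doublets and clusters respectively.  Class
fractions are reported as percentages of *particles*, not of groups.

The polar-domain statistics bin particles and cluster centroids along the
cell's apical–basal axis: a band within 2 µm of the apical edge, a 2-µm-wide
band centred on the midline, and a band within 2 µm of the basal edge.
Band areas are obtained by clipping the analyzed-region polygon with each
band strip.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import DisjointSet
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from shapely import affinity
from shapely.geometry import box

from .datatypes import CellAxis, EMImage, ParticleGroup, ParticleSet, classify_size

DEFAULT_DMAX_NM = 55.0
DEFAULT_BAND_UM = 2.0
DOMAINS = ("apical", "central", "basal")


# ---------------------------------------------------------------------------
# particle extraction from EM images
# ---------------------------------------------------------------------------

def detect_gold_particles(
    image: EMImage,
    intensity_threshold: float,
    area_range_px: tuple[float, float] = (1.0, np.inf),
) -> ParticleSet:
    """Extract gold-particle centroids from a thresholded EM image.

    Connected components (8-connectivity) of ``image >= threshold`` are
    filtered by pixel area and reduced to centroids, converted to nm via the
    image calibration.  The analysis is deterministic for fixed inputs.
    """
    from skimage.measure import label, regionprops

    a = np.asarray(image.data, dtype=float)
    mask = a >= intensity_threshold
    labelled = label(mask, connectivity=2)
    lo, hi = area_range_px
    coords = []
    for prop in regionprops(labelled):
        if lo <= prop.area <= hi:
            r, c = prop.centroid
            coords.append((c * image.scale_nm_per_px, r * image.scale_nm_per_px))
    if not coords:
        warnings.warn("no connected components within the area range", stacklevel=2)
        return ParticleSet(xy_nm=np.empty((0, 2)), source="frl")
    return ParticleSet(xy_nm=np.asarray(coords, dtype=float), source="frl")


# ---------------------------------------------------------------------------
# single-linkage grouping
# ---------------------------------------------------------------------------

def link_particles(
    particles: ParticleSet,
    dmax_nm: float = DEFAULT_DMAX_NM,
    gold_diameter_nm: float = 0.0,
) -> list[ParticleGroup]:
    """Partition the particles into single-linkage groups at ``dmax_nm``.

    Groups are the connected components of the graph that joins every pair
    at centre-to-centre distance <= ``dmax_nm`` (inclusive).  Every particle
    belongs to exactly one group; groups are returned sorted by their
    smallest member index.
    """
    if dmax_nm <= 0:
        raise ValueError("dmax must be positive")
    xy = particles.xy_nm
    n = len(xy)
    if n == 0:
        return []
    ds = DisjointSet(range(n))
    if n > 1:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(dmax_nm, output_type="ndarray")
        for i, j in pairs:
            ds.merge(int(i), int(j))
    groups = []
    for comp in ds.subsets():
        members = tuple(sorted(int(i) for i in comp))
        groups.append(_make_group(xy, members, gold_diameter_nm))
    groups.sort(key=lambda g: g.members[0])
    return groups


def _make_group(xy: np.ndarray, members: tuple[int, ...], gold_diameter_nm: float) -> ParticleGroup:
    pts = xy[list(members)]
    centroid = pts.mean(axis=0)
    return ParticleGroup(
        members=members,
        group_class=classify_size(len(members)),
        diameter_nm=group_diameter(pts, gold_diameter_nm),
        centroid_nm=(float(centroid[0]), float(centroid[1])),
    )


def group_diameter(points_nm: np.ndarray, gold_diameter_nm: float = 0.0) -> float:
    """Feret-style group diameter: max pairwise centre distance + label size.

    A singleton's diameter is the gold-label diameter alone (0 by default).
    """
    pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
    if len(pts) == 0:
        raise ValueError("empty group")
    if len(pts) == 1:
        return float(gold_diameter_nm)
    return float(pdist(pts).max()) + float(gold_diameter_nm)


# ---------------------------------------------------------------------------
# classification and summaries
# ---------------------------------------------------------------------------

def classify_particle_groups(groups: Sequence[ParticleGroup]) -> dict:
    """Counts per class and percentages of particles per class.

    Percentages are computed over particles (a 4-particle cluster
    contributes 4 to the clustered tally), matching the convention in which
    the scattered/doublet/clustered fractions sum to ~100% of particles.
    """
    n_groups = {c: 0 for c in ("scattered", "doublet", "cluster")}
    n_particles = {c: 0 for c in ("scattered", "doublet", "cluster")}
    for g in groups:
        n_groups[g.group_class] += 1
        n_particles[g.group_class] += g.size
    total = sum(n_particles.values())
    if total == 0:
        return {
            "n_groups": n_groups,
            "n_particles": n_particles,
            "total_particles": 0,
            "fractions_percent": None,
            "flags": ("empty",),
        }
    fractions = {c: 100.0 * n_particles[c] / total for c in n_particles}
    return {
        "n_groups": n_groups,
        "n_particles": n_particles,
        "total_particles": total,
        "fractions_percent": fractions,
        "flags": (),
    }


def assign_membrane_domains(
    particles: ParticleSet,
    groups: Optional[Sequence[ParticleGroup]] = None,
    band_um: float = DEFAULT_BAND_UM,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label particles by polar band and summarize per-domain statistics.

    A particle is *apical* if its axial distance from the apical edge is at
    most ``band_um``, *basal* analogously from the basal edge, *central* if
    within ``band_um / 2`` of the midline (a band of total width ``band_um``),
    and *unassigned* otherwise.  The apical/basal labels take precedence over
    central in short cells.  Densities divide counts by the analyzed-region
    area clipped to each band.

    Returns the per-particle labels and a per-domain summary table with
    particle and cluster densities, particle-class fractions, and mean
    particles per cluster.
    """
    if particles.axis is None:
        raise ValueError("particle set carries no cell axis")
    axis = particles.axis
    band_nm = band_um * 1000.0
    if axis.length_nm <= 2 * band_nm:
        raise ValueError(
            f"cell length {axis.length_nm:.0f} nm must exceed twice the band ({2 * band_nm:.0f} nm); bands overlap"
        )

    d = axis.distance_from_apical(particles.xy_nm)
    labels = _band_labels(d, axis.length_nm, band_nm)

    group_list = list(groups) if groups is not None else []
    cluster_domains = []
    for g in group_list:
        if g.group_class == "cluster":
            dd = float(axis.distance_from_apical(np.asarray([g.centroid_nm]))[0])
            cluster_domains.append(_band_labels(np.asarray([dd]), axis.length_nm, band_nm)[0])

    particle_class = np.full(len(particles), "scattered", dtype=object)
    for g in group_list:
        for m in g.members:
            particle_class[m] = g.group_class

    rows = []
    for domain in DOMAINS:
        area = band_area_um2(particles, domain, band_um)
        in_band = labels == domain
        n_part = int(np.count_nonzero(in_band))
        n_clust = sum(1 for cd in cluster_domains if cd == domain)
        class_counts = {c: int(np.count_nonzero(particle_class[in_band] == c)) for c in ("scattered", "doublet", "cluster")}
        sizes = [g.size for g, cd in zip([g for g in group_list if g.group_class == "cluster"], cluster_domains) if cd == domain]
        rows.append(
            {
                "domain": domain,
                "band_area_um2": area,
                "n_particles": n_part,
                "particle_density_per_um2": n_part / area if area > 0 else np.nan,
                "n_clusters": n_clust,
                "cluster_density_per_um2": n_clust / area if area > 0 else np.nan,
                "scattered_percent": 100.0 * class_counts["scattered"] / n_part if n_part else np.nan,
                "doublet_percent": 100.0 * class_counts["doublet"] / n_part if n_part else np.nan,
                "clustered_percent": 100.0 * class_counts["cluster"] / n_part if n_part else np.nan,
                "mean_particles_per_cluster": float(np.mean(sizes)) if sizes else np.nan,
            }
        )
    return labels, pd.DataFrame(rows)


def _band_labels(d_apical_nm: np.ndarray, length_nm: float, band_nm: float) -> np.ndarray:
    d = np.asarray(d_apical_nm, dtype=float)
    labels = np.full(d.shape, "unassigned", dtype=object)
    central = np.abs(d - length_nm / 2.0) <= band_nm / 2.0
    labels[central] = "central"
    labels[d <= band_nm] = "apical"
    labels[(length_nm - d) <= band_nm] = "basal"
    return labels


def band_area_um2(particles: ParticleSet, domain: str, band_um: float = DEFAULT_BAND_UM) -> float:
    """Area (µm²) of the analyzed region clipped to one polar band strip."""
    if particles.region is None or particles.axis is None:
        raise ValueError("band area needs the analyzed-region polygon and the cell axis")
    axis = particles.axis
    band_nm = band_um * 1000.0
    sign = 1.0 if axis.basal_edge_nm > axis.apical_edge_nm else -1.0
    if domain == "apical":
        lo, hi = 0.0, band_nm
    elif domain == "basal":
        lo, hi = axis.length_nm - band_nm, axis.length_nm
    elif domain == "central":
        lo, hi = axis.length_nm / 2 - band_nm / 2, axis.length_nm / 2 + band_nm / 2
    else:
        raise ValueError(f"unknown domain {domain!r}")

    # Rotate the frame so the apical->basal direction becomes +y, then clip
    # with an axis-aligned strip; rotation preserves areas.
    ux, uy = axis.direction
    angle_deg = 90.0 - np.degrees(np.arctan2(uy, ux))
    rotated = affinity.rotate(particles.region, angle_deg, origin=(0, 0))
    # After rotation the axial coordinate s = p·u becomes the y coordinate.
    s_a, s_b = axis.apical_edge_nm + sign * lo, axis.apical_edge_nm + sign * hi
    minx, _, maxx, _ = rotated.bounds
    strip = box(minx - 1.0, min(s_a, s_b), maxx + 1.0, max(s_a, s_b))
    return float(rotated.intersection(strip).area) / 1e6


def particles_per_cluster_gradient(
    groups: Sequence[ParticleGroup],
    particles: ParticleSet,
    bin_um: float,
) -> pd.DataFrame:
    """Bin clusters by centroid distance from the apical edge.

    Returns one row per bin covering the cell length with the cluster count
    and the mean particles per cluster; empty bins carry a missing mean, not
    zero.
    """
    if bin_um <= 0:
        raise ValueError("bin width must be positive")
    if particles.axis is None:
        raise ValueError("particle set carries no cell axis")
    clusters = [g for g in groups if g.group_class == "cluster"]
    length_um = particles.axis.length_nm / 1000.0
    n_bins = max(1, int(np.ceil(length_um / bin_um)))
    edges = np.arange(n_bins + 1) * bin_um
    counts = np.zeros(n_bins, dtype=int)
    sums = np.zeros(n_bins, dtype=float)
    for g in clusters:
        d_um = float(particles.axis.distance_from_apical(np.asarray([g.centroid_nm]))[0]) / 1000.0
        idx = min(int(d_um // bin_um), n_bins - 1)
        if 0 <= d_um <= length_um:
            counts[idx] += 1
            sums[idx] += g.size
    if not clusters:
        return pd.DataFrame(columns=["bin_left_um", "bin_right_um", "n_clusters", "mean_particles_per_cluster"])
    mean_ppc = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left_um": edges[:-1],
            "bin_right_um": edges[1:],
            "n_clusters": counts,
            "mean_particles_per_cluster": mean_ppc,
        }
    )


def iem_profile_summary(
    groups_per_image: Sequence[Sequence[ParticleGroup]],
    membrane_profile_length_um: Optional[Sequence[float]] = None,
) -> dict:
    """Mean ± SD of cluster counts (size >= 3) per thin-section image.

    When membrane profile lengths are given, per-µm counts are summarized
    as well.  SD is the sample SD for more than one image and 0 for a single
    image.
    """
    if len(groups_per_image) < 1:
        raise ValueError("need at least one image")
    counts = np.asarray([sum(1 for g in gs if g.group_class == "cluster") for gs in groups_per_image], dtype=float)
    out = {
        "n_images": len(counts),
        "clusters_per_image_mean": float(counts.mean()),
        "clusters_per_image_sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
    }
    if membrane_profile_length_um is not None:
        lengths = np.asarray(membrane_profile_length_um, dtype=float)
        if len(lengths) != len(counts):
            raise ValueError("one profile length per image required")
        if np.any(lengths <= 0):
            raise ValueError("profile lengths must be positive")
        per_um = counts / lengths
        out["clusters_per_um_mean"] = float(per_um.mean())
        out["clusters_per_um_sd"] = float(per_um.std(ddof=1)) if len(per_um) > 1 else 0.0
    return out


def groups_table(groups: Sequence[ParticleGroup], domains: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Flatten groups into the output table written by the CLI."""
    rows = []
    for i, g in enumerate(groups):
        rows.append(
            {
                "group_id": i,
                "size": g.size,
                "class": g.group_class,
                "diameter_nm": g.diameter_nm,
                "centroid_x_nm": g.centroid_nm[0],
                "centroid_y_nm": g.centroid_nm[1],
                "domain": domains[i] if domains is not None else (g.domain or ""),
            }
        )
    return pd.DataFrame(rows, columns=["group_id", "size", "class", "diameter_nm", "centroid_x_nm", "centroid_y_nm", "domain"])
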