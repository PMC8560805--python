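"""Structure detection: nuclei, merged-channel cilium candidates, basal
bodies, and the cilium-to-cell assignment.

The central trick of the assay lives in :func:`merge_axoneme`: the
acetylated-tubulin (axoneme) and ARL13B (membrane) channels each show
staining gaps along the cilium, but rarely at the same position, so the
pixel-wise maximum of the two contrast-normalized planes yields a
continuous cilium signal that a single channel cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import feature, filters, measure, morphology, restoration, segmentation, transform

from .config import DetectionConfig
from .io import FieldImage


@dataclass
class NucleusSet:
    """Labeled nuclei of one field (labels contiguous ``1..count``)."""

    label_raster: np.ndarray
    count: int


@dataclass
class CiliumCandidate:
    """One connected component of the merged ciliary signal."""

    cilium_id: int
    mask: np.ndarray  # boolean, full field size
    skeleton: np.ndarray  # ordered (N, 2) pixel path, longest geodesic
    skeleton_length_px: float
    area_um2: float
    bbox: tuple[int, int, int, int]
    base_anchor: tuple[float, float] | None = None
    n_fragments: int = 1  # pre-closing pieces merged into this candidate

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.skeleton[0], self.skeleton[-1]


@dataclass
class CellAssignment:
    """Per-nucleus cilium status and the inverse candidate→nucleus map."""

    nucleus_candidate: dict[int, int | None]
    candidate_nucleus: dict[int, int | None]

    def has_candidate(self, label: int) -> bool:
        return self.nucleus_candidate.get(label) is not None


# ---------------------------------------------------------------------------
# nuclei


def _subtract_background(plane: np.ndarray, radius_px: int) -> np.ndarray:
    """Rolling-ball background subtraction, computed on a 4x-downscaled
    copy for speed (the background varies on a much coarser scale than
    one pixel) and upsampled back."""
    if radius_px <= 0:
        return plane
    factor = 4
    small = transform.downscale_local_mean(plane, (factor, factor))
    bg = restoration.rolling_ball(small, radius=max(radius_px // factor, 1))
    bg = transform.resize(bg, plane.shape, order=1, anti_aliasing=False)
    return np.clip(plane - bg, 0.0, None)


def segment_nuclei(field: FieldImage,
                   config: DetectionConfig | None = None) -> NucleusSet:
    """Count and label nuclei in the DAPI plane.

    Chain: rolling-ball background subtraction → global Otsu → fill
    holes → minimum-area filter → distance-transform watershed to split
    touching nuclei.  Deterministic.
    """
    config = config or DetectionConfig()
    plane = field.plane("nucleus")
    px = field.pixel_size_um
    corrected = _subtract_background(plane, config.background_radius_px)
    if corrected.max() - corrected.min() < 1e-6:
        return NucleusSet(np.zeros(plane.shape, dtype=np.int32), 0)
    binary = corrected > filters.threshold_otsu(corrected)
    binary = ndi.binary_fill_holes(binary)
    min_px = int(round(config.nucleus_min_area_um2 / px**2))
    binary = morphology.remove_small_objects(binary, max_size=min_px - 1)
    if not binary.any():
        return NucleusSet(np.zeros(plane.shape, dtype=np.int32), 0)

    dist = ndi.distance_transform_edt(binary)
    dist_s = ndi.gaussian_filter(dist, 2.0)
    min_dist_px = max(int(round(config.nucleus_split_min_distance_um / px)), 1)
    coords = feature.peak_local_max(
        dist_s, min_distance=min_dist_px, labels=binary, exclude_border=False
    )
    if len(coords) == 0:
        labels, n = ndi.label(binary)
        return NucleusSet(labels.astype(np.int32), int(n))
    seed_mask = np.zeros(binary.shape, dtype=bool)
    seed_mask[tuple(coords.T)] = True
    markers, _ = ndi.label(seed_mask)
    labels = segmentation.watershed(-dist_s, markers, mask=binary)
    labels, _, _ = segmentation.relabel_sequential(labels)
    return NucleusSet(labels.astype(np.int32), int(labels.max()))


# ---------------------------------------------------------------------------
# merged ciliary signal


def _rescale_percentile(plane: np.ndarray,
                        percentiles: tuple[float, float]) -> np.ndarray:
    lo, hi = np.percentile(plane, percentiles)
    if hi - lo < 1e-9:
        return np.zeros_like(plane, dtype=np.float64)
    return np.clip((plane - lo) / (hi - lo), 0.0, 1.0)


def merge_axoneme(field: FieldImage,
                  config: DetectionConfig | None = None) -> np.ndarray:
    """Combine the axoneme and membrane planes into one cilium raster.

    Each plane is contrast-normalized (percentile 1–99.9 rescale to
    [0, 1]) before taking the pixel-wise maximum, so a gap in either
    stain is bridged by the other.  Commutative in its two inputs.
    """
    config = config or DetectionConfig()
    a = _rescale_percentile(field.plane("axoneme"), config.contrast_percentiles)
    m = _rescale_percentile(field.plane("membrane"), config.contrast_percentiles)
    return np.maximum(a, m)


# ---------------------------------------------------------------------------
# cilium candidates


def _longest_geodesic(skel: np.ndarray, spur_px: int) -> tuple[np.ndarray, float]:
    """Ordered longest geodesic path through a skeleton mask.

    Builds the 8-neighbor pixel graph (weights 1 / sqrt(2)), prunes side
    branches shorter than ``spur_px`` (a spur is an endpoint-to-junction
    path; true cilium ends reach no junction and are kept), then returns
    the weighted diameter path and its length in pixel units.
    """
    coords = [tuple(c) for c in np.argwhere(skel)]
    if not coords:
        return np.empty((0, 2), dtype=int), 0.0
    if len(coords) == 1:
        return np.array(coords), 0.0
    cset = set(coords)
    g = nx.Graph()
    g.add_nodes_from(coords)
    for r, c in coords:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) <= (0, 0):
                    continue
                nb = (r + dr, c + dc)
                if nb in cset:
                    g.add_edge((r, c), nb,
                               weight=1.0 if dr * dc == 0 else np.sqrt(2.0))
    # prune short spurs hanging off junctions
    if spur_px > 0:
        junctions = {n for n in g if g.degree(n) >= 3}
        if junctions:
            for end in [n for n in g if g.degree(n) == 1]:
                path = [end]
                node = end
                while g.degree(node) <= 2 and len(path) <= spur_px:
                    nxt = [n for n in g.neighbors(node) if n not in path]
                    if not nxt:
                        break
                    node = nxt[0]
                    path.append(node)
                if node in junctions and len(path) - 1 <= spur_px:
                    g.remove_nodes_from(path[:-1])
    if g.number_of_nodes() == 0:
        return np.array([coords[0]]), 0.0
    # weighted tree diameter via double Dijkstra
    comp = max(nx.connected_components(g), key=len)
    start = next(iter(comp))
    dist = nx.single_source_dijkstra_path_length(g, start, weight="weight")
    u = max(dist, key=dist.get)
    dist_u, paths_u = nx.single_source_dijkstra(g, u, weight="weight")
    v = max(dist_u, key=dist_u.get)
    return np.array(paths_u[v]), float(dist_u[v])


def segment_cilia(merged: np.ndarray, pixel_size_um: float,
                  config: DetectionConfig | None = None,
                  spur_px: int = 3) -> list[CiliumCandidate]:
    """Segment cilium candidates from the merged ciliary raster.

    Otsu threshold → morphological closing (bridges residual sub-gaps)
    → connected components; components below the minimum area or
    touching the field border are discarded.  Each candidate carries its
    morphological skeleton's longest geodesic path.
    """
    merged = np.asarray(merged, dtype=np.float64)
    if not np.all(np.isfinite(merged)):
        raise ValueError("merged raster contains non-finite values")
    if merged.max() - merged.min() < 1e-6:
        return []
    binary = merged > filters.threshold_otsu(merged)
    config = config or DetectionConfig()
    pre_labels, _ = ndi.label(binary, structure=np.ones((3, 3)))
    closed = morphology.closing(
        binary, morphology.disk(config.cilium_closing_radius_px)
    )
    labels = measure.label(closed, connectivity=2)
    min_px = config.cilium_min_area_um2 / pixel_size_um**2
    h, w = merged.shape
    out: list[CiliumCandidate] = []
    cid = 0
    for region in measure.regionprops(labels):
        if region.area < min_px:
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue
        mask = labels == region.label
        skel = morphology.skeletonize(mask)
        path, length_px = _longest_geodesic(skel, spur_px)
        frags = np.unique(pre_labels[mask])
        out.append(
            CiliumCandidate(
                cilium_id=cid,
                mask=mask,
                skeleton=path,
                skeleton_length_px=length_px,
                area_um2=float(region.area) * pixel_size_um**2,
                bbox=region.bbox,
                n_fragments=int((frags > 0).sum()),
            )
        )
        cid += 1
    return out


# ---------------------------------------------------------------------------
# basal bodies


def detect_basal_bodies(field: FieldImage,
                        config: DetectionConfig | None = None) -> np.ndarray:
    """Detect basal-body puncta as LoG blobs; returns (N, 2) sub-pixel
    centers (row, col).  An absent plane yields an empty array."""
    config = config or DetectionConfig()
    if not field.has("basal_body"):
        return np.empty((0, 2))
    plane = field.plane("basal_body")
    if plane.max() - plane.min() < 1e-6:
        return np.empty((0, 2))
    lo, hi = config.blob_sigma_px
    blobs = feature.blob_log(plane, min_sigma=lo, max_sigma=hi, num_sigma=5,
                             threshold=config.blob_threshold)
    centers = []
    h, w = plane.shape
    for r, c, _s in blobs:
        # intensity-weighted sub-pixel refinement in a 5x5 window
        r0, r1 = max(int(r) - 2, 0), min(int(r) + 3, h)
        c0, c1 = max(int(c) - 2, 0), min(int(c) + 3, w)
        win = plane[r0:r1, c0:c1]
        tot = win.sum()
        if tot <= 0:
            centers.append((r, c))
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        centers.append(((rr * win).sum() / tot, (cc * win).sum() / tot))
    return np.array(centers).reshape(-1, 2)


# ---------------------------------------------------------------------------
# assignment


def _nucleus_boundary_trees(nuclei: NucleusSet) -> dict[int, cKDTree]:
    trees = {}
    for label in range(1, nuclei.count + 1):
        mask = nuclei.label_raster == label
        boundary = mask & ~ndi.binary_erosion(mask)
        trees[label] = cKDTree(np.argwhere(boundary))
    return trees


def assign_cilia_to_cells(
    candidates: list[CiliumCandidate],
    nuclei: NucleusSet,
    basal_bodies: np.ndarray,
    pixel_size_um: float,
    config: DetectionConfig | None = None,
) -> CellAssignment:
    """Anchor candidates to basal bodies and assign them to nuclei.

    A candidate is anchored to the nearest basal-body punctum within the
    anchor radius of either skeleton endpoint; its base is the anchored
    endpoint (or, unanchored, whichever endpoint is closer to the chosen
    nucleus).  Each candidate goes to the nucleus with the smallest
    boundary-to-base distance within the assignment radius; when several
    candidates compete for one nucleus the largest wins and the rest
    stay unassigned.  Primary-cilium biology admits one cilium per cell.
    """
    config = config or DetectionConfig()
    bb_tree = cKDTree(basal_bodies) if len(basal_bodies) else None
    anchor_r = config.base_anchor_radius_um / pixel_size_um
    assign_r = config.nucleus_assignment_radius_um / pixel_size_um
    trees = _nucleus_boundary_trees(nuclei)

    # base point per candidate (anchored endpoint preferred)
    bases: dict[int, list[np.ndarray]] = {}
    for cand in candidates:
        e0, e1 = cand.endpoints
        cand.base_anchor = None
        if bb_tree is not None:
            d0, i0 = bb_tree.query(np.asarray(e0, dtype=float))
            d1, i1 = bb_tree.query(np.asarray(e1, dtype=float))
            d, i, e = (d0, i0, e0) if d0 <= d1 else (d1, i1, e1)
            if d <= anchor_r:
                cand.base_anchor = tuple(basal_bodies[i])
                bases[cand.cilium_id] = [np.asarray(e, dtype=float)]
        if cand.cilium_id not in bases:
            bases[cand.cilium_id] = [np.asarray(e0, float), np.asarray(e1, float)]

    # candidate -> nearest nucleus within the assignment radius
    prefer: list[tuple[float, float, int, int]] = []  # (dist, -area, cid, label)
    for cand in candidates:
        best: tuple[float, int] | None = None
        for label, tree in trees.items():
            if tree.n == 0:
                continue
            d = min(tree.query(b)[0] for b in bases[cand.cilium_id])
            if d <= assign_r and (best is None or d < best[0]):
                best = (d, label)
        if best is not None:
            prefer.append((best[0], -cand.area_um2, cand.cilium_id, best[1]))

    nucleus_candidate: dict[int, int | None] = {
        lab: None for lab in range(1, nuclei.count + 1)
    }
    candidate_nucleus: dict[int, int | None] = {
        c.cilium_id: None for c in candidates
    }
    # larger area wins a contested nucleus
    for _d, _na, cid, label in sorted(prefer, key=lambda t: (t[3], t[1], t[0])):
        if nucleus_candidate[label] is None:
            nucleus_candidate[label] = cid
            candidate_nucleus[cid] = label
    return CellAssignment(nucleus_candidate, candidate_nucleus)
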