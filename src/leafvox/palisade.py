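"""Palisade cell geometry from three paradermal slices.

Full 3D instance segmentation of mesophyll cells is avoided: instead,
three paradermal planes are sampled through the palisade layer (the first
plane fully below the adaxial epidermis, the last plane of the palisade,
and the plane midway between them), individual cells are delineated in
each plane by a marker-controlled watershed on the distance transform, and
each cell's radius is estimated from a disk of equivalent projected area,
d = 2·sqrt(A/π).  A palisade cell is then modelled as two stacked frusta
(truncated cones) spanning top→middle and middle→bottom, giving a single
cell volume

    V = (π·h/3)·(r_a² + r_a·r_b + r_b²)

and lateral surface area

    S = π·(r_a + r_b)·sqrt(h² + (r_a − r_b)²)

summed over the two frusta.  Lateral (not total) area is used because the
end caps of palisade cells are typically pressed against the epidermis or
neighbouring cells rather than exposed to airspace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .stack_io import LabeledStack

__all__ = [
    "PalisadeCellTable",
    "select_paradermal_slices",
    "label_cells_2d",
    "cell_density",
    "equivalent_diameters",
    "frustum_volume",
    "frustum_lateral_area",
    "palisade_summary",
]


@dataclass
class PalisadeCellTable:
    """Per-scan palisade summary built from three paradermal slices."""

    slice_indices: tuple[int, int, int]  # (top, middle, bottom), axis-1
    diameters_um: dict[str, list[float]]  # per slice, enclosed cells only
    r_top_um: float
    r_mid_um: float
    r_bot_um: float
    h_top_mid_um: float
    h_mid_bot_um: float
    D_pal_per_mm2: float
    V_pal_um3: float
    S_pal_um2: float
    S_over_V_per_um: float
    n_cells: dict[str, int] = field(default_factory=dict)


def frustum_volume(r_a: float, r_b: float, h_ab: float) -> float:
    """Volume of a truncated cone, (π·h/3)·(r_a² + r_a·r_b + r_b²)."""
    if r_a < 0 or r_b < 0:
        raise ValueError("radii must be non-negative")
    if h_ab <= 0:
        raise ValueError("height must be positive")
    return math.pi * h_ab / 3.0 * (r_a**2 + r_a * r_b + r_b**2)


def frustum_lateral_area(r_a: float, r_b: float, h_ab: float) -> float:
    """Lateral area of a truncated cone, π·(r_a+r_b)·sqrt(h² + (r_a−r_b)²)."""
    if r_a < 0 or r_b < 0:
        raise ValueError("radii must be non-negative")
    if h_ab <= 0:
        raise ValueError("height must be positive")
    return math.pi * (r_a + r_b) * math.sqrt(h_ab**2 + (r_a - r_b) ** 2)


def select_paradermal_slices(
    stack: LabeledStack,
    bounds: tuple[int, int] | None = None,
    jump_threshold: float = 0.10,
) -> tuple[int, int, int]:
    """Axis-1 indices of the (top, middle, bottom) palisade planes.

    The top plane is the first paradermal plane below the adaxial
    epidermis containing only mesophyll (cells and airspace).  The bottom
    of the palisade is not encoded in the tissue labels, so it is either
    supplied via *bounds* or detected as the largest discontinuity (>
    *jump_threshold*) in the per-plane airspace fraction below the top —
    the palisade→spongy transition shows up as a porosity jump.
    """
    if bounds is not None:
        top, bottom = int(bounds[0]), int(bounds[1])
        if bottom - top < 2:
            raise ValueError("palisade thinner than 3 planes")
        return top, (top + bottom) // 2, bottom

    vol = stack.volume
    leg = stack.legend
    mes_labels = {leg.label("mesophyll_cell"), leg.label("airspace")}
    top = None
    for j in range(vol.shape[1]):
        present = set(int(x) for x in np.unique(vol[:, j, :]))
        if present and present <= mes_labels and leg.label("mesophyll_cell") in present:
            top = j
            break
    if top is None:
        raise ValueError("no all-mesophyll paradermal plane found")

    # porosity profile below the top; the palisade/spongy transition is a jump
    cell = vol == leg.label("mesophyll_cell")
    air = vol == leg.label("airspace")
    with np.errstate(invalid="ignore"):
        frac = air[:, top:, :].sum(axis=(0, 2)) / np.maximum(
            (cell | air)[:, top:, :].sum(axis=(0, 2)), 1
        )
    mes_planes = (cell | air)[:, top:, :].any(axis=(0, 2))
    frac = frac[: int(np.argmin(mes_planes)) or len(frac)]
    if len(frac) < 3:
        raise ValueError("palisade thinner than 3 planes")
    jumps = np.abs(np.diff(frac))
    j_star = int(np.argmax(jumps))
    if jumps[j_star] < jump_threshold:
        raise ValueError(
            "palisade bottom not detectable from the porosity profile; "
            "pass bounds=(top, bottom) explicitly"
        )
    bottom = top + j_star
    if bottom - top < 2:
        raise ValueError("palisade thinner than 3 planes")
    return top, (top + bottom) // 2, bottom


def label_cells_2d(cell_mask: np.ndarray, h: float = 2.0) -> np.ndarray:
    """Watershed labelling of individual cells in a paradermal plane.

    Markers are the h-maxima (depth *h*, in voxels) of the Euclidean
    distance transform of the cell mask; the watershed of the negated
    distance transform then assigns every cell pixel a unique positive
    label, with non-cell pixels left 0.
    """
    cell_mask = np.asarray(cell_mask, bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    dist = ndimage.distance_transform_edt(cell_mask)
    maxima = h_maxima(dist, h)
    markers, _ = ndimage.label(maxima)
    return watershed(-dist, markers, mask=cell_mask)


def _edge_sets(labels: np.ndarray) -> tuple[set[int], set[int]]:
    """Labels touching (left or bottom) edges, and labels touching any edge."""
    left = set(np.unique(labels[:, 0]))
    bottom = set(np.unique(labels[-1, :]))
    top = set(np.unique(labels[0, :]))
    right = set(np.unique(labels[:, -1]))
    return (left | bottom) - {0}, (left | bottom | top | right) - {0}


def cell_density(cell_labels: np.ndarray, voxel_size_um: float) -> float:
    """Cell packing density (cells mm⁻²).

    Cells touching the left or bottom image edge are excluded so each cell
    straddling a tile boundary is counted exactly once across tiles.
    """
    excluded, _ = _edge_sets(cell_labels)
    n = len(set(np.unique(cell_labels)) - {0} - excluded)
    area_mm2 = cell_labels.size * (voxel_size_um * 1e-3) ** 2
    return n / area_mm2


def equivalent_diameters(cell_labels: np.ndarray, voxel_size_um: float) -> list[float]:
    """Equivalent-disk diameters (µm) of cells completely enclosed in the image."""
    _, touching_any = _edge_sets(cell_labels)
    diameters = []
    for lab in sorted(set(np.unique(cell_labels)) - {0} - touching_any):
        area = np.count_nonzero(cell_labels == lab) * voxel_size_um**2
        diameters.append(2.0 * math.sqrt(area / math.pi))
    return diameters


def palisade_summary(
    stack: LabeledStack,
    bounds: tuple[int, int] | None = None,
    h: float = 2.0,
    min_cells: int = 20,
) -> PalisadeCellTable:
    """Two-stacked-frusta palisade cell model for one scan.

    Median equivalent radii are taken at the top, middle and bottom planes
    of the palisade; the cell volume and lateral surface are the sums over
    the top→middle and middle→bottom frusta; the packing density is
    measured on the middle plane.
    """
    top, mid, bot = select_paradermal_slices(stack, bounds=bounds)
    leg = stack.legend
    v = stack.voxel_size_um
    radii = {}
    diam = {}
    counts = {}
    d_pal = 0.0
    for name, j in (("top", top), ("middle", mid), ("bottom", bot)):
        mask = stack.volume[:, j, :] == leg.label("mesophyll_cell")
        labels = label_cells_2d(mask, h=h)
        ds = equivalent_diameters(labels, v)
        if len(ds) < min_cells:
            warnings.warn(
                f"only {len(ds)} enclosed cells in the {name} plane "
                f"(recommended >= {min_cells})",
                stacklevel=2,
            )
        if not ds:
            raise ValueError(f"no enclosed cells in the {name} plane")
        radii[name] = float(np.median(ds)) / 2.0
        diam[name] = ds
        counts[name] = len(ds)
        if name == "middle":
            d_pal = cell_density(labels, v)

    h1 = (mid - top) * v
    h2 = (bot - mid) * v
    v_pal = frustum_volume(radii["top"], radii["middle"], h1) + frustum_volume(
        radii["middle"], radii["bottom"], h2
    )
    s_pal = frustum_lateral_area(radii["top"], radii["middle"], h1) + (
        frustum_lateral_area(radii["middle"], radii["bottom"], h2)
    )
    return PalisadeCellTable(
        slice_indices=(top, mid, bot),
        diameters_um=diam,
        r_top_um=radii["top"],
        r_mid_um=radii["middle"],
        r_bot_um=radii["bottom"],
        h_top_mid_um=h1,
        h_mid_bot_um=h2,
        D_pal_per_mm2=d_pal,
        V_pal_um3=v_pal,
        S_pal_um2=s_pal,
        S_over_V_per_um=s_pal / v_pal,
        n_cells=counts,
    )
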