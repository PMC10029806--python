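"""Synthetic hypostomatous-leaf phantoms with analytic ground truth.

Real microCT leaf scans are large and irreproducible at desk scale, so the
pipeline is validated on voxel phantoms that emulate the geometric features
the trait extractors measure: two epidermes sandwiching a mesophyll, a
palisade layer of elongated frustum-shaped cells on a hexagonal lattice, a
porous spongy layer whose airspace is connected to the outside through
abaxial stomatal pores.  Every phantom carries a :class:`GroundTruth`
record holding exact post-voxelization tissue volumes and thicknesses plus
the analytic (pre-voxelization) cell geometry, so measured traits can be
compared against known values at a stated tolerance.

Two generators are provided:

``generate_slab_phantom``
    A layered slab whose mesophyll is solid cell material pierced by a
    regular lattice of rectangular air channels sized to hit a target
    porosity exactly; each channel opens to the abaxial surface through a
    stomatal pore.  Geometry is fully deterministic — ideal for exact
    conservation and partition tests.

``generate_leaf_phantom``
    Adds cellular structure: hexagonally packed palisade frusta and a
    spongy layer perforated by randomly placed spherical pores grown from
    the stomatal channels until the target porosity is reached, which
    guarantees the airspace stays connected to the stomata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stack_io import DEFAULT_LEGEND, LabelLegend, LabeledStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_slab_phantom",
    "generate_leaf_phantom",
    "two_stoma_symmetric_spec",
]

#: Background padding (voxels) added above and below the leaf slab.
_PAD = 4


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric parameters of a synthetic leaf.

    Defaults describe a thin dicot leaf at 1 µm voxels: a 200 µm lamina
    with 15 µm epidermes, half the mesophyll occupied by palisade cells of
    ~6–9 µm radius on a 20 µm pitch, a spongy layer of 30 % porosity and
    abaxial stomata every 60 µm.
    """

    voxel_size_um: float = 1.0
    leaf_thickness_um: float = 200.0
    epidermis_thickness_um: float = 15.0
    palisade_fraction: float = 0.5
    palisade_radius_top_um: float = 6.0
    palisade_radius_bottom_um: float = 9.0
    palisade_pitch_um: float = 20.0
    spongy_target_porosity: float = 0.30
    stoma_pitch_um: float = 60.0
    stoma_radius_um: float = 4.0
    lateral_extent_um: tuple[float, float] = (120.0, 120.0)
    rng_seed: int = 0
    legend: LabelLegend = field(default_factory=LabelLegend)

    def __post_init__(self) -> None:
        lengths = {
            "voxel_size_um": self.voxel_size_um,
            "leaf_thickness_um": self.leaf_thickness_um,
            "epidermis_thickness_um": self.epidermis_thickness_um,
            "palisade_radius_top_um": self.palisade_radius_top_um,
            "palisade_radius_bottom_um": self.palisade_radius_bottom_um,
            "palisade_pitch_um": self.palisade_pitch_um,
            "stoma_pitch_um": self.stoma_pitch_um,
            "stoma_radius_um": self.stoma_radius_um,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if any(e <= 0 for e in self.lateral_extent_um):
            raise ValueError("lateral extents must be positive")
        if not 0 < self.palisade_fraction < 1:
            raise ValueError("palisade_fraction must be in (0, 1)")
        if not 0 <= self.spongy_target_porosity < 1:
            raise ValueError("spongy_target_porosity must be in [0, 1)")
        if max(self.palisade_radius_top_um, self.palisade_radius_bottom_um) >= (
            self.palisade_pitch_um / 2
        ):
            raise ValueError("palisade radii must be < palisade_pitch/2")
        if self.stoma_radius_um >= self.stoma_pitch_um / 2:
            raise ValueError("stoma_radius_um must be < stoma_pitch/2")
        if 2 * self.epidermis_thickness_um >= self.leaf_thickness_um:
            raise ValueError("epidermes thicker than the leaf")


@dataclass
class GroundTruth:
    """Known traits of a generated phantom.

    ``volumes_um3`` and ``thickness_um`` are exact post-voxelization values
    (voxel counts × voxel volume, layer extents × voxel size).  The
    analytic fields hold pre-voxelization geometry — frustum surface/volume
    per palisade cell and the porosity the generator targeted — which
    measured values should approach within voxelization tolerance.
    """

    volumes_um3: dict[str, float]
    thickness_um: dict[str, float]
    theta_ias: float
    f_mes: float
    stoma_count: int
    analytic_theta_ias: float | None = None
    analytic_S_pal_um2: float | None = None
    analytic_V_pal_um3: float | None = None
    palisade_radii_um: tuple[float, float] | None = None
    palisade_bounds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        v = self.volumes_um3
        mes = v["mesophyll_cell"] + v["airspace"]
        if mes > 0:
            assert abs(self.theta_ias - v["airspace"] / mes) < 1e-9


def _voxels(length_um: float, voxel: float) -> int:
    return max(1, round(length_um / voxel))


def _lattice_positions(extent_vox: int, pitch_vox: float) -> np.ndarray:
    """Centers of a 1D lattice at the given pitch, centered in the extent."""
    n = max(1, int(extent_vox // pitch_vox))
    span = (n - 1) * pitch_vox
    start = (extent_vox - 1 - span) / 2.0
    return start + pitch_vox * np.arange(n)


def _layer_bounds(spec: PhantomSpec) -> dict[str, tuple[int, int]]:
    vox = spec.voxel_size_um
    t_leaf = _voxels(spec.leaf_thickness_um, vox)
    t_ep = _voxels(spec.epidermis_thickness_um, vox)
    t_mes = t_leaf - 2 * t_ep
    if t_mes < 3:
        raise ValueError("mesophyll thinner than 3 voxels; spec infeasible")
    top = _PAD
    return {
        "epidermis_adaxial": (top, top + t_ep),
        "mesophyll": (top + t_ep, top + t_ep + t_mes),
        "epidermis_abaxial": (top + t_ep + t_mes, top + t_ep + t_mes + t_ep),
        "leaf": (top, top + t_leaf),
    }


def _finalize(
    spec: PhantomSpec,
    volume: np.ndarray,
    bounds: dict[str, tuple[int, int]],
    n_stomata: int,
    analytic_theta: float | None,
    analytic_S_pal: float | None = None,
    analytic_V_pal: float | None = None,
    palisade_radii: tuple[float, float] | None = None,
    palisade_bounds: tuple[int, int] | None = None,
) -> tuple[LabeledStack, GroundTruth]:
    leg = spec.legend
    stack = LabeledStack(
        volume=volume, voxel_size_um=spec.voxel_size_um, legend=leg, oriented=True
    )
    vv = stack.voxel_volume_um3
    counts = stack.label_counts()
    volumes = {role: counts[role] * vv for role in counts}
    v_mes = volumes["mesophyll_cell"] + volumes["airspace"]
    v_leaf = sum(v for role, v in volumes.items() if role != "background")
    theta = volumes["airspace"] / v_mes if v_mes > 0 else 0.0
    vox = spec.voxel_size_um
    thickness = {
        "leaf": (bounds["leaf"][1] - bounds["leaf"][0]) * vox,
        "mesophyll": (bounds["mesophyll"][1] - bounds["mesophyll"][0]) * vox,
        "epidermis_adaxial": (
            bounds["epidermis_adaxial"][1] - bounds["epidermis_adaxial"][0]
        )
        * vox,
        "epidermis_abaxial": (
            bounds["epidermis_abaxial"][1] - bounds["epidermis_abaxial"][0]
        )
        * vox,
    }
    truth = GroundTruth(
        volumes_um3=volumes,
        thickness_um=thickness,
        theta_ias=theta,
        f_mes=v_mes / v_leaf if v_leaf > 0 else 0.0,
        stoma_count=n_stomata,
        analytic_theta_ias=analytic_theta,
        analytic_S_pal_um2=analytic_S_pal,
        analytic_V_pal_um3=analytic_V_pal,
        palisade_radii_um=palisade_radii,
        palisade_bounds=palisade_bounds,
    )
    return stack, truth


def _carve_stomata(
    volume: np.ndarray,
    spec: PhantomSpec,
    bounds: dict[str, tuple[int, int]],
    centers: list[tuple[float, float]],
) -> None:
    """Pierce the abaxial epidermis with a stomatal pore under each center."""
    leg = spec.legend
    vox = spec.voxel_size_um
    r = spec.stoma_radius_um / vox
    j0, j1 = bounds["epidermis_abaxial"]
    i_grid, k_grid = np.meshgrid(
        np.arange(volume.shape[0]), np.arange(volume.shape[2]), indexing="ij"
    )
    for ci, ck in centers:
        pore = (i_grid - ci) ** 2 + (k_grid - ck) ** 2 <= r**2
        for j in range(j0, j1):
            plane = volume[:, j, :]
            plane[pore] = leg.stoma


def generate_slab_phantom(spec: PhantomSpec) -> tuple[LabeledStack, GroundTruth]:
    """Deterministic layered slab with rectangular air channels.

    The mesophyll is solid cell material pierced by square vertical air
    channels on the stomatal lattice; the shared channel cross-section is
    sized so the voxelized porosity matches ``spongy_target_porosity``
    (interpreted for this variant as the porosity of the whole mesophyll).
    Each channel opens through a stomatal pore in the abaxial epidermis.
    """
    leg = spec.legend
    vox = spec.voxel_size_um
    bounds = _layer_bounds(spec)
    n0 = _voxels(spec.lateral_extent_um[0], vox)
    n2 = _voxels(spec.lateral_extent_um[1], vox)
    n1 = bounds["leaf"][1] + _PAD
    volume = np.full((n0, n1, n2), leg.background, dtype=np.uint8)

    j = bounds["epidermis_adaxial"]
    volume[:, j[0] : j[1], :] = leg.epidermis_adaxial
    j = bounds["mesophyll"]
    volume[:, j[0] : j[1], :] = leg.mesophyll_cell
    j = bounds["epidermis_abaxial"]
    volume[:, j[0] : j[1], :] = leg.epidermis_abaxial

    pitch_vox = spec.stoma_pitch_um / vox
    pos0 = _lattice_positions(n0, pitch_vox)
    pos2 = _lattice_positions(n2, pitch_vox)
    centers = [(i, k) for i in pos0 for k in pos2]
    n_ch = len(centers)

    # choose a square channel window achieving the target porosity; the
    # window criterion |i - center| < w/2 keeps channels mirror-symmetric
    # about the lattice, which the vaporshed symmetry fixtures rely on
    target = spec.spongy_target_porosity
    analytic_theta = 0.0
    jm0, jm1 = bounds["mesophyll"]
    if target > 0:
        u0 = _axis_indicators(pos0, n0, pitch_vox)
        u2 = _axis_indicators(pos2, n2, pitch_vox)
        best_theta, best_pair = None, None
        for w0, ind0 in u0.items():
            for w2, ind2 in u2.items():
                theta = ind0.sum() * ind2.sum() / (n0 * n2)
                if best_theta is None or abs(theta - target) < abs(
                    best_theta - target
                ):
                    best_theta, best_pair = theta, (w0, w2)
        if best_theta is None or abs(best_theta - target) > 0.02:
            raise ValueError(
                "air channels would overlap before reaching the target "
                "porosity; reduce porosity or widen the stoma pitch"
            )
        analytic_theta = float(best_theta)
        footprint = np.outer(u0[best_pair[0]], u2[best_pair[1]])
        region = volume[:, jm0:jm1, :]
        region[np.broadcast_to(footprint[:, None, :], region.shape)] = leg.airspace

    _carve_stomata(volume, spec, bounds, centers)
    return _finalize(spec, volume, bounds, n_ch, analytic_theta)


def _axis_indicators(
    positions: np.ndarray, n: int, pitch_vox: float
) -> dict[int, np.ndarray]:
    """Indicator vectors of symmetric windows |i − c| < w/2 per width w.

    Widths whose windows would leave the grid or merge neighbouring
    channels are dropped.  The strict symmetric criterion keeps the
    channel pattern mirror-symmetric whenever the lattice is.
    """
    out: dict[int, np.ndarray] = {}
    for w in range(1, max(2, int(math.ceil(pitch_vox)) + 1)):
        ind = np.zeros(n, dtype=bool)
        ok = True
        for c in positions:
            lo, hi = math.floor(c - w / 2) + 1, math.ceil(c + w / 2) - 1
            if lo < 0 or hi >= n:
                ok = False
                break
            ind[lo : hi + 1] = True
        if not ok:
            break
        # reject widths whose windows are empty or fuse adjacent channels
        n_runs = int((np.diff(np.r_[0, ind.astype(np.int8), 0]) == 1).sum())
        if n_runs < len(positions):
            continue
        out[w] = ind
    return out


def _hex_lattice(n0: int, n2: int, pitch: float) -> np.ndarray:
    """Hexagonal lattice of (axis0, axis2) centers covering the plane."""
    row_pitch = pitch * math.sqrt(3) / 2
    rows = _lattice_positions(n0, row_pitch)
    centers = []
    for idx, r in enumerate(rows):
        cols = _lattice_positions(n2, pitch) + (pitch / 2 if idx % 2 else 0.0)
        for c in cols:
            if c <= n2 - 1:
                centers.append((r, c))
    return np.asarray(centers)


def _frustum_volume(r_a: float, r_b: float, h: float) -> float:
    return math.pi * h / 3.0 * (r_a**2 + r_a * r_b + r_b**2)


def _frustum_lateral(r_a: float, r_b: float, h: float) -> float:
    return math.pi * (r_a + r_b) * math.sqrt(h**2 + (r_a - r_b) ** 2)


def generate_leaf_phantom(spec: PhantomSpec) -> tuple[LabeledStack, GroundTruth]:
    """Cellular leaf phantom: palisade frusta over a porous spongy layer.

    Palisade cells are voxelized by center-inclusion: a voxel belongs to a
    cell when its center lies within the cell's circular cross-section,
    whose radius is interpolated linearly from ``palisade_radius_top_um``
    to ``palisade_radius_bottom_um``.  Spongy porosity is built by growing
    spherical pores from the stomatal channels (each new pore must touch
    already-connected airspace), which keeps the whole airspace reachable
    from the stomata.
    """
    leg = spec.legend
    vox = spec.voxel_size_um
    bounds = _layer_bounds(spec)
    n0 = _voxels(spec.lateral_extent_um[0], vox)
    n2 = _voxels(spec.lateral_extent_um[1], vox)
    n1 = bounds["leaf"][1] + _PAD
    volume = np.full((n0, n1, n2), leg.background, dtype=np.uint8)

    j = bounds["epidermis_adaxial"]
    volume[:, j[0] : j[1], :] = leg.epidermis_adaxial
    j = bounds["epidermis_abaxial"]
    volume[:, j[0] : j[1], :] = leg.epidermis_abaxial

    jm0, jm1 = bounds["mesophyll"]
    t_mes = jm1 - jm0
    t_pal = max(3, round(spec.palisade_fraction * t_mes))
    j_pal0, j_pal1 = jm0, jm0 + t_pal  # palisade spans [j_pal0, j_pal1)
    j_sp0, j_sp1 = j_pal1, jm1

    # --- palisade: hexagonally packed frusta, radius linear top -> bottom
    centers = _hex_lattice(n0, n2, spec.palisade_pitch_um / vox)
    r_top = spec.palisade_radius_top_um / vox
    r_bot = spec.palisade_radius_bottom_um / vox
    i_grid, k_grid = np.meshgrid(np.arange(n0), np.arange(n2), indexing="ij")
    d2_min = np.full((n0, n2), np.inf)
    for ci, ck in centers:
        d2 = (i_grid - ci) ** 2 + (k_grid - ck) ** 2
        np.minimum(d2_min, d2, out=d2_min)
    for j in range(j_pal0, j_pal1):
        frac = (j - j_pal0) / max(t_pal - 1, 1)
        r_j = r_top + (r_bot - r_top) * frac
        plane = np.where(d2_min <= r_j**2, leg.mesophyll_cell, leg.airspace)
        volume[:, j, :] = plane

    # --- spongy: solid matrix + stomatal channels + connected pores
    volume[:, j_sp0:j_sp1, :] = leg.mesophyll_cell
    pitch_vox = spec.stoma_pitch_um / vox
    pos0 = _lattice_positions(n0, pitch_vox)
    pos2 = _lattice_positions(n2, pitch_vox)
    stoma_centers = [(i, k) for i in pos0 for k in pos2]

    rng = np.random.default_rng(spec.rng_seed)
    for widen in range(3):  # retry with wider channels if disconnected
        spongy = np.zeros((n0, j_sp1 - j_sp0, n2), dtype=bool)
        ch_half = spec.stoma_radius_um / vox + 1 + widen
        for ci, ck in stoma_centers:
            i0, i1 = int(round(ci - ch_half)), int(round(ci + ch_half)) + 1
            k0, k1 = int(round(ck - ch_half)), int(round(ck + ch_half)) + 1
            spongy[max(i0, 0) : i1, :, max(k0, 0) : k1] = True
        _grow_pores(spongy, spec.spongy_target_porosity, rng)
        vol_try = volume.copy()
        vol_try[:, j_sp0:j_sp1, :][spongy] = leg.airspace
        _carve_stomata(vol_try, spec, bounds, stoma_centers)
        if _airspace_connected(vol_try, leg):
            volume = vol_try
            break
    else:
        raise RuntimeError("could not connect spongy airspace to the stomata")

    h_pal = t_pal * vox
    stack, truth = _finalize(
        spec,
        volume,
        bounds,
        len(stoma_centers),
        analytic_theta=None,
        analytic_S_pal=_frustum_lateral(
            spec.palisade_radius_top_um, spec.palisade_radius_bottom_um, h_pal
        ),
        analytic_V_pal=_frustum_volume(
            spec.palisade_radius_top_um, spec.palisade_radius_bottom_um, h_pal
        ),
        palisade_radii=(spec.palisade_radius_top_um, spec.palisade_radius_bottom_um),
        palisade_bounds=(j_pal0, j_pal1 - 1),
    )
    return stack, truth


def _grow_pores(spongy_air: np.ndarray, target: float, rng: np.random.Generator) -> None:
    """Add spherical pores touching existing air until porosity >= target."""
    if target <= 0:
        return
    shape = spongy_air.shape
    total = spongy_air.size
    r_lo = 2.0
    r_hi = max(3.0, min(shape[1] / 2.0, 6.0))
    attempts = 0
    max_attempts = 20000
    while spongy_air.sum() / total < target and attempts < max_attempts:
        attempts += 1
        c = rng.uniform([0, 0, 0], [s - 1 for s in shape])
        r = rng.uniform(r_lo, r_hi)
        lo = np.maximum(np.floor(c - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + r + 2).astype(int), shape)
        sub = tuple(slice(lo[a], hi[a]) for a in range(3))
        gi, gj, gk = np.meshgrid(
            *[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"
        )
        sphere = (gi - c[0]) ** 2 + (gj - c[1]) ** 2 + (gk - c[2]) ** 2 <= r**2
        # connectivity guarantee: a pore must overlap already-connected air
        if not (spongy_air[sub] & sphere).any():
            continue
        spongy_air[sub] |= sphere


def _airspace_connected(volume: np.ndarray, legend: LabelLegend) -> bool:
    """True if every airspace voxel is reachable from some stoma voxel."""
    from scipy import ndimage

    air = volume == legend.airspace
    if not air.any():
        return True
    stoma = volume == legend.stoma
    reach = air | stoma
    labels, n = ndimage.label(reach, structure=np.ones((3, 3, 3), dtype=int))
    stoma_components = set(np.unique(labels[stoma])) - {0}
    air_components = set(np.unique(labels[air])) - {0}
    return air_components <= stoma_components


def two_stoma_symmetric_spec(**overrides) -> PhantomSpec:
    """Spec whose slab phantom holds exactly two mirror-symmetric stomata.

    The lateral extent along axis 0 is set to twice the stomatal pitch
    (two lattice sites mirrored about the axis-0 midplane) and to one
    pitch along axis 2 (a single site), which the symmetry tests of the
    vaporshed partition rely on.
    """
    params = dict(
        stoma_pitch_um=60.0,
        lateral_extent_um=(120.0, 60.0),
    )
    params.update(overrides)
    pitch = params["stoma_pitch_um"]
    params["lateral_extent_um"] = (2 * pitch, pitch)
    return PhantomSpec(**params)
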