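"""Reading, validating and orienting segmented leaf label stacks.

A leaf scan enters the pipeline as a 3D integer label volume (multi-page
TIFF) in which every voxel is assigned to one of seven tissue roles:
background, adaxial/abaxial epidermis, mesophyll cell, intercellular
airspace, vasculature or stomatal pore.  All downstream trait extraction
assumes the *canonical orientation*: axis 0 runs along the leaf length
(slice index), axis 1 is the leaf normal with the adaxial (upper) side at
low indices, and axis 2 runs across the leaf width.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "LabelLegend",
    "LabeledStack",
    "DEFAULT_LEGEND",
    "read_stack",
    "write_stack",
    "canonicalize",
]

#: Tissue roles every legend must define.
TISSUE_ROLES = (
    "background",
    "mesophyll_cell",
    "airspace",
    "epidermis_adaxial",
    "epidermis_abaxial",
    "vasculature",
    "stoma",
)


@dataclass(frozen=True)
class LabelLegend:
    """Mapping from tissue role to the integer label used in the volume.

    Labels must be distinct non-negative integers and background must be 0.
    """

    background: int = 0
    mesophyll_cell: int = 1
    airspace: int = 2
    epidermis_adaxial: int = 3
    epidermis_abaxial: int = 4
    vasculature: int = 5
    stoma: int = 6

    def __post_init__(self) -> None:
        values = [getattr(self, role) for role in TISSUE_ROLES]
        if self.background != 0:
            raise ValueError("background label must be 0")
        if any((not isinstance(v, (int, np.integer))) or v < 0 for v in values):
            raise ValueError("labels must be non-negative integers")
        if len(set(values)) != len(values):
            raise ValueError("labels must be distinct")

    def as_dict(self) -> dict[str, int]:
        return {role: int(getattr(self, role)) for role in TISSUE_ROLES}

    @classmethod
    def from_dict(cls, mapping: dict[str, int]) -> "LabelLegend":
        missing = set(TISSUE_ROLES) - set(mapping)
        if missing:
            raise ValueError(f"legend missing roles: {sorted(missing)}")
        return cls(**{k: int(v) for k, v in mapping.items() if k in TISSUE_ROLES})

    @property
    def known_labels(self) -> frozenset[int]:
        return frozenset(int(getattr(self, role)) for role in TISSUE_ROLES)

    def label(self, role: str) -> int:
        if role not in TISSUE_ROLES:
            raise KeyError(f"unknown tissue role {role!r}")
        return int(getattr(self, role))


DEFAULT_LEGEND = LabelLegend()


@dataclass
class LabeledStack:
    """A segmented 3D leaf volume with voxel-size metadata.

    Parameters
    ----------
    volume
        3D integer array of tissue labels.
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    legend
        The :class:`LabelLegend` decoding the integer labels.
    oriented
        True once the stack is in canonical orientation (adaxial side at
        low axis-1 indices).
    """

    volume: np.ndarray
    voxel_size_um: float
    legend: LabelLegend = field(default_factory=LabelLegend)
    oriented: bool = False

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.volume.ndim}D")
        if not np.issubdtype(self.volume.dtype, np.integer):
            raise TypeError(f"volume must have integer dtype, got {self.volume.dtype}")
        vs = self.voxel_size_um
        if np.ndim(vs) > 0:
            sizes = np.asarray(vs, dtype=float).ravel()
            if not np.allclose(sizes, sizes[0]):
                raise ValueError(f"anisotropic voxel sizes not supported: {sizes}")
            vs = float(sizes[0])
        self.voxel_size_um = float(vs)
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self.validate_labels()

    def validate_labels(self) -> None:
        present = np.unique(self.volume)
        unknown = sorted(set(int(v) for v in present) - self.legend.known_labels)
        if unknown:
            raise ValueError(
                f"volume contains labels absent from legend: {unknown}"
            )

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of voxels belonging to one tissue role."""
        return self.volume == self.legend.label(role)

    def label_counts(self) -> dict[str, int]:
        """Voxel count per tissue role."""
        return {
            role: int(np.count_nonzero(self.volume == self.legend.label(role)))
            for role in TISSUE_ROLES
        }

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_size_um**3

    def copy_with(self, **changes) -> "LabeledStack":
        return dataclasses.replace(self, **changes)


def read_stack(
    path: str | Path,
    legend: LabelLegend = DEFAULT_LEGEND,
    voxel_size_um: float = 1.0,
) -> LabeledStack:
    """Read a multi-page TIFF into a validated :class:`LabeledStack`.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    TypeError
        If the TIFF does not hold an integer pixel type.
    ValueError
        If the volume contains labels absent from *legend* (the error
        message lists the offending labels).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    volume = tifffile.imread(path)
    if volume.ndim == 2:
        volume = volume[np.newaxis]
    if not np.issubdtype(volume.dtype, np.integer):
        raise TypeError(
            f"{path.name}: expected integer pixel type, got {volume.dtype}"
        )
    return LabeledStack(volume=volume, voxel_size_um=voxel_size_um, legend=legend)


def write_stack(stack: LabeledStack, path: str | Path) -> Path:
    """Write a stack as a lossless multi-page TIFF (one page per axis-0 slice)."""
    path = Path(path)
    if stack.volume.shape[0] == 0:
        raise ValueError("cannot write an empty (0-slice) stack")
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    max_label = int(stack.volume.max(initial=0))
    dtype = np.uint8 if max_label < 256 else np.uint16
    tifffile.imwrite(path, stack.volume.astype(dtype), photometric="minisblack")
    return path


def _centroid_along(mask: np.ndarray, axis: int) -> float:
    coords = np.nonzero(mask)[axis]
    return float(coords.mean())


def canonicalize(stack: LabeledStack) -> LabeledStack:
    """Permute/flip axes so the leaf normal is axis 1 with adaxial side first.

    The leaf normal is identified as the axis along which the adaxial and
    abaxial epidermis centroids are farthest apart (in voxel units); the
    stack is then flipped if needed so the adaxial centroid sits at the
    lower axis-1 index.  Only axis permutations and flips are applied, so
    per-label voxel counts are preserved exactly.
    """
    ad = stack.mask("epidermis_adaxial")
    ab = stack.mask("epidermis_abaxial")
    if not ad.any() or not ab.any():
        raise ValueError(
            "cannot canonicalize: both epidermis labels must be present"
        )
    separations = [
        abs(_centroid_along(ad, axis) - _centroid_along(ab, axis))
        for axis in range(3)
    ]
    normal_axis = int(np.argmax(separations))
    order = [a for a in range(3) if a != normal_axis]
    order.insert(1, normal_axis)
    volume = np.transpose(stack.volume, order)
    ad_c = _centroid_along(np.transpose(ad, order), 1)
    ab_c = _centroid_along(np.transpose(ab, order), 1)
    if ad_c > ab_c:
        volume = volume[:, ::-1, :]
    return stack.copy_with(volume=np.ascontiguousarray(volume), oriented=True)
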