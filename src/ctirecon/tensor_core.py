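"""Symmetric 3x3 tensor fields and their eigen-algebra.

A tensor field stores one symmetric 3x3 matrix per voxel as its 6 unique
components in the fixed order ``(xx, xy, xz, yy, yz, zz)``.  The same
container is used for water diffusion tensors (mm^2/s) and electrical
conductivity tensors (S/m); the :class:`Quantity` tag keeps the two from
being mixed in arithmetic.

Unit conventions used throughout the package:

* diffusivities are in mm^2/s,
* b-values in s/mm^2,
* conductivities in S/m.

A scale factor ``eta`` multiplying a diffusion tensor into a conductivity
tensor therefore carries units S*s/(m*mm^2).  Literature values quoted in
S*s/mm^3 are converted on ingestion by the factor 1000 (S/mm -> S/m), see
:data:`ctirecon.models.S_S_PER_MM3_TO_INTERNAL`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed storage order of the 6 unique components.
COMPONENT_ORDER = ("xx", "xy", "xz", "yy", "yz", "zz")

#: Index map from (row, col) of the full matrix into the 6-vector.
_MAT_IDX = np.array([[0, 1, 2], [1, 3, 4], [2, 4, 5]])

#: Negative eigenvalues within ``-PSD_TOL * lambda_max`` are clamped to 0;
#: anything more negative is a hard error.
PSD_TOL = 1e-12


class Quantity(str, enum.Enum):
    """Physical quantity carried by a tensor field."""

    DIFFUSION = "diffusion_mm2_per_s"
    CONDUCTIVITY = "conductivity_S_per_m"


def _as_quantity(q) -> Quantity:
    return q if isinstance(q, Quantity) else Quantity(q)


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 tensor volume.

    Parameters
    ----------
    values
        Array of shape ``(*grid_shape, 6)`` holding the unique components
        in :data:`COMPONENT_ORDER`.
    quantity
        Physical quantity tag; arithmetic between different quantities is
        rejected.
    voxel_size_mm
        Spatial resolution, one entry per grid axis.
    mask
        Boolean validity flag of shape ``grid_shape``.  Masked-out voxels
        carry arbitrary values and are excluded from every computation.
    """

    values: np.ndarray
    quantity: Quantity
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim < 1 or self.values.shape[-1] != 6:
            raise ValueError(
                f"tensor values must have a trailing axis of 6 components, "
                f"got shape {self.values.shape}"
            )
        self.quantity = _as_quantity(self.quantity)
        if self.mask is None:
            self.mask = np.ones(self.grid_shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match grid "
                    f"{self.grid_shape}"
                )

    # ------------------------------------------------------------------
    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[:-1]

    def as_matrices(self) -> np.ndarray:
        """Full symmetric matrices, shape ``(*grid_shape, 3, 3)``."""
        return self.values[..., _MAT_IDX]

    @classmethod
    def from_matrices(cls, matrices, quantity, voxel_size_mm=(1.0, 1.0, 1.0),
                      mask=None, symmetry_tol=1e-10) -> "TensorField":
        """Build a field from full 3x3 matrices, checking symmetry."""
        matrices = np.asarray(matrices, dtype=float)
        if matrices.shape[-2:] != (3, 3):
            raise ValueError("expected trailing (3, 3) matrix axes")
        asym = np.abs(matrices - np.swapaxes(matrices, -1, -2))
        scale = np.maximum(np.abs(matrices).max(axis=(-2, -1), keepdims=True), 1.0)
        if np.any(asym > symmetry_tol * scale):
            raise ValueError("input matrices are not symmetric within tolerance")
        sym = 0.5 * (matrices + np.swapaxes(matrices, -1, -2))
        vals = np.stack(
            [sym[..., 0, 0], sym[..., 0, 1], sym[..., 0, 2],
             sym[..., 1, 1], sym[..., 1, 2], sym[..., 2, 2]],
            axis=-1,
        )
        return cls(vals, quantity, voxel_size_mm, mask)

    # -- arithmetic with quantity guard --------------------------------
    def _check_compatible(self, other: "TensorField"):
        if not isinstance(other, TensorField):
            raise TypeError("expected a TensorField")
        if self.quantity != other.quantity:
            raise ValueError(
                f"cannot mix quantities {self.quantity.value} and "
                f"{other.quantity.value}"
            )
        if self.grid_shape != other.grid_shape:
            raise ValueError("grid shapes differ")

    def __add__(self, other: "TensorField") -> "TensorField":
        self._check_compatible(other)
        return replace(self, values=self.values + other.values,
                       mask=self.mask & other.mask)

    def __sub__(self, other: "TensorField") -> "TensorField":
        self._check_compatible(other)
        return replace(self, values=self.values - other.values,
                       mask=self.mask & other.mask)

    def scaled(self, factor, quantity=None) -> "TensorField":
        """Multiply by a scalar or per-voxel scalar map.

        ``quantity`` must be given when the factor changes the physical
        quantity (e.g. a diffusion-to-conductivity scale factor).
        """
        factor = np.asarray(factor, dtype=float)
        if factor.ndim > 0:
            if factor.shape != self.grid_shape:
                raise ValueError("factor map shape does not match grid")
            factor = factor[..., None]
        q = self.quantity if quantity is None else _as_quantity(quantity)
        return TensorField(self.values * factor, q, self.voxel_size_mm,
                           self.mask.copy())


@dataclass
class EigenField:
    """Per-voxel eigendecomposition of a :class:`TensorField`.

    ``eigenvalues`` are sorted descending (longitudinal first);
    ``eigenvectors[..., :, k]`` is the unit eigenvector of
    ``eigenvalues[..., k]``.  Masked-out voxels carry NaN sentinels.
    """

    eigenvalues: np.ndarray      # (*grid, 3), descending
    eigenvectors: np.ndarray     # (*grid, 3, 3), columns are eigenvectors
    source_quantity: Quantity
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.source_quantity = _as_quantity(self.source_quantity)
        if self.mask is None:
            self.mask = np.ones(self.eigenvalues.shape[:-1], dtype=bool)

    @property
    def grid_shape(self) -> tuple:
        return self.eigenvalues.shape[:-1]


# ----------------------------------------------------------------------
def eig_decompose(tensor_field: TensorField) -> EigenField:
    """Per-voxel eigendecomposition with descending eigenvalue sort.

    Raises on non-finite entries at masked-in voxels and on eigenvalues
    more negative than ``-PSD_TOL`` times the largest eigenvalue of the
    same voxel; small negatives within that tolerance are clamped to 0.
    """
    vals = tensor_field.values
    mask = tensor_field.mask
    bad = ~np.isfinite(vals).all(axis=-1) & mask
    if bad.any():
        voxel = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite tensor entries at masked-in voxel {voxel}")

    mats = tensor_field.as_matrices().copy()
    # Masked-out voxels may hold garbage; substitute identity so eigh is safe.
    mats[~mask] = np.eye(3)
    w, v = np.linalg.eigh(mats)          # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]

    lam_max = np.maximum(np.abs(w).max(axis=-1, keepdims=True), 0.0)
    floor = -PSD_TOL * np.maximum(lam_max, np.finfo(float).tiny)
    too_negative = (w < floor) & mask[..., None]
    if too_negative.any():
        voxel = tuple(int(i) for i in np.argwhere(too_negative.any(axis=-1))[0])
        raise ValueError(
            f"tensor at voxel {voxel} is not positive semidefinite "
            f"(eigenvalue below {-PSD_TOL} * lambda_max)"
        )
    w = np.where(w < 0.0, 0.0, w)

    w = np.where(mask[..., None], w, np.nan)
    v = np.where(mask[..., None, None], v, np.nan)
    return EigenField(w, v, tensor_field.quantity,
                      tensor_field.voxel_size_mm, mask.copy())


def compose_tensor(eigen_field: EigenField, orthonormal_tol: float = 1e-8) -> TensorField:
    """Rebuild ``S diag(lambda) S^T`` from an eigen field."""
    v = eigen_field.eigenvectors
    w = eigen_field.eigenvalues
    mask = eigen_field.mask

    v_safe = np.where(mask[..., None, None], v, np.eye(3))
    gram = np.einsum("...ki,...kj->...ij", v_safe, v_safe)
    err = np.abs(gram - np.eye(3)).max(axis=(-2, -1))
    if np.any(err[mask] > orthonormal_tol):
        voxel = tuple(int(i) for i in np.argwhere((err > orthonormal_tol) & mask)[0])
        raise ValueError(f"eigenvector triad at voxel {voxel} is not orthonormal")

    w_safe = np.where(mask[..., None], w, 0.0)
    mats = np.einsum("...ik,...k,...jk->...ij", v_safe, w_safe, v_safe)
    return TensorField.from_matrices(
        mats, eigen_field.source_quantity, eigen_field.voxel_size_mm,
        mask.copy(), symmetry_tol=1e-8)


def mean_scalar(tensor_field: TensorField) -> np.ndarray:
    """Per-voxel mean eigenvalue ``(l1 + l2 + l3)/3 = trace/3``.

    This is the mean diffusivity for diffusion tensors and ``sigma_L``
    (mean conductivity) for conductivity tensors.  NaN on masked-out
    voxels.
    """
    v = tensor_field.values
    out = (v[..., 0] + v[..., 3] + v[..., 5]) / 3.0
    return np.where(tensor_field.mask, out, np.nan)


def anisotropy_ratio(tensor_field: TensorField) -> np.ndarray:
    """Per-voxel anisotropy ratio ``2*l1 / (l2 + l3)`` of the eigenvalues.

    Equals 1 for isotropic tensors.  Voxels whose transversal eigenvalue
    sum is zero get a NaN sentinel and a warning.
    """
    eig = eig_decompose(tensor_field)
    lam = eig.eigenvalues
    denom = lam[..., 1] + lam[..., 2]
    zero = (denom <= 0.0) & tensor_field.mask
    if zero.any():
        warnings.warn(
            f"anisotropy_ratio: {int(zero.sum())} voxel(s) with zero "
            f"transversal eigenvalue sum set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = 2.0 * lam[..., 0] / denom
    ar = np.where(zero, np.nan, ar)
    return np.where(tensor_field.mask, ar, np.nan)


def isotropic_field(scalar_map, quantity, voxel_size_mm=(1.0, 1.0, 1.0),
                    mask=None) -> TensorField:
    """Build ``scalar * I`` tensors from a per-voxel scalar map."""
    scalar_map = np.asarray(scalar_map, dtype=float)
    vals = np.zeros(scalar_map.shape + (6,))
    vals[..., 0] = scalar_map
    vals[..., 3] = scalar_map
    vals[..., 5] = scalar_map
    return TensorField(vals, quantity, voxel_size_mm, mask)
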