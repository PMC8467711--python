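"""Synthetic phantoms, brain-like objects and forward signal simulation.

Generates ground-truth conductivity/diffusion tensor pairs with known
extracellular volume fraction and apparent extracellular ion
concentration, then forward-simulates everything the reconstruction
models consume:

* multi-b diffusion-weighted stacks via the two-compartment
  bi-exponential signal model (fast extracellular tensor component plus
  slow intracellular isotropic component), and
* the high-frequency conductivity map via the concentration-mobility
  relation ``sigma_H = ce * (alpha*dew + (1-alpha)*diw*beta)``.

The ground truth satisfies ``C = alpha * ce * De`` voxelwise, so the CTI
reconstruction chain inverts it algebraically at zero noise.

The six built-in phantom compartments (EL1..EL4, GVS1, GVS2) mirror a
published three-compartment phantom pair: NaCl concentration, CuSO4
dopant, extracellular volume fraction, mobility class and reference
conductivity at 10 Hz.  Absolute ion concentrations are not published;
``ce`` is back-solved per compartment so the mean conductivity of the
ground-truth tensor equals the quoted reference value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tensor_core import Quantity, TensorField, isotropic_field, mean_scalar

# Default diffusivities (mm^2/s).  The phantom recipe states only the
# mobility class, not diffusivities; these stand-ins are configurable.
DEW_HIGH_MOBILITY = 2.0e-3
DEW_LOW_MOBILITY = 1.1e-3
DIW_DEFAULT = 0.4e-3

#: Ratio of intracellular to extracellular ion concentration effect.
BETA_DEFAULT = 0.41

#: Multi-b acquisition protocol (s/mm^2).
DEFAULT_B_VALUES = (50.0, 150.0, 300.0, 500.0, 700.0, 1000.0, 1400.0,
                    1800.0, 2200.0, 2600.0, 3000.0, 3600.0, 4000.0,
                    4500.0, 5000.0)

#: Literature isotropic conductivities (S/m) for brain tissue.
SIGMA_WM, SIGMA_GM, SIGMA_CSF = 0.14, 0.27, 1.79


# ----------------------------------------------------------------------
# gradient direction sets
# ----------------------------------------------------------------------
def icosahedral6() -> np.ndarray:
    """Six icosahedral vertex directions.

    The set is a tight frame: ``mean(u u^T) = I/3`` exactly, so the mean
    of directional diffusivities ``u^T D u`` equals ``trace(D)/3``.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    raw = np.array([
        [0.0, 1.0, phi], [0.0, -1.0, phi],
        [1.0, phi, 0.0], [-1.0, phi, 0.0],
        [phi, 0.0, 1.0], [phi, 0.0, -1.0],
    ])
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` roughly uniform unit directions on the half-sphere."""
    i = np.arange(n) + 0.5
    z = i / n                       # upper half-sphere
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z ** 2)
    dirs = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def default_directions(n: int = 6) -> np.ndarray:
    return icosahedral6() if n == 6 else fibonacci_sphere(n)


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CompartmentSpec:
    """One phantom compartment: composition, geometry and ground truth."""

    name: str
    nacl_g_per_L: float
    cuso4_g_per_L: float
    extracellular_volume_fraction: float
    mobility_class: str                       # "high" | "low"
    sigma_ref_S_per_m: float
    dew_mm2_per_s: float | None = None        # default from mobility class
    diw_mm2_per_s: float = DIW_DEFAULT
    shape: tuple | None = None                # ("cylinder", cx, cy, r) fractions

    def __post_init__(self):
        a = self.extracellular_volume_fraction
        if not 0.0 < a <= 1.0:
            raise ValueError(f"{self.name}: alpha must be in (0, 1], got {a}")
        if self.mobility_class not in ("high", "low"):
            raise ValueError(f"{self.name}: unknown mobility class "
                             f"{self.mobility_class!r}")
        if self.sigma_ref_S_per_m <= 0:
            raise ValueError(f"{self.name}: sigma_ref must be positive")
        if self.dew < self.diw_mm2_per_s:
            raise ValueError(f"{self.name}: dew must be >= diw")

    @property
    def dew(self) -> float:
        if self.dew_mm2_per_s is not None:
            return self.dew_mm2_per_s
        return (DEW_HIGH_MOBILITY if self.mobility_class == "high"
                else DEW_LOW_MOBILITY)


# Phantom compartment recipes (NaCl g/L, CuSO4 g/L, alpha, mobility, sigma_ref).
EL1 = CompartmentSpec("EL1", 7.5, 0.0, 1.00, "high", 1.56)
EL2 = CompartmentSpec("EL2", 3.5, 1.0, 1.00, "high", 0.83)
GVS1 = CompartmentSpec("GVS1", 7.5, 0.0, 0.10, "high", 0.29)
EL3 = CompartmentSpec("EL3", 3.0, 0.0, 1.00, "low", 0.55)
EL4 = CompartmentSpec("EL4", 3.0, 0.0, 1.00, "high", 0.70)
GVS2 = CompartmentSpec("GVS2", 3.0, 0.0, 0.50, "low", 0.45)

PHANTOM_PRESETS = {
    "phantom1": (EL1, EL2, GVS1),
    "phantom2": (EL3, EL4, GVS2),
}

# Default cylinder layout: three parallel cylinders in a triangle.
_DEFAULT_LAYOUT = (
    ("cylinder", 0.50, 0.735, 0.155),
    ("cylinder", 0.295, 0.38, 0.155),
    ("cylinder", 0.705, 0.38, 0.155),
)


@dataclass
class GroundTruth:
    """Known tensors and scalar maps of a simulated object."""

    C_true: TensorField                 # S/m
    D_true: TensorField                 # extracellular diffusion tensor, mm^2/s
    alpha_map: np.ndarray               # extracellular volume fraction
    ce_map: np.ndarray                  # apparent extracellular ion concentration
    sigmaH_map: np.ndarray              # high-frequency conductivity, S/m
    labels: np.ndarray                  # compartment/tissue id, 0 = background
    label_names: dict                   # id -> name
    dew_map: np.ndarray                 # scalar extracellular diffusivity
    diw_map: np.ndarray                 # scalar intracellular diffusivity
    beta: float = BETA_DEFAULT
    compartments: tuple = ()
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def grid_shape(self) -> tuple:
        return self.labels.shape

    def roi_masks(self) -> dict:
        return {name: self.labels == lid
                for lid, name in self.label_names.items()}

    def spec_sheet(self) -> pd.DataFrame:
        """Machine-readable table of compartment parameters."""
        rows = []
        for lid, name in self.label_names.items():
            roi = self.labels == lid
            spec = next((s for s in self.compartments if s.name == name), None)
            row = {
                "name": name,
                "alpha": float(np.mean(self.alpha_map[roi])),
                "ce": float(np.mean(self.ce_map[roi])),
                "sigma_H_S_per_m": float(np.mean(self.sigmaH_map[roi])),
                "sigma_L_S_per_m": float(np.nanmean(mean_scalar(self.C_true)[roi])),
                "dew_mm2_per_s": float(np.mean(self.dew_map[roi])),
                "diw_mm2_per_s": float(np.mean(self.diw_map[roi])),
                "n_voxels": int(roi.sum()),
            }
            if spec is not None:
                row.update({
                    "nacl_g_per_L": spec.nacl_g_per_L,
                    "cuso4_g_per_L": spec.cuso4_g_per_L,
                    "extracellular_volume_fraction_pct": 100.0 * spec.extracellular_volume_fraction,
                    "mobility": spec.mobility_class,
                    "sigma_ref_S_per_m": spec.sigma_ref_S_per_m,
                })
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class MultiBStack:
    """Multi-b diffusion-weighted signal stack.

    ``signals[..., k]`` is the diffusion-weighted image of acquisition
    ``k`` with b-value ``b_values[k]`` (> 0) along unit direction
    ``directions[k]``; ``s0`` is the unweighted (b=0) image.
    """

    signals: np.ndarray            # (*grid, n_acq)
    b_values_s_per_mm2: np.ndarray  # (n_acq,)
    directions: np.ndarray          # (n_acq, 3), unit norm
    s0: np.ndarray                  # (*grid,)
    mask: np.ndarray | None = None
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.b_values_s_per_mm2 = np.asarray(self.b_values_s_per_mm2, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        n = self.signals.shape[-1]
        if self.b_values_s_per_mm2.shape != (n,):
            raise ValueError("b_values length does not match signal count")
        if self.directions.shape != (n, 3):
            raise ValueError("directions shape does not match signal count")
        if np.any(self.b_values_s_per_mm2 <= 0):
            raise ValueError("b-values must be strictly positive (b=0 lives in s0)")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("gradient directions must be unit norm within 1e-8")
        if self.mask is None:
            self.mask = np.ones(self.grid_shape, dtype=bool)
        if np.any(self.signals[self.mask] < 0):
            raise ValueError("signals must be nonnegative")
        if np.any(self.s0[self.mask] <= 0):
            raise ValueError("s0 must be positive on masked-in voxels")

    @property
    def grid_shape(self) -> tuple:
        return self.signals.shape[:-1]

    @property
    def n_acquisitions(self) -> int:
        return self.signals.shape[-1]


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------
def _cylinder_mask(grid_shape, cx_frac, cy_frac, r_frac) -> np.ndarray:
    nx, ny = grid_shape[0], grid_shape[1]
    scale = min(nx, ny)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dist2 = (x - cx_frac * nx) ** 2 + (y - cy_frac * ny) ** 2
    in_plane = dist2 <= (r_frac * scale) ** 2
    return np.broadcast_to(in_plane[..., None], grid_shape).copy()


def make_phantom(specs, grid_shape=(64, 64, 64), seed: int = 0,
                 beta: float = BETA_DEFAULT,
                 voxel_size_mm=(1.0, 1.0, 1.0)) -> GroundTruth:
    """Build a multi-compartment phantom with isotropic ground truth.

    Each compartment gets an isotropic extracellular diffusion tensor
    (diffusivity from its mobility class), the stated extracellular
    volume fraction, and an apparent ion concentration back-solved so
    that ``mean_scalar(C_true)`` equals its reference conductivity.
    """
    specs = tuple(specs)
    if isinstance(specs, str):
        raise TypeError("pass a sequence of CompartmentSpec")
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 4:
        raise ValueError(f"degenerate grid {grid_shape}")

    labels = np.zeros(grid_shape, dtype=np.int32)
    label_names = {}
    for i, spec in enumerate(specs):
        shape = spec.shape or _DEFAULT_LAYOUT[i % len(_DEFAULT_LAYOUT)]
        if shape[0] != "cylinder":
            raise ValueError(f"unsupported shape {shape[0]!r}")
        m = _cylinder_mask(grid_shape, *shape[1:])
        if np.any(labels[m] != 0):
            raise ValueError(
                f"compartment {spec.name!r} overlaps a previous compartment")
        labels[m] = i + 1
        label_names[i + 1] = spec.name

    alpha = np.ones(grid_shape)
    ce = np.zeros(grid_shape)
    dew = np.zeros(grid_shape)
    diw = np.zeros(grid_shape)
    for i, spec in enumerate(specs):
        roi = labels == i + 1
        a = spec.extracellular_volume_fraction
        alpha[roi] = a
        dew[roi] = spec.dew
        diw[roi] = spec.diw_mm2_per_s
        # mean_scalar(C) = alpha * ce * dew  for isotropic De = dew * I
        ce[roi] = spec.sigma_ref_S_per_m / (a * spec.dew)

    mask = labels > 0
    D_true = isotropic_field(dew, Quantity.DIFFUSION, voxel_size_mm, mask)
    C_true = D_true.scaled(alpha * ce, Quantity.CONDUCTIVITY)
    sigmaH = ce * (alpha * dew + (1.0 - alpha) * diw * beta)
    return GroundTruth(C_true, D_true, alpha, ce, sigmaH, labels, label_names,
                       dew, diw, beta, specs, tuple(voxel_size_mm))


def make_phantom_preset(name: str, grid_shape=(64, 64, 64), seed: int = 0,
                        **kwargs) -> GroundTruth:
    """Build one of the two built-in three-compartment phantoms."""
    if name not in PHANTOM_PRESETS:
        raise KeyError(f"unknown phantom preset {name!r}; "
                       f"choose from {sorted(PHANTOM_PRESETS)}")
    return make_phantom(PHANTOM_PRESETS[name], grid_shape, seed, **kwargs)


def make_brain(grid_shape=(64, 64, 8),
               wm_eigenvalues=(1.7e-3, 0.4e-3, 0.3e-3),
               seed: int = 0,
               beta: float = BETA_DEFAULT,
               ce_variation: float = 0.2,
               voxel_size_mm=(1.0, 1.0, 1.0)):
    """Brain-like object: anisotropic WM annulus, isotropic GM shell, CSF core.

    WM fibers run circumferentially around the grid axis (principal
    eigenvector tangential in-plane), so the principal direction varies
    smoothly across the region.  The apparent ion concentration is
    modulated by a smooth random field of relative amplitude
    ``ce_variation`` (renormalised to tissue mean 1, so tissue-mean
    conductivities stay exactly at the literature anchors 0.14 / 0.27 /
    1.79 S/m for WM / GM / CSF).

    Returns ``(GroundTruth, masks)`` with ``masks`` a dict of boolean
    WM/GM/CSF volumes.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 4 or min(grid_shape[:2]) < 16:
        raise ValueError(f"grid {grid_shape} too small for three nested regions")
    wm_eigenvalues = np.asarray(wm_eigenvalues, dtype=float)
    if wm_eigenvalues.shape != (3,) or np.any(wm_eigenvalues <= 0):
        raise ValueError("wm_eigenvalues must be three positive diffusivities")

    nx, ny, nz = grid_shape
    x, y = np.meshgrid(np.arange(nx) - (nx - 1) / 2.0,
                       np.arange(ny) - (ny - 1) / 2.0, indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2)
    scale = min(nx, ny) / 2.0
    csf2d = r <= 0.15 * scale
    wm2d = (r > 0.15 * scale) & (r <= 0.55 * scale)
    gm2d = (r > 0.55 * scale) & (r <= 0.85 * scale)

    def extrude(m2d):
        return np.broadcast_to(m2d[..., None], grid_shape).copy()

    masks = {"CSF": extrude(csf2d), "WM": extrude(wm2d), "GM": extrude(gm2d)}
    labels = np.zeros(grid_shape, dtype=np.int32)
    label_names = {1: "WM", 2: "GM", 3: "CSF"}
    labels[masks["WM"]] = 1
    labels[masks["GM"]] = 2
    labels[masks["CSF"]] = 3
    mask = labels > 0

    # Tissue parameters: alpha, isotropic dew (mean diffusivity), diw, target sigma.
    # diw is kept well below the smallest WM eigenvalue: where the
    # directional extracellular diffusivity equals diw the two decay
    # components merge and the fit cannot identify alpha.
    tissue = {
        "WM": dict(alpha=0.30, diw=0.1e-3, sigma=SIGMA_WM),
        "GM": dict(alpha=0.40, dew=1.0e-3, diw=0.1e-3, sigma=SIGMA_GM),
        "CSF": dict(alpha=1.00, dew=3.0e-3, diw=0.0, sigma=SIGMA_CSF),
    }
    tissue["WM"]["dew"] = float(wm_eigenvalues.mean())

    # WM tensor: principal axis tangential, middle radial, smallest axial.
    phi = np.arctan2(y, x)
    e1 = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=-1)
    e2 = np.stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=-1)
    e3 = np.broadcast_to(np.array([0.0, 0.0, 1.0]), e1.shape)
    wm_mat2d = (wm_eigenvalues[0] * e1[..., :, None] * e1[..., None, :]
                + wm_eigenvalues[1] * e2[..., :, None] * e2[..., None, :]
                + wm_eigenvalues[2] * e3[..., :, None] * e3[..., None, :])
    mats = np.zeros(grid_shape + (3, 3))
    mats[...] = np.eye(3) * 1e-3            # background placeholder
    mats[masks["WM"]] = np.broadcast_to(
        wm_mat2d[:, :, None, :, :], grid_shape + (3, 3))[masks["WM"]]
    for name in ("GM", "CSF"):
        mats[masks[name]] = np.eye(3) * tissue[name]["dew"]

    alpha = np.ones(grid_shape)
    dew = np.full(grid_shape, 1e-3)
    diw = np.zeros(grid_shape)
    ce = np.zeros(grid_shape)

    # Smooth multiplicative ce modulation with tissue mean exactly 1.
    rng = np.random.default_rng(seed)
    if ce_variation > 0:
        kx, ky = rng.uniform(0.5, 1.5, size=2)
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        mod2d = np.sin(2 * np.pi * kx * x / nx + px) * np.sin(2 * np.pi * ky * y / ny + py)
        mod = 1.0 + ce_variation * extrude(mod2d) / max(np.abs(mod2d).max(), 1e-12)
    else:
        mod = np.ones(grid_shape)

    for name, par in tissue.items():
        roi = masks[name]
        alpha[roi] = par["alpha"]
        dew[roi] = par["dew"]
        diw[roi] = par["diw"]
        m = mod[roi] / mod[roi].mean()
        ce[roi] = par["sigma"] / (par["alpha"] * par["dew"]) * m

    D_true = TensorField.from_matrices(mats, Quantity.DIFFUSION,
                                       voxel_size_mm, mask)
    C_true = D_true.scaled(alpha * ce, Quantity.CONDUCTIVITY)
    sigmaH = ce * (alpha * dew + (1.0 - alpha) * diw * beta)
    truth = GroundTruth(C_true, D_true, alpha, ce, sigmaH, labels, label_names,
                        dew, diw, beta, (), tuple(voxel_size_mm))
    return truth, masks


# ----------------------------------------------------------------------
# forward simulation
# ----------------------------------------------------------------------
def simulate_dwi(truth: GroundTruth, b_values=DEFAULT_B_VALUES,
                 directions=None, noise_sd: float = 0.0, seed: int = 0,
                 s0_value: float = 1000.0) -> MultiBStack:
    """Forward-simulate the bi-exponential multi-b DWI stack.

    Per acquisition ``(b, u)`` the signal ratio is
    ``alpha * exp(-b u^T De u) + (1 - alpha) * exp(-b diw)``.
    ``noise_sd`` adds voxelwise Gaussian noise (in signal units, clipped
    at zero); use :func:`add_rician_noise` for magnitude-MRI noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    b_values = np.asarray(b_values, dtype=float)
    if directions is None:
        directions = icosahedral6()
    directions = np.asarray(directions, dtype=float)
    if b_values.size == 0 or directions.size == 0:
        raise ValueError("b_values and directions must be non-empty")
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)

    # full shell x direction sampling
    bb = np.repeat(b_values, len(directions))
    uu = np.tile(directions, (len(b_values), 1))

    mats = truth.D_true.as_matrices()
    mask = truth.mask
    adc = np.einsum("ki,...ij,kj->...k", uu, mats, uu)     # (*grid, n_acq)
    alpha = truth.alpha_map[..., None]
    ratio = (alpha * np.exp(-bb * adc)
             + (1.0 - alpha) * np.exp(-bb * truth.diw_map[..., None]))

    s0 = np.where(mask, s0_value, 0.0).astype(float)
    # keep s0 positive everywhere so MultiBStack validation of background rows
    # is driven by the mask, not by zero divisions downstream
    s0[~mask] = s0_value
    signals = s0[..., None] * ratio
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signals = np.clip(signals + rng.normal(0.0, noise_sd, signals.shape), 0.0, None)
    return MultiBStack(signals, bb, uu, s0, mask.copy(), truth.voxel_size_mm)


def simulate_sigma_h(truth: GroundTruth, noise_sd: float = 0.0,
                     seed: int = 0) -> np.ndarray:
    """High-frequency conductivity map from the ground-truth maps."""
    if truth.beta <= 0:
        raise ValueError("beta must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    sigma_h = truth.ce_map * (truth.alpha_map * truth.dew_map
                              + (1.0 - truth.alpha_map) * truth.diw_map * truth.beta)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma_h = sigma_h + rng.normal(0.0, noise_sd, sigma_h.shape)
    return sigma_h


def add_rician_noise(stack: MultiBStack, snr: float, seed: int = 0) -> MultiBStack:
    """Magnitude-MRI (Rician) noise: ``sqrt((s + n1)^2 + n2^2)``.

    ``n1, n2`` are independent zero-mean Gaussians with standard
    deviation ``mean(s0 on mask) / snr``; applied to the weighted
    signals and to s0.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    sd = float(np.mean(stack.s0[stack.mask])) / snr
    rng = np.random.default_rng(seed)

    def rice(arr):
        n1 = rng.normal(0.0, sd, arr.shape)
        n2 = rng.normal(0.0, sd, arr.shape)
        return np.sqrt((arr + n1) ** 2 + n2 ** 2)

    return replace(stack, signals=rice(stack.signals), s0=rice(stack.s0))
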