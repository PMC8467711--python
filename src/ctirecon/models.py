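"""The five conductivity tensor reconstructions: LEM, FEM, VCM, VFM, CTI.

All five share the premise that the conductivity tensor C and the water
diffusion tensor D have the same eigenvectors; they differ in how the
scale between the two is determined:

* LEM — a single global scale factor, either the empirical literature
  constant 0.844 S*s/mm^3 or matched from tissue-mean diffusivities and
  reference conductivities.
* FEM — a global constant derived from force equilibrium,
  ``0.76 q^2 N / (kB T)``, applied to the fast (extracellular) diffusion
  tensor of a bi-exponential fit.
* VCM — a per-voxel scale constraining ``trace(C) = 3 sigma_iso`` with a
  literature (or measured) isotropic conductivity per tissue.
* VFM — eigenvalues of C as volume-fraction-weighted sums of literature
  compartment conductivities; fractions solved from a linear system in
  exponentials of literature diffusivities.  WM only; GM/CSF take
  literature isotropic values.
* CTI — a per-voxel scale ``alpha * sigma_H / (alpha dew + (1-alpha)
  diw beta)`` from the high-frequency conductivity and the multi-b fit.

Internal scale factors carry units S*s/(m*mm^2): conductivities are S/m
and diffusivities mm^2/s throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .multib_fit import BiexpFitField
from .tensor_core import (EigenField, Quantity, TensorField, compose_tensor,
                          eig_decompose, isotropic_field)

#: Conversion of literature scale factors quoted in S*s/mm^3 to the
#: internal S*s/(m*mm^2) convention (1 S/mm = 1000 S/m).
S_S_PER_MM3_TO_INTERNAL = 1000.0

#: Conversion of an SI scale factor (S*s/m^3, i.e. sigma[S/m] per d[m^2/s])
#: to the internal convention (d in mm^2/s): 1 mm^2/s = 1e-6 m^2/s.
SI_PER_M3_TO_INTERNAL = 1e-6


@dataclass
class LiteratureConstants:
    """Every literature constant consumed by the five models.

    The VFM compartment conductivities/diffusivities are not published
    in the source comparison (cited to earlier work); the defaults below
    are configurable stand-ins.
    """

    sigma_wm: float = 0.14            # S/m
    sigma_gm: float = 0.27            # S/m
    sigma_csf: float = 1.79           # S/m
    eta_empirical: float = 0.844      # S*s/mm^3, converted on use
    q: float = 1.6e-19                # C
    N: float = 2.0e25                 # m^-3
    kBT: float = 4.1e-21              # J
    fem_prefactor: float = 0.76
    beta: float = 0.41
    # VFM literature compartments (stand-in defaults, sigma_t1W = sigma_t2W)
    vfm_sigma_lW: float = 1.1         # S/m
    vfm_sigma_tW: float = 0.13        # S/m
    vfm_sigma_iso: float = 0.27       # S/m
    vfm_d_lW: float = 1.7e-3          # mm^2/s
    vfm_d_tW: float = 0.3e-3          # mm^2/s
    vfm_d_iso: float = 0.8e-3         # mm^2/s
    vfm_b: float = 700.0              # s/mm^2

    def __post_init__(self):
        positive = ("sigma_wm", "sigma_gm", "sigma_csf", "eta_empirical",
                    "q", "N", "kBT", "fem_prefactor", "vfm_sigma_lW",
                    "vfm_sigma_tW", "vfm_sigma_iso", "vfm_d_lW", "vfm_d_tW",
                    "vfm_d_iso", "vfm_b")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScaleFactorField:
    """Scale factor eta between diffusion and conductivity tensors.

    ``eta`` is in internal units S*s/(m*mm^2); scalar for global models
    (LEM, FEM), a per-voxel map for VCM and CTI.
    """

    eta: np.ndarray | float
    scope: str                       # "global" | "per_voxel"
    model: str                       # "LEM" | "FEM" | "VCM" | "CTI"

    def __post_init__(self):
        eta = np.asarray(self.eta, dtype=float)
        if np.any(eta[np.isfinite(eta)] <= 0):
            raise ValueError("eta must be positive wherever defined")


# ----------------------------------------------------------------------
# LEM
# ----------------------------------------------------------------------
def lem_scale_factor(d_means, sigma_refs) -> float:
    """Least-squares global scale factor from tissue means.

    ``eta = sum(d_k sigma_k) / sum(d_k^2)`` over reference tissues (WM
    and GM for the brain; measured compartments for a phantom), with
    ``d_k`` ROI-mean diffusivities (mm^2/s) and ``sigma_k`` reference
    conductivities (S/m).  Result is in internal units S*s/(m*mm^2).
    """
    d = np.atleast_1d(np.asarray(d_means, dtype=float))
    s = np.atleast_1d(np.asarray(sigma_refs, dtype=float))
    if d.shape != s.shape or d.size == 0:
        raise ValueError("d_means and sigma_refs must be matching non-empty")
    if np.any(d <= 0):
        raise ValueError("mean diffusivities must be positive")
    return float(np.sum(d * s) / np.sum(d ** 2))


def reconstruct_lem(D: TensorField, masks: dict | None = None,
                    mode: str = "empirical",
                    consts: LiteratureConstants | None = None,
                    roi_refs: dict | None = None):
    """Linear eigenvalue model: ``C = eta * D`` with a global eta.

    ``mode="empirical"`` uses the literature constant
    ``consts.eta_empirical`` (quoted in S*s/mm^3, converted internally);
    ``mode="matched"`` computes eta from ROI-mean diffusivities of the
    mask ROIs against reference conductivities (``roi_refs`` maps ROI
    name to sigma in S/m; defaults to WM/GM literature values).

    Returns ``(C, ScaleFactorField)``.
    """
    from .tensor_core import mean_scalar   # local import avoids cycle noise

    consts = consts or LiteratureConstants()
    if mode == "empirical":
        eta = consts.eta_empirical * S_S_PER_MM3_TO_INTERNAL
    elif mode == "matched":
        if not masks:
            raise ValueError("matched mode requires tissue masks")
        refs = roi_refs or {"WM": consts.sigma_wm, "GM": consts.sigma_gm}
        md = mean_scalar(D)
        d_means, sigma_refs = [], []
        for name, sigma in refs.items():
            roi = masks[name] & D.mask
            if not roi.any():
                raise ValueError(f"empty tissue mask {name!r}")
            d_means.append(float(np.nanmean(md[roi])))
            sigma_refs.append(sigma)
        eta = lem_scale_factor(d_means, sigma_refs)
    else:
        raise ValueError(f"unknown LEM mode {mode!r}")

    C = D.scaled(eta, Quantity.CONDUCTIVITY)
    return C, ScaleFactorField(eta, "global", "LEM")


# ----------------------------------------------------------------------
# FEM
# ----------------------------------------------------------------------
def fem_scale_factor(consts: LiteratureConstants | None = None,
                     units: str = "internal") -> float:
    """Force-equilibrium global scale factor ``0.76 q^2 N / (kB T)``.

    ``units="si"`` returns S*s/m^3 (sigma per d in m^2/s);
    ``units="internal"`` converts for diffusivities in mm^2/s.
    """
    consts = consts or LiteratureConstants()
    eta_si = consts.fem_prefactor * consts.q ** 2 * consts.N / consts.kBT
    if units == "si":
        return eta_si
    if units == "internal":
        return eta_si * SI_PER_M3_TO_INTERNAL
    raise ValueError(f"unknown units {units!r}")


def reconstruct_fem(Df: TensorField,
                    consts: LiteratureConstants | None = None):
    """Force equilibrium model: ``C = eta_FEM * Df`` (fast tensor)."""
    eta = fem_scale_factor(consts)
    C = Df.scaled(eta, Quantity.CONDUCTIVITY)
    return C, ScaleFactorField(eta, "global", "FEM")


# ----------------------------------------------------------------------
# VCM
# ----------------------------------------------------------------------
def sigma_iso_from_labels(labels: np.ndarray, mapping: dict) -> np.ndarray:
    """Per-voxel sigma_iso map from a label volume (labels absent from
    the mapping get NaN)."""
    out = np.full(labels.shape, np.nan)
    for lab, sigma in mapping.items():
        out[labels == lab] = sigma
    return out


def reconstruct_vcm(D: TensorField, sigma_iso_map):
    """Volume constraint model: ``C = 3 sigma_iso / trace(D) * D``.

    ``trace(C) = 3 sigma_iso`` holds exactly at every voxel.  Voxels
    with zero trace (or undefined sigma_iso) are masked out with a
    warning.  Returns ``(C, ScaleFactorField)``.
    """
    sigma_iso_map = np.asarray(sigma_iso_map, dtype=float)
    if sigma_iso_map.shape != D.grid_shape:
        raise ValueError("sigma_iso map shape does not match grid")
    trace = D.values[..., 0] + D.values[..., 3] + D.values[..., 5]
    usable = D.mask & (trace > 0) & np.isfinite(sigma_iso_map)
    dropped = D.mask & ~usable
    if dropped.any():
        warnings.warn(
            f"reconstruct_vcm: masking out {int(dropped.sum())} voxel(s) with "
            f"zero trace or undefined sigma_iso", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = 3.0 * sigma_iso_map / trace
    eta = np.where(usable, eta, np.nan)
    C = TensorField(np.where(usable[..., None], D.values * eta[..., None], 0.0),
                    Quantity.CONDUCTIVITY, D.voxel_size_mm, usable)
    return C, ScaleFactorField(eta, "per_voxel", "VCM")


# ----------------------------------------------------------------------
# VFM
# ----------------------------------------------------------------------
def _vfm_system(consts: LiteratureConstants):
    """Coefficient matrix of the volume-fraction linear system.

    Treating the exponentials of the literature diffusivities as fixed
    coefficients and eliminating ``alpha_iso = 1 - sum(fractions)``,
    the three equations become ``(E - e_iso) a = y - e_iso`` with E the
    matrix of compartment exponentials and ``y = exp(-b d_eig)``.
    """
    b = consts.vfm_b
    el = np.exp(-b * consts.vfm_d_lW)
    et = np.exp(-b * consts.vfm_d_tW)     # d_t1W = d_t2W
    ei = np.exp(-b * consts.vfm_d_iso)
    E = np.array([[el, et, et],
                  [et, el, et],
                  [et, et, el]])
    A = E - ei
    if abs(np.linalg.det(A)) < 1e-30:
        raise ValueError("VFM coefficient matrix is singular for these constants")
    return A, ei, b


def solve_vfm_fractions(d_eigs, consts: LiteratureConstants | None = None,
                        clip_tol: float = 1e-9):
    """Solve the WM volume fractions from diffusion eigenvalues.

    Parameters
    ----------
    d_eigs
        Array ``(..., 3)`` of diffusion eigenvalues (descending) in
        mm^2/s.

    Returns
    -------
    fractions : ndarray ``(..., 4)``
        ``(alpha_l, alpha_t1, alpha_t2, alpha_iso)``, clipped to the
        simplex.
    ill_posed : ndarray bool
        True where the raw solution left the simplex by more than
        ``clip_tol`` (flagged, values still clipped).
    """
    consts = consts or LiteratureConstants()
    d_eigs = np.asarray(d_eigs, dtype=float)
    if d_eigs.shape[-1] != 3:
        raise ValueError("d_eigs must have trailing axis of 3 eigenvalues")
    A, ei, b = _vfm_system(consts)
    y = np.exp(-b * d_eigs) - ei
    a = np.einsum("ij,...j->...i", np.linalg.inv(A), y)

    total = a.sum(axis=-1)
    ill = (np.min(a, axis=-1) < -clip_tol) | (total > 1.0 + clip_tol)
    a = np.clip(a, 0.0, 1.0)
    total = a.sum(axis=-1, keepdims=True)
    scale = np.where(total > 1.0, total, 1.0)
    a = a / scale
    a_iso = np.clip(1.0 - a.sum(axis=-1), 0.0, 1.0)
    return np.concatenate([a, a_iso[..., None]], axis=-1), ill


def vfm_forward_eigs(fractions, consts: LiteratureConstants | None = None):
    """Compose diffusion eigenvalues from volume fractions (inverse of
    :func:`solve_vfm_fractions`; used for round-trip checks)."""
    consts = consts or LiteratureConstants()
    fractions = np.asarray(fractions, dtype=float)
    A, ei, b = _vfm_system(consts)
    # original system: E a + alpha_iso e_iso = y  with  alpha_iso = 1 - sum(a),
    # i.e. y = (E - e_iso) a + e_iso
    y = np.einsum("ij,...j->...i", A, fractions[..., :3]) + ei
    return -np.log(y) / b


def reconstruct_vfm(D: TensorField, masks: dict,
                    consts: LiteratureConstants | None = None):
    """Volume fraction model.

    WM voxels: eigenvalues of C are volume-fraction-weighted sums of the
    literature compartment conductivities, with the transversal
    constraint ``sigma_t1 = sigma_t2`` enforced (the two weighted sums
    are averaged); eigenvectors are copied from D.  GM and CSF voxels
    get literature isotropic conductivities.

    Returns ``(C, fractions, ill_posed)``.
    """
    consts = consts or LiteratureConstants()
    if not masks or "WM" not in masks:
        raise ValueError("VFM requires a WM mask (plus optional GM/CSF masks)")
    eig = eig_decompose(D)
    lam = eig.eigenvalues

    wm = masks["WM"] & D.mask
    fractions = np.zeros(D.grid_shape + (4,))
    ill = np.zeros(D.grid_shape, dtype=bool)
    frac_wm, ill_wm = solve_vfm_fractions(lam[wm], consts)
    fractions[wm] = frac_wm
    ill[wm] = ill_wm

    al, at1, at2, aiso = (frac_wm[..., k] for k in range(4))
    s_lw, s_tw, s_iso = consts.vfm_sigma_lW, consts.vfm_sigma_tW, consts.vfm_sigma_iso
    sig_l = al * s_lw + (at1 + at2) * s_tw + aiso * s_iso
    sig_t1 = al * s_tw + at1 * s_lw + at2 * s_tw + aiso * s_iso
    sig_t2 = al * s_tw + at1 * s_tw + at2 * s_lw + aiso * s_iso
    sig_t = 0.5 * (sig_t1 + sig_t2)          # sigma_t1 = sigma_t2 constraint

    sig_eigs = np.zeros(D.grid_shape + (3,))
    sig_eigs[wm] = np.stack([sig_l, sig_t, sig_t], axis=-1)

    vecs = np.where(wm[..., None, None], np.nan_to_num(eig.eigenvectors, nan=0.0),
                    np.eye(3))
    out_mask = wm.copy()
    for name, sigma in (("GM", consts.sigma_gm), ("CSF", consts.sigma_csf)):
        if name in masks:
            roi = masks[name] & D.mask & ~wm
            sig_eigs[roi] = sigma
            out_mask |= roi

    C = compose_tensor(EigenField(sig_eigs, vecs, Quantity.CONDUCTIVITY,
                                  D.voxel_size_mm, out_mask))
    return C, fractions, ill


# ----------------------------------------------------------------------
# CTI
# ----------------------------------------------------------------------
def estimate_ce(sigma_h, alpha, dew, diw, beta: float):
    """Apparent extracellular ion concentration
    ``ce = sigma_H / (alpha dew + (1 - alpha) diw beta)``.

    Zero/invalid denominators yield NaN with a warning.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    sigma_h = np.asarray(sigma_h, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    denom = alpha * np.asarray(dew, dtype=float) \
        + (1.0 - alpha) * np.asarray(diw, dtype=float) * beta
    bad = ~(denom > 0)
    if bad.any():
        warnings.warn(
            f"estimate_ce: {int(bad.sum())} voxel(s) with nonpositive "
            f"denominator set to NaN", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ce = sigma_h / denom
    return np.where(bad, np.nan, ce)


def reconstruct_cti(sigma_h, fit: BiexpFitField, beta: float = 0.41):
    """Conductivity tensor imaging: per-voxel
    ``eta = alpha sigma_H / (alpha dew + (1-alpha) diw beta)``,
    ``C = eta * De`` with De the fast tensor of the bi-exponential fit.

    Returns ``(C, ScaleFactorField)``.
    """
    sigma_h = np.asarray(sigma_h, dtype=float)
    if sigma_h.shape != fit.grid_shape:
        raise ValueError("sigma_H grid does not match the fit grid")
    ce = np.full(fit.grid_shape, np.nan)
    m = fit.mask
    ce[m] = estimate_ce(sigma_h[m], fit.alpha[m], fit.dew[m], fit.diw[m], beta)
    eta = fit.alpha * ce
    usable = fit.mask & np.isfinite(eta) & (eta > 0)
    eta = np.where(usable, eta, np.nan)
    C = TensorField(
        np.where(usable[..., None], fit.Df.values * np.nan_to_num(eta)[..., None], 0.0),
        Quantity.CONDUCTIVITY, fit.Df.voxel_size_mm, usable)
    return C, ScaleFactorField(eta, "per_voxel", "CTI")
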