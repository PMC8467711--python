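"""Comparison statistics for reconstructed conductivity tensors.

ROI summaries (mean +/- sample SD with voxel counts), relative errors of
mean conductivity against per-compartment references, signed relative
difference maps against a reference reconstruction, pooled linear
regression R^2 between conductivity and diffusion tensor components, and
anisotropy-ratio summaries.

Conventions: sample SD (ddof=1); relative errors reported as absolute
percentages; relative differences keep their sign voxelwise and are
summarised as mean absolute values per ROI; ROI erosion is 2-D in-plane,
slice by slice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from .tensor_core import TensorField, anisotropy_ratio, eig_decompose, mean_scalar


# ----------------------------------------------------------------------
def roi_erode(mask: np.ndarray, width: int = 2) -> np.ndarray:
    """Erode each ROI label in-plane by ``width`` pixels.

    Accepts a boolean mask or an integer label volume (label 0 =
    background); erosion uses the full 3x3 structuring element per
    z-slice.  Raises if any label erodes to empty.
    """
    if width < 0:
        raise ValueError("width must be nonnegative")
    mask = np.asarray(mask)
    if width == 0:
        return mask.copy()
    structure = np.ones((3, 3), dtype=bool)

    def erode_binary(m):
        out = np.zeros_like(m)
        for z in range(m.shape[2]):
            out[:, :, z] = binary_erosion(m[:, :, z], structure,
                                          iterations=width)
        return out

    if mask.dtype == bool:
        out = erode_binary(mask)
        if mask.any() and not out.any():
            raise ValueError("mask eroded to empty")
        return out

    out = np.zeros_like(mask)
    for lab in np.unique(mask):
        if lab == 0:
            continue
        m = erode_binary(mask == lab)
        if not m.any():
            raise ValueError(f"label {lab} eroded to empty")
        out[m] = lab
    return out


# ----------------------------------------------------------------------
def roi_stats(field, masks: dict, stat_name: str = "value") -> pd.DataFrame:
    """Mean, sample SD and voxel count of a scalar volume per ROI."""
    field = np.asarray(field, dtype=float)
    rows = []
    for name, roi in masks.items():
        vals = field[np.asarray(roi, dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"empty ROI {name!r}")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append({"roi": name, "stat": stat_name,
                     "mean": float(vals.mean()), "sd": sd,
                     "n_voxels": int(vals.size)})
    return pd.DataFrame(rows)


def relative_error(recon: TensorField, references: dict, masks: dict) -> pd.DataFrame:
    """Percent error of ROI-mean conductivity vs per-compartment references.

    ``100 * |mean(sigma_L) - sigma_ref| / sigma_ref`` per ROI, with
    sigma_L the mean eigenvalue (trace/3).
    """
    sig_l = mean_scalar(recon)
    rows = []
    for name, sigma_ref in references.items():
        roi = np.asarray(masks[name], dtype=bool)
        vals = sig_l[roi]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"empty ROI {name!r}")
        mean = float(vals.mean())
        rows.append({
            "roi": name,
            "sigma_ref_S_per_m": sigma_ref,
            "sigma_mean_S_per_m": mean,
            "rel_error_pct": 100.0 * abs(mean - sigma_ref) / sigma_ref,
            "n_voxels": int(vals.size),
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
_DIR_NAMES = ("l", "t1", "t2")


def relative_difference_map(c_method: TensorField, c_reference: TensorField,
                            masks: dict | None = None):
    """Signed percent difference of eigenvalues vs a reference method.

    ``rd_DIR = (sigma_DIR,ref - sigma_DIR,method) / sigma_DIR,ref * 100``
    per voxel and direction (l, t1, t2 = descending eigenvalues).
    Voxels with a zero reference eigenvalue are excluded (NaN).

    Returns ``(maps, summary)``: a dict of per-direction volumes and,
    when ``masks`` is given, a table of mean |rd| per ROI and direction.
    """
    if c_method.grid_shape != c_reference.grid_shape:
        raise ValueError("grids differ between method and reference")
    lam_m = eig_decompose(c_method).eigenvalues
    lam_r = eig_decompose(c_reference).eigenvalues
    both = c_method.mask & c_reference.mask

    maps = {}
    n_excluded = 0
    for k, name in enumerate(_DIR_NAMES):
        ref = lam_r[..., k]
        ok = both & (ref != 0) & np.isfinite(ref)
        n_excluded += int((both & ~ok).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rd = (ref - lam_m[..., k]) / ref * 100.0
        maps[name] = np.where(ok, rd, np.nan)

    summary = None
    if masks is not None:
        rows = []
        for roi_name, roi in masks.items():
            roi = np.asarray(roi, dtype=bool)
            for name in _DIR_NAMES:
                vals = maps[name][roi]
                vals = vals[np.isfinite(vals)]
                rows.append({"roi": roi_name, "direction": name,
                             "mean_abs_rd_pct": float(np.abs(vals).mean())
                             if vals.size else np.nan,
                             "n_voxels": int(vals.size)})
        summary = pd.DataFrame(rows)
    return maps, summary


# ----------------------------------------------------------------------
def regression_r2(c_field: TensorField, d_field: TensorField,
                  masks: dict) -> dict:
    """Pooled OLS R^2 between conductivity and diffusion components.

    Pools voxels of all ROIs and regresses the longitudinal eigenvalues
    (sigma_l vs d_l) and the averaged transversal eigenvalues
    (sigma_t = (sigma_t1+sigma_t2)/2 vs d_t) with an intercept.  A
    constant regressor yields NaN.
    """
    if c_field.grid_shape != d_field.grid_shape:
        raise ValueError("grids differ between conductivity and diffusion fields")
    lam_c = eig_decompose(c_field).eigenvalues
    lam_d = eig_decompose(d_field).eigenvalues
    pool = np.zeros(c_field.grid_shape, dtype=bool)
    for roi in masks.values():
        pool |= np.asarray(roi, dtype=bool)
    pool &= c_field.mask & d_field.mask
    if not pool.any():
        raise ValueError("no voxels in the pooled ROIs")

    def r2(x, y):
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return np.nan
        r = np.corrcoef(x, y)[0, 1]
        return float(r * r)

    out = {
        "longitudinal": r2(lam_d[pool][:, 0], lam_c[pool][:, 0]),
        "transversal": r2(lam_d[pool][:, 1:].mean(axis=1),
                          lam_c[pool][:, 1:].mean(axis=1)),
    }
    return out


def anisotropy_summary(c_field: TensorField, d_field: TensorField,
                       wm_mask) -> pd.DataFrame:
    """Mean +/- SD anisotropy ratios of C and D over a WM ROI."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    rows = []
    for label, field in (("AR_C", c_field), ("AR_D", d_field)):
        ar = anisotropy_ratio(field)[wm_mask]
        ar = ar[np.isfinite(ar)]
        if ar.size == 0:
            raise ValueError("empty WM ROI for anisotropy summary")
        rows.append({"metric": label, "mean": float(ar.mean()),
                     "sd": float(np.std(ar, ddof=1)) if ar.size > 1 else 0.0,
                     "n_voxels": int(ar.size)})
    return pd.DataFrame(rows)
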