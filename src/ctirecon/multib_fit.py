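"""Diffusion parameter estimation from multi-b DWI stacks.

Two estimation routes are provided:

* :func:`fit_dti` — log-linear least-squares single-tensor fit at one
  b-shell (the b = 700 s/mm^2 shell by convention for the LEM/VCM/VFM
  reconstructions), and
* :func:`fit_biexponential` / :func:`assemble_fast_slow` — per-direction
  bi-exponential fits ``S(b)/S(0) = vf exp(-b df) + vs exp(-b ds)``
  with ``vf + vs = 1`` and ``df >= ds >= 0``, assembled into fast/slow
  tensors and an extracellular volume fraction for the FEM and CTI
  reconstructions.

The bi-exponential problem is non-convex; fits are made deterministic by
a fixed multi-start grid (df in {1,2,3}e-3, ds in {0.1,0.3,0.5}e-3,
vf in {0.3,0.5,0.8}), with ties broken towards larger vf.  The voxelwise
batch path runs a vectorised damped Gauss-Newton refinement of the best
starts; duplicate decay curves (common in piecewise-constant synthetic
objects) are fitted once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synthetic_data import MultiBStack
from .tensor_core import Quantity, TensorField

#: Deterministic multi-start grid (df, ds, vf).
START_DF = (1.0e-3, 2.0e-3, 3.0e-3)
START_DS = (0.1e-3, 0.3e-3, 0.5e-3)
START_VF = (0.3, 0.5, 0.8)

#: Components closer than this (mm^2/s) are merged into a mono-exponential.
MONO_MERGE_TOL = 1e-5

_DF_MAX = 0.05  # generous upper bound on diffusivity, mm^2/s


# ----------------------------------------------------------------------
@dataclass
class BiexpFitField:
    """Per-voxel bi-exponential fit results.

    Directional arrays have shape ``(*grid, n_dir)``; scalar maps
    ``(*grid,)``.  ``Df``/``Ds`` are the fast/slow tensors assembled from
    the directional diffusivities; ``alpha`` is the mean fast fraction
    over directions; ``dew``/``diw`` the mean fast/slow diffusivities.
    """

    vf: np.ndarray
    vs: np.ndarray
    df: np.ndarray
    ds: np.ndarray
    Df: TensorField
    Ds: TensorField
    alpha: np.ndarray
    dew: np.ndarray
    diw: np.ndarray
    fit_quality: np.ndarray          # per-voxel RMS residual over directions
    mask: np.ndarray

    @property
    def grid_shape(self) -> tuple:
        return self.alpha.shape


# ----------------------------------------------------------------------
# single-tensor DTI fit
# ----------------------------------------------------------------------
def _design_matrix(bb: np.ndarray, uu: np.ndarray) -> np.ndarray:
    """Rows ``b * (ux^2, 2 ux uy, 2 ux uz, uy^2, 2 uy uz, uz^2)``."""
    ux, uy, uz = uu[:, 0], uu[:, 1], uu[:, 2]
    return bb[:, None] * np.stack(
        [ux ** 2, 2 * ux * uy, 2 * ux * uz, uy ** 2, 2 * uy * uz, uz ** 2],
        axis=1)


def fit_dti(stack: MultiBStack, b_used: float = 700.0,
            b_tol: float = 0.5) -> TensorField:
    """Log-linear least-squares tensor fit at a single b-shell.

    Solves ``ln(S0/S) = b u^T D u`` over all directions of the shell
    nearest ``b_used``.  Voxels with nonpositive signals have those
    acquisitions excluded (with a warning); PSD is enforced by the
    tensor-field clamping policy on decomposition.
    """
    sel = np.abs(stack.b_values_s_per_mm2 - b_used) <= b_tol
    if not sel.any():
        raise ValueError(f"no acquisitions at b = {b_used} s/mm^2")
    bb = stack.b_values_s_per_mm2[sel]
    uu = stack.directions[sel]
    A = _design_matrix(bb, uu)
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError(
            f"need >= 6 non-collinear directions at b = {b_used}, "
            f"got rank {np.linalg.matrix_rank(A)} from {sel.sum()} acquisitions")

    mask = stack.mask
    sig = stack.signals[..., sel][mask]            # (n_vox, n_sel)
    s0 = stack.s0[mask][:, None]
    good = sig > 0
    n_bad = int((~good).sum())
    if n_bad:
        warnings.warn(f"fit_dti: excluding {n_bad} nonpositive signal(s)",
                      RuntimeWarning, stacklevel=2)

    pinv = np.linalg.pinv(A)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(s0 / sig)
    d6 = np.empty((sig.shape[0], 6))
    all_good = good.all(axis=1)
    d6[all_good] = y[all_good] @ pinv.T
    for i in np.nonzero(~all_good)[0]:
        g = good[i]
        if g.sum() < 6 or np.linalg.matrix_rank(A[g]) < 6:
            d6[i] = 0.0
            continue
        d6[i] = np.linalg.lstsq(A[g], y[i, g], rcond=None)[0]

    values = np.zeros(stack.grid_shape + (6,))
    values[mask] = d6
    return TensorField(values, Quantity.DIFFUSION, stack.voxel_size_mm,
                       mask.copy())


# ----------------------------------------------------------------------
# bi-exponential fitting
# ----------------------------------------------------------------------
def _canonicalize(vf, df, ds, bb, decay):
    """Order components fast-first and merge near-equal components."""
    if ds > df:
        vf, df, ds = 1.0 - vf, ds, df
    if df - ds < MONO_MERGE_TOL or vf >= 1.0 - 1e-9:
        # effectively mono-exponential: report vf = 1 with the apparent d
        d_app = vf * df + (1.0 - vf) * ds if df - ds < MONO_MERGE_TOL else df
        return 1.0, d_app, 0.0
    return vf, df, ds


def _fit_mono_batch(decays, bb, n_newton=30):
    """Mono-exponential fit ``y = exp(-b d)`` per curve.

    Log-linear seed followed by Newton steps on the signal-space SSE.
    Returns ``(d, sse)``.
    """
    b = bb.ravel()
    with np.errstate(divide="ignore"):
        logs = -np.log(np.clip(decays, 1e-300, None))
    d = np.clip(logs @ b / (b @ b), 0.0, _DF_MAX)
    for _ in range(n_newton):
        e = np.exp(-b * d[:, None])
        res = decays - e
        grad = np.sum(b * e * res, axis=1)         # -0.5 dSSE/dd
        curv = np.sum((b * e) ** 2, axis=1)
        d = np.clip(d + grad / np.maximum(curv, 1e-300), 0.0, _DF_MAX)
    e = np.exp(-b * d[:, None])
    sse = ((decays - e) ** 2).sum(axis=1)
    return d, sse


def fit_biexponential(decay, b_values):
    """Constrained bi-exponential fit of a single decay curve.

    Parameters
    ----------
    decay
        Signal ratios ``S(b)/S(0)`` per b-value, values in (0, 1.5].
    b_values
        Matching b-values (s/mm^2), at least 4 distinct values.

    Returns
    -------
    (vf, df, vs, ds)
        Volume fractions and diffusivities with ``vf + vs = 1`` and
        ``df >= ds >= 0``.
    """
    decay = np.asarray(decay, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if decay.shape != b_values.shape:
        raise ValueError("decay and b_values must have matching shapes")
    if np.unique(b_values).size < 4:
        raise ValueError("need at least 4 distinct b-values")
    if np.any(decay <= 0) or np.any(decay > 1.5):
        raise ValueError("decay ratios must lie in (0, 1.5]")

    def resid(x):
        vf, df, r = x
        return (vf * np.exp(-b_values * df)
                + (1.0 - vf) * np.exp(-b_values * r * df) - decay)

    best = None
    for df0 in START_DF:
        for ds0 in START_DS:
            for vf0 in START_VF:
                x0 = np.array([vf0, df0, min(ds0 / df0, 1.0)])
                try:
                    sol = least_squares(resid, x0, bounds=([0, 1e-9, 0], [1, _DF_MAX, 1]),
                                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
                except Exception:           # pragma: no cover - defensive
                    continue
                cost = sol.cost
                vf = sol.x[0]
                if (best is None or cost < best[0] - 1e-15
                        or (abs(cost - best[0]) <= 1e-15 and vf > best[1])):
                    best = (cost, vf, sol.x)
    if best is None:
        raise RuntimeError("bi-exponential fit failed to converge from all starts")
    vf, df, r = best[2]
    vf, df, ds = _canonicalize(vf, df, r * df, b_values, decay)
    # Nested-model competition: prefer the mono-exponential whenever it
    # fits equally well (the bi-exponential minimum is degenerate there).
    d_mono, sse_mono = _fit_mono_batch(decay[None, :], b_values[None, :])
    sse_bi = 2.0 * best[0]
    if sse_mono[0] <= sse_bi * (1.0 + 1e-9) + 1e-18 * b_values.size:
        vf, df, ds = 1.0, float(d_mono[0]), 0.0
    return vf, df, 1.0 - vf, ds


# -- vectorised batch fitter -------------------------------------------
def _model_and_jac(params, bb):
    vf = params[:, 0:1]
    df = params[:, 1:2]
    r = params[:, 2:3]
    ef = np.exp(-bb * df)
    es = np.exp(-bb * r * df)
    m = vf * ef + (1.0 - vf) * es
    j = np.stack([
        ef - es,
        -bb * (vf * ef + (1.0 - vf) * r * es),
        -(1.0 - vf) * bb * df * es,
    ], axis=-1)                                   # (N, B, 3)
    return m, j


def _lm_refine(params, decays, bb, n_iter=60):
    """Damped Gauss-Newton with box projection, vectorised over curves."""
    lo = np.array([0.0, 1e-9, 0.0])
    hi = np.array([1.0, _DF_MAX, 1.0])
    lam = np.full(decays.shape[0], 1e-3)
    m, _ = _model_and_jac(params, bb)
    sse = ((m - decays) ** 2).sum(axis=1)
    eye = np.eye(3)
    for _ in range(n_iter):
        m, j = _model_and_jac(params, bb)
        res = decays - m
        g = np.einsum("nbk,nb->nk", j, res)
        h = np.einsum("nbk,nbl->nkl", j, j)
        a = h + lam[:, None, None] * eye
        try:
            step = np.linalg.solve(a, g[..., None])[..., 0]
        except np.linalg.LinAlgError:     # pragma: no cover - defensive
            a = h + (lam[:, None, None] + 1e-8) * eye
            step = np.linalg.solve(a, g[..., None])[..., 0]
        trial = np.clip(params + step, lo, hi)
        mt, _ = _model_and_jac(trial, bb)
        sse_t = ((mt - decays) ** 2).sum(axis=1)
        accept = sse_t <= sse
        params = np.where(accept[:, None], trial, params)
        sse = np.where(accept, sse_t, sse)
        lam = np.where(accept, lam / 3.0, lam * 10.0)
        lam = np.clip(lam, 1e-12, 1e8)
    return params, sse


def fit_biexponential_batch(decays, b_values, n_refine_starts=4,
                            n_iter=150, dedupe=True):
    """Vectorised bi-exponential fit of many decay curves.

    Evaluates the fixed multi-start grid, refines the best
    ``n_refine_starts`` starts per curve with a damped Gauss-Newton
    loop, and canonicalises the winners (ties towards larger vf).
    Identical curves (to 12 decimals) are fitted once.

    Returns arrays ``(vf, df, ds, rms_residual)`` of shape ``(N,)``.
    """
    decays = np.asarray(decays, dtype=float)
    bb = np.asarray(b_values, dtype=float)[None, :]
    if decays.ndim != 2 or decays.shape[1] != bb.shape[1]:
        raise ValueError("decays must be (n_curves, n_b)")

    if dedupe:
        uniq, inverse = np.unique(np.round(decays, 12), axis=0,
                                  return_inverse=True)
    else:
        uniq, inverse = decays, np.arange(decays.shape[0])
    n = uniq.shape[0]

    starts = np.array([[vf, df, min(ds / df, 1.0)]
                       for df in START_DF for ds in START_DS
                       for vf in START_VF])       # (27, 3)
    # SSE of every start against every curve without forming (n, 27, B):
    m0 = (starts[:, 0:1] * np.exp(-bb * starts[:, 1:2])
          + (1 - starts[:, 0:1]) * np.exp(-bb * starts[:, 2:3] * starts[:, 1:2]))
    sse0 = (np.sum(uniq ** 2, axis=1)[:, None]
            - 2.0 * uniq @ m0.T + np.sum(m0 ** 2, axis=1)[None, :])
    order = np.argsort(sse0, axis=1)[:, :n_refine_starts]

    best_params = np.empty((n, 3))
    best_sse = np.full(n, np.inf)
    best_vf = np.full(n, -1.0)
    for k in range(order.shape[1]):
        p0 = starts[order[:, k]]
        p, sse = _lm_refine(p0.copy(), uniq, bb, n_iter=n_iter)
        better = (sse < best_sse - 1e-16) | (
            (np.abs(sse - best_sse) <= 1e-16) & (p[:, 0] > best_vf))
        best_params[better] = p[better]
        best_sse[better] = sse[better]
        best_vf[better] = p[better, 0]

    vf = np.empty(n)
    df = np.empty(n)
    ds = np.empty(n)
    for i in range(n):
        vf[i], df[i], ds[i] = _canonicalize(
            best_params[i, 0], best_params[i, 1],
            best_params[i, 2] * best_params[i, 1], bb[0], uniq[i])

    # Nested-model competition (see fit_biexponential): on effectively
    # mono-exponential curves the simpler model wins the tie.
    d_mono, sse_mono = _fit_mono_batch(uniq, bb)
    mono = sse_mono <= best_sse * (1.0 + 1e-9) + 1e-18 * bb.shape[1]
    vf[mono] = 1.0
    df[mono] = d_mono[mono]
    ds[mono] = 0.0
    best_sse = np.where(mono, sse_mono, best_sse)
    rms = np.sqrt(best_sse / bb.shape[1])
    return vf[inverse], df[inverse], ds[inverse], rms[inverse]


# ----------------------------------------------------------------------
# fast/slow tensor assembly
# ----------------------------------------------------------------------
def _group_directions(stack: MultiBStack):
    """Unique directions and, per direction, the acquisition indices."""
    uniq, inv = np.unique(np.round(stack.directions, 10), axis=0,
                          return_inverse=True)
    groups = [np.nonzero(inv == k)[0] for k in range(len(uniq))]
    return uniq, groups


def _is_orthogonal_triad(dirs: np.ndarray) -> bool:
    if dirs.shape != (3, 3):
        return False
    gram = np.abs(dirs @ dirs.T) - np.eye(3)
    return bool(np.abs(gram).max() < 1e-8)


def assemble_fast_slow(stack: MultiBStack, mode: str = "tensor6plus",
                       n_iter: int = 150) -> BiexpFitField:
    """Per-direction bi-exponential fits assembled into fast/slow tensors.

    ``mode="orthogonal3"`` requires exactly 3 mutually orthogonal
    directions and builds diagonal tensors in that measurement frame
    (axis-aligned directions assumed); ``mode="tensor6plus"`` requires
    >= 6 directions of full rank and least-squares fits the directional
    diffusivities to a full tensor.
    """
    dirs, groups = _group_directions(stack)
    n_dir = len(dirs)
    if mode == "orthogonal3":
        if not _is_orthogonal_triad(dirs):
            raise ValueError("orthogonal3 mode needs exactly 3 orthogonal directions")
    elif mode == "tensor6plus":
        A = _design_matrix(np.ones(n_dir), dirs)
        if n_dir < 6 or np.linalg.matrix_rank(A) < 6:
            raise ValueError("tensor6plus mode needs >= 6 directions of full rank")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mask = stack.mask
    n_vox = int(mask.sum())
    grid = stack.grid_shape
    vf_d = np.zeros((n_vox, n_dir))
    df_d = np.zeros((n_vox, n_dir))
    ds_d = np.zeros((n_vox, n_dir))
    rms_d = np.zeros((n_vox, n_dir))

    s0 = stack.s0[mask]
    for k, idx in enumerate(groups):
        bvals = stack.b_values_s_per_mm2[idx]
        order = np.argsort(bvals)
        decays = stack.signals[..., idx][mask][:, order] / s0[:, None]
        decays = np.clip(decays, 1e-12, None)
        vf_d[:, k], df_d[:, k], ds_d[:, k], rms_d[:, k] = \
            fit_biexponential_batch(decays, bvals[order], n_iter=n_iter)

    def full(map2d):
        out = np.zeros(grid + map2d.shape[1:])
        out[mask] = map2d
        return out

    alpha = full(vf_d.mean(axis=1)[:, None])[..., 0]
    dew = full(df_d.mean(axis=1)[:, None])[..., 0]
    diw = full(ds_d.mean(axis=1)[:, None])[..., 0]
    quality = full(np.sqrt((rms_d ** 2).mean(axis=1))[:, None])[..., 0]

    def to_tensor(d_directional):
        values = np.zeros(grid + (6,))
        if mode == "orthogonal3":
            # diagonal in the measurement frame; map each direction to its axis
            axis = np.abs(dirs).argmax(axis=1)
            diag_idx = {0: 0, 1: 3, 2: 5}
            flat = np.zeros((n_vox, 6))
            for k in range(3):
                flat[:, diag_idx[int(axis[k])]] = d_directional[:, k]
            values[mask] = flat
        else:
            A = _design_matrix(np.ones(n_dir), dirs)
            pinv = np.linalg.pinv(A)
            values[mask] = d_directional @ pinv.T
        return TensorField(values, Quantity.DIFFUSION, stack.voxel_size_mm,
                           mask.copy())

    Df = to_tensor(df_d)
    Ds = to_tensor(ds_d)
    return BiexpFitField(full(vf_d), full(1.0 - vf_d), full(df_d), full(ds_d),
                         Df, Ds, alpha, dew, diw, quality, mask.copy())
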