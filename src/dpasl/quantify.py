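"""Voxelwise quantification of ATT, CBF and kw from a DP-pCASL series.

Pipeline: control-label differencing (optionally PCA physiological-noise
reduction of the repeat stack), FEAST transit-time inversion from the short
PLD pair, kw inversion of the (optionally TV-regularized) diffusion-weighted
signal ratio at the long PLD, and CBF inversion of the long-PLD b=0 signal.
All maps carry a companion uint8 flag volume; clamps and saturations never
pass silently.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import kinetics
from .kinetics import (
    FLAG_CLAMPED,
    FLAG_MISSING,
    PhysioState,
)
from .protocol import AcquisitionProtocol

__all__ = [
    "AslSeries",
    "ParameterMaps",
    "compute_diff",
    "pca_denoise",
    "map_att",
    "map_cbf",
    "map_kw",
    "tv_regularize",
    "quantify_series",
]

log = logging.getLogger(__name__)

Condition = tuple[float, float]  # (pld seconds, b-value s/mm^2)


@dataclasses.dataclass
class AslSeries:
    """Raw control/label volumes per (PLD, b) condition plus M0 and mask.

    ``data[cond]`` has shape ``grid + (2 * n_pairs,)`` with control and label
    volumes interleaved according to ``order`` ("control-first" or
    "label-first").
    """

    data: dict[Condition, np.ndarray]
    m0: np.ndarray
    mask: np.ndarray
    order: str = "control-first"

    def __post_init__(self) -> None:
        if self.order not in ("control-first", "label-first"):
            raise ValueError(f"unknown interleave order: {self.order!r}")
        shape = self.m0.shape
        for cond, vol in self.data.items():
            if vol.shape[:-1] != shape:
                raise ValueError(f"condition {cond} grid does not match M0")
            if vol.shape[-1] % 2:
                raise ValueError(f"condition {cond}: unpaired volume count")
            if vol.shape[-1] < 4:
                raise ValueError(f"condition {cond}: need at least 2 repeats")
        if self.mask.shape != shape:
            raise ValueError("mask grid does not match M0")
        if np.any(self.mask & ~np.isfinite(self.m0)):
            raise ValueError("mask includes non-finite M0 voxels")


@dataclasses.dataclass
class ParameterMaps:
    """Quantified (CBF, ATT, kw) maps with a shared flag bitfield."""

    cbf: np.ndarray
    att: np.ndarray
    kw: np.ndarray
    flags: np.ndarray

    def counts(self) -> dict[str, int]:
        return {
            "missing": int((self.flags & FLAG_MISSING > 0).sum()),
            "clamped": int((self.flags & FLAG_CLAMPED > 0).sum()),
            "saturated": int((self.flags & kinetics.FLAG_SATURATED > 0).sum()),
            "floored": int((self.flags & kinetics.FLAG_FLOOR > 0).sum()),
        }


def compute_diff(series: AslSeries):
    """Pairwise control-label differences, normalized by M0.

    Returns ``(means, stacks, flags)``: per condition the repeat-mean
    difference map and the per-pair difference stack (last axis = pair), both
    as fractions of M0, plus a flag map marking voxels with nonpositive or
    non-finite M0 (set to NaN, never silently propagated into the mask).
    """
    m0 = np.asarray(series.m0, dtype=float)
    bad = ~np.isfinite(m0) | (m0 <= 0)
    flags = np.where(bad, np.uint8(FLAG_MISSING), np.uint8(0))
    safe_m0 = np.where(bad, 1.0, m0)
    means: dict[Condition, np.ndarray] = {}
    stacks: dict[Condition, np.ndarray] = {}
    for cond, vol in series.data.items():
        ctrl = vol[..., 0::2] if series.order == "control-first" else vol[..., 1::2]
        lab = vol[..., 1::2] if series.order == "control-first" else vol[..., 0::2]
        if ctrl.shape[-1] != lab.shape[-1]:
            raise ValueError(f"condition {cond}: mismatched control/label counts")
        stack = (ctrl - lab) / safe_m0[..., None]
        stack[bad] = np.nan
        stacks[cond] = stack
        means[cond] = stack.mean(axis=-1)
    return means, stacks, flags


def pca_denoise(stack: np.ndarray, retain_fraction: float = 0.8, mask=None):
    """Remove high-variance structured noise from a repeat difference stack.

    The repeat-mean difference (the perfusion signal proper) is removed,
    principal components of the residual repeat-by-voxel matrix are ranked by
    variance, and the minimal leading (highest-variance) set whose removal
    leaves at most ``retain_fraction`` of the residual variance is discarded
    as structured physiological noise.  The repeat mean is restored exactly,
    so the mean difference map is untouched.  ``retain_fraction=1`` is the
    identity.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must lie in (0, 1]")
    stack = np.asarray(stack, dtype=float)
    n_rep = stack.shape[-1]
    if n_rep < 3:
        raise ValueError("need at least 3 repeats for PCA denoising")
    if retain_fraction == 1.0:
        return stack.copy()
    grid = stack.shape[:-1]
    if mask is None:
        mask = np.isfinite(stack).all(axis=-1)
    x = stack[mask]  # (V, n_rep)
    mu = x.mean(axis=1, keepdims=True)
    resid = (x - mu).T  # (n_rep, V)
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return stack.copy()
    # discard the smallest leading set whose removal leaves <= retain_fraction
    remaining = 1.0 - np.cumsum(var) / total
    n_discard = int(np.searchsorted(-remaining, -retain_fraction) + 1)
    n_discard = min(n_discard, len(var))
    noise = u[:, :n_discard] * s[:n_discard] @ vt[:n_discard]
    clean = resid - noise
    clean -= clean.mean(axis=0, keepdims=True)  # repeat mean preserved exactly
    out = stack.copy()
    out[mask] = mu + clean.T
    return out


def map_att(diff_uncrushed, diff_crushed, proto: AcquisitionProtocol, pld: float = 0.9):
    """FEAST transit-time map from the short-PLD crushed/uncrushed pair.

    Returns ``(att_ms, flags)``.  The ratio is clamped into (0, 1] with a
    clamp flag; voxels with nonpositive or non-finite uncrushed signal are
    missing.
    """
    un = np.asarray(diff_uncrushed, dtype=float)
    cr = np.asarray(diff_crushed, dtype=float)
    flags = np.zeros(un.shape, dtype=np.uint8)
    ok = np.isfinite(un) & np.isfinite(cr) & (un > 0)
    flags[~ok] |= FLAG_MISSING
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ok, cr / np.where(ok, un, 1.0), np.nan)
    clamp_hi = ok & (r > 1.0)
    clamp_lo = ok & (r <= 0.0)
    eps = 1e-12
    r = np.where(clamp_hi, 1.0, r)
    r = np.where(clamp_lo, eps, r)
    flags[clamp_hi | clamp_lo] |= FLAG_CLAMPED
    att, inv_flags = kinetics.feast_invert_att(r, proto, pld=pld)
    flags |= np.asarray(inv_flags, dtype=np.uint8)
    return att, flags


def map_cbf(
    diff_b0,
    att_map,
    proto: AcquisitionProtocol,
    pld: float = 1.8,
    mode: str = "att",
    kw_map=None,
    r1t=None,
    m0=None,
):
    """CBF map from the long-PLD b=0 difference signal.

    ``diff_b0`` is expected as a fraction of M0 (pass ``m0`` to normalize raw
    differences).  ``mode`` selects the transit-time-aware exact inverse or
    the consensus white-paper closed form.  If ``kw_map`` is given, the
    att-aware mode inverts the two-compartment total signal (which differs
    from the single-compartment total whenever T1t != T1b), making the
    inversion consistent with water exchange already estimated.
    """
    dm = np.asarray(diff_b0, dtype=float)
    if m0 is not None:
        m0 = np.asarray(m0, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dm = np.where(m0 > 0, dm / np.where(m0 > 0, m0, 1.0), np.nan)
    flags = np.where(np.isfinite(dm), np.uint8(0), np.uint8(FLAG_MISSING))
    if mode == "att" and kw_map is not None:
        sig = kinetics.spa_forward(
            PhysioState(cbf=1.0, att=att_map, kw=kw_map), proto, pld, r1t=r1t
        )
        unit = np.asarray(sig.dM_total, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cbf = np.where(unit > 0, dm / np.where(unit > 0, unit, 1.0), np.nan)
        neg = cbf < 0
        if np.any(neg):
            log.info("map_cbf: clipped %d negative CBF voxels", int(np.sum(neg)))
        cbf = np.where(neg, 0.0, cbf)
        flags = flags | np.where(neg, np.uint8(kinetics.FLAG_FLOOR), np.uint8(0))
    else:
        cbf = kinetics.buxton_invert_cbf(dm, att_map, proto, pld, mode=mode)
        cbf = np.asarray(cbf, dtype=float)
    return cbf, flags


def map_kw(
    diff_b0,
    diff_crushed,
    att_map,
    proto: AcquisitionProtocol,
    r1t=None,
    pld: float = 1.8,
    reg_weight: float = 0.0,
    mask=None,
):
    """kw map from the long-PLD diffusion-weighted signal ratio.

    The ratio A = crushed/uncrushed is clamped into [0, 1) (flagged), then
    optionally denoised by edge-preserving total-variation minimization
    (``reg_weight > 0``) before the monotone kw inversion.
    """
    if reg_weight < 0:
        raise ValueError("reg_weight must be nonnegative")
    un = np.asarray(diff_b0, dtype=float)
    cr = np.asarray(diff_crushed, dtype=float)
    flags = np.zeros(un.shape, dtype=np.uint8)
    ok = np.isfinite(un) & np.isfinite(cr) & (un > 0) & np.isfinite(
        np.asarray(att_map, dtype=float)
    )
    flags[~ok] |= FLAG_MISSING
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(ok, cr / np.where(ok, un, 1.0), np.nan)
    hi = ok & (a >= 1.0)
    lo = ok & (a < 0.0)
    a = np.where(hi, np.nextafter(1.0, 0.0), a)
    a = np.where(lo, 0.0, a)
    flags[hi | lo] |= FLAG_CLAMPED
    if reg_weight > 0:
        reg_mask = ok if mask is None else (ok & mask)
        a = tv_regularize(a, reg_weight, mask=reg_mask)
        a = np.clip(a, 0.0, np.nextafter(1.0, 0.0))
    kw = np.full(un.shape, np.nan)
    if ok.any():
        kw_ok, kw_flags = kinetics.spa_invert_kw(
            a[ok],
            np.asarray(att_map, dtype=float)[ok],
            r1t=None if r1t is None else np.broadcast_to(r1t, un.shape)[ok],
            proto=proto,
            pld=pld,
        )
        kw[ok] = kw_ok
        flags[ok] |= np.asarray(kw_flags, dtype=np.uint8)
    return kw, flags


def _difference_matrix(mask: np.ndarray) -> sp.csr_matrix:
    """Sparse first-difference operator between neighboring in-mask voxels."""
    idx = -np.ones(mask.shape, dtype=int)
    idx[mask] = np.arange(int(mask.sum()))
    rows_i, rows_j = [], []
    for ax in range(mask.ndim):
        sl_a = [slice(None)] * mask.ndim
        sl_b = [slice(None)] * mask.ndim
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        a = idx[tuple(sl_a)].ravel()
        b = idx[tuple(sl_b)].ravel()
        keep = (a >= 0) & (b >= 0)
        rows_i.append(a[keep])
        rows_j.append(b[keep])
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    n_edges = i.size
    n = int(mask.sum())
    data = np.concatenate([np.ones(n_edges), -np.ones(n_edges)])
    rows = np.concatenate([np.arange(n_edges), np.arange(n_edges)])
    cols = np.concatenate([i, j])
    return sp.csr_matrix((data, (rows, cols)), shape=(n_edges, n))


def tv_regularize(
    field: np.ndarray,
    weight: float,
    mask=None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    rho: float = 1.0,
):
    """Anisotropic total-variation denoising: argmin_u 1/2||u-f||^2 + w*TV(u).

    Solved by ADMM with an exact sparse linear solve per iteration; operates
    only on in-mask voxels (out-of-mask values pass through unchanged).
    ``weight=0`` is the identity; the solution's TV never exceeds the
    input's.  Emits a warning and returns the last iterate if the residuals
    have not converged after ``max_iter`` sweeps.
    """
    if weight < 0:
        raise ValueError("weight must be nonnegative")
    field = np.asarray(field, dtype=float)
    if weight == 0:
        return field.copy()
    if mask is None:
        mask = np.isfinite(field)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(field)
    out = field.copy()
    f = field[mask]
    n = f.size
    if n == 0:
        return out
    d = _difference_matrix(mask)
    if d.shape[0] == 0:
        return out
    lhs = (sp.eye(n) + rho * (d.T @ d)).tocsc()
    solve = spla.factorized(lhs)
    u = f.copy()
    z = d @ u
    y = np.zeros_like(z)
    converged = False
    for _ in range(max_iter):
        u = solve(f + rho * (d.T @ (z - y)))
        du = d @ u
        z_old = z
        z = np.sign(du + y) * np.maximum(np.abs(du + y) - weight / rho, 0.0)
        y = y + du - z
        r_prim = np.linalg.norm(du - z)
        r_dual = rho * np.linalg.norm(d.T @ (z - z_old))
        eps_pri = 1e-8 * np.sqrt(len(z)) + tol * max(
            np.linalg.norm(du), np.linalg.norm(z)
        )
        eps_dual = 1e-8 * np.sqrt(n) + tol * rho * np.linalg.norm(d.T @ y)
        if r_prim <= eps_pri and r_dual <= eps_dual:
            converged = True
            break
    if not converged:
        warnings.warn("tv_regularize: ADMM did not converge; returning last iterate")
    out[mask] = u
    return out


def quantify_series(
    series: AslSeries,
    proto: AcquisitionProtocol,
    reg_weight: float = 0.0,
    cbf_mode: str = "att",
    r1t_map=None,
    pca_retain: float | None = None,
) -> ParameterMaps:
    """Full quantification: series -> (CBF, ATT, kw) maps.

    Conditions are identified from the protocol: the shortest PLD pair feeds
    the FEAST ATT inversion, the longest PLD pair the kw and CBF inversions.
    Order of operations: differencing (+ optional PCA denoising with
    ``pca_retain``), ATT, kw, then CBF (att-aware mode inverts the
    two-compartment total using the recovered kw).
    """
    means, stacks, diff_flags = compute_diff(series)
    if pca_retain is not None:
        means = {
            cond: pca_denoise(stack, retain_fraction=pca_retain).mean(axis=-1)
            for cond, stack in stacks.items()
        }
    pld_short, pld_long = min(proto.plds), max(proto.plds)
    b_short = proto.b_values_per_pld[proto.plds.index(pld_short)]
    b_long = proto.b_values_per_pld[proto.plds.index(pld_long)]

    att, att_flags = map_att(
        means[(pld_short, b_short[0])], means[(pld_short, b_short[1])], proto, pld_short
    )
    kw, kw_flags = map_kw(
        means[(pld_long, b_long[0])],
        means[(pld_long, b_long[1])],
        att,
        proto,
        r1t=r1t_map,
        pld=pld_long,
        reg_weight=reg_weight,
        mask=series.mask,
    )
    cbf, cbf_flags = map_cbf(
        means[(pld_long, b_long[0])],
        att,
        proto,
        pld=pld_long,
        mode=cbf_mode,
        kw_map=kw if cbf_mode == "att" else None,
        r1t=r1t_map,
    )
    flags = diff_flags | att_flags | kw_flags | cbf_flags
    outside = ~series.mask
    for arr in (cbf, att, kw):
        arr[outside] = np.nan
    flags[outside] |= FLAG_MISSING
    maps = ParameterMaps(cbf=cbf, att=att, kw=kw, flags=flags)
    log.info("quantify_series flags: %s", maps.counts())
    return maps
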