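"""Kinetic models linking (CBF, ATT, kw) to DP-pCASL difference signals.

The forward models are the single-compartment continuous-labeling (Buxton)
solution and a two-compartment single-pass approximation (SPA) in which
labeled water is delivered to a capillary pool (relaxing at the blood rate
R1b = 1/T1b) and exchanges into a tissue pool (relaxing at R1t = 1/T1t) at
the blood-brain-barrier water-exchange rate kw.  No venous outflow of label
is modeled (single pass).

Unit conventions (package-wide):

* externally, ATT is in milliseconds, kw in min^-1 and CBF in ml/100g/min;
* internally, times are seconds, rates s^-1, and the delivered flux is
  f = CBF / (6000 * lambda) in s^-1 per unit tissue volume;
* all signals are expressed as fractions of the equilibrium magnetization M0.

The diffusion weightings are idealized: b = 50 s/mm^2 at the long PLD is a
perfect crusher of capillary label (the tissue compartment alone survives),
b = 0 is crusher-free, and the b = 14 s/mm^2 signal at the short PLD reflects
label that has arrived by the voxel's transit time while the b = 0 reference
assumes the earliest arrival ``att_floor`` (FEAST ratio).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = [
    "PhysioState",
    "CompartmentSignal",
    "FLAG_NONE",
    "FLAG_MISSING",
    "FLAG_CLAMPED",
    "FLAG_SATURATED",
    "FLAG_FLOOR",
    "buxton_forward",
    "buxton_invert_cbf",
    "spa_forward",
    "spa_ratio",
    "spa_invert_kw",
    "feast_ratio",
    "feast_invert_att",
    "kw_att_sensitivity",
]

log = logging.getLogger(__name__)

MS = 1000.0

# bit flags shared by inversion routines and the map-level quantification
FLAG_NONE = 0
FLAG_MISSING = 1  # input missing / not invertible
FLAG_CLAMPED = 2  # input clamped into the valid domain
FLAG_SATURATED = 4  # inversion hit the upper search bound
FLAG_FLOOR = 8  # inversion clamped at the lower bound


@dataclasses.dataclass(frozen=True)
class PhysioState:
    """Per-voxel (or per-subject) physiological parameter triplet.

    cbf in ml/100g/min, att in ms, kw in min^-1.  Fields may be scalars or
    numpy arrays of a common shape.
    """

    cbf: np.ndarray | float
    att: np.ndarray | float
    kw: np.ndarray | float = 0.0

    def validate(self, proto: AcquisitionProtocol) -> None:
        cbf, att, kw = map(np.asarray, (self.cbf, self.att, self.kw))
        if np.any(cbf < 0):
            raise ValueError("cbf must be nonnegative")
        if np.any(kw < 0):
            raise ValueError("kw must be nonnegative")
        lo = proto.att_floor * MS
        hi = (proto.label_dur + proto.pld_max) * MS
        if np.any(att < lo) or np.any(att > hi):
            raise ValueError(f"att must lie in [{lo}, {hi}] ms")


@dataclasses.dataclass(frozen=True)
class CompartmentSignal:
    """Capillary and tissue label content as fractions of M0."""

    dM_cap: np.ndarray | float
    dM_tis: np.ndarray | float

    @property
    def dM_total(self) -> np.ndarray | float:
        return self.dM_cap + self.dM_tis


def _flux(cbf, proto: AcquisitionProtocol):
    """Delivered label flux in s^-1 (per unit tissue volume, per unit M0a)."""
    return np.asarray(cbf, dtype=float) / (6000.0 * proto.lambda_part)


def buxton_forward(physio: PhysioState, proto: AcquisitionProtocol, pld: float):
    """Single-compartment CASL difference signal at readout time tau + pld.

    Label created continuously during the tau-long labeling block arrives
    delta = att/1000 s after it was created and decays at the blood rate
    1/T1b throughout.  The result is the piecewise rising-then-decaying
    solution, continuous in both readout time and transit time; it is zero
    while no label has arrived (delta >= tau + pld) and reduces to the
    consensus closed form  2 alpha f T1b (1 - e^{-tau/T1b}) e^{-pld/T1b}
    once all label has arrived (delta <= pld).
    """
    if pld < 0:
        raise ValueError("negative post-labeling delay")
    att = np.asarray(physio.att, dtype=float)
    if np.any(att < 0):
        raise ValueError("negative transit time")
    t1b = proto.t1_blood
    tau = proto.label_dur
    f = _flux(physio.cbf, proto)
    delta = att / MS
    t = tau + pld
    avail = t - delta  # time since first label arrival
    dur = np.clip(avail, 0.0, tau)  # portion of the bolus that has arrived
    post = np.clip(avail - tau, 0.0, None)  # decay after the bolus has fully arrived
    dm = (
        2.0
        * proto.label_eff
        * f
        * t1b
        * np.exp(-delta / t1b)
        * (1.0 - np.exp(-dur / t1b))
        * np.exp(-post / t1b)
    )
    return dm if dm.ndim else float(dm)


def buxton_invert_cbf(
    dM,
    att,
    proto: AcquisitionProtocol,
    pld: float,
    mode: str = "att",
):
    """Invert the single-compartment model for CBF (ml/100g/min).

    ``mode="att"`` divides by the forward signal of a unit-CBF voxel at the
    given transit time (exact algebraic inverse, the model being linear in
    CBF).  ``mode="whitepaper"`` applies the consensus closed form, which
    ignores the transit time (valid when att <= pld).  Negative estimates are
    clipped to zero and the clip count logged; non-finite inputs propagate
    as NaN (masked voxels).
    """
    dM = np.asarray(dM, dtype=float)
    if mode == "att":
        unit = buxton_forward(PhysioState(cbf=1.0, att=att), proto, pld)
        unit = np.asarray(unit, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cbf = np.where(unit > 0, dM / np.where(unit > 0, unit, 1.0), np.nan)
    elif mode == "whitepaper":
        t1b = proto.t1_blood
        denom = (
            2.0
            * proto.label_eff
            * t1b
            * (1.0 - np.exp(-proto.label_dur / t1b))
            * np.exp(-pld / t1b)
        )
        cbf = 6000.0 * proto.lambda_part * dM / denom
    else:
        raise ValueError(f"unknown CBF inversion mode: {mode!r}")
    neg = np.asarray(cbf < 0)
    if neg.any():
        log.info("buxton_invert_cbf: clipped %d negative CBF values", int(neg.sum()))
        cbf = np.where(neg, 0.0, cbf)
    cbf = np.where(np.isfinite(dM), cbf, np.nan)
    return cbf if cbf.ndim else float(cbf)


def _dexp(a, b, u):
    """(exp(-a u) - exp(-b u)) / (b - a), with its b -> a limit u exp(-a u)."""
    a, b, u = np.broadcast_arrays(*(np.asarray(x, dtype=float) for x in (a, b, u)))
    diff = b - a
    near = np.abs(diff) < 1e-10
    safe = np.where(near, 1.0, diff)
    out = (np.exp(-a * u) - np.exp(-b * u)) / safe
    lim = u * np.exp(-a * u)
    return np.where(near, lim, out)


def spa_forward(
    physio: PhysioState,
    proto: AcquisitionProtocol,
    pld: float,
    r1t=None,
) -> CompartmentSignal:
    """Two-compartment single-pass solution at readout time tau + pld.

    Capillary pool: filled at rate a(t) = 2 alpha f e^{-delta R1b} during the
    bolus, cleared at R1b + k with k = kw/60 s^-1.  Tissue pool: fed at
    k * dM_cap, relaxing at R1t (default 1/T1_tissue, overridable per voxel).
    Closed-form piecewise solution; both components are nonnegative.
    """
    if pld < 0:
        raise ValueError("negative post-labeling delay")
    r1b = 1.0 / proto.t1_blood
    r1t = np.asarray(1.0 / proto.t1_tissue if r1t is None else r1t, dtype=float)
    tau = proto.label_dur
    k = np.asarray(physio.kw, dtype=float) / 60.0
    f = _flux(physio.cbf, proto)
    delta = np.asarray(physio.att, dtype=float) / MS
    rc = r1b + k

    avail = tau + pld - delta
    d1 = np.clip(avail, 0.0, tau)  # time spent in the inflow phase
    d2 = np.clip(avail - tau, 0.0, None)  # time since inflow ended

    a0 = 2.0 * proto.label_eff * f * np.exp(-delta * r1b)
    with np.errstate(over="ignore"):
        # end of inflow phase
        mc1 = a0 / rc * (1.0 - np.exp(-rc * d1))
        mt1 = (
            a0
            * k
            / rc
            * ((1.0 - np.exp(-r1t * d1)) / r1t - _dexp(rc, r1t, d1))
        )
        # free decay phase
        mc = mc1 * np.exp(-rc * d2)
        mt = mt1 * np.exp(-r1t * d2) + k * mc1 * _dexp(rc, r1t, d2)
    mc = np.where(avail > 0, mc, 0.0)
    mt = np.where(avail > 0, mt, 0.0)
    if mc.ndim == 0:
        return CompartmentSignal(float(mc), float(mt))
    return CompartmentSignal(mc, mt)


def spa_ratio(physio: PhysioState, proto: AcquisitionProtocol, pld: float, r1t=None):
    """Diffusion-weighting signal ratio A = dM_tis / (dM_cap + dM_tis).

    Models b = 50 s/mm^2 as a perfect capillary crusher, so A is the
    crushed/uncrushed ratio.  A is strictly increasing in kw and independent
    of CBF (both compartments scale linearly with the delivered flux).
    Undefined (NaN) where no label has arrived.
    """
    sig = spa_forward(physio, proto, pld, r1t=r1t)
    total = np.asarray(sig.dM_total, dtype=float)
    tis = np.asarray(sig.dM_tis, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, tis / np.where(total > 0, total, 1.0), np.nan)
    return a if a.ndim else float(a)


def spa_invert_kw(
    A,
    att,
    r1t=None,
    proto: AcquisitionProtocol | None = None,
    pld: float = 1.8,
    kw_max: float = 1000.0,
    tol: float = 1e-8,
    max_iter: int = 80,
):
    """Invert the ratio A for kw (min^-1) by vectorized monotone bisection.

    Returns ``(kw, flags)``.  A <= 0 maps to kw = 0 (floor flag when A < 0);
    A at or beyond the ratio of ``kw_max`` maps to ``kw_max`` with the
    saturation flag; NaN propagates with the missing flag.  The bisection
    runs until the model ratio matches A to within ``tol`` everywhere.
    """
    if proto is None:
        proto = AcquisitionProtocol()
    A = np.asarray(A, dtype=float)
    att_arr = np.asarray(att, dtype=float)
    scalar = A.ndim == 0 and att_arr.ndim == 0
    A, att_arr = np.atleast_1d(A), np.atleast_1d(att_arr)
    A, att_arr = np.broadcast_arrays(A, att_arr)
    r1t_arr = np.broadcast_to(
        np.asarray(1.0 / proto.t1_tissue if r1t is None else r1t, dtype=float), A.shape
    )

    def ratio(kw, sel=slice(None)):
        return np.asarray(
            spa_ratio(
                PhysioState(cbf=50.0, att=att_arr[sel], kw=kw),
                proto,
                pld,
                r1t=r1t_arr[sel],
            )
        )

    kw = np.zeros(A.shape)
    flags = np.zeros(A.shape, dtype=np.uint8)
    missing = ~np.isfinite(A)
    flags[missing] |= FLAG_MISSING
    kw[missing] = np.nan

    a_hi = ratio(np.full(A.shape, kw_max))
    sat = np.isfinite(A) & (A >= a_hi)
    kw[sat] = kw_max
    flags[sat] |= FLAG_SATURATED
    floor = np.isfinite(A) & (A <= 0)
    flags[np.isfinite(A) & (A < 0)] |= FLAG_FLOOR

    active = np.isfinite(A) & ~sat & ~floor
    if active.any():
        idx = np.nonzero(active)
        target = A[idx]
        lo = np.zeros(target.shape)
        hi = np.full(target.shape, kw_max)
        mid = 0.5 * (lo + hi)
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            val = ratio(mid, idx)
            err = val - target
            if np.all(np.abs(err) <= tol):
                break
            high = err > 0
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
        kw[idx] = mid
    if scalar:
        return float(kw[0]), int(flags[0])
    return kw, flags


# -- FEAST ------------------------------------------------------------------

_FEAST_CACHE: dict = {}


def _feast_table(proto: AcquisitionProtocol, pld: float):
    key = (proto, pld)
    tab = _FEAST_CACHE.get(key)
    if tab is None:
        lo = proto.att_floor * MS
        hi = (proto.label_dur + pld) * MS
        att_grid = np.arange(lo, hi, 1.0)  # 1 ms grid
        r = np.asarray(
            feast_ratio(att_grid, proto, pld=pld), dtype=float
        )
        # keep the strictly decreasing tail (r is flat at 1 for att <= pld)
        dec = np.nonzero(np.diff(r) < 0)[0]
        start = dec[0] if dec.size else 0
        tab = (att_grid[start:], r[start:])
        _FEAST_CACHE[key] = tab
    return tab


def feast_ratio(att, proto: AcquisitionProtocol, pld: float = 0.9):
    """Crushed/uncrushed FEAST signal ratio r(att) in (0, 1].

    r = buxton_forward(att) / buxton_forward(att_floor): the b = 14 s/mm^2
    signal reflects label arrived by the voxel transit time, the b = 0
    reference assumes the earliest arrival att_floor.  r equals 1 wherever
    the whole bolus has arrived (att <= pld) and decreases strictly to 0 on
    (pld, pld + tau).
    """
    att = np.asarray(att, dtype=float)
    lo = proto.att_floor * MS
    hi = (proto.label_dur + pld) * MS
    if np.any(att < lo) or np.any(att >= hi):
        raise ValueError(f"att outside FEAST domain [{lo}, {hi}) ms")
    num = buxton_forward(PhysioState(cbf=1.0, att=att), proto, pld)
    den = buxton_forward(PhysioState(cbf=1.0, att=lo), proto, pld)
    r = np.asarray(num, dtype=float) / den
    return r if r.ndim else float(r)


def feast_invert_att(r, proto: AcquisitionProtocol, pld: float = 0.9):
    """Invert the FEAST ratio for ATT (ms) by table lookup + interpolation.

    Returns ``(att, flags)``.  r >= 1 maps to att_floor (clamp flag when
    r > 1); r <= 0 or non-finite is missing (NaN).  The lookup uses a 1 ms
    grid, so the inversion is accurate to about 1 ms.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).astype(float)
    att_grid, r_grid = _feast_table(proto, pld)
    flags = np.zeros(r.shape, dtype=np.uint8)
    att = np.full(r.shape, np.nan)

    missing = ~np.isfinite(r) | (r <= 0)
    flags[missing] |= FLAG_MISSING
    high = np.isfinite(r) & (r >= 1.0)
    att[high] = proto.att_floor * MS
    flags[np.isfinite(r) & (r > 1.0)] |= FLAG_CLAMPED

    ok = np.isfinite(r) & (r > 0) & (r < 1.0)
    if ok.any():
        # np.interp needs ascending xp: r_grid is strictly decreasing
        att[ok] = np.interp(r[ok], r_grid[::-1], att_grid[::-1])
    if scalar:
        return float(att[0]), int(flags[0])
    return att, flags


def kw_att_sensitivity(
    A,
    att,
    att_shift,
    r1t=None,
    proto: AcquisitionProtocol | None = None,
    pld: float = 1.8,
    **kwargs,
):
    """kw re-estimated after shifting ATT by ``att_shift`` ms.

    Used to ask whether an observed kw difference between groups could be an
    artifact of a transit-time difference (e.g. re-estimating female kw with
    ATT lengthened by 60 ms to match the male mean).  Returns the same
    ``(kw, flags)`` as :func:`spa_invert_kw` at the shifted transit time.
    """
    if proto is None:
        proto = AcquisitionProtocol()
    shifted = np.asarray(att, dtype=float) + att_shift
    if np.any(shifted >= (proto.label_dur + pld) * MS) or np.any(shifted < 0):
        raise ValueError("shifted att outside the model domain")
    return spa_invert_kw(A, shifted, r1t=r1t, proto=proto, pld=pld, **kwargs)
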