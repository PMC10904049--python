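"""Whole-cell and single-channel Ca(V)1.2 current analysis.

Whole-cell side: linear leak removal (P/3 sub-pulse protocol, or
subtraction of the Cd2+-insensitive background), liquid-junction
correction, Boltzmann fits of I-V relations

    I(V) = G_max (V - V_rev) / (1 + exp(-(V - V50)/k))

and per-voltage conductance fold changes between conditions on ramp
families, with conductance optionally normalized to cell capacitance.

Single-channel side: half-height idealization of ramp or step sweeps
against a calibrated unitary current line i(V) = gamma (V - V_rev,sc),
ensemble open probability per voltage bin normalized by the channel count,
channel counting from maximal stacked openings under agonist, and
Boltzmann fits of P_O(V).  Fractional shortening of sarcomere-length
traces is included as the contractility read-out.

Convention: sweep currents are expressed relative to the holding current,
so a purely affine (ohmic + offset) leak is annihilated exactly by P/3
subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class IVCurve:
    """Current-voltage relation on a strictly increasing voltage grid."""

    voltages: np.ndarray  # mV, junction-corrected
    currents: np.ndarray  # pA (or pA/pF if normalized)
    capacitance: float | None = None  # pF

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, float)
        i = np.asarray(self.currents, float)
        if v.shape != i.shape:
            raise ValueError("voltages and currents must have equal length")
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltages must be strictly increasing")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)


@dataclass(frozen=True)
class BoltzmannIvFit:
    g_max: float     # nS (or nS/pF)
    v50: float       # mV
    k_slope: float   # mV
    v_rev: float     # mV
    residual_norm: float


@dataclass(frozen=True)
class UnitaryIV:
    """Open-channel current line i(V) = gamma * (V - v_rev_sc)."""

    gamma: float     # slope conductance, pA/mV; sign of i carried by (V - v_rev_sc)
    v_rev_sc: float  # single-channel reversal potential, mV

    def __call__(self, v_mV):
        return self.gamma * (np.asarray(v_mV, float) - self.v_rev_sc)


@dataclass(frozen=True)
class SingleChannelSweep:
    time_ms: np.ndarray
    current_pA: np.ndarray
    voltage_mV: np.ndarray
    sampling_rate_khz: float
    filter_cutoff_khz: float | None = None


@dataclass(frozen=True)
class IdealizedTrace:
    """Per-sample stacked open count with a validity mask."""

    state: np.ndarray     # int, 0..n_channels
    valid: np.ndarray     # bool; False where |i(V)| under the noise floor
    voltage_mV: np.ndarray
    n_channels: int
    baseline_pA: float


@dataclass(frozen=True)
class PoCurve:
    voltages: np.ndarray  # bin centers, mV
    po: np.ndarray        # per-channel open probability in [0, 1]
    n_sweeps: int
    n_channels: int


# ---------------------------------------------------------------- whole-cell

def p3_leak_subtract(main_sweep, sub_sweeps) -> np.ndarray:
    """Remove linear leak using three 1/3-amplitude sub-pulse sweeps.

    corrected = main - 3 * mean(sub_sweeps).  With sweeps expressed
    relative to holding, any current affine in voltage cancels exactly.
    """
    main = np.asarray(main_sweep, float)
    subs = np.asarray(sub_sweeps, float)
    if subs.ndim != 2 or subs.shape[1] != main.shape[0]:
        raise ValueError("sub sweeps must match the main sweep length")
    return main - 3.0 * subs.mean(axis=0)


def cd_subtract(iv_total: IVCurve, iv_cd: IVCurve) -> IVCurve:
    """Isolate the Cd2+-sensitive Ca-channel current by pointwise subtraction."""
    if not np.array_equal(iv_total.voltages, iv_cd.voltages):
        raise ValueError("voltage grids differ")
    return IVCurve(voltages=iv_total.voltages,
                   currents=iv_total.currents - iv_cd.currents,
                   capacitance=iv_total.capacitance)


def junction_correct(voltages, offset: float = -10.0) -> np.ndarray:
    """Apply a liquid-junction-potential offset (mV) to all voltages."""
    return np.asarray(voltages, float) + offset


def boltzmann_iv(v, g_max, v50, k, v_rev):
    v = np.asarray(v, float)
    arg = np.clip(-(v - v50) / k, -700.0, 700.0)  # multistart can wander
    return g_max * (v - v_rev) / (1.0 + np.exp(arg))


def fit_iv_boltzmann(iv: IVCurve, v_rev_init: float = 60.0,
                     seed: int = 0) -> BoltzmannIvFit:
    """Nonlinear least-squares Boltzmann fit of an I-V relation.

    Five multistart initializations (seeded jitter around data-driven
    guesses); ties broken by lowest residual norm, then lowest |V50|.
    """
    v, i = iv.voltages, iv.currents
    if len(v) < 8:
        raise ValueError("need >= 8 voltage points")
    rng = np.random.default_rng(seed)
    peak = i[np.argmax(np.abs(i))]
    g0 = abs(peak) / max(abs(v_rev_init - v[np.argmax(np.abs(i))]), 1.0) * 2
    candidates = []
    for trial in range(5):
        p0 = (g0 * (1 + 0.3 * rng.standard_normal()),
              float(rng.uniform(v.min(), 0.5 * (v.min() + v.max()))),
              float(rng.uniform(3.0, 12.0)),
              v_rev_init + 5.0 * rng.standard_normal())
        try:
            popt, _ = curve_fit(boltzmann_iv, v, i, p0=p0, maxfev=5000)
        except RuntimeError:
            continue
        if popt[2] <= 0 or not popt[3] > popt[1]:
            continue
        r = float(np.linalg.norm(i - boltzmann_iv(v, *popt)))
        candidates.append((r, abs(popt[1]), popt))
    if not candidates:
        raise RuntimeError("Boltzmann I-V fit did not converge")
    r, _, popt = min(candidates, key=lambda c: (c[0], c[1]))
    return BoltzmannIvFit(g_max=float(popt[0]), v50=float(popt[1]),
                          k_slope=float(popt[2]), v_rev=float(popt[3]),
                          residual_norm=r)


def ramp_fold_change(before: list[IVCurve], after: list[IVCurve],
                     v_rev: float, exclusion_mV: float = 10.0,
                     normalize_capacitance: bool = False):
    """Per-voltage conductance fold change between two ramp-trace families.

    G(V) = I(V)/(V - v_rev) per trace (divided by capacitance when
    normalizing to cell size), averaged within each condition; the fold is
    G_after/G_before with |V - v_rev| < exclusion_mV masked out.  Returns
    (voltages, fold) restricted to the unmasked grid.
    """
    if len(before) < 10 or len(after) < 10:
        raise ValueError("need >= 10 traces per condition")
    grid = before[0].voltages
    for tr in list(before) + list(after):
        if not np.array_equal(tr.voltages, grid):
            raise ValueError("all traces must share one voltage grid")
        if normalize_capacitance and tr.capacitance is None:
            raise ValueError("capacitance required for normalization")

    keep = np.abs(grid - v_rev) >= exclusion_mV

    def mean_g(traces):
        gs = []
        for tr in traces:
            g = tr.currents[keep] / (grid[keep] - v_rev)
            if normalize_capacitance:
                g = g / tr.capacitance
            gs.append(g)
        return np.mean(gs, axis=0)

    return grid[keep], mean_g(after) / mean_g(before)


# ------------------------------------------------------------ single-channel

def idealize_half_height(sweep: SingleChannelSweep, unitary: UnitaryIV,
                         n_channels: int = 1,
                         min_amp_pA: float = 0.2) -> IdealizedTrace:
    """Half-height idealization of a sweep into stacked open levels.

    The per-sample open count is the baseline-corrected current divided by
    the unitary current i(V), rounded with level thresholds at the
    half-amplitude points (an exact half rounds down), clipped to
    [0, n_channels].  Samples where |i(V)| < ``min_amp_pA`` are flagged
    invalid and excluded from downstream P_O.  Baseline = median of
    closed-classified samples, one refinement pass.
    """
    i_unit = unitary(sweep.voltage_mV)
    valid = np.abs(i_unit) >= min_amp_pA
    cur = np.asarray(sweep.current_pA, float)

    def classify(baseline):
        with np.errstate(divide="ignore", invalid="ignore"):
            level = (cur - baseline) / i_unit
        level = np.where(valid, level, 0.0)
        state = np.ceil(level - 0.5).astype(int)  # half-height, half -> down
        return np.clip(state, 0, n_channels)

    state = classify(0.0)
    closed = valid & (state == 0)
    baseline = float(np.median(cur[closed])) if closed.any() else 0.0
    state = classify(baseline)
    return IdealizedTrace(state=state, valid=valid,
                          voltage_mV=np.asarray(sweep.voltage_mV, float),
                          n_channels=n_channels, baseline_pA=baseline)


def ensemble_po(sweeps: list[IdealizedTrace], n_channels: int,
                v_bin: float = 5.0) -> PoCurve:
    """Per-channel open probability per voltage bin over a sweep ensemble.

    Bins are ``v_bin`` wide and centered on multiples of ``v_bin`` so that
    e.g. P_O at +30 mV comes from the bin [27.5, 32.5).
    """
    if len(sweeps) < 2:
        raise ValueError("need >= 2 sweeps")
    volts = np.concatenate([s.voltage_mV[s.valid] for s in sweeps])
    states = np.concatenate([s.state[s.valid] for s in sweeps])
    if volts.size == 0:
        raise ValueError("no valid samples")
    centers_idx = np.round(volts / v_bin).astype(int)
    uniq = np.unique(centers_idx)
    po = np.array([states[centers_idx == c].mean() / n_channels
                   for c in uniq])
    return PoCurve(voltages=uniq * v_bin, po=po,
                   n_sweeps=len(sweeps), n_channels=n_channels)


def po_at(curve: PoCurve, v_mV: float = 30.0) -> float:
    """P_O from the bin containing the requested voltage."""
    idx = np.argmin(np.abs(curve.voltages - v_mV))
    if abs(curve.voltages[idx] - v_mV) > (curve.voltages[1] - curve.voltages[0]
                                          if len(curve.voltages) > 1 else np.inf):
        raise ValueError(f"no bin near {v_mV} mV")
    return float(curve.po[idx])


def count_channels(sweeps_after_agonist: list[IdealizedTrace]) -> int:
    """Channel count = maximal simultaneous stacked open level under agonist.

    Raises if no openings occurred (count undefined).
    """
    if len(sweeps_after_agonist) < 50:
        raise ValueError("need >= 50 sweeps to count channels")
    m = max(int(s.state[s.valid].max()) if s.valid.any() else 0
            for s in sweeps_after_agonist)
    if m == 0:
        raise ValueError("no openings observed; channel count undefined")
    return m


def boltzmann_po(v, po_max, v50, k):
    arg = np.clip(-(np.asarray(v, float) - v50) / k, -700.0, 700.0)
    return po_max / (1.0 + np.exp(arg))


def fit_po_boltzmann(curve: PoCurve, seed: int = 0):
    """Boltzmann fit of P_O(V); returns (po_max, v50, k_slope)."""
    v, p = curve.voltages, curve.po
    rng = np.random.default_rng(seed)
    candidates = []
    for _ in range(5):
        p0 = (min(max(p.max(), 0.01), 1.0),
              float(rng.uniform(v.min(), v.max())),
              float(rng.uniform(3.0, 12.0)))
        try:
            popt, _ = curve_fit(boltzmann_po, v, p, p0=p0,
                                bounds=([1e-6, -np.inf, 1e-3],
                                        [1.0, np.inf, np.inf]),
                                maxfev=5000)
        except RuntimeError:
            continue
        r = float(np.linalg.norm(p - boltzmann_po(v, *popt)))
        candidates.append((r, abs(popt[1]), popt))
    if not candidates:
        raise RuntimeError("P_O Boltzmann fit did not converge")
    _, _, popt = min(candidates, key=lambda c: (c[0], c[1]))
    return float(popt[0]), float(popt[1]), float(popt[2])


# -------------------------------------------------------------- contractility

def fractional_shortening(time_s, length_um, stim_times_s):
    """Mean fractional shortening over stimulated contractions, in percent.

    Per contraction FS = (L_relax - L_min)/L_relax, with L_relax the
    sarcomere length immediately before the stimulus and L_min the minimum
    before the next stimulus.  Returns (mean_percent, warn_flag); the flag
    is set when fewer than 8 contractions were analyzable.
    """
    t = np.asarray(time_s, float)
    ln = np.asarray(length_um, float)
    fs = []
    stims = sorted(stim_times_s)
    for j, t0 in enumerate(stims):
        t1 = stims[j + 1] if j + 1 < len(stims) else t[-1] + 1e-12
        pre = ln[t < t0]
        win = ln[(t >= t0) & (t < t1)]
        if pre.size == 0 or win.size == 0:
            continue
        l_relax = float(pre[-1])
        l_min = float(win.min())
        if l_relax <= 0:
            continue
        fs.append((l_relax - l_min) / l_relax)
    if not fs:
        raise ValueError("no analyzable contractions")
    return 100.0 * float(np.mean(fs)), len(fs) < 8
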