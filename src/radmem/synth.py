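"""Seeded generators for every input modality the analysis modules consume.

Each generator is a forward model of the corresponding measurement:

* ``gen_flow_fret`` — lognormally expressed donor/acceptor pairs binding by
  1:1 mass action, plus a collisional FRET component proportional to the
  membrane-localized acceptor density, pushed through the exact 3-cube
  intensity model (so the noise-free output is exactly invertible by
  :mod:`radmem.fretflow`).
* ``gen_cell_image`` — non-overlapping elliptical cells with a bright
  membrane rim over cytosolic fluorescence, Poisson + Gaussian noise.
* ``gen_channel_sweeps`` — two-state Markov gating simulated exactly with
  piecewise-constant rates per sample on a voltage ramp (or hold), unitary
  current synthesis and optional Bessel low-pass filtering.
* ``gen_iv`` — Boltzmann-activated channel current plus linear leak, with a
  matching leak-only background for subtraction tests.
* ``gen_sequences`` — a basic-hydrophobic C-terminal protein with named
  phospho-site variants (S->A, S->D) derived deterministically from one
  base record.
* ``gen_shortening`` — periodic sarcomere-shortening transients.

Every generator takes a master ``seed`` and derives one independent RNG
stream per modality (``default_rng([seed, crc32(modality)])``), so adding
a generator never perturbs the others, and returns a machine-readable
truth record alongside the data.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict

import numpy as np
import pandas as pd
from scipy import signal

from .ephys import IVCurve, SingleChannelSweep, UnitaryIV, boltzmann_iv
from .fretflow import SpectralParams, free_acceptor
from .seqcharge import ProteinSequence


def modality_rng(seed: int, modality: str) -> np.random.Generator:
    """Independent RNG stream for one modality, derived from the master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(modality.encode())])


# ------------------------------------------------------------------ flow FRET

def gen_flow_fret(seed: int, n_events: int = 2000, kd: float = 100.0,
                  e_d_max: float = 0.3, f_mem: float = 0.0,
                  coll_coeff: float = 0.0,
                  mu_d: float = 0.0, sigma_d: float = 1.0,
                  mu_a: float = 0.0, sigma_a: float = 1.0,
                  expression_scale: float = 100.0,
                  noise_sigma: float = 0.02,
                  params: SpectralParams = SpectralParams()):
    """Forward 3-cube model of a FRET 2-hybrid flow experiment.

    Donor/acceptor totals are lognormal(mu, sigma) * expression_scale;
    binding FRET is ``e_d_max * bound/d_total`` by mass action at the true
    ``kd`` (``kd=inf`` disables binding); collisional FRET adds
    ``coll_coeff * f_mem * a_total``.  Gaussian noise of SD ``noise_sigma``
    is added to E_D before synthesizing intensities, so the noise-free
    limit round-trips exactly through ``compute_fret_points``.

    Returns ``(events DataFrame with s_dd,s_da,s_aa, truth dict)``.
    """
    rng = modality_rng(seed, "flow_fret")
    d = expression_scale * rng.lognormal(mu_d, sigma_d, n_events)
    a = expression_scale * rng.lognormal(mu_a, sigma_a, n_events)
    if np.isfinite(kd):
        a_free = free_acceptor(d, a, kd)
        bound_frac = a_free / (kd + a_free)  # = bound/d_total by mass action
    else:
        bound_frac = np.zeros(n_events)
    e_d = e_d_max * bound_frac + coll_coeff * f_mem * a
    if noise_sigma > 0:
        e_d = e_d + rng.normal(0.0, noise_sigma, n_events)
    d_quenched = d / params.f_d            # s_dd + F_c/G
    s_aa = a / params.f_a
    s_dd = (1.0 - e_d) * d_quenched
    f_c = params.g_factor * e_d * d_quenched
    s_da = f_c + params.r_d * s_dd + params.r_a * s_aa
    events = pd.DataFrame({"s_dd": s_dd, "s_da": s_da, "s_aa": s_aa})
    truth = {"seed": seed, "modality": "flow_fret", "n_events": n_events,
             "kd": kd, "e_d_max": e_d_max, "f_mem": f_mem,
             "coll_coeff": coll_coeff, "mu_d": mu_d, "sigma_d": sigma_d,
             "mu_a": mu_a, "sigma_a": sigma_a,
             "expression_scale": expression_scale,
             "noise_sigma": noise_sigma, "params": asdict(params)}
    return events, truth


# ------------------------------------------------------------------- imaging

def gen_cell_image(seed: int, shape: tuple[int, int] = (512, 512),
                   n_cells: int = 8, radius_range: tuple[int, int] = (20, 40),
                   rim_width: int = 2, contrast: float = 4.0,
                   cytosol_level: float = 200.0, background: float = 20.0,
                   poisson_noise: bool = True, gauss_sigma: float = 2.0,
                   max_attempts: int = 1000):
    """Synthetic micrograph: bright-rimmed elliptical cells on dark background.

    Rim intensity = contrast * cytosol_level over a rim of ``rim_width``
    pixels (peeled by 8-connected erosion, mirroring the analysis).  Cells
    are placed without overlap (with a 4-px moat); placement failure after
    ``max_attempts`` raises.  Returns ``(image float64 array, truth
    DataFrame with cell, row, col, a, b, area, contrast)``.
    """
    from scipy import ndimage
    from skimage.draw import ellipse

    rng = modality_rng(seed, "image")
    h, w = shape
    occupied = np.zeros(shape, bool)
    img = np.full(shape, background, float)
    rows = []
    placed = 0
    attempts = 0
    while placed < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells")
        a = rng.integers(radius_range[0], radius_range[1] + 1)
        b = rng.integers(radius_range[0], radius_range[1] + 1)
        cy = rng.integers(a + 2, h - a - 2)
        cx = rng.integers(b + 2, w - b - 2)
        rr, cc = ellipse(cy, cx, a, b, shape=shape)
        mask = np.zeros(shape, bool)
        mask[rr, cc] = True
        moat = ndimage.binary_dilation(mask, iterations=4)
        if (moat & occupied).any():
            continue
        occupied |= moat
        interior = mask
        for _ in range(rim_width):
            interior = ndimage.binary_erosion(interior, np.ones((3, 3), bool))
        rim = mask & ~interior
        img[interior] = cytosol_level
        img[rim] = contrast * cytosol_level
        rows.append({"cell": placed + 1, "row": int(cy), "col": int(cx),
                     "a": int(a), "b": int(b), "area": int(mask.sum()),
                     "contrast": contrast})
        placed += 1
    if poisson_noise:
        img = rng.poisson(img).astype(float)
    if gauss_sigma > 0:
        img = img + rng.normal(0.0, gauss_sigma, shape)
    img = np.clip(img, 0.0, None)
    return img, pd.DataFrame(rows)


# ------------------------------------------------------------ single channel

def _simulate_two_state(rng, k_open: np.ndarray, k_close: float,
                        dt_s: float, start_open: bool = False) -> np.ndarray:
    """Exact jump simulation with per-sample piecewise-constant rates.

    The state is recorded at each sample boundary; within a sample the
    waiting times are exponential with that sample's rates.
    """
    n = len(k_open)
    state = np.empty(n, bool)
    s = start_open
    for i in range(n):
        state[i] = s
        remaining = dt_s
        while True:
            rate = k_close if s else k_open[i]
            if rate <= 0:
                break
            dwell = rng.exponential(1.0 / rate)
            if dwell >= remaining:
                break
            remaining -= dwell
            s = not s
    return state


def gen_channel_sweeps(seed: int, n_sweeps: int = 100, n_channels: int = 1,
                       duration_ms: float = 200.0,
                       sampling_khz: float = 10.0,
                       v_start: float = -80.0, v_end: float = 70.0,
                       hold_mV: float | None = None,
                       k_open0: float = 50.0, v_e_mV: float = 20.0,
                       k_close: float = 200.0,
                       unitary: UnitaryIV = UnitaryIV(gamma=0.05,
                                                      v_rev_sc=60.0),
                       noise_sd_frac: float = 0.15,
                       filter_khz: float | None = 2.0):
    """Two-state Markov channel gating on a voltage ramp (or fixed hold).

    Opening rate ``k_open(V) = k_open0 * exp(V / v_e_mV)`` (evaluated at
    ``hold_mV`` when holding, in which case the rate is ``k_open0``
    constant if ``v_e_mV`` is None-like; pass ``v_e_mV=np.inf`` for
    voltage-independent opening), closing rate constant.  Channels gate
    independently; the summed state drives
    ``i = state * gamma * (V - V_rev,sc) + noise`` with Gaussian noise of
    SD ``noise_sd_frac * |i_unitary|`` (floored at its ramp median), then
    an optional 4-pole low-pass Bessel filter.

    Returns ``(list of SingleChannelSweep, list of true state arrays,
    truth dict)``.
    """
    rng = modality_rng(seed, "channel")
    n = int(round(duration_ms * sampling_khz))
    t_ms = np.arange(n) / sampling_khz
    if hold_mV is not None:
        v = np.full(n, float(hold_mV))
    else:
        v = v_start + (v_end - v_start) * t_ms / duration_ms
    dt_s = 1e-3 / sampling_khz
    k_open = k_open0 * np.exp(v / v_e_mV) if np.isfinite(v_e_mV) \
        else np.full(n, k_open0)
    i_unit = unitary(v)
    amp_ref = np.median(np.abs(i_unit))
    noise_sd = noise_sd_frac * amp_ref
    sos = None
    if filter_khz is not None:
        sos = signal.bessel(4, filter_khz * 1e3, btype="low",
                            fs=sampling_khz * 1e3, output="sos")
    sweeps, truths = [], []
    for _ in range(n_sweeps):
        total = np.zeros(n, int)
        for _ch in range(n_channels):
            p_open0 = k_open[0] / (k_open[0] + k_close)
            total += _simulate_two_state(
                rng, k_open, k_close, dt_s,
                start_open=bool(rng.random() < p_open0))
        cur = total * i_unit
        if noise_sd > 0:
            cur = cur + rng.normal(0.0, noise_sd, n)
        if sos is not None:
            cur = signal.sosfilt(sos, cur)
        sweeps.append(SingleChannelSweep(
            time_ms=t_ms, current_pA=cur, voltage_mV=v,
            sampling_rate_khz=sampling_khz, filter_cutoff_khz=filter_khz))
        truths.append(total)
    truth = {"seed": seed, "modality": "channel", "n_sweeps": n_sweeps,
             "n_channels": n_channels, "k_open0": k_open0,
             "v_e_mV": v_e_mV, "k_close": k_close,
             "gamma": unitary.gamma, "v_rev_sc": unitary.v_rev_sc,
             "hold_mV": hold_mV, "noise_sd": float(noise_sd),
             "filter_khz": filter_khz, "sampling_khz": sampling_khz}
    return sweeps, truths, truth


# ------------------------------------------------------------------ I-V data

def gen_iv(seed: int, v_min: float = -60.0, v_max: float = 60.0,
           step: float = 5.0, g_max: float = 10.0, v50: float = -15.0,
           k_slope: float = 6.0, v_rev: float = 60.0,
           g_leak: float = 1.0, noise_sd: float = 0.0,
           capacitance: float | None = None):
    """Boltzmann-activated I-V plus linear leak, with a leak-only background.

    Returns ``(iv_total, iv_background, truth)``; subtracting the
    background (the Cd2+-insensitive component) recovers the channel
    current exactly in the noise-free limit.
    """
    rng = modality_rng(seed, "iv")
    v = np.arange(v_min, v_max + step / 2, step)
    chan = boltzmann_iv(v, g_max, v50, k_slope, v_rev)
    leak = g_leak * v
    noise = rng.normal(0.0, noise_sd, v.shape) if noise_sd > 0 else 0.0
    iv_total = IVCurve(voltages=v, currents=chan + leak + noise,
                       capacitance=capacitance)
    iv_bg = IVCurve(voltages=v, currents=leak, capacitance=capacitance)
    truth = {"seed": seed, "modality": "iv", "g_max": g_max, "v50": v50,
             "k_slope": k_slope, "v_rev": v_rev, "g_leak": g_leak,
             "noise_sd": noise_sd}
    return iv_total, iv_bg, truth


# ----------------------------------------------------------------- sequences

#: C-terminal serine positions edited in the variant family (2/4/6 sites).
DEFAULT_CTD_SERINES = (272, 300, 261, 290, 257, 284)
DEFAULT_NTD_SERINES = (25, 38)


def gen_sequences(seed: int, length: int = 307,
                  ctd_start: int = 251, ntd_end: int = 45,
                  basic_frac: float = 0.3, hydrophobic_frac: float = 0.3,
                  motif_span: tuple[int, int] = (270, 297),
                  ctd_serines: tuple[int, ...] = DEFAULT_CTD_SERINES,
                  ntd_serines: tuple[int, ...] = DEFAULT_NTD_SERINES):
    """Base protein with a polybasic-hydrophobic C-terminal domain + variants.

    The CTD is enriched in Lys/Arg and hydrophobic residues, and
    ``motif_span`` (inclusive) carries a dense alternating basic/
    hydrophobic membrane-binding motif so the BH scan peaks there; listed
    positions are forced to Ser so the phospho-site variant family can be
    derived deterministically: N-2SA, C-2SA, 4SA (Ser->Ala) and C-2SD,
    C-4SD, C-6SD (Ser->Asp).  Returns ``(dict name -> ProteinSequence,
    truth dict)``; the base record is under key 'WT'.
    """
    rng = modality_rng(seed, "sequence")
    aa_basic = "KR"
    aa_acidic = "DE"
    aa_hydro = "LIVFM"
    aa_polar = "GASTNQ"
    chars = []
    for pos in range(1, length + 1):
        in_ctd = pos >= ctd_start
        r = rng.random()
        if motif_span[0] <= pos <= motif_span[1]:
            pool = aa_basic if r < 0.55 else aa_hydro
        elif in_ctd:
            if r < basic_frac:
                pool = aa_basic
            elif r < basic_frac + hydrophobic_frac:
                pool = aa_hydro
            elif r < basic_frac + hydrophobic_frac + 0.05:
                pool = aa_acidic
            else:
                pool = aa_polar
        else:
            if r < 0.12:
                pool = aa_basic
            elif r < 0.24:
                pool = aa_acidic
            elif r < 0.55:
                pool = aa_hydro
            else:
                pool = aa_polar
        chars.append(pool[rng.integers(len(pool))])
    for pos in (*ctd_serines, *ntd_serines):
        chars[pos - 1] = "S"
    regions = {"NTD": (1, ntd_end + 1), "CTD": (ctd_start, length + 1)}
    base = ProteinSequence(id="WT", residues="".join(chars), regions=regions)
    edits = {
        "N-2SA": [(p, "A") for p in ntd_serines[:2]],
        "C-2SA": [(p, "A") for p in ctd_serines[:2]],
        "4SA": [(p, "A") for p in (*ntd_serines[:2], *ctd_serines[:2])],
        "C-2SD": [(p, "D") for p in ctd_serines[:2]],
        "C-4SD": [(p, "D") for p in ctd_serines[:4]],
        "C-6SD": [(p, "D") for p in ctd_serines[:6]],
    }
    from .seqcharge import apply_variant
    variants = {"WT": base}
    for name, subs in edits.items():
        variants[name] = apply_variant(base, subs, new_id=name)
    truth = {"seed": seed, "modality": "sequence", "length": length,
             "ctd_serines": list(ctd_serines), "ntd_serines": list(ntd_serines),
             "edits": {k: [[p, a] for p, a in v] for k, v in edits.items()}}
    return variants, truth


def write_fasta(variants: dict[str, ProteinSequence], path) -> None:
    with open(path, "w") as fh:
        for name, seq in variants.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i:i + 60] + "\n")


# ---------------------------------------------------------------- shortening

def gen_shortening(seed: int, n_beats: int = 10, rate_hz: float = 1.0,
                   l_relax_um: float = 1.80, fs_frac: float = 0.10,
                   sampling_hz: float = 200.0, twitch_ms: float = 300.0,
                   noise_um: float = 0.0):
    """Periodic sarcomere-shortening transients (half-sine twitches).

    Each beat dips from ``l_relax_um`` by ``fs_frac * l_relax_um`` at its
    nadir.  Returns ``(time_s, length_um, stim_times_s, truth)``.
    """
    rng = modality_rng(seed, "shortening")
    total_s = (n_beats + 1) / rate_hz
    t = np.arange(0.0, total_s, 1.0 / sampling_hz)
    ln = np.full_like(t, l_relax_um)
    stims = [(j + 0.5) / rate_hz for j in range(n_beats)]
    tw = twitch_ms * 1e-3
    for t0 in stims:
        in_tw = (t >= t0) & (t < t0 + tw)
        phase = (t[in_tw] - t0) / tw
        ln[in_tw] -= fs_frac * l_relax_um * np.sin(np.pi * phase)
    if noise_um > 0:
        ln = ln + rng.normal(0.0, noise_um, t.shape)
    truth = {"seed": seed, "modality": "shortening", "n_beats": n_beats,
             "l_relax_um": l_relax_um, "fs_frac": fs_frac}
    return t, ln, np.asarray(stims), truth
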