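"""Flow-cytometric three-cube FRET: efficiencies, binding isotherms, membrane slope.

Each cell yields three intensities: donor excitation/donor emission
(``s_dd``), donor excitation/acceptor emission (``s_da``, the raw FRET
channel) and acceptor excitation/acceptor emission (``s_aa``).  After
crosstalk removal the sensitized emission is

    F_c = s_da - r_d * s_dd - r_a * s_aa

and the donor-centric FRET efficiency E_D = F_c / (F_c + G * s_dd), where
the G factor converts sensitized emission into quenched-donor units.
Relative donor/acceptor abundances follow as d = f_d (s_dd + F_c/G) and
a = f_a s_aa.

Binding of a donor-tagged to an acceptor-tagged protein is quantified by
fitting E_D against the free acceptor concentration with a 1:1 isotherm
E_D = E_max * a_free / (K_d,EFF + a_free), where a_free is recomputed from
total abundances by mass action at the current K_d iterate (self-consistent
fixed point).  Separately, the fraction of acceptor at the plasma membrane
is probed through collisional FRET: after binning cells by directly excited
acceptor fluorescence (S_A,direct), the slope of mean E_D versus S_A,direct
is proportional to the membrane-localized acceptor fraction f_mem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class SpectralParams:
    """Crosstalk ratios and scale factors of the 3-cube measurement."""

    r_d: float = 0.1   # donor bleed-through into the FRET channel
    r_a: float = 0.05  # acceptor cross-excitation into the FRET channel
    g_factor: float = 2.0
    f_d: float = 1.0   # fluorescence -> relative donor concentration
    f_a: float = 1.0   # fluorescence -> relative acceptor concentration

    def __post_init__(self) -> None:
        if self.r_d < 0 or self.r_a < 0:
            raise ValueError("crosstalk ratios must be >= 0")
        if min(self.g_factor, self.f_d, self.f_a) <= 0:
            raise ValueError("g_factor, f_d, f_a must be > 0")


@dataclass(frozen=True)
class BindingFit:
    kd_eff: float
    e_d_max: float
    residual_norm: float
    ci_kd: tuple[float, float]
    n_points: int
    n_iterations: int


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    n_bins: int
    bin_means: pd.DataFrame  # columns: s_a_direct, e_d


def compute_fret_points(events: pd.DataFrame, p: SpectralParams) -> pd.DataFrame:
    """Per-cell E_D and abundances from raw 3-channel intensities.

    ``events`` needs columns ``s_dd, s_da, s_aa``.  Returns a frame with
    ``e_d, d_total, a_total, s_a_direct, valid``; events whose efficiency
    denominator ``F_c + G s_dd`` is nonpositive are flagged invalid rather
    than clamped, and must be excluded before fitting.
    """
    s_dd = events["s_dd"].to_numpy(float)
    s_da = events["s_da"].to_numpy(float)
    s_aa = events["s_aa"].to_numpy(float)
    f_c = s_da - p.r_d * s_dd - p.r_a * s_aa
    denom = f_c + p.g_factor * s_dd
    valid = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        e_d = np.where(valid, f_c / denom, np.nan)
    d_total = p.f_d * (s_dd + f_c / p.g_factor)
    a_total = p.f_a * s_aa
    return pd.DataFrame({
        "e_d": e_d, "d_total": d_total, "a_total": a_total,
        "s_a_direct": s_aa, "valid": valid,
    })


def free_acceptor(d_total, a_total, kd: float):
    """Free acceptor concentration under 1:1 mass action.

    Bound complex B solves B^2 - (d+a+kd) B + d a = 0; the physical root is
    ``B = ((d+a+kd) - sqrt((d+a+kd)^2 - 4 d a)) / 2`` and a_free = a - B.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    d = np.asarray(d_total, float)
    a = np.asarray(a_total, float)
    if np.any(d < 0) or np.any(a < 0):
        raise ValueError("abundances must be >= 0")
    s = d + a + kd
    disc = s * s - 4.0 * d * a
    disc = np.maximum(disc, 0.0)  # analytically >= 0; guard roundoff
    bound = (s - np.sqrt(disc)) / 2.0
    return a - bound


def _isotherm(a_free, e_max, kd):
    return e_max * a_free / (kd + a_free)


def _fit_once(d, a, e_d, kd_start: float, e_start: float,
              rtol: float = 1e-6, max_iter: int = 100):
    """Self-consistent isotherm fit: a_free from the current kd iterate."""
    kd, e_max = kd_start, e_start
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        a_free = free_acceptor(d, a, kd)
        if np.ptp(a_free) == 0:
            raise ValueError("degenerate a_free span: all values equal")
        popt, _ = curve_fit(_isotherm, a_free, e_d, p0=(e_max, kd),
                            bounds=([1e-12, 1e-12], [1.0, np.inf]),
                            maxfev=2000)
        e_new, kd_new = popt
        if abs(kd_new - kd) <= rtol * max(kd, 1e-30):
            kd, e_max = kd_new, e_new
            break
        kd, e_max = kd_new, e_new
    else:
        raise RuntimeError("binding fit did not converge")
    return kd, e_max, n_iter


def fit_binding_isotherm(points: pd.DataFrame,
                         n_boot: int = 500,
                         seed: int = 0,
                         kd_init: float | None = None) -> BindingFit:
    """Fit E_D vs self-consistent free acceptor with a 1:1 isotherm.

    ``points`` needs ``e_d, d_total, a_total`` (and optionally ``valid``).
    Fixed-point iteration on K_d,EFF to relative tolerance 1e-6, at most
    100 iterations; the confidence interval is a seeded percentile
    bootstrap over cells (2.5-97.5%).
    """
    if "valid" in points:
        points = points[points["valid"]]
    if len(points) < 10:
        raise ValueError("need >= 10 valid points")
    d = points["d_total"].to_numpy(float)
    a = points["a_total"].to_numpy(float)
    e = points["e_d"].to_numpy(float)
    a_span = free_acceptor(d, a, kd_init or np.median(a) + 1e-12)
    pos = a_span[a_span > 0]
    if pos.size and pos.max() / max(pos.min(), 1e-300) < 10:
        raise ValueError("a_free spans less than one decade")
    kd0 = kd_init if kd_init is not None else float(np.median(a)) or 1.0
    kd, e_max, n_iter = _fit_once(d, a, e, kd0, min(max(e.max(), 0.05), 1.0))
    a_free = free_acceptor(d, a, kd)
    resid = e - _isotherm(a_free, e_max, kd)
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(e), len(e))
        try:
            kd_b, _, _ = _fit_once(d[idx], a[idx], e[idx], kd, e_max,
                                   max_iter=50)
            boot.append(kd_b)
        except (RuntimeError, ValueError):
            continue
    if boot:
        ci = tuple(np.percentile(boot, [2.5, 97.5]))
    else:
        ci = (np.nan, np.nan)
    return BindingFit(kd_eff=float(kd), e_d_max=float(e_max),
                      residual_norm=float(np.linalg.norm(resid)),
                      ci_kd=(float(ci[0]), float(ci[1])),
                      n_points=len(e), n_iterations=n_iter)


def fit_membrane_slope(points: pd.DataFrame, n_bins: int = 20) -> SlopeFit:
    """Binned-slope estimator of membrane-localized acceptor fraction.

    Valid events are split into ``n_bins`` equal-count bins by S_A,direct;
    an ordinary least-squares line through the per-bin means of
    (S_A,direct, E_D) gives the slope, which is proportional to f_mem.
    The intercept absorbs baseline FRET and is not interpreted.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if "valid" in points:
        points = points[points["valid"]]
    if len(points) < 5 * n_bins:
        raise ValueError(f"need >= {5 * n_bins} points for {n_bins} bins")
    order = np.argsort(points["s_a_direct"].to_numpy(), kind="stable")
    sa = points["s_a_direct"].to_numpy(float)[order]
    ed = points["e_d"].to_numpy(float)[order]
    chunks = np.array_split(np.arange(len(sa)), n_bins)
    if any(len(c) == 0 for c in chunks):
        raise ValueError("empty bins after filtering")
    bx = np.array([sa[c].mean() for c in chunks])
    by = np.array([ed[c].mean() for c in chunks])
    slope, intercept = np.polyfit(bx, by, 1)
    return SlopeFit(slope=float(slope), intercept=float(intercept),
                    n_bins=n_bins,
                    bin_means=pd.DataFrame({"s_a_direct": bx, "e_d": by}))


def read_events(path) -> pd.DataFrame:
    """Read a 3-channel event CSV with required header s_dd,s_da,s_aa."""
    df = pd.read_csv(path)
    missing = {"s_dd", "s_da", "s_aa"} - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    return df
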