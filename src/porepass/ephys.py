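"""Single-channel electrophysiology analysis.

Implements the standard patch-clamp workflow for a chloride-selective
mechanosensitive channel recorded in asymmetric / symmetric NaCl:

* Goldman–Hodgkin–Katz bi-ionic algebra relating the reversal potential to
  the permeability ratio P_Cl/P_Na,

      Erev = (RT/F) · ln[(P_Na·[Na]o + P_Cl·[Cl]i) / (P_Na·[Na]i + P_Cl·[Cl]o)],

  and its closed-form inverse;
* reversal-potential interpolation from I–V data and off-line leak
  subtraction;
* Gaussian fits of single-channel amplitude histograms;
* slope conductance from ordinary least squares on single-channel I–V
  points (pA vs mV, slope × 1000 → pS);
* single-exponential deactivation kinetics after stimulus end;
* fold-change summaries between conditions.

Currents follow the amplifier convention in which inward current at
negative potentials is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "SolutionPair",
    "PermeabilityResult",
    "SweepTrace",
    "AmplitudeFit",
    "IVFit",
    "DecayFit",
    "rt_over_f",
    "ghk_erev",
    "ghk_ratio_from_erev",
    "interpolate_erev",
    "leak_subtract",
    "fit_amplitude_histogram",
    "slope_conductance",
    "deactivation_tau",
    "fold_change",
]

GAS_CONSTANT = 8.31446261815324  # J/(mol K)
FARADAY = 96485.33212331  # C/mol


class EphysError(Exception):
    pass


def rt_over_f(temperature: float = 298.15) -> float:
    """Thermal voltage RT/F in mV (25.693 mV at 298.15 K)."""
    if temperature <= 0:
        raise EphysError("temperature must be positive (K)")
    return GAS_CONSTANT * temperature / FARADAY * 1e3


@dataclass(frozen=True)
class SolutionPair:
    """Extracellular/intracellular Na+ and Cl− concentrations (mM)."""

    na_out: float
    na_in: float
    cl_out: float
    cl_in: float
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("na_out", "na_in", "cl_out", "cl_in", "temperature"):
            if getattr(self, name) <= 0:
                raise EphysError(f"{name} must be positive")

    @classmethod
    def symmetric_nacl(cls, mM: float, temperature: float = 298.15) -> "SolutionPair":
        return cls(mM, mM, mM, mM, temperature)

    @classmethod
    def asymmetric_nacl(
        cls, out_mM: float, in_mM: float, temperature: float = 298.15
    ) -> "SolutionPair":
        """NaCl-only solutions, e.g. 150 mM out / 30 mM in for selectivity."""
        return cls(out_mM, in_mM, out_mM, in_mM, temperature)


@dataclass(frozen=True)
class PermeabilityResult:
    ratio_cl_na: float
    erev: float  # mV


@dataclass
class SweepTrace:
    """One sweep: time (s), current (pA) and stimulus series."""

    time: np.ndarray
    current: np.ndarray
    pressure: np.ndarray | None = None  # mmHg
    voltage: np.ndarray | float | None = None  # mV
    sampling_rate: float | None = None  # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise EphysError("time and current must have equal length")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * max(1.0, dt[0])):
            raise EphysError("time base must be uniform and increasing")
        if self.sampling_rate is None and len(dt):
            self.sampling_rate = 1.0 / float(dt[0])


@dataclass
class AmplitudeFit:
    """Gaussian mixture fit of a current histogram."""

    means: np.ndarray  # pA, sorted by |mean| ascending (closed level first)
    sds: np.ndarray
    weights: np.ndarray  # normalised
    single_channel_amplitude: float  # pA
    flagged: bool = False
    message: str = ""


@dataclass(frozen=True)
class IVFit:
    slope: float  # pS
    erev_intercept: float  # mV
    r_squared: float


@dataclass(frozen=True)
class DecayFit:
    tau: float  # s
    amplitude: float  # pA
    baseline: float  # pA
    fit_window: tuple[float, float]


# ---------------------------------------------------------------------------
# GHK


def ghk_erev(sol: SolutionPair, ratio_cl_na: float) -> float:
    """Reversal potential (mV) for a given P_Cl/P_Na (P_Na ≡ 1)."""
    if ratio_cl_na <= 0:
        raise EphysError("permeability ratio must be positive")
    r = ratio_cl_na
    num = sol.na_out + r * sol.cl_in
    den = sol.na_in + r * sol.cl_out
    return rt_over_f(sol.temperature) * math.log(num / den)


def ghk_ratio_from_erev(sol: SolutionPair, erev: float) -> float:
    """Invert the GHK relation: P_Cl/P_Na from a measured Erev (mV).

    Feasible Erev lies strictly between the Cl− and Na+ Nernst potentials
    of the solution pair; outside (or for degenerate symmetric products
    [Na]o·[Cl]o = [Na]i·[Cl]i) a domain error is raised.
    """
    vt = rt_over_f(sol.temperature)
    if abs(sol.na_out * sol.cl_out - sol.na_in * sol.cl_in) < 1e-12 * sol.na_out * sol.cl_out:
        raise EphysError(
            "degenerate solutions (symmetric ionic product): Erev carries no "
            "permeability information"
        )
    e_na = vt * math.log(sol.na_out / sol.na_in)  # ratio -> 0 limit
    e_cl = vt * math.log(sol.cl_in / sol.cl_out)  # ratio -> inf limit
    lo, hi = sorted((e_na, e_cl))
    if not (lo < erev < hi):
        raise EphysError(
            f"Erev {erev:.2f} mV outside the feasible open interval "
            f"({lo:.2f}, {hi:.2f}) mV for these solutions"
        )
    x = math.exp(erev / vt)
    ratio = (sol.na_out - x * sol.na_in) / (x * sol.cl_out - sol.cl_in)
    if ratio <= 0:
        raise EphysError("Erev maps to a non-positive permeability ratio")
    return ratio


def interpolate_erev(iv_points) -> float:
    """Zero-current crossing (mV) by linear interpolation of (V, I) data."""
    pts = sorted((float(v), float(i)) for v, i in iv_points)
    if len(pts) < 2:
        raise EphysError("need at least two I-V points")
    v = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    exact = np.flatnonzero(i == 0)
    if len(exact):
        return float(v[exact[0]])
    sign_change = np.flatnonzero(np.diff(np.sign(i)) != 0)
    if not len(sign_change):
        raise EphysError("I-V data do not bracket zero current")
    k = sign_change[0]
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


# ---------------------------------------------------------------------------
# Sweeps


def leak_subtract(
    sweep: SweepTrace, baseline_window: tuple[float, float], mode: str = "constant"
) -> SweepTrace:
    """Subtract the pre-stimulus leak from a sweep.

    ``mode="constant"`` removes the baseline-window mean; ``mode="linear"``
    removes a least-squares line fitted in the window (drift correction).
    """
    lo, hi = baseline_window
    mask = (sweep.time >= lo) & (sweep.time <= hi)
    if not mask.any():
        raise EphysError("baseline window contains no samples")
    if mode == "constant":
        corrected = sweep.current - sweep.current[mask].mean()
    elif mode == "linear":
        coef = np.polyfit(sweep.time[mask], sweep.current[mask], 1)
        corrected = sweep.current - np.polyval(coef, sweep.time)
    else:
        raise EphysError(f"unknown leak-subtraction mode {mode!r}")
    return SweepTrace(
        time=sweep.time.copy(),
        current=corrected,
        pressure=sweep.pressure,
        voltage=sweep.voltage,
        sampling_rate=sweep.sampling_rate,
    )


def _gaussian_mixture(x, *params):
    k = len(params) // 3
    out = np.zeros_like(x, dtype=float)
    for j in range(k):
        a, mu, sd = params[3 * j : 3 * j + 3]
        out += a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return out


def fit_amplitude_histogram(
    sweep: SweepTrace,
    n_components: int = 2,
    bin_width: float = 0.2,
    rng_seed: int = 0,
) -> AmplitudeFit:
    """Fit a Gaussian mixture to the current amplitude histogram.

    The histogram (bin width in pA) is fitted by least squares on binned
    counts, with component means initialised at histogram peaks (padded by
    seeded jitter around the heaviest peak when fewer peaks than
    components are found — such fits are flagged).  The single-channel
    amplitude is |mean(open) − mean(closed)| of the two heaviest adjacent
    components.
    """
    if n_components < 2:
        raise EphysError("n_components must be >= 2")
    cur = sweep.current
    edges = np.arange(cur.min() - bin_width, cur.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(cur, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # discrete traces (noiseless or near-noiseless): the histogram mass sits
    # in at most n_components isolated bins — take the sample means per bin
    # exactly instead of fitting
    occupied = np.flatnonzero(counts)
    if 2 <= len(occupied) <= n_components:
        means, sds, weights = [], [], []
        for b in occupied:
            sel = (cur >= edges[b]) & (cur < edges[b + 1])
            means.append(float(cur[sel].mean()))
            sds.append(max(float(cur[sel].std()), 1e-9))
            weights.append(float(sel.sum()))
        means = np.array(means)
        sds = np.array(sds)
        weights = np.array(weights) / np.sum(weights)
        order = np.argsort(np.abs(means))
        means, sds, weights = means[order], sds[order], weights[order]
        heavy = np.sort(np.argsort(weights)[::-1][:2])
        return AmplitudeFit(
            means=means, sds=sds, weights=weights,
            single_channel_amplitude=float(abs(means[heavy[1]] - means[heavy[0]])),
            flagged=len(occupied) < n_components,
            message="" if len(occupied) == n_components else
            f"only {len(occupied)} occupied histogram bins for {n_components} components",
        )
    if len(occupied) == 1:
        level = float(cur.mean())
        return AmplitudeFit(
            means=np.array([level]), sds=np.array([max(float(cur.std()), 1e-9)]),
            weights=np.array([1.0]), single_channel_amplitude=0.0,
            flagged=True, message="degenerate fit: single current level",
        )

    # light smoothing so noise ripples on a level do not split its peak
    smooth = np.convolve(counts.astype(float), [0.25, 0.5, 0.25], mode="same")
    peak_idx, props = signal.find_peaks(
        smooth,
        distance=max(1, int(round(1.0 / bin_width))),
        prominence=max(1.0, smooth.max() * 0.05),
    )
    peak_idx = peak_idx[np.argsort(props["prominences"])[::-1]]
    flagged = len(peak_idx) < n_components
    message = "" if not flagged else (
        f"found {len(peak_idx)} histogram peak(s) for {n_components} components"
    )
    rng = np.random.default_rng(rng_seed)
    mus = list(centers[peak_idx[:n_components]])
    while len(mus) < n_components:
        base = mus[0] if mus else float(centers[np.argmax(counts)])
        mus.append(base + rng.normal(scale=max(1.0, 5 * bin_width)))
    p0 = []
    for mu in mus:
        p0 += [float(counts.max()), float(mu), max(bin_width, np.std(cur) / n_components)]
    try:
        lower = [0.0, centers[0] - 1, 1e-6] * n_components
        upper = [np.inf, centers[-1] + 1, np.ptp(centers) + 1] * n_components
        popt, _ = optimize.curve_fit(
            _gaussian_mixture, centers, counts, p0=p0,
            bounds=(lower, upper), maxfev=20000,
        )
    except RuntimeError:
        flagged = True
        message = (message + "; " if message else "") + "mixture fit did not converge"
        popt = np.array(p0)

    amps = popt[0::3]
    means = popt[1::3]
    sds = np.abs(popt[2::3])
    # component weights ~ area of each Gaussian
    areas = amps * sds
    if areas.sum() <= 0:
        weights = np.full(n_components, 1.0 / n_components)
    else:
        weights = areas / areas.sum()
    order = np.argsort(np.abs(means))  # closed (near 0) first
    means, sds, weights = means[order], sds[order], weights[order]

    heavy = np.argsort(weights)[::-1][:2]
    heavy = np.sort(heavy)
    amplitude = float(abs(means[heavy[1]] - means[heavy[0]]))
    if amplitude < bin_width:
        flagged = True
        message = (message + "; " if message else "") + "degenerate fit: levels coincide"
    return AmplitudeFit(
        means=means, sds=sds, weights=weights,
        single_channel_amplitude=amplitude,
        flagged=flagged, message=message,
    )


def slope_conductance(iv_points) -> IVFit:
    """Slope conductance (pS) from OLS on single-channel (V mV, i pA)."""
    pts = [(float(v), float(i)) for v, i in iv_points]
    voltages = {v for v, _ in pts}
    if len(voltages) < 3:
        raise EphysError("need amplitudes at >= 3 distinct voltages")
    v = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    res = stats.linregress(v, i)
    slope_ps = res.slope * 1000.0  # pA/mV -> pS
    erev = -res.intercept / res.slope if res.slope != 0 else math.nan
    return IVFit(slope=float(slope_ps), erev_intercept=float(erev),
                 r_squared=float(res.rvalue**2))


def deactivation_tau(
    sweep: SweepTrace, stim_end: float, fit_window: float
) -> DecayFit:
    """Single-exponential fit of current decay after stimulus end.

    Fits I(t) = A·exp(−(t − stim_end)/τ) + baseline over
    [stim_end, stim_end + fit_window] by nonlinear least squares; τ is
    initialised from the 1/e crossing of the decaying segment.
    """
    if fit_window <= 0:
        raise EphysError("fit_window must be positive")
    t0, t1 = stim_end, stim_end + fit_window
    if t1 > sweep.time[-1] + 1e-12:
        raise EphysError("fit window extends past the end of the sweep")
    mask = (sweep.time >= t0) & (sweep.time <= t1)
    t = sweep.time[mask] - stim_end
    i = sweep.current[mask]
    if len(t) < 4:
        raise EphysError("fit window contains too few samples")

    baseline0 = float(np.mean(i[-max(3, len(i) // 10):]))
    a0 = float(i[0] - baseline0)
    if abs(a0) < 1e-9 or np.ptp(i) < 1e-9:
        raise EphysError("segment does not decay (flat trace)")
    # 1/e crossing for the initial tau guess
    target = baseline0 + a0 / math.e
    crossing = np.flatnonzero((i - target) * np.sign(a0) <= 0)
    tau0 = float(t[crossing[0]]) if len(crossing) and t[crossing[0]] > 0 else float(t[-1] / 3)
    tau0 = max(tau0, float(t[1]))

    def model(tt, a, tau, base):
        return a * np.exp(-tt / tau) + base

    try:
        popt, _ = optimize.curve_fit(
            model, t, i, p0=[a0, tau0, baseline0],
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise EphysError(f"deactivation fit did not converge: {exc}") from exc
    a, tau, base = popt
    if tau <= 0 or not np.isfinite(tau):
        raise EphysError("deactivation fit returned a non-positive tau")
    return DecayFit(tau=float(tau), amplitude=float(a), baseline=float(base),
                    fit_window=(float(t0), float(t1)))


def fold_change(a: float, b: float) -> float:
    """Ratio a/b (e.g. WT conductance over mutant conductance)."""
    if b == 0:
        raise EphysError("fold_change denominator is zero")
    return a / b
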