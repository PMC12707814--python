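"""Analysis chain for whole-cell recordings.

Covers the voltage-clamp side — membrane-test estimation of R_S / R_I / C_M,
series-resistance quality control, sweep averaging, pre/post pharmacology
subtraction, charge integration of auto-evoked inhibition (AEI), single-
exponential decay fitting, spontaneous-IPSC detection — and the
current-clamp side: boxcar-smoothed dV/dt phase-plane construction and
monophasic/biphasic waveform classification.

Sign conventions: inward currents are negative samples; reported charges are
the positive magnitude of the inward integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import (
    EmptyInputError,
    FitFailureError,
    InconsistentEstimateError,
    UnclassifiableWaveformError,
    ValidationError,
)
from .synth_ephys import ProtocolSpec, SweepSet

#: Series-resistance exclusion rule: absolute ceiling (MΩ) and relative drift.
RS_MAX_MOHM = 30.0
RS_MAX_CHANGE = 0.30

#: Baseline period (ms) before the first step used for offset removal.
BASELINE_MS = 50.0


@dataclass
class MembraneTestResult:
    """Passive properties from the double test pulse.

    ``R_I`` is the total input resistance ΔV / steady-state step current
    (series + membrane); ``R_S`` comes from the back-extrapolated peak
    transient; ``C_M`` from the transient's integrated charge.
    """

    R_S: float
    R_I: float
    C_M: float
    tau_ms: float

    @property
    def R_m(self) -> float:
        return self.R_I - self.R_S


@dataclass(frozen=True)
class AnalysisWindow:
    """Charge/decay window relative to the (last) step end, in ms."""

    start_offset_ms: float = 10.0
    length_ms: float = 500.0

    def __post_init__(self):
        if self.start_offset_ms <= 0 or self.length_ms <= 0:
            raise ValidationError("window offsets must be > 0")


@dataclass
class AEIResult:
    charge: float
    decay_k: float | None
    window: AnalysisWindow
    n_sweeps_averaged: int


@dataclass
class DecayFit:
    k: float  # ms^-1
    amplitude: float  # pA at window-peak time
    offset: float  # pA
    rmse: float
    converged: bool


@dataclass
class PhasePlane:
    V: np.ndarray  # mV, smoothed
    dVdt: np.ndarray  # V/s
    smoothing_points: int
    sample_interval_us: float


@dataclass
class ClassifierParams:
    onset_V_per_s: float = 10.0
    trough_depth_fraction: float = 0.10
    smooth_points: int = 5


@dataclass
class WaveformLabel:
    label: str  # "monophasic" | "biphasic"
    n_upstroke_maxima: int
    trough_depth_fraction: float


@dataclass
class QCResult:
    passed: bool
    reason: str


@dataclass
class IPSCEvents:
    times_ms: np.ndarray
    amplitudes_pA: np.ndarray

    @property
    def n(self) -> int:
        return int(self.times_ms.size)


# ---------------------------------------------------------------------------
# sweep utilities


def average_sweeps(sweeps) -> np.ndarray:
    """Pointwise mean across sweeps; accepts a SweepSet or a list of traces."""
    if isinstance(sweeps, SweepSet):
        arr = sweeps.sweeps
    else:
        traces = [np.asarray(s, dtype=float) for s in sweeps]
        if not traces:
            raise EmptyInputError("no sweeps to average")
        if traces[0].ndim == 0:  # a single 1D trace was passed
            traces = [np.asarray(sweeps, dtype=float)]
        n0 = traces[0].shape[-1]
        if any(t.shape[-1] != n0 for t in traces):
            raise ValidationError("sweeps have unequal lengths")
        arr = np.vstack(traces)
    if arr.size == 0:
        raise EmptyInputError("no sweeps to average")
    return arr.mean(axis=0)


def _first_step_onset_ms(protocol: ProtocolSpec) -> float:
    return protocol.step_epochs()[0][0]


def subtract_conditions(
    pre,
    post,
    protocol: ProtocolSpec | None = None,
    baseline_ms: float = BASELINE_MS,
) -> np.ndarray:
    """Pre − post difference trace with pre-step baseline offset removed.

    ``pre``/``post`` may be SweepSets (averaged internally) or 1D averaged
    traces; their time bases must match.
    """
    if isinstance(pre, SweepSet):
        if isinstance(post, SweepSet) and post.sample_interval_us != pre.sample_interval_us:
            raise ValidationError("sample intervals differ between conditions")
        protocol = protocol or pre.protocol
        dt_ms = pre.sample_interval_us / 1000.0
        pre_avg = average_sweeps(pre)
    else:
        pre_avg = np.asarray(pre, dtype=float)
        if protocol is None:
            raise ValidationError("protocol required when passing bare traces")
        dt_ms = protocol.dt_ms
    post_avg = average_sweeps(post) if isinstance(post, SweepSet) else np.asarray(post, dtype=float)
    if pre_avg.shape != post_avg.shape:
        raise ValidationError("pre/post traces have different lengths")
    diff = pre_avg - post_avg
    onset = _first_step_onset_ms(protocol)
    i0 = max(0, int(round((onset - baseline_ms) / dt_ms)))
    i1 = max(i0 + 1, int(round(onset / dt_ms)))
    return diff - diff[i0:i1].mean()


def _window_slice(trace: np.ndarray, protocol: ProtocolSpec, window: AnalysisWindow) -> tuple[slice, float]:
    """Sample slice of the analysis window, anchored to the last step's end."""
    dt_ms = protocol.dt_ms
    anchor = protocol.step_epochs()[-1][1]
    i0 = int(round((anchor + window.start_offset_ms) / dt_ms))
    i1 = int(round((anchor + window.start_offset_ms + window.length_ms) / dt_ms))
    if i0 < 0 or i1 >= trace.size:
        raise ValidationError("analysis window exceeds trace length")
    return slice(i0, i1 + 1), dt_ms


def aei_charge(
    diff_trace: np.ndarray,
    protocol: ProtocolSpec,
    window: AnalysisWindow = AnalysisWindow(),
) -> float:
    """Charge (pC) of the inward difference current over the analysis window.

    Trapezoidal integral over [step end + 10 ms, step end + 510 ms] (second
    step for paired protocols), sign-corrected so inward charge is positive.
    """
    trace = np.asarray(diff_trace, dtype=float)
    sl, dt_ms = _window_slice(trace, protocol, window)
    return float(-np.trapezoid(trace[sl], dx=dt_ms) / 1000.0)  # pA·ms -> pC


def aei_charge_per_pulse(
    diff_trace: np.ndarray,
    protocol: ProtocolSpec,
    window: AnalysisWindow = AnalysisWindow(),
) -> list[float]:
    """Charge after each pulse separately; windows truncated at the next pulse."""
    trace = np.asarray(diff_trace, dtype=float)
    dt_ms = protocol.dt_ms
    epochs = protocol.step_epochs()
    out = []
    for j, (_on, off) in enumerate(epochs):
        end_ms = off + window.start_offset_ms + window.length_ms
        if j + 1 < len(epochs):
            end_ms = min(end_ms, epochs[j + 1][0])
        i0 = int(round((off + window.start_offset_ms) / dt_ms))
        i1 = min(int(round(end_ms / dt_ms)), trace.size - 1)
        if i0 >= i1:
            out.append(0.0)
            continue
        out.append(float(-np.trapezoid(trace[i0 : i1 + 1], dx=dt_ms) / 1000.0))
    return out


# ---------------------------------------------------------------------------
# membrane test


def _fit_exponential(t_ms: np.ndarray, y: np.ndarray, k_bounds=(1e-4, 10.0)) -> tuple[float, float, float]:
    """Fit y = A·exp(−k t) + C; returns (A, k, C).  Log-linear initialisation."""
    tail_n = max(3, y.size // 10)
    c0 = float(min(np.median(y[-tail_n:]), y.max() - 1e-9))
    pos = y - c0 + 1e-12
    sel = pos > pos.max() * 1e-3
    if sel.sum() < 3:
        raise FitFailureError("no decaying phase to fit")
    slope, intercept = np.polyfit(t_ms[sel], np.log(pos[sel]), 1)
    k0 = float(np.clip(-slope, k_bounds[0] * 2, k_bounds[1] / 2))
    a0 = float(np.exp(intercept))

    def model(t, a, k, c):
        return a * np.exp(-k * t) + c

    try:
        popt, _ = optimize.curve_fit(
            model,
            t_ms,
            y,
            p0=(a0, k0, c0),
            bounds=([0.0, k_bounds[0], -np.inf], [np.inf, k_bounds[1], np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"exponential fit failed: {exc}") from exc
    a, k, c = (float(v) for v in popt)
    if a <= 0 or not np.isfinite(k) or k <= k_bounds[0] * 1.001:
        raise FitFailureError("degenerate exponential fit")
    return a, k, c


def membrane_test(sweeps: SweepSet) -> MembraneTestResult:
    """Estimate R_S, R_I and C_M from the averaged double test pulse.

    The two polarity responses are sign-corrected and averaged.  The peak
    transient is back-extrapolated to the step onset by an exponential fit
    (the sampled peak undershoots the instantaneous ΔV/R_S); R_I is
    ΔV / steady-state current over the final 20% of the step; C_M converts
    the transient charge Q_t = A·τ through the RC relation
    C_M = Q_t·(R_S + R_m)² / (ΔV·R_m²) with R_m = R_I − R_S.
    """
    proto = sweeps.protocol
    if proto is None or proto.kind != "membrane_test":
        raise ValidationError("membrane_test requires a membrane_test SweepSet")
    avg = average_sweeps(sweeps)
    dt_ms = proto.dt_ms
    epochs = proto.step_epochs()
    dV = abs(proto.step_mV)
    if dV == 0:
        raise ValidationError("membrane test needs a nonzero step")
    base_n = max(1, int(round(epochs[0][0] / dt_ms)))
    baseline = avg[:base_n].mean()

    responses = []
    for (on, off), sign in zip(epochs, (-1.0, 1.0)):
        i_on = int(round(on / dt_ms))
        i_off = int(round(off / dt_ms))
        responses.append(sign * (avg[i_on:i_off] - baseline))
    n = min(len(r) for r in responses)
    resp = np.mean([r[:n] for r in responses], axis=0)

    n_ss = max(1, int(round(0.2 * n)))
    i_ss_rough = float(resp[-n_ss:].mean())
    if i_ss_rough <= 0:
        raise InconsistentEstimateError("non-positive steady-state current")
    peak_idx = int(np.argmax(resp))
    t_rel = np.arange(peak_idx, n) * dt_ms  # measured from step onset
    y = resp[peak_idx:]
    if y.max() <= i_ss_rough:
        raise FitFailureError("no detectable transient peak")
    # the fit's offset is the steady state; the tail mean alone is biased
    # when the clamp time constant is slow relative to the 5 ms pulse
    a, k, i_ss = _fit_exponential(t_rel, y)
    if i_ss <= 0:
        raise InconsistentEstimateError("non-positive steady-state current")
    i_peak0 = a + i_ss  # transient amplitude extrapolated to step onset
    r_s = 1000.0 * dV / i_peak0
    r_i = 1000.0 * dV / i_ss
    r_m = r_i - r_s
    if r_m <= 0:
        raise InconsistentEstimateError("estimated R_m <= 0 (R_I < R_S)")
    tau = 1.0 / k
    q_t = a * tau  # pA·ms = fC
    c_m = q_t * (r_s + r_m) ** 2 / (dV * r_m**2)  # fC/mV = pF
    return MembraneTestResult(R_S=r_s, R_I=r_i, C_M=c_m, tau_ms=tau)


def qc_series_resistance(history) -> QCResult:
    """Apply the series-resistance exclusion rule to a recording's R_S history.

    Fail if any value exceeds 30 MΩ, or if the spread (max − min) relative to
    the first value exceeds 30%.
    """
    vals = np.asarray(list(history), dtype=float)
    if vals.size == 0:
        raise EmptyInputError("empty R_S history")
    if np.any(vals > RS_MAX_MOHM):
        return QCResult(False, f"R_S exceeded {RS_MAX_MOHM:.0f} MΩ (max {vals.max():.1f})")
    change = (vals.max() - vals.min()) / vals[0]
    if change > RS_MAX_CHANGE:
        return QCResult(False, f"R_S changed by {100 * change:.0f}% (> {100 * RS_MAX_CHANGE:.0f}%)")
    return QCResult(True, "ok")


# ---------------------------------------------------------------------------
# decay fit


def fit_decay(
    avg_trace: np.ndarray,
    protocol: ProtocolSpec,
    window: AnalysisWindow = AnalysisWindow(),
) -> DecayFit:
    """Single-exponential decay rate k (ms⁻¹) of the inward current.

    Fits I(t) = A·exp(−k·t) + C to the sign-corrected average response from
    the post-window-start peak onward, over the same window used for charge.
    """
    trace = np.asarray(avg_trace, dtype=float)
    sl, dt_ms = _window_slice(trace, protocol, window)
    y_all = -trace[sl]  # inward -> positive
    if np.ptp(y_all) < 1e-12:
        raise FitFailureError("constant trace: no decaying phase")
    peak = int(np.argmax(y_all))
    y = y_all[peak:]
    if y.size < 10:
        raise FitFailureError("decaying phase too short")
    t = np.arange(y.size) * dt_ms
    a, k, c = _fit_exponential(t, y, k_bounds=(1e-4, 1.0))
    resid = y - (a * np.exp(-k * t) + c)
    return DecayFit(k=k, amplitude=a, offset=c, rmse=float(np.sqrt(np.mean(resid**2))), converged=True)


# ---------------------------------------------------------------------------
# spontaneous IPSCs


def detect_spontaneous_ipscs(
    trace: np.ndarray,
    sample_interval_us: float,
    threshold_pA: float = 15.0,
    min_separation_ms: float = 5.0,
) -> IPSCEvents:
    """Detect inward events as baseline-relative threshold crossings.

    Baseline is the trace median (robust to sparse events); peaks of the
    inward deviation above ``threshold_pA`` separated by at least
    ``min_separation_ms`` are returned with estimated onset times (last
    crossing of 5% of the peak before the peak) and peak amplitudes.
    """
    x = np.asarray(trace, dtype=float)
    dt_ms = sample_interval_us / 1000.0
    inward = np.median(x) - x
    dist = max(1, int(round(min_separation_ms / dt_ms)))
    peaks, props = signal.find_peaks(inward, height=threshold_pA, distance=dist)
    onsets = []
    for p, h in zip(peaks, props["peak_heights"]):
        i = p
        while i > 0 and inward[i - 1] > 0.05 * h:
            i -= 1
        onsets.append(i * dt_ms)
    return IPSCEvents(times_ms=np.asarray(onsets), amplitudes_pA=props["peak_heights"])


# ---------------------------------------------------------------------------
# phase plane & classification


def _boxcar_shrink(x: np.ndarray, points: int) -> np.ndarray:
    """Sliding mean over ``points`` samples; the window shrinks at the edges.

    The window at index i is [i − p//2, i + (p − p//2 − 1)] clipped to the
    trace, matching a centred 20-point (100 µs at 5 µs sampling) filter.
    """
    n = x.size
    lo_off = points // 2
    hi_off = points - lo_off - 1
    cum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.clip(i - lo_off, 0, n)
    hi = np.clip(i + hi_off + 1, 0, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def phase_plane(
    voltage_trace: np.ndarray,
    sample_interval_us: float,
    smoothing_points: int = 20,
) -> PhasePlane:
    """Smoothed V and dV/dt for phase-plane analysis.

    The voltage is boxcar-smoothed (``smoothing_points`` samples, shrinking
    windows at the edges) before central-difference differentiation; dV/dt is
    in V/s (mV/ms), V in mV.
    """
    v = np.asarray(voltage_trace, dtype=float)
    if v.size < smoothing_points + 2:
        raise ValidationError("trace shorter than the smoothing filter")
    dt_ms = sample_interval_us / 1000.0
    vs = _boxcar_shrink(v, smoothing_points)
    dvdt = np.gradient(vs, dt_ms)  # central differences, one-sided at edges
    return PhasePlane(V=vs, dVdt=dvdt, smoothing_points=smoothing_points, sample_interval_us=sample_interval_us)


def classify_waveform(pp: PhasePlane, params: ClassifierParams = ClassifierParams()) -> WaveformLabel:
    """Label the action-potential upstroke as monophasic or biphasic.

    The upstroke is the contiguous run with dV/dt above ``onset_V_per_s``
    ending at the global dV/dt maximum.  After light smoothing, local maxima
    of dV/dt along the upstroke are counted; the profile is biphasic iff two
    maxima are separated by a trough at least ``trough_depth_fraction`` below
    the smaller maximum ("initial segment bump").
    """
    dvdt = pp.dVdt
    i_max = int(np.argmax(dvdt))
    if dvdt[i_max] <= params.onset_V_per_s:
        raise UnclassifiableWaveformError("no suprathreshold upstroke")
    i_start = i_max
    while i_start > 0 and dvdt[i_start - 1] > params.onset_V_per_s:
        i_start -= 1
    seg = dvdt[i_start : i_max + 1]
    if params.smooth_points > 1 and seg.size > params.smooth_points:
        seg = _boxcar_shrink(seg, params.smooth_points)
    interior, _ = signal.find_peaks(seg)
    candidates = sorted(set(interior.tolist()) | {seg.size - 1})
    best_depth = 0.0
    for a_i in range(len(candidates)):
        for b_i in range(a_i + 1, len(candidates)):
            a, b = candidates[a_i], candidates[b_i]
            if b - a < 2:
                continue
            trough = float(seg[a + 1 : b].min())
            smaller = float(min(seg[a], seg[b]))
            if smaller <= 0:
                continue
            depth = 1.0 - trough / smaller
            best_depth = max(best_depth, depth)
    label = "biphasic" if (len(candidates) >= 2 and best_depth >= params.trough_depth_fraction) else "monophasic"
    return WaveformLabel(label=label, n_upstroke_maxima=len(candidates), trough_depth_fraction=best_depth)
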