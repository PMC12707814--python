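"""Synthetic whole-cell recordings with known ground truth.

Simulates the voltage-clamp protocols used to quantify auto-evoked
inhibition (AEI) in olfactory-bulb dopaminergic neurons — passive membrane
test pulses, depolarising AEI steps under pharmacological conditions,
spontaneous IPSCs, cadmium-sensitive tail currents — and high-rate
current-clamp action potentials with monophasic or biphasic upstrokes.

The passive cell is a single-compartment RC circuit (series resistance R_s,
membrane resistance R_m, capacitance C_m); evoked synaptic components are
phenomenological kernels whose *analysis-window* charge (10–510 ms after the
step end, the same window the analysis side integrates) equals the
archetype's ground-truth value.  All randomness flows from explicit seeds.

Units: current pA, voltage mV, time ms inside kernels, resistance MΩ,
capacitance pF (so R·C is in µs), charge pC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Analysis window relative to step end (ms): [start offset, start + length].
GABA_WINDOW_MS = (10.0, 510.0)

#: Kinetic constants of the synaptic kernels (ms).
GABA_RISE_TAU_MS = 1.0
TAIL_DECAY_TAU_MS = 20.0
SIPSC_RISE_TAU_MS = 0.5
SIPSC_DECAY_TAU_MS = 10.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing of one voltage- or current-clamp protocol.

    ``step_mV`` is the absolute command potential during steps; ``holding_mV``
    the command between them.  ``baseline_ms``/``post_ms`` pad the sweep
    around the steps.
    """

    kind: str
    holding_mV: float
    step_mV: float
    step_ms: float
    inter_stim_ms: float = 0.0
    n_repeats: int = 3
    inter_sweep_s: float = 30.0
    sample_interval_us: float = 20.0
    baseline_ms: float = 100.0
    post_ms: float = 600.0

    def __post_init__(self):
        if self.sample_interval_us <= 0:
            raise ValidationError("sample_interval_us must be > 0")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if self.kind == "aei_paired" and self.inter_stim_ms != 50.0:
            raise ValidationError("paired protocol uses a 50 ms inter-stimulus interval")

    @property
    def dt_ms(self) -> float:
        return self.sample_interval_us / 1000.0

    def step_epochs(self) -> list[tuple[float, float]]:
        """(on, off) times in ms of each voltage step within the sweep."""
        if self.kind == "membrane_test":
            # double pulse: -dV then +dV around the holding potential
            a = self.baseline_ms
            gap = self.inter_stim_ms or 10.0
            return [(a, a + self.step_ms), (a + self.step_ms + gap, a + 2 * self.step_ms + gap)]
        if self.kind == "aei_paired":
            a = self.baseline_ms
            return [
                (a, a + self.step_ms),
                (a + self.step_ms + self.inter_stim_ms, a + 2 * self.step_ms + self.inter_stim_ms),
            ]
        a = self.baseline_ms
        return [(a, a + self.step_ms)]

    @property
    def duration_ms(self) -> float:
        return self.step_epochs()[-1][1] + self.post_ms

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms / self.dt_ms)) + 1


def membrane_test_protocol(**overrides) -> ProtocolSpec:
    """Double test pulse: 5 ms steps to −10 and +10 mV from −60 mV, 50 kHz."""
    kw = dict(
        kind="membrane_test",
        holding_mV=-60.0,
        step_mV=10.0,  # magnitude; both polarities are generated
        step_ms=5.0,
        inter_stim_ms=10.0,
        n_repeats=3,
        sample_interval_us=20.0,
        baseline_ms=10.0,
        post_ms=10.0,
    )
    kw.update(overrides)
    return ProtocolSpec(**kw)


def aei_protocol(kind: str = "aei_single", **overrides) -> ProtocolSpec:
    """AEI step protocols: depolarise from −80 mV to 0 mV, 50 kHz, 3 sweeps.

    ``aei_single``: one 10 ms step; ``aei_long``: one 100 ms step;
    ``aei_paired``: two 10 ms steps, 50 ms apart.
    """
    if kind not in {"aei_single", "aei_paired", "aei_long"}:
        raise ValidationError(f"unknown AEI protocol kind {kind!r}")
    kw = dict(
        kind=kind,
        holding_mV=-80.0,
        step_mV=0.0,
        step_ms=100.0 if kind == "aei_long" else 10.0,
        inter_stim_ms=50.0 if kind == "aei_paired" else 0.0,
        n_repeats=3,
        inter_sweep_s=30.0,
        sample_interval_us=20.0,
        baseline_ms=100.0,
        post_ms=600.0,
    )
    kw.update(overrides)
    return ProtocolSpec(**kw)


@dataclass
class CellArchetype:
    """Ground-truth parameters of one simulated cell.

    Defaults describe the anaxonic dopaminergic archetype; use
    :func:`default_archetype` for the per-subtype presets.
    """

    subtype: str = "anaxonic"
    R_s_true: float = 12.0
    R_m_true: float = 672.0
    C_m_true: float = 41.57
    aei_charge_true: float = 44.11
    aei_decay_k_true: float = 0.03
    tail_charge_true: float = 0.0
    sipsc_rate: float = 2.0
    sipsc_amp_mean: float = 30.0
    noise_sd: float = 5.0
    holding_pA: float = -20.0

    def __post_init__(self):
        if min(self.R_s_true, self.R_m_true, self.C_m_true) <= 0:
            raise ValidationError("resistances and capacitance must be > 0")
        if self.aei_charge_true < 0 or self.tail_charge_true < 0:
            raise ValidationError("charges must be >= 0")
        if self.aei_decay_k_true <= 0:
            raise ValidationError("aei_decay_k_true must be > 0")


#: Subtype presets anchored to the study's group means: anaxonic cells show
#: large AEI (≈44 pC) and high input resistance; axon-bearing cells show
#: little or no AEI (≈4 pC), lower input resistance, and a cadmium-sensitive
#: tail current (≈15 pC).
SUBTYPE_PRESETS: dict[str, dict] = {
    "anaxonic": dict(
        subtype="anaxonic",
        R_s_true=12.0,
        R_m_true=672.0,  # R_input 683.8 MΩ minus R_s
        C_m_true=41.57,
        aei_charge_true=44.11,
        aei_decay_k_true=0.03,
        tail_charge_true=0.0,
    ),
    "axon_bearing": dict(
        subtype="axon_bearing",
        R_s_true=12.0,
        R_m_true=312.0,  # R_input 324.0 MΩ minus R_s
        C_m_true=46.08,
        aei_charge_true=3.8,
        aei_decay_k_true=0.03,
        tail_charge_true=15.33,
    ),
}


def default_archetype(subtype: str, **overrides) -> CellArchetype:
    if subtype not in SUBTYPE_PRESETS:
        raise ValidationError(f"unknown subtype {subtype!r}")
    kw = dict(SUBTYPE_PRESETS[subtype])
    kw.update(overrides)
    return CellArchetype(**kw)


@dataclass(frozen=True)
class Pharmacology:
    """Bath-condition flags; each independently toggles a current component."""

    gabazine: bool = False
    cadmium: bool = False
    da_blockers: bool = False


@dataclass
class SweepSet:
    """A set of equal-length sweeps with protocol metadata."""

    sweeps: np.ndarray  # (n_sweeps, n_samples)
    sample_interval_us: float
    units: str
    protocol: ProtocolSpec | None = None
    t0_ms: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.units not in {"pA", "mV"}:
            raise ValidationError("units must be 'pA' or 'mV'")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def time_ms(self) -> np.ndarray:
        n = self.sweeps.shape[1]
        return self.t0_ms + np.arange(n) * self.sample_interval_us / 1000.0


# ---------------------------------------------------------------------------
# passive RC responses


def rc_tau_ms(arch: CellArchetype) -> float:
    """Clamp time constant C_m·(R_s‖R_m); pF·MΩ = µs, returned in ms."""
    r_par = arch.R_s_true * arch.R_m_true / (arch.R_s_true + arch.R_m_true)
    return arch.C_m_true * r_par / 1000.0


def rc_step_current(t_ms: np.ndarray, dV_mV: float, arch: CellArchetype) -> np.ndarray:
    """Closed-form current (pA) after a voltage step of ``dV_mV`` at t = 0.

    Peak ΔV/R_s relaxing to steady state ΔV/(R_s + R_m); zero for t < 0.
    """
    t = np.asarray(t_ms, dtype=float)
    i_ss = 1000.0 * dV_mV / (arch.R_s_true + arch.R_m_true)
    i_0 = 1000.0 * dV_mV / arch.R_s_true
    tau = rc_tau_ms(arch)
    out = np.zeros_like(t)
    m = t >= 0
    out[m] = i_ss + (i_0 - i_ss) * np.exp(-t[m] / tau)
    return out


def _passive_trace(t_ms: np.ndarray, proto: ProtocolSpec, arch: CellArchetype, dV: float) -> np.ndarray:
    """Superposed RC on/off responses for every step epoch (shared ΔV)."""
    trace = np.zeros_like(t_ms)
    for on, off in proto.step_epochs():
        trace += rc_step_current(t_ms - on, dV, arch)
        trace += rc_step_current(t_ms - off, -dV, arch)
    return trace


# ---------------------------------------------------------------------------
# synaptic kernels, normalised to analysis-window charge


def _window_integral_biexp(k_decay: float, tau_rise: float, w0: float, w1: float) -> float:
    """∫ (e^{-k t} − e^{-t/τ}) dt over [w0, w1] (per unit amplitude)."""
    a = (np.exp(-k_decay * w0) - np.exp(-k_decay * w1)) / k_decay
    b = tau_rise * (np.exp(-w0 / tau_rise) - np.exp(-w1 / tau_rise))
    return float(a - b)


def gaba_kernel(t_ms: np.ndarray, charge_pC: float, k_decay: float) -> np.ndarray:
    """Inward (negative) GABA-A conductance current starting at t = 0.

    Difference-of-exponentials with a 1 ms rise and 1/k decay, scaled so its
    integral over the 10–510 ms analysis window equals ``charge_pC``.
    """
    t = np.asarray(t_ms, dtype=float)
    w0, w1 = GABA_WINDOW_MS
    norm = _window_integral_biexp(k_decay, GABA_RISE_TAU_MS, w0, w1)
    amp = 1000.0 * charge_pC / norm  # pA, since t is in ms
    out = np.zeros_like(t)
    m = t >= 0
    out[m] = -amp * (np.exp(-k_decay * t[m]) - np.exp(-t[m] / GABA_RISE_TAU_MS))
    return out


def tail_kernel(t_ms: np.ndarray, charge_pC: float) -> np.ndarray:
    """Inward mono-exponential calcium tail current starting at t = 0.

    Decay 20 ms, scaled so the 10–510 ms window integral equals ``charge_pC``.
    """
    t = np.asarray(t_ms, dtype=float)
    w0, w1 = GABA_WINDOW_MS
    tau = TAIL_DECAY_TAU_MS
    norm = tau * (np.exp(-w0 / tau) - np.exp(-w1 / tau))
    amp = 1000.0 * charge_pC / norm
    out = np.zeros_like(t)
    m = t >= 0
    out[m] = -amp * np.exp(-t[m] / tau)
    return out


def sipsc_kernel(t_ms: np.ndarray, amp_pA: float) -> np.ndarray:
    """Inward spontaneous-IPSC waveform (0.5 ms rise, 10 ms decay), peak ≈ amp."""
    t = np.asarray(t_ms, dtype=float)
    tr, td = SIPSC_RISE_TAU_MS, SIPSC_DECAY_TAU_MS
    tp = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-tp / td) - np.exp(-tp / tr)
    out = np.zeros_like(t)
    m = t >= 0
    out[m] = -(amp_pA / peak) * (np.exp(-t[m] / td) - np.exp(-t[m] / tr))
    return out


# ---------------------------------------------------------------------------
# simulators


def simulate_membrane_test(arch: CellArchetype, proto: ProtocolSpec | None = None, seed: int = 0) -> SweepSet:
    """Voltage-clamp double test pulse (−ΔV then +ΔV) for one cell."""
    proto = proto or membrane_test_protocol()
    if proto.kind != "membrane_test":
        raise ValidationError("protocol kind must be 'membrane_test'")
    rng = np.random.default_rng(seed)
    t = np.arange(proto.n_samples) * proto.dt_ms
    (on1, off1), (on2, off2) = proto.step_epochs()
    dV = abs(proto.step_mV)
    clean = arch.holding_pA + np.zeros_like(t)
    for on, off, s in ((on1, off1, -dV), (on2, off2, dV)):
        clean += rc_step_current(t - on, s, arch) + rc_step_current(t - off, -s, arch)
    sweeps = clean[None, :] + rng.normal(0.0, arch.noise_sd, size=(proto.n_repeats, t.size)) if arch.noise_sd > 0 else np.tile(clean, (proto.n_repeats, 1))
    return SweepSet(
        sweeps=sweeps,
        sample_interval_us=proto.sample_interval_us,
        units="pA",
        protocol=proto,
        meta={"seed": seed, "archetype": arch, "polarity_mV": (-dV, dV)},
    )


def simulate_aei(
    arch: CellArchetype,
    proto: ProtocolSpec | None = None,
    pharm: Pharmacology = Pharmacology(),
    seed: int = 0,
) -> SweepSet:
    """Voltage-clamp AEI sweeps for one cell under given bath conditions.

    Each step's end triggers (unless blocked) an inward GABA component with
    analysis-window charge ``aei_charge_true`` (absent under gabazine) and a
    tail component with charge ``tail_charge_true`` (absent under cadmium).
    Spontaneous IPSCs arrive as a Poisson process, suppressed by gabazine.
    Component random draws use seed substreams so a shared seed yields
    identical event times and noise across pharmacological conditions.
    """
    proto = proto or aei_protocol()
    if proto.kind not in {"aei_single", "aei_paired", "aei_long"}:
        raise ValidationError("protocol kind must be an AEI protocol")
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_ev = np.random.default_rng(ss[0])
    rng_noise = np.random.default_rng(ss[1])
    t = np.arange(proto.n_samples) * proto.dt_ms
    dV = proto.step_mV - proto.holding_mV
    passive = arch.holding_pA + _passive_trace(t, proto, arch, dV)

    gaba = np.zeros_like(t)
    tail = np.zeros_like(t)
    for _on, off in proto.step_epochs():
        if not pharm.gabazine and arch.aei_charge_true > 0:
            gaba += gaba_kernel(t - off, arch.aei_charge_true, arch.aei_decay_k_true)
        if not pharm.cadmium and arch.tail_charge_true > 0:
            tail += tail_kernel(t - off, arch.tail_charge_true)

    n = proto.n_repeats
    sipsc = np.zeros((n, t.size))
    duration = proto.duration_ms
    for i in range(n):
        n_ev = rng_ev.poisson(arch.sipsc_rate * duration / 1000.0)
        times = rng_ev.uniform(0.0, duration, size=n_ev)
        amps = np.clip(rng_ev.normal(arch.sipsc_amp_mean, 0.3 * arch.sipsc_amp_mean, size=n_ev), 0.0, None)
        if not pharm.gabazine:
            for t_ev, a in zip(times, amps):
                sipsc[i] += sipsc_kernel(t - t_ev, a)

    noise = rng_noise.normal(0.0, arch.noise_sd, size=(n, t.size)) if arch.noise_sd > 0 else 0.0
    sweeps = passive[None, :] + gaba[None, :] + tail[None, :] + sipsc + noise
    return SweepSet(
        sweeps=sweeps,
        sample_interval_us=proto.sample_interval_us,
        units="pA",
        protocol=proto,
        meta={
            "seed": seed,
            "archetype": arch,
            "pharmacology": pharm,
            "components": {"gaba": gaba, "tail": tail, "sipsc": sipsc},
        },
    )


def simulate_sipsc_recording(
    arch: CellArchetype,
    duration_ms: float = 60_000.0,
    pharm: Pharmacology = Pharmacology(),
    seed: int = 0,
    sample_interval_us: float = 20.0,
) -> SweepSet:
    """Step-free holding recording of spontaneous IPSCs (e.g. 1 min at −80 mV).

    Gabazine suppresses the events; the noise stream is drawn independently
    of the event stream so shared seeds align across conditions.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_ev = np.random.default_rng(ss[0])
    rng_noise = np.random.default_rng(ss[1])
    dt = sample_interval_us / 1000.0
    t = np.arange(int(round(duration_ms / dt)) + 1) * dt
    trace = np.full_like(t, arch.holding_pA)
    n_ev = rng_ev.poisson(arch.sipsc_rate * duration_ms / 1000.0)
    times = rng_ev.uniform(0.0, duration_ms, size=n_ev)
    amps = np.clip(rng_ev.normal(arch.sipsc_amp_mean, 0.3 * arch.sipsc_amp_mean, size=n_ev), 0.0, None)
    if not pharm.gabazine:
        for t_ev, a in zip(times, amps):
            trace += sipsc_kernel(t - t_ev, a)
    if arch.noise_sd > 0:
        trace = trace + rng_noise.normal(0.0, arch.noise_sd, size=t.size)
    return SweepSet(
        sweeps=trace[None, :],
        sample_interval_us=sample_interval_us,
        units="pA",
        protocol=None,
        meta={"seed": seed, "pharmacology": pharm, "n_events_true": int(n_ev)},
    )


# --- action potentials ------------------------------------------------------

#: Waveform constants (mV amplitudes, ms time constants).  The biphasic shape
#: superposes a small fast axon-initial-segment surrogate and a delayed large
#: somatic component; repolarisation is slow (caesium-filled pipette).
SPIKE_SHAPES = {
    "anaxonic": dict(components=[(85.0, 0.10, 0.0)], repol_tau=2.0),
    "axon_bearing": dict(components=[(20.0, 0.05, 0.0), (70.0, 0.07, 0.45)], repol_tau=2.0),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def spike_waveform(subtype: str, t_ms: np.ndarray, t0_ms: float = 5.0, v_rest: float = -60.0) -> np.ndarray:
    """Noise-free AP voltage trace for a subtype (monophasic or biphasic)."""
    shape = SPIKE_SHAPES[subtype]
    v = np.full_like(np.asarray(t_ms, dtype=float), v_rest)
    total = 0.0
    last_delay = 0.0
    for amp, rise, delay in shape["components"]:
        v = v + amp * _sigmoid((t_ms - t0_ms - delay) / rise)
        total += amp
        last_delay = max(last_delay, delay)
    # slow logistic repolarisation back to rest
    v = v - total * _sigmoid((t_ms - t0_ms - last_delay - 1.2) / shape["repol_tau"])
    return v


def simulate_spike(
    arch: CellArchetype,
    seed: int = 0,
    noise_mV: float = 0.0,
    duration_ms: float = 15.0,
    sample_interval_us: float = 5.0,
) -> SweepSet:
    """Current-clamp single action potential at 200 kHz (5 µs interval).

    Anaxonic cells produce a single smooth upstroke (one dV/dt maximum);
    axon-bearing cells an early initial-segment component followed by the
    somatic spike (two separable dV/dt maxima).
    """
    if arch.subtype not in SPIKE_SHAPES:
        raise ValidationError(f"unknown subtype {arch.subtype!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_ms * 1000.0 / sample_interval_us)) + 1) * sample_interval_us / 1000.0
    v = spike_waveform(arch.subtype, t)
    if noise_mV > 0:
        v = v + rng.normal(0.0, noise_mV, size=v.shape)
    return SweepSet(
        sweeps=v[None, :],
        sample_interval_us=sample_interval_us,
        units="mV",
        protocol=None,
        meta={"seed": seed, "subtype": arch.subtype, "noise_mV": noise_mV},
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Between-cell and between-animal variability of cohort parameters.

    Coefficients of variation act on the log scale (lognormal draws with the
    mean corrected so the arithmetic mean equals the subtype preset).  The
    defaults approximate the study's between-cell spread (SEM·√n) for AEI
    charge and passive properties.
    """

    cell_cv: dict = field(
        default_factory=lambda: {
            "R_m_true": 0.45,
            "C_m_true": 0.20,
            "aei_charge_true": 0.70,
            "aei_decay_k_true": 0.30,
            "R_s_true": 0.20,
        }
    )
    animal_sd_log: float = 0.20


def make_cohort(
    n_cells_per_subtype: int,
    n_animals: int,
    seed: int = 0,
    spec: CohortSpec | None = None,
    subtypes: tuple[str, ...] = ("anaxonic", "axon_bearing"),
    overrides: dict | None = None,
) -> list[tuple[CellArchetype, str]]:
    """Draw a cohort of cells nested in animals, per subtype.

    ``n_animals`` animals are created *per subtype* and cells are dealt to
    them round-robin; every drawn parameter receives a shared animal-level
    lognormal effect (SD ``animal_sd_log`` on the log scale) and a cell-level
    lognormal effect (per-parameter CV), both mean-corrected.  Deterministic
    per seed.
    """
    if n_animals < 1:
        raise ValidationError("n_animals must be >= 1")
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    cohort: list[tuple[CellArchetype, str]] = []
    for s_i, subtype in enumerate(subtypes):
        base = dict(SUBTYPE_PRESETS[subtype])
        if overrides:
            base.update(overrides.get(subtype, {}))
        a_sd = spec.animal_sd_log
        animal_eff = {
            f"{subtype}_a{j}": rng.normal(0.0, a_sd) if a_sd > 0 else 0.0
            for j in range(n_animals)
        }
        for i in range(n_cells_per_subtype):
            animal = f"{subtype}_a{i % n_animals}"
            kw = dict(base)
            for name, cv in spec.cell_cv.items():
                mean = float(base[name])
                if mean <= 0:
                    continue
                sig_c = np.sqrt(np.log1p(cv**2))
                z = animal_eff[animal] + (rng.normal(0.0, sig_c) if cv > 0 else 0.0)
                corr = 0.5 * (a_sd**2 + sig_c**2)
                kw[name] = mean * np.exp(z - corr)
            cohort.append((CellArchetype(**kw), animal))
    return cohort


def quiet_archetype(subtype: str = "anaxonic", **overrides) -> CellArchetype:
    """Archetype with all noise sources off (noise_sd = 0, no sIPSCs)."""
    kw = dict(noise_sd=0.0, sipsc_rate=0.0)
    kw.update(overrides)
    return default_archetype(subtype, **kw)
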