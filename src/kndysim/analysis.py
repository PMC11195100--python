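"""Measurements applied to simulated traces: I-V relations, Boltzmann fits,
drug-subtraction current isolation, M-current relaxation amplitude, slow-EPSP
metrics, rheobase / F-I curves, firing-pattern classification and
two-parameter regime maps.

All routines operate on :class:`~kndysim.model.SimTrace` objects (or families
thereof) and return small dataclasses or tidy DataFrames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import butter, sosfiltfilt

from .model import SimTrace, simulate, simulate_family
from .params import NeuronParams, ParameterError
from .protocols import StepFamilyProtocol, StimulusProtocol


class AnalysisError(ValueError):
    pass


class FitQualityWarning(UserWarning):
    """Fit requested on data that violates the expected monotone shape."""


# ------------------------------------------------------------------ I-V curves

@dataclass
class IVCurve:
    """Step potential vs (baseline-subtracted) current and current density."""

    step_potentials: np.ndarray    # mV
    current: np.ndarray            # pA
    Cm_used: float                 # pF
    mode: str = "peak"             # "peak" or "steady"

    def __post_init__(self):
        self.step_potentials = np.asarray(self.step_potentials, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.step_potentials.shape != self.current.shape:
            raise AnalysisError("step_potentials and current must align")

    @property
    def density(self) -> np.ndarray:
        """Current density in pA/pF."""
        return self.current / self.Cm_used

    @property
    def peak_potential(self) -> float:
        """Step potential of the absolute-extremum current."""
        return float(self.step_potentials[np.argmax(np.abs(self.current))])

    def at(self, v: float) -> float:
        i = np.argmin(np.abs(self.step_potentials - v))
        if abs(self.step_potentials[i] - v) > 1e-6:
            raise AnalysisError(f"no step at {v} mV")
        return float(self.current[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"V_mV": self.step_potentials,
                             "I_pA": self.current,
                             "density_pA_per_pF": self.density})


def _step_annotations(trace: SimTrace):
    meta = dict(trace.protocol.meta)
    try:
        return meta["step"], (meta["step_t0"], meta["step_t1"])
    except KeyError as e:
        raise AnalysisError(
            "trace lacks step-family annotations; simulate with simulate_family"
        ) from e


def peak_iv(traces: list[SimTrace], Cm: float | None = None,
            mode: str = "peak", baseline_ms: float = 50.0,
            signal: str = "clamp") -> IVCurve:
    """Build an I-V curve from one voltage-clamp trace per step.

    The holding-current baseline (mean over the final ``baseline_ms`` before
    the step) is subtracted.  ``mode="peak"`` takes the absolute extremum
    within the step (inward currents negative); ``mode="steady"`` averages the
    final 5% of the step, the convention for K+-current densities measured at
    the end of 500-ms pulses."""
    if not traces:
        raise AnalysisError("empty trace family")
    if mode not in ("peak", "steady"):
        raise AnalysisError(f"unknown mode {mode!r}")
    vs, curr = [], []
    for tr in traces:
        v, (t0, t1) = _step_annotations(tr)
        y = tr.net_ionic if signal == "clamp" else tr.current(signal)
        base = y[tr.window(t0 - baseline_ms, t0)].mean()
        seg = y[tr.window(t0, t1)] - base
        if mode == "peak":
            curr.append(seg[np.argmax(np.abs(seg))])
        else:
            n = max(1, int(round(0.05 * len(seg))))
            curr.append(seg[-n:].mean())
        vs.append(v)
    order = np.argsort(vs)
    Cm = Cm if Cm is not None else traces[0].params.Cm
    return IVCurve(np.asarray(vs)[order], np.asarray(curr)[order], Cm, mode)


def conductance_curve(iv: IVCurve, erev: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized conductance G/Gmax = I / (V - Erev), for activation fits."""
    df = iv.step_potentials - erev
    if np.any(np.abs(df) < 1e-9):
        raise AnalysisError("step at the reversal potential; cannot normalize")
    g = iv.current / df
    gmax = np.max(np.abs(g))
    if gmax == 0:
        raise AnalysisError("all-zero currents")
    return iv.step_potentials, g / np.max(g)


# ------------------------------------------------------------- Boltzmann fits

@dataclass
class BoltzmannFit:
    V_half: float        # mV
    k: float             # mV, > 0
    Imax: float
    kind: str            # activation | inactivation
    rss: float
    convention: str = "standard"

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "activation":
            return self.Imax / (1.0 + np.exp((self.V_half - v) / self.k))
        return self.Imax / (1.0 + np.exp((v - self.V_half) / self.k))


def fit_boltzmann(voltages, values, kind: str = "activation",
                  convention: str = "standard") -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalized activation or
    (steady-state availability) inactivation curve.

    ``convention="one_minus"`` fits the complementary form 1 - 1/(1+exp(...))
    that some texts print for inactivation; the recovered V1/2 is identical,
    the slope keeps its conventional positive sign."""
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(values, dtype=float)
    if v.size < 4:
        raise AnalysisError("need at least 4 points for a Boltzmann fit")
    if kind not in ("activation", "inactivation"):
        raise AnalysisError(f"unknown kind {kind!r}")
    if convention not in ("standard", "one_minus"):
        raise AnalysisError(f"unknown convention {convention!r}")

    rising = kind == "activation"
    yy = 1.0 - y if (convention == "one_minus") else y
    # monotonicity sanity check against noise-tolerant trend
    trend = np.polyfit(v, yy, 1)[0]
    if (trend > 0) != rising and abs(trend) > 1e-4:
        warnings.warn("data trend contradicts the requested Boltzmann kind",
                      FitQualityWarning, stacklevel=2)

    sign = 1.0 if rising else -1.0

    def model(vv, vh, kk, imax):
        return imax / (1.0 + np.exp(sign * (vh - vv) / kk))

    vh0 = v[np.argmin(np.abs(yy - 0.5 * yy.max()))]
    p0 = (vh0, 8.0, float(yy.max()) or 1.0)
    popt, _ = curve_fit(model, v, yy, p0=p0, maxfev=20000)
    vh, kk, imax = popt
    resid = yy - model(v, *popt)
    return BoltzmannFit(V_half=float(vh), k=float(abs(kk)), Imax=float(imax),
                        kind=kind, rss=float(resid @ resid),
                        convention=convention)


# ------------------------------------------------------ subtraction pharmacology

def drug_subtraction(control, treated):
    """Drug-sensitive component: pointwise control - treated.

    Accepts a pair of SimTraces recorded under identical protocols (returns a
    new SimTrace whose current decomposition is the difference) or a pair of
    IVCurves (returns an IVCurve)."""
    if isinstance(control, IVCurve) and isinstance(treated, IVCurve):
        if not np.allclose(control.step_potentials, treated.step_potentials):
            raise AnalysisError("IV curves measured at different potentials")
        if control.mode != treated.mode:
            raise AnalysisError("IV curves measured in different modes")
        return IVCurve(control.step_potentials.copy(),
                       control.current - treated.current,
                       control.Cm_used, control.mode)
    if isinstance(control, SimTrace) and isinstance(treated, SimTrace):
        if control.protocol.content_hash != treated.protocol.content_hash:
            raise AnalysisError("traces come from different protocols")
        if control.t.shape != treated.t.shape:
            raise AnalysisError("traces sampled differently")
        return replace(control, currents=control.currents - treated.currents)
    raise AnalysisError("control and treated must both be SimTrace or IVCurve")


def m_current_amplitude(trace: SimTrace, early_ms: float = 10.0,
                        late_window: tuple[float, float] = (475.0, 500.0)) -> float:
    """M-current relaxation amplitude of one deactivation-step sweep.

    Amplitude = mean current in the first ``early_ms`` of the step minus the
    mean sustained current in ``late_window`` (ms from step onset)."""
    _, (t0, t1) = _step_annotations(trace)
    if t1 - t0 < late_window[1]:
        raise AnalysisError("step shorter than the late measurement window")
    y = trace.net_ionic
    # open interval at step onset: the sample at exactly t0 closes the
    # preceding (prepulse) segment
    m_early = (trace.t > t0) & (trace.t <= t0 + early_ms)
    early = y[m_early].mean()
    late = y[trace.window(t0 + late_window[0], t0 + late_window[1])].mean()
    return float(early - late)


# ------------------------------------------------------------------- slow EPSP

@dataclass
class SlowEpspMeasurement:
    R1: float                     # mV
    R2: float | None              # mV (None with a single epoch)
    ratio: float | None           # R2/R1; None when undefined
    filter_cutoff: float          # Hz


def lowpass(trace_v: np.ndarray, dt_ms: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of a sampled signal."""
    sos = butter(4, cutoff_hz, fs=1000.0 / dt_ms, output="sos")
    return sosfiltfilt(sos, trace_v)


def slow_epsp_metrics(trace: SimTrace, cutoff: float = 2.0,
                      post_window_s: float = 10.0,
                      baseline_s: float = 5.0,
                      min_amplitude: float = 0.5) -> SlowEpspMeasurement:
    """Slow-EPSP amplitude(s) from a stimulation-train trace.

    The membrane potential is low-pass filtered at ``cutoff``; for each
    stimulation epoch the amplitude is the filtered peak within
    ``post_window_s`` after train end minus the pre-train baseline mean.
    With two epochs the R2/R1 ratio is reported; it is undefined (None) when
    R1 falls below ``min_amplitude`` mV."""
    epochs = trace.protocol.epochs
    if not epochs:
        raise AnalysisError("protocol has no stimulation epochs")
    if len(epochs) > 2:
        raise AnalysisError("at most two stimulation epochs supported")
    f = lowpass(trace.V, trace.dt, cutoff)
    amps = []
    for (t_on, t_off) in epochs:
        base = f[trace.window(max(0.0, t_on - baseline_s * 1000.0), t_on)].mean()
        m = trace.window(t_off, t_off + post_window_s * 1000.0)
        amps.append(float(f[m].max() - base))
    r1 = amps[0]
    r2 = amps[1] if len(amps) == 2 else None
    ratio = (r2 / r1) if (r2 is not None and r1 > min_amplitude) else None
    return SlowEpspMeasurement(R1=r1, R2=r2, ratio=ratio, filter_cutoff=cutoff)


# ------------------------------------------------------------ spikes and F-I

def spike_times(trace: SimTrace, threshold: float = -20.0,
                refractory_ms: float = 2.0) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings with a refractory gap."""
    v = trace.V
    ix = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold))
    if ix.size == 0:
        return np.empty(0)
    t = trace.t[ix + 1]
    keep = [0]
    for i in range(1, t.size):
        if t[i] - t[keep[-1]] >= refractory_ms:
            keep.append(i)
    return t[keep]


RHEOBASE_NOT_REACHED = float("nan")


@dataclass
class FICurve:
    current_pA: np.ndarray
    rate_hz: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"I_pA": self.current_pA, "rate_Hz": self.rate_hz})


def rheobase_from_ramp(trace: SimTrace, threshold: float = -20.0) -> float:
    """Injected current (pA) at the first spike of a current ramp.

    Returns NaN (not-reached sentinel) for subthreshold-only ramps."""
    st = spike_times(trace, threshold)
    if st.size == 0:
        return RHEOBASE_NOT_REACHED
    i = np.searchsorted(trace.t, st[0])
    return float(trace.injected[min(i, trace.injected.size - 1)])


def fi_curve(traces: list[SimTrace], threshold: float = -20.0) -> FICurve:
    """Firing rate per injected current step from a current-clamp family."""
    amps, rates = [], []
    for tr in traces:
        amp, (t0, t1) = _step_annotations(tr)
        st = spike_times(tr, threshold)
        n = np.sum((st >= t0) & (st < t1))
        amps.append(amp)
        rates.append(1000.0 * n / (t1 - t0))
    order = np.argsort(amps)
    return FICurve(np.asarray(amps)[order], np.asarray(rates)[order])


def rheobase_and_fi(ramp_trace: SimTrace, step_traces: list[SimTrace],
                    threshold: float = -20.0) -> tuple[float, FICurve]:
    return rheobase_from_ramp(ramp_trace, threshold), fi_curve(step_traces, threshold)


# ------------------------------------------------- firing-pattern classification

FIRING_LABELS = ("phasic_burst", "irregular_burst", "tonic", "irregular", "silent")


@dataclass
class FiringConfig:
    """Thresholds of the rule cascade (documented package constants)."""

    spike_threshold: float = -20.0    # mV upward crossing
    refractory_ms: float = 2.0
    silent_rate_hz: float = 0.1       # below this mean rate -> silent
    intra_burst_isi_ms: float = 80.0
    min_quiescence_ms: float = 300.0  # gap separating bursts
    min_spikes_per_burst: int = 2
    burst_fraction: float = 0.5       # spikes inside bursts for burst labels
    bimodal_separation_mv: float = 10.0
    bimodal_min_weight: float = 0.05
    tonic_cv: float = 0.5             # ISI CV below -> tonic
    min_duration_s: float = 10.0


@dataclass
class FiringClass:
    label: str
    features: dict = field(default_factory=dict)


def _up_down_modes(v: np.ndarray, clip_at: float = -30.0):
    """Two-means split of the subthreshold membrane-potential distribution."""
    sub = np.clip(v, None, clip_at)
    c1, c2 = np.percentile(sub, 10), np.percentile(sub, 90)
    for _ in range(100):
        mid = 0.5 * (c1 + c2)
        lo, hi = sub[sub <= mid], sub[sub > mid]
        if lo.size == 0 or hi.size == 0:
            break
        n1, n2 = lo.mean(), hi.mean()
        if abs(n1 - c1) + abs(n2 - c2) < 1e-9:
            c1, c2 = n1, n2
            break
        c1, c2 = n1, n2
    w = np.mean(sub > 0.5 * (c1 + c2))
    return abs(c2 - c1), float(min(w, 1 - w))


def burst_groups(st: np.ndarray, cfg: FiringConfig) -> list[np.ndarray]:
    """Group spikes into bursts: intra-burst ISI <= threshold and bursts
    flanked by at least the minimum quiescence."""
    if st.size == 0:
        return []
    groups, cur = [], [st[0]]
    for dt, t in zip(np.diff(st), st[1:]):
        if dt <= cfg.intra_burst_isi_ms:
            cur.append(t)
        else:
            groups.append(np.asarray(cur))
            cur = [t]
    groups.append(np.asarray(cur))
    # a burst must contain enough spikes and be separated from neighbours
    bursts = []
    for i, g in enumerate(groups):
        if g.size < cfg.min_spikes_per_burst:
            continue
        gap_ok = True
        if i > 0 and g[0] - groups[i - 1][-1] < cfg.min_quiescence_ms:
            gap_ok = False
        if i < len(groups) - 1 and groups[i + 1][0] - g[-1] < cfg.min_quiescence_ms:
            gap_ok = False
        if gap_ok:
            bursts.append(g)
    return bursts


def classify_firing(trace: SimTrace, config: FiringConfig | None = None) -> FiringClass:
    """Deterministic rule cascade assigning one of the five firing labels.

    silent: mean rate below threshold.  Burst labels require most spikes to
    fall into bursts (>=2 spikes, intra-burst ISI <= 80 ms, >= 300 ms
    quiescence between bursts); phasic bursting additionally requires a
    bimodal (up/down-state) subthreshold potential distribution.  Remaining
    trains split tonic vs irregular at ISI CV = 0.5."""
    cfg = config or FiringConfig()
    dur_s = (trace.t[-1] - trace.t[0]) / 1000.0
    if dur_s < cfg.min_duration_s:
        raise AnalysisError(
            f"need >= {cfg.min_duration_s} s of activity, got {dur_s:.1f} s")
    st = spike_times(trace, cfg.spike_threshold, cfg.refractory_ms)
    rate = st.size / dur_s
    feats = {"spike_count": int(st.size), "mean_rate_hz": float(rate)}
    if rate < cfg.silent_rate_hz:
        return FiringClass("silent", feats)

    isi = np.diff(st)
    cv = float(isi.std() / isi.mean()) if isi.size >= 2 else 0.0
    feats["isi_cv"] = cv
    bursts = burst_groups(st, cfg)
    in_burst = sum(g.size for g in bursts)
    feats["burst_count"] = len(bursts)
    feats["burst_spike_fraction"] = in_burst / st.size
    if bursts:
        feats["intra_burst_rate_hz"] = float(np.mean(
            [1000.0 * (g.size - 1) / (g[-1] - g[0]) for g in bursts if g.size > 1] or [0.0]))
    sep, wmin = _up_down_modes(trace.V)
    bimodal = sep >= cfg.bimodal_separation_mv and wmin >= cfg.bimodal_min_weight
    feats["updown_separation_mv"] = float(sep)
    feats["updown_state"] = bool(bimodal)

    if len(bursts) >= 2 and feats["burst_spike_fraction"] >= cfg.burst_fraction:
        return FiringClass("phasic_burst" if bimodal else "irregular_burst", feats)
    if cv < cfg.tonic_cv:
        return FiringClass("tonic", feats)
    return FiringClass("irregular", feats)


# ------------------------------------------------------------------ regime maps

@dataclass
class RegimeMap:
    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    labels: np.ndarray            # (n1, n2) object array of label strings

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {self.axis1_name: g1, self.axis2_name: g2,
             "label": self.labels[i, j]}
            for i, g1 in enumerate(self.axis1_values)
            for j, g2 in enumerate(self.axis2_values)
        ]
        return pd.DataFrame(rows)

    def label_at(self, i: int, j: int) -> str:
        return str(self.labels[i, j])

    def boundary(self) -> pd.DataFrame:
        """Firing/silent transition front: for each axis-2 value, the first
        axis-1 value (scanning upward) whose label is not silent/failed."""
        rows = []
        for j, g2 in enumerate(self.axis2_values):
            onset = None
            for i, g1 in enumerate(self.axis1_values):
                if self.labels[i, j] not in ("silent", "failed"):
                    onset = g1
                    break
            rows.append({self.axis2_name: g2,
                         f"{self.axis1_name}_onset": onset})
        return pd.DataFrame(rows)


def regime_map(base: NeuronParams, axis1: tuple[str, np.ndarray],
               axis2: tuple[str, np.ndarray], protocol: StimulusProtocol,
               config: FiringConfig | None = None,
               settle_first: bool = True) -> RegimeMap:
    """Classify firing across a 2-D grid of conductance values.

    Each grid point re-simulates ``protocol`` with the two conductances
    replaced; integration failures become the label "failed" rather than
    aborting the sweep."""
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if vals1.size == 0 or vals2.size == 0:
        raise AnalysisError("empty axis grid")
    labels = np.empty((vals1.size, vals2.size), dtype=object)
    for i, g1 in enumerate(vals1):
        for j, g2 in enumerate(vals2):
            p = base.copy()
            p.channels[name1].gbar = float(g1)
            p.channels[name2].gbar = float(g2)
            try:
                tr = simulate(p, protocol)
                labels[i, j] = classify_firing(tr, config).label
            except Exception:
                labels[i, j] = "failed"
    return RegimeMap(name1, vals1, name2, vals2, labels)
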