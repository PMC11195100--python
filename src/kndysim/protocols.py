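"""Declarative stimulation protocols and in-silico pharmacology.

Protocols are immutable value objects: ordered segments of clamp mode,
command waveform and NKB/Dyn receptor drive.  Step families (I-V, M-current,
F-I) are represented by :class:`StepFamilyProtocol`, which expands into one
sweep per step; sweeps start from the steady state at the holding command,
standing in for the 5-s inter-sweep pacing of the recordings.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine as en
from .params import NeuronParams, ParameterError


@dataclass(frozen=True)
class DriveCommand:
    """NKB or Dyn receptor drive during one segment.

    ``level`` is a constant ligand occupancy in [0, 1]; alternatively a pulse
    train (``train_freq`` Hz, ``pulse_width`` ms, ``train_duration`` ms) of
    unit-amplitude ligand pulses, emulating high-frequency stimulation.
    """

    level: float = 0.0
    train_freq: float = 0.0
    pulse_width: float = 5.0
    train_duration: float = 0.0

    @property
    def is_train(self) -> bool:
        return self.train_freq > 0

    @property
    def n_pulses(self) -> int:
        if not self.is_train:
            return 0
        return int(round(self.train_freq * self.train_duration / 1000.0))

    def validate(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ParameterError("drive level must be in [0, 1]")


OFF = DriveCommand()


@dataclass(frozen=True)
class Segment:
    """One contiguous protocol epoch."""

    duration: float                  # ms
    mode: str = "cc"                 # "cc" current clamp | "vc" voltage clamp
    command: float = 0.0             # pA (cc) or mV (vc) at segment start
    command_rate: float = 0.0        # pA/ms or mV/ms ramp slope
    nkb: DriveCommand = OFF
    dyn: DriveCommand = OFF

    def validate(self) -> None:
        if self.duration <= 0:
            raise ParameterError("segment duration must be > 0")
        if self.mode not in ("cc", "vc"):
            raise ParameterError(f"unknown clamp mode {self.mode!r}")
        self.nkb.validate()
        self.dyn.validate()

    def to_seg_vector(self) -> np.ndarray:
        s = np.zeros(en.SEG_LEN)
        s[en.SEG_MODE] = en.MODE_VC if self.mode == "vc" else en.MODE_CC
        s[en.SEG_DUR] = self.duration
        s[en.SEG_CMD0] = self.command
        s[en.SEG_RATE] = self.command_rate
        for d, base in ((self.nkb, en.SEG_NKB_MODE), (self.dyn, en.SEG_DYN_MODE)):
            if d.is_train:
                s[base] = 1.0
                s[base + 1] = d.train_freq
                s[base + 2] = d.pulse_width
                s[base + 3] = d.train_duration
            else:
                s[base] = 0.0
                s[base + 1] = d.level
                s[base + 3] = self.duration
        return s


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, contiguous segments plus analysis annotations.

    ``epochs`` lists (start, end) ms of stimulation trains, used by the
    slow-EPSP metrics; other annotations ride in ``meta``.
    """

    segments: tuple[Segment, ...]
    name: str = "custom"
    epochs: tuple[tuple[float, float], ...] = ()
    meta: tuple = ()

    def validate(self) -> None:
        if not self.segments:
            raise ParameterError("protocol needs at least one segment")
        for s in self.segments:
            s.validate()

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @property
    def nkb_pulse_count(self) -> int:
        return sum(s.nkb.n_pulses for s in self.segments)

    @property
    def content_hash(self) -> str:
        arr = np.concatenate([s.to_seg_vector() for s in self.segments])
        return hashlib.sha256(arr.tobytes()).hexdigest()[:16]

    # -- serialization (same human-editable config family as parameters) --
    def to_dict(self) -> dict:
        def drive(d: DriveCommand):
            if d.is_train:
                return {"train_freq": d.train_freq, "pulse_width": d.pulse_width,
                        "train_duration": d.train_duration}
            return {"level": d.level}

        return {
            "name": self.name,
            "epochs": [list(e) for e in self.epochs],
            "meta": [list(m) for m in self.meta],
            "segments": [
                {"duration": s.duration, "mode": s.mode, "command": s.command,
                 "command_rate": s.command_rate, "nkb": drive(s.nkb),
                 "dyn": drive(s.dyn)}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        segs = tuple(
            Segment(duration=s["duration"], mode=s["mode"],
                    command=s["command"], command_rate=s.get("command_rate", 0.0),
                    nkb=DriveCommand(**s.get("nkb", {})),
                    dyn=DriveCommand(**s.get("dyn", {})))
            for s in d["segments"]
        )
        p = cls(segs, name=d.get("name", "custom"),
                epochs=tuple(tuple(e) for e in d.get("epochs", [])),
                meta=tuple(tuple(m) for m in d.get("meta", [])))
        p.validate()
        return p


@dataclass(frozen=True)
class StepFamilyProtocol:
    """A family of identical sweeps differing only in one step command."""

    mode: str                        # "vc" or "cc"
    hold: float                      # holding command (mV or pA)
    steps: tuple[float, ...]         # per-sweep step commands
    step_duration: float             # ms
    pre_duration: float = 200.0      # ms at hold before the (pre)pulse
    post_duration: float = 100.0     # ms at hold after the step
    prepulse: tuple[float, float] | None = None   # (command, duration ms)
    inter_sweep_s: float = 5.0       # pacing; sweeps start settled at hold
    name: str = "step_family"

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def step_window(self) -> tuple[float, float]:
        t0 = self.pre_duration + (self.prepulse[1] if self.prepulse else 0.0)
        return (t0, t0 + self.step_duration)

    def sweep(self, i: int) -> StimulusProtocol:
        segs = [Segment(self.pre_duration, self.mode, self.hold)]
        if self.prepulse is not None:
            segs.append(Segment(self.prepulse[1], self.mode, self.prepulse[0]))
        segs.append(Segment(self.step_duration, self.mode, self.steps[i]))
        segs.append(Segment(self.post_duration, self.mode, self.hold))
        w0, w1 = self.step_window
        return StimulusProtocol(
            tuple(segs), name=f"{self.name}[{self.steps[i]:g}]",
            meta=(("step", self.steps[i]), ("step_t0", w0), ("step_t1", w1)),
        )

    def sweeps(self):
        return [self.sweep(i) for i in range(self.n_steps)]


# ----------------------------------------------------------- paper's protocols

def ca_iv_protocol(v_max: float = 30.0) -> StepFamilyProtocol:
    """Ca-current I-V family: 150-ms steps from a -80 mV hold, 10-mV
    increments.  The upper bound is configurable; +30 mV by default."""
    steps = tuple(np.arange(-80.0, v_max + 1e-9, 10.0))
    return StepFamilyProtocol(
        mode="vc", hold=-80.0, steps=steps, step_duration=150.0,
        pre_duration=200.0, name="ca_iv",
    )


def k_iv_protocol() -> StepFamilyProtocol:
    """K-current I-V family: 500-ms steps, -60..+40 mV in 10-mV increments
    from a -70 mV hold, paced at 0.2 Hz."""
    steps = tuple(np.arange(-60.0, 40.0 + 1e-9, 10.0))
    return StepFamilyProtocol(
        mode="vc", hold=-70.0, steps=steps, step_duration=500.0,
        pre_duration=200.0, inter_sweep_s=5.0, name="k_iv",
    )


def m_current_protocol() -> StepFamilyProtocol:
    """M-current deactivation family: 300-ms prepulse to -20 mV, then 500-ms
    steps from -30 down to -75 mV in 5-mV decrements."""
    steps = tuple(np.arange(-30.0, -75.0 - 1e-9, -5.0))
    return StepFamilyProtocol(
        mode="vc", hold=-70.0, steps=steps, step_duration=500.0,
        pre_duration=200.0, prepulse=(-20.0, 300.0), name="m_deactivation",
    )


def ramp_protocol(rate_pA_per_s: float, max_current: float,
                  baseline_ms: float = 500.0) -> StimulusProtocol:
    """Current-clamp ramp from 0 to ``max_current`` pA at ``rate_pA_per_s``.

    A zero rate degenerates to a constant zero-current segment."""
    if rate_pA_per_s > 0:
        ramp_ms = 1000.0 * max_current / rate_pA_per_s
        ramp = Segment(ramp_ms, "cc", 0.0, command_rate=rate_pA_per_s / 1000.0)
    else:
        ramp = Segment(2000.0, "cc", 0.0)
    return StimulusProtocol(
        (Segment(baseline_ms, "cc", 0.0), ramp),
        name=f"ramp_{rate_pA_per_s:g}pA_per_s",
        meta=(("ramp_start_ms", baseline_ms), ("ramp_rate_pA_per_ms", rate_pA_per_s / 1000.0)),
    )


def nkb_synchronization_protocol(
    observe_s: float = 60.0,
    pre_s: float = 10.0,
    freq_hz: float = 20.0,
    train_s: float = 10.0,
    dyn_co_release: bool = True,
) -> StimulusProtocol:
    """High-frequency stimulation: 20-Hz ligand pulses for 10 s at zero
    injected current, then an observation window for the slow EPSP.

    Dyn is co-released with NKB by default (each pulse drives both
    receptors); disable to probe the TRPC5/GIRK balance independently."""
    train_nkb = DriveCommand(train_freq=freq_hz, pulse_width=5.0,
                             train_duration=train_s * 1000.0)
    train_dyn = train_nkb if dyn_co_release else OFF
    t0 = pre_s * 1000.0
    return StimulusProtocol(
        (
            Segment(t0, "cc", 0.0),
            Segment(train_s * 1000.0, "cc", 0.0, nkb=train_nkb, dyn=train_dyn),
            Segment(observe_s * 1000.0, "cc", 0.0),
        ),
        name="nkb_sync",
        epochs=((t0, t0 + train_s * 1000.0),),
    )


def slow_epsp_pair_protocol(gap_s: float = 90.0, observe_s: float = 60.0,
                            dyn_co_release: bool = True) -> StimulusProtocol:
    """Two successive stimulation epochs for the R2/R1 ratio measurement."""
    p1 = nkb_synchronization_protocol(observe_s=gap_s, dyn_co_release=dyn_co_release)
    p2 = nkb_synchronization_protocol(observe_s=observe_s, pre_s=0.001,
                                      dyn_co_release=dyn_co_release)
    off = p1.total_duration
    return StimulusProtocol(
        p1.segments + p2.segments,
        name="nkb_sync_pair",
        epochs=p1.epochs + tuple((a + off, b + off) for a, b in p2.epochs),
    )


def spontaneous_protocol(duration_s: float = 20.0) -> StimulusProtocol:
    """Zero-input current clamp for firing-pattern observation."""
    return StimulusProtocol((Segment(duration_s * 1000.0, "cc", 0.0),),
                            name="spontaneous")


def current_steps_protocol(amplitudes_pA, step_ms: float = 1000.0,
                           pre_ms: float = 500.0) -> StepFamilyProtocol:
    """Current-clamp step family for F-I curves."""
    return StepFamilyProtocol(
        mode="cc", hold=0.0, steps=tuple(float(a) for a in amplitudes_pA),
        step_duration=step_ms, pre_duration=pre_ms, post_duration=200.0,
        name="fi_steps",
    )


def saturating_drive_protocol(duration_s: float = 30.0, nkb: float = 1.0,
                              dyn: float = 1.0) -> StimulusProtocol:
    """Constant saturating NKB/Dyn occupancy (regime-map conditions)."""
    return StimulusProtocol(
        (Segment(duration_s * 1000.0, "cc", 0.0,
                 nkb=DriveCommand(level=nkb), dyn=DriveCommand(level=dyn)),),
        name="saturating_drive",
    )


# --------------------------------------------------------------- pharmacology

# drug -> {channel: block fraction}; "state" marks HVA-subtype antagonists
# whose fractional block of the lumped I_Ca depends on the physiological
# state (printed percentage contributions of the whole-cell Ca current).
_FULL_BLOCKS = {
    "none": {},
    "apamin": {"SK": 1.0},
    "iberiotoxin": {"BK": 1.0},
    "xe991": {"M": 1.0},
    "tta-p2": {"T": 1.0},
    "cadmium": {"T": 1.0, "Ca": 1.0},
    "ttx": {"NaT": 1.0, "NaP": 1.0},
    # intracellular Cs+/TEA recording context: all K+ conductances blocked
    "cs_internal": {"A": 1.0, "BK": 1.0, "SK": 1.0, "M": 1.0, "GIRK": 1.0},
}

_HVA_FRACTIONS = {
    # state_label -> (L, N, P/Q, R) fractions of the lumped HVA Ca current
    "OVX": {"nifedipine": 0.261, "conotoxin-gvia": 0.251,
            "agatoxin-iva": 0.039, "snx-482": 0.311},
    "OVX_E2": {"nifedipine": 0.249, "conotoxin-gvia": 0.246,
               "agatoxin-iva": 0.110, "snx-482": 0.270},
}
# omega-conotoxin MVIIC blocks N- and P/Q-type together
for _state, _f in _HVA_FRACTIONS.items():
    _f["conotoxin-mviic"] = _f["conotoxin-gvia"] + _f["agatoxin-iva"]

_ALIASES = {
    "ibtx": "iberiotoxin", "xe-991": "xe991", "ttap2": "tta-p2",
    "cd": "cadmium", "conogvia": "conotoxin-gvia", "agaiva": "agatoxin-iva",
    "snx": "snx-482", "conomviic": "conotoxin-mviic",
}


def known_drugs() -> list[str]:
    return sorted(set(_FULL_BLOCKS) | set(_HVA_FRACTIONS["OVX"]))


def apply_drug(params: NeuronParams, drug: str) -> NeuronParams:
    """Return a copy of ``params`` with the drug's conductance block applied.

    Full blockers set block_fraction to 1; HVA-subtype antagonists apply the
    state-appropriate fractional block of the lumped Ca conductance.  Blocks
    combine by maximum, so every blocker is idempotent."""
    key = _ALIASES.get(drug.lower(), drug.lower())
    state = params.state_label if params.state_label in _HVA_FRACTIONS else "OVX"
    if key in _FULL_BLOCKS:
        blocks = _FULL_BLOCKS[key]
    elif key in _HVA_FRACTIONS[state]:
        blocks = {"Ca": _HVA_FRACTIONS[state][key]}
    else:
        raise ParameterError(
            f"unknown drug {drug!r}; known: {', '.join(known_drugs())}"
        )
    out = params.copy()
    for ch, frac in blocks.items():
        out.channels[ch].block_fraction = max(out.channels[ch].block_fraction, frac)
    return out
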