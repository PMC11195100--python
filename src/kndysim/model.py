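"""Membrane dynamics and simulation of the 12-current KNDy neuron model.

The membrane follows Cm dVm/dt = I_inj - sum(I_ionic) with the twelve
Hodgkin-Huxley-style currents NaT, NaP, A, BK, h, SK, M, T, Ca (lumped HVA),
TRPC5, GIRK and leak.  Gating variables relax first-order toward
voltage- (or calcium-/ligand-) dependent steady states.  Voltage clamp is
ideal: Vm tracks the command exactly and the clamp current equals the total
ionic current.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine as en
from .params import NeuronParams, ParameterError, STATE_NAMES, pack_params
from .protocols import Segment, StepFamilyProtocol, StimulusProtocol


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


class ModeError(ValueError):
    """Raised when current- and voltage-clamp modes are mixed up."""


@dataclass
class SolverOptions:
    """Adaptive RK5(4) settings (Dormand-Prince pair)."""

    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = 1.0   # ms
    dt_out: float = 0.25    # ms sampling interval of stored traces


@dataclass
class NeuronState:
    """Dynamic state: membrane potential, calcium, gates and receptor drive."""

    Vm: float
    Ca_i: float
    gating: np.ndarray          # the 14 gating variables, engine order
    drive: np.ndarray           # (a_NKB, a_Dyn)

    def to_vector(self) -> np.ndarray:
        y = np.empty(en.NSTATE)
        y[en.IV], y[en.ICA] = self.Vm, self.Ca_i
        y[en.GATE_SLICE] = self.gating
        y[en.IA_NKB:en.IA_DYN + 1] = self.drive
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "NeuronState":
        return cls(Vm=float(y[en.IV]), Ca_i=float(y[en.ICA]),
                   gating=np.asarray(y[en.GATE_SLICE], dtype=float).copy(),
                   drive=np.asarray(y[en.IA_NKB:en.IA_DYN + 1], dtype=float).copy())

    def validate(self) -> None:
        if self.Ca_i < 0:
            raise ParameterError("Ca_i must be >= 0")
        if np.any((self.gating < 0) | (self.gating > 1)):
            raise ParameterError("gating variables must lie in [0, 1]")
        if np.any((self.drive < 0) | (self.drive > 1)):
            raise ParameterError("drive levels must lie in [0, 1]")


def gating_steady_state(Vm, V_half, k, kind: str = "activation"):
    """Boltzmann steady state 1 / (1 + exp((V1/2 - V)/k)).

    ``kind="activation"`` rises with Vm, ``kind="inactivation"`` falls; the
    midpoint value is 1/2 in both conventions.  k must be nonzero."""
    if np.any(np.asarray(k) == 0):
        raise ParameterError("Boltzmann slope k must be nonzero")
    Vm = np.asarray(Vm, dtype=float)
    k = abs(np.asarray(k, dtype=float))
    if kind == "activation":
        out = 1.0 / (1.0 + np.exp((V_half - Vm) / k))
    elif kind == "inactivation":
        out = 1.0 / (1.0 + np.exp((Vm - V_half) / k))
    else:
        raise ParameterError(f"unknown kind {kind!r}")
    return out if out.ndim else float(out)


def membrane_rhs(state: NeuronState, params: NeuronParams,
                 I_inj: float | None = None, V_cmd: float | None = None):
    """Evaluate the state derivatives in one clamp mode.

    Exactly one of ``I_inj`` (current clamp, pA) or ``V_cmd`` (ideal voltage
    clamp, mV) must be given.  Returns ``(dstate, clamp_current)``;
    ``clamp_current`` is the total ionic current (pA) under voltage clamp and
    None in current clamp."""
    if (I_inj is None) == (V_cmd is None):
        raise ModeError("supply exactly one of I_inj (cc) or V_cmd (vc)")
    state.validate()
    p = pack_params(params)
    y = state.to_vector()
    seg = np.zeros(en.SEG_LEN)
    if V_cmd is not None:
        y[en.IV] = V_cmd
        seg[en.SEG_MODE] = en.MODE_VC
        seg[en.SEG_CMD0] = V_cmd
    else:
        seg[en.SEG_CMD0] = I_inj
    # drives held at their instantaneous levels (no ligand input)
    dy = np.empty(en.NSTATE)
    icurr = np.empty(en.NCURR)
    ginf = np.empty(en.NSTATE)
    total = en.rhs(0.0, y, p, seg, dy, icurr, ginf)
    # the derivative vector reuses the state layout but holds rates, so it is
    # returned without range validation
    dstate = NeuronState.__new__(NeuronState)
    dstate.Vm = float(dy[en.IV])
    dstate.Ca_i = float(dy[en.ICA])
    dstate.gating = dy[en.GATE_SLICE].copy()
    dstate.drive = dy[en.IA_NKB:en.IA_DYN + 1].copy()
    return dstate, (float(total) if V_cmd is not None else None)


def ionic_current_names() -> tuple[str, ...]:
    return en.CURRENT_NAMES


def clamp_steady_state(params: NeuronParams, V: float,
                       nkb: float = 0.0, dyn: float = 0.0) -> np.ndarray:
    """Exact steady state under ideal voltage clamp at potential ``V``.

    The voltage-gated Ca currents depend only on V, so the calcium fixed
    point is closed-form; calcium-gated variables then follow."""
    p = pack_params(params)
    y = np.zeros(en.NSTATE)
    y[en.IV] = V
    a_nkb = p[en.P_KON_NKB] * nkb / (p[en.P_KON_NKB] * nkb + 1.0 / p[en.P_TAU_NKB]) if nkb > 0 else 0.0
    a_dyn = p[en.P_KON_DYN] * dyn / (p[en.P_KON_DYN] * dyn + 1.0 / p[en.P_TAU_DYN]) if dyn > 0 else 0.0
    y[en.IA_NKB], y[en.IA_DYN] = a_nkb, a_dyn
    ginf = np.empty(en.NSTATE)
    y[en.ICA] = p[en.P_CA0]
    en.gate_inf(y, p, ginf)
    y[en.GATE_SLICE] = ginf[en.GATE_SLICE]
    icurr = np.empty(en.NCURR)
    en.ionic_currents(y, p, icurr)
    influx = max(0.0, -p[en.P_KCA] * icurr[8])
    y[en.ICA] = p[en.P_CA0] + influx * p[en.P_TAUCA]
    en.gate_inf(y, p, ginf)   # refresh Ca-dependent gates at the Ca fixed point
    y[en.GATE_SLICE] = ginf[en.GATE_SLICE]
    return y


@dataclass
class SimTrace:
    """A simulated trace with per-current decomposition.

    ``V`` is the membrane potential (mV); under voltage clamp it equals the
    command and ``clamp_current`` holds the recorded current (pA).  The
    ``currents`` matrix (n x 12) stores the per-channel decomposition in the
    order of :func:`ionic_current_names`; it sums to the net ionic current.
    """

    t: np.ndarray                  # ms
    states: np.ndarray             # (n, 18)
    currents: np.ndarray           # (n, 12) pA
    segment_index: np.ndarray      # which protocol segment each sample is in
    injected: np.ndarray           # commanded I_inj (pA; 0 under vc)
    is_vc: np.ndarray              # bool per sample
    params: NeuronParams
    protocol: StimulusProtocol
    solver: SolverOptions = field(default_factory=SolverOptions)

    @property
    def V(self) -> np.ndarray:
        return self.states[:, en.IV]

    @property
    def Ca_i(self) -> np.ndarray:
        return self.states[:, en.ICA]

    @property
    def net_ionic(self) -> np.ndarray:
        return self.currents.sum(axis=1)

    @property
    def clamp_current(self) -> np.ndarray:
        """Recorded current under ideal voltage clamp (pA)."""
        return np.where(self.is_vc, self.net_ionic, np.nan)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def current(self, name: str) -> np.ndarray:
        return self.currents[:, en.CURRENT_NAMES.index(name)]

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with t in [t0, t1)."""
        return (self.t >= t0) & (self.t < t1)

    def to_frame(self) -> pd.DataFrame:
        d = {"t_ms": self.t, "Vm_mV": self.V, "I_clamp_pA": self.clamp_current,
             "Ca_uM": self.Ca_i}
        for i, nm in enumerate(en.CURRENT_NAMES):
            d[f"I_{nm}_pA"] = self.currents[:, i]
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        buf = io.StringIO()
        import hashlib
        phash = hashlib.sha256(
            repr(sorted(self.params.to_dict().items())).encode()
        ).hexdigest()[:16]
        buf.write(f"# kndysim trace  state={self.params.state_label}"
                  f"  params_hash={phash}"
                  f"  protocol={self.protocol.name}"
                  f"  protocol_hash={self.protocol.content_hash}\n")
        buf.write(f"# Cm_pF={self.params.Cm}  rtol={self.solver.rtol}"
                  f"  atol={self.solver.atol}  dt_out_ms={self.solver.dt_out}\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def settle(params: NeuronParams, duration_s: float = 5.0,
           v0: float = -70.0, solver: SolverOptions | None = None) -> np.ndarray:
    """Settle the free membrane at zero input, the default initial state.

    Starts from ``v0`` with all gates at steady state and integrates
    ``duration_s`` of current clamp to remove initial-condition transients."""
    solver = solver or SolverOptions()
    y = clamp_steady_state(params, v0)
    p = pack_params(params)
    seg = Segment(duration_s * 1000.0, "cc", 0.0).to_seg_vector()
    out = np.empty((1, en.NSTATE))
    bad = en.integrate_segment(y, p, seg, duration_s * 1000.0, 1,
                               solver.rtol, solver.atol, solver.max_step, out)
    if bad >= 0:
        raise IntegrationError(f"settling diverged at t={bad:.3f} ms")
    return y


def simulate(params: NeuronParams, protocol: StimulusProtocol,
             y0: np.ndarray | None = None,
             solver: SolverOptions | None = None) -> SimTrace:
    """Integrate a protocol and return the sampled trace.

    The initial state defaults to the settled resting state (current clamp)
    or the holding steady state of the first segment (voltage clamp)."""
    if isinstance(protocol, StepFamilyProtocol):
        raise ModeError("use simulate_family() for step families")
    protocol.validate()
    solver = solver or SolverOptions()
    p = pack_params(params)
    if y0 is None:
        first = protocol.segments[0]
        if first.mode == "vc":
            y0 = clamp_steady_state(params, first.command)
        else:
            y0 = settle(params, solver=solver)
    y = np.asarray(y0, dtype=float).copy()

    ts, states, seg_ix, inj, isvc = [np.array([0.0])], [y.copy()[None, :]], [[0]], [[_inj_at(protocol.segments[0], 0.0)]], [[protocol.segments[0].mode == "vc"]]
    t_off = 0.0
    for si, segobj in enumerate(protocol.segments):
        n_out = max(1, int(round(segobj.duration / solver.dt_out)))
        dt = segobj.duration / n_out
        out = np.empty((n_out, en.NSTATE))
        bad = en.integrate_segment(y, p, segobj.to_seg_vector(), dt, n_out,
                                   solver.rtol, solver.atol, solver.max_step, out)
        if bad >= 0:
            raise IntegrationError(
                f"non-finite state at t={t_off + bad:.3f} ms in segment {si}"
                f" ({segobj.mode}, command {segobj.command:g})"
            )
        tt = t_off + dt * np.arange(1, n_out + 1)
        ts.append(tt)
        states.append(out)
        seg_ix.append(np.full(n_out, si))
        inj.append([_inj_at(segobj, t - t_off) for t in tt])
        isvc.append(np.full(n_out, segobj.mode == "vc"))
        t_off += segobj.duration

    states = np.vstack(states)
    curr = np.empty((states.shape[0], en.NCURR))
    en.currents_for_states(states, p, curr)
    return SimTrace(
        t=np.concatenate(ts), states=states, currents=curr,
        segment_index=np.concatenate([np.asarray(s) for s in seg_ix]),
        injected=np.concatenate([np.asarray(v, dtype=float) for v in inj]),
        is_vc=np.concatenate([np.asarray(v, dtype=bool) for v in isvc]),
        params=params, protocol=protocol, solver=solver,
    )


def _inj_at(seg: Segment, t_rel: float) -> float:
    if seg.mode == "vc":
        return 0.0
    return seg.command + seg.command_rate * t_rel


def simulate_family(params: NeuronParams, family: StepFamilyProtocol,
                    solver: SolverOptions | None = None) -> list[SimTrace]:
    """Simulate every sweep of a step family.

    Voltage-clamp sweeps start from the holding steady state; current-clamp
    sweeps start from the settled resting state (computed once)."""
    solver = solver or SolverOptions()
    if family.mode == "vc":
        y0 = clamp_steady_state(params, family.hold)
    else:
        y0 = settle(params, solver=solver)
    return [simulate(params, family.sweep(i), y0=y0.copy(), solver=solver)
            for i in range(family.n_steps)]
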