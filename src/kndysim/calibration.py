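"""Conductance calibration against drug-sensitive current-density targets.

Under ideal voltage clamp every gate is independent of the channel's own
maximal conductance, so the drug-sensitive steady-state density is exactly
linear in gbar.  Calibration therefore reduces to a one-dimensional linear
least-squares problem with a unique solution whenever the channel passes any
current at the target potentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import AnalysisError, peak_iv, drug_subtraction
from .model import simulate, simulate_family
from .params import NeuronParams
from .protocols import (
    StepFamilyProtocol,
    apply_drug,
    ca_iv_protocol,
    k_iv_protocol,
    spontaneous_protocol,
)


class CalibrationError(ValueError):
    pass


# channel -> the selective blocker used to isolate its current
BLOCKER = {"SK": "apamin", "BK": "iberiotoxin", "M": "xe991",
           "T": "tta-p2", "Ca": "cadmium"}


def drug_sensitive_iv(params: NeuronParams, channel: str,
                      family: StepFamilyProtocol | None = None,
                      mode: str = "steady"):
    """Drug-sensitive I-V curve for one channel: control minus full block."""
    if family is None:
        family = k_iv_protocol() if channel in ("SK", "BK", "M", "A", "GIRK") \
            else ca_iv_protocol()
    blocked = params.copy()
    blocked.channels[channel].block_fraction = 1.0
    ctrl = peak_iv(simulate_family(params, family), mode=mode)
    trt = peak_iv(simulate_family(blocked, family), mode=mode)
    return drug_subtraction(ctrl, trt)


def calibrate_conductance(channel: str, targets, params: NeuronParams,
                          drug_context: list[str] = ("ttx",),
                          family: StepFamilyProtocol | None = None,
                          mode: str = "steady") -> float:
    """Fit gbar (nS) so the simulated drug-sensitive steady-state density
    matches the target (V, density pA/pF) points in unweighted least squares.

    ``drug_context`` lists drugs present in the recording bath (TTX by
    default).  The density is linear in gbar, so the solution is closed-form;
    a negative estimate is clamped to zero with a warning."""
    targets = [(float(v), float(d)) for v, d in targets]
    if not targets:
        raise CalibrationError("no calibration targets given")
    ctx = params
    for drug in drug_context:
        ctx = apply_drug(ctx, drug)
    # density per unit conductance
    unit = ctx.copy()
    unit.channels[channel].gbar = 1.0
    unit.channels[channel].block_fraction = 0.0
    iv = drug_sensitive_iv(unit, channel, family=family, mode=mode)
    u = np.array([iv.at(v) / iv.Cm_used for v, _ in targets])
    d = np.array([dens for _, dens in targets])
    denom = float(u @ u)
    curve_scale = np.max(np.abs(iv.density))
    # degenerate when the channel is essentially closed at every target
    # potential relative to where it actually conducts
    if curve_scale < 1e-9 or np.max(np.abs(u)) < 0.01 * curve_scale:
        raise CalibrationError(
            f"{channel}: channel passes no current at the target potentials; "
            "the objective is flat in gbar")
    g = float(u @ d) / denom
    if g < 0:
        warnings.warn(f"{channel}: calibration extrapolated a negative "
                      "conductance; clamping to 0", stacklevel=2)
        g = 0.0
    return g


@dataclass
class StateContributionReport:
    """Per-channel drug-sensitive steady-state densities of one state."""

    k_densities: pd.DataFrame        # K+ channels at +40 mV, pA/pF
    ca_densities: pd.DataFrame       # Ca channels at -10 mV (peak), pA/pF
    repolarization: pd.DataFrame     # % contribution over a burst


def repolarization_shares(params: NeuronParams, duration_s: float = 15.0,
                          channels=("BK", "SK", "M", "A", "GIRK")) -> pd.DataFrame:
    """Percent contribution of each K+ current to the total repolarizing
    (outward) current over a spontaneous simulation, per sample."""
    tr = simulate(params, spontaneous_protocol(duration_s))
    parts = {ch: np.clip(tr.current(ch), 0.0, None) for ch in channels}
    tot = np.sum(list(parts.values()), axis=0)
    ok = tot > 1e-9
    df = pd.DataFrame({"t_ms": tr.t[ok]})
    for ch, x in parts.items():
        df[f"{ch}_pct"] = 100.0 * x[ok] / tot[ok]
    return df


def verify_state_contributions(params: NeuronParams,
                               duration_s: float = 15.0) -> StateContributionReport:
    """Measure what each channel contributes in the state's standard assays:
    K+ channels as drug-sensitive densities at the +40 mV step of the
    K+-current protocol, Ca channels at the -10 mV step of the Ca protocol,
    and the per-time-point split of the repolarizing current during
    spontaneous activity."""
    ttx = apply_drug(params, "ttx")
    rows = []
    for ch in ("SK", "BK", "M", "A"):
        iv = drug_sensitive_iv(ttx, ch, mode="steady")
        rows.append({"channel": ch, "V_mV": 40.0,
                     "density_pA_per_pF": iv.at(40.0) / iv.Cm_used})
    kdf = pd.DataFrame(rows)
    ca_ctx = apply_drug(ttx, "cs_internal")
    rows = []
    for ch in ("Ca", "T"):
        iv = drug_sensitive_iv(ca_ctx, ch, family=ca_iv_protocol(), mode="peak")
        rows.append({"channel": ch, "V_mV": -10.0,
                     "density_pA_per_pF": iv.at(-10.0) / iv.Cm_used})
    cadf = pd.DataFrame(rows)
    rep = repolarization_shares(params, duration_s)
    return StateContributionReport(kdf, cadf, rep)
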