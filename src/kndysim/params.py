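"""Neuron parameter sets: the 12 channel blocks, calcium handling and
receptor-drive kinetics, with YAML round-tripping and shipped presets.

Two presets model the ovariectomized mouse ("ovx") and the estradiol-treated
ovariectomized mouse ("ovx_e2").  They share all gating kinetics and differ
in a documented set of maximal conductances (Ca, T, h, TRPC5, GIRK, BK, M and
SK), reflecting the estradiol-driven changes in channel expression.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import _engine as en

CHANNEL_NAMES = (
    "NaT", "NaP", "A", "BK", "h", "SK", "M", "T", "Ca", "TRPC5", "GIRK", "leak",
)

STATE_NAMES = (
    "V", "Ca_i", "m_NaT", "h_NaT", "m_NaP", "m_A", "h_A", "b_BK", "r_h",
    "s_SK", "w_M", "m_T", "h_T", "m_Ca", "h_Ca", "c_TRPC5", "a_NKB", "a_Dyn",
)


class ParameterError(ValueError):
    """Raised for invalid channel or neuron parameters."""


@dataclass
class ChannelParams:
    """One ionic conductance: maximal conductance, reversal and gating.

    ``gating`` maps gate names to descriptor dicts.  Voltage gates carry
    ``kind`` ("activation" rising, "inactivation" falling), ``vhalf`` (mV),
    ``k`` (mV, > 0), ``exponent`` and either a constant ``tau`` (ms) or a
    bell-shaped (``tau_min``, ``tau_amp``, ``tau_vpeak``, ``tau_sigma``)
    voltage dependence.  Calcium gates carry ``ca_half`` (uM) and ``hill``.
    """

    name: str
    gbar: float
    erev: float
    gating: dict = field(default_factory=dict)
    block_fraction: float = 0.0

    def validate(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ParameterError(f"unknown channel name {self.name!r}")
        if self.gbar < 0:
            raise ParameterError(f"{self.name}: gbar must be >= 0")
        if not 0.0 <= self.block_fraction <= 1.0:
            raise ParameterError(f"{self.name}: block_fraction must be in [0, 1]")
        for gname, g in self.gating.items():
            exp = g.get("exponent", 1)
            if exp != int(exp) or exp < 0:
                raise ParameterError(
                    f"{self.name}.{gname}: exponent must be a non-negative integer"
                )
            if "k" in g and g["k"] == 0:
                raise ParameterError(f"{self.name}.{gname}: slope k must be nonzero")

    @property
    def g_effective(self) -> float:
        """Conductance after pharmacological block (never negative)."""
        return self.gbar * (1.0 - self.block_fraction)


@dataclass
class CalciumParams:
    """Bulk intracellular Ca handling: single pool, linear extrusion."""

    ca_rest: float = 0.1        # uM
    tau: float = 150.0          # ms, extrusion/buffering time constant
    influx_per_pA: float = 6e-5  # uM per pA per ms of inward VGCC current

    def validate(self) -> None:
        if self.ca_rest < 0 or self.tau <= 0 or self.influx_per_pA < 0:
            raise ParameterError("invalid calcium-handling parameters")


@dataclass
class DriveParams:
    """First-order NKB / Dyn receptor activation kinetics."""

    nkb_on_rate: float = 0.03    # 1/ms while ligand pulse is on
    nkb_tau_off: float = 15000.0  # ms
    dyn_on_rate: float = 0.03
    dyn_tau_off: float = 3000.0

    def validate(self) -> None:
        if min(self.nkb_on_rate, self.dyn_on_rate) < 0:
            raise ParameterError("drive on-rates must be >= 0")
        if min(self.nkb_tau_off, self.dyn_tau_off) <= 0:
            raise ParameterError("drive decay time constants must be > 0")


@dataclass
class NeuronParams:
    """Full single-neuron parameter set (one physiological state)."""

    Cm: float
    channels: dict[str, ChannelParams]
    calcium: CalciumParams = field(default_factory=CalciumParams)
    drive: DriveParams = field(default_factory=DriveParams)
    state_label: str = "custom"

    def validate(self) -> None:
        if self.Cm <= 0:
            raise ParameterError("Cm must be > 0")
        names = list(self.channels)
        if sorted(names) != sorted(CHANNEL_NAMES):
            raise ParameterError(
                f"expected exactly the 12 channels {CHANNEL_NAMES}, got {names}"
            )
        for ch in self.channels.values():
            ch.validate()
        self.calcium.validate()
        self.drive.validate()

    # -- convenience -------------------------------------------------------
    def copy(self) -> "NeuronParams":
        return copy.deepcopy(self)

    def with_conductance(self, name: str, gbar: float) -> "NeuronParams":
        """Copy with one channel's maximal conductance replaced."""
        out = self.copy()
        out.channels[name].gbar = float(gbar)
        out.state_label = "custom" if gbar != self.channels[name].gbar else self.state_label
        return out

    def to_dict(self) -> dict:
        return {
            "state_label": self.state_label,
            "Cm": self.Cm,
            "calcium": dataclasses.asdict(self.calcium),
            "drive": dataclasses.asdict(self.drive),
            "channels": {
                n: {
                    "gbar": ch.gbar,
                    "erev": ch.erev,
                    "block_fraction": ch.block_fraction,
                    "gating": copy.deepcopy(ch.gating),
                }
                for n, ch in self.channels.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NeuronParams":
        channels = {
            n: ChannelParams(
                name=n,
                gbar=float(c["gbar"]),
                erev=float(c["erev"]),
                block_fraction=float(c.get("block_fraction", 0.0)),
                gating=copy.deepcopy(c.get("gating", {})),
            )
            for n, c in d["channels"].items()
        }
        p = cls(
            Cm=float(d["Cm"]),
            channels=channels,
            calcium=CalciumParams(**d.get("calcium", {})),
            drive=DriveParams(**d.get("drive", {})),
            state_label=d.get("state_label", "custom"),
        )
        p.validate()
        return p

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "NeuronParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------- presets

def _read_preset_yaml(name: str) -> dict:
    ref = resources.files("kndysim") / "presets" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def load_preset(name: str) -> NeuronParams:
    """Load a shipped preset ("ovx" or "ovx_e2") or a YAML file path."""
    if name in ("ovx", "ovx_e2"):
        d = _read_preset_yaml("common")
        state = _read_preset_yaml(name)
        for ch, g in state["conductances"].items():
            d["channels"][ch]["gbar"] = float(g)
        d["state_label"] = state["state_label"]
        return NeuronParams.from_dict(d)
    path = Path(name)
    if path.exists():
        return NeuronParams.load(path)
    raise ParameterError(f"unknown preset {name!r} (known: ovx, ovx_e2)")


# --------------------------------------------------------------------- packing

def _vgate(p, ch, gate, i_vh, i_k, i_p):
    g = ch.gating[gate]
    sign = 1.0 if g.get("kind", "activation") == "activation" else 1.0
    p[i_vh] = g["vhalf"]
    p[i_k] = abs(g["k"]) * sign
    p[i_p] = g.get("exponent", 1)


def _tau_bell(p, ch, gate, i_tmin, i_tamp, i_tvp, i_tsig):
    g = ch.gating[gate]
    if "tau" in g:
        p[i_tmin], p[i_tamp], p[i_tvp], p[i_tsig] = g["tau"], 0.0, 0.0, 1.0
    else:
        p[i_tmin] = g["tau_min"]
        p[i_tamp] = g["tau_amp"]
        p[i_tvp] = g["tau_vpeak"]
        p[i_tsig] = g["tau_sigma"]


def pack_params(np_: NeuronParams) -> np.ndarray:
    """Flatten a NeuronParams into the engine's parameter vector."""
    np_.validate()
    p = np.zeros(en.NPARAM)
    p[en.P_CM] = np_.Cm
    p[en.P_CA0] = np_.calcium.ca_rest
    p[en.P_TAUCA] = np_.calcium.tau
    p[en.P_KCA] = np_.calcium.influx_per_pA
    ch = np_.channels

    p[en.PL_G] = ch["leak"].g_effective
    p[en.PL_E] = ch["leak"].erev

    c = ch["NaT"]
    p[en.PNAT_G], p[en.PNAT_E] = c.g_effective, c.erev
    _vgate(p, c, "m", en.PNAT_MVH, en.PNAT_MK, en.PNAT_MP)
    _tau_bell(p, c, "m", en.PNAT_MTMIN, en.PNAT_MTAMP, en.PNAT_MTVP, en.PNAT_MTSIG)
    _vgate(p, c, "h", en.PNAT_HVH, en.PNAT_HK, en.PNAT_HP)
    _tau_bell(p, c, "h", en.PNAT_HTMIN, en.PNAT_HTAMP, en.PNAT_HTVP, en.PNAT_HTSIG)

    c = ch["NaP"]
    p[en.PNAP_G], p[en.PNAP_E] = c.g_effective, c.erev
    _vgate(p, c, "m", en.PNAP_VH, en.PNAP_K, en.PNAP_P)
    p[en.PNAP_TAU] = c.gating["m"]["tau"]

    c = ch["A"]
    p[en.PA_G], p[en.PA_E] = c.g_effective, c.erev
    _vgate(p, c, "m", en.PA_MVH, en.PA_MK, en.PA_MP)
    p[en.PA_MTAU] = c.gating["m"]["tau"]
    _vgate(p, c, "h", en.PA_HVH, en.PA_HK, en.PA_HP)
    p[en.PA_HTAU] = c.gating["h"]["tau"]
    p[en.PA_HFLOOR] = c.gating["h"].get("floor", 0.0)

    c = ch["BK"]
    p[en.PBK_G], p[en.PBK_E] = c.g_effective, c.erev
    _vgate(p, c, "b", en.PBK_VH, en.PBK_K, en.PBK_P)
    p[en.PBK_TAU] = c.gating["b"]["tau"]
    p[en.PBK_KCA] = c.gating["b"]["ca_half"]
    p[en.PBK_NCA] = c.gating["b"]["hill"]

    c = ch["h"]
    p[en.PH_G], p[en.PH_E] = c.g_effective, c.erev
    _vgate(p, c, "r", en.PH_VH, en.PH_K, en.PH_P)
    _tau_bell(p, c, "r", en.PH_TMIN, en.PH_TAMP, en.PH_TVP, en.PH_TSIG)

    c = ch["SK"]
    p[en.PSK_G], p[en.PSK_E] = c.g_effective, c.erev
    g = c.gating["s"]
    p[en.PSK_KCA], p[en.PSK_NCA] = g["ca_half"], g["hill"]
    p[en.PSK_P], p[en.PSK_TAU] = g.get("exponent", 1), g["tau"]

    c = ch["M"]
    p[en.PM_G], p[en.PM_E] = c.g_effective, c.erev
    _vgate(p, c, "w", en.PM_VH, en.PM_K, en.PM_P)
    p[en.PM_TAU] = c.gating["w"]["tau"]

    c = ch["T"]
    p[en.PT_G], p[en.PT_E] = c.g_effective, c.erev
    _vgate(p, c, "m", en.PT_MVH, en.PT_MK, en.PT_MP)
    p[en.PT_MTAU] = c.gating["m"]["tau"]
    _vgate(p, c, "h", en.PT_HVH, en.PT_HK, en.PT_HP)
    _tau_bell(p, c, "h", en.PT_HTMIN, en.PT_HTAMP, en.PT_HTVP, en.PT_HTSIG)

    c = ch["Ca"]
    p[en.PCA_G], p[en.PCA_E] = c.g_effective, c.erev
    _vgate(p, c, "m", en.PCA_MVH, en.PCA_MK, en.PCA_MP)
    p[en.PCA_MTAU] = c.gating["m"]["tau"]
    _vgate(p, c, "h", en.PCA_HVH, en.PCA_HK, en.PCA_HP)
    p[en.PCA_HTAU] = c.gating["h"]["tau"]
    p[en.PCA_HFLOOR] = c.gating["h"].get("floor", 0.0)

    c = ch["TRPC5"]
    p[en.PT5_G], p[en.PT5_E] = c.g_effective, c.erev
    g = c.gating["c"]
    p[en.PT5_KCA], p[en.PT5_NCA] = g["ca_half"], g["hill"]
    p[en.PT5_P], p[en.PT5_TAU] = g.get("exponent", 1), g["tau"]
    p[en.PT5_WNKB] = g.get("nkb_weight", 1.0)

    c = ch["GIRK"]
    p[en.PGIRK_G], p[en.PGIRK_E] = c.g_effective, c.erev
    p[en.PGIRK_FC] = c.gating["d"].get("constitutive", 0.0)

    p[en.P_KON_NKB] = np_.drive.nkb_on_rate
    p[en.P_TAU_NKB] = np_.drive.nkb_tau_off
    p[en.P_KON_DYN] = np_.drive.dyn_on_rate
    p[en.P_TAU_DYN] = np_.drive.dyn_tau_off
    return p
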