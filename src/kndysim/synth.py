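"""Synthetic datasets with known ground truth: multi-cell voltage-clamp
I-V data with the group structure of patch-clamp studies, membrane-potential
traces with prescribed firing statistics, and qPCR CT pools with injected
fold changes.

Every generator is a pure function of its specification and a seed."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine as en
from .model import SimTrace, SolverOptions
from .params import load_preset
from .protocols import spontaneous_protocol


class SynthError(ValueError):
    pass


# ------------------------------------------------------- voltage-clamp cohorts

@dataclass
class VClampGroupSpec:
    """One recording group: a mean density curve with biological scatter.

    ``mean_density`` (pA/pF) is evaluated on ``voltages`` (mV).  Cells get a
    multiplicative offset with SD ``between_cell_sd`` (as a fraction of the
    mean curve), plus additive within-trace noise ``noise_sd`` (pA/pF)."""

    name: str
    voltages: np.ndarray
    mean_density: np.ndarray
    between_cell_sd: float
    noise_sd: float = 0.2

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.mean_density = np.asarray(self.mean_density, dtype=float)
        if self.voltages.shape != self.mean_density.shape:
            raise SynthError("voltages and mean_density must align")
        if self.between_cell_sd < 0 or self.noise_sd < 0:
            raise SynthError("spreads must be non-negative")


def ca_density_template(voltages, peak_density: float,
                        v_peak: float = -10.0) -> np.ndarray:
    """Smooth inward Ca-current density curve peaking at ``v_peak`` with
    magnitude ``peak_density`` (pA/pF), emulating whole-cell I-V shapes."""
    v = np.asarray(voltages, dtype=float)
    act = 1.0 / (1.0 + np.exp((-38.0 - v) / 9.0)) ** 2
    drive = v - 60.0
    raw = act * drive   # negative (inward) around the peak
    return peak_density * raw / abs(raw[np.argmin(np.abs(v - v_peak))])


def generate_vclamp_cells(groups: list[VClampGroupSpec], n_cells,
                          seed: int) -> pd.DataFrame:
    """Per-cell I-V density data for each group, tidy format.

    ``n_cells`` is an int (same for every group) or a per-group list.
    Columns: group, cell, V_mV, density_pA_per_pF."""
    rng = np.random.default_rng(seed)
    if np.isscalar(n_cells):
        n_cells = [int(n_cells)] * len(groups)
    if len(n_cells) != len(groups):
        raise SynthError("n_cells must match the number of groups")
    frames = []
    for spec, n in zip(groups, n_cells):
        if n < 2:
            raise SynthError("need at least 2 cells per group")
        offsets = rng.normal(1.0, spec.between_cell_sd, size=n)
        noise = rng.normal(0.0, spec.noise_sd, size=(n, spec.voltages.size))
        dens = offsets[:, None] * spec.mean_density[None, :] + noise
        for c in range(n):
            frames.append(pd.DataFrame({
                "group": spec.name, "cell": f"{spec.name}_{c:04d}",
                "V_mV": spec.voltages, "density_pA_per_pF": dens[c],
            }))
    return pd.concat(frames, ignore_index=True)


def vclamp_group_summary(df: pd.DataFrame, at_voltage: float) -> pd.DataFrame:
    """Mean +/- SEM of per-cell density at one step potential, by group."""
    sel = df[np.isclose(df["V_mV"], at_voltage)]
    g = sel.groupby("group")["density_pA_per_pF"]
    return pd.DataFrame({"mean": g.mean(), "sem": g.sem(), "n": g.size()})


# ----------------------------------------------------------- synthetic spiking

@dataclass
class SpikeTrainSpec:
    """Ground-truth firing pattern for classifier fixtures."""

    pattern: str                   # tonic | irregular | burst | silent
    rate_hz: float = 5.0           # mean rate (tonic/irregular)
    cv: float = 0.1                # ISI coefficient of variation
    intra_burst_isi_ms: float = 30.0
    spikes_per_burst: int = 4
    inter_burst_ms: float = 2000.0
    updown: bool = True            # bursts ride a depolarized up-state


def generate_spike_train(spec: SpikeTrainSpec, duration_s: float,
                         seed: int, dt_ms: float = 0.25) -> SimTrace:
    """Synthetic membrane-potential trace whose label is known by
    construction.  Spikes are stereotyped 2-ms triangular waveforms on a
    -65 mV baseline; burst patterns optionally add a -55 mV up-state."""
    rng = np.random.default_rng(seed)
    dur = duration_s * 1000.0
    n = int(round(dur / dt_ms))
    t = dt_ms * np.arange(n)
    v = np.full(n, -65.0)

    spike_t: list[float] = []
    if spec.pattern in ("tonic", "irregular"):
        mean_isi = 1000.0 / spec.rate_hz
        shape = 1.0 / max(spec.cv, 1e-3) ** 2
        tt = 0.0
        while tt < dur:
            tt += rng.gamma(shape, mean_isi / shape)
            if tt < dur:
                spike_t.append(tt)
    elif spec.pattern == "burst":
        tt = 500.0
        while tt < dur:
            for k in range(spec.spikes_per_burst):
                s = tt + k * spec.intra_burst_isi_ms
                if s < dur:
                    spike_t.append(s)
            if spec.updown:
                a = int(max(0.0, tt - 20.0) / dt_ms)
                b = int(min(dur, tt + spec.spikes_per_burst
                            * spec.intra_burst_isi_ms + 20.0) / dt_ms)
                v[a:b] = -52.0
            tt += spec.inter_burst_ms
    elif spec.pattern != "silent":
        raise SynthError(f"unknown pattern {spec.pattern!r}")

    for s in spike_t:
        i = int(s / dt_ms)
        w = max(1, int(1.0 / dt_ms))
        up = np.linspace(0, 1, w, endpoint=False)
        down = np.linspace(1, 0, w)
        prof = np.concatenate([up, down]) * 75.0   # peaks near +10 mV
        j = min(n, i + prof.size)
        v[i:j] = np.maximum(v[i:j], v[i:j] + prof[: j - i])

    states = np.zeros((n, en.NSTATE))
    states[:, en.IV] = v
    states[:, en.ICA] = 0.05
    return SimTrace(
        t=t, states=states, currents=np.zeros((n, en.NCURR)),
        segment_index=np.zeros(n, dtype=int), injected=np.zeros(n),
        is_vc=np.zeros(n, dtype=bool), params=load_preset("ovx"),
        protocol=spontaneous_protocol(duration_s), solver=SolverOptions(dt_out=dt_ms),
    )


# --------------------------------------------------------------- qPCR cohorts

def generate_qpcr_pools(fold_changes: dict[str, float], ct_sd: float,
                        n_animals: int, pools_per_animal: int, seed: int,
                        reference_gene: str = "Gapdh",
                        groups: tuple[str, str] = ("oil", "e2"),
                        base_ct: float = 24.0,
                        reference_ct: float = 18.0) -> pd.DataFrame:
    """CT table for a two-group experiment with known true fold changes.

    ``fold_changes`` maps target genes to the second group's expression
    relative to the first; a fold change F shifts the target CT by
    -log2(F).  Gaussian noise of SD ``ct_sd`` cycles is added per
    measurement.  Returns the tidy CT table consumed by the ddCT pipeline."""
    if ct_sd < 0:
        raise SynthError("ct_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, grp in enumerate(groups):
        for a in range(n_animals):
            animal = f"{grp}_{a:02d}"
            for pool in range(pools_per_animal):
                ref_ct = reference_ct + rng.normal(0.0, ct_sd)
                rows.append({"animal": animal, "group": grp,
                             "gene": reference_gene, "pool": pool,
                             "ct": ref_ct})
                for gene, fc in fold_changes.items():
                    shift = -np.log2(fc) if gi == 1 else 0.0
                    rows.append({"animal": animal, "group": grp,
                                 "gene": gene, "pool": pool,
                                 "ct": base_ct + shift + rng.normal(0.0, ct_sd)})
    return pd.DataFrame(rows)
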