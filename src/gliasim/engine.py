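"""Time-grid simulation engine with delayed spike and SIC delivery.

Execution is single-process and advances all cells on a fixed grid.  Per
grid step, the engine (1) delivers spikes whose emission time plus delay
falls in the step, (2) delivers the slow inward current: for every
astrocyte->neuron edge the contribution is ``weight * F_SIC`` evaluated
from the source astrocyte's state the edge's delay earlier (SIC is
sampled once per grid step, piecewise constant in between), (3) draws
Poisson drive and Gaussian noise from per-cell counter-based RNG
streams, (4) steps every cell with the adaptive RKF45 integrators, and
(5) enqueues emitted spikes.  Spike times are grid-aligned (recorded at
the end of the grid step in which the potential crossed threshold).

Global cell ids: excitatory neurons occupy ``[0, n_exc)``, inhibitory
``[n_exc, n_exc + n_inh)``, astrocytes the following ``n_astro`` ids.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels as _k
from .connectivity import NetworkGraph
from .params import AdexParams, AstrocyteParams

__all__ = ["Network", "SimulationConfig", "DriveSpec", "Recording",
           "run", "poisson_drive"]


@dataclass
class Network:
    """A constructed network: populations, per-cell parameters, edges."""

    n_exc: int
    n_inh: int
    n_astro: int
    neuron_params: np.ndarray        # (n_exc + n_inh, 15)
    astro_params: np.ndarray         # (n_astro, 18)
    graph: NetworkGraph
    is_surrogate: np.ndarray | None = None   # (n_astro,) uint8
    init_neuron_state: np.ndarray | None = None
    init_astro_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.n_exc + self.n_inh
        if self.neuron_params.shape != (n, 15):
            raise ValueError("neuron_params must have shape (n_neurons, 15)")
        if self.astro_params.shape != (self.n_astro, 18):
            raise ValueError("astro_params must have shape (n_astro, 18)")
        if self.is_surrogate is None:
            self.is_surrogate = np.zeros(self.n_astro, dtype=np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def astro_gid0(self) -> int:
        return self.n_neurons

    @classmethod
    def homogeneous(cls, n_exc: int, n_inh: int, n_astro: int,
                    exc_params: AdexParams, inh_params: AdexParams,
                    astro_params: AstrocyteParams, graph: NetworkGraph,
                    surrogate_sic: float | None = None) -> "Network":
        """Build a network whose cells share per-population parameters.

        If ``surrogate_sic`` is given, all astrocytes are replaced by
        surrogates that emit this constant SIC drive.
        """
        np_arr = np.vstack([np.tile(exc_params.as_array(), (n_exc, 1)),
                            np.tile(inh_params.as_array(), (n_inh, 1))])
        ap = np.tile(astro_params.as_array(), (n_astro, 1))
        is_surr = np.zeros(n_astro, dtype=np.uint8)
        if surrogate_sic is not None:
            is_surr[:] = 1
            ap[:, _k.A_SIC_CONST] = surrogate_sic
        return cls(n_exc=n_exc, n_inh=n_inh, n_astro=n_astro,
                   neuron_params=np_arr, astro_params=ap, graph=graph,
                   is_surrogate=is_surr)

    def default_neuron_state(self) -> np.ndarray:
        s = np.zeros((self.n_neurons, 7))
        s[:, 0] = self.neuron_params[:, _k.N_EL]  # rest at leak reversal
        return s

    def default_astro_state(self) -> np.ndarray:
        s = np.zeros((self.n_astro, 3))
        s[:, 0] = np.minimum(0.073, self.astro_params[:, _k.A_CA_TOT])
        s[:, 1] = self.astro_params[:, _k.A_IP3_0]
        s[:, 2] = 0.793
        return s


@dataclass
class DriveSpec:
    """External drives: per-population Poisson input and Gaussian noise.

    Poisson drive arrives as excitatory conductance events of the given
    weight (nS) within the step they are drawn; neuronal current noise
    (pA) is redrawn each grid step and held constant within it.  The
    astrocytic Poisson drive has its own weight (dimensionless, scales
    ``delta_IP3``); astrocytic calcium noise is part of the astrocyte
    parameters.
    """

    poisson_rate_exc: float = 0.0      # spikes/s per excitatory neuron
    poisson_rate_inh: float = 0.0      # spikes/s per inhibitory neuron
    poisson_weight: float = 1.0        # nS
    noise_sd_exc: float = 0.0          # pA
    noise_sd_inh: float = 0.0          # pA
    poisson_rate_astro: float = 0.0    # events/s per astrocyte
    poisson_weight_astro: float = 1.0  # dimensionless

    def __post_init__(self) -> None:
        for name in ("poisson_rate_exc", "poisson_rate_inh", "poisson_rate_astro"):
            if getattr(self, name) < 0:
                raise ValueError(f"DriveSpec.{name} must be >= 0")


@dataclass
class SimulationConfig:
    grid_step: float = 0.1          # ms
    duration: float = 1000.0        # ms
    master_seed: int = 1
    tol: float = 1e-6               # integrator tolerance
    record_interval: float = 1.0    # ms between trace samples
    record_neurons: Sequence[int] = ()   # gids: V and W traces
    record_astro: Sequence[int] = ()     # gids: Ca and IP3 traces
    record_sic: Sequence[int] = ()       # gids: summed I_SIC traces
    spike_capacity: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")


@dataclass
class Recording:
    """Spikes plus sampled continuous traces.

    ``spikes`` has columns (cell_id, time_ms).  Wide trace arrays are
    kept per variable; ``traces`` assembles the long-form table
    (time, cell_id, variable, value).
    """

    spikes: pd.DataFrame
    times: np.ndarray
    neuron_ids: np.ndarray
    astro_ids: np.ndarray
    sic_ids: np.ndarray
    v: np.ndarray
    w: np.ndarray
    ca: np.ndarray
    ip3: np.ndarray
    i_sic: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def traces(self) -> pd.DataFrame:
        frames = []
        for ids, arr, var in ((self.neuron_ids, self.v, "V"),
                              (self.neuron_ids, self.w, "W"),
                              (self.astro_ids, self.ca, "Ca"),
                              (self.astro_ids, self.ip3, "IP3"),
                              (self.sic_ids, self.i_sic, "I_SIC")):
            if len(ids) == 0:
                continue
            t = np.repeat(self.times, len(ids))
            cid = np.tile(ids, len(self.times))
            frames.append(pd.DataFrame(
                {"time": t, "cell_id": cid, "variable": var,
                 "value": arr.ravel()}))
        if not frames:
            return pd.DataFrame(columns=["time", "cell_id", "variable", "value"])
        return pd.concat(frames, ignore_index=True)

    def trace(self, variable: str, gid: int) -> np.ndarray:
        """Sampled trace of one variable for one cell."""
        lookup = {"V": (self.neuron_ids, self.v), "W": (self.neuron_ids, self.w),
                  "Ca": (self.astro_ids, self.ca), "IP3": (self.astro_ids, self.ip3),
                  "I_SIC": (self.sic_ids, self.i_sic)}
        ids, arr = lookup[variable]
        idx = np.nonzero(ids == gid)[0]
        if len(idx) == 0:
            raise KeyError(f"cell {gid} was not recorded for {variable}")
        return arr[:, idx[0]]

    def spike_trains(self, gids: Sequence[int]) -> dict[int, np.ndarray]:
        by_cell = {int(g): np.empty(0) for g in gids}
        for g, grp in self.spikes.groupby("cell_id"):
            if int(g) in by_cell:
                by_cell[int(g)] = grp["time_ms"].to_numpy()
        return by_cell

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(path / "spikes.csv", index=False)
        self.traces.to_csv(path / "traces.csv", index=False)
        with open(path / "meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)


def poisson_drive(rate: float, dt: float, rng: np.random.Generator) -> int:
    """Spike count of a Poisson drive in one grid step of dt ms."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return int(rng.poisson(rate * dt / 1000.0))


def _delay_steps(delays: np.ndarray, dt: float, label: str) -> np.ndarray:
    steps = np.round(np.asarray(delays, dtype=float) / dt).astype(np.int64)
    if np.any(np.abs(steps * dt - delays) > 1e-9) or np.any(steps < 1):
        raise ValueError(
            f"{label} delays must be positive multiples of grid_step={dt}")
    return steps


def _build_csr(net: Network, dt: float):
    """Spike-routing CSR over neuron sources; codes 0=exc, 1=inh, 2=astro."""
    prim = net.graph.primary_edges
    tin = net.graph.third_in_edges
    gid0 = net.astro_gid0
    srcs = []
    tgts = []
    ws = []
    ds = []
    codes = []
    if len(prim):
        srcs.append(prim["source"].to_numpy(np.int64))
        tgts.append(prim["target"].to_numpy(np.int64))
        ws.append(prim["weight"].to_numpy(float))
        ds.append(_delay_steps(prim["delay"].to_numpy(), dt, "primary"))
        codes.append(np.where(prim["kind"].to_numpy() == "exc", 0, 1).astype(np.uint8))
    if len(tin):
        srcs.append(tin["source"].to_numpy(np.int64))
        astro_idx = tin["astrocyte"].to_numpy(np.int64) - gid0
        if np.any(astro_idx < 0) or np.any(astro_idx >= net.n_astro):
            raise ValueError("third_in edge references a non-astrocyte id")
        tgts.append(astro_idx)
        ws.append(tin["weight"].to_numpy(float))
        ds.append(_delay_steps(tin["delay"].to_numpy(), dt, "third_in"))
        codes.append(np.full(len(tin), 2, dtype=np.uint8))
    if srcs:
        src = np.concatenate(srcs)
        tgt = np.concatenate(tgts)
        w = np.concatenate(ws)
        d = np.concatenate(ds)
        code = np.concatenate(codes)
    else:
        src = np.empty(0, np.int64)
        tgt = np.empty(0, np.int64)
        w = np.empty(0, float)
        d = np.empty(0, np.int64)
        code = np.empty(0, np.uint8)
    if len(src) and (src.min() < 0 or src.max() >= net.n_neurons):
        raise ValueError("spike edge with non-neuron source")
    order = np.argsort(src, kind="stable")
    src, tgt, w, d, code = src[order], tgt[order], w[order], d[order], code[order]
    indptr = np.zeros(net.n_neurons + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, tgt, w, d, code


def run(network: Network, config: SimulationConfig,
        drives: DriveSpec | None = None) -> Recording:
    """Advance a constructed network and return its Recording."""
    drives = drives or DriveSpec()
    dt = config.grid_step
    n_steps = int(round(config.duration / dt))
    net = network
    n, m = net.n_neurons, net.n_astro

    indptr, e_tgt, e_w, e_d, e_code = _build_csr(net, dt)

    tout = net.graph.third_out_edges
    gid0 = net.astro_gid0
    if len(tout):
        so_astro = tout["astrocyte"].to_numpy(np.int64) - gid0
        so_tgt = tout["target"].to_numpy(np.int64)
        if np.any(so_astro < 0) or np.any(so_astro >= m):
            raise ValueError("third_out edge references a non-astrocyte source")
        if np.any(so_tgt < 0) or np.any(so_tgt >= n):
            raise ValueError("third_out edge references a non-neuron target")
        so_w = tout["weight"].to_numpy(float)
        so_d = _delay_steps(tout["delay"].to_numpy(), dt, "third_out")
    else:
        so_astro = np.empty(0, np.int64)
        so_tgt = np.empty(0, np.int64)
        so_w = np.empty(0, float)
        so_d = np.empty(0, np.int64)

    buf_len = int(e_d.max()) + 1 if len(e_d) else 2
    f_len = int(so_d.max()) + 1 if len(so_d) else 2

    ns_arr = (net.init_neuron_state.copy() if net.init_neuron_state is not None
              else net.default_neuron_state())
    as_arr = (net.init_astro_state.copy() if net.init_astro_state is not None
              else net.default_astro_state())

    lam_step_n = np.zeros(n)
    lam_step_n[:net.n_exc] = drives.poisson_rate_exc * dt / 1000.0
    lam_step_n[net.n_exc:] = drives.poisson_rate_inh * dt / 1000.0
    w_drive_n = np.full(n, drives.poisson_weight, dtype=float)
    noise_sd_n = np.zeros(n)
    noise_sd_n[:net.n_exc] = drives.noise_sd_exc
    noise_sd_n[net.n_exc:] = drives.noise_sd_inh
    lam_step_a = np.full(m, drives.poisson_rate_astro * dt / 1000.0)
    w_drive_a = np.full(m, drives.poisson_weight_astro, dtype=float)

    rec_steps = max(1, int(round(config.record_interval / dt)))
    n_samples = n_steps // rec_steps

    def _gids_to_idx(gids, lo, hi, what):
        arr = np.asarray(list(gids), dtype=np.int64)
        if len(arr) and (arr.min() < lo or arr.max() >= hi):
            raise ValueError(f"{what} recording id out of range")
        return arr - lo

    rec_n_ids = _gids_to_idx(config.record_neurons, 0, n, "neuron")
    rec_a_ids = _gids_to_idx(config.record_astro, gid0, gid0 + m, "astrocyte")
    sic_ids = _gids_to_idx(config.record_sic, 0, n, "I_SIC")

    rec_v = np.zeros((n_samples, len(rec_n_ids)))
    rec_w = np.zeros((n_samples, len(rec_n_ids)))
    rec_ca = np.zeros((n_samples, len(rec_a_ids)))
    rec_ip3 = np.zeros((n_samples, len(rec_a_ids)))
    rec_isic = np.zeros((n_samples, len(sic_ids)))

    cap = config.spike_capacity or max(
        100_000, int(n * config.duration / 1000.0 * 100) + 10_000)
    for _attempt in range(4):
        spike_cell = np.zeros(cap, dtype=np.int64)
        spike_step = np.zeros(cap, dtype=np.int64)
        ns_try = ns_arr.copy()
        as_try = as_arr.copy()
        buf_exc = np.zeros((buf_len, n))
        buf_inh = np.zeros((buf_len, n))
        buf_ip3 = np.zeros((buf_len, m))
        f_hist = np.zeros((f_len, m))
        n_spk, overflow, err_cell = _k.run_kernel(
            n_steps, dt, config.tol, config.master_seed,
            net.neuron_params, ns_try, net.astro_params, as_try,
            net.is_surrogate,
            lam_step_n, w_drive_n, noise_sd_n, lam_step_a, w_drive_a,
            indptr, e_tgt, e_w, e_d, e_code,
            so_astro, so_tgt, so_w, so_d,
            buf_exc, buf_inh, buf_ip3, f_hist,
            rec_steps, rec_n_ids, rec_a_ids, sic_ids,
            rec_v, rec_w, rec_ca, rec_ip3, rec_isic,
            spike_cell, spike_step)
        if err_cell >= 0:
            raise RuntimeError(
                f"integration failure in cell {err_cell}; "
                f"state dump: neuron={ns_try[err_cell] if err_cell < n else None}, "
                f"astro={as_try[err_cell - n] if err_cell >= n else None}")
        if not overflow:
            break
        cap = max(cap * 4, n_spk + 1)
    else:  # pragma: no cover
        raise RuntimeError("spike buffer overflow not resolved")

    spikes = pd.DataFrame({
        "cell_id": spike_cell[:n_spk],
        "time_ms": (spike_step[:n_spk] + 1) * dt,
    })
    times = (np.arange(1, n_samples + 1) * rec_steps) * dt
    meta = {
        "grid_step": dt, "duration": config.duration,
        "master_seed": config.master_seed, "tol": config.tol,
        "n_exc": net.n_exc, "n_inh": net.n_inh, "n_astro": net.n_astro,
    }
    return Recording(spikes=spikes, times=times,
                     neuron_ids=rec_n_ids, astro_ids=rec_a_ids + gid0,
                     sic_ids=sic_ids, v=rec_v, w=rec_w, ca=rec_ca,
                     ip3=rec_ip3, i_sic=rec_isic, meta=meta)
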