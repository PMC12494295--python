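"""Builders and runners for the benchmark networks and the use-case models.

Benchmark networks keep a 4:1 excitatory:inhibitory neuron ratio and a
1:1 astrocyte:neuron ratio (scale 1 = 20,000 cells).  Weak scaling
preserves expected per-cell connection counts by rescaling the pairwise
Bernoulli probability as 1/scale.  Three variants are provided: "sparse"
(low-rate asynchronous activity), "synchronous" (differs only in the
inhibitory delay and synaptic time constant), and "surrogate" (the
astrocytes are replaced by surrogates emitting a constant SIC chosen so
the neuronal firing rate is close to the sparse model).

The use-case models describe a slice-like circuit of 400 excitatory and
100 inhibitory neurons with 100 astrocytes in four regimes: "ttx"
(synaptic weights zero, bursts evoked solely by SIC), "block_async" and
"block_burst" (block pools of size one, asynchronous vs network-wide
bursting, switched by the neuron-to-astrocyte weight), and
"random_pool" (random pools of size five with sparse attachment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis
from .connectivity import (NetworkGraph, PrimaryRuleSpec, SynSpec,
                           ThirdFactorSpec, build_pools, primary_connect,
                           tbp_connect)
from .engine import DriveSpec, Network, Recording, SimulationConfig, run
from .params import AdexParams, AstrocyteParams

__all__ = [
    "BenchmarkSpec", "UseCaseSpec", "ScanSpec",
    "build_benchmark", "build_use_case", "run_experiment",
    "astro_parameter_scan", "network_bursts", "sic_response_spikes",
    "BENCHMARK", "USE_CASE",
]


def _empty_primary() -> pd.DataFrame:
    return pd.DataFrame(columns=["source", "target", "weight", "delay", "kind"])


def _empty_third_in() -> pd.DataFrame:
    return pd.DataFrame(columns=["source", "astrocyte", "weight", "delay"])


def _empty_third_out() -> pd.DataFrame:
    return pd.DataFrame(columns=["astrocyte", "target", "weight", "delay"])


# ---------------------------------------------------------------------------
# Benchmark models
# ---------------------------------------------------------------------------

#: Benchmark model parameters.  The connectivity block (p_primary = 0.1,
#: p_third_if_primary = 0.5, random pools of 10) yields a mean astrocytic
#: in-degree of 400 at scale 1.  Drive and weights realize the sparse
#: low-rate regime; the synchronous variant only changes the inhibitory
#: delay and synaptic time constant.
BENCHMARK: dict = {
    "p_primary": 0.1,
    "p_third_if_primary": 0.5,
    "S_pool": 10,
    "w_exc": 1.0,          # nS
    "w_inh": 4.0,          # nS (magnitude)
    "d_exc": 2.0,          # ms
    "d_inh": 1.0,          # ms (sparse)
    "d_inh_sync": 2.0,     # ms (synchronous)
    "tau_syn_exc": 2.0,    # ms
    "tau_syn_inh": 4.0,    # ms (sparse)
    "tau_syn_inh_sync": 8.0,   # ms (synchronous)
    "poisson_rate": 1800.0,    # spikes/s per neuron
    "w_pre_to_astro": 1.0,     # dimensionless IP3 scaling
    "w_astro_to_post": 0.01,   # pA
    "d_sic": 2.0,              # ms
    "delta_IP3": 0.2,          # uM per unit-weight spike
    "tau_IP3": 300.0,          # ms
    "surrogate_sic": 6.86,     # constant F_SIC of the surrogate variant
    # (mean F_SIC measured in the sparse variant, so firing rates match)
    "neuron": {"tau_syn_exc": 2.0, "tau_syn_inh": 4.0},
}


@dataclass
class BenchmarkSpec:
    """Benchmark network specification; scale 1 means 20,000 cells."""

    scale: float = 1.0
    variant: str = "sparse"            # sparse | synchronous | surrogate
    primary_rule: str = "pairwise_bernoulli"
    S_pool: int = BENCHMARK["S_pool"]
    master_seed: int = 1

    def __post_init__(self) -> None:
        if self.variant not in ("sparse", "synchronous", "surrogate"):
            raise ValueError(f"unknown benchmark variant {self.variant!r}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        for count in (8000 * self.scale, 2000 * self.scale, 10000 * self.scale):
            if abs(count - round(count)) > 1e-9:
                raise ValueError(
                    f"scale {self.scale} gives non-integer population sizes")


def build_benchmark(spec: BenchmarkSpec) -> tuple[Network, DriveSpec]:
    """Construct the benchmark network for one variant and scale."""
    cfg = BENCHMARK
    n_exc = int(round(8000 * spec.scale))
    n_inh = int(round(2000 * spec.scale))
    n_astro = int(round(10000 * spec.scale))
    n_neurons = n_exc + n_inh
    rng = np.random.default_rng(spec.master_seed)

    p_eff = min(1.0, cfg["p_primary"] / spec.scale)
    neuron_ids = np.arange(n_neurons)
    exc_ids = neuron_ids[:n_exc]
    inh_ids = neuron_ids[n_exc:]
    astro_gids = np.arange(n_neurons, n_neurons + n_astro)

    expected = p_eff * n_neurons  # expected primary in/out-degree anchors
    rule_specs = {
        "pairwise_bernoulli": PrimaryRuleSpec("pairwise_bernoulli", p_primary=p_eff),
        "fixed_in_degree": PrimaryRuleSpec("fixed_in_degree",
                                           K_in=int(round(expected))),
        "fixed_out_degree": PrimaryRuleSpec("fixed_out_degree",
                                            K_out=int(round(expected))),
        "fixed_total_number": PrimaryRuleSpec(
            "fixed_total_number", N_total=int(round(p_eff * n_neurons * n_neurons))),
    }
    # primary connections: all neurons -> all neurons, weight/delay by source kind
    frames = []
    for src_pop, kind, w, d in ((exc_ids, "exc", cfg["w_exc"], cfg["d_exc"]),
                                (inh_ids, "inh", cfg["w_inh"],
                                 cfg["d_inh_sync"] if spec.variant == "synchronous"
                                 else cfg["d_inh"])):
        rs = rule_specs[spec.primary_rule]
        if rs.rule == "fixed_in_degree":
            rs = replace(rs, K_in=int(round(p_eff * len(src_pop))))
        elif rs.rule == "fixed_total_number":
            rs = replace(rs, N_total=int(round(p_eff * len(src_pop) * n_neurons)))
        s, t = primary_connect(src_pop, neuron_ids, rs, rng)
        frames.append(pd.DataFrame({
            "source": s, "target": t, "weight": w, "delay": d, "kind": kind}))
    primary = (pd.concat(frames, ignore_index=True) if frames
               else _empty_primary())

    pools = build_pools("random", spec.S_pool, neuron_ids, astro_gids, rng)
    third = ThirdFactorSpec(p_third_if_primary=cfg["p_third_if_primary"],
                            pool_type="random", S_pool=spec.S_pool)
    graph = tbp_connect(primary, pools, third,
                        {"third_in": SynSpec(cfg["w_pre_to_astro"], cfg["d_exc"]),
                         "third_out": SynSpec(cfg["w_astro_to_post"], cfg["d_sic"])},
                        rng)

    tau_i = (cfg["tau_syn_inh_sync"] if spec.variant == "synchronous"
             else cfg["tau_syn_inh"])
    nrn = AdexParams(tau_syn_exc=cfg["tau_syn_exc"], tau_syn_inh=tau_i)
    astro = AstrocyteParams(delta_IP3=cfg["delta_IP3"], tau_IP3=cfg["tau_IP3"])
    net = Network.homogeneous(
        n_exc, n_inh, n_astro, nrn, nrn, astro, graph,
        surrogate_sic=cfg["surrogate_sic"] if spec.variant == "surrogate" else None)
    drives = DriveSpec(poisson_rate_exc=cfg["poisson_rate"],
                       poisson_rate_inh=cfg["poisson_rate"],
                       poisson_weight=cfg["w_exc"])
    return net, drives


# ---------------------------------------------------------------------------
# Use-case models
# ---------------------------------------------------------------------------

#: Use-case model parameters.  The astrocyte block holds the fitted
#: single-astrocyte configuration (Poisson input of about 4 events/s,
#: IP3 decay of about 1 s, IP3 increment of about 0.05 uM); in network
#: simulations with active synapses the astrocytic Poisson rate is
#: reduced to 70% of the fitted value.  Neuron parameter sets derive
#: from the initial-bursting (excitatory) and tonic-spiking (inhibitory)
#: AdEx configurations, selected so that a SIC-like current evokes a
#: burst of a few spikes lasting about a second.
USE_CASE: dict = {
    "N_E": 400, "N_I": 100, "N_A": 100,
    "p_primary": 0.2,
    "w_exc": 5.0, "w_inh": 5.0,        # nS
    "delay": 1.0,                      # ms, all connection classes
    "lambda_E": 2700.0, "lambda_I": 2500.0,   # spikes/s
    "poisson_weight": 1.35,          # nS, drive events
    "lambda_A_fitted": 7.0,            # events/s, single-astrocyte fit
    "lambda_A_network_factor": 0.7,
    "noise_sd_exc": 30.0, "noise_sd_inh": 30.0,   # pA
    "noise_sd_exc_ttx": 10.0, "noise_sd_inh_ttx": 10.0,
    "astro": {                        # fitted astrocyte parameter set
        "delta_IP3": 0.015, "tau_IP3": 2000.0,
        "Ca_tot": 1.5, "IP3_0": 0.20, "noise_sd": 0.0005,
    },
    "exc_neuron": {                   # initial-bursting derived set
        "C_m": 130.0, "g_L": 18.0, "E_L": -58.0, "Delta_T": 2.0,
        "V_T": -50.0, "a": 4.0, "tau_w": 2000.0, "b": 200.0,
        "V_reset": -55.0, "V_peak": 0.0, "t_ref": 2.0,
        "E_exc": 0.0, "E_inh": -85.0, "tau_syn_exc": 0.2, "tau_syn_inh": 4.0,
    },
    "inh_neuron": {                   # tonic-spiking derived set
        "C_m": 200.0, "g_L": 10.0, "E_L": -58.0, "Delta_T": 2.0,
        "V_T": -50.0, "a": 2.0, "tau_w": 300.0, "b": 80.0,
        "V_reset": -58.0, "V_peak": 0.0, "t_ref": 2.0,
        "E_exc": 0.0, "E_inh": -85.0, "tau_syn_exc": 0.2, "tau_syn_inh": 4.0,
    },
    "heterogeneity": {                # relative Gaussian SD and cutoff
        "rel_sd": 0.02, "rel_cutoff": 0.05,
        "astro_fields": ["Ca_tot", "IP3_0", "delta_IP3", "tau_IP3"],
        "neuron_fields": ["b", "V_reset"],
    },
    "regimes": {
        "ttx": {"pool_type": "block", "S_pool": 1, "p_third": 0.2,
                "w_pre_to_astro": 0.2, "w_astro_to_post": 1.35,
                "zero_primary": True, "poisson_neurons": False,
                "lambda_A_factor": 1.0},
        "block_async": {"pool_type": "block", "S_pool": 1, "p_third": 0.2,
                        "w_pre_to_astro": 0.2, "w_astro_to_post": 1.5,
                        "zero_primary": False, "poisson_neurons": True,
                        "lambda_A_factor": 0.7},
        "block_burst": {"pool_type": "block", "S_pool": 1, "p_third": 0.2,
                        "w_pre_to_astro": 0.31, "w_astro_to_post": 1.5,
                        "zero_primary": False, "poisson_neurons": True,
                        "lambda_A_factor": 0.7},
        "random_pool": {"pool_type": "random", "S_pool": 5, "p_third": 0.03,
                        "w_pre_to_astro": 1.0, "w_astro_to_post": 10.0,
                        "zero_primary": False, "poisson_neurons": True,
                        "lambda_A_factor": 0.7},
    },
}


@dataclass
class UseCaseSpec:
    regime: str = "block_async"
    master_seed: int = 1
    heterogeneous: bool = True

    def __post_init__(self) -> None:
        if self.regime not in USE_CASE["regimes"]:
            raise ValueError(f"unknown use-case regime {self.regime!r}")


def _truncated_gaussian(rng, mean, rel_sd, rel_cutoff, size):
    """Per-cell parameter draw: Gaussian around the fitted mean with a
    relative SD, redrawn outside the relative cutoff band."""
    lo, hi = mean * (1 - rel_cutoff), mean * (1 + rel_cutoff)
    if mean < 0:
        lo, hi = hi, lo
    out = rng.normal(mean, abs(mean) * rel_sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, abs(mean) * rel_sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def use_case_block_target_order(n_exc: int, n_inh: int) -> list[int]:
    """Interleave targets as 4 excitatory + 1 inhibitory per astrocyte
    block, giving 100 groups of 4 E + 1 I for the default sizes."""
    order = []
    for g in range(n_inh):
        order.extend(range(4 * g, 4 * g + 4))
        order.append(n_exc + g)
    return order


def build_use_case(spec: UseCaseSpec) -> tuple[Network, DriveSpec]:
    cfg = USE_CASE
    reg = cfg["regimes"][spec.regime]
    n_e, n_i, n_a = cfg["N_E"], cfg["N_I"], cfg["N_A"]
    n_neurons = n_e + n_i
    rng = np.random.default_rng(spec.master_seed)

    neuron_ids = np.arange(n_neurons)
    exc_ids = neuron_ids[:n_e]
    inh_ids = neuron_ids[n_e:]
    astro_gids = np.arange(n_neurons, n_neurons + n_a)

    w_exc = 0.0 if reg["zero_primary"] else cfg["w_exc"]
    w_inh = 0.0 if reg["zero_primary"] else cfg["w_inh"]
    frames = []
    for src_pop, kind, w in ((exc_ids, "exc", w_exc), (inh_ids, "inh", w_inh)):
        s, t = primary_connect(
            src_pop, neuron_ids,
            PrimaryRuleSpec("pairwise_bernoulli", p_primary=cfg["p_primary"]),
            rng)
        frames.append(pd.DataFrame({
            "source": s, "target": t, "weight": w,
            "delay": cfg["delay"], "kind": kind}))
    primary = pd.concat(frames, ignore_index=True)

    if reg["pool_type"] == "block":
        target_order = use_case_block_target_order(n_e, n_i)
    else:
        target_order = list(neuron_ids)
    pools = build_pools(reg["pool_type"], reg["S_pool"], target_order,
                        astro_gids, rng)
    graph = tbp_connect(
        primary, pools,
        ThirdFactorSpec(reg["p_third"], reg["pool_type"], reg["S_pool"]),
        {"third_in": SynSpec(reg["w_pre_to_astro"], cfg["delay"]),
         "third_out": SynSpec(reg["w_astro_to_post"], cfg["delay"])},
        rng)

    exc_p = AdexParams.from_dict(cfg["exc_neuron"])
    inh_p = AdexParams.from_dict(cfg["inh_neuron"])
    astro_p = AstrocyteParams.from_dict(
        {**{}, **cfg["astro"]})
    net = Network.homogeneous(n_e, n_i, n_a, exc_p, inh_p, astro_p, graph)

    if spec.heterogeneous:
        het = cfg["heterogeneity"]
        from .params import AdexParams as _AP  # field order = column order
        from dataclasses import fields as _fields
        ncols = {f.name: i for i, f in enumerate(_fields(_AP))}
        for name in het["neuron_fields"]:
            col = ncols[name]
            mean_e, mean_i = getattr(exc_p, name), getattr(inh_p, name)
            if mean_e != 0:
                net.neuron_params[:n_e, col] = _truncated_gaussian(
                    rng, mean_e, het["rel_sd"], het["rel_cutoff"], n_e)
            if mean_i != 0:
                net.neuron_params[n_e:, col] = _truncated_gaussian(
                    rng, mean_i, het["rel_sd"], het["rel_cutoff"], n_i)
        from .params import AstrocyteParams as _ASP
        acols = {f.name: i for i, f in enumerate(_fields(_ASP))}
        for name in het["astro_fields"]:
            col = acols[name]
            net.astro_params[:, col] = _truncated_gaussian(
                rng, getattr(astro_p, name), het["rel_sd"], het["rel_cutoff"], n_a)

    # start membrane potentials spread out; a synchronized drive onset
    # would otherwise kick the network out of the low-rate state
    init = net.default_neuron_state()
    init[:, 0] = rng.uniform(-70.0, -55.0, size=net.n_neurons)
    net.init_neuron_state = init

    lam_a = cfg["lambda_A_fitted"] * reg["lambda_A_factor"]
    if reg["poisson_neurons"]:
        drives = DriveSpec(
            poisson_rate_exc=cfg["lambda_E"], poisson_rate_inh=cfg["lambda_I"],
            poisson_weight=cfg["poisson_weight"],
            noise_sd_exc=cfg["noise_sd_exc"], noise_sd_inh=cfg["noise_sd_inh"],
            poisson_rate_astro=lam_a)
    else:
        drives = DriveSpec(
            noise_sd_exc=cfg["noise_sd_exc_ttx"],
            noise_sd_inh=cfg["noise_sd_inh_ttx"],
            poisson_rate_astro=lam_a)
    return net, drives


# ---------------------------------------------------------------------------
# Experiment runner and summary statistics
# ---------------------------------------------------------------------------

def neuron_groups(net: Network) -> dict[int, set[int]]:
    """Map astrocyte gid -> set of neurons receiving SIC from it."""
    groups: dict[int, set[int]] = {}
    for astro, tgt in zip(net.graph.third_out_edges["astrocyte"],
                          net.graph.third_out_edges["target"]):
        groups.setdefault(int(astro), set()).add(int(tgt))
    return groups


def within_group_pairs(net: Network) -> set[tuple[int, int]]:
    """Neuron pairs sharing at least one SIC source astrocyte."""
    pairs: set[tuple[int, int]] = set()
    for members in neuron_groups(net).values():
        mem = sorted(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                pairs.add((mem[i], mem[j]))
    return pairs


def network_bursts(spikes: pd.DataFrame, window: tuple[float, float],
                   bin_width: float = 100.0,
                   threshold_factor: float = 2.0,
                   merge_gap: float = 1000.0,
                   min_duration: float = 300.0) -> pd.DataFrame:
    """Network-wide bursts from the population rate.

    The population spike count is binned at ``bin_width`` ms; a network
    burst is a contiguous region where the count exceeds
    ``threshold_factor`` times the median count.  Within a collective
    event the rate fluctuates around the threshold, so above-threshold
    regions separated by less than ``merge_gap`` ms are merged, and
    merged regions shorter than ``min_duration`` ms (isolated count
    fluctuations) are discarded.  Returns a table with
    (onset_ms, offset_ms, duration_ms).
    """
    t0, t1 = window
    edges = np.arange(t0, t1 + bin_width, bin_width)
    counts, _ = np.histogram(spikes["time_ms"], bins=edges)
    thresh = threshold_factor * max(np.median(counts), 1.0)
    above = counts > thresh
    recs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if recs and edges[i] - recs[-1]["offset_ms"] < merge_gap:
                recs[-1]["offset_ms"] = edges[j + 1]
                recs[-1]["duration_ms"] = (recs[-1]["offset_ms"]
                                           - recs[-1]["onset_ms"])
            else:
                recs.append({"onset_ms": edges[i], "offset_ms": edges[j + 1],
                             "duration_ms": edges[j + 1] - edges[i]})
            i = j + 1
        i += 1
    recs = [r for r in recs if r["duration_ms"] >= min_duration]
    return pd.DataFrame(recs, columns=["onset_ms", "offset_ms", "duration_ms"])


def run_experiment(spec: UseCaseSpec, duration: float = 120_000.0,
                   warmup: float = 5000.0,
                   record_interval: float = 10.0,
                   n_all_pair_sample: int = 2000,
                   corr_window: float = 2000.0, corr_stride: float = 4.0,
                   tol: float = 1e-6,
                   grid_step: float = 0.1) -> tuple[Recording, dict]:
    """Run one use-case model and compute its summary statistics.

    Returns the Recording and a summary dict with population rates, the
    calcium-transient and burst tables, within-group vs all-pairs
    correlation and burst-onset-distance contrasts (KS statistic and
    Bonferroni-corrected p over the four tests), and network bursts.
    """
    net, drives = build_use_case(spec)
    n_neurons = net.n_neurons
    cfg = SimulationConfig(
        grid_step=grid_step, duration=warmup + duration,
        master_seed=spec.master_seed, tol=tol,
        record_interval=record_interval,
        record_astro=range(net.astro_gid0, net.astro_gid0 + net.n_astro),
        record_sic=range(n_neurons))
    rec = run(net, cfg, drives)
    window = (warmup, warmup + duration)
    minutes = duration / 60000.0

    spk = rec.spikes[(rec.spikes["time_ms"] >= window[0])
                     & (rec.spikes["time_ms"] < window[1])]
    exc_spk = spk[spk["cell_id"] < net.n_exc]
    inh_spk = spk[(spk["cell_id"] >= net.n_exc) & (spk["cell_id"] < n_neurons)]

    in_window = (rec.times >= window[0]) & (rec.times <= window[1])
    times = rec.times[in_window]

    # calcium transients: threshold is the SIC trigger level, in uM
    ttable = analysis.TransientTable(model_time=duration)
    for col, gid in enumerate(rec.astro_ids):
        th = (net.astro_params[col, 14] + 1.0) / 1000.0
        ttable.rows[int(gid)] = analysis.detect_transients(
            times, rec.ca[in_window, col], threshold=th)

    # SIC-gated bursts per neuron
    btable = analysis.BurstTable(model_time=duration)
    trains = rec.spike_trains(range(n_neurons))
    for col, gid in enumerate(rec.sic_ids):
        kind = "exc" if gid < net.n_exc else "inh"
        wins = analysis.sic_windows_from_trace(times, rec.i_sic[in_window, col])
        st = trains[int(gid)]
        st = st[(st >= window[0]) & (st < window[1])]
        btable.rows[int(gid)] = analysis.detect_bursts(st, kind, wins)

    # pairwise correlation: sliding-window binning
    bt = analysis.bin_counts(trains, width=corr_window, stride=corr_stride,
                             window=window)
    rmat, _ = analysis.pairwise_correlation(bt)
    wg = within_group_pairs(net)
    iu = np.triu_indices(n_neurons, k=1)
    all_vals = rmat[iu]
    wg_idx = np.array([[i, j] for i, j in sorted(wg)], dtype=int)
    within_vals = rmat[wg_idx[:, 0], wg_idx[:, 1]] if len(wg_idx) else np.empty(0)

    # burst-onset distances: within-group pairs vs a seeded sample of all pairs
    rng = np.random.default_rng(spec.master_seed + 7)
    onsets = {gid: row.onsets for gid, row in btable.rows.items()}
    within_d = np.concatenate(
        [analysis.burst_onset_distance(onsets[i], onsets[j])
         for i, j in sorted(wg)] or [np.empty(0)])
    n_pairs_total = len(iu[0])
    sample = rng.choice(n_pairs_total, size=min(n_all_pair_sample, n_pairs_total),
                        replace=False)
    all_d = np.concatenate(
        [analysis.burst_onset_distance(onsets[int(iu[0][k])],
                                       onsets[int(iu[1][k])])
         for k in sample] or [np.empty(0)])

    n_tests = 4  # two contrasts in each of two measures (per the study design)
    vw = within_vals[~np.isnan(within_vals)] if len(within_vals) else within_vals
    va = all_vals[~np.isnan(all_vals)]
    if len(vw) and len(va):
        corr_D, corr_p = analysis.group_contrast(vw, va, n_tests=n_tests)
    else:  # too little activity for a contrast (very short runs)
        corr_D, corr_p = float("nan"), float("nan")
    if len(within_d) and len(all_d):
        dist_D, dist_p = analysis.group_contrast(within_d, all_d, n_tests=n_tests)
    else:
        dist_D, dist_p = float("nan"), float("nan")

    nb = network_bursts(spk, window)
    tsum = ttable.summary()
    bsum = btable.summary()
    def _nanmean(series):
        vals = np.asarray(series, dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if len(vals) else float("nan")

    summary = {
        "regime": spec.regime,
        "duration_ms": duration,
        "rate_exc": len(exc_spk) / net.n_exc / (duration / 1000.0),
        "rate_inh": len(inh_spk) / net.n_inh / (duration / 1000.0),
        "transient_freq_per_min": _nanmean(tsum["freq_per_min"]),
        "transient_duration_s": _nanmean(tsum["mean_duration_s"]),
        "transient_peak_uM": float(np.nanmax(tsum["max_peak_uM"]))
        if tsum["max_peak_uM"].notna().any() else float("nan"),
        "burst_freq_per_min": _nanmean(bsum["burst_freq_per_min"]),
        "max_spikes_per_burst": int(max(
            (row.n_spikes.max() for row in btable.rows.values()
             if len(row.n_spikes)), default=0)),
        "corr_within_mean": _nanmean(within_vals),
        "corr_all_mean": _nanmean(all_vals),
        "ks_corr_D": corr_D, "ks_corr_p": corr_p,
        "ks_dist_D": dist_D, "ks_dist_p": dist_p,
        "n_network_bursts": int(len(nb)),
        "network_burst_duration_s": float(nb["duration_ms"].mean() / 1000.0)
        if len(nb) else float("nan"),
    }
    extras = {"transients": ttable, "bursts": btable, "network_bursts": nb,
              "corr_within": within_vals, "corr_all": all_vals,
              "dist_within": within_d, "dist_all": all_d}
    return rec, {**summary, "tables": extras}


# ---------------------------------------------------------------------------
# Single-astrocyte parameter scan
# ---------------------------------------------------------------------------

@dataclass
class ScanSpec:
    """Random-sampling scan of the five free astrocyte parameters.

    Each sampled set drives a single noise-driven astrocyte; a set is
    accepted if its calcium transients fall in the acceptance ranges
    (period from frequency per minute, duration in s, peak in uM).
    """

    n_samples: int = 50
    duration: float = 300_000.0        # ms per evaluation
    intervals: dict = field(default_factory=lambda: {
        "lambda_A": (1.0, 10.0), "delta_IP3": (0.01, 0.2),
        "Ca_tot": (0.5, 2.0), "IP3_0": (0.05, 0.3),
        "tau_IP3": (300.0, 3000.0),
    })
    freq_range: tuple[float, float] = (0.1, 1.5)     # transients/min
    duration_range: tuple[float, float] = (1.0, 20.0)  # s
    peak_range: tuple[float, float] = (0.2, 0.7)     # uM
    noise_sd: float = USE_CASE["astro"]["noise_sd"]
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for k, (lo, hi) in self.intervals.items():
            if not lo < hi:
                raise ValueError(f"empty sampling interval for {k}")


def simulate_single_astrocyte(astro: AstrocyteParams, lambda_A: float,
                              duration: float, seed: int,
                              record_interval: float = 10.0,
                              grid_step: float = 0.1) -> Recording:
    """Simulate one Poisson-driven astrocyte in isolation."""
    graph = NetworkGraph(primary_edges=_empty_primary(),
                         third_in_edges=_empty_third_in(),
                         third_out_edges=_empty_third_out(), pools={})
    net = Network(n_exc=0, n_inh=0, n_astro=1,
                  neuron_params=np.zeros((0, 15)),
                  astro_params=astro.as_array()[None, :], graph=graph)
    cfg = SimulationConfig(grid_step=grid_step, duration=duration,
                           master_seed=seed, record_interval=record_interval,
                           record_astro=[0])
    return run(net, cfg, DriveSpec(poisson_rate_astro=lambda_A))


def evaluate_astro_set(astro: AstrocyteParams, lambda_A: float,
                       duration: float, seed: int) -> dict:
    rec = simulate_single_astrocyte(astro, lambda_A, duration, seed)
    th = (astro.SIC_th + 1.0) / 1000.0
    row = analysis.detect_transients(rec.times, rec.ca[:, 0], threshold=th)
    n = len(row.onsets)
    return {
        "n_transients": n,
        "freq_per_min": n / (duration / 60000.0),
        "mean_duration_s": float(np.mean(row.offsets - row.onsets)) / 1000.0
        if n else float("nan"),
        "max_peak_uM": float(np.max(row.peaks)) if n else float("nan"),
    }


def accept_astro_stats(stats: dict, spec: ScanSpec) -> bool:
    if stats["n_transients"] == 0:
        return False
    return (spec.freq_range[0] <= stats["freq_per_min"] <= spec.freq_range[1]
            and spec.duration_range[0] <= stats["mean_duration_s"] <= spec.duration_range[1]
            and spec.peak_range[0] <= stats["max_peak_uM"] <= spec.peak_range[1])


def astro_parameter_scan(spec: ScanSpec,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample parameter sets, simulate each, and mark acceptance."""
    rng = rng or np.random.default_rng(spec.seed)
    recs = []
    for i in range(spec.n_samples):
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in spec.intervals.items()}
        astro = AstrocyteParams(
            delta_IP3=draw["delta_IP3"], Ca_tot=draw["Ca_tot"],
            IP3_0=draw["IP3_0"], tau_IP3=draw["tau_IP3"],
            noise_sd=spec.noise_sd)
        stats = evaluate_astro_set(astro, draw["lambda_A"], spec.duration,
                                   seed=spec.seed + 1000 + i)
        recs.append({**draw, **stats,
                     "accepted": accept_astro_stats(stats, spec)})
    return pd.DataFrame(recs)


def sensitivity_retest(accepted_row: dict, spec: ScanSpec,
                       fractions=(0.01, 0.05, 0.10), n_seeds: int = 5) -> pd.DataFrame:
    """Re-test an accepted set with each parameter perturbed by +-1/5/10%."""
    recs = []
    names = ("lambda_A", "delta_IP3", "Ca_tot", "IP3_0", "tau_IP3")
    for name in names:
        for frac in fractions:
            for sign in (+1, -1):
                draw = {k: accepted_row[k] for k in names}
                draw[name] = draw[name] * (1 + sign * frac)
                ok = 0
                for s in range(n_seeds):
                    astro = AstrocyteParams(
                        delta_IP3=draw["delta_IP3"], Ca_tot=draw["Ca_tot"],
                        IP3_0=draw["IP3_0"], tau_IP3=draw["tau_IP3"],
                        noise_sd=spec.noise_sd)
                    stats = evaluate_astro_set(astro, draw["lambda_A"],
                                               spec.duration, seed=spec.seed + s)
                    ok += int(accept_astro_stats(stats, spec))
                recs.append({"parameter": name, "fraction": sign * frac,
                             "n_accepted": ok, "n_seeds": n_seeds})
    return pd.DataFrame(recs)


def sic_response_spikes(p: AdexParams, amplitude: float,
                        duration: float = 1000.0, total: float = 3000.0,
                        grid_step: float = 0.1) -> tuple[int, float]:
    """Neuron-selection check: spikes evoked by a SIC-mimicking current
    step of the given amplitude (pA) and duration; returns (n_spikes,
    burst_length_ms)."""
    from .core_models import step_neuron
    from .params import NeuronState
    s = NeuronState(v=p.E_L)
    n_steps = int(round(total / grid_step))
    on = int(round(duration / grid_step))
    spike_times = []
    for k in range(n_steps):
        i_sic = amplitude if k < on else 0.0
        s, spiked = step_neuron(s, grid_step, (), I_SIC=i_sic, p=p)
        if spiked:
            spike_times.append((k + 1) * grid_step)
    if not spike_times:
        return 0, 0.0
    return len(spike_times), spike_times[-1] - spike_times[0]
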