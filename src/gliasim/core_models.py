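"""Point-model dynamics: Li-Rinzel astrocyte, surrogate, SIC-receiving AdEx.

The astrocyte follows the two-variable Li-Rinzel reduction of the De
Young-Keizer IP3-receptor model, extended with spike-driven IP3
production and a calcium-dependent slow-inward-current (SIC) output in
the Nadkarni-Jung form.  Calcium is conserved between cytosol and ER:
the ER concentration is always derived from the cytosolic one.

The logarithm in the SIC expression is the natural logarithm.  Internal
concentrations are in uM; the SIC threshold ``SIC_th`` is stored in nM
and the uM -> nM conversion is applied explicitly in :func:`sic_output`.

All functions are pure: they take a state, return a new state, and never
mutate their inputs.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from . import _kernels as _k
from .params import (AdexParams, AstrocyteParams, AstrocyteState, NeuronState,
                     SurrogateParams)

__all__ = [
    "calcium_er", "gating_steady_states", "astrocyte_rhs",
    "apply_input_spikes", "sic_output", "step_astrocyte", "step_neuron",
    "surrogate_output",
]


def calcium_er(ca: float, p: AstrocyteParams) -> float:
    """ER calcium concentration from conservation of total calcium.

    ``ca + r_ER_cyt * calcium_er(ca) == Ca_tot`` holds exactly.
    """
    if not (0.0 <= ca <= p.Ca_tot):
        raise ValueError(f"ca={ca} outside [0, Ca_tot={p.Ca_tot}]")
    return (p.Ca_tot - ca) / p.r_ER_cyt


def gating_steady_states(ip3: float, ca: float, p: AstrocyteParams) -> tuple[float, float]:
    """Steady-state IP3R gating variables (m_inf, n_inf)."""
    if ip3 < 0 or ca < 0:
        raise ValueError("ip3 and ca must be non-negative")
    return ip3 / (ip3 + p.Kd_IP3_1), ca / (ca + p.Kd_act)


def astrocyte_rhs(s: AstrocyteState, p: AstrocyteParams) -> tuple[float, float, float]:
    """Smooth derivatives (dca, dh, dip3) of the Li-Rinzel system.

    The stochastic calcium flux is not part of the right-hand side; it is
    applied as a per-step increment by :func:`step_astrocyte`.
    """
    s.validate(p)
    dca, dh, dip3 = _k.astro_rhs(s.ca, s.ip3, s.h, p.as_array())
    return dca, dh, dip3


def apply_input_spikes(s: AstrocyteState, weight_sum: float, p: AstrocyteParams) -> AstrocyteState:
    """Instantaneous IP3 increment from presynaptic spikes.

    Each unit of summed connection weight raises [IP3] by ``delta_IP3``;
    calcium and gating are untouched.  Astrocytes accept only excitatory
    input, so ``weight_sum`` must be non-negative.
    """
    if weight_sum < 0:
        raise ValueError("inhibitory (negative-weight) input to astrocytes is unsupported")
    return replace(s, ip3=s.ip3 + p.delta_IP3 * weight_sum)


def sic_output(ca: float, p: AstrocyteParams) -> float:
    """Dimensionless SIC drive F_SIC as a function of cytosolic calcium.

    F_SIC = SIC_scale * ln((ca[nM] - SIC_th)/nM) whenever the argument of
    the log exceeds one (i.e. ca > SIC_th + 1 nM), else 0.  The result is
    continuous, non-negative and non-decreasing in ca; multiplying by an
    astrocyte-to-neuron weight (pA) gives the current delivered.
    """
    if ca < 0:
        raise ValueError("ca must be non-negative")
    return _k.sic_from_ca(ca, p.SIC_th, p.SIC_scale)


def step_astrocyte(s: AstrocyteState, dt: float, weight_sum: float,
                   noise_draw: float, p: AstrocyteParams,
                   tol: float = 1e-6) -> AstrocyteState:
    """Advance an astrocyte by one grid step of length ``dt`` ms.

    Order of operations: spike-driven IP3 increments are applied first,
    the deterministic system is integrated with embedded adaptive RKF45
    (substeps bounded by ``dt``), then the pre-scaled Gaussian calcium
    increment ``noise_draw`` is added and the state is clamped
    (ca in [0, Ca_tot], h in [0, 1]).
    """
    s.validate(p)
    if weight_sum < 0:
        raise ValueError("weight_sum must be non-negative")
    ca, ip3, h, ok = _k.astro_grid_step(
        s.ca, s.ip3, s.h, p.as_array(), dt, weight_sum, noise_draw, tol)
    if not ok:
        raise RuntimeError(
            f"astrocyte integration substep underflow; state was ca={s.ca}, "
            f"ip3={s.ip3}, h={s.h}, dt={dt}")
    return AstrocyteState(ca=ca, ip3=ip3, h=h)


def step_neuron(s: NeuronState, dt: float,
                i_syn_events: Iterable[tuple[str, float]] | Sequence = (),
                I_SIC: float = 0.0, I_noise: float = 0.0,
                p: AdexParams | None = None,
                tol: float = 1e-6) -> tuple[NeuronState, bool]:
    """Advance an AdEx neuron by one grid step; returns (state, spiked).

    ``i_syn_events`` lists weighted spike arrivals for this step as
    ``("exc"|"inh", weight_nS)`` pairs.  A single arrival of weight w
    drives the alpha conductance to a peak of exactly w at ``tau_syn``
    after arrival.  On a V_peak crossing the reset is applied (v ->
    V_reset, w -> w + b) and v is held at V_reset for ``t_ref``.
    """
    if p is None:
        p = AdexParams()
    s.validate()
    state = np.array([s.v, s.w, s.g_exc, s.dg_exc, s.g_inh, s.dg_inh,
                      s.refr_remaining], dtype=np.float64)
    for kind, weight in i_syn_events:
        if kind == "exc":
            state[3] += weight * math.e / p.tau_syn_exc
        elif kind == "inh":
            state[5] += weight * math.e / p.tau_syn_inh
        else:
            raise ValueError(f"unknown synaptic event kind {kind!r}")
    spiked, ok = _k.neuron_grid_step(state, p.as_array(), dt, I_SIC, I_noise, tol)
    if not ok:
        raise RuntimeError(f"neuron integration substep underflow; state dump: {state}")
    new = NeuronState(v=state[0], w=state[1], g_exc=state[2], dg_exc=state[3],
                      g_inh=state[4], dg_inh=state[5], refr_remaining=state[6])
    return new, bool(spiked)


def surrogate_output(p: SurrogateParams) -> float:
    """Constant SIC drive of the surrogate astrocyte (input-independent)."""
    return p.sic_const
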