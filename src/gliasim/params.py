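"""Parameter and state records for the point models.

Units follow the convention used throughout the package: time in ms,
voltage in mV, current in pA, conductance in nS, capacitance in pF, and
intracellular concentrations in uM.  The single exception is the SIC
threshold ``SIC_th``, which is stored in nM because the SIC expression is
defined on the nM scale (see :func:`gliasim.core_models.sic_output`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from importlib import resources

import numpy as np

__all__ = [
    "AstrocyteParams",
    "AstrocyteState",
    "AdexParams",
    "NeuronState",
    "SurrogateParams",
    "load_default_astrocyte_params",
]


@dataclass
class AstrocyteParams:
    """Li-Rinzel calcium dynamics with IP3 input and SIC output.

    Defaults are the published Li-Rinzel / De Young-Keizer constants with
    the Nadkarni-Jung SIC threshold, expressed in uM and ms.
    """

    r_ER_cyt: float = 0.185      # ER/cytosol volume ratio (dimensionless)
    v_IP3R: float = 0.006        # max IP3R release rate (1/ms)
    Kd_IP3_1: float = 0.13       # first IP3 dissociation constant (uM)
    Kd_IP3_2: float = 0.9434     # second IP3 dissociation constant (uM)
    Kd_act: float = 0.08234      # Ca dissociation constant, activation (uM)
    Kd_inh: float = 1.049        # Ca dissociation constant, inhibition (uM)
    k_IP3R: float = 0.0002       # Ca-inhibition binding constant (1/(uM*ms))
    v_SERCA: float = 0.0009      # max SERCA pump rate (uM/ms)
    Km_SERCA: float = 0.1        # SERCA half-activation (uM)
    v_L: float = 0.00011         # ER leak rate constant (1/ms)
    Ca_tot: float = 2.0          # total calcium wrt cytosolic volume (uM)
    IP3_0: float = 0.16          # baseline IP3 (uM)
    tau_IP3: float = 7142.0      # IP3 decay time constant (ms)
    delta_IP3: float = 0.0002    # IP3 increment per unit-weight spike (uM)
    SIC_th: float = 196.69       # SIC calcium threshold theta_SIC (nM)
    SIC_scale: float = 1.0       # SIC scale a_SIC (dimensionless)
    noise_sd: float = 0.0        # calcium noise SD per sqrt(ms) (uM/sqrt(ms))

    def __post_init__(self) -> None:
        positive = (
            "r_ER_cyt", "v_IP3R", "Kd_IP3_1", "Kd_IP3_2", "Kd_act",
            "Kd_inh", "k_IP3R", "v_SERCA", "Km_SERCA", "v_L", "Ca_tot",
            "IP3_0", "tau_IP3", "delta_IP3",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"AstrocyteParams.{name} must be > 0")
        if self.SIC_th < 0:
            raise ValueError("AstrocyteParams.SIC_th must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("AstrocyteParams.noise_sd must be >= 0")

    def as_array(self) -> np.ndarray:
        """Flatten to the column layout used by the numba kernels."""
        return np.array(
            [self.r_ER_cyt, self.v_IP3R, self.Kd_IP3_1, self.Kd_IP3_2,
             self.Kd_act, self.Kd_inh, self.k_IP3R, self.v_SERCA,
             self.Km_SERCA, self.v_L, self.Ca_tot, self.IP3_0,
             self.tau_IP3, self.delta_IP3, self.SIC_th, self.SIC_scale,
             self.noise_sd, 0.0],
            dtype=np.float64,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AstrocyteParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown astrocyte parameters: {sorted(unknown)}")
        return cls(**d)


@dataclass
class AstrocyteState:
    """Cytosolic calcium (uM), IP3 (uM) and IP3R gating variable h."""

    ca: float = 0.073
    ip3: float = 0.16
    h: float = 0.793

    def validate(self, p: AstrocyteParams) -> None:
        if not (0.0 <= self.ca <= p.Ca_tot):
            raise ValueError(f"ca={self.ca} outside [0, Ca_tot={p.Ca_tot}]")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError(f"h={self.h} outside [0, 1]")
        if self.ip3 < 0.0:
            raise ValueError(f"ip3={self.ip3} negative")


@dataclass
class AdexParams:
    """Adaptive exponential integrate-and-fire neuron with alpha-shaped
    conductance synapses.  Defaults are the standard AdEx reference set."""

    C_m: float = 281.0           # pF
    g_L: float = 30.0            # nS
    E_L: float = -70.6           # mV
    Delta_T: float = 2.0         # mV
    V_T: float = -50.4           # mV
    a: float = 4.0               # nS
    tau_w: float = 144.0         # ms
    b: float = 80.5              # pA
    V_reset: float = -60.0       # mV
    V_peak: float = 0.0          # mV
    t_ref: float = 2.0           # ms
    E_exc: float = 0.0           # mV
    E_inh: float = -85.0         # mV
    tau_syn_exc: float = 0.2     # ms
    tau_syn_inh: float = 2.0     # ms

    def __post_init__(self) -> None:
        if not self.Delta_T > 0:
            raise ValueError("AdexParams.Delta_T must be > 0")
        for name in ("tau_w", "tau_syn_exc", "tau_syn_inh", "C_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"AdexParams.{name} must be > 0")
        if not self.V_reset < self.V_peak:
            raise ValueError("AdexParams requires V_reset < V_peak")
        if self.t_ref < 0:
            raise ValueError("AdexParams.t_ref must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.C_m, self.g_L, self.E_L, self.Delta_T, self.V_T, self.a,
             self.tau_w, self.b, self.V_reset, self.V_peak, self.t_ref,
             self.E_exc, self.E_inh, self.tau_syn_exc, self.tau_syn_inh],
            dtype=np.float64,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AdexParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown neuron parameters: {sorted(unknown)}")
        return cls(**d)


@dataclass
class NeuronState:
    """AdEx state: membrane potential, adaptation current, and the two
    alpha-conductance state pairs (value and derivative)."""

    v: float = -70.6             # mV
    w: float = 0.0               # pA
    g_exc: float = 0.0           # nS
    dg_exc: float = 0.0          # nS/ms
    g_inh: float = 0.0           # nS
    dg_inh: float = 0.0          # nS/ms
    refr_remaining: float = 0.0  # ms

    def validate(self) -> None:
        if self.refr_remaining < 0:
            raise ValueError("refr_remaining must be >= 0")


@dataclass
class SurrogateParams:
    """Astrocyte stand-in emitting a constant SIC, no internal dynamics."""

    sic_const: float = 0.0

    def __post_init__(self) -> None:
        if self.sic_const < 0:
            raise ValueError("SurrogateParams.sic_const must be >= 0")


def load_default_astrocyte_params() -> AstrocyteParams:
    """Load the shipped ``astrocyte_default.json`` parameter record."""
    text = resources.files("gliasim.data").joinpath("astrocyte_default.json").read_text()
    return AstrocyteParams.from_dict(json.loads(text))
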