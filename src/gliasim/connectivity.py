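"""Tripartite network generation.

A network is described by three edge tables: primary neuron->neuron
synapses, ``third_in`` neuron->astrocyte edges and ``third_out``
astrocyte->neuron edges.  Primary connections are drawn by one of four
standard rules (pairwise Bernoulli, fixed in-degree, fixed out-degree,
fixed total number).  The third-factor Bernoulli-with-pool (TBP) rule
then attaches, independently for each eligible primary connection and
with probability ``p_third_if_primary``, one astrocyte drawn uniformly
from the target neuron's pool, creating one third_in and one third_out
edge per attachment.  Only connections with an excitatory source are
eligible; repeated selection of the same astrocyte for the same target
creates multapses.

Generation order is fixed (targets in ascending position, sources in
ascending id within a target), so a single seed fully determines the
graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PrimaryRuleSpec", "ThirdFactorSpec", "SynSpec", "NetworkGraph",
    "build_pools", "primary_connect", "tbp_connect",
]

_PRIMARY_RULES = ("pairwise_bernoulli", "fixed_in_degree",
                  "fixed_out_degree", "fixed_total_number")


@dataclass
class PrimaryRuleSpec:
    """Primary neuron->neuron connection rule.

    Multapse defaults follow common simulator practice: the pairwise
    Bernoulli rule performs one trial per ordered pair (no multapses),
    the fixed-degree and fixed-total rules allow them unless disabled.
    """

    rule: str
    p_primary: float | None = None
    K_in: int | None = None
    K_out: int | None = None
    N_total: int | None = None
    allow_autapses: bool = False
    allow_multapses: bool | None = None

    def __post_init__(self) -> None:
        if self.rule not in _PRIMARY_RULES:
            raise ValueError(f"unknown primary rule {self.rule!r}")
        if self.rule == "pairwise_bernoulli":
            if self.p_primary is None or not (0.0 <= self.p_primary <= 1.0):
                raise ValueError("pairwise_bernoulli requires 0 <= p_primary <= 1")
        if self.rule == "fixed_in_degree" and (self.K_in is None or self.K_in < 0):
            raise ValueError("fixed_in_degree requires K_in >= 0")
        if self.rule == "fixed_out_degree" and (self.K_out is None or self.K_out < 0):
            raise ValueError("fixed_out_degree requires K_out >= 0")
        if self.rule == "fixed_total_number" and (self.N_total is None or self.N_total < 0):
            raise ValueError("fixed_total_number requires N_total >= 0")
        if self.allow_multapses is None:
            self.allow_multapses = self.rule != "pairwise_bernoulli"


@dataclass
class ThirdFactorSpec:
    """TBP rule parameters: attachment probability, pool type and size."""

    p_third_if_primary: float
    pool_type: str = "random"
    S_pool: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_third_if_primary <= 1.0):
            raise ValueError("p_third_if_primary must be in [0, 1]")
        if self.pool_type not in ("random", "block"):
            raise ValueError(f"unknown pool_type {self.pool_type!r}")
        if self.S_pool < 1:
            raise ValueError("S_pool must be a positive integer")


@dataclass
class SynSpec:
    """Weight and delay of one connection class.

    Weights are in nS for neuron->neuron synapses; third_in weights are
    the dimensionless IP3 scaling and third_out weights are in pA.
    Delays must be positive multiples of the simulation grid step.
    """

    weight: float
    delay: float = 1.0

    def __post_init__(self) -> None:
        if self.delay <= 0:
            raise ValueError("delay must be positive (at least one grid step)")


@dataclass
class NetworkGraph:
    """The three edge tables plus the astrocyte pool assignment."""

    primary_edges: pd.DataFrame
    third_in_edges: pd.DataFrame
    third_out_edges: pd.DataFrame
    pools: dict[int, list[int]] = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.third_in_edges) != len(self.third_out_edges):
            raise ValueError("third_in / third_out edge counts differ")
        for astro, tgt in zip(self.third_out_edges["astrocyte"],
                              self.third_out_edges["target"]):
            if astro not in self.pools.get(int(tgt), ()):  # pragma: no cover
                raise ValueError(f"astrocyte {astro} not in pool of target {tgt}")

    def to_csv_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.primary_edges.to_csv(path / "primary_edges.csv", index=False)
        self.third_in_edges.to_csv(path / "third_in_edges.csv", index=False)
        self.third_out_edges.to_csv(path / "third_out_edges.csv", index=False)
        with open(path / "pools.json", "w") as fh:
            json.dump({str(k): [int(a) for a in v] for k, v in self.pools.items()}, fh)

    @classmethod
    def from_csv_dir(cls, path: str | Path) -> "NetworkGraph":
        path = Path(path)
        with open(path / "pools.json") as fh:
            pools = {int(k): [int(a) for a in v] for k, v in json.load(fh).items()}
        return cls(
            primary_edges=pd.read_csv(path / "primary_edges.csv"),
            third_in_edges=pd.read_csv(path / "third_in_edges.csv"),
            third_out_edges=pd.read_csv(path / "third_out_edges.csv"),
            pools=pools,
        )


def build_pools(pool_type: str, S_pool: int, target_ids, astro_ids,
                rng: np.random.Generator) -> dict[int, list[int]]:
    """Assign each target neuron its fixed astrocyte pool.

    Random pools draw ``S_pool`` distinct astrocytes uniformly without
    replacement, independently per target.  Block pools tile the
    astrocyte population deterministically over targets *in the order
    given* (callers control interleaving by ordering ``target_ids``):
    with ``S_pool == 1`` the number of targets must be a multiple of the
    number of astrocytes and consecutive targets share one astrocyte;
    with ``S_pool > 1`` there must be exactly ``S_pool`` astrocytes per
    target and pools are disjoint contiguous blocks.
    """
    target_ids = [int(t) for t in target_ids]
    astro_ids = np.asarray(astro_ids, dtype=np.int64)
    n_t, n_a = len(target_ids), len(astro_ids)
    pools: dict[int, list[int]] = {}
    if pool_type == "random":
        if S_pool > n_a:
            raise ValueError(
                f"random pools need S_pool <= number of astrocytes "
                f"({S_pool} > {n_a})")
        for t in target_ids:
            pools[t] = [int(a) for a in rng.choice(astro_ids, size=S_pool,
                                                   replace=False)]
    elif pool_type == "block":
        if S_pool == 1:
            if n_a == 0 or n_t % n_a != 0:
                raise ValueError(
                    f"block pools with S_pool=1 require the number of target "
                    f"neurons ({n_t}) to be a multiple of the number of "
                    f"astrocytes ({n_a})")
            per_astro = n_t // n_a
            for i, t in enumerate(target_ids):
                pools[t] = [int(astro_ids[i // per_astro])]
        else:
            if n_a != S_pool * n_t:
                raise ValueError(
                    f"block pools with S_pool={S_pool} require exactly "
                    f"S_pool * n_targets astrocytes ({S_pool}*{n_t}={S_pool * n_t}, "
                    f"got {n_a})")
            for i, t in enumerate(target_ids):
                pools[t] = [int(a) for a in astro_ids[i * S_pool:(i + 1) * S_pool]]
    else:
        raise ValueError(f"unknown pool_type {pool_type!r}")
    return pools


def primary_connect(sources, targets, spec: PrimaryRuleSpec,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw primary connections; returns (source_ids, target_ids) arrays."""
    sources = np.asarray(sources, dtype=np.int64)
    targets = np.asarray(targets, dtype=np.int64)
    n_s, n_t = len(sources), len(targets)
    src_out: list[np.ndarray] = []
    tgt_out: list[np.ndarray] = []

    if spec.rule == "pairwise_bernoulli":
        p = float(spec.p_primary)
        for t in targets:
            mask = rng.random(n_s) < p
            if not spec.allow_autapses:
                mask &= sources != t
            chosen = sources[mask]
            src_out.append(chosen)
            tgt_out.append(np.full(len(chosen), t, dtype=np.int64))
    elif spec.rule == "fixed_in_degree":
        for t in targets:
            cand = sources if spec.allow_autapses else sources[sources != t]
            if not spec.allow_multapses and spec.K_in > len(cand):
                raise ValueError(
                    f"K_in={spec.K_in} infeasible without multapses "
                    f"({len(cand)} admissible sources)")
            chosen = rng.choice(cand, size=spec.K_in,
                                replace=spec.allow_multapses)
            src_out.append(np.sort(chosen))
            tgt_out.append(np.full(spec.K_in, t, dtype=np.int64))
    elif spec.rule == "fixed_out_degree":
        for s in sources:
            cand = targets if spec.allow_autapses else targets[targets != s]
            if not spec.allow_multapses and spec.K_out > len(cand):
                raise ValueError(
                    f"K_out={spec.K_out} infeasible without multapses "
                    f"({len(cand)} admissible targets)")
            chosen = rng.choice(cand, size=spec.K_out,
                                replace=spec.allow_multapses)
            src_out.append(np.full(spec.K_out, s, dtype=np.int64))
            tgt_out.append(np.sort(chosen))
    elif spec.rule == "fixed_total_number":
        pairs: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        n_admissible = n_s * n_t
        if not spec.allow_autapses:
            n_admissible -= len(np.intersect1d(sources, targets))
        if not spec.allow_multapses and spec.N_total > n_admissible:
            raise ValueError(
                f"N_total={spec.N_total} infeasible without multapses "
                f"({n_admissible} admissible pairs)")
        while len(pairs) < spec.N_total:
            s = int(sources[rng.integers(n_s)])
            t = int(targets[rng.integers(n_t)])
            if not spec.allow_autapses and s == t:
                continue
            if not spec.allow_multapses:
                if (s, t) in seen:
                    continue
                seen.add((s, t))
            pairs.append((s, t))
        if pairs:
            arr = np.array(pairs, dtype=np.int64)
            src_out.append(arr[:, 0])
            tgt_out.append(arr[:, 1])

    if src_out:
        return np.concatenate(src_out), np.concatenate(tgt_out)
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)


def tbp_connect(primary_edges: pd.DataFrame, pools: dict[int, list[int]],
                third_spec: ThirdFactorSpec,
                syn_specs: dict[str, SynSpec],
                rng: np.random.Generator) -> NetworkGraph:
    """Apply the TBP rule to a table of primary connections.

    ``primary_edges`` must have columns (source, target, weight, delay,
    kind); rows with ``kind == "exc"`` (excitatory source) are eligible
    for astrocyte attachment.  ``syn_specs`` supplies the ``third_in``
    and ``third_out`` weight/delay.  Returns the full
    :class:`NetworkGraph`; one third_in/third_out edge pair is appended
    per attachment event, duplicates included.
    """
    eligible = primary_edges[primary_edges["kind"] == "exc"]
    tgts = eligible["target"].to_numpy(dtype=np.int64)
    srcs = eligible["source"].to_numpy(dtype=np.int64)
    missing = [int(t) for t in np.unique(tgts) if t not in pools or not pools[int(t)]]
    if missing:
        raise ValueError(f"empty or missing astrocyte pool for targets {missing[:5]}")

    attach = rng.random(len(eligible)) < third_spec.p_third_if_primary
    u = rng.random(int(attach.sum()))
    a_src = srcs[attach]
    a_tgt = tgts[attach]
    astro = np.empty(len(a_tgt), dtype=np.int64)
    for i in range(len(a_tgt)):
        pool = pools[int(a_tgt[i])]
        astro[i] = pool[int(u[i] * len(pool))]

    ti = syn_specs["third_in"]
    to = syn_specs["third_out"]
    third_in = pd.DataFrame({
        "source": a_src, "astrocyte": astro,
        "weight": np.full(len(a_src), ti.weight),
        "delay": np.full(len(a_src), ti.delay)})
    third_out = pd.DataFrame({
        "astrocyte": astro, "target": a_tgt,
        "weight": np.full(len(a_src), to.weight),
        "delay": np.full(len(a_src), to.delay)})
    return NetworkGraph(primary_edges=primary_edges, third_in_edges=third_in,
                        third_out_edges=third_out, pools=pools)
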