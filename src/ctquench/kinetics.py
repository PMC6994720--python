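"""Coarse-grained excitation-quenching kinetics of the LHCII monomer.

The model lumps the eight Chl-a Q_y excitations into three transient
states — a pool of six chlorophylls, Chl a612 (site L1) and Chl a603
(site L2) — coupled by fast excitation exchange, plus the two
charge-transfer states Lut1⁺a612⁻ and Lut2⁺a603⁻ reachable by Marcus
charge separation from their partner chlorophyll.  Three absorbing sinks
terminate the excitation: intrinsic chlorophyll decay, and charge
recombination out of each CT state.

The master equation dp/dt = K·p is linear, so the mean excitation
lifetime has the closed form τ = 1ᵀ(−K)⁻¹p₀ and the fraction of
excitation leaving through each sink is the corresponding sink-rate row
applied to (−K)⁻¹p₀.  Matrix-exponential propagation and a stochastic
jump (Gillespie) simulator are provided as independent oracles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .constants import ROOM_T, thermal_energy
from .marcus import MarcusParams, detailed_balance_reverse, marcus_rate

__all__ = [
    "KineticNetwork",
    "LifetimeResult",
    "build_network",
    "pre_equilibrium_network",
    "mean_lifetime",
    "survival_curve",
    "dg_scan",
    "crossing_dg",
    "simulate_jump",
    "stationary_distribution",
    "STATE_LABELS",
    "SINK_LABELS",
    "POOL_QY_ENERGY",
    "POOL_DEGENERACY",
]

STATE_LABELS = ("pool", "a612", "a603", "CT1", "CT2")
SINK_LABELS = ("intrinsic", "rec_CT1", "rec_CT2")

#: Default Q_y free energy (cm⁻¹) of the lumped chlorophyll manifold: the
#: mean of the a612/a603 ensemble means.  The a612/a603 split (39 cm⁻¹) is
#: below both k_BT and the sampling uncertainty of the means, so the
#: default network treats the whole Q_y manifold as degenerate.
POOL_QY_ENERGY = 15567.5
POOL_DEGENERACY = 6


@dataclass
class KineticNetwork:
    """Labeled first-order network with transient states and absorbing sinks.

    ``rates[i, j]`` is the transition rate j→i between transient states,
    in ns⁻¹; ``sink_rates[s, j]`` the rate from transient j into sink s.
    ``free_energies`` are *effective* per-state free energies in cm⁻¹,
    with any state degeneracy absorbed as −k_BT·ln g, so detailed balance
    reads k_ij/k_ji = exp(−(G_i−G_j)/k_BT) on every reversible edge.
    """

    states: tuple[str, ...]
    sinks: tuple[str, ...]
    rates: np.ndarray
    sink_rates: np.ndarray
    p0: np.ndarray
    free_energies: np.ndarray | None = None
    temperature: float = ROOM_T

    def __post_init__(self) -> None:
        n = len(self.states)
        self.rates = np.asarray(self.rates, dtype=float)
        self.sink_rates = np.asarray(self.sink_rates, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.rates.shape != (n, n):
            raise ValueError("rates must be (n_states, n_states)")
        if self.sink_rates.shape != (len(self.sinks), n):
            raise ValueError("sink_rates must be (n_sinks, n_states)")
        off = self.rates[~np.eye(n, dtype=bool)]
        if np.any(off < 0) or np.any(self.sink_rates < 0):
            raise ValueError("transition rates must be non-negative")
        if np.any(self.p0 < 0) or abs(self.p0.sum() - 1.0) > 1e-10:
            raise ValueError("p0 must be a probability vector")

    @property
    def generator(self) -> np.ndarray:
        """Transient-block generator K (ns⁻¹): dp/dt = K p.

        Diagonal entries balance all outflow, including flow into sinks,
        so the full (states + sinks) generator has zero column sums.
        """
        K = self.rates.copy()
        np.fill_diagonal(K, 0.0)
        out = K.sum(axis=0) + self.sink_rates.sum(axis=0)
        K[np.diag_indices_from(K)] = -out
        return K

    @property
    def full_generator(self) -> np.ndarray:
        """Generator over transients + sinks (sinks absorbing)."""
        n, s = len(self.states), len(self.sinks)
        G = np.zeros((n + s, n + s))
        G[:n, :n] = self.generator
        G[n:, :n] = self.sink_rates
        return G


@dataclass
class LifetimeResult:
    """Mean excitation lifetime and channel-resolved quenched fractions."""

    tau_ps: float
    fractions: dict[str, float]
    occupancy_ns: dict[str, float] = field(default_factory=dict)

    def fraction(self, sink: str) -> float:
        return self.fractions[sink]


def build_network(
    k_cs1: float,
    k_cs2: float,
    dg1: float,
    dg2: float,
    recombination_time_ps: float = 10.0,
    intrinsic_time_ns: float = 4.0,
    exchange_time_ps: float = 5.0,
    temperature: float = ROOM_T,
    qy_energies: dict[str, float] | None = None,
) -> KineticNetwork:
    """Assemble the five-state quenching network.

    Parameters
    ----------
    k_cs1, k_cs2 : float
        Marcus charge-separation rates (ns⁻¹) a612→CT1 and a603→CT2.
    dg1, dg2 : float
        Driving forces (cm⁻¹) of the two charge separations; the reverse
        rates follow from detailed balance.
    recombination_time_ps : float
        CT recombination time to the ground/dark-state sink (default 10 ps).
    intrinsic_time_ns : float
        Unquenched chlorophyll excited-state lifetime (default 4 ns).
    exchange_time_ps : float
        Elementary pool→Chl excitation-exchange time (default 5 ps; the
        results are insensitive in the fast-exchange regime).
    qy_energies : dict, optional
        Q_y free energies (cm⁻¹) for "pool", "a612", "a603"; defaults to a
        degenerate manifold at ``POOL_QY_ENERGY``.

    The initial excitation is equally partitioned over the eight
    chlorophylls: p₀ = (6/8, 1/8, 1/8, 0, 0).
    """
    for name, val in {
        "k_cs1": k_cs1,
        "k_cs2": k_cs2,
        "recombination_time_ps": recombination_time_ps,
        "intrinsic_time_ns": intrinsic_time_ns,
        "exchange_time_ps": exchange_time_ps,
    }.items():
        if val <= 0 and name.startswith("k_") is False:
            raise ValueError(f"{name} must be positive")
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    kbt = thermal_energy(temperature)
    qy = {"pool": POOL_QY_ENERGY, "a612": POOL_QY_ENERGY, "a603": POOL_QY_ENERGY}
    if qy_energies:
        qy.update(qy_energies)

    # effective free energies (degeneracy absorbed for the pool)
    g_eff = np.array(
        [
            qy["pool"] - kbt * math.log(POOL_DEGENERACY),
            qy["a612"],
            qy["a603"],
            qy["a612"] + dg1,
            qy["a603"] + dg2,
        ]
    )

    k_ex = 1e3 / exchange_time_ps  # ns⁻¹
    rates = np.zeros((5, 5))
    # pool -> a612/a603 at the elementary exchange rate; reverse by DB
    for i in (1, 2):
        rates[i, 0] = k_ex
        rates[0, i] = k_ex * math.exp(-(g_eff[0] - g_eff[i]) / kbt)
    # charge separation, reverse by detailed balance
    rates[3, 1] = k_cs1
    rates[1, 3] = detailed_balance_reverse(k_cs1, dg1, temperature)
    rates[4, 2] = k_cs2
    rates[2, 4] = detailed_balance_reverse(k_cs2, dg2, temperature)

    sink_rates = np.zeros((3, 5))
    sink_rates[0, :3] = 1.0 / intrinsic_time_ns
    sink_rates[1, 3] = 1e3 / recombination_time_ps
    sink_rates[2, 4] = 1e3 / recombination_time_ps

    p0 = np.array([6.0, 1.0, 1.0, 0.0, 0.0]) / 8.0
    return KineticNetwork(
        states=STATE_LABELS,
        sinks=SINK_LABELS,
        rates=rates,
        sink_rates=sink_rates,
        p0=p0,
        free_energies=g_eff,
        temperature=temperature,
    )


def pre_equilibrium_network(
    k_cs1: float,
    k_cs2: float,
    dg1: float,
    dg2: float,
    recombination_time_ps: float = 10.0,
    intrinsic_time_ns: float = 4.0,
    temperature: float = ROOM_T,
    qy_energies: dict[str, float] | None = None,
) -> KineticNetwork:
    """Fast-exchange reduction: the Q_y manifold lumped into one state.

    The pool/a612/a603 states are replaced by a single equilibrated
    chlorophyll state; charge separation proceeds at the Boltzmann weight
    of the donor chlorophyll times its Marcus rate.  This is the
    analytical limit of :func:`build_network` as exchange_time → 0.
    """
    kbt = thermal_energy(temperature)
    qy = {"pool": POOL_QY_ENERGY, "a612": POOL_QY_ENERGY, "a603": POOL_QY_ENERGY}
    if qy_energies:
        qy.update(qy_energies)
    weights = np.array(
        [
            POOL_DEGENERACY * math.exp(-qy["pool"] / kbt),
            math.exp(-qy["a612"] / kbt),
            math.exp(-qy["a603"] / kbt),
        ]
    )
    weights = weights / weights.sum()
    g_chl = -kbt * math.log(
        POOL_DEGENERACY * math.exp(-qy["pool"] / kbt)
        + math.exp(-qy["a612"] / kbt)
        + math.exp(-qy["a603"] / kbt)
    )
    rates = np.zeros((3, 3))
    rates[1, 0] = weights[1] * k_cs1
    rates[0, 1] = detailed_balance_reverse(k_cs1, dg1, temperature)
    rates[2, 0] = weights[2] * k_cs2
    rates[0, 2] = detailed_balance_reverse(k_cs2, dg2, temperature)
    sink_rates = np.zeros((3, 3))
    sink_rates[0, 0] = 1.0 / intrinsic_time_ns
    sink_rates[1, 1] = 1e3 / recombination_time_ps
    sink_rates[2, 2] = 1e3 / recombination_time_ps
    return KineticNetwork(
        states=("chl_eq", "CT1", "CT2"),
        sinks=SINK_LABELS,
        rates=rates,
        sink_rates=sink_rates,
        p0=np.array([1.0, 0.0, 0.0]),
        free_energies=np.array([g_chl, qy["a612"] + dg1, qy["a603"] + dg2]),
        temperature=temperature,
    )


def _unreachable_states(net: KineticNetwork) -> list[str]:
    n = len(net.states)
    reaches = net.sink_rates.sum(axis=0) > 0
    changed = True
    while changed:
        changed = False
        for j in range(n):
            if reaches[j]:
                continue
            # j reaches a sink if it flows into any state that does
            if np.any((net.rates[:, j] > 0) & reaches):
                reaches[j] = True
                changed = True
    return [net.states[j] for j in range(n) if not reaches[j]]


def mean_lifetime(net: KineticNetwork) -> LifetimeResult:
    """Closed-form mean lifetime and per-sink quenched fractions.

    τ = 1ᵀ(−K)⁻¹p₀ (the time integral of total transient population,
    CT states included) reported in ps; fraction through sink s is
    r_s·(−K)⁻¹p₀ where r_s is the s-th sink-rate row.  The fractions sum
    to one for any network in which every state can reach a sink.
    """
    bad = _unreachable_states(net)
    if bad:
        raise ValueError(
            f"network does not decay: states {bad} cannot reach any sink"
        )
    occ = np.linalg.solve(-net.generator, net.p0)  # ns spent in each state
    fractions = net.sink_rates @ occ
    return LifetimeResult(
        tau_ps=float(occ.sum() * 1e3),
        fractions={s: float(f) for s, f in zip(net.sinks, fractions)},
        occupancy_ns={s: float(o) for s, o in zip(net.states, occ)},
    )


def survival_curve(net: KineticNetwork, times_ps: np.ndarray) -> pd.DataFrame:
    """Propagate dp/dt = Kp on a time grid; returns per-state populations.

    Columns: ``time_ps``, one per transient state, and ``total``.  The
    total is monotonically non-increasing; its trapezoid integral
    converges to the closed-form mean lifetime on a fine grid.
    """
    t = np.asarray(times_ps, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times_ps must be a non-empty 1-D grid")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times_ps must be non-negative and strictly increasing")
    K = net.generator
    rows = [expm(K * (ti * 1e-3)) @ net.p0 for ti in t]
    pops = np.vstack(rows)
    df = pd.DataFrame(pops, columns=list(net.states))
    df.insert(0, "time_ps", t)
    df["total"] = pops.sum(axis=1)
    return df


def dg_scan(
    dg1_values,
    marcus_l1: MarcusParams,
    k_cs2: float,
    dg2: float,
    **network_kwargs,
) -> pd.DataFrame:
    """Lifetime versus the L1 driving force.

    For each ΔG₁, the a612→CT1 rate is recomputed through the Marcus
    expression with the site's fixed V and λ, the reverse rate follows
    from detailed balance, and the network is re-solved.  Returns a table
    with columns ``dg1_cm1, k_cs1_ns, tau_ps, frac_CT1, frac_CT2``.
    """
    dg1_values = np.asarray(list(dg1_values), dtype=float)
    if dg1_values.size == 0:
        raise ValueError("empty scan list")
    records = []
    for dg1 in dg1_values:
        k1 = marcus_rate(marcus_l1.with_driving_force(float(dg1)))
        net = build_network(k1, k_cs2, float(dg1), dg2, **network_kwargs)
        res = mean_lifetime(net)
        records.append(
            {
                "dg1_cm1": float(dg1),
                "k_cs1_ns": k1,
                "tau_ps": res.tau_ps,
                "frac_CT1": res.fractions["rec_CT1"],
                "frac_CT2": res.fractions["rec_CT2"],
            }
        )
    return pd.DataFrame.from_records(records)


def crossing_dg(scan: pd.DataFrame, target_tau_ps: float) -> float | None:
    """ΔG₁ at which the scanned lifetime crosses a target, by linear interpolation.

    Returns None when the target is not bracketed by the scan.
    """
    tau = scan["tau_ps"].to_numpy()
    dg = scan["dg1_cm1"].to_numpy()
    for i in range(len(tau) - 1):
        lo, hi = sorted((tau[i], tau[i + 1]))
        if lo <= target_tau_ps <= hi and tau[i] != tau[i + 1]:
            w = (target_tau_ps - tau[i]) / (tau[i + 1] - tau[i])
            return float(dg[i] + w * (dg[i + 1] - dg[i]))
    return None


def stationary_distribution(net: KineticNetwork) -> np.ndarray:
    """Stationary distribution of the sink-free network (detailed-balance check).

    Ignores all sink rates and returns the null-space probability vector
    of the conservative generator built from the transient rates alone.
    """
    K = net.rates.copy()
    np.fill_diagonal(K, 0.0)
    K[np.diag_indices_from(K)] = -K.sum(axis=0)
    w, v = np.linalg.eig(K)
    i = int(np.argmin(np.abs(w)))
    p = np.real(v[:, i])
    p = np.abs(p)
    return p / p.sum()


def simulate_jump(
    net: KineticNetwork,
    n_trajectories: int,
    rng: np.random.Generator,
    max_steps: int = 1_000_000,
) -> dict:
    """Stochastic-jump (Gillespie) oracle for lifetime and sink fractions.

    Propagates all trajectories synchronously with vectorized draws.
    Returns mean absorption time (ps) with its standard error and the
    per-sink absorption fractions.
    """
    n, s = len(net.states), len(net.sinks)
    # per-state outgoing rate table: transitions to other transients, then sinks
    targets = np.zeros((n, n + s))
    for j in range(n):
        targets[j, :n] = net.rates[:, j]
        targets[j, j] = 0.0
        targets[j, n:] = net.sink_rates[:, j]
    total = targets.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("every state needs a positive total outgoing rate")
    cumprob = np.cumsum(targets / total[:, None], axis=1)

    state = rng.choice(n, size=n_trajectories, p=net.p0)
    t = np.zeros(n_trajectories)
    sink_hit = np.full(n_trajectories, -1, dtype=int)
    alive = np.arange(n_trajectories)
    for _ in range(max_steps):
        if alive.size == 0:
            break
        cur = state[alive]
        t[alive] += rng.exponential(1.0 / total[cur])
        u = rng.random(alive.size)
        nxt = (cumprob[cur] < u[:, None]).sum(axis=1)
        absorbed = nxt >= n
        sink_hit[alive[absorbed]] = nxt[absorbed] - n
        state[alive[~absorbed]] = nxt[~absorbed]
        alive = alive[~absorbed]
    else:
        raise RuntimeError("jump simulation did not absorb within max_steps")

    t_ps = t * 1e3
    frac = np.array([(sink_hit == k).mean() for k in range(s)])
    return {
        "tau_ps": float(t_ps.mean()),
        "tau_se_ps": float(t_ps.std(ddof=1) / math.sqrt(n_trajectories)),
        "fractions": {lbl: float(f) for lbl, f in zip(net.sinks, frac)},
        "n": int(n_trajectories),
    }
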