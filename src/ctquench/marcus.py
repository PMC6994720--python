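"""Marcus charge-separation parameters and rates from fluctuating energies.

Within linear response, an ensemble of vertical excitation energies sampled
along a trajectory determines both the adiabatic free energy of each
electronic state and the reorganization energy of a radiationless transition
between two states:

* adiabatic free energy of state X:  G_X = ⟨E_X⟩ − σ_X² / (2 k_B T)
* reorganization energy:             λ    = σ_ΔE² / (2 k_B T)

where σ² is the (unbiased) sample variance and ΔE the per-snapshot energy
gap between the two states.  The driving force of charge separation is the
difference of adiabatic free energies ΔG = G_CT − G_LE (negative = downhill),
and the nonadiabatic rate follows the classical Marcus expression

    k = (2π/ħ) · V² · (4π λ k_B T)^(−1/2) · exp(−(ΔG + λ)² / (4 λ k_B T))

evaluated consistently in wavenumber units and reported in ns⁻¹.  The
electronic coupling V enters as the ensemble root-mean-square (Condon
approximation over the ensemble).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import ROOM_T, HBAR_CM_S, thermal_energy

__all__ = [
    "StateEnsemble",
    "MarcusParams",
    "EnsembleSummary",
    "adiabatic_energy",
    "reorganization_energy",
    "driving_force",
    "marcus_rate",
    "detailed_balance_reverse",
    "summarize_ensemble",
    "STATE_LE",
    "STATE_LUT",
    "STATE_CT",
    "STATE_CT_REV",
    "PAIR_LE_LUT",
    "PAIR_LE_CT",
]

# Canonical state labels for a Lut/Chl-a dimer.
STATE_LE = "Chl* Qy"          # locally excited chlorophyll, lowest bright state
STATE_LUT = "Lut* S2"         # bright carotenoid state
STATE_CT = "Lut+Chl-"         # lowest charge-transfer state (electron Lut -> Chl)
STATE_CT_REV = "Lut-Chl+"     # reverse charge-transfer state

PAIR_LE_LUT = "Chl*/Lut*"
PAIR_LE_CT = "Chl*/Lut+Chl-"


@dataclass
class StateEnsemble:
    """Per-snapshot vertical energies of one electronic state of one dimer.

    Parameters
    ----------
    state : str
        Electronic-state label (one of the module-level ``STATE_*`` labels
        for the standard pipeline, but any string is accepted).
    energies : ndarray
        Vertical energies in cm⁻¹, one per snapshot.
    blocks : ndarray
        Integer block (monomer) label per snapshot.
    site : str
        Binding-site label, e.g. ``"L1"``.
    temperature : float
        Temperature in kelvin at which the ensemble was sampled.
    """

    state: str
    energies: np.ndarray
    blocks: np.ndarray | None = None
    site: str = ""
    temperature: float = ROOM_T

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 1:
            raise ValueError("energies must be one-dimensional")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("all energies must be finite")
        if self.blocks is None:
            self.blocks = np.zeros(self.energies.size, dtype=int)
        else:
            self.blocks = np.asarray(self.blocks, dtype=int)
            if self.blocks.shape != self.energies.shape:
                raise ValueError("blocks must align with energies")

    @property
    def n(self) -> int:
        return int(self.energies.size)

    def mean(self) -> float:
        return float(np.mean(self.energies))

    def ci95(self) -> float:
        """95% confidence half-width of the mean (normal approximation)."""
        if self.n < 2:
            raise ValueError("need at least 2 samples for a confidence interval")
        return float(1.96 * np.std(self.energies, ddof=1) / math.sqrt(self.n))


@dataclass(frozen=True)
class MarcusParams:
    """Inputs of the classical Marcus rate.

    coupling : V, electronic coupling in cm⁻¹ (RMS over the ensemble)
    reorganization : λ in cm⁻¹
    driving_force : ΔG = G_CT − G_LE in cm⁻¹ (negative = downhill)
    temperature : kelvin
    """

    coupling: float
    reorganization: float
    driving_force: float
    temperature: float = ROOM_T

    def __post_init__(self) -> None:
        if self.reorganization <= 0:
            raise ValueError(
                f"reorganization energy must be positive, got {self.reorganization}"
            )
        if self.coupling < 0:
            raise ValueError("coupling is an RMS and must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def with_driving_force(self, dg: float) -> "MarcusParams":
        return replace(self, driving_force=dg)


def adiabatic_energy(ensemble: StateEnsemble) -> float:
    """Adiabatic free energy G_X = ⟨E_X⟩ − σ_X²/(2 k_B T) of a state, in cm⁻¹.

    The second term converts the vertical-energy average into the free
    energy of the state minimum, assuming Gaussian energy fluctuations
    (linear response).  Uses the unbiased (n−1) sample variance.
    """
    if ensemble.n < 2:
        raise ValueError("adiabatic energy needs >= 2 samples (variance undefined)")
    var = float(np.var(ensemble.energies, ddof=1))
    return ensemble.mean() - var / (2.0 * thermal_energy(ensemble.temperature))


def reorganization_energy(gap_samples: np.ndarray, temperature: float = ROOM_T) -> float:
    """Reorganization energy λ = σ_ΔE²/(2 k_B T) from energy-gap samples.

    ``gap_samples`` are per-snapshot energy differences (cm⁻¹) between the
    two states of the radiationless transition, paired snapshot by snapshot.
    """
    gap = np.asarray(gap_samples, dtype=float)
    if gap.ndim != 1 or gap.size < 2:
        raise ValueError("need >= 2 paired gap samples")
    return float(np.var(gap, ddof=1)) / (2.0 * thermal_energy(temperature))


def driving_force(g_ct: float, g_le: float) -> float:
    """ΔG = G_CT − G_LE (cm⁻¹); negative means charge separation is downhill."""
    return float(g_ct) - float(g_le)


def marcus_rate(p: MarcusParams) -> float:
    """Classical Marcus charge-separation rate in ns⁻¹.

    k = (2π/ħ)·V²·(4πλk_BT)^(−1/2)·exp(−(ΔG+λ)²/(4λk_BT)), with V, λ, ΔG in
    cm⁻¹ and ħ in cm⁻¹·s, giving k in s⁻¹; the result is returned in ns⁻¹.
    """
    kbt = thermal_energy(p.temperature)
    lam = p.reorganization
    prefactor = 2.0 * math.pi / HBAR_CM_S * p.coupling**2 / math.sqrt(
        4.0 * math.pi * lam * kbt
    )
    activation = (p.driving_force + lam) ** 2 / (4.0 * lam * kbt)
    return prefactor * math.exp(-activation) * 1e-9


def detailed_balance_reverse(
    k_forward: float, dg: float, temperature: float = ROOM_T
) -> float:
    """Reverse rate fixed by detailed balance: k_r = k_f · exp(ΔG/k_BT).

    With ΔG the free-energy drop of the *forward* step (product minus
    reactant), this guarantees k_f/k_r = exp(−ΔG/k_BT) so a closed two-state
    system relaxes to the Boltzmann distribution.
    """
    if k_forward < 0:
        raise ValueError("forward rate must be non-negative")
    return k_forward * math.exp(dg / thermal_energy(temperature))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def _rms_ci95(x: np.ndarray) -> float:
    # Delta method on the mean square: Var(RMS) ≈ Var(V²)/(4·RMS²).
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    ms = float(np.mean(np.square(x)))
    if ms == 0.0:
        return 0.0
    var_ms = float(np.var(np.square(x), ddof=1)) / x.size
    return 1.96 * math.sqrt(var_ms / (4.0 * ms))


@dataclass
class EnsembleSummary:
    """One-site summary: ensemble statistics, Marcus parameters and rate.

    Energy means carry 95% CIs (normal approximation, 1.96·s/√n); coupling
    averages are root-mean-square values.  ``to_frame`` renders the summary
    as a tidy table with one row per quantity.
    """

    site: str
    n: int
    temperature: float
    energy_mean: dict[str, float] = field(default_factory=dict)
    energy_ci95: dict[str, float] = field(default_factory=dict)
    coupling_rms: dict[str, float] = field(default_factory=dict)
    coupling_ci95: dict[str, float] = field(default_factory=dict)
    adiabatic: dict[str, float] = field(default_factory=dict)
    reorganization: float = float("nan")
    driving_force: float = float("nan")
    rate_ns: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows: list[tuple[str, float, float]] = []
        for state, mean in self.energy_mean.items():
            rows.append((f"E({state})", mean, self.energy_ci95[state]))
        for pair, rms in self.coupling_rms.items():
            rows.append((f"V({pair})", rms, self.coupling_ci95[pair]))
        rows.append(("lambda_CT-LE", self.reorganization, float("nan")))
        rows.append(("dG_CT-LE", self.driving_force, float("nan")))
        rows.append(("k_CS (1/ns)", self.rate_ns, float("nan")))
        df = pd.DataFrame(rows, columns=["parameter", "value", "ci95"])
        df.insert(0, "site", self.site)
        return df

    @property
    def marcus_params(self) -> MarcusParams:
        return MarcusParams(
            coupling=self.coupling_rms[PAIR_LE_CT],
            reorganization=self.reorganization,
            driving_force=self.driving_force,
            temperature=self.temperature,
        )


def summarize_ensemble(
    ensembles: dict[str, StateEnsemble] | list[StateEnsemble],
    couplings: dict[str, np.ndarray],
    temperature: float = ROOM_T,
) -> EnsembleSummary:
    """Assemble the full one-site summary from state and coupling ensembles.

    Parameters
    ----------
    ensembles
        State ensembles keyed (or labeled) by state; must contain the
        locally excited state ``STATE_LE`` and the charge-transfer state
        ``STATE_CT`` with identical snapshot counts (they are paired to form
        the energy gap for λ).
    couplings
        Signed coupling samples (cm⁻¹) keyed by pair label.
    """
    if isinstance(ensembles, list):
        ensembles = {e.state: e for e in ensembles}
    if not ensembles:
        raise ValueError("no state ensembles given")
    if not couplings:
        raise ValueError("no coupling samples given")
    for key in (STATE_LE, STATE_CT):
        if key not in ensembles:
            raise ValueError(f"missing required state ensemble {key!r}")
    le, ct = ensembles[STATE_LE], ensembles[STATE_CT]
    if le.n != ct.n:
        raise ValueError(
            f"LE and CT ensembles must be paired snapshot-by-snapshot "
            f"(got {le.n} vs {ct.n} samples)"
        )
    if PAIR_LE_CT not in couplings:
        raise ValueError(f"missing coupling samples for pair {PAIR_LE_CT!r}")

    site = le.site
    summary = EnsembleSummary(site=site, n=le.n, temperature=temperature)
    for state, ens in ensembles.items():
        summary.energy_mean[state] = ens.mean()
        summary.energy_ci95[state] = ens.ci95()
        summary.adiabatic[state] = adiabatic_energy(
            replace_temperature(ens, temperature)
        )
    for pair, samples in couplings.items():
        arr = np.asarray(samples, dtype=float)
        if arr.size == 0:
            raise ValueError(f"empty coupling sample set for {pair!r}")
        summary.coupling_rms[pair] = _rms(arr)
        summary.coupling_ci95[pair] = _rms_ci95(arr)

    gap = ct.energies - le.energies
    summary.reorganization = reorganization_energy(gap, temperature)
    summary.driving_force = driving_force(
        summary.adiabatic[STATE_CT], summary.adiabatic[STATE_LE]
    )
    summary.rate_ns = marcus_rate(summary.marcus_params)
    return summary


def replace_temperature(ens: StateEnsemble, temperature: float) -> StateEnsemble:
    if ens.temperature == temperature:
        return ens
    return StateEnsemble(
        state=ens.state,
        energies=ens.energies,
        blocks=ens.blocks,
        site=ens.site,
        temperature=temperature,
    )
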