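"""Synthetic ensembles and structures emulating the LHCII charge-transfer study.

No trajectory or quantum-chemistry data ship with this package, so every
downstream stage is exercised on synthetic data with the same statistical
and geometric structure the analysis assumes:

* per-snapshot vertical energies of the four electronic states of a
  Lut/Chl-a dimer (Chl* Q_y, Lut* S₂, Lut⁺Chl⁻, Lut⁻Chl⁺), drawn from a
  correlated multivariate normal whose defaults are calibrated so that the
  fluctuation-based estimators recover the reference reorganization
  energies (5405 / 5052 cm⁻¹) and driving forces (−82 / +951 cm⁻¹) of the
  L1 and L2 sites;
* signed electronic-coupling samples with prescribed RMS;
* idealized dimer geometries (planar macrocycle proxy + polyene chain)
  with exactly constructed bond-length alternation, for the descriptor
  stage;
* descriptor tables with controlled variance shares for the regression
  stage.

All generators are driven by `numpy.random.default_rng` seeded from the
spec, so identical specs give bitwise-identical output.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import ROOM_T, thermal_energy
from .descriptors import CT_COLUMN, DimerStructure
from .marcus import (
    PAIR_LE_CT,
    PAIR_LE_LUT,
    STATE_CT,
    STATE_CT_REV,
    STATE_LE,
    STATE_LUT,
    StateEnsemble,
)

__all__ = [
    "EnsembleSpec",
    "StructureSpec",
    "REFERENCE_STATS",
    "REFERENCE_N",
    "default_ensemble_spec",
    "calibrated_spreads",
    "generate_state_ensemble",
    "generate_coupling_samples",
    "generate_dimer_structure",
    "generate_descriptor_dataset",
    "STATE_ORDER",
]

STATE_ORDER: tuple[str, ...] = (STATE_LE, STATE_LUT, STATE_CT, STATE_CT_REV)

# Reference per-site ensemble statistics the defaults are calibrated to
# (energies/couplings in cm⁻¹; CIs are 95% half-widths of the mean at the
# reference sample size below; couplings are RMS values).
REFERENCE_N = 240
REFERENCE_BLOCKS = 3
REFERENCE_STATS: dict[str, dict] = {
    "L1": {
        "means": {
            STATE_LE: 15587.0,
            STATE_LUT: 21114.0,
            STATE_CT: 20255.0,
            STATE_CT_REV: 26027.0,
        },
        "ci95": {STATE_LE: 72.0, STATE_LUT: 137.0, STATE_CT: 193.0, STATE_CT_REV: 185.0},
        "coupling_rms": {PAIR_LE_LUT: 88.0, PAIR_LE_CT: 240.0},
        "reorganization": 5405.0,
        "driving_force": -82.0,
        "rate_ns": 34.0,
    },
    "L2": {
        "means": {
            STATE_LE: 15548.0,
            STATE_LUT: 20700.0,
            STATE_CT: 21067.0,
            STATE_CT_REV: 25214.0,
        },
        "ci95": {STATE_LE: 74.0, STATE_LUT: 135.0, STATE_CT: 191.0, STATE_CT_REV: 173.0},
        "coupling_rms": {PAIR_LE_LUT: 176.0, PAIR_LE_CT: 279.0},
        "reorganization": 5052.0,
        "driving_force": 951.0,
        "rate_ns": 4.9,
    },
}

# Independent substreams of the spec seed, one per generator.
_STREAM_ENERGIES = 0
_STREAM_COUPLINGS = 1
_STREAM_STRUCTURE = 2
_STREAM_DESCRIPTORS = 3


@dataclass
class EnsembleSpec:
    """Statistical specification of one site's synthetic ensembles.

    ``correlations`` maps unordered state-label pairs to fluctuation
    correlation coefficients; unlisted pairs are uncorrelated.
    ``coupling_fluctuates=False`` freezes couplings at their RMS value
    (useful for degenerate-case tests).
    """

    site: str
    means: dict[str, float]
    sigmas: dict[str, float]
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    coupling_rms: dict[str, float] = field(default_factory=dict)
    n_snapshots: int = REFERENCE_N
    n_blocks: int = REFERENCE_BLOCKS
    seed: int = 0
    temperature: float = ROOM_T
    coupling_fluctuates: bool = True

    def __post_init__(self) -> None:
        if self.site not in ("L1", "L2"):
            raise ValueError(f"site must be 'L1' or 'L2', got {self.site!r}")
        if self.n_snapshots < 2:
            raise ValueError("n_snapshots must be >= 2")
        if self.n_blocks < 1 or self.n_snapshots % self.n_blocks:
            raise ValueError("n_snapshots must be divisible by n_blocks")
        for state in STATE_ORDER:
            if state not in self.means or state not in self.sigmas:
                raise ValueError(f"missing mean/sigma for state {state!r}")
            if self.sigmas[state] < 0:
                raise ValueError(f"sigma for {state!r} must be >= 0")
        for (a, b), rho in self.correlations.items():
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"correlation for ({a}, {b}) outside [-1, 1]")
        for pair, rms in self.coupling_rms.items():
            if rms < 0:
                raise ValueError(f"coupling RMS for {pair!r} must be >= 0")
        # fail fast on a non-PSD correlation matrix
        self.correlation_matrix()

    def correlation_matrix(self) -> np.ndarray:
        """4×4 fluctuation correlation matrix in ``STATE_ORDER``; PSD-checked."""
        idx = {s: i for i, s in enumerate(STATE_ORDER)}
        corr = np.eye(len(STATE_ORDER))
        for (a, b), rho in self.correlations.items():
            if a not in idx or b not in idx:
                raise ValueError(f"unknown state in correlation key ({a}, {b})")
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {eigmin:.3e}); adjust the correlations"
            )
        return corr


def calibrated_spreads(
    mean_le: float,
    mean_ct: float,
    driving_force: float,
    reorganization: float,
    temperature: float = ROOM_T,
    sigma_ratio: float = 2.0,
) -> tuple[float, float, float]:
    """Solve (σ_LE, σ_CT, ρ) so the fluctuation estimators hit their targets.

    Two population constraints pin the spreads of the LE/CT pair given the
    σ_CT = ratio·σ_LE convention (CT states couple more strongly to the
    environment, hence the default 1:2 ratio):

    * driving force:  ΔG = (μ_CT − μ_LE) − (σ_CT² − σ_LE²)/(2 k_B T)
    * reorganization: λ·2k_BT = σ_LE² + σ_CT² − 2ρσ_LEσ_CT

    Returns (σ_LE, σ_CT, ρ) in cm⁻¹ / dimensionless.
    """
    if sigma_ratio <= 1.0:
        raise ValueError("sigma_ratio must exceed 1")
    two_kbt = 2.0 * thermal_energy(temperature)
    diff = (mean_ct - mean_le - driving_force) * two_kbt  # σ_CT² − σ_LE²
    if diff <= 0:
        raise ValueError("targets imply σ_CT <= σ_LE; not representable")
    var_le = diff / (sigma_ratio**2 - 1.0)
    var_ct = sigma_ratio**2 * var_le
    rho = (var_le + var_ct - reorganization * two_kbt) / (
        2.0 * math.sqrt(var_le * var_ct)
    )
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"calibration needs |rho| < 1, got {rho:.3f}")
    return math.sqrt(var_le), math.sqrt(var_ct), rho


def default_ensemble_spec(
    site: str,
    n_snapshots: int = REFERENCE_N,
    seed: int = 0,
    temperature: float = ROOM_T,
) -> EnsembleSpec:
    """Calibrated default spec for site ``"L1"`` or ``"L2"``.

    LE/CT spreads and their correlation come from :func:`calibrated_spreads`
    so that λ and ΔG estimators recover the reference values in population;
    the spreads of the two remaining states are back-solved from the
    reference 95% CIs of their means (σ = CI·√n/1.96 at the reference n).
    """
    if site not in REFERENCE_STATS:
        raise ValueError(f"unknown site {site!r}")
    ref = REFERENCE_STATS[site]
    s_le, s_ct, rho = calibrated_spreads(
        ref["means"][STATE_LE],
        ref["means"][STATE_CT],
        ref["driving_force"],
        ref["reorganization"],
        temperature=temperature,
    )
    ci_sigma = lambda ci: ci * math.sqrt(REFERENCE_N) / 1.96  # noqa: E731
    sigmas = {
        STATE_LE: s_le,
        STATE_CT: s_ct,
        STATE_LUT: ci_sigma(ref["ci95"][STATE_LUT]),
        STATE_CT_REV: ci_sigma(ref["ci95"][STATE_CT_REV]),
    }
    return EnsembleSpec(
        site=site,
        means=dict(ref["means"]),
        sigmas=sigmas,
        correlations={(STATE_LE, STATE_CT): rho},
        coupling_rms=dict(ref["coupling_rms"]),
        n_snapshots=n_snapshots,
        seed=seed,
        temperature=temperature,
    )


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    return np.arange(n) * n_blocks // n


def generate_state_ensemble(spec: EnsembleSpec) -> dict[str, StateEnsemble]:
    """Draw correlated per-snapshot energies for all four states of a site.

    Samples come from a multivariate normal with the spec means, spreads
    and correlations; each snapshot is tagged with its (statistically
    identical) monomer block.  Identical specs yield identical samples.
    """
    corr = spec.correlation_matrix()
    sig = np.array([spec.sigmas[s] for s in STATE_ORDER])
    mu = np.array([spec.means[s] for s in STATE_ORDER])
    cov = corr * np.outer(sig, sig)
    # eigen transform instead of Cholesky: tolerates zero spreads
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng([spec.seed, _STREAM_ENERGIES])
    z = rng.standard_normal((spec.n_snapshots, len(STATE_ORDER)))
    samples = mu + z @ root.T
    blocks = _block_labels(spec.n_snapshots, spec.n_blocks)
    return {
        state: StateEnsemble(
            state=state,
            energies=samples[:, i],
            blocks=blocks,
            site=spec.site,
            temperature=spec.temperature,
        )
        for i, state in enumerate(STATE_ORDER)
    }


def generate_coupling_samples(spec: EnsembleSpec) -> dict[str, np.ndarray]:
    """Signed coupling samples (cm⁻¹) per pair, with the spec target RMS.

    Couplings are drawn zero-mean Gaussian with scale equal to the target
    RMS (sign fluctuates; only the magnitude is physical), or held constant
    at the RMS when ``spec.coupling_fluctuates`` is false.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_COUPLINGS])
    out: dict[str, np.ndarray] = {}
    for pair, rms in spec.coupling_rms.items():
        if spec.coupling_fluctuates:
            out[pair] = rng.normal(0.0, rms, spec.n_snapshots)
        else:
            out[pair] = np.full(spec.n_snapshots, rms)
    return out


# ---------------------------------------------------------------------------
# structures


@dataclass
class StructureSpec:
    """Geometric specification of an idealized Chl/Lut dimer proxy.

    The chlorin is a planar macrocycle proxy: a closed ring of
    ``ring_atoms`` carbons with alternating
    single/double bonds whose chord lengths are solved so the ring BLA
    equals ``chl_bla`` exactly.  The lutein is a planar zigzag polyene of
    ``polyene_bonds`` conjugated bonds split into two conjugation paths
    with independent BLA targets, built from ideal 1.40 ± BLA/2 Å bonds.
    The chain is placed at ``displacement`` (Å) from the ring center, in
    the ring frame; ``jitter`` adds isotropic Gaussian coordinate noise
    after the exact construction.
    """

    polyene_bonds: int = 18
    chl_bla: float = 0.045
    lut_bla_a: float = 0.10
    lut_bla_b: float = 0.10
    ring_atoms: int = 16
    ring_radius: float = 3.59
    displacement: tuple[float, float, float] = (0.5, 0.0, 3.0)
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polyene_bonds < 3:
            raise ValueError("polyene needs at least 3 conjugated bonds")
        if self.ring_atoms < 6 or self.ring_atoms % 2:
            raise ValueError("ring_atoms must be an even number >= 6")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        for name in ("chl_bla", "lut_bla_a", "lut_bla_b"):
            t = getattr(self, name)
            if not (-0.2 <= t <= 0.2):
                raise ValueError(f"{name} outside the physical range [-0.2, 0.2] Å")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")

    @property
    def bla_targets(self) -> dict[str, float]:
        return {
            "chl_a": self.chl_bla,
            "chl_b": self.chl_bla,
            "lut_a": self.lut_bla_a,
            "lut_b": self.lut_bla_b,
        }


_MEAN_BOND = 1.40  # Å, mean conjugated C–C bond
_ZIGZAG_DEG = 30.0  # half-angle of the polyene zigzag


def _ring_coordinates(n_atoms: int, radius: float, target_bla: float) -> np.ndarray:
    """Planar ring with alternating chords achieving the target BLA exactly."""
    m = n_atoms // 2
    base = math.pi / m  # equal angular step

    def f(delta: float) -> float:
        ds = 2 * radius * math.sin((base + delta) / 2)
        dd = 2 * radius * math.sin((base - delta) / 2)
        return ds - dd - target_bla

    hi = base - 1e-9
    delta = brentq(f, -hi, hi, xtol=1e-14)
    steps = np.empty(n_atoms)
    steps[0::2] = base - delta  # double bonds: shorter chords
    steps[1::2] = base + delta  # single bonds
    angles = np.concatenate([[0.0], np.cumsum(steps[:-1])])
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_atoms)]
    )


def _chain_coordinates(bond_lengths: np.ndarray) -> np.ndarray:
    """Planar zigzag chain with the given bond lengths, centered at origin."""
    alpha = math.radians(_ZIGZAG_DEG)
    n = len(bond_lengths)
    dirs = np.column_stack(
        [
            np.full(n, math.cos(alpha)),
            np.where(np.arange(n) % 2 == 0, math.sin(alpha), -math.sin(alpha)),
            np.zeros(n),
        ]
    )
    pos = np.vstack([np.zeros(3), np.cumsum(dirs * bond_lengths[:, None], axis=0)])
    return pos - pos.mean(axis=0)


def generate_dimer_structure(spec: StructureSpec) -> DimerStructure:
    """Build the idealized dimer with annotated paths, overlap sets and frame.

    The BLA of every conjugation path equals its target exactly before
    jitter.  A cross-pigment contact below 0.5 Å raises a warning (not an
    error): such structures are geometrically legal but sterically absurd.
    """
    n_ring = spec.ring_atoms
    ring = _ring_coordinates(n_ring, spec.ring_radius, spec.chl_bla)

    nb = spec.polyene_bonds
    half = nb // 2
    targets = np.where(np.arange(nb) < half, spec.lut_bla_a, spec.lut_bla_b)
    # bonds alternate double/single along the chain
    signs = np.where(np.arange(nb) % 2 == 0, -0.5, +0.5)
    lengths = _MEAN_BOND + signs * targets
    chain = _chain_coordinates(lengths) + np.asarray(spec.displacement, dtype=float)

    coords = np.vstack([ring, chain])
    if spec.jitter > 0:
        rng = np.random.default_rng([spec.seed, _STREAM_STRUCTURE])
        coords = coords + rng.normal(0.0, spec.jitter, coords.shape)

    n_chain = nb + 1
    serials = np.arange(1, n_ring + n_chain + 1)
    atoms = pd.DataFrame(
        {
            "serial": serials,
            "name": [f"C{i}" for i in range(1, n_ring + n_chain + 1)],
            "element": "C",
            "pigment": ["CHL"] * n_ring + ["LUT"] * n_chain,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )

    def ring_bond(i: int) -> tuple[int, int, str]:
        tag = "double" if i % 2 == 0 else "single"
        return (i + 1, (i + 1) % n_ring + 1, tag)

    def chain_bond(i: int) -> tuple[int, int, str]:
        tag = "double" if i % 2 == 0 else "single"
        return (n_ring + i + 1, n_ring + i + 2, tag)

    m = n_ring // 2
    paths = {
        "chl_a": [ring_bond(i) for i in range(m)],
        "chl_b": [ring_bond(i) for i in range(m, n_ring)],
        "lut_a": [chain_bond(i) for i in range(half)],
        "lut_b": [chain_bond(i) for i in range(half, nb)],
    }
    core = range(n_chain // 4, n_chain - n_chain // 4)  # central chain atoms
    overlap_sets = {
        "CHL": [int(s) for s in serials[:n_ring]],
        "LUT": [int(n_ring + i + 1) for i in core],
    }
    frame_serials = (1, 1 + n_ring // 3, 1 + (2 * n_ring) // 3)

    structure = DimerStructure(
        atoms=atoms,
        paths=paths,
        overlap_sets=overlap_sets,
        frame_serials=frame_serials,
    )
    d = np.linalg.norm(
        coords[:n_ring, None, :] - coords[None, n_ring:, :], axis=-1
    )
    if float(d.min()) < 0.5:
        warnings.warn(
            f"cross-pigment contact of {d.min():.2f} Å (< 0.5 Å); "
            "structure kept but likely unphysical",
            stacklevel=2,
        )
    return structure


# ---------------------------------------------------------------------------
# descriptor datasets


def generate_descriptor_dataset(
    n: int,
    variance_shares: tuple[float, float] = (0.55, 0.20),
    seed: int = 0,
    site: str = "L1",
    ct_mean: float = 20255.0,
    ct_sd: float = 1600.0,
    bla_mean: float = 0.08,
    bla_sd: float = 0.01,
    overlap_mean: float = 0.07,
    overlap_sd: float = 0.012,
) -> pd.DataFrame:
    """Per-frame descriptor table with controlled CT-variance shares.

    The CT energy is an exact linear function of the four BLA columns and
    the overlap column plus Gaussian noise; coefficients are scaled so the
    population variance shares of the BLA block and the overlap equal
    ``variance_shares``.  The four BLAs and the overlap are mutually
    independent by construction, so the hierarchical regression shares are
    identifiable.  The (x, y) ring-frame columns carry no CT signal.
    """
    s_bla, s_inter = variance_shares
    if s_bla < 0 or s_inter < 0:
        raise ValueError("variance shares must be non-negative")
    if s_bla + s_inter > 1.0:
        raise ValueError("variance shares must sum to at most 1")
    if n < 2:
        raise ValueError("need n >= 2 frames")
    rng = np.random.default_rng([seed, _STREAM_DESCRIPTORS])
    blas = rng.normal(bla_mean, bla_sd, (n, 4))
    overlap = np.clip(rng.normal(overlap_mean, overlap_sd, n), 0.0, None)
    x = rng.normal(1.5, 0.5, n)
    y = rng.normal(0.5, 0.5, n)
    coef_bla = ct_sd * math.sqrt(s_bla / 4.0) / bla_sd
    coef_ov = -ct_sd * math.sqrt(s_inter) / overlap_sd  # larger overlap stabilizes CT
    noise_sd = ct_sd * math.sqrt(max(1.0 - s_bla - s_inter, 0.0))
    ct = (
        ct_mean
        + coef_bla * (blas - bla_mean).sum(axis=1)
        + coef_ov * (overlap - overlap_mean)
        + rng.normal(0.0, noise_sd, n)
    )
    table = pd.DataFrame(blas, columns=["bla1", "bla2", "bla3", "bla4"])
    table["overlap"] = overlap
    table["x"] = x
    table["y"] = y
    table[CT_COLUMN] = ct
    table["site"] = site
    return table
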