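"""Geometric descriptors of Lut/Chl-a dimers and CT-energy variance decomposition.

The energy of the Lut→Chl charge-transfer state fluctuates with the
conformation of the pigment pair.  Two families of geometric coordinates
capture most of that variability:

* intramolecular — bond-length alternation (BLA) along the conjugation
  paths of the chlorin macrocycle and the lutein polyene, the standard
  proxy for π-conjugation;
* intermolecular — a simplified overlap of spherical atomic densities
  between the two pigments, plus the position of the lutein in the frame
  of the chlorin ring.

A hierarchical ordinary-least-squares decomposition then attributes
CT-energy variance to the intramolecular block first and to the
intermolecular block incrementally.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DimerStructure",
    "RegressionDecomposition",
    "bla",
    "density_overlap",
    "sphere_intersection_volume",
    "gaussian_overlap_value",
    "ring_frame_position",
    "decompose_variance",
    "ct_shift_from_overlap",
    "implied_overlap_coefficient",
    "BLA_BLOCK",
    "INTERMOLECULAR_BLOCK",
    "CT_COLUMN",
]

# Canonical descriptor-table column blocks.
BLA_BLOCK: tuple[str, ...] = ("bla1", "bla2", "bla3", "bla4")
INTERMOLECULAR_BLOCK: tuple[str, ...] = ("overlap", "x", "y")
CT_COLUMN = "ct_energy_cm1"

#: Default sphere radius for the density overlap (Å); carbon van der Waals.
DEFAULT_OVERLAP_RADIUS = 1.7

_BOND_TAGS = frozenset({"single", "double"})
_MAX_BOND_LENGTH = 2.0  # Å; sanity bound for a covalent bond


@dataclass
class DimerStructure:
    """Coordinates and conjugation annotations for one Chl/Lut pair.

    Attributes
    ----------
    atoms : DataFrame
        Columns ``serial, name, element, pigment, x, y, z`` (Å), one row
        per atom; serials unique.
    paths : dict
        Conjugation paths: path id → list of ``(serial_i, serial_j, tag)``
        bonds with tag in {"single", "double"}.
    overlap_sets : dict
        Pigment tag → list of atom serials entering the density overlap.
        Exactly two pigments, disjoint serial sets.
    frame_serials : tuple of int
        Three atom serials fixing the chlorin ring frame: origin, x-axis
        direction, and the in-plane reference completing the x–y plane.
    """

    atoms: pd.DataFrame
    paths: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    overlap_sets: dict[str, list[int]] = field(default_factory=dict)
    frame_serials: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        required = {"serial", "element", "pigment", "x", "y", "z"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns {sorted(missing)}")
        serials = self.atoms["serial"].to_numpy()
        if len(np.unique(serials)) != len(serials):
            raise ValueError("atom serial numbers must be unique")
        self._index = {int(s): i for i, s in enumerate(serials)}
        self._xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        for pid, bonds in self.paths.items():
            for a, b, tag in bonds:
                if tag not in _BOND_TAGS:
                    raise ValueError(f"path {pid!r}: unknown bond tag {tag!r}")
        if self.overlap_sets:
            sets = [set(v) for v in self.overlap_sets.values()]
            if len(sets) == 2 and sets[0] & sets[1]:
                raise ValueError("overlap atom sets must be disjoint across pigments")

    def coords(self, serials) -> np.ndarray:
        """Coordinates (n, 3) of the given atom serials, in input order."""
        try:
            idx = [self._index[int(s)] for s in np.atleast_1d(serials)]
        except KeyError as exc:
            raise KeyError(f"unknown atom serial {exc.args[0]}") from None
        return self._xyz[idx]


def bla(structure: DimerStructure, path_id: str) -> float:
    """Bond-length alternation of a conjugation path, in Å.

    Defined as mean(single-bond lengths) − mean(double-bond lengths) over
    the tagged bonds of the path.  Positive BLA means longer single bonds,
    i.e. localized π-conjugation.
    """
    if path_id not in structure.paths:
        raise KeyError(f"no conjugation path {path_id!r}")
    bonds = structure.paths[path_id]
    lengths: dict[str, list[float]] = {"single": [], "double": []}
    for a, b, tag in bonds:
        d = float(np.linalg.norm(structure.coords(a) - structure.coords(b)))
        if d > _MAX_BOND_LENGTH:
            raise ValueError(
                f"path {path_id!r}: atoms {a}-{b} are {d:.2f} Å apart, not bonded"
            )
        lengths[tag].append(d)
    if not lengths["single"] or not lengths["double"]:
        raise ValueError(
            f"path {path_id!r} needs at least one single and one double bond"
        )
    return float(np.mean(lengths["single"]) - np.mean(lengths["double"]))


def sphere_intersection_volume(distance: float, radius: float) -> float:
    """Closed-form intersection volume (Å³) of two equal spheres.

    For spheres of radius R at center distance d the lens volume is
    π(2R−d)²(4R+d)/12 for d < 2R and 0 beyond contact.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = float(distance)
    if d >= 2.0 * radius:
        return 0.0
    return math.pi * (2.0 * radius - d) ** 2 * (4.0 * radius + d) / 12.0


def gaussian_overlap_value(distance: float, radius: float) -> float:
    """Smooth alternative to the hard-sphere lens: Gaussian density overlap.

    Each atom carries a normalized isotropic Gaussian density of width
    σ = R/2; the pair overlap is the density product integral scaled by the
    squared sphere volume so the result keeps Å³ units and decays smoothly
    with distance.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    sigma = radius / 2.0
    v0 = 4.0 / 3.0 * math.pi * radius**3
    return (
        v0**2
        * (4.0 * math.pi * sigma**2) ** -1.5
        * math.exp(-(distance**2) / (4.0 * sigma**2))
    )


def density_overlap(
    structure: DimerStructure,
    radius: float = DEFAULT_OVERLAP_RADIUS,
    model: str = "sphere",
) -> float:
    """Inter-pigment density overlap (Å³).

    Sums, over all cross-pigment pairs of the two annotated overlap atom
    sets, the intersection volume of two uniform spheres of the given
    radius centered on the atoms (``model="sphere"``), or the Gaussian
    variant (``model="gaussian"``).  Symmetric in the two sets and exactly
    zero (sphere model) once every pair distance exceeds 2·radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(structure.overlap_sets) != 2:
        raise ValueError("structure must annotate exactly two overlap atom sets")
    for tag, serials in structure.overlap_sets.items():
        if not serials:
            raise ValueError(f"overlap set {tag!r} is empty")
    (set_a, set_b) = structure.overlap_sets.values()
    ca, cb = structure.coords(set_a), structure.coords(set_b)
    dists = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1).ravel()
    if model == "sphere":
        fn = sphere_intersection_volume
    elif model == "gaussian":
        fn = gaussian_overlap_value
    else:
        raise ValueError(f"unknown overlap model {model!r}")
    return float(sum(fn(d, radius) for d in dists))


def ring_frame_position(structure: DimerStructure) -> tuple[float, float]:
    """Lutein position (x, y) in the chlorin-ring frame, in Å.

    The frame is built from the three annotated ring atoms: origin at the
    first, x-axis toward the second, y-axis the Gram–Schmidt
    orthogonalization of the direction to the third.  The reported point is
    the centroid of the lutein overlap atom set projected onto that plane.
    """
    if structure.frame_serials is None:
        raise ValueError("structure has no ring-frame atom annotation")
    o, px, py = (structure.coords(s)[0] for s in structure.frame_serials)
    ex = px - o
    nx = np.linalg.norm(ex)
    if nx < 1e-9:
        raise ValueError("ring-frame atoms are degenerate")
    ex = ex / nx
    v = py - o
    v = v - np.dot(v, ex) * ex
    ny = np.linalg.norm(v)
    if ny < 1e-9:
        raise ValueError("ring-frame atoms are collinear")
    ey = v / ny
    lut_tag = _lutein_tag(structure)
    centroid = structure.coords(structure.overlap_sets[lut_tag]).mean(axis=0)
    rel = centroid - o
    return float(np.dot(rel, ex)), float(np.dot(rel, ey))


def _lutein_tag(structure: DimerStructure) -> str:
    # the lutein set is whichever overlap set is not on the ring-frame pigment
    frame_serial = structure.frame_serials[0]
    frame_pigment = structure.atoms.set_index("serial").loc[frame_serial, "pigment"]
    for tag in structure.overlap_sets:
        if tag != frame_pigment:
            return tag
    raise ValueError("could not identify the lutein overlap set")


@dataclass
class RegressionDecomposition:
    """Hierarchical variance decomposition of the CT energy.

    ``shares`` holds one entry per predictor block, in fitting order: the
    first is the plain R² of the first block, later entries are increments
    of R² when the block is added.  Shares and the residual sum to one.
    The incremental shares depend on block order (collinearity between
    blocks is credited to earlier blocks).
    """

    block_order: tuple[str, ...]
    shares: tuple[float, ...]
    residual: float
    r2_full: float
    coefficients: pd.Series
    stderr: pd.Series
    n: int

    def __post_init__(self) -> None:
        total = sum(self.shares) + self.residual
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"variance shares must sum to 1, got {total}")


def decompose_variance(
    table: pd.DataFrame,
    blocks: dict[str, tuple[str, ...]] | None = None,
    response: str = CT_COLUMN,
) -> RegressionDecomposition:
    """Hierarchical OLS variance decomposition of the CT energy.

    Fits ordinary least squares of ``response`` on successive predictor
    blocks (default: the four BLA columns, then the intermolecular columns
    that are present) and reports the incremental R² of each block, the
    residual share, and the full-model coefficients with standard errors.
    """
    if blocks is None:
        inter = tuple(c for c in INTERMOLECULAR_BLOCK if c in table.columns)
        blocks = {"bla": BLA_BLOCK, "intermolecular": inter}
    all_cols: list[str] = []
    for name, cols in blocks.items():
        if not cols:
            raise ValueError(f"predictor block {name!r} is empty")
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"block {name!r}: missing columns {missing}")
        all_cols.extend(cols)
    if response not in table.columns:
        raise ValueError(f"missing response column {response!r}")
    clean = table[all_cols + [response]]
    if clean.isna().any().any():
        raise ValueError("regression columns contain missing values")
    n = len(clean)
    if n <= len(all_cols) + 1:
        raise ValueError(f"need n > {len(all_cols) + 1} rows, got {n}")

    X_full = sm.add_constant(clean[all_cols].to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        culprits = _collinear_columns(clean[all_cols])
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")

    y = clean[response].to_numpy(dtype=float)
    shares: list[float] = []
    prev_r2 = 0.0
    cols_so_far: list[str] = []
    for name, cols in blocks.items():
        cols_so_far.extend(cols)
        fit = sm.OLS(y, sm.add_constant(clean[cols_so_far].to_numpy(dtype=float))).fit()
        shares.append(float(fit.rsquared) - prev_r2)
        prev_r2 = float(fit.rsquared)
    full_fit = sm.OLS(y, X_full).fit()
    names = ["const"] + all_cols
    return RegressionDecomposition(
        block_order=tuple(blocks),
        shares=tuple(shares),
        residual=1.0 - prev_r2,
        r2_full=float(full_fit.rsquared),
        coefficients=pd.Series(full_fit.params, index=names),
        stderr=pd.Series(full_fit.bse, index=names),
        n=n,
    )


def _collinear_columns(df: pd.DataFrame) -> list[str]:
    cols = list(df.columns)
    X = df.to_numpy(dtype=float)
    keep: list[int] = []
    flagged: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == (
            len(keep) + 2
        ):
            keep.append(j)
        else:
            flagged.append(cols[j])
    return flagged


def ct_shift_from_overlap(coefficient: float, delta_overlap: float) -> float:
    """CT-energy shift (cm⁻¹) implied by an overlap change, linear model.

    ``coefficient`` is the regression slope of CT energy on overlap
    (cm⁻¹/Å³); the shift is simply coefficient × Δoverlap.
    """
    return float(coefficient) * float(delta_overlap)


def implied_overlap_coefficient(ct_shift: float, delta_overlap: float) -> float:
    """Slope magnitude (cm⁻¹/Å³) implied by a CT shift over an overlap gap."""
    if delta_overlap == 0:
        raise ValueError("overlap gap must be nonzero")
    return abs(float(ct_shift) / float(delta_overlap))
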