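"""Geometric descriptors: BLA, density overlap, ring frame, regression."""
import math

import numpy as np
import pandas as pd
import pytest

from ctquench.descriptors import (
    DimerStructure,
    bla,
    ct_shift_from_overlap,
    decompose_variance,
    density_overlap,
    gaussian_overlap_value,
    implied_overlap_coefficient,
    ring_frame_position,
    sphere_intersection_volume,
)
from ctquench.synthetic import StructureSpec, generate_descriptor_dataset, generate_dimer_structure


def _two_atom_structure(distance, with_annotations=True):
    atoms = pd.DataFrame(
        {
            "serial": [1, 2],
            "name": ["C1", "C2"],
            "element": ["C", "C"],
            "pigment": ["CHL", "LUT"],
            "x": [0.0, distance],
            "y": [0.0, 0.0],
            "z": [0.0, 0.0],
        }
    )
    return DimerStructure(
        atoms=atoms,
        overlap_sets={"CHL": [1], "LUT": [2]} if with_annotations else {},
    )


def _rigid_transform(structure, rotation=None, translation=None):
    xyz = structure.atoms[["x", "y", "z"]].to_numpy()
    if rotation is not None:
        xyz = xyz @ np.asarray(rotation).T
    if translation is not None:
        xyz = xyz + np.asarray(translation)
    atoms = structure.atoms.copy()
    atoms[["x", "y", "z"]] = xyz
    return DimerStructure(
        atoms=atoms,
        paths=structure.paths,
        overlap_sets=structure.overlap_sets,
        frame_serials=structure.frame_serials,
    )


class TestBla:
    def test_uniform_bonds_give_zero(self):
        st = generate_dimer_structure(StructureSpec(chl_bla=0.0, lut_bla_a=0.0, lut_bla_b=0.0))
        for pid in st.paths:
            assert bla(st, pid) == pytest.approx(0.0, abs=1e-9)

    def test_alternating_145_135(self):
        # ideal 1.45/1.35 alternation is the textbook polyene: BLA = 0.10
        st = generate_dimer_structure(StructureSpec(lut_bla_a=0.10, lut_bla_b=0.10))
        assert bla(st, "lut_a") == pytest.approx(0.10, abs=1e-9)

    def test_round_trip_with_generator(self):
        st = generate_dimer_structure(StructureSpec(lut_bla_a=0.07))
        assert bla(st, "lut_a") == pytest.approx(0.07, abs=1e-12)

    def test_single_tag_path_rejected(self, default_structure):
        st = default_structure
        st.paths["broken"] = [b for b in st.paths["lut_a"] if b[2] == "double"]
        try:
            with pytest.raises(ValueError, match="single and one double"):
                bla(st, "broken")
        finally:
            del st.paths["broken"]

    def test_unknown_path_rejected(self, default_structure):
        with pytest.raises(KeyError):
            bla(default_structure, "no_such_path")


class TestDensityOverlap:
    def test_coincident_atoms_full_sphere(self):
        st = _two_atom_structure(0.0)
        r = 1.7
        assert density_overlap(st, r) == pytest.approx(4.0 / 3.0 * math.pi * r**3)

    def test_beyond_contact_zero(self):
        st = _two_atom_structure(3.5)
        assert density_overlap(st, 1.7) == 0.0

    def test_monte_carlo_oracle(self, rng):
        # rejection-sampling volume of a single lens vs the closed form
        r, d = 1.7, 1.9
        box_lo, box_hi = np.array([-r, -r, -r]), np.array([d + r, r, r])
        n = 400_000
        pts = rng.uniform(box_lo, box_hi, (n, 3))
        inside = (np.linalg.norm(pts, axis=1) < r) & (
            np.linalg.norm(pts - [d, 0, 0], axis=1) < r
        )
        vol_box = np.prod(box_hi - box_lo)
        mc = inside.mean() * vol_box
        se = vol_box * math.sqrt(inside.mean() * (1 - inside.mean()) / n)
        assert abs(sphere_intersection_volume(d, r) - mc) < 3 * se

    def test_symmetry_in_sets(self, default_structure):
        st = default_structure
        flipped = DimerStructure(
            atoms=st.atoms,
            paths=st.paths,
            overlap_sets=dict(reversed(list(st.overlap_sets.items()))),
            frame_serials=st.frame_serials,
        )
        assert density_overlap(st, 1.7) == pytest.approx(density_overlap(flipped, 1.7))

    def test_rigid_motion_invariance(self, default_structure):
        base = density_overlap(default_structure, 1.7)
        th = 0.7
        rot = np.array(
            [
                [math.cos(th), -math.sin(th), 0],
                [math.sin(th), math.cos(th), 0],
                [0, 0, 1],
            ]
        )
        moved = _rigid_transform(default_structure, rotation=rot, translation=[5.0, -2.0, 1.0])
        assert density_overlap(moved, 1.7) == pytest.approx(base, rel=1e-12)

    def test_gaussian_variant_smooth_and_decreasing(self):
        vals = [gaussian_overlap_value(d, 1.7) for d in (0.0, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.0  # smooth: no hard cutoff

    def test_invalid_radius_rejected(self, default_structure):
        with pytest.raises(ValueError):
            density_overlap(default_structure, -1.0)


class TestRingFrame:
    def test_translation_invariance(self, default_structure):
        base = ring_frame_position(default_structure)
        moved = _rigid_transform(default_structure, translation=[10.0, -3.0, 7.0])
        assert ring_frame_position(moved) == pytest.approx(base, abs=1e-9)

    def test_rotation_equivariance(self, default_structure):
        # rotating the whole dimer leaves the in-frame coordinates unchanged
        th = math.pi / 2
        rot = np.array(
            [
                [math.cos(th), -math.sin(th), 0],
                [math.sin(th), math.cos(th), 0],
                [0, 0, 1],
            ]
        )
        base = ring_frame_position(default_structure)
        moved = _rigid_transform(default_structure, rotation=rot)
        assert ring_frame_position(moved) == pytest.approx(base, abs=1e-9)

    def test_centroid_at_origin_maps_to_zero(self):
        atoms = pd.DataFrame(
            {
                "serial": [1, 2, 3, 4],
                "name": ["C1", "C2", "C3", "C4"],
                "element": ["C"] * 4,
                "pigment": ["CHL", "CHL", "CHL", "LUT"],
                "x": [0.0, 1.0, 0.0, 0.0],
                "y": [0.0, 0.0, 1.0, 0.0],
                "z": [0.0, 0.0, 0.0, 0.0],
            }
        )
        st = DimerStructure(
            atoms=atoms,
            overlap_sets={"CHL": [1, 2, 3], "LUT": [4]},
            frame_serials=(1, 2, 3),
        )
        assert ring_frame_position(st) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_collinear_frame_rejected(self):
        atoms = pd.DataFrame(
            {
                "serial": [1, 2, 3, 4],
                "name": ["C1", "C2", "C3", "C4"],
                "element": ["C"] * 4,
                "pigment": ["CHL", "CHL", "CHL", "LUT"],
                "x": [0.0, 1.0, 2.0, 0.0],
                "y": [0.0, 0.0, 0.0, 1.0],
                "z": [0.0, 0.0, 0.0, 0.0],
            }
        )
        st = DimerStructure(
            atoms=atoms,
            overlap_sets={"CHL": [1, 2, 3], "LUT": [4]},
            frame_serials=(1, 2, 3),
        )
        with pytest.raises(ValueError, match="collinear"):
            ring_frame_position(st)


class TestDecomposeVariance:
    def test_noiseless_full_r2(self):
        tab = generate_descriptor_dataset(400, (0.7, 0.3), seed=0)
        d = decompose_variance(tab)
        assert d.r2_full == pytest.approx(1.0, abs=1e-9)
        assert d.residual == pytest.approx(0.0, abs=1e-9)

    def test_shares_sum_to_one(self):
        tab = generate_descriptor_dataset(240, (0.55, 0.20), seed=3)
        d = decompose_variance(tab)
        assert sum(d.shares) + d.residual == pytest.approx(1.0, abs=1e-10)
        assert all(s >= 0 for s in d.shares)

    def test_permuted_response_kills_association(self, rng):
        tab = generate_descriptor_dataset(2000, (0.55, 0.20), seed=4)
        tab = tab.assign(ct_energy_cm1=rng.permutation(tab["ct_energy_cm1"].to_numpy()))
        d = decompose_variance(tab)
        p = 7  # predictors in the full model
        assert d.r2_full < 5 * p / len(tab)

    def test_rank_deficiency_names_columns(self):
        tab = generate_descriptor_dataset(240, seed=5)
        tab["bla4"] = tab["bla1"] * 2.0
        with pytest.raises(ValueError, match="bla4"):
            decompose_variance(tab)

    def test_too_few_rows_rejected(self):
        tab = generate_descriptor_dataset(8, seed=6)
        with pytest.raises(ValueError, match="rows"):
            decompose_variance(tab)


class TestOverlapExtrapolation:
    def test_zero_gap_zero_shift(self):
        assert ct_shift_from_overlap(4e4, 0.0) == 0.0

    def test_linearity(self):
        assert ct_shift_from_overlap(4e4, 0.10) == pytest.approx(
            2 * ct_shift_from_overlap(4e4, 0.05)
        )

    def test_reference_magnitude_arithmetic(self):
        # a 5e-2 A^3 overlap gap under a 4e4 cm-1/A^3 slope is a 2000 cm-1 shift
        assert ct_shift_from_overlap(4.0e4, 5.0e-2) == pytest.approx(2000.0)
        assert implied_overlap_coefficient(2000.0, 9.8e-2 - 4.7e-2) == pytest.approx(
            2000.0 / 5.1e-2
        )

    def test_zero_gap_coefficient_rejected(self):
        with pytest.raises(ValueError):
            implied_overlap_coefficient(2000.0, 0.0)
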