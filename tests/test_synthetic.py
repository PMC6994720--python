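"""Generator calibration, reproducibility, and geometric construction."""
import math

import numpy as np
import pytest

from ctquench.constants import KB_CM
from ctquench.descriptors import bla, density_overlap
from ctquench.marcus import (
    PAIR_LE_CT,
    STATE_CT,
    STATE_LE,
    adiabatic_energy,
    driving_force,
    reorganization_energy,
)
from ctquench.synthetic import (
    REFERENCE_STATS,
    EnsembleSpec,
    StructureSpec,
    calibrated_spreads,
    default_ensemble_spec,
    generate_coupling_samples,
    generate_descriptor_dataset,
    generate_dimer_structure,
    generate_state_ensemble,
)

KBT = KB_CM * 300.0


class TestEnsembleGeneration:
    def test_zero_spread_is_degenerate(self):
        spec = default_ensemble_spec("L1")
        spec.sigmas = {s: 0.0 for s in spec.sigmas}
        spec.correlations = {}
        ens = generate_state_ensemble(spec)
        for state, e in ens.items():
            assert np.all(e.energies == spec.means[state])

    def test_seed_reproducibility_bitwise(self):
        a = generate_state_ensemble(default_ensemble_spec("L2", seed=42))
        b = generate_state_ensemble(default_ensemble_spec("L2", seed=42))
        for state in a:
            assert np.array_equal(a[state].energies, b[state].energies)
        c = generate_coupling_samples(default_ensemble_spec("L2", seed=42))
        d = generate_coupling_samples(default_ensemble_spec("L2", seed=42))
        for pair in c:
            assert np.array_equal(c[pair], d[pair])

    def test_non_psd_correlation_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            spec = default_ensemble_spec("L1")
            EnsembleSpec(
                site="L1",
                means=spec.means,
                sigmas=spec.sigmas,
                correlations={
                    (STATE_LE, STATE_CT): 0.9,
                    (STATE_LE, "Lut* S2"): 0.9,
                    (STATE_CT, "Lut* S2"): -0.9,
                },
            )

    def test_block_labels_cover_three_monomers(self):
        ens = generate_state_ensemble(default_ensemble_spec("L1", n_snapshots=240))
        blocks = ens[STATE_LE].blocks
        assert sorted(set(blocks)) == [0, 1, 2]
        assert np.all(np.bincount(blocks) == 80)

    def test_ct_mean_within_reference_ci(self):
        # sample mean of the L1 CT state should sit near 20255 (CI 193 at n=240)
        ens = generate_state_ensemble(default_ensemble_spec("L1", seed=0))
        mean = ens[STATE_CT].mean()
        assert abs(mean - 20255.0) < 3 * 193.0

    def test_gap_variance_matches_reorganization_target(self):
        spec = default_ensemble_spec("L1", n_snapshots=21_000, seed=5)
        ens = generate_state_ensemble(spec)
        gap = ens[STATE_CT].energies - ens[STATE_LE].energies
        lam_hat = float(np.var(gap, ddof=1)) / (2 * KBT)
        se = math.sqrt(2.0 / gap.size) * 5405.0  # relative s.e. of a variance
        assert abs(lam_hat - 5405.0) < 3 * se


class TestCalibration:
    @pytest.mark.parametrize("site", ["L1", "L2"])
    def test_population_constraints_hold_exactly(self, site):
        ref = REFERENCE_STATS[site]
        s_le, s_ct, rho = calibrated_spreads(
            ref["means"][STATE_LE],
            ref["means"][STATE_CT],
            ref["driving_force"],
            ref["reorganization"],
        )
        gap_var = s_le**2 + s_ct**2 - 2 * rho * s_le * s_ct
        assert gap_var / (2 * KBT) == pytest.approx(ref["reorganization"], rel=1e-12)
        dg = (ref["means"][STATE_CT] - s_ct**2 / (2 * KBT)) - (
            ref["means"][STATE_LE] - s_le**2 / (2 * KBT)
        )
        assert dg == pytest.approx(ref["driving_force"], abs=1e-9)
        assert s_ct == pytest.approx(2 * s_le)
        assert -1 < rho < 1

    @pytest.mark.parametrize("site,lam,dg", [("L1", 5405.0, -82.0), ("L2", 5052.0, 951.0)])
    def test_downstream_estimators_recover_targets(self, site, lam, dg):
        spec = default_ensemble_spec(site, n_snapshots=21_000, seed=9)
        ens = generate_state_ensemble(spec)
        gap = ens[STATE_CT].energies - ens[STATE_LE].energies
        lam_hat = reorganization_energy(gap, 300.0)
        dg_hat = driving_force(
            adiabatic_energy(ens[STATE_CT]), adiabatic_energy(ens[STATE_LE])
        )
        n = spec.n_snapshots
        se_lam = math.sqrt(2.0 / n) * lam
        assert abs(lam_hat - lam) < 3 * se_lam
        # dG estimator s.e. is dominated by the variance-term fluctuations
        se_dg = math.sqrt(
            2 / n * (spec.sigmas[STATE_CT] ** 2 / (2 * KBT)) ** 2
            + 2 / n * (spec.sigmas[STATE_LE] ** 2 / (2 * KBT)) ** 2
            + (spec.sigmas[STATE_CT] ** 2 + spec.sigmas[STATE_LE] ** 2) / n
        )
        assert abs(dg_hat - dg) < 3 * se_dg


class TestCouplings:
    def test_constant_coupling_exact_rms(self):
        spec = default_ensemble_spec("L1")
        spec.coupling_fluctuates = False
        coup = generate_coupling_samples(spec)
        assert np.all(coup[PAIR_LE_CT] == 240.0)

    def test_rms_converges_to_scale(self):
        spec = default_ensemble_spec("L1", n_snapshots=99_999, seed=3)
        coup = generate_coupling_samples(spec)
        rms = float(np.sqrt(np.mean(coup[PAIR_LE_CT] ** 2)))
        # RMS of n zero-mean normals: relative s.e. ~ 1/sqrt(2n)
        assert abs(rms - 240.0) < 3 * 240.0 / math.sqrt(2 * spec.n_snapshots)

    def test_sign_fluctuates(self):
        coup = generate_coupling_samples(default_ensemble_spec("L1", seed=1))
        assert (coup[PAIR_LE_CT] > 0).any() and (coup[PAIR_LE_CT] < 0).any()

    def test_negative_rms_rejected(self):
        spec = default_ensemble_spec("L1")
        with pytest.raises(ValueError, match="RMS"):
            EnsembleSpec(
                site="L1",
                means=spec.means,
                sigmas=spec.sigmas,
                coupling_rms={PAIR_LE_CT: -5.0},
            )


class TestStructures:
    def test_bla_exact_before_jitter(self):
        spec = StructureSpec(chl_bla=0.07, lut_bla_a=0.10, lut_bla_b=0.03)
        st = generate_dimer_structure(spec)
        for pid, target in spec.bla_targets.items():
            assert bla(st, pid) == pytest.approx(target, abs=1e-9)

    def test_large_displacement_zeroes_overlap(self):
        st = generate_dimer_structure(StructureSpec(displacement=(100.0, 0.0, 0.0)))
        assert density_overlap(st, 1.7) == 0.0

    def test_jitter_mean_bla_unbiased(self):
        target, vals = 0.10, []
        for seed in range(100):
            st = generate_dimer_structure(StructureSpec(jitter=0.01, seed=seed))
            vals.append(bla(st, "lut_a"))
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        # jitter inflates bond lengths slightly (E|b+e| > |b|), but the
        # alternation difference stays centered on the target
        assert abs(np.mean(vals) - target) < 3 * se + 1e-4

    def test_overlap_decreases_with_separation(self):
        prev = math.inf
        for dz in (2.5, 3.0, 3.3, 3.6):
            st = generate_dimer_structure(StructureSpec(displacement=(0.0, 0.0, dz)))
            cur = density_overlap(st, 1.7)
            assert cur < prev
            prev = cur

    def test_clash_warns_but_returns(self):
        with pytest.warns(UserWarning, match="contact"):
            st = generate_dimer_structure(StructureSpec(displacement=(0.0, 0.0, 0.1)))
        assert st.atoms.shape[0] > 0

    def test_structure_reproducible(self):
        a = generate_dimer_structure(StructureSpec(jitter=0.02, seed=7))
        b = generate_dimer_structure(StructureSpec(jitter=0.02, seed=7))
        assert np.array_equal(
            a.atoms[["x", "y", "z"]].to_numpy(), b.atoms[["x", "y", "z"]].to_numpy()
        )

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            StructureSpec(polyene_bonds=2)
        with pytest.raises(ValueError):
            StructureSpec(jitter=-0.1)
        with pytest.raises(ValueError):
            StructureSpec(chl_bla=0.5)


class TestDescriptorDataset:
    def test_noiseless_bla_only_r2_one(self):
        from ctquench.descriptors import decompose_variance

        tab = generate_descriptor_dataset(500, (1.0, 0.0), seed=0)
        d = decompose_variance(tab)
        assert d.shares[0] == pytest.approx(1.0, abs=1e-9)

    def test_large_n_share_recovery(self):
        from ctquench.descriptors import decompose_variance

        tab = generate_descriptor_dataset(100_000, (0.55, 0.20), seed=1)
        d = decompose_variance(tab)
        assert d.shares[0] == pytest.approx(0.55, abs=0.02)
        assert d.shares[1] == pytest.approx(0.20, abs=0.02)

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            generate_descriptor_dataset(100, (0.9, 0.2))
        with pytest.raises(ValueError):
            generate_descriptor_dataset(100, (-0.1, 0.2))

    def test_reproducible(self):
        a = generate_descriptor_dataset(100, seed=5)
        b = generate_descriptor_dataset(100, seed=5)
        assert a.equals(b)
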