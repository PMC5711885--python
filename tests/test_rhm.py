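"""Residue classification, slab partitioning, helix RHM energies, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scramblefit import (
    MembraneSlab,
    bootstrap_sd,
    classify_residue,
    compare_constructs,
    compute_sasa,
    rhm_from_table,
    rhm_profile,
)
from scramblefit.rhm import SIGMA_RES, residue_exposures, residue_mismatch_area
from scramblefit.synthetic import toy_helix_structure

SLAB = MembraneSlab(-15.0, 15.0)
# wide slab whose bounds clear every surface point of a 20-residue helix
WIDE_SLAB = MembraneSlab(-25.0, 25.0)


def mc_area_outside_slab(structure, slab, residue_filter, rng, n_samples=4000):
    """Brute-force oracle: random points on each expanded atomic sphere,
    all-pairs occlusion, area of accessible points with z outside the slab."""
    coords = structure.coords
    radii = structure.radii + 1.4
    total = 0.0
    for i, atom in enumerate(structure.atoms):
        if not residue_filter(atom):
            continue
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + radii[i] * v
        accessible = np.ones(n_samples, dtype=bool)
        for j in range(coords.shape[0]):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        outside = accessible & ~(
            (pts[:, 2] >= slab.z_lower) & (pts[:, 2] <= slab.z_upper)
        )
        total += outside.mean() * 4 * np.pi * radii[i] ** 2
    return total


class TestClassifyResidue:
    @pytest.mark.parametrize("z", [-20.0, 0.0, 14.0, 30.0])
    def test_ser_thr_always_exempt(self, z):
        assert classify_residue("SER", z, SLAB) == "exempt"
        assert classify_residue("THR", z, SLAB) == "exempt"

    def test_interfacial_trp_exempt(self):
        assert classify_residue("TRP", 15.0, SLAB) == "exempt"
        assert classify_residue("TRP", -13.0, SLAB) == "exempt"  # within margin
        assert classify_residue("TRP", 0.0, SLAB) == "polar"

    def test_arg_lys_snorkeling(self):
        assert classify_residue("ARG", 14.0, SLAB) == "exempt"
        assert classify_residue("LYS", -16.5, SLAB) == "exempt"
        assert classify_residue("ARG", 0.0, SLAB) == "polar"

    def test_canonical_hydrophobic(self):
        assert classify_residue("LEU", 0.0, SLAB) == "hydrophobic"

    def test_unknown_residue_polar_with_warning(self):
        with pytest.warns(UserWarning, match="unknown residue"):
            assert classify_residue("XYZ", 0.0, SLAB) == "polar"


class TestMismatchArea:
    def test_hydrophobic_inside_slab_zero(self):
        helix = toy_helix_structure("L" * 20)
        exp = residue_exposures(helix, WIDE_SLAB)
        assert all(e.sa_res == 0.0 for e in exp.values())

    def test_polar_outside_slab_zero(self):
        helix = toy_helix_structure("N" * 10)
        # slab far below the helix: nothing polar is buried
        slab = MembraneSlab(-100.0, -50.0)
        exp = residue_exposures(helix, slab)
        assert all(e.sa_res == 0.0 for e in exp.values())

    def test_partition_completeness(self):
        helix = toy_helix_structure("LIVFAMLIVW")
        exp = residue_exposures(helix, SLAB)
        for e in exp.values():
            assert e.sa_inside + e.sa_outside == pytest.approx(e.sa_prot, rel=1e-9)

    def test_mismatch_area_dispatch(self):
        assert residue_mismatch_area("hydrophobic", 3.0, 7.0) == 7.0
        assert residue_mismatch_area("polar", 3.0, 7.0) == 3.0
        assert residue_mismatch_area("exempt", 3.0, 7.0) == 0.0


class TestHelixEnergy:
    def test_fully_embedded_hydrophobic_helix_zero(self):
        helix = toy_helix_structure("A" * 20)
        profile = rhm_profile(helix, WIDE_SLAB)
        assert profile[0].energy == 0.0

    def test_poly_ser_zero_anywhere(self):
        helix = toy_helix_structure("S" * 20, z_offset=10.0)
        assert rhm_profile(helix, SLAB)[0].energy == 0.0

    def test_additivity(self):
        helix = toy_helix_structure("LIVFAMLIVWKRSETLIVFA", z_offset=6.0)
        profile = rhm_profile(helix, SLAB)[0]
        assert profile.energy == pytest.approx(
            SIGMA_RES * sum(e.sa_res for e in profile.contributions)
        )

    def test_protruding_helix_matches_point_count_oracle(self):
        helix = toy_helix_structure("L" * 20, z_offset=10.0)
        energy = rhm_profile(helix, SLAB, n_points=4000)[0].energy
        rng = np.random.default_rng(99)
        oracle_area = mc_area_outside_slab(
            helix, SLAB, lambda a: True, rng, n_samples=8000
        )
        assert energy == pytest.approx(SIGMA_RES * oracle_area, rel=0.02)

    def test_translation_invariance(self):
        helix = toy_helix_structure("LIVFAMLIVW", z_offset=8.0)
        base = rhm_profile(helix, SLAB)[0].energy
        moved_xy = rhm_profile(helix.translated(dx=50.0, dy=-20.0), SLAB)[0].energy
        assert moved_xy == pytest.approx(base, rel=1e-9)
        shifted = rhm_profile(
            helix.translated(dz=7.0), MembraneSlab(-8.0, 22.0)
        )[0].energy
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_point_budget_convergence(self):
        helix = toy_helix_structure("LIVFAMLIVWKRSET", z_offset=9.0)
        e960 = rhm_profile(helix, SLAB, n_points=960)[0].energy
        e4000 = rhm_profile(helix, SLAB, n_points=4000)[0].energy
        assert e960 == pytest.approx(e4000, rel=0.02)

    def test_slab_width_monotonicity(self):
        hydrophobic = toy_helix_structure("L" * 20, z_offset=8.0)
        polar = toy_helix_structure("N" * 20, z_offset=8.0)
        widths = [10.0, 15.0, 20.0, 25.0]
        e_hydro = [
            rhm_profile(hydrophobic, MembraneSlab(-w, w))[0].energy for w in widths
        ]
        e_polar = [rhm_profile(polar, MembraneSlab(-w, w))[0].energy for w in widths]
        assert all(a >= b - 1e-12 for a, b in zip(e_hydro, e_hydro[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(e_polar, e_polar[1:]))

    def test_sigma_res_scaling(self):
        # 100 A^2 of mismatch area costs 0.28 kcal/mol
        table = pd.DataFrame(
            {"helix": ["TM4"], "res_name": ["LEU"], "res_seq": [1],
             "sa_prot": [120.0], "sa_mem": [100.0]}
        )
        assert rhm_from_table(table)[0].energy == pytest.approx(0.28)


class TestRhmFromTable:
    def test_polar_penalty_is_buried_area(self):
        table = pd.DataFrame(
            {"helix": ["TM1"], "res_name": ["ASN"], "res_seq": [1],
             "sa_prot": [80.0], "sa_mem": [30.0]}
        )
        assert rhm_from_table(table)[0].energy == pytest.approx(SIGMA_RES * 50.0)

    def test_exempt_rows_zero(self):
        table = pd.DataFrame(
            {"helix": ["TM1"] * 2, "res_name": ["SER", "THR"], "res_seq": [1, 2],
             "sa_prot": [80.0, 60.0], "sa_mem": [30.0, 20.0]}
        )
        assert rhm_from_table(table)[0].energy == 0.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            rhm_from_table(pd.DataFrame({"helix": ["TM1"]}))


class TestBootstrapSd:
    def test_constant_replicates_zero_sd(self):
        assert bootstrap_sd([3.3, 3.3, 3.3, 3.3], seed=0) == 0.0

    def test_single_outlier_enumerated_values(self):
        # triples of {0,0,0,12} have mean 0 or 4; the SD of four such means
        # can only take the enumerable values below
        possible = set()
        for means in itertools.product([0.0, 4.0], repeat=4):
            possible.add(round(float(np.std(means, ddof=1)), 10))
        sd = bootstrap_sd([0.0, 0.0, 0.0, 12.0], seed=5)
        assert round(sd, 10) in possible

    def test_bounded_by_triple_mean_spread(self):
        triple_means = [np.mean(c) for c in itertools.combinations([1, 2, 3, 4], 3)]
        max_sd = max(
            np.std(m, ddof=1)
            for m in itertools.product(triple_means, repeat=4)
        )
        for seed in range(10):
            assert 0.0 <= bootstrap_sd([1, 2, 3, 4], seed=seed) <= max_sd + 1e-12

    def test_reproducible(self):
        vals = [1.0, 2.5, 0.7, 4.1, 3.3]
        assert bootstrap_sd(vals, seed=42) == bootstrap_sd(vals, seed=42)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            bootstrap_sd([1.0, 2.0, 3.0], seed=0)


class TestCompareConstructs:
    def test_identical_profiles_zero_delta(self):
        prof = {"TM4": [1.0, 1.1, 0.9, 1.0]}
        res = compare_constructs(prof, prof)
        assert res.loc[0, "delta"] == 0.0

    def test_clear_separation_tiny_p(self):
        res = compare_constructs(
            {"TM4": [1.0, 1.0, 1.0, 1.0]}, {"TM4": [2.0, 2.0, 2.0, 2.0001]}
        )
        assert res.loc[0, "delta"] == pytest.approx(1.0, abs=1e-4)
        assert res.loc[0, "p_value"] < 0.002

    def test_matches_closed_form_t(self):
        from scipy import stats

        a = [1.2, 1.5, 1.1, 1.4]
        b = [2.0, 2.2, 1.9, 2.3]
        res = compare_constructs({"TM4": a}, {"TM4": b})
        na, nb = len(a), len(b)
        sa2, sb2 = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
        t_stat = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_expected = 2 * stats.t.sf(abs(t_stat), na + nb - 2)
        assert res.loc[0, "p_value"] == pytest.approx(p_expected)

    def test_degenerate_equal_groups(self):
        res = compare_constructs({"TM4": [1.0, 1.0]}, {"TM4": [1.0, 1.0]})
        assert res.loc[0, "p_value"] == 1.0
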