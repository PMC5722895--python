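"""PRE rate/distance conversions, error propagation, restraint building."""

import math

import numpy as np
import pandas as pd
import pytest

import tfdimer as t
from tfdimer.restraints import (BOUND_HIGH_A, BOUND_LOW_A, RATIO_HIGH,
                                RATIO_LOW, read_peak_table)


class TestPreFromRatio:
    def test_ratio_one_gives_zero(self, pre_config):
        assert t.pre_from_ratio(1.0, pre_config) == 0.0

    @pytest.mark.parametrize("ratio,expected", [
        (0.5, 69.3147), (0.15, 189.712),
    ])
    def test_direct_evaluation(self, ratio, expected):
        cfg = t.PREConfig(two_tau_inept_s=0.010)
        assert t.pre_from_ratio(ratio, cfg) == pytest.approx(expected,
                                                             abs=0.05)

    def test_above_one_clamps_with_warning(self, pre_config):
        with pytest.warns(UserWarning):
            assert t.pre_from_ratio(1.05, pre_config) == 0.0

    def test_non_positive_raises(self, pre_config):
        with pytest.raises(ValueError):
            t.pre_from_ratio(0.0, pre_config)


class TestDistanceFromPre:
    def test_power_law(self, pre_config):
        r1 = t.distance_from_pre(100.0, pre_config)
        r2 = t.distance_from_pre(50.0, pre_config)
        assert r2 / r1 == pytest.approx(2.0 ** (1 / 6), rel=1e-12)

    def test_monotone_decreasing(self, pre_config):
        pres = np.geomspace(1.0, 1e4, 30)
        rs = [t.distance_from_pre(p, pre_config) for p in pres]
        assert np.all(np.diff(rs) < 0)

    def test_inverse_of_forward(self, pre_config):
        for d in (5.0, 16.12, 30.0):
            pre = t.pre_from_distance(d, pre_config)
            assert t.distance_from_pre(pre, pre_config) == pytest.approx(d)

    def test_non_positive_raises(self, pre_config):
        with pytest.raises(ValueError):
            t.distance_from_pre(0.0, pre_config)


class TestCalibration:
    def test_default_anchors_low_boundary(self, pre_config):
        assert t.distance_from_ratio(RATIO_LOW, pre_config) == pytest.approx(
            BOUND_LOW_A, abs=1e-9)

    def test_other_boundary_reproduced(self, pre_config):
        """Calibrating at 0.15 -> 16.12 Å pins 0.85 at 24.28 Å."""
        assert round(t.distance_from_ratio(RATIO_HIGH, pre_config), 2) == \
            BOUND_HIGH_A

    def test_reverse_calibration(self):
        two_tau = t.calibrate_two_tau_inept(ratio=RATIO_HIGH,
                                            distance_A=BOUND_HIGH_A)
        cfg = t.PREConfig(two_tau_inept_s=two_tau)
        assert round(t.distance_from_ratio(RATIO_LOW, cfg), 2) == BOUND_LOW_A

    def test_boundary_ratio_is_delay_free(self):
        """r(0.85)/r(0.15) = (ln0.15/ln0.85)^(1/6) for any constants."""
        expected = (math.log(RATIO_LOW) / math.log(RATIO_HIGH)) ** (1 / 6)
        assert expected == pytest.approx(1.5062, abs=1e-4)
        for cfg in (t.PREConfig(), t.PREConfig(tau_c_s=10e-9,
                                               frequency_hz=900e6,
                                               two_tau_inept_s=0.005)):
            got = t.distance_from_ratio(RATIO_HIGH, cfg) \
                / t.distance_from_ratio(RATIO_LOW, cfg)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_composition_monotone_in_ratio(self, pre_config):
        ratios = np.linspace(0.01, 0.99, 40)
        ds = [t.distance_from_ratio(r, pre_config) for r in ratios]
        assert np.all(np.diff(ds) > 0)


class TestErrorPropagation:
    def test_zero_noise_zero_sigma(self, pre_config):
        assert t.propagate_distance_error(0.5, 1.0, 0.0, pre_config) == 0.0

    def test_matches_monte_carlo(self, pre_config):
        """Analytic sigma_r within 5% of a 1e5-sample Monte Carlo at
        ratio 0.5 with 2% volume noise."""
        v_ox, v_red, noise = 0.5, 1.0, 0.02
        analytic = t.propagate_distance_error(v_ox, v_red, noise, pre_config)
        rng = np.random.default_rng(42)
        n = 100_000
        ox = v_ox + noise * rng.standard_normal(n)
        red = v_red + noise * rng.standard_normal(n)
        ratios = np.clip(ox / red, 1e-6, 1 - 1e-9)
        pre = -np.log(ratios) / pre_config.two_tau_inept_s
        r = (pre_config.spectral_factor_cm6_per_s / pre) ** (1 / 6) * 1e8
        assert analytic == pytest.approx(float(np.std(r)), rel=0.05)

    def test_diverges_near_ratio_one(self, pre_config):
        s1 = t.propagate_distance_error(0.90, 1.0, 0.01, pre_config)
        s2 = t.propagate_distance_error(0.999, 1.0, 0.01, pre_config)
        assert s2 > 10 * s1


def _row(residue=20, v_ox=0.5, v_red=1.0, broadened=False, overlapped=False,
         label_site=5):
    return pd.DataFrame([{"residue": residue, "v_ox": v_ox, "v_red": v_red,
                          "broadened": broadened, "overlapped": overlapped,
                          "label_site": label_site}]).iloc[0]


class TestClassifyRestraint:
    def test_bounded_with_margins(self):
        cfg = t.PREConfig(noise_sd=0.001)
        cat, rs = t.classify_restraint(_row(v_ox=0.5), cfg)
        assert cat == "bounded" and rs.klass == "PRE-bounded"
        r = t.distance_from_ratio(0.5, cfg)
        assert rs.lower == pytest.approx(r - 4.0)
        assert rs.upper == pytest.approx(r + 4.0)
        assert rs.ambiguity == "ambiguous"

    def test_broadened_gets_upper_limit(self, pre_config):
        cat, rs = t.classify_restraint(_row(v_ox=np.nan, broadened=True),
                                       pre_config)
        assert cat == "upper"
        assert rs.upper == pytest.approx(BOUND_LOW_A + 4.0)

    def test_weak_pre_gets_lower_limit_both_pairings(self, pre_config):
        cat, rs = t.classify_restraint(_row(v_ox=0.9), pre_config)
        assert cat == "lower"
        d085 = t.distance_from_ratio(RATIO_HIGH, pre_config)
        assert rs.lower == pytest.approx(d085 - 4.0, abs=1e-9)
        assert round(rs.lower, 2) == round(BOUND_HIGH_A - 4.0, 2)
        assert math.isinf(rs.upper)
        assert rs.ambiguity == "both"

    def test_noisy_quantification_discarded(self):
        # large volume noise pushes sigma_r over the 1 Å cutoff
        cfg = t.PREConfig(noise_sd=0.2)
        cat, rs = t.classify_restraint(_row(v_ox=0.8), cfg)
        assert cat == "discarded" and rs is None

    def test_overlapped_rejected(self, pre_config):
        with pytest.raises(ValueError):
            t.classify_restraint(_row(overlapped=True), pre_config)

    def test_totality_every_row_in_one_class(self, bundle):
        rs, counts = t.classify_peak_table(bundle.peak_table,
                                           bundle.pre_config)
        usable = (~bundle.peak_table["overlapped"]).sum()
        assert counts["bounded"] + counts["upper"] + counts["lower"] \
            + counts["discarded"] == usable
        assert counts["selected"] == len(rs)
        # deterministic per seed
        rs2, counts2 = t.classify_peak_table(bundle.peak_table,
                                             bundle.pre_config)
        assert counts2 == counts


class TestClassifyIntraInter:
    def test_rule_application(self, bundle):
        cfg = bundle.pre_config
        prot = bundle.protomer
        strong_near = _row(v_ox=0.2)
        # construct rows against the real monomer geometry
        cb_site = bundle.label_sites[0]
        dists = {}
        for res in np.unique(prot.resid):
            d = np.linalg.norm(prot.coords_of("A", cb_site, "CB")
                               - prot.coords_of("A", int(res), "H"))
            dists[int(res)] = float(d)
        near = min(dists, key=dists.get)
        far = max(dists, key=dists.get)
        assert dists[far] > 25.0
        row_near = _row(residue=near, v_ox=0.2, label_site=cb_site)
        row_far = _row(residue=far, v_ox=0.2, label_site=cb_site)
        assert t.classify_intra_inter(row_near, prot, cfg) == "intra"
        assert t.classify_intra_inter(row_far, prot, cfg) == "inter"
        weak = _row(residue=far, v_ox=0.95, label_site=cb_site)
        assert t.classify_intra_inter(weak, prot, cfg) == "uninformative"


class TestBuildEfn:
    def test_selection_rules(self, toy_protomer):
        s, dmap = toy_protomer
        rs = t.build_efn(s, dmap)
        assert rs
        linkers = dmap.linker_residues()
        ca = s.select(chain="A", atom="CA")
        lookup = {int(r): c for r, c in zip(ca.resid, ca.coord)}
        for r in rs:
            sep = r.resid2 - r.resid1
            assert 1 <= sep <= 10
            assert 3.0 <= r.target <= 15.0
            assert r.resid1 not in linkers and r.resid2 not in linkers
            assert not any(r.resid1 < lr < r.resid2 for lr in linkers)
            d = np.linalg.norm(lookup[r.resid1] - lookup[r.resid2])
            assert d == pytest.approx(r.target)
            assert r.upper - r.lower == pytest.approx(1.0)

    def test_exhaustive_against_brute_force(self, toy_protomer):
        s, dmap = toy_protomer
        rs = {(r.resid1, r.resid2) for r in t.build_efn(s, dmap)}
        ca = s.select(chain="A", atom="CA")
        lookup = {int(r): c for r, c in zip(ca.resid, ca.coord)}
        linkers = dmap.linker_residues()
        expected = set()
        for i in lookup:
            for j in lookup:
                if not (1 <= j - i <= 10):
                    continue
                if i in linkers or j in linkers or \
                        any(i < lr < j for lr in linkers):
                    continue
                d = np.linalg.norm(lookup[i] - lookup[j])
                if 3.0 <= d <= 15.0:
                    expected.add((i, j))
        assert rs == expected

    def test_invariant_under_rigid_motion(self, toy_protomer):
        from scipy.spatial.transform import Rotation
        s, dmap = toy_protomer
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = t.Transform(rot, np.array([5.0, -2.0, 9.0]))
        n0 = len(t.build_efn(s, dmap))
        n1 = len(t.build_efn(s.transformed(moved), dmap))
        assert n0 == n1


class TestSymmetryRestraints:
    def test_exact_dimer_has_zero_violation(self, toy_protomer):
        s, dmap = toy_protomer
        rs = t.symmetry_restraints(np.unique(s.resid), dmap)
        dimer = t.make_c2_dimer(s)
        energy = t.restraint_energy(dimer, rs)
        assert energy["symmetry"] == pytest.approx(0.0, abs=1e-18)

    def test_off_axis_shift_stays_symmetric(self, toy_protomer):
        """Translating chain B perpendicular to the two-fold axis moves the
        axis but keeps the arrangement C2: d(A_i,B_j) = d(B_i,A_j) still."""
        s, dmap = toy_protomer
        rs = t.symmetry_restraints(np.unique(s.resid), dmap)
        dimer = t.make_c2_dimer(s)
        from tfdimer.structure import Structure
        coords = dimer.coord.copy()
        coords[dimer.chain == "B"] += np.array([2.0, 0.0, 0.0])
        shifted = Structure(dimer.chain, dimer.resid, dimer.resname,
                            dimer.atom, coords)
        energy = t.restraint_energy(shifted, rs)
        assert energy["symmetry"] == pytest.approx(0.0, abs=1e-18)

    def test_broken_symmetry_detected_by_brute_force(self, toy_protomer):
        # a shift along the two-fold axis makes the arrangement a screw,
        # which the distance-symmetry restraints must detect
        s, dmap = toy_protomer
        rs = t.symmetry_restraints(np.unique(s.resid), dmap)
        dimer = t.make_c2_dimer(s)
        coords = dimer.coord.copy()
        coords[dimer.chain == "B"] += np.array([0.0, 0.0, 2.0])
        from tfdimer.structure import Structure
        broken = Structure(dimer.chain, dimer.resid, dimer.resname,
                           dimer.atom, coords)
        energy = t.restraint_energy(broken, rs)
        # brute-force evaluation of the same equalities
        expected = 0.0
        for r in rs:
            d1 = np.linalg.norm(broken.coords_of("A", r.resid1, "CA")
                                - broken.coords_of("B", r.resid2, "CA"))
            d2 = np.linalg.norm(broken.coords_of("B", r.resid1, "CA")
                                - broken.coords_of("A", r.resid2, "CA"))
            expected += (d1 - d2) ** 2
        assert energy["symmetry"] == pytest.approx(expected, rel=1e-12)
        assert energy["symmetry"] > 0

    def test_single_chain_errors(self, toy_protomer):
        s, dmap = toy_protomer
        rs = t.symmetry_restraints(np.unique(s.resid), dmap)
        with pytest.raises(t.StructureError):
            t.restraint_energy(s.with_chain("A"), rs)
        with pytest.raises(ValueError):
            t.symmetry_restraints([1], dmap)


class TestRestraintIO:
    def test_empty_list(self):
        text = t.write_restraints([])
        assert text.startswith("#")
        assert t.read_restraints(text) == []

    def test_tsv_round_trip(self, bundle):
        rs, _ = t.classify_peak_table(bundle.peak_table, bundle.pre_config)
        back = t.read_restraints(t.write_restraints(rs, cfg=bundle.pre_config))
        assert len(back) == len(rs)
        for a, b in zip(rs, back):
            assert (a.chain1, a.resid1, a.atom1) == (b.chain1, b.resid1, b.atom1)
            assert a.klass == b.klass and a.ambiguity == b.ambiguity
            assert a.target == pytest.approx(b.target)
            assert a.upper == pytest.approx(b.upper)

    def test_xplor_margins(self):
        r = t.DistanceRestraint("A", 49, "CB", "B", 165, "H",
                                12.0, 8.0, 16.0, "PRE-bounded", "fixed")
        text = t.write_restraints([r], dialect="xplor")
        assert "12.00 4.00 4.00" in text
        assert "resid 49" in text and "resid 165" in text


def test_peak_table_round_trip(bundle):
    from tfdimer.restraints import write_peak_table
    df = bundle.peak_table
    back = read_peak_table(write_peak_table(df))
    np.testing.assert_allclose(back["v_ox"], df["v_ox"])
    assert (back["broadened"] == df["broadened"]).all()
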