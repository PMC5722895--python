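"""Docking/annealing engine: energies, ambiguity semantics, model handling."""

import numpy as np
import pytest

import tfdimer as t
from tfdimer.annealing import (_CompiledEnergy, rigid_bodies,
                               satisfied_fraction)
from tfdimer.restraints import DistanceRestraint


class TestEffectiveDistance:
    def test_single_pair_passthrough(self):
        assert t.effective_distance([7.3]) == pytest.approx(7.3)

    def test_two_equal_pairs(self):
        assert t.effective_distance([10.0, 10.0]) == pytest.approx(
            10.0 * 2 ** (-1 / 6), rel=1e-12)

    def test_distant_pair_negligible(self):
        assert t.effective_distance([2.0, 1000.0]) == pytest.approx(2.0,
                                                                    abs=1e-6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            t.effective_distance([])


class TestAirRestraints:
    def test_contacting_pair_zero_violation(self):
        # two single-residue protomers in 2 Å contact: pooled effective
        # distance falls below the 3 Å bound, zero violation
        from tfdimer.structure import Structure
        dimer = Structure(["A", "A", "B", "B"], [1, 1, 1, 1],
                          ["ALA"] * 4, ["CA", "CB", "CA", "CB"],
                          [[0.0, 0, 0], [1.5, 0, 0],
                           [3.5, 0, 0], [5.0, 0, 0]])
        rs = t.air_restraints({1}, set(), {1}, set(), dimer)
        energy = t.restraint_energy(dimer, rs)
        assert energy["AIR"] == pytest.approx(0.0, abs=1e-12)

    def test_truth_interface_airs_nearly_satisfied(self, bundle):
        active = bundle.active_residues
        passive = t.select_passive(active, bundle.protomer)
        rs = t.air_restraints(active, passive, active, passive,
                              bundle.truth_dimer)
        report = t.violation_report(bundle.truth_dimer, rs)
        # CA/CB-resolution contacts sit near 4.5 Å, so pooled effective
        # distances hover just above the 3 Å bound
        assert report["effective_A"].min() < 5.0
        assert (report["violation_A"] < 4.0).all()

    def test_separated_protomers_violate_as_brute_force(self, bundle):
        from tfdimer.structure import Structure
        dimer = bundle.truth_dimer
        coords = dimer.coord.copy()
        coords[dimer.chain == "B"] += np.array([50.0, 0.0, 0.0])
        far = Structure(dimer.chain, dimer.resid, dimer.resname, dimer.atom,
                        coords)
        res = sorted(bundle.active_residues)[0]
        rs = t.air_restraints({res}, set(), {res}, set(), far)
        energy = t.restraint_energy(far, rs)
        report = t.violation_report(far, rs)
        deff = report["effective_A"].to_numpy()
        expected = sum((d - 3.0) ** 2 for d in deff)
        assert energy["AIR"] == pytest.approx(expected, rel=1e-9)

    def test_empty_active_raises(self, bundle):
        with pytest.raises(ValueError):
            t.air_restraints(set(), set(), set(), set(), bundle.truth_dimer)


class TestRestraintEnergy:
    def test_satisfied_is_zero(self, bundle):
        rs, _ = t.classify_peak_table(bundle.peak_table, bundle.pre_config)
        energy = t.restraint_energy(bundle.truth_dimer, rs)
        assert energy["PRE-bounded"] == 0.0
        assert energy["PRE-upper"] == 0.0
        assert energy["PRE-lower"] == 0.0

    def test_violation_formula(self):
        # one bounded restraint violated by exactly 2 Å
        r = DistanceRestraint("A", 1, "CA", "A", 2, "CA",
                              5.0, 3.0, 7.0, "EFN", "fixed")
        from tfdimer.structure import Structure
        dimer = Structure(["A", "A", "B", "B"], [1, 2, 1, 2],
                          ["ALA"] * 4, ["CA"] * 4,
                          [[0, 0, 0], [9.0, 0, 0],
                           [0, 50, 0], [9.0, 50, 0]])
        energy = t.restraint_energy(dimer, [r], weights={"EFN": 1.0})
        assert energy["EFN"] == pytest.approx(2 * 4.0)  # both chains

    def test_clash_repulsion_formula(self):
        from tfdimer.structure import Structure
        dimer = Structure(["A", "B"], [1, 1], ["ALA"] * 2, ["CA"] * 2,
                          [[0, 0, 0], [3.0, 0, 0]])
        energy = t.restraint_energy(dimer, [])
        assert energy["repulsion"] == pytest.approx(0.25)

    def test_compiled_agrees_with_reference(self, bundle, rng):
        """Vectorized annealer energy equals the loop-based evaluator."""
        rs, _ = t.classify_peak_table(bundle.peak_table, bundle.pre_config)
        efn = t.build_efn(bundle.protomer, bundle.domain_map)
        sym = t.symmetry_restraints(np.unique(bundle.protomer.resid),
                                    bundle.domain_map)
        allrs = rs + efn + sym
        _, junctions = rigid_bodies(bundle.protomer, bundle.domain_map)
        compiled = _CompiledEnergy(bundle.protomer, allrs, junctions, {}, 3.5)
        for _ in range(3):
            p = bundle.protomer.coord + rng.normal(0, 3.0, size=3)
            from tfdimer.structure import Structure
            prot = Structure(bundle.protomer.chain, bundle.protomer.resid,
                             bundle.protomer.resname, bundle.protomer.atom, p)
            dimer = t.make_c2_dimer(prot)
            ref = t.restraint_energy(dimer, allrs, junctions=junctions)
            got = compiled(p)
            pre_ref = ref["PRE-bounded"] + ref["PRE-upper"]
            assert got["PRE-ambiguous"] == pytest.approx(pre_ref, abs=1e-9)
            for key in ("PRE-lower", "EFN", "symmetry", "repulsion",
                        "connectivity"):
                assert got.get(key, 0.0) == pytest.approx(ref[key], abs=1e-9)


@pytest.fixture(scope="module")
def small_run(bundle):
    rs, _ = t.classify_peak_table(bundle.peak_table, bundle.pre_config)
    efn = t.build_efn(bundle.protomer, bundle.domain_map)
    sym = t.symmetry_restraints(np.unique(bundle.protomer.resid),
                                bundle.domain_map)
    allrs = rs + efn + sym
    cfg = t.AnnealConfig(seed=3, n_runs=2, n_keep=1, n_steps=150,
                         n_polish=50)
    return bundle, allrs, cfg


class TestAnnealDimer:
    def test_deterministic_per_seed(self, small_run):
        bundle, allrs, cfg = small_run
        m1 = t.anneal_dimer(bundle.protomer, bundle.domain_map, allrs, cfg)
        m2 = t.anneal_dimer(bundle.protomer, bundle.domain_map, allrs, cfg)
        np.testing.assert_array_equal(m1[0].structure.coord,
                                      m2[0].structure.coord)
        assert m1[0].energy == m2[0].energy

    def test_models_are_exactly_c2(self, small_run):
        bundle, allrs, cfg = small_run
        models = t.anneal_dimer(bundle.protomer, bundle.domain_map, allrs, cfg)
        for m in models:
            a = m.structure.select(chain="A").coord
            b = m.structure.select(chain="B").coord
            image = a @ t.C2_TRANSFORM.rotation.T
            assert np.max(np.abs(image - b)) < 1e-9

    def test_no_restraints_raises(self, bundle):
        cfg = t.AnnealConfig(seed=0, n_runs=1, n_keep=1, n_steps=10)
        with pytest.raises(ValueError):
            t.anneal_dimer(bundle.protomer, bundle.domain_map, [], cfg)


class TestSelectModels:
    @staticmethod
    def _dummy(energy, run):
        from tfdimer.structure import Structure
        s = Structure(["A", "A", "A", "B", "B", "B"], [1, 2, 3] * 2,
                      ["ALA"] * 6, ["CA"] * 6, np.arange(18.0).reshape(6, 3))
        return t.DimerModel(s, {"total": energy}, {"run": run})

    def test_lowest_energy_prefix(self):
        models = [self._dummy(e, i) for i, e in enumerate([5.0, 1.0, 3.0,
                                                           0.5, 2.0])]
        picked = t.select_models(models, 3)
        assert [m.total_energy for m in picked] == [0.5, 1.0, 2.0]

    def test_ties_break_by_run_index(self):
        models = [self._dummy(1.0, i) for i in (4, 2, 7)]
        picked = t.select_models(models, 2)
        assert [m.provenance["run"] for m in picked] == [2, 4]

    def test_too_many_requested_raises(self):
        with pytest.raises(ValueError):
            t.select_models([self._dummy(1.0, 0)], 2)


class TestViolationReport:
    def test_truth_pose_fully_satisfied(self, bundle):
        rs, _ = t.classify_peak_table(bundle.peak_table, bundle.pre_config)
        efn = t.build_efn(bundle.protomer, bundle.domain_map)
        report = t.violation_report(bundle.truth_dimer, rs + efn)
        assert (report["violation_A"] <= 1e-9).all()
        frac = satisfied_fraction(report)
        assert (frac == 1.0).all()

    def test_displaced_domain_localizes_violations(self, bundle):
        from tfdimer.structure import Structure
        rs, _ = t.classify_peak_table(bundle.peak_table, bundle.pre_config)
        dimer = bundle.truth_dimer
        ppd = set(bundle.domain_map.residues("PPD").tolist())
        coords = dimer.coord.copy()
        move = np.isin(dimer.resid, list(ppd))
        coords[move] += np.array([10.0, 0, 0])
        displaced = Structure(dimer.chain, dimer.resid, dimer.resname,
                              dimer.atom, coords)
        report = t.violation_report(displaced, rs)
        violated = report[report["violation_A"] > 1e-6]
        assert len(violated) > 0
        touched = [rs[i].resid1 in ppd or rs[i].resid2 in ppd
                   for i in violated["index"]]
        assert all(touched)

    def test_empty_restraints_empty_table(self, bundle):
        report = t.violation_report(bundle.truth_dimer, [])
        assert report.empty


class TestInterfaceContacts:
    def test_buried_vs_distal(self, bundle):
        contacts = t.interface_contacts(
            bundle.truth_dimer, [int(r) for r in
                                 np.unique(bundle.protomer.resid)])
        near = contacts["min_distance_A"].min()
        far = contacts["min_distance_A"].max()
        assert near < 5.0
        assert far > 15.0

    def test_monomer_input_raises(self, bundle):
        with pytest.raises(t.StructureError):
            t.interface_contacts(bundle.protomer.with_chain("A"), [1])


def test_interface_rmsd_zero_for_identical(bundle):
    assert t.interface_ca_rmsd(bundle.truth_dimer, bundle.truth_dimer) == \
        pytest.approx(0.0, abs=1e-9)


def test_interface_rmsd_chain_swap_invariance(bundle):
    from tfdimer.structure import Structure
    d = bundle.truth_dimer
    swapped = Structure(np.where(d.chain == "A", "B", "A"), d.resid,
                        d.resname, d.atom, d.coord)
    assert t.interface_ca_rmsd(swapped, d) == pytest.approx(0.0, abs=1e-9)
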