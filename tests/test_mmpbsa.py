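import numpy as np
import pandas as pd
import pytest

from ppiscreen.mmpbsa import (BETA_DEFAULT, GAMMA_DEFAULT, FrameEnergyTable,
                              HBondCriterion, detect_hbonds, frame_deltas,
                              min_contact_distance, nonpolar_term, summarize,
                              summary_from_means)
from ppiscreen.reference import (MMPBSA_COMPLEXES, PRINTED_DG_SOLV_OVERRIDE,
                                 REPORTED_ENERGIES)
from ppiscreen.synthetic import make_hb_frame


def make_table(n_frames, fill):
    """fill(species) -> dict of component -> array/scalar."""
    rows = []
    for sp in ("complex", "protein", "inhibitor"):
        comp = fill(sp)
        block = pd.DataFrame({"frame": np.arange(n_frames), "species": sp})
        for k in ("E_vdW", "E_elec", "G_PB", "SASA"):
            block[k] = comp[k]
        rows.append(block)
    return FrameEnergyTable(pd.concat(rows, ignore_index=True))


class TestNonpolarTerm:
    def test_zero_sasa_gives_offset(self):
        assert nonpolar_term(0.0) == pytest.approx(-1.008)

    def test_zero_gamma_gives_beta(self):
        assert nonpolar_term(1234.0, gamma=0.0) == pytest.approx(BETA_DEFAULT)

    def test_default_parameters(self):
        assert nonpolar_term(1000.0) == pytest.approx(4.412)

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_term(-1.0)


class TestFrameDeltas:
    def test_additive_components_cancel(self):
        t = make_table(3, lambda sp: {"E_vdW": {"complex": 10.0, "protein": 6.0,
                                                "inhibitor": 4.0}[sp],
                                      "E_elec": {"complex": -8.0, "protein": -3.0,
                                                 "inhibitor": -5.0}[sp],
                                      "G_PB": 0.0 if sp != "complex" else 0.0,
                                      "SASA": 100.0 if sp == "complex" else 50.0})
        d = frame_deltas(t)
        assert np.allclose(d["dE_vdW"], 0.0)
        assert np.allclose(d["dE_elec"], 0.0)
        # SASA: 100 - 50 - 50 = 0, so dG_NP = gamma*0 - beta = +1.008
        assert np.allclose(d["dG_NP"], -BETA_DEFAULT)

    def test_single_frame_integers(self):
        t = make_table(1, lambda sp: {k: {"complex": 10.0, "protein": 3.0,
                                          "inhibitor": 2.0}[sp]
                                      for k in ("E_vdW", "E_elec", "G_PB", "SASA")})
        d = frame_deltas(t)
        for comp in ("dE_vdW", "dE_elec", "dG_PB"):
            assert d[comp].iloc[0] == pytest.approx(5.0)
        assert d["dG_NP"].iloc[0] == pytest.approx(GAMMA_DEFAULT * 5.0 - BETA_DEFAULT)

    def test_matches_brute_force_recomputation(self, rng):
        vals = {sp: {k: rng.normal(size=100) for k in ("E_vdW", "E_elec", "G_PB")}
                for sp in ("complex", "protein", "inhibitor")}
        for sp in vals:
            vals[sp]["SASA"] = rng.uniform(100, 5000, 100)
        t = make_table(100, lambda sp: vals[sp])
        d = frame_deltas(t)
        for comp in ("E_vdW", "E_elec", "G_PB"):
            expected = vals["complex"][comp] - vals["protein"][comp] - vals["inhibitor"][comp]
            assert np.allclose(d["d" + comp], expected)
        np_delta = (nonpolar_term(vals["complex"]["SASA"])
                    - nonpolar_term(vals["protein"]["SASA"])
                    - nonpolar_term(vals["inhibitor"]["SASA"]))
        assert np.allclose(d["dG_NP"], np_delta)

    def test_frame_mismatch_rejected(self):
        rows = [pd.DataFrame({"frame": range(5), "species": "complex",
                              "E_vdW": 0.0, "E_elec": 0.0, "G_PB": 0.0, "SASA": 0.0}),
                pd.DataFrame({"frame": range(4), "species": "protein",
                              "E_vdW": 0.0, "E_elec": 0.0, "G_PB": 0.0, "SASA": 0.0}),
                pd.DataFrame({"frame": range(5), "species": "inhibitor",
                              "E_vdW": 0.0, "E_elec": 0.0, "G_PB": 0.0, "SASA": 0.0})]
        with pytest.raises(ValueError, match="identical frames"):
            FrameEnergyTable(pd.concat(rows, ignore_index=True))


class TestSummarize:
    def test_identities_hold_exactly(self, rng):
        d = pd.DataFrame({k: rng.normal(size=50)
                          for k in ("dE_vdW", "dE_elec", "dG_PB", "dG_NP")})
        s = summarize(d, entropy_term=12.5, entropy_sem=1.5)
        assert s.dE_MM_gas.value == pytest.approx(s.dE_vdW.value + s.dE_elec.value, abs=1e-12)
        assert s.dG_solv.value == pytest.approx(s.dG_PB.value + s.dG_NP.value, abs=1e-12)
        assert s.dH.value == pytest.approx(s.dE_MM_gas.value + s.dG_solv.value, abs=1e-12)
        assert s.dG.value == pytest.approx(s.dH.value + s.entropy_term.value, abs=1e-12)
        assert s.dG_elec_tot.value == pytest.approx(s.dE_elec.value + s.dG_PB.value, abs=1e-12)
        assert s.dG.sem == pytest.approx(np.hypot(s.dH.sem, 1.5))

    def test_entropy_only_sem_mode(self, rng):
        d = pd.DataFrame({k: rng.normal(size=50)
                          for k in ("dE_vdW", "dE_elec", "dG_PB", "dG_NP")})
        s = summarize(d, entropy_term=12.5, entropy_sem=1.5, sem_mode="entropy_only")
        assert s.dG.sem == 1.5

    def test_constant_series_has_zero_sem(self):
        d = pd.DataFrame({k: np.full(10, v) for k, v in
                          [("dE_vdW", -30.0), ("dE_elec", -5.0),
                           ("dG_PB", 20.0), ("dG_NP", -2.0)]})
        s = summarize(d, entropy_term=15.0)
        for row in (s.dE_vdW, s.dE_elec, s.dG_PB, s.dG_NP, s.dH):
            assert row.sem == 0.0
        assert s.dH.value == pytest.approx(-17.0)
        assert s.dG.value == pytest.approx(-2.0)

    def test_too_few_frames_rejected(self):
        d = pd.DataFrame({k: [1.0] for k in ("dE_vdW", "dE_elec", "dG_PB", "dG_NP")})
        with pytest.raises(ValueError, match="2 frames"):
            summarize(d, entropy_term=0.0)


class TestPublishedEnergyTable:
    """Cross-checks of the six published complex columns.

    Each derived row (dE_MM_gas, dG_solv, dG_elec_tot, dH, dG) is recomputed
    from the printed component means; agreement is to printed precision.
    The T23-RANKL column is a documented inconsistency: its printed dG_solv
    (24.20) does not equal its own dG_PB + dG_NP (21.17), and the printed
    downstream rows follow the printed dG_solv.
    """

    @pytest.mark.parametrize("name", [k for k in MMPBSA_COMPLEXES
                                      if k != "T23-RANKL"])
    def test_consistent_columns_reproduce_dh_dg(self, name):
        comp = MMPBSA_COMPLEXES[name]
        s = summary_from_means(comp["dE_vdW"][0], comp["dE_elec"][0],
                               comp["dG_PB"][0], comp["dG_NP"][0],
                               comp["entropy_term"][0])
        assert s.dH.value == pytest.approx(REPORTED_ENERGIES[name]["dH"], abs=0.015)
        assert s.dG.value == pytest.approx(REPORTED_ENERGIES[name]["dG"], abs=0.015)

    def test_t23_rankl_inconsistency_is_real(self):
        comp = MMPBSA_COMPLEXES["T23-RANKL"]
        from_components = comp["dG_PB"][0] + comp["dG_NP"][0]      # 21.17
        printed = PRINTED_DG_SOLV_OVERRIDE["T23-RANKL"]            # 24.20
        assert abs(from_components - printed) > 1.0                # genuinely inconsistent

    def test_t23_rankl_downstream_follows_printed_solvation(self):
        comp = MMPBSA_COMPLEXES["T23-RANKL"]
        s = summary_from_means(comp["dE_vdW"][0], comp["dE_elec"][0],
                               comp["dG_PB"][0], comp["dG_NP"][0],
                               comp["entropy_term"][0],
                               dG_solv=PRINTED_DG_SOLV_OVERRIDE["T23-RANKL"])
        assert s.dH.value == pytest.approx(REPORTED_ENERGIES["T23-RANKL"]["dH"], abs=0.015)
        assert s.dG.value == pytest.approx(REPORTED_ENERGIES["T23-RANKL"]["dG"], abs=0.015)


class TestHydrogenBonds:
    def test_collinear_short_contact_fires(self):
        coords, donors, acceptors = make_hb_frame(2.9, 180.0)
        events = detect_hbonds(coords, donors, acceptors)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(2.9)
        assert events[0].angle == pytest.approx(180.0)

    def test_distance_beyond_cutoff_does_not_fire(self):
        coords, donors, acceptors = make_hb_frame(3.6, 180.0)
        assert detect_hbonds(coords, donors, acceptors) == []

    def test_bent_geometry_does_not_fire(self):
        coords, donors, acceptors = make_hb_frame(2.9, 100.0)
        assert detect_hbonds(coords, donors, acceptors) == []

    def test_angle_exactly_at_cutoff_fires(self):
        coords, donors, acceptors = make_hb_frame(3.0, 120.0)
        events = detect_hbonds(coords, donors, acceptors)
        assert len(events) == 1

    def test_rigid_motion_invariance(self):
        for seed in range(10):
            coords, donors, acceptors = make_hb_frame(2.9, 150.0, rigid_seed=seed)
            events = detect_hbonds(coords, donors, acceptors)
            assert len(events) == 1
            assert events[0].distance == pytest.approx(2.9, abs=1e-9)
            assert events[0].angle == pytest.approx(150.0, abs=1e-9)

    def test_missing_hydrogen_rejected(self):
        coords, _, acceptors = make_hb_frame(2.9, 180.0)
        with pytest.raises(ValueError, match="hydrogen"):
            detect_hbonds(coords, [(0, 99)], acceptors)

    def test_custom_criterion(self):
        coords, donors, acceptors = make_hb_frame(3.6, 180.0)
        loose = HBondCriterion(distance_cutoff=4.0, angle_cutoff=90.0)
        assert len(detect_hbonds(coords, donors, acceptors, loose)) == 1


class TestMinContactDistance:
    def test_three_four_five(self):
        frame = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        mean, sd = min_contact_distance([frame], group_a=[1], target_atom=0)
        assert (mean, sd) == (5.0, 0.0)

    def test_repeated_frames_zero_sd(self):
        frame = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [2.0, 0.0, 0.0]])
        mean, sd = min_contact_distance([frame] * 8, group_a=[1, 2], target_atom=0)
        assert sd == 0.0
        assert mean == pytest.approx(np.sqrt(3))

    def test_planted_minima_match_exhaustive_scan(self, rng):
        frames = [rng.normal(scale=5.0, size=(12, 3)) for _ in range(50)]
        group = [2, 5, 7, 11]
        mean, sd = min_contact_distance(frames, group, target_atom=0)
        mins = [min(np.linalg.norm(f[a] - f[0]) for a in group) for f in frames]
        assert mean == pytest.approx(np.mean(mins))
        assert sd == pytest.approx(np.std(mins))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            min_contact_distance([np.zeros((3, 3))], [], 0)
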