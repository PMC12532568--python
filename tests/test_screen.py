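import numpy as np
import pandas as pd
import pytest

from conftest import make_results_records
from lc3screen.config import ScreenConfig
from lc3screen.errors import NoTransitionError, UsageError, ValidationError
from lc3screen.io import PlateMap, ResultsTable
from lc3screen.screen import (
    TOXIC_SENTINEL,
    DoseResponseProfile,
    build_dose_response,
    compute_flux,
    export_heatmap_matrix,
    fit_ic50,
    flux_ratio,
    normalize_to_vehicle,
    rank_hits,
)
from lc3screen.synthetic import make_flux_groups, make_screen


def _table(vehicle_values, treatment_values, phase="pre_nh4cl", treatment_excluded=None):
    recs = make_results_records("P1", "A01", phase, vehicle_values)
    recs += make_results_records(
        "P1", "B01", phase, treatment_values,
        excluded=treatment_excluded, reason="displaced during acquisition",
    )
    return ResultsTable.from_records(recs)


def _platemap(phases=("pre_nh4cl",)):
    rows = []
    for phase in phases:
        rows.append(dict(plate="P1", well="A01", compound="DMSO", dose_um=0.0,
                         phase=phase, role="vehicle", toxic=False, notes=""))
        rows.append(dict(plate="P1", well="B01", compound="thymol", dose_um=50.0,
                         phase=phase, role="treatment", toxic=False, notes=""))
    return PlateMap(pd.DataFrame(rows))


class TestNormalizeToVehicle:
    def test_fold_change_arithmetic(self):
        table = _table([0.02, 0.02], [0.04, 0.04])
        resp = normalize_to_vehicle(table, _platemap())
        assert resp.group("thymol", 50.0, "pre_nh4cl")["fold_change"] == pytest.approx(2.0)
        assert resp.group("DMSO", 0.0, "pre_nh4cl")["fold_change"] == pytest.approx(1.0)

    def test_treatment_equal_to_vehicle_gives_unity(self):
        table = _table([0.03, 0.05], [0.05, 0.03])
        resp = normalize_to_vehicle(table, _platemap())
        assert resp.group("thymol", 50.0, "pre_nh4cl")["fold_change"] == pytest.approx(1.0)

    def test_excluded_larvae_omitted_from_means(self):
        table = _table([0.02, 0.02], [0.04, 0.04, np.nan], treatment_excluded=[False, False, True])
        resp = normalize_to_vehicle(table, _platemap())
        g = resp.group("thymol", 50.0, "pre_nh4cl")
        assert g["fold_change"] == pytest.approx(2.0)
        assert g["n"] == 2

    def test_stratum_without_vehicle_raises(self):
        recs = make_results_records("P1", "B01", "pre_nh4cl", [0.04])
        pm = _platemap()
        with pytest.raises(ValidationError, match="vehicle"):
            normalize_to_vehicle(ResultsTable.from_records(recs), pm)

    def test_vehicle_mean_zero_gives_absent_fc_with_reason(self):
        table = _table([0.0, 0.0], [0.04])
        resp = normalize_to_vehicle(table, _platemap())
        g = resp.group("thymol", 50.0, "pre_nh4cl")
        assert np.isnan(g["fold_change"])
        assert g["fc_reason"] == "vehicle mean is 0"

    def test_normalization_idempotent_for_vehicle(self):
        """Normalizing already-normalized data keeps the vehicle at FC 1."""
        table = _table([0.02, 0.02], [0.04, 0.04])
        resp = normalize_to_vehicle(table, _platemap())
        renorm = resp.larvae.rename(columns={"normalized": "value2"})
        recs = [dict(plate=r.plate, well=r.well, larva=r.larva, phase=r.phase,
                     metric="relative_puncta_area", value=r.value2, units="",
                     excluded=False, exclusion_reason="")
                for r in renorm.itertuples()]
        resp2 = normalize_to_vehicle(ResultsTable.from_records(recs), _platemap())
        assert resp2.group("DMSO", 0.0, "pre_nh4cl")["fold_change"] == pytest.approx(1.0)

    def test_planted_effect_recovered_in_monte_carlo(self):
        """Planted 1.8x effect, n=20/group, CV 20%: FC lands in [1.6, 2.0].

        Delta-method oracle for the coverage: the FC estimator is a ratio of
        two independent group means, each with CV 0.2/sqrt(20), so
        sd(FC) = 1.8 * 0.2 * sqrt(2/20) = 0.114 and the +-0.2 window spans
        +-1.76 sigma = 92% expected coverage.  The test asserts coverage at
        the oracle value minus binomial slack (3 sd at n=200 runs).
        """
        rng = np.random.default_rng(2024)
        hits = 0
        n_runs = 200
        sigma = np.sqrt(np.log1p(0.2**2))
        for _ in range(n_runs):
            veh = rng.lognormal(np.log(0.02) - sigma**2 / 2, sigma, 20)
            trt = rng.lognormal(np.log(0.036) - sigma**2 / 2, sigma, 20)
            table = _table(list(veh), list(trt))
            fc = normalize_to_vehicle(table, _platemap()).group("thymol", 50.0, "pre_nh4cl")["fold_change"]
            hits += 1.6 <= fc <= 2.0
        expected = 0.92
        slack = 3 * np.sqrt(expected * (1 - expected) / n_runs)
        assert hits / n_runs >= expected - slack


class TestComputeFlux:
    def _two_phase_table(self, pre_mean, post_mean):
        recs = []
        for phase, v_mean, t_mean in (("pre_nh4cl", 0.02, pre_mean), ("post_nh4cl", 0.02, post_mean)):
            recs += make_results_records("P1", "A01", phase, [v_mean * 0 + 0.02] * 2)
            recs += make_results_records("P1", "B01", phase, [t_mean] * 3)
        return ResultsTable.from_records(recs)

    def test_flux_ratio_arithmetic(self):
        table = self._two_phase_table(0.03, 0.06)
        resp = normalize_to_vehicle(table, _platemap(phases=("pre_nh4cl", "post_nh4cl")))
        flux = compute_flux(resp)
        row = flux[flux["compound"] == "thymol"].iloc[0]
        assert row["flux_ratio"] == pytest.approx(2.0)

    def test_identical_phase_means_give_no_flux(self):
        table = self._two_phase_table(0.05, 0.05)
        resp = normalize_to_vehicle(table, _platemap(phases=("pre_nh4cl", "post_nh4cl")))
        row = compute_flux(resp).set_index("compound").loc["thymol"]
        assert row["flux_ratio"] == pytest.approx(1.0)

    def test_missing_phase_gives_absent_flux_with_reason(self):
        table = _table([0.02] * 2, [0.04] * 2)
        resp = normalize_to_vehicle(table, _platemap())
        row = compute_flux(resp).set_index("compound").loc["thymol"]
        assert np.isnan(row["flux_ratio"])
        assert row["flux_reason"] == "missing phase"

    def test_planted_flux_ratio_recovered(self):
        pre, post, truth = make_flux_groups(flux_ratio=1.5, n_larvae=30, seed=9)
        assert flux_ratio(pre, post) == pytest.approx(truth.expectations["flux_ratio"], abs=0.15)

    def test_flux_ratio_requires_positive_pre_mean(self):
        with pytest.raises(UsageError):
            flux_ratio(np.zeros(3), np.ones(3))


class TestDoseResponse:
    def _profile(self, fc_post, toxic):
        return DoseResponseProfile(
            compound="X", doses_um=[10.0, 50.0, 100.0, 250.0],
            fc_post=fc_post, fc_pre=[1.0] * 4, toxic=toxic,
        )

    def test_e_max_is_max_over_doses(self):
        p = self._profile([1.0, 1.2, 1.8, 2.5], [False] * 4)
        assert p.e_max == pytest.approx(2.5)

    def test_toxic_top_dose_masked_from_e_max(self):
        p = self._profile([1.0, 1.2, 1.8, 2.5], [False, False, False, True])
        assert p.e_max == pytest.approx(1.8)

    def test_all_toxic_compound_is_excluded(self):
        p = self._profile([1.0, 1.2, 1.8, 2.5], [True] * 4)
        assert p.e_max is None

    def test_e_max_monotone_under_new_nontoxic_dose(self):
        p = self._profile([1.0, 1.2, 1.8, 2.1], [False] * 4)
        before = p.e_max
        p.doses_um.append(500.0)
        p.fc_post.append(1.5)
        p.fc_pre.append(1.0)
        p.toxic.append(False)
        assert p.e_max >= before

    def test_profiles_from_generator_screen(self):
        table, pm, truth = make_screen(n_compounds=4, active_indices=(0,), seed=1,
                                       n_larvae_per_group=8, toxic_cells=((3, 250.0),))
        resp = normalize_to_vehicle(table, pm)
        profiles = {p.compound: p for p in build_dose_response(resp)}
        assert len(profiles) == 4
        assert profiles["C04"].toxic == [False, False, False, True]
        assert all(p.doses_um == sorted(p.doses_um) for p in profiles.values())


class TestRankHits:
    def _profiles(self, e_maxes, doses=None):
        out = []
        for i, e in enumerate(e_maxes):
            dose = (doses or [100.0] * len(e_maxes))[i]
            out.append(DoseResponseProfile(
                compound=f"C{i}", doses_um=[dose], fc_post=[e], fc_pre=[1.0], toxic=[False]))
        return out

    def test_descending_e_max_order(self):
        ranked = rank_hits(self._profiles([2.5, 1.1, 1.9]))
        assert ranked["e_max"].tolist() == [2.5, 1.9, 1.1]

    def test_tie_broken_by_lower_achieving_dose(self):
        ranked = rank_hits(self._profiles([2.0, 2.0], doses=[100.0, 50.0]))
        assert ranked["compound"].tolist() == ["C1", "C0"]

    def test_hit_flag_respects_threshold(self):
        ranked = rank_hits(self._profiles([2.5, 1.1]), hit_fc_threshold=1.5)
        assert ranked.set_index("compound")["hit"].to_dict() == {"C0": True, "C1": False}

    def test_rank_order_invariant_to_global_rescaling(self):
        """Fold changes are scale-free: rescaling all areas keeps the order."""
        table, pm, _ = make_screen(n_compounds=6, active_indices=(2,), seed=5, n_larvae_per_group=6)
        base = rank_hits(build_dose_response(normalize_to_vehicle(table, pm)))
        scaled = table.frame.copy()
        scaled["value"] *= 7.3
        resp2 = normalize_to_vehicle(ResultsTable(scaled), pm)
        again = rank_hits(build_dose_response(resp2))
        assert base["compound"].tolist() == again["compound"].tolist()


class TestHeatmapMatrix:
    def test_toxic_cell_encoded_as_sentinel(self):
        profiles = [
            DoseResponseProfile(compound=f"C{i}", doses_um=[10.0, 50.0, 100.0, 250.0],
                                fc_post=[1.0, 1.1, 1.2, 1.3], fc_pre=[1.0] * 4,
                                toxic=[False, False, i == 0, False])
            for i in range(3)
        ]
        mat = export_heatmap_matrix(profiles)
        assert mat.shape == (3, 4)
        assert (mat.values == TOXIC_SENTINEL).sum() == 1

    def test_empty_profile_list(self):
        assert export_heatmap_matrix([]).empty

    def test_row_order_matches_ranking(self):
        table, pm, _ = make_screen(n_compounds=5, active_indices=(1,), seed=8, n_larvae_per_group=6)
        profiles = build_dose_response(normalize_to_vehicle(table, pm))
        mat = export_heatmap_matrix(profiles)
        assert mat.index.tolist() == rank_hits(profiles)["compound"].tolist()


class TestFitIC50:
    @staticmethod
    def _curve(x, bottom, top, ic50, hill):
        return bottom + (top - bottom) / (1 + (x / ic50) ** hill)

    def test_noise_free_fit_is_exact(self):
        x = np.array([10.0, 30, 60, 100, 180, 300, 1000, 3000])
        y = self._curve(x, 0.0, 1.0, 100.0, 1.0)
        fit = fit_ic50(x, y)
        assert fit.ic50 == pytest.approx(100.0, rel=1e-3)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(1.0, abs=1e-6)

    def test_flat_responses_signal_no_transition(self):
        x = np.array([10.0, 30, 100, 300, 1000])
        y = np.full_like(x, 1.0) + np.linspace(0, 0.02, 5)
        with pytest.raises(NoTransitionError):
            fit_ic50(x, y)

    def test_too_few_doses_rejected(self):
        with pytest.raises(UsageError):
            fit_ic50(np.array([10.0, 100, 1000]), np.array([1.0, 0.5, 0.0]))

    def test_deterministic_given_fixed_data(self):
        rng = np.random.default_rng(0)
        x = np.geomspace(10, 3000, 8)
        y = self._curve(x, 0.05, 1.0, 250.0, 1.5) + rng.normal(0, 0.03, 8)
        f1, f2 = fit_ic50(x, y), fit_ic50(x, y)
        assert f1.ic50 == f2.ic50 and f1.hill == f2.hill
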