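"""Nelson-Aalen, Aalen-Johansen, Kaplan-Meier and cumulative incidence."""

import numpy as np
import pandas as pd
import pytest

from aamsm import msdata, nonparam
from aamsm.nonparam import (
    aalen_johansen,
    cumulative_incidence,
    kaplan_meier,
    nelson_aalen,
    reverse_kaplan_meier,
)
from aamsm.registry import StatePath

from conftest import two_state_data


class TestNelsonAalen:
    def test_hand_computed_increment(self, two_state_structure):
        # 2 at risk, one 1->2 event at t=3: dA = 1/2, variance 1/4
        data = two_state_data([3.0, 5.0], [1, 0])
        (h,) = nelson_aalen(data, two_state_structure)
        assert h.times.tolist() == [3.0]
        assert h.dA.tolist() == [0.5]
        assert h.var.tolist() == [0.25]

    def test_transition_without_events_is_identically_zero(self, structure):
        path = StatePath("p", [(1, 0.0), (2, 10.0)], "censored", 20.0)
        haz = nelson_aalen(msdata.expand_long_format([path], structure), structure)
        by_trans = {h.trans: h for h in haz}
        assert len(by_trans[1].times) == 1
        for q in set(by_trans) - {1}:
            assert len(by_trans[q].times) == 0
            assert by_trans[q].cumulative(1e9) == 0.0

    def test_increments_match_brute_force_risk_sets(self, small_long, structure):
        haz = nelson_aalen(small_long, structure)
        soj = small_long.drop_duplicates(["patient_id", "visit"])
        rng = np.random.default_rng(1)
        for h in haz:
            if len(h.times) == 0:
                continue
            for k in rng.choice(len(h.times), size=min(5, len(h.times)), replace=False):
                t = h.times[k]
                at_risk = ((soj["from_state"] == h.from_state)
                           & (soj["Tstart"] < t) & (t <= soj["Tstop"])).sum()
                events = ((small_long["trans"] == h.trans)
                          & (small_long["status"] == 1)
                          & (small_long["Tstop"] == t)).sum()
                assert h.Y[k] == at_risk
                assert h.dA[k] == pytest.approx(events / at_risk)


class TestAalenJohansen:
    def test_two_state_reduction_equals_kaplan_meier(self, two_state_structure):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 200)
        c = rng.uniform(1, 15, 200)
        times, status = np.minimum(t, c), (t <= c).astype(int)
        data = two_state_data(times, status)
        traj = aalen_johansen(nelson_aalen(data, two_state_structure),
                              structure=two_state_structure)
        km = kaplan_meier(times, status)
        for u in np.sort(times[status == 1]):
            assert traj.at(u)[0] == pytest.approx(km.at(u), abs=1e-12)

    def test_no_events_gives_identity_and_zero_covariance(self, two_state_structure):
        data = two_state_data([4.0, 6.0], [0, 0])
        traj = aalen_johansen(nelson_aalen(data, two_state_structure),
                              structure=two_state_structure)
        assert np.allclose(traj.probs, [[1.0, 0.0]])
        assert np.allclose(traj.cov, 0.0)

    def test_rows_sum_to_one_and_absorbing_monotone(self, small_long, structure):
        traj = aalen_johansen(nelson_aalen(small_long, structure),
                              structure=structure, keep_matrices=True)
        assert np.max(np.abs(traj.probs.sum(axis=1) - 1)) < 1e-10
        assert np.max(np.abs(traj.matrices.sum(axis=2) - 1)) < 1e-10
        for s in structure.absorbing:
            occ = traj.occupation(s)
            assert np.all(np.diff(occ) >= -1e-12)
        assert traj.probs.min() >= -1e-12 and traj.probs.max() <= 1 + 1e-12

    def test_starting_later_uses_only_later_events(self, two_state_structure):
        data = two_state_data([2.0, 4.0, 6.0, 8.0], [1, 1, 1, 0])
        haz = nelson_aalen(data, two_state_structure)
        traj = aalen_johansen(haz, s=3.0, structure=two_state_structure)
        # only the events at 4 and 6 contribute: (1-1/3)(1-1/2) = 1/3
        assert traj.at(7.0)[0] == pytest.approx(1 / 3)

    def test_delta_method_se_close_to_bootstrap(self, structure):
        from aamsm import simulate
        cfg = simulate.SimulatorConfig(n_patients=50, n_eltrombopag=0)
        co = simulate.simulate_cohort(cfg, seed=9)
        data = msdata.expand_long_format(co.paths, structure)
        traj = aalen_johansen(nelson_aalen(data, structure), structure=structure)
        t_med = float(np.median(traj.times))
        i = np.searchsorted(traj.times, t_med, side="right") - 1
        se_delta = np.sqrt(np.diag(traj.cov[i]))
        rng = np.random.default_rng(0)
        pats = [p for p in co.paths]
        boot = []
        for _ in range(200):
            take = rng.integers(0, len(pats), len(pats))
            bp = []
            for j, k in enumerate(take):
                p = pats[k]
                bp.append(StatePath(f"b{j}", p.visits, p.terminal_status,
                                    p.censoring_day))
            d = msdata.expand_long_format(bp, structure)
            tr = aalen_johansen(nelson_aalen(d, structure), structure=structure,
                                compute_var=False)
            boot.append(tr.at(t_med))
        se_boot = np.asarray(boot).std(axis=0)
        mask = se_boot > 0.01      # compare only states actually visited
        ratio = se_delta[mask] / se_boot[mask]
        assert np.all((0.7 <= ratio) & (ratio <= 1.4))


class TestKaplanMeier:
    def test_no_deaths_flat_at_one(self):
        km = kaplan_meier([5.0, 7.0, 9.0], [0, 0, 0])
        assert np.allclose(km.estimate, 1.0)

    def test_single_death_among_four(self):
        km = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0])
        assert km.at(1.0) == pytest.approx(0.75)

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.exponential(10, 60), 1) + 0.1
        s = rng.integers(0, 2, 60)
        km = kaplan_meier(t, s)
        for u in np.unique(t[s == 1]):
            prod = 1.0
            for v in np.unique(t[s == 1]):
                if v <= u:
                    d = ((t == v) & (s == 1)).sum()
                    Y = (t >= v).sum()
                    prod *= 1 - d / Y
            assert km.at(u) == pytest.approx(prod)

    def test_all_censored_at_zero_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([0.0, 0.0], [0, 0])


class TestReverseKaplanMeier:
    def test_all_alive_at_56_gives_median_56(self):
        fu = reverse_kaplan_meier([56.0] * 8, [0] * 8)
        assert fu.median == pytest.approx(56.0)

    def test_all_dead_median_not_reached(self):
        fu = reverse_kaplan_meier([10.0, 20.0, 30.0], [1, 1, 1])
        assert np.allclose(fu.estimate, 1.0)
        assert np.isinf(fu.median)

    def test_median_recovers_known_censoring_distribution(self):
        # uniform administrative censoring on [100, 300] with rare deaths:
        # median follow-up ~ 200
        rng = np.random.default_rng(11)
        n = 4000
        cens = rng.uniform(100, 300, n)
        death = rng.exponential(5000, n)
        t = np.minimum(cens, death)
        s = (death <= cens).astype(int)
        fu = reverse_kaplan_meier(t, s)
        assert fu.median == pytest.approx(200.0, abs=10.0)


class TestCumulativeIncidence:
    def test_single_cause_reduces_to_one_minus_km(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(8, 100)
        s = rng.integers(0, 2, 100)
        (cif,) = cumulative_incidence(t, s, ["event"]).values()
        km = kaplan_meier(t, s)
        for u in np.sort(t[s == 1]):
            assert cif.estimate[np.searchsorted(cif.times, u)] == pytest.approx(
                1 - km.at(u), abs=1e-12
            )

    def test_cifs_and_survival_partition_unity(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(8, 150)
        e = rng.integers(0, 3, 150)
        cifs = cumulative_incidence(t, e, ["a", "b"])
        km = kaplan_meier(t, (e > 0).astype(int))
        total = sum(c.estimate for c in cifs.values())
        grid = next(iter(cifs.values())).times
        surv = np.array([km.at(u) for u in grid])
        assert np.max(np.abs(total + surv - 1)) < 1e-12

    def test_toy_two_cause_hand_computation(self):
        # 6 subjects: cause-1 events at 1 and 3, cause-2 at 2, censored 2.5,
        # cause-1 at 4, censored 5
        t = [1.0, 2.0, 2.5, 3.0, 4.0, 5.0]
        e = [1, 2, 0, 1, 1, 0]
        cifs = cumulative_incidence(t, e, ["relapse", "death"])
        cif1 = cifs["relapse"]
        # hand computation: S(t-) * d/Y summed over event times
        # t=1: S=1,    d1=1, Y=6 -> 1/6
        # t=2: S=5/6,  d2=1, Y=5 (cause 2)
        # t=3: S=5/6*4/5=2/3, d1=1, Y=3 -> 2/9
        # t=4: S=2/3*2/3=4/9,  d1=1, Y=2 -> 2/9
        expect_1 = 1 / 6 + 2 / 9 + 2 / 9
        assert cif1.at(4.5) == pytest.approx(expect_1)
        assert cifs["death"].at(4.5) == pytest.approx(5 / 6 * (1 / 5))

    def test_preset_analyses_run_on_synthetic_registry(self, small_cohort):
        first = nonparam.cif_transfusion_independence_first_line(
            small_cohort.records, small_cohort.paths
        )
        any_line = nonparam.cif_transfusion_independence_any_line(
            small_cohort.records, small_cohort.paths
        )
        c1 = first["transfusion independence (first line)"]
        c2 = any_line["transfusion independence (any line)"]
        # more patients ever reach independence than do so on first line
        assert c2.estimate[-1] >= c1.estimate[-1]
        assert 0.0 <= c1.estimate.min() and c1.estimate.max() <= 1.0
        # both presets rise steeply in the first year
        year = np.searchsorted(c1.times, 365.25)
        assert c1.estimate[year - 1] > 0.4
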