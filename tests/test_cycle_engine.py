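import math

import numpy as np
import pytest

from multifission.cycle_engine import (
    Event,
    GrowthParams,
    GrowthState,
    PatternType,
    PhaseDurations,
    ScenarioConfig,
    StarchParams,
    advance_growth,
    daughters_released,
    dna_fold_increase,
    growth_rate,
    schedule_reproduction,
    simulate_culture,
    starch_step,
)
from conftest import SINGLE_COHORT_LIGHT


class TestGrowthRate:
    def test_zero_in_dark(self):
        assert growth_rate(0.0, GrowthParams()) == 0.0

    def test_saturates_at_mu_max(self):
        g = GrowthParams()
        assert growth_rate(1e12, g) == pytest.approx(g.mu_max, rel=1e-9)

    def test_monotone_in_light_and_reduced_by_stress(self):
        g = GrowthParams()
        assert growth_rate(360.0, g) > growth_rate(80.0, g) > 0
        assert growth_rate(360.0, g, rho_growth=2.0) == pytest.approx(
            growth_rate(360.0, g) / 2.0
        )

    def test_rejects_negative_light(self):
        with pytest.raises(ValueError):
            growth_rate(-1.0, GrowthParams())


class TestAdvanceGrowth:
    def test_full_step_completes_after_ln2_over_rate(self):
        rate = 0.2
        gs = GrowthState()
        cp = None
        while cp is None:
            gs, cp = advance_growth(gs, 0.01, rate)
        assert cp == pytest.approx(math.log(2.0) / rate, abs=1e-9)
        assert gs.proxies["volume"] == 2.0

    def test_dark_freezes_proxies(self):
        gs = GrowthState()
        gs2, cp = advance_growth(gs, 5.0, rate=0.0)
        assert cp is None
        assert gs2.proxies == gs.proxies

    def test_two_steps_give_exact_fourfold(self):
        gs = GrowthState()
        cps = []
        for _ in range(5000):
            gs, cp = advance_growth(gs, 0.01, 0.3, idle_length=1.0, max_steps=2)
            if cp is not None:
                cps.append(cp)
        assert len(cps) == 2
        assert gs.proxies["volume"] == 4.0
        # second step starts only after the idle interval
        assert cps[1] >= cps[0] + 1.0 + math.log(2.0) / 0.3 - 1e-9

    def test_idle_interval_blocks_growth(self):
        gs = GrowthState(idle_until=10.0)
        gs2, cp = advance_growth(gs, 1.0, 0.5)
        assert cp is None and gs2.proxies["volume"] == 1.0

    def test_proxy_cap_freezes_capped_proxy(self):
        gs = GrowthState(caps={"rna": 1})
        for _ in range(5000):
            gs, _ = advance_growth(gs, 0.01, 0.4, max_steps=2)
        assert gs.proxies["volume"] == 4.0
        assert gs.proxies["rna"] == 2.0


class TestScheduleReproduction:
    def test_empty_commitments_give_empty_log(self):
        for pat in PatternType:
            assert schedule_reproduction(pat, [], PhaseDurations()) == []

    def test_rejects_unsorted_commitments(self):
        with pytest.raises(ValueError):
            schedule_reproduction(PatternType.PARACHLORELLA, [5.0, 2.0], PhaseDurations())

    def test_haematococcus_two_sequences_hand_enumerated(self):
        # S,S then M,M then FISSION,FISSION then release; nuclei 1,1,1,2,4
        ev = schedule_reproduction(PatternType.HAEMATOCOCCUS, [2.0, 5.0], PhaseDurations())
        kinds = [e.kind for e in ev if e.kind != "CP"]
        assert kinds == [
            "S_start", "S_end", "S_start", "S_end",
            "M", "M", "FISSION", "FISSION", "DAUGHTER_RELEASE",
        ]
        nuclei = [1]
        for k in kinds:
            if k == "M":
                nuclei.append(nuclei[-1] * 2)
            elif k in ("S_start", "S_end"):
                nuclei.append(nuclei[-1])
        assert nuclei[-2:] == [2, 4]

    def test_parachlorella_three_sequences_fission_cascade(self):
        # successive fissions into 2, 4, 8 spaced by M + C = 1 h
        ev = schedule_reproduction(PatternType.PARACHLORELLA, [2.0, 5.0, 8.0], PhaseDurations())
        fissions = [e.time for e in ev if e.kind == "FISSION"]
        assert len(fissions) == 3
        assert np.allclose(np.diff(fissions), 1.0)
        m_times = [e.time for e in ev if e.kind == "M"]
        last_s_end = max(e.time for e in ev if e.kind == "S_end")
        assert min(m_times) > last_s_end
        # each M immediately precedes its fission (binuclear state lasts C)
        for m, f in zip(m_times, fissions):
            assert f == pytest.approx(m + PhaseDurations().C)

    def test_consecutive_replication_rounds_respect_gap(self):
        phase = PhaseDurations()
        ev = schedule_reproduction(PatternType.PARACHLORELLA, [2.0, 2.5, 3.0], phase)
        starts = [e.time for e in ev if e.kind == "S_start"]
        ends = [e.time for e in ev if e.kind == "S_end"]
        for s, prev_end in zip(starts[1:], ends):
            assert s >= prev_end + phase.inter_S_gap - 1e-9

    def test_chlamydomonas_has_no_s_before_last_commitment(self):
        ev = schedule_reproduction(
            PatternType.CLUSTERED_CHLAMYDOMONAS, [2.0, 5.0, 8.0], PhaseDurations()
        )
        first_s = min(e.time for e in ev if e.kind == "S_start")
        assert first_s >= 8.0 + PhaseDurations().pS - 1e-9


class TestSimpleStatistics:
    @pytest.mark.parametrize(
        "fractions,expected",
        [({4: 1.0}, 16.0), ({4: 0.5, 3: 0.5}, 12.0), ({0: 1.0}, 1.0), ({2: 1.0}, 4.0)],
    )
    def test_population_dna_fold(self, fractions, expected):
        assert dna_fold_increase(fractions) == expected

    def test_dna_fold_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            dna_fold_increase({4: -0.5, 3: 1.5})
        with pytest.raises(ValueError):
            dna_fold_increase({4: 0.5})

    @pytest.mark.parametrize("n,expected", [(4, 16), (3, 8), (0, 1), (1, 2)])
    def test_daughters_released(self, n, expected):
        assert daughters_released(n) == expected

    def test_daughters_rejects_negative(self):
        with pytest.raises(ValueError):
            daughters_released(-1)


class TestStarchStep:
    def test_dark_without_decay_is_constant(self):
        p = StarchParams(maintenance_dark=0.0)
        assert starch_step(5.0, 100.0, 0.05, 0.0, p, dark=True) == 5.0

    def test_full_division_cost_empties_pool(self):
        p = StarchParams(division_cost=1.0)
        assert starch_step(5.0, 100.0, 0.05, 0.0, p, dark=True, fissions=1) == 0.0

    def test_pool_clamped_at_zero(self):
        p = StarchParams(sigma_max=1e-6, maintenance_light=10.0)
        assert starch_step(0.01, 100.0, 1.0, 50.0, p) == 0.0

    def test_synthesis_increases_with_light(self):
        p = StarchParams()
        lo = starch_step(5.0, 100.0, 0.05, 50.0, p)
        hi = starch_step(5.0, 100.0, 0.05, 300.0, p)
        assert hi > lo


PATTERN_NUCLEI_BOUND = {
    PatternType.PARACHLORELLA: lambda n: 2,
    PatternType.HAEMATOCOCCUS: lambda n: 2**n,
    PatternType.CLUSTERED_CHLAMYDOMONAS: lambda n: 2**n,
    PatternType.CONSECUTIVE_SCENEDESMUS: lambda n: 2**n,
}


@pytest.mark.parametrize("pattern", list(PatternType))
@pytest.mark.parametrize("n", [1, 2, 3, 4])
class TestPatternLaws:
    """Structural laws every simulated pattern must obey, for n = 1..4."""

    @pytest.fixture()
    def run(self, pattern, n):
        cfg = ScenarioConfig(
            I_i=SINGLE_COHORT_LIGHT[n],
            pattern=pattern,
            cohort_fractions={n: 1.0},
            horizon=32.0,
        )
        return simulate_culture(cfg)

    def test_completes_without_truncation(self, run, pattern, n):
        assert not run.truncated
        assert run.daughters_per_mother() == 2**n

    def test_event_ordering(self, run, pattern, n):
        ev = run.cohorts[n].events
        times = {k: [e.time for e in ev if e.kind == k] for k in
                 ("CP", "S_start", "S_end", "M", "FISSION", "DAUGHTER_RELEASE")}
        assert len(times["S_start"]) == len(times["M"]) == len(times["FISSION"]) == n
        assert all(a <= b for a, b in zip(times["M"], times["M"][1:]))
        assert max(times["M"]) <= min(times["FISSION"]) or pattern is PatternType.PARACHLORELLA
        assert times["DAUGHTER_RELEASE"][0] >= max(times["FISSION"])
        if pattern in (PatternType.PARACHLORELLA, PatternType.HAEMATOCOCCUS):
            # every replication round ends before the first nuclear division
            assert max(times["S_end"]) <= min(times["M"])
        if pattern is PatternType.CLUSTERED_CHLAMYDOMONAS:
            assert min(times["S_start"]) >= max(times["CP"])

    def test_nuclei_and_ploidy_bounds(self, run, pattern, n):
        d = run.cohorts[n].data
        assert d["nuclei"].max() <= PATTERN_NUCLEI_BOUND[pattern](n)
        if pattern is PatternType.PARACHLORELLA:
            # uninuclear polyploidization up to 2^n C before any division
            assert d["ploidy_C"].max() == 2**n
            assert d["nuclei"].max() <= 2
        if pattern in (PatternType.CLUSTERED_CHLAMYDOMONAS, PatternType.CONSECUTIVE_SCENEDESMUS):
            assert d["ploidy_C"].max() <= 2.0
        if pattern is PatternType.HAEMATOCOCCUS:
            ev = run.cohorts[n].events
            first_fission = min(e.time for e in ev if e.kind == "FISSION")
            pre = d[d["time_h"] < first_fission]
            assert pre["nuclei"].max() == 2**n

    def test_dna_conserved_through_divisions(self, run, pattern, n):
        d = run.cohorts[n].data
        ev = run.cohorts[n].events
        last_s_end = max(e.time for e in ev if e.kind == "S_end")
        release = next(e.time for e in ev if e.kind == "DAUGHTER_RELEASE")
        win = d[(d["time_h"] >= last_s_end) & (d["time_h"] < release)]
        total = win["dna_pg_per_cell"] * win["protoplasts"]
        assert np.allclose(total, 0.1 * 2**n, rtol=1e-12)

    def test_no_dna_synthesis_outside_s_phases(self, run, pattern, n):
        d = run.cohorts[n].data
        ev = run.cohorts[n].events
        total = (d["dna_pg_per_cell"] * d["protoplasts"]).to_numpy()
        in_s = np.zeros(len(d), dtype=bool)
        t = d["time_h"].to_numpy()
        for e in ev:
            if e.kind == "S_start":
                s_end = next(x.time for x in ev if x.kind == "S_end" and x.k == e.k)
                in_s |= (t >= e.time - 1e-9) & (t <= s_end + 1e-9)
        release = next(e.time for e in ev if e.kind == "DAUGHTER_RELEASE")
        increases = np.diff(total) > 1e-12
        outside = ~in_s[1:] & (t[1:] < release)
        assert not np.any(increases & outside)

    def test_growth_step_law_at_release(self, run, pattern, n):
        c = run.cohorts[n]
        d = c.data
        pre = d[d["time_h"] < c.release_time].iloc[-1]
        assert pre["volume_rel"] == pytest.approx(2**n, rel=1e-6)
        assert pre["dry_matter_rel"] == pytest.approx(2**n, rel=1e-6)


class TestSimulateCulture:
    def test_highest_light_reaches_sixteenfold_dna_and_dry_matter(self, fig5_500):
        assert fig5_500.dna_fold == pytest.approx(16.0, rel=1e-12)
        assert fig5_500.data["dry_matter_ug_per_ml"].iloc[-1] == 1600.0
        assert fig5_500.data["dna_pg_per_cell"].max() == pytest.approx(1.6, rel=1e-12)

    def test_lowest_light_two_doublings(self, fig5_110):
        assert fig5_110.dna_fold == pytest.approx(4.0, rel=1e-12)
        assert fig5_110.data["dry_matter_ug_per_ml"].iloc[-1] == 400.0

    def test_mixed_cohort_population_mean(self, fig5_250):
        assert fig5_250.dna_fold == pytest.approx(12.0, rel=1e-12)
        assert fig5_250.daughters_per_mother() == pytest.approx(12.0)

    def test_cell_concentration_multiplies_at_release(self, fig5_500):
        conc = fig5_500.data["cell_conc_1e6_per_ml"]
        assert conc.iloc[0] == 1.0
        assert conc.iloc[-1] == 16.0

    def test_dry_matter_continuous_across_release(self, fig5_500):
        dm = fig5_500.data["dry_matter_ug_per_ml"].to_numpy()
        assert np.max(np.abs(np.diff(dm))) < 100.0  # no 2^n jump at release

    def test_dark_freezes_biomass_but_events_fire(self, fig5_500):
        d = fig5_500.data
        dark = d[(d["time_h"] >= 18.0) & (d["time_h"] < 25.0)]
        assert dark["mean_light"].max() == 0.0
        # culture biomass constant through the dark period (continuous
        # across the daughter release inside it)
        dm = fig5_500.cohorts[4].data
        dark_c = dm[(dm["time_h"] >= 18.0) & (dm["time_h"] < 25.0)]
        assert dark_c["dry_matter_ug_per_ml"].nunique() == 1
        assert any(
            e.kind == "FISSION" and e.time >= 18.0 for e in fig5_500.cohorts[4].events
        )

    def test_mean_light_nonincreasing_while_biomass_grows(self, fig5_500):
        d = fig5_500.data
        light = d[d["time_h"] < 18.0]["mean_light"].to_numpy()
        assert np.all(np.diff(light) <= 1e-9)

    def test_completed_steps_monotone_in_light(self):
        completed = []
        for I in (110.0, 250.0, 500.0):
            tr = simulate_culture(ScenarioConfig(I_i=I, cohort_fractions={4: 1.0}))
            completed.append(tr.cohorts[4].data["completed_steps"].iloc[-1])
        assert completed == sorted(completed)

    def test_zero_cohort_yields_single_cell_no_events(self):
        tr = simulate_culture(ScenarioConfig(I_i=500.0, cohort_fractions={0: 1.0}))
        assert tr.events == []
        assert tr.data["cell_conc_1e6_per_ml"].nunique() == 1
        assert tr.dna_fold == 1.0

    def test_dark_scenario_produces_no_commitments(self):
        tr = simulate_culture(
            ScenarioConfig(
                I_i=500.0, light_schedule=((0.01, 100.0),), cohort_fractions={4: 1.0}
            )
        )
        assert tr.events == []
        # only the single initial light instant contributes any growth
        assert tr.data["dry_matter_ug_per_ml"].iloc[-1] == pytest.approx(100.0, rel=0.03)

    def test_short_horizon_sets_truncation_flag(self):
        tr = simulate_culture(
            ScenarioConfig(I_i=500.0, cohort_fractions={4: 1.0}, horizon=20.0)
        )
        assert tr.truncated

    def test_rejects_invalid_configs(self):
        with pytest.raises(ValueError):
            ScenarioConfig(I_i=500.0, cohort_fractions={4: 0.5})
        with pytest.raises(ValueError):
            ScenarioConfig(I_i=500.0, cohort_fractions={5: 1.0}, max_sequences=4)
        with pytest.raises(ValueError):
            ScenarioConfig(I_i=-10.0)
        with pytest.raises(ValueError):
            ScenarioConfig(I_i=500.0, retardation=(0.5, 1.0))

    def test_deuterium_retardation_slows_growth(self):
        base = simulate_culture(
            ScenarioConfig(I_i=300.0, light_schedule=None, cohort_fractions={1: 1.0})
        )
        slow = simulate_culture(
            ScenarioConfig(
                I_i=300.0,
                light_schedule=None,
                cohort_fractions={1: 1.0},
                retardation=(2.0, 2.0),
                horizon=50.0,
            )
        )
        cp_base = next(e.time for e in base.events if e.kind == "CP")
        cp_slow = next(e.time for e in slow.events if e.kind == "CP")
        assert cp_slow > 1.9 * cp_base


def test_event_rejects_unknown_kind():
    with pytest.raises(ValueError):
        Event(0.0, "MITOSIS")
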