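"""Engine behaviour: expected-value progression, cost bucketing, aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p2i import (
    ARCHETYPE_IDS,
    Project,
    aggregate,
    expected_cost_per_launch,
    expected_phase_cost,
    expected_total_cost,
    project_timeline,
    read_portfolio_csv,
    round_launches_for_report,
    write_portfolio_csv,
)


class TestProjectTimeline:
    def test_simple_repurposed_trajectory(self, ps):
        """Phase-2 entry in 2017: two 2.14-year phases, launch mass 0.457x0.681."""
        ptl = project_timeline(Project("repurposed_simple", entry_phase=2), ps)
        (s2, e2), (s3, e3) = ptl.phase_intervals
        assert (s2, e2) == (2017.0, pytest.approx(2019.14))
        assert (s3, e3) == (pytest.approx(2019.14), pytest.approx(2021.28))
        assert ptl.launch_mass == pytest.approx(0.457 * 0.681, rel=1e-12)
        assert ptl.launch_time == pytest.approx(2021.28)

    def test_simple_vaccine_launch_time_and_mass(self, ps):
        ptl = project_timeline(Project("vaccine_simple"), ps)
        assert ptl.launch_time == pytest.approx(2017 + 3.36 + 1.57 + 2.23 + 2.33)
        assert ptl.launch_mass == pytest.approx(0.41 * 0.684 * 0.459 * 0.708, rel=1e-12)

    def test_zero_capacity_zeroes_everything(self, ps):
        ptl = project_timeline(
            Project("nce_complex", capacity_factor=0.0, multiplicity=5), ps)
        assert ptl.launch_mass == 0.0
        assert all(m == 0.0 for m in ptl.entry_mass)
        assert all(c == 0.0 for c in ptl.phase_cost)
        assert sum(ptl.yearly_cost.values()) == 0.0

    def test_intervals_partition_entry_to_launch(self, ps):
        """Phase intervals abut with no gaps from entry to launch."""
        for aid in ARCHETYPE_IDS:
            proj = Project(aid, entry_phase=ps.archetype(aid).entry_phase_default)
            ptl = project_timeline(proj, ps)
            assert ptl.phase_intervals[0][0] == proj.entry_time
            for (_, end), (start, _) in zip(ptl.phase_intervals, ptl.phase_intervals[1:]):
                assert end == start
            assert ptl.phase_intervals[-1][1] == ptl.launch_time

    def test_entry_mass_non_increasing(self, ps):
        for aid in ARCHETYPE_IDS:
            ptl = project_timeline(
                Project(aid, entry_phase=ps.archetype(aid).entry_phase_default), ps)
            masses = ptl.entry_mass
            assert all(b <= a for a, b in zip(masses, masses[1:]))

    def test_entry_before_applicable_phase_rejected(self, ps):
        with pytest.raises(ValueError, match="earliest applicable"):
            project_timeline(Project("repurposed_simple", entry_phase=0), ps)

    def test_entry_outside_horizon_warns(self, ps):
        with pytest.warns(UserWarning, match="horizon"):
            project_timeline(Project("vaccine_simple", entry_time=2045.0), ps)

    def test_unfunded_phase_costs_nothing(self, ps):
        ptl = project_timeline(
            Project("repurposed_simple", entry_phase=2, funded_phases={2}), ps)
        assert ptl.phase_cost[0] == pytest.approx(5.8)
        assert ptl.phase_cost[1] == 0.0


class TestExpectedPhaseCost:
    def test_nce_simple_phase3(self, ps):
        """Entry mass into phase 3 (0.65 x 0.597 x 0.388) times $32.8M."""
        cost = expected_phase_cost(Project("nce_simple"), 3, ps)
        assert cost == pytest.approx(0.65 * 0.597 * 0.388 * 32.8, rel=1e-12)

    def test_certain_entry_pays_full_point_cost(self, ps):
        cost = expected_phase_cost(Project("vaccine_simple", entry_phase=3), 3, ps)
        assert cost == pytest.approx(111.1)

    def test_non_applicable_phase_is_free(self, ps):
        assert expected_phase_cost(Project("repurposed_simple", entry_phase=2), 2, ps,
                                   ) > 0
        # preclinical precedes entry and is non-applicable: zero either way
        assert expected_phase_cost(Project("repurposed_simple", entry_phase=2), 0, ps) == 0.0

    def test_bound_estimates(self, ps):
        low = expected_phase_cost(Project("vaccine_simple", entry_phase=3), 3, ps, "low")
        high = expected_phase_cost(Project("vaccine_simple", entry_phase=3), 3, ps, "high")
        assert (low, high) == (pytest.approx(56.6), pytest.approx(165.6))


class TestCostPerLaunch:
    def test_diagnostic_assay_closed_form(self, ps):
        """(3.0 + 0.5x2.0 + 0.5x3.5) / 0.5 = 11.5 $M."""
        assert expected_cost_per_launch("diagnostic_assay", None, ps) == pytest.approx(
            11.5, rel=1e-12)

    def test_complex_vaccine_is_the_maximum(self, ps):
        vals = {aid: expected_cost_per_launch(aid, None, ps) for aid in ARCHETYPE_IDS}
        assert max(vals, key=vals.get) == "vaccine_complex"
        assert vals["vaccine_complex"] == pytest.approx(936.6, abs=0.5)

    def test_all_archetypes_below_one_billion(self, ps):
        for aid in ARCHETYPE_IDS:
            assert 0 < expected_cost_per_launch(aid, None, ps) < 1000.0

    def test_low_point_high_ordering(self, ps):
        for aid in ARCHETYPE_IDS:
            low = expected_cost_per_launch(aid, None, ps, "low")
            point = expected_cost_per_launch(aid, None, ps, "point")
            high = expected_cost_per_launch(aid, None, ps, "high")
            assert low <= point <= high


class TestAggregate:
    def test_empty_portfolio_is_zero_over_horizon(self, ps):
        tl = aggregate([], ps)
        assert tl.years == list(ps.horizon_years)
        assert all(v == 0.0 for v in tl.yearly_cost.values())
        assert all(v == 0.0 for v in tl.yearly_launches.values())

    def test_two_identical_projects_double_one(self, ps):
        p = Project("biologic_simple", multiplicity=2)
        one = aggregate([p], ps)
        two = aggregate([p, p], ps)
        for y in one.years:
            assert two.yearly_cost[y] == pytest.approx(2 * one.yearly_cost[y], rel=1e-12)
            assert two.yearly_launches[y] == pytest.approx(
                2 * one.yearly_launches[y], rel=1e-12)

    def test_cumulative_launches_simple_repurposed(self, ps):
        tl = aggregate([Project("repurposed_simple", entry_phase=2)], ps)
        assert tl.cumulative_launches_by(2030) == pytest.approx(0.311217, abs=1e-6)
        # launch in 2021; nothing before
        assert tl.cumulative_launches_by(2020) == 0.0

    def test_conservation_of_cost(self, ps):
        """Calendar bucketing redistributes cost but never creates or loses it."""
        portfolio = [
            Project("vaccine_complex", entry_time=2018.3, multiplicity=3),
            Project("repurposed_simple", entry_phase=2, entry_time=2019.0,
                    capacity_factor=0.8),
            Project("diagnostic_platform", entry_phase=1, entry_time=2020.5),
        ]
        tl = aggregate(portfolio, ps)
        direct = sum(expected_total_cost(p, ps) for p in portfolio)
        assert sum(tl.yearly_cost.values()) == pytest.approx(direct, rel=1e-12)

    def test_occupancy_time_average(self, ps):
        """A phase fully covering a year contributes its whole entry mass."""
        tl = aggregate([Project("repurposed_simple", entry_phase=2,
                                entry_time=2017.0, multiplicity=2)], ps)
        # phase 2 interval [2017, 2019.14) fully covers 2017 and 2018
        assert tl.yearly_occupancy[2017][2] == pytest.approx(2.0, rel=1e-12)
        assert tl.yearly_occupancy[2018][2] == pytest.approx(2.0, rel=1e-12)
        assert tl.yearly_occupancy[2019][2] == pytest.approx(2 * 0.14, abs=1e-9)

    def test_tidy_frame_schema(self, ps):
        df = aggregate([Project("nce_simple")], ps).to_frame()
        assert list(df.columns) == ["year", "metric", "phase", "value"]
        assert set(df["metric"]) == {"cost", "occupancy", "launches", "cumulative_launches"}


@settings(max_examples=50, derandomize=True)
@given(alpha=st.floats(min_value=0.0, max_value=8.0, allow_nan=False),
       mult=st.integers(min_value=0, max_value=6))
def test_homogeneity_in_multiplicity(alpha, mult):
    """Scaling the candidate count scales masses, costs and launches exactly."""
    from p2i import load_default_params
    ps = load_default_params()
    base = project_timeline(Project("nce_innovative", multiplicity=1.0), ps)
    scaled = project_timeline(Project("nce_innovative", multiplicity=alpha * mult
                                      if mult else 0.0), ps)
    factor = alpha * mult if mult else 0.0
    assert scaled.launch_mass == pytest.approx(factor * base.launch_mass, abs=1e-12)
    assert scaled.total_cost == pytest.approx(factor * base.total_cost, rel=1e-12, abs=1e-12)


@pytest.mark.parametrize("x,expected", [
    (0.3112, 0), (10.5, 11), (3.49, 3), (0.5, 1), (2.5, 3), (0.0, 0),
])
def test_round_launches_half_away_from_zero(x, expected):
    assert round_launches_for_report(x) == expected


def test_round_launches_rejects_negative():
    with pytest.raises(ValueError):
        round_launches_for_report(-0.1)


def test_portfolio_csv_round_trip(ps, tmp_path):
    portfolio = [
        Project("vaccine_simple", 0, 2017.0, 2.0, 1.0, frozenset({0, 1, 2, 3}), "malaria"),
        Project("repurposed_simple", 2, 2019.0, 1.5, 0.75, frozenset({2, 3}), None),
    ]
    path = tmp_path / "portfolio.csv"
    write_portfolio_csv(portfolio, path)
    back = read_portfolio_csv(path)
    assert back == portfolio


def test_oversized_portfolio_warns(ps, tmp_path):
    rows = "\n".join("vaccine_simple,0,2017,1,1.0,," for _ in range(151))
    path = tmp_path / "big.csv"
    path.write_text("archetype_id,entry_phase,entry_year,multiplicity,capacity_factor,funded_phases,label\n"
                    + rows + "\n")
    with pytest.warns(UserWarning, match="150"):
        read_portfolio_csv(path)
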