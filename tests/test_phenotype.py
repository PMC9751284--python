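"""Bead calibration, division assignment, cohort statistics, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macscreen import phenotype as ph
from macscreen import pipeline
from macscreen.synthetic_data import (
    CompoundEffect,
    CytonParams,
    expected_population,
    sample_flow_events,
    simulate_population,
)


class TestAbsoluteCount:
    def test_ratio_formula(self):
        assert ph.absolute_count(2000, 400, 10_000) == 50_000
        assert ph.absolute_count(0, 100, 10_000) == 0

    def test_no_beads_is_calibration_failure(self):
        with pytest.raises(ValueError):
            ph.absolute_count(100, 0, 10_000)

    @given(
        live=st.integers(0, 10**6),
        beads=st.integers(1, 10**5),
        added=st.integers(1, 10**6),
        k=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, live, beads, added, k):
        base = ph.absolute_count(live, beads, added)
        assert ph.absolute_count(k * live, beads, added) == pytest.approx(k * base)
        assert ph.absolute_count(live, beads, k * added) == pytest.approx(k * base)

    def test_unbiased_on_sampled_events(self):
        """Bead-ratio estimate of total live cells is unbiased over seeds."""
        p = CytonParams(n0=1000)
        st_ = simulate_population(p, CompoundEffect(), [72.0], seed=0)[0]
        truth = st_.total_live
        ests = []
        for s in range(200):
            ev = sample_flow_events(st_, seed=s)
            live = int((~ev.is_bead & ev.viable).sum())
            beads = int(ev.is_bead.sum())
            ests.append(ph.absolute_count(live, beads, ev.attrs["beads_added"]))
        ests = np.asarray(ests)
        assert abs(ests.mean() - truth) <= 3 * ests.std(ddof=1) / np.sqrt(len(ests))


class TestAssignDivisions:
    def test_exact_halving(self):
        gens = ph.assign_divisions([1e4, 1e4 / 8, 1e4 / 2], i0=1e4)
        assert list(gens) == [0, 3, 1]

    def test_clamping(self):
        assert ph.assign_divisions([1e4 / 2**12], i0=1e4, max_gen=8)[0] == 8
        assert ph.assign_divisions([4e4], i0=1e4)[0] == 0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ph.assign_divisions([0.0], i0=1e4)
        with pytest.raises(ValueError):
            ph.assign_divisions([1.0], i0=-1.0)

    def test_accuracy_at_10pct_cv(self):
        """At CTV noise CV 10%, >= 99% of events get their true generation."""
        p = CytonParams(n0=2000)
        st_ = simulate_population(p, CompoundEffect(), [72.0], seed=1)[0]
        ev = sample_flow_events(st_, ctv_cv=0.10, seed=2)
        live = ev[~ev.is_bead & ev.viable]
        gens = ph.assign_divisions(live["ctv"].to_numpy(), i0=1e4)
        assert (gens == live["true_generation"].to_numpy()).mean() >= 0.99


class TestCohortStatistics:
    def test_cohort_numbers_perfect_doubling(self):
        c = ph.cohort_numbers(ph.DivisionCensus([100, 200, 400], [0, 0, 0]))
        assert list(c) == [100, 100, 100]

    def test_cohort_numbers_empty(self):
        assert list(ph.cohort_numbers(ph.DivisionCensus([0, 0, 0], [0, 0, 0]))) == [0, 0, 0]

    def test_mdn_by_hand(self):
        """N=[100,100] -> C=[100,50] -> MDN = 50/150 = 1/3."""
        census = ph.DivisionCensus([100, 100], [0, 0])
        assert ph.mean_division_number(census) == pytest.approx(1 / 3)

    def test_mdn_all_undivided(self):
        assert ph.mean_division_number(ph.DivisionCensus([500], [0])) == 0.0

    def test_mdn_scale_invariant(self):
        a = ph.DivisionCensus([10, 40, 20], [0, 0, 0])
        b = ph.DivisionCensus([30, 120, 60], [0, 0, 0])
        assert ph.mean_division_number(a) == pytest.approx(ph.mean_division_number(b))

    def test_mdn_empty_is_error(self):
        with pytest.raises(ValueError):
            ph.mean_division_number(ph.DivisionCensus([0.0], [0.0]))

    def test_differentiation_fraction_bounds(self):
        assert ph.differentiation_fraction(ph.DivisionCensus([50, 50], [0, 0])) == 0.0
        assert ph.differentiation_fraction(ph.DivisionCensus([50, 50], [50, 50])) == 100.0

    def test_cd138_fraction_increases_with_generation(self):
        """Division-linked differentiation: per-generation CD138 fraction rises."""
        p = CytonParams(n0=4000, p_diff0=0.0, p_diff_slope=0.05)
        st_ = expected_population(p, CompoundEffect(), [72.0])[0]
        frac = st_.asc / np.maximum(st_.census(), 1e-12)
        populated = st_.census() > 1.0
        assert (np.diff(frac[populated]) >= -1e-9).all()

    def test_total_cohort_constant_without_death(self):
        """Precursor cohort analysis: sum of C_i is time-invariant, death-free."""
        p = CytonParams(n0=1000, death_hazard=0.0)
        totals = []
        for st_ in simulate_population(p, CompoundEffect(), [24, 48, 72], seed=5):
            census = ph.DivisionCensus(st_.census(), st_.asc)
            totals.append(ph.cohort_numbers(census).sum())
        assert np.allclose(totals, 1000)

    def test_mdn_trajectory_matches_oracle(self):
        """Flow-estimated MDN tracks the expectation-derived MDN within 3 MC-SE."""
        p = CytonParams(n0=1000)
        eff = CompoundEffect(s_div=0.9)
        exp_states = expected_population(p, eff, [48.0, 72.0])
        mdn_exp = [
            ph.mean_division_number(ph.DivisionCensus(s.census(), s.asc))
            for s in exp_states
        ]
        for k, t in enumerate([48.0, 72.0]):
            ests = []
            for s in range(60):
                st_ = simulate_population(p, eff, [t], seed=1000 + s)[0]
                ev = sample_flow_events(st_, seed=2000 + s)
                census = ph.build_census(ev, i0=1e4)
                ests.append(ph.mean_division_number(census))
            ests = np.asarray(ests)
            se = ests.std(ddof=1) / np.sqrt(len(ests))
            assert abs(ests.mean() - mdn_exp[k]) <= 3 * se


class TestClassification:
    @staticmethod
    def _reps(count, mdn, cd138, n=6, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "count_24h": count * (1 + jitter * rng.standard_normal(n)),
                "mdn_72h": mdn * (1 + jitter * rng.standard_normal(n)),
                "cd138_pct_72h": cd138 * (1 + jitter * rng.standard_normal(n)),
            }
        )

    def test_identical_groups_are_none(self):
        t = self._reps(1000, 3.0, 30.0, jitter=0.02, seed=1)
        c = self._reps(1000, 3.0, 30.0, jitter=0.02, seed=2)
        cls = ph.classify_compound(t, c)
        assert (cls.survival, cls.proliferation, cls.differentiation) == (
            "none", "none", "none",
        )

    def test_significant_but_small_effect_stays_none(self):
        """A 3% shift with tiny noise is significant but below the effect band."""
        t = self._reps(1030, 3.0, 30.0, jitter=0.001, seed=3)
        c = self._reps(1000, 3.0, 30.0, jitter=0.001, seed=4)
        assert ph.classify_compound(t, c).survival == "none"

    def test_requires_replicates(self):
        t = self._reps(1000, 3.0, 30.0, n=1)
        c = self._reps(1000, 3.0, 30.0, n=6)
        with pytest.raises(ValueError):
            ph.classify_compound(t, c)

    def test_archetype_recovery(self):
        """Survival- and differentiation-only archetypes land on their axes."""
        p = CytonParams()
        comps = {
            "control": CompoundEffect(),
            "killer": CompoundEffect(s_surv=3.0),
            "prc2": CompoundEffect(s_diff=2.0),
        }
        hits = 0
        n_plates = 10
        for k in range(n_plates):
            tbl = pipeline.simulate_plate_phenotypes(p, comps, replicates=6, seed=300 + k)
            cls = ph.classify_plate(tbl)
            ok = tuple(cls.loc["killer", ["survival", "proliferation", "differentiation"]]) == (
                "down", "none", "none",
            ) and tuple(
                cls.loc["prc2", ["survival", "proliferation", "differentiation"]]
            ) == ("none", "none", "up")
            hits += ok
        assert hits >= 9

    def test_missing_control_is_error(self):
        tbl = pipeline.simulate_plate_phenotypes(
            CytonParams(n0=200), {"a": CompoundEffect()}, replicates=2, seed=0
        )
        with pytest.raises(ValueError):
            ph.classify_plate(tbl, control_id="control")
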