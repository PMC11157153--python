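import dataclasses

import numpy as np
import pytest

from modshift.ptm_inference import (
    InferenceConfig,
    PtmEntry,
    PtmTable,
    default_ptm_table,
    enumerate_feasible_patterns,
    enumerate_k_solutions,
    solve_min_both,
    solve_min_error,
    solve_min_ptm,
)

OX = PtmEntry("Ox", 15.9949, 2, {"O": 1})
PH = PtmEntry("Ph", 79.966, 3, {"H": 1, "P": 1, "O": 3})


def _cfg(ref_mass=43652.8, ppm=36.0, **kw):
    return InferenceConfig(reference_mass=ref_mass, mass_tolerance_ppm=ppm, **kw)


class TestEnumerate:
    def test_zero_shift_admits_empty_pattern(self):
        out = enumerate_feasible_patterns(0.0, default_ptm_table(), 0.1)
        assert out[0].counts == (0,) * 9
        assert out[0].error == 0.0

    def test_single_oxidation_for_16da(self):
        table = PtmTable([OX])
        out = enumerate_feasible_patterns(16.0, table, 0.1)
        assert len(out) == 1
        assert out[0].counts == (1,)

    def test_two_phospho_exact(self):
        table = PtmTable([PH, dataclasses.replace(OX, upper_bound=3)])
        out = enumerate_feasible_patterns(159.93, table, 0.05)
        assert len(out) == 1
        assert out[0].counts == (2, 0)

    def test_box_guard(self):
        table = PtmTable([PtmEntry(f"m{i}", 10.0 + i, 100, None) for i in range(5)])
        with pytest.raises(ValueError, match="tighten"):
            enumerate_feasible_patterns(50.0, table, 1.0)


class TestWorkedExamples:
    """Canonical worked decompositions for the stock PTM table."""

    def test_16da_is_one_oxidation_under_all_objectives(self, p53_ref):
        table = default_ptm_table()
        for objective in ("min_ptm", "min_error", "min_both"):
            cfg = _cfg(p53_ref.reference_mass, 36.0, objective=objective)
            [sol] = enumerate_k_solutions(16.0, table, cfg)
            assert str(sol) == "1[Ox]"

    def test_120p7_min_ptm_is_cysteinylation(self, p53_ref):
        cfg = _cfg(p53_ref.reference_mass, 36.0)
        sol = solve_min_ptm(120.7, default_ptm_table(), cfg)
        assert str(sol) == "1[Cys]"
        assert sol.total_ptms == 1
        assert sol.error == pytest.approx(1.56, abs=0.05)

    def test_120p7_min_both_is_phosphate_plus_sodium(self, p53_ref):
        table = default_ptm_table()
        cfg = _cfg(p53_ref.reference_mass, 36.0)
        sol = solve_min_both(120.7, table, cfg)
        assert sorted(sol.as_dict()) == ["Na", "Ph-OH"]
        # cross-check against the exhaustive oracle
        feasible = enumerate_feasible_patterns(120.7, table, cfg.eps_max, cfg)
        best = min(feasible, key=lambda p: p.combined_score)
        assert sol.counts == best.counts


def _random_instance(rng):
    n = rng.integers(2, 5)
    masses = rng.uniform(5.0, 130.0, n)
    ubs = rng.integers(1, 4, n)
    table = PtmTable(
        [PtmEntry(f"m{i}", float(masses[i]), int(ubs[i]), None) for i in range(n)]
    )
    # half the time aim near a feasible sum, otherwise anywhere
    if rng.random() < 0.5:
        counts = rng.integers(0, ubs + 1)
        obs = float(masses @ counts) + rng.normal(0, 0.5)
    else:
        obs = float(rng.uniform(0, 300))
    return table, abs(obs)


class TestOracleEquivalence:
    def test_optima_match_brute_force_on_random_instances(self, rng):
        cfg_template = dict(reference_mass=40000.0, mass_tolerance_ppm=30.0)
        for _ in range(50):
            table, obs = _random_instance(rng)
            cfg = InferenceConfig(**cfg_template)
            feasible = enumerate_feasible_patterns(obs, table, cfg.eps_max, cfg)
            got_p = solve_min_ptm(obs, table, cfg)
            got_e = solve_min_error(obs, table, cfg)
            got_b = solve_min_both(obs, table, cfg)
            if not feasible:
                assert got_p is None and got_e is None and got_b is None
                continue
            assert got_p.total_ptms == min(p.total_ptms for p in feasible)
            assert got_e.error == pytest.approx(
                min(p.error for p in feasible), abs=1e-9
            )
            assert got_b.combined_score == pytest.approx(
                min(p.combined_score for p in feasible), abs=1e-9
            )

    def test_second_lap_matches_oracle_second_best_error(self, rng):
        hits = 0
        for _ in range(40):
            table, obs = _random_instance(rng)
            cfg = InferenceConfig(reference_mass=40000.0, mass_tolerance_ppm=40.0)
            feasible = enumerate_feasible_patterns(obs, table, cfg.eps_max, cfg)
            errors = sorted({round(p.error, 9) for p in feasible})
            if len(errors) < 2:
                continue
            first = solve_min_error(obs, table, cfg)
            second = solve_min_error(obs, table, cfg, previous_eps=first.error)
            assert second is not None
            assert second.error == pytest.approx(errors[1], abs=2e-3)
            hits += 1
        assert hits >= 5  # the generator must exercise the multi-solution case


class TestLaps:
    def test_single_lap_equals_single_solve(self, p53_ref):
        table = default_ptm_table()
        cfg = _cfg(p53_ref.reference_mass, 36.0, objective="min_ptm", laps=1)
        [only] = enumerate_k_solutions(200.7, table, cfg)
        assert only.counts == solve_min_ptm(200.7, table, cfg).counts

    @pytest.mark.parametrize("objective", ["min_ptm", "min_error", "min_both"])
    def test_objective_strictly_increases_across_laps(self, objective, p53_ref):
        table = default_ptm_table()
        cfg = _cfg(p53_ref.reference_mass, 36.0, objective=objective, laps=5)
        sols = enumerate_k_solutions(297.8, table, cfg)
        assert len(sols) >= 2
        if objective == "min_ptm":
            values = [s.total_ptms for s in sols]
        elif objective == "min_error":
            values = [s.error for s in sols]
        else:
            values = [s.combined_score for s in sols]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_early_stop_when_solutions_exhausted(self):
        table = PtmTable([OX])
        cfg = _cfg(43652.8, 36.0, objective="min_ptm", laps=10)
        sols = enumerate_k_solutions(16.0, table, cfg)
        # only 1[Ox] and 2[Ox]... 2 Ox = 31.99, outside eps of 16 -> 1 sol
        assert len(sols) == 1


class TestInvariants:
    def test_all_outputs_feasible(self, rng, p53_ref):
        table = default_ptm_table()
        cfg = _cfg(p53_ref.reference_mass, 36.0, objective="min_both", laps=3)
        for obs in rng.uniform(10, 450, 10):
            for sol in enumerate_k_solutions(float(obs), table, cfg):
                assert sol.error <= cfg.eps_max + 1e-9
                assert all(
                    0 <= c <= ub
                    for c, ub in zip(sol.counts, table.upper_bounds)
                )
                assert sol.total_ptms == sum(sol.counts)
                assert sol.inferred_mass == pytest.approx(
                    float(table.masses @ np.array(sol.counts))
                )

    def test_wider_tolerance_never_worsens_optima(self, p53_ref):
        table = default_ptm_table()
        for obs in (120.7, 216.7, 377.3):
            prev_ptm, prev_err = None, None
            for ppm in (10.0, 20.0, 36.0, 72.0):
                cfg = _cfg(p53_ref.reference_mass, ppm)
                p = solve_min_ptm(obs, table, cfg)
                e = solve_min_error(obs, table, cfg)
                if p is not None and prev_ptm is not None:
                    assert p.total_ptms <= prev_ptm
                if e is not None and prev_err is not None:
                    assert e.error <= prev_err + 1e-9
                prev_ptm = p.total_ptms if p is not None else prev_ptm
                prev_err = e.error if e is not None else prev_err

    def test_infeasible_shift_reported_as_none(self):
        table = PtmTable([OX])
        cfg = _cfg(43652.8, 1.0)
        assert solve_min_ptm(7.7, table, cfg) is None
        assert solve_min_error(7.7, table, cfg) is None
        assert solve_min_both(7.7, table, cfg) is None


class TestPtmTableIO:
    def test_csv_round_trip(self, tmp_path):
        table = default_ptm_table()
        path = tmp_path / "ptms.csv"
        table.to_csv(path)
        back = PtmTable.from_csv(path)
        assert back.names == table.names
        np.testing.assert_allclose(back.masses, table.masses, rtol=1e-6)
        assert list(back.upper_bounds) == list(table.upper_bounds)

    def test_mass_only_rows(self, tmp_path):
        path = tmp_path / "ptms.csv"
        path.write_text("name,mass,upper_bound\nX,100.5,2\n")
        table = PtmTable.from_csv(path)
        assert table.entries[0].mass == 100.5

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            PtmTable([OX, dataclasses.replace(OX)])

    def test_average_vs_monoisotopic_masses(self):
        avg = default_ptm_table(average=True)
        mono = default_ptm_table(average=False)
        i = avg.names.index("Cys")
        assert avg.masses[i] == pytest.approx(119.14, abs=0.01)
        assert mono.masses[i] == pytest.approx(119.004, abs=0.01)
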