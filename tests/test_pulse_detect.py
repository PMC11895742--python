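"""Pulse likelihood, placement search, count selection, bootstrap CIs."""

import itertools

import numpy as np
import pytest

from stratext.column import column_from_thicknesses
from stratext.occurrence_db import compute_ranges
from stratext.pulse_detect import (
    RecoveryProfile,
    _prep,
    estimate_recovery,
    fit_interval,
    fit_k_pulses,
    lads_in_window,
    per_clade_pulses,
    pulse_confidence,
    select_pulse_count,
)
from stratext.synthetic_data import SimConfig, simulate_occurrences


def make_window(n_beds=20):
    col = column_from_thicknesses([str(i + 1) for i in range(n_beds)], [0.5] * n_beds)
    return col.window("1", str(n_beds))


def profile(p, n_beds=20, eps=1e-4):
    return RecoveryProfile(window=make_window(n_beds), p=np.full(n_beds, p), eps=eps)


def oracle_loglik(lads, recovery, pulses):
    """Exhaustive per-taxon assignment: best valid pulse for each LAD."""
    logp, cum = _prep(recovery)
    total = 0.0
    for l in lads.values():
        best = -np.inf
        for P in pulses:
            if P >= l:
                best = max(best, logp[l] + cum[P + 1] - cum[l + 1])
        total += best
    return total


def oracle_best_placement(lads, recovery, k):
    """Grid scan over all k-subsets of observed LAD beds."""
    cand = sorted(set(lads.values()))
    best = (-np.inf, None)
    for combo in itertools.combinations(cand, k):
        ll = oracle_loglik(lads, recovery, combo)
        if ll > best[0] + 1e-12:
            best = (ll, combo)
    return best


class TestRecoveryEstimate:
    def test_fully_sampled_bed_has_p_one(self, column10):
        occs = []
        from stratext.occurrence_db import Occurrence

        for t in "ABCD":
            for b in ("2", "5"):
                occs.append(Occurrence(t, "Mollusca", b))
        ranges = compute_ranges(occs, column10)
        rec = estimate_recovery(ranges, column10.window("1", "10"))
        assert rec.p[1] == 1.0 and rec.p[4] == 1.0

    def test_partial_sampling_fraction(self, column10):
        from stratext.occurrence_db import Occurrence

        occs = [Occurrence(t, "Mollusca", b) for t in "ABCD" for b in ("2", "6")]
        occs.append(Occurrence("A", "Mollusca", "4"))
        ranges = compute_ranges(occs, column10)
        rec = estimate_recovery(ranges, column10.window("1", "10"))
        assert rec.p[3] == pytest.approx(0.25)

    def test_empty_bed_gets_floor(self, column10):
        from stratext.occurrence_db import Occurrence

        occs = [Occurrence(t, "Mollusca", "2") for t in "AB"]
        ranges = compute_ranges(occs, column10)
        rec = estimate_recovery(ranges, column10.window("1", "10"))
        assert rec.p[7] == pytest.approx(1.0 / (2 * 2))


class TestFitKPulses:
    def test_complete_sampling_single_bed_pulse(self):
        rec = profile(1.0)
        lads = {f"t{i}": 7 for i in range(10)}
        m = fit_k_pulses(lads, rec, k=1)
        assert m.pulse_beds == ["8"] and m.loglik == pytest.approx(0.0)

    def test_complete_sampling_two_clusters(self):
        rec = profile(1.0)
        lads = {f"a{i}": 4 for i in range(5)} | {f"b{i}": 15 for i in range(5)}
        m = fit_k_pulses(lads, rec, k=2)
        assert m.pulse_beds == ["5", "16"] and m.loglik == pytest.approx(0.0)
        assert {m.assignment[f"a{i}"] for i in range(5)} == {0}
        assert {m.assignment[f"b{i}"] for i in range(5)} == {1}

    def test_too_few_distinct_lad_beds(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_k_pulses({"a": 3, "b": 3}, profile(0.7), k=2)

    def test_simulated_single_pulse_recovered_within_one_bed(self):
        cfg = SimConfig(n_taxa=50, n_beds=20, true_k=1, pulse_beds=[17], recovery_p=0.6, seed=42)
        occs, truth = simulate_occurrences(cfg)
        col = cfg.column()
        ranges = compute_ranges(occs, col)
        window = col.window("1", "20")
        lads = lads_in_window(ranges, window)
        rec = RecoveryProfile(window=window, p=np.full(20, 0.6), eps=1e-3)
        m = fit_k_pulses(lads, rec, k=1)
        fitted_bed = int(m.pulse_beds[0]) - 1
        assert abs(fitted_bed - 17) <= 1
        # the fitted optimum must equal the exhaustive scan's
        ll, combo = oracle_best_placement(lads, rec, 1)
        assert m.loglik == pytest.approx(ll, abs=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_bruteforce_on_random_instances(self, k, rng):
        rec = profile(0.65, n_beds=12, eps=1e-3)
        for trial in range(15):
            n_taxa = int(rng.integers(6, 25))
            lad_beds = rng.choice(np.arange(12), size=int(rng.integers(max(k, 2), 8)), replace=False)
            lads = {f"t{i}": int(rng.choice(lad_beds)) for i in range(n_taxa)}
            if len(set(lads.values())) < k:
                continue
            m = fit_k_pulses(lads, rec, k=k)
            ll, combo = oracle_best_placement(lads, rec, k)
            assert m.loglik == pytest.approx(ll, abs=1e-9)

    def test_nesting_likelihood_never_decreases_with_k(self, rng):
        rec = profile(0.7, n_beds=15, eps=1e-3)
        lads = {f"t{i}": int(b) for i, b in enumerate(rng.integers(0, 15, size=40))}
        lls = [fit_k_pulses(lads, rec, k).loglik for k in range(1, min(5, len(set(lads.values()))) )]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


class TestFitInterval:
    def test_complete_sampling_uniform_lads(self):
        rec = profile(1.0, n_beds=30)
        lads = {f"t{i}": 4 + (i % 21) for i in range(42)}  # beds 5..25
        m = fit_interval(lads, rec)
        lo, hi = m.interval_beds
        assert int(lo) == 5 and int(hi) == 25

    def test_single_lad_bed_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|single"):
            fit_interval({"a": 3, "b": 3}, profile(0.7))

    def test_simulated_interval_bounds_within_two_beds(self):
        cfg = SimConfig(
            n_taxa=80, n_beds=30, true_k=0, interval_beds=(5, 25), recovery_p=0.7, seed=11
        )
        occs, truth = simulate_occurrences(cfg)
        col = cfg.column()
        window = col.window("1", "30")
        lads = lads_in_window(compute_ranges(occs, col), window)
        rec = RecoveryProfile(window=window, p=np.full(30, 0.7), eps=1e-3)
        m = fit_interval(lads, rec, window)
        lo, hi = (int(b) - 1 for b in m.interval_beds)
        assert abs(lo - 5) <= 2 and abs(hi - 25) <= 2


class TestSelection:
    def test_single_bed_complete_sampling_selects_one_pulse(self):
        rec = profile(1.0)
        lads = {f"t{i}": 9 for i in range(12)}
        m = select_pulse_count(lads, rec, K_max=3, seed=0)
        assert m.k == 1 and m.pulse_beds == ["10"]

    def test_two_distant_clusters_select_two_pulses(self):
        rec = profile(1.0)
        lads = {f"a{i}": 3 for i in range(10)} | {f"b{i}": 16 for i in range(10)}
        m = select_pulse_count(lads, rec, K_max=3, seed=0)
        assert m.k == 2 and m.pulse_beds == ["4", "17"]

    def test_selection_is_deterministic_given_seed(self):
        cfg = SimConfig(n_taxa=50, true_k=2, pulse_beds=[8, 15], recovery_p=0.7, seed=5)
        occs, _ = simulate_occurrences(cfg)
        col = cfg.column()
        window = col.window("1", "20")
        lads = lads_in_window(compute_ranges(occs, col), window)
        rec = RecoveryProfile(window=window, p=np.full(20, 0.7), eps=1e-3)
        m1 = select_pulse_count(lads, rec, K_max=3, seed=99)
        m2 = select_pulse_count(lads, rec, K_max=3, seed=99)
        assert m1.k == m2.k and m1.pulse_beds == m2.pulse_beds and m1.loglik == m2.loglik


class TestPulseConfidence:
    def test_zero_width_ci_under_complete_sampling(self):
        rec = profile(1.0)
        lads = {f"t{i}": 7 for i in range(10)}
        m = pulse_confidence(fit_k_pulses(lads, rec, 1), n_boot=49, seed=3)
        (lo, hi), = m.pulse_cis
        assert lo == hi == m.pulse_heights[0]

    def test_cis_deterministic_given_seed(self):
        cfg = SimConfig(n_taxa=40, true_k=1, pulse_beds=[12], recovery_p=0.7, seed=2)
        occs, _ = simulate_occurrences(cfg)
        col = cfg.column()
        window = col.window("1", "20")
        lads = lads_in_window(compute_ranges(occs, col), window)
        rec = RecoveryProfile(window=window, p=np.full(20, 0.7), eps=1e-3)
        m = fit_k_pulses(lads, rec, 1)
        c1 = pulse_confidence(m, n_boot=99, seed=7).pulse_cis
        c2 = pulse_confidence(m, n_boot=99, seed=7).pulse_cis
        assert c1 == c2

    def test_ci_covers_truth_in_most_replicates(self):
        # coverage spot check at modest replicate count; the pulse CI is a
        # percentile bootstrap over taxa at fixed k
        hits = 0
        n_rep = 30
        for s in range(n_rep):
            cfg = SimConfig(n_taxa=60, true_k=1, pulse_beds=[14], recovery_p=0.7, seed=100 + s)
            occs, _ = simulate_occurrences(cfg)
            col = cfg.column()
            window = col.window("1", "20")
            lads = lads_in_window(compute_ranges(occs, col), window)
            rec = RecoveryProfile(window=window, p=np.full(20, 0.7), eps=1e-3)
            m = pulse_confidence(fit_k_pulses(lads, rec, 1), n_boot=99, seed=s, confidence=0.95)
            (lo, hi), = m.pulse_cis
            truth_height = col.bed("15").midpoint
            hits += lo - 1e-9 <= truth_height <= hi + 1e-9
        assert hits >= int(0.8 * n_rep)


class TestPerClade:
    def test_small_clade_reported_insufficient(self, column10):
        from stratext.occurrence_db import Occurrence

        occs = [Occurrence(f"t{i}", "Bryozoa", b) for i in range(3) for b in ("2", "4")]
        ranges = compute_ranges(occs, column10)
        out = per_clade_pulses(ranges, column10.window("1", "10"), min_richness=10)
        assert out["Bryozoa"] == "insufficient"

    def test_two_clades_with_distinct_pulses_recovered(self):
        col = column_from_thicknesses([str(i + 1) for i in range(20)], [0.5] * 20)
        window = col.window("1", "20")
        occs = []
        rng = np.random.default_rng(8)
        for clade, pulse in (("Arthropoda", 6), ("Mollusca", 15)):
            cfg = SimConfig(n_taxa=40, true_k=1, pulse_beds=[pulse], recovery_p=0.8,
                            seed=int(rng.integers(1 << 30)))
            sim_occs, _ = simulate_occurrences(cfg)
            for o in sim_occs:
                occs.append(
                    type(o)(f"{clade}_{o.taxon}", clade, o.bed_id, o.qualifier, o.habitat,
                            o.is_palynomorph, o.source, o.resolved)
                )
        ranges = compute_ranges(occs, col)
        rec = RecoveryProfile(window=window, p=np.full(20, 0.8), eps=1e-3)
        out = per_clade_pulses(ranges, window, min_richness=5, seed=1, recovery=rec)
        arth, moll = out["Arthropoda"], out["Mollusca"]
        assert abs(int(arth.pulse_beds[-1]) - 7) <= 1
        assert abs(int(moll.pulse_beds[-1]) - 16) <= 1
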