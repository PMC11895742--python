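"""Simulation studies validating each statistical component.

Each study generates data with the synthetic-data module under the
conditions the methods assume, runs the corresponding estimator, and
returns summary metrics (recovery rates, biases, type-I error rates).
They are the package's standing validation experiments: the test suite
asserts thresholds on their outputs and the acceptance script reports
them.  All studies are deterministic functions of their seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import assoc, segmented
from .column import column_from_thicknesses
from .occurrence_db import compute_ranges
from .pulse_detect import (
    RecoveryProfile,
    fit_k_pulses,
    lads_in_window,
    select_pulse_count,
)
from .synthetic_data import SimConfig, simulate_occurrences


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _fit_sim(cfg: SimConfig, seed: int, K_max: int = 3, n_boot: int = 99):
    """Simulate one occurrence dataset and run pulse-count selection."""
    cfg.seed = int(seed)
    occs, truth = simulate_occurrences(cfg)
    col = cfg.column()
    window = col.window("1", str(cfg.n_beds))
    lads = lads_in_window(compute_ranges(occs, col), window)
    rec = RecoveryProfile(
        window=window, p=cfg.recovery_vector(), eps=1.0 / (2 * max(len(lads), 1))
    )
    model = select_pulse_count(lads, rec, window, K_max=K_max, n_boot=n_boot, seed=int(seed))
    return model, truth


def pulse_single_recovery(n_rep: int = 200, seed: int = 0) -> dict:
    """One true pulse: 60 taxa, 20 beds, recovery 0.7, pulse at bed 16."""
    true_bed = 15
    seeds = _child_seeds(seed, n_rep)
    k_hits = 0
    errors = []
    for s in seeds:
        cfg = SimConfig(n_taxa=60, n_beds=20, true_k=1, pulse_beds=[true_bed], recovery_p=0.7)
        model, _ = _fit_sim(cfg, s)
        if model.k == 1:
            k_hits += 1
            errors.append((int(model.pulse_beds[0]) - 1) - true_bed)
    return {
        "k1_selected_pct": 100.0 * k_hits / n_rep,
        "pulse_bias_beds": float(np.mean(errors)) if errors else np.nan,
        "n": n_rep,
    }


def pulse_two_recovery(n_rep: int = 200, seed: int = 0) -> dict:
    """Two pulses 8 beds apart, 40 taxa assigned to each, recovery 0.7."""
    seeds = _child_seeds(seed, n_rep)
    k_hits = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        # exactly 40 taxa per pulse: merge two single-pulse populations
        occs, lows = [], []
        col = None
        for pulse, tag in ((7, "lo"), (15, "hi")):
            cfg = SimConfig(
                n_taxa=40, n_beds=20, true_k=1, pulse_beds=[pulse], recovery_p=0.7,
                seed=int(rng.integers(2**31)),
            )
            sub, _ = simulate_occurrences(cfg)
            col = cfg.column()
            for o in sub:
                occs.append(
                    type(o)(f"{tag}_{o.taxon}", o.clade, o.bed_id, o.qualifier, o.habitat,
                            o.is_palynomorph, o.source, o.resolved)
                )
        window = col.window("1", "20")
        lads = lads_in_window(compute_ranges(occs, col), window)
        rec = RecoveryProfile(window=window, p=np.full(20, 0.7),
                              eps=1.0 / (2 * max(len(lads), 1)))
        model = select_pulse_count(lads, rec, window, K_max=3, n_boot=99, seed=int(s))
        k_hits += model.k == 2
    return {"k2_selected_pct": 100.0 * k_hits / n_rep, "n": n_rep}


def interval_recovery(n_rep: int = 200, seed: int = 0) -> dict:
    """Continuous extinction over 15 beds, recovery 0.8: k=0 expected."""
    seeds = _child_seeds(seed, n_rep)
    k_hits = 0
    for s in seeds:
        cfg = SimConfig(
            n_taxa=60, n_beds=20, true_k=0, interval_beds=(3, 17), recovery_p=0.8
        )
        model, _ = _fit_sim(cfg, s)
        k_hits += model.k == 0
    return {"interval_selected_pct": 100.0 * k_hits / n_rep, "n": n_rep}


def bruteforce_agreement(n_instances: int = 60, seed: int = 0) -> dict:
    """fit_k_pulses vs exhaustive placement scan on small instances."""
    rng = np.random.default_rng(seed)
    col = column_from_thicknesses([str(i + 1) for i in range(12)], [0.5] * 12)
    window = col.window("1", "12")
    agree = total = 0
    for _ in range(n_instances):
        p = rng.uniform(0.3, 0.9)
        rec = RecoveryProfile(window=window, p=np.full(12, p), eps=1e-3)
        n_lad_beds = int(rng.integers(3, 9))
        lad_beds = rng.choice(np.arange(12), size=n_lad_beds, replace=False)
        lads = {f"t{i}": int(rng.choice(lad_beds)) for i in range(int(rng.integers(6, 30)))}
        uniq = sorted(set(lads.values()))
        from .pulse_detect import _prep

        logp, cum = _prep(rec)
        for k in range(1, min(3, len(uniq)) + 1):
            fitted = fit_k_pulses(lads, rec, k, window)
            best = -np.inf
            for combo in itertools.combinations(uniq, k):
                ll = 0.0
                for l in lads.values():
                    cand = [logp[l] + cum[P + 1] - cum[l + 1] for P in combo if P >= l]
                    ll += max(cand) if cand else -np.inf
                best = max(best, ll)
            total += 1
            agree += abs(fitted.loglik - best) < 1e-9
    return {"agreement_pct": 100.0 * agree / total, "n": total}


def segmented_recovery(n_rep: int = 200, seed: int = 0) -> dict:
    """One-break recovery and straight-line type-I control.

    100 samples over 6 m, break at 3.0 m, slopes 0 then 2 per metre,
    noise sd = 10% of the signal's range.  Reported: the share of
    replicates with the fitted breakpoint within ±0.5 m and (strictly)
    within half of one inter-sample spacing; and the share of pure-line
    replicates where BIC selection keeps zero breakpoints.
    """
    seeds = _child_seeds(seed, 2 * n_rep)
    x = np.linspace(0.0, 6.0, 100)
    spacing = x[1] - x[0]
    psi, slope2 = 3.0, 2.0
    signal = slope2 * np.clip(x - psi, 0.0, None)
    sigma = 0.10 * np.ptp(signal)
    within_half_m = within_half_spacing = 0
    for s in seeds[:n_rep]:
        rng = np.random.default_rng(int(s))
        y = signal + rng.normal(0.0, sigma, x.size)
        fit = segmented.fit_segmented(x, y, k=1, seed=int(s))
        err = abs(fit.breakpoints[0] - psi)
        within_half_m += err <= 0.5
        within_half_spacing += err <= 0.5 * spacing
    line = 1.0 + 0.5 * x
    sigma_line = 0.10 * np.ptp(line)
    k0 = 0
    for s in seeds[n_rep:]:
        rng = np.random.default_rng(int(s))
        y = line + rng.normal(0.0, sigma_line, x.size)
        k0 += segmented.select_segmented(x, y, K_max=3, seed=int(s)).n_breakpoints == 0
    return {
        "break_within_half_height_unit_pct": 100.0 * within_half_m / n_rep,
        "break_within_half_spacing_pct": 100.0 * within_half_spacing / n_rep,
        "line_k0_selected_pct": 100.0 * k0 / n_rep,
        "n": n_rep,
    }


def glm_recovery(n_rep: int = 200, n_obs: int = 200, seed: int = 0) -> dict:
    """Poisson slope recovery and the intercept-only closed form."""
    seeds = _child_seeds(seed, n_rep)
    slopes = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        x = rng.uniform(-1.0, 1.0, n_obs)
        y = rng.poisson(np.exp(1.0 + 2.0 * x))
        res = assoc.fit_poisson_glm(y, pd.DataFrame({"x": x}))
        slopes.append(res.params["x"])
    bias_pct = 100.0 * abs(float(np.mean(slopes)) - 2.0) / 2.0
    intercept_err = abs(
        float(assoc.fit_poisson_glm([2, 2, 2]).params["const"]) - np.log(2.0)
    )
    return {
        "slope_bias_pct": bias_pct,
        "intercept_only_abs_error": intercept_err,
        "n": n_rep,
    }


def dbrda_validation(n_sims: int = 1000, n_perm: int = 199, seed: int = 0) -> dict:
    """Unconstrained-PCoA agreement and permutation type-I error.

    Type-I: random 30-taxon × 12-bed incidence, Jaccard distances, one
    independent Gaussian constraint; rejection rate at alpha = 0.05.
    The PCoA cross-check eigendecomposes the Gower-centered matrix
    directly, independent of the dbRDA code path.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(10, 2))
    diff = pts[:, None, :] - pts[None, :, :]
    d = pd.DataFrame(np.sqrt((diff**2).sum(-1)))
    res = assoc.partial_dbrda(d)
    # independent principal-coordinate reference: direct double-centering
    A = -0.5 * d.to_numpy() ** 2
    n = len(A)
    C = np.eye(n) - np.ones((n, n)) / n
    ref = np.sort(np.linalg.eigvalsh(C @ A @ C))[::-1]
    ours = np.sort(res.unconstrained_eigenvalues)[::-1]
    max_diff = float(np.max(np.abs(ours - ref[: len(ours)])))

    seeds = _child_seeds(seed + 1, n_sims)
    rejections = 0
    for s in seeds:
        r = np.random.default_rng(int(s))
        inc = pd.DataFrame(
            (r.random((30, 12)) < 0.4).astype(int), columns=[f"b{i}" for i in range(12)]
        )
        dist = assoc.jaccard_distances(inc)
        x = pd.DataFrame({"x": r.normal(size=12)})
        out = assoc.partial_dbrda(dist, constraints=x)
        out = assoc.permutation_test_dbrda(out, n_perm=n_perm, seed=int(s))
        rejections += out.overall_p <= 0.05
    return {
        "pcoa_max_eigenvalue_diff": max_diff,
        "perm_type1_rate": rejections / n_sims,
        "n": n_sims,
    }


def range_ci_coverage(n_taxa: int = 10000, H: int = 5, seed: int = 0) -> dict:
    """C = 0.5 uniform-recovery CI bracketing rate over simulated taxa."""
    rng = np.random.default_rng(seed)
    u = np.sort(rng.uniform(0.0, 1.0, size=(n_taxa, H)), axis=1)
    obs_range = u[:, -1] - u[:, 0]
    C = 0.5
    ext = obs_range * ((1.0 - C) ** (-1.0 / (H - 1)) - 1.0)
    coverage = float(np.mean(u[:, -1] + ext >= 1.0))
    return {"coverage_pct": 100.0 * coverage, "n": n_taxa}
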