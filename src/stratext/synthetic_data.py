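"""Synthetic stratigraphic datasets with known truth.

Generators that emulate the statistical structure the analysis assumes:
occurrence matrices from per-bed Bernoulli sampling of taxa whose true
extinctions follow k discrete pulses or a continuous interval (the
Signor–Lipps thinning model); proxy series that are piecewise-linear in
height with additive Gaussian noise; and richness counts tied to the
proxies through a log-linear Poisson link.  Every generator is a pure
function of its configuration and seed and returns the ground truth
alongside the data, so recovery tests never re-derive anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .column import StratColumn, column_from_thicknesses
from .occurrence_db import Occurrence
from .proxy_db import ProxySeries


@dataclass
class ProxySpec:
    """Piecewise-linear truth for one synthetic proxy."""

    name: str
    intercept: float
    slopes: list[float]  # one per segment, bottom-up
    breakpoints: list[float]  # heights, strictly increasing; len = len(slopes) - 1
    noise_sd: float
    n_samples: int = 100

    def mean(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        out = self.intercept + self.slopes[0] * h
        prev = self.slopes[0]
        for bp, s in zip(self.breakpoints, self.slopes[1:]):
            out = out + (s - prev) * np.clip(h - bp, 0.0, None)
            prev = s
        return out


@dataclass
class SimConfig:
    """Full specification of a synthetic section and its biota.

    Defaults give a section of 20 equal beds with 60 taxa, a single
    extinction pulse three-quarters of the way up, and uniform per-bed
    recovery probability 0.7 — a sampling regime under which pulse
    timing is recoverable but visibly smeared by the Signor–Lipps
    effect.
    """

    n_taxa: int = 60
    n_beds: int = 20
    bed_thickness: float = 0.5
    true_k: int = 1  # 0 => continuous extinction interval
    pulse_beds: list[int] = field(default_factory=lambda: [15])  # bed positions (0-based)
    interval_beds: tuple[int, int] = (3, 17)
    recovery_p: float | list[float] = 0.7
    proxies: list[ProxySpec] = field(default_factory=list)
    glm_coefficients: list[float] = field(default_factory=list)  # beta0, beta1, ...
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_k > 0 and len(self.pulse_beds) != self.true_k:
            raise ValueError("pulse_beds length must equal true_k")
        for b in self.pulse_beds:
            if not 0 <= b < self.n_beds:
                raise ValueError("pulse bed outside the column")
        p = np.atleast_1d(np.asarray(self.recovery_p, dtype=float))
        if np.any((p < 0) | (p > 1)):
            raise ValueError("recovery probabilities must lie in [0, 1]")

    def column(self) -> StratColumn:
        return column_from_thicknesses(
            [str(i + 1) for i in range(self.n_beds)],
            [self.bed_thickness] * self.n_beds,
        )

    def recovery_vector(self) -> np.ndarray:
        p = np.asarray(self.recovery_p, dtype=float)
        if p.ndim == 0:
            return np.full(self.n_beds, float(p))
        if len(p) != self.n_beds:
            raise ValueError("per-bed recovery vector length mismatch")
        return p


def simulate_occurrences(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw an occurrence table plus its truth record.

    Each taxon gets a true extinction bed — its assigned pulse, or a
    uniform draw over the interval — and an origination bed uniform at
    or below it; it is then recorded in each lived-through bed with the
    bed's recovery probability.  Taxa never recovered anywhere are
    dropped (and counted in the truth record), mirroring the fact that
    wholly unsampled species are invisible to any database.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = cfg.recovery_vector()
    if cfg.true_k > 0:
        assignment = rng.integers(0, cfg.true_k, size=cfg.n_taxa)
        ext = np.array(cfg.pulse_beds)[assignment]
    else:
        lo, hi = cfg.interval_beds
        ext = rng.integers(lo, hi + 1, size=cfg.n_taxa)
        assignment = None
    orig = np.array([rng.integers(0, e + 1) for e in ext])
    occs: list[Occurrence] = []
    dropped = 0
    kept_idx = []
    for t in range(cfg.n_taxa):
        beds = np.arange(orig[t], ext[t] + 1)
        hits = beds[rng.random(len(beds)) < p[beds]]
        if len(hits) == 0:
            dropped += 1
            continue
        kept_idx.append(t)
        for b in hits:
            occs.append(
                Occurrence(
                    taxon=f"sp{t:04d}",
                    clade="Problematica",
                    bed_id=str(b + 1),
                    source="synthetic",
                )
            )
    truth = {
        "true_k": cfg.true_k,
        "pulse_beds": list(cfg.pulse_beds),
        "interval_beds": tuple(cfg.interval_beds),
        "extinction_beds": {f"sp{t:04d}": int(ext[t]) for t in kept_idx},
        "origination_beds": {f"sp{t:04d}": int(orig[t]) for t in kept_idx},
        "assignment": (
            {f"sp{t:04d}": int(assignment[t]) for t in kept_idx} if assignment is not None else None
        ),
        "n_dropped": dropped,
    }
    return occs, truth


def simulate_proxy(spec: ProxySpec, column: StratColumn, rng: np.random.Generator):
    """Sample one proxy series on the column with Gaussian noise."""
    h = np.sort(rng.uniform(column.base, column.top, size=spec.n_samples))
    mean = spec.mean(h)
    values = mean + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    truth = {
        "breakpoints": list(spec.breakpoints),
        "slopes": list(spec.slopes),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
    }
    return ProxySeries(proxy=spec.name, heights=h, values=values), truth


def simulate_linked_richness(
    proxy_beds: pd.DataFrame, coefficients, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts per bed with log-linear dependence on proxies.

    counts_b ~ Poisson(exp(beta0 + sum_j beta_j * x_{bj})).
    """
    beta = np.asarray(coefficients, dtype=float)
    X = proxy_beds.to_numpy(float)
    if len(beta) != X.shape[1] + 1:
        raise ValueError("coefficient vector must be [intercept] + one per proxy column")
    eta = beta[0] + X @ beta[1:]
    if np.any(eta > 50):
        raise ValueError("Poisson mean overflow: linear predictor exceeds exp(50)")
    return rng.poisson(np.exp(eta))


def occurrences_to_frame(occs: list[Occurrence]) -> pd.DataFrame:
    """Occurrence records in the CSV dialect the loader reads."""
    return pd.DataFrame(
        {
            "taxon": [o.taxon for o in occs],
            "clade": [o.clade for o in occs],
            "bed_id": [o.bed_id for o in occs],
            "qualifier": [o.qualifier for o in occs],
            "habitat": [o.habitat for o in occs],
            "palynomorph": [o.is_palynomorph for o in occs],
            "source": [o.source for o in occs],
            "resolved": [o.resolved for o in occs],
        }
    )


def fixture_mini_meishan():
    """A small deterministic section used throughout docs and tests.

    12 beds, 40 taxa with a known two-pulse extinction (beds 6 and 11,
    0-based positions 5 and 10) under recovery probability 0.9, and four
    proxies: one with a single breakpoint at the first pulse horizon,
    one pure trend, one flat series with an implanted spike, and one
    noisy flat series.  Deterministic: built from a fixed internal seed.
    """
    cfg = SimConfig(
        n_taxa=40,
        n_beds=12,
        bed_thickness=0.5,
        true_k=2,
        pulse_beds=[5, 10],
        recovery_p=0.9,
        proxies=[
            ProxySpec("proxy_break", intercept=1.0, slopes=[0.2, -2.0], breakpoints=[2.75],
                      noise_sd=0.15, n_samples=80),
            ProxySpec("proxy_trend", intercept=-3.0, slopes=[1.0], breakpoints=[],
                      noise_sd=0.2, n_samples=60),
            ProxySpec("proxy_spike", intercept=0.5, slopes=[0.0], breakpoints=[],
                      noise_sd=0.05, n_samples=60),
            ProxySpec("proxy_flat", intercept=2.0, slopes=[0.0], breakpoints=[],
                      noise_sd=0.3, n_samples=60),
        ],
        glm_coefficients=[2.5, -0.5, 0.3],
        seed=20240513,
    )
    rng = np.random.default_rng(cfg.seed)
    column = cfg.column()
    occs, truth = simulate_occurrences(cfg, rng)
    proxies = {}
    proxy_truth = {}
    for spec in cfg.proxies:
        series, t = simulate_proxy(spec, column, rng)
        proxies[spec.name] = series
        proxy_truth[spec.name] = t
    # implant a volcanic-tracer-style spike into the flat spike proxy
    spike = proxies["proxy_spike"]
    spike.values[len(spike) // 2] += 3.0
    proxy_truth["proxy_spike"]["spike_index"] = len(spike) // 2
    return {
        "config": cfg,
        "column": column,
        "occurrences": occs,
        "truth": truth,
        "proxies": proxies,
        "proxy_truth": proxy_truth,
        "recovery_p": 0.9,
    }
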