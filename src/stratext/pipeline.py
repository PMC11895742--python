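"""End-to-end orchestration: occurrences → pulses, proxies → state
shifts → imputation → association models, from a single configuration.

The stages mirror the analysis workflow for a bed-resolved section:
vet the occurrence database, build stratigraphic ranges, detect
extinction pulses per clade and pooled, standardize and aggregate the
proxy series, fit segmented regressions and impute unsampled beds,
restrict to the analysis window where fossil and proxy coverage
overlap, then run the correlation/VIF screen, the paired Poisson GLMs,
the partial dbRDA with permutation tests, and the proxy-variance
versus extinction-rate check.  Every stochastic step derives its seed
from the config, so a rerun with the same config reproduces the report
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, occurrence_db, proxy_db, pulse_detect, segmented
from .column import Bed, StratColumn


@dataclass
class AnalysisConfig:
    """Configuration for a full run.

    ``window`` defaults to beds 22–29a, the interval over which proxy
    coverage overlaps the fossil record at a Meishan-style section;
    endpoints are inclusive.
    """

    seed: int
    occurrences_csv: str | None = None
    column_csv: str | None = None
    synonyms_csv: str | None = None
    proxies_csv: str | None = None
    tie_points_csv: str | None = None
    window: tuple[str, str] = ("22", "29a")
    ci_confidence: float = 0.95
    K_max_pulses: int = 3
    K_max_segments: int = 3
    min_clade_richness: int = 10
    vif_threshold: float = 10.0
    forced_drops: tuple[str, ...] = ()
    focal_pair: tuple[str, str] | None = None
    condition_columns: tuple[str, ...] = ()
    n_perm: int = 199
    n_boot: int = 99

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        for key in ("window", "focal_pair"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(str(v) for v in raw[key])
        for key in ("forced_drops", "condition_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def run_full_analysis(
    config: AnalysisConfig,
    data: dict | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage and return (optionally write) the report bundle.

    *data* may supply in-memory inputs (keys ``column``, ``occurrences``,
    ``proxies``, optionally ``synonyms``) in place of the CSV paths —
    the synthetic fixture plugs in this way.
    """
    log: list[str] = []
    column, occs, synonyms, proxies = _load_inputs(config, data, log)

    ranges = _ranges_stage(occs, synonyms, column, log)
    try:
        window = column.window(*config.window)
    except (KeyError, ValueError) as exc:
        raise StageError("window", exc) from exc
    if len(window) < 2:
        raise StageError("window", ValueError("analysis window has fewer than 2 beds"))

    recovery = None
    if data is not None and "recovery_p" in data:
        p = np.broadcast_to(np.asarray(data["recovery_p"], float), (len(window),)).copy()
        recovery = pulse_detect.RecoveryProfile(window=window, p=p)
        log.append("using supplied recovery profile (known sampling regime)")
    pulses = _pulse_stage(ranges, window, config, log, recovery)
    seg_fits, per_bed, tags, anomalies = _proxy_stage(proxies, window, config, log)
    assoc_out = _assoc_stage(ranges, proxies, per_bed, window, config, log)

    report = {
        "config": config,
        "log": log,
        "ranges": ranges,
        "pulses": pulses,
        "segmented_fits": seg_fits,
        "proxy_beds": per_bed,
        "proxy_status": tags,
        "anomalies": anomalies,
        **assoc_out,
    }
    if outdir is not None:
        write_report(report, outdir)
    return report


@_stage("load")
def _load_inputs(config: AnalysisConfig, data: dict | None, log: list[str]):
    if data is not None:
        column = data["column"]
        occs = data["occurrences"]
        synonyms = data.get("synonyms", {})
        proxies = data["proxies"]
    else:
        column = StratColumn.from_csv(config.column_csv)
        occs = occurrence_db.load_occurrences(config.occurrences_csv, column)
        synonyms = (
            occurrence_db.load_synonyms(config.synonyms_csv) if config.synonyms_csv else {}
        )
        proxies = proxy_db.load_proxies(config.proxies_csv, column)
        if config.tie_points_csv:
            ties = proxy_db.load_tie_points(config.tie_points_csv)
            proxies = {k: proxy_db.map_core_to_outcrop(v, ties) for k, v in proxies.items()}
            log.append("core-to-outcrop scaling applied to all proxy series")
    log.append(f"loaded {len(occs)} occurrences, {len(proxies)} proxies, {len(column)} beds")
    return column, occs, synonyms, proxies


@_stage("ranges")
def _ranges_stage(occs, synonyms, column, log):
    vetted = occurrence_db.vet_occurrences(occs, synonyms)
    log.append(f"vetting kept {len(vetted)} of {len(occs)} occurrences")
    resolved, n_dropped = occurrence_db.drop_unresolved(vetted)
    log.append(f"dropped {n_dropped} occurrences not resolved to a single bed")
    ranges = occurrence_db.compute_ranges(resolved, column)
    log.append(f"computed {len(ranges)} taxon ranges")
    return ranges


@_stage("pulses")
def _pulse_stage(ranges, window, config, log, recovery=None):
    out = pulse_detect.per_clade_pulses(
        ranges,
        window,
        min_richness=config.min_clade_richness,
        K_max=config.K_max_pulses,
        n_boot=config.n_boot,
        seed=config.seed,
        recovery=recovery,
    )
    for clade, model in out.items():
        if isinstance(model, str):
            log.append(f"pulses[{clade}]: insufficient richness")
        else:
            log.append(f"pulses[{clade}]: k={model.k} at beds {model.pulse_beds}")
    return out


@_stage("proxies")
def _proxy_stage(proxies, window, config, log):
    seg_fits, per_bed, tags, anomalies = {}, {}, {}, {}
    for name, series in proxies.items():
        fit = segmented.select_segmented(
            series.heights, series.values, K_max=config.K_max_segments, seed=config.seed
        )
        seg_fits[name] = fit
        anomalies[name] = segmented.flag_anomalies(series.heights, series.values, fit)
        agg = proxy_db.aggregate_to_beds(series, window)
        filled, tag = proxy_db.impute_missing(agg, fit, window)
        per_bed[name] = filled
        tags[name] = tag
        n_imp = int((tag == "imputed").sum())
        n_spk = int(anomalies[name].flags.sum())
        log.append(
            f"proxy {name}: {fit.n_breakpoints} breakpoint(s), "
            f"{n_imp} bed(s) imputed, {n_spk} spike(s) flagged"
        )
    return seg_fits, pd.DataFrame(per_bed), pd.DataFrame(tags), anomalies


@_stage("assoc")
def _assoc_stage(ranges, proxies, per_bed, window, config, log):
    richness = occurrence_db.richness_per_bed(ranges, window)
    rates = occurrence_db.extinction_rate_per_bed(ranges, window)

    screen = assoc.correlation_screen(per_bed)
    reduced, audit = assoc.drop_collinear(
        per_bed, vif_threshold=config.vif_threshold, forced_drops=config.forced_drops
    )
    for entry in audit:
        log.append(f"collinearity drop: {entry['column']} ({entry['reason']})")

    if config.focal_pair and all(c in per_bed.columns for c in config.focal_pair):
        a, b = config.focal_pair
        base = reduced
        for c in (a, b):
            if c not in base.columns:
                base = pd.concat([base, per_bed[[c]]], axis=1)
        glm = assoc.run_glm_pair(richness, base, focal_a=a, focal_b=b)
        log.append(
            f"GLM pair: AIC {glm['aic_a']:.2f} (keep {a}) vs {glm['aic_b']:.2f} (keep {b})"
        )
    else:
        glm = {"model_a": assoc.fit_poisson_glm(richness, reduced), "model_b": None}
        log.append("single GLM fitted (no focal pair configured)")

    incidence = _incidence_matrix(ranges, window)
    dist = assoc.jaccard_distances(incidence)
    condition = (
        per_bed[list(config.condition_columns)] if config.condition_columns else None
    )
    constraints = reduced.drop(columns=list(config.condition_columns), errors="ignore")
    dbrda = assoc.partial_dbrda(dist, constraints, condition)
    dbrda = assoc.permutation_test_dbrda(dbrda, n_perm=config.n_perm, seed=config.seed)
    log.append(f"dbRDA: {dbrda.proportion_constrained:.3f} of inertia constrained, "
               f"overall p={dbrda.overall_p:.4f}")

    var_by_bed = _within_bed_variance(proxies, window)
    var_rate = assoc.variance_vs_extinction_rate(var_by_bed, rates)

    return {
        "richness": richness,
        "extinction_rates": rates,
        "correlations": screen,
        "vif_audit": audit,
        "glm": glm,
        "dbrda": dbrda,
        "variance_vs_rate": var_rate,
        "incidence": incidence,
    }


def _incidence_matrix(ranges, window: list[Bed]) -> pd.DataFrame:
    """Taxa × beds 0/1 sampled-incidence matrix over the window."""
    idx = {b.order_index: j for j, b in enumerate(window)}
    taxa = [r.taxon for r in ranges]
    M = np.zeros((len(taxa), len(window)), dtype=int)
    for i, r in enumerate(ranges):
        for h in r.horizons:
            j = idx.get(h)
            if j is not None:
                M[i, j] = 1
    return pd.DataFrame(M, index=taxa, columns=[b.id for b in window])


def _within_bed_variance(proxies, window: list[Bed]) -> pd.DataFrame:
    out = {}
    for name, series in proxies.items():
        vals = np.full(len(window), np.nan)
        for j, bed in enumerate(window):
            sel = (series.heights >= bed.base_height) & (series.heights < bed.top_height)
            if sel.sum() >= 2:
                vals[j] = float(np.var(series.values[sel], ddof=1))
        out[name] = vals
    return pd.DataFrame(out, index=[b.id for b in window])


def write_report(report: dict, outdir: str | Path) -> None:
    """Serialize the report bundle: TSV/CSV/JSON named by figure analog."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pulse_rows = []
    for clade, model in report["pulses"].items():
        if isinstance(model, str):
            pulse_rows.append({"clade": clade, "status": model})
        else:
            pulse_rows.append(
                {
                    "clade": clade,
                    "status": "fitted",
                    "k": model.k,
                    "pulse_beds": ";".join(model.pulse_beds),
                    "pulse_heights_m": ";".join(f"{h:.6g}" for h in model.pulse_heights),
                    "interval_beds": (
                        ";".join(model.interval_beds) if model.interval_beds else ""
                    ),
                    "loglik": f"{model.loglik:.6g}",
                    "bic": f"{model.score:.6g}",
                }
            )
    pd.DataFrame(pulse_rows).to_csv(outdir / "fig2_pulses.tsv", sep="\t", index=False)

    seg_rows = []
    for name, fit in report["segmented_fits"].items():
        seg_rows.append(
            {
                "proxy": name,
                "n_breakpoints": fit.n_breakpoints,
                "breakpoints_m": ";".join(f"{b:.6g}" for b in fit.breakpoints),
                "segment_slopes": ";".join(f"{s:.6g}" for s in fit.segment_slopes),
                "bic": f"{fit.bic:.6g}",
            }
        )
    pd.DataFrame(seg_rows).to_csv(outdir / "fig3_breakpoints.tsv", sep="\t", index=False)

    glm = report["glm"]
    frames = []
    for tag in ("model_a", "model_b"):
        if glm.get(tag) is not None:
            f = glm[tag].summary_frame()
            f.insert(0, "model", tag)
            frames.append(f)
    pd.concat(frames).to_csv(outdir / "table1_glm.tsv", sep="\t", float_format="%.6g")

    dbrda = report["dbrda"]
    dbrda.site_scores.to_csv(outdir / "fig4_scores.csv", float_format="%.6g")
    if not dbrda.biplot_scores.empty:
        dbrda.biplot_scores.to_csv(outdir / "fig4_biplot.csv", float_format="%.6g")
    report["variance_vs_rate"].to_csv(
        outdir / "variance_rate.tsv", sep="\t", index=False, float_format="%.6g"
    )
    report["proxy_beds"].to_csv(outdir / "proxy_beds.csv", float_format="%.6g")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(
            {
                "log": report["log"],
                "dbrda_overall_p": dbrda.overall_p,
                "dbrda_term_p": dbrda.term_p.to_dict() if dbrda.term_p is not None else None,
                "seed": report["config"].seed,
            },
            fh,
            indent=2,
        )
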