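"""End-to-end orchestration of the heat-stress analysis.

Stages run in dependency order — thermal exposure, respirometry,
intracellular pH, isotopes, phenotypes, then the cross-cutting statistics
— each consuming instrument-export tables (real or synthetic) and emitting
tidy result tables. A failed stream is recorded and skipped without
aborting independent streams. Cohorts are analyzed separately throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import isotopes as iso
from . import morphometrics as morpho
from . import ph_imaging as phmod
from . import respirometry as resp
from . import stats as st
from . import thermal

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "pattern_summary"]


@dataclass
class RunConfig:
    """Input paths per data stream (any subset) and run parameters."""

    temperature_logs: str | None = None
    offset_pairs: str | None = None
    o2_traces: str | None = None
    plate_map: str | None = None
    protein: str | None = None
    cells: str | None = None
    standards: str | None = None
    isotopes: str | None = None
    phenotypes: str | None = None
    outdir: str = "results"
    seed: int = 0
    bootstrap: int = 200
    mmm_c: float = 25.0
    threshold_c: float = 26.0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ResultBundle:
    exposure: pd.DataFrame | None = None
    rates: pd.DataFrame | None = None
    metabolic_summaries: pd.DataFrame | None = None
    thermal_performance: pd.DataFrame | None = None
    phi: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    pulse_report: object = None
    phenotypes: pd.DataFrame | None = None
    stats_reports: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


# --- individual stages ------------------------------------------------------


def analyze_thermal(
    logs: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    mmm_c: float = 25.0,
    threshold_c: float = 26.0,
) -> pd.DataFrame:
    """Exposure table: per (cohort, treatment) mean/max daily mean and eDHW.

    Container loggers are offset-corrected when paired spot measurements
    are supplied, averaged into one daily treatment series, then
    accumulated into eDHW.
    """
    logs = logs.copy()
    logs["timestamp"] = pd.to_datetime(logs["timestamp"])
    if "cohort" not in logs.columns:
        logs["cohort"] = ""
    rows = []
    for (cohort, treatment), g in logs.groupby(["cohort", "treatment"]):
        daily_frames = []
        for logger_id, gl in g.groupby("logger_id"):
            series = thermal.TemperatureSeries(
                logger_id=str(logger_id),
                treatment=str(treatment),
                timestamps=pd.DatetimeIndex(gl["timestamp"]),
                temps_c=gl["temperature"].to_numpy(dtype=float),
            )
            if pairs is not None:
                sel = pairs[pairs["treatment"].astype(str) == str(treatment)]
                if "cohort" in pairs.columns:
                    sel = sel[sel["cohort"] == cohort]
                if len(sel):
                    series = thermal.apply_container_offset(
                        series, list(zip(sel["t_tank"], sel["t_container"]))
                    )
            daily_frames.append(
                pd.DataFrame(
                    [
                        {"date": d.date, "mean_c": d.mean_c}
                        for d in thermal.daily_means(series)
                    ]
                )
            )
        daily = pd.concat(daily_frames).groupby("date")["mean_c"].mean()
        summaries = [
            thermal.DailySummary(date=dt, mean_c=m, min_c=m, max_c=m, n_obs=1)
            for dt, m in daily.items()
        ]
        exp = thermal.compute_edhw(
            summaries, mmm_c=mmm_c, threshold_c=threshold_c, treatment=str(treatment)
        )
        rows.append(
            {
                "cohort": cohort,
                "treatment": treatment,
                "mean_c": float(daily.mean()),
                "max_daily_mean_c": float(daily.max()),
                "edhw_c_week": exp.edhw_c_week,
                "hot_days": exp.hot_days,
            }
        )
    return pd.DataFrame(rows).sort_values(["cohort", "treatment"]).reset_index(drop=True)


def analyze_respirometry(
    traces: pd.DataFrame,
    plate_map: pd.DataFrame,
    protein: pd.DataFrame,
    bootstrap: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rates per vial×light, per-animal metabolic summaries, thermal optima."""
    pm = plate_map.set_index("vial_id")
    prot = protein.set_index("animal_id")["protein_ug"]

    animal_rates: list[resp.RateEstimate] = []
    blank_rates: list[resp.RateEstimate] = []
    for (vial, light), g in traces.groupby(["vial_id", "light_umol"]):
        g = g.sort_values("timestamp_s")
        row = pm.loc[vial]
        animal = row["animal_id"]
        animal = None if (pd.isna(animal) or animal == "") else str(animal)
        trace = resp.O2Trace(
            vial_id=str(vial),
            animal_id=animal,
            light_umol=float(light),
            timestamps_s=g["timestamp_s"].to_numpy(dtype=float),
            o2_umol_l=g["o2_umol_l"].to_numpy(dtype=float),
            temperature_c=float(row["temperature_c"]),
        )
        est = resp.extract_rate(trace)
        (blank_rates if animal is None else animal_rates).append(est)

    corrected = resp.blank_correct(animal_rates, blank_rates)
    dark_blanks = resp._blank_stats([b for b in blank_rates if b.light_umol == 0.0])

    rate_rows = []
    by_animal: dict[str, list] = {}
    animal_meta: dict[str, tuple] = {}
    for c in corrected:
        r = c.rate
        row = pm.loc[r.vial_id]
        by_animal.setdefault(r.animal_id, []).append(c)
        animal_meta[r.animal_id] = (bool(row["symbiotic"]), r.temperature_c)
        rate_rows.append(
            {
                "animal_id": r.animal_id,
                "vial_id": r.vial_id,
                "temperature_c": r.temperature_c,
                "light_umol": r.light_umol,
                "slope_umol_l_min": r.slope_umol_l_min,
                "corrected_slope_umol_l_min": c.corrected_slope_umol_l_min,
                "r_squared": r.r_squared,
                "blank_mean": c.blank_mean,
                "blank_se": c.blank_se,
            }
        )

    summaries: list[resp.MetabolicSummary] = []
    for animal, cs in by_animal.items():
        symbiotic, temp = animal_meta[animal]
        dark = [c for c in cs if c.rate.light_umol == 0.0]
        below = False
        if dark:
            bmean, bse, _ = dark_blanks[(temp, 0.0)]
            below = resp.flag_below_lod(dark[0].rate, bmean, bse)
        if below:
            summaries.append(
                resp.MetabolicSummary(
                    animal_id=animal, temperature_c=temp, symbiotic=symbiotic,
                    below_lod=True,
                )
            )
            continue
        p_ug = float(prot[animal])
        points = tuple(
            sorted(
                (
                    c.rate.light_umol,
                    resp.normalize_to_protein(
                        resp.to_total_o2(c.corrected_slope_umol_l_min), p_ug
                    ),
                )
                for c in cs
            )
        )
        curve = resp.PICurve(
            animal_id=animal, symbiotic=symbiotic, temperature_c=temp, points=points
        )
        summaries.append(resp.fit_pi_curve(curve))

    summary_df = pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "temperature_c": s.temperature_c,
                "symbiotic": s.symbiotic,
                "p_max": s.p_max,
                "ledr": s.ledr,
                "ledr_consumption": None if s.ledr is None else -s.ledr,
                "edf": s.edf,
                "below_lod": s.below_lod,
            }
            for s in summaries
        ]
    )

    perf_rows = []
    for symbiotic in (True, False):
        group = [s for s in summaries if s.symbiotic == symbiotic and not s.below_lod]
        for metric in ("p_max", "ledr"):
            try:
                tp = resp.fit_thermal_performance(
                    group, metric=metric, n_bootstrap=bootstrap, seed=seed
                )
            except ValueError as exc:
                logger.warning("thermal performance (%s, symbiotic=%s): %s",
                               metric, symbiotic, exc)
                continue
            perf_rows.append(
                {
                    "symbiotic": symbiotic,
                    "metric": metric,
                    "t_opt_c": tp.t_opt_c,
                    "t_opt_se_c": tp.t_opt_se_c,
                    "edf": tp.edf,
                    "n_bootstrap": tp.n_bootstrap,
                }
            )
    return pd.DataFrame(rate_rows), summary_df, pd.DataFrame(perf_rows)


def analyze_ph(cells: pd.DataFrame, standards: pd.DataFrame) -> pd.DataFrame:
    """Per-animal median pH by cell class, with cohort/treatment metadata."""
    curve = phmod.fit_calibration(list(zip(standards["ph"], standards["ratio"])))
    measurements = [
        phmod.CellMeasurement(
            cell_id=str(r.cell_id),
            animal_id=str(r.animal_id),
            cell_class=str(r.cell_class),
            i_585=float(r.i_585),
            i_640=float(r.i_640),
            bg_585=float(r.bg_585),
            bg_640=float(r.bg_640),
        )
        for r in cells.itertuples(index=False)
    ]
    records = phmod.summarize_phi(measurements, curve)
    phi = pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "cell_class": r.cell_class,
                "median_ph": r.median_ph,
                "n_cells": r.n_cells,
            }
            for r in records
        ]
    )
    meta_cols = [c for c in ("cohort", "treatment", "symbiotic") if c in cells.columns]
    if meta_cols:
        meta = cells[["animal_id", *meta_cols]].drop_duplicates("animal_id")
        meta["animal_id"] = meta["animal_id"].astype(str)
        phi = phi.merge(meta, on="animal_id", how="left")
    return phi


def analyze_isotopes(samples_df: pd.DataFrame, alpha: float = 0.05):
    """Enrichment summaries plus the pulse-validation contrast report."""
    samples = []
    for r in samples_df.to_dict("records"):
        samples.append(
            iso.IsotopeSample(
                animal_id=str(r["animal_id"]),
                symbiotic=bool(r.get("symbiotic", True)),
                fraction=str(r["fraction"]),
                delta13c_permil=r.get("delta13c_permil"),
                atom_pct_13c=r.get("atom_pct_13c"),
                dry_mass_mg=float(r.get("dry_mass_mg", np.nan)),
                treatment=str(r.get("treatment", "")),
            )
        )
    summaries = iso.summarize_enrichment(samples)
    enrichment = pd.DataFrame(
        [
            {"group": s.group, "mean_ap": s.mean_ap, "se_ap": s.se_ap, "n": s.n}
            for s in summaries
        ]
    )
    report = iso.pulse_validation_contrast(samples, alpha=alpha)
    return enrichment, report


def analyze_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-animal phenotype table with scores and normalizations."""
    color = size = counts = None
    if {"roi_red_intensity", "standard_red_intensity"} <= set(pheno.columns):
        color = pheno[["animal_id", "roi_red_intensity", "standard_red_intensity"]]
    if {"disk_px", "ruler_px_per_cm"} <= set(pheno.columns):
        size = pheno[["animal_id", "disk_px", "ruler_px_per_cm"]]
    count_cols = [c for c in pheno.columns if c.startswith("count_rep")]
    if count_cols and "protein_ug" in pheno.columns:
        counts = pheno[["animal_id", *count_cols, "protein_ug"]]
    elif {"cells_per_animal", "protein_ug"} <= set(pheno.columns):
        counts = pheno[["animal_id", "cells_per_animal", "protein_ug"]]
    tidy = morpho.join_phenotypes(color=color, size=size, counts=counts)
    meta_cols = [
        c for c in ("cohort", "treatment", "symbiotic", "container")
        if c in pheno.columns
    ]
    if meta_cols:
        tidy = tidy.merge(
            pheno[["animal_id", *meta_cols]].drop_duplicates("animal_id"),
            on="animal_id",
            how="left",
        )
    return tidy


def _response_report(
    data: pd.DataFrame,
    response: str,
    container_col: str | None,
    alpha: float,
) -> dict:
    """Model-select treatment effect on one response, then Tukey contrasts."""
    candidates = [
        st.CandidateModel(f"{response} ~ 1", name="intercept"),
        st.CandidateModel(f"{response} ~ C(treatment)", name="treatment"),
    ]
    if container_col and data[container_col].nunique() > 1:
        candidates.append(
            st.CandidateModel(
                f"{response} ~ C(treatment)",
                kind="mixed",
                groups=container_col,
                name="treatment+container",
            )
        )
    fits = st.fit_candidates(data, candidates)
    best, ranking = st.rank_by_aicc(fits)
    contrast_fit = best if best.candidate.kind != "gam" else None
    contrasts = st.tukey_contrasts(
        data, response, "treatment", fit=contrast_fit, alpha=alpha
    )
    return {"ranking": ranking, "best": best.candidate.label(), "contrasts": contrasts}


def analyze_stats(
    phenotypes: pd.DataFrame | None,
    phi: pd.DataFrame | None,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Cross-cutting statistics, per cohort: model selection + Tukey on
    symbiont density and pH, plus PCA/PERMANOVA on the symbiotic phenotype
    profile by treatment."""
    reports: dict = {}
    if phenotypes is not None and "treatment" in phenotypes.columns:
        for cohort, g in phenotypes.groupby("cohort"):
            sym = g[g["symbiotic"] == True]  # noqa: E712
            if sym["treatment"].nunique() < 2:
                continue
            rep = {}
            rep["density"] = _response_report(
                sym.assign(log_cells=np.log(sym["cells_per_animal"])),
                "log_cells",
                "container" if "container" in sym.columns else None,
                alpha,
            )
            pvars = [
                c for c in ("cells_per_animal", "protein_ug", "color_score_pct",
                            "oral_disk_cm")
                if c in sym.columns
            ]
            if len(pvars) >= 2 and len(sym) >= 6:
                X = sym[pvars].to_numpy(dtype=float)
                rep["permanova"] = st.permanova(
                    X, sym["treatment"].to_numpy(), n_perm=999, seed=seed
                )
                rep["pca"] = st.pca(X)
            reports[f"phenotypes/{cohort}"] = rep
    if phi is not None and "treatment" in phi.columns:
        for (cohort, cls), g in phi.groupby(["cohort", "cell_class"]):
            if g["treatment"].nunique() < 2:
                continue
            reports[f"phi/{cohort}/{cls}"] = {
                "contrasts": st.tukey_contrasts(g, "median_ph", "treatment", alpha=alpha)
            }
    return reports


# --- orchestration ----------------------------------------------------------


def _read(path):
    return None if path is None else pd.read_csv(path)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute all stages for which inputs are configured.

    Each stage's outputs are written under ``config.outdir`` together with
    a manifest recording the configuration, seeds, and output hashes.
    Failure of one stream is logged into ``bundle.errors`` and does not
    abort the others.
    """
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 — stream isolation is the contract
            logger.error("stage %s failed: %s", name, exc)
            bundle.errors[name] = str(exc)
            return None

    if config.temperature_logs:
        bundle.exposure = stage(
            "thermal",
            lambda: analyze_thermal(
                _read(config.temperature_logs),
                _read(config.offset_pairs),
                mmm_c=config.mmm_c,
                threshold_c=config.threshold_c,
            ),
        )
    if config.o2_traces and config.plate_map and config.protein:
        def _resp():
            rates, summ, perf = analyze_respirometry(
                _read(config.o2_traces),
                _read(config.plate_map),
                _read(config.protein),
                bootstrap=config.bootstrap,
                seed=config.seed,
            )
            bundle.rates = rates
            bundle.metabolic_summaries = summ
            bundle.thermal_performance = perf
        stage("respirometry", _resp)
    if config.cells and config.standards:
        bundle.phi = stage(
            "ph", lambda: analyze_ph(_read(config.cells), _read(config.standards))
        )
    if config.isotopes:
        def _iso():
            enrichment, report = analyze_isotopes(_read(config.isotopes), config.alpha)
            bundle.enrichment = enrichment
            bundle.pulse_report = report
        stage("isotopes", _iso)
    if config.phenotypes:
        bundle.phenotypes = stage(
            "phenotypes", lambda: analyze_phenotypes(_read(config.phenotypes))
        )
    if bundle.phenotypes is not None or bundle.phi is not None:
        bundle.stats_reports = stage(
            "stats",
            lambda: analyze_stats(
                bundle.phenotypes, bundle.phi, seed=config.seed, alpha=config.alpha
            ),
        ) or {}

    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": {},
        "errors": bundle.errors,
    }
    for name in (
        "exposure", "rates", "metabolic_summaries", "thermal_performance",
        "phi", "enrichment", "phenotypes",
    ):
        df = getattr(bundle, name)
        if df is None:
            continue
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["outputs"][name] = {"path": str(path), "sha256": digest}
    if bundle.pulse_report is not None:
        rep = bundle.pulse_report
        (out / "pulse_report.txt").write_text(
            "13C pulse validation\n"
            f"group means (atom-%): {rep.group_means}\n"
            f"pulse successful: {rep.pulse_successful}\n"
            + "".join(f"warning: {w}\n" for w in rep.warnings)
        )
        rep.contrasts.to_csv(out / "pulse_contrasts.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle.manifest = manifest
    return bundle


def pattern_summary(
    phenotypes: pd.DataFrame,
    phi: pd.DataFrame,
    pulse_report,
    alpha: float = 0.05,
) -> dict:
    """Headline qualitative findings from the pipeline's own statistics.

    * HD cohort: significant symbiont loss at 31 vs 25 °C (with the loss
      fraction), and whether the LD cohort shows any significant 31 vs 25
      density change.
    * pH: whether 31 °C cells are significantly more acidic than 25 °C in
      every (cohort, cell class) group.
    * Isotopes: whether the pulse ordering symbiont > host > aposymbiotic
      holds with significance.
    """
    out: dict = {}
    for cohort, g in phenotypes.groupby("cohort"):
        sym = g[g["symbiotic"] == True].copy()  # noqa: E712
        sym["log_cells"] = np.log(sym["cells_per_animal"])
        ct = st.tukey_contrasts(sym, "log_cells", "treatment", alpha=alpha)
        row = ct.table[ct.table["pair"].isin(["25-31", "31-25"])]
        sig = bool(row["p_adj"].iloc[0] < alpha) if len(row) else False
        mean25 = sym.loc[sym["treatment"] == "25", "cells_per_animal"].mean()
        mean31 = sym.loc[sym["treatment"] == "31", "cells_per_animal"].mean()
        out[f"{cohort}_loss_significant"] = sig and mean31 < mean25
        out[f"{cohort}_loss_fraction_31v25"] = float(1.0 - mean31 / mean25)
    ph_ok = True
    for (cohort, cls), g in phi.groupby(["cohort", "cell_class"]):
        if g["treatment"].nunique() < 2:
            continue
        ct = st.tukey_contrasts(g, "median_ph", "treatment", alpha=alpha)
        row = ct.table[ct.table["pair"].isin(["25-31", "31-25"])]
        med25 = g.loc[g["treatment"] == "25", "median_ph"].mean()
        med31 = g.loc[g["treatment"] == "31", "median_ph"].mean()
        ok = len(row) > 0 and bool(row["p_adj"].iloc[0] < alpha) and med31 < med25
        ph_ok = ph_ok and ok
    out["ph_lower_at_31_everywhere"] = ph_ok
    out["pulse_ordering_significant"] = bool(pulse_report.pulse_successful)
    return out
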