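"""Config-driven end-to-end analysis pipeline.

Fixed stage order: read/simulate -> QC -> δ¹³C corrections -> per-group
descriptive summaries -> Layman metrics + SEA/SEAc + SEAb -> ellipse
overlaps -> seasonal trend fits -> pairwise tests, sex t-tests and the
correlation screen. Each stage writes a tidy CSV; a JSON run report
records the config echo, seed, counts and software versions. A single
global seed fans out to per-stage child streams via
``numpy.random.SeedSequence(seed).spawn``, so adding a stage never
perturbs the randomness of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .niche_metrics import (
    DegenerateGroupError,
    IsotopePoints,
    SEAbConfig,
    ellipse_overlap,
    fit_standard_ellipse,
    layman_metrics,
    sample_seab,
)
from .qc_corrections import QCConfig, SuessModel, apply_qc, correct_table, default_suess_model, load_suess_model
from .sample_io import SampleTable, iter_groups, read_sample_table
from .synthetic_data import generate_samples, wildcat_survey_scenario
from .trend_stats import (
    assign_season,
    correlation_screen,
    fit_trend,
    pairwise_wilcoxon,
    pooled_t_test,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("isoniche")

#: Publication-style rounding: 1 decimal for ‰ and ‰² metrics.
REPORT_DECIMALS = 1


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of input_path / scenario."""

    input_path: str | None = None
    dialect: str = "csv"
    scenario: str | None = None  # "wildcat_survey" or None
    qc: QCConfig = field(default_factory=QCConfig)
    suess_series_path: str | None = None
    seab: SEAbConfig = field(default_factory=SEAbConfig)
    run_seab: bool = True
    overlap_pairs: tuple[tuple[str, str], ...] = ()  # (taxon A, taxon B) per region & pooled
    trend_isotopes: tuple[str, ...] = ("d13C_cor", "d15N", "d34S")
    correlation_variables: tuple[str, ...] = ()
    output_dir: str = "isoniche_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError("exactly one of input_path / scenario must be set")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    table: SampleTable  # QC-retained, corrected
    qc_report: object
    summaries: pd.DataFrame
    niche: pd.DataFrame
    seab: pd.DataFrame
    overlaps: pd.DataFrame
    trends: pd.DataFrame
    tests: pd.DataFrame
    correlations: pd.DataFrame
    report: dict


def _points(samples, label) -> IsotopePoints:
    arr = np.array([(s.d13C_cor, s.d15N) for s in samples], dtype=float)
    return IsotopePoints(label, arr)


def _group_views(table: SampleTable):
    """(label, samples) for each taxon×region group plus per-taxon pools."""
    views = []
    for taxon in ("domestic_cat", "hybrid", "wildcat"):
        pooled = [s for s in table if s.taxon == taxon]
        if pooled:
            views.append(((taxon, "All samples"), pooled))
    views.extend(iter_groups(table))
    return views


def _summaries(table: SampleTable) -> pd.DataFrame:
    rows = []
    for (taxon, region), samples in _group_views(table):
        row = {"taxon": taxon, "region": region, "n": len(samples)}
        for name, getter in (
            ("d13C_cor", lambda s: s.d13C_cor),
            ("d15N", lambda s: s.d15N),
            ("d34S", lambda s: s.d34S),
        ):
            vals = np.array([getter(s) for s in samples if getter(s) is not None], dtype=float)
            if vals.size == 0:
                continue
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[f"{name}_min"] = vals.min()
            row[f"{name}_max"] = vals.max()
        rows.append(row)
    return pd.DataFrame(rows)


def _niche_stage(table: SampleTable, seab_cfg: SEAbConfig, seed_seq, run_seab: bool):
    niche_rows, seab_rows, fits = [], [], {}
    groups = _group_views(table)
    children = seed_seq.spawn(len(groups))
    for ((taxon, region), samples), child in zip(groups, children):
        label = f"{taxon}|{region}"
        row = {"taxon": taxon, "region": region, "n": len(samples)}
        pts = _points(samples, label)
        lay = layman_metrics(pts)
        row.update(
            dC_range=lay.dC_range, dN_range=lay.dN_range, TA=lay.TA,
            CD=lay.CD, NND=lay.NND, SDNND=lay.SDNND,
        )
        try:
            fit = fit_standard_ellipse(pts)
            fits[(taxon, region)] = fit
            row.update(SEA=fit.SEA, SEAc=fit.SEAc, computable=True)
        except DegenerateGroupError as exc:
            log.info("niche: %s not computable (%s)", label, exc)
            row.update(SEA=None, SEAc=None, computable=False)
        niche_rows.append(row)
        if run_seab and row["computable"] and len(samples) >= 3:
            post = sample_seab(pts, seab_cfg, seed=child)
            seab_rows.append(
                {"taxon": taxon, "region": region, "n": len(samples), **post.summaries()}
            )
    return pd.DataFrame(niche_rows), pd.DataFrame(seab_rows), fits


def _overlap_stage(fits, pairs) -> pd.DataFrame:
    rows = []
    regions = sorted({region for (_t, region) in fits})
    for taxon_a, taxon_b in pairs:
        for region in regions:
            fa, fb = fits.get((taxon_a, region)), fits.get((taxon_b, region))
            if fa is None or fb is None:
                continue
            res = ellipse_overlap(fa, fb)
            rows.append(
                {
                    "taxon_A": taxon_a, "taxon_B": taxon_b, "region": region,
                    "area_A": res.area_A, "area_B": res.area_B,
                    "area_intersection": res.area_intersection,
                    "prop_of_B_pct": res.prop_of_B,
                }
            )
    return pd.DataFrame(rows)


def _trend_stage(table: SampleTable, isotopes) -> pd.DataFrame:
    rows = []
    getters = {
        "d13C_cor": lambda s: s.d13C_cor,
        "d15N": lambda s: s.d15N,
        "d34S": lambda s: s.d34S,
    }
    for (taxon, region), samples in iter_groups(table):
        seasons = {"all": samples}
        for s in samples:
            seasons.setdefault(assign_season(s.month), []).append(s)
        for season, subset in seasons.items():
            for iso in isotopes:
                data = [
                    (s.year, getters[iso](s))
                    for s in subset
                    if s.year is not None and getters[iso](s) is not None
                ]
                years = [y for y, _ in data]
                if len(data) < 3 or len(set(years)) < 2:
                    continue
                values = [v for _, v in data]
                label = f"{taxon}|{region}|{season}"
                for method in ("ols", "huber"):
                    fit = fit_trend(years, values, method, label=label, isotope=iso)
                    rows.append(
                        {
                            "taxon": taxon, "region": region, "season": season,
                            "isotope": iso, "method": method, "n": fit.n,
                            "slope": fit.slope, "intercept": fit.intercept,
                            "r_squared": fit.r_squared, "p_value": fit.p_value,
                        }
                    )
    return pd.DataFrame(rows)


def _test_stage(table: SampleTable, correlation_variables) -> tuple[pd.DataFrame, pd.DataFrame]:
    getters = {
        "d13C_cor": lambda s: s.d13C_cor,
        "d15N": lambda s: s.d15N,
        "d34S": lambda s: s.d34S,
    }
    test_rows = []
    for iso, getter in getters.items():
        groups = {}
        for s in table:
            v = getter(s)
            if v is not None:
                groups.setdefault(s.taxon, []).append(v)
        groups = {k: np.array(v) for k, v in groups.items() if len(v) >= 1}
        if len(groups) >= 2:
            for res in pairwise_wilcoxon(groups, isotope=iso):
                test_rows.append(
                    {
                        "test": "wilcoxon", "isotope": iso,
                        "group_A": res.pair[0], "group_B": res.pair[1],
                        "statistic": res.statistic,
                        "p_raw": res.p_raw, "p_adjusted": res.p_adjusted,
                    }
                )
    # Sex t-tests on Thuringian (case study 2) wildcats, the study's focus.
    wild2 = [s for s in table if s.taxon == "wildcat" and s.case_study == 2]
    for iso, getter in getters.items():
        females = [getter(s) for s in wild2 if s.sex == "female" and getter(s) is not None]
        males = [getter(s) for s in wild2 if s.sex == "male" and getter(s) is not None]
        if len(females) >= 2 and len(males) >= 2:
            t, df, p = pooled_t_test(females, males)
            test_rows.append(
                {
                    "test": "t_female_vs_male", "isotope": iso,
                    "group_A": "female", "group_B": "male",
                    "statistic": t, "df": df, "p_raw": p, "p_adjusted": None,
                }
            )
    corr_rows = []
    if correlation_variables:
        wild2_table = SampleTable(wild2, table.provenance)
        if len(wild2_table) >= 3:
            for e in correlation_screen(
                wild2_table, variables=list(correlation_variables)
            ):
                corr_rows.append(dataclasses.asdict(e))
    return pd.DataFrame(test_rows), pd.DataFrame(corr_rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the report bundle.

    Deterministic end to end: a second run with the same config and seed
    reproduces every numeric output, stochastic stages included.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        log.info("run start: config hash %s, seed %d", cfg_hash, config.seed)
        seq = np.random.SeedSequence(config.seed)
        stage_seeds = dict(zip(["simulate", "seab"], seq.spawn(2)))

        log.info("stage 1: input")
        if config.scenario is not None:
            if config.scenario != "wildcat_survey":
                raise ValueError(f"unknown scenario {config.scenario!r}")
            sim_seed = int(stage_seeds["simulate"].generate_state(1)[0] % (2**31))
            table, truth = generate_samples(wildcat_survey_scenario(seed=sim_seed))
        else:
            table, truth = read_sample_table(config.input_path, config.dialect), None

        log.info("stage 2: QC (%d rows in)", len(table))
        retained, qc_report = apply_qc(table, config.qc)
        log.info("QC retained %d / %d", qc_report.n_retained, qc_report.n_input)

        log.info("stage 3: corrections")
        model = (
            load_suess_model(config.suess_series_path)
            if config.suess_series_path
            else default_suess_model()
        )
        corrected = correct_table(retained, model)

        log.info("stage 4: summaries")
        summaries = _summaries(corrected)

        log.info("stage 5: niche metrics")
        niche, seab, fits = _niche_stage(
            corrected, config.seab, stage_seeds["seab"], config.run_seab
        )

        log.info("stage 6: overlaps")
        pairs = config.overlap_pairs or (("hybrid", "wildcat"), ("domestic_cat", "wildcat"))
        overlaps = _overlap_stage(fits, pairs)

        log.info("stage 7: trends")
        trends = _trend_stage(corrected, config.trend_isotopes)

        log.info("stage 8: tests and correlations")
        tests, correlations = _test_stage(corrected, config.correlation_variables)

        for name, df in (
            ("summaries", summaries), ("niche", niche), ("seab", seab),
            ("overlaps", overlaps), ("trends", trends), ("tests", tests),
            ("correlations", correlations),
        ):
            df.to_csv(outdir / f"{name}_{cfg_hash}.csv", index=False, float_format="%.12g")

        report = {
            "config": _jsonable(dataclasses.asdict(config)),
            "config_hash": cfg_hash,
            "seed": config.seed,
            "versions": {
                "isoniche": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "counts": {
                "n_input": qc_report.n_input,
                "n_retained": qc_report.n_retained,
                "n_excluded_by_reason": qc_report.n_excluded_by_reason,
                "n_groups": int(len(niche)),
            },
            "truth": truth,
        }
        with open(outdir / f"report_{cfg_hash}.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("run complete")
        return PipelineResult(
            corrected, qc_report, summaries, niche, seab, overlaps, trends,
            tests, correlations, report,
        )
    finally:
        log.removeHandler(handler)
        handler.close()


def rounded_view(df: pd.DataFrame) -> pd.DataFrame:
    """Publication-style view: ‰ and ‰² columns rounded to 1 decimal."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(REPORT_DECIMALS)
    return out
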