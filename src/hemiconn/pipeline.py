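"""End-to-end orchestration: generate -> build -> measure -> harmonize -> analyze.

Every stage is a thin wrapper over the library modules; the pipeline owns
ordering (length-normalize -> cortical subset -> commissural ratio ->
invert -> graph metrics), seeding, logging, and file layout. Runs are
deterministic given the configuration seed and every CSV output starts
with a version/config-hash annotation line (``# hemiconn ...``), so two
runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as hio
from .combat import apply_combat, fit_combat, pca_diagnostic
from .connectome import Connectome, cortical_subgraph, hemisphere_blocks, normalize_by_length
from .metrics import (DEFAULT_CC_EXPONENT, HemisphericMetrics, commissural_ratio,
                      subject_metrics)
from .stats import (INTER_MEASURES, INTRA_MEASURES, RATIO_MEASURES, anova_tukey,
                    battery_report, bonferroni, residualize, run_correlation_battery,
                    split_groups)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "read_cohort", "compute_metrics_table",
           "full_chain", "harmonize_tables", "HARMONIZED_SCALARS"]

log = logging.getLogger("hemiconn")

# record scalars harmonized alongside the connectivity metrics
HARMONIZED_SCALARS = ["gmf", "wmf", "lvf", "cc_area", "brain_volume"]
METRIC_COLUMNS = [
    "commissural_ratio", "cc_ratio", "spl_left", "spl_right", "spl_mean",
    "eff_left", "eff_right", "eff_mean",
    "ratio_commissural_spl", "ratio_commissural_eff",
    "ratio_ccratio_spl", "ratio_ccratio_eff",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML or JSON."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cc_exponent: float = DEFAULT_CC_EXPONENT
    commissural_weights: str = "raw"        # "raw" counts or "normalized"
    on_midline: str = "warn"
    combat_mode: str = "full"
    combat_tol: float = 1e-4
    combat_max_iter: int = 100
    edss_cutoff: float = 3.0
    sdmt_cutoff: float = 40.0
    boundary_high: bool = True
    include_center_covariate: bool = False
    outdir: str = "results/run"
    data_dir: str | None = None             # defaults to <outdir>/cohort
    seed: int | None = None                 # overrides cohort.seed when set
    log_level: str = "INFO"

    def resolved(self) -> "PipelineConfig":
        cohort = self.cohort
        if self.seed is not None:
            cohort = replace(cohort, seed=int(self.seed))
        return replace(self, cohort=cohort, seed=None)

    def config_hash(self) -> str:
        # hash the scientific configuration only, not paths or logging
        d = asdict(self)
        for key in ("outdir", "data_dir", "log_level"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]

    def version_string(self) -> str:
        return f"hemiconn-{__version__}+cfg.{self.config_hash()}"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)


def _annotated_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
                   index: bool = True) -> None:
    body = df.to_csv(index=index, float_format="%.12g")
    path.write_text(f"# {cfg.version_string()}\n{body}")


def read_annotated_csv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def read_cohort(directory: str | Path):
    """Load and validate a written cohort; logs excluded subjects.

    Returns ``(connectomes, records, ground_truth)``; subjects whose
    matrices violate the connectome invariants are excluded and reported.
    """
    connectomes, records, gt, errors = hio.read_cohort(directory)
    for sid, msg in errors.items():
        log.warning("SUBJECT_EXCLUDED id=%s reason=%s", sid, msg)
    if errors:
        log.warning("QC_EXCLUDED n=%d of %d", len(errors),
                    len(errors) + len(records))
    return connectomes, records, gt


def full_chain(c: Connectome, cc_area: float, brain_volume: float, *,
               commissural_weights: str = "raw",
               cc_exponent: float = DEFAULT_CC_EXPONENT,
               on_midline: str = "warn") -> HemisphericMetrics:
    """Per-subject chain: normalize, subset to cortex, measure.

    Graph metrics always run on the length-normalized cortical graph. The
    commissural ratio defaults to raw streamline counts (the share of
    streamlines whose endpoints lie in opposite hemispheres); set
    ``commissural_weights="normalized"`` to compute it on the
    length-normalized matrix instead.
    """
    if commissural_weights not in ("raw", "normalized"):
        raise ValueError("commissural_weights must be 'raw' or 'normalized'")
    norm_cort = cortical_subgraph(normalize_by_length(c))
    m = subject_metrics(norm_cort, cc_area, brain_volume,
                        cc_exponent=cc_exponent, on_midline=on_midline)
    if commissural_weights == "raw":
        raw_cort = cortical_subgraph(c)
        _, _, inter, total = hemisphere_blocks(raw_cort, on_midline=on_midline)
        comm = commissural_ratio(inter, total)
        m = dataclasses.replace(
            m, commissural_ratio=comm,
            ratio_commissural_spl=comm / m.spl_mean,
            ratio_commissural_eff=comm / m.eff_mean,
        )
    return m


def compute_metrics_table(connectomes, records: pd.DataFrame, *,
                          commissural_weights: str = "raw",
                          cc_exponent: float = DEFAULT_CC_EXPONENT,
                          on_midline: str = "warn") -> pd.DataFrame:
    """One row of HemisphericMetrics per subject, indexed by subject id."""
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # midline warning repeats per subject
        for sid, conn in zip(records.index, connectomes):
            m = full_chain(conn, float(records.at[sid, "cc_area"]),
                           float(records.at[sid, "brain_volume"]),
                           commissural_weights=commissural_weights,
                           cc_exponent=cc_exponent, on_midline=on_midline)
            rows[sid] = m.as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df


def harmonize_tables(metrics: pd.DataFrame, records: pd.DataFrame, *,
                     mode: str = "full", tol: float = 1e-4,
                     max_iter: int = 100):
    """ComBat over the metric table plus the volumetric record scalars.

    Covariates preserved: age, sex, and diagnosis (HC/MS binary, subtypes
    collapsed). Returns ``(harmonized_metrics, harmonized_records, model)``
    where harmonized_records is the record table with the harmonized
    scalar columns substituted in.
    """
    features = metrics[METRIC_COLUMNS].join(records[HARMONIZED_SCALARS])
    covs = pd.DataFrame({
        "age": records["age"].astype(float),
        "sex": records["sex"].astype(float),
        "diagnosis_ms": (~records["diagnosis"].astype(str).str.upper().eq("HC"))
        .astype(float),
    }, index=records.index)
    model = fit_combat(features, records["center"], covs, mode=mode,
                       tol=tol, max_iter=max_iter)
    adj = apply_combat(model, features, records["center"], covs)
    h_metrics = metrics.copy()
    h_metrics[METRIC_COLUMNS] = adj[METRIC_COLUMNS]
    h_records = records.copy()
    h_records[HARMONIZED_SCALARS] = adj[HARMONIZED_SCALARS]
    return h_metrics, h_records, model


def _group_comparisons(metrics: pd.DataFrame, records: pd.DataFrame,
                       cfg: PipelineConfig) -> tuple[pd.DataFrame, list[str]]:
    """Three-group ANOVA + Tukey per measure, for EDSS and SDMT splits.

    Measures are age/sex-residualized first; Bonferroni on the ANOVA p
    within each split's family of measures.
    """
    measures = INTER_MEASURES + INTRA_MEASURES + RATIO_MEASURES
    covs = pd.DataFrame({"age": records["age"].astype(float),
                         "sex": records["sex"].astype(float)},
                        index=records.index)
    rows, notes = [], []
    for score in ("edss", "sdmt"):
        labels, n_excl = split_groups(
            records, score, edss_cutoff=cfg.edss_cutoff,
            sdmt_cutoff=cfg.sdmt_cutoff, boundary_high=cfg.boundary_high)
        notes.append(f"{score} split: groups "
                     f"{labels.value_counts().to_dict()}, excluded={n_excl}")
        p_raw = []
        comps = []
        for meas in measures:
            resid = residualize(metrics[meas].to_numpy(dtype=float), covs)
            gc = anova_tukey(resid, labels.to_numpy())
            gc.metric = meas
            comps.append((meas, gc))
            p_raw.append(gc.p_value)
        p_corr = bonferroni(p_raw)
        for (meas, gc), pc in zip(comps, p_corr):
            for _, t in gc.tukey.iterrows():
                rows.append({
                    "split": score, "metric": meas,
                    "f_stat": gc.f_stat, "p_anova": gc.p_value,
                    "p_anova_corrected": pc, "family_size": len(measures),
                    "group1": t["group1"], "group2": t["group2"],
                    "mean_diff": t["mean_diff"], "p_tukey": t["p_adj"],
                    "n_excluded": gc.n_excluded,
                })
    return pd.DataFrame(rows), notes


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory.

    Writes: config snapshot, cohort files, metrics.csv, harmonized
    metrics/records, ComBat model JSON, PCA diagnostic summary,
    correlations.csv, group_comparisons.csv, report.txt, run.log.
    """
    cfg = config.resolved()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        return _run_stages(cfg, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(cfg: PipelineConfig, outdir: Path) -> Path:
    (outdir / "config_snapshot.json").write_text(
        json.dumps({"version": cfg.version_string(), **asdict(cfg)}, indent=1))

    log.info("stage=generate seed=%d n=%d", cfg.cohort.seed, cfg.cohort.n_subjects)
    cohort = generate_cohort(cfg.cohort)
    data_dir = Path(cfg.data_dir) if cfg.data_dir else outdir / "cohort"
    write_cohort(cohort, data_dir)

    log.info("stage=metrics")
    connectomes, records, _ = read_cohort(data_dir)
    metrics = compute_metrics_table(
        connectomes, records, commissural_weights=cfg.commissural_weights,
        cc_exponent=cfg.cc_exponent, on_midline=cfg.on_midline)
    _annotated_csv(metrics, outdir / "metrics.csv", cfg)

    log.info("stage=harmonize mode=%s", cfg.combat_mode)
    h_metrics, h_records, model = harmonize_tables(
        metrics, records, mode=cfg.combat_mode, tol=cfg.combat_tol,
        max_iter=cfg.combat_max_iter)
    model.save(outdir / "combat_model.json")
    _annotated_csv(h_metrics, outdir / "harmonized_metrics.csv", cfg)
    _annotated_csv(h_records, outdir / "harmonized_records.csv", cfg)
    diag = pca_diagnostic(metrics[METRIC_COLUMNS], h_metrics[METRIC_COLUMNS],
                          records["center"])
    pca_df = pd.DataFrame({
        "pc1_center_separation": [diag.separation_before, diag.separation_after],
        "explained_pc1": [diag.explained_before[0], diag.explained_after[0]],
    }, index=pd.Index(["before", "after"], name="stage"))
    _annotated_csv(pca_df, outdir / "pca_diagnostic.csv", cfg)
    log.info("pca center separation before=%.4f after=%.4f",
             diag.separation_before, diag.separation_after)

    log.info("stage=analyze")
    results = run_correlation_battery(
        h_metrics, h_records,
        include_center_covariate=cfg.include_center_covariate)
    corr_df = pd.DataFrame([r.as_dict() for r in results])
    _annotated_csv(corr_df, outdir / "correlations.csv", cfg, index=False)
    groups_df, notes = _group_comparisons(h_metrics, h_records, cfg)
    _annotated_csv(groups_df, outdir / "group_comparisons.csv", cfg, index=False)

    n_hc = int(records["diagnosis"].astype(str).str.upper().eq("HC").sum())
    report = [
        f"# {cfg.version_string()}",
        f"subjects: n={len(records)} (HC={n_hc}, MS={len(records) - n_hc}) "
        f"across {records['center'].nunique()} centers",
        *notes,
        "",
        battery_report(results),
    ]
    (outdir / "report.txt").write_text("\n".join(report))
    log.info("done outdir=%s", outdir)
    return outdir
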