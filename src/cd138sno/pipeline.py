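"""End-to-end orchestration: classify -> DEG -> annotate -> score -> survival.

A single configuration drives the whole analysis, either on user-supplied
files (clinical CSV + expression TSV, optionally a GMT and an annotation
table) or on a freshly simulated cohort. Every stage writes a plain-text
table under the output directory and the run is fully deterministic for a
fixed configuration and seed (the config hash and seed are recorded in the
report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import deg as deg_mod
from . import ihc, signatures, snorna, survival as surv
from .expression import ExpressionMatrix
from .simulate import SimulationConfig, config_from_mapping, generate_cohort, write_bundle

logger = logging.getLogger("cd138sno")

DEFAULT_COX_COVARIATES = [
    "age_lt40", "t_stage", "n_positive", "hg3", "ki67_high",
    "hr_pos", "her2_pos", "cd138_group1",
    "radiotherapy", "chemotherapy", "endocrine", "anti_her2",
]

ASSOCIATION_COVARIATES = [
    "age_lt40", "t_stage", "n_positive", "hg3", "ki67_high",
    "hr_pos", "her2_pos", "brain_met",
    "radiotherapy", "chemotherapy", "endocrine", "anti_her2",
]

REQUIRED_CLINICAL_COLUMNS = [
    "case_id", "tumor_intensity", "tumor_proportion",
    "stroma_intensity", "stroma_proportion", "rfs_time", "rfs_event",
]


@dataclass
class PipelineConfig:
    clinical_path: Optional[str] = None
    expression_path: Optional[str] = None
    gmt_path: Optional[str] = None  # default: bundled signatures
    annotation_path: Optional[str] = None  # default: bundled snoRNA table
    simulate: Optional[SimulationConfig] = None
    tumor_cut: int = 2
    stroma_cut: int = 1
    delta_threshold: float = 1.0
    alpha: float = 0.05
    ssgsea_exponent: float = 0.25
    cox_covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COX_COVARIATES))
    outdir: str = "cd138sno_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = self.clinical_path is not None or self.expression_path is not None
        if self.simulate is not None and has_paths:
            raise ValueError("config must give either input paths or a simulate block, not both")
        if self.simulate is None and not (self.clinical_path and self.expression_path):
            raise ValueError("config needs clinical_path and expression_path, or a simulate block")
        if self.tumor_cut not in (0, 1, 2, 3) or self.stroma_cut not in (0, 1, 2, 3):
            raise ValueError("intensity cutoffs must lie in 0..3")
        if self.simulate is not None:
            self.simulate.validate()


@dataclass
class ReportBundle:
    groups: pd.DataFrame
    group_counts: dict
    degs: pd.DataFrame
    volcano: pd.DataFrame
    annotations: pd.DataFrame
    unmatched_snornas: list[str]
    host_genes: list[str]
    scores: pd.DataFrame
    survival: dict
    associations: pd.DataFrame
    metadata: dict


def config_from_file(path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a mapping")
    sim = raw.pop("simulate", None)
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown pipeline config fields: {sorted(unknown)}")
    config = PipelineConfig(**raw)
    if sim is not None:
        config.simulate = config_from_mapping(sim)
    config.validate()
    return config


def config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis-relevant configuration (not output location)."""
    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)
    payload.pop("log_level", None)
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_clinical(path) -> pd.DataFrame:
    clinical = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical CSV {path}: missing columns {missing}")
    clinical["case_id"] = clinical["case_id"].astype(str)
    return clinical


def bundled_gmt_path():
    return resources.files("cd138sno").joinpath("data/signatures.gmt")


def _load_gene_sets(gmt_path) -> dict[str, signatures.GeneSet]:
    if gmt_path is None:
        ref = bundled_gmt_path()
        with resources.as_file(ref) as p:
            return signatures.read_gmt(p)
    return signatures.read_gmt(gmt_path)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis and write all stage outputs under the outdir."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim_config = dataclasses.replace(config.simulate, seed=config.seed)
        bundle = _stage("simulate")(generate_cohort)(sim_config)
        write_bundle(bundle, outdir / "simulated_inputs")
        clinical, matrix = bundle.clinical, bundle.expression
    else:
        clinical = _stage("load")(load_clinical)(config.clinical_path)
        matrix = _stage("load_expr")(ExpressionMatrix.from_tsv)(config.expression_path)
        expr_ids = [str(s) for s in matrix.samples]
        if list(clinical["case_id"]) != expr_ids:
            raise RuntimeError(
                "pipeline stage 'load' failed: clinical and expression sample "
                "identifiers differ or are ordered differently"
            )

    # --- classification ---------------------------------------------------
    @_stage("classify")
    def _classify():
        obs = ihc.observations_from_clinical(clinical)
        return ihc.classify_cohort(obs, config.tumor_cut, config.stroma_cut)

    groups_table, group_counts = _classify()
    groups_table.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    group1_mask = (groups_table["group"] == 1).to_numpy()

    # --- DEG screen -------------------------------------------------------
    @_stage("deg")
    def _deg():
        records = deg_mod.screen_degs(
            matrix, group1_mask, config.delta_threshold, config.alpha
        )
        return records, deg_mod.records_to_frame(records), deg_mod.volcano_table(records)

    deg_records, degs_frame, volcano = _deg()
    degs_frame.to_csv(outdir / "degs.tsv", sep="\t", index=False)
    volcano.to_csv(outdir / "volcano.tsv", sep="\t", index=False)

    # --- snoRNA annotation ------------------------------------------------
    @_stage("annotate")
    def _annotate():
        table = snorna.load_annotation_table(config.annotation_path)
        up_snornas = [
            r.symbol for r in deg_records
            if r.is_deg and r.direction == "up" and r.biotype == "snoRNA"
        ]
        matched, unmatched = snorna.annotate_snornas(up_snornas, table)
        return matched, unmatched, snorna.unique_host_genes(matched)

    matched, unmatched, hosts = _annotate()
    annotations = pd.DataFrame(
        [r.__dict__ for r in matched], columns=snorna.ANNOTATION_COLUMNS
    )
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    (outdir / "host_genes.txt").write_text("".join(f"{g}\n" for g in hosts))
    (outdir / "unmatched_snornas.txt").write_text("".join(f"{s}\n" for s in unmatched))

    # --- signature scoring ------------------------------------------------
    @_stage("score")
    def _score():
        sets = _load_gene_sets(config.gmt_path)
        module_set = sets.pop("SNORNA_MODULE", None)
        scores = signatures.score_cohort(matrix, sets, config.ssgsea_exponent)
        if module_set is not None:
            scores["snorna_module"] = signatures.snorna_module_score(matrix, module_set)
        for col in list(scores.columns):
            scores[f"{col}_z"] = signatures.zscore(scores[col].to_numpy())
        return scores

    scores = _score()
    scores.to_csv(outdir / "scores.tsv", sep="\t")

    # --- survival & associations -----------------------------------------
    @_stage("survival")
    def _survival():
        times = clinical["rfs_time"].to_numpy(dtype=float)
        events = clinical["rfs_event"].to_numpy(dtype=int)
        groups = groups_table["group"].to_numpy()

        km_by_group = {}
        for g in sorted(np.unique(groups)):
            sel = groups == g
            if sel.sum() == 0:
                continue
            curve = surv.km_estimate(times[sel], events[sel]) if events[sel].sum() else None
            km_by_group[int(g)] = (
                None
                if curve is None
                else {
                    "event_times": curve.event_times.tolist(),
                    "at_risk": curve.at_risk.tolist(),
                    "events": curve.events.tolist(),
                    "survival": curve.survival.tolist(),
                }
            )
        chi2, df_lr, p_lr = surv.logrank_test(times, events, groups)

        covariate_frame = clinical.copy()
        covariate_frame["cd138_group1"] = group1_mask.astype(int)
        cox_cols = [c for c in config.cox_covariates if c in covariate_frame.columns]
        univariable = {}
        for col in cox_cols:
            if covariate_frame[col].nunique() < 2:
                univariable[col] = {"skipped": "constant covariate"}
                continue
            fit = surv.cox_fit(covariate_frame[[col]], times, events, run_schoenfeld=False)
            row = fit.summary.iloc[0]
            univariable[col] = {
                "hr": row["hr"], "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                "p": row["p"], "converged": fit.converged,
            }
        multi_cols = [c for c in cox_cols if covariate_frame[c].nunique() >= 2]
        multivariable = None
        try:
            fit = surv.cox_fit(covariate_frame[multi_cols], times, events)
            multivariable = {
                "table": fit.summary.reset_index(names="covariate").to_dict(orient="records"),
                "c_index": fit.c_index,
                "converged": fit.converged,
                "flag": fit.flag,
                "schoenfeld_p": fit.schoenfeld_p,
            }
        except ValueError as err:
            multivariable = {"error": str(err)}

        return {
            "km_by_group": km_by_group,
            "logrank": {"chi_square": chi2, "df": df_lr, "p": p_lr},
            "cox_univariable": univariable,
            "cox_multivariable": multivariable,
        }

    survival_results = _survival()
    with open(outdir / "survival.json", "w") as fh:
        json.dump(survival_results, fh, indent=1, default=float)

    # --- association tables (Group 1 vs others) --------------------------
    @_stage("associations")
    def _associations():
        rows = []
        others_mask = ~group1_mask
        for col in ASSOCIATION_COVARIATES:
            if col not in clinical.columns:
                continue
            flag = clinical[col].astype(int).to_numpy()
            table = [
                [int(flag[group1_mask].sum()), int((1 - flag[group1_mask]).sum())],
                [int(flag[others_mask].sum()), int((1 - flag[others_mask]).sum())],
            ]
            variants = surv.association_2x2_variants(table)
            rows.append(
                {
                    "variable": col,
                    "group1_pos": table[0][0], "group1_neg": table[0][1],
                    "others_pos": table[1][0], "others_neg": table[1][1],
                    **variants,
                }
            )
        return pd.DataFrame(rows)

    associations = _associations()
    associations.to_csv(outdir / "contingency.tsv", sep="\t", index=False)

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_cases": int(len(clinical)),
        "n_genes": int(matrix.n_genes),
        "group_counts": {str(int(g)): c for g, c in group_counts.items()},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(metadata, fh, indent=1)

    return ReportBundle(
        groups=groups_table,
        group_counts=group_counts,
        degs=degs_frame,
        volcano=volcano,
        annotations=annotations,
        unmatched_snornas=unmatched,
        host_genes=hosts,
        scores=scores,
        survival=survival_results,
        associations=associations,
        metadata=metadata,
    )


def validate_inputs(
    clinical_path=None, expression_path=None, gmt_path=None, annotation_path=None
) -> list[dict]:
    """Validate input files; one pass/fail entry per provided file.

    The first offending record (file, column, row) is named in the message.
    """
    report = []

    def entry(name, path, check):
        try:
            check()
            report.append({"file": str(path), "kind": name, "ok": True, "message": "pass"})
        except Exception as err:
            report.append({"file": str(path), "kind": name, "ok": False, "message": str(err)})

    if clinical_path is not None:
        def check_clinical():
            clinical = load_clinical(clinical_path)
            for row in clinical.itertuples():
                for comp in ("tumor", "stroma"):
                    iv = getattr(row, f"{comp}_intensity")
                    if iv not in (0, 1, 2, 3):
                        raise ValueError(
                            f"row {row.Index} case {row.case_id}: {comp}_intensity {iv} "
                            "outside the 0-3 range"
                        )
                if not row.rfs_time > 0:
                    raise ValueError(
                        f"row {row.Index} case {row.case_id}: rfs_time must be > 0"
                    )
                if row.rfs_event not in (0, 1):
                    raise ValueError(
                        f"row {row.Index} case {row.case_id}: rfs_event must be 0/1"
                    )
        entry("clinical", clinical_path, check_clinical)

    if expression_path is not None:
        entry("expression", expression_path, lambda: ExpressionMatrix.from_tsv(expression_path))
    if gmt_path is not None:
        entry("gmt", gmt_path, lambda: signatures.read_gmt(gmt_path))
    if annotation_path is not None:
        entry("annotation", annotation_path, lambda: snorna.load_annotation_table(annotation_path))
    return report
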