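"""Synthetic breast-cancer cohort generator.

Emulates the statistical structure of a compartment-specific CD138 cohort of
~111 invasive ductal carcinomas so every downstream stage (classification,
DEG screen, signature scoring, survival modeling) is testable without
external data:

* four-group membership drawn with probabilities 45/111, 35/111, 19/111,
  12/111 (tumor/stroma positivity groups 0-3);
* IHC intensities drawn inside the score range that reproduces each case's
  group exactly under the binary rules (tumor positive -> 2 or 3, stroma
  positive -> 1-3), with positive proportions uniform on 10-100%;
* clinicopathological covariates as independent Bernoulli draws with
  group-conditional frequencies matching the observed cohort;
* gene expression Gaussian on the log2(TPM + 1) scale, back-transformed to
  TPM; designated marker genes (the Group-1-enriched snoRNAs and the
  CD138-positive/negative protein-coding signatures) are shifted by a signed
  effect in Group 1;
* recurrence-free survival exponential with hazard
  baseline_hazard * exp(group1_log_hr * 1[group = 1]) and administrative
  censoring uniform on (0, censor_time_max].

All draws come from sub-streams of one seed, derived per component, so e.g.
adding genes never changes the clinical draws.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

#: Default Group-1 hazard ratio of recurrence (log scale).
DEFAULT_GROUP1_HR = 4.877

#: Group-1-enriched snoRNA markers (up in Group 1).
SNORNA_MARKERS = (
    "SNORA21", "SNORA1", "SNORA25", "SNORD14D", "SNORA70", "SNORA14B",
    "SNORA22C", "SNORD111", "SNORD111B", "SNORA21B", "SNORA67",
)

#: Protein-coding markers up in Group 1 (the CD138-positive signature).
CODING_UP_MARKERS = ("S100A7", "CD24", "GLYATL2")

#: Protein-coding markers down in Group 1 (the CD138-negative signature).
CODING_DOWN_MARKERS = (
    "RERG", "SLC39A6", "NAT1", "SCUBE2", "PIP", "NPY1R", "SLC7A2",
    "GRIA2", "FSIP1", "PTPRT", "SERPINA3",
)

DEFAULT_EFFECT_MAGNITUDE = 1.5


def default_effects(magnitude: float = DEFAULT_EFFECT_MAGNITUDE) -> dict[str, float]:
    """Signed per-marker shifts in mean log2(TPM+1) for Group 1."""
    effects = {sym: magnitude for sym in SNORNA_MARKERS + CODING_UP_MARKERS}
    effects.update({sym: -magnitude for sym in CODING_DOWN_MARKERS})
    return effects


#: Group-conditional Bernoulli frequencies (p_group1, p_others) estimated
#: from the observed 35-vs-76 split of the study cohort.
DEFAULT_COVARIATE_FREQS: dict[str, tuple[float, float]] = {
    "age_lt40": (6 / 35, 4 / 76),
    "t_stage": (16 / 35, 35 / 76),
    "n_positive": (17 / 35, 15 / 76),
    "hg3": (17 / 35, 24 / 76),
    "ki67_high": (21 / 35, 48 / 76),
    "hr_pos": (18 / 35, 54 / 76),
    "her2_pos": (14 / 35, 10 / 76),
    "brain_met": (4 / 35, 0 / 76),
    "radiotherapy": (21 / 35, 48 / 76),
    "chemotherapy": (19 / 35, 36 / 76),
    "endocrine": (15 / 35, 47 / 76),
    "anti_her2": (10 / 35, 6 / 76),
}

CLINICAL_COLUMNS = [
    "case_id", "group_true",
    "tumor_intensity", "tumor_proportion", "stroma_intensity", "stroma_proportion",
    *DEFAULT_COVARIATE_FREQS.keys(),
    "rfs_time", "rfs_event",
]


@dataclass
class SimulationConfig:
    n_cases: int = 111
    group_probs: tuple[float, float, float, float] = (45 / 111, 35 / 111, 19 / 111, 12 / 111)
    n_genes_per_biotype: dict[str, int] = field(
        default_factory=lambda: {
            "protein_coding": 200, "snoRNA": 40, "lncRNA": 60, "misc_RNA": 30,
        }
    )
    effect_log2: dict[str, float] = field(default_factory=default_effects)
    noise_sd_log2: float = 1.0
    baseline_log2_range: tuple[float, float] = (0.5, 8.0)
    group1_log_hr: float = math.log(DEFAULT_GROUP1_HR)
    baseline_hazard: float = 0.002  # events per month
    censor_time_max: float = 120.0  # months
    covariate_freqs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_FREQS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if len(self.group_probs) != 4:
            raise ValueError("group_probs must have 4 entries")
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ValueError("group_probs must sum to 1 within 1e-9")
        if any(p < 0 for p in self.group_probs):
            raise ValueError("group_probs must be nonnegative")
        for biotype, n in self.n_genes_per_biotype.items():
            if n <= 0:
                raise ValueError(f"n_genes_per_biotype[{biotype!r}] must be positive")
        if not self.noise_sd_log2 > 0:
            raise ValueError("noise_sd_log2 must be > 0")
        if not self.baseline_hazard > 0:
            raise ValueError("baseline_hazard must be > 0")
        if not self.censor_time_max > 0:
            raise ValueError("censor_time_max must be > 0")
        lo, hi = self.baseline_log2_range
        if not lo <= hi:
            raise ValueError("baseline_log2_range must be a nondecreasing interval")
        for name, (p1, p0) in self.covariate_freqs.items():
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise ValueError(f"covariate_freqs[{name!r}] must be probabilities")


@dataclass
class CohortBundle:
    clinical: pd.DataFrame
    expression: ExpressionMatrix
    truth: dict

    def __post_init__(self) -> None:
        clin_ids = self.clinical["case_id"].tolist()
        expr_ids = list(self.expression.samples)
        if clin_ids != expr_ids:
            raise ValueError("clinical and expression sample identifiers differ")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ["groups", "ihc", "covariates", "expression", "survival"]
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_survival(
    groups: Sequence[int],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) per case under the Group-1 proportional hazard.

    Event times are exponential with rate baseline_hazard * exp(group1_log_hr)
    for Group 1 and baseline_hazard otherwise; censoring is uniform on
    (0, censor_time_max]. event = 1 iff the event time falls within follow-up.
    """
    groups = np.asarray(groups)
    if groups.size == 0:
        raise ValueError("groups must be nonempty")
    config.validate()
    if rng is None:
        rng = _substreams(config.seed)["survival"]
    rates = config.baseline_hazard * np.exp(
        config.group1_log_hr * (groups == 1).astype(float)
    )
    event_times = rng.exponential(1.0 / rates)
    censor_times = (1.0 - rng.uniform(size=groups.size)) * config.censor_time_max
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    return times, events


def _draw_ihc(groups: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Draw intensities/proportions reproducing each group under the binary rule."""
    n = len(groups)
    tumor_positive = np.isin(groups, (1, 3))
    stroma_positive = np.isin(groups, (2, 3))
    tumor_intensity = np.where(
        tumor_positive, rng.integers(2, 4, size=n), rng.integers(0, 2, size=n)
    )
    stroma_intensity = np.where(stroma_positive, rng.integers(1, 4, size=n), 0)
    tumor_prop = np.where(tumor_intensity > 0, rng.uniform(10, 100, size=n), 0.0)
    stroma_prop = np.where(stroma_intensity > 0, rng.uniform(10, 100, size=n), 0.0)
    return pd.DataFrame(
        {
            "tumor_intensity": tumor_intensity,
            "tumor_proportion": np.round(tumor_prop, 1),
            "stroma_intensity": stroma_intensity,
            "stroma_proportion": np.round(stroma_prop, 1),
        }
    )


def _gene_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Lay out the simulated gene universe: markers first, then filler genes.

    Marker symbols are drawn from the bundled signatures so downstream
    symbol-matched scoring works out of the box; SDC1 (CD138 itself) is
    included as a neutral protein-coding gene. Filler lncRNAs carry the "0"
    missing-symbol placeholder used by the expression-table dialect.
    """
    markers_by_biotype = {
        "snoRNA": list(SNORNA_MARKERS),
        "protein_coding": list(CODING_UP_MARKERS + CODING_DOWN_MARKERS) + ["SDC1"],
    }
    rows = []
    for biotype, n in config.n_genes_per_biotype.items():
        markers = markers_by_biotype.get(biotype, [])
        if len(markers) > n:
            raise ValueError(
                f"n_genes_per_biotype[{biotype!r}]={n} is smaller than the "
                f"{len(markers)} marker genes of that biotype"
            )
        for i in range(n):
            if i < len(markers):
                symbol = markers[i]
            elif biotype == "lncRNA":
                symbol = "0"
            else:
                symbol = f"{biotype.upper().replace('_', '')}SIM{i}"
            rows.append({"biotype": biotype, "symbol": symbol})
    catalog = pd.DataFrame(rows)
    catalog.index = pd.Index(
        [f"ENSGSIM{i:08d}" for i in range(len(catalog))], name="gene_id"
    )
    for sym in config.effect_log2:
        if sym not in set(catalog["symbol"]):
            raise ValueError(f"effect_log2 names unknown marker symbol {sym!r}")
    return catalog


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic cohort bundle (clinical + expression + truth).

    Deterministic for a fixed ``config.seed``; each component draws from its
    own seed sub-stream.
    """
    config.validate()
    rngs = _substreams(config.seed)
    n = config.n_cases
    case_ids = [f"case{i + 1:04d}" for i in range(n)]

    groups = rngs["groups"].choice(4, size=n, p=np.asarray(config.group_probs))
    ihc = _draw_ihc(groups, rngs["ihc"])

    cov_rng = rngs["covariates"]
    covariates = {}
    for name, (p1, p0) in config.covariate_freqs.items():
        probs = np.where(groups == 1, p1, p0)
        covariates[name] = cov_rng.binomial(1, probs)

    catalog = _gene_catalog(config)
    expr_rng = rngs["expression"]
    lo, hi = config.baseline_log2_range
    baseline = expr_rng.uniform(lo, hi, size=len(catalog))
    effects = catalog["symbol"].map(config.effect_log2).fillna(0.0).to_numpy()
    means = baseline[:, None] + effects[:, None] * (groups == 1)[None, :]
    log_values = means + expr_rng.normal(0.0, config.noise_sd_log2, size=means.shape)
    tpm = np.clip(np.exp2(log_values) - 1.0, 0.0, None)

    times, events = simulate_survival(groups, config, rngs["survival"])

    clinical = pd.DataFrame({"case_id": case_ids, "group_true": groups})
    clinical = pd.concat([clinical, ihc], axis=1)
    for name, values in covariates.items():
        clinical[name] = values
    clinical["rfs_time"] = np.round(times, 4)
    clinical["rfs_event"] = events
    clinical = clinical[CLINICAL_COLUMNS + [c for c in clinical.columns if c not in CLINICAL_COLUMNS]]

    expression = ExpressionMatrix.from_arrays(
        gene_ids=catalog.index,
        symbols=catalog["symbol"],
        biotypes=catalog["biotype"],
        samples=case_ids,
        values=tpm,
    )

    truth = {
        "config": _config_to_jsonable(config),
        "group_true": {cid: int(g) for cid, g in zip(case_ids, groups)},
        "effect_log2_by_symbol": dict(config.effect_log2),
        "group1_log_hr": config.group1_log_hr,
    }
    return CohortBundle(clinical=clinical, expression=expression, truth=truth)


def _config_to_jsonable(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["group_probs"] = list(config.group_probs)
    out["baseline_log2_range"] = list(config.baseline_log2_range)
    out["covariate_freqs"] = {k: list(v) for k, v in config.covariate_freqs.items()}
    return out


def config_from_mapping(raw: Mapping) -> SimulationConfig:
    """Build a config from a parsed YAML/JSON mapping, with validation."""
    kwargs = dict(raw)
    if "group_probs" in kwargs:
        kwargs["group_probs"] = tuple(float(p) for p in kwargs["group_probs"])
    if "baseline_log2_range" in kwargs:
        kwargs["baseline_log2_range"] = tuple(float(v) for v in kwargs["baseline_log2_range"])
    if "covariate_freqs" in kwargs:
        kwargs["covariate_freqs"] = {
            k: (float(v[0]), float(v[1])) for k, v in kwargs["covariate_freqs"].items()
        }
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(SimulationConfig)}
    if unknown:
        raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
    config = SimulationConfig(**kwargs)
    config.validate()
    return config


def write_bundle(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write clinical.csv, expression.tsv and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / "clinical.csv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    bundle.clinical.to_csv(paths["clinical"], index=False)
    bundle.expression.to_tsv(paths["expression"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1)
    return paths
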