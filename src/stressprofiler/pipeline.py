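"""End-to-end orchestration: configuration, I/O, logging and the report.

A run simulates (or loads) the behavioral cohort, classifies it, builds
the prevalence contingency table with its chi-square/phi statistics, runs
the group statistics on the molecular panel, and writes every artifact as
CSV/JSON with provenance (seed, config hash) plus an audit log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .profiler import (
    BatteryConfig,
    DEFAULT_BATTERY,
    TestSpec,
    classify,
    compute_cutoffs,
    flag_extremes,
    prevalence_table,
)
from .synthetic import (
    CohortParams,
    PanelParams,
    simulate_behavior_cohort,
    simulate_expression_panel,
)

__all__ = [
    "RunConfig",
    "battery_from_dict",
    "load_config",
    "read_animal_table",
    "run_pipeline",
    "write_report",
]

log = logging.getLogger("stressprofiler")

#: documented column dictionary for animal tables
ANIMAL_COLUMNS = {
    "animal_id": "unique animal identifier",
    "prenatal": "prenatal group label (e.g. control / PNS)",
    "adult_exposure": "adult exposure label (trauma / no_trauma)",
    "sex": "animal sex",
    "risk_assessment_time": "risk assessment time (s); extreme = low",
    "startle_peak_latency": "latency to peak startle amplitude (ms); extreme = low",
    "ppi_percent": "percent pre-pulse inhibition; extreme = low",
    "dark_phase_activity": "home-cage activity in the non-active phase; extreme = high",
    "marbles_buried_percent": "percent of marbles buried; extreme = high",
}


@dataclass
class RunConfig:
    """Validated run configuration (parsed from the YAML config file)."""

    battery: BatteryConfig = field(default_factory=lambda: DEFAULT_BATTERY)
    animal_table: str | None = None  # CSV path; None -> simulate
    out_dir: str = "stressprofiler_out"
    seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 10_000
    group_column: str = "prenatal"


def battery_from_dict(spec: dict) -> BatteryConfig:
    tests = tuple(
        TestSpec(t["name"], t.get("column", t["name"]), t["direction"])
        for t in spec["tests"]
    )
    return BatteryConfig(
        tests=tests,
        min_extreme_tests=int(spec.get("min_extreme_tests", 3)),
        percentile=float(spec.get("percentile", 0.20)),
        require_complete=bool(spec.get("require_complete", True)),
        min_score_filter=spec.get("min_score_filter"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse the YAML run configuration; missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    battery = battery_from_dict(raw["battery"]) if "battery" in raw else DEFAULT_BATTERY
    cfg = RunConfig(
        battery=battery,
        animal_table=raw.get("animal_table"),
        out_dir=str(raw.get("out_dir", "stressprofiler_out")),
        seed=int(raw.get("seed", 0)),
        alpha=float(raw.get("alpha", 0.05)),
        n_permutations=int(raw.get("n_permutations", 10_000)),
        group_column=str(raw.get("group_column", "prenatal")),
    )
    if cfg.animal_table is not None and not Path(cfg.animal_table).exists():
        raise FileNotFoundError(f"animal_table not found: {cfg.animal_table}")
    return cfg


def read_animal_table(path: str | Path, battery: BatteryConfig = DEFAULT_BATTERY) -> pd.DataFrame:
    """Typed, validated animal table from CSV.

    Battery columns must be present; unknown columns are preserved but
    ignored; duplicate animal ids are an error.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty animal table: {path}")
    if "animal_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'animal_id'")
    dup = df["animal_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate animal ids: {sorted(df.loc[dup, 'animal_id'].unique())}"
        )
    missing = [c for c in battery.columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing battery column(s): {missing}")
    for c in battery.columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {
            "tests": [(t.name, t.column, t.direction) for t in cfg.battery.tests],
            "min_extreme_tests": cfg.battery.min_extreme_tests,
            "percentile": cfg.battery.percentile,
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "n_permutations": cfg.n_permutations,
            "group_column": cfg.group_column,
            "animal_table": cfg.animal_table,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate (or load) -> classify -> contingency stats -> panel stats.

    Returns the report bundle as a dict of tables and summary statistics;
    pass it to :func:`write_report` to persist with provenance.
    """
    log.info("run starts: seed=%d config=%s", cfg.seed, _config_hash(cfg))
    if cfg.animal_table:
        table = read_animal_table(cfg.animal_table, cfg.battery)
        log.info("loaded %d animals from %s", len(table), cfg.animal_table)
    else:
        table = simulate_behavior_cohort(CohortParams(seed=cfg.seed))
        log.info("simulated %d animals", len(table))

    # classification applies to the trauma-exposed animals, cutoffs pooled
    if "adult_exposure" in table.columns:
        exposed = table[table["adult_exposure"] == "trauma"]
        if exposed.empty:
            exposed = table
    else:
        exposed = table
    cutoffs = compute_cutoffs(exposed, cfg.battery)
    for name, cut in cutoffs.cutoffs.items():
        log.info(
            "cutoff %s (%s): %.4f over n=%d", name,
            cutoffs.directions[name], cut, cutoffs.reference_sizes[name],
        )
    flags = flag_extremes(exposed, cutoffs)
    result = classify(flags, cfg.battery, table=exposed)
    ct = prevalence_table(result, exposed[cfg.group_column])
    chi = st.yates_chi_square(ct)
    log.info(
        "prevalence table %s; chi2_corrected=%.3f p=%.3f phi=%.3f",
        [[ct.a, ct.b], [ct.c, ct.d]], chi.statistic_corrected, chi.p, chi.phi,
    )

    panel = simulate_expression_panel(table, PanelParams(seed=cfg.seed))
    anovas = {}
    for gene, sub in panel.groupby("gene"):
        anovas[gene] = st.two_way_anova(
            sub["expression"], sub["prenatal"], sub["adult_exposure"],
            a_name="prenatal", b_name="adult_exposure",
        )
    three_way = st.mixed_three_way_anova(
        panel, subject="animal_id", between_a="prenatal",
        between_b="adult_exposure", within="gene", value="expression",
    )
    trauma_gilz = panel[(panel["gene"] == "GILZ") & (panel["adult_exposure"] == "trauma")]
    if len(trauma_gilz) >= 3:
        r, p, n = st.pearson_correlation(
            trauma_gilz["percent_methylation"], trauma_gilz["expression"]
        )
    else:
        r = p = np.nan
        n = len(trauma_gilz)
    log.info("methylation-expression coupling: r=%.3f p=%.3g n=%d", r, p, n)

    classification = pd.concat(
        [
            exposed[["animal_id", cfg.group_column]].reset_index(drop=True),
            flags.reset_index(drop=True).add_prefix("flag_"),
            result.score.reset_index(drop=True),
            result.n_tests_observed.reset_index(drop=True),
            result.label.reset_index(drop=True),
        ],
        axis=1,
    )
    return {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "animal_table": table,
        "classification": classification,
        "cutoffs": pd.DataFrame(
            {
                "cutoff": cutoffs.cutoffs,
                "direction": cutoffs.directions,
                "reference_n": cutoffs.reference_sizes,
            }
        ),
        "contingency": ct,
        "chi_square": chi,
        "panel": panel,
        "anova_per_gene": anovas,
        "three_way_anova": three_way,
        "methylation_coupling": {"r": float(r), "p": float(p), "n": int(n)},
    }


def write_report(bundle: dict, out_dir: str | Path) -> Path:
    """Persist the report bundle as CSV + JSON with provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["animal_table"].to_csv(out / "animal_table.csv", index=False)
    bundle["classification"].to_csv(out / "classification.csv", index=False)
    bundle["cutoffs"].to_csv(out / "cutoffs.csv", index_label="test")
    bundle["panel"].to_csv(out / "panel.csv", index=False)
    for gene, tab in bundle["anova_per_gene"].items():
        tab.terms.to_csv(out / f"anova_{gene}.csv", index_label="term")
    bundle["three_way_anova"].terms.to_csv(out / "anova_three_way.csv", index_label="term")
    ct, chi = bundle["contingency"], bundle["chi_square"]
    summary = {
        "seed": bundle["seed"],
        "config_hash": bundle["config_hash"],
        "contingency": [[ct.a, ct.b], [ct.c, ct.d]],
        "groups": list(ct.row_names),
        "prevalence": {
            ct.row_names[0]: ct.a / (ct.a + ct.b),
            ct.row_names[1]: ct.c / (ct.c + ct.d),
        },
        "chi_square_corrected": chi.statistic_corrected,
        "chi_square_p": chi.p,
        "phi": chi.phi,
        "methylation_coupling": bundle["methylation_coupling"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("report written to %s", out)
    return out
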