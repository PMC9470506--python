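"""End-to-end orchestration: synthesize -> HRV -> score -> screen -> mediate.

Every stage writes flat CSV/JSON so any stage can be re-run or audited in
isolation, and the final report is deterministic for a fixed configuration
and seed (its SHA-256 is reproducible bit for bit).
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

from . import __version__
from .errors import ConfigError, ZeroVarianceError
from .synthetic import (CohortConfig, generate_cohort, EPOCH_WINDOWS,
                        MOTION_DEGREES_BY_MINUTE)
from .hrv import analyse_session, spectral_table
from .instruments import MotionProfile, motion_ssq_association, TLX_SUBSCALES, MINICEX_ITEMS
from .cohort_stats import (compare_groups, one_sample_vs_reference,
                           correlation_screen, fisher_exact)
from .multilevel import moderated_mediation

log = logging.getLogger("vrss.pipeline")

DEFAULT_EPOCHS = [("baseline", 0.0, 300.0), ("t0_5", 300.0, 600.0),
                  ("t6_10", 600.0, 900.0)]

#: correlation-screen edge list (exposure, response) pairs
SCREEN_PAIRS = [
    ("ssq_total", "vlf_t6_10"),
    ("ssq_total", "physical_demand"),
    ("ssq_total", "frustration"),
    ("ssq_total", "physical_examination"),
    ("vlf_t6_10", "physical_examination"),
    ("frustration", "counseling_skills"),
    ("age", "counseling_skills"),
    ("ss_positive", "vlf_t6_10"),
    ("ss_positive", "physical_examination"),
]

_KNOWN_KEYS = {"cohort", "epochs", "hrv", "thresholds", "multilevel",
               "outdir", "seed"}
_HRV_KEYS = {"max_rel_change", "absolute_bounds_ms"}
_THRESH_KEYS = {"screen_alpha", "multilevel_alpha"}
_ML_KEYS = {"x", "m", "y", "w", "grouping", "random_slope"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    epochs: list = field(default_factory=lambda: list(DEFAULT_EPOCHS))
    max_rel_change: float = 0.20
    absolute_bounds_ms: tuple = (300.0, 2000.0)
    screen_alpha: float = 0.01
    multilevel_alpha: float = 0.05
    mediation: dict = field(default_factory=lambda: {
        "x": "ssq_total", "m": "vlf_t6_10", "y": "physical_examination",
        "w": "frustration", "grouping": "ss_status", "random_slope": False})
    outdir: str = "vrss_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for label, start, end in self.epochs:
            if end <= start:
                raise ConfigError(f"epoch {label!r} has end <= start")
        for name in ("screen_alpha", "multilevel_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")

    def canonical(self) -> str:
        d = {
            "cohort": yaml.safe_load(_cohort_yaml(self.cohort)),
            "epochs": [[l, float(a), float(b)] for l, a, b in self.epochs],
            "hrv": {"max_rel_change": self.max_rel_change,
                    "absolute_bounds_ms": list(self.absolute_bounds_ms)},
            "thresholds": {"screen_alpha": self.screen_alpha,
                           "multilevel_alpha": self.multilevel_alpha},
            "multilevel": dict(self.mediation),
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _cohort_yaml(cfg: CohortConfig) -> str:
    import tempfile
    with tempfile.NamedTemporaryFile("w+", suffix=".yaml") as fh:
        cfg.to_yaml(fh.name)
        fh.seek(0)
        return fh.read()


def validate_config(path: str | Path) -> RunConfig:
    """Load and schema-check a YAML run configuration.

    Unknown keys anywhere in the document are rejected, defaults are filled
    for everything omitted, and numeric constraints are enforced.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except Exception as exc:
        raise ConfigError(f"cannot read config: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "cohort" in raw:
        try:
            kwargs["cohort"] = CohortConfig.from_dict(raw["cohort"])
        except TypeError as exc:
            raise ConfigError(f"bad cohort section: {exc}") from exc
    if "epochs" in raw:
        kwargs["epochs"] = [(e["label"], float(e["start_s"]), float(e["end_s"]))
                            for e in raw["epochs"]]
    if "hrv" in raw:
        unknown = set(raw["hrv"]) - _HRV_KEYS
        if unknown:
            raise ConfigError(f"unknown hrv keys: {sorted(unknown)}")
        if "max_rel_change" in raw["hrv"]:
            kwargs["max_rel_change"] = float(raw["hrv"]["max_rel_change"])
        if "absolute_bounds_ms" in raw["hrv"]:
            kwargs["absolute_bounds_ms"] = tuple(raw["hrv"]["absolute_bounds_ms"])
    if "thresholds" in raw:
        unknown = set(raw["thresholds"]) - _THRESH_KEYS
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        kwargs.update({k: float(v) for k, v in raw["thresholds"].items()})
    if "multilevel" in raw:
        unknown = set(raw["multilevel"]) - _ML_KEYS
        if unknown:
            raise ConfigError(f"unknown multilevel keys: {sorted(unknown)}")
        med = dict(RunConfig().mediation)
        med.update(raw["multilevel"])
        kwargs["mediation"] = med
    if "outdir" in raw:
        kwargs["outdir"] = str(raw["outdir"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
        if "cohort" in kwargs:
            kwargs["cohort"].seed = kwargs["seed"]
        else:
            kwargs["cohort"] = CohortConfig(seed=kwargs["seed"])
    return RunConfig(**kwargs)


def _round_floats(obj, ndigits: int = 9):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        if np.isnan(obj):
            return None
        return float(f"{float(obj):.{ndigits}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {"package": "vrss", "version": __version__,
                       "config_hash": config.config_hash(),
                       "seed": config.seed},
        "stages": {},
        "warnings": [],
    }

    # --- stage 1: synthesize ---------------------------------------------
    log.info("stage synth: generating cohort")
    try:
        config.cohort.seed = config.seed
        cohort = generate_cohort(config.cohort)
        cohort.write(outdir / "cohort")
        report["stages"]["synth"] = {
            "status": "ok",
            "n_participants": int(len(cohort.participants)),
            "n_ss_positive": int((cohort.participants.ss_status == "ss_positive").sum()),
        }
    except Exception as exc:
        report["stages"]["synth"] = {"status": "failed", "error": str(exc)}
        return _finalise(report, outdir)

    # --- stage 2: HRV ------------------------------------------------------
    log.info("stage hrv: spectral analysis of %d sessions", len(cohort.rr_series))
    spectral = None
    try:
        if cohort.rr_series:
            results = {}
            for pid, rr in sorted(cohort.rr_series.items()):
                specs = analyse_session(
                    rr, config.epochs, max_rel_change=config.max_rel_change,
                    absolute_bounds_ms=config.absolute_bounds_ms)
                results[pid] = specs
            spectral = spectral_table(results)
            spectral.to_csv(outdir / "spectral.csv", index=False)
            report["stages"]["hrv"] = {
                "status": "ok", "n_rows": int(len(spectral)),
                "n_unusable": int(spectral["vlf"].isna().sum()),
            }
        else:
            report["stages"]["hrv"] = {"status": "skipped",
                                       "reason": "cohort generated without RR series"}
    except Exception as exc:
        report["stages"]["hrv"] = {"status": "failed", "error": str(exc)}
        return _finalise(report, outdir)

    # --- stage 3: cohort table (instrument scoring + join) -----------------
    try:
        table = cohort.cohort_table(spectral=spectral)
        table.to_csv(outdir / "cohort_table.csv", index=False)
        report["stages"]["score"] = {"status": "ok",
                                     "n_rows": int(len(table)),
                                     "columns": sorted(table.columns)}
    except Exception as exc:
        report["stages"]["score"] = {"status": "failed", "error": str(exc)}
        return _finalise(report, outdir)

    # --- stage 4: statistical screen ---------------------------------------
    try:
        report["stages"]["stats"] = _stats_stage(table, cohort, config, outdir)
    except Exception as exc:
        report["stages"]["stats"] = {"status": "failed", "error": str(exc)}
        return _finalise(report, outdir)

    # --- stage 5: moderated mediation --------------------------------------
    med = config.mediation
    try:
        res = moderated_mediation(table, x=med["x"], m=med["m"], y=med["y"],
                                  w=med.get("w"), grouping=med["grouping"],
                                  random_slope=bool(med.get("random_slope", False)))
        payload = res.as_dict()
        (outdir / "mediation.json").write_text(
            json.dumps(_round_floats(payload), indent=1, sort_keys=True))
        report["stages"]["mediate"] = {"status": "ok", **payload}
    except ZeroVarianceError as exc:
        report["stages"]["mediate"] = {"status": "degenerate", "error": str(exc)}
        report["warnings"].append(f"mediation degenerate: {exc}")
    except Exception as exc:
        report["stages"]["mediate"] = {"status": "failed", "error": str(exc)}

    return _finalise(report, outdir)


def _stats_stage(table: pd.DataFrame, cohort, config: RunConfig,
                 outdir: Path) -> dict:
    pos = table[table.ss_status == "ss_positive"]
    neg = table[table.ss_status == "ss_negative"]
    comparisons = []
    hrv_vars = [c for c in table.columns
                if any(c.startswith(b) for b in ("vlf_", "lf_", "hf_", "tp_",
                                                 "mean_rr_"))]
    group_vars = hrv_vars + list(TLX_SUBSCALES) + list(MINICEX_ITEMS)
    for var in group_vars:
        if len(pos) == 0 or len(neg) == 0:
            comparisons.append({"variable": var, "test": "skipped",
                                "statistic": np.nan, "p": np.nan,
                                "degenerate": True,
                                "note": "one subgroup is empty"})
            continue
        res = compare_groups(pos[var], neg[var], paired=False, variable=var,
                             groups=("ss_positive", "ss_negative"),
                             alpha=config.screen_alpha)
        comparisons.append({"variable": var, "test": res.test_name,
                            "statistic": res.statistic, "p": res.p_two_sided,
                            "degenerate": res.degenerate,
                            "significant": res.significant})
    for var in TLX_SUBSCALES:
        res = one_sample_vs_reference(table[var], ref=10.0, variable=var,
                                      alpha=config.screen_alpha)
        comparisons.append({"variable": f"{var}_vs_ref10", "test": res.test_name,
                            "statistic": res.statistic, "p": res.p_two_sided,
                            "degenerate": res.degenerate,
                            "significant": res.significant})
    comp_df = pd.DataFrame(comparisons)
    comp_df.to_csv(outdir / "comparisons.csv", index=False)

    sex_table = [[int((pos.sex == "F").sum()), int((pos.sex == "M").sum())],
                 [int((neg.sex == "F").sum()), int((neg.sex == "M").sum())]] \
        if len(pos) and len(neg) else None
    sex_fisher = fisher_exact(sex_table) if sex_table else {"p_two_sided": None,
                                                            "degenerate": True}

    pairs = [p for p in SCREEN_PAIRS if p[0] in table and p[1] in table]
    screen = correlation_screen(table, pairs, dichotomous={"ss_positive"},
                                alpha=config.screen_alpha)
    screen.to_csv(outdir / "correlations.csv", index=False)

    motion = MotionProfile({float(k): v
                            for k, v in MOTION_DEGREES_BY_MINUTE.items()})
    motion_res = motion_ssq_association(motion, cohort.temporal_profiles())

    return {
        "status": "ok",
        "n_comparisons": int(len(comp_df)),
        "n_significant": int(comp_df.get("significant",
                                         pd.Series(dtype=bool)).eq(True).sum()),
        "sex_fisher_p": sex_fisher["p_two_sided"],
        "screen_edges": _round_floats(screen.to_dict("records")),
        "motion_association": _round_floats(motion_res),
    }


def _finalise(report: dict, outdir: Path) -> dict:
    failed = any(s.get("status") == "failed" for s in report["stages"].values())
    report["ok"] = not failed
    report = _round_floats(report)
    text = json.dumps(report, indent=1, sort_keys=True)
    (outdir / "report.json").write_text(text)
    report["report_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    return report
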