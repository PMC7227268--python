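"""Run configuration and the end-to-end analysis pipeline.

One YAML config drives every command: paths, exclusion rules, matching
spec, exposure definitions, adjustment covariates, gap-fill width and
seed.  ``run_pipeline`` executes read -> exclude -> sample -> classify ->
fit -> report, writing every artifact (matched sets, analysis table,
odds-ratio report, baseline table, log) stamped with a hash of the config
and the seed, so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clogit, cohort as cohort_mod, exposure, matching, report, simulate

__all__ = ["RunConfig", "load_config", "run_pipeline", "PipelineError"]

logger = logging.getLogger("nestedcc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    subjects_path: str | None = None
    feedlog_path: str | None = None
    output_dir: str = "ncc_output"
    seed: int = 0
    max_gap: int = 2
    controls_per_case: int = 4
    exact_factors: tuple[str, ...] = ("sex",)
    distance_factors: tuple[str, ...] = ("gestational_age", "birth_weight")
    ridge_epsilon: float = 1e-8
    adjust_for: tuple[str, ...] = ("trial_arm",)
    exposures: tuple[dict, ...] = ()
    exclusions: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)

    def matching_spec(self) -> matching.MatchingSpec:
        return matching.MatchingSpec(
            exact_factors=tuple(self.exact_factors),
            distance_factors=tuple(self.distance_factors),
            controls_per_case=self.controls_per_case,
            ridge_epsilon=self.ridge_epsilon,
        )

    def exposure_definitions(self) -> list[exposure.ExposureDefinition]:
        if not self.exposures:
            return exposure.default_definitions()
        defs = []
        for e in self.exposures:
            defs.append(
                exposure.ExposureDefinition(
                    name=e["name"],
                    kind=e["kind"],
                    k=e.get("k"),
                    exposed_types=frozenset(
                        e.get("exposed_types", exposure.DEFAULT_EXPOSED_TYPES)
                    ),
                )
            )
        return defs

    def exclusion_rules(self) -> cohort_mod.ExclusionRules:
        ex = self.exclusions or {}
        return cohort_mod.ExclusionRules(
            require_feed_log=bool(ex.get("require_feed_log", False)),
            withdrawn_ids=tuple(ex.get("withdrawn_ids", ())),
            exclude_ids=tuple(ex.get("exclude_ids", ())),
        )

    def simulation_config(self) -> simulate.SimulationConfig:
        sim = dict(self.simulation or {})
        sim.setdefault("seed", self.seed)
        return simulate.SimulationConfig(**sim)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run config; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**raw)
    for tup_field in ("exact_factors", "distance_factors", "adjust_for", "exposures"):
        setattr(cfg, tup_field, tuple(getattr(cfg, tup_field) or ()))
    return cfg


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(logging.INFO)
    logger.handlers = [
        logging.StreamHandler(),
        logging.FileHandler(out_dir / "run.log", mode="w"),
    ]
    for h in logger.handlers:
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("read")
def _read(config: RunConfig) -> cohort_mod.Cohort:
    if not config.subjects_path or not config.feedlog_path:
        raise ValueError("subjects_path and feedlog_path are required")
    return cohort_mod.read_cohort(config.subjects_path, config.feedlog_path)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; return paths of the written artifacts."""
    out_dir = Path(config.output_dir)
    _setup_logging(out_dir)
    stamp = f"config {config.digest()} seed {config.seed}"
    logger.info("pipeline start (%s)", stamp)

    cohort = _read(config)
    logger.info("read %d subjects, %d feed records",
                cohort.n_subjects, len(cohort.feed_log))

    cohort, exclusion_report = _stage("exclude")(cohort_mod.exclude_invalid)(
        cohort, config.exclusion_rules()
    )
    logger.info("excluded %d subject(s)", exclusion_report["id"].nunique())

    spec = config.matching_spec()
    sets = _stage("sample")(matching.sample_all)(cohort, spec, seed=config.seed)
    sets_frame = matching.matched_sets_frame(sets)

    definitions = config.exposure_definitions()
    rows = _stage("classify")(exposure.build_analysis_table)(
        sets, cohort, definitions, config.max_gap
    )

    fits: dict[tuple[str, str], object] = {}
    for d in definitions:
        for adjustment, covs in (
            ("unadjusted", ()),
            ("adjusted", tuple(config.adjust_for)),
        ):
            try:
                fits[(d.name, adjustment)] = clogit.fit_clogit(
                    rows, d.name, adjust_for=covs
                )
            except ValueError as exc:
                logger.warning("fit %s/%s failed: %s", d.name, adjustment, exc)
                fits[(d.name, adjustment)] = exc
    or_report = clogit.odds_ratio_report(fits)
    baseline = _stage("report")(report.baseline_table)(cohort, sets)

    header = f"# {stamp}\n"
    artifacts = {}

    def write_csv(name, frame):
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
        artifacts[name] = path

    write_csv("matched_sets.csv", sets_frame)
    write_csv("analysis_table.csv", rows)
    write_csv("or_report.csv", or_report)
    write_csv("exclusions.csv", exclusion_report)
    path = out_dir / "baseline_table.txt"
    path.write_text(header + baseline.to_text() + "\n\n"
                    + clogit.format_report(or_report) + "\n")
    artifacts["baseline_table.txt"] = path
    logger.info("pipeline done; %d artifacts in %s", len(artifacts) + 1, out_dir)
    return artifacts
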