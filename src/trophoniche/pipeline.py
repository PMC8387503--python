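"""End-to-end orchestration: simulate → prep → aggregate → cluster → fit → Ɛ → report.

The pipeline mirrors the analysis order of a two-tracer dietary-niche study:
tracer corrections first, then data-driven aggregation of prey into
functional groups, a period split at a configured boundary date (records on
the boundary fall in the later period), hierarchical clustering of consumers
within each period, a Bayesian mixing model per period with the clusters as
fixed groups and individuals as random effects, and finally the
specialization index Ɛ computed on the diet posterior.

Everything is reproducible: all stage seeds derive from the single run seed,
outputs embed a fingerprint of the resolved configuration, and rerunning
with the same config and seed regenerates the report byte-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mixing_model import (
    MixingConfig,
    SourceDistribution,
    TDFSpec,
    fit_mixing_model,
    summarize_posterior,
)
from .multivar_stats import (
    hierarchical_cluster,
    merge_sources,
    pairwise_permanova,
    permanova,
    select_k_dunn,
    simper,
    lda_validate,
)
from .specialization import StrategyThresholds, epsilon_posterior
from .synthetic_data import (
    Scenario,
    generate_consumers,
    generate_fa_profiles,
    generate_prey_samples,
    scenario_from_dict,
    scenario_to_dict,
)
from .tracer_prep import CorrectionModel, apply_corrections_table

__all__ = [
    "PipelineError",
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "write_report",
    "validate_report",
    "load_table",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    Either a ``scenario`` (simulated inputs) or file paths to prey/consumer
    (and optionally FA) tables must be provided.  ``split_date`` is the
    regime boundary (records on the boundary fall in the later period).
    """

    scenario: Scenario | None = None
    prey_path: str | None = None
    consumers_path: str | None = None
    fa_path: str | None = None
    split_date: dt.date = dt.date(2002, 1, 1)
    alpha: float = 0.05
    n_permutations: int = 9999
    cluster_k_range: tuple[int, int] = (2, 6)
    mixing: MixingConfig = field(default_factory=MixingConfig)
    tdf: TDFSpec = field(default_factory=TDFSpec)
    corrections: CorrectionModel | None = None
    thresholds: StrategyThresholds = field(default_factory=StrategyThresholds)
    include_fa: bool = True
    joint: bool = False
    write_posterior: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario is None and (self.prey_path is None or self.consumers_path is None):
            raise PipelineError("config", ValueError("need a scenario or input table paths"))
        for path in (self.prey_path, self.consumers_path, self.fa_path):
            if path is not None and not Path(path).exists():
                raise PipelineError("config", FileNotFoundError(path))

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None, outdir: str | None = None) -> "RunConfig":
        """Load a run configuration from a YAML file.

        Top-level keys: scenario (dict schema or "regime_shift"), input paths,
        split_date, alpha, n_permutations, cluster_k_range, mixing (MixingConfig
        fields), tdf, corrections, thresholds, include_fa, joint, seed.
        """
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "scenario" in cfg and cfg["scenario"] is not None:
            kwargs["scenario"] = scenario_from_dict(cfg["scenario"], seed=seed)
        for key in (
            "prey_path",
            "consumers_path",
            "fa_path",
            "alpha",
            "n_permutations",
            "include_fa",
            "joint",
            "write_posterior",
            "seed",
        ):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "split_date" in cfg:
            kwargs["split_date"] = dt.date.fromisoformat(str(cfg["split_date"]))
        if "cluster_k_range" in cfg:
            kwargs["cluster_k_range"] = tuple(cfg["cluster_k_range"])
        if "mixing" in cfg:
            kwargs["mixing"] = MixingConfig(**cfg["mixing"])
        if "tdf" in cfg:
            kwargs["tdf"] = TDFSpec(**cfg["tdf"])
        if "corrections" in cfg:
            kwargs["corrections"] = CorrectionModel.from_dict(cfg["corrections"] or {})
        if "thresholds" in cfg:
            kwargs["thresholds"] = StrategyThresholds(**cfg["thresholds"])
        if seed is not None:
            kwargs["seed"] = seed
        if outdir is not None:
            kwargs["outdir"] = outdir
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {
            "scenario": scenario_to_dict(self.scenario) if self.scenario else None,
            "prey_path": self.prey_path,
            "consumers_path": self.consumers_path,
            "fa_path": self.fa_path,
            "split_date": self.split_date.isoformat(),
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "cluster_k_range": list(self.cluster_k_range),
            "mixing": dataclasses.asdict(self.mixing),
            "tdf": dataclasses.asdict(self.tdf),
            "corrections": (
                {
                    effect: {
                        tracer: dataclasses.asdict(c)
                        for tracer, c in getattr(self.corrections, effect).items()
                    }
                    for effect in ("lipid", "dmso")
                }
                if self.corrections
                else None
            ),
            "thresholds": dataclasses.asdict(self.thresholds),
            "include_fa": self.include_fa,
            "joint": self.joint,
            "write_posterior": self.write_posterior,
            "seed": self.seed,
        }
        return d

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable pipeline outcome (see ``data/report_schema.json``)."""

    fingerprint: str
    seed: int
    version: str
    counts: dict
    functional_groups: dict
    prey_pairwise: list
    fa: dict | None
    clusters: dict
    diets: dict
    epsilon: dict
    convergence: dict
    warnings: list
    config: dict
    posteriors: dict = field(default_factory=dict, repr=False)  # not serialised

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self) if f.name != "posteriors"}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, default=_jsonify, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _records(df: pd.DataFrame) -> list:
    return json.loads(df.to_json(orient="records"))


def load_table(path: str) -> pd.DataFrame:
    """Read a pipeline CSV, skipping fingerprint comment headers."""
    return pd.read_csv(path, comment="#")


def _write_csv(df: pd.DataFrame, path: Path, fingerprint: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fingerprint: {fingerprint}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and return the report.

    Any stage failure raises a stage-tagged :class:`PipelineError`; artifacts
    from completed stages remain on disk when an output directory is set.
    """
    fingerprint = config.fingerprint()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    collected_warnings: list[str] = []
    t0 = time.perf_counter()

    def _stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.perf_counter() - t0)

    # ---- stage: inputs ---------------------------------------------------
    try:
        _stage("inputs")
        if config.scenario is not None:
            scenario = config.scenario.with_seed(int(seeds[0].generate_state(1)[0]) % 2**31)
            prey_specs = scenario.prey_specs or scenario.sources
            prey = generate_prey_samples(
                list(prey_specs), seed=int(seeds[1].generate_state(1)[0]) % 2**31
            )
            consumers, truth = generate_consumers(scenario)
            fa = None
            if config.include_fa and all(s.fa_alpha is not None for s in prey_specs):
                fa = generate_fa_profiles(
                    list(prey_specs), seed=int(seeds[2].generate_state(1)[0]) % 2**31
                )
            ecology = {s.unit: s.ecology for s in prey_specs}
        else:
            prey = load_table(config.prey_path)
            consumers = load_table(config.consumers_path)
            truth = None
            fa = load_table(config.fa_path) if config.fa_path else None
            ecology = (
                dict(zip(prey["species"] + "_" + prey["region"].str.lower(), prey["ecology"]))
                if "ecology" in prey.columns
                else {}
            )
        n_prey_in, n_consumers_in = len(prey), len(consumers)
        if outdir:
            _write_csv(prey, outdir / "prey.csv", fingerprint)
            _write_csv(consumers, outdir / "consumers.csv", fingerprint)
            if truth is not None:
                _write_csv(truth, outdir / "truth.csv", fingerprint)
            if fa is not None:
                _write_csv(fa, outdir / "fa.csv", fingerprint)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - tagged and re-raised
        raise PipelineError("inputs", exc) from exc

    # ---- stage: corrections ---------------------------------------------
    try:
        _stage("corrections")
        model = config.corrections
        if model is None:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = CorrectionModel.null(warn=True)
            collected_warnings += [str(w.message) for w in caught]
        consumers, corr_counts = apply_corrections_table(consumers, model)
        prey, prey_corr_counts = apply_corrections_table(prey, model)
    except Exception as exc:
        raise PipelineError("corrections", exc) from exc

    # ---- stage: prey aggregation ----------------------------------------
    try:
        _stage("aggregate-prey")
        prey = prey.assign(
            unit=np.where(
                prey["region"].astype(str).isin(["NA", "nan"]),
                prey["species"],
                prey["species"].astype(str) + "_" + prey["region"].astype(str).str.lower(),
            )
        )
        units = sorted(prey["unit"].unique())
        iso_pairwise = pairwise_permanova(
            prey[["d13C", "d15N"]].to_numpy(),
            prey["unit"].to_numpy(),
            n_permutations=config.n_permutations,
            seed=int(seeds[3].generate_state(1)[0]) % 2**31,
        )
        groups = merge_sources(units, iso_pairwise, ecology, alpha=config.alpha)
        group_of_unit = {m: fg.name for fg in groups for m in fg.members}
        prey["functional_group"] = prey["unit"].map(group_of_unit)
        sources = [
            SourceDistribution.from_samples(
                fg.name,
                prey.loc[prey["functional_group"] == fg.name, "d13C"],
                prey.loc[prey["functional_group"] == fg.name, "d15N"],
            )
            for fg in groups
        ]
        if outdir:
            payload = {
                "fingerprint": fingerprint,
                "functional_groups": {fg.name: list(fg.members) for fg in groups},
                "pairwise": _records(iso_pairwise),
            }
            (outdir / "groups.json").write_text(json.dumps(payload, sort_keys=True, indent=2))
    except Exception as exc:
        raise PipelineError("aggregate-prey", exc) from exc

    # ---- stage: fatty acids (reporting only) -----------------------------
    fa_block = None
    try:
        if fa is not None:
            _stage("fatty-acids")
            fa_cols = [c for c in fa.columns if c not in ("id", "species", "region")]
            fa_units = np.where(
                fa["region"].astype(str).isin(["NA", "nan"]),
                fa["species"],
                fa["species"].astype(str) + "_" + fa["region"].astype(str).str.lower(),
            )
            overall = permanova(
                fa[fa_cols].to_numpy(),
                fa_units,
                n_permutations=config.n_permutations,
                seed=int(seeds[4].generate_state(1)[0]) % 2**31,
            )
            fa_pairwise = pairwise_permanova(
                fa[fa_cols].to_numpy(),
                fa_units,
                n_permutations=min(config.n_permutations, 999),
                seed=int(seeds[4].generate_state(1)[0]) % 2**31,
            )
            top = fa_pairwise.loc[fa_pairwise["pseudo_f"].idxmax()]
            top_simper = simper(
                fa[fa_cols], fa_units, (top["group_a"], top["group_b"]), cutoff=0.70
            )
            fa_block = {
                "overall": {"pseudo_f": overall.pseudo_f, "p_value": overall.p_value},
                "pairwise": _records(fa_pairwise),
                "top_pair_simper": {
                    "pair": [top["group_a"], top["group_b"]],
                    "cutoff": top_simper.cutoff,
                    "n_variables_to_cutoff": len(top_simper.cutoff_set),
                    "variables": list(top_simper.cutoff_set),
                },
            }
    except Exception as exc:
        raise PipelineError("fatty-acids", exc) from exc

    # ---- stage: period split + clustering --------------------------------
    try:
        _stage("cluster")
        dates = pd.to_datetime(consumers["date"]).dt.date
        consumers = consumers.assign(
            period=np.where(dates < config.split_date, "pre", "post")
        )
        periods = [p for p in ("pre", "post") if (consumers["period"] == p).any()]
        cluster_block: dict = {}
        cluster_labels = pd.Series(index=consumers.index, dtype=object)
        for pi, period in enumerate(periods, start=1):
            mask = consumers["period"] == period
            sub = consumers.loc[mask, ["d13C", "d15N"]].to_numpy()
            tree = hierarchical_cluster(sub, method="ward", standardize=True)
            kmax = min(config.cluster_k_range[1], mask.sum() - 1)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                sol = select_k_dunn(tree, range(config.cluster_k_range[0], kmax + 1))
            collected_warnings += [f"{period}: {w.message}" for w in caught]
            labels = [f"{pi}.{c}" for c in sol.labels]
            cluster_labels.loc[mask] = labels
            try:
                acc = lda_validate(sub, sol.labels)
            except Exception as exc:  # e.g. singleton cluster
                collected_warnings.append(f"{period}: LDA validation skipped ({exc})")
                acc = None
            cluster_block[period] = {
                "k": sol.k,
                "dunn": sol.dunn,
                "dunn_by_k": {str(k): v for k, v in sol.dunn_by_k.items()},
                "low_dunn": sol.low_dunn,
                "lda_accuracy": acc,
                "sizes": pd.Series(labels).value_counts().sort_index().to_dict(),
            }
        consumers = consumers.assign(cluster=cluster_labels)
        assert consumers.groupby("id")["period"].nunique().le(2).all()
        if outdir:
            _write_csv(
                consumers[["id", "date", "period", "cluster", "d13C", "d15N"]],
                outdir / "clusters.csv",
                fingerprint,
            )
    except Exception as exc:
        raise PipelineError("cluster", exc) from exc

    # ---- stage: mixing model ---------------------------------------------
    try:
        _stage("fit-mixing")
        diet_block: dict = {}
        convergence_block: dict = {}
        eps_block: dict = {}
        posteriors: dict = {}
        fit_sets = (
            {"joint": consumers}
            if config.joint
            else {p: consumers[consumers["period"] == p] for p in periods}
        )
        for fi, (tag, sub) in enumerate(fit_sets.items()):
            mix_cfg = dataclasses.replace(
                config.mixing,
                fixed_effect="cluster",
                random_effect="id",
                seed=int(seeds[5].generate_state(4)[fi]) % 2**31,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                posterior, report = fit_mixing_model(sub, sources, mix_cfg, tdf=config.tdf)
            collected_warnings += [f"{tag}: {w.message}" for w in caught]
            posteriors[tag] = posterior
            diet_block[tag] = {
                "by_group": _records(summarize_posterior(posterior, by="group")),
                "overall": _records(
                    summarize_posterior(
                        posterior, by="period", period_map={i: tag for i in posterior.individual_ids}
                    )
                ),
            }
            convergence_block[tag] = {
                "rhat": report.rhat,
                "rhat_ok": report.rhat_ok,
                "geweke_ok": report.geweke_ok,
            }
            eps = epsilon_posterior(posterior, thresholds=config.thresholds)
            eps_block[tag] = {
                "per_individual": _records(
                    eps.per_unit[eps.per_unit["unit_type"] == "individual"]
                ),
                "per_group": _records(eps.per_unit[eps.per_unit["unit_type"] == "group"]),
                "summary": _records(eps.summary_by("individual")),
            }
            if outdir and config.write_posterior:
                _write_csv(posterior.to_long_frame(), outdir / f"posterior_{tag}.csv", fingerprint)
        if outdir:
            (outdir / "convergence.json").write_text(
                json.dumps(
                    {"fingerprint": fingerprint, **convergence_block},
                    sort_keys=True,
                    indent=2,
                    default=_jsonify,
                )
            )
    except Exception as exc:
        raise PipelineError("fit-mixing", exc) from exc

    # ---- stage: report ----------------------------------------------------
    try:
        _stage("report")
        report = RunReport(
            fingerprint=fingerprint,
            seed=config.seed,
            version=__version__,
            counts={
                "prey_rows_in": n_prey_in,
                "prey_rows_used": int(len(prey)),
                "consumer_rows_in": n_consumers_in,
                "consumer_rows_used": int(len(consumers)),
                "consumers_per_period": consumers["period"].value_counts().to_dict(),
                "corrections_applied": {"consumers": corr_counts, "prey": prey_corr_counts},
            },
            functional_groups={fg.name: list(fg.members) for fg in groups},
            prey_pairwise=_records(iso_pairwise),
            fa=fa_block,
            clusters=cluster_block,
            diets=diet_block,
            epsilon=eps_block,
            convergence=convergence_block,
            warnings=sorted(set(collected_warnings)),
            config=json.loads(json.dumps(config.to_dict(), default=_jsonify)),
            posteriors=posteriors,
        )
        if report.counts["consumer_rows_used"] != report.counts["consumer_rows_in"]:
            raise ValueError("consumer rows were dropped during the run")
        if outdir:
            write_report(report, outdir)
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("report", exc) from exc


# ---------------------------------------------------------------------------
# Report output and validation
# ---------------------------------------------------------------------------


def write_report(report: RunReport, outdir, formats=("json", "md")) -> list[Path]:
    """Write the report as JSON and/or human-readable Markdown."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = outdir / "report.json"
        path.write_text(report.to_json())
        written.append(path)
    if "md" in formats:
        path = outdir / "report.md"
        path.write_text(_render_markdown(report))
        written.append(path)
    return written


def _md_table(rows: list[dict], columns: list[str]) -> str:
    def fmt(v):
        return f"{v:.3f}" if isinstance(v, float) else str(v)

    lines = ["| " + " | ".join(columns) + " |", "|" + "---|" * len(columns)]
    for row in rows:
        lines.append("| " + " | ".join(fmt(row.get(c, "")) for c in columns) + " |")
    return "\n".join(lines)


def _render_markdown(report: RunReport) -> str:
    parts = [
        "# Dietary-niche pipeline report",
        f"- fingerprint: `{report.fingerprint}`  |  seed: {report.seed}  |  version: {report.version}",
        f"- consumers: {report.counts['consumer_rows_used']} "
        f"({report.counts['consumers_per_period']})",
        "",
        "## Functional prey groups",
        _md_table(
            [{"group": g, "members": ", ".join(m)} for g, m in report.functional_groups.items()],
            ["group", "members"],
        ),
    ]
    for period, block in report.clusters.items():
        parts += [
            "",
            f"## Clusters ({period})",
            f"k = {block['k']}, Dunn = {block['dunn']:.3f}, LOO-LDA accuracy = "
            + (
                f"{block['lda_accuracy']:.3f}"
                if block["lda_accuracy"] is not None
                else "n/a"
            ),
        ]
    for period, block in report.diets.items():
        parts += [
            "",
            f"## Estimated diet proportions ({period})",
            _md_table(block["by_group"], ["unit_id", "source", "mean", "sd"]),
        ]
    for period, block in report.epsilon.items():
        parts += [
            "",
            f"## Specialization index ({period})",
            _md_table(block["summary"], ["by", "mean", "std", "min", "max", "count"]),
        ]
    if report.warnings:
        parts += ["", "## Warnings"] + [f"- {w}" for w in report.warnings]
    return "\n".join(parts) + "\n"


def validate_report(data: dict, schema: dict | None = None, path: str = "$") -> list[str]:
    """Structural validation of a report dict against the shipped schema.

    Checks required keys and basic types ("object", "array", "string",
    "number", "integer", "boolean", "null"); returns a list of problems
    (empty = valid).
    """
    if schema is None:
        schema = json.loads(
            resources.files("trophoniche.data").joinpath("report_schema.json").read_text()
        )
    problems: list[str] = []

    def check(value, sch, where):
        types = sch.get("type")
        if types:
            if isinstance(types, str):
                types = [types]
            ok = any(
                (t == "object" and isinstance(value, dict))
                or (t == "array" and isinstance(value, list))
                or (t == "string" and isinstance(value, str))
                or (t == "number" and isinstance(value, (int, float)) and not isinstance(value, bool))
                or (t == "integer" and isinstance(value, int) and not isinstance(value, bool))
                or (t == "boolean" and isinstance(value, bool))
                or (t == "null" and value is None)
                for t in types
            )
            if not ok:
                problems.append(f"{where}: expected {types}, got {type(value).__name__}")
                return
        if isinstance(value, dict):
            for key in sch.get("required", []):
                if key not in value:
                    problems.append(f"{where}: missing required key {key!r}")
            props = sch.get("properties", {})
            for key, sub in props.items():
                if key in value:
                    check(value[key], sub, f"{where}.{key}")
        if isinstance(value, list) and "items" in sch:
            for i, item in enumerate(value):
                check(item, sch["items"], f"{where}[{i}]")

    check(data, schema, path)
    return problems
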