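"""End-to-end orchestration: ingest -> integrate -> metrics -> reports.

A run is described by one declarative YAML config naming, per disorder,
the per-source input files, plus a schema-profile file, the target
assembly, the concordance policy and optional disorder groups.  The
pipeline emits, per disorder: the consolidated registry (JSON), the Venn
region counts (TSV), the data-level completeness table (TSV) and the
concordance table (TSV); plus one schema-level completeness table and,
per group, aggregate completeness/concordance tables.  Everything is
deterministic on fixed inputs — reruns are byte-identical.

Group aggregation sums per-disorder counts without cross-disorder
deduplication: a variation linked to two disorders of a group is counted
once per disorder.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from . import ingest, metrics
from .integrate import (
    IntegratedDataset,
    integrate,
    overlap_regions,
    write_overlap_tsv,
    write_registry,
)
from .metrics import ConcordancePolicy, ConcordanceResult
from .model import DisorderSpec, SchemaProfile
from .synthetic import _slug as slugify

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is inconsistent or references missing files."""


@dataclass(frozen=True)
class DisorderRun:
    """One disorder and its per-source input files."""

    spec: DisorderSpec
    source_paths: Mapping[str, Path]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    disorders: tuple[DisorderRun, ...]
    schema_profiles_path: Path
    output_dir: Path
    target_assembly: str = "GRCh38"
    policy: ConcordancePolicy = ConcordancePolicy()
    groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    cdl_style: str = "half_up"
    csl_style: str = "truncate"

    def validate(self) -> None:
        if not self.disorders:
            raise ConfigError("at least one disorder is required")
        if not self.schema_profiles_path.exists():
            raise ConfigError(f"schema profile file not found: "
                              f"{self.schema_profiles_path}")
        for run in self.disorders:
            if not run.source_paths:
                raise ConfigError(f"disorder {run.spec.name!r} lists no sources")
            for source, path in run.source_paths.items():
                if not Path(path).exists():
                    raise ConfigError(f"input for {run.spec.name!r}/{source!r} "
                                      f"not found: {path}")
        names = {run.spec.name for run in self.disorders}
        for group, members in self.groups.items():
            unknown = set(members) - names
            if unknown:
                raise ConfigError(f"group {group!r} references unknown "
                                  f"disorders {sorted(unknown)}")


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Load a run configuration from its YAML form."""
    path = Path(path)
    payload = yaml.safe_load(path.read_text(encoding="utf-8"))
    base = path.parent

    def resolve(p: str) -> Path:
        candidate = Path(p)
        return candidate if candidate.is_absolute() else base / candidate

    disorders = []
    for entry in payload.get("disorders", []):
        spec = ingest.disorder_spec_from_config(entry)
        source_paths = {source: resolve(p)
                        for source, p in entry.get("sources", {}).items()}
        disorders.append(DisorderRun(spec=spec, source_paths=source_paths))
    policy_cfg = payload.get("policy", {})
    policy = ConcordancePolicy(
        strict_mode=bool(policy_cfg.get("strict_mode", False)),
        gwas_p_threshold=float(policy_cfg.get("gwas_p_threshold", 5e-8)),
        denominator=policy_cfg.get("denominator", "evidence"),
    )
    return RunConfig(
        disorders=tuple(disorders),
        schema_profiles_path=resolve(payload["schema_profiles"]),
        output_dir=resolve(payload.get("output_dir", "out")),
        target_assembly=payload.get("assembly", "GRCh38"),
        policy=policy,
        groups={g: tuple(members)
                for g, members in payload.get("groups", {}).items()},
        cdl_style=payload.get("cdl_style", "half_up"),
        csl_style=payload.get("csl_style", "truncate"),
    )


def _write_csl_tsv(profiles: Sequence[SchemaProfile], path: Path,
                   style: str) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "entities_represented", "entities_total",
                         "csl_percent"])
        for profile in profiles:
            result = metrics.csl(profile, style=style)
            writer.writerow([result.source, result.entities_represented,
                             result.entities_total, result.percent_display])


def _write_cdl_tsv(rows: Sequence[metrics.CDLResult], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["disorder", "source", "n_in_source", "n_unique_total",
                         "cdl_percent"])
        for row in rows:
            writer.writerow([row.disorder_label, row.source, row.n_in_source,
                             row.n_unique_total, row.percent_display])


def _write_concordance_tsv(result: ConcordanceResult, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["label", "mode", "concordant", "discordant",
                         "concordance_percent"])
        writer.writerow([result.label, "interpretation",
                         result.interp_concordant, result.interp_discordant,
                         result.interp_percent])
        writer.writerow([result.label, "gwas", result.gwas_concordant,
                         result.gwas_discordant, result.gwas_percent])


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and return the emitted artifact paths.

    Configuration errors surface before any computation; a broken input
    file aborts the run with file context.
    """
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    profiles = ingest.load_schema_profiles(config.schema_profiles_path)
    csl_path = out / "csl.tsv"
    _write_csl_tsv(profiles, csl_path, config.csl_style)
    bundle["csl"] = csl_path

    datasets: dict[str, IntegratedDataset] = {}
    concordances: dict[str, ConcordanceResult] = {}
    for run in config.disorders:
        name = run.spec.name
        logger.info("processing disorder %s", name)
        per_source = {}
        for source, path in run.source_paths.items():
            records = ingest.read_source_file(path, expected_source=source)
            per_source[source] = ingest.filter_by_disorder(records, run.spec)
        dataset = integrate(per_source, run.spec, config.target_assembly)
        datasets[name] = dataset
        disorder_dir = out / slugify(name)
        disorder_dir.mkdir(parents=True, exist_ok=True)

        registry = write_registry(dataset, disorder_dir / "registry.json")
        bundle[f"{name}/registry"] = registry

        overlap = overlap_regions(dataset)
        overlap_path = write_overlap_tsv(overlap, disorder_dir / "overlap.tsv")
        bundle[f"{name}/overlap"] = overlap_path

        cdl_rows = [metrics.cdl(dataset, source, style=config.cdl_style)
                    for source in dataset.sources]
        cdl_path = disorder_dir / "cdl.tsv"
        _write_cdl_tsv(cdl_rows, cdl_path)
        bundle[f"{name}/cdl"] = cdl_path

        concordance = metrics.concordance_summary(dataset, config.policy,
                                                  style=config.cdl_style)
        concordances[name] = concordance
        concordance_path = disorder_dir / "concordance.tsv"
        _write_concordance_tsv(concordance, concordance_path)
        bundle[f"{name}/concordance"] = concordance_path

    all_sources: list[str] = []
    for run in config.disorders:
        for source in run.source_paths:
            if source not in all_sources:
                all_sources.append(source)

    for group, members in config.groups.items():
        group_dir = out / f"group_{slugify(group)}"
        group_dir.mkdir(parents=True, exist_ok=True)
        member_datasets = [datasets[m] for m in members]
        rows = []
        for source in all_sources:
            present = [d for d in member_datasets if source in d.sources]
            if not present:
                continue
            rows.append(metrics.aggregate_cdl(present, source, group,
                                              style=config.cdl_style))
        cdl_path = group_dir / "cdl.tsv"
        _write_cdl_tsv(rows, cdl_path)
        bundle[f"group:{group}/cdl"] = cdl_path

        aggregate = metrics.aggregate_concordance(
            [concordances[m] for m in members], group,
            style=config.cdl_style)
        concordance_path = group_dir / "concordance.tsv"
        _write_concordance_tsv(aggregate, concordance_path)
        bundle[f"group:{group}/concordance"] = concordance_path

    return bundle


def render_tables(output_dir: Union[str, Path]) -> str:
    """Render every TSV artifact under an output directory as aligned text.

    Presentation only: the values are read back from the emitted TSVs, so
    the rendered text always matches the machine-readable artifacts.
    """
    output_dir = Path(output_dir)
    blocks = []
    for tsv in sorted(output_dir.rglob("*.tsv")):
        with tsv.open(encoding="utf-8", newline="") as handle:
            rows = list(csv.reader(handle, delimiter="\t"))
        if not rows:
            continue
        widths = [max(len(row[i]) for row in rows if i < len(row))
                  for i in range(max(map(len, rows)))]
        lines = ["  ".join(cell.ljust(widths[i])
                           for i, cell in enumerate(row)).rstrip()
                 for row in rows]
        title = tsv.relative_to(output_dir).as_posix()
        blocks.append("\n".join([f"== {title} =="] + lines))
    return "\n\n".join(blocks) + "\n"
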