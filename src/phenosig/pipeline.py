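"""End-to-end orchestration: inputs -> mapping -> profiling -> reports.

The pipeline is deterministic: re-running an identical configuration
byte-reproduces every output file (randomness exists only in the study
generator). Outputs written to the configured directory:

* ``signatures.tsv``       sample x vitamin CPI / auxotrophy / mapped fraction
* ``cpm.tsv``              per-sample phylotype x vitamin phenotype values
* ``group_signatures.tsv`` group x vitamin mean +- SD (n)
* ``classes.tsv``          per-phylotype auxotrophy-pattern class
* ``comparison.tsv``       species-level D-vs-E comparison (when configured)
* ``run_report.json``      mapped fractions, warnings, config echo, version
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import classes_to_frame, classify_taxon, compare_groups
from .copy_number import load_copy_number_table, renormalize_profile
from .errors import ConfigError
from .mapping import (
    DEFAULT_THRESHOLDS,
    MappingThresholds,
    load_profiles,
    map_profile,
)
from .profiling import (
    aggregate_group,
    community_phenotype_matrix,
    community_signature,
    cpm_to_frame,
    group_signatures_to_frame,
    phenotype_index,
    signatures_to_frame,
)
from .reference import load_reference_collection

logger = logging.getLogger(__name__)

PCT_FMT = "%.4f"


@dataclass
class PipelineConfig:
    bpm: str
    profiles: str
    outdir: str
    metadata: str | None = None
    copy_numbers: str | None = None
    thresholds: MappingThresholds = DEFAULT_THRESHOLDS
    aux_threshold: float = 0.0
    proto_threshold: float = 1.0
    multi_min: int = 3
    groups_d: list[str] = field(default_factory=list)
    groups_e: list[str] = field(default_factory=list)
    min_abundance: float = 1e-4
    test: str = "mannwhitney"
    raw_fractions: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thresholds:
            cfg.thresholds = MappingThresholds(**thresholds)
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d


@dataclass
class RunReport:
    mapped_fractions: dict[str, float]
    warnings: list[str]
    outputs: list[str]
    config: dict
    version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full projection for every sample in the profile table."""
    for attr in ("bpm", "profiles", "metadata", "copy_numbers"):
        path = getattr(config, attr)
        if path is not None and not Path(path).is_file():
            raise ConfigError(f"{attr} file not found: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    root = logging.getLogger("phenosig")
    root.addHandler(collector)
    try:
        collection = load_reference_collection(config.bpm)
        _, profiles = load_profiles(config.profiles, config.metadata)
        if config.copy_numbers:
            table = load_copy_number_table(config.copy_numbers)
            profiles = [renormalize_profile(p, table, collection) for p in profiles]
        cpms, signatures, mapped_fractions = [], [], {}
        index_vectors = {}
        for prof in profiles:
            mappings, mapped = map_profile(prof, collection, config.thresholds)
            mapped_fractions[prof.sample_id] = mapped
            cpm = community_phenotype_matrix(mappings, prof, collection.panel)
            cpms.append(cpm)
            signatures.append(community_signature(cpm))
            for m in mappings:
                if m.mapped and m.phylotype_id not in index_vectors:
                    index_vectors[m.phylotype_id] = phenotype_index(m, collection.panel)
        classes = [
            classify_taxon(
                idx, config.aux_threshold, config.proto_threshold, config.multi_min
            )
            for _, idx in sorted(index_vectors.items())
        ]
        outputs = []

        def write(frame, name, float_format=PCT_FMT):
            path = outdir / name
            frame.to_csv(path, sep="\t", index=False, float_format=float_format)
            outputs.append(str(path))

        write(signatures_to_frame(signatures, config.raw_fractions), "signatures.tsv",
              "%.6g" if config.raw_fractions else PCT_FMT)
        write(cpm_to_frame(cpms), "cpm.tsv", "%.6g")
        groupable = [s for s in signatures if s.group_label]
        if groupable:
            write(group_signatures_to_frame(aggregate_group(groupable)), "group_signatures.tsv")
        write(classes_to_frame(classes), "classes.tsv", "%.6g")
        if config.groups_d and config.groups_e:
            side_d = [p for p in profiles if p.group_label in config.groups_d]
            side_e = [p for p in profiles if p.group_label in config.groups_e]
            comparison = compare_groups(
                side_d, side_e, config.min_abundance, config.test
            )
            write(comparison.reset_index(), "comparison.tsv", "%.6g")
        report = RunReport(
            mapped_fractions=mapped_fractions,
            warnings=collector.messages,
            outputs=outputs,
            config=config.echo(),
        )
        report.to_json(outdir / "run_report.json")
        return report
    finally:
        root.removeHandler(collector)
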