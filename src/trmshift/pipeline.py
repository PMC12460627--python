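"""End-to-end orchestration: simulate -> annotate -> test, with artifacts.

A pipeline run is driven by a :class:`PipelineConfig` (optionally loaded
from YAML) and writes all of its artifacts into one output directory:
``cells.tsv``, the count matrix triplet and ``scores.tsv`` when the
annotation stage runs, ``report.tsv`` / ``report.json``,
``resolved-config.yaml`` (the configuration with every default filled in)
and ``run.log``.  Given the same seed a run is deterministic down to the
bytes of its report files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from .annotate import Signature, assign_labels, score_cells
from .errors import ValidationError
from .permutation import AbundanceReport, PermutationConfig, run_abundance_test
from .simulate import (
    GROUPS,
    COMPARTMENTS,
    GeneratorConfig,
    default_profiles,
    sample_counts,
    sample_labels,
)

log = logging.getLogger("trmshift")

FORMAT_VERSIONS = {
    "cells.tsv": "cell-table-tsv v1",
    "matrix.mtx": "matrix-market coordinate integer (1-based)",
    "scores.tsv": "signature-score-tsv v1",
    "report.tsv": "abundance-report-tsv v1",
    "report.json": "abundance-report-json v1",
    "resolved-config.yaml": "pipeline-config-yaml v1",
}


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    out_dir: str = "trmshift_out"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    annotate: bool = False
    test: bool = True
    # external inputs (used when the corresponding stage is not simulated)
    cells_path: str | None = None
    mtx_path: str | None = None
    genes_path: str | None = None
    barcodes_path: str | None = None
    gmt_path: str | None = None
    # stage parameters
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    marker_fold_change: float = 8.0
    top_fraction: float = 0.05
    min_score: float = 0.1
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        # the run seed drives both stochastic stages
        self.generator = GeneratorConfig(
            n_cells_per_stratum=dict(self.generator.n_cells_per_stratum),
            n_genes=self.generator.n_genes,
            baseline_mean=self.generator.baseline_mean,
            dispersion=self.generator.dispersion,
            seed=self.seed,
        )
        self.permutation = PermutationConfig(
            n_perm=self.permutation.n_perm,
            seed=self.seed,
            scope=self.permutation.scope,
            fdr_family=self.permutation.fdr_family,
            include_unassigned=self.permutation.include_unassigned,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        gen = data.pop("generator", {})
        if "n_cells_per_stratum" in gen:
            gen["n_cells_per_stratum"] = {
                _parse_stratum(k): int(v)
                for k, v in gen["n_cells_per_stratum"].items()
            }
        perm = data.pop("permutation", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            generator=GeneratorConfig(**gen),
            permutation=PermutationConfig(**perm),
            **data,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(tio.read_yaml(path))

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulate": self.simulate,
            "annotate": self.annotate,
            "test": self.test,
            "cells_path": self.cells_path,
            "mtx_path": self.mtx_path,
            "genes_path": self.genes_path,
            "barcodes_path": self.barcodes_path,
            "gmt_path": self.gmt_path,
            "generator": {
                "n_cells_per_stratum": {
                    f"{g}/{c}": int(n)
                    for (g, c), n in self.generator.n_cells_per_stratum.items()
                },
                "n_genes": self.generator.n_genes,
                "baseline_mean": self.generator.baseline_mean,
                "dispersion": self.generator.dispersion,
                "seed": self.generator.seed,
            },
            "marker_fold_change": self.marker_fold_change,
            "top_fraction": self.top_fraction,
            "min_score": self.min_score,
            "permutation": {
                "n_perm": self.permutation.n_perm,
                "seed": self.permutation.seed,
                "scope": self.permutation.scope,
                "fdr_family": self.permutation.fdr_family,
                "include_unassigned": self.permutation.include_unassigned,
            },
            "alpha": self.alpha,
        }


def _parse_stratum(key: str) -> tuple[str, str]:
    parts = key.replace("/", " ").replace(",", " ").split()
    if len(parts) != 2 or parts[0] not in GROUPS or parts[1] not in COMPARTMENTS:
        raise ValidationError(
            f"stratum key {key!r} must be '<group>/<compartment>' with group in "
            f"{GROUPS} and compartment in {COMPARTMENTS}"
        )
    return parts[0], parts[1]


def _check_inputs(config: PipelineConfig) -> None:
    """Fail on missing inputs before any computation starts."""
    required: list[tuple[str, str | None]] = []
    if not config.simulate:
        if config.annotate:
            required += [
                ("mtx_path", config.mtx_path),
                ("genes_path", config.genes_path),
                ("barcodes_path", config.barcodes_path),
                ("gmt_path", config.gmt_path),
            ]
        required.append(("cells_path", config.cells_path))
    for name, path in required:
        if path is None:
            raise ValidationError(f"{name} is required by the enabled stages")
        if not Path(path).exists():
            raise ValidationError(f"{name}: no such file {path}")


def run_pipeline(config: PipelineConfig) -> AbundanceReport | None:
    """Run the enabled stages and write all artifacts to ``config.out_dir``."""
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: AbundanceReport | None = None
    try:
        log.info(
            "pipeline start: seed=%d n_perm=%d alpha=%g",
            config.seed, config.permutation.n_perm, config.alpha,
        )
        tio.write_yaml(config.to_dict(), out / "resolved-config.yaml")
        log.info("wrote resolved-config.yaml [%s]",
                 FORMAT_VERSIONS["resolved-config.yaml"])
        profiles = default_profiles(config.marker_fold_change)

        if config.simulate:
            t0 = time.perf_counter()
            cells = sample_labels(profiles, config.generator)
            log.info("simulate: %d cells in %.2fs", len(cells),
                     time.perf_counter() - t0)
        else:
            cells = tio.read_cell_table(config.cells_path)
            log.info("loaded %d cells from %s", len(cells), config.cells_path)

        if config.annotate:
            t0 = time.perf_counter()
            if config.simulate:
                counts = sample_counts(cells, profiles, config.generator)
                tio.write_count_matrix(counts, out)
                log.info("wrote matrix.mtx/genes.tsv/barcodes.tsv [%s]",
                         FORMAT_VERSIONS["matrix.mtx"])
                signatures = [
                    Signature(p.name, tuple(p.marker_genes)) for p in profiles
                ]
            else:
                counts = tio.read_count_matrix(
                    config.mtx_path, config.genes_path, config.barcodes_path
                )
                signatures = tio.read_gmt(config.gmt_path)
            scores = score_cells(counts, signatures, config.top_fraction)
            labels = assign_labels(scores, config.min_score)
            cells = cells.copy()
            cells["subset"] = cells["cell_id"].map(labels).fillna("unassigned")
            tio.write_scores(scores, out / "scores.tsv")
            log.info("annotate: scored %d signatures x %d cells in %.2fs [%s]",
                     scores.shape[0], scores.shape[1], time.perf_counter() - t0,
                     FORMAT_VERSIONS["scores.tsv"])

        tio.write_cell_table(cells, out / "cells.tsv")
        log.info("wrote cells.tsv [%s]", FORMAT_VERSIONS["cells.tsv"])

        if config.test:
            t0 = time.perf_counter()
            report = run_abundance_test(cells, config.permutation)
            tio.write_report_tsv(report, out / "report.tsv")
            tio.write_report_json(report, out / "report.json")
            log.info(
                "test: %d rows, seed=%d n_perm=%d in %.2fs [%s; %s]",
                len(report.table), report.seed, report.n_perm,
                time.perf_counter() - t0, FORMAT_VERSIONS["report.tsv"],
                FORMAT_VERSIONS["report.json"],
            )
        log.info("pipeline done")
    finally:
        log.removeHandler(handler)
        handler.close()
    return report


def summarize(report: AbundanceReport, alpha: float = 0.05) -> str:
    """Human-readable per-compartment summary of FDR-significant subsets."""
    if report.table.empty:
        raise ValidationError("empty report")
    lines = []
    for compartment, block in report.table.groupby("compartment", sort=True):
        lines.append(f"[{compartment}] (alpha = {alpha:g})")
        hits = block[block["q_fdr"] < alpha]
        if hits.empty:
            lines.append("  no subsets pass FDR")
            continue
        for _, row in hits.iterrows():
            direction = "enriched" if row["odds_ratio"] > 1 else "depleted"
            lines.append(
                f"  {row['subset']}: {direction} in TG "
                f"(OR = {row['odds_ratio']:.2f}, "
                f"95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}, "
                f"p = {row['p_emp']:.4g}, q = {row['q_fdr']:.4g})"
            )
    return "\n".join(lines)
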