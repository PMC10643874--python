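"""End-to-end orchestration from a single YAML config.

Three modes:

* ``simulate_and_run`` — simulate a cohort of amplicon FASTQs with planted
  neuron fractions, process and classify them, and compare estimates
  against the planted truth.
* ``run_on_fastq`` — same processing/classification on user FASTQs listed
  in a sample sheet.
* ``dmr_only`` — sliding-window DMR discovery on a beta matrix (either a
  user TSV or a simulated matrix).

Every run writes a manifest (config hash, seed, versions), per-stage
structured logs with reads entering/leaving each filter, and its result
tables; all files are written atomically (temp file + rename) so a failed
run never leaves silent partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .amplicon import AmpliconReference, example_references, load_references_yaml
from .arrays import BetaMatrix
from .classify import (
    SampleResult,
    cohort_summary,
    compute_sample_ratio,
    plot_ratios_by_group,
    results_to_frame,
)
from .dmr import apply_qc, dmrs_to_bed, qc_bimodality, refine_dmrs, sliding_window_dmr
from .errors import ConfigurationError
from .reads import FILTER_ORDER, attrition_counts, calls_to_frame, process_fastq
from .simulate import (
    ArraySimConfig,
    CohortSpec,
    FractionDistribution,
    GroupSpec,
    ReadSimConfig,
    study_cohort,
    simulate_beta_matrix,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Thresholds", "run_pipeline", "load_config"]

MODES = ("simulate_and_run", "run_on_fastq", "dmr_only")


@dataclass(frozen=True)
class Thresholds:
    """All tunable gates, defaulting to the published analysis values."""

    p_threshold: float = 1e-5
    min_abs_delta: float = 0.6
    window_probe_count: int = 5
    min_mean_quality: float = 9.0
    min_length: int = 200
    max_primer_edits: int = 2
    min_span_fraction: float = 0.95
    conversion_failure_tolerance: int = 0
    cutoff: float = 0.05
    min_reads: int = 100

    def validate(self) -> None:
        for name in ("p_threshold", "min_abs_delta", "min_span_fraction", "cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"thresholds.{name}: must be in [0, 1]")


@dataclass
class PipelineConfig:
    mode: str = "simulate_and_run"
    seed: int = 0
    output_dir: str = "neurocfdna_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    # simulate_and_run
    cohort: CohortSpec | None = None
    reads: ReadSimConfig | None = None
    # run_on_fastq
    fastq_dir: str | None = None
    sample_sheet: str | None = None
    references_yaml: str | None = None
    # dmr_only
    betas: str | None = None
    groups: str | None = None
    array: ArraySimConfig | None = None
    make_plot: bool = True

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode: {self.mode!r} not one of {MODES}")
        self.thresholds.validate()
        if self.mode == "run_on_fastq":
            for name in ("fastq_dir", "sample_sheet"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(
                        f"[stage run_on_fastq] {name}: missing or nonexistent path {path!r}"
                    )
            if self.references_yaml is not None and not Path(self.references_yaml).exists():
                raise ConfigurationError(
                    f"[stage run_on_fastq] references_yaml: nonexistent path "
                    f"{self.references_yaml!r}"
                )
        if self.mode == "dmr_only" and self.betas is not None:
            for name in ("betas", "groups"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(
                        f"[stage dmr_only] {name}: missing or nonexistent path {path!r}"
                    )


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file, applying the
    packaged defaults for anything unspecified."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    thr = Thresholds(**raw.get("thresholds", {}))
    cohort = None
    if "cohort" in raw:
        c = raw["cohort"]
        if c == "study_shaped":
            cohort = study_cohort(seed=raw.get("seed", 0))
        else:
            cohort = CohortSpec(
                groups=tuple(
                    GroupSpec(
                        g["label"], g["n_samples"],
                        FractionDistribution.from_dict(g["fraction_distribution"]),
                    )
                    for g in c["groups"]
                ),
                replicates_per_sample=c.get("replicates_per_sample", 2),
                seed=c.get("seed", raw.get("seed", 0)),
            )
    reads = None
    if "reads" in raw:
        reads = ReadSimConfig(amplicon=None, **raw["reads"])
    array = ArraySimConfig(**raw["array"]) if "array" in raw else None
    return PipelineConfig(
        mode=raw.get("mode", "simulate_and_run"),
        seed=raw.get("seed", 0),
        output_dir=raw.get("output_dir", "neurocfdna_out"),
        thresholds=thr,
        cohort=cohort,
        reads=reads,
        fastq_dir=raw.get("fastq_dir"),
        sample_sheet=raw.get("sample_sheet"),
        references_yaml=raw.get("references_yaml"),
        betas=raw.get("betas"),
        groups=raw.get("groups"),
        array=array,
        make_plot=raw.get("make_plot", True),
    )


# ---------------------------------------------------------------------------

def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_df(df: pd.DataFrame, path: Path) -> None:
    _atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=False))


def _write_text(text: str, path: Path) -> None:
    _atomic_write(path, lambda tmp: Path(tmp).write_text(text))


def _manifest(config: PipelineConfig, out: Path) -> None:
    canon = yaml.safe_dump(_to_plain(config), sort_keys=True)
    manifest = {
        "package": "neurocfdna",
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
    }
    _write_text(json.dumps(manifest, indent=2) + "\n", out / "manifest.json")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


# ---------------------------------------------------------------------------

def _classify_fastqs(
    sheet: pd.DataFrame,
    fastq_dir: Path,
    references: list[AmpliconReference],
    thr: Thresholds,
    out: Path,
) -> tuple[list[SampleResult], pd.DataFrame]:
    """Process + classify every sample-replicate FASTQ in the sheet."""
    results: list[SampleResult] = []
    attrition_rows = []
    call_frames = []
    for _, row in sheet.iterrows():
        fastq = fastq_dir / row["fastq"]
        if not fastq.exists():
            raise ConfigurationError(
                f"[stage read_processing] fastq: missing file {fastq}"
            )
        calls = process_fastq(
            fastq,
            references,
            min_mean_quality=thr.min_mean_quality,
            min_length=thr.min_length,
            max_primer_edits=thr.max_primer_edits,
            min_span_fraction=thr.min_span_fraction,
            conversion_failure_tolerance=thr.conversion_failure_tolerance,
        )
        res = compute_sample_ratio(
            calls,
            sample_id=row["sample_id"],
            replicate_id=int(row["replicate"]),
            min_reads=thr.min_reads,
            cutoff=thr.cutoff,
        )
        results.append(res)
        att = attrition_counts(calls)
        logger.info(
            "sample %s rep %s: %d reads in, %d passed, attrition %s",
            row["sample_id"], row["replicate"], att["input"], att["passed"],
            {k: att[k] for k in FILTER_ORDER},
        )
        attrition_rows.append(
            {"sample_id": row["sample_id"], "replicate": row["replicate"], **att}
        )
        cf = calls_to_frame(calls)
        cf.insert(0, "sample_id", row["sample_id"])
        cf.insert(1, "replicate", row["replicate"])
        call_frames.append(cf)
    _write_df(pd.DataFrame(attrition_rows), out / "filter_attrition.tsv")
    _write_df(pd.concat(call_frames, ignore_index=True), out / "per_read_calls.tsv")
    return results, pd.DataFrame(attrition_rows)


def _report_cohort(
    results: list[SampleResult], groups: pd.Series, out: Path, make_plot: bool
) -> None:
    report = cohort_summary(results, groups)
    _write_df(report.per_sample, out / "per_sample_results.tsv")
    _write_df(report.per_group, out / "cohort_report.tsv")
    _write_text(report.to_text(), out / "cohort_report.txt")
    if make_plot:
        plot_ratios_by_group(report, out / "ratios_by_group.png")


def _dmr_stage(matrix: BetaMatrix, thr: Thresholds, out: Path) -> pd.DataFrame:
    qc = qc_bimodality(matrix)
    _write_df(qc.reset_index(names="sample_id"), out / "sample_qc.tsv")
    n_fail = int((~qc["passed"]).sum())
    if n_fail:
        logger.info("bimodality QC excluded %d sample(s)", n_fail)
    matrix = apply_qc(matrix, qc)
    windows = sliding_window_dmr(matrix, thr.window_probe_count, thr.p_threshold)
    logger.info("sliding-window scan: %d merged significant regions", len(windows))
    dmrs = refine_dmrs(windows, thr.min_abs_delta)
    table = dmrs_to_bed(dmrs, None)
    _write_df(table, out / "dmrs.tsv")
    logger.info(
        "delta refinement: %d/%d regions at |delta| >= %g",
        int(table["passes_delta_filter"].sum()), len(table), thr.min_abs_delta,
    )
    return table


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured mode; returns the output directory.

    Deterministic given the seed; halts with a stage-named error on any
    upstream failure (no silent partial outputs).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _manifest(config, out)
    thr = config.thresholds

    if config.mode == "dmr_only":
        if config.betas is not None:
            matrix = BetaMatrix.from_tsv(config.betas, config.groups)
        else:
            array_cfg = config.array or ArraySimConfig(seed=config.seed)
            matrix, truth = simulate_beta_matrix(array_cfg)
            truth.regions_to_bed(out / "planted_regions.tsv")
        _dmr_stage(matrix, thr, out)
        return out

    if config.mode == "simulate_and_run":
        cohort = config.cohort or study_cohort(seed=config.seed)
        reads_cfg = config.reads or ReadSimConfig()
        if reads_cfg.amplicon is None:
            reads_cfg = dataclasses.replace(
                reads_cfg, amplicon=example_references()[0]
            )
        references = [reads_cfg.amplicon]
        fastq_dir = out / "fastq"
        truth = simulate_cohort(cohort, reads_cfg, fastq_dir)
        sheet = truth[["sample_id", "replicate", "group", "fastq"]]
        results, _ = _classify_fastqs(sheet, fastq_dir, references, thr, out)
        groups = truth.drop_duplicates("sample_id").set_index("sample_id")["group"]
        _report_cohort(results, groups, out, config.make_plot)
        # truth-vs-estimate comparison
        est = results_to_frame(results)
        cmp = truth.merge(est, on=["sample_id", "replicate"])
        cmp["abs_error"] = (cmp["neuron_ratio"] - cmp["planted_fraction"]).abs()
        _write_df(
            cmp[["sample_id", "replicate", "group", "planted_fraction",
                 "neuron_ratio", "abs_error"]],
            out / "truth_vs_estimate.tsv",
        )
        mae = cmp["abs_error"].mean()
        logger.info("truth-vs-estimate: mean absolute ratio error %.5f", mae)
        _write_text(
            json.dumps({"mean_absolute_error": float(mae)}) + "\n",
            out / "truth_vs_estimate_summary.json",
        )
        return out

    # run_on_fastq
    sheet = pd.read_csv(config.sample_sheet, sep="\t")
    for col in ("sample_id", "replicate", "group", "fastq"):
        if col not in sheet.columns:
            raise ConfigurationError(
                f"[stage run_on_fastq] sample_sheet: missing column {col!r}"
            )
    references = (
        load_references_yaml(config.references_yaml)
        if config.references_yaml
        else example_references()
    )
    results, _ = _classify_fastqs(sheet, Path(config.fastq_dir), references, thr, out)
    groups = sheet.drop_duplicates("sample_id").set_index("sample_id")["group"]
    _report_cohort(results, groups, out, config.make_plot)
    return out
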