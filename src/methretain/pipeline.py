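"""End-to-end pipeline: QC filter -> retention -> enrichment -> classification
(-> cohort summary when cohort inputs are given), with a reproducibility
manifest recording parameters, seed and input checksums.

All stage outputs are plain TSV with ``#``-prefixed header comments
recording the generating parameters, so they can be consumed directly from
R or a spreadsheet. Config parsing is strict: unknown keys are errors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .arrays import (
    apply_detection_filter,
    read_beta_matrix,
    read_manifest,
    read_sample_sheet,
    summarize_beta,
)
from .classify import (
    ClassificationThresholds,
    classification_summary,
    classify_probes,
    de_novo_chromosome_share,
)
from .cohort import cohort_summary
from .enrichment import enrichment_analysis
from .errors import ConfigError
from .retention import parental_high_fraction, retention_table

# Defaults follow the published analysis: detection p 0.05, high-methylation
# cutoffs {0.6, 0.7, 0.85}, enrichment at 0.7, significance at 1e-6.
_PARAM_DEFAULTS = {
    "detection_threshold": 0.05,
    "cutoffs": [0.6, 0.7, 0.85],
    "enrichment_cutoff": 0.7,
    "alpha": 1e-6,
    "classification_cutoff": 0.7,
    "t_low": 0.3,
    "mono_low": 0.3,
    "mono_high": 0.7,
    "t_high": 0.7,
}


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    manifest: str
    betas: str
    samples: str
    outdir: str
    detection_p: str | None = None
    cohort_betas: str | None = None
    cohort_samples: str | None = None
    parental_id: str = "parental_1"
    compromised_id: str = "resistant_1"
    seed: int = 0
    parameters: dict = field(default_factory=lambda: dict(_PARAM_DEFAULTS))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        params = dict(_PARAM_DEFAULTS)
        user_params = raw.pop("parameters", {})
        unknown_p = set(user_params) - set(_PARAM_DEFAULTS)
        if unknown_p:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown_p)}")
        params.update(user_params)
        known = {f.name for f in dataclasses.fields(cls)} - {"parameters"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"manifest", "betas", "samples", "outdir"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(parameters=params, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a mapping")
        return cls.from_dict(raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path: str | Path, header_params: dict) -> None:
    """Write a stage TSV with ``#``-comment header lines for provenance."""
    with open(path, "w") as fh:
        for key, value in header_params.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=True, na_rep="NA", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON).

    Stages: detection-p QC filter (if detection_p given), per-sample beta
    summaries, retention table, enrichment analysis, promoter-probe
    classification, and cohort summary when cohort inputs are present.
    An ``_INCOMPLETE`` marker guards against consuming partial output.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "_INCOMPLETE"
    marker.write_text("run in progress\n")
    params = config.parameters

    stage = "load"
    try:
        manifest = read_manifest(config.manifest)
        betas = read_beta_matrix(config.betas)
        samples = read_sample_sheet(config.samples)

        stage = "qc"
        n_removed = 0
        if config.detection_p is not None:
            detp = read_beta_matrix(config.detection_p)
            betas, n_removed = apply_detection_filter(
                betas, detp, params["detection_threshold"]
            )
        summaries = pd.DataFrame(
            [dataclasses.asdict(summarize_beta(betas, s)) for s in betas.sample_ids]
        ).set_index("sample_id")
        write_tsv(summaries, outdir / "beta_summaries.tsv",
                  {"stage": "qc", "n_probes_removed": n_removed,
                   "detection_threshold": params["detection_threshold"]})

        stage = "retention"
        rtable = retention_table(
            betas, manifest, config.parental_id, config.compromised_id,
            params["cutoffs"],
        )
        write_tsv(rtable.set_index("chromosome"), outdir / "retention.tsv",
                  {"stage": "retention", "parental": config.parental_id,
                   "compromised": config.compromised_id,
                   "cutoffs": params["cutoffs"]})
        baseline = parental_high_fraction(
            betas, manifest, config.parental_id, params["enrichment_cutoff"]
        )
        write_tsv(baseline.to_frame(), outdir / "parental_high_fraction.tsv",
                  {"stage": "retention", "cutoff": params["enrichment_cutoff"]})

        stage = "enrichment"
        enr = enrichment_analysis(
            betas, manifest, config.parental_id, config.compromised_id,
            params["enrichment_cutoff"], params["alpha"],
        )
        write_tsv(enr.set_index("chromosome"), outdir / "enrichment.tsv",
                  {"stage": "enrichment", "cutoff": params["enrichment_cutoff"],
                   "alpha": params["alpha"]})

        stage = "classification"
        thresholds = ClassificationThresholds(
            t_low=params["t_low"], mono_low=params["mono_low"],
            mono_high=params["mono_high"], t_high=params["t_high"],
        )
        calls = classify_probes(
            betas, manifest, samples, config.parental_id, config.compromised_id,
            params["classification_cutoff"], thresholds,
        )
        write_tsv(calls, outdir / "probe_classes.tsv",
                  {"stage": "classification",
                   "cutoff": params["classification_cutoff"]})
        genome = classification_summary(calls, "genome_wide") if len(calls) else None
        chrx = classification_summary(calls, "chrX_only") if len(calls) else None

        stage = "cohort"
        cohort_done = False
        if config.cohort_betas is not None and config.cohort_samples is not None:
            cbetas = read_beta_matrix(config.cohort_betas)
            csamples = read_sample_sheet(config.cohort_samples)
            de_novo_probes = calls.index[calls["category"] == "unmethylated_in_normal"]
            shared = de_novo_probes.intersection(cbetas.probe_ids)
            if len(shared):
                csum = cohort_summary(cbetas, csamples, shared)
                write_tsv(csum, outdir / "cohort_summary.tsv",
                          {"stage": "cohort", "n_probes": len(shared)})
                cohort_done = True
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    report = {
        "version": __version__,
        "seed": config.seed,
        "parameters": params,
        "inputs": {
            name: {"path": p, "sha256": _sha256(p)}
            for name, p in {
                "manifest": config.manifest,
                "betas": config.betas,
                "samples": config.samples,
                "detection_p": config.detection_p,
                "cohort_betas": config.cohort_betas,
                "cohort_samples": config.cohort_samples,
            }.items()
            if p is not None
        },
        "qc": {"n_probes_removed": n_removed, "n_probes_kept": betas.n_probes},
        "classification": {
            "n_selected": int(len(calls)),
            "genome_wide": dataclasses.asdict(genome) if genome else None,
            "pct_de_novo_genome": genome.pct_de_novo if genome else None,
            "chrX_only": dataclasses.asdict(chrx) if chrx else None,
            "pct_de_novo_chrX": chrx.pct_de_novo if chrx else None,
            "pct_de_novo_on_chrX": de_novo_chromosome_share(calls) if len(calls) else None,
        },
        "cohort_summarized": cohort_done,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    marker.unlink()
    return report
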