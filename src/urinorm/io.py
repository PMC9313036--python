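"""Delimited-text I/O, run configuration, and the end-to-end pipeline.

All tables round-trip through plain CSV/TSV (header row, sample IDs in the
first column, UTF-8, 6 significant digits); a JSON manifest records the
full configuration, seed and library versions so every output is
regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import GeneratorConfig, SyntheticTruth, generate_cohort
from .concordance import (
    dilution_recovery,
    pairwise_mean_r2,
    sign_concordance,
    summaries_to_frame,
)
from .correlations import apply_reference_order, cluster_order, correlation_matrix
from .normalize import (
    IS_LABELS,
    NormalizationSpec,
    NormalizedTable,
    apply_scheme,
    standard_schemes,
)
from .regression import association_scan, bonferroni_threshold, effective_tests, records_to_frame
from .tables import ConfigurationError, MetaboliteTable, ValidationError, as_positive_frame

logger = logging.getLogger("urinorm")

FLOAT_FORMAT = "%.6g"

#: Scheme names accepted in configuration files and on the command line.
KNOWN_SCHEMES = ("ABS", "IS-CREA", "IS-GLUC", "IS-UREA", "IS-PSEURID", "CS", "PQN", "DESEQ2")


def spec_from_name(name: str) -> NormalizationSpec:
    """Map a scheme label like ``is-crea`` or ``pqn`` to its spec."""
    upper = name.strip().upper()
    for ref, label in IS_LABELS.items():
        if upper == label:
            return NormalizationSpec("IS", reference_metabolite=ref)
    if upper in ("ABS", "CS", "PQN", "DESEQ2"):
        return NormalizationSpec(upper)
    raise ConfigurationError(f"unknown scheme {name!r}; expected one of {KNOWN_SCHEMES}")


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect:
        return {"csv": ",", "tsv": "\t"}[dialect]
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_metabolite_table(path, dialect: str | None = None) -> MetaboliteTable:
    """Read a sample x metabolite table from delimited text.

    Expects a header row, sample IDs in the first column, and a strictly
    positive numeric body; duplicate metabolite or sample names, missing
    cells, and non-numeric cells are rejected with the offending location
    in the message.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    header = path.read_text(encoding="utf-8").splitlines()[0].split(sep)[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValidationError(f"duplicate metabolite name in header: {dup!r}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan)
    return MetaboliteTable(raw)


def write_table(frame: pd.DataFrame, path, dialect: str | None = None,
                index_label: str = "sample_id") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=_sep_for(path, dialect), float_format=FLOAT_FORMAT,
                 index_label=index_label)


def write_normalized(norm: NormalizedTable, path) -> None:
    """Write normalized values plus a ``<stem>.scale_factors`` sidecar."""
    path = Path(path)
    write_table(norm.values, path)
    sidecar = path.with_name(path.stem + ".scale_factors" + path.suffix)
    write_table(norm.scale_factors.to_frame(), sidecar)


def write_cohort(table: MetaboliteTable, covariates: pd.DataFrame,
                 truth: SyntheticTruth, config: GeneratorConfig, outdir) -> dict:
    """Write a synthetic cohort: observed table, covariates, truth sidecars,
    and a JSON metadata record with the full generator configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(table.data, outdir / "metabolites.csv")
    write_table(covariates, outdir / "covariates.csv")
    write_table(truth.physiological_matrix, outdir / "truth_physiological.csv")
    write_table(truth.dilution_factors.to_frame(), outdir / "truth_dilution.csv")
    meta = {
        "generator_config": _jsonable(dataclasses.asdict(config)),
        "true_effects": truth.true_effects,
        "cluster_assignment": truth.cluster_assignment,
        "seed": truth.seed,
    }
    (outdir / "cohort_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): float(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    output_dir: str = "urinorm_run"
    input_table: str | None = None       # observed concentrations; None -> generate
    input_covariates: str | None = None
    schemes: tuple[str, ...] = KNOWN_SCHEMES
    outcomes: tuple[str, ...] = ("BMI", "MAP")
    adjust_covariates: tuple[str, ...] = ("sex",)
    alpha: float = 0.05
    variance_cut: float = 0.99
    linkage: str = "average"
    n_clusters: int = 8
    reference_scheme: str = "IS-CREA"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int | None = None
    make_plots: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        gen = data.pop("generator", None)
        config = cls(**data)
        if gen:
            config.generator = GeneratorConfig(**gen)
        return config

    def validate(self) -> "RunConfig":
        for scheme in self.schemes:
            spec_from_name(scheme)
        if self.reference_scheme.upper() not in {s.upper() for s in self.schemes}:
            raise ConfigurationError(
                f"reference scheme {self.reference_scheme!r} not among schemes"
            )
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        return self


def run_pipeline(config: RunConfig) -> Path:
    """Run generate -> normalize -> correlate -> associate -> compare.

    Writes every table plus a machine-readable manifest to
    ``config.output_dir`` and returns that directory. Reruns with the same
    configuration are bit-identical for all numeric outputs.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "generate"
    try:
        truth = None
        if config.input_table:
            table = read_metabolite_table(config.input_table)
            covariates = pd.read_csv(config.input_covariates, index_col=0)
        else:
            if config.seed is not None:
                config.generator.seed = config.seed
            table, covariates, truth = generate_cohort(config.generator)
            write_cohort(table, covariates, truth, config.generator, outdir / "cohort")
        logger.info("%s: table %s, covariates %s", stage, table.shape, covariates.shape)

        stage = "normalize"
        specs = [spec_from_name(s) for s in config.schemes]
        normalized = [apply_scheme(table, spec) for spec in specs]
        for norm in normalized:
            write_normalized(norm, outdir / "normalized" / f"{norm.label}.csv")
            logger.info("%s: %s -> %s", stage, norm.label, norm.values.shape)

        stage = "correlate"
        adjust_cov = covariates[list(config.adjust_covariates)]
        reference_result = None
        results = {}
        for norm in normalized:
            for adjusted in (True, False):
                result = correlation_matrix(
                    norm, covariates=adjust_cov if adjusted else None, adjust=adjusted
                )
                results[(norm.label, adjusted)] = result
        reference_result = cluster_order(
            results[(config.reference_scheme.upper(), True)],
            linkage=config.linkage, n_clusters=config.n_clusters,
        )
        results[(config.reference_scheme.upper(), True)] = reference_result
        for (label, adjusted), result in results.items():
            result = apply_reference_order(result, reference_result)
            results[(label, adjusted)] = result
            tag = "sexadj" if adjusted else "unadj"
            write_table(result.ordered_matrix(),
                        outdir / "correlations" / f"{label}_{tag}.csv",
                        index_label="metabolite")

        stage = "associate"
        m_eff = effective_tests(table, config.variance_cut)
        threshold = bonferroni_threshold(config.alpha, m_eff, config.variance_cut)
        outcome_frame = covariates[list(config.outcomes)]
        records = []
        for adjusted in (True, False):
            records += association_scan(
                normalized, outcome_frame,
                covariates=adjust_cov if adjusted else None,
                threshold=threshold, sex_adjusted=adjusted,
            )
        write_table(records_to_frame(records).set_index("scheme"),
                    outdir / "associations.csv", index_label="scheme")

        stage = "compare"
        summaries = pairwise_mean_r2(normalized)
        write_table(summaries_to_frame(summaries).set_index("scheme_a"),
                    outdir / "pairwise_mean_r2.csv", index_label="scheme_a")
        concordances = sign_concordance(records, config.reference_scheme.upper())
        recovery = {}
        if truth is not None:
            import warnings as _warnings
            for norm in normalized:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    recovery[norm.label] = dilution_recovery(norm, truth)
        write_table(
            pd.DataFrame({
                "sign_concordance": pd.Series(concordances),
                "dilution_recovery": pd.Series(recovery, dtype=float),
            }),
            outdir / "scheme_agreement.csv", index_label="scheme",
        )

        if config.make_plots:
            stage = "plot"
            from .plots import correlation_heatmap, forest_plot
            for (label, adjusted), result in results.items():
                if adjusted:
                    correlation_heatmap(result, outdir / "plots" / f"{label}_heatmap.png")
            for outcome in config.outcomes:
                forest_plot(records, outcome, outdir / "plots" / f"forest_{outcome}.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "urinorm_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": _jsonable(dataclasses.asdict(config)),
        "m_eff": m_eff,
        "p_threshold": threshold.threshold,
        "n_records": len(records),
        "stages": ["generate", "normalize", "correlate", "associate", "compare"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
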