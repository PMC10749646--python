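"""End-to-end orchestration: file I/O, configuration and report generation.

The pipeline runs the full analysis in a fixed order — tally (with reverse
recoding) → original/revised classification → dichotomization → scree →
GCM fit → consensus classification → importance coefficients → optional
resilience rerun — and is fully deterministic: one configuration and one
master seed fix every output byte.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (
    ClassificationResult,
    DichotomizationScheme,
    binary_matrix,
    classify_attribute,
)
from .gcm import (
    GCMPosterior,
    MCMCSettings,
    ResilienceResult,
    ScreeResult,
    fit_gcm,
    resilience_rerun,
    scree_analysis,
)
from .survey import (
    AttributeSpec,
    ResponsePair,
    SurveyDataset,
    SurveyError,
    tally_all,
)
from .timko import TimkoPoint, coefficient_table

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "PipelineError",
    "read_manifest",
    "read_survey",
    "write_survey",
    "run_pipeline",
    "write_report",
]

log = logging.getLogger("kanocca")

_CSV_COLUMNS = ["respondent_id", "attribute_id", "functional_code", "dysfunctional_code"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``seed`` is mandatory and drives every stochastic stage.  ``drop_items``
    triggers the resilience rerun when non-empty.
    """

    input: str | Path
    manifest: str | Path | None = None
    seed: int = 0
    chains: int = 3
    samples: int = 10_000
    burnin: int = 2_000
    thin: int = 10
    ratio_threshold: float = 1.75
    negative_loading_tolerance: float = 0.25
    drop_items: list[str] = field(default_factory=list)
    make_figure: bool = False

    @property
    def mcmc(self) -> MCMCSettings:
        return MCMCSettings(
            chains=self.chains,
            samples=self.samples,
            burnin=self.burnin,
            seed=self.seed,
            thin=self.thin,
        )


@dataclass
class AnalysisReport:
    """Everything one pipeline run produced."""

    classifications: dict[str, ClassificationResult]
    timko: list[TimkoPoint]
    posterior: GCMPosterior
    scree: ScreeResult
    resilience: ResilienceResult | None
    config: PipelineConfig
    counts: dict[str, int]


def read_manifest(path: str | Path | None = None) -> list[AttributeSpec]:
    """Read an attribute manifest (YAML); None loads the shipped default."""
    if path is None:
        with resources.files("kanocca.data").joinpath("attributes.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not raw or "attributes" not in raw:
        raise SurveyError("manifest must contain an 'attributes' list")
    return [
        AttributeSpec(
            id=str(item["id"]),
            label=str(item.get("label", "")),
            group=str(item.get("group", "")),
            reverse_recoded=bool(item.get("reverse_recoded", False)),
        )
        for item in raw["attributes"]
    ]


def read_survey(path: str | Path, attributes: list[AttributeSpec]) -> SurveyDataset:
    """Read a long-format survey CSV, reporting malformed rows by line number.

    Expected columns: respondent_id, attribute_id, functional_code,
    dysfunctional_code (codes 1-5).  Unknown attribute ids, out-of-range
    codes and duplicate (respondent, attribute) keys are collected and
    raised as one itemized error.
    """
    known = {a.id for a in attributes}
    pairs: dict[tuple[str, str], ResponsePair] = {}
    respondents: list[str] = []
    seen_resp: set[str] = set()
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CSV_COLUMNS:
            raise SurveyError(
                f"{path}: header must be {','.join(_CSV_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            resp = (row["respondent_id"] or "").strip()
            attr = (row["attribute_id"] or "").strip()
            if not resp or not attr:
                errors.append(f"line {lineno}: empty respondent or attribute id")
                continue
            if attr not in known:
                errors.append(f"line {lineno}: unknown attribute id {attr!r}")
                continue
            codes = []
            bad = False
            for col in ("functional_code", "dysfunctional_code"):
                try:
                    code = int(row[col])
                except (TypeError, ValueError):
                    errors.append(f"line {lineno}: {col} {row[col]!r} is not an integer")
                    bad = True
                    continue
                if not 1 <= code <= 5:
                    errors.append(f"line {lineno}: {col}={code} outside 1-5")
                    bad = True
                codes.append(code)
            if bad:
                continue
            key = (resp, attr)
            if key in pairs:
                errors.append(f"line {lineno}: duplicate pair for {key}")
                continue
            pairs[key] = ResponsePair(codes[0], codes[1])
            if resp not in seen_resp:
                seen_resp.add(resp)
                respondents.append(resp)
    if errors:
        raise SurveyError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    if n_rows == 0:
        raise SurveyError(f"{path}: no data rows")
    return SurveyDataset(respondents=respondents, attributes=list(attributes), pairs=pairs)


def write_survey(dataset: SurveyDataset, path: str | Path) -> None:
    """Write a survey in the long CSV dialect (lossless round trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for resp in dataset.respondents:
            for spec in dataset.attributes:
                pair = dataset.pairs.get((resp, spec.id))
                if pair is not None:
                    writer.writerow(
                        [resp, spec.id, int(pair.functional), int(pair.dysfunctional)]
                    )


def run_pipeline(config: PipelineConfig, dataset: SurveyDataset | None = None) -> AnalysisReport:
    """Run the full analysis; see the module docstring for stage order.

    ``dataset`` bypasses file reading (``config.input`` is then only echoed
    into the metadata).
    """

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    if dataset is None:
        attributes = stage("manifest")(read_manifest, config.manifest)
        dataset = stage("read")(read_survey, config.input, attributes)
    n_expected = len(dataset.respondents) * len(dataset.attributes)
    counts = {
        "respondents": len(dataset.respondents),
        "attributes": len(dataset.attributes),
        "pairs": len(dataset.pairs),
        "pairs_missing": n_expected - len(dataset.pairs),
    }
    log.info("read %d respondents x %d attributes (%d pairs, %d missing)",
             counts["respondents"], counts["attributes"], counts["pairs"],
             counts["pairs_missing"])

    tallies = stage("tally")(tally_all, dataset)

    gcm_data = stage("dichotomize")(binary_matrix, dataset, DichotomizationScheme.RELEVANCE)
    scree_data = stage("dichotomize")(
        binary_matrix, dataset, DichotomizationScheme.RELEVANCE_WITH_REVERSE
    )

    scree = stage("scree")(
        scree_analysis,
        scree_data,
        ratio_threshold=config.ratio_threshold,
        negative_loading_tolerance=config.negative_loading_tolerance,
    )
    counts["scree_omitted"] = scree.n_omitted
    log.info("scree: ratio %.2f, %d zero-variance respondent(s) omitted, %d culture(s)",
             scree.ratio_first_second, scree.n_omitted, scree.n_cultures)

    posterior = stage("gcm_fit")(
        fit_gcm,
        gcm_data,
        chains=config.chains,
        samples=config.samples,
        burnin=config.burnin,
        seed=config.seed,
        thin=config.thin,
    )
    log.info("gcm: cohort competency %.3f (SD %.3f), guessing bias %.3f (SD %.3f), max rhat %.3f",
             posterior.theta_mean, posterior.theta_sd, posterior.g_mean,
             posterior.g_sd, posterior.max_rhat)

    truth = dict(zip(posterior.item_ids, posterior.item_truth))

    def _classify():
        return {
            attr: classify_attribute(attr, tally, item_truth=truth[attr])
            for attr, tally in tallies.items()
        }

    classifications = stage("classify")(_classify)
    timko = stage("timko")(coefficient_table, tallies, "mark")

    resilience = None
    if config.drop_items:
        resilience = stage("resilience")(
            resilience_rerun,
            dataset,
            config.drop_items,
            config.mcmc,
            classifications,
        )
        log.info("resilience: dropped %s, %d classification(s) changed",
                 config.drop_items, len(resilience.changed))

    return AnalysisReport(
        classifications=classifications,
        timko=timko,
        posterior=posterior,
        scree=scree,
        resilience=resilience,
        config=config,
        counts=counts,
    )


def _report_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    truth = dict(zip(report.posterior.item_ids, report.posterior.item_truth))
    binary = dict(zip(report.posterior.item_ids, report.posterior.binary_truth))
    difficulty = dict(zip(report.posterior.item_ids, report.posterior.delta_mean))
    for attr, res in report.classifications.items():
        pct = res.tally.percentages
        rows.append(
            {
                "attribute_id": attr,
                **{f"pct_{c.value.lower()}": pct[c] for c in pct},
                "n": res.tally.n,
                "original": str(res.original),
                "revised": str(res.revised),
                "cca": str(res.cca) if res.cca is not None else "",
                "item_truth": truth.get(attr, np.nan),
                "binary_truth": binary.get(attr, ""),
                "item_difficulty": difficulty.get(attr, np.nan),
                "tie_flag": res.tie_flag,
            }
        )
    return pd.DataFrame(rows)


def _timko_frame(points: list[TimkoPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "attribute_id": p.attribute_id,
                "better": p.better if p.better is not None else "undefined",
                "worse": p.worse if p.worse is not None else "undefined",
                "quadrant": str(p.quadrant) if p.quadrant is not None else "undefined",
                "on_boundary": p.on_boundary,
            }
            for p in points
        ]
    )


def _timko_figure(points: list[TimkoPoint], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for p in points:
        if p.better is None:
            continue
        ax.scatter(p.worse, p.better, color="tab:blue")
        ax.annotate(p.attribute_id, (p.worse, p.better), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("worse (dissatisfaction if absent)")
    ax.set_ylabel("better (satisfaction if present)")
    ax.set_title("Importance coefficients")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_report(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Write all report artifacts; on failure, partial outputs are removed.

    Files: ``report.csv`` (per-attribute percentages, classifications,
    truth/difficulty), ``timko.csv`` (plot data), ``eigenvalues.csv``,
    ``posterior_summary.csv`` (per item) and ``run_metadata.json`` (config
    echo, cohort summaries, counts, versions).  Numbers are written at full
    precision; rounding is a display concern.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        p = outdir / "report.csv"
        _report_frame(report).to_csv(p, index=False)
        written.append(p)

        p = outdir / "timko.csv"
        _timko_frame(report.timko).to_csv(p, index=False)
        written.append(p)

        p = outdir / "eigenvalues.csv"
        pd.DataFrame(
            {
                "rank": np.arange(1, report.scree.eigenvalues.size + 1),
                "eigenvalue": report.scree.eigenvalues,
            }
        ).to_csv(p, index=False)
        written.append(p)

        p = outdir / "posterior_summary.csv"
        pd.DataFrame(
            {
                "attribute_id": report.posterior.item_ids,
                "item_truth": report.posterior.item_truth,
                "binary_truth": report.posterior.binary_truth,
                "item_difficulty": report.posterior.delta_mean,
            }
        ).to_csv(p, index=False)
        written.append(p)

        meta = {
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(report.config).items()
            },
            "counts": report.counts,
            "cohort": {
                "competency_mean": report.posterior.theta_mean,
                "competency_sd": report.posterior.theta_sd,
                "guessing_bias_mean": report.posterior.g_mean,
                "guessing_bias_sd": report.posterior.g_sd,
            },
            "scree": {
                "ratio_first_second": report.scree.ratio_first_second,
                "n_cultures": report.scree.n_cultures,
                "n_omitted": report.scree.n_omitted,
                "negative_loading_fraction": report.scree.negative_loading_fraction,
            },
            "max_rhat": (
                None
                if np.isnan(report.posterior.max_rhat)
                else report.posterior.max_rhat
            ),
            "resilience_changed": (
                report.resilience.changed if report.resilience is not None else None
            ),
            "versions": _versions(),
        }
        p = outdir / "run_metadata.json"
        p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        written.append(p)

        if report.config.make_figure:
            p = outdir / "timko.png"
            _timko_figure(report.timko, p)
            written.append(p)
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
    return written


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("kanocca", "numpy", "scipy", "pandas", "arviz"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out
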