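"""File formats and the end-to-end analysis driver.

All tabular interchange is tab-delimited UTF-8 with a header row and "."
decimals: expression matrices are genes x patients (first column the gene
id), clinical tables carry patient_id/time/event, gene signatures travel in
standard GMT files, and the pipeline-variant design is a YAML manifest
listing each variant's factor levels.
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
from .datagen import PipelineVariant, SimulationConfig
from .ensemble import (
    VoteMatrix,
    classify_views,
    combine_signatures,
    ensemble_score,
    matched_individual_classify,
    unanimous_classify,
)
from .exceptions import ConfigError, InputError, ParseError
from .resampling import aspect_paired_comparison, sweep_ensemble_size
from .scoring import RiskClassification, Signature
from .survival import evaluate_classification, survival_frame

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- expression

def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x patients matrix; strict about shape and content."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - wrap any pandas parse failure
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: matrix has 0 patient columns")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dupes[:5]}")
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            line = df.index.get_loc(bad) + 2  # header is line 1
            raise ParseError(
                f"{path}: non-numeric cell at line {line}, column {col!r}"
            ) from None
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = "gene_id"
    return out


# ------------------------------------------------------------------ clinical

def write_clinical_tsv(survival: pd.DataFrame, path) -> None:
    out = survival_frame(survival).copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t")


def read_clinical_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: {exc}") from exc
    required = {"patient_id", "time", "event"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: clinical table needs columns {sorted(required)}")
    df = df.set_index("patient_id")
    try:
        return survival_frame(df)
    except InputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> list[Signature]:
    """Read gene signatures from a GMT file (name, description, genes...)."""
    path = Path(path)
    signatures = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, description = fields[0], fields[1]
            genes, seen = [], set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "%s:%d: duplicate gene %r in signature %r dropped",
                        path, lineno, g, name,
                    )
                    continue
                seen.add(g)
                genes.append(g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: signature {name!r} has no genes")
            signatures.append(Signature(name=name, genes=tuple(genes),
                                        description=description))
    if not signatures:
        raise ParseError(f"{path}: no signatures found")
    return signatures


def write_gmt(signatures: list[Signature], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description or "na", *sig.genes]) + "\n")


# ------------------------------------------------------------ design manifest

def write_design_manifest(design: list[PipelineVariant], path) -> None:
    payload = {
        "variants": [
            {
                "algorithm": v.algorithm,
                "annotation": v.annotation,
                "handling": v.handling,
                "platform_tag": v.platform_tag,
            }
            for v in design
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_design_manifest(path) -> list[PipelineVariant]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "variants" not in payload:
        raise ParseError(f"{path}: manifest must contain a 'variants' list")
    out = []
    for i, entry in enumerate(payload["variants"]):
        try:
            out.append(
                PipelineVariant(
                    entry["algorithm"], entry["annotation"], entry["handling"],
                    entry.get("platform_tag", ""),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: malformed variant entry #{i}: {exc}") from exc
    if not out:
        raise ParseError(f"{path}: empty variant list")
    return out


def expression_filename(variant: PipelineVariant) -> str:
    return "expr_" + variant.key.replace("|", "_") + ".tsv"


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Configuration of a full ensemble-classification run."""

    expression_dir: Path
    design_manifest: Path
    clinical: Path
    gmt: Path
    output_dir: Path
    signatures: list[str] = field(default_factory=list)  # empty = all
    alpha: float = 0.05
    reps: int = 2000
    sweep_sizes: list[int] = field(default_factory=list)  # empty = 1..M
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("expression_dir", "design_manifest", "clinical", "gmt"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        self.output_dir = Path(self.output_dir)
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if int(self.reps) < 1:
            raise ConfigError("reps must be a positive integer")


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: run config must be a mapping")
    try:
        return RunConfig(**payload)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# ----------------------------------------------------------- classification IO

def write_classification_tsv(
    rc: RiskClassification, scores, path
) -> None:
    """Per-patient TSV: patient_id, ensemble_score (or signature score), label."""
    df = pd.DataFrame(
        {"score": pd.Series(scores).reindex(rc.labels.index), "label": rc.labels}
    )
    df.index.name = "patient_id"
    df["source"] = rc.source
    df.to_csv(path, sep="\t")


# ------------------------------------------------------------------ full run

def _evaluation_row(ev) -> dict:
    c = ev.cox
    return {
        "source": ev.source,
        "n_high": ev.n_high, "n_low": ev.n_low, "n_unclassified": ev.n_unclassified,
        "hr": c.hr, "ci_low": c.ci95[0], "ci_high": c.ci95[1],
        "wald_p": c.wald_p, "n_events": c.n_events, "estimable": c.estimable,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full ensemble workflow from files on disk.

    Per signature: classify per pipeline variant, form ensemble scores and
    the unanimity classification, evaluate everything by Cox modelling,
    compare at matched patient counts, sweep ensemble size, and (with two
    or more signatures) combine the first two by intersect and union.
    Writes TSV/JSON outputs plus a log sufficient to reproduce the run.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load-inputs"
    try:
        design = read_design_manifest(config.design_manifest)
        clinical = read_clinical_tsv(config.clinical)
        signatures = read_gmt(config.gmt)
        if config.signatures:
            wanted = set(config.signatures)
            unknown = wanted - {s.name for s in signatures}
            if unknown:
                raise ConfigError(f"unknown signatures requested: {sorted(unknown)}")
            signatures = [s for s in signatures if s.name in wanted]
        views = {}
        for variant in design:
            p = Path(config.expression_dir) / expression_filename(variant)
            if not p.exists():
                raise InputError(f"expression matrix missing for {variant.key}: {p}")
            views[variant] = read_expression_tsv(p)
        patients = next(iter(views.values())).columns
        for variant, mat in views.items():
            if list(mat.columns) != list(patients):
                raise InputError(
                    f"patient columns of {variant.key} disagree with the design's"
                )
        missing = patients.difference(clinical.index).tolist()
        if missing:
            raise InputError(
                f"patients absent from clinical table: {missing[:10]}"
            )
        clinical = clinical.loc[patients]

        results: dict = {"signatures": {}}
        evaluations = []
        hr_rows = {}
        ensembles: dict[str, RiskClassification] = {}

        for sig in signatures:
            stage = f"classify:{sig.name}"
            votes, score_vectors = classify_views(views, sig)

            stage = f"ensemble:{sig.name}"
            escore = ensemble_score(votes)
            ens = unanimous_classify(escore, source=f"{sig.name}:ensemble")
            ensembles[sig.name] = ens
            write_classification_tsv(
                ens, escore.counts, out_dir / f"ensemble_{sig.name}.tsv"
            )

            stage = f"evaluate:{sig.name}"
            ev_ens = evaluate_classification(ens, clinical)
            evaluations.append({"signature": sig.name, **_evaluation_row(ev_ens)})
            hr_by_variant = {}
            for key in votes.variants:
                rc = RiskClassification(labels=votes.votes[key], source=key)
                ev = evaluate_classification(rc, clinical)
                evaluations.append({"signature": sig.name, **_evaluation_row(ev)})
                hr_by_variant[key] = ev.cox.hr
            hr_rows[sig.name] = hr_by_variant

            stage = f"matched:{sig.name}"
            k_high, k_low = ev_ens.n_high, ev_ens.n_low
            for key in votes.variants:
                matched = matched_individual_classify(
                    score_vectors[key], k_high, k_low
                )
                ev = evaluate_classification(matched, clinical)
                evaluations.append(
                    {"signature": sig.name, **_evaluation_row(ev),
                     "source": f"{key}:matched"}
                )

            stage = f"sweep:{sig.name}"
            sizes = config.sweep_sizes or list(range(1, votes.m + 1))
            sweep = sweep_ensemble_size(
                votes, clinical, sizes, reps=config.reps, seed=config.seed
            )
            sweep.draws.to_csv(
                out_dir / f"sweep_draws_{sig.name}.tsv", sep="\t", index=False
            )
            sweep.summary.to_csv(out_dir / f"sweep_summary_{sig.name}.tsv", sep="\t")
            results["signatures"][sig.name] = {
                "n_genes_used": score_vectors[votes.variants[0]].n_genes_used,
                "ensemble": _evaluation_row(ev_ens),
            }

        stage = "compare-aspects"
        hr_table = pd.DataFrame(hr_rows)
        aspect_frames = []
        for aspect in ("algorithm", "annotation", "handling"):
            try:
                aspect_frames.append(aspect_paired_comparison(hr_table, aspect))
            except Exception as exc:  # degenerate HRs or non-factorial design
                logger.warning("aspect comparison %s skipped: %s", aspect, exc)
        if aspect_frames:
            pd.concat(aspect_frames, ignore_index=True).to_csv(
                out_dir / "aspect_comparisons.tsv", sep="\t", index=False
            )

        stage = "combine-signatures"
        if len(signatures) >= 2:
            a, b = signatures[0].name, signatures[1].name
            for mode in ("intersect", "union"):
                combined = combine_signatures(ensembles[a], ensembles[b], mode)
                ev = evaluate_classification(combined, clinical)
                evaluations.append({"signature": f"{a}+{b}", **_evaluation_row(ev)})
                write_classification_tsv(
                    combined,
                    pd.Series(np.nan, index=combined.labels.index),
                    out_dir / f"combined_{mode}_{a}_{b}.tsv",
                )

        stage = "write-outputs"
        ev_df = pd.DataFrame(evaluations)
        ev_df.to_csv(out_dir / "evaluations.tsv", sep="\t", index=False)
        results["n_patients"] = int(len(patients))
        results["n_variants"] = len(design)
        results["seed"] = config.seed
        with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(results, fh, indent=2, default=float)
        _write_run_log(config, out_dir)
        return results
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc


def _write_run_log(config: RunConfig, out_dir: Path) -> None:
    echo = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    payload = {
        "sigensemble_version": __version__,
        "config": echo,
    }
    with open(out_dir / "run_log.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ------------------------------------------------------------- simulate + dump

def simulate_to_disk(
    sim_config: SimulationConfig,
    design: list[PipelineVariant],
    out_dir,
) -> None:
    """Generate a cohort, render all views, and write the full input bundle."""
    from .datagen import render_pipeline_views, simulate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(sim_config)
    views = render_pipeline_views(cohort, design)
    for variant, matrix in views.items():
        write_expression_tsv(matrix, out_dir / expression_filename(variant))
    write_clinical_tsv(cohort.survival, out_dir / "clinical.tsv")
    write_design_manifest(design, out_dir / "design.yaml")
    write_gmt(
        [Signature("synthetic_signature", tuple(cohort.signature_genes),
                   "latent-risk-driven genes of the synthetic cohort")],
        out_dir / "signatures.gmt",
    )
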