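"""Signature scoring and risk-group assignment for one pipeline variant.

The score of a patient is a sum over the signature's genes of +1/-1
indicators: +1 when the patient's expression of the gene lies strictly
above the cohort median, -1 otherwise.  Patients are then split into high
and low risk groups at the median score.  Both steps depend only on ranks,
so any strictly increasing per-gene transform of the matrix (a log2
transform in particular) leaves the classification unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import InputError, SignatureCoverageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Signature:
    """A named list of up-regulated genes: high expression, poor survival."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise InputError(f"signature {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


class GeneDichotomy(NamedTuple):
    values: pd.Series  # +1 / -1 per patient
    constant: bool  # all inputs equal: every patient is sent low


@dataclass
class ScoreVector:
    """Per-patient integer signature scores.

    With N genes used, every score lies in {-N, -N+2, ..., N} (parity of N).
    """

    scores: pd.Series
    n_genes_used: int
    signature_name: str = ""
    genes_used: tuple[str, ...] = ()
    constant_genes: tuple[str, ...] = ()
    missing_genes: tuple[str, ...] = ()


@dataclass
class RiskClassification:
    """Per-patient labels in {high, low, unclassified} with provenance."""

    labels: pd.Series
    source: str = ""
    degenerate: bool = False  # all scores tied: everyone went low

    @property
    def classified(self) -> pd.Index:
        return self.labels.index[self.labels != "unclassified"]

    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {
            "high": int(c.get("high", 0)),
            "low": int(c.get("low", 0)),
            "unclassified": int(c.get("unclassified", 0)),
        }


def median_dichotomize_gene(values: pd.Series) -> GeneDichotomy:
    """Split one gene's expression at the cohort median.

    Strictly-greater rule: values above the median map to +1, values at or
    below it to -1.  A constant vector maps everyone to -1 and raises the
    ``constant`` diagnostic instead of erroring.
    """
    values = pd.Series(values)
    if len(values) < 2:
        raise InputError("median dichotomization needs at least 2 patients")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise InputError("non-finite expression value in gene vector")
    med = np.median(arr)
    out = pd.Series(np.where(arr > med, 1, -1), index=values.index)
    return GeneDichotomy(out, bool(np.all(arr == arr[0])))


def _dedupe_rows(matrix: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """One row per requested gene; duplicate ids keep the most variable row."""
    sub = matrix.loc[matrix.index.isin(genes)]
    if not sub.index.has_duplicates:
        return sub
    rows = []
    for gene in sub.index.unique():
        block = sub.loc[[gene]]
        rows.append(block.iloc[[int(np.argmax(block.var(axis=1).to_numpy()))]])
    return pd.concat(rows)


def signature_score(matrix: pd.DataFrame, signature: Signature) -> ScoreVector:
    """Sum of per-gene +1/-1 median dichotomizations over the signature.

    Genes absent from the matrix are dropped (logged; N reported reflects
    the drop).  An empty intersection is an error naming the signature.
    """
    present = [g for g in signature.genes if g in matrix.index]
    missing = tuple(g for g in signature.genes if g not in matrix.index)
    if not present:
        raise SignatureCoverageError(
            f"no gene of signature {signature.name!r} is present in the matrix"
        )
    if missing:
        logger.warning(
            "signature %s: %d/%d genes absent from matrix, using N=%d",
            signature.name, len(missing), len(signature), len(present),
        )
    sub = _dedupe_rows(matrix, present)
    sub = sub.loc[present]  # signature order
    arr = sub.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise InputError("signature scoring needs at least 2 patients")
    if not np.isfinite(arr).all():
        raise InputError("non-finite expression value in matrix")
    med = np.median(arr, axis=1, keepdims=True)
    dich = np.where(arr > med, 1, -1)
    constant = tuple(np.asarray(present)[(arr == arr[:, :1]).all(axis=1)])
    scores = pd.Series(dich.sum(axis=0), index=matrix.columns, name="score")
    return ScoreVector(
        scores=scores,
        n_genes_used=len(present),
        signature_name=signature.name,
        genes_used=tuple(present),
        constant_genes=constant,
        missing_genes=missing,
    )


def classify_by_median_score(
    scores: ScoreVector | pd.Series, source: str = ""
) -> RiskClassification:
    """Median-dichotomize signature scores into high and low risk groups.

    Same strict rule as the gene level: score strictly above the median
    score is high risk, otherwise low.  No patient is unclassified here;
    an all-equal score vector sends everyone low and sets ``degenerate``.
    """
    if isinstance(scores, ScoreVector):
        if not source:
            source = scores.signature_name
        scores = scores.scores
    if len(scores) < 2:
        raise InputError("classification needs at least 2 patients")
    arr = scores.to_numpy(dtype=float)
    med = np.median(arr)
    labels = pd.Series(np.where(arr > med, "high", "low"), index=scores.index)
    return RiskClassification(
        labels=labels, source=source, degenerate=bool(np.all(arr == arr[0]))
    )
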