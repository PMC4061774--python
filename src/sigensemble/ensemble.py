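"""Unanimity-vote ensemble classification across pipeline variants.

Each pipeline variant's high/low classification is one vote.  The ensemble
score of a patient is the number of variants voting high (0..M for M
variants); only unanimous patients (score 0 or M) are assigned a risk
group, everyone else is deemed unreliable and left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import PipelineVariant
from .exceptions import InputError
from .scoring import (
    RiskClassification,
    ScoreVector,
    Signature,
    classify_by_median_score,
    signature_score,
)

_LABELS = ("high", "low")


@dataclass
class VoteMatrix:
    """Patients x pipeline-variants grid of high/low votes."""

    votes: pd.DataFrame  # rows patients, columns variant keys

    def __post_init__(self) -> None:
        df = self.votes
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise InputError(f"duplicate variant labels in vote matrix: {dupes}")
        bad = df.isna()
        if bad.to_numpy().any():
            pat = df.index[bad.any(axis=1)][0]
            var = df.columns[bad.loc[pat]][0]
            raise InputError(f"missing vote for patient {pat!r}, variant {var!r}")
        values = set(np.unique(df.to_numpy()))
        if not values <= set(_LABELS):
            raise InputError(f"votes must be 'high'/'low', got {sorted(values - set(_LABELS))}")

    @property
    def patients(self) -> pd.Index:
        return self.votes.index

    @property
    def variants(self) -> list[str]:
        return list(self.votes.columns)

    @property
    def m(self) -> int:
        return self.votes.shape[1]

    def high_indicator(self) -> np.ndarray:
        """Boolean patients x variants array, True where the vote is high."""
        return (self.votes == "high").to_numpy()

    @classmethod
    def from_classifications(
        cls, classifications: dict[str, RiskClassification]
    ) -> "VoteMatrix":
        if not classifications:
            raise InputError("no classifications supplied")
        cols = {}
        for key, rc in classifications.items():
            if (rc.labels == "unclassified").any():
                raise InputError(
                    f"classification {key!r} contains unclassified patients; "
                    "votes must be high/low"
                )
            cols[key] = rc.labels
        return cls(pd.DataFrame(cols))


@dataclass
class EnsembleScore:
    """Per-patient count of high votes out of M variants."""

    counts: pd.Series
    m: int

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if ((arr < 0) | (arr > self.m)).any():
            raise InputError(f"ensemble scores must lie in [0, {self.m}]")


def ensemble_score(votes: VoteMatrix) -> EnsembleScore:
    """Count high votes per patient (the 0..M ensemble score)."""
    if votes.m < 1:
        raise InputError("vote matrix has no variants")
    counts = pd.Series(
        votes.high_indicator().sum(axis=1), index=votes.patients, name="ensemble_score"
    )
    return EnsembleScore(counts=counts, m=votes.m)


def unanimous_classify(
    scores: EnsembleScore, source: str = "ensemble"
) -> RiskClassification:
    """Assign risk groups only on unanimous votes (score 0 or M)."""
    arr = scores.counts.to_numpy()
    labels = np.full(len(arr), "unclassified", dtype=object)
    labels[arr == scores.m] = "high"
    labels[arr == 0] = "low"
    return RiskClassification(
        labels=pd.Series(labels, index=scores.counts.index), source=source
    )


def matched_individual_classify(
    scores: ScoreVector, k_high: int, k_low: int
) -> RiskClassification:
    """Label exactly k_high top-scoring and k_low bottom-scoring patients.

    Used to compare a single pipeline against an ensemble at equal group
    sizes: patients are ordered by signature score (descending; ties broken
    by patient id for determinism), the top k_high become high risk and the
    bottom k_low become low risk, everyone else is unclassified.
    """
    if k_high < 0 or k_low < 0:
        raise InputError("k_high and k_low must be non-negative")
    s = scores.scores
    n = len(s)
    if k_high + k_low > n:
        raise InputError(f"k_high + k_low = {k_high + k_low} exceeds {n} patients")
    order = (
        pd.DataFrame({"score": s, "pid": s.index.astype(str)})
        .sort_values(["score", "pid"], ascending=[False, True], kind="stable")
        .index
    )
    labels = pd.Series("unclassified", index=s.index, dtype=object)
    if k_high:
        labels.loc[order[:k_high]] = "high"
    if k_low:
        labels.loc[order[n - k_low:]] = "low"
    return RiskClassification(labels=labels, source=f"{scores.signature_name}:matched")


def combine_signatures(
    a: RiskClassification, b: RiskClassification, mode: str
) -> RiskClassification:
    """Combine two signatures' (ensemble) classifications.

    intersect: a patient keeps a label only when both classifications agree
    on it.  union: a label from either classification is kept when the
    other agrees or abstains (unclassified).  Conflicting high/low labels
    are excluded (unclassified) in both modes.
    """
    if mode not in ("intersect", "union"):
        raise InputError(f"mode must be 'intersect' or 'union', got {mode!r}")
    if set(a.labels.index) != set(b.labels.index):
        raise InputError("classifications cover different patient sets")
    bl = b.labels.reindex(a.labels.index)
    out = pd.Series("unclassified", index=a.labels.index, dtype=object)
    agree = (a.labels == bl) & (a.labels != "unclassified")
    out[agree] = a.labels[agree]
    if mode == "union":
        only_a = (bl == "unclassified") & (a.labels != "unclassified")
        only_b = (a.labels == "unclassified") & (bl != "unclassified")
        out[only_a] = a.labels[only_a]
        out[only_b] = bl[only_b]
    return RiskClassification(
        labels=out, source=f"{mode}({a.source},{b.source})"
    )


def classify_views(
    views: dict[PipelineVariant, pd.DataFrame], signature: Signature
) -> tuple[VoteMatrix, dict[str, ScoreVector]]:
    """Score and classify a signature on every pipeline view.

    Convenience wrapper over the scoring module producing the vote matrix
    the ensemble consumes, plus the per-variant score vectors.
    """
    classifications: dict[str, RiskClassification] = {}
    score_vectors: dict[str, ScoreVector] = {}
    for variant, matrix in views.items():
        sv = signature_score(matrix, signature)
        score_vectors[variant.key] = sv
        classifications[variant.key] = classify_by_median_score(sv, source=variant.key)
    return VoteMatrix.from_classifications(classifications), score_vectors
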