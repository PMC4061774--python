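"""Synthetic cohort generation and pipeline-variant views.

Real inputs to the ensemble-classification workflow are expression matrices
produced by running one microarray normalization pipeline per variant of a
three-factor design (algorithm x probe annotation x dataset handling).  This
module emulates that situation without raw array data: a latent per-patient
risk variable drives both the expression of a block of "signature" genes and
the hazard of an event, each pipeline variant observes the same underlying
matrix through independent noise, and the log2 algorithm variants are exact
elementwise log2 transforms of their normal-space partners — the property
that makes them produce identical rank-based classifications.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DesignError

ALGORITHMS = ("RMA", "GCRMA", "MAS5", "log2MAS5", "MBEI", "log2MBEI")
ANNOTATIONS = ("default", "alternative")
HANDLINGS = ("separate", "merged")

#: log2 algorithm variants and the normal-space algorithm each one transforms.
LOG_PAIRS = {"log2MAS5": "MAS5", "log2MBEI": "MBEI"}


@dataclass(frozen=True)
class PipelineVariant:
    """One labelled point of the factorial pre-processing design.

    The full design crosses 6 normalization algorithms with 2 probe
    annotations and 2 dataset-handling modes, giving 24 variants.  Two of
    the six algorithms (log2MAS5, log2MBEI) are declared monotone log2
    transforms of MAS5 and MBEI respectively.
    """

    algorithm: str
    annotation: str
    handling: str
    platform_tag: str = ""

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise DesignError(f"unknown algorithm {self.algorithm!r}")
        if self.annotation not in ANNOTATIONS:
            raise DesignError(f"unknown annotation {self.annotation!r}")
        if self.handling not in HANDLINGS:
            raise DesignError(f"unknown handling {self.handling!r}")

    @property
    def is_log_variant(self) -> bool:
        return self.algorithm in LOG_PAIRS

    @property
    def key(self) -> str:
        """Stable text label, e.g. ``"RMA|default|separate"``."""
        parts = [self.algorithm, self.annotation, self.handling]
        if self.platform_tag:
            parts.append(self.platform_tag)
        return "|".join(parts)

    @classmethod
    def from_key(cls, key: str) -> "PipelineVariant":
        parts = key.split("|")
        if len(parts) not in (3, 4):
            raise DesignError(f"malformed variant key {key!r}")
        tag = parts[3] if len(parts) == 4 else ""
        return cls(parts[0], parts[1], parts[2], tag)

    def monotone_pair(self) -> "PipelineVariant":
        """The normal-space variant this log2 variant transforms."""
        if not self.is_log_variant:
            raise DesignError(f"{self.key} is not a log2 variant")
        return replace(self, algorithm=LOG_PAIRS[self.algorithm])


def full_factorial_design(platform_tag: str = "") -> list[PipelineVariant]:
    """Enumerate the complete 6 x 2 x 2 = 24 variant design."""
    return [
        PipelineVariant(alg, ann, hand, platform_tag)
        for alg, ann, hand in itertools.product(ALGORITHMS, ANNOTATIONS, HANDLINGS)
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a single moderately sized breast-cancer-like cohort:
    200 patients, 500 genes of which 20 form the prognostic signature, unit
    latent-risk loading and unit gene noise, pipeline noise equal to gene
    noise, a log hazard ratio of 1 per unit latent risk, baseline hazard
    0.05 per time unit and administrative censoring uniform on (0, 30].
    """

    n_patients: int = 200
    n_genes: int = 500
    signature_size: int = 20
    effect_size: float = 1.0
    noise_sd_gene: float = 1.0
    noise_sd_pipeline: float = 1.0
    log_hazard_beta: float = 1.0
    baseline_hazard: float = 0.05
    censor_horizon: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_patients) < 2:
            raise ConfigError("n_patients must be >= 2")
        if int(self.n_genes) < 1:
            raise ConfigError("n_genes must be a positive integer")
        if not 1 <= int(self.signature_size) <= int(self.n_genes):
            raise ConfigError("signature_size must be in [1, n_genes]")
        if self.noise_sd_gene < 0:
            raise ConfigError("noise_sd_gene must be non-negative")
        if self.noise_sd_pipeline < 0:
            raise ConfigError("noise_sd_pipeline must be non-negative")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.censor_horizon <= 0:
            raise ConfigError("censor_horizon must be positive")
        for name in ("effect_size", "log_hazard_beta"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")


@dataclass
class SyntheticCohort:
    """A simulated cohort: expression, survival, and the generating truth."""

    latent_risk: pd.Series
    base_expression: pd.DataFrame  # genes x patients
    survival: pd.DataFrame  # index patient_id; columns time, event
    truth_labels: pd.Series  # {high, low} from median split of latent risk
    signature_genes: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    @property
    def patients(self) -> pd.Index:
        return self.base_expression.columns


def _substream(seed: int, *labels: str) -> np.random.Generator:
    """Derive an independent generator keyed by (seed, labels).

    Labels are hashed with CRC-32 so that adding a variant to a design
    never perturbs the noise drawn for any other variant.
    """
    words = [int(seed) & 0x7FFFFFFF]
    words += [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(words))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort under the latent-risk model.

    Latent risk z is standard normal per patient.  Each signature gene is
    ``effect_size * z`` plus independent Gaussian noise; other genes are
    pure noise.  Event times are exponential with rate
    ``baseline_hazard * exp(log_hazard_beta * z)``; censoring times are
    uniform on (0, censor_horizon]; observed time is the minimum and the
    event indicator marks whether the event preceded censoring.
    """
    n, g = int(config.n_patients), int(config.n_genes)
    k = int(config.signature_size)
    rng = _substream(config.seed, "cohort")

    patients = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    genes = pd.Index([f"G{i:04d}" for i in range(g)], name="gene_id")

    z = rng.standard_normal(n)
    expr = rng.standard_normal((g, n)) * config.noise_sd_gene
    expr[:k] += config.effect_size * z  # signature block rides the risk

    rate = config.baseline_hazard * np.exp(config.log_hazard_beta * z)
    event_time = rng.exponential(1.0 / rate)
    # 1 - U in (0, 1] keeps censoring (and hence observed) times positive.
    censor_time = config.censor_horizon * (1.0 - rng.random(n))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    latent = pd.Series(z, index=patients, name="latent_risk")
    labels = pd.Series(
        np.where(z > np.median(z), "high", "low"), index=patients, name="truth"
    )
    survival = pd.DataFrame({"time": time, "event": event}, index=patients)

    return SyntheticCohort(
        latent_risk=latent,
        base_expression=pd.DataFrame(expr, index=genes, columns=patients),
        survival=survival,
        truth_labels=labels,
        signature_genes=list(genes[:k]),
        config=config,
    )


def _shift_positive(values: np.ndarray) -> np.ndarray:
    """Shift a matrix so every entry is strictly positive (rank-preserving)."""
    lo = values.min()
    if lo <= 0:
        values = values + (1.0 - lo)
    return values


def render_pipeline_views(
    cohort: SyntheticCohort,
    design: list[PipelineVariant],
    noise_sd_pipeline: float | None = None,
    seed: int | None = None,
) -> dict[PipelineVariant, pd.DataFrame]:
    """Produce one expression matrix per pipeline variant.

    Every normal-space variant sees the base matrix through independent
    Gaussian noise (its own substream) and is shifted to strict positivity
    so that the log2 view is defined.  Every log2 variant is the exact
    elementwise log2 of its normal-space partner's matrix — no extra noise,
    so the pair can never disagree on any rank-based classification.
    """
    if not design:
        raise DesignError("design must contain at least one variant")
    keys = [v.key for v in design]
    if len(set(keys)) != len(keys):
        raise DesignError("design contains duplicate variants")
    if noise_sd_pipeline is None:
        noise_sd_pipeline = cohort.config.noise_sd_pipeline if cohort.config else 0.0
    if noise_sd_pipeline < 0:
        raise ConfigError("noise_sd_pipeline must be non-negative")
    if seed is None:
        seed = cohort.config.seed if cohort.config else 0

    base = cohort.base_expression
    views: dict[PipelineVariant, pd.DataFrame] = {}
    for variant in design:
        if variant.is_log_variant:
            continue
        rng = _substream(seed, "view", variant.key)
        noisy = base.to_numpy() + rng.standard_normal(base.shape) * noise_sd_pipeline
        views[variant] = pd.DataFrame(
            _shift_positive(noisy), index=base.index, columns=base.columns
        )
    for variant in design:
        if not variant.is_log_variant:
            continue
        pair = variant.monotone_pair()
        if pair not in views:
            raise DesignError(
                f"log2 variant {variant.key} requires its pair {pair.key} in the design"
            )
        views[variant] = np.log2(views[pair])
    # preserve the caller's ordering
    return {v: views[v] for v in design}
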