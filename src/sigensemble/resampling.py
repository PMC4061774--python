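"""Ensemble-size resampling and pipeline-aspect comparisons.

How many pipeline variants does an ensemble need?  For each ensemble size
n, random n-subsets of the variants are drawn repeatedly (each subset drawn
without internal replacement; subsets may repeat across the 2000 default
replicates), the unanimity ensemble is evaluated by Cox modelling, and the
mean hazard ratio (summarized on the log2 scale) and mean percentage of
patients classified are reported per n.  Subgrouping by a single design
aspect supports exhaustive enumeration instead of sampling, and variants
differing in exactly one aspect are compared with paired t-tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import PipelineVariant
from .exceptions import InputError, PairingError
from .ensemble import VoteMatrix
from .survival import fit_cox_binary, paired_t_test, survival_frame

_ASPECTS = ("algorithm", "annotation", "handling")


def _evaluate_subset(
    high: np.ndarray,
    patients: pd.Index,
    subset: np.ndarray,
    surv: pd.DataFrame,
) -> tuple[float, float, float]:
    """Unanimity-classify a variant subset and Cox-evaluate it.

    Returns (hr, wald_p, pct_classified); hr and p are NaN when the fit is
    non-estimable.
    """
    s = high[:, subset].sum(axis=1)
    n_sub = len(subset)
    is_high = s == n_sub
    is_low = s == 0
    classified = is_high | is_low
    pct = 100.0 * classified.mean()
    if not is_high.any() or not is_low.any():
        return float("nan"), float("nan"), pct
    idx = patients[classified]
    labels = pd.Series(
        np.where(is_high[classified], "high", "low"), index=idx
    )
    res = fit_cox_binary(surv.loc[idx], labels)
    if not res.estimable:
        return float("nan"), float("nan"), pct
    return res.hr, res.wald_p, pct


@dataclass
class EnsembleSweepResult:
    """Replicate-level and per-n summary outputs of an ensemble-size sweep."""

    draws: pd.DataFrame  # n, replicate, hr, wald_p, pct_classified
    summary: pd.DataFrame  # per n: mean_hr, mean_log2_hr, mean_pct_classified...
    reps: int
    seed: int


def _summarize(draws: pd.DataFrame) -> pd.DataFrame:
    def agg(group: pd.DataFrame) -> pd.Series:
        hr = group["hr"].to_numpy()
        ok = np.isfinite(hr)
        return pd.Series(
            {
                "mean_hr": hr[ok].mean() if ok.any() else np.nan,
                "mean_log2_hr": np.log2(hr[ok]).mean() if ok.any() else np.nan,
                "mean_pct_classified": group["pct_classified"].mean(),
                "hr_range": hr[ok].max() - hr[ok].min() if ok.any() else np.nan,
                "n_excluded": int((~ok).sum()),
            }
        )

    out = draws.groupby("n", sort=True).apply(agg, include_groups=False)
    out.index.name = "n"
    return out


def sweep_ensemble_size(
    votes: VoteMatrix,
    survival,
    n_values,
    reps: int = 2000,
    seed: int = 0,
) -> EnsembleSweepResult:
    """Randomly sample n-variant ensembles for each requested size n.

    Each replicate draws n variants uniformly without replacement, builds
    the unanimity ensemble and evaluates it.  Replicates with a
    non-estimable Cox fit are kept as NaN rows and excluded from the per-n
    means (the exclusion count is reported).  Fixed seed => identical sweep.
    """
    n_values = [int(n) for n in n_values]
    m = votes.m
    if reps < 1:
        raise InputError("reps must be >= 1")
    for n in n_values:
        if not 1 <= n <= m:
            raise InputError(f"ensemble size {n} outside [1, {m}]")
    surv = survival_frame(survival).loc[votes.patients]
    high = votes.high_indicator()
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    rows = []
    for n in n_values:
        for rep in range(reps):
            subset = rng.choice(m, size=n, replace=False)
            hr, p, pct = _evaluate_subset(high, votes.patients, subset, surv)
            rows.append((n, rep, hr, p, pct))
    draws = pd.DataFrame(
        rows, columns=["n", "replicate", "hr", "wald_p", "pct_classified"]
    )
    return EnsembleSweepResult(
        draws=draws, summary=_summarize(draws), reps=reps, seed=int(seed)
    )


def subgroup_variants(
    variants: list[str], aspect: str, level: str
) -> list[str]:
    """Variant keys whose design factor ``aspect`` equals ``level``."""
    if aspect not in _ASPECTS:
        raise InputError(f"aspect must be one of {_ASPECTS}, got {aspect!r}")
    chosen = [
        key
        for key in variants
        if getattr(PipelineVariant.from_key(key), aspect) == level
    ]
    if not chosen:
        raise InputError(f"no variant has {aspect} == {level!r}")
    return chosen


def exhaustive_subgroup_sweep(
    votes: VoteMatrix,
    survival,
    aspect: str,
    level: str,
    n_values=None,
) -> pd.DataFrame:
    """Enumerate every n-subset of the variants sharing one aspect level.

    With the full factorial design a subgroup has 4 variants when fixing
    the algorithm and 12 when fixing annotation or handling, so n runs
    1..4 or 1..12.  Returns the complete enumeration, one row per
    combination, supporting averages per n.
    """
    keys = subgroup_variants(votes.variants, aspect, level)
    positions = [votes.variants.index(k) for k in keys]
    if n_values is None:
        n_values = range(1, len(keys) + 1)
    surv = survival_frame(survival).loc[votes.patients]
    high = votes.high_indicator()
    rows = []
    for n in n_values:
        n = int(n)
        if not 1 <= n <= len(keys):
            raise InputError(f"subset size {n} outside [1, {len(keys)}]")
        for combo in itertools.combinations(positions, n):
            hr, p, pct = _evaluate_subset(high, votes.patients, np.array(combo), surv)
            combo_keys = ",".join(votes.variants[i] for i in combo)
            rows.append((n, combo_keys, hr, p, pct))
    return pd.DataFrame(
        rows, columns=["n", "combination", "hr", "wald_p", "pct_classified"]
    )


def aspect_paired_comparison(hr_table: pd.DataFrame, aspect: str) -> pd.DataFrame:
    """Paired t-tests of hazard ratios between levels of one design aspect.

    ``hr_table`` holds one row per pipeline variant (index = variant keys)
    and one column per signature, each cell the variant's hazard ratio for
    that signature.  For every unordered pair of aspect levels, variants
    are paired off by their remaining design factors; the HR differences
    (pooled across signatures) feed a paired t-test.
    """
    if aspect not in _ASPECTS:
        raise InputError(f"aspect must be one of {_ASPECTS}, got {aspect!r}")
    variants = [PipelineVariant.from_key(k) for k in hr_table.index]
    others = [f for f in _ASPECTS if f != aspect] + ["platform_tag"]

    def rest(v: PipelineVariant) -> tuple:
        return tuple(getattr(v, f) for f in others)

    by_level: dict[str, dict[tuple, str]] = {}
    for v in variants:
        by_level.setdefault(getattr(v, aspect), {})[rest(v)] = v.key
    levels = sorted(by_level)
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        ka, kb = by_level[la], by_level[lb]
        shared = sorted(set(ka) & set(kb))
        unpaired = sorted(set(ka) ^ set(kb))
        if unpaired or not shared:
            offenders = [ka.get(u, kb.get(u)) for u in unpaired]
            raise PairingError(
                f"levels {la!r}/{lb!r} of {aspect} do not pair off; "
                f"unpaired variants: {offenders}"
            )
        a_vals, b_vals = [], []
        for sig in hr_table.columns:
            for combo in shared:
                a_vals.append(hr_table.loc[ka[combo], sig])
                b_vals.append(hr_table.loc[kb[combo], sig])
        res = paired_t_test(a_vals, b_vals)
        diff = float(np.mean(np.asarray(a_vals) - np.asarray(b_vals)))
        rows.append(
            {
                "aspect": aspect, "level_a": la, "level_b": lb,
                "n_pairs": len(a_vals), "t": res.t, "p": res.p, "df": res.df,
                "mean_hr_diff": diff,
                "higher": la if diff > 0 else (lb if diff < 0 else "tie"),
            }
        )
    return pd.DataFrame(rows)
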