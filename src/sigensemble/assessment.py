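"""Per-gene prognostic screening and the factorial count model.

Single-gene screening mirrors the signature machinery at the gene level:
patients are median-dichotomized on each gene's abundance, a univariate Cox
model is fitted per gene, and Wald p-values are FDR-adjusted (within each
pipeline variant separately).  The number of significant genes per variant
is then modelled as a linear function of the design factors — annotation,
platform, dataset handling and algorithm — first with main effects only,
then with all pairwise interactions refined by backward stepwise AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .exceptions import InputError, ModelError
from .survival import bh_fdr, fit_cox_binary, spearman, survival_frame

#: factor -> baseline level of the count model's treatment coding
FACTOR_BASELINES = {
    "annotation": "alternative",
    "platform": "HG-U133A",
    "handling": "merged",
    "algorithm": "GCRMA",
}


def per_gene_prognosis(matrix: pd.DataFrame, survival) -> pd.DataFrame:
    """Univariate Cox screen of every gene in one pipeline variant's matrix.

    Returns a DataFrame indexed by gene with columns hr, p, q, estimable.
    Genes whose Cox fit is non-estimable (constant expression, monotone
    likelihood, ...) carry NaN and are excluded from the FDR input; the
    BH adjustment runs over estimable genes only.
    """
    df = survival_frame(survival)
    if not matrix.columns.isin(df.index).all():
        missing = matrix.columns.difference(df.index).tolist()
        raise InputError(f"patients missing from survival table: {missing[:5]}")
    if matrix.shape[1] < 2:
        raise InputError("per-gene screening needs at least 2 patients")
    surv = df.loc[matrix.columns]
    if surv["event"].sum() < 1:
        raise InputError("per-gene screening needs at least 1 event")

    arr = matrix.to_numpy(dtype=float)
    med = np.median(arr, axis=1, keepdims=True)
    high = arr > med  # strict rule, as for signature genes

    hrs = np.full(len(matrix), np.nan)
    ps = np.full(len(matrix), np.nan)
    ok = np.zeros(len(matrix), dtype=bool)
    labels = np.empty(matrix.shape[1], dtype=object)
    for i in range(len(matrix)):
        labels[:] = "low"
        labels[high[i]] = "high"
        res = fit_cox_binary(surv, pd.Series(labels, index=matrix.columns))
        if res.estimable:
            hrs[i], ps[i], ok[i] = res.hr, res.wald_p, True
    qs = np.full(len(matrix), np.nan)
    if ok.any():
        qs[ok] = bh_fdr(ps[ok])
    out = pd.DataFrame(
        {"hr": hrs, "p": ps, "q": qs, "estimable": ok}, index=matrix.index
    )
    out.index.name = "gene"
    return out


def build_prognosis_table(
    per_variant: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Stack per-variant screens into one long table (gene, variant, ...)."""
    frames = []
    for key, tab in per_variant.items():
        t = tab.reset_index()
        t.insert(1, "variant", key)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def significance_summary(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Both marginals of the q <= alpha indicator matrix.

    ``table`` is the long-format prognosis table (columns gene, variant, q).
    Returns per-variant significant-gene counts and per-gene counts of
    variants in which the gene reaches significance.
    """
    if not {"gene", "variant", "q"} <= set(table.columns):
        raise InputError("prognosis table needs columns gene, variant, q")
    sig = table.assign(sig=(table["q"] <= alpha).fillna(False).astype(int))
    per_variant = sig.groupby("variant", sort=False)["sig"].sum()
    per_gene = sig.groupby("gene", sort=False)["sig"].sum()
    return {
        "per_variant": per_variant.rename("n_significant"),
        "per_gene": per_gene.rename("n_variants_significant"),
    }


def pipeline_concordance(table: pd.DataFrame) -> pd.DataFrame:
    """Variant x variant Spearman correlation of per-gene q-values.

    Each cell correlates the q-values of the genes estimable in both
    variants; cells with fewer than 3 shared genes are NaN.  The matrix is
    symmetric with a unit diagonal.
    """
    wide = table.pivot(index="gene", columns="variant", values="q")
    variants = list(wide.columns)
    out = pd.DataFrame(np.eye(len(variants)), index=variants, columns=variants)
    for i, a in enumerate(variants):
        for b in variants[i + 1:]:
            pair = wide[[a, b]].dropna()
            rho = spearman(pair[a], pair[b]) if len(pair) >= 3 else float("nan")
            out.loc[a, b] = out.loc[b, a] = rho
    return out


@dataclass(frozen=True)
class CountModelSpec:
    """A factorial linear model for significant-gene counts.

    Treatment coding with fixed baselines (alternative annotation,
    HG-U133A platform, merged handling, GCRMA algorithm); the 6-level
    algorithm factor contributes 5 dummy codes.
    """

    response: str = "n_significant"
    main_effects: tuple[str, ...] = ("annotation", "platform", "handling", "algorithm")
    interactions: tuple[tuple[str, str], ...] = ()
    baselines: dict = dc_field(default_factory=lambda: dict(FACTOR_BASELINES))

    @classmethod
    def full_pairwise(cls, response: str = "n_significant") -> "CountModelSpec":
        mains = ("annotation", "platform", "handling", "algorithm")
        inter = tuple(
            (a, b) for i, a in enumerate(mains) for b in mains[i + 1:]
        )
        return cls(response=response, main_effects=mains, interactions=inter)

    def drop_term(self, term) -> "CountModelSpec":
        if isinstance(term, tuple):
            return CountModelSpec(
                self.response, self.main_effects,
                tuple(t for t in self.interactions if t != term), self.baselines,
            )
        if any(term in pair for pair in self.interactions):
            raise ModelError(
                f"cannot drop main effect {term!r} while an interaction retains it"
            )
        return CountModelSpec(
            self.response, tuple(t for t in self.main_effects if t != term),
            self.interactions, self.baselines,
        )


def _factor_dummies(data: pd.DataFrame, factor: str, baseline: str) -> pd.DataFrame:
    levels = sorted(set(data[factor].astype(str)))
    if baseline not in levels:
        raise ModelError(f"baseline {baseline!r} absent from factor {factor!r}")
    cols = {}
    for lev in levels:
        if lev == baseline:
            continue
        cols[f"{factor}[{lev}]"] = (data[factor].astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=data.index)


def design_matrix(data: pd.DataFrame, spec: CountModelSpec) -> pd.DataFrame:
    """Build the treatment-coded design matrix (with intercept)."""
    for f in spec.main_effects:
        if f not in data.columns:
            raise InputError(f"factor column {f!r} missing from data")
    X = pd.DataFrame({"(Intercept)": np.ones(len(data))}, index=data.index)
    blocks = {
        f: _factor_dummies(data, f, spec.baselines[f]) for f in spec.main_effects
    }
    for f in spec.main_effects:
        X = pd.concat([X, blocks[f]], axis=1)
    for fa, fb in spec.interactions:
        for ca in blocks[fa].columns:
            for cb in blocks[fb].columns:
                X[f"{ca}:{cb}"] = blocks[fa][ca] * blocks[fb][cb]
    return X


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC of a Gaussian linear model, n ln(RSS/n) + 2(k+1), constant dropped.

    k counts the mean parameters (design-matrix columns); +1 for the error
    variance.  Only AIC differences are ever compared.
    """
    if rss <= 0:
        rss = np.finfo(float).tiny
    return float(n * np.log(rss / n) + 2 * (k + 1))


@dataclass
class CountModelFit:
    spec: CountModelSpec
    coefficients: pd.DataFrame  # estimate, se, t, p per design column
    r_squared_adjusted: float
    aic: float
    rss: float
    n_obs: int
    df_resid: int


def fit_count_model(data: pd.DataFrame, spec: CountModelSpec) -> CountModelFit:
    """OLS fit of significant-gene counts on the coded factorial design.

    The coefficient table follows the usual linear-model layout (estimate,
    standard error, t value, two-sided p).  Adjusted R-squared is reported:
    with as many parameters as informative contrasts it can be negative.
    """
    import statsmodels.api as sm

    if spec.response not in data.columns:
        raise InputError(f"response column {spec.response!r} missing from data")
    y = data[spec.response].to_numpy(dtype=float)
    X = design_matrix(data, spec)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X)
        raise ModelError(f"rank-deficient design; aliased terms: {aliased}")
    res = sm.OLS(y, X).fit()
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    rss = float(res.ssr)
    n, k = len(y), X.shape[1]
    r2adj = float(res.rsquared_adj) if n > k else float("nan")
    return CountModelFit(
        spec=spec, coefficients=coef, r_squared_adjusted=r2adj,
        aic=gaussian_aic(rss, n, k), rss=rss, n_obs=n, df_resid=n - k,
    )


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    kept: list[int] = []
    aliased: list[str] = []
    arr = X.to_numpy()
    for j in range(arr.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(arr[:, cand]) == len(cand):
            kept.append(j)
        else:
            aliased.append(X.columns[j])
    return aliased


def stepwise_aic_backward(
    data: pd.DataFrame, spec: CountModelSpec
) -> tuple[CountModelSpec, CountModelFit]:
    """Backward stepwise refinement by AIC, respecting marginality.

    At each step the single removable term (any interaction; a main effect
    only once no retained interaction contains it) whose removal lowers
    AIC the most is dropped; the procedure stops when no removal lowers
    AIC.  The result's AIC is never above the initial model's.
    """
    current = fit_count_model(data, spec)
    while True:
        candidates: list = list(current.spec.interactions)
        in_inter = {f for pair in current.spec.interactions for f in pair}
        candidates += [f for f in current.spec.main_effects if f not in in_inter]
        best = None
        for term in candidates:
            trial_spec = current.spec.drop_term(term)
            trial = fit_count_model(data, trial_spec)
            if trial.aic < current.aic - 1e-9 and (
                best is None or trial.aic < best.aic
            ):
                best = trial
        if best is None:
            return current.spec, current
        current = best
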