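"""Association metrics, confounder screening and grouped attributions.

Out-of-fold model predictions are compared with their clinical targets by
Pearson's r and Spearman's ρ (two-sided p-values), the coefficient of
determination R² of the simple regression of the target on the prediction
(whose p equals Pearson's in the simple case), and the mean squared error.
Significance stars follow the conventional scheme: p < 0.001 (***),
p < 0.01 (**), p < 0.05 (*), otherwise n.s.

Confounder screening uses the change-in-estimate statistic: a0 is the
ordinary-least-squares slope of the target on the model score, a_adj the
slope of the score after adding the covariate (age, or sex coded 0/1), and

    change = |a0 − a_adj| / |a_adj| ,

flagged when the change exceeds the 10% cut-off (strictly).

Feature attributions use the additive Shapley decomposition built into the
boosted-tree models, computed on the test-fold subjects of each
cross-validation iteration, absolute values averaged and summed within each
feature family × task group, normalized to fractions per target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .clinical import ScaleItemValue, SubdomainMappingSpec, normalize_item
from .features import parse_feature_name
from .modeling import CVResult, FoldAssignment, ModelSpec, cross_validate


class InsufficientDataError(ValueError):
    pass


class AttributionUnsupportedError(TypeError):
    """The model variant exposes no additive attribution."""


@dataclass(frozen=True)
class AssociationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    r_squared: float
    r_squared_p: float
    mse: float
    n: int
    undefined: bool = False  # zero variance on either side


def associate(predictions, truth) -> AssociationResult:
    """Association between per-subject predictions and target values.

    Pairwise-complete: pairs with a missing value on either side are
    dropped; fewer than three remaining pairs is an error.  Zero variance
    on either side yields an explicitly flagged undefined result (NaN
    correlations, mse still reported).
    """
    x = np.asarray(predictions, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predictions and truth must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need ≥ 3 paired values, got {n}")
    mse = float(np.mean((x - y) ** 2))
    if np.std(x) == 0 or np.std(y) == 0:
        return AssociationResult(
            math.nan, math.nan, math.nan, math.nan, math.nan, math.nan,
            mse, n, undefined=True,
        )
    pr = st.pearsonr(x, y)
    sr = st.spearmanr(x, y)
    reg = st.linregress(x, y)  # truth on prediction
    return AssociationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        r_squared=float(reg.rvalue**2),
        r_squared_p=float(reg.pvalue),
        mse=mse,
        n=n,
    )


def significance_label(p: float) -> str:
    """Star label for a p-value; the 0.05 boundary is strictly n.s."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def association_table(
    aggregated: pd.DataFrame, targets: pd.DataFrame
) -> pd.DataFrame:
    """Associate every aggregated prediction column with its target column;
    tidy rows with stars for r, ρ and R²."""
    rows = []
    for t in aggregated.columns:
        if t not in targets.columns:
            continue
        common = aggregated.index.intersection(targets.index)
        a = associate(aggregated.loc[common, t], targets.loc[common, t])
        rows.append(
            {
                "target": t,
                "pearson_r": a.pearson_r,
                "pearson_sig": "n/a" if a.undefined else significance_label(a.pearson_p),
                "spearman_rho": a.spearman_rho,
                "spearman_sig": "n/a" if a.undefined else significance_label(a.spearman_p),
                "r_squared": a.r_squared,
                "r_squared_sig": "n/a" if a.undefined else significance_label(a.r_squared_p),
                "mse": a.mse,
                "n": a.n,
                "undefined": a.undefined,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConfounderReport:
    covariate: str
    a0: float
    a_adj: float
    change: float
    exceeds_cutoff: bool
    degenerate: bool = False
    n: int = 0


CONFOUNDER_CUTOFF = 0.10


def confounder_change(score, target, covariate, name: str = "covariate") -> ConfounderReport:
    """Change-in-estimate of the score→target association after covariate
    adjustment, both slopes from ordinary least squares."""
    import statsmodels.api as sm

    s = np.asarray(score, dtype=float)
    t = np.asarray(target, dtype=float)
    c = np.asarray(covariate)
    if c.dtype.kind in "OUS":  # sex labels → binary indicator
        levels = sorted(set(map(str, c)))
        if len(levels) > 2:
            raise ValueError(f"categorical covariate with >2 levels: {levels}")
        c = np.array([levels.index(str(v)) for v in c], dtype=float)
    else:
        c = c.astype(float)
    ok = ~(np.isnan(s) | np.isnan(t) | np.isnan(c))
    s, t, c = s[ok], t[ok], c[ok]
    n = int(s.size)
    if n < 10:
        raise InsufficientDataError(f"need ≥ 10 complete triples, got {n}")
    x0 = sm.add_constant(s)
    a0 = float(sm.OLS(t, x0).fit().params[1])
    xa = sm.add_constant(np.column_stack([s, c]))
    fit_adj = sm.OLS(t, xa).fit()
    a_adj = float(fit_adj.params[1])
    if abs(a_adj) < 1e-12 or not np.isfinite(fit_adj.params).all():
        return ConfounderReport(name, a0, a_adj, math.inf, True, degenerate=True, n=n)
    change = abs(a0 - a_adj) / abs(a_adj)
    return ConfounderReport(
        covariate=name,
        a0=a0,
        a_adj=a_adj,
        change=change,
        exceeds_cutoff=change > CONFOUNDER_CUTOFF,
        n=n,
    )


def confounder_table(
    aggregated: pd.DataFrame,
    targets: pd.DataFrame,
    demographics: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
) -> pd.DataFrame:
    """Change-in-estimate for every target × covariate pair."""
    rows = []
    for t in aggregated.columns:
        if t not in targets.columns:
            continue
        common = aggregated.index.intersection(targets.index).intersection(
            demographics.index
        )
        for cov in covariates:
            try:
                rep = confounder_change(
                    aggregated.loc[common, t],
                    targets.loc[common, t],
                    demographics.loc[common, cov],
                    name=cov,
                )
            except InsufficientDataError:
                continue
            rows.append(
                {
                    "target": t,
                    "covariate": cov,
                    "a0": rep.a0,
                    "a_adj": rep.a_adj,
                    "change": rep.change,
                    "exceeds_cutoff": rep.exceeds_cutoff,
                    "degenerate": rep.degenerate,
                    "n": rep.n,
                }
            )
    return pd.DataFrame(rows)


def subdomain_vs_items(
    features: pd.DataFrame,
    items_by_subject: Mapping[str, Sequence[ScaleItemValue]],
    mapping: SubdomainMappingSpec,
    subdomains: Sequence[str],
    folds: Sequence[FoldAssignment],
    base_seed: int = 0,
    n_estimators: int = 100,
) -> pd.DataFrame:
    """Train one model per subdomain score and one per constituent
    normalized item (same folds, same architecture); report Spearman ρ with
    stars for each and whether the subdomain model beats every item model.
    """
    from .clinical import subdomain_score

    rows = []
    for sd in subdomains:
        item_defs = mapping.items_for(sd)
        if not item_defs:
            import warnings

            warnings.warn(f"subdomain {sd!r} has no constituent items; skipped")
            continue
        # build the target frame: the subdomain score plus each normalized item
        target_cols: dict[str, dict[str, float]] = {f"subdomain::{sd}": {}}
        for it in item_defs:
            target_cols[f"item::{it.scale}—{it.item}"] = {}
        for sid, items in items_by_subject.items():
            score, _ = subdomain_score(items, mapping, sd)
            target_cols[f"subdomain::{sd}"][sid] = score
            by_key = {i.key: i for i in items}
            for it in item_defs:
                obs = by_key.get((it.scale, it.item))
                target_cols[f"item::{it.scale}—{it.item}"][sid] = (
                    normalize_item(obs) if obs is not None and not obs.missing else math.nan
                )
        targets = pd.DataFrame(target_cols).reindex(features.index)
        spec = ModelSpec(variant="independent", targets=tuple(targets.columns),
                         n_estimators=n_estimators)
        cv = cross_validate(features, targets, spec, folds, base_seed=base_seed)
        agg = cv.aggregated()
        sd_rho = None
        item_rhos = []
        for col in targets.columns:
            a = associate(agg[col].reindex(targets.index), targets[col])
            kind, name = col.split("::", 1)
            rho = a.spearman_rho
            if kind == "subdomain":
                sd_rho = rho
            else:
                item_rhos.append(rho)
            rows.append(
                {
                    "subdomain": sd,
                    "kind": kind,
                    "target": name,
                    "spearman_rho": rho,
                    "sig": "n/a" if a.undefined else significance_label(a.spearman_p),
                    "n": a.n,
                }
            )
        beats_all = bool(
            sd_rho is not None
            and item_rhos
            and all((not math.isnan(r) and sd_rho > r) or math.isnan(r) for r in item_rhos)
        )
        for row in rows:
            if row["subdomain"] == sd and "subdomain_beats_all_items" not in row:
                row["subdomain_beats_all_items"] = beats_all
    return pd.DataFrame(rows)


def attribution_by_family(
    cv_result: CVResult, features: pd.DataFrame
) -> pd.DataFrame:
    """Group additive feature attributions by family × task per target.

    Uses the TreeSHAP decomposition built into the boosted models,
    evaluated on each iteration's test-fold subjects; |values| are averaged
    per feature over all test predictions, summed within family × task and
    normalized to fractions per target.  Raises
    :class:`AttributionUnsupportedError` for the joint variant.
    """
    if cv_result.spec.variant == "joint":
        raise AttributionUnsupportedError(
            "the joint extra-trees variant exposes no additive attribution; "
            "use the independently optimized variant"
        )
    if not cv_result.models:
        raise ValueError("cross_validate must be run with keep_models=True")
    names = list(features.columns)
    acc: dict[str, np.ndarray] = {}
    cnt: dict[str, int] = {}
    for fm in cv_result.models:
        x_test = features.loc[list(fm.test_subjects)]
        contrib = fm.model.predict(x_test, pred_contrib=True)[:, :-1]  # drop bias
        t = fm.target or "*"
        acc[t] = acc.get(t, np.zeros(len(names))) + np.abs(contrib).sum(axis=0)
        cnt[t] = cnt.get(t, 0) + contrib.shape[0]
    rows = []
    for t, total in acc.items():
        mean_abs = total / max(cnt[t], 1)
        groups: dict[tuple[str, str], float] = {}
        for name, v in zip(names, mean_abs):
            family, task, _ = parse_feature_name(name)
            groups[(family, task)] = groups.get((family, task), 0.0) + float(v)
        tot = sum(groups.values())
        degenerate = tot <= 0
        for (family, task), v in sorted(groups.items()):
            rows.append(
                {
                    "target": t,
                    "family": family,
                    "task": task,
                    "share": (1.0 / len(groups)) if degenerate else v / tot,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
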