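"""Paired-masking cross-validation over predictor sets.

The CV design masks pollinators, not hybrids: in every cycle a random 25%
of the pollinator lines is drawn and *all* of their hybrids (one per
tester) form the validation set, so no pollinator contributes hybrids to
both sides of the split. All predictor sets see the same splits within a
cycle (paired design), which makes the downstream ANOVA / Tukey
comparisons within-cycle contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import CrossPlan, CvResult, OmicsMatrix, RelationshipKernel
from .reml import ConvergenceError, fit_reml, predict_unobserved


@dataclass
class PredictorSet:
    """A labelled, unordered combination of kernels (e.g. G, GT, A+D+E)."""

    label: str
    kernels: list[RelationshipKernel]

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("a predictor set needs at least one kernel")
        ids = list(self.kernels[0].ids)
        for k in self.kernels:
            if list(k.ids) != ids:
                raise ValueError("kernels of one predictor set must share ids")


def cv_split(plan: CrossPlan, fraction: float = 0.25,
             rng: np.random.Generator | int | None = None
             ) -> tuple[list[str], list[str], list[str]]:
    """Sample ``ceil(fraction * n_pollinators)`` pollinators; every hybrid of
    a sampled pollinator goes to validation. Returns (train hybrids,
    validation hybrids, masked pollinators)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if len(plan) == 0:
        raise ValueError("empty cross plan")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pollinators = plan.pollinators
    n_mask = math.ceil(fraction * len(pollinators))
    masked = list(rng.choice(pollinators, size=n_mask, replace=False))
    masked_set = set(masked)
    val, train = [], []
    for _, row in plan.pairs.iterrows():
        (val if row["pollinator"] in masked_set else train).append(row["hybrid"])
    return train, val, masked


def run_cv(
    phenotypes: pd.Series,
    predictor_sets: list[PredictorSet],
    plan: CrossPlan,
    model: str = "gblup",
    cycles: int = 1000,
    fraction: float = 0.25,
    seed: int = 0,
    trait: str = "trait",
) -> CvResult:
    """Run the paired cross-validation.

    ``phenotypes`` is indexed by hybrid id; hybrids with missing phenotype
    stay in the kernels but are excluded from fitting and from the accuracy
    computation. Per cycle and predictor set the Pearson correlation
    between predicted and observed validation phenotypes is recorded; a
    fit failure leaves that cell missing and the run continues.
    """
    rng = np.random.default_rng(seed)
    labels = [ps.label for ps in predictor_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate predictor-set labels")
    acc = np.full((cycles, len(predictor_sets)), np.nan)
    masked_lists: list[list[str]] = []
    failures: list[tuple[int, str]] = []
    observed = phenotypes.dropna()

    for c in range(cycles):
        train, val, masked = cv_split(plan, fraction, rng)
        masked_lists.append(masked)
        train_obs = [h for h in train if h in observed.index]
        val_obs = [h for h in val if h in observed.index]
        if len(train_obs) < 3 or len(val_obs) < 3:
            failures.append((c, "too few observed hybrids"))
            continue
        y_tr = observed[train_obs].to_numpy()
        y_va = observed[val_obs].to_numpy()
        for s, ps in enumerate(predictor_sets):
            try:
                sub = [k.reorder(train_obs) for k in ps.kernels]
                fit = fit_reml(y_tr, sub)
                cross = [k.submatrix(val_obs, train_obs) for k in ps.kernels]
                yhat = predict_unobserved(fit, cross)
                if np.std(yhat) == 0 or np.std(y_va) == 0:
                    acc[c, s] = 0.0
                else:
                    acc[c, s] = stats.pearsonr(yhat, y_va)[0]
            except (ConvergenceError, np.linalg.LinAlgError) as exc:
                failures.append((c, f"{ps.label}: {exc}"))
    df = pd.DataFrame(acc, columns=labels)
    return CvResult(df, masked_lists, seed, model, trait, failures)


def subsample_features(om: OmicsMatrix, n_features: int, n_subsets: int,
                       seed: int = 0) -> list[OmicsMatrix]:
    """Draw ``n_subsets`` independent uniform feature subsets (without
    replacement within a subset), for feature-count-matched comparisons."""
    total = om.shape[1]
    if n_features > total:
        raise ValueError(f"requested {n_features} of {total} features")
    rng = np.random.default_rng(seed)
    out = []
    feats = np.asarray(om.features)
    for _ in range(n_subsets):
        idx = np.sort(rng.choice(total, size=n_features, replace=False))
        out.append(om.subset_features(list(feats[idx])))
    return out


def _compact_letters(labels: list[str], significant: set[tuple[str, str]],
                     means: pd.Series) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Sets sharing a letter are not significantly different; significantly
    different pairs never share a letter.
    """
    order = sorted(labels, key=lambda l: -means[l])
    columns: list[set[str]] = [set(order)]
    for a, b in significant:
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.extend([col - {a}, col - {b}])
        # absorb columns contained in others
        columns = [c for c in columns
                   if c and not any(c < other for other in columns)]
        # deduplicate
        uniq: list[set[str]] = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    columns.sort(key=lambda col: min(order.index(l) for l in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {l: "" for l in labels}
    for i, col in enumerate(columns):
        for l in order:
            if l in col:
                letters[l] += alphabet[i % len(alphabet)]
    return letters


def compare_predictor_sets(result: CvResult, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across predictor sets followed by Tukey HSD, with a
    compact letter display. Cycles with any missing accuracy are dropped
    (pairwise complete design kept simple: listwise within the table)."""
    df = result.accuracies.dropna(axis=0, how="any")
    labels = list(df.columns)
    if len(labels) == 1:
        return pd.DataFrame({"set": labels, "mean": [df[labels[0]].mean()],
                             "sd": [df[labels[0]].std()], "letters": ["a"]})
    if df.shape[0] < 2:
        raise ValueError("need at least 2 complete cycles")
    groups = [df[l].to_numpy() for l in labels]
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance: ANOVA undefined")
    f_stat, p_anova = stats.f_oneway(*groups)
    long = df.melt(var_name="set", value_name="accuracy")
    tukey = pairwise_tukeyhsd(long["accuracy"], long["set"], alpha=alpha)
    tk = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    significant = {
        tuple(sorted((str(r["group1"]), str(r["group2"]))))
        for _, r in tk.iterrows() if bool(r["reject"])
    }
    means = df.mean()
    letters = _compact_letters(labels, significant, means)
    out = pd.DataFrame({
        "set": labels,
        "mean": [means[l] for l in labels],
        "sd": [df[l].std() for l in labels],
        "letters": [letters[l] for l in labels],
    }).sort_values("mean", ascending=False).reset_index(drop=True)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(p_anova)
    out.attrs["n_cycles"] = int(df.shape[0])
    out.attrs["tukey"] = tk
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_models(result_a: CvResult, result_b: CvResult) -> pd.DataFrame:
    """Welch two-sample t test per predictor set between two model classes
    (e.g. gBLUP vs RKHS) on per-cycle accuracies."""
    if list(result_a.sets) != list(result_b.sets):
        raise ValueError("results must cover the same predictor sets")
    if result_a.trait != result_b.trait:
        warnings.warn("comparing results from different traits")
    rows = []
    for s in result_a.sets:
        a = result_a.accuracies[s].dropna().to_numpy()
        b = result_b.accuracies[s].dropna().to_numpy()
        if np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "trait": result_a.trait, "set": s,
            "model_a": result_a.model, "model_b": result_b.model,
            "mean_a": a.mean(), "mean_b": b.mean(),
            "mean_diff": a.mean() - b.mean(),
            "t": float(t), "p": float(p), "stars": _stars(float(p)),
        })
    return pd.DataFrame(rows)
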