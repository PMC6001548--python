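"""Predictive validity of CS+/CS- scoring methods.

A scoring method (model-based or model-free) reduces each subject to one
score per condition. Its predictive validity is the evidence for a model in
which CS+ and CS- scores are drawn from distributions with equal variance
but different means, quantified by regressing the event-type indicator
(CS+ = 1, CS- = 0) on the scores with one intercept per subject and
converting the residual sum of squares to an Akaike information criterion

    AIC = n log(RSS / n) + 2 k,      k = n_subjects + 1.

k is identical for all methods compared on the same observations and drops
from AIC differences; smaller AIC means higher evidence, and an absolute
difference above 3 is conventionally decisive. The paired t test, two-sided
p and paired Cohen's d are reported alongside.

A within-subject label-permutation procedure checks that a method is not
biased toward either condition: labels are shuffled within subject
(preserving trial counts), condition means and the paired t are recomputed,
and the t and p values are averaged over permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidityResult",
    "PermutationResult",
    "paired_t",
    "predictive_validity",
    "compare_methods",
    "permutation_unbiasedness",
    "DECISIVE_DELTA_AIC",
]

#: |ΔAIC| above this is regarded as decisive evidence
DECISIVE_DELTA_AIC = 3.0

_POSITIVE_DEFAULT = "CS+"


@dataclass
class ValidityResult:
    """Predictive validity of one scoring method."""

    aic: float
    t: float
    df: int
    p: float
    d: float
    n_obs: int
    rss: float
    k: int
    method: str = ""
    degenerate: bool = False


@dataclass
class PermutationResult:
    mean_t: float
    mean_p: float
    t_values: np.ndarray = field(repr=False)
    p_values: np.ndarray = field(repr=False)
    n_perm: int = 0
    df: int = 0


def aic_from_rss(n: int, rss: float, k: int) -> float:
    """Akaike information criterion n*log(RSS/n) + 2k (natural log)."""
    if rss <= 0:
        return float("-inf")
    return float(n * np.log(rss / n) + 2 * k)


def paired_t(x, y) -> tuple[float, int, float, float]:
    """Paired t test with effect size.

    Returns (t, df, two-sided p, paired Cohen's d = mean(diff)/SD(diff)).
    If the differences have zero variance, t is 0 (p = 1) when the mean
    difference is also zero and NaN otherwise.
    """
    diffs = np.asarray(x, float) - np.asarray(y, float)
    n = diffs.size
    if n < 2:
        raise ValueError("paired t requires at least 2 pairs")
    df = n - 1
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0, 0.0
        return float("nan"), df, float("nan"), float("nan")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), float(mean / sd)


def _score_frame(scores) -> pd.DataFrame:
    df = pd.DataFrame(scores)
    missing = {"subject", "condition", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"score table lacks columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["score"].to_numpy(float))):
        raise ValueError("scores must be finite")
    return df


def predictive_validity(
    scores, positive: str | None = None, method: str = ""
) -> ValidityResult:
    """Predictive validity of a condition-wise score table.

    ``scores`` is a DataFrame-like with columns (subject, condition, score),
    exactly two conditions, each subject contributing both. The dependent
    variable is the condition indicator; predictors are the score plus one
    intercept per subject, fitted by least squares. Zero variance in the
    per-subject score differences leaves t undefined (flagged degenerate);
    the AIC is still computed.
    """
    df = _score_frame(scores)
    conds = sorted(df["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    if positive is None:
        positive = _POSITIVE_DEFAULT if _POSITIVE_DEFAULT in conds else conds[0]
    negative = next(c for c in conds if c != positive)
    pivot = df.pivot_table(index="subject", columns="condition", values="score", aggfunc="mean")
    if pivot.isna().any().any():
        raise ValueError("each subject must contribute both conditions")
    n_subj = pivot.shape[0]
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")

    # long form: one row per subject x condition
    y = np.concatenate([np.ones(n_subj), np.zeros(n_subj)])
    s = np.concatenate([pivot[positive].to_numpy(float), pivot[negative].to_numpy(float)])
    dummies = np.vstack([np.eye(n_subj), np.eye(n_subj)])
    X = np.column_stack([s, dummies])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = 2 * n_subj
    k = n_subj + 1
    aic = aic_from_rss(n, rss, k)
    if not np.isfinite(aic):
        warnings.warn("zero residual sum of squares; AIC is -inf", stacklevel=2)

    t, dof, p, d = paired_t(pivot[positive], pivot[negative])
    degenerate = not np.isfinite(t)
    if degenerate:
        warnings.warn("zero variance in score differences; t undefined", stacklevel=2)
    return ValidityResult(
        aic=float(aic), t=t, df=dof, p=p, d=d, n_obs=n, rss=rss, k=k,
        method=method, degenerate=degenerate,
    )


def compare_methods(results) -> pd.DataFrame:
    """Rank scoring methods by AIC.

    ``results`` is a mapping name -> ValidityResult or an iterable of
    results carrying their ``method`` name. All must stem from the same
    observations (equal n); otherwise the AICs are incomparable. Returns a
    DataFrame sorted ascending by AIC with the difference to the best
    method and a decisive flag (|ΔAIC| > 3). Ties are broken by method
    name for deterministic output.
    """
    if isinstance(results, dict):
        items = [(name, res) for name, res in results.items()]
    else:
        items = [(res.method, res) for res in results]
    if len(items) < 2:
        raise ValueError("need at least 2 methods to compare")
    n_set = {res.n_obs for _, res in items}
    if len(n_set) != 1:
        raise ValueError("incomparable AIC: methods computed on different observations")
    items.sort(key=lambda kv: (kv[1].aic, kv[0]))
    best = items[0][1].aic
    return pd.DataFrame(
        {
            "method": [name for name, _ in items],
            "aic": [res.aic for _, res in items],
            "delta_aic": [res.aic - best for _, res in items],
            "decisive": [res.aic - best > DECISIVE_DELTA_AIC for _, res in items],
        }
    )


def permutation_unbiasedness(
    trial_scores,
    n_perm: int = 1000,
    seed: int | None = None,
    include_identity: bool = False,
    score_fn=None,
) -> PermutationResult:
    """Within-subject label-permutation check of condition (un)biasedness.

    ``trial_scores`` is a DataFrame-like with columns (subject, condition,
    score) at the trial level and exactly two conditions. For each
    permutation, condition labels are shuffled within subject (preserving
    per-subject trial counts), condition-wise mean scores are recomputed,
    and the paired t over subjects is collected; the mean t and mean
    two-sided p over permutations are returned. Seeded and reproducible.

    ``include_identity=True`` makes the first draw the identity assignment,
    which reproduces the unpermuted t exactly. ``score_fn`` is a hook for
    re-running a full model inversion per permutation: it receives a
    DataFrame with permuted ``condition`` labels and must return a mapping
    subject -> (positive score, negative score). The default re-aggregates
    the trial scores by their permuted labels.
    """
    df = _score_frame(trial_scores)
    conds = sorted(df["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    positive = _POSITIVE_DEFAULT if _POSITIVE_DEFAULT in conds else conds[0]
    negative = next(c for c in conds if c != positive)
    counts = df.groupby(["subject", "condition"]).size().unstack(fill_value=0)
    if (counts < 2).any().any():
        raise ValueError("need at least 2 trials per condition per subject")
    subjects = sorted(df["subject"].unique())
    n_subj = len(subjects)
    dof = n_subj - 1
    rng = np.random.default_rng(seed)

    if score_fn is not None:
        tvals = np.empty(n_perm)
        pvals = np.empty(n_perm)
        for r in range(n_perm):
            perm_df = df.copy()
            if not (include_identity and r == 0):
                perm_df["condition"] = (
                    perm_df.groupby("subject")["condition"]
                    .transform(lambda c: rng.permutation(c.to_numpy()))
                )
            per_subject = score_fn(perm_df)
            pos = np.array([per_subject[s][0] for s in subjects])
            neg = np.array([per_subject[s][1] for s in subjects])
            tvals[r], _, pvals[r], _ = paired_t(pos, neg)
    else:
        # vectorized: per subject, order trials so the first n_pos slots
        # carry the positive label, then permute scores into the slots
        diffs = np.empty((n_perm, n_subj))
        for j, subj in enumerate(subjects):
            sub = df[df["subject"] == subj]
            # identity ordering: positive-labelled trials first
            order = np.argsort(sub["condition"].to_numpy() != positive, kind="stable")
            s = sub["score"].to_numpy(float)[order]
            n_pos = int((sub["condition"] == positive).sum())
            idx = np.argsort(rng.random((n_perm, s.size)), axis=1)
            if include_identity:
                idx[0] = np.arange(s.size)
            perm = s[idx]
            diffs[:, j] = perm[:, :n_pos].mean(axis=1) - perm[:, n_pos:].mean(axis=1)
        mean = diffs.mean(axis=1)
        sd = diffs.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = mean / (sd / np.sqrt(n_subj))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    return PermutationResult(
        mean_t=float(np.mean(tvals)),
        mean_p=float(np.mean(pvals)),
        t_values=tvals,
        p_values=pvals,
        n_perm=n_perm,
        df=dof,
    )
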