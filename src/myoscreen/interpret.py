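"""Permutation-sampling Shapley feature-impact estimation for the ensemble.

Impacts are computed on the voting model's continuous positive-class score,
not the hard label. For each subject, feature orderings are sampled uniformly
and one background subject is drawn per ordering; marginal contributions are
accumulated along the ordering (features "absent" take the background draw's
values). The telescoping sum over one ordering equals
score(x) - score(background draw), so the averaged impacts satisfy local
accuracy relative to the background-mean base value up to Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ImpactSummary:
    """Per-subject Shapley values and per-feature aggregate importance."""

    values: pd.DataFrame          # rows: subjects, columns: features
    feature_values: pd.DataFrame  # the explained feature matrix (same shape)
    base_value: float             # expected model score over the background
    standard_errors: pd.DataFrame # Monte-Carlo SE of each Shapley value
    model_scores: np.ndarray      # score(x) per explained subject

    @property
    def mean_abs_impact(self) -> pd.Series:
        return self.values.abs().mean(axis=0).sort_values(ascending=False)

    @property
    def ordering(self) -> list[str]:
        return list(self.mean_abs_impact.index)


def shapley_impacts(score_fn, x: np.ndarray, background: np.ndarray,
                    n_permutations: int = 200, seed: int = 0,
                    feature_names=None, subject_ids=None) -> ImpactSummary:
    """Monte-Carlo permutation estimate of Shapley values.

    ``score_fn`` maps an (n, d) matrix to n scores; ``background`` supplies
    the replacement values for absent features. All (d + 1) coalition
    evaluations per sampled ordering are batched into one ``score_fn`` call
    per subject.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background sample must be non-empty")
    n, d = x.shape
    rng = np.random.default_rng(seed)
    feature_names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(d)]
    subject_ids = list(subject_ids) if subject_ids is not None else list(range(n))

    base = float(np.mean(score_fn(background)))
    impacts = np.empty((n, d))
    ses = np.empty((n, d))
    model_scores = np.asarray(score_fn(x), dtype=float)

    for i in range(n):
        orders = np.array([rng.permutation(d) for _ in range(n_permutations)])
        z_idx = rng.integers(0, background.shape[0], size=n_permutations)
        # chain[t, s] = mixed vector after inserting the first s features of
        # ordering t into background draw z_t; s runs 0..d
        chains = np.empty((n_permutations, d + 1, d))
        chains[:, 0, :] = background[z_idx]
        for s in range(d):
            chains[:, s + 1, :] = chains[:, s, :]
            chains[np.arange(n_permutations), s + 1, orders[:, s]] = x[i, orders[:, s]]
        vals = np.asarray(score_fn(chains.reshape(-1, d)), dtype=float)
        vals = vals.reshape(n_permutations, d + 1)
        marg = np.diff(vals, axis=1)               # (T, d) in ordering position
        contrib = np.empty_like(marg)
        rows = np.repeat(np.arange(n_permutations), d)
        contrib[rows, orders.ravel()] = marg.ravel()
        impacts[i] = contrib.mean(axis=0)
        ses[i] = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)

    return ImpactSummary(
        values=pd.DataFrame(impacts, index=subject_ids, columns=feature_names),
        feature_values=pd.DataFrame(x, index=subject_ids, columns=feature_names),
        base_value=base,
        standard_errors=pd.DataFrame(ses, index=subject_ids, columns=feature_names),
        model_scores=model_scores,
    )


def rank_and_drop(summary: ImpactSummary, n_drop: int = 3) -> list[str]:
    """Drop the ``n_drop`` features with smallest mean |impact|; return the
    retained features in descending importance. Ties at the cut drop the
    lexicographically later names."""
    importance = summary.mean_abs_impact
    if len(importance) <= n_drop:
        raise ValueError("need more features than n_drop")
    # sort by (-importance, name): equal importances keep earlier names first
    order = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = order[: len(order) - n_drop]
    return [name for name, _ in kept]


def summary_plot_data(summary: ImpactSummary) -> pd.DataFrame:
    """Long-form (feature, subject, shapley_value, feature_value) table with
    features in descending mean-|impact| order, ready for beeswarm rendering."""
    ordering = summary.ordering
    rows = []
    for feat in ordering:
        for subj in summary.values.index:
            rows.append({
                "feature": feat,
                "subject": subj,
                "shapley_value": float(summary.values.loc[subj, feat]),
                "feature_value": float(summary.feature_values.loc[subj, feat]),
            })
    return pd.DataFrame(rows)
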