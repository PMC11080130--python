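"""Shared test utilities: stub ensemble members and exact-test oracles."""

import itertools

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin


class FixedProba(BaseEstimator, ClassifierMixin):
    """Stub member returning a fixed positive-class probability function."""

    def __init__(self, fn=None):
        self.fn = fn

    def fit(self, x, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, x):
        p1 = np.asarray(self.fn(np.atleast_2d(x)), dtype=float)
        return np.column_stack([1 - p1, p1])

    def predict(self, x):
        return (self.predict_proba(x)[:, 1] >= 0.5).astype(int)


def fitted_stub(fn, y=(0, 1)):
    return FixedProba(fn).fit(np.zeros((2, 1)), np.array(y))


def mwu_oracle(a, b):
    """Two-sided exact p by brute-force enumeration of all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    sums = np.asarray([sum(ranks[list(idx)])
                       for idx in itertools.combinations(range(len(pooled)), n_a)])
    p_low = np.mean(sums <= obs + 1e-9)
    p_high = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


def wilcoxon_oracle(d):
    """Exact p by enumeration of all 2^n sign assignments on midranked |d|."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    sums = np.asarray([sum(r for r, s in zip(ranks, signs) if s)
                       for signs in itertools.product([False, True], repeat=len(d))])
    p_low = np.mean(sums <= obs + 1e-9)
    p_high = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))
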