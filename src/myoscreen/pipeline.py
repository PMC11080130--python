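"""End-to-end glue: dataset -> feature table -> statistics -> CV -> impacts.

The classifier input follows the study configuration: per subject, the nine
features at both contraction levels averaged over forearm channels two and
three (FCR, FDS), minus the three least important features
(CWT_power at 20% MVC, WE at 20% MVC, SSC at 50% MVC) — 15 entries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as clf
from . import features as feat
from . import interpret as interp
from . import preprocess as prep
from . import stats as st
from .simulate import StudyDataset

CLASSIFIER_CHANNELS = ("FCR", "FDS")            # channels two and three
DEFAULT_DROP = ("CWT_power@20", "WE@20", "SSC@50")
GROUP_CODE = {"healthy": 0, "sarcopenic": 1}


def extract_feature_table(dataset: StudyDataset, channels=None,
                          filter_spec: prep.FilterSpec | None = None,
                          scales=feat.DEFAULT_SCALES,
                          zc_ssc_rel_threshold: float = 0.01) -> pd.DataFrame:
    """Filter, segment, window and featurize every trial of every subject.

    Returns the long-form window-level table of sub-maximal trials with both
    raw and MVC-normalized values. ``channels`` restricts which channels are
    featurized (the stationarity criterion always uses all recorded channels).
    """
    filter_spec = filter_spec or prep.FilterSpec()
    rows_mvc, rows_sub = [], []
    for subj in dataset.subjects:
        for trial in subj.trials:
            filtered = prep.apply_filters(trial, filter_spec)
            segment, _ = prep.select_segment(filtered)
            for wm in prep.make_windows(segment):
                if channels is not None and wm.channel not in channels:
                    continue
                table = feat.window_features(
                    wm.windows, zc_ssc_rel_threshold=zc_ssc_rel_threshold,
                    scales=scales)
                long = table.melt(id_vars="window", var_name="feature",
                                  value_name="raw")
                long["subject"] = subj.subject_id
                long["group"] = subj.group
                long["sex"] = subj.sex
                long["level"] = trial.level
                long["channel"] = wm.channel
                long["trial"] = trial.trial_id
                (rows_mvc if trial.level == "MVC" else rows_sub).append(long)
    mvc_table = pd.concat(rows_mvc, ignore_index=True)
    sub_table = pd.concat(rows_sub, ignore_index=True)
    return feat.mvc_normalize(sub_table, mvc_table)


def _level_tag(level: str) -> str:
    return str(int(round(float(level) * 100)))


def subject_vectors(table: pd.DataFrame, channels=CLASSIFIER_CHANNELS,
                    drop=DEFAULT_DROP):
    """Build the classifier matrix: features x levels from the channel mean.

    Returns (x, y, feature_names, subject_ids) with a fixed feature ordering
    shared by all subjects.
    """
    agg = feat.aggregate(table, channel_set=channels, mode="classify")
    agg = agg.assign(name=lambda d: d["feature"] + "@" + d["level"].map(_level_tag))
    wide = agg.pivot_table(index="subject", columns="name", values="value")
    keep = [c for c in wide.columns if c not in set(drop or ())]
    wide = wide[sorted(keep)]
    if wide.isna().any().any():
        raise ValueError("missing feature entries for some subjects")
    meta = agg.drop_duplicates("subject").set_index("subject")["group"]
    y = meta.loc[wide.index].map(GROUP_CODE).to_numpy()
    return wide.to_numpy(), y, list(wide.columns), list(wide.index)


def comparison_report(table: pd.DataFrame, channels=None) -> pd.DataFrame:
    """The study's statistical battery on the channel/trial-averaged table."""
    agg = feat.aggregate(table, channel_set=channels, mode="stats")
    return st.feature_comparison_report(agg)


def fit_full_ensemble(x: np.ndarray, y: np.ndarray,
                      spec: clf.EnsembleSpec | None = None):
    """Fit members and voting weights on all provided subjects (used for the
    all-cohort impact summary; cross_validate handles leakage-safe evaluation)."""
    spec = spec or clf.EnsembleSpec()
    members = clf.fit_members(x, y, spec)
    w = clf.search_weights(members, x, y, spec)
    return members, w


def ensemble_score_fn(members, weights):
    """Positive-class weighted probability score as a matrix -> vector map."""
    def score(x: np.ndarray) -> np.ndarray:
        return clf.soft_vote(members, weights, np.atleast_2d(x))[0]
    return score


def impact_summary(x: np.ndarray, y: np.ndarray, feature_names, subject_ids,
                   spec: clf.EnsembleSpec | None = None,
                   n_permutations: int = 200, background_size: int = 50,
                   seed: int = 0) -> interp.ImpactSummary:
    """Shapley impacts of the voting score for every subject, with a background
    of up to ``background_size`` subjects."""
    members, w = fit_full_ensemble(x, y, spec)
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(x), size=min(background_size, len(x)), replace=False)
    return interp.shapley_impacts(
        ensemble_score_fn(members, w), x, x[bg_idx],
        n_permutations=n_permutations, seed=seed,
        feature_names=feature_names, subject_ids=subject_ids)
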