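"""Per-post PD-relatedness verdicts: classifier plus rule-based flags.

The recall-optimized classifier is applied only to posts containing at least
one dictionary term; explicit-mention rules (a "parkinson" substring, a
standalone case-sensitive "PD") are applied to every post and always win:

    pd_related = (dict_hit AND classifier positive) OR parkinson OR pd_abbrev

A post is ``exercise_only`` when its PD-relatedness rests entirely on
exercise-tagged dictionary matches with no explicit mention; the
exercise-excluded sensitivity analysis drops exactly those posts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify
from .features import FeatureSpace, build_features
from .lexicon import TermDictionary, dictionary_flag, explicit_mention, preprocess_for_match

__all__ = ["flag_corpus", "summarize_flags"]


def flag_corpus(
    posts: pd.DataFrame,
    dictionary: TermDictionary,
    model=None,
    space: FeatureSpace | None = None,
    participants: pd.DataFrame | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Flag every post in a corpus.

    ``posts`` needs columns post_id, participant_id, timestamp, text.  When a
    trained model and fitted feature space are given, dictionary-hit posts
    get a classifier probability; without a model the classifier contributes
    no positives and only the explicit-mention rules can flag (the degenerate
    unlabeled-corpus path).

    Returns one row per post: dict_hit, matched_terms, classifier_prob (NaN
    when no dictionary hit or no model), parkinson_mention, pd_abbrev,
    pd_related, exercise_only.
    """
    if model is not None:
        if space is None or not space.fitted:
            raise ValueError("a fitted FeatureSpace is required with a model")
        if participants is None:
            raise ValueError("participants metadata is required with a model")
        if not hasattr(model, "predict_proba"):
            raise ValueError("model must be trained and expose predict_proba")

    n = len(posts)
    dict_hit = np.zeros(n, dtype=bool)
    matched_terms: list[list[str]] = []
    all_exercise = np.zeros(n, dtype=bool)
    parkinson = np.zeros(n, dtype=bool)
    pd_abbrev = np.zeros(n, dtype=bool)

    for i, text in enumerate(posts["text"]):
        hit, matches = dictionary_flag(text, dictionary, tokens=preprocess_for_match(text))
        dict_hit[i] = hit
        matched_terms.append([term for term, _ in matches])
        all_exercise[i] = hit and all(tag == "exercise" for _, tag in matches)
        parkinson[i], pd_abbrev[i] = explicit_mention(text)

    prob = np.full(n, np.nan)
    clf_positive = np.zeros(n, dtype=bool)
    if model is not None and dict_hit.any():
        subset = posts.loc[dict_hit]
        X = build_features(subset, participants, space)
        p, labels = classify.predict(model, X, threshold)
        prob[dict_hit] = p
        clf_positive[dict_hit] = labels.astype(bool)

    pd_related = (dict_hit & clf_positive) | parkinson | pd_abbrev
    exercise_only = pd_related & all_exercise & ~(parkinson | pd_abbrev)

    return pd.DataFrame(
        {
            "post_id": posts["post_id"].to_numpy(),
            "participant_id": posts["participant_id"].to_numpy(),
            "timestamp": posts["timestamp"].to_numpy(),
            "dict_hit": dict_hit,
            "matched_terms": matched_terms,
            "classifier_prob": prob,
            "parkinson_mention": parkinson,
            "pd_abbrev": pd_abbrev,
            "pd_related": pd_related,
            "exercise_only": exercise_only,
        }
    )


def summarize_flags(flags: pd.DataFrame, participants: pd.DataFrame) -> dict:
    """Per-participant counts and cohort shares.

    Participants with zero posts are excluded from the cohort shares
    (mirroring the exclusion of empty archives from analysis).
    """
    per = (
        flags.groupby("participant_id")
        .agg(
            n_posts=("post_id", "size"),
            n_pd_related=("pd_related", "sum"),
            n_explicit=("parkinson_mention", lambda s: int((s | flags.loc[s.index, "pd_abbrev"]).sum())),
            n_exercise_only=("exercise_only", "sum"),
        )
        .reset_index()
    )
    per = participants[["id", "group"]].merge(
        per, left_on="id", right_on="participant_id", how="left"
    )
    per[["n_posts", "n_pd_related", "n_explicit", "n_exercise_only"]] = (
        per[["n_posts", "n_pd_related", "n_explicit", "n_exercise_only"]].fillna(0).astype(int)
    )
    per = per.drop(columns=["participant_id"])

    active = per[per["n_posts"] > 0]
    shares = {
        "n_active_participants": int(len(active)),
        "share_with_flagged_post": float((active["n_pd_related"] > 0).mean()) if len(active) else float("nan"),
        "share_with_explicit_post": float((active["n_explicit"] > 0).mean()) if len(active) else float("nan"),
    }
    return {"per_participant": per, **shares}
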