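"""Model feature representation for post classification.

Each post is represented by four concatenated blocks, all fitted on training
data only and applied unchanged to test data:

1. TF-IDF over noun-default lemma 1-/2-/3-grams with document frequency >= 2
   (raw term count x smoothed idf = ln((1+N)/(1+df)) + 1, rows L2-normalized
   within the block);
2. TF-IDF over word-cluster unigrams (tokens mapped through a token ->
   cluster lookup table; out-of-vocabulary tokens share a reserved OOV id),
   same frequency threshold and weighting;
3. age at time of posting, min-max scaled to [0, 1] by training bounds (the
   whole matrix stays nonnegative, so a multinomial Naive Bayes applies);
4. one-hot gender and diagnosis-group indicators for levels seen in
   training (an unseen level yields an all-zero block).

Age at posting is derived from age at interview minus the interview-to-post
gap in years (birth dates are not collected), floored at 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dataclass_field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .textproc import lemmatize_noun, remove_stopwords

__all__ = [
    "clean_for_model",
    "lemmatize",
    "load_cluster_table",
    "map_clusters",
    "FeatureSpace",
    "fit_feature_space",
    "build_features",
    "OOV_CLUSTER",
]

OOV_CLUSTER = "OOV"

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_TAG_RE = re.compile(r"[@#]\w+")
_SPECIAL_RE = re.compile(r"[^\w\s]|_")


def clean_for_model(text: str) -> list[str]:
    """Remove URLs, @-tags, #-hashtags, punctuation and stop words; lowercase."""
    text = _URL_RE.sub(" ", text)
    text = _TAG_RE.sub(" ", text)
    text = _SPECIAL_RE.sub(" ", text)
    return remove_stopwords(text.lower().split())


def lemmatize(tokens: list[str]) -> list[str]:
    """Noun-default lemmatization; unknown/uninflected words pass through."""
    return [lemmatize_noun(t) for t in tokens]


def load_cluster_table(path: str | Path | None = None) -> dict[str, str]:
    """Load a two-column token -> cluster-id table (TAB separated).

    Without a path the bundled synthetic fixture table is used; any larger
    clustering resource with the same layout can be supplied at run time.
    """
    if path is None:
        raw = resources.files("pdsocial.data").joinpath("clusters.tsv").read_text("utf-8")
    else:
        raw = Path(path).read_text("utf-8")
    table: dict[str, str] = {}
    for line in raw.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token, _, cluster = line.partition("\t")
        if token and cluster:
            table[token.strip()] = cluster.strip()
    if not table:
        raise ValueError("cluster table is empty")
    return table


def map_clusters(tokens: list[str], cluster_table: dict[str, str]) -> list[str]:
    """Replace each token by its cluster id; unknown tokens map to OOV."""
    if not cluster_table:
        raise ValueError("cluster table is required")
    return [cluster_table.get(t, OOV_CLUSTER) for t in tokens]


def _lemma_doc(text: str) -> str:
    return " ".join(lemmatize(clean_for_model(text)))


def _cluster_doc(text: str, table: dict[str, str]) -> str:
    return " ".join(map_clusters(clean_for_model(text), table))


def _age_at_posting(posts: pd.DataFrame, participants: pd.DataFrame) -> np.ndarray:
    meta = participants.set_index("id")
    missing = set(posts["participant_id"]) - set(meta.index)
    if missing:
        raise ValueError(f"posts reference unknown participants: {sorted(missing)[:5]}")
    age = meta.loc[posts["participant_id"], "age_at_interview"].to_numpy(dtype=float)
    if np.isnan(age).any():
        raise ValueError("participant without age_at_interview")
    interview = pd.to_datetime(
        meta.loc[posts["participant_id"], "interview_date"], utc=True
    ).astype("int64").to_numpy() / 1e9
    if np.isnan(interview).any():
        raise ValueError("participant without interview_date")
    years_before = (interview - posts["timestamp"].to_numpy(dtype=float)) / (365.25 * 86400)
    return np.maximum(age - years_before, 0.0)


@dataclass
class FeatureSpace:
    """Fitted feature transformations (text vocabularies, age bounds, levels)."""

    ngram_range: tuple[int, int] = (1, 3)
    min_df: int = 2
    cluster_table: dict[str, str] = dataclass_field(default_factory=load_cluster_table)
    _lemma_vec: TfidfVectorizer | None = None
    _cluster_vec: TfidfVectorizer | None = None
    age_bounds: tuple[float, float] = (0.0, 1.0)
    gender_levels: tuple[str, ...] = ()
    group_levels: tuple[str, ...] = ()

    @property
    def fitted(self) -> bool:
        return self._lemma_vec is not None

    @property
    def lemma_vocab(self) -> dict[str, int]:
        return dict(self._lemma_vec.vocabulary_)

    @property
    def cluster_vocab(self) -> dict[str, int]:
        return dict(self._cluster_vec.vocabulary_)

    def column_names(self) -> list[str]:
        lemma = [f"lemma:{t}" for t, _ in sorted(self.lemma_vocab.items(), key=lambda kv: kv[1])]
        clusters = [f"cluster:{t}" for t, _ in sorted(self.cluster_vocab.items(), key=lambda kv: kv[1])]
        onehot = [f"gender:{g}" for g in self.gender_levels] + [f"group:{g}" for g in self.group_levels]
        return lemma + clusters + ["age"] + onehot

    def fit(self, posts: pd.DataFrame, participants: pd.DataFrame) -> "FeatureSpace":
        if self.fitted:
            raise RuntimeError("FeatureSpace is fitted exactly once")
        if len(posts) < 2:
            raise ValueError("need at least 2 training posts")
        self._lemma_vec = TfidfVectorizer(
            token_pattern=r"(?u)\S+",
            lowercase=False,
            ngram_range=self.ngram_range,
            min_df=self.min_df,
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )
        self._cluster_vec = TfidfVectorizer(
            token_pattern=r"(?u)\S+",
            lowercase=False,
            ngram_range=(1, 1),
            min_df=self.min_df,
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )
        lemma_docs = [_lemma_doc(t) for t in posts["text"]]
        cluster_docs = [_cluster_doc(t, self.cluster_table) for t in posts["text"]]
        try:
            self._lemma_vec.fit(lemma_docs)
            self._cluster_vec.fit(cluster_docs)
        except ValueError as exc:
            raise ValueError("degenerate training set: no vocabulary survives min_df") from exc

        age = _age_at_posting(posts, participants)
        self.age_bounds = (float(age.min()), float(age.max()))
        meta = participants.set_index("id")
        train_meta = meta.loc[pd.unique(posts["participant_id"])]
        self.gender_levels = tuple(sorted(train_meta["gender"].astype(str).unique()))
        self.group_levels = tuple(sorted(train_meta["group"].astype(str).unique()))
        return self

    def transform(self, posts: pd.DataFrame, participants: pd.DataFrame) -> sp.csr_matrix:
        if not self.fitted:
            raise RuntimeError("FeatureSpace must be fitted first")
        lemma = self._lemma_vec.transform([_lemma_doc(t) for t in posts["text"]])
        clusters = self._cluster_vec.transform(
            [_cluster_doc(t, self.cluster_table) for t in posts["text"]]
        )
        age = _age_at_posting(posts, participants)
        lo, hi = self.age_bounds
        scaled = np.clip((age - lo) / (hi - lo), 0.0, 1.0) if hi > lo else np.zeros_like(age)

        meta = participants.set_index("id")
        gender = meta.loc[posts["participant_id"], "gender"].astype(str).to_numpy()
        group = meta.loc[posts["participant_id"], "group"].astype(str).to_numpy()
        onehot_cols = [
            (gender == level).astype(float) for level in self.gender_levels
        ] + [(group == level).astype(float) for level in self.group_levels]
        dense = np.column_stack([scaled, *onehot_cols]) if onehot_cols else scaled[:, None]
        return sp.hstack([lemma, clusters, sp.csr_matrix(dense)], format="csr")


def fit_feature_space(
    train_posts: pd.DataFrame,
    train_participants: pd.DataFrame,
    cluster_table: dict[str, str] | None = None,
    ngram_range: tuple[int, int] = (1, 3),
    min_df: int = 2,
) -> FeatureSpace:
    """Fit all feature transformations on training data."""
    space = FeatureSpace(
        ngram_range=ngram_range,
        min_df=min_df,
        cluster_table=cluster_table if cluster_table is not None else load_cluster_table(),
    )
    return space.fit(train_posts, train_participants)


def build_features(
    posts: pd.DataFrame, participants: pd.DataFrame, space: FeatureSpace
) -> sp.csr_matrix:
    """Transform posts into the fitted feature space (training IDFs/bounds)."""
    return space.transform(posts, participants)
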