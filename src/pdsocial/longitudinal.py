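"""Pre/post-diagnosis phase assignment and normalized posting summaries.

PD-related content is normalized by post volume, not account age:

    percentage = 100 * (PD-related posts) / (total posts)

computed overall, pre-diagnosis and post-diagnosis (post date strictly
before the diagnosis date is "pre"; the diagnosis day itself counts as
"post").  Participants without a diagnosis date (typically caregivers)
contribute to "overall" only.  A timeframe with zero posts has an
*undefined* percentage (NaN, never zero), and such participants drop out of
that cell of the cohort table and of paired statistics.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .features import clean_for_model

log = logging.getLogger(__name__)

__all__ = [
    "pd_percentage",
    "assign_phase",
    "TimeframeSummary",
    "participant_summary",
    "cohort_table",
    "keyword_frequencies",
]

_SECONDS_PER_YEAR = 365.25 * 86400


def pd_percentage(n_pd: float, n_total: float) -> float:
    """100 * n_pd / n_total; undefined (NaN) when the timeframe has no posts."""
    if n_total == 0:
        return float("nan")
    return 100.0 * n_pd / n_total


def parse_diagnosis_date(value) -> float:
    """Diagnosis date -> epoch seconds (UTC midnight); NaN when missing.

    Year-only values are coerced to July 1 of that year (diagnosis recall is
    often year-granular) with a log message.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return float("nan")
    if text.isdigit() and len(text) == 4:
        log.info("year-only diagnosis date %s coerced to %s-07-01", text, text)
        text = f"{text}-07-01"
    moment = datetime.fromisoformat(text)
    if moment.tzinfo is None:
        moment = moment.replace(tzinfo=timezone.utc)
    return moment.timestamp()


def assign_phase(timestamp: float, diagnosis_date) -> str:
    """'pre' | 'post' | 'unknown' for one post.

    The diagnosis day itself counts as post-diagnosis (day-level resolution
    is all the metadata offers, and the boundary must be fixed).
    """
    dx = parse_diagnosis_date(diagnosis_date)
    if np.isnan(dx):
        return "unknown"
    post_day = datetime.fromtimestamp(timestamp, tz=timezone.utc).date()
    dx_day = datetime.fromtimestamp(dx, tz=timezone.utc).date()
    return "pre" if post_day < dx_day else "post"


@dataclass
class TimeframeSummary:
    """Per-participant counts and percentages by timeframe."""

    participant_id: str
    group: str
    n_posts: int
    n_pd: int
    pct: float
    n_posts_pre: int
    n_pd_pre: int
    pct_pre: float
    n_posts_post: int
    n_pd_post: int
    pct_post: float
    # same fields with exercise-only posts excluded from the PD counts
    pct_excl: float
    pct_pre_excl: float
    pct_post_excl: float
    account_span_years: float
    years_pre_diagnosis: float


def participant_summary(
    flags: pd.DataFrame, participant: pd.Series | dict
) -> TimeframeSummary:
    """Summarize one participant's flags into per-timeframe percentages.

    ``flags`` must be the participant's rows (post_id, timestamp, pd_related,
    exercise_only).  Account span is (last - first post)/365.25 d; years
    pre-diagnosis is (diagnosis - first post)/365.25 d floored at 0.
    """
    pid = participant["id"]
    group = participant["group"]
    dx = parse_diagnosis_date(participant.get("diagnosis_date"))

    n = len(flags)
    if n == 0:
        nan = float("nan")
        return TimeframeSummary(pid, group, 0, 0, nan, 0, 0, nan, 0, 0, nan, nan, nan, nan, nan, nan)

    ts = flags["timestamp"].to_numpy(dtype=float)
    related = flags["pd_related"].to_numpy(dtype=bool)
    related_excl = related & ~flags["exercise_only"].to_numpy(dtype=bool)

    if np.isnan(dx):
        phase = np.full(n, "unknown", dtype=object)
    else:
        days = ts // 86400
        dx_day = dx // 86400
        phase = np.where(days < dx_day, "pre", "post").astype(object)
    pre = phase == "pre"
    post = phase == "post"

    span = (ts.max() - ts.min()) / _SECONDS_PER_YEAR
    years_pre = max(0.0, (dx - ts.min()) / _SECONDS_PER_YEAR) if not np.isnan(dx) else float("nan")

    return TimeframeSummary(
        participant_id=pid,
        group=group,
        n_posts=n,
        n_pd=int(related.sum()),
        pct=pd_percentage(related.sum(), n),
        n_posts_pre=int(pre.sum()),
        n_pd_pre=int(related[pre].sum()),
        pct_pre=pd_percentage(related[pre].sum(), pre.sum()),
        n_posts_post=int(post.sum()),
        n_pd_post=int(related[post].sum()),
        pct_post=pd_percentage(related[post].sum(), post.sum()),
        pct_excl=pd_percentage(related_excl.sum(), n),
        pct_pre_excl=pd_percentage(related_excl[pre].sum(), pre.sum()),
        pct_post_excl=pd_percentage(related_excl[post].sum(), post.sum()),
        account_span_years=float(span),
        years_pre_diagnosis=float(years_pre),
    )


def summaries_frame(summaries: list[TimeframeSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def cohort_table(summaries: list[TimeframeSummary]) -> pd.DataFrame:
    """Group x timeframe aggregate: N, mean percent, SD.

    Participants with an undefined percentage for a timeframe are excluded
    from that cell; a single-participant cell reports SD as NaN (printed
    elsewhere as "NA"); rows cover both the all-posts and exercise-excluded
    variants.
    """
    frame = summaries_frame(summaries)
    rows = []
    variants = (
        ("all", {"overall": "pct", "pre": "pct_pre", "post": "pct_post"}),
        ("excluding_exercise", {"overall": "pct_excl", "pre": "pct_pre_excl", "post": "pct_post_excl"}),
    )
    for variant, columns in variants:
        for group, block in frame.groupby("group", sort=True):
            for timeframe, column in columns.items():
                values = block[column].dropna()
                rows.append(
                    {
                        "variant": variant,
                        "group": group,
                        "timeframe": timeframe,
                        "n": int(len(values)),
                        "mean_pct": float(values.mean()) if len(values) else float("nan"),
                        "sd_pct": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def keyword_frequencies(
    flags: pd.DataFrame,
    posts: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    group: str | None = None,
    phase: str | None = None,
    top_k: int = 20,
) -> list[tuple[str, int]]:
    """Most frequent tokens in PD-related posts for a stratum.

    Tokens come from the model cleaning pipeline; ties are broken
    lexicographically.  An empty stratum yields an empty list.
    """
    merged = flags.merge(posts[["post_id", "text"]], on="post_id")
    mask = merged["pd_related"].to_numpy(dtype=bool)
    if group is not None:
        if participants is None:
            raise ValueError("participants metadata is required to filter by group")
        meta = participants.set_index("id")
        mask &= (meta.loc[merged["participant_id"], "group"] == group).to_numpy()
        if phase is not None:
            dx = meta.loc[merged["participant_id"], "diagnosis_date"].map(parse_diagnosis_date).to_numpy()
            days = merged["timestamp"].to_numpy(dtype=float) // 86400
            with np.errstate(invalid="ignore"):
                is_pre = days < (dx // 86400)
            known = ~np.isnan(dx)
            mask &= known & (is_pre if phase == "pre" else ~is_pre)
    elif phase is not None:
        raise ValueError("phase filtering requires a group and participants metadata")

    counts: Counter[str] = Counter()
    for text in merged.loc[mask, "text"]:
        counts.update(clean_for_model(text))
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:top_k]
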