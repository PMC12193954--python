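"""Synthetic movement-disorder cohorts with Facebook-export-style archives.

Real donated archives cannot be shared, so every downstream stage is tested
against generated data with known ground truth.  The generator emulates the
study conditions: a cohort of people with Parkinson's disease (PD),
essential tremor (ET), atypical parkinsonism (AP) and caregivers (CG);
account spans of roughly 14 +/- 3 years with diagnosis about 5 years after
account creation (90% of accounts predate diagnosis); thousands of posts per
participant; PD-related content at phase-specific rates (defaults: PD 1.7%
pre- and 4.0% post-diagnosis); multi-file JSON archives with deliberate
overlap, exact and near duplicates, reshared "memories" carrying "N years
ago" stamps, and occasional encoding corruption.

Post texts are built from templates that embed dictionary terms: PD-related
templates carry symptom/medication/advocacy/exercise vocabulary, and a
configurable share of irrelevant templates embeds the same terms in non-PD
contexts ("I fell in love"), so the classification task is non-trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import NEAR_DUPLICATE_WINDOW_S, make_post_id

__all__ = [
    "SynthConfig",
    "Cohort",
    "generate_cohort",
    "generate_labeled_corpus",
    "inject_duplicates",
    "write_export",
    "simulate_archives",
]

YEAR_S = int(365.25 * 86400)

GROUPS = ("PD", "ET", "AP", "CG")

#: Retained event kinds: what the deduplicator is expected to keep.
RETAINED_KINDS = ("original", "reshare")


# ---------------------------------------------------------------------------
# Template pools
# ---------------------------------------------------------------------------

_SYMPTOM_SLOT = (
    "tremor", "stiffness", "dizziness", "fatigue", "cramps", "numbness",
    "tingling", "weakness", "drooling", "dyskinesia",
)
_MED_SLOT = (
    "carbidopa", "levodopa", "sinemet", "rasagiline", "amantadine",
    "ropinirole", "pramipexole", "rytary", "azilect", "neupro",
)

_PD_TEMPLATES = (
    "My {sym} was worse this morning, could barely hold my coffee",
    "Started a new dose of {med} today, fingers crossed it helps",
    "The neurologist says my {sym} is finally responding to the meds",
    "Follow-up at the movement disorder clinic went well, {med} dose unchanged",
    "Anyone else get {sym} at night? My doctor wants to adjust my prescription",
    "Freezing up in doorways again, this disease is humbling",
    "My handwriting keeps shrinking, the doctor called it micrographia",
    "Speech therapy is helping, my voice is stronger every week",
    "Deep brain stimulation consult next month, nervous but hopeful",
    "Support group tonight at 7, caregivers and care partners welcome",
    "Join our team for Moving Day, walking to fund research for a cure",
    "Proud to volunteer at the foundation fundraiser this weekend",
    "The wearing off between doses hit hard at dinner tonight",
    "Fell in the kitchen yesterday, the tremor threw my balance off",
    "Swallowing has been difficult this week, seeing the specialist Friday",
    "Insomnia again, third sleepless night with restless legs",
    "Physical therapy twice a week now for the stiffness and balance",
    "My café order shook right out of my hand, the tremor’s winning today",
    "Enrolled in a clinical trial for a new dopamine agonist",
    "Grateful for my care partner, couldn’t manage these symptoms alone",
)

_EXPLICIT_TEMPLATES = (
    "Parkinson’s walk on Saturday, come support the tulip drive",
    "My PD meds changed again, hoping for fewer side effects this time",
    "Five years since my Parkinson’s diagnosis and still fighting",
    "Our PD support group meets Thursday, newcomers welcome",
    "Reading everything I can about Parkinson disease research these days",
)

_EXERCISE_TEMPLATES = (
    "Rock Steady Boxing tonight, best workout of the week",
    "Morning yoga then coffee with the girls",
    "Twenty miles on the bike today, the cycling crew keeps me honest",
    "Hit the gym early for a treadmill session",
    "Tai chi in the park, so peaceful this morning",
    "Signed up for the spring 5k with my neighbors",
    "Zumba class had me laughing the whole hour",
    "Stretching and pilates to start the day right",
    "Long hike on the ridge trail, my legs are jelly",
    "Dance class with my sweetheart every Thursday now",
)

_AMBIGUOUS_TEMPLATES = (
    "I fell in love with this little café downtown",
    "Dead tired after chasing the grandkids all weekend",
    "Shaking off a rough week with ice cream and a movie",
    "Slow cooker pot roast for Sunday dinner, recipe in the comments",
    "My memory of that summer at the lake is still so vivid",
    "Stiff competition at trivia night but we took second place",
    "Can’t sleep, too excited for the wedding tomorrow",
    "The pipes burst again, what a pain this old house is",
    "Took a hard fall at the skating rink, just bruises thankfully",
    "Doctor Who marathon this weekend, who’s in?",
    "The hospital drama finale had me in tears",
    "Balance the checkbook day, my least favorite chore",
    "Traffic was exhausting, two hours to get across town",
    "Dropped my phone and now the screen is frozen, so frustrating",
    "Dance class recital photos are up, the kids were adorable",
    "The garden is sleeping for the winter, see you in spring",
    "Fell asleep during the movie again, getting old I guess",
    "This cold medicine makes me so dizzy",
    "The appointment at the DMV took all afternoon",
    "My knees ache when it rains, getting old isn’t for sissies",
)

_PLAIN_TEMPLATES = (
    "Happy birthday to my wonderful niece, love you bunches",
    "Beautiful sunset at the beach tonight",
    "Go Dawgs! What a game that was",
    "Who has a good zucchini bread recipe to share?",
    "Garage sale Saturday morning, everything must go",
    "Congratulations to the graduating seniors of 2015!",
    "First tomatoes from the garden, summer is here",
    "The grandkids’ school play was the cutest thing ever",
    "Book club picked a mystery novel this month",
    "Road trip photos finally uploaded, what a vacation",
    "Volleyball league starts Tuesday night",
    "New coffee shop downtown has the best pie",
    "Thankful for family and friends this Thanksgiving",
    "Snow day! The whole neighborhood is out sledding",
    "Our anniversary dinner was perfect, twenty five years",
    "The concert last night was unforgettable",
    "Puppy update: he finally learned to sit",
    "Spring cleaning day two, the closet is winning",
    "The mountains were breathtaking this weekend",
    "Movie night with popcorn and the classics",
)


def _render(templates, n_fill: int = 0):
    pool = []
    for template in templates:
        if "{sym}" in template:
            pool.extend(template.format(sym=s) for s in _SYMPTOM_SLOT)
        elif "{med}" in template:
            pool.extend(template.format(med=m) for m in _MED_SLOT)
        else:
            pool.append(template)
    return tuple(pool)


PD_POOL = _render(_PD_TEMPLATES)
EXPLICIT_POOL = _render(_EXPLICIT_TEMPLATES)
EXERCISE_POOL = _render(_EXERCISE_TEMPLATES)
AMBIGUOUS_POOL = _render(_AMBIGUOUS_TEMPLATES)
PLAIN_POOL = _render(_PLAIN_TEMPLATES)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_rate_pre():
    return {"PD": 0.017, "ET": 0.010, "AP": 0.093, "CG": 0.011}


def _default_rate_post():
    return {"PD": 0.040, "ET": 0.007, "AP": 0.049, "CG": 0.010}


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the cohort that shared archives (30 PD, 3 ET, 1 AP,
    12 CG), 14 +/- 3 account-years, 4018 +/- 5570 posts per participant
    (lognormal, moment matched), diagnosis 5 +/- 6 years after account
    creation with 90% of accounts predating diagnosis, and phase-specific
    PD-content rates per group.
    """

    n_pd: int = 30
    n_et: int = 3
    n_ap: int = 1
    n_cg: int = 12
    years_active: tuple[float, float] = (14.0, 3.0)
    posts_per_participant: tuple[float, float] = (4018.0, 5570.0)
    years_pre_diagnosis: tuple[float, float] = (5.0, 6.0)
    rate_pre: dict[str, float] = field(default_factory=_default_rate_pre)
    rate_post: dict[str, float] = field(default_factory=_default_rate_post)
    exercise_fraction: float = 0.45
    explicit_fraction: float = 0.15
    ambient_hit_rate: float = 0.15
    cg_diagnosis_rate: float = 0.75
    account_before_diagnosis_rate: float = 0.9
    comment_fraction: float = 0.3
    dup_exact_rate: float = 0.08
    dup_near_rate: float = 0.04
    reshare_rate: float = 0.03
    memory_rate: float = 0.05
    mojibake_rate: float = 0.02
    overlap_fraction: float = 0.2
    min_posts: int = 5
    interview_date: str = "2024-06-15"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("n_pd", "n_et", "n_ap", "n_cg", "min_posts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.posts_per_participant[0] <= 0:
            raise ValueError("posts_per_participant mean must be > 0")
        rate_fields = (
            "exercise_fraction", "explicit_fraction", "ambient_hit_rate",
            "cg_diagnosis_rate", "account_before_diagnosis_rate",
            "comment_fraction", "dup_exact_rate", "dup_near_rate",
            "reshare_rate", "memory_rate", "mojibake_rate", "overlap_fraction",
        )
        for name in rate_fields:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for rates in (self.rate_pre, self.rate_post):
            for group, value in rates.items():
                if group not in GROUPS:
                    raise ValueError(f"unknown group {group!r}")
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"rate for {group} must be in [0, 1]")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def replace(self, **updates) -> "SynthConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(updates)
        return SynthConfig(**current)


@dataclass
class Cohort:
    """A generated cohort: metadata, event stream, and ground truth."""

    participants: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame

    @property
    def expected_post_count(self) -> int:
        """Number of posts the deduplicator is expected to recover."""
        return int(self.events["dup_kind"].isin(RETAINED_KINDS).sum())


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_AGE_PARAMS = {"PD": (69.2, 10.1), "ET": (54.1, 25.1), "AP": (68.6, 15.8), "CG": (62.6, 13.8)}
_WOMEN_SHARE = {"PD": 0.34, "ET": 0.0, "AP": 0.33, "CG": 0.80}


def _lognormal(rng, mean, sd, size):
    if sd <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _epoch(date_str: str) -> int:
    return int(datetime.fromisoformat(date_str).replace(tzinfo=timezone.utc).timestamp())


def _draw_years_pre(rng, config, span_years) -> float:
    """Years between account creation and diagnosis (negative: account after dx)."""
    if rng.random() < config.account_before_diagnosis_rate:
        mean, sd = config.years_pre_diagnosis
        upper = max(0.4, span_years - 0.2)
        for _ in range(200):
            draw = rng.normal(mean, sd)
            if 0.3 <= draw <= upper:
                return float(draw)
        return float(min(max(mean, 0.3), upper))
    return float(-rng.uniform(0.5, 4.0))


def _make_participants(config: SynthConfig, rng) -> pd.DataFrame:
    rows = []
    interview_ts = _epoch(config.interview_date)
    counts = {"PD": config.n_pd, "ET": config.n_et, "AP": config.n_ap, "CG": config.n_cg}
    idx = 0
    for group in GROUPS:
        for _ in range(counts[group]):
            idx += 1
            pid = f"p{idx:03d}"
            mean_age, sd_age = _AGE_PARAMS[group]
            age = float(np.clip(rng.normal(mean_age, sd_age), 25.0, 95.0))
            gender = "F" if rng.random() < _WOMEN_SHARE[group] else "M"
            span = float(np.clip(rng.normal(*config.years_active), 1.0, 19.0))
            account_start = interview_ts - int(span * YEAR_S)
            has_dx = group != "CG" or rng.random() < config.cg_diagnosis_rate
            if has_dx:
                years_pre = _draw_years_pre(rng, config, span)
                dx_ts = account_start + int(years_pre * YEAR_S)
                dx_date = datetime.fromtimestamp(dx_ts, tz=timezone.utc).date().isoformat()
            else:
                dx_ts = np.nan
                dx_date = ""
            rows.append(
                {
                    "id": pid,
                    "group": group,
                    "gender": gender,
                    "age_at_interview": round(age, 1),
                    "interview_date": config.interview_date,
                    "diagnosis_date": dx_date,
                    "_interview_ts": interview_ts,
                    "_account_start_ts": account_start,
                    "_diagnosis_ts": dx_ts,
                }
            )
    return pd.DataFrame(rows)


def _choose_texts(rng, is_pd, is_exercise, is_explicit, ambient):
    texts = np.empty(len(is_pd), dtype=object)
    for mask, pool in (
        (is_pd & is_exercise, EXERCISE_POOL),
        (is_pd & ~is_exercise & is_explicit, EXPLICIT_POOL),
        (is_pd & ~is_exercise & ~is_explicit, PD_POOL),
        (~is_pd & ambient, AMBIGUOUS_POOL),
        (~is_pd & ~ambient, PLAIN_POOL),
    ):
        k = int(mask.sum())
        if k:
            picks = rng.integers(0, len(pool), k)
            texts[mask] = [pool[j] for j in picks]
    return texts


def _space_out(frame: pd.DataFrame) -> pd.DataFrame:
    """Force >= 180 s between occurrences of the same text (retained events).

    Guarantees the ground truth equals what the deduplicator must recover:
    without spacing, two independently generated identical texts falling
    within the near-duplicate window would be (correctly) merged by the
    deduplicator but counted twice in the truth.
    """
    frame = frame.sort_values("timestamp", kind="stable").reset_index(drop=True)
    last: dict[str, int] = {}
    ts = frame["timestamp"].to_numpy().copy()
    texts = frame["text"].tolist()
    for i, text in enumerate(texts):
        prev = last.get(text)
        if prev is not None and ts[i] - prev < NEAR_DUPLICATE_WINDOW_S:
            ts[i] = prev + NEAR_DUPLICATE_WINDOW_S
        last[text] = int(ts[i])
    frame["timestamp"] = ts
    return frame.sort_values("timestamp", kind="stable").reset_index(drop=True)


def _participant_events(config: SynthConfig, rng, participant) -> pd.DataFrame:
    group = participant["group"]
    n_posts = int(max(config.min_posts, round(_lognormal(rng, *config.posts_per_participant, 1)[0])))
    start = participant["_account_start_ts"]
    end = participant["_interview_ts"]
    ts = np.sort(rng.integers(start, end, n_posts))

    dx_ts = participant["_diagnosis_ts"]
    if np.isnan(dx_ts):
        phase = np.full(n_posts, "unknown", dtype=object)
        rate = np.full(n_posts, (config.rate_pre[group] + config.rate_post[group]) / 2.0)
    else:
        pre = ts < dx_ts
        phase = np.where(pre, "pre", "post").astype(object)
        rate = np.where(pre, config.rate_pre[group], config.rate_post[group])

    is_pd = rng.random(n_posts) < rate
    is_exercise = is_pd & (rng.random(n_posts) < config.exercise_fraction)
    is_explicit = rng.random(n_posts) < config.explicit_fraction
    ambient = rng.random(n_posts) < config.ambient_hit_rate
    texts = _choose_texts(rng, is_pd, is_exercise, is_explicit, ambient)

    frame = pd.DataFrame(
        {
            "participant_id": participant["id"],
            "timestamp": ts.astype(np.int64),
            "text": texts,
            "kind": np.where(rng.random(n_posts) < config.comment_fraction, "comment", "post"),
            "dup_kind": "original",
            "is_memory": rng.random(n_posts) < config.memory_rate,
            "is_mojibake": rng.random(n_posts) < config.mojibake_rate,
            "phase": phase,
            "is_pd": is_pd,
            "is_exercise": is_exercise,
        }
    )
    return _space_out(frame)


def inject_duplicates(events: pd.DataFrame, config: SynthConfig, rng) -> pd.DataFrame:
    """Add export artifacts to a time-sorted event stream.

    Reshares (>= 180 s later; retained by the deduplicator, so they carry
    their own ground-truth label) are added first and the spacing invariant
    re-imposed; exact copies (same timestamp and text) and near copies
    (< 180 s) are then attached to final timestamps.  ``dup_kind`` marks
    which rows the deduplicator must remove ("exact"/"near").
    """
    if events.empty:
        return events.copy()

    base = events.copy()
    reshare_mask = rng.random(len(base)) < config.reshare_rate
    reshares = base.loc[reshare_mask].copy()
    if len(reshares):
        offsets = rng.integers(200, 200 + 90 * 86400, len(reshares))
        reshares["timestamp"] = reshares["timestamp"].to_numpy() + offsets
        reshares["dup_kind"] = "reshare"
    retained = _space_out(pd.concat([base, reshares], ignore_index=True))

    copies = []
    for rate, kind, lo, hi in (
        (config.dup_exact_rate, "exact", 0, 1),
        (config.dup_near_rate, "near", 1, NEAR_DUPLICATE_WINDOW_S),
    ):
        mask = rng.random(len(retained)) < rate
        block = retained.loc[mask].copy()
        if len(block):
            block["timestamp"] = block["timestamp"].to_numpy() + rng.integers(lo, hi, len(block))
            block["dup_kind"] = kind
            copies.append(block)

    out = pd.concat([retained, *copies], ignore_index=True)
    return out.sort_values(["timestamp", "text"], kind="stable").reset_index(drop=True)


def generate_cohort(config: SynthConfig | None = None) -> Cohort:
    """Generate participants, per-participant event streams, and ground truth.

    Ground-truth labels cover exactly the events the deduplicator retains
    (originals and deliberate reshares); injected exact/near duplicates carry
    no label because they must disappear during ingestion.
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants = _make_participants(config, rng)

    frames = []
    for _, participant in participants.iterrows():
        events = _participant_events(config, rng, participant)
        frames.append(inject_duplicates(events, config, rng))
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame(
            columns=[
                "participant_id", "timestamp", "text", "kind", "dup_kind",
                "is_memory", "is_mojibake", "phase", "is_pd", "is_exercise",
            ]
        )

    events["post_id"] = [
        make_post_id(pid, int(ts), text)
        for pid, ts, text in zip(events["participant_id"], events["timestamp"], events["text"])
    ]
    retained = events[events["dup_kind"].isin(RETAINED_KINDS)]
    truth = pd.DataFrame(
        {
            "post_id": retained["post_id"].to_numpy(),
            "is_pd_related": retained["is_pd"].to_numpy(),
            "is_exercise": retained["is_exercise"].to_numpy(),
        }
    )
    return Cohort(participants=participants, events=events, truth=truth)


# ---------------------------------------------------------------------------
# Export writing
# ---------------------------------------------------------------------------

_MEMORY_PREFIXES = ("{n} years ago ", "{n} years ago: ", "{n} months ago ")


def _render_text(row, rng) -> str:
    text = row.text
    if row.is_memory:
        prefix = _MEMORY_PREFIXES[rng.integers(0, len(_MEMORY_PREFIXES))]
        text = prefix.format(n=int(rng.integers(1, 11))) + text
    if row.is_mojibake:
        # UTF-8 bytes mis-read as Latin-1; a no-op for pure-ASCII text.
        text = text.encode("utf-8").decode("latin-1")
    return text


def write_export(
    participant_id: str,
    events: pd.DataFrame,
    out_dir: str | Path,
    rng=None,
    overlap_fraction: float = 0.2,
) -> list[Path]:
    """Write one participant's events as a multi-file JSON archive.

    Produces ``posts.json``, ``comments.json`` and text-free ``pages.json``/
    ``groups.json``.  A fraction of posts is deliberately duplicated into
    ``comments.json`` (files are not mutually exclusive); memory posts get an
    "N years ago" prefix and mojibake rows are written double-encoded.
    """
    if events.empty:
        raise ValueError("cannot write an export for an empty event stream")
    if rng is None:
        rng = np.random.default_rng(0)
    directory = Path(out_dir) / participant_id
    directory.mkdir(parents=True, exist_ok=True)

    rendered = {idx: _render_text(row, rng) for idx, row in enumerate(events.itertuples(index=False))}
    kinds = events["kind"].to_numpy()
    timestamps = events["timestamp"].to_numpy()

    posts_payload = [
        {"timestamp": int(timestamps[i]), "data": [{"post": rendered[i]}]}
        for i in range(len(events))
        if kinds[i] == "post"
    ]
    comments_payload = [
        {"timestamp": int(timestamps[i]), "comment": {"comment": rendered[i]}}
        for i in range(len(events))
        if kinds[i] != "post"
    ]
    # Deliberate cross-file overlap: some posts also appear in comments.json.
    post_indices = [i for i in range(len(events)) if kinds[i] == "post"]
    n_overlap = int(round(overlap_fraction * len(post_indices)))
    if n_overlap:
        chosen = rng.choice(len(post_indices), size=n_overlap, replace=False)
        for j in sorted(chosen):
            i = post_indices[j]
            comments_payload.append(
                {"timestamp": int(timestamps[i]), "comment": {"comment": rendered[i]}}
            )

    pages_payload = [{"name": "Local Community Events"}, {"name": "Neighborhood Watch"}]
    groups_payload = [{"name": "Recipe Swap", "member_count": 1204}]

    paths = []
    for name, payload in (
        ("posts.json", posts_payload),
        ("comments.json", comments_payload),
        ("pages.json", pages_payload),
        ("groups.json", groups_payload),
    ):
        path = directory / name
        path.write_text(json.dumps(payload, ensure_ascii=False, indent=1), "utf-8")
        paths.append(path)
    return paths


def simulate_archives(config: SynthConfig | None = None, out_dir: str | Path = "synthetic") -> Cohort:
    """Generate a cohort and write archives, participant table and labels.

    Layout: ``<out_dir>/archives/<pid>/*.json``, ``participants.tsv``
    (id, group, gender, age_at_interview, interview_date, diagnosis_date)
    and ``labels.tsv`` (post_id, is_pd_related, is_exercise).
    """
    config = config or SynthConfig()
    cohort = generate_cohort(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    for pid, group in cohort.events.groupby("participant_id", sort=True):
        write_export(pid, group, out / "archives", rng, config.overlap_fraction)
    cohort.participants.drop(columns=[c for c in cohort.participants if c.startswith("_")]).to_csv(
        out / "participants.tsv", sep="\t", index=False
    )
    cohort.truth.to_csv(out / "labels.tsv", sep="\t", index=False)
    return cohort


# ---------------------------------------------------------------------------
# Labeled corpus (ground-truth stand-in)
# ---------------------------------------------------------------------------


def generate_labeled_corpus(
    n_posts: int = 6750,
    pos_fraction: float = 0.356,
    exercise_fraction: float = 0.45,
    explicit_fraction: float = 0.10,
    n_pwpd: int = 14,
    n_cg: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A dictionary-bearing labeled corpus mirroring ground-truth construction.

    Every post contains at least one dictionary term: positives come from
    PD/exercise/advocacy templates, negatives exclusively from ambiguous
    templates (the annotated subset was selected by dictionary hit, so plain
    text never reaches the annotators).  Defaults mirror the annotated set:
    6750 posts by 14 PwPD and 5 caregivers, 35.6% labeled PD-related.

    Returns (posts, labels, participants).
    """
    rng = np.random.default_rng(seed)
    config = SynthConfig(
        n_pd=n_pwpd, n_et=0, n_ap=0, n_cg=n_cg,
        posts_per_participant=(max(1.0, n_posts / max(1, n_pwpd + n_cg)), 0.0),
        seed=seed,
    )
    participants = _make_participants(config, rng)

    n_pos = int(round(pos_fraction * n_posts))
    is_pd = np.zeros(n_posts, dtype=bool)
    is_pd[:n_pos] = True
    rng.shuffle(is_pd)
    is_exercise = is_pd & (rng.random(n_posts) < exercise_fraction)
    is_explicit = rng.random(n_posts) < explicit_fraction
    ambient = np.ones(n_posts, dtype=bool)  # negatives are always dictionary-bearing
    texts = _choose_texts(rng, is_pd, is_exercise, is_explicit, ambient)

    owner = rng.integers(0, len(participants), n_posts)
    start = participants["_account_start_ts"].to_numpy()[owner]
    end = participants["_interview_ts"].to_numpy()[owner]
    ts = (start + rng.random(n_posts) * (end - start)).astype(np.int64)
    pids = participants["id"].to_numpy()[owner]

    posts = pd.DataFrame(
        {
            "post_id": [make_post_id(p, int(t), x) for p, t, x in zip(pids, ts, texts)],
            "participant_id": pids,
            "timestamp": ts,
            "text": texts,
            "kind": "post",
        }
    )
    labels = pd.DataFrame(
        {"post_id": posts["post_id"], "is_pd_related": is_pd, "is_exercise": is_exercise}
    )
    return posts, labels, participants
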