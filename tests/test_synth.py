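import json

import numpy as np
import pandas as pd
import pytest

from pdsocial.ingest import deduplicate, read_export
from pdsocial.lexicon import dictionary_flag
from pdsocial.synth import (
    RETAINED_KINDS,
    Cohort,
    SynthConfig,
    generate_cohort,
    generate_labeled_corpus,
    inject_duplicates,
    simulate_archives,
    write_export,
)


def tiny_config(**overrides):
    base = dict(
        n_pd=2, n_et=0, n_ap=0, n_cg=1,
        posts_per_participant=(60.0, 20.0), seed=5,
    )
    base.update(overrides)
    return SynthConfig(**base)


# ---------------------------------------------------------------------------
# Configuration validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "bad",
    [
        {"n_pd": -1},
        {"posts_per_participant": (0.0, 1.0)},
        {"memory_rate": 1.5},
        {"rate_pre": {"PD": -0.1, "ET": 0, "AP": 0, "CG": 0}},
        {"seed": "nope"},
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        tiny_config(**bad)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def test_zero_rates_give_zero_pd_labels():
    zero = {g: 0.0 for g in ("PD", "ET", "AP", "CG")}
    cohort = generate_cohort(tiny_config(rate_pre=zero, rate_post=zero))
    assert not cohort.truth["is_pd_related"].any()


def test_labels_cover_exactly_the_retained_posts(small_cohort):
    retained = small_cohort.events[small_cohort.events["dup_kind"].isin(RETAINED_KINDS)]
    assert len(small_cohort.truth) == len(retained)
    assert small_cohort.truth["post_id"].is_unique


def test_realized_post_phase_rate_within_binomial_tolerance():
    rate = 0.04
    cohort = generate_cohort(
        tiny_config(n_pd=30, n_cg=0, posts_per_participant=(4000.0, 0.0),
                    rate_post={"PD": rate, "ET": 0, "AP": 0, "CG": 0})
    )
    events = cohort.events[cohort.events["dup_kind"] == "original"]
    post_phase = events[events["phase"] == "post"]
    n = len(post_phase)
    realized = post_phase["is_pd"].mean()
    sd = np.sqrt(rate * (1 - rate) / n)
    assert abs(realized - rate) < 3 * sd


def test_same_seed_reproduces_cohort_exactly():
    a = generate_cohort(tiny_config())
    b = generate_cohort(tiny_config())
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.participants, b.participants)


def test_account_creation_mostly_precedes_diagnosis():
    cohort = generate_cohort(tiny_config(n_pd=40, n_cg=0, seed=9))
    meta = cohort.participants
    before = (
        pd.to_datetime(meta["diagnosis_date"]).astype("int64") / 1e9
        > meta["_account_start_ts"]
    )
    assert before.mean() >= 0.75  # configured 90%, small-sample slack


# ---------------------------------------------------------------------------
# Duplicate injection
# ---------------------------------------------------------------------------


def base_events():
    return pd.DataFrame(
        {
            "participant_id": "p", "timestamp": [0, 1000, 5000],
            "text": ["alpha one", "beta two", "gamma three"],
            "kind": "post", "dup_kind": "original",
            "is_memory": False, "is_mojibake": False,
            "phase": "post", "is_pd": False, "is_exercise": False,
        }
    )


def test_zero_dup_rates_leave_events_unchanged():
    cfg = tiny_config(dup_exact_rate=0, dup_near_rate=0, reshare_rate=0)
    out = inject_duplicates(base_events(), cfg, np.random.default_rng(0))
    assert list(out["dup_kind"]) == ["original"] * 3


def test_exact_copies_are_marked_removable():
    cfg = tiny_config(dup_exact_rate=1.0, dup_near_rate=0, reshare_rate=0)
    out = inject_duplicates(base_events(), cfg, np.random.default_rng(0))
    assert (out["dup_kind"] == "exact").sum() == 3
    exact = out[out["dup_kind"] == "exact"]
    orig = out[out["dup_kind"] == "original"]
    assert set(zip(exact["timestamp"], exact["text"])) == set(zip(orig["timestamp"], orig["text"]))


def test_near_copy_removable_reshare_retained():
    cfg = tiny_config(dup_exact_rate=0, dup_near_rate=1.0, reshare_rate=1.0)
    out = inject_duplicates(base_events(), cfg, np.random.default_rng(1))
    # every original got one near copy (<180 s, removable) and one reshare (>=180 s)
    assert (out["dup_kind"] == "near").sum() == 6  # reshares also get near copies
    removable = out["dup_kind"].isin(["near", "exact"]).sum()
    retained = out["dup_kind"].isin(RETAINED_KINDS).sum()
    assert retained == 6 and removable == 6
    # dedup must recover exactly the retained events
    from pdsocial.ingest import RawEntry

    entries = [
        RawEntry("p", int(r.timestamp), r.text, "mem", "post")
        for r in out.itertuples()
    ]
    assert len(deduplicate(entries)) == retained


# ---------------------------------------------------------------------------
# Export writing
# ---------------------------------------------------------------------------


def test_export_conserves_texts_across_overlapping_files(tmp_path):
    cohort = generate_cohort(tiny_config(dup_exact_rate=0, dup_near_rate=0,
                                         reshare_rate=0, memory_rate=0, mojibake_rate=0))
    pid = cohort.participants["id"][0]
    events = cohort.events[cohort.events["participant_id"] == pid]
    write_export(pid, events, tmp_path, np.random.default_rng(0), overlap_fraction=0.2)
    harvested = read_export(tmp_path / pid, pid)
    assert {(e.timestamp, e.text) for e in harvested} == set(
        zip(events["timestamp"], events["text"])
    )


def test_memory_rate_one_prefixes_every_post(tmp_path):
    cohort = generate_cohort(tiny_config(memory_rate=1.0, mojibake_rate=0))
    pid = cohort.participants["id"][0]
    events = cohort.events[cohort.events["participant_id"] == pid]
    write_export(pid, events, tmp_path, np.random.default_rng(0))
    for entry in read_export(tmp_path / pid, pid):
        assert " ago" in entry.text


def test_mojibake_rate_one_corrupts_but_repairs(tmp_path):
    cohort = generate_cohort(tiny_config(mojibake_rate=1.0, memory_rate=0,
                                         dup_exact_rate=0, dup_near_rate=0, reshare_rate=0))
    pid = cohort.participants["id"][0]
    events = cohort.events[cohort.events["participant_id"] == pid]
    write_export(pid, events, tmp_path, np.random.default_rng(0), overlap_fraction=0.0)
    raw = json.loads((tmp_path / pid / "posts.json").read_text("utf-8"))
    originals = set(events.loc[events["kind"] == "post", "text"])
    written = {r["data"][0]["post"] for r in raw}
    # every non-ASCII text is corrupted on disk (ASCII is invariant under the transform)
    assert all(t not in originals for t in written if not t.isascii())
    assert any(not t.isascii() for t in written)
    # ...but ingestion repairs all of them exactly
    posts = deduplicate(read_export(tmp_path / pid, pid))
    assert {p.text for p in posts} == set(events["text"])


def test_simulate_archives_is_byte_identical_under_seed(tmp_path):
    cfg = tiny_config()
    simulate_archives(cfg, tmp_path / "a")
    simulate_archives(cfg, tmp_path / "b")
    files_a = sorted((tmp_path / "a").rglob("*.*"))
    files_b = sorted((tmp_path / "b").rglob("*.*"))
    assert [f.name for f in files_a] == [f.name for f in files_b]
    for fa, fb in zip(files_a, files_b):
        assert fa.read_bytes() == fb.read_bytes()


def test_dedup_recovers_expected_count_from_archives(tmp_path, small_config, small_cohort):
    simulate_archives(small_config, tmp_path)
    total = 0
    recovered_ids = set()
    for pid in small_cohort.participants["id"]:
        posts = deduplicate(read_export(tmp_path / "archives" / pid, pid))
        total += len(posts)
        recovered_ids.update(p.post_id for p in posts)
    assert total == small_cohort.expected_post_count
    assert recovered_ids == set(small_cohort.truth["post_id"])


# ---------------------------------------------------------------------------
# Labeled corpus
# ---------------------------------------------------------------------------


def test_labeled_corpus_shape_and_prevalence(dictionary):
    posts, labels, participants = generate_labeled_corpus(n_posts=900, seed=2)
    assert len(posts) == len(labels) == 900
    prevalence = labels["is_pd_related"].mean()
    assert abs(prevalence - 0.356) < 0.01
    # the annotated subset is dictionary-selected: every post has a hit
    assert all(dictionary_flag(t, dictionary)[0] for t in posts["text"])


def test_labeled_positives_always_dictionary_flagged(dictionary):
    posts, labels, _ = generate_labeled_corpus(n_posts=600, seed=8)
    positives = posts.loc[labels["is_pd_related"].to_numpy(), "text"]
    assert all(dictionary_flag(t, dictionary)[0] for t in positives)
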