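"""End-to-end orchestration: simulate, ingest, train, flag, summarize, test.

A run is driven by a :class:`RunConfig` (loadable from YAML); every stage
logs counts in and out, and all randomness flows from the configured seed,
so a rerun of the same configuration reproduces its outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, flagging, longitudinal, stats, synth
from .features import fit_feature_space, load_cluster_table
from .ingest import deduplicate, read_export
from .lexicon import load_dictionary

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "simulate", "run"]


@dataclass
class RunConfig:
    """Paths, seeds and options for a pipeline run."""

    out_dir: str = "output"
    archives_dir: str | None = None
    participants_path: str | None = None
    labels_path: str | None = None
    dictionary_path: str | None = None
    cluster_table_path: str | None = None
    seed: int = 0
    test_fraction: float = 0.2
    threshold: float = 0.5
    bootstrap_b: int = 1000
    families: tuple[str, ...] | None = None
    grids: dict | None = None
    top_k_keywords: int = 20
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synth" in payload and isinstance(payload["synth"], dict):
            payload["synth"] = synth.SynthConfig(**payload["synth"])
        if "families" in payload and payload["families"] is not None:
            payload["families"] = tuple(payload["families"])
        return cls(**payload)


def simulate(config: RunConfig) -> synth.Cohort:
    """Write synthetic archives, participant table and labels under out_dir."""
    out = Path(config.out_dir)
    cohort = synth.simulate_archives(config.synth, out)
    realized = cohort.truth["is_pd_related"].mean() if len(cohort.truth) else float("nan")
    log.info(
        "simulate: %d participants, %d events (%d retained), PD-related rate %.4f",
        len(cohort.participants), len(cohort.events),
        cohort.expected_post_count, realized,
    )
    return cohort


def _ingest_corpus(archives_dir: Path, participants: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pid in participants["id"]:
        directory = archives_dir / pid
        if not directory.is_dir():
            log.warning("ingest: no archive directory for %s", pid)
            continue
        entries = read_export(directory, pid)
        posts = deduplicate(entries)
        log.info("ingest: %s %d entries -> %d posts", pid, len(entries), len(posts))
        rows.extend(vars(p) for p in posts)
    return pd.DataFrame(rows, columns=["post_id", "participant_id", "timestamp", "text", "kind"])


def _train(config: RunConfig, corpus: pd.DataFrame, participants, dictionary, labels):
    from .lexicon import dictionary_flag

    labeled = corpus.merge(labels, on="post_id")
    hit_mask = np.array([dictionary_flag(t, dictionary)[0] for t in labeled["text"]])
    labeled = labeled.loc[hit_mask].reset_index(drop=True)
    y = labeled["is_pd_related"].astype(int).to_numpy()
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        log.warning("train: not enough labeled dictionary-hit posts per class; skipping")
        return None, None, []

    train_idx, test_idx = classify.split_data(
        np.arange(len(y)), y, test_fraction=config.test_fraction, seed=config.seed
    )
    train_posts = labeled.iloc[train_idx]
    test_posts = labeled.iloc[test_idx]
    cluster_table = load_cluster_table(config.cluster_table_path)
    space = fit_feature_space(train_posts, participants, cluster_table=cluster_table)
    X_train = space.transform(train_posts, participants)
    X_test = space.transform(test_posts, participants)
    log.info("train: %d train / %d test labeled posts", len(train_idx), len(test_idx))

    candidates = classify.train_candidates(
        X_train, y[train_idx], families=config.families, grids=config.grids, seed=config.seed
    )
    candidates["ensemble"] = classify.build_ensemble(candidates)
    reports = [
        classify.evaluate(c, X_test, y[test_idx], B=config.bootstrap_b, seed=config.seed)
        for c in candidates.values()
    ]
    selected = classify.select_model(reports)
    log.info("train: selected %s (macro recall %.3f)", selected.family, selected.macro_recall)
    model = candidates[selected.family].estimator
    return model, space, reports


def run(config: RunConfig) -> dict:
    """Execute ingest -> lexicon -> train -> flag -> longitudinal -> stats.

    Returns the collected in-memory results and writes TSV/JSON reports
    under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.participants_path is None or config.archives_dir is None:
        raise ValueError("run requires archives_dir and participants_path")
    participants = pd.read_csv(
        config.participants_path, sep="\t", dtype={"id": str, "diagnosis_date": str}
    )
    participants["diagnosis_date"] = participants["diagnosis_date"].fillna("")

    corpus = _ingest_corpus(Path(config.archives_dir), participants)
    corpus.to_csv(out / "corpus.tsv", sep="\t", index=False)
    dictionary = load_dictionary(config.dictionary_path)

    model, space, reports = None, None, []
    if config.labels_path:
        labels = pd.read_csv(config.labels_path, sep="\t")
        model, space, reports = _train(config, corpus, participants, dictionary, labels)
    if reports:
        table = pd.DataFrame([r.to_dict() for r in reports]).drop(columns=["params"])
        table.sort_values("macro_recall", ascending=False).to_csv(
            out / "model_table.tsv", sep="\t", index=False
        )
        (out / "metrics.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=2, sort_keys=True, default=str)
        )

    flags = flagging.flag_corpus(
        corpus, dictionary, model=model, space=space,
        participants=participants, threshold=config.threshold,
    )
    export = flags.copy()
    export["matched_terms"] = export["matched_terms"].map(";".join)
    export.to_csv(out / "flags.tsv", sep="\t", index=False)
    log.info("flag: %d posts, %d PD-related", len(flags), int(flags["pd_related"].sum()))

    summaries = []
    for _, participant in participants.iterrows():
        block = flags[flags["participant_id"] == participant["id"]]
        summaries.append(longitudinal.participant_summary(block, participant))
    longitudinal.summaries_frame(summaries).to_csv(out / "summaries.tsv", sep="\t", index=False)
    table3 = longitudinal.cohort_table(summaries)
    table3.to_csv(out / "table3.tsv", sep="\t", index=False)

    keyword_rows = []
    for group in sorted(participants["group"].unique()):
        for phase in (None, "pre", "post"):
            ranked = longitudinal.keyword_frequencies(
                flags, corpus, participants, group=group, phase=phase,
                top_k=config.top_k_keywords,
            )
            stratum = group if phase is None else f"{group}_{phase}"
            keyword_rows.extend(
                {"stratum": stratum, "term": term, "count": count} for term, count in ranked
            )
    pd.DataFrame(keyword_rows, columns=["stratum", "term", "count"]).to_csv(
        out / "keywords.tsv", sep="\t", index=False
    )

    stat_results = _stats_battery(summaries)
    (out / "stats.json").write_text(json.dumps(stat_results, indent=2, sort_keys=True))

    summary = flagging.summarize_flags(flags, participants)
    return {
        "corpus": corpus,
        "flags": flags,
        "reports": reports,
        "model": model,
        "summaries": summaries,
        "cohort_table": table3,
        "stats": stat_results,
        "participant_summary": summary,
    }


def _paired(summaries, group, attr_pre, attr_post):
    pre = [getattr(s, attr_pre) for s in summaries if s.group == group]
    post = [getattr(s, attr_post) for s in summaries if s.group == group]
    return np.asarray(pre), np.asarray(post)


def _stats_battery(summaries) -> dict:
    results = {}
    for group in ("PD", "CG"):
        for label, attrs in (
            ("all", ("pct_pre", "pct_post")),
            ("excluding_exercise", ("pct_pre_excl", "pct_post_excl")),
        ):
            pre, post = _paired(summaries, group, *attrs)
            key = f"wilcoxon_{group.lower()}_{label}"
            try:
                results[key] = stats.wilcoxon_signed_rank(pre, post).to_dict()
            except ValueError as exc:
                results[key] = {"error": str(exc)}
    pd_pre = np.asarray([s.pct_pre for s in summaries if s.group == "PD"])
    cg_pre = np.asarray([s.pct_pre for s in summaries if s.group == "CG"])
    pd_pre = pd_pre[~np.isnan(pd_pre)]
    cg_pre = cg_pre[~np.isnan(cg_pre)]
    try:
        results["mann_whitney_pre_pd_vs_cg"] = stats.mann_whitney_u(pd_pre, cg_pre).to_dict()
    except ValueError as exc:
        results["mann_whitney_pre_pd_vs_cg"] = {"error": str(exc)}
    try:
        results["shapiro_pd_pre"] = stats.shapiro_wilk(pd_pre).to_dict()
    except ValueError as exc:
        results["shapiro_pd_pre"] = {"error": str(exc)}
    return results
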