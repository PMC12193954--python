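"""Generate a small synthetic cohort and write Facebook-export-style archives.

Each participant gets a directory of overlapping JSON files (posts,
comments, pages, groups) plus a ground-truth label table, so every later
stage can be checked against known answers.
"""

from pathlib import Path

from pdsocial import SynthConfig, simulate_archives

config = SynthConfig(
    n_pd=4, n_et=1, n_ap=1, n_cg=2,
    posts_per_participant=(200.0, 80.0),
    seed=7,
)
out = Path("scratch/example_cohort")
cohort = simulate_archives(config, out)

print(f"participants: {len(cohort.participants)}")
print(f"events written (incl. injected duplicates): {len(cohort.events)}")
print(f"unique posts a deduplicator should recover: {cohort.expected_post_count}")
print(f"PD-related ground-truth share: {cohort.truth['is_pd_related'].mean():.3f}")
print(f"archives under: {out / 'archives'}")
# The gap between events written and posts to recover is export noise:
# exact/near duplicates and cross-file overlap that ingestion must remove.
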