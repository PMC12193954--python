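"""Harvest an archive, repair encodings, strip memory stamps, deduplicate.

Run 01_simulate_archives.py first.  The recovered post count should equal
the generator's expected count exactly: every export artifact (duplicate
file entries, near-duplicate re-saves, "N years ago" memory stamps,
mojibake) is undone, while deliberate reshares >= 180 s apart survive.
"""

from pathlib import Path

import pandas as pd

from pdsocial import deduplicate, read_export

archives = Path("scratch/example_cohort/archives")
labels = pd.read_csv("scratch/example_cohort/labels.tsv", sep="\t")

total_entries = 0
posts = []
for directory in sorted(archives.iterdir()):
    entries = read_export(directory)
    total_entries += len(entries)
    posts.extend(deduplicate(entries))

print(f"raw harvested entries: {total_entries}")
print(f"posts after dedup:     {len(posts)}")
print(f"ground-truth posts:    {len(labels)}")
recovered = {p.post_id for p in posts} == set(labels["post_id"])
print(f"post ids match ground truth exactly: {recovered}")
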