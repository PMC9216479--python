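"""Collection-level summary tables.

Reproduces the release-note style reports: the provenance split with
percentages, the per-phylum composition at the sub-kingdom ranks, and the
sequence-length distribution — here from printed release counts (the
percentage arithmetic) and from a small synthetic build (the composition).
"""

import tempfile
from pathlib import Path

import yaml

from coiref import generate_corpus
from coiref.pipeline import load_config, run_pipeline
from coiref.summarize import composition_by_rank, provenance_table

# --- provenance arithmetic on the published release counts
summary = provenance_table(2_195_176, 201_719, 3_211_953, decimals=2, mode="truncate")
print(f"release total: {summary.total:,}")
for key, count in summary.counts.items():
    print(f"  {key}: {count:,} ({summary.percentages[key]}%)")

# --- composition and lengths of a synthetic build
workdir = Path(tempfile.mkdtemp(prefix="coiref_example_"))
generate_corpus(seed=3, outdir=workdir)
cfg = load_config(yaml.safe_load((workdir / "config.yaml").read_text()), workdir)
result = run_pipeline(cfg)

rows, totals = composition_by_rank(
    [result.resolutions[m.record_id].lineage for m in result.merged]
)
print("\nsynthetic collection composition (distinct species per phylum):")
for row in rows:
    print(f"  {row.phylum}: {row.seq_count} seqs, {row.counts['species']} species"
          f" ({row.percentages['species']}%)")
print(f"collection-wide distinct taxa: {totals}")
print(f"lengths: min={result.lengths.min} max={result.lengths.max} mode={result.lengths.mode}")
# Percentages are relative to collection-wide distinct totals, so shared
# taxa keep column sums >= the total only when phyla are disjoint.
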