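"""End-to-end curation pipeline.

Orchestrates the full workflow over one set of input files: parse both
sources, run every record through the ordered curation stages (length ->
translation/HMM -> trusted cutoff -> annotation -> contamination ->
internal-N -> stop codon), merge the survivors, harmonize taxonomy, build
metadata and write the collection plus its reports.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation_check, contamination, integrate, metadata, summarize, taxonomy
from .io_formats import (
    DEFAULT_BOLD_COLUMNS,
    ParseIssue,
    SequenceRecord,
    Source,
    read_acc2taxid,
    read_bold_tsv,
    read_embl_flatfile,
    read_hmm_profile,
    read_taxdump,
    write_collection,
)
from .profile_search import ProfileHMM, best_frame_hit, passes_tc
from .quality_filters import (
    STAGES,
    CurationDecision,
    FilterConfig,
    StageResult,
    internal_n_gate,
    length_gate,
    stop_codon_gate,
    trim_terminal_n,
)
from .translation import mito_code_for, six_frame_translate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "curate_record", "load_config"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options of one pipeline run."""

    ena_flatfiles: list[str] = field(default_factory=list)
    bold_tsv: list[str] = field(default_factory=list)
    hmm_profile: str = ""
    taxdump_nodes: str = ""
    taxdump_names: str = ""
    taxdump_gencode: str | None = None
    acc2taxid: str | None = None
    blast_tab: str | None = None
    output_dir: str = "out"

    filters: FilterConfig = field(default_factory=FilterConfig)
    marker: str = "COI-5P"
    bold_columns: dict[str, str] = field(default_factory=dict)
    backend: str = "builtin"        # "builtin" | "hmmer" (parsed domtblout)
    domtbl: str | None = None       # required when backend == "hmmer"
    gate_mode: str = "cut_tc"       # "cut_tc" | "manual"
    tc_override: float | None = None
    skip_contamination: bool = False
    reject_clade_names: tuple[str, ...] = contamination.DEFAULT_REJECT_CLADE_NAMES
    permalinks: metadata.PermalinkTemplates = field(default_factory=metadata.PermalinkTemplates)

    def resolve_paths(self, base: Path) -> None:
        """Interpret relative input paths against ``base`` (the config dir)."""

        def fix(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        self.ena_flatfiles = [fix(p) for p in self.ena_flatfiles]
        self.bold_tsv = [fix(p) for p in self.bold_tsv]
        self.hmm_profile = fix(self.hmm_profile)
        self.taxdump_nodes = fix(self.taxdump_nodes)
        self.taxdump_names = fix(self.taxdump_names)
        self.taxdump_gencode = fix(self.taxdump_gencode)
        self.acc2taxid = fix(self.acc2taxid)
        self.blast_tab = fix(self.blast_tab)
        self.domtbl = fix(self.domtbl)
        self.output_dir = fix(self.output_dir)


_CONFIG_KEYS = {
    "ena_flatfiles", "bold_tsv", "hmm_profile", "taxdump_nodes", "taxdump_names",
    "taxdump_gencode", "acc2taxid", "blast_tab", "output_dir", "marker",
    "bold_columns", "backend", "domtbl", "gate_mode", "tc_override",
    "skip_contamination", "reject_clade_names", "filters",
}
_FILTER_KEYS = {
    "min_len", "max_len", "max_internal_n", "apply_length_to",
    "stop_check_scope", "cds_overlap_min", "no_cds_policy",
}


def load_config(payload: dict, base: Path | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML mapping; unknown keys are fatal."""
    unknown = set(payload) - _CONFIG_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    filters_payload = payload.pop("filters", {}) or {}
    unknown = set(filters_payload) - _FILTER_KEYS
    if unknown:
        raise KeyError(f"unknown filter key(s): {', '.join(sorted(unknown))}")
    cfg = PipelineConfig(**payload, filters=FilterConfig(**filters_payload))
    if base is not None:
        cfg.resolve_paths(base)
    return cfg


@dataclass
class PipelineResult:
    decisions: dict[str, CurationDecision]
    merged: list[integrate.MergedRecord]
    resolutions: dict[str, taxonomy.LineageResolution]
    metadata: dict[str, metadata.MetadataRecord]
    synonyms: list[str]
    updated_bold: int
    provenance: summarize.ProvenanceSummary
    composition: list[summarize.CompositionRow]
    lengths: summarize.LengthStats
    parse_issues: list[ParseIssue]
    output_dir: Path


def curate_record(
    record: SequenceRecord,
    profile: ProfileHMM,
    store,
    cfg: PipelineConfig,
    blast_hits,
    reject_clades,
):
    """Run one record through the ordered curation stages.

    Returns (CurationDecision, trimmed sequence, hit, synonym overlaps).
    Stages after the first failure are reported as "skipped".
    """
    results: list[StageResult] = []
    trimmed = record.sequence
    hit = None
    synonym_overlaps: list = []
    failed = False

    def finish():
        remaining = STAGES[len(results) :]
        for stage in remaining:
            results.append(StageResult(stage, "skipped", "not evaluated"))
        return CurationDecision(record.record_id, not failed, results)

    # 1. length
    if record.source is Source.BOLD and cfg.filters.apply_length_to == "ENA_only":
        results.append(StageResult("length", "n/a", "length gate restricted to ENA"))
    elif length_gate(record.sequence, cfg.filters):
        results.append(StageResult("length", "pass", f"{len(record.sequence)} nt"))
    else:
        failed = True
        results.append(
            StageResult(
                "length",
                "fail",
                f"{len(record.sequence)} nt outside [{cfg.filters.min_len}, {cfg.filters.max_len}]",
            )
        )
        return finish(), trimmed, hit, synonym_overlaps

    # 2. translation + profile search
    taxid = _record_taxid(record, store)
    code = mito_code_for(taxid, store)
    frames = six_frame_translate(record.sequence, code)
    hit = best_frame_hit(profile, frames, len(record.sequence))
    if hit is None:
        failed = True
        results.append(StageResult("hmm", "fail", "sequence too short to translate"))
        return finish(), trimmed, hit, synonym_overlaps
    results.append(
        StageResult("hmm", "pass", f"frame {hit.frame:+d}, {hit.score_bits:.1f} bits")
    )

    # 3. trusted cutoff
    tc_override = cfg.tc_override if cfg.gate_mode == "manual" or cfg.tc_override is not None else None
    if passes_tc(hit, profile, tc_override):
        results.append(StageResult("tc", "pass", f"{hit.score_bits:.1f} bits"))
    else:
        failed = True
        threshold = tc_override if tc_override is not None else profile.tc
        results.append(
            StageResult("tc", "fail", f"{hit.score_bits:.1f} bits < TC {threshold}")
        )
        return finish(), trimmed, hit, synonym_overlaps

    # 4. annotation consistency (ENA only)
    if record.source is Source.ENA:
        ok, _overlap, reason = annotation_check.validate_ena_record(
            record, hit, cfg.filters.cds_overlap_min, cfg.filters.no_cds_policy
        )
        if ok:
            results.append(StageResult("annotation", "pass", reason))
            synonym_overlaps = annotation_check.contributing_synonym_overlaps(
                record, hit, cfg.filters.cds_overlap_min
            )
        else:
            failed = True
            results.append(StageResult("annotation", "fail", reason))
            return finish(), trimmed, hit, synonym_overlaps
    else:
        results.append(StageResult("annotation", "n/a", "no feature table (BOLD)"))

    # 5. contamination screen
    if cfg.skip_contamination or blast_hits is None:
        results.append(StageResult("contamination", "skipped", "screen disabled"))
    else:
        ok, reason = contamination.contamination_gate(
            record.record_id, blast_hits, store, reject_clades
        )
        if ok:
            results.append(StageResult("contamination", "pass", reason))
        else:
            failed = True
            results.append(StageResult("contamination", "fail", reason))
            return finish(), trimmed, hit, synonym_overlaps

    # 6. terminal-N trim + internal-N cap
    trimmed, n_lead, n_trail = trim_terminal_n(record.sequence)
    if not trimmed:
        failed = True
        results.append(StageResult("internal_n", "fail", "empty after terminal-N trim"))
        return finish(), trimmed, hit, synonym_overlaps
    if internal_n_gate(trimmed, cfg.filters):
        results.append(
            StageResult(
                "internal_n", "pass",
                f"{trimmed.count('N')} internal N (trimmed {n_lead}+{n_trail})",
            )
        )
    else:
        failed = True
        results.append(
            StageResult(
                "internal_n", "fail",
                f"{trimmed.count('N')} internal N > {cfg.filters.max_internal_n}",
            )
        )
        return finish(), trimmed, hit, synonym_overlaps

    # 7. stop codons in the matched envelope
    frame_peptide = next(f for f in frames if f.frame == hit.frame)
    if stop_codon_gate(hit, frame_peptide, cfg.filters):
        results.append(StageResult("stop_codon", "pass", "no stop in envelope"))
    else:
        failed = True
        results.append(StageResult("stop_codon", "fail", "stop codon inside matched envelope"))
    return finish(), trimmed, hit, synonym_overlaps


def _record_taxid(record: SequenceRecord, store):
    if record.source is Source.ENA:
        if record.accession in store.acc2taxid:
            return store.acc2taxid[record.accession]
        hint = record.raw_taxon_names.get("taxid")
        if hint and hint.isdigit() and store.contains(int(hint)):
            return int(hint)
        return None
    species = record.raw_taxon_names.get("species")
    if species:
        candidates = store.taxid_for_name(species)
        if len(candidates) == 1:
            return candidates[0]
    return None


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full build; writes all output files under ``output_dir``."""
    outdir = Path(cfg.output_dir)

    store = read_taxdump(
        open(cfg.taxdump_nodes), open(cfg.taxdump_names),
        open(cfg.taxdump_gencode) if cfg.taxdump_gencode else None,
    )
    if cfg.acc2taxid:
        store.acc2taxid = read_acc2taxid(open(cfg.acc2taxid))
    with open(cfg.hmm_profile) as fh:
        profile = read_hmm_profile(fh)
    if cfg.gate_mode == "cut_tc" and profile.tc is None and cfg.tc_override is None:
        raise ValueError(
            "profile carries no TC line; supply tc_override or gate_mode='manual'"
        )

    blast_hits = None
    if cfg.blast_tab and not cfg.skip_contamination:
        with open(cfg.blast_tab) as fh:
            blast_hits = contamination.parse_blast_tab(fh)
    reject_clades = contamination.default_reject_clades(store) if cfg.reject_clade_names == contamination.DEFAULT_REJECT_CLADE_NAMES else {
        t for name in cfg.reject_clade_names for t in store.taxid_for_name(name)
    }

    parse_issues: list[ParseIssue] = []
    ena_records: list[SequenceRecord] = []
    for path in cfg.ena_flatfiles:
        with open(path) as fh:
            recs, issues = read_embl_flatfile(fh)
        ena_records.extend(recs)
        parse_issues.extend(issues)
    bold_records: list[SequenceRecord] = []
    for path in cfg.bold_tsv:
        with open(path) as fh:
            recs, skipped = read_bold_tsv(fh, cfg.bold_columns or None, cfg.marker)
        bold_records.extend(recs)
        if skipped:
            logger.info("%s: %d BOLD rows skipped", path, skipped)

    decisions: dict[str, CurationDecision] = {}
    trimmed_seqs: dict[str, str] = {}
    all_synonym_overlaps: list = []
    ena_kept: list[SequenceRecord] = []
    bold_kept: list[SequenceRecord] = []
    stage_tallies: Counter[tuple[str, str]] = Counter()

    for record in ena_records + bold_records:
        decision, trimmed, _hit, syn = curate_record(
            record, profile, store, cfg, blast_hits, reject_clades
        )
        decisions[record.record_id] = decision
        for sr in decision.stage_results:
            stage_tallies[(sr.stage, sr.status)] += 1
        if decision.kept:
            final = SequenceRecord(
                record_id=record.record_id,
                source=record.source,
                sequence=trimmed,
                accession=record.accession,
                process_id=record.process_id,
                features=record.features,
                raw_taxon_names=record.raw_taxon_names,
                raw_metadata=record.raw_metadata,
            )
            trimmed_seqs[record.record_id] = trimmed
            (ena_kept if record.source is Source.ENA else bold_kept).append(final)
            all_synonym_overlaps.extend(syn)

    for stage in STAGES:
        logger.info(
            "stage %-13s pass=%d fail=%d skipped=%d",
            stage,
            stage_tallies[(stage, "pass")] + stage_tallies[(stage, "n/a")],
            stage_tallies[(stage, "fail")],
            stage_tallies[(stage, "skipped")],
        )

    merged = integrate.merge_sources(ena_kept, bold_kept)
    resolutions = {rec.record_id: taxonomy.resolve_record_lineage(rec, store) for rec in merged}
    meta = {
        rec.record_id: metadata.build_metadata(
            rec, resolutions[rec.record_id].lineage, store, cfg.permalinks
        )
        for rec in merged
    }
    synonyms = annotation_check.harvest_synonyms(all_synonym_overlaps)
    merged_by_id = {rec.record_id: rec for rec in merged}
    update_rows, updated_bold = taxonomy.taxonomy_update_report(
        {rid: res for rid, res in resolutions.items() if merged_by_id[rid].bold is not None}
    )

    provenance = summarize.provenance_summary(merged)
    composition, _totals = summarize.composition_by_rank(
        [resolutions[rec.record_id].lineage for rec in merged]
    )
    lengths = summarize.length_histogram(len(rec.sequence) for rec in merged)

    # ---- outputs
    outdir.mkdir(parents=True, exist_ok=True)
    lineages = {rid: res.lineage for rid, res in resolutions.items()}
    write_collection(
        merged, lineages, meta, outdir / "collection.fasta", outdir / "collection.tsv"
    )
    with open(outdir / "synonyms.tsv", "w") as fh:
        for label in synonyms:
            fh.write(label + "\n")
    with open(outdir / "taxonomy_updates.tsv", "w") as fh:
        fh.write("record_id\trank\told_name\tnew_name\n")
        for row in update_rows:
            fh.write("\t".join(row) + "\n")
    with open(outdir / "rejections.tsv", "w") as fh:
        fh.write("record_id\tstage\treason\n")
        for rid in sorted(decisions):
            d = decisions[rid]
            if not d.kept:
                sr = next(s for s in d.stage_results if s.status == "fail")
                fh.write(f"{rid}\t{sr.stage}\t{sr.detail}\n")
    summary = {
        "provenance": {"counts": provenance.counts, "total": provenance.total,
                        "percentages": provenance.percentages},
        "composition": [
            {"phylum": row.phylum, "seq_count": row.seq_count,
             "counts": row.counts, "percentages": row.percentages}
            for row in composition
        ],
        "lengths": {"min": lengths.min, "max": lengths.max, "mode": lengths.mode,
                     "histogram": {str(k): v for k, v in lengths.histogram.items()}},
        "synonym_count": len(synonyms),
        "updated_bold_records": updated_bold,
        "parse_issues": len(parse_issues),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")

    if not merged:
        logger.warning("no records survived curation; outputs are empty")

    return PipelineResult(
        decisions=decisions,
        merged=merged,
        resolutions=resolutions,
        metadata=meta,
        synonyms=synonyms,
        updated_bold=updated_bold,
        provenance=provenance,
        composition=composition,
        lengths=lengths,
        parse_issues=parse_issues,
        output_dir=outdir,
    )
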