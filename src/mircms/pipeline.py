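"""End-to-end orchestration: clean -> annotate -> discover -> DE -> degradome.

`run_all` chains the stages over a validated configuration, writes one TSV
per stage plus a machine-readable summary, and stops at the first failing
stage leaving earlier outputs intact. Output is deterministic: fixed sort
orders and fixed 6-decimal p-value formatting (full precision is kept in a
parallel column).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import annotate, degradome, diffexpr, novel, preprocess
from .io import SequenceRecord, read_fasta, read_fastq

logger = logging.getLogger("mircms")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters with their pipeline-wide defaults."""

    adapter: str | None = None
    min_len: int = preprocess.MIN_LEN
    max_len: int = preprocess.MAX_LEN
    max_sub: int = annotate.DEFAULT_MAX_SUB
    max_shift: int = annotate.DEFAULT_MAX_SHIFT
    min_count: int = novel.DEFAULT_MIN_COUNT
    flank: int = novel.DEFAULT_FLANK
    alpha: float = diffexpr.DEFAULT_ALPHA
    scale: int = diffexpr.DEFAULT_SCALE
    max_score: float = degradome.DEFAULT_MAX_SCORE
    min_match: int = degradome.DEFAULT_MIN_MATCH
    seed: int = 0
    libraries: tuple[str, str] = ("MF", "CMS")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        if "libraries" in data:
            data["libraries"] = tuple(data["libraries"])
        return cls.from_mapping(data)

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        for name in ("scale", "min_count", "flank", "min_match"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RunReport:
    tallies: dict[str, Any] = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)


def _fmt_p(p: float) -> str:
    return f"{p:.6f}"


def _load_reads(path: Path) -> list[SequenceRecord]:
    with open(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


def write_tags_tsv(tags, path: Path, libraries) -> None:
    with open(path, "w") as out:
        out.write("sequence\t" + "\t".join(libraries) + "\n")
        for tag in tags:
            counts = "\t".join(str(tag.counts.get(lib, 0)) for lib in libraries)
            out.write(f"{tag.sequence}\t{counts}\n")


def write_de_tsv(results, path: Path) -> None:
    with open(path, "w") as out:
        out.write(
            "identifier\tnorm_1\tnorm_2\tp_AC\tp_Fisher\tp_Chi2x2\t"
            "p_AC_full\tp_Fisher_full\tp_Chi2x2_full\tdirection\tsignificant\n"
        )
        for r in results:
            out.write(
                f"{r.identifier}\t{r.pair.x:g}\t{r.pair.y:g}\t"
                f"{_fmt_p(r.p_ac)}\t{_fmt_p(r.p_fisher)}\t{_fmt_p(r.p_chi2)}\t"
                f"{r.p_ac!r}\t{r.p_fisher!r}\t{r.p_chi2!r}\t"
                f"{r.direction}\t{int(r.significant)}\n"
            )


def run_all(
    config: PipelineConfig,
    reads: Mapping[str, Path],
    output_dir: str | Path,
    genome: Path | None = None,
    transcripts: Path | None = None,
    degradome_tags: Mapping[str, Path] | None = None,
    mature_catalog: Path | None = None,
    exclusion: list[Path] | None = None,
) -> RunReport:
    """Run every configured stage; inputs are paths keyed by library label.

    Stages needing absent inputs are skipped (and logged); a missing genome
    with discovery implicitly requested is a configuration error raised
    before any stage runs.
    """
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    lib1, lib2 = config.libraries
    for lib in (lib1, lib2):
        if lib not in reads:
            raise ValueError(f"no reads supplied for library {lib!r}")

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    # preprocess ------------------------------------------------------------
    t0 = stage("preprocess")
    try:
        per_lib_tags = {}
        for lib in (lib1, lib2):
            records = _load_reads(Path(reads[lib]))
            n_in = len(records)
            if config.adapter:
                records = [
                    r for r in (
                        preprocess.trim_adapter(rec, config.adapter) for rec in records
                    ) if r is not None
                ]
            kept, tally = preprocess.filter_reads(records, config.min_len, config.max_len)
            per_lib_tags[lib] = preprocess.collapse(kept, lib)
            report.tallies[f"{lib}_reads_in"] = n_in
            report.tallies[f"{lib}_reads_kept"] = tally.kept
            report.tallies[f"{lib}_rejected_junk"] = tally.junk
            report.tallies[f"{lib}_rejected_length"] = tally.too_short + tally.too_long
        tags = preprocess.merge_tags(per_lib_tags[lib1], per_lib_tags[lib2])
        report.tallies["unique_tags"] = len(tags)
        tag_path = out_dir / "tags.tsv"
        write_tags_tsv(tags, tag_path, (lib1, lib2))
        report.outputs["tags"] = tag_path
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc
    logger.info("stage preprocess done in %.2fs", time.perf_counter() - t0)

    # annotate --------------------------------------------------------------
    annotated_seqs: set[str] = set()
    if mature_catalog is not None:
        t0 = stage("annotate")
        try:
            catalog = [
                annotate.MatureRecord(r.identifier, r.sequence)
                for r in read_fasta(mature_catalog)
            ]
            ann_path = out_dir / "annotation.tsv"
            n_hits = 0
            with open(ann_path, "w") as out:
                out.write("sequence\tassigned_name\tsubs\tleft_shift\tright_shift\t"
                          + "\t".join((lib1, lib2)) + "\n")
                for tag in tags:
                    hit = annotate.match_mature(
                        tag.sequence, catalog, config.max_sub, config.max_shift
                    )
                    if hit is None:
                        continue
                    n_hits += 1
                    annotated_seqs.add(tag.sequence)
                    subs = ";".join(f"{p}{a}{b}" for p, a, b in hit.substitutions)
                    out.write(
                        f"{tag.sequence}\t{hit.assigned_name}\t{subs or '.'}\t"
                        f"{hit.left_shift}\t{hit.right_shift}\t"
                        f"{tag.counts.get(lib1, 0)}\t{tag.counts.get(lib2, 0)}\n"
                    )
            report.tallies["annotated_tags"] = n_hits
            report.outputs["annotation"] = ann_path
        except Exception as exc:
            raise PipelineError("annotate", exc) from exc
        logger.info("stage annotate done in %.2fs", time.perf_counter() - t0)

    # novel discovery -------------------------------------------------------
    if genome is not None:
        t0 = stage("novel")
        try:
            genome_records = read_fasta(genome)
            exclusion_cats = [read_fasta(p) for p in (exclusion or [])]
            unannotated = [t for t in tags if t.sequence not in annotated_seqs]
            candidates = novel.discover(
                unannotated, genome_records, exclusion_cats,
                min_count=config.min_count, flank=config.flank,
            )
            cand_path = out_dir / "novel_candidates.tsv"
            with open(cand_path, "w") as out:
                out.write("candidate_id\tsequence\tseq_id\tstart\tend\tstrand\t"
                          "arm\tpaired_bases\tstructure\n")
                for c in candidates:
                    sid, start, end, strand = c.locus
                    out.write(
                        f"{c.candidate_id}\t{c.tag_sequence}\t{sid}\t{start}\t{end}\t"
                        f"{strand}\t{c.arm}\t{c.paired_mature_bases}\t{c.structure}\n"
                    )
            report.tallies["novel_candidates"] = len(candidates)
            report.outputs["novel"] = cand_path
        except Exception as exc:
            raise PipelineError("novel", exc) from exc
        logger.info("stage novel done in %.2fs", time.perf_counter() - t0)

    # differential expression ----------------------------------------------
    t0 = stage("de")
    try:
        results = diffexpr.de_from_tags(
            tags, lib1, lib2, scale=config.scale, alpha=config.alpha
        )
        de_path = out_dir / "differential_expression.tsv"
        write_de_tsv(results, de_path)
        n_sig = sum(r.significant for r in results)
        report.tallies["de_significant"] = n_sig
        report.tallies["de_up"] = sum(r.significant and r.direction == "up" for r in results)
        report.tallies["de_down"] = sum(
            r.significant and r.direction == "down" for r in results
        )
        report.outputs["de"] = de_path
    except Exception as exc:
        raise PipelineError("de", exc) from exc
    logger.info("stage de done in %.2fs", time.perf_counter() - t0)

    # degradome -------------------------------------------------------------
    if transcripts is not None and degradome_tags:
        t0 = stage("degradome")
        try:
            transcript_records = read_fasta(transcripts)
            deg_by_lib = {}
            for lib, path in degradome_tags.items():
                deg_by_lib[lib] = [
                    preprocess.SequenceTag(r.sequence, {lib: _header_count(r.identifier)})
                    for r in read_fasta(path)
                ]
            tplots = degradome.build_tplot(
                deg_by_lib, transcript_records, min_match=config.min_match
            )
            mirnas = {f"tag_{i}": t.sequence for i, t in enumerate(tags)}
            sites = degradome.classify_targets(
                mirnas, transcript_records, tplots, max_score=config.max_score
            )
            site_path = out_dir / "target_sites.tsv"
            with open(site_path, "w") as out:
                out.write("mirna_id\ttranscript_id\tcleavage_site\tcategory\t"
                          "norm_reads\tannotation\n")
                for s in sites:
                    norm = ";".join(
                        f"{lib}={v:.6f}" for lib, v in sorted(s.norm_reads.items())
                    )
                    out.write(
                        f"{s.mirna_id}\t{s.transcript_id}\t{s.cleavage_position}\t"
                        f"{s.category}\t{norm}\t{s.annotation}\n"
                    )
            report.tallies["target_sites"] = len(sites)
            report.outputs["degradome"] = site_path
        except Exception as exc:
            raise PipelineError("degradome", exc) from exc
        logger.info("stage degradome done in %.2fs", time.perf_counter() - t0)

    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as out:
        json.dump(
            {"tallies": report.tallies,
             "outputs": {k: str(v) for k, v in report.outputs.items()}},
            out, indent=2, sort_keys=True,
        )
        out.write("\n")
    report.outputs["summary"] = summary_path
    return report


def _header_count(identifier: str) -> int:
    """Degradome FASTA headers may carry counts as '>tag_1 count=7' or
    '>tag_1_x7'; default 1."""
    if "count=" in identifier:
        return int(identifier.split("count=")[1].split()[0])
    if "_x" in identifier:
        tail = identifier.rsplit("_x", 1)[1]
        if tail.isdigit():
            return int(tail)
    return 1


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.ERROR if quiet else logging.INFO
    logging.basicConfig(
        stream=sys.stderr, level=level, format="[%(asctime)s] %(levelname)s %(message)s"
    )
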