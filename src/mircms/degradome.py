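"""Degradome (PARE) target detection and five-category cleavage classification.

Degradome tags are 5' ends of uncapped, sliced transcripts; stacking them on
a transcript gives a "t-plot" of cleavage evidence by position. miRNA target
sites are found by complementarity scoring, the predicted cleavage position
(opposite miRNA positions 10–11) is checked for degradome signal, and each
supported position is classified by its abundance relative to the rest of
the transcript's signal:

  category 0 — more than one raw read, position is the transcript's unique
               maximum;
  category 1 — more than one raw read, tied for the maximum;
  category 2 — more than one raw read, below the maximum but above the
               median of signal positions;
  category 3 — more than one raw read, at or below that median;
  category 4 — exactly one raw read at the position.

The singleton rule is evaluated first, which resolves the overlap when the
transcript-wide maximum itself is 1. The median is taken over positions
carrying at least one read — over all transcript positions it would collapse
to 0 on long transcripts and category 2 would swallow category 3.

Alignment scoring follows the plant-target convention: mismatch 1, G:U
wobble 0.5, gap 2, every penalty doubled in the miRNA seed/core region
(positions 2–13, 5'-counted), and sites kept up to a total score of 7.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import SequenceRecord, reverse_complement
from .preprocess import SequenceTag

DEFAULT_MIN_MATCH = 20
DEFAULT_MAX_SCORE = 7.0
MISMATCH_PENALTY = 1.0
GU_PENALTY = 0.5
GAP_PENALTY = 2.0
CORE_START, CORE_END = 2, 13  # 1-based miRNA positions with doubled penalties
CORE_MULTIPLIER = 2.0
NORM_SCALE = 1_000_000


@dataclass
class TPlot:
    """Per-transcript degradome profile: 1-based position -> raw read count."""

    transcript_id: str
    length: int
    abundance: dict[int, int] = field(default_factory=dict)

    def add(self, position: int, count: int) -> None:
        if not (1 <= position <= self.length):
            raise ValueError(
                f"{self.transcript_id}: position {position} outside 1..{self.length}"
            )
        self.abundance[position] = self.abundance.get(position, 0) + count


@dataclass(frozen=True)
class TargetAlignment:
    mirna_sequence: str
    transcript_id: str
    site_start: int  # 1-based, inclusive, on the transcript
    site_end: int
    states: tuple[str, ...]  # per miRNA position: "match" | "mismatch" | "GU"
    score: float
    cleavage_position: int  # transcript base opposite miRNA position 10


@dataclass(frozen=True)
class TargetSite:
    """One classified cleavage event (a row of the target table)."""

    mirna_id: str
    transcript_id: str
    cleavage_position: int
    category: int
    library_categories: Mapping[str, int]
    norm_reads: Mapping[str, float]
    annotation: str = ""


def build_tplot(
    degradome_tags: Mapping[str, Sequence[SequenceTag]] | Sequence[SequenceTag],
    transcripts: Sequence[SequenceRecord],
    min_match: int = DEFAULT_MIN_MATCH,
) -> dict[str, dict[str, TPlot]]:
    """Anchor degradome tags on transcripts: a tag adds its raw count at
    every position where its first ``min_match`` bases exactly match the
    transcript. Returns {library -> {transcript_id -> TPlot}}; tags hitting
    several transcripts contribute to each.
    """
    if not isinstance(degradome_tags, Mapping):
        degradome_tags = {"default": list(degradome_tags)}
    out: dict[str, dict[str, TPlot]] = {}
    for library, tags in degradome_tags.items():
        plots = {t.identifier: TPlot(t.identifier, len(t.sequence)) for t in transcripts}
        for tag in tags:
            probe = tag.sequence[:min_match]
            if len(probe) < min_match:
                continue
            count = tag.counts.get(library, tag.total_count)
            for t in transcripts:
                start = t.sequence.find(probe)
                while start != -1:
                    plots[t.identifier].add(start + 1, count)
                    start = t.sequence.find(probe, start + 1)
        out[library] = {k: v for k, v in plots.items() if v.abundance}
    return out


def _pair_state(mirna_base: str, target_base: str) -> str:
    """State of one miRNA base against the transcript base it lies opposite.
    The miRNA binds the transcript antisense, so a match means the target
    base is the complement; G:U wobble covers miRNA G opposite target T(U)
    and miRNA T(U) opposite target G."""
    if target_base == reverse_complement(mirna_base):
        return "match"
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return "GU"
    return "mismatch"


def score_alignment(
    mirna: str, site_sequence: str, transcript_id: str = "", site_start: int = 1
) -> TargetAlignment:
    """Score an ungapped anchored alignment of a miRNA against a same-length
    candidate site (transcript 5'->3'; miRNA position 1 pairs the site's
    last base). Length differences are charged as gaps."""
    states: list[str] = []
    score = 0.0
    n = len(mirna)
    for pos in range(1, n + 1):  # 1-based miRNA position, 5'-counted
        mult = CORE_MULTIPLIER if CORE_START <= pos <= CORE_END else 1.0
        t_index = len(site_sequence) - pos  # miRNA 5' pairs site 3' end
        if t_index < 0:
            states.append("gap")
            score += GAP_PENALTY * mult
            continue
        state = _pair_state(mirna[pos - 1], site_sequence[t_index])
        states.append(state)
        if state == "mismatch":
            score += MISMATCH_PENALTY * mult
        elif state == "GU":
            score += GU_PENALTY * mult
    score += GAP_PENALTY * max(0, len(site_sequence) - n)  # unpaired site overhang
    cleavage = site_start + len(site_sequence) - 10  # opposite miRNA position 10
    return TargetAlignment(
        mirna, transcript_id, site_start, site_start + len(site_sequence) - 1,
        tuple(states), score, cleavage,
    )


def find_sites(
    mirna: str,
    transcript: SequenceRecord,
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[TargetAlignment]:
    """All candidate sites on a transcript scoring at or below ``max_score``.

    Sites are same-length windows slid along the transcript (the ungapped
    case dominates plant targets); the predicted cleavage lies opposite
    miRNA positions 10–11 and is reported as the position opposite base 10.
    """
    n = len(mirna)
    hits = []
    for start in range(0, len(transcript.sequence) - n + 1):
        site = transcript.sequence[start : start + n]
        aln = score_alignment(mirna, site, transcript.identifier, start + 1)
        if aln.score <= max_score:
            hits.append(aln)
    return hits


def assign_category(tplot: TPlot, position: int) -> int:
    """Classify one signal-bearing position of a t-plot into category 0–4."""
    reads = tplot.abundance.get(position, 0)
    if reads == 0:
        raise ValueError(
            f"{tplot.transcript_id}:{position}: no degradome signal at position"
        )
    if reads == 1:
        return 4
    values = list(tplot.abundance.values())
    peak = max(values)
    if reads == peak:
        return 0 if values.count(peak) == 1 else 1
    return 2 if reads > statistics.median(values) else 3


def classify_targets(
    mirnas: Mapping[str, str],
    transcripts: Sequence[SequenceRecord],
    tplots: Mapping[str, Mapping[str, TPlot]],
    library_totals: Mapping[str, float] | None = None,
    max_score: float = DEFAULT_MAX_SCORE,
    annotations: Mapping[str, str] | None = None,
) -> list[TargetSite]:
    """Emit the classified target table.

    For each (miRNA, transcript) pair, complementarity sites whose predicted
    cleavage position carries at least one degradome read in at least one
    library become TargetSites with per-library categories and per-million
    normalized read support. The overall category is taken from the library
    with the strongest raw support at the site. Sorted by miRNA id then
    transcript id then position.
    """
    if library_totals is None:
        library_totals = {
            lib: sum(sum(tp.abundance.values()) for tp in plots.values())
            for lib, plots in tplots.items()
        }
    sites: list[TargetSite] = []
    by_id = {t.identifier: t for t in transcripts}
    for mirna_id in sorted(mirnas):
        for t_id in sorted(by_id):
            for aln in find_sites(mirnas[mirna_id], by_id[t_id], max_score):
                lib_cats: dict[str, int] = {}
                norm: dict[str, float] = {}
                best_lib, best_reads = None, 0
                for lib, plots in tplots.items():
                    tp = plots.get(t_id)
                    reads = tp.abundance.get(aln.cleavage_position, 0) if tp else 0
                    if reads == 0:
                        continue
                    lib_cats[lib] = assign_category(tp, aln.cleavage_position)
                    total = library_totals.get(lib) or 1.0
                    norm[lib] = reads * NORM_SCALE / total
                    if reads > best_reads:
                        best_lib, best_reads = lib, reads
                if best_lib is None:
                    continue
                sites.append(
                    TargetSite(
                        mirna_id=mirna_id,
                        transcript_id=t_id,
                        cleavage_position=aln.cleavage_position,
                        category=lib_cats[best_lib],
                        library_categories=lib_cats,
                        norm_reads=norm,
                        annotation=(annotations or {}).get(t_id, ""),
                    )
                )
    return sites
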