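"""Novel candidate miRNA discovery from unannotated tags.

A tag survives database exclusion (mRNA / structural ncRNA / repeats, plus a
low-abundance cutoff), its genomic loci are extended into two asymmetric
precursor windows, each window is folded, and the tag is accepted as a
candidate when it sits on one arm of a hairpin with enough of its bases
paired against the opposite arm. Accepted candidates are named
``PC-{5p|3p}-{serial}`` in discovery order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .fold import max_pairing_structure, pair_table
from .io import SequenceRecord, reverse_complement
from .preprocess import SequenceTag

DEFAULT_MIN_COUNT = 5
DEFAULT_FLANK = 160
SHORT_FLANK = 20
MIN_WINDOW = 40
MIN_PAIRED_BASES = 14
MAX_DUPLEX_BULGE = 10

Folder = Callable[[str], str]  # sequence -> dot-bracket


@dataclass(frozen=True)
class PrecursorWindow:
    """A candidate precursor region around a genomic tag occurrence.

    Coordinates are 1-based inclusive on the source (plus) strand; minus-strand
    windows carry the reverse-complemented sequence so the tag always appears
    in forward orientation, with tag offset relative to that sequence."""

    seq_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    sequence: str
    tag_offset: int  # 0-based offset of the tag within `sequence`


@dataclass
class HairpinCandidate:
    candidate_id: str
    tag_sequence: str
    locus: tuple[str, int, int, str]
    window_sequence: str
    structure: str
    arm: str  # "5p" | "3p"
    paired_mature_bases: int
    loop_span: tuple[int, int]  # 1-based inclusive on the window; gap tag↔partner


@dataclass(frozen=True)
class Rejection:
    reason: str


def exclude_annotated(
    tags: Iterable[SequenceTag],
    exclusion_catalogs: Sequence[Sequence[SequenceRecord]],
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[SequenceTag]:
    """Drop tags occurring (either strand) in any exclusion catalog, and
    low-abundance tags with total raw count below ``min_count``."""
    catalog_seqs = [rec.sequence for cat in exclusion_catalogs for rec in cat]
    kept = []
    for tag in tags:
        if tag.total_count < min_count:
            continue
        probe_fwd = tag.sequence
        probe_rev = reverse_complement(tag.sequence)
        if any(probe_fwd in s or probe_rev in s for s in catalog_seqs):
            continue
        kept.append(tag)
    return kept


def _occurrences(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def locate_windows(
    tag: str,
    genome: Sequence[SequenceRecord],
    flank: int = DEFAULT_FLANK,
    short_flank: int = SHORT_FLANK,
) -> list[PrecursorWindow]:
    """Two asymmetric precursor windows per exact genomic occurrence of the
    tag (either strand): long-left/short-right and short-left/long-right,
    clipped to the sequence bounds. The asymmetry covers both arm polarities
    without knowing a priori which hairpin arm the tag comes from. A tag that
    never occurs yields an empty list."""
    windows: list[PrecursorWindow] = []
    for chrom in genome:
        for strand, probe in (("+", tag), ("-", reverse_complement(tag))):
            for occ in _occurrences(chrom.sequence, probe):
                occ_start, occ_end = occ + 1, occ + len(tag)  # 1-based
                for left, right in ((flank, short_flank), (short_flank, flank)):
                    w_start = max(1, occ_start - left)
                    w_end = min(len(chrom.sequence), occ_end + right)
                    seq = chrom.sequence[w_start - 1 : w_end]
                    if strand == "-":
                        seq = reverse_complement(seq)
                        offset = w_end - occ_end
                    else:
                        offset = occ_start - w_start
                    windows.append(
                        PrecursorWindow(chrom.identifier, w_start, w_end, strand, seq, offset)
                    )
    return windows


def fold_window(window: PrecursorWindow | str, folder: Folder | None = None) -> str | Rejection:
    """Fold a precursor window to dot-bracket; windows under 40 nt are
    rejected as too short to host a hairpin around a mature tag."""
    seq = window if isinstance(window, str) else window.sequence
    if len(seq) < MIN_WINDOW:
        return Rejection("window too short")
    folder = folder or max_pairing_structure
    structure = folder(seq)
    if len(structure) != len(seq):
        raise ValueError("folder returned structure of wrong length")
    return structure


def evaluate_candidate(
    tag: str,
    window: PrecursorWindow,
    structure: str,
) -> tuple[str, int, tuple[int, int]] | Rejection:
    """Apply the hairpin-arm acceptance rules to a folded window.

    Accepted iff (a) the tag lies entirely on one arm — every paired tag base
    has its partner strictly on one side of the tag and no base pair falls
    wholly inside the tag (which would mean the tag spans the terminal loop);
    (b) at least 14 tag bases are paired; (c) the partners form a compact
    region on the opposite arm — partner span at most tag length plus a
    bulge allowance — so the tag and its star-side partner form a genuine
    duplex rather than scattered chance pairings. Returns
    (arm, paired bases, loop span).
    """
    pairs = pair_table(structure)
    s = window.tag_offset
    e = s + len(tag) - 1
    partners = []
    for i in range(s, e + 1):
        if i in pairs:
            j = pairs[i]
            if s <= j <= e:
                return Rejection("tag folds onto itself (spans the loop)")
            partners.append(j)
    if len(partners) < MIN_PAIRED_BASES:
        return Rejection(f"only {len(partners)} tag bases paired (< {MIN_PAIRED_BASES})")
    span = max(partners) - min(partners) + 1
    if span > len(tag) + MAX_DUPLEX_BULGE:
        return Rejection(
            f"partner region span {span} too wide for a {len(tag)}-nt duplex"
        )
    if all(j > e for j in partners):
        arm = "5p"
        loop = (e + 2, min(partners))  # 1-based: gap between tag end and partner region
    elif all(j < s for j in partners):
        arm = "3p"
        loop = (max(partners) + 2, s)
    else:
        return Rejection("tag pairs onto both sides (straddles the loop)")
    return arm, len(partners), loop


class CandidateNamer:
    """Serial PC-{arm}-{n} ids in discovery order (stable across re-runs
    given a fixed input order)."""

    def __init__(self) -> None:
        self._serial = 0

    def next_id(self, arm: str) -> str:
        self._serial += 1
        return f"PC-{arm}-{self._serial}"


def call_candidate(
    tag: str,
    window: PrecursorWindow,
    structure: str,
    namer: CandidateNamer | None = None,
) -> HairpinCandidate | Rejection:
    """Accept or reject one (tag, folded window) as a hairpin candidate."""
    verdict = evaluate_candidate(tag, window, structure)
    if isinstance(verdict, Rejection):
        return verdict
    arm, paired, loop = verdict
    namer = namer or CandidateNamer()
    return HairpinCandidate(
        candidate_id=namer.next_id(arm),
        tag_sequence=tag,
        locus=(window.seq_id, window.start, window.end, window.strand),
        window_sequence=window.sequence,
        structure=structure,
        arm=arm,
        paired_mature_bases=paired,
        loop_span=loop,
    )


def _subwindows(window: PrecursorWindow, flanks: Sequence[int], tag_len: int
                ) -> list[PrecursorWindow]:
    """Nested sub-flank windows around the tag occurrence inside ``window``.

    A genuine precursor places its star arm within tens of bases of the
    mature, so tight windows recover the duplex that a global fold of a long
    window can bury under scattered pairings; the full window is kept as the
    last rung of the ladder."""
    subs = []
    s = window.tag_offset
    e = s + tag_len  # exclusive
    for f in flanks:
        for left, right in ((f, SHORT_FLANK), (SHORT_FLANK, f)):
            lo = max(0, s - left)
            hi = min(len(window.sequence), e + right)
            if hi - lo < MIN_WINDOW:
                continue
            if window.strand == "+":
                new_start = window.start + lo
                new_end = window.start + hi - 1
            else:  # window.sequence is already reverse-complemented
                new_end = window.end - lo
                new_start = window.end - hi + 1
            subs.append(
                PrecursorWindow(
                    window.seq_id, new_start, new_end, window.strand,
                    window.sequence[lo:hi], s - lo,
                )
            )
    return subs


def discover(
    tags: Iterable[SequenceTag],
    genome: Sequence[SequenceRecord],
    exclusion_catalogs: Sequence[Sequence[SequenceRecord]] = (),
    min_count: int = DEFAULT_MIN_COUNT,
    flank: int = DEFAULT_FLANK,
    folder: Folder | None = None,
    sub_flanks: Sequence[int] = (40, 80, DEFAULT_FLANK),
) -> list[HairpinCandidate]:
    """Full discovery pass: exclusion -> windows -> folding -> calling.

    Each genomic occurrence is probed with a ladder of nested sub-flank
    windows in both arm polarities; the occurrence is reported once, as its
    best-pairing accepted fold. All loci per tag are kept — multi-copy
    precursors (e.g. nuclear and organellar copies of one hairpin) stay
    separate records.
    """
    namer = CandidateNamer()
    candidates: list[HairpinCandidate] = []
    survivors = exclude_annotated(tags, exclusion_catalogs, min_count=min_count)
    for tag in survivors:
        windows = locate_windows(tag.sequence, genome, flank=flank)
        by_locus: dict[tuple[str, str, int], list[PrecursorWindow]] = {}
        for w in windows:
            # Group the two asymmetric windows of one occurrence together.
            occ_key = (w.seq_id, w.strand,
                       w.start + w.tag_offset if w.strand == "+" else w.end - w.tag_offset)
            by_locus.setdefault(occ_key, []).append(w)
        for occ_key in sorted(by_locus):
            best: HairpinCandidate | None = None
            probes: list[PrecursorWindow] = []
            seen_spans: set[tuple[int, int]] = set()
            for w in by_locus[occ_key]:
                for sub in _subwindows(w, sub_flanks, len(tag.sequence)):
                    if (sub.start, sub.end) in seen_spans:
                        continue
                    seen_spans.add((sub.start, sub.end))
                    probes.append(sub)
            for w in probes:
                structure = fold_window(w, folder)
                if isinstance(structure, Rejection):
                    continue
                probe_namer = CandidateNamer()  # don't consume serials on rejects
                result = call_candidate(tag.sequence, w, structure, probe_namer)
                if isinstance(result, Rejection):
                    continue
                if best is None or result.paired_mature_bases > best.paired_mature_bases:
                    best = result
            if best is not None:
                best.candidate_id = namer.next_id(best.arm)
                candidates.append(best)
    return candidates
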