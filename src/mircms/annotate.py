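"""Matching tags against a mature/precursor miRNA catalog and naming variants.

A sequenced tag rarely equals its reference mature exactly; isomiR variants
differ by 5'/3' end shifts and internal substitutions. Names encode those
edits with a compact suffix grammar:

  _L+n / _L-n   5' end n nt longer / shorter than the reference mature
  _R+n / _R-n   3' end n nt longer / shorter
  _Nss<p><R><O>...  N substitutions, each position (1-based on the observed
                    tag) + reference base + observed base, ascending

e.g. ``ath-miR156h_L+1`` (one extra 5' base), ``ath-miR159c_R-2``,
``ahy-miR167-5p_1ss21TC`` (position-21 T→C). Tags matching a precursor
outside any annotated mature span are named by arm: ``<precursor>-p5`` /
``-p3`` (5' or 3' of the hairpin midpoint).

Matching is ungapped: for each candidate end-shift the tag is laid over the
reference and substitutions are counted in the overlap. The best hit
minimizes (substitution count, total |shift|, catalog name), which makes
annotation fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

DEFAULT_MAX_SUB = 2
DEFAULT_MAX_SHIFT = 3


@dataclass(frozen=True)
class MatureRecord:
    name: str
    sequence: str
    precursor_name: str = ""
    arm: str = "unknown"  # "5p" | "3p" | "unknown"


@dataclass(frozen=True)
class PrecursorRecord:
    name: str
    sequence: str
    # (start, end, arm) 1-based inclusive spans of annotated matures
    mature_spans: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        for start, end, _arm in self.mature_spans:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"{self.name}: mature span ({start},{end}) outside 1..{len(self.sequence)}"
                )


@dataclass
class AnnotationHit:
    tag_sequence: str
    matched_name: str
    # (position 1-based on the observed tag, reference base, observed base)
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    left_shift: int = 0   # >0: tag 5' end extends beyond the reference
    right_shift: int = 0  # >0: tag 3' end extends beyond the reference

    @property
    def assigned_name(self) -> str:
        return self.matched_name + variant_suffix(self)


def variant_suffix(hit: AnnotationHit) -> str:
    """Suffix encoding the hit's edits; empty for an exact match."""
    parts: list[str] = []
    if hit.left_shift:
        parts.append(f"_L{hit.left_shift:+d}")
    if hit.right_shift:
        parts.append(f"_R{hit.right_shift:+d}")
    if hit.substitutions:
        subs = sorted(hit.substitutions)
        body = "".join(f"{pos}{ref}{obs}" for pos, ref, obs in subs)
        parts.append(f"_{len(subs)}ss{body}")
    return "".join(parts)


def _align_at_shift(tag: str, ref: str, left_shift: int) -> tuple[int, list[tuple[int, str, str]]] | None:
    """Overlay tag on ref with the tag's 5' end ``left_shift`` nt 5' of the
    reference 5' end; return (right_shift, substitutions) or None if there is
    no overlap."""
    right_shift = (len(tag) - left_shift) - len(ref)
    subs: list[tuple[int, str, str]] = []
    overlap = 0
    for i, base in enumerate(tag):  # i: 0-based tag position
        j = i - left_shift  # aligned 0-based reference position
        if 0 <= j < len(ref):
            overlap += 1
            if base != ref[j]:
                subs.append((i + 1, ref[j], base))
    if overlap == 0:
        return None
    return right_shift, subs


def match_mature(
    tag: str,
    catalog: Sequence[MatureRecord],
    max_sub: int = DEFAULT_MAX_SUB,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> AnnotationHit | None:
    """Best catalog hit for a tag, or None when nothing falls inside the
    substitution/shift tolerances."""
    if not catalog:
        raise ValueError("empty mature catalog")
    best: tuple[int, int, str, AnnotationHit] | None = None
    for rec in catalog:
        for left in range(-max_shift, max_shift + 1):
            res = _align_at_shift(tag, rec.sequence, left)
            if res is None:
                continue
            right, subs = res
            if abs(right) > max_shift or len(subs) > max_sub:
                continue
            key = (len(subs), abs(left) + abs(right), rec.name)
            if best is None or key < best[:3]:
                best = (*key, AnnotationHit(tag, rec.name, subs, left, right))
    return best[3] if best else None


def apply_suffix_edits(hit: AnnotationHit, reference: str) -> str:
    """Reconstruct the observed tag from the reference and the hit's edits.

    Bases the tag gains outside the reference (positive shifts) are taken
    from the hit's own sequence — the grammar does not record them — so this
    is a consistency check, not a free-standing decoder for extensions.
    """
    n = len(reference) + hit.left_shift + hit.right_shift
    out = []
    for i in range(n):  # 0-based position on the reconstructed tag
        j = i - hit.left_shift
        if 0 <= j < len(reference):
            out.append(reference[j])
        else:
            out.append(hit.tag_sequence[i])
    for pos, ref_base, obs_base in hit.substitutions:
        assert out[pos - 1] == ref_base
        out[pos - 1] = obs_base
    return "".join(out)


def combine_catalogs(*catalogs: Sequence[MatureRecord]) -> list[MatureRecord]:
    """Union mature catalogs (e.g. known + newly discovered), deduplicating
    by name; the first record seen under a name wins."""
    seen: dict[str, MatureRecord] = {}
    for catalog in catalogs:
        for rec in catalog:
            seen.setdefault(rec.name, rec)
    return list(seen.values())


def assign_arm(tag: str, precursors: Iterable[PrecursorRecord]) -> str | None:
    """Name a tag that matches a precursor outside any annotated mature span.

    The arm is decided by midpoints: a match centered 5' of the precursor
    midpoint is ``-p5``, otherwise ``-p3``. Tags overlapping a mature span
    return None (they belong to :func:`match_mature`).
    """
    for prec in precursors:
        start = prec.sequence.find(tag)
        while start != -1:
            lo, hi = start + 1, start + len(tag)  # 1-based inclusive
            overlaps_mature = any(
                not (hi < s or lo > e) for s, e, _ in prec.mature_spans
            )
            if not overlaps_mature:
                tag_mid = (lo + hi) / 2
                prec_mid = (1 + len(prec.sequence)) / 2
                arm = "p5" if tag_mid < prec_mid else "p3"
                return f"{prec.name}-{arm}"
            start = prec.sequence.find(tag, start + 1)
    return None
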