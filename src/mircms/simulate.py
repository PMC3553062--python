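"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure of a two-condition plant
small-RNA experiment: a genome with planted hairpin precursors (21-nt mature
on one arm, fully paired against the other, loop >= 8) and shuffled decoy
loci; two sequencing libraries whose per-tag counts are negative-binomially
dispersed around planted means with planted fold changes between the
male-sterile (CMS) and maintainer-fertile (MF) conditions; and degradome tag
pileups engineered to realize each of the five cleavage categories. All
randomness flows from one integer seed through ``numpy.random.Generator``,
so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import SequenceRecord, reverse_complement
from .preprocess import SequenceTag

BASES = np.array(list("ACGT"))
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # standard small-RNA 3' adapter
MATURE_LEN = 21
LOOP_LEN = 8
DEFAULT_LENGTH_MIX = {21: 0.60, 24: 0.25, 22: 0.08, 20: 0.07}


@dataclass
class PlantedPrecursor:
    locus: tuple[str, int, int, str]  # seq id, start, end (1-based incl.), strand
    arm: str  # arm carrying the mature: "5p" | "3p"
    mature: str
    precursor: str


@dataclass
class PlantedTag:
    sequence: str
    mf_mean: float
    cms_mean: float

    @property
    def fold_change(self) -> float:
        return self.cms_mean / self.mf_mean if self.mf_mean else float("inf")


@dataclass
class PlantedSite:
    mirna_id: str
    transcript_id: str
    cleavage_position: int
    category: int


@dataclass
class SimulationTruth:
    seed: int
    precursors: list[PlantedPrecursor] = field(default_factory=list)
    decoy_loci: list[tuple[str, int, int]] = field(default_factory=list)
    expression: list[PlantedTag] = field(default_factory=list)
    de_tags: list[str] = field(default_factory=list)
    degradome_sites: list[PlantedSite] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _shuffled(rng: np.random.Generator, seq: str) -> str:
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def make_genome(
    seed: int,
    n_hairpins: int = 20,
    n_decoys: int = 20,
    size: int = 100_000,
) -> tuple[SequenceRecord, SimulationTruth]:
    """Random genome with planted hairpin precursors and decoy loci.

    Each precursor is a 21-nt mature on one arm, its full reverse complement
    on the other (21 paired bases) and a loop of at least 8 nt; decoys are
    shuffled precursor sequences, which preserves composition but destroys
    pairing. Loci are evenly spaced so windows never overlap.
    """
    if size <= 0 or n_hairpins < 0 or n_decoys < 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    genome = list(_random_seq(rng, size))
    truth = SimulationTruth(seed=seed)
    n_loci = n_hairpins + n_decoys
    if n_loci:
        spacing = size // (n_loci + 1)
        for i in range(n_loci):
            mature = _random_seq(rng, MATURE_LEN)
            loop = _random_seq(rng, LOOP_LEN)
            arm = "5p" if rng.random() < 0.5 else "3p"
            if arm == "5p":
                precursor = mature + loop + reverse_complement(mature)
                mat_offset = 0
            else:
                precursor = reverse_complement(mature) + loop + mature
                mat_offset = MATURE_LEN + LOOP_LEN
            start = spacing * (i + 1)  # 0-based insertion point
            if i < n_hairpins:
                genome[start : start + len(precursor)] = precursor
                truth.precursors.append(
                    PlantedPrecursor(
                        locus=("chrS", start + 1, start + len(precursor), "+"),
                        arm=arm,
                        mature=mature,
                        precursor=precursor,
                    )
                )
            else:
                decoy = _shuffled(rng, precursor)
                genome[start : start + len(decoy)] = decoy
                truth.decoy_loci.append(("chrS", start + 1, start + len(decoy)))
            _ = mat_offset  # mature position recoverable from arm + locus
    record = SequenceRecord("chrS", "".join(genome))
    return record, truth


def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2; Poisson at 0."""
    if dispersion <= 0:
        return rng.poisson(means)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + means)
    return rng.negative_binomial(size_param, p)


def simulate_libraries(
    truth: SimulationTruth,
    depth: int = 200_000,
    fold_changes: Mapping[str, float] | None = None,
    dispersion: float = 0.1,
    length_mix: Mapping[int, float] | None = None,
    n_background: int = 300,
    adapter: str = DEFAULT_ADAPTER,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Two read libraries (MF, CMS) as adapter-carrying reads.

    Planted mature sequences plus random background tags receive NB counts
    around means that split ``depth`` across tags; CMS means are MF means
    times the planted fold change for DE tags. Background read lengths follow
    ``length_mix`` (21-nt dominant, 24-nt secondary by default). The 3'
    adapter is appended so the cleaning stage is exercised end to end.
    """
    rng = np.random.default_rng(truth.seed + 1)
    length_mix = dict(length_mix or DEFAULT_LENGTH_MIX)
    fold_changes = dict(fold_changes or {})

    tags: list[str] = [p.mature for p in truth.precursors]
    lengths = np.array(list(length_mix))
    probs = np.array(list(length_mix.values()), dtype=float)
    probs /= probs.sum()
    for _ in range(n_background):
        n = int(rng.choice(lengths, p=probs))
        tags.append(_random_seq(rng, n))
    tags = list(dict.fromkeys(tags))  # dedupe, order-preserving

    if depth <= 0:
        truth.expression = []
        truth.de_tags = []
        return [], []

    # Skewed abundance: exponential weights, scaled so means sum to depth.
    weights = rng.exponential(1.0, size=len(tags))
    mf_means = weights / weights.sum() * depth
    mf_means = np.maximum(mf_means, 1.0)
    cms_means = mf_means.copy()
    truth.expression = []
    truth.de_tags = []
    for i, seq in enumerate(tags):
        fc = fold_changes.get(seq, 1.0)
        cms_means[i] = mf_means[i] * fc
        truth.expression.append(PlantedTag(seq, float(mf_means[i]), float(cms_means[i])))
        if fc != 1.0:
            truth.de_tags.append(seq)

    libraries: list[list[SequenceRecord]] = []
    for lib, means in (("MF", mf_means), ("CMS", cms_means)):
        counts = _draw_counts(rng, means, dispersion)
        reads = []
        serial = 0
        for seq, c in zip(tags, counts):
            read_seq = seq + adapter
            for _ in range(int(c)):
                serial += 1
                reads.append(SequenceRecord(f"{lib}_{serial}", read_seq))
        libraries.append(reads)
    return libraries[0], libraries[1]


def simulate_degradome(
    transcripts: Sequence[SequenceRecord],
    planted_sites: Sequence[PlantedSite],
    signal: int = 20,
    noise_positions: int = 30,
    tag_length: int = 20,
    seed: int = 0,
    library: str = "default",
) -> list[SequenceTag]:
    """Degradome tags realizing each planted site's intended category.

    Counts are engineered per transcript: a category-0 site gets a dominant
    unique maximum (``signal`` reads), category 1 a duplicated maximum,
    category 2 a count above the noise median, category 3 at the median,
    category 4 a singleton; uniform low-count noise tags fill
    ``noise_positions`` other positions of each targeted transcript.
    """
    rng = np.random.default_rng(seed)
    by_transcript = {t.identifier: t for t in transcripts}
    tag_counts: dict[str, int] = {}

    def emit(t: SequenceRecord, position: int, count: int) -> None:
        if position < 1 or position + tag_length - 1 > len(t.sequence):
            raise ValueError(
                f"{t.identifier}: site at {position} leaves no room for a "
                f"{tag_length}-nt tag"
            )
        seq = t.sequence[position - 1 : position - 1 + tag_length]
        tag_counts[seq] = tag_counts.get(seq, 0) + count

    sites_by_t: dict[str, list[PlantedSite]] = {}
    for site in planted_sites:
        if site.transcript_id not in by_transcript:
            raise ValueError(f"unknown transcript {site.transcript_id}")
        sites_by_t.setdefault(site.transcript_id, []).append(site)

    for t_id, sites in sites_by_t.items():
        t = by_transcript[t_id]
        occupied = {s.cleavage_position for s in sites}
        # Noise: counts 2..3 so the noise median is well below the planted
        # maximum and above a singleton.
        noise_level = 2
        free = [
            p for p in range(1, len(t.sequence) - tag_length + 2) if p not in occupied
        ]
        n_noise = min(noise_positions, len(free))
        noise_pos = rng.choice(free, size=n_noise, replace=False) if n_noise else []
        noise_set = {int(p) for p in noise_pos}
        for p in sorted(noise_set):
            emit(t, p, int(noise_level + rng.integers(0, 2)))
        spare = iter(p for p in free if p not in noise_set)
        # Categories 2/3 are defined relative to the transcript maximum, so
        # they need a dominant position elsewhere unless a planted 0/1 site
        # already provides one.
        if (
            any(s.category in (2, 3) for s in sites)
            and not any(s.category in (0, 1) for s in sites)
        ):
            emit(t, next(spare), signal)
        for site in sites:
            if site.category == 0:
                if signal <= 1:
                    raise ValueError("category 0 needs signal > 1")
                emit(t, site.cleavage_position, signal)
            elif site.category == 1:
                if signal <= 1:
                    raise ValueError("category 1 needs signal > 1")
                emit(t, site.cleavage_position, signal)
                emit(t, next(spare), signal)  # duplicate maximum elsewhere
            elif site.category == 2:
                if n_noise < 2:
                    raise ValueError(
                        "category 2 needs >= 2 noise positions to sit between "
                        "median and maximum"
                    )
                emit(t, site.cleavage_position, max(4, signal // 4))
            elif site.category == 3:
                emit(t, site.cleavage_position, 2)
            elif site.category == 4:
                emit(t, site.cleavage_position, 1)
            else:
                raise ValueError(f"category {site.category} outside 0–4")

    return [
        SequenceTag(seq, {library: n})
        for seq, n in sorted(tag_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
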