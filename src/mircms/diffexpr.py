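"""Two-library differential expression of tag counts.

Counts from the two libraries (maintainer-fertile, MF, as library 1 and
male-sterile, CMS, as library 2) are rescaled to a common total and compared
with three digital-expression statistics; a tag is called differentially
expressed only when all three agree at the significance threshold
(default 0.01):

* **Audic–Claverie**: the exact point probability of observing ``y`` tags in
  library 2 given ``x`` in library 1,

      p(y|x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

  which with equal totals reduces to C(x+y, x) / 2^(x+y+1). Computed in log
  space so large counts never overflow. Note this is the point probability,
  not a tail sum — that convention is what reproduces the study tables this
  package validates against.
* **Fisher's exact test**, two-sided by doubling the smaller one-sided
  hypergeometric tail of the 2x2 table [[x, N1-x], [y, N2-y]], clamped at 1.
* **Pearson chi-square** on the same 2x2 table, 1 df, no continuity
  correction (a Yates correction would not reproduce the reference values).

In the regime N >> counts all three depend essentially only on (x, y); the
calls are insensitive to the exact library totals used for normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma, log, exp
from typing import Iterable, Mapping, Sequence

from scipy.stats import chi2, hypergeom

DEFAULT_SCALE = 1_000_000
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class CountPair:
    """Counts of one tag in two libraries with the library totals on the
    same scale: x out of N1 (library 1, MF), y out of N2 (library 2, CMS)."""

    x: float
    y: float
    n1: float
    n2: float

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")
        if not (0 <= self.x <= self.n1 and 0 <= self.y <= self.n2):
            raise ValueError(
                f"counts ({self.x}, {self.y}) outside [0, total] for totals "
                f"({self.n1}, {self.n2})"
            )


@dataclass
class DEResult:
    identifier: str
    pair: CountPair
    p_ac: float
    p_fisher: float
    p_chi2: float
    direction: str = "unchanged"  # "up" | "down" | "unchanged" (CMS vs MF)
    significant: bool = False


def normalize(count: float, library_total: float, scale: int = DEFAULT_SCALE) -> int:
    """Rescale a raw count to a common library total (default tags per
    million), rounding to the nearest integer."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return round(count * scale / library_total)


def ac_test(pair: CountPair) -> float:
    """Audic–Claverie point probability p(y|x), log-space."""
    x, y, r = pair.x, pair.y, pair.n2 / pair.n1
    log_p = (
        y * log(r)
        + lgamma(x + y + 1)
        - lgamma(x + 1)
        - lgamma(y + 1)
        - (x + y + 1) * log(1 + r)
    )
    return exp(log_p)


def fisher_test(pair: CountPair) -> float:
    """Two-sided Fisher exact p by tail doubling on [[x, N1-x], [y, N2-y]]."""
    x, y = int(pair.x), int(pair.y)
    n1, n2 = int(pair.n1), int(pair.n2)
    # X ~ Hypergeom(M = N1+N2 population, n = x+y successes, N = N1 draws)
    lower = float(hypergeom.cdf(x, n1 + n2, x + y, n1))
    upper = float(hypergeom.sf(x - 1, n1 + n2, x + y, n1))
    return min(1.0, 2.0 * min(lower, upper))


def chi2_test(pair: CountPair) -> float:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table."""
    x, y, n1, n2 = pair.x, pair.y, pair.n1, pair.n2
    if x + y == 0:
        warnings.warn("chi-square undefined for x + y = 0; returning p = 1")
        return 1.0
    n = n1 + n2
    # Pearson statistic for [[x, n1-x], [y, n2-y]] in closed form.
    col1, col2 = x + y, n - x - y
    stat = (
        n * (x * (n2 - y) - y * (n1 - x)) ** 2 / (n1 * n2 * col1 * col2)
    )
    return float(chi2.sf(stat, df=1))


def evaluate_pair(identifier: str, pair: CountPair) -> DEResult:
    return DEResult(identifier, pair, ac_test(pair), fisher_test(pair), chi2_test(pair))


def call_de(results: Iterable[DEResult], alpha: float = DEFAULT_ALPHA) -> list[DEResult]:
    """Annotate results with direction and the consensus significance call:
    significant iff all three p-values are at or below ``alpha``."""
    out = []
    for res in results:
        x_norm = res.pair.x / res.pair.n1
        y_norm = res.pair.y / res.pair.n2
        if y_norm > x_norm:
            res.direction = "up"
        elif y_norm < x_norm:
            res.direction = "down"
        else:
            res.direction = "unchanged"
        res.significant = (
            res.p_ac <= alpha and res.p_fisher <= alpha and res.p_chi2 <= alpha
        )
        out.append(res)
    return out


def de_from_tags(
    tags: Sequence,
    library_1: str,
    library_2: str,
    totals: Mapping[str, float] | None = None,
    scale: int = DEFAULT_SCALE,
    alpha: float = DEFAULT_ALPHA,
) -> list[DEResult]:
    """Run the full DE stage on collapsed SequenceTags.

    Raw per-library counts are normalized to ``scale`` using the library
    totals (computed from the tag set itself when not supplied), then the
    three tests are run on the normalized pairs with equal totals ``scale``.
    """
    if totals is None:
        totals = {
            library_1: sum(t.counts.get(library_1, 0) for t in tags),
            library_2: sum(t.counts.get(library_2, 0) for t in tags),
        }
    results = []
    for tag in tags:
        x = normalize(tag.counts.get(library_1, 0), totals[library_1], scale)
        y = normalize(tag.counts.get(library_2, 0), totals[library_2], scale)
        pair = CountPair(x, y, scale, scale)
        results.append(evaluate_pair(tag.sequence, pair))
    return call_de(results, alpha=alpha)
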