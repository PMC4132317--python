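"""Composition-preserving shuffle null model and score-tier classification.

The survey's significance control: for every query, a "random analog"
(a uniform permutation of its residues, so length and composition are
preserved exactly) is searched against the same proteome, and the ten
best bit scores of the native and the analog searches are compared
with a pooled-variance two-sample Student's t-test.  A query whose
analog scores approach its own is flagged "exclusive": its similarity
signal is attributable to composition/periodicity (typically coiled
coil) rather than homology.

Tier semantics for reported maxima: below 50 bits similarity is
considered very low (omitted from rendered tables); 100 bits and above
is high.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pairwise_align import ScoringScheme, bit_score, evalue, encode, local_align_score
from .seqio import ProteinRecord

#: default flag rule: analog max within this ratio of native max ...
EXCLUSIVITY_RATIO = 0.7
#: ... and t-test fails to separate the two top-k lists at this level
ALPHA = 0.05
#: ... and the native max itself is at least "significant" (>= moderate tier)
EXCLUSIVITY_MIN_BITS = 50.0

TIER_THRESHOLDS = (50.0, 100.0)


class SimilarityTier(enum.IntEnum):
    low = 0
    moderate = 1
    high = 2


def classify_tier(max_bits: float, thresholds: tuple[float, float] = TIER_THRESHOLDS) -> SimilarityTier:
    """low < thresholds[0] <= moderate < thresholds[1] <= high."""
    if max_bits < 0:
        raise ValueError("bit score must be >= 0")
    lo, hi = thresholds
    if max_bits < lo:
        return SimilarityTier.low
    if max_bits < hi:
        return SimilarityTier.moderate
    return SimilarityTier.high


def random_analog(record: ProteinRecord, seed: int) -> ProteinRecord:
    """Uniform random permutation of the residues (Fisher-Yates).

    Length and residue multiset are preserved exactly; the id gets a
    ``_shuffled`` suffix.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(record.seq))
    rng.shuffle(letters)
    return ProteinRecord(
        id=record.id + "_shuffled",
        seq="".join(letters.tolist()),
        description=record.description,
        taxon=record.taxon,
    )


def top_k_scores(
    query: ProteinRecord,
    proteome: list[ProteinRecord],
    scheme: ScoringScheme,
    k: int = 10,
    e_max: float = 100.0,
    db_size: int | None = None,
) -> list[float]:
    """Bit scores of the k best distinct subjects with E <= e_max, descending.

    The E-value search space is (query length) x (total proteome
    residues) unless ``db_size`` overrides the latter.  Ties at the
    k-th rank are broken by subject id so the result is deterministic
    regardless of proteome order.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    n_db = db_size if db_size is not None else sum(len(r.seq) for r in proteome)
    q = encode(query.seq)
    scored: list[tuple[float, str]] = []
    for rec in proteome:
        raw = local_align_score(q, encode(rec.seq), scheme)
        bits = bit_score(raw, scheme)
        if evalue(bits, len(query.seq), n_db) <= e_max:
            scored.append((bits, rec.id))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [bits for bits, _ in scored[:k]]


def students_t(a: list[float], b: list[float]) -> tuple[float, float]:
    """Classic pooled-variance two-sample t-test (two-sided).

    df = len(a) + len(b) - 2.  Zero pooled variance is handled by
    contract: equal means give (0, 1); unequal means give a signed
    infinite t with p = 0.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must have at least 2 observations")
    aa, bb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    va = aa.var(ddof=1)
    vb = bb.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if aa.mean() == bb.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, aa.mean() - bb.mean()), 0.0
    t, p = stats.ttest_ind(aa, bb, equal_var=True)
    return float(t), float(p)


def welch_t(a: list[float], b: list[float]) -> tuple[float, float]:
    """Welch's unequal-variance alternative (available by choice)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


@dataclass
class NullComparison:
    """Native-vs-shuffled-analog search comparison for one query."""

    query_id: str
    native_max: float
    random_max: float
    native_top: list[float] = field(default_factory=list)
    random_top: list[float] = field(default_factory=list)
    t_stat: float | None = None
    p_value: float | None = None
    exclusive_flag: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if sorted(self.native_top, reverse=True) != self.native_top:
            raise ValueError("native_top must be sorted descending")
        if self.native_top and self.native_max != self.native_top[0]:
            raise ValueError("native_max must equal native_top[0]")


def null_comparison(
    query: ProteinRecord,
    proteome: list[ProteinRecord],
    scheme: ScoringScheme,
    seed: int,
    k: int = 10,
    e_max: float = 100.0,
    n_analogs: int = 1,
    exclusivity_ratio: float = EXCLUSIVITY_RATIO,
    alpha: float = ALPHA,
    min_bits: float = EXCLUSIVITY_MIN_BITS,
    use_welch: bool = False,
) -> NullComparison:
    """Compare native vs shuffled-analog top-k search scores.

    With ``n_analogs > 1`` the analog score lists are pooled and the
    best k kept (one analog, as in the original procedure, is the
    default).  The exclusivity flag fires when the analog's maximum
    reaches ``exclusivity_ratio`` of the native maximum, the t-test
    fails to separate the lists at ``alpha``, and the native maximum is
    itself at least ``min_bits`` (scores below the reporting floor are
    not evidence of anything).  When either side has fewer than 2
    qualifying scores, t/p stay None and the flag is decided on the
    max-ratio (and floor) alone.
    """
    native = top_k_scores(query, proteome, scheme, k=k, e_max=e_max)
    pooled: list[float] = []
    for a in range(n_analogs):
        analog = random_analog(query, seed + a)
        pooled.extend(top_k_scores(analog, proteome, scheme, k=k, e_max=e_max))
    pooled.sort(reverse=True)
    rand = pooled[:k]

    native_max = native[0] if native else 0.0
    random_max = rand[0] if rand else 0.0

    t = p = None
    if len(native) >= 2 and len(rand) >= 2:
        test = welch_t if use_welch else students_t
        t, p = test(native, rand)

    ratio_hit = native_max > 0 and random_max >= exclusivity_ratio * native_max
    t_fails = p is None or p >= alpha
    flag = bool(ratio_hit and t_fails and native_max >= min_bits)
    return NullComparison(
        query_id=query.id,
        native_max=native_max,
        random_max=random_max,
        native_top=native,
        random_top=rand,
        t_stat=t,
        p_value=p,
        exclusive_flag=flag,
        seed=seed,
    )
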