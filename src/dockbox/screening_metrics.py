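"""Virtual-screening ranking metrics and nonparametric tests.

A screening run produces a ranked library: compounds ordered by docking
score, lower (more negative) meaning stronger predicted binding, each
labelled active or decoy.  This module scores how early the actives
appear:

* enrichment factors EF at a top fraction (EF^1%, EF^10%),
* BEDROC (Boltzmann-enhanced discrimination of ROC; alpha = 20
  concentrates about 80% of the weight in the top 8% of the library),
* the rank-based enrichment AUC (probability a random active outranks a
  random decoy, ties counting one half), and
* ACT-50%: the smallest top fraction of the library holding half of the
  actives.

It also provides the two nonparametric tests used to compare score
distributions and paired protocol results: the Mann-Whitney U test and
the Wilcoxon signed-rank test, each with exact enumeration at small
sample sizes and a tie- and continuity-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedLibrary",
    "MetricReport",
    "ScoreClassSummary",
    "enrichment_factor",
    "bedroc",
    "bedroc_weight_fraction",
    "enrichment_auc",
    "act_fraction",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "score_class_summary",
    "metric_report",
    "MANN_WHITNEY_EXACT_MAX",
    "WILCOXON_EXACT_MAX",
]

#: exact-enumeration size limits for the two tests; above these the normal
#: approximation with tie and continuity corrections is used
MANN_WHITNEY_EXACT_MAX = 12
WILCOXON_EXACT_MAX = 15


@dataclass
class RankedLibrary:
    """A ranked screening result.

    Entries are sorted ascending by score (best first) with ties kept in
    stable input order.  ``labels`` is boolean, True for actives.
    """

    ids: list[str]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must have equal length")
        if len(self.ids) == 0:
            raise ValueError("ranked library is empty")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        order = np.argsort(self.scores, kind="stable")
        self.ids = [self.ids[i] for i in order]
        self.scores = self.scores[order]
        self.labels = self.labels[order]

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, float, str | bool]]
    ) -> "RankedLibrary":
        """Build from ``(id, score, label)`` tuples.

        Labels may be booleans or the strings ``active`` / ``decoy``.
        """
        ids, scores, labels = [], [], []
        for cid, score, label in entries:
            ids.append(str(cid))
            scores.append(float(score))
            labels.append(_parse_label(label))
        return cls(ids, np.array(scores), np.array(labels))

    @classmethod
    def from_table(cls, path: str | Path) -> "RankedLibrary":
        """Read a delimited table with ``id``, ``score``, ``label`` columns."""
        table = pd.read_csv(path, sep=None, engine="python")
        table.columns = [c.strip().lower() for c in table.columns]
        required = {"id", "score", "label"}
        if not required.issubset(table.columns):
            raise ValueError(f"ranked table needs columns {sorted(required)}")
        return cls.from_entries(
            zip(table["id"], table["score"], table["label"])
        )

    def to_table(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(
            {
                "id": self.ids,
                "score": self.scores,
                "label": np.where(self.labels, "active", "decoy"),
            }
        ).to_csv(path, sep=sep, index=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def n_decoys(self) -> int:
        return self.n - self.n_actives

    def active_ranks(self) -> np.ndarray:
        """1-based rank positions of the actives."""
        return np.nonzero(self.labels)[0] + 1


def _parse_label(label: str | bool) -> bool:
    if isinstance(label, (bool, np.bool_)):
        return bool(label)
    text = str(label).strip().lower()
    if text in ("active", "1", "true"):
        return True
    if text in ("decoy", "inactive", "0", "false"):
        return False
    raise ValueError(f"unrecognised label {label!r}")


@dataclass(frozen=True)
class MetricReport:
    """The standard panel of screening metrics for one target."""

    ef_1pct: float
    ef_10pct: float
    bedroc20: float
    auc: float
    act50: float

    def as_dict(self) -> dict[str, float]:
        return {
            "EF1%": self.ef_1pct,
            "EF10%": self.ef_10pct,
            "BEDROC20": self.bedroc20,
            "AUC": self.auc,
            "ACT-50%": self.act50,
        }


@dataclass(frozen=True)
class ScoreClassSummary:
    """Per-class score statistics and the Mann-Whitney comparison."""

    mean_active: float
    sd_active: float
    mean_decoy: float
    sd_decoy: float
    abs_difference: float
    mw_u: float
    mw_p: float


def _require_both_classes(lib: RankedLibrary) -> None:
    if lib.n_actives == 0:
        raise ValueError("library contains no actives")
    if lib.n_decoys == 0:
        raise ValueError("library contains no decoys")


def enrichment_factor(lib: RankedLibrary, top_fraction: float) -> float:
    """Enrichment factor at a top fraction of the ranked library.

    The top set holds ``ceil(top_fraction * N)`` compounds (at least one);
    the factor is the active density in that set divided by the active
    density in the whole library, so 1.0 is the random expectation.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    if lib.n_actives == 0:
        raise ValueError("enrichment undefined: library contains no actives")
    top_n = max(1, math.ceil(top_fraction * lib.n))
    actives_top = int(lib.labels[:top_n].sum())
    return (actives_top / top_n) / (lib.n_actives / lib.n)


def bedroc(lib: RankedLibrary, alpha: float = 20.0) -> float:
    """BEDROC score: exponentially early-weighted enrichment in [0, 1].

    Each active at 1-based rank r contributes ``exp(-alpha * r / N)``.
    The robust initial enhancement (the weighted sum over actives divided
    by its expectation under a uniform rank distribution) is then mapped
    onto [0, 1] with its minimum and maximum at the observed active
    fraction Ra = n / N:

        BEDROC = RIE * Ra * sinh(a/2) / (cosh(a/2) - cosh(a/2 - a*Ra))
                 + 1 / (1 - exp(a * (1 - Ra)))
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    _require_both_classes(lib)
    big_n = lib.n
    n = lib.n_actives
    ra = n / big_n
    ranks = lib.active_ranks()
    s = float(np.sum(np.exp(-alpha * ranks / big_n)))
    rie = (s / n) / (
        (1.0 / big_n) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / big_n) - 1.0)
    )
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    return rie * factor + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))


def bedroc_weight_fraction(
    alpha: float = 20.0, top_fraction: float = 0.08, n_total: int = 100_000
) -> float:
    """Fraction of total exponential rank weight in the library's top part.

    For alpha = 20 about 80% of the weight sits in the top 8%; this is the
    early-recognition character of the BEDROC score.  Computed on a
    discrete library of ``n_total`` ranks.
    """
    if alpha <= 0 or not (0 < top_fraction <= 1) or n_total < 1:
        raise ValueError("invalid weight-fraction parameters")
    ranks = np.arange(1, n_total + 1)
    weights = np.exp(-alpha * ranks / n_total)
    k = math.ceil(top_fraction * n_total)
    return float(weights[:k].sum() / weights.sum())


def enrichment_auc(lib: RankedLibrary) -> float:
    """Rank-based AUC: probability an active outranks a decoy.

    Computed by the rank-sum (Mann-Whitney) identity with midrank ties, so
    tied scores contribute one half.  1.0 is a perfect ranking, 0.5 random.
    """
    _require_both_classes(lib)
    ranks = stats.rankdata(lib.scores)  # midranks, ascending (best = low)
    r_active = float(ranks[lib.labels].sum())
    n_a, n_d = lib.n_actives, lib.n_decoys
    u_active = n_a * n_d + n_a * (n_a + 1) / 2.0 - r_active
    return u_active / (n_a * n_d)


def act_fraction(lib: RankedLibrary, recovery: float = 0.5) -> float:
    """Smallest top fraction of the library containing ``recovery`` of actives.

    ACT-50% with the default recovery of one half.  The required active
    count is ``ceil(recovery * n_actives)``.
    """
    if not (0.0 < recovery <= 1.0):
        raise ValueError("recovery must be in (0, 1]")
    if lib.n_actives == 0:
        raise ValueError("ACT fraction undefined: library contains no actives")
    required = math.ceil(recovery * lib.n_actives)
    cumulative = np.cumsum(lib.labels)
    k = int(np.searchsorted(cumulative, required) + 1)
    return k / lib.n


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------

def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U the statistic of ``sample_a``.  For combined
    sizes up to 12 the null distribution is enumerated exactly over all
    assignments of the observed midranks, which handles ties correctly; a
    tie- and continuity-corrected normal approximation is used otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    if n_a + n_b <= MANN_WHITNEY_EXACT_MAX:
        p = _mann_whitney_exact_p(ranks, n_a, u_obs)
    else:
        _, p = stats.mannwhitneyu(
            a, b, alternative="two-sided", use_continuity=True,
            method="asymptotic",
        )
    return u_obs, float(min(p, 1.0))


def _mann_whitney_exact_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating rank assignments (ties included)."""
    n = len(ranks)
    mu = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mu)
    total = math.comb(n, n_a)
    offset = n_a * (n_a + 1) / 2.0
    hits = 0
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_signed_rank(paired_diffs: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; absolute differences receive midranks.
    Returns ``(W, p)`` with W the positive-rank sum.  Up to 15 nonzero
    differences the 2^n sign patterns are enumerated exactly; beyond that
    a tie- and continuity-corrected normal approximation is used.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero: no signed ranks to test")
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX:
        p = _wilcoxon_exact_p(ranks, w_obs)
    else:
        _, p = stats.wilcoxon(
            d, alternative="two-sided", correction=True, method="approx",
            zero_method="wilcox",
        )
    return w_obs, float(min(p, 1.0))


def _wilcoxon_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p over all sign patterns (symmetric null)."""
    n = len(ranks)
    mu = ranks.sum() / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    for pattern in range(1 << n):
        w = 0.0
        for i in range(n):
            if pattern >> i & 1:
                w += ranks[i]
        if abs(w - mu) >= dev - 1e-12:
            hits += 1
    return hits / (1 << n)


def score_class_summary(lib: RankedLibrary) -> ScoreClassSummary:
    """Per-class score means/SDs and their Mann-Whitney comparison.

    SDs are sample standard deviations (ddof = 1; zero for singleton
    classes).  The absolute difference of class means is the headline
    separation between actives and decoys.
    """
    _require_both_classes(lib)
    active_scores = lib.scores[lib.labels]
    decoy_scores = lib.scores[~lib.labels]

    def _sd(x: np.ndarray) -> float:
        return float(x.std(ddof=1)) if x.size > 1 else 0.0

    u, p = mann_whitney_u(active_scores, decoy_scores)
    return ScoreClassSummary(
        mean_active=float(active_scores.mean()),
        sd_active=_sd(active_scores),
        mean_decoy=float(decoy_scores.mean()),
        sd_decoy=_sd(decoy_scores),
        abs_difference=abs(float(active_scores.mean() - decoy_scores.mean())),
        mw_u=u,
        mw_p=p,
    )


def metric_report(
    lib: RankedLibrary,
    ef_fractions: tuple[float, float] = (0.01, 0.10),
    bedroc_alpha: float = 20.0,
) -> MetricReport:
    """Compute the standard metric panel for one ranked library."""
    return MetricReport(
        ef_1pct=enrichment_factor(lib, ef_fractions[0]),
        ef_10pct=enrichment_factor(lib, ef_fractions[1]),
        bedroc20=bedroc(lib, bedroc_alpha),
        auc=enrichment_auc(lib),
        act50=act_fraction(lib, 0.5),
    )
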