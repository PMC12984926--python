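"""Co-differential-regulation screening of phosphosite pairs.

An *anchor* site (a protein's predominant phosphosite) is paired with
every candidate partner site.  Over the shared experimental conditions the
joint per-condition states are tallied into a 2x2 contingency table:

====  =============================================================
cell  meaning (per condition)
====  =============================================================
a     neither site called (both N)
b     exactly one of the two sites called
c     discordant calls — UD or DU (negative co-regulation events)
d     concordant calls — UU or DD (positive co-regulation events)
====  =============================================================

The association is scored with a two-sided Fisher's exact test computed
from scratch on the table ``[[a, b], [c, d]]`` (sum of hypergeometric
point probabilities over all tables with the observed margins that are no
more probable than the observed one).  Pairs are then classified positive
(UU/DD dominate) or negative (UD/DU dominate) and passed through
high-confidence filters: FET p below alpha, supporting-event count at
least a fraction of the anchor's differential frequency, and independent
evidence from a minimum number of studies (PMIDs) and experimental
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .ingest import RegulationMatrix, SiteKey

logger = logging.getLogger(__name__)

#: Relative tolerance for the "no more probable than observed" comparison;
#: guards against floating-point boundary misclassification of tied tables.
FET_REL_TOL = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairStateCounts:
    """Joint-state tallies for one (anchor, partner) pair over all conditions."""

    anchor: SiteKey
    partner: SiteKey
    uu: int
    dd: int
    ud: int
    du: int
    a: int
    b: int
    supporting_pmids_pos: frozenset[str] = frozenset()
    supporting_pmids_neg: frozenset[str] = frozenset()
    supporting_conditions_pos: frozenset[str] = frozenset()
    supporting_conditions_neg: frozenset[str] = frozenset()

    @property
    def c(self) -> int:
        """Discordant (negative co-regulation) event count: ud + du."""
        return self.ud + self.du

    @property
    def d(self) -> int:
        """Concordant (positive co-regulation) event count: uu + dd."""
        return self.uu + self.dd

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class CoRegulationCall:
    """One screened pair: counts, FET p-value, direction and filter outcome."""

    pair: PairStateCounts
    fet_p: float
    direction: str  # positive | negative | none
    passes_filters: bool = False
    filter_log: dict = field(default_factory=dict, compare=False)
    fet_p_adj: float | None = None
    annotations: frozenset[str] = frozenset()

    @property
    def supporting_count(self) -> int:
        if self.direction == "positive":
            return self.pair.d
        if self.direction == "negative":
            return self.pair.c
        return 0

    @property
    def supporting_pmids(self) -> frozenset[str]:
        if self.direction == "negative":
            return self.pair.supporting_pmids_neg
        return self.pair.supporting_pmids_pos

    @property
    def supporting_conditions(self) -> frozenset[str]:
        if self.direction == "negative":
            return self.pair.supporting_conditions_neg
        return self.pair.supporting_conditions_pos

    @property
    def odds_ratio(self) -> float:
        """Convenience effect size (a*d)/(b*c); inf when b*c = 0 and a*d > 0."""
        p = self.pair
        if p.b * p.c == 0:
            return float("inf") if p.a * p.d > 0 else float("nan")
        return (p.a * p.d) / (p.b * p.c)


@dataclass(frozen=True)
class ConfidenceCriteria:
    """High-confidence inclusion criteria for screened pairs."""

    alpha: float = 0.05
    freq_fraction: float = 0.10
    min_pmids: int = 3
    min_conditions: int = 3
    dominance_ratio: float = 1.0
    bh_adjust: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.freq_fraction < 0:
            raise ValueError("freq_fraction must be >= 0")
        if self.min_pmids < 1 or self.min_conditions < 1:
            raise ValueError("min_pmids and min_conditions must be >= 1")


# ---------------------------------------------------------------------------
# Pair coding
# ---------------------------------------------------------------------------


def code_pair_states(
    matrix: RegulationMatrix, anchor: SiteKey, partner: SiteKey
) -> PairStateCounts:
    """Tally joint per-condition states for one pair.

    The first position of each two-letter code is the anchor's state, the
    second the partner's: UU/DD are concordant (d-events), UD/DU are
    discordant (c-events).  Conditions where both are N count into ``a``,
    exactly one called into ``b``.  Supporting PMIDs/conditions collect the
    evidence behind d-events (positive) and c-events (negative).
    """
    if anchor == partner:
        raise ValueError(f"self-pairing disallowed: {anchor}")
    a_states = matrix.site_states(anchor)
    p_states = matrix.site_states(partner)
    return _code_from_vectors(
        matrix, anchor, partner, a_states, p_states
    )


def _code_from_vectors(
    matrix: RegulationMatrix,
    anchor: SiteKey,
    partner: SiteKey,
    a_states: np.ndarray,
    p_states: np.ndarray,
) -> PairStateCounts:
    conditions = np.asarray(matrix.conditions, dtype=object)
    uu = (a_states == "U") & (p_states == "U")
    dd = (a_states == "D") & (p_states == "D")
    ud = (a_states == "U") & (p_states == "D")
    du = (a_states == "D") & (p_states == "U")
    both_n = (a_states == "N") & (p_states == "N")
    one_n = ((a_states == "N") | (p_states == "N")) & ~both_n
    pos_conditions = conditions[uu | dd]
    neg_conditions = conditions[ud | du]
    pmids = matrix.condition_pmids
    return PairStateCounts(
        anchor=anchor,
        partner=partner,
        uu=int(uu.sum()),
        dd=int(dd.sum()),
        ud=int(ud.sum()),
        du=int(du.sum()),
        a=int(both_n.sum()),
        b=int(one_n.sum()),
        supporting_pmids_pos=frozenset(pmids[c] for c in pos_conditions),
        supporting_pmids_neg=frozenset(pmids[c] for c in neg_conditions),
        supporting_conditions_pos=frozenset(pos_conditions),
        supporting_conditions_neg=frozenset(neg_conditions),
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (from scratch)
# ---------------------------------------------------------------------------


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    With margins fixed, the probability of a table is hypergeometric:

        P(a) = (a+b)! (c+d)! (a+c)! (b+d)! / ( n! a! b! c! d! )

    The two-sided p-value sums P over every table with the observed
    margins whose point probability does not exceed the observed table's
    (within relative tolerance :data:`FET_REL_TOL`).  Factorials are
    handled in log space; the result is clipped into (0, 1].
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, r2, c1 = a + b, c + d, a + c
    # support of the a-cell given fixed margins
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    log_probs = _log_hypergeom_pmf(support, n, r1, c1)
    log_obs = _log_hypergeom_pmf(np.array([a]), n, r1, c1)[0]
    # include tables whose probability is <= observed, with relative slack
    include = log_probs <= log_obs + np.log1p(FET_REL_TOL)
    if include.all():
        return 1.0  # the whole support is at least as extreme; the mass sums to 1 exactly
    p = float(np.exp(log_probs[include]).sum())
    return min(p, 1.0)


def _log_hypergeom_pmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """log P(a = k) for the 2x2 hypergeometric with total n, row1 sum r1, col1 sum c1."""
    r2, c2 = n - r1, n - c1
    return (
        gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1) + gammaln(c2 + 1)
        - gammaln(n + 1)
        - gammaln(k + 1) - gammaln(r1 - k + 1) - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
    )


def fisher_exact_one_sided_tail(a: int, b: int, c: int, d: int) -> float:
    """Upper one-sided tail P(A >= a) under the same hypergeometric null.

    Provided for the invariant that the two-sided p is never smaller than
    the matching one-sided tail built from identical point probabilities.
    """
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    hi = min(r1, c1)
    support = np.arange(a, hi + 1)
    return float(min(np.exp(_log_hypergeom_pmf(support, n, r1, c1)).sum(), 1.0))


# ---------------------------------------------------------------------------
# Classification and filtering
# ---------------------------------------------------------------------------


def classify_coregulation(
    pair: PairStateCounts, criteria: ConfidenceCriteria | None = None
) -> str:
    """Direction call from the c/d dominance: positive, negative or none (ties -> none)."""
    criteria = criteria or ConfidenceCriteria()
    c, d = pair.c, pair.d
    if d > 0 and d > c and d / max(c, 1) >= criteria.dominance_ratio:
        return "positive"
    if c > 0 and c > d and c / max(d, 1) >= criteria.dominance_ratio:
        return "negative"
    return "none"


def apply_confidence_filters(
    call: CoRegulationCall,
    anchor_diff_frequency: int,
    criteria: ConfidenceCriteria | None = None,
) -> CoRegulationCall:
    """Evaluate the high-confidence inclusion criteria; returns the call with
    ``passes_filters`` and a per-criterion ``filter_log`` set.

    A pair passes only if all hold: FET p < alpha; supporting-event count
    (d for positive, c for negative) at least ``freq_fraction`` of the
    anchor's differential frequency; supporting PMIDs >= ``min_pmids``;
    supporting conditions >= ``min_conditions``; and a direction was called.
    """
    criteria = criteria or ConfidenceCriteria()
    p = call.fet_p_adj if (criteria.bh_adjust and call.fet_p_adj is not None) else call.fet_p
    log = {
        "has_direction": call.direction in ("positive", "negative"),
        "alpha": p < criteria.alpha,
        "frequency": call.supporting_count >= criteria.freq_fraction * anchor_diff_frequency,
        "min_pmids": len(call.supporting_pmids) >= criteria.min_pmids,
        "min_conditions": len(call.supporting_conditions) >= criteria.min_conditions,
    }
    return replace(call, passes_filters=all(log.values()), filter_log=log)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

_STATE_CODE = {"N": 0, "U": 1, "D": 2}


def coregulation_screen(
    matrix: RegulationMatrix,
    anchor: SiteKey,
    criteria: ConfidenceCriteria | None = None,
    include_same_protein: bool = False,
) -> list[CoRegulationCall]:
    """Screen an anchor site against every candidate partner in the matrix.

    By default the partner universe excludes sites on the anchor's own
    protein (the screen targets phosphosites in *other* proteins);
    ``include_same_protein`` widens it to intra-protein pairs.  Results are
    sorted by FET p ascending, then supporting-event count descending, then
    partner identity — a deterministic pure function of the matrix.
    """
    criteria = criteria or ConfidenceCriteria()
    if anchor not in matrix.states.index:
        raise ValueError(f"anchor {anchor} not in matrix")
    partners = [
        s
        for s in matrix.sites
        if s != anchor and (include_same_protein or s.protein_symbol != anchor.protein_symbol)
    ]
    anchor_states = matrix.site_states(anchor)
    anchor_freq = int((anchor_states != "N").sum())
    calls: list[CoRegulationCall] = []
    for partner in partners:
        pair = _code_from_vectors(
            matrix, anchor, partner, anchor_states, matrix.site_states(partner)
        )
        p = fisher_exact_two_sided(pair.a, pair.b, pair.c, pair.d)
        direction = classify_coregulation(pair, criteria)
        calls.append(CoRegulationCall(pair=pair, fet_p=p, direction=direction))
    if criteria.bh_adjust and calls:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([c.fet_p for c in calls], method="fdr_bh")[1]
        calls = [replace(c, fet_p_adj=float(q)) for c, q in zip(calls, adj)]
    calls = [apply_confidence_filters(c, anchor_freq, criteria) for c in calls]
    calls.sort(
        key=lambda c: (
            c.fet_p,
            -c.supporting_count,
            c.pair.partner.protein_symbol,
            c.pair.partner.position,
            c.pair.partner.residue,
        )
    )
    _log_funnel(calls, anchor)
    return calls


def _log_funnel(calls: list[CoRegulationCall], anchor: SiteKey) -> None:
    if not calls:
        logger.info("screen %s: no candidate partners", anchor)
        return
    n = len(calls)
    by = {k: sum(1 for c in calls if c.filter_log.get(k)) for k in calls[0].filter_log}
    passing = sum(c.passes_filters for c in calls)
    logger.info(
        "screen %s: %d pairs; pass alpha %d, frequency %d, min_pmids %d, "
        "min_conditions %d; high-confidence %d (%d positive, %d negative)",
        anchor, n, by.get("alpha", 0), by.get("frequency", 0), by.get("min_pmids", 0),
        by.get("min_conditions", 0), passing,
        sum(1 for c in calls if c.passes_filters and c.direction == "positive"),
        sum(1 for c in calls if c.passes_filters and c.direction == "negative"),
    )


def screen_to_frame(calls: list[CoRegulationCall]) -> pd.DataFrame:
    """Flatten screen results to a DataFrame (one row per pair)."""
    rows = []
    for call in calls:
        p = call.pair
        row = {
            "partner_protein": p.partner.protein_symbol,
            "partner_site": p.partner.site_label,
            "uu": p.uu, "dd": p.dd, "ud": p.ud, "du": p.du,
            "a": p.a, "b": p.b, "c": p.c, "d": p.d, "n": p.n,
            "fet_p": call.fet_p,
            "fet_p_adj": call.fet_p_adj if call.fet_p_adj is not None else "",
            "odds_ratio": call.odds_ratio,
            "direction": call.direction,
            "passes_filters": call.passes_filters,
            "n_supporting_pmids": len(call.supporting_pmids),
            "n_supporting_conditions": len(call.supporting_conditions),
        }
        for k, v in call.filter_log.items():
            row[f"filter_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_screen_tsv(calls: list[CoRegulationCall], path) -> pd.DataFrame:
    df = screen_to_frame(calls)
    df.to_csv(path, sep="\t", index=False)
    return df
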