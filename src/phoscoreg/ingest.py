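"""Reading, validation and normalization of phosphosite observation tables.

Two kinds of observations are handled:

* **profiling records** — a site detected in a stand-alone phosphoproteome
  inventory (no control comparison), identified by a dataset id;
* **differential records** — a site quantified in one treatment-vs-control
  comparison ("experimental condition"), carrying a fold change, a p-value
  and the study (PubMed id) the comparison came from.

Both kinds carry mass-spectrometry localization evidence (localization
probability and/or A-score) used for class-1 confidence filtering.  After
filtering, per-condition regulation states are called (U = up, D = down,
N = not called) and assembled into a sites x conditions
:class:`RegulationMatrix`, the substrate for all downstream screening.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid phospho-acceptor residues.
ACCEPTOR_RESIDUES = frozenset("STY")

#: Regulation states.  N collapses "detected but unchanged" and "not
#: detected" into one level (see docs/methods.md).
STATES = ("U", "D", "N")

_SITE_RE = re.compile(r"^([A-Za-z])(\d+)$")


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SiteKey:
    """Identity of one phosphosite: protein symbol + residue + 1-based position.

    Equality and ordering ignore the (optional) accession: two observations
    of PKN1 S916 are the same site regardless of which protein accession
    version a study reported.
    """

    protein_symbol: str
    residue: str
    position: int
    accession: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.residue not in ACCEPTOR_RESIDUES:
            raise ValidationError(
                f"residue {self.residue!r} of {self.protein_symbol} is not one of S/T/Y"
            )
        if self.position < 1:
            raise ValidationError(
                f"position {self.position} of {self.protein_symbol} is not >= 1"
            )

    @property
    def site_label(self) -> str:
        """Residue+position, e.g. ``'S916'``."""
        return f"{self.residue}{self.position}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.protein_symbol}:{self.site_label}"


@dataclass(frozen=True)
class ProfilingRecord:
    """One detection of a site in one profiling dataset."""

    site: SiteKey
    dataset_id: str
    localization_probability: float | None = None
    a_score: float | None = None


@dataclass(frozen=True)
class DifferentialRecord:
    """One quantification of a site in one treatment-vs-control comparison."""

    site: SiteKey
    condition_code: str
    pmid: str
    fold_change: float
    p_value: float | None = None
    localization_probability: float | None = None
    a_score: float | None = None

    def __post_init__(self) -> None:
        if not (self.fold_change > 0):
            raise ValidationError(
                f"fold_change must be > 0, got {self.fold_change!r} for "
                f"{self.site} in {self.condition_code}"
            )


@dataclass(frozen=True)
class DifferentialThresholds:
    """Cutoffs for confidence filtering and regulation calling.

    Defaults reproduce the conventional phosphoproteomic criteria: class-1
    sites have localization probability >= 0.75 or A-score > 13; a site is
    called up-regulated when its treatment/control ratio exceeds 1.3 (down
    below 0.76) at study-level significance p < 0.05.
    """

    fc_up: float = 1.3
    fc_down: float = 0.76
    p_cutoff: float = 0.05
    loc_prob_min: float = 0.75
    a_score_min: float = 13.0
    #: treat a missing p-value as passing significance (for corpora where
    #: significance filtering happened upstream)
    allow_missing_p: bool = False

    def __post_init__(self) -> None:
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValidationError(
                f"need fc_down < 1 < fc_up, got {self.fc_down}, {self.fc_up}"
            )
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValidationError(f"p_cutoff must be in (0,1), got {self.p_cutoff}")


@dataclass
class RegulationMatrix:
    """Sites x experimental conditions with states in {U, D, N}.

    ``states`` is a pandas DataFrame indexed by :class:`SiteKey` with one
    column per condition code; ``condition_pmids`` maps each condition to
    the study it came from.
    """

    states: pd.DataFrame
    condition_pmids: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in self.states.columns if not self.condition_pmids.get(c)]
        if missing:
            raise ValidationError(f"conditions without a pmid: {missing[:5]}")
        bad = set(np.unique(self.states.to_numpy())) - set(STATES) if self.states.size else set()
        if bad:
            raise ValidationError(f"invalid states {sorted(bad)}")

    @property
    def sites(self) -> list[SiteKey]:
        return list(self.states.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.states.columns)

    @property
    def n_conditions(self) -> int:
        return self.states.shape[1]

    def site_states(self, site: SiteKey) -> np.ndarray:
        """State vector of one site across all conditions."""
        return self.states.loc[site].to_numpy()

    def differential_frequency(self, site: SiteKey) -> int:
        """Number of conditions in which the site is called U or D."""
        return int((self.site_states(site) != "N").sum())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def parse_site_label(raw_site: str) -> tuple[str, int]:
    """Split ``'S562'`` into ``('S', 562)``; reject malformed labels."""
    m = _SITE_RE.match(raw_site.strip())
    if m is None:
        raise ValidationError(f"malformed site string {raw_site!r} (expect e.g. 'S562')")
    residue, pos = m.group(1).upper(), int(m.group(2))
    if residue not in ACCEPTOR_RESIDUES:
        raise ValidationError(f"site {raw_site!r}: residue {residue!r} not in S/T/Y")
    if pos < 1:
        raise ValidationError(f"site {raw_site!r}: position must be >= 1")
    return residue, pos


def normalize_site_key(
    raw_protein: str,
    raw_site: str,
    alias_table: Mapping[str, Iterable[str]] | None = None,
    accession: str | None = None,
) -> SiteKey:
    """Build a :class:`SiteKey`, mapping protein aliases to canonical symbols.

    ``alias_table`` maps canonical symbol -> iterable of aliases (matched
    case-insensitively).  Symbols without an alias entry pass through
    upper-cased, with a one-time warning per symbol.
    """
    residue, pos = parse_site_label(raw_site)
    symbol = raw_protein.strip().upper()
    if alias_table:
        lookup = _alias_lookup(alias_table)
        if symbol in lookup:
            symbol = lookup[symbol]
        else:
            _warn_unknown_symbol(symbol)
    return SiteKey(protein_symbol=symbol, residue=residue, position=pos, accession=accession)


_warned_symbols: set[str] = set()


def _warn_unknown_symbol(symbol: str) -> None:
    if symbol not in _warned_symbols:
        _warned_symbols.add(symbol)
        logger.warning("protein symbol %r not in alias table; passed through", symbol)


def _alias_lookup(alias_table: Mapping[str, Iterable[str]]) -> dict[str, str]:
    lookup: dict[str, str] = {}
    for canonical, aliases in alias_table.items():
        canon = canonical.strip().upper()
        lookup[canon] = canon
        for alias in aliases:
            lookup[alias.strip().upper()] = canon
    return lookup


def is_class1(
    localization_probability: float | None,
    a_score: float | None,
    thresholds: DifferentialThresholds,
) -> bool:
    """Class-1 confidence: loc. probability >= 0.75 (inclusive) OR A-score > 13 (strict)."""
    if localization_probability is not None and localization_probability >= thresholds.loc_prob_min:
        return True
    if a_score is not None and a_score > thresholds.a_score_min:
        return True
    return False


def filter_class1(records: Sequence, thresholds: DifferentialThresholds | None = None) -> list:
    """Keep only class-1 records; drop (and count) records with no evidence at all."""
    thresholds = thresholds or DifferentialThresholds()
    kept, no_evidence, low_confidence = [], 0, 0
    for rec in records:
        if rec.localization_probability is None and rec.a_score is None:
            no_evidence += 1
            continue
        if is_class1(rec.localization_probability, rec.a_score, thresholds):
            kept.append(rec)
        else:
            low_confidence += 1
    logger.info(
        "class-1 filter: kept %d / %d records (%d below confidence, %d without evidence)",
        len(kept), len(records), low_confidence, no_evidence,
    )
    return kept


def call_regulation(record: DifferentialRecord, thresholds: DifferentialThresholds | None = None) -> str:
    """Call U / D / N for one differential record.

    U requires fold change strictly above ``fc_up`` (default 1.3) with
    p < ``p_cutoff``; D requires fold change strictly below ``fc_down``
    (default 0.76) with p < ``p_cutoff``.  A missing p-value fails
    significance unless ``allow_missing_p`` is set.
    """
    thresholds = thresholds or DifferentialThresholds()
    if not (record.fold_change > 0) or math.isnan(record.fold_change):
        raise ValidationError(f"fold_change must be > 0: {record}")
    if record.p_value is None:
        significant = thresholds.allow_missing_p
    else:
        significant = record.p_value < thresholds.p_cutoff
    if not significant:
        return "N"
    if record.fold_change > thresholds.fc_up:
        return "U"
    if record.fold_change < thresholds.fc_down:
        return "D"
    return "N"


def build_regulation_matrix(
    records: Sequence[DifferentialRecord],
    thresholds: DifferentialThresholds | None = None,
    conditions: Mapping[str, str] | None = None,
) -> RegulationMatrix:
    """Call states and assemble the sites x conditions matrix.

    Sites absent from a condition's source dataset get N.  Identical
    duplicate (site, condition) records collapse to one; duplicates whose
    called states conflict raise an error (a conflict is a curation
    problem, not something to vote over).

    ``conditions`` optionally pre-registers the full condition -> pmid
    roster of the corpus, so that conditions in which no site was observed
    still contribute all-N columns (dropping them would deflate the
    "neither called" cell of every downstream contingency table).
    """
    thresholds = thresholds or DifferentialThresholds()
    calls: dict[tuple[SiteKey, str], str] = {}
    pmids: dict[str, str] = dict(conditions) if conditions else {}
    conflicts: list[str] = []
    funnel = {"U": 0, "D": 0, "N": 0}
    for rec in records:
        state = call_regulation(rec, thresholds)
        funnel[state] += 1
        key = (rec.site, rec.condition_code)
        prev = calls.get(key)
        if prev is not None and prev != state:
            conflicts.append(f"{rec.site} in {rec.condition_code}: {prev} vs {state}")
            continue
        calls[key] = state
        existing_pmid = pmids.get(rec.condition_code)
        if existing_pmid is not None and existing_pmid != rec.pmid:
            conflicts.append(
                f"condition {rec.condition_code}: pmid {existing_pmid} vs {rec.pmid}"
            )
        pmids[rec.condition_code] = rec.pmid
    if conflicts:
        raise ValidationError(
            "conflicting duplicate records: " + "; ".join(sorted(conflicts)[:10])
        )
    sites = sorted({site for site, _ in calls})
    conditions = sorted(pmids)
    data = np.full((len(sites), len(conditions)), "N", dtype=object)
    site_ix = {s: i for i, s in enumerate(sites)}
    cond_ix = {c: j for j, c in enumerate(conditions)}
    for (site, cond), state in calls.items():
        data[site_ix[site], cond_ix[cond]] = state
    states = pd.DataFrame(data, index=pd.Index(sites), columns=conditions)
    logger.info(
        "regulation matrix: %d sites x %d conditions (%d U, %d D, %d N calls from records)",
        len(sites), len(conditions), funnel["U"], funnel["D"], funnel["N"],
    )
    return RegulationMatrix(states=states, condition_pmids=pmids)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

DIFFERENTIAL_COLUMNS = ["protein", "site", "condition_code", "pmid", "fold_change",
                        "p_value", "loc_prob", "a_score"]
PROFILING_COLUMNS = ["protein", "site", "dataset_id", "loc_prob", "a_score"]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_differential_tsv(
    path,
    alias_table: Mapping[str, Iterable[str]] | None = None,
) -> list[DifferentialRecord]:
    """Read a differential-observation TSV.

    Required columns: protein, site, condition_code, pmid and either
    ``fold_change`` (ratio scale) or ``log2_fold_change`` (converted via
    2**x); optional p_value, loc_prob, a_score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pmid": str, "condition_code": str})
    required = {"protein", "site", "condition_code", "pmid"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if "fold_change" in df.columns:
        fc = df["fold_change"].astype(float)
    elif "log2_fold_change" in df.columns:
        fc = np.power(2.0, df["log2_fold_change"].astype(float))
    else:
        raise ValidationError(f"{path}: need a fold_change or log2_fold_change column")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        try:
            site = normalize_site_key(str(d["protein"]), str(d["site"]), alias_table)
            records.append(
                DifferentialRecord(
                    site=site,
                    condition_code=str(d["condition_code"]),
                    pmid=str(d["pmid"]),
                    fold_change=float(fc.iloc[i]),
                    p_value=_opt_float(d.get("p_value")),
                    localization_probability=_opt_float(d.get("loc_prob")),
                    a_score=_opt_float(d.get("a_score")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
    return records


def read_profiling_tsv(
    path,
    alias_table: Mapping[str, Iterable[str]] | None = None,
) -> list[ProfilingRecord]:
    """Read a profiling-observation TSV (protein, site, dataset_id, loc_prob, a_score)."""
    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str})
    missing = {"protein", "site", "dataset_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        try:
            site = normalize_site_key(str(d["protein"]), str(d["site"]), alias_table)
            records.append(
                ProfilingRecord(
                    site=site,
                    dataset_id=str(d["dataset_id"]),
                    localization_probability=_opt_float(d.get("loc_prob")),
                    a_score=_opt_float(d.get("a_score")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
    return records


def read_conditions_tsv(path) -> dict[str, str]:
    """Read a condition roster TSV (condition_code, pmid)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"condition_code", "pmid"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["condition_code"], df["pmid"]))


def read_alias_tsv(path) -> dict[str, list[str]]:
    """Read an alias table TSV (canonical_symbol, alias; one pair per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"canonical_symbol", "alias"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    table: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(row.canonical_symbol.strip().upper(), []).append(row.alias.strip())
    return table
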