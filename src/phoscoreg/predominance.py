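"""Detection-frequency ranking and predominant-phosphosite selection.

A protein's *predominant* phosphosite is the one most frequently observed
across the corpus: its differential frequency counts conditions with a
U or D call, its profiling frequency counts distinct profiling datasets
where the site was detected.  Ranking is by differential frequency, with
profiling frequency and then position breaking ties deterministically.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .ingest import ProfilingRecord, RegulationMatrix, SiteKey

logger = logging.getLogger(__name__)

#: Columns of the site-frequency table (indexed by SiteKey).
FREQUENCY_COLUMNS = ["profiling_frequency", "differential_frequency", "rank"]


def compute_detection_frequencies(
    matrix: RegulationMatrix,
    profiling: Sequence[ProfilingRecord] = (),
) -> pd.DataFrame:
    """Per-site detection frequencies over differential conditions and profiling datasets.

    Returns a DataFrame indexed by :class:`SiteKey` with integer columns
    ``profiling_frequency`` (distinct dataset_ids containing the site),
    ``differential_frequency`` (conditions with a U or D call) and
    ``rank`` (1-based, by :func:`rank_sites` order).  The number of
    differential conditions is attached as ``.attrs['n_conditions']``.
    """
    prof_counts: dict[SiteKey, set[str]] = {}
    for rec in profiling:
        prof_counts.setdefault(rec.site, set()).add(rec.dataset_id)

    sites = sorted(set(matrix.sites) | set(prof_counts))
    rows = []
    for site in sites:
        diff_freq = matrix.differential_frequency(site) if site in matrix.states.index else 0
        rows.append(
            {
                "profiling_frequency": len(prof_counts.get(site, ())),
                "differential_frequency": diff_freq,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(sites), dtype=int)
    if table.empty:
        table = pd.DataFrame(columns=FREQUENCY_COLUMNS[:2], dtype=int)
    order = rank_sites(table)
    table["rank"] = 0
    for i, site in enumerate(order, start=1):
        table.loc[site, "rank"] = i
    table.attrs["n_conditions"] = matrix.n_conditions
    return table


def rank_sites(table: pd.DataFrame) -> list[SiteKey]:
    """Rank-order sites: differential frequency desc, profiling frequency desc, position asc."""
    return sorted(
        table.index,
        key=lambda s: (
            -int(table.loc[s, "differential_frequency"]),
            -int(table.loc[s, "profiling_frequency"]),
            s.position,
            s.protein_symbol,
            s.residue,
        ),
    )


def select_predominant(
    table: pd.DataFrame,
    min_fraction: float = 0.0,
    top_k: int | None = None,
) -> list[SiteKey]:
    """Select predominant site(s): frequency-qualified sites, capped at ``top_k`` by rank.

    A site qualifies when its differential frequency is at least
    ``min_fraction`` of the number of differential conditions.  The rank-1
    site is always returned when the table is non-empty, even if it misses
    the fraction cut — by definition the highest-frequency site is the
    predominant one.
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError(f"min_fraction must be in [0,1], got {min_fraction}")
    if table.empty:
        return []
    order = rank_sites(table)
    n_conditions = int(table.attrs.get("n_conditions", 0))
    threshold = min_fraction * n_conditions
    selected = [
        s for s in order if table.loc[s, "differential_frequency"] >= threshold
    ]
    if not selected:
        # the rank-1 site is predominant by definition even below the cut
        selected = [order[0]]
    if top_k is not None:
        selected = selected[:top_k]
    logger.info(
        "predominant selection: %d of %d sites (min_fraction=%.2f over %d conditions, top_k=%s)",
        len(selected), len(table), min_fraction, n_conditions, top_k,
    )
    return selected


def frequency_table_tsv(table: pd.DataFrame, path) -> pd.DataFrame:
    """Write the site ranking with both frequencies to TSV; returns the flat frame."""
    flat = _flatten(table).sort_values("rank") if not table.empty else _flatten(table)
    flat.to_csv(path, sep="\t", index=False)
    return flat


def export_lollipop_table(
    table: pd.DataFrame,
    domain_annotations: pd.DataFrame | None = None,
    path=None,
) -> pd.DataFrame:
    """Per-position frequency table for lollipop-style plotting.

    ``domain_annotations`` is an optional frame with columns
    ``domain``, ``start``, ``end`` (1-based inclusive residue range); a
    site falling inside a range gets that domain label.
    """
    rows = []
    for site in (rank_sites(table) if not table.empty else []):
        label = ""
        if domain_annotations is not None and len(domain_annotations):
            hit = domain_annotations[
                (domain_annotations["start"] <= site.position)
                & (site.position <= domain_annotations["end"])
            ]
            if len(hit):
                label = ";".join(hit["domain"].astype(str))
        rows.append(
            {
                "position": site.position,
                "residue": site.residue,
                "profiling_frequency": int(table.loc[site, "profiling_frequency"]),
                "differential_frequency": int(table.loc[site, "differential_frequency"]),
                "domain_label": label,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["position", "residue", "profiling_frequency",
                 "differential_frequency", "domain_label"],
    )
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out


def _flatten(table: pd.DataFrame) -> pd.DataFrame:
    rows = [
        {
            "protein": s.protein_symbol,
            "site": s.site_label,
            "profiling_frequency": int(table.loc[s, "profiling_frequency"]),
            "differential_frequency": int(table.loc[s, "differential_frequency"]),
            "rank": int(table.loc[s, "rank"]),
        }
        for s in table.index
    ]
    return pd.DataFrame(
        rows,
        columns=["protein", "site", "profiling_frequency", "differential_frequency", "rank"],
    )
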