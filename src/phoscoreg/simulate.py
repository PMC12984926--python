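"""Synthetic phosphoproteomic corpus generator.

Emulates the statistical structure of a curated multi-study corpus: many
small studies (PMIDs) each contributing a few treatment-vs-control
conditions, sparse per-condition detection (dropout), one planted
high-frequency anchor site, planted positively and negatively co-regulated
partner sites, and independent null sites.  Every generated site's role is
recorded in a truth table, so recovery of planted structure is directly
checkable.

Per condition the generative process is:

* the anchor is detected with probability ``anchor_detection_prob`` and,
  when detected, called U with probability ``up_prob`` (else D);
* a positive partner is detected with probability
  ``partner_detection_coupling`` given the anchor is detected (else
  ``null_detection_prob``) and, when both are detected, copies the
  anchor's direction with probability ``agreement_prob`` (else flips);
* a negative partner behaves identically but copies the *opposite*
  direction with probability ``agreement_prob``;
* null sites are detected with probability ``null_detection_prob`` with an
  independent coin-flip direction.

Detected calls are materialized as differential records with
direction-consistent fold changes (truncated log-normal above 1.3 for U,
below 0.76 for D) and significant p-values (Uniform(0, 0.05)); a
configurable ``near_miss_fraction`` of records instead gets a sub-threshold
fold change or a non-significant p-value, so the regulation caller's N
branch is exercised by realistic data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import (
    DifferentialRecord,
    DifferentialThresholds,
    ProfilingRecord,
    RegulationMatrix,
    SiteKey,
    build_regulation_matrix,
    filter_class1,
)

ROLES = ("anchor", "positive_partner", "negative_partner", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_conditions: int = 200
    conditions_per_study: int = 3
    n_null_sites: int = 20
    n_pos_partners: int = 1
    n_neg_partners: int = 1
    anchor_detection_prob: float = 0.5
    null_detection_prob: float = 0.25
    agreement_prob: float = 0.9
    partner_detection_coupling: float = 0.9
    up_prob: float = 0.5
    #: log-normal parameters for direction-consistent fold changes,
    #: truncated to the calling region (> 1.3 up, < 0.76 down)
    fc_up_mu: float = math.log(1.8)
    fc_up_sigma: float = 0.25
    fc_down_mu: float = math.log(0.55)
    fc_down_sigma: float = 0.25
    near_miss_fraction: float = 0.10
    n_profiling_datasets: int = 40
    anchor_protein: str = "PKN1"
    anchor_site: str = "S562"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "anchor_detection_prob": self.anchor_detection_prob,
            "null_detection_prob": self.null_detection_prob,
            "agreement_prob": self.agreement_prob,
            "partner_detection_coupling": self.partner_detection_coupling,
            "up_prob": self.up_prob,
            "near_miss_fraction": self.near_miss_fraction,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_conditions < 1:
            raise ValueError("n_conditions must be >= 1")
        if self.conditions_per_study < 1:
            raise ValueError("conditions_per_study must be >= 1")


@dataclass
class SyntheticCorpus:
    """Generated records plus the planted-role truth table."""

    differential_records: list[DifferentialRecord]
    profiling_records: list[ProfilingRecord]
    truth: pd.DataFrame  # columns: protein, site, role, detection_prob, agreement_prob
    config: SimulationConfig
    #: full condition -> pmid roster, including conditions with no detection
    condition_pmids: dict[str, str] = None

    @property
    def anchor(self) -> SiteKey:
        row = self.truth[self.truth["role"] == "anchor"].iloc[0]
        return _site_from_row(row)

    def sites_with_role(self, role: str) -> list[SiteKey]:
        return [_site_from_row(r) for _, r in self.truth[self.truth["role"] == role].iterrows()]


def _site_from_row(row) -> SiteKey:
    return SiteKey(row["protein"], row["site"][0], int(row["site"][1:]))


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def simulate_corpus(config: SimulationConfig | None = None) -> SyntheticCorpus:
    """Generate a corpus; a fixed seed yields a byte-identical corpus."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_conditions

    conditions = [f"C{i + 1:05d}" for i in range(n)]
    pmids = [f"PMID{1 + i // cfg.conditions_per_study:07d}" for i in range(n)]

    anchor = SiteKey(cfg.anchor_protein, cfg.anchor_site[0], int(cfg.anchor_site[1:]))
    anchor_detected = rng.random(n) < cfg.anchor_detection_prob
    anchor_up = rng.random(n) < cfg.up_prob

    sites: list[SiteKey] = [anchor]
    roles: list[str] = ["anchor"]
    detected_rows = [anchor_detected]
    up_rows = [anchor_up]

    def partner_states(negative: bool) -> tuple[np.ndarray, np.ndarray]:
        det = np.where(
            anchor_detected,
            rng.random(n) < cfg.partner_detection_coupling,
            rng.random(n) < cfg.null_detection_prob,
        )
        agree = rng.random(n) < cfg.agreement_prob
        independent_up = rng.random(n) < cfg.up_prob
        target = ~anchor_up if negative else anchor_up
        up = np.where(anchor_detected, np.where(agree, target, ~target), independent_up)
        return det, up

    for j in range(cfg.n_pos_partners):
        det, up = partner_states(negative=False)
        sites.append(SiteKey(f"POSP{j + 1:04d}", "S", 100 + j))
        roles.append("positive_partner")
        detected_rows.append(det)
        up_rows.append(up)
    for j in range(cfg.n_neg_partners):
        det, up = partner_states(negative=True)
        sites.append(SiteKey(f"NEGP{j + 1:04d}", "T", 200 + j))
        roles.append("negative_partner")
        detected_rows.append(det)
        up_rows.append(up)
    for j in range(cfg.n_null_sites):
        sites.append(SiteKey(f"NULL{j + 1:04d}", "S", 300 + j))
        roles.append("null")
        detected_rows.append(rng.random(n) < cfg.null_detection_prob)
        up_rows.append(rng.random(n) < cfg.up_prob)

    differential = _materialize_records(
        cfg, rng, sites, detected_rows, up_rows, conditions, pmids
    )
    profiling = _profiling_records(cfg, rng, sites, roles)

    truth = pd.DataFrame(
        {
            "protein": [s.protein_symbol for s in sites],
            "site": [s.site_label for s in sites],
            "role": roles,
            "detection_prob": [
                cfg.anchor_detection_prob if r == "anchor"
                else cfg.partner_detection_coupling if r.endswith("partner")
                else cfg.null_detection_prob
                for r in roles
            ],
            "agreement_prob": [
                cfg.agreement_prob if r.endswith("partner") else "" for r in roles
            ],
        }
    )
    return SyntheticCorpus(
        differential_records=differential,
        profiling_records=profiling,
        truth=truth,
        config=cfg,
        condition_pmids=dict(zip(conditions, pmids)),
    )


def _materialize_records(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sites: list[SiteKey],
    detected_rows: list[np.ndarray],
    up_rows: list[np.ndarray],
    conditions: list[str],
    pmids: list[str],
) -> list[DifferentialRecord]:
    records: list[DifferentialRecord] = []
    for site, detected, up in zip(sites, detected_rows, up_rows):
        idx = np.flatnonzero(detected)
        m = len(idx)
        if m == 0:
            continue
        near_miss = rng.random(m) < cfg.near_miss_fraction
        miss_by_fc = rng.random(m) < 0.5  # near-miss via fc band vs via p-value
        fc = np.where(
            up[idx],
            _truncated_lognormal(rng, cfg.fc_up_mu, cfg.fc_up_sigma, lower=1.3, size=m),
            _truncated_lognormal(rng, cfg.fc_down_mu, cfg.fc_down_sigma, upper=0.76, size=m),
        )
        fc_near = rng.uniform(0.77, 1.29, size=m)
        fc = np.where(near_miss & miss_by_fc, fc_near, fc)
        p = rng.uniform(0.0, 0.05, size=m)
        p = np.where(near_miss & ~miss_by_fc, rng.uniform(0.05, 1.0, size=m), p)
        use_loc = rng.random(m) < 0.5
        loc_prob = rng.uniform(0.75, 1.0, size=m)
        a_score = rng.uniform(13.5, 40.0, size=m)
        for k, i in enumerate(idx):
            records.append(
                DifferentialRecord(
                    site=site,
                    condition_code=conditions[i],
                    pmid=pmids[i],
                    fold_change=float(fc[k]),
                    p_value=float(p[k]),
                    localization_probability=float(loc_prob[k]) if use_loc[k] else None,
                    a_score=None if use_loc[k] else float(a_score[k]),
                )
            )
    return records


def _profiling_records(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sites: list[SiteKey],
    roles: list[str],
) -> list[ProfilingRecord]:
    records: list[ProfilingRecord] = []
    datasets = [f"D{i + 1:04d}" for i in range(cfg.n_profiling_datasets)]
    for site, role in zip(sites, roles):
        prob = cfg.anchor_detection_prob if role == "anchor" else cfg.null_detection_prob
        detected = rng.random(cfg.n_profiling_datasets) < prob
        loc = rng.uniform(0.75, 1.0, size=cfg.n_profiling_datasets)
        for i in np.flatnonzero(detected):
            records.append(
                ProfilingRecord(
                    site=site,
                    dataset_id=datasets[i],
                    localization_probability=float(loc[i]),
                )
            )
    return records


def _truncated_lognormal(
    rng: np.random.Generator,
    mu: float,
    sigma: float,
    size: int,
    lower: float | None = None,
    upper: float | None = None,
) -> np.ndarray:
    """Log-normal rejection-sampled into (lower, inf) or (0, upper)."""
    out = np.exp(rng.normal(mu, sigma, size=size))
    for _ in range(1000):
        bad = np.zeros(size, dtype=bool)
        if lower is not None:
            bad |= out <= lower
        if upper is not None:
            bad |= out >= upper
        if not bad.any():
            return out
        out[bad] = np.exp(rng.normal(mu, sigma, size=int(bad.sum())))
    raise RuntimeError("truncated log-normal failed to converge; check mu/sigma vs bounds")


def corpus_matrix(
    corpus: SyntheticCorpus, thresholds: DifferentialThresholds | None = None
) -> RegulationMatrix:
    """Run the standard ingest path (class-1 filter, calling) on a corpus.

    The corpus's full condition roster is pre-registered so conditions
    without any detection keep their all-N column.
    """
    records = filter_class1(corpus.differential_records, thresholds)
    return build_regulation_matrix(records, thresholds, conditions=corpus.condition_pmids)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------


def write_fixture_files(corpus: SyntheticCorpus, out_dir) -> dict[str, Path]:
    """Write ingest-format TSVs plus the truth table; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "differential": out / "differential.tsv",
        "profiling": out / "profiling.tsv",
        "conditions": out / "conditions.tsv",
        "truth": out / "truth.tsv",
        "config": out / "simulation_config.json",
    }
    pd.DataFrame(
        {"condition_code": list(corpus.condition_pmids),
         "pmid": list(corpus.condition_pmids.values())}
    ).to_csv(paths["conditions"], sep="\t", index=False)
    diff = pd.DataFrame(
        [
            {
                "protein": r.site.protein_symbol,
                "site": r.site.site_label,
                "condition_code": r.condition_code,
                "pmid": r.pmid,
                "fold_change": f"{r.fold_change:.6g}",
                "p_value": f"{r.p_value:.6g}" if r.p_value is not None else "",
                "loc_prob": f"{r.localization_probability:.4f}"
                if r.localization_probability is not None else "",
                "a_score": f"{r.a_score:.4f}" if r.a_score is not None else "",
            }
            for r in corpus.differential_records
        ],
        columns=["protein", "site", "condition_code", "pmid", "fold_change",
                 "p_value", "loc_prob", "a_score"],
    )
    diff.to_csv(paths["differential"], sep="\t", index=False)
    prof = pd.DataFrame(
        [
            {
                "protein": r.site.protein_symbol,
                "site": r.site.site_label,
                "dataset_id": r.dataset_id,
                "loc_prob": f"{r.localization_probability:.4f}"
                if r.localization_probability is not None else "",
                "a_score": f"{r.a_score:.4f}" if r.a_score is not None else "",
            }
            for r in corpus.profiling_records
        ],
        columns=["protein", "site", "dataset_id", "loc_prob", "a_score"],
    )
    prof.to_csv(paths["profiling"], sep="\t", index=False)
    corpus.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"].write_text(json.dumps(asdict(corpus.config), indent=2) + "\n")
    return paths
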