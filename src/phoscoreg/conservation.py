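"""Window-based phosphosite conservation scoring over a family alignment.

Given a multiple sequence alignment of a kinase family (e.g. PKN1/PKN2/
PKN3) and a phosphosite on one member (the reference), the site position
is mapped to its alignment column and scored as a convex combination of

* ``acceptor_fraction`` — the fraction of non-reference members carrying a
  compatible phospho-acceptor in the site column (S and T are treated as
  interchangeable acceptors; Y sites require Y), and
* ``window_identity`` — the mean per-column identity to the reference over
  a +/- ``window_radius`` residue window around the site (default 5),
  truncated at the sequence ends; gaps count as mismatches.

``score = w * acceptor_fraction + (1 - w) * window_identity`` with mixing
weight ``w = 0.5`` by default.  Sites scoring at or above the threshold
(default 0.75) classify as conserved.  This is a fully specified surrogate
for family conservation; it is not calibrated against any external
resource's scores.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import pandas as pd
from Bio import AlignIO

from .ingest import SiteKey, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_RADIUS = 5
DEFAULT_MIXING_WEIGHT = 0.5
DEFAULT_THRESHOLD = 0.75

GAP = "-"


@dataclass(frozen=True)
class AlignedFamily:
    """A protein-family MSA plus the id of the member carrying scored sites."""

    members: tuple[tuple[str, str], ...]  # (sequence_id, aligned_sequence)
    reference_id: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("empty family")
        lengths = {len(seq) for _, seq in self.members}
        if len(lengths) != 1:
            raise ValidationError(f"aligned sequences differ in length: {sorted(lengths)}")
        if self.reference_id not in {sid for sid, _ in self.members}:
            raise ValidationError(f"reference_id {self.reference_id!r} not in alignment")

    @property
    def reference_sequence(self) -> str:
        return next(seq for sid, seq in self.members if sid == self.reference_id)

    @property
    def others(self) -> list[str]:
        return [seq for sid, seq in self.members if sid != self.reference_id]

    @property
    def alignment_length(self) -> int:
        return len(self.members[0][1])


@dataclass(frozen=True)
class SiteConservation:
    """Conservation result for one site."""

    site: SiteKey
    alignment_column: int  # 1-based
    window_radius: int
    acceptor_fraction: float
    window_identity: float
    score: float
    conserved: bool
    threshold: float = DEFAULT_THRESHOLD


def read_alignment(path, reference_id: str) -> AlignedFamily:
    """Load an aligned FASTA or Clustal file (format auto-detected by content)."""
    with open(path) as fh:
        text = fh.read()
    return parse_alignment(text, reference_id)


def parse_alignment(text: str, reference_id: str) -> AlignedFamily:
    fmt = "clustal" if text.lstrip()[:7].upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise ValidationError(f"cannot parse {fmt} alignment: {exc}") from exc
    members = tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    return AlignedFamily(members=members, reference_id=reference_id)


def map_site_to_column(family: AlignedFamily, site: SiteKey) -> int:
    """1-based alignment column whose ungapped reference index equals the site position.

    The reference residue at the returned column must match the site's
    residue; a mismatch means the site belongs to a different sequence
    version and is an error.
    """
    ref = family.reference_sequence
    ungapped = 0
    for col, ch in enumerate(ref, start=1):
        if ch == GAP:
            continue
        ungapped += 1
        if ungapped == site.position:
            if ch != site.residue:
                raise ValidationError(
                    f"{site}: reference {family.reference_id} has {ch!r} at "
                    f"position {site.position}, expected {site.residue!r}"
                )
            return col
    raise ValidationError(
        f"{site}: position {site.position} beyond ungapped reference length {ungapped}"
    )


def _window_columns(family: AlignedFamily, column: int, radius: int) -> list[int]:
    """Alignment columns of the reference residues within +/- radius of the site.

    The window lives in reference-residue space: reference-gap columns are
    never part of it, and it truncates at the sequence ends.
    """
    ref = family.reference_sequence
    residue_cols = [i + 1 for i, ch in enumerate(ref) if ch != GAP]
    idx = residue_cols.index(column)
    lo = max(0, idx - radius)
    hi = min(len(residue_cols), idx + radius + 1)
    return residue_cols[lo:hi]


def conservation_score(
    family: AlignedFamily,
    site: SiteKey,
    window_radius: int = DEFAULT_WINDOW_RADIUS,
    mixing_weight: float = DEFAULT_MIXING_WEIGHT,
    threshold: float = DEFAULT_THRESHOLD,
) -> SiteConservation:
    """Score one site's family conservation (see module docstring for the formula).

    A single-member family scores 1.0 by convention (nothing to diverge
    from).  Window columns where every non-reference member has a gap are
    skipped from the identity average.
    """
    if not (0.0 <= mixing_weight <= 1.0):
        raise ValueError(f"mixing_weight must be in [0,1], got {mixing_weight}")
    if window_radius < 0:
        raise ValueError("window_radius must be >= 0")
    column = map_site_to_column(family, site)
    others = family.others
    if not others:
        return SiteConservation(
            site=site, alignment_column=column, window_radius=window_radius,
            acceptor_fraction=1.0, window_identity=1.0, score=1.0,
            conserved=1.0 >= threshold, threshold=threshold,
        )
    acceptors = {"S", "T"} if site.residue in ("S", "T") else {"Y"}
    acceptor_fraction = sum(
        seq[column - 1] in acceptors for seq in others
    ) / len(others)

    identities = []
    for col in _window_columns(family, column, window_radius):
        ref_ch = family.reference_sequence[col - 1]
        col_chars = [seq[col - 1] for seq in others]
        if all(ch == GAP for ch in col_chars):
            continue  # all-gap column carries no signal
        identities.append(sum(ch == ref_ch for ch in col_chars) / len(col_chars))
    window_identity = sum(identities) / len(identities) if identities else 0.0

    score = mixing_weight * acceptor_fraction + (1.0 - mixing_weight) * window_identity
    return SiteConservation(
        site=site,
        alignment_column=column,
        window_radius=window_radius,
        acceptor_fraction=acceptor_fraction,
        window_identity=window_identity,
        score=score,
        conserved=classify_conserved(score, threshold),
        threshold=threshold,
    )


def classify_conserved(score: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Inclusive boundary: a score equal to the threshold classifies as conserved."""
    return score >= threshold


def conservation_table(results: list[SiteConservation], path=None) -> pd.DataFrame:
    """Flatten results to a TSV-ready frame (site, column, components, score, class)."""
    rows = [
        {
            "protein": r.site.protein_symbol,
            "site": r.site.site_label,
            "alignment_column": r.alignment_column,
            "acceptor_fraction": r.acceptor_fraction,
            "window_identity": r.window_identity,
            "score": r.score,
            "conserved": r.conserved,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=["protein", "site", "alignment_column", "acceptor_fraction",
                 "window_identity", "score", "conserved"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
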