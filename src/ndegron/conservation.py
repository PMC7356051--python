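"""Ortholog conservation of the P1' residue and its destabilizing property.

For each cleavage site the 60-residue reference window is globally aligned
to every member of an ortholog family; the member residue falling in the
P1' column is classified under the Arg/N-degron rule.  Two fractions
summarise a family: *identity conservation* (member P1' equals the
reference residue) and *property conservation* (member P1' is destabilizing
regardless of identity).  Members whose alignment places a gap at the P1'
column are missing data and are excluded from both denominators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .alignment import GAP, AlignmentParams, align_pair, map_p1prime
from .rules import ResidueClass, RuleTable, classify_residue, default_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologFamily:
    """A reference cleavage-site window plus homolog sequences."""

    family_id: str
    reference_window: str
    window_p1prime_offset: int  # 1-based within the reference window
    members: tuple[tuple[str, str], ...]  # (species, sequence)

    def __post_init__(self) -> None:
        if not self.reference_window:
            raise ValueError(f"{self.family_id}: empty reference window")
        if not 1 <= self.window_p1prime_offset <= len(self.reference_window):
            raise ValueError(
                f"{self.family_id}: P1' offset {self.window_p1prime_offset} "
                f"outside window of length {len(self.reference_window)}"
            )
        if not self.members:
            raise ValueError(f"{self.family_id}: family needs >= 1 member")

    @property
    def reference_p1prime(self) -> str:
        return self.reference_window[self.window_p1prime_offset - 1]


@dataclass(frozen=True)
class AlignedSite:
    """One member's residue at the reference P1' column."""

    species: str
    aligned_residue: str  # one-letter code or "-" for a gap
    classification: ResidueClass | None
    destabilizing: bool | None

    def __post_init__(self) -> None:
        if (self.aligned_residue == GAP) != (self.classification is None):
            raise ValueError("classification must be absent iff the site is a gap")


@dataclass(frozen=True)
class ConservationReport:
    family_id: str
    reference_residue: str
    aligned_sites: tuple[AlignedSite, ...]
    identity_conservation: float
    property_conservation: float
    n_gap: int

    @property
    def n_members(self) -> int:
        return len(self.aligned_sites)


def family_conservation(
    family: OrthologFamily,
    table: RuleTable | None = None,
    params: AlignmentParams | None = None,
) -> ConservationReport:
    """Align each member to the reference window and score P1' conservation.

    A member whose alignment fails (e.g. empty/invalid sequence) is recorded
    as a gap with a warning and the run continues.  Fractions are NaN when
    every member is a gap.
    """
    table = table or default_table()
    params = params or AlignmentParams()
    sites: list[AlignedSite] = []
    for species, seq in family.members:
        try:
            aln = align_pair(family.reference_window, seq, params)
            residue = map_p1prime(aln, family.window_p1prime_offset)
        except ValueError as exc:
            logger.warning(
                "family %s member %s: alignment failed (%s); recorded as gap",
                family.family_id, species, exc,
            )
            residue = GAP
        if residue == GAP:
            sites.append(AlignedSite(species, GAP, None, None))
        else:
            result = classify_residue(residue, table)
            sites.append(
                AlignedSite(species, residue, result.residue_class,
                            result.destabilizing)
            )
    non_gap = [s for s in sites if s.aligned_residue != GAP]
    if non_gap:
        identity = sum(
            1 for s in non_gap if s.aligned_residue == family.reference_p1prime
        ) / len(non_gap)
        prop = sum(1 for s in non_gap if s.destabilizing) / len(non_gap)
    else:
        identity = prop = math.nan
    return ConservationReport(
        family_id=family.family_id,
        reference_residue=family.reference_p1prime,
        aligned_sites=tuple(sites),
        identity_conservation=identity,
        property_conservation=prop,
        n_gap=len(sites) - len(non_gap),
    )


def screen_families(
    families: list[OrthologFamily],
    table: RuleTable | None = None,
    params: AlignmentParams | None = None,
) -> tuple[list[ConservationReport], pd.DataFrame, int]:
    """Conservation reports for a panel of families.

    Returns the per-family reports (ordered by family_id), a summary
    DataFrame (one row per family), and the number of families whose
    destabilizing property is fully conserved (property_conservation == 1).
    """
    reports = [
        family_conservation(fam, table, params)
        for fam in sorted(families, key=lambda f: f.family_id)
    ]
    rows = [
        {
            "family_id": r.family_id,
            "reference_p1prime": r.reference_residue,
            "n_members": r.n_members,
            "n_gap": r.n_gap,
            "identity_conservation": r.identity_conservation,
            "property_conservation": r.property_conservation,
        }
        for r in reports
    ]
    table_df = pd.DataFrame(
        rows,
        columns=[
            "family_id", "reference_p1prime", "n_members", "n_gap",
            "identity_conservation", "property_conservation",
        ],
    )
    n_fully_conserved = sum(1 for r in reports if r.property_conservation == 1.0)
    return reports, table_df, n_fully_conserved
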