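"""Protease cleavage events and N-degron annotation of neo-N-termini.

A protease cut between residues P1 and P1' releases a C-terminal fragment
whose new N-terminus is the P1' residue; whether that residue is
destabilizing under the Arg/N-degron rule decides whether the fragment
carries a candidate N-degron.  This module represents cleavage sites in
1-based substrate coordinates (a site is keyed by its P1 position; the
fragment starts at P1' = P1+1, matching the convention of naming a fragment
by its first residue), extracts the P4-P4' octamer and a wider context
window around each cut, and summarises a site table into per-class counts
and the fraction of destabilizing neo-N-termini.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .rules import ClassificationResult, RuleTable, classify_residue, default_table

GAP_PAD = "-"

#: Default half-width of the context window beyond the octamer; 8 + 2*26
#: gives the 60-residue window used for ortholog searches.
DEFAULT_FLANK = 26


class SiteError(ValueError):
    """A cleavage site that cannot generate a C-terminal fragment."""


@dataclass(frozen=True)
class SubstrateRecord:
    """A substrate protein sequence."""

    substrate_id: str
    sequence: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.substrate_id}: empty sequence")
        if not self.sequence.isupper() or not self.sequence.isalpha():
            raise ValueError(
                f"{self.substrate_id}: sequence must be uppercase letters"
            )


@dataclass(frozen=True)
class CleavageSite:
    """A protease cut, keyed by the 1-based position of its P1 residue.

    ``fragment_id`` groups alternative sites that release the same fragment
    (deduplicated in fragment-level counts); the ``primary`` flag marks the
    site that classifies the fragment.  ``acetylated`` forces the P1'
    classification to UNKNOWN (acetylated N-termini escape the Arg branch).
    """

    substrate_id: str
    protease: str
    p1_position: int
    octamer: str = ""
    fragment_id: str = ""
    primary: bool = True
    acetylated: bool = False
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p1_position < 1:
            raise ValueError(
                f"{self.substrate_id}: p1_position must be >= 1, "
                f"got {self.p1_position}"
            )

    @property
    def effective_fragment_id(self) -> str:
        return self.fragment_id or f"{self.substrate_id}:{self.p1_position + 1}"


@dataclass(frozen=True)
class FragmentAnnotation:
    """A classified neo-N-terminal fragment generated by one cleavage site."""

    site: CleavageSite
    p1prime_residue: str
    classification: ClassificationResult
    fragment_span: tuple[int, int]  # 1-based inclusive, P1'..C-terminus
    window: str
    window_p1prime_offset: int  # 1-based position of P1' within window
    window_truncated: bool


@dataclass(frozen=True)
class AnnotationError:
    """Per-site failure record; annotation of the remaining sites continues."""

    site: CleavageSite
    reason: str


@dataclass(frozen=True)
class AnnotationSummary:
    """Counts over an annotated site table.

    ``fraction_destabilizing`` uses classified (non-UNKNOWN) sites as the
    denominator, so ambiguous P1' residues do not bias the headline
    fraction.  Fragment-level counts deduplicate alternative sites sharing a
    ``fragment_id`` and classify each fragment by its primary site.
    """

    n_sites: int
    n_classified: int
    class_counts: Mapping[str, int]
    protease_counts: Mapping[str, int]
    fraction_destabilizing: float
    n_fragments: int
    n_fragments_destabilizing: int
    n_errors: int = 0


def cleave(sequence: str, p1_position: int) -> tuple[str, str]:
    """Split a sequence after the P1 residue; returns (N-, C-) fragments.

    The concatenation of the two fragments reconstructs the input.  A cut at
    or beyond the last residue leaves no C-terminal fragment and raises
    :class:`SiteError`.
    """
    if not 1 <= p1_position < len(sequence):
        raise SiteError(
            f"p1_position {p1_position} leaves no C-terminal fragment "
            f"(sequence length {len(sequence)})"
        )
    return sequence[:p1_position], sequence[p1_position:]


def extract_octamer(sequence: str, p1_position: int) -> str:
    """The P4-P4' octamer around a cut, '-'-padded at sequence termini."""
    if not 1 <= p1_position < len(sequence):
        raise SiteError(
            f"p1_position {p1_position} invalid for sequence of length "
            f"{len(sequence)}"
        )
    chars = []
    for pos in range(p1_position - 3, p1_position + 5):  # 1-based P4..P4'
        chars.append(sequence[pos - 1] if 1 <= pos <= len(sequence) else GAP_PAD)
    return "".join(chars)


def extract_window(
    sequence: str, p1_position: int, flank: int = DEFAULT_FLANK
) -> tuple[str, int, bool]:
    """Context window spanning the octamer plus `flank` residues each side.

    Returns ``(window, window_p1prime_offset, truncated)``.  At the default
    flank of 26 the complete window is 60 residues with P1' at (1-based)
    offset 31; near the termini the window is truncated (never padded) and
    the offset records where P1' actually falls.
    """
    if not 1 <= p1_position < len(sequence):
        raise SiteError(
            f"p1_position {p1_position} invalid for sequence of length "
            f"{len(sequence)}"
        )
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = max(1, p1_position - 3 - flank)
    end = min(len(sequence), p1_position + 4 + flank)
    truncated = (start > p1_position - 3 - flank) or (end < p1_position + 4 + flank)
    window = sequence[start - 1 : end]
    offset = p1_position + 1 - start + 1  # 1-based position of P1' in window
    return window, offset, truncated


def annotate(
    substrates: Iterable[SubstrateRecord],
    sites: Iterable[CleavageSite],
    table: RuleTable | None = None,
    flank: int = DEFAULT_FLANK,
) -> tuple[list[FragmentAnnotation], AnnotationSummary, list[AnnotationError]]:
    """Classify every cleavage site's P1' residue under the N-degron rule.

    Sites whose substrate is missing or whose position is invalid produce
    :class:`AnnotationError` records; the run continues.  Output is sorted
    by (substrate_id, p1_position) for reproducible diffs.
    """
    table = table or default_table()
    by_id = {s.substrate_id: s for s in substrates}
    annotations: list[FragmentAnnotation] = []
    errors: list[AnnotationError] = []
    for site in sorted(sites, key=lambda s: (s.substrate_id, s.p1_position)):
        sub = by_id.get(site.substrate_id)
        if sub is None:
            errors.append(AnnotationError(site, "unknown substrate_id"))
            continue
        try:
            _, c_fragment = cleave(sub.sequence, site.p1_position)
            window, offset, truncated = extract_window(
                sub.sequence, site.p1_position, flank
            )
        except SiteError as exc:
            errors.append(AnnotationError(site, str(exc)))
            continue
        p1prime = c_fragment[0]
        result = classify_residue(p1prime, table, acetylated=site.acetylated)
        annotations.append(
            FragmentAnnotation(
                site=site,
                p1prime_residue=p1prime,
                classification=result,
                fragment_span=(site.p1_position + 1, len(sub.sequence)),
                window=window,
                window_p1prime_offset=offset,
                window_truncated=truncated,
            )
        )
    return annotations, summarize(annotations, n_errors=len(errors)), errors


def summarize(
    annotations: Iterable[FragmentAnnotation], n_errors: int = 0
) -> AnnotationSummary:
    """Per-class / per-protease counts and the destabilizing fraction."""
    annotations = list(annotations)
    class_counts = Counter(a.classification.residue_class.value for a in annotations)
    protease_counts = Counter(a.site.protease for a in annotations)
    n_sites = len(annotations)
    n_unknown = class_counts.get("UNKNOWN", 0)
    n_classified = n_sites - n_unknown
    n_destab = sum(1 for a in annotations if a.classification.destabilizing)
    fragments: dict[str, bool] = {}
    for a in annotations:
        fid = a.site.effective_fragment_id
        if a.site.primary or fid not in fragments:
            fragments[fid] = a.classification.destabilizing
    return AnnotationSummary(
        n_sites=n_sites,
        n_classified=n_classified,
        class_counts=dict(class_counts),
        protease_counts=dict(protease_counts),
        fraction_destabilizing=(n_destab / n_classified) if n_classified else 0.0,
        n_fragments=len(fragments),
        n_fragments_destabilizing=sum(fragments.values()),
        n_errors=n_errors,
    )
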