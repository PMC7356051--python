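"""The Arg/N-degron residue hierarchy and its enzymatic cascade.

The Arg/N-degron pathway relates the in vivo half-life of a protein to the
identity of its (nonacetylated) N-terminal residue.  Destabilizing N-termini
fall into mechanistically distinct tiers:

* **primary type-1** — basic residues (Arg, Lys, His), bound directly by the
  type-1 site of the UBR-family N-recognins;
* **primary type-2** — bulky hydrophobics (Phe, Trp, Tyr, Leu, Ile), bound by
  the type-2 site;
* **secondary** — Asp and Glu, which must first be arginylated by the ATE1
  arginyl-transferase;
* **tertiary** — Asn and Gln, which are deamidated (NTAN1 and NTAQ1
  respectively) to Asp/Glu before arginylation, and Cys, which is oxidized
  (to Cys-sulfinate/-sulfonate, written ``C*``) before arginylation.

Everything else (Ala, Gly, Met, Pro, Ser, Thr, Val) is stabilizing; the
ambiguity codes B, J, O, U, X, Z classify as UNKNOWN.  The hierarchy is held
in a :class:`RuleTable` which ships with this default but can be loaded from
a YAML document so alternative degron grammars can be screened.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Token for oxidized N-terminal cysteine (Cys-sulfinate or -sulfonate).
OXIDIZED_CYS = "C*"

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY_CODES = frozenset("BJOUXZ")

#: MetAP specificity: initiator Met is removed when residue 2 has a small
#: side chain.  Configurable on :class:`RuleTable`.
DEFAULT_MET_EXCISION_SET = frozenset("ACGPSTV")

VALID_ENZYMES = frozenset({"NTAN1", "NTAQ1", "CYS_OXIDATION", "ATE1", "METAP"})


class ResidueClass(str, enum.Enum):
    """Tier of an N-terminal residue in the Arg/N-degron hierarchy."""

    PRIMARY_TYPE1 = "PRIMARY_TYPE1"
    PRIMARY_TYPE2 = "PRIMARY_TYPE2"
    SECONDARY = "SECONDARY"
    TERTIARY = "TERTIARY"
    STABILIZING = "STABILIZING"
    UNKNOWN = "UNKNOWN"

    @property
    def destabilizing(self) -> bool:
        return self in _DESTABILIZING_CLASSES


_DESTABILIZING_CLASSES = {
    ResidueClass.PRIMARY_TYPE1,
    ResidueClass.PRIMARY_TYPE2,
    ResidueClass.SECONDARY,
    ResidueClass.TERTIARY,
}


class RecogninSite(str, enum.Enum):
    """Which UBR substrate-binding site ultimately engages the N-terminus.

    Secondary/tertiary residues funnel to N-terminal Arg via the cascade, so
    they report TYPE1_SITE.
    """

    TYPE1_SITE = "TYPE1_SITE"
    TYPE2_SITE = "TYPE2_SITE"
    NONE = "NONE"


@dataclass(frozen=True)
class EnzymaticStep:
    """One enzymatic conversion of an N-terminal residue (e.g. NTAN1: N→D)."""

    enzyme: str
    input_residue: str
    output_residue: str

    def __post_init__(self) -> None:
        if self.enzyme not in VALID_ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.input_residue == self.output_residue:
            raise ValueError(
                f"{self.enzyme}: step must change the residue "
                f"({self.input_residue!r} -> {self.output_residue!r})"
            )

    def __str__(self) -> str:  # e.g. "NTAN1:N>D"
        return f"{self.enzyme}:{self.input_residue}>{self.output_residue}"


@dataclass(frozen=True)
class ClassificationResult:
    """Classification of a single N-terminal residue."""

    residue: str
    residue_class: ResidueClass
    destabilizing: bool
    cascade: tuple[EnzymaticStep, ...]
    recognin_site: RecogninSite


@dataclass(frozen=True)
class MetExcisionResult:
    mature_first_residue: str
    excised: bool


class RuleTableError(ValueError):
    """Raised when a rule table violates the degron-grammar invariants."""


class RuleTable:
    """Residue-class map, enzymatic cascades and recognin-site assignment.

    Parameters
    ----------
    class_map
        Mapping of one-letter residue code to :class:`ResidueClass` for all
        twenty canonical residues.  Ambiguity codes are implied UNKNOWN and
        must not appear.
    cascades
        Mapping of residue to the ordered enzymatic steps converting it to a
        primary destabilizing residue.  Must be non-empty exactly for
        SECONDARY and TERTIARY residues, and every cascade must terminate at
        a PRIMARY_TYPE1 residue (Arg in the default grammar).
    recognin_site
        Mapping of residue to the UBR binding site that ultimately engages
        it; unlisted residues map to ``NONE``.
    met_excision_set
        Second-position residues that permit MetAP removal of initiator Met.
    """

    def __init__(
        self,
        class_map: Mapping[str, ResidueClass],
        cascades: Mapping[str, Sequence[EnzymaticStep]],
        recognin_site: Mapping[str, RecogninSite],
        met_excision_set: frozenset[str] = DEFAULT_MET_EXCISION_SET,
    ) -> None:
        self.class_map = dict(class_map)
        self.cascades = {r: tuple(steps) for r, steps in cascades.items()}
        self.recognin_site = dict(recognin_site)
        self.met_excision_set = frozenset(met_excision_set)
        self._validate()

    def _validate(self) -> None:
        assigned = set(self.class_map)
        if assigned != CANONICAL_RESIDUES:
            missing = CANONICAL_RESIDUES - assigned
            extra = assigned - CANONICAL_RESIDUES
            raise RuleTableError(
                f"class_map must cover exactly the 20 canonical residues "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        needs_cascade = {
            r
            for r, c in self.class_map.items()
            if c in (ResidueClass.SECONDARY, ResidueClass.TERTIARY)
        }
        has_cascade = {r for r, s in self.cascades.items() if s}
        if needs_cascade != has_cascade:
            raise RuleTableError(
                "cascades must be non-empty exactly for secondary/tertiary "
                f"residues (expected {sorted(needs_cascade)}, "
                f"got {sorted(has_cascade)})"
            )
        for residue, steps in self.cascades.items():
            if not steps:
                continue
            if steps[0].input_residue != residue:
                raise RuleTableError(
                    f"cascade for {residue!r} must start from it, "
                    f"got {steps[0]}"
                )
            for prev, nxt in zip(steps, steps[1:]):
                if prev.output_residue != nxt.input_residue:
                    raise RuleTableError(
                        f"cascade for {residue!r} is not chained: "
                        f"{prev} then {nxt}"
                    )
            final = steps[-1].output_residue
            if self.class_map.get(final) is not ResidueClass.PRIMARY_TYPE1:
                raise RuleTableError(
                    f"cascade for {residue!r} must terminate at a primary "
                    f"type-1 residue, ends at {final!r}"
                )

    # -- construction ------------------------------------------------------

    @classmethod
    def default(cls) -> "RuleTable":
        """The mammalian Arg/N-degron table bundled with the package."""
        with resources.files("ndegron.data").joinpath("default_rules.yaml").open() as fh:
            return cls._from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_mapping(doc)

    @classmethod
    def _from_mapping(cls, doc: Mapping) -> "RuleTable":
        try:
            class_map = {
                str(res): ResidueClass(label)
                for label, residues in doc["classes"].items()
                for res in residues
            }
            cascades = {}
            for res, steps in doc.get("cascades", {}).items():
                chain, current = [], str(res)
                for step in steps:
                    nxt = str(step["to"])
                    chain.append(EnzymaticStep(step["enzyme"], current, nxt))
                    current = nxt
                cascades[str(res)] = chain
            recognin = {
                str(res): RecogninSite(site)
                for site, residues in doc.get("recognin", {}).items()
                for res in residues
            }
        except (KeyError, TypeError, ValueError) as exc:
            raise RuleTableError(f"malformed rule-table document: {exc}") from exc
        met_set = frozenset(doc.get("met_excision", DEFAULT_MET_EXCISION_SET))
        return cls(class_map, cascades, recognin, met_set)

    # -- queries -----------------------------------------------------------

    def residue_class(self, residue: str) -> ResidueClass:
        if residue in self.class_map:
            return self.class_map[residue]
        return ResidueClass.UNKNOWN

    def destabilizing_set(self) -> frozenset[str]:
        return frozenset(
            r for r, c in self.class_map.items() if c.destabilizing
        )

    def stabilizing_set(self) -> frozenset[str]:
        return frozenset(
            r for r, c in self.class_map.items() if c is ResidueClass.STABILIZING
        )


def classify_residue(
    residue: str,
    table: RuleTable | None = None,
    *,
    acetylated: bool = False,
) -> ClassificationResult:
    """Classify a single N-terminal residue under the Arg/N-degron rule.

    Parameters
    ----------
    residue
        One-letter amino-acid code.  Ambiguity codes (B, J, O, U, X, Z) and
        anything unassigned classify as UNKNOWN (not destabilizing).
    table
        Rule table; the bundled mammalian default when omitted.
    acetylated
        Nα-terminally acetylated N-termini escape the Arg branch entirely
        (the Ac/N-degron branch is not modelled); when set the residue is
        reported UNKNOWN regardless of identity.
    """
    if not isinstance(residue, str) or len(residue) != 1:
        raise ValueError(f"residue must be a single character, got {residue!r}")
    table = table or default_table()
    if acetylated:
        return ClassificationResult(
            residue, ResidueClass.UNKNOWN, False, (), RecogninSite.NONE
        )
    cls = table.residue_class(residue)
    return ClassificationResult(
        residue=residue,
        residue_class=cls,
        destabilizing=cls.destabilizing,
        cascade=table.cascades.get(residue, ()),
        recognin_site=table.recognin_site.get(residue, RecogninSite.NONE),
    )


def cascade_path(residue: str, table: RuleTable | None = None) -> list[EnzymaticStep]:
    """Ordered enzymatic steps converting `residue` to a primary residue.

    Empty for primary and stabilizing residues; raises for residues the
    table does not classify (UNKNOWN).
    """
    table = table or default_table()
    if table.residue_class(residue) is ResidueClass.UNKNOWN:
        raise KeyError(f"cannot query cascade of unclassified residue {residue!r}")
    return list(table.cascades.get(residue, ()))


def apply_met_excision(
    sequence: str, table: RuleTable | None = None
) -> MetExcisionResult:
    """Apply MetAP initiator-methionine removal to a protein sequence.

    Met is excised when the sequence starts with M and the second residue is
    in the table's small-side-chain set (default A, C, G, P, S, T, V).
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    table = table or default_table()
    if sequence[0] == "M" and sequence[1] in table.met_excision_set:
        return MetExcisionResult(sequence[1], True)
    return MetExcisionResult(sequence[0], False)


_DEFAULT_TABLE: RuleTable | None = None


def default_table() -> RuleTable:
    """The bundled mammalian rule table (cached singleton)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = RuleTable.default()
    return _DEFAULT_TABLE
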