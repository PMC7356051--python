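"""Synthetic substrates and ortholog families with known ground truth.

The generators emulate the statistical structure of a protease-substrate
screen — a table of cleavage sites whose P1' residues are destabilizing
with a controlled probability, and star-topology ortholog families whose
P1' column mutates under a controlled substitution model — so that every
pipeline stage can be exercised against exact, bookkept truth without any
database retrieval.  Defaults mirror the screen this package models: a
MEROPS-scale panel of ~125 substrates with a 21% destabilizing P1'
fraction, and ortholog panels in which P1' substitutions are rare and
property-preserving.

All randomness flows through a mandatory integer seed; identical configs
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conservation import OrthologFamily
from .fragments import CleavageSite, SubstrateRecord, extract_octamer
from .rules import CANONICAL_RESIDUES, RuleTable, default_table

_CANONICAL = sorted(CANONICAL_RESIDUES)


class ConfigError(ValueError):
    """An infeasible or invalid generator configuration."""


@dataclass(frozen=True)
class SubstrateGenConfig:
    """Configuration for the synthetic substrate/site generator.

    ``p_destab`` is the probability that an implanted P1' residue is drawn
    (uniformly, or per ``destab_weights``) from the destabilizing set; the
    default 0.21 matches the destabilizing fraction reported for known
    caspase-1 substrates.
    """

    seed: int
    n_substrates: int = 125
    length_range: tuple[int, int] = (80, 300)
    sites_per_substrate: int = 1
    p_destab: float = 0.21
    flank: int = 26
    destab_weights: Sequence[float] | None = None
    stab_weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_destab <= 1.0:
            raise ConfigError("p_destab must be in [0, 1]")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ConfigError("length_range must satisfy 10 <= min <= max")
        if self.n_substrates < 1 or self.sites_per_substrate < 1:
            raise ConfigError("need >= 1 substrate and >= 1 site per substrate")


@dataclass(frozen=True)
class FamilyGenConfig:
    """Configuration for the synthetic ortholog-family generator.

    ``p1prime_sub_rate`` is the probability that a member's P1' column
    carries a substitution; ``p_property_preserving`` the probability such a
    substitution stays within the destabilizing set (1.0 emulates the
    observation that ortholog P1' changes remain destabilizing).  Indels are
    kept out of a protected ±3-residue zone around P1' so gap/residue truth
    at the column is governed solely by the P1' model.
    """

    seed: int
    n_members: int = 20
    sub_rate: float = 0.03
    p1prime_sub_rate: float = 0.1
    p_property_preserving: float = 1.0
    indel_rate: float = 0.01
    max_indel_length: int = 2

    def __post_init__(self) -> None:
        for name in ("sub_rate", "p1prime_sub_rate", "p_property_preserving",
                     "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_members < 1:
            raise ConfigError("need >= 1 member")


@dataclass(frozen=True)
class SiteTruth:
    substrate_id: str
    p1_position: int
    p1prime_residue: str
    residue_class: str
    destabilizing: bool


@dataclass(frozen=True)
class MemberTruth:
    species: str
    state: str  # identical | property_preserving_sub | property_breaking_sub | gap
    p1prime_residue: str


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator bookkeeping: the exact state of every site / member."""

    sites: tuple[SiteTruth, ...] = ()
    members: tuple[MemberTruth, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sites": [vars(s) for s in self.sites],
            "members": [vars(m) for m in self.members],
        }


def _draw_residue(rng: np.random.Generator, pool: list[str],
                  weights: Sequence[float] | None) -> str:
    if weights is None:
        return pool[rng.integers(len(pool))]
    w = np.asarray(weights, dtype=float)
    if len(w) != len(pool) or w.sum() <= 0:
        raise ConfigError("weight vector must match the residue pool")
    return pool[rng.choice(len(pool), p=w / w.sum())]


def gen_substrates(
    config: SubstrateGenConfig, table: RuleTable | None = None
) -> tuple[list[SubstrateRecord], list[CleavageSite], SyntheticTruth]:
    """Generate substrates with implanted cleavage sites and truth labels.

    Site P1 positions are uniform over the flank-respecting range (the full
    context window fits inside the sequence) and drawn without replacement;
    the residue at P1' is implanted from the destabilizing set with
    probability ``p_destab``, otherwise from the stabilizing set.
    """
    table = table or default_table()
    rng = np.random.default_rng(config.seed)
    destab = sorted(table.destabilizing_set())
    stab = sorted(table.stabilizing_set())
    lo, hi = config.length_range
    substrates: list[SubstrateRecord] = []
    sites: list[CleavageSite] = []
    truths: list[SiteTruth] = []
    width = len(str(config.n_substrates))
    for k in range(config.n_substrates):
        sid = f"SYN{k + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(_CANONICAL, size=length))
        # positions where the full octamer + flank window fits
        p1_lo, p1_hi = config.flank + 4, length - config.flank - 4
        if p1_hi - p1_lo + 1 < config.sites_per_substrate:
            raise ConfigError(
                f"{sid}: {config.sites_per_substrate} sites do not fit in "
                f"length {length} at flank {config.flank}"
            )
        positions = sorted(
            int(p) for p in rng.choice(
                np.arange(p1_lo, p1_hi + 1), size=config.sites_per_substrate,
                replace=False,
            )
        )
        for p1 in positions:
            if rng.random() < config.p_destab:
                residue = _draw_residue(rng, destab, config.destab_weights)
            else:
                residue = _draw_residue(rng, stab, config.stab_weights)
            seq[p1] = residue  # 0-based index p1 == 1-based position p1+1 (P1')
        sequence = "".join(seq)
        substrates.append(
            SubstrateRecord(sid, sequence, species="synthetic",
                            description="synthetic substrate")
        )
        for p1 in positions:
            residue = sequence[p1]
            cls = table.residue_class(residue)
            sites.append(
                CleavageSite(
                    substrate_id=sid, protease="synthetic-protease",
                    p1_position=p1, octamer=extract_octamer(sequence, p1),
                )
            )
            truths.append(
                SiteTruth(sid, p1, residue, cls.value, cls.destabilizing)
            )
    return substrates, sites, SyntheticTruth(sites=tuple(truths))


def gen_ortholog_family(
    reference_window: str,
    window_p1prime_offset: int,
    config: FamilyGenConfig,
    family_id: str = "synthetic-family",
    table: RuleTable | None = None,
) -> tuple[OrthologFamily, SyntheticTruth]:
    """Generate a star-topology ortholog family from a reference window.

    Each member is derived independently from the reference: background
    substitutions at ``sub_rate`` per site (uniform over the other 19
    residues), a P1' column governed by ``p1prime_sub_rate`` and
    ``p_property_preserving``, and indels of 1..``max_indel_length``
    residues at ``indel_rate`` per position outside the protected ±3 zone
    around P1'.
    """
    table = table or default_table()
    if len(reference_window) < 20:
        raise ValueError("reference window must be >= 20 residues")
    if not 1 <= window_p1prime_offset <= len(reference_window):
        raise ValueError(
            f"P1' offset {window_p1prime_offset} outside window of length "
            f"{len(reference_window)}"
        )
    rng = np.random.default_rng(config.seed)
    ref_p1prime = reference_window[window_p1prime_offset - 1]
    destab = sorted(table.destabilizing_set())
    stab = sorted(table.stabilizing_set())
    p1_idx = window_p1prime_offset - 1  # 0-based
    members: list[tuple[str, str]] = []
    truths: list[MemberTruth] = []
    width = len(str(config.n_members))
    for k in range(config.n_members):
        species = f"species_{k + 1:0{width}d}"
        seq = list(reference_window)
        # background substitutions (never at the P1' column)
        for i in range(len(seq)):
            if i != p1_idx and rng.random() < config.sub_rate:
                others = [r for r in _CANONICAL if r != seq[i]]
                seq[i] = others[rng.integers(len(others))]
        # P1' substitution model
        state = "identical"
        if rng.random() < config.p1prime_sub_rate:
            if rng.random() < config.p_property_preserving:
                pool = [r for r in destab if r != ref_p1prime]
                state = "property_preserving_sub"
            else:
                pool = [r for r in stab if r != ref_p1prime]
                state = "property_breaking_sub"
            seq[p1_idx] = pool[rng.integers(len(pool))]
        member_p1prime = seq[p1_idx]
        # indels outside the protected zone around P1'
        out: list[str] = []
        protected = range(p1_idx - 3, p1_idx + 4)
        for i, ch in enumerate(seq):
            if i not in protected and rng.random() < config.indel_rate:
                size = int(rng.integers(1, config.max_indel_length + 1))
                if rng.random() < 0.5:
                    continue  # delete this residue (size collapsed to 1)
                out.append(ch)
                out.extend(rng.choice(_CANONICAL, size=size))
            else:
                out.append(ch)
        members.append((species, "".join(out)))
        truths.append(MemberTruth(species, state, member_p1prime))
    family = OrthologFamily(
        family_id=family_id,
        reference_window=reference_window,
        window_p1prime_offset=window_p1prime_offset,
        members=tuple(members),
    )
    return family, SyntheticTruth(members=tuple(truths))
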