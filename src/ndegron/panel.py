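"""The bundled panel of proinflammatory fragments with candidate N-degrons.

Fourteen protease-generated proinflammatory fragments whose P1' residue is
destabilizing under the Arg/N-degron rule: nine released by caspase-1
activity (including the self-cleavage fragments of the inflammatory
caspases themselves) and five by other endopeptidases (DPP1 processing of
granzymes A/M/K, proteinase-3 processing of IL-36β/γ).  Ataxin-3 carries
two alternative cleavage sites (Glu245, the primary one, and Leu249) that
release a single counted fragment, so the panel holds 14 fragments over 15
sites.

The panel stores fragment identities, P1' residues and 1-based P1'
positions; full substrate sequences are NOT deposited with these fragment
lists, so each context sequence here is SYNTHETIC non-biological filler
(deterministic stabilizing-residue pattern) carrying only the implanted
P1' residue — and Asp at P1 for caspase sites, matching caspase
specificity.  Classification depends only on the P1' residue, so the
filler does not affect any count this package reports.

Known reported-position discrepancies, resolved in favour of the primary fragment
listing: CASP5 P1' appears as Gln138 and elsewhere as Gln137 (138 used);
RAB39a appears as Cys149 and elsewhere as position 144 (149 used).
"""

from __future__ import annotations

from dataclasses import dataclass

from .conservation import OrthologFamily
from .fragments import CleavageSite, SubstrateRecord, extract_octamer, extract_window
from .simulate import FamilyGenConfig, gen_ortholog_family

CASPASE1 = "caspase-1"
DPP1 = "DPP1"
PROTEINASE3 = "proteinase-3"

#: Stabilizing-residue filler pattern for synthetic sequence context.
_FILLER = "AGSTVPTSGA"


@dataclass(frozen=True)
class PanelSite:
    p1prime_position: int  # 1-based position of P1' (the fragment's first residue)
    p1prime_residue: str
    primary: bool = True


@dataclass(frozen=True)
class PanelFragment:
    fragment_id: str
    substrate_id: str
    protein_name: str
    protease: str
    sites: tuple[PanelSite, ...]
    note: str = ""


PANEL: tuple[PanelFragment, ...] = (
    # Nine fragments from the caspase-1 substrate screen
    PanelFragment("Asn120-CASP1", "CASP1", "caspase-1", CASPASE1,
                  (PanelSite(120, "N"),), "self-cleavage after the CARD domain"),
    PanelFragment("Gln81-CASP4", "CASP4", "caspase-4", CASPASE1,
                  (PanelSite(81, "Q"),), "self-cleavage"),
    PanelFragment("Gln138-CASP5", "CASP5", "caspase-5", CASPASE1,
                  (PanelSite(138, "Q"),),
                  "self-cleavage; also reported as Gln137 — 138 used"),
    PanelFragment("Cys149-RAB39A", "RAB39A", "Rab39a", CASPASE1,
                  (PanelSite(149, "C"),),
                  "also reported as position 144 — 149 used"),
    PanelFragment("Tyr37-IL18", "IL18", "IL-18", CASPASE1,
                  (PanelSite(37, "Y"),)),
    PanelFragment("Tyr49-CCL3", "CCL3", "CCL3", CASPASE1,
                  (PanelSite(49, "Y"),)),
    PanelFragment("Glu245-ATXN3", "ATXN3", "Ataxin-3", CASPASE1,
                  (PanelSite(245, "E", primary=True),
                   PanelSite(249, "L", primary=False)),
                  "two alternative sites releasing one counted fragment"),
    PanelFragment("Cys50-HNRNPA2B1", "HNRNPA2B1",
                  "heterogeneous nuclear ribonucleoproteins A2/B1", CASPASE1,
                  (PanelSite(50, "C"),)),
    PanelFragment("Leu680-MATR3", "MATR3", "Matrin-3", CASPASE1,
                  (PanelSite(680, "L"),)),
    # Five fragments generated by other endopeptidases
    PanelFragment("Ile29-GRZA", "GRZA", "granzyme A", DPP1,
                  (PanelSite(29, "I"),), "activation-peptide removal"),
    PanelFragment("Ile27-GRZM", "GRZM", "granzyme M", DPP1,
                  (PanelSite(27, "I"),), "activation-peptide removal"),
    PanelFragment("Ile26-GRZK", "GRZK", "granzyme K", DPP1,
                  (PanelSite(26, "I"),), "activation-peptide removal"),
    PanelFragment("Glu6-IL36B", "IL36B", "IL-36 beta", PROTEINASE3,
                  (PanelSite(6, "E"),)),
    PanelFragment("Tyr16-IL36G", "IL36G", "IL-36 gamma", PROTEINASE3,
                  (PanelSite(16, "Y"),)),
)


def _synthetic_context(fragment: PanelFragment, tail: int = 60) -> str:
    """Synthetic (non-biological) substrate sequence for one panel entry.

    Stabilizing filler long enough to hold every site plus a C-terminal
    tail, with the reported P1' residues implanted at their positions and
    Asp at P1 for caspase-generated sites.
    """
    length = max(s.p1prime_position for s in fragment.sites) + tail
    seq = list("M" + _FILLER * (length // len(_FILLER) + 1))[:length]
    for site in fragment.sites:
        seq[site.p1prime_position - 1] = site.p1prime_residue
        if fragment.protease == CASPASE1 and site.p1prime_position >= 2:
            seq[site.p1prime_position - 2] = "D"  # caspases cleave after Asp
    return "".join(seq)


def fragment_panel(
    include_families: bool = True,
    family_config: FamilyGenConfig | None = None,
    flank: int = 26,
) -> tuple[list[SubstrateRecord], list[CleavageSite], list[OrthologFamily]]:
    """The bundled 14-fragment / 15-site panel, with ortholog families.

    Substrate sequences are synthetic filler context around the reported P1'
    residues (see module docstring).  The ortholog families emulate the
    panel's reported conservation behaviour — P1' substitutions are rare
    and always property-preserving — via the seeded family generator; pass
    ``include_families=False`` to skip them.
    """
    substrates: list[SubstrateRecord] = []
    sites: list[CleavageSite] = []
    families: list[OrthologFamily] = []
    for idx, frag in enumerate(PANEL):
        sequence = _synthetic_context(frag)
        substrates.append(
            SubstrateRecord(
                substrate_id=frag.substrate_id,
                sequence=sequence,
                species="Homo sapiens",
                description=(
                    f"{frag.protein_name} [synthetic non-biological context; "
                    f"only P1' residues are as reported]"
                ),
            )
        )
        for site in frag.sites:
            p1 = site.p1prime_position - 1
            sites.append(
                CleavageSite(
                    substrate_id=frag.substrate_id,
                    protease=frag.protease,
                    p1_position=p1,
                    octamer=extract_octamer(sequence, p1),
                    fragment_id=frag.fragment_id,
                    primary=site.primary,
                )
            )
            if include_families and site.primary:
                window, offset, _ = extract_window(sequence, p1, flank)
                cfg = family_config or FamilyGenConfig(
                    seed=20_000 + idx, n_members=12,
                    sub_rate=0.03, p1prime_sub_rate=0.08,
                    p_property_preserving=1.0, indel_rate=0.01,
                )
                family, _truth = gen_ortholog_family(
                    window, offset, cfg, family_id=frag.fragment_id
                )
                families.append(family)
    return substrates, sites, families
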