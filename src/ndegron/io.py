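"""Readers and writers for the pipeline's file formats.

FASTA for substrate sequences and ortholog families (via Bio.SeqIO), TSV
for site tables, annotations and conservation reports (tab-delimited,
UTF-8, ``#`` comment lines), JSON for summaries and generator truth.
Species tags travel in FASTA descriptions as ``OS=<species>``; a family
FASTA's first record is the reference window and carries
``p1prime_offset=<k>`` in its description.

All writers are deterministic (stable ordering, fractions at 6 significant
digits) and atomic: output lands in a temporary file which is moved into
place on success, so a failed run never leaves a partial file.
"""

from __future__ import annotations

import json
import logging
import os
import re
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import ConservationReport, OrthologFamily
from .fragments import CleavageSite, FragmentAnnotation, SubstrateRecord

logger = logging.getLogger(__name__)

_OS_RE = re.compile(r"OS=(.+?)(?:\s+\w\w=|$)")
_OFFSET_RE = re.compile(r"p1prime_offset=(\d+)")

SITE_COLUMNS = ["substrate_id", "protease", "p1_position"]
_KNOWN_SITE_COLUMNS = SITE_COLUMNS + ["octamer", "fragment_id", "primary", "acetylated"]


class ParseError(ValueError):
    """A malformed input file, with location information in the message."""


@contextmanager
def atomic_write(path: str | Path, mode: str = "w") -> Iterator:
    """Write to a temp file in the target directory; move into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# -- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SubstrateRecord]:
    """Read substrate records; species parsed from an ``OS=`` tag if present."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _OS_RE.search(rec.description)
        try:
            records.append(
                SubstrateRecord(
                    substrate_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    species=m.group(1).strip() if m else "",
                    description=rec.description,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Iterable[SubstrateRecord], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for rec in records:
            desc = rec.description
            if rec.species and f"OS={rec.species}" not in desc:
                desc = f"{desc} OS={rec.species}".strip()
            seqrec = SeqRecord(Seq(rec.sequence), id=rec.substrate_id,
                               description=desc)
            SeqIO.write(seqrec, fh, "fasta")


# -- site tables -----------------------------------------------------------

def read_site_table(path: str | Path) -> list[CleavageSite]:
    """Read a cleavage-site TSV (columns substrate_id, protease, p1_position).

    Optional columns octamer, fragment_id, primary, acetylated are used when
    present; unknown extra columns are preserved on the records.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in _KNOWN_SITE_COLUMNS]
    sites = []
    for idx, row in df.iterrows():
        try:
            p1 = int(row["p1_position"])
        except ValueError as exc:
            raise ParseError(
                f"{path}: row {idx + 1}: p1_position {row['p1_position']!r} "
                "is not an integer"
            ) from exc
        try:
            sites.append(
                CleavageSite(
                    substrate_id=row["substrate_id"],
                    protease=row["protease"],
                    p1_position=p1,
                    octamer=row.get("octamer", ""),
                    fragment_id=row.get("fragment_id", ""),
                    primary=_parse_bool(row.get("primary", "true")),
                    acetylated=_parse_bool(row.get("acetylated", "false")),
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {idx + 1}: {exc}") from exc
    return sites


def _parse_bool(value: str) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def write_site_table(sites: Iterable[CleavageSite], path: str | Path) -> None:
    sites = list(sites)
    extra_cols = sorted({c for s in sites for c in s.extra})
    with atomic_write(path) as fh:
        fh.write("# cleavage sites: tab-delimited, 1-based P1 positions\n")
        header = _KNOWN_SITE_COLUMNS + extra_cols
        fh.write("\t".join(header) + "\n")
        for s in sites:
            row = [s.substrate_id, s.protease, str(s.p1_position), s.octamer,
                   s.fragment_id, str(s.primary).lower(),
                   str(s.acetylated).lower()]
            row += [str(s.extra.get(c, "")) for c in extra_cols]
            fh.write("\t".join(row) + "\n")


# -- annotations -----------------------------------------------------------

ANNOTATION_COLUMNS = [
    "substrate_id", "protease", "p1_position", "p1prime", "class",
    "destabilizing", "recognin_site", "cascade", "fragment_id", "window",
    "window_offset", "truncated",
]


def write_annotations(
    annotations: Iterable[FragmentAnnotation], path: str | Path
) -> None:
    with atomic_write(path) as fh:
        fh.write("# N-degron annotations: tab-delimited, 1-based coordinates\n")
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in annotations:
            cascade = ";".join(str(step) for step in a.classification.cascade)
            row = [
                a.site.substrate_id, a.site.protease, str(a.site.p1_position),
                a.p1prime_residue, a.classification.residue_class.value,
                str(a.classification.destabilizing).lower(),
                a.classification.recognin_site.value, cascade,
                a.site.effective_fragment_id, a.window,
                str(a.window_p1prime_offset), str(a.window_truncated).lower(),
            ]
            fh.write("\t".join(row) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       keep_default_na=False, na_values=[])


# -- ortholog families -----------------------------------------------------

def read_family_fasta(path: str | Path) -> OrthologFamily:
    """Read one family FASTA: reference window first, then member records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty family file")
    ref = records[0]
    m = _OFFSET_RE.search(ref.description)
    if not m:
        raise ParseError(
            f"{path}: reference record {ref.id!r} lacks a "
            "p1prime_offset=<k> tag"
        )
    members = []
    for rec in records[1:]:
        sp = _OS_RE.search(rec.description)
        members.append((sp.group(1).strip() if sp else rec.id,
                        str(rec.seq).upper()))
    return OrthologFamily(
        family_id=Path(path).stem,
        reference_window=str(ref.seq).upper(),
        window_p1prime_offset=int(m.group(1)),
        members=tuple(members),
    )


def write_family_fasta(family: OrthologFamily, path: str | Path) -> None:
    with atomic_write(path) as fh:
        ref = SeqRecord(
            Seq(family.reference_window), id=f"{family.family_id}|reference",
            description=f"p1prime_offset={family.window_p1prime_offset}",
        )
        SeqIO.write(ref, fh, "fasta")
        for species, seq in family.members:
            rec = SeqRecord(Seq(seq), id=f"{family.family_id}|{species}",
                            description=f"OS={species}")
            SeqIO.write(rec, fh, "fasta")


def write_conservation_report(
    reports: Iterable[ConservationReport], tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Per-member TSV plus an optional per-family JSON summary."""
    reports = list(reports)
    with atomic_write(tsv_path) as fh:
        fh.write("# P1' conservation: tab-delimited\n")
        fh.write("family_id\tspecies\taligned_residue\tclass\tdestabilizing\n")
        for r in reports:
            for s in r.aligned_sites:
                cls = s.classification.value if s.classification else ""
                destab = "" if s.destabilizing is None else str(s.destabilizing).lower()
                fh.write(f"{r.family_id}\t{s.species}\t{s.aligned_residue}\t"
                         f"{cls}\t{destab}\n")
    if json_path is not None:
        summary = {
            r.family_id: {
                "reference_p1prime": r.reference_residue,
                "n_members": r.n_members,
                "n_gap": r.n_gap,
                "identity_conservation": float(_fmt(r.identity_conservation)),
                "property_conservation": float(_fmt(r.property_conservation)),
            }
            for r in reports
        }
        write_json(summary, json_path)


def write_json(obj, path: str | Path) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
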