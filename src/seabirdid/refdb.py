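"""Reference-database parsing, curation and in-silico PCR.

A reference database is a per-marker collection of taxonomically labelled
mitochondrial sequences against which unknowns are compared. Databases are
stored as FASTA; two header dialects are understood:

* canonical: ``>accession|family|genus|species[|provenance]`` — pipes
  delimit fields, the species field is the full binomial (spaces or
  underscores accepted);
* lenient:   ``>accession Genus_species`` — missing ranks are filled from
  a taxonomy side-table.

The dialect is auto-detected per file; mixing dialects in one file is an
error. Curation is a soft delete: excluded records stay in the file model
with ``provenance=excluded`` so the exclusion trail is auditable, but they
are omitted from every downstream computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import ValidationError
from .iupac import SEQUENCE_ALPHABET, count_mismatches, reverse_complement
from .markers import PrimerPair, TaxonLabel, TaxonomyTable

logger = logging.getLogger(__name__)

MIN_SEQUENCE_LENGTH = 100

KNOWN_PROVENANCE = "known_provenance"
PUBLIC_REPOSITORY = "public_repository"
EXCLUDED = "excluded"
_PROVENANCES = (KNOWN_PROVENANCE, PUBLIC_REPOSITORY, EXCLUDED)


@dataclass(frozen=True)
class ReferenceSequence:
    """One taxonomically labelled reference sequence for one marker."""

    accession: str
    taxon: TaxonLabel
    marker_id: str
    sequence: str
    provenance: str = PUBLIC_REPOSITORY
    note: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < MIN_SEQUENCE_LENGTH:
            raise ValidationError(
                f"{self.accession}: sequence length {len(seq)} < {MIN_SEQUENCE_LENGTH}"
            )
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.accession}: characters outside the IUPAC alphabet: {sorted(bad)}"
            )
        if self.provenance not in _PROVENANCES:
            raise ValidationError(
                f"{self.accession}: unknown provenance {self.provenance!r}"
            )

    @property
    def active(self) -> bool:
        return self.provenance != EXCLUDED


@dataclass(frozen=True)
class Haplotype:
    """A group of identical (or mutually nested) sequences of one species."""

    species: str
    representative: str  # accession of the longest member
    members: tuple[str, ...]
    sequence: str


@dataclass
class CurationReport:
    """Audit trail of a curation pass."""

    applied: list[tuple[str, str]] = field(default_factory=list)
    not_found: list[tuple[str, str]] = field(default_factory=list)
    shared_haplotypes: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    per_species: pd.DataFrame | None = None
    per_family: pd.DataFrame | None = None

    def to_tsv(self, path: str | Path, db: "ReferenceDatabase") -> None:
        rows = []
        reasons = {acc: reason for acc, reason in self.applied}
        for rec in db.records:
            rows.append(
                {
                    "accession": rec.accession,
                    "species": rec.taxon.species,
                    "genus": rec.taxon.genus,
                    "family": rec.taxon.family,
                    "status": "excluded" if not rec.active else "active",
                    "reason": reasons.get(rec.accession, rec.note),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ReferenceDatabase:
    """A validated per-marker reference sequence collection."""

    marker_id: str
    records: list[ReferenceSequence]
    haplotypes: dict[str, list[Haplotype]] = field(default_factory=dict)
    shared_haplotype_flags: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.marker_id != self.marker_id:
                raise ValidationError(
                    f"{rec.accession}: marker {rec.marker_id} does not match database "
                    f"marker {self.marker_id}"
                )
            if rec.accession in seen:
                raise ValidationError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)

    # -- views -------------------------------------------------------------
    @property
    def active_records(self) -> list[ReferenceSequence]:
        return [r for r in self.records if r.active]

    def species_present(self, listed_only: bool = False) -> set[str]:
        """Species with at least one active record."""
        return {
            r.taxon.species
            for r in self.active_records
            if not listed_only or r.taxon.listed
        }

    def labels(self) -> dict[str, TaxonLabel]:
        return {r.accession: r.taxon for r in self.active_records}

    def get(self, accession: str) -> ReferenceSequence:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)


# ---------------------------------------------------------------------------
# FASTA parsing / serialization
# ---------------------------------------------------------------------------

def _parse_canonical_header(header: str) -> tuple[str, str, str, str, str]:
    parts = [p.strip() for p in header.split("|")]
    if len(parts) not in (4, 5):
        raise ValidationError(
            f"malformed canonical header {header!r}: expected "
            "accession|family|genus|species[|provenance]"
        )
    accession, family, genus, species = parts[:4]
    provenance = parts[4] if len(parts) == 5 else PUBLIC_REPOSITORY
    species = species.replace("_", " ")
    return accession, family, genus, species, provenance


def _parse_lenient_header(header: str) -> tuple[str, str]:
    parts = header.split(None, 1)
    if len(parts) != 2 or "_" not in parts[1]:
        raise ValidationError(
            f"malformed lenient header {header!r}: expected 'accession Genus_species'"
        )
    accession = parts[0]
    species = parts[1].strip().replace("_", " ")
    if len(species.split()) < 2:
        raise ValidationError(f"malformed lenient header {header!r}: species not binomial")
    return accession, species


def parse_reference_fasta(
    source: str | Path | TextIO,
    marker_id: str,
    taxonomy: TaxonomyTable | None = None,
) -> ReferenceDatabase:
    """Parse and validate a reference database FASTA.

    The header dialect (canonical pipe-delimited, or lenient with a
    taxonomy side-table) is auto-detected from the first record; mixing
    dialects within a file raises. Sequences are uppercased; non-IUPAC
    characters, duplicate accessions, malformed headers and empty files
    are hard errors.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return parse_reference_fasta(fh, marker_id, taxonomy)

    seq_records = list(SeqIO.parse(source, "fasta"))
    if not seq_records:
        raise ValidationError("empty FASTA: no records found")

    dialect = "canonical" if "|" in seq_records[0].description else "lenient"
    records: list[ReferenceSequence] = []
    for sr in seq_records:
        header = sr.description
        this_dialect = "canonical" if "|" in header else "lenient"
        if this_dialect != dialect:
            raise ValidationError(
                f"{header!r}: mixed header dialects in one file "
                f"(file is {dialect}, record is {this_dialect})"
            )
        if dialect == "canonical":
            accession, family, genus, species, provenance = _parse_canonical_header(header)
            listed = False
            if taxonomy is not None:
                hit = taxonomy.lookup(species)
                listed = hit.listed if hit is not None else False
            taxon = TaxonLabel(species=species, genus=genus, family=family, listed=listed)
        else:
            accession, species = _parse_lenient_header(header)
            if taxonomy is not None:
                taxon = taxonomy.label_for(species)
            else:
                taxon = TaxonLabel(species=species)
            provenance = PUBLIC_REPOSITORY
        records.append(
            ReferenceSequence(
                accession=accession,
                taxon=taxon,
                marker_id=marker_id,
                sequence=str(sr.seq),
                provenance=provenance,
            )
        )
    return ReferenceDatabase(marker_id=marker_id, records=records)


def write_reference_fasta(db: ReferenceDatabase, dest: str | Path | TextIO) -> None:
    """Serialize a database in the canonical header dialect (all records,
    including soft-deleted ones, so the file round-trips)."""
    out = [
        SeqRecord(
            Seq(rec.sequence),
            id="",
            description=f"{rec.accession}|{rec.taxon.family}|{rec.taxon.genus}"
            f"|{rec.taxon.species.replace(' ', '_')}|{rec.provenance}",
        )
        for rec in db.records
    ]
    # SeqIO prints "id description"; keep only the description.
    buf = StringIO()
    for sr in out:
        buf.write(f">{sr.description}\n")
        seq = str(sr.seq)
        for i in range(0, len(seq), 70):
            buf.write(seq[i : i + 70] + "\n")
    text = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

def collapse_haplotypes(db: ReferenceDatabase) -> ReferenceDatabase:
    """Group identical active sequences of each species into haplotypes.

    Sequences identical after uppercasing, or fully nested (one a
    substring of the other, i.e. identical over their common overlap when
    one read is a truncation of the other), share one haplotype. Groups
    never span species; identical sequences appearing in two or more
    species are flagged ``shared_haplotype``. Idempotent.
    """
    by_species: dict[str, list[ReferenceSequence]] = {}
    for rec in db.active_records:
        by_species.setdefault(rec.taxon.species, []).append(rec)

    haplotypes: dict[str, list[Haplotype]] = {}
    for species in sorted(by_species):
        recs = sorted(
            by_species[species], key=lambda r: (-len(r.sequence), r.sequence, r.accession)
        )
        groups: list[list[ReferenceSequence]] = []
        for rec in recs:
            hosts = [
                g for g in groups
                if rec.sequence == g[0].sequence or rec.sequence in g[0].sequence
            ]
            if len(hosts) == 1:
                hosts[0].append(rec)
            else:
                # ambiguous containment (or none): keep as its own haplotype
                groups.append([rec])
        haplotypes[species] = [
            Haplotype(
                species=species,
                representative=g[0].accession,
                members=tuple(sorted(r.accession for r in g)),
                sequence=g[0].sequence,
            )
            for g in groups
        ]

    # flag identical sequences shared across species
    shared: dict[str, list[str]] = {}
    for species, haps in haplotypes.items():
        for hap in haps:
            shared.setdefault(hap.sequence, []).append(species)
    flags = [
        (seq, tuple(sorted(species_list)))
        for seq, species_list in shared.items()
        if len(set(species_list)) > 1
    ]
    for _, species_list in flags:
        logger.warning("shared_haplotype: identical sequence in %s", ", ".join(species_list))

    return ReferenceDatabase(
        marker_id=db.marker_id,
        records=list(db.records),
        haplotypes=haplotypes,
        shared_haplotype_flags=sorted(flags, key=lambda x: x[1]),
    )


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def curate(
    db: ReferenceDatabase, exclusions: Iterable[tuple[str, str]]
) -> tuple[ReferenceDatabase, CurationReport]:
    """Apply accession exclusions (soft delete) and build an audit report.

    Reference sequences with demonstrably wrong taxonomy (e.g. a museum
    specimen whose lineage-diagnostic motif contradicts its label) are
    excluded rather than removed, so the decision is auditable. Unknown
    accessions produce a warning in the report, not an error.
    """
    report = CurationReport()
    wanted = {acc: reason for acc, reason in exclusions}
    new_records: list[ReferenceSequence] = []
    for rec in db.records:
        if rec.accession in wanted:
            reason = wanted.pop(rec.accession)
            new_records.append(replace(rec, provenance=EXCLUDED, note=reason))
            report.applied.append((rec.accession, reason))
        else:
            new_records.append(rec)
    for acc, reason in wanted.items():
        logger.warning("exclusion accession %s not found in database", acc)
        report.not_found.append((acc, reason))

    curated = collapse_haplotypes(
        ReferenceDatabase(marker_id=db.marker_id, records=new_records)
    )
    report.shared_haplotypes = list(curated.shared_haplotype_flags)

    rows = []
    for species, haps in curated.haplotypes.items():
        family = next(
            r.taxon.family for r in curated.active_records if r.taxon.species == species
        )
        rows.append(
            {
                "species": species,
                "family": family,
                "n_records": sum(len(h.members) for h in haps),
                "n_haplotypes": len(haps),
            }
        )
    report.per_species = pd.DataFrame(
        rows, columns=["species", "family", "n_records", "n_haplotypes"]
    )
    if rows:
        report.per_family = (
            report.per_species.groupby("family", as_index=False)[
                ["n_records", "n_haplotypes"]
            ]
            .sum()
            .assign(
                n_species=report.per_species.groupby("family")["species"]
                .count()
                .values
            )
        )
    else:
        report.per_family = pd.DataFrame(
            columns=["family", "n_records", "n_haplotypes", "n_species"]
        )
    return curated, report


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _find_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where ``primer`` can anneal to ``template``."""
    n, k = len(template), len(primer)
    return [
        i
        for i in range(n - k + 1)
        if count_mismatches(primer, template[i : i + k]) <= max_mismatch
    ]


def extract_amplicon(
    template: str, primers: PrimerPair, max_mismatch: int = 0
) -> str | None:
    """In-silico PCR: return the insert between the primer binding sites.

    Both strands are scanned. Primer codes match IUPAC-aware (a code
    matches when its base set intersects the template code's set; inosine
    and N match anything); the reverse primer is matched against its
    reverse complement on the scanned strand. The insert excludes the
    primer sites themselves. When several site pairs qualify, the pair
    whose insert length is closest to the expected length wins; exact
    ties keep the first by position, with a logged warning. No hit
    returns ``None``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    template = template.upper()
    fwd = primers.forward.upper()
    rev_site = reverse_complement(primers.reverse)

    candidates: list[tuple[int, int, int, str]] = []  # (|len - expected|, strand, f_start, insert)
    for strand_idx, strand in enumerate((template, reverse_complement(template))):
        if len(strand) < len(fwd) + len(rev_site):
            continue
        f_hits = _find_sites(strand, fwd, max_mismatch)
        r_hits = _find_sites(strand, rev_site, max_mismatch)
        for f in f_hits:
            insert_start = f + len(fwd)
            for r in r_hits:
                if r >= insert_start:
                    insert = strand[insert_start:r]
                    candidates.append(
                        (
                            abs(len(insert) - primers.expected_insert_length),
                            strand_idx,
                            f,
                            insert,
                        )
                    )
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        logger.warning(
            "multiple equally good amplicons (insert lengths %d); keeping first by position",
            len(candidates[0][3]),
        )
    return candidates[0][3]
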