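"""Identification of unknown specimens and comparison with visual records.

Unknown feather-derived sequences are identified marker by marker against
the reference alignments using the same neighbour semantics as the
reference evaluation, then combined by an ordered decision tree:
cytochrome b is consulted first and the control region only when species
resolution is insufficient. One special case is handled explicitly — the
shy/white-capped albatross pair (*Thalassarche cauta* / *T. steadi*),
morphologically and genetically near-identical, is separated by a
diagnostic SNP in control-region copy 2, domain 1; the diagnostic column
is learned from the reference alignment rather than hard-coded, and the
call carries its documented ~3% error rate as a caveat. Genetic
identifications can finally be reconciled against the fishery e-logbook's
visual identifications rank by rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .distance import (
    DEFAULT_IDENTITY_FLOOR,
    DEFAULT_MIN_OVERLAP,
    MarkerAlignment,
    align_query,
    p_distance,
)
from .errors import UnalignableQueryError, ValidationError
from .markers import MarkerDef, TaxonomyTable
from .refdb import ReferenceDatabase

logger = logging.getLogger(__name__)

CAUTA = "Thalassarche cauta"
STEADI = "Thalassarche steadi"
#: Documented error rate of the cauta/steadi control-region SNP call.
SNP_ERROR_CAVEAT = "snp_call_~3%_error"
CR_COPY_CAVEAT = "cr_copy_uncertain"


class Rank(str, Enum):
    SPECIES = "species"
    SISTER_SET = "sister_set"
    GENUS = "genus"
    FAMILY = "family"
    NONE = "none"


RANK_ORDER = {
    Rank.SPECIES: 0,
    Rank.SISTER_SET: 1,
    Rank.GENUS: 2,
    Rank.FAMILY: 3,
    Rank.NONE: 4,
}


class SnpCall(str, Enum):
    CAUTA = "cauta"
    STEADI = "steadi"
    NOT_APPLICABLE = "not_applicable"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class QuerySpecimen:
    """An unknown specimen with one sequence per attempted marker."""

    specimen_id: str
    sequences: dict[str, str]  # marker_id -> sequence
    date: str = ""
    fishery: str = ""
    visual_taxon: str = ""
    visual_rank: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError(
                f"{self.specimen_id}: at least one marker sequence is required"
            )


@dataclass
class MarkerAssignment:
    """Evidence from one marker for one specimen."""

    marker_id: str
    rank: Rank
    candidates: list[tuple[str, float]] = field(default_factory=list)  # (species, nearest d)
    caveats: set[str] = field(default_factory=set)
    taxon: str = ""  # genus or family name for coarse ranks
    aligned_row: str | None = None

    def __post_init__(self) -> None:
        if self.rank is Rank.SPECIES and len(self.candidates) != 1:
            raise ValidationError("species rank requires exactly one candidate")
        if self.rank is Rank.NONE and self.candidates:
            raise ValidationError("rank none requires an empty candidate list")

    @property
    def candidate_species(self) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.candidates)


@dataclass
class CombinedAssignment:
    """Final decision-tree output for one specimen."""

    specimen_id: str
    final_taxon: str
    final_rank: Rank
    evidence: list[MarkerAssignment]
    snp_call: SnpCall = SnpCall.NOT_APPLICABLE

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "final_taxon": self.final_taxon,
            "final_rank": self.final_rank.value,
            "snp_call": self.snp_call.value,
            "evidence": [
                {
                    "marker_id": ev.marker_id,
                    "rank": ev.rank.value,
                    "candidates": [
                        {"species": sp, "nearest_distance": d} for sp, d in ev.candidates
                    ],
                    "caveats": sorted(ev.caveats),
                    "taxon": ev.taxon,
                }
                for ev in self.evidence
            ],
        }


@dataclass
class MarkerPanel:
    """Everything needed to query one marker: definition, curated
    database and its reference alignment."""

    marker: MarkerDef
    db: ReferenceDatabase
    alignment: MarkerAlignment


# ---------------------------------------------------------------------------
# Per-marker assignment
# ---------------------------------------------------------------------------

def assign_marker(
    query: str,
    panel: MarkerPanel,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    family_multiplier: float = 2.0,
) -> MarkerAssignment:
    """Identify one sequence against one marker panel.

    Neighbours within the species threshold: a single species gives rank
    ``species``; several species of one genus give a ``sister_set``.
    With no species-threshold neighbour, the genus threshold is tried for
    a ``genus`` call; failing that, a nearest reference within
    ``family_multiplier`` x genus threshold supports a ``family`` bin
    (bycatch reporting uses family-level tallies), else rank ``none``.
    Control-region calls in genera with uncertain CR copy amplification
    carry the ``cr_copy_uncertain`` caveat.
    """
    marker = panel.marker
    labels = panel.db.labels()
    try:
        row = align_query(
            query, panel.alignment, min_overlap=min_overlap, identity_floor=identity_floor
        )
    except UnalignableQueryError as exc:
        logger.info("%s: %s", marker.marker_id, exc)
        return MarkerAssignment(
            marker_id=marker.marker_id, rank=Rank.NONE, caveats={"unalignable"}
        )

    # nearest distance per species
    nearest: dict[str, float] = {}
    nearest_any: tuple[float, str] | None = None
    for acc in panel.alignment.ids:
        d, _ = p_distance(row, panel.alignment.rows[acc], min_overlap=min_overlap)
        if np.isnan(d):
            continue
        sp = labels[acc].species
        if sp not in nearest or d < nearest[sp]:
            nearest[sp] = d
        if nearest_any is None or d < nearest_any[0]:
            nearest_any = (d, acc)

    def _caveats(species_set: frozenset[str]) -> set[str]:
        out: set[str] = set()
        if marker.caution_genera:
            genera = {sp.split()[0] for sp in species_set}
            if genera & marker.caution_genera:
                out.add(CR_COPY_CAVEAT)
        return out

    hits = sorted(
        ((sp, d) for sp, d in nearest.items() if d <= marker.species_threshold),
        key=lambda x: (x[1], x[0]),
    )
    if hits:
        species_set = frozenset(sp for sp, _ in hits)
        genera = {sp.split()[0] for sp in species_set}
        if len(hits) == 1:
            return MarkerAssignment(
                marker_id=marker.marker_id,
                rank=Rank.SPECIES,
                candidates=hits,
                caveats=_caveats(species_set),
                taxon=hits[0][0],
                aligned_row=row,
            )
        if len(genera) == 1:
            return MarkerAssignment(
                marker_id=marker.marker_id,
                rank=Rank.SISTER_SET,
                candidates=hits,
                caveats=_caveats(species_set),
                taxon=next(iter(genera)),
                aligned_row=row,
            )
        # species-threshold neighbours spanning several genera: fall through
        # to the coarser genus logic below

    genus_hits = sorted(
        ((sp, d) for sp, d in nearest.items() if d <= marker.genus_threshold),
        key=lambda x: (x[1], x[0]),
    )
    genera = {sp.split()[0] for sp, _ in genus_hits}
    if len(genera) == 1:
        return MarkerAssignment(
            marker_id=marker.marker_id,
            rank=Rank.GENUS,
            candidates=genus_hits,
            caveats=_caveats(frozenset(sp for sp, _ in genus_hits)),
            taxon=next(iter(genera)),
            aligned_row=row,
        )
    if nearest_any is not None and nearest_any[0] <= family_multiplier * marker.genus_threshold:
        family = labels[nearest_any[1]].family
        cands = genus_hits or [
            (labels[nearest_any[1]].species, nearest_any[0])
        ]
        return MarkerAssignment(
            marker_id=marker.marker_id,
            rank=Rank.FAMILY,
            candidates=cands,
            taxon=family,
            aligned_row=row,
        )
    return MarkerAssignment(
        marker_id=marker.marker_id, rank=Rank.NONE, aligned_row=row
    )


# ---------------------------------------------------------------------------
# Diagnostic SNP for the shy / white-capped albatross pair
# ---------------------------------------------------------------------------

def cauta_steadi_snp(
    query_row: str,
    alignment: MarkerAlignment,
    labels: dict[str, str],
) -> SnpCall:
    """Call cauta vs steadi from fixed-difference alignment columns.

    Diagnostic columns are those where every cauta reference carries one
    unambiguous base and every steadi reference a different one; the
    query is called by majority vote over them. A query with gaps or
    ambiguities at all diagnostic columns — or an alignment with no
    fixed difference — is ``indeterminate``.
    """
    cauta_rows = [alignment.rows[a] for a, sp in labels.items() if sp == CAUTA]
    steadi_rows = [alignment.rows[a] for a, sp in labels.items() if sp == STEADI]
    if not cauta_rows or not steadi_rows:
        logger.warning("SNP rule needs references for both cauta and steadi")
        return SnpCall.INDETERMINATE

    bases = set("ACGT")
    diagnostic: list[tuple[int, str, str]] = []
    for col in range(alignment.n_columns):
        ca = {r[col] for r in cauta_rows}
        st = {r[col] for r in steadi_rows}
        if len(ca) == 1 and len(st) == 1:
            (a,), (b,) = ca, st
            if a in bases and b in bases and a != b:
                diagnostic.append((col, a, b))
    if not diagnostic:
        logger.warning("no fixed-difference column between cauta and steadi references")
        return SnpCall.INDETERMINATE

    votes = {"cauta": 0, "steadi": 0}
    for col, a, b in diagnostic:
        q = query_row[col]
        if q == a:
            votes["cauta"] += 1
        elif q == b:
            votes["steadi"] += 1
    if votes["cauta"] == votes["steadi"]:
        return SnpCall.INDETERMINATE
    return SnpCall.CAUTA if votes["cauta"] > votes["steadi"] else SnpCall.STEADI


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------

def decision_tree(
    specimen: QuerySpecimen,
    panels: dict[str, MarkerPanel],
    order: list[str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    family_multiplier: float = 2.0,
) -> CombinedAssignment:
    """Ordered multi-marker identification of one specimen.

    Markers are consulted in ``order`` (default Cytb then CR); once a
    marker reaches rank species the remaining markers are not needed.
    A control-region sister set of exactly {cauta, steadi} triggers the
    diagnostic SNP rule, which can upgrade the call to species level
    (with the SNP error caveat). The final rank is never coarser than the
    best single-marker rank among the evidence.
    """
    order = order or ["Cytb_AP", "CRBird_AP"]
    evidence: list[MarkerAssignment] = []
    snp_call = SnpCall.NOT_APPLICABLE

    for marker_id in order:
        if marker_id not in specimen.sequences or marker_id not in panels:
            continue
        panel = panels[marker_id]
        assignment = assign_marker(
            specimen.sequences[marker_id],
            panel,
            min_overlap=min_overlap,
            identity_floor=identity_floor,
            family_multiplier=family_multiplier,
        )
        if (
            marker_id == "CRBird_AP"
            and assignment.rank is Rank.SISTER_SET
            and assignment.candidate_species == frozenset({CAUTA, STEADI})
            and assignment.aligned_row is not None
        ):
            species_labels = {a: t.species for a, t in panel.db.labels().items()}
            snp_call = cauta_steadi_snp(
                assignment.aligned_row, panel.alignment, species_labels
            )
            if snp_call in (SnpCall.CAUTA, SnpCall.STEADI):
                winner = CAUTA if snp_call is SnpCall.CAUTA else STEADI
                dist = dict(assignment.candidates)[winner]
                assignment = MarkerAssignment(
                    marker_id=marker_id,
                    rank=Rank.SPECIES,
                    candidates=[(winner, dist)],
                    caveats=assignment.caveats | {SNP_ERROR_CAVEAT},
                    taxon=winner,
                    aligned_row=assignment.aligned_row,
                )
        evidence.append(assignment)
        if assignment.rank is Rank.SPECIES:
            break

    if not evidence:
        return CombinedAssignment(
            specimen_id=specimen.specimen_id,
            final_taxon="",
            final_rank=Rank.NONE,
            evidence=[],
        )
    best = min(evidence, key=lambda ev: RANK_ORDER[ev.rank])
    if best.rank is Rank.SPECIES:
        taxon = best.candidates[0][0]
    elif best.rank is Rank.SISTER_SET:
        taxon = " / ".join(sorted(best.candidate_species))
    elif best.rank is Rank.GENUS:
        taxon = f"{best.taxon} sp."
    elif best.rank is Rank.FAMILY:
        taxon = best.taxon
    else:
        taxon = ""
    return CombinedAssignment(
        specimen_id=specimen.specimen_id,
        final_taxon=taxon,
        final_rank=best.rank,
        evidence=evidence,
        snp_call=snp_call,
    )


# ---------------------------------------------------------------------------
# I/O: query FASTA and e-log TSV
# ---------------------------------------------------------------------------

def read_query_fasta(path: str | Path) -> list[QuerySpecimen]:
    """Read unknown specimens from FASTA with ``>specimen_id|marker`` headers."""
    per_specimen: dict[str, dict[str, str]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for sr in SeqIO.parse(fh, "fasta"):
            parts = sr.description.split("|")
            if len(parts) != 2:
                raise ValidationError(
                    f"malformed query header {sr.description!r}: expected specimen_id|marker"
                )
            sid, marker = parts[0].strip(), parts[1].strip()
            if sid not in per_specimen:
                per_specimen[sid] = {}
                order.append(sid)
            if marker in per_specimen[sid]:
                raise ValidationError(f"duplicate marker {marker} for specimen {sid}")
            per_specimen[sid][marker] = str(sr.seq).upper()
    if not per_specimen:
        raise ValidationError("empty query FASTA")
    return [QuerySpecimen(specimen_id=sid, sequences=per_specimen[sid]) for sid in order]


def read_elog(path: str | Path) -> pd.DataFrame:
    """Read e-logbook records (specimen_id, date, fishery, visual_taxon,
    visual_rank); duplicate specimen ids are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"specimen_id", "visual_taxon", "visual_rank"}
    if not required.issubset(df.columns):
        raise ValidationError(f"e-log must have columns {sorted(required)}")
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate e-log specimen ids: {dupes}")
    return df


# ---------------------------------------------------------------------------
# Genetic vs visual comparison
# ---------------------------------------------------------------------------

_RANK_LEVEL = {"species": 3, "sister_set": 2, "genus": 2, "family": 1, "none": 0}


def _lift(taxon: str, rank: str, level: int, taxonomy: TaxonomyTable) -> str | None:
    """Name of ``taxon`` at coarser ``level`` (3=species, 2=genus, 1=family),
    or None when the rank is too coarse to know."""
    if _RANK_LEVEL.get(rank, 0) < level:
        return None
    if rank == "species":
        label = taxonomy.label_for(taxon)
        return {3: label.species, 2: label.genus, 1: label.family}[level]
    if rank in ("genus", "sister_set"):
        genus = taxon.split()[0]
        if level == 2:
            return genus
        return taxonomy.family_of_genus.get(genus, "other")
    if rank == "family":
        return taxon if level == 1 else None
    return None


def compare_to_visual(
    combined: list[CombinedAssignment],
    elog: pd.DataFrame,
    taxonomy: TaxonomyTable,
) -> pd.DataFrame:
    """Per-specimen genetic-vs-visual agreement at family/genus/species rank.

    Agreement is Y/N where both identifications reach the rank, ``n/a``
    where either is coarser (or the specimen has no e-log record).
    """
    elog_by_id = {row["specimen_id"]: row for _, row in elog.iterrows()}
    rows = []
    for ca in combined:
        rec = elog_by_id.get(ca.specimen_id)
        entry = {
            "specimen_id": ca.specimen_id,
            "visual_taxon": rec["visual_taxon"] if rec is not None else "no AFMA record",
            "visual_rank": rec["visual_rank"] if rec is not None else "",
            "genetic_taxon": ca.final_taxon,
            "genetic_rank": ca.final_rank.value,
        }
        genetic_taxon = ca.final_taxon
        if ca.final_rank is Rank.GENUS:
            genetic_taxon = ca.final_taxon.replace(" sp.", "")
        for level, name in ((1, "family"), (2, "genus"), (3, "species")):
            if rec is None:
                entry[f"agreement_{name}"] = "n/a"
                continue
            vis = _lift(rec["visual_taxon"].replace(" spp.", "").replace(" sp.", ""),
                        rec["visual_rank"], level, taxonomy)
            gen = _lift(genetic_taxon, ca.final_rank.value, level, taxonomy)
            if vis is None or gen is None:
                entry[f"agreement_{name}"] = "n/a"
            else:
                entry[f"agreement_{name}"] = "Y" if vis == gen else "N"
        rows.append(entry)
    return pd.DataFrame(rows)


def agreement_summary(table: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Counts of Y/N/n-a per rank from a comparison table."""
    out: dict[str, dict[str, int]] = {}
    for name in ("family", "genus", "species"):
        col = table[f"agreement_{name}"]
        out[name] = {
            "Y": int((col == "Y").sum()),
            "N": int((col == "N").sum()),
            "n/a": int((col == "n/a").sum()),
        }
    return out
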