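"""Distance-threshold identification outcomes and species resolution.

Each reference sequence is classified by the species labels of its
neighbours — the sequences within the species threshold (1.5% by
default, i.e. sharing >= 98.5% identity; ties at exactly the threshold
are neighbours). Species are then scored by the connected components of
an ambiguity graph whose edges join species that fall within the
threshold of each other: an isolated species is resolvable, a
two-species component is a sister pair, a larger component is an
unresolvable cluster. Missing distances (insufficient overlap) are
treated as above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .markers import PROCELLARIIFORM_FAMILIES


class Outcome(str, Enum):
    CORRECT = "correct"
    AMBIGUOUS = "ambiguous"
    INCORRECT = "incorrect"
    NO_ID = "no_id"


class Category(str, Enum):
    SPECIES = "species"
    SISTER_SPECIES = "sister_species"
    MULTIPLE_SPECIES = "multiple_species"
    NO_REFERENCE = "no_reference"


#: Ranking used when combining markers (best first).
CATEGORY_RANK = {
    Category.SPECIES: 0,
    Category.SISTER_SPECIES: 1,
    Category.MULTIPLE_SPECIES: 2,
    Category.NO_REFERENCE: 3,
}


@dataclass(frozen=True)
class IdOutcome:
    """Per-sequence threshold-identification outcome."""

    accession: str
    outcome: Outcome
    neighbors: tuple[str, ...]
    nearest_distance: float  # nan when no non-missing distance exists

    def __post_init__(self) -> None:
        if (self.outcome is Outcome.NO_ID) != (len(self.neighbors) == 0):
            raise ValueError("no_id iff the neighbour set is empty")


@dataclass(frozen=True)
class SpeciesResolutionRecord:
    """Resolution category of one species under one marker (or combined)."""

    species: str
    category: Category
    partners: frozenset[str] = field(default_factory=frozenset)
    n_sequences: int = 0
    single_sequence: bool = False

    def __post_init__(self) -> None:
        if self.category is Category.SPECIES and self.partners:
            raise ValueError("a resolvable species has no partners")
        if self.category is Category.SISTER_SPECIES and len(self.partners) != 1:
            raise ValueError("a sister species has exactly one partner")
        if self.category is Category.NO_REFERENCE and self.n_sequences != 0:
            raise ValueError("no_reference implies zero sequences")


def _neighbors(
    dm: DistanceMatrix, i: int, threshold: float
) -> tuple[list[int], float]:
    row = dm.d[i].copy()
    row[i] = np.nan
    mask = ~np.isnan(row) & (row <= threshold)
    idx = np.flatnonzero(mask).tolist()
    finite = row[~np.isnan(row)]
    nearest = float(finite.min()) if finite.size else float("nan")
    return idx, nearest


def thresh_id(
    accession: str,
    dm: DistanceMatrix,
    labels: dict[str, str],
    threshold: float,
) -> IdOutcome:
    """Classify one sequence by its neighbours' species labels.

    No neighbour -> ``no_id``; all conspecific -> ``correct``; none
    conspecific -> ``incorrect``; a mixture -> ``ambiguous``.
    """
    i = dm.index(accession)
    own = labels[accession]
    idx, nearest = _neighbors(dm, i, threshold)
    neigh = tuple(dm.ids[j] for j in idx)
    if not neigh:
        outcome = Outcome.NO_ID
    else:
        spp = {labels[a] for a in neigh}
        if spp == {own}:
            outcome = Outcome.CORRECT
        elif own in spp:
            outcome = Outcome.AMBIGUOUS
        else:
            outcome = Outcome.INCORRECT
    return IdOutcome(
        accession=accession, outcome=outcome, neighbors=neigh, nearest_distance=nearest
    )


def all_outcomes(
    dm: DistanceMatrix, labels: dict[str, str], threshold: float
) -> list[IdOutcome]:
    return [thresh_id(acc, dm, labels, threshold) for acc in dm.ids]


def species_resolution(
    dm: DistanceMatrix,
    labels: dict[str, str],
    threshold: float,
    species_universe: set[str] | None = None,
) -> list[SpeciesResolutionRecord]:
    """Score every species by the ambiguity-graph component it sits in.

    Edge (A, B) exists when any sequence of A has a neighbour belonging
    to B. An isolated species (all its sequences' outcomes are correct,
    or no_id for singleton haplotypes whose intraspecific variation
    cannot be evaluated) is category ``species``; components of two are
    ``sister_species``; larger components are ``multiple_species``.
    Species in ``species_universe`` absent from the data are
    ``no_reference``.
    """
    present = sorted(set(labels[a] for a in dm.ids))
    universe = set(species_universe) if species_universe is not None else set(present)
    if not universe.issuperset(present):
        raise ValueError("species_universe must cover all species present in labels")

    graph = nx.Graph()
    graph.add_nodes_from(present)
    for i, acc in enumerate(dm.ids):
        own = labels[acc]
        idx, _ = _neighbors(dm, i, threshold)
        for j in idx:
            other = labels[dm.ids[j]]
            if other != own:
                graph.add_edge(own, other)

    counts: dict[str, int] = {}
    for acc in dm.ids:
        counts[labels[acc]] = counts.get(labels[acc], 0) + 1

    records: list[SpeciesResolutionRecord] = []
    component_of = {}
    for comp in nx.connected_components(graph):
        for sp in comp:
            component_of[sp] = frozenset(comp)
    for sp in sorted(universe):
        if sp not in counts:
            records.append(
                SpeciesResolutionRecord(species=sp, category=Category.NO_REFERENCE)
            )
            continue
        comp = component_of[sp]
        if len(comp) == 1:
            cat, partners = Category.SPECIES, frozenset()
        elif len(comp) == 2:
            cat, partners = Category.SISTER_SPECIES, comp - {sp}
        else:
            cat, partners = Category.MULTIPLE_SPECIES, comp - {sp}
        records.append(
            SpeciesResolutionRecord(
                species=sp,
                category=cat,
                partners=partners,
                n_sequences=counts[sp],
                single_sequence=counts[sp] == 1,
            )
        )
    return records


def combine_marker_resolutions(
    per_marker: dict[str, list[SpeciesResolutionRecord]],
    order: list[str] | None = None,
) -> list[SpeciesResolutionRecord]:
    """Best category per species across markers.

    Ranking: species > sister_species > multiple_species > no_reference;
    partners come from the first marker (in ``order``) achieving the best
    category.
    """
    markers = order if order is not None else sorted(per_marker)
    by_species: dict[str, dict[str, SpeciesResolutionRecord]] = {}
    for marker in markers:
        for rec in per_marker[marker]:
            by_species.setdefault(rec.species, {})[marker] = rec

    combined: list[SpeciesResolutionRecord] = []
    for sp in sorted(by_species):
        recs = by_species[sp]
        best_marker = min(
            (m for m in markers if m in recs),
            key=lambda m: (CATEGORY_RANK[recs[m].category], markers.index(m)),
        )
        best = recs[best_marker]
        n_seq = max(r.n_sequences for r in recs.values())
        if best.category is Category.NO_REFERENCE:
            combined.append(SpeciesResolutionRecord(species=sp, category=Category.NO_REFERENCE))
        else:
            combined.append(
                SpeciesResolutionRecord(
                    species=sp,
                    category=best.category,
                    partners=best.partners,
                    n_sequences=n_seq,
                    single_sequence=n_seq == 1,
                )
            )
    return combined


def genus_assignment(
    accession: str,
    dm: DistanceMatrix,
    labels_genus: dict[str, str],
    genus_threshold: float,
) -> str | frozenset[str] | None:
    """Genus-level neighbour call.

    Returns the single genus of all neighbours within the genus
    threshold, a frozenset of genera when several qualify, or ``None``
    when no neighbour exists.
    """
    i = dm.index(accession)
    idx, _ = _neighbors(dm, i, genus_threshold)
    genera = frozenset(labels_genus[dm.ids[j]] for j in idx)
    if not genera:
        return None
    if len(genera) == 1:
        return next(iter(genera))
    return genera


@dataclass
class ResolutionSummary:
    """Per-family and total counts of resolvable species (Table-2 shape)."""

    scope: str  # "listed" or "all"
    table: pd.DataFrame  # rows: families + Total

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def family_summary(
    records: list[SpeciesResolutionRecord],
    families: dict[str, str],
    scope: str = "all",
    species_universe: set[str] | None = None,
) -> ResolutionSummary:
    """Summarize resolution categories by family.

    ``with_reference`` counts species with data; ``species_id`` and
    ``sister_id`` count the resolvable and sister-pair species. Rates are
    reported both over species with a reference (per-marker utility) and
    over the full universe.
    """
    universe = (
        set(species_universe)
        if species_universe is not None
        else {r.species for r in records}
    )
    by_family: dict[str, dict[str, int]] = {}
    rec_by_species = {r.species: r for r in records}
    for sp in sorted(universe):
        fam = families.get(sp, "other")
        row = by_family.setdefault(
            fam, {"n_species": 0, "with_reference": 0, "species_id": 0, "sister_id": 0}
        )
        row["n_species"] += 1
        rec = rec_by_species.get(sp)
        if rec is None or rec.category is Category.NO_REFERENCE:
            continue
        row["with_reference"] += 1
        if rec.category is Category.SPECIES:
            row["species_id"] += 1
        elif rec.category is Category.SISTER_SPECIES:
            row["sister_id"] += 1

    fams = [f for f in PROCELLARIIFORM_FAMILIES if f in by_family] + sorted(
        f for f in by_family if f not in PROCELLARIIFORM_FAMILIES
    )
    rows = []
    for fam in fams:
        rows.append({"family": fam, **by_family[fam]})
    total = {
        "family": "Total",
        "n_species": sum(r["n_species"] for r in rows) if rows else 0,
        "with_reference": sum(r["with_reference"] for r in rows) if rows else 0,
        "species_id": sum(r["species_id"] for r in rows) if rows else 0,
        "sister_id": sum(r["sister_id"] for r in rows) if rows else 0,
    }
    rows.append(total)
    df = pd.DataFrame(rows, columns=["family", "n_species", "with_reference", "species_id", "sister_id"])
    with np.errstate(invalid="ignore", divide="ignore"):
        df["species_id_rate_of_ref"] = np.where(
            df["with_reference"] > 0, df["species_id"] / df["with_reference"], np.nan
        )
        df["species_id_rate_of_universe"] = np.where(
            df["n_species"] > 0, df["species_id"] / df["n_species"], np.nan
        )
    for _, row in df.iterrows():
        assert row["species_id"] + row["sister_id"] <= row["with_reference"]
    return ResolutionSummary(scope=scope, table=df)


def outcomes_to_tsv(
    outcomes: list[IdOutcome], labels: dict[str, str], path: str | Path
) -> None:
    rows = [
        {
            "accession": o.accession,
            "species": labels[o.accession],
            "outcome": o.outcome.value,
            "nearest_distance": o.nearest_distance,
            "neighbor_species": ";".join(sorted({labels[a] for a in o.neighbors})),
        }
        for o in outcomes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def resolutions_to_tsv(
    records: list[SpeciesResolutionRecord], marker: str, path: str | Path
) -> None:
    rows = [
        {
            "species": r.species,
            "marker": marker,
            "category": r.category.value,
            "partners": ";".join(sorted(r.partners)),
            "n_sequences": r.n_sequences,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
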