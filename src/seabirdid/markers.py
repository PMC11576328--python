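"""Marker and primer definitions for seabird bycatch barcoding.

Three short mitochondrial amplicons are used to identify albatrosses,
petrels and shearwaters (order Procellariiformes) from degraded samples
such as feathers: a 367 bp COI fragment, a 305 bp cytochrome-b fragment
and a 379 bp fragment of control-region copy 2, domain 1. Short fragments
(< 400 bp) amplify reliably from degraded DNA; the thresholds attached to
each marker drive the distance-based identification rules downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources

from .iupac import PRIMER_ALPHABET

#: The four procellariiform families covered by the reference databases.
PROCELLARIIFORM_FAMILIES = ("Diomedeidae", "Procellariidae", "Hydrobatidae", "Oceanitidae")

MARKER_IDS = ("COI_AP", "Cytb_AP", "CRBird_AP")

#: Short CLI aliases for the three markers.
MARKER_ALIASES = {"coi": "COI_AP", "cytb": "Cytb_AP", "cr": "CRBird_AP"}


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate PCR primer pair.

    Both primers are written 5'->3'; the reverse primer anneals to the
    opposite strand, so on the plus strand its binding site reads as the
    primer's reverse complement. ``expected_insert_length`` is the length
    of the amplified insert between the two binding sites, in bp.
    ``annealing_temp`` (degrees C) is metadata only.
    """

    name: str
    forward: str
    reverse: str
    expected_insert_length: int
    annealing_temp: float | None = None

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primer sequences must be non-empty")
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            bad = set(seq.upper()) - PRIMER_ALPHABET
            if bad:
                raise ValueError(f"{label} primer contains non-IUPAC characters {sorted(bad)}")
        if self.expected_insert_length <= 0:
            raise ValueError("expected_insert_length must be positive")


@dataclass(frozen=True)
class MarkerDef:
    """A marker with its primers and identification thresholds.

    ``species_threshold`` and ``genus_threshold`` are uncorrected-distance
    fractions: a neighbour within ``species_threshold`` supports a
    species-level call, within ``genus_threshold`` a genus-level call.
    ``caution_genera`` flags genera in which the control region is
    duplicated and the amplified copy is uncertain, so CR-based calls
    carry a caveat.
    """

    marker_id: str
    primers: PrimerPair
    species_threshold: float = 0.015
    genus_threshold: float = 0.04
    caution_genera: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.marker_id not in MARKER_IDS:
            raise ValueError(f"unknown marker_id {self.marker_id!r}")
        if not (0.0 < self.species_threshold < self.genus_threshold < 1.0):
            raise ValueError("require 0 < species_threshold < genus_threshold < 1")


def default_markers() -> dict[str, MarkerDef]:
    """The three production marker definitions.

    Species threshold is 1.5% for every marker (neighbours share >= 98.5%
    identity); genus threshold is 4% for the coding markers and 7% for the
    faster-evolving control region.
    """
    return {
        "COI_AP": MarkerDef(
            marker_id="COI_AP",
            primers=PrimerPair(
                name="BirdCOIF/jgHCO2198R",
                forward="GGNACMGGRTGRACHGTNTAYCCNCC",
                reverse="TAIACYTCIGGRTGICCRAARAAYCA",
                expected_insert_length=367,
                annealing_temp=45.0,
            ),
        ),
        "Cytb_AP": MarkerDef(
            marker_id="Cytb_AP",
            primers=PrimerPair(
                name="Cytb2-F/Cytb2-R",
                forward="TAYATYGGCCARACCYTYGTAG",
                reverse="GTTYTCTGGRTCDCCKARYA",
                expected_insert_length=305,
                annealing_temp=53.0,
            ),
        ),
        "CRBird_AP": MarkerDef(
            marker_id="CRBird_AP",
            primers=PrimerPair(
                name="CRBird_F/CRBird_R",
                forward="CAGCCTATGTGTTGATGTGCA",
                reverse="CGGGTTGCTGATTTCTCGTG",
                expected_insert_length=379,
                annealing_temp=50.0,
            ),
            genus_threshold=0.07,
            caution_genera=frozenset({"Phoebastria", "Procellaria"}),
        ),
    }


@dataclass(frozen=True)
class TaxonLabel:
    """Taxonomic identity of a reference sequence.

    ``listed`` marks membership of the 36 ACAP/TAP species of management
    concern; it is a label only and never changes how distances or
    assignments are computed.
    """

    species: str
    genus: str = ""
    family: str = "other"
    listed: bool = False

    def __post_init__(self) -> None:
        if not self.species.strip():
            raise ValueError("species must be non-empty")
        genus = self.genus or self.species.split()[0]
        object.__setattr__(self, "genus", genus)
        if genus != self.species.split()[0]:
            raise ValueError(
                f"genus {genus!r} does not match binomial {self.species!r}"
            )
        if self.listed and self.family not in PROCELLARIIFORM_FAMILIES:
            raise ValueError(
                f"listed species {self.species!r} must belong to a procellariiform family"
            )


@dataclass(frozen=True)
class TaxonomyTable:
    """Side-table mapping species -> genus -> family plus the listed flag."""

    by_species: dict[str, TaxonLabel]
    family_of_genus: dict[str, str]

    def lookup(self, species: str) -> TaxonLabel | None:
        return self.by_species.get(species)

    def label_for(self, species: str) -> TaxonLabel:
        """Best-effort label: table entry, else genus-to-family fallback."""
        hit = self.by_species.get(species)
        if hit is not None:
            return hit
        genus = species.split()[0]
        family = self.family_of_genus.get(genus, "other")
        return TaxonLabel(species=species, genus=genus, family=family, listed=False)

    @property
    def listed_species(self) -> frozenset[str]:
        return frozenset(s for s, t in self.by_species.items() if t.listed)


def load_taxonomy(path=None) -> TaxonomyTable:
    """Load a taxonomy side-table (TSV: species, genus, family, listed).

    Without ``path``, loads the packaged table covering the 36 ACAP/TAP
    listed species and the non-listed taxa that appear in the case study.
    """
    if path is None:
        ref = resources.files("seabirdid.data").joinpath("listed_species.tsv")
        with ref.open("r", encoding="utf-8") as fh:
            return _parse_taxonomy(fh)
    with open(path, encoding="utf-8") as fh:
        return _parse_taxonomy(fh)


def _parse_taxonomy(fh) -> TaxonomyTable:
    reader = csv.DictReader(fh, delimiter="\t")
    required = {"species", "genus", "family", "listed"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(f"taxonomy table must have columns {sorted(required)}")
    by_species: dict[str, TaxonLabel] = {}
    family_of_genus: dict[str, str] = {}
    for row in reader:
        label = TaxonLabel(
            species=row["species"].strip(),
            genus=row["genus"].strip(),
            family=row["family"].strip(),
            listed=row["listed"].strip() in ("1", "true", "True", "yes"),
        )
        if label.species in by_species:
            raise ValueError(f"duplicate species {label.species!r} in taxonomy table")
        by_species[label.species] = label
        family_of_genus.setdefault(label.genus, label.family)
    return TaxonomyTable(by_species=by_species, family_of_genus=family_of_genus)


def with_thresholds(marker: MarkerDef, species: float | None = None,
                    genus: float | None = None) -> MarkerDef:
    """Return a copy of ``marker`` with overridden thresholds."""
    kwargs = {}
    if species is not None:
        kwargs["species_threshold"] = species
    if genus is not None:
        kwargs["genus_threshold"] = genus
    return replace(marker, **kwargs)
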