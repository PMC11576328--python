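"""Shared fixtures: toy FASTA builders and small synthetic worlds."""

from __future__ import annotations

import numpy as np
import pytest

from seabirdid import (
    SimSpec,
    build_marker_alignment,
    default_markers,
    simulate_reference_db,
)
from seabirdid.assign import MarkerPanel

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_seq(rng: np.random.Generator, seq: str, n_sites: int) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sites, replace=False):
        out[pos] = rng.choice([b for b in BASES if b != out[pos]])
    return "".join(out)


def canonical_fasta(records: list[tuple[str, str, str, str, str]]) -> str:
    """records: (accession, family, genus, species, sequence)."""
    out = []
    for acc, fam, gen, sp, seq in records:
        out.append(f">{acc}|{fam}|{gen}|{sp.replace(' ', '_')}")
        out.append(seq)
    return "\n".join(out) + "\n"


@pytest.fixture(scope="session")
def toy_fasta() -> str:
    """Three records, two species, sequences 120 nt."""
    rng = np.random.default_rng(11)
    s1 = random_seq(rng, 120)
    s2 = mutate_seq(rng, s1, 1)  # conspecific haplotype
    s3 = mutate_seq(rng, s1, 30)  # congener
    return canonical_fasta(
        [
            ("ACC001", "Diomedeidae", "Thalassarche", "Thalassarche cauta", s1),
            ("ACC002", "Diomedeidae", "Thalassarche", "Thalassarche cauta", s2),
            ("ACC003", "Diomedeidae", "Thalassarche", "Thalassarche bulleri", s3),
        ]
    )


@pytest.fixture(scope="session")
def resolvable_world():
    """Synthetic world with a clean barcode gap: every species resolvable."""
    spec = SimSpec(
        n_families=2,
        n_genera_per_family=2,
        n_species_per_genus=3,
        n_haplotypes_per_species=2,
        seq_length=350,
        intraspecific_divergence=0.005,
        interspecific_divergence=0.05,
        seed=42,
    )
    dbs, truth = simulate_reference_db(spec)
    return spec, dbs, truth


@pytest.fixture(scope="session")
def sister_world():
    """Synthetic world containing one sub-threshold sister pair."""
    spec = SimSpec(
        n_families=2,
        n_genera_per_family=1,
        n_species_per_genus=3,
        n_haplotypes_per_species=2,
        seq_length=350,
        intraspecific_divergence=0.005,
        interspecific_divergence=0.05,
        sister_pairs=(("GenusA1 species1", "GenusA1 species2"),),
        seed=43,
    )
    dbs, truth = simulate_reference_db(spec)
    return spec, dbs, truth


@pytest.fixture(scope="session")
def resolvable_panels(resolvable_world):
    _, dbs, _ = resolvable_world
    markers = default_markers()
    return {
        m: MarkerPanel(marker=markers[m], db=db, alignment=build_marker_alignment(db))
        for m, db in dbs.items()
    }


@pytest.fixture(scope="session")
def sister_panels(sister_world):
    _, dbs, _ = sister_world
    markers = default_markers()
    return {
        m: MarkerPanel(marker=markers[m], db=db, alignment=build_marker_alignment(db))
        for m, db in dbs.items()
    }
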