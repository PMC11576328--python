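"""Synthetic reference databases and degraded query sets.

The generator emulates the statistical structure the identification
method assumes: multiple species per genus across several families, a few
haplotypes per species with low intraspecific divergence, clearly larger
interspecific divergence (a "barcode gap"), optional sub-threshold sister
pairs, marker-length fragments, and feather-style degradation
(truncation plus ambiguity codes). Substitutions are uniform over sites
and bases (Jukes-Cantor-like): only the distance structure matters for
evaluating the classifier, not a realistic substitution process.
Divergence targets are enforced by rejection-resampling, so realized
p-distances land within +/-20% of the targets. Everything is reproducible
from a single integer seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import TaxonLabel
from .refdb import ReferenceDatabase, ReferenceSequence, collapse_haplotypes
from .threshid import Category

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_MARKERS = ("Cytb_AP", "CRBird_AP")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic world.

    ``intraspecific_divergence`` is the target maximum p-distance among a
    species' haplotypes; ``interspecific_divergence`` the target minimum
    p-distance between (non-sister) congeneric species. ``sister_pairs``
    lists species-name pairs whose divergence is drawn uniformly below
    ``sister_divergence_max`` (the species threshold), making them
    unresolvable by design.
    """

    n_families: int = 4
    n_genera_per_family: int = 2
    n_species_per_genus: int = 3
    n_haplotypes_per_species: int = 2
    seq_length: int = 350
    intraspecific_divergence: float = 0.005
    interspecific_divergence: float = 0.05
    sister_pairs: tuple[tuple[str, str], ...] = ()
    sister_divergence_max: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100")
        if not (0 <= self.intraspecific_divergence < self.interspecific_divergence):
            raise ValueError("require intraspecific < interspecific divergence")
        if self.interspecific_divergence > 0.75:
            raise ValueError("interspecific divergence above random-sequence saturation")
        names = set(self.species_names())
        for a, b in self.sister_pairs:
            if a.split()[0] != b.split()[0]:
                raise ValueError(f"sister pair {(a, b)} must be congeneric")
            if a not in names or b not in names:
                raise ValueError(f"sister pair {(a, b)} not in generated species")

    # -- deterministic naming ---------------------------------------------
    def family_names(self) -> list[str]:
        return [f"Family{string.ascii_uppercase[i]}" for i in range(self.n_families)]

    def genus_names(self, family_idx: int) -> list[str]:
        fam = string.ascii_uppercase[family_idx]
        return [f"Genus{fam}{g + 1}" for g in range(self.n_genera_per_family)]

    def species_names(self) -> list[str]:
        out = []
        for f in range(self.n_families):
            for genus in self.genus_names(f):
                for s in range(self.n_species_per_genus):
                    out.append(f"{genus} species{s + 1}")
        return out


@dataclass
class TruthSet:
    """Answer key for a synthetic world and its query sets."""

    species_of_specimen: dict[str, str] = field(default_factory=dict)
    expected_category: dict[str, Category] = field(default_factory=dict)

    def expected_rank(self, species: str) -> str:
        cat = self.expected_category[species]
        return {"species": "species", "sister_species": "sister_set"}.get(
            cat.value, "none"
        )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _substitute(rng: np.random.Generator, seq: np.ndarray, sites) -> np.ndarray:
    out = seq.copy()
    for pos in sites:
        current = out[pos]
        choices = _BASES[_BASES != current]
        out[pos] = rng.choice(choices)
    return out


def _mutate(rng: np.random.Generator, seq: np.ndarray, n_sites: int) -> np.ndarray:
    """Substitute ``n_sites`` distinct random positions with a different base."""
    return _substitute(rng, seq, rng.choice(len(seq), size=n_sites, replace=False))


def _mutate_stratified(rng: np.random.Generator, seq: np.ndarray, n_sites: int) -> np.ndarray:
    """Substitute one site per equal-width stratum.

    Spreading interspecific substitutions evenly along the fragment means
    every marker-length window of a truncated read retains close to the
    full-length divergence, so windowed distance estimates do not dip
    below the species threshold by sampling accident.
    """
    L = len(seq)
    edges = np.linspace(0, L, n_sites + 1)
    sites = [int(rng.integers(int(edges[i]), max(int(edges[i]) + 1, int(edges[i + 1]))))
             for i in range(n_sites)]
    return _substitute(rng, seq, sites)


#: Minimum spacing between sister-pair diagnostic sites. Any window with
#: >= 100 comparable sites (the overlap floor) then sees at most one
#: diagnostic difference per ~150 bp, keeping the windowed distance of a
#: sister pair safely below the species threshold.
_SISTER_SITE_SPACING = 150


def _spaced_sites(rng: np.random.Generator, length: int, k: int, gap: int) -> list[int]:
    """k sorted positions in [0, length) with pairwise spacing >= gap."""
    slack = length - (k - 1) * (gap - 1)
    if slack < k:
        raise ValueError("cannot place sites with the requested spacing")
    ys = np.sort(rng.choice(slack, size=k, replace=False))
    return [int(y) + i * (gap - 1) for i, y in enumerate(ys)]


def _pdist(a: np.ndarray, b: np.ndarray) -> float:
    return float((a != b).sum() / len(a))


def _generate_genus(
    rng: np.random.Generator,
    spec: SimSpec,
    species: list[str],
    sister_of: dict[str, str],
    max_tries: int = 500,
) -> dict[str, list[np.ndarray]]:
    """Haplotypes for one genus, rejection-resampled to hit the targets."""
    L = spec.seq_length
    intra, inter = spec.intraspecific_divergence, spec.interspecific_divergence
    k_inter = max(1, round(L * inter / 2))
    n_hap = spec.n_haplotypes_per_species
    k_intra = max(1, round(L * intra)) if n_hap == 2 else max(1, round(L * intra / 2))
    # sister-site count: the uniform divergence draw, capped so sites can
    # keep the minimum spacing (window-robust sub-threshold divergence)
    k_sister_cap = 1 + (L - 1) // _SISTER_SITE_SPACING

    independents = [sp for sp in species if sp not in sister_of]
    for _ in range(max_tries):
        ancestor = _random_seq(rng, L)
        base: dict[str, np.ndarray] = {}
        for sp in independents:
            base[sp] = _mutate_stratified(rng, ancestor, k_inter)

        haps: dict[str, list[np.ndarray]] = {}
        for sp in independents:
            haps[sp] = [base[sp]] + [
                _mutate(rng, base[sp], k_intra) if intra > 0 else base[sp].copy()
                for _ in range(n_hap - 1)
            ]
        for sp in species:
            if sp not in sister_of:
                continue
            # a sister species mirrors its partner's haplotype structure
            # (shared intraspecific polymorphism, as in recently diverged
            # pairs) plus a few widely spaced diagnostic substitutions
            u = rng.uniform(0.0, spec.sister_divergence_max)
            k = min(k_sister_cap, max(1, round(L * u)))
            sites = _spaced_sites(rng, L, k, _SISTER_SITE_SPACING)
            partner = sister_of[sp]
            targets = {
                pos: rng.choice(_BASES[_BASES != base[partner][pos]]) for pos in sites
            }
            haps[sp] = []
            for hap in haps[partner]:
                mirrored = hap.copy()
                for pos, tgt in targets.items():
                    mirrored[pos] = tgt
                haps[sp].append(mirrored)

        if _genus_ok(spec, species, sister_of, haps):
            return haps
    raise ValueError(
        "could not satisfy divergence targets; the SimSpec may be unsatisfiable"
    )


def _genus_ok(
    spec: SimSpec,
    species: list[str],
    sister_of: dict[str, str],
    haps: dict[str, list[np.ndarray]],
) -> bool:
    intra, inter = spec.intraspecific_divergence, spec.interspecific_divergence
    # intraspecific: realized max within +/-20% of target (when evaluable)
    for sp in species:
        hs = haps[sp]
        dists = [
            _pdist(hs[i], hs[j]) for i in range(len(hs)) for j in range(i + 1, len(hs))
        ]
        if dists and intra > 0:
            realized = max(dists)
            if not (0.8 * intra <= realized <= 1.2 * intra):
                return False
            if realized >= spec.sister_divergence_max:
                return False
    # interspecific: realized min among non-sister congeners within +/-20%
    sister_pairs = {frozenset((a, b)) for a, b in sister_of.items()}
    cross = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            dmin = min(_pdist(x, y) for x in haps[a] for y in haps[b])
            if frozenset((a, b)) in sister_pairs:
                if not (0.0 < dmin <= spec.sister_divergence_max):
                    return False
            else:
                cross.append(dmin)
    if cross:
        dmin = min(cross)
        if not (0.8 * inter <= dmin <= 1.2 * inter):
            return False
        if dmin <= spec.sister_divergence_max:
            return False
    return True


def simulate_reference_db(
    spec: SimSpec, markers: tuple[str, ...] = DEFAULT_MARKERS
) -> tuple[dict[str, ReferenceDatabase], TruthSet]:
    """Generate one reference database per marker plus the answer key.

    Each genus descends from its own random ancestral sequence; species
    are stratified mutation draws from it, haplotypes smaller random
    draws from each species, and sister-pair species mirror their
    partner's haplotypes plus a few widely spaced diagnostic sites. The
    same species structure (different sequences) is emitted for every
    marker.
    """
    sister_of: dict[str, str] = {b: a for a, b in spec.sister_pairs}
    truth = TruthSet()
    for sp in spec.species_names():
        in_pair = any(sp in pair for pair in spec.sister_pairs)
        truth.expected_category[sp] = (
            Category.SISTER_SPECIES if in_pair else Category.SPECIES
        )

    seed_seq = np.random.SeedSequence(spec.seed)
    marker_seeds = seed_seq.spawn(len(markers))
    dbs: dict[str, ReferenceDatabase] = {}
    for marker_id, child in zip(markers, marker_seeds):
        rng = np.random.default_rng(child)
        records: list[ReferenceSequence] = []
        for f in range(spec.n_families):
            family = spec.family_names()[f]
            for genus in spec.genus_names(f):
                species = [
                    f"{genus} species{s + 1}" for s in range(spec.n_species_per_genus)
                ]
                local_sisters = {
                    b: a for b, a in sister_of.items() if b in species
                }
                haps = _generate_genus(rng, spec, species, local_sisters)
                for sp in species:
                    slug = sp.replace(" ", "_")
                    for h, hap in enumerate(haps[sp]):
                        records.append(
                            ReferenceSequence(
                                accession=f"{marker_id}-{slug}-h{h + 1}",
                                taxon=TaxonLabel(
                                    species=sp, genus=genus, family=family
                                ),
                                marker_id=marker_id,
                                sequence=hap.tobytes().decode(),
                                provenance="known_provenance",
                            )
                        )
        dbs[marker_id] = collapse_haplotypes(
            ReferenceDatabase(marker_id=marker_id, records=records)
        )
    return dbs, truth


def degrade(
    sequence: str,
    min_len: int = 150,
    max_len: int = 350,
    ambiguity_rate: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> str:
    """Feather-style degradation: truncate to a random window and sprinkle Ns.

    A contiguous window with length uniform in [min_len, max_len] (capped
    at the sequence length) is kept; each retained base is replaced by N
    with probability ``ambiguity_rate``.
    """
    if min_len < 100:
        raise ValueError("min_len must be >= 100")
    if not (0 <= ambiguity_rate < 0.05):
        raise ValueError("ambiguity_rate must be in [0, 0.05)")
    if len(sequence) < min_len:
        raise ValueError(f"sequence length {len(sequence)} shorter than min_len {min_len}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hi = min(max_len, len(sequence))
    length = int(rng.integers(min_len, hi + 1))
    start = int(rng.integers(0, len(sequence) - length + 1))
    window = np.frombuffer(sequence[start : start + length].encode(), dtype="S1").copy()
    mask = rng.random(length) < ambiguity_rate
    window[mask] = b"N"
    return window.tobytes().decode()


@dataclass(frozen=True)
class DegradeParams:
    min_len: int = 150
    max_len: int = 350
    ambiguity_rate: float = 0.01


def make_query_set(
    dbs: dict[str, ReferenceDatabase],
    truth: TruthSet,
    n_queries: int,
    degrade_params: DegradeParams | None = None,
    seed: int = 0,
    species_pool: list[str] | None = None,
) -> tuple[list[dict], TruthSet]:
    """Sample degraded query specimens with a truth answer key.

    Species are sampled with replacement (optionally restricted to
    ``species_pool``); for every marker with records of the sampled
    species a random haplotype is degraded and emitted. Returns a list of
    specimen dicts ``{specimen_id, sequences: {marker: seq}}`` and the
    updated truth set.
    """
    degrade_params = degrade_params or DegradeParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    all_species = sorted(
        {r.taxon.species for db in dbs.values() for r in db.active_records}
    )
    pool = sorted(species_pool) if species_pool is not None else all_species
    queries: list[dict] = []
    for q in range(n_queries):
        sp = pool[int(rng.integers(0, len(pool)))]
        sid = f"Q{q + 1:04d}"
        sequences: dict[str, str] = {}
        for marker_id in sorted(dbs):
            recs = [r for r in dbs[marker_id].active_records if r.taxon.species == sp]
            if not recs:
                continue
            rec = recs[int(rng.integers(0, len(recs)))]
            sequences[marker_id] = degrade(
                rec.sequence,
                min_len=degrade_params.min_len,
                max_len=degrade_params.max_len,
                ambiguity_rate=degrade_params.ambiguity_rate,
                seed=rng,
            )
        queries.append({"specimen_id": sid, "sequences": sequences})
        truth.species_of_specimen[sid] = sp
    return queries, truth


def write_query_fasta(queries: list[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in queries:
            for marker_id, seq in q["sequences"].items():
                fh.write(f">{q['specimen_id']}|{marker_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def write_answer_key(truth: TruthSet, path) -> None:
    rows = [
        {
            "specimen_id": sid,
            "true_species": sp,
            "expected_rank": truth.expected_rank(sp),
        }
        for sid, sp in sorted(truth.species_of_specimen.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
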