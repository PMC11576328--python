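"""Per-marker assignment, decision tree, SNP rule and e-log comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seabirdid import (
    Category,
    QuerySpecimen,
    Rank,
    SnpCall,
    assign_marker,
    build_marker_alignment,
    cauta_steadi_snp,
    compare_to_visual,
    decision_tree,
    default_markers,
    distance_matrix,
    load_taxonomy,
    parse_reference_fasta,
    species_resolution,
)
from seabirdid.assign import MarkerPanel, agreement_summary, read_elog
from seabirdid.casestudy import load_case_study
from seabirdid.errors import ValidationError
from seabirdid.synthetic import DegradeParams, make_query_set

from conftest import canonical_fasta, mutate_seq, random_seq
from io import StringIO


def panel_from(records, marker_id="Cytb_AP"):
    markers = default_markers()
    db = parse_reference_fasta(StringIO(canonical_fasta(records)), marker_id)
    return MarkerPanel(
        marker=markers[marker_id], db=db, alignment=build_marker_alignment(db)
    )


@pytest.fixture(scope="module")
def albatross_panel():
    """Two well-separated species plus one sister pair, 350 nt."""
    rng = np.random.default_rng(50)
    base = random_seq(rng, 350)
    cauta = mutate_seq(rng, base, 30)
    steadi = mutate_seq(rng, cauta, 2)  # sub-threshold partner (d ~ 0.006)
    bulleri = mutate_seq(rng, base, 60)
    return panel_from(
        [
            ("C1", "Diomedeidae", "Thalassarche", "Thalassarche cauta", cauta),
            ("S1", "Diomedeidae", "Thalassarche", "Thalassarche steadi", steadi),
            ("B1", "Diomedeidae", "Thalassarche", "Thalassarche bulleri", bulleri),
            ("X1", "Diomedeidae", "Diomedea", "Diomedea exulans", base),
        ],
        marker_id="CRBird_AP",
    )


class TestAssignMarker:
    def test_identical_to_reference_is_species_at_zero(self, albatross_panel):
        query = albatross_panel.db.get("B1").sequence
        got = assign_marker(query, albatross_panel)
        assert got.rank is Rank.SPECIES
        assert got.candidates == [("Thalassarche bulleri", 0.0)]

    def test_subthreshold_pair_gives_sister_set(self, albatross_panel):
        query = albatross_panel.db.get("C1").sequence
        got = assign_marker(query, albatross_panel)
        assert got.rank is Rank.SISTER_SET
        assert got.candidate_species == {"Thalassarche cauta", "Thalassarche steadi"}

    def test_equidistant_synthetic_query_sister_set(self):
        rng = np.random.default_rng(51)
        base = random_seq(rng, 350)
        a = mutate_seq(rng, base, 40)
        b = mutate_seq(rng, a, 4)
        panel = panel_from(
            [
                ("A1", "Procellariidae", "Pterodroma", "Pterodroma macroptera", a),
                ("B1", "Procellariidae", "Pterodroma", "Pterodroma lessonii", b),
            ]
        )
        # query halfway between the pair: 2 of the 4 separating sites flipped
        sites = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        query = list(a)
        for pos in sites[:2]:
            query[pos] = b[pos]
        got = assign_marker("".join(query), panel)
        assert got.rank is Rank.SISTER_SET
        assert got.candidate_species == {"Pterodroma macroptera", "Pterodroma lessonii"}
        d = dict(got.candidates)
        assert d["Pterodroma macroptera"] == pytest.approx(d["Pterodroma lessonii"])

    def test_genus_fallback_between_congeners(self, albatross_panel):
        # a sequence ~2.5% from both cauta and steadi: beyond species
        # threshold, within the genus threshold, single genus
        rng = np.random.default_rng(52)
        cauta = albatross_panel.db.get("C1").sequence
        query = mutate_seq(rng, cauta, 9)
        got = assign_marker(query, albatross_panel)
        assert got.rank is Rank.GENUS
        assert got.taxon == "Thalassarche"

    def test_family_fallback_beyond_genus_threshold(self, albatross_panel):
        # ~9% from everything: beyond the 7% CR genus threshold but inside
        # the 2x family window
        rng = np.random.default_rng(53)
        cauta = albatross_panel.db.get("C1").sequence
        query = mutate_seq(rng, cauta, 32)
        got = assign_marker(query, albatross_panel)
        assert got.rank is Rank.FAMILY
        assert got.taxon == "Diomedeidae"

    def test_unalignable_query_rank_none(self, albatross_panel):
        rng = np.random.default_rng(54)
        got = assign_marker(random_seq(rng, 350), albatross_panel)
        assert got.rank is Rank.NONE
        assert "unalignable" in got.caveats

    def test_cr_caution_genus_caveat(self):
        rng = np.random.default_rng(55)
        base = random_seq(rng, 350)
        panel = panel_from(
            [
                ("P1", "Diomedeidae", "Phoebastria", "Phoebastria albatrus", base),
                ("P2", "Diomedeidae", "Phoebastria", "Phoebastria nigripes",
                 mutate_seq(rng, base, 40)),
            ],
            marker_id="CRBird_AP",
        )
        got = assign_marker(base, panel)
        assert got.rank is Rank.SPECIES
        assert "cr_copy_uncertain" in got.caveats


class TestCautaSteadiSnp:
    def test_references_requeried_call_their_own_species(self, albatross_panel):
        aln = albatross_panel.alignment
        labels = {a: t.species for a, t in albatross_panel.db.labels().items()}
        assert cauta_steadi_snp(aln.rows["C1"], aln, labels) is SnpCall.CAUTA
        assert cauta_steadi_snp(aln.rows["S1"], aln, labels) is SnpCall.STEADI

    def test_n_at_all_diagnostic_columns_indeterminate(self, albatross_panel):
        aln = albatross_panel.alignment
        labels = {a: t.species for a, t in albatross_panel.db.labels().items()}
        cauta_row = aln.rows["C1"]
        steadi_row = aln.rows["S1"]
        masked = "".join(
            "N" if (c != s and c != "-" and s != "-") else c
            for c, s in zip(cauta_row, steadi_row)
        )
        assert cauta_steadi_snp(masked, aln, labels) is SnpCall.INDETERMINATE

    def test_no_fixed_difference_indeterminate(self):
        rng = np.random.default_rng(56)
        seq = random_seq(rng, 350)
        panel = panel_from(
            [
                ("C1", "Diomedeidae", "Thalassarche", "Thalassarche cauta", seq),
                ("S1", "Diomedeidae", "Thalassarche", "Thalassarche steadi", seq),
                ("B1", "Diomedeidae", "Thalassarche", "Thalassarche bulleri",
                 mutate_seq(rng, seq, 40)),
            ],
            marker_id="CRBird_AP",
        )
        labels = {a: t.species for a, t in panel.db.labels().items()}
        got = cauta_steadi_snp(panel.alignment.rows["C1"], panel.alignment, labels)
        assert got is SnpCall.INDETERMINATE


@pytest.fixture(scope="module")
def two_marker_world():
    """Cytb cannot separate the cauta/steadi pair; CR carries one SNP."""
    rng = np.random.default_rng(57)
    cytb_base = random_seq(rng, 305)
    cytb_cauta = mutate_seq(rng, cytb_base, 20)
    cr_base = random_seq(rng, 379)
    cr_cauta = mutate_seq(rng, cr_base, 25)
    cr_steadi = mutate_seq(rng, cr_cauta, 1)  # the single diagnostic SNP
    markers = default_markers()
    cytb_db = parse_reference_fasta(
        StringIO(
            canonical_fasta(
                [
                    ("CY1", "Diomedeidae", "Thalassarche", "Thalassarche cauta", cytb_cauta),
                    ("CY2", "Diomedeidae", "Thalassarche", "Thalassarche steadi", cytb_cauta),
                    ("CY3", "Diomedeidae", "Diomedea", "Diomedea exulans", cytb_base),
                ]
            )
        ),
        "Cytb_AP",
    )
    cr_db = parse_reference_fasta(
        StringIO(
            canonical_fasta(
                [
                    ("CR1", "Diomedeidae", "Thalassarche", "Thalassarche cauta", cr_cauta),
                    ("CR2", "Diomedeidae", "Thalassarche", "Thalassarche steadi", cr_steadi),
                    ("CR3", "Diomedeidae", "Diomedea", "Diomedea exulans", cr_base),
                ]
            )
        ),
        "CRBird_AP",
    )
    return {
        "Cytb_AP": MarkerPanel(
            marker=markers["Cytb_AP"], db=cytb_db, alignment=build_marker_alignment(cytb_db)
        ),
        "CRBird_AP": MarkerPanel(
            marker=markers["CRBird_AP"], db=cr_db, alignment=build_marker_alignment(cr_db)
        ),
    }, {"cytb_cauta": cytb_cauta, "cr_cauta": cr_cauta, "cr_steadi": cr_steadi,
        "cytb_base": cytb_base, "cr_base": cr_base}


class TestDecisionTree:
    def test_cytb_species_call_stops_the_tree(self, two_marker_world):
        panels, seqs = two_marker_world
        sp = QuerySpecimen(
            specimen_id="Q1",
            sequences={"Cytb_AP": seqs["cytb_base"], "CRBird_AP": seqs["cr_base"]},
        )
        got = decision_tree(sp, panels)
        assert got.final_rank is Rank.SPECIES
        assert got.final_taxon == "Diomedea exulans"
        assert [ev.marker_id for ev in got.evidence] == ["Cytb_AP"]

    def test_snp_upgrades_cauta_steadi_sister_set(self, two_marker_world):
        panels, seqs = two_marker_world
        sp = QuerySpecimen(
            specimen_id="Q2",
            sequences={"Cytb_AP": seqs["cytb_cauta"], "CRBird_AP": seqs["cr_steadi"]},
        )
        got = decision_tree(sp, panels)
        assert got.snp_call is SnpCall.STEADI
        assert got.final_rank is Rank.SPECIES
        assert got.final_taxon == "Thalassarche steadi"
        cr_ev = got.evidence[-1]
        assert "snp_call_~3%_error" in cr_ev.caveats

    def test_unresolvable_sister_pair_stays_sister(self, sister_world, sister_panels):
        spec, dbs, _ = sister_world
        a, b = spec.sister_pairs[0]
        rec = next(r for r in dbs["Cytb_AP"].active_records if r.taxon.species == a)
        cr_rec = next(r for r in dbs["CRBird_AP"].active_records if r.taxon.species == a)
        sp = QuerySpecimen(
            specimen_id="Q3",
            sequences={"Cytb_AP": rec.sequence, "CRBird_AP": cr_rec.sequence},
        )
        got = decision_tree(sp, sister_panels)
        assert got.final_rank is Rank.SISTER_SET
        assert got.final_taxon == f"{a} / {b}"

    def test_final_rank_never_coarser_than_best_evidence(self, resolvable_world, resolvable_panels):
        _, dbs, truth = resolvable_world
        queries, truth = make_query_set(
            dbs, truth, 12, DegradeParams(ambiguity_rate=0.02), seed=5
        )
        from seabirdid.assign import RANK_ORDER

        for q in queries:
            sp = QuerySpecimen(specimen_id=q["specimen_id"], sequences=q["sequences"])
            got = decision_tree(sp, resolvable_panels)
            best = min(RANK_ORDER[ev.rank] for ev in got.evidence)
            assert RANK_ORDER[got.final_rank] == best

    def test_roundtrip_references_recover_their_species(self, resolvable_world, resolvable_panels):
        """Every reference of a `species`-category species re-queries to itself."""
        _, dbs, _ = resolvable_world
        db = dbs["Cytb_AP"]
        aln = resolvable_panels["Cytb_AP"].alignment
        dm = distance_matrix(aln)
        labels = {a: t.species for a, t in db.labels().items()}
        resolvable = {
            r.species
            for r in species_resolution(dm, labels, 0.015)
            if r.category is Category.SPECIES
        }
        for rec in db.active_records:
            if rec.taxon.species not in resolvable:
                continue
            got = assign_marker(rec.sequence, resolvable_panels["Cytb_AP"])
            assert got.rank is Rank.SPECIES
            assert got.candidates[0][0] == rec.taxon.species


class TestCompareToVisual:
    def test_genus_level_visual_vs_species_genetic(self):
        combined, elog = load_case_study()
        table = compare_to_visual(combined, elog, load_taxonomy())
        row = table[table["visual_taxon"] == "Ardenna spp."].iloc[0]
        assert row["agreement_family"] == "Y"
        assert row["agreement_genus"] == "Y"
        assert row["agreement_species"] == "n/a"

    def test_full_agreement_when_both_species_match(self):
        combined, elog = load_case_study()
        table = compare_to_visual(combined, elog, load_taxonomy())
        rows = table[
            (table["visual_taxon"] == "Ardenna carneipes")
            & (table["genetic_taxon"] == "Ardenna carneipes")
        ]
        assert (rows[["agreement_family", "agreement_genus", "agreement_species"]] == "Y").all().all()

    def test_case_study_species_agreement_count(self):
        combined, elog = load_case_study()
        table = compare_to_visual(combined, elog, load_taxonomy())
        summary = agreement_summary(table)
        assert summary["species"]["Y"] == 2
        assert summary["family"]["Y"] == 56
        assert len(table) == 59

    def test_no_elog_record_marked(self):
        combined, elog = load_case_study()
        table = compare_to_visual(combined, elog, load_taxonomy())
        missing = table[table["visual_taxon"] == "no AFMA record"]
        assert len(missing) == 3
        assert (missing["agreement_species"] == "n/a").all()

    def test_duplicate_elog_ids_rejected(self, tmp_path):
        path = tmp_path / "elog.tsv"
        pd.DataFrame(
            {
                "specimen_id": ["B1", "B1"],
                "visual_taxon": ["Ardenna carneipes"] * 2,
                "visual_rank": ["species"] * 2,
            }
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            read_elog(path)
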