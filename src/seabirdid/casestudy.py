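"""Bundled fisheries case-study identification records.

Fifty-nine bycaught seabirds from Australian longline fisheries
(2019-2022) with the fishery operators' visual e-logbook identifications
alongside the genetic identifications, grouped by interaction. The raw
feather sequences are not distributed with the package; these records
support the genetic-vs-visual agreement analysis and serve as the worked
example for the ``compare`` stage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .assign import CombinedAssignment, Rank


def load_case_study() -> tuple[list[CombinedAssignment], pd.DataFrame]:
    """Expand the grouped records into per-specimen assignments and e-log rows.

    Returns the genetic identifications as :class:`CombinedAssignment`
    objects (specimen ids ``B001``..``B059``) and the e-logbook as a
    DataFrame; specimens whose interaction had no e-log entry are absent
    from the e-log frame.
    """
    ref = resources.files("seabirdid.data").joinpath("case_study_agreement_records.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        groups = pd.read_csv(fh, sep="\t", dtype=str).fillna("")

    combined: list[CombinedAssignment] = []
    elog_rows: list[dict] = []
    counter = 0
    for _, g in groups.iterrows():
        for _ in range(int(g["n"])):
            counter += 1
            sid = f"B{counter:03d}"
            combined.append(
                CombinedAssignment(
                    specimen_id=sid,
                    final_taxon=g["genetic_taxon"],
                    final_rank=Rank(g["genetic_rank"]),
                    evidence=[],
                )
            )
            if g["visual_rank"] != "none":
                elog_rows.append(
                    {
                        "specimen_id": sid,
                        "date": g["date"],
                        "fishery": g["fishery"],
                        "visual_taxon": g["visual_taxon"],
                        "visual_rank": g["visual_rank"],
                    }
                )
    elog = pd.DataFrame(
        elog_rows, columns=["specimen_id", "date", "fishery", "visual_taxon", "visual_rank"]
    )
    return combined, elog
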