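"""Run configuration: thresholds, alignment scoring and pipeline options.

A single YAML file configures every stage; all defaults reproduce the
production settings (1.5% species threshold, 4%/7% genus thresholds,
pairwise deletion, 100-site overlap floor, Cytb-then-CR tree order).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .distance import AlignmentScoring
from .errors import ValidationError
from .markers import MarkerDef, default_markers, with_thresholds


@dataclass
class RunConfig:
    markers: dict[str, MarkerDef] = field(default_factory=default_markers)
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    min_overlap: int = 100
    deletion: str = "pairwise"
    identity_floor: float = 0.75
    family_multiplier: float = 2.0
    tree_order: list[str] = field(default_factory=lambda: ["Cytb_AP", "CRBird_AP"])
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tree_order:
            raise ValidationError("tree_order must be non-empty")
        if self.deletion not in ("pairwise", "complete"):
            raise ValidationError(f"unknown deletion mode {self.deletion!r}")
        for marker_id in self.tree_order:
            if marker_id not in self.markers:
                raise ValidationError(f"tree_order marker {marker_id!r} not configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        markers = default_markers()
        for marker_id, overrides in (raw.pop("markers", {}) or {}).items():
            if marker_id not in markers:
                raise ValidationError(f"unknown marker {marker_id!r} in config")
            markers[marker_id] = with_thresholds(
                markers[marker_id],
                species=overrides.get("species_threshold"),
                genus=overrides.get("genus_threshold"),
            )
        scoring = AlignmentScoring(**(raw.pop("scoring", {}) or {}))
        return cls(markers=markers, scoring=scoring, **raw)

    def echo(self) -> dict:
        """JSON-serializable echo of the effective configuration."""
        out = {
            "min_overlap": self.min_overlap,
            "deletion": self.deletion,
            "identity_floor": self.identity_floor,
            "family_multiplier": self.family_multiplier,
            "tree_order": list(self.tree_order),
            "seed": self.seed,
            "scoring": asdict(self.scoring),
            "markers": {
                m: {
                    "species_threshold": d.species_threshold,
                    "genus_threshold": d.genus_threshold,
                    "caution_genera": sorted(d.caution_genera),
                }
                for m, d in sorted(self.markers.items())
            },
        }
        return out


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir: str | Path, config: RunConfig, inputs: list[str | Path]) -> None:
    """Machine-readable provenance record: config echo, input checksums,
    tool version. Deliberately timestamp-free so re-runs are byte-identical."""
    record = {
        "tool": "seabirdid",
        "version": __version__,
        "config": config.echo(),
        # keyed by file name (not full path) so identical runs in different
        # working directories produce identical artifacts
        "inputs": {Path(p).name: sha256_of(p) for p in sorted(map(str, inputs))},
    }
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n", encoding="utf-8")
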