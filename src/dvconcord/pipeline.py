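"""Orchestration: generate → extract → harmonize → link → concord → report.

``run_pipeline`` drives the whole analysis from a :class:`RunConfig` (usually
parsed from a YAML file), writing one summary-table set per requested window
plus a JSON run manifest (config echo, seed, versions, exclusion counts) from
which every output is re-derivable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .concordance import Cell, classify_corpus, tabulate
from .extraction import (
    extract_corpus,
    load_events,
    write_events,
    write_mentions,
)
from .lexicon import (
    default_crosswalk,
    default_hierarchy,
    default_lexicon,
    load_crosswalk,
    load_hierarchy,
    load_lexicon,
)
from .linkage import (
    WindowSpec,
    harmonize_records,
    link_events,
    load_hospital_records,
    write_hospital_records,
    write_linked,
)
from .synthetic import CohortConfig, generate_cohort, write_gold

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_WINDOWS = ("1m", "3m", "6m", "12m", "48h", "none")


@dataclass
class RunConfig:
    """Paths, windows, and switches for one pipeline run."""

    events_path: Optional[Path] = None
    hospital_path: Optional[Path] = None
    outdir: Path = Path("dvconcord_out")
    windows: Sequence[str] = DEFAULT_WINDOWS
    lexicon_path: Optional[Path] = None
    crosswalk_path: Optional[Path] = None
    hierarchy_path: Optional[Path] = None
    seed: int = 0
    window_semantics: str = "overlap"  # or "start"
    generate: Optional[CohortConfig] = None  # synthesize inputs when set

    def __post_init__(self):
        if not self.windows:
            raise ValueError("window list must be nonempty")
        for w in self.windows:
            WindowSpec.from_label(w)  # validates
        if self.window_semantics not in ("overlap", "start"):
            raise ValueError(f"unknown window semantics {self.window_semantics!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generate", None)
        cfg = cls(
            events_path=Path(raw["events"]) if raw.get("events") else None,
            hospital_path=Path(raw["hospital"]) if raw.get("hospital") else None,
            outdir=Path(raw.get("outdir", "dvconcord_out")),
            windows=tuple(str(w) for w in raw.get("windows", DEFAULT_WINDOWS)),
            lexicon_path=Path(raw["lexicon"]) if raw.get("lexicon") else None,
            crosswalk_path=Path(raw["crosswalk"]) if raw.get("crosswalk") else None,
            hierarchy_path=Path(raw["hierarchy"]) if raw.get("hierarchy") else None,
            seed=int(raw.get("seed", 0)),
            window_semantics=str(raw.get("window_semantics", "overlap")),
        )
        if gen is not None:
            gen = dict(gen)
            gen.setdefault("seed", cfg.seed)
            cfg.generate = CohortConfig(**gen)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lexicon = load_lexicon(config.lexicon_path) if config.lexicon_path else default_lexicon()
    crosswalk = (
        load_crosswalk(config.crosswalk_path) if config.crosswalk_path else default_crosswalk()
    )
    hierarchy = (
        load_hierarchy(config.hierarchy_path) if config.hierarchy_path else default_hierarchy()
    )

    if config.generate is not None:
        cohort = generate_cohort(config.generate, lexicon)
        events, records = cohort.events, cohort.records
        write_events(events, outdir / "events.csv")
        write_hospital_records(records, outdir / "hospital.csv")
        write_gold(cohort.gold, outdir / "gold.csv")
    else:
        if config.events_path is None or config.hospital_path is None:
            raise ValueError("events and hospital paths are required unless generating")
        for p in (config.events_path, config.hospital_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        events = load_events(config.events_path)
        records = load_hospital_records(config.hospital_path)

    mentions, summary = extract_corpus(events, lexicon)
    write_mentions(mentions, outdir / "mentions.csv")
    harmonized, n_unmappable = harmonize_records(records, crosswalk, hierarchy)

    window_stats = {}
    for wlabel in config.windows:
        window = WindowSpec.from_label(wlabel)
        linked = link_events(
            events, harmonized, window, semantics=config.window_semantics
        )
        wdir = outdir / f"window_{window.label}"
        wdir.mkdir(parents=True, exist_ok=True)
        write_linked(linked, wdir / "linked.csv")
        pairs = classify_corpus(events, mentions, linked)
        tables = tabulate(pairs)
        tables.write(wdir)
        window_stats[window.label] = {
            "two_by_two": {c.value: n for c, n in tables.two_by_two.items()},
            "per_role_both": {r.value: n for r, n in tables.per_role_both.items()},
            "per_role_agreement": {
                r.value: n for r, n in tables.per_role_agreement.items()
            },
        }
        logger.info(
            "window %s: BOTH=%d MENTION_ONLY=%d HOSPITAL_ONLY=%d NEITHER=%d",
            window.label,
            tables.two_by_two[Cell.BOTH],
            tables.two_by_two[Cell.MENTION_ONLY],
            tables.two_by_two[Cell.HOSPITAL_ONLY],
            tables.two_by_two[Cell.NEITHER],
        )

    manifest = {
        "dvconcord_version": __version__,
        "seed": config.seed,
        "windows": list(config.windows),
        "window_semantics": config.window_semantics,
        "n_events": len(events),
        "n_hospital_records": len(records),
        "n_unmappable_records": n_unmappable,
        "n_mentions": summary.n_mentions,
        "n_events_with_mention": summary.n_events_with_mention,
        "generated": config.generate is not None,
        "lexicon_entries": len(lexicon),
        "window_stats": window_stats,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
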