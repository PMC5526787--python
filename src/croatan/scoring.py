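"""Consolidated 1-9 guide scoring and per-gene slate assembly.

Guides are first banded by combined forest score into stringency groups A, B
and C (score 0 is excluded outright). Within a group, a guide earns one
point per orthogonal test it passes — cut-site conservation and frameshift
likelihood — giving the final score 3*group + passes + 1, a bijection from
(group, passes) onto 1..9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .genome_io import TargetSite

DEFAULT_BANDS = {"A": (1, 3), "B": (4, 6), "C": (7, 10)}
_GROUP_INDEX = {"A": 0, "B": 1, "C": 2}


def validate_bands(bands: dict[str, tuple[int, int]]):
    seen: set[int] = set()
    for name in ("A", "B", "C"):
        if name not in bands:
            raise ConfigError(f"band config missing group {name}")
        lo, hi = bands[name]
        if lo > hi or lo < 1 or hi > 10:
            raise ConfigError(f"band {name} [{lo},{hi}] outside 1..10 or inverted")
        rng = set(range(lo, hi + 1))
        if rng & seen:
            raise ConfigError(f"band {name} overlaps another band")
        seen |= rng
    if seen != set(range(1, 11)):
        raise ConfigError("bands must jointly cover forest scores 1..10")


def assign_group(forest_score: int, band_config: dict | None = None) -> str:
    """Map a combined 0-10 forest score to group A/B/C or 'excluded'."""
    bands = band_config or DEFAULT_BANDS
    validate_bands(bands)
    if not 0 <= forest_score <= 10:
        raise ValidationError(f"forest score {forest_score} outside 0-10")
    if forest_score == 0:
        return "excluded"
    for name, (lo, hi) in bands.items():
        if lo <= forest_score <= hi:
            return name
    raise ConfigError("bands do not cover forest score "
                      f"{forest_score}")  # pragma: no cover


@dataclass
class CroatanRecord:
    site: TargetSite
    forest_score: int
    group: str
    conservation_pass: bool
    fsm_pass: bool
    croatan_score: Optional[int] = None

    def __post_init__(self):
        if self.group != "excluded" and self.croatan_score is None:
            self.croatan_score = consolidate(self)


def consolidate(record: "CroatanRecord") -> int:
    """3*group + tests_passed + 1: group A spans 1-3, B 4-6, C 7-9."""
    if record.group == "excluded":
        raise ValidationError("cannot consolidate an excluded guide")
    g = _GROUP_INDEX[record.group]
    tests = int(record.conservation_pass) + int(record.fsm_pass)
    return 3 * g + tests + 1


def design_gene_slate(gene_id: str, scored_records: Sequence[CroatanRecord],
                      guides_per_gene: int = 10,
                      gene_strand: str = "+") -> list[CroatanRecord]:
    """Rank a gene's scored guides and return the top slate.

    Order: consolidated score desc, forest score desc, then 5'-most cut in
    the transcript first (genomic position ascending on '+' genes,
    descending on '-'). A shortfall returns fewer guides, never padding.
    """
    recs = [r for r in scored_records if r.group != "excluded"]
    if not recs:
        return []
    sign = 1 if gene_strand == "+" else -1
    recs = sorted(recs, key=lambda r: (-r.croatan_score, -r.forest_score,
                                       sign * r.site.cut_coord, r.site.site_id))
    return recs[:guides_per_gene]


def slate_to_frame(gene_id: str, slate: Sequence[CroatanRecord]) -> pd.DataFrame:
    rows = [{
        "site_id": r.site.site_id,
        "gene": gene_id,
        "forest_score": r.forest_score,
        "group": r.group,
        "cons_pass": r.conservation_pass,
        "fsm_pass": r.fsm_pass,
        "croatan_score": r.croatan_score,
        "rank": i + 1,
    } for i, r in enumerate(slate)]
    return pd.DataFrame(rows, columns=[
        "site_id", "gene", "forest_score", "group", "cons_pass", "fsm_pass",
        "croatan_score", "rank",
    ])
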