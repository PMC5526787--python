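"""CIGAR-based classification of dual-cut genomic scars from amplicon SAM.

Read pairs are mapped to the amplicon spanning both guide target sites.
Insertions and deletions are read off the CIGAR strings, merged per
fragment, and attributed to the two cut sites: an indel inside only one
attribution window is an h- or c-side indel, indels in both windows a dual
indel, and a deletion running from one window through the other a fragment
deletion — subclassified DSB-DSB when it is the exact blunt re-ligation of
the two break ends with no other edit on the fragment.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
import pysam

from .errors import FormatError, ValidationError

SCAR_CLASSES = ("no_edit", "h_indel", "c_indel", "dual_indel", "fragment_deletion")


@dataclass
class AmpliconSpec:
    amplicon_id: str
    sequence: str
    cut_h: int
    cut_c: int
    attribution_window: int = 5

    def __post_init__(self):
        if not self.cut_h < self.cut_c:
            raise ValidationError("cut_h must be left of cut_c")
        if self.cut_h + self.attribution_window > self.cut_c - self.attribution_window:
            raise ValidationError("attribution windows overlap")

    def window(self, cut: int) -> tuple[int, int]:
        return cut - self.attribution_window, cut + self.attribution_window


@dataclass(frozen=True)
class Edit:
    kind: str       # "D" or "I"
    start: int      # reference coordinate (insertion: position before which bases go)
    length: int

    @property
    def end(self) -> int:
        return self.start + (self.length if self.kind == "D" else 0)


@dataclass
class ScarCall:
    fragment_id: str
    scar_class: str
    subclass: Optional[str] = None          # dsb_dsb | non_dsb_dsb
    deletion_span: Optional[tuple[int, int]] = None
    n_offwindow_edits: int = 0


def _read_edits(read: pysam.AlignedSegment) -> tuple[list[Edit], tuple[int, int]]:
    """Indel list and aligned reference span of one read from its CIGAR."""
    edits = []
    ref = read.reference_start
    qlen = 0
    for op, length in read.cigartuples:
        if op in (0, 7, 8):       # M, =, X
            ref += length
            qlen += length
        elif op == 2:             # D
            edits.append(Edit("D", ref, length))
            ref += length
        elif op == 1:             # I
            edits.append(Edit("I", ref, length))
            qlen += length
        elif op in (4, 5):        # clips: not edits
            if op == 4:
                qlen += length
        # N/P unsupported for amplicons; ignore
    if read.query_sequence is not None and qlen != len(read.query_sequence):
        raise ValidationError(
            f"{read.query_name}: CIGAR consumes {qlen} query bases, "
            f"sequence is {len(read.query_sequence)}"
        )
    return edits, (read.reference_start, ref)


@dataclass
class FragmentAlignment:
    fragment_id: str
    edits: list[Edit] = field(default_factory=list)
    spans: list[tuple[int, int]] = field(default_factory=list)
    discordant: bool = False


def parse_alignments(sam_path, amplicon: AmpliconSpec
                     ) -> tuple[list[FragmentAlignment], dict]:
    """Merge mate CIGARs into per-fragment edit lists.

    Unmapped or single-mapped fragments are excluded (and counted in the
    returned stats), as are fragments whose mates disagree about an edit
    both should have observed.
    """
    per_fragment: dict[str, list] = defaultdict(list)
    stats = Counter()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        try:
            for read in fh:
                if read.is_secondary or read.is_supplementary:
                    continue
                if read.is_unmapped:
                    per_fragment[read.query_name].append(None)
                    continue
                try:
                    edits, span = _read_edits(read)
                except ValidationError:
                    stats["cigar_errors"] += 1
                    per_fragment[read.query_name].append(None)
                    continue
                per_fragment[read.query_name].append((edits, span))
        except OSError as exc:  # htslib aborts on malformed records
            raise FormatError(f"malformed SAM {sam_path}: {exc}") from exc

    fragments: list[FragmentAlignment] = []
    for name, mates in sorted(per_fragment.items()):
        mapped = [m for m in mates if m is not None]
        if len(mapped) < len(mates) or not mapped:
            stats["excluded_unmapped"] += 1
            continue
        frag = FragmentAlignment(fragment_id=name)
        for edits, span in mapped:
            frag.spans.append(span)
        # mate concordance: an edit inside the other mate's span must be shared
        for i, (edits_i, span_i) in enumerate(mapped):
            for e in edits_i:
                for j, (edits_j, span_j) in enumerate(mapped):
                    if i == j:
                        continue
                    inside = span_j[0] < e.start and e.end < span_j[1]
                    if inside and e not in edits_j:
                        frag.discordant = True
        if frag.discordant:
            stats["excluded_discordant"] += 1
            continue
        merged = sorted(set(e for edits, _ in mapped for e in edits),
                        key=lambda e: (e.start, e.kind, e.length))
        frag.edits = merged
        fragments.append(frag)
        stats["fragments"] += 1
    return fragments, dict(stats)


def _touches(edit: Edit, window: tuple[int, int]) -> bool:
    lo, hi = window
    if edit.kind == "I":
        return lo <= edit.start <= hi
    return edit.start <= hi and edit.end >= lo


def classify_fragment(edits: Iterable[Edit], amplicon: AmpliconSpec,
                      fragment_id: str = "") -> ScarCall:
    """Assign one fragment's merged edits to a scar class."""
    edits = list(edits)
    wh = amplicon.window(amplicon.cut_h)
    wc = amplicon.window(amplicon.cut_c)
    # fragment deletion: one deletion overlapping both windows
    for e in edits:
        if e.kind == "D" and _touches(e, wh) and _touches(e, wc):
            exact = (e.start == amplicon.cut_h and e.end == amplicon.cut_c
                     and len(edits) == 1)
            others = [x for x in edits if x is not e]
            return ScarCall(
                fragment_id=fragment_id,
                scar_class="fragment_deletion",
                subclass="dsb_dsb" if exact else "non_dsb_dsb",
                deletion_span=(e.start, e.end),
                n_offwindow_edits=sum(
                    not (_touches(x, wh) or _touches(x, wc)) for x in others),
            )
    in_h = any(_touches(e, wh) for e in edits)
    in_c = any(_touches(e, wc) for e in edits)
    off = sum(not (_touches(e, wh) or _touches(e, wc)) for e in edits)
    if in_h and in_c:
        cls = "dual_indel"
    elif in_h:
        cls = "h_indel"
    elif in_c:
        cls = "c_indel"
    else:
        cls = "no_edit"
    return ScarCall(fragment_id=fragment_id, scar_class=cls,
                    n_offwindow_edits=off)


def classify_sam(sam_path, amplicon: AmpliconSpec) -> tuple[list[ScarCall], dict]:
    fragments, stats = parse_alignments(sam_path, amplicon)
    calls = [classify_fragment(f.edits, amplicon, f.fragment_id)
             for f in fragments]
    return calls, stats


def tally_scars(calls: list[ScarCall], top_n: int = 10) -> dict:
    """Class fractions and the most frequent deletion haplotypes.

    Fractions sum to 1 over classified fragments; fragment deletions are
    additionally broken down by (start, end) span ranked by frequency.
    """
    if not calls:
        raise ValidationError("no classified fragments to tally")
    n = len(calls)
    by_class = Counter(c.scar_class for c in calls)
    fractions = {cls: by_class.get(cls, 0) / n for cls in SCAR_CLASSES}
    sub = Counter(c.subclass for c in calls if c.scar_class == "fragment_deletion")
    dels = Counter(c.deletion_span for c in calls
                   if c.scar_class == "fragment_deletion")
    top = [{"start": s, "end": e, "rate": cnt / n}
           for (s, e), cnt in sorted(dels.items(),
                                     key=lambda kv: (-kv[1], kv[0]))[:top_n]]
    return {
        "n_fragments": n,
        "class_fractions": fractions,
        "subclass_fractions": {
            "dsb_dsb": sub.get("dsb_dsb", 0) / n,
            "non_dsb_dsb": sub.get("non_dsb_dsb", 0) / n,
        },
        "top_deletions": top,
    }


def tally_multi_sample(calls_by_sample: dict[str, list[ScarCall]],
                       top_n: int = 10) -> dict:
    """Average per-class rates over samples (e.g. two cell lines)."""
    if not calls_by_sample:
        raise ValidationError("no samples to tally")
    tallies = {s: tally_scars(c, top_n) for s, c in calls_by_sample.items()}
    classes = SCAR_CLASSES
    avg = {cls: sum(t["class_fractions"][cls] for t in tallies.values())
           / len(tallies) for cls in classes}
    return {"per_sample": tallies, "mean_class_fractions": avg}


def tally_to_frame(tally: dict) -> pd.DataFrame:
    rows = [{"class": k, "fraction": v}
            for k, v in tally["class_fractions"].items()]
    return pd.DataFrame(rows)
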