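"""Dual-guide pair scoring, maximum weight matching and construct assembly.

For each gene the top-20 consolidated guides are reranked for off-target
risk, the top 10 survivors are scored pairwise with the heuristics below,
and five constructs are chosen by maximum weight matching on the resulting
10x10 matrix:

* overlapping target intervals -> final pair score 0 (no increments);
* cuts < 10 kb apart whose inter-DSB distance is not divisible by 3 and
  which share at least one transcript -> base score 2.5 (the blunt DSB-DSB
  re-ligation scar would be a frameshift on a common isoform), else base 0;
* +1 when the consolidated scores are imbalanced (one < 7 and one > 7), so
  every construct tends to carry at least one potent effector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import PairingError, ValidationError
from .genome_io import TargetSite, revcomp
from .scoring import CroatanRecord


def seed_pam_occurrences(site: TargetSite, genome: dict[str, str]) -> int:
    """Occurrences of the guide's 12-nt 3'-proximal seed + NGG, both strands."""
    seed = site.protospacer[-12:]
    count = 0
    for seq in genome.values():
        for s in (seq.upper(), revcomp(seq.upper())):
            start = 0
            while (i := s.find(seed, start)) != -1:
                if i + 14 < len(s) and s[i + 13:i + 15] == "GG":
                    count += 1
                start = i + 1
    return count


def offtarget_risk(site: TargetSite, genome: dict[str, str]) -> int:
    """Exact seed+PAM matches elsewhere in the genome (own site excluded)."""
    return max(0, seed_pam_occurrences(site, genome) - 1)


def offtarget_rerank(top20: Sequence[CroatanRecord], genome: dict[str, str],
                     keep: int = 10,
                     risk_fn: Optional[Callable[[TargetSite], float]] = None
                     ) -> list[CroatanRecord]:
    """Re-sort candidates by (off-target risk asc, score desc); keep the top.

    ``risk_fn`` plugs in an alternative off-target scorer; the default
    counts exact genomic matches of the 12-nt seed plus NGG.
    """
    if len(top20) > 20:
        raise ValidationError("rerank expects at most 20 candidate guides")
    if len(top20) < 2:
        raise PairingError("need at least 2 guides to pair")
    risk = risk_fn or (lambda s: offtarget_risk(s, genome))
    ranked = sorted(
        top20,
        key=lambda r: (risk(r.site), -r.croatan_score, -r.forest_score,
                       r.site.site_id),
    )
    out = ranked[:keep]
    if len(out) < 2:
        raise PairingError("fewer than 2 guides survive off-target reranking")
    return out


def _intervals_overlap(a: TargetSite, b: TargetSite) -> bool:
    if a.chromosome != b.chromosome:
        return False
    (s1, e1), (s2, e2) = a.interval, b.interval
    return s1 < e2 and s2 < e1


def pair_score(a: CroatanRecord, b: CroatanRecord,
               max_distance: int = 10_000) -> float:
    """Heuristic score for pairing two guides in one dual construct."""
    if _intervals_overlap(a.site, b.site):
        return 0.0
    score = 0.0
    dist = abs(a.site.cut_coord - b.site.cut_coord)
    shared = set(a.site.overlapping_transcripts) & set(b.site.overlapping_transcripts)
    if a.site.chromosome == b.site.chromosome and dist < max_distance \
            and dist % 3 != 0 and shared:
        score = 2.5
    lo, hi = sorted((a.croatan_score, b.croatan_score))
    if lo < 7 and hi > 7:
        score += 1.0
    return score


@dataclass
class PairScoreMatrix:
    guides: list[str]
    scores: np.ndarray

    def weight(self, i: int, j: int) -> float:
        return float(self.scores[i, j])


def build_matrix(guides: Sequence[CroatanRecord],
                 max_distance: int = 10_000) -> PairScoreMatrix:
    """Symmetric pair-score matrix over a gene's (up to 10) guides."""
    ids = [g.site.site_id for g in guides]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate guide ids in slate")
    n = len(guides)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = pair_score(guides[i], guides[j], max_distance)
    return PairScoreMatrix(guides=ids, scores=m)


def max_weight_matching(matrix: PairScoreMatrix) -> list[tuple[str, str]]:
    """Maximum-weight matching (blossom) on the pair-score graph.

    Returns disjoint guide-id pairs, each sorted, the list sorted, so the
    output is deterministic for a given matrix.
    """
    n = len(matrix.guides)
    if n < 2:
        raise PairingError("need at least 2 guides to match")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        g.add_edge(i, j, weight=matrix.scores[i, j])
    mate = nx.max_weight_matching(g, maxcardinality=False)
    pairs = [tuple(sorted((matrix.guides[i], matrix.guides[j]))) for i, j in mate]
    return sorted(pairs)


def matching_weight(matrix: PairScoreMatrix,
                    pairs: Sequence[tuple[str, str]]) -> float:
    idx = {gid: i for i, gid in enumerate(matrix.guides)}
    return float(sum(matrix.scores[idx[a], idx[b]] for a, b in pairs))


@dataclass
class ConstructDesign:
    h_guide: str
    c_guide: str
    barcode: str
    pair_score: float
    gene: str


class BarcodeAllocator:
    """Deterministic DNA barcodes with a minimum pairwise Hamming distance."""

    def __init__(self, length: int = 12, min_hamming: int = 3, rng_seed: int = 0,
                 pool: Optional[Sequence[str]] = None):
        self.length = length
        self.min_hamming = min_hamming
        self._rng = np.random.default_rng(rng_seed)
        self._issued: list[str] = []
        self._pool = list(pool) if pool is not None else None
        self._max_attempts = 10_000

    def _hamming_ok(self, bc: str) -> bool:
        return all(sum(x != y for x, y in zip(bc, prev)) >= self.min_hamming
                   for prev in self._issued)

    def next(self) -> str:
        if self._pool is not None:
            while self._pool:
                bc = self._pool.pop(0)
                if self._hamming_ok(bc):
                    self._issued.append(bc)
                    return bc
            raise PairingError("barcode pool exhausted")
        for _ in range(self._max_attempts):
            bc = "".join(self._rng.choice(list("ACGT"), size=self.length))
            if self._hamming_ok(bc):
                self._issued.append(bc)
                return bc
        raise PairingError("barcode space exhausted")  # pragma: no cover


def assemble_constructs(matching: Sequence[tuple[str, str]],
                        guides_by_id: dict[str, CroatanRecord],
                        barcode_allocator: BarcodeAllocator,
                        matrix: Optional[PairScoreMatrix] = None,
                        gene: str = "") -> list[ConstructDesign]:
    """Place each matched pair into an ordered hU6/cU6 cassette with a barcode.

    The higher-scoring guide takes the human-U6 position (tie: lexicographic
    guide id).
    """
    constructs = []
    for a, b in matching:
        ra, rb = guides_by_id[a], guides_by_id[b]
        if ra.croatan_score > rb.croatan_score:
            h, c = a, b
        elif rb.croatan_score > ra.croatan_score:
            h, c = b, a
        else:  # tie: lexicographic
            h, c = sorted((a, b))
        score = (matching_weight(matrix, [(a, b)]) if matrix is not None
                 else pair_score(ra, rb))
        constructs.append(ConstructDesign(
            h_guide=h, c_guide=c, barcode=barcode_allocator.next(),
            pair_score=score, gene=gene or (ra.site.gene_id or ""),
        ))
    return constructs


def combinatorial_pairs(guides: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered (hU6, cU6) pairs over a guide set, self-pairs included.

    A 100-guide library placed in both promoter positions yields 10,000
    ordered pairs.
    """
    return [(a, b) for a in guides for b in guides]


CASSETTE_FLANKS = {
    "five_prime": "ACCG",
    "linker_hu6": "GTTTCGTCCTTTCCACAAG",
    "linker_cu6": "CGACTAAGAGCATCGAG",
    "three_prime": "GTTT",
}


def cassette_layout(construct: ConstructDesign,
                    protospacers: dict[str, str],
                    flanks: dict[str, str] = CASSETTE_FLANKS) -> str:
    """sgRNA1-hU6-barcode-cU6-sgRNA2 oligo layout for one construct."""
    return (flanks["five_prime"] + protospacers[construct.h_guide]
            + flanks["linker_hu6"] + construct.barcode
            + flanks["linker_cu6"] + protospacers[construct.c_guide]
            + flanks["three_prime"])
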