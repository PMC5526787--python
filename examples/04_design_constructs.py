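"""Design dual-guide constructs for one gene: slate, pair, match, assemble.

Ten scored guides are pairwise scored with the heuristics (2.5 base for
close, frame-shifting, same-transcript pairs; +1 for imbalanced scores;
0 for overlaps) and five constructs are chosen by maximum weight matching.
"""

from croatan import TargetSite
from croatan.pairing import (BarcodeAllocator, assemble_constructs,
                             build_matrix, matching_weight,
                             max_weight_matching)
from croatan.scoring import CroatanRecord


def guide(i, cut, score):
    proto = "ACGTACGTACGTACGTACGT"
    site = TargetSite(site_id=f"g{i:02d}", chromosome="chr1", strand="+",
                      protospacer=proto, pam="AGG", cut_coord=cut,
                      context30="TTTT" + proto + "AGGTTT",
                      overlapping_transcripts=["tx1"])
    return CroatanRecord(site=site, forest_score=score,
                         group="C" if score >= 7 else "B",
                         conservation_pass=True, fsm_pass=True,
                         croatan_score=score)


slate = [guide(i, 1000 + 101 * i, score)
         for i, score in enumerate([9, 9, 8, 8, 8, 6, 5, 5, 4, 4])]
matrix = build_matrix(slate)
matching = max_weight_matching(matrix)
constructs = assemble_constructs(matching, {g.site.site_id: g for g in slate},
                                 BarcodeAllocator(rng_seed=0), matrix,
                                 gene="GENE1")

print(f"pair matrix: {matrix.scores.shape}, "
      f"total matched weight {matching_weight(matrix, matching):.1f}")
for c in constructs:
    print(f"  hU6={c.h_guide} cU6={c.c_guide} barcode={c.barcode} "
          f"pair_score={c.pair_score}")
# Five disjoint pairs cover all ten guides; the higher-scoring guide of each
# pair sits at the human-U6 position and the barcode identifies the pair in
# sequencing readouts.
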