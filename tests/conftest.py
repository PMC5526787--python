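import numpy as np
import pytest

from croatan import potency
from croatan import simulate as sim
from croatan.genome_io import TargetSite
from croatan.scoring import CroatanRecord


@pytest.fixture(scope="session")
def efficacy_fixture():
    """Seed-3 planted-signal efficacy table, split into train/test halves."""
    df, truth = sim.make_efficacy_dataset(sim.EfficacyConfig(rng_seed=3))
    assert len(df) == 400
    return df.iloc[:300].reset_index(drop=True), df.iloc[300:].reset_index(drop=True), truth


@pytest.fixture(scope="session")
def small_ensemble(efficacy_fixture):
    """Stringency ladder trained at reduced forest size for test speed."""
    train, _, _ = efficacy_fixture
    cfg = potency.EnsembleConfig(trees_per_forest=60, rng_seed=17)
    return potency.train_ensemble(train, "doench-like", cfg)


@pytest.fixture(scope="session")
def sim_genome(tmp_path_factory):
    genome, gff, truth = sim.make_genome(sim.GenomeConfig(rng_seed=1, n_genes=6))
    d = tmp_path_factory.mktemp("genome")
    sim.write_fasta(genome, d / "genome.fa")
    (d / "genes.gff3").write_text(gff)
    return genome, d / "genome.fa", d / "genes.gff3", truth


def make_record(site_id: str, cut: int, croatan_score: int = 9,
                transcripts=("t1",), strand: str = "+",
                protospacer: str = None, chrom: str = "chr1",
                forest_score: int = 9) -> CroatanRecord:
    """A minimal scored guide for pairing/slate tests."""
    proto = protospacer or "A" * 20
    ctx = "TTTT" + proto + "AGGTTT"
    site = TargetSite(
        site_id=site_id, chromosome=chrom, strand=strand, protospacer=proto,
        pam="AGG", cut_coord=cut, context30=ctx,
        overlapping_transcripts=list(transcripts),
    )
    group = "C" if forest_score >= 7 else ("B" if forest_score >= 4 else "A")
    return CroatanRecord(site=site, forest_score=forest_score, group=group,
                         conservation_pass=True, fsm_pass=True,
                         croatan_score=croatan_score)


def brute_force_matching_weight(weights: np.ndarray) -> float:
    """Max total weight over all perfect matchings (even n) by recursion."""
    n = weights.shape[0]

    def rec(remaining):
        if not remaining:
            return 0.0
        a = remaining[0]
        best = 0.0
        for b in remaining[1:]:
            rest = [x for x in remaining[1:] if x != b]
            best = max(best, weights[a, b] + rec(rest))
        return best

    return rec(list(range(n)))
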