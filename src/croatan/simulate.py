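"""Synthetic fixtures with planted ground truth for every toolkit input.

Each generator is a pure function of its config (all randomness flows from
``rng_seed``) and returns both the artifact and a machine-readable truth
record, so downstream recovery can be asserted without any external data:

* a small genome (FASTA + GFF3) of non-overlapping multi-exon genes whose
  CDS are stop-free and rich in NGG sites;
* sgRNA efficacy tables where potency follows a known sequence rule
  (protospacer GC plus a planted positional 3-mer) with gaussian noise;
* microhomology resolution tables drawn from known linear coefficients;
* pooled-screen count tables with negative-binomial noise and essential-gene
  depletion planted on the normalized (CPM log-ratio) scale;
* amplicon SAM files of read pairs carrying planted scar classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError
from .genome_io import revcomp
from .scars import AmpliconSpec, Edit

_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in ("TAA", "TAG", "TGA")]


# ---------------------------------------------------------------- genome

@dataclass
class GenomeConfig:
    rng_seed: int = 1
    n_genes: int = 40
    exon_codons: tuple[int, int] = (60, 60)   # codons per exon
    intron_len: int = 80
    spacer_len: int = 100
    min_ngg_sites: int = 20


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS, size=n_codons)) + "TAA"


def _count_ngg(seq: str) -> int:
    n = sum(1 for i in range(1, len(seq) - 1) if seq[i:i + 2] == "GG")
    n += sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CC")
    return n


def make_genome(config: GenomeConfig | None = None):
    """Synthetic chromosome with two-exon genes on alternating strands.

    Returns (genome dict, gff3 text, truth dict). CDS lengths are divisible
    by 3, the translated CDS has no internal stop, and each gene carries at
    least ``min_ngg_sites`` candidate PAM sites.
    """
    config = config or GenomeConfig()
    rng = np.random.default_rng(config.rng_seed)
    if config.n_genes < 1:
        raise ConfigError("need at least one gene")
    chrom_parts: list[str] = []
    pos = 0
    gff = ["##gff-version 3"]
    truth = {"genes": [], "rng_seed": config.rng_seed}
    for gi in range(config.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        for _attempt in range(50):
            cds = _random_cds(rng, sum(config.exon_codons))
            if _count_ngg(cds) >= config.min_ngg_sites:
                break
        else:  # pragma: no cover
            raise ConfigError("could not satisfy the NGG-site floor")
        l1 = config.exon_codons[0] * 3
        s1, s2 = cds[:l1], cds[l1:]
        intron = "".join(rng.choice(list("ACGT"), size=config.intron_len))
        spacer = "".join(rng.choice(list("ACGT"), size=config.spacer_len))
        chrom_parts.append(spacer)
        pos += len(spacer)
        gstart = pos
        if strand == "+":
            exon_a, exon_b = s1, s2
        else:
            exon_a, exon_b = revcomp(s2), revcomp(s1)
        e1 = (pos, pos + len(exon_a))
        e2 = (e1[1] + len(intron), e1[1] + len(intron) + len(exon_b))
        chrom_parts += [exon_a, intron, exon_b]
        pos = e2[1]
        gid, tid = f"gene{gi:03d}", f"tx{gi:03d}"
        gff.append("\t".join(["chr1", "sim", "gene", str(gstart + 1), str(pos),
                              ".", strand, ".", f"ID={gid}"]))
        gff.append("\t".join(["chr1", "sim", "mRNA", str(gstart + 1), str(pos),
                              ".", strand, ".", f"ID={tid};Parent={gid}"]))
        for (es, ee) in (e1, e2):
            gff.append("\t".join(["chr1", "sim", "exon", str(es + 1), str(ee),
                                  ".", strand, ".", f"Parent={tid}"]))
            gff.append("\t".join(["chr1", "sim", "CDS", str(es + 1), str(ee),
                                  ".", strand, "0", f"Parent={tid}"]))
        truth["genes"].append({
            "gene_id": gid, "transcript_id": tid, "strand": strand,
            "exons": [list(e1), list(e2)], "cds_spliced": cds,
        })
    chrom_parts.append("".join(np.random.default_rng(config.rng_seed + 1)
                               .choice(list("ACGT"), size=config.spacer_len)))
    genome = {"chr1": "".join(chrom_parts)}
    return genome, "\n".join(gff) + "\n", truth


# ---------------------------------------------------------------- efficacy

@dataclass
class EfficacyConfig:
    rng_seed: int = 2
    n_genes: int = 40
    guides_per_gene: int = 10
    gc_weight: float = 3.0
    kmer_weight: float = 2.0
    planted_kmer: str = "GCA"
    kmer_position: int = 12      # offset within the 30-nt context
    kmer_probability: float = 0.5
    noise_sd: float = 0.5


def _random_context(rng: np.random.Generator) -> str:
    ctx = list(rng.choice(list("ACGT"), size=30))
    ctx[25] = ctx[26] = "G"      # PAM NGG at offsets 24-26
    return "".join(ctx)


def efficacy_signal(ctx: str, config: EfficacyConfig) -> float:
    proto = ctx[4:24]
    gc = sum(b in "GC" for b in proto) / 20.0
    k = config.kmer_position
    has = ctx[k:k + len(config.planted_kmer)] == config.planted_kmer
    return config.gc_weight * gc + config.kmer_weight * float(has)


def make_efficacy_dataset(config: EfficacyConfig | None = None):
    """Efficacy table whose potency follows a planted positional rule."""
    config = config or EfficacyConfig()
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    for gi in range(config.n_genes):
        for _ in range(config.guides_per_gene):
            ctx = _random_context(rng)
            if rng.random() < config.kmer_probability:
                k = config.kmer_position
                ctx = (ctx[:k] + config.planted_kmer
                       + ctx[k + len(config.planted_kmer):])
                ctx = ctx[:25] + "GG" + ctx[27:]   # keep the PAM
            eff = efficacy_signal(ctx, config) + rng.normal(0, config.noise_sd)
            rows.append({"context30": ctx, "gene_id": f"gene{gi:03d}",
                         "efficacy": eff})
    df = pd.DataFrame(rows)
    truth = asdict(config)
    return df, truth


# ---------------------------------------------------------------- repair table

@dataclass
class RepairTableConfig:
    rng_seed: int = 5
    n_rows: int = 500
    intercept: float = 0.1
    length_coef: float = 0.05
    gc_coef: float = 0.3
    distance_coef: float = -0.01
    noise_sd: float = 0.01
    length_range: tuple[int, int] = (2, 12)
    distance_range: tuple[int, int] = (0, 30)


def make_resolution_table(config: RepairTableConfig | None = None):
    """Resolution-frequency table drawn from known linear coefficients."""
    config = config or RepairTableConfig()
    if config.length_range[0] >= config.length_range[1]:
        raise ConfigError("degenerate length range gives a rank-deficient design")
    if config.distance_range[0] >= config.distance_range[1]:
        raise ConfigError("degenerate distance range gives a rank-deficient design")
    rng = np.random.default_rng(config.rng_seed)
    length = rng.integers(config.length_range[0], config.length_range[1] + 1,
                          size=config.n_rows)
    gc = rng.uniform(0, 1, size=config.n_rows)
    dist = rng.integers(config.distance_range[0], config.distance_range[1] + 1,
                        size=config.n_rows)
    freq = (config.intercept + config.length_coef * length + config.gc_coef * gc
            + config.distance_coef * dist
            + rng.normal(0, config.noise_sd, size=config.n_rows))
    df = pd.DataFrame({"length": length, "gc_fraction": gc, "distance": dist,
                       "frequency": freq})
    truth = {"intercept": config.intercept,
             "coefficients": {"length": config.length_coef,
                              "gc_fraction": config.gc_coef,
                              "distance": config.distance_coef},
             "noise_sd": config.noise_sd}
    return df, truth


# ---------------------------------------------------------------- screen

@dataclass
class ScreenConfig:
    rng_seed: int = 11
    n_replicates: int = 3
    depth_per_construct: int = 1000
    eg_delta: float = -2.0
    synergy_factor: float = 1.5   # same-EG dual constructs deplete 1.5x
    dispersion: float = 0.05
    abundance_sd: float = 0.3     # lognormal sd of reference abundances


def _construct_deltas(library: pd.DataFrame, config: ScreenConfig) -> np.ndarray:
    """Planted per-construct depletion on the normalized log2 scale."""
    if {"class_h", "class_c"} <= set(library.columns):
        d = np.zeros(len(library))
        h_eg = (library["class_h"] == "EG").to_numpy()
        c_eg = (library["class_c"] == "EG").to_numpy()
        d[h_eg | c_eg] = config.eg_delta
        same_eg = (h_eg & c_eg
                   & (library["gene_h"] == library["gene_c"]).to_numpy())
        d[same_eg] = config.eg_delta * config.synergy_factor
        return d
    if "class" in library.columns:
        return np.where(library["class"] == "EG", config.eg_delta, 0.0)
    raise ConfigError("library needs a 'class' or 'class_h'/'class_c' column")


def make_screen(library: pd.DataFrame, config: ScreenConfig | None = None):
    """Negative-binomial count table with composition-consistent depletion.

    Depletion is planted on the CPM log-ratio scale: constructs carrying the
    planted delta have expected normalized LFC equal to delta, while
    unaffected constructs absorb the complementary composition shift (as
    they do in a real pooled screen under normalization).
    """
    config = config or ScreenConfig()
    rng = np.random.default_rng(config.rng_seed)
    n = len(library)
    deltas = _construct_deltas(library, config)
    p = np.exp(rng.normal(0, config.abundance_sd, size=n))
    p /= p.sum()
    affected = deltas != 0
    mass_aff = p[affected].sum()
    # solve the normalization identity sum(p * 2^lfc) = 1 for the null guides
    lfc = deltas.astype(float).copy()
    if (~affected).any():
        resid = 1.0 - float((p[affected] * 2.0 ** deltas[affected]).sum())
        if resid <= 0:
            raise ConfigError("planted depletion leaves no mass for null guides")
        lfc[~affected] = np.log2(resid / p[~affected].sum())
    elif not np.isclose(mass_aff, 1.0):  # pragma: no cover
        raise ConfigError("all constructs affected but masses inconsistent")
    q = p * 2.0 ** lfc
    depth = config.depth_per_construct * n
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for tp, abundance in (("reference", p), ("final", q)):
            mean = abundance * depth
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mean / shape)
            counts = rng.poisson(lam)
            for cid, cnt in zip(library["construct"], counts):
                rows.append({"construct": cid, "replicate": f"rep{rep}",
                             "timepoint": tp, "count": int(cnt)})
    truth = {"eg_delta": config.eg_delta,
             "synergy_factor": config.synergy_factor,
             "planted_lfc": dict(zip(library["construct"], lfc.round(6)))}
    return pd.DataFrame(rows), truth


def make_single_guide_library(n_eg: int = 20, n_neg: int = 20,
                              guides_per_gene: int = 5) -> pd.DataFrame:
    rows = []
    for cls, n in (("EG", n_eg), ("NEG", n_neg)):
        for g in range(n):
            gene = f"{cls}{g:02d}"
            for k in range(guides_per_gene):
                rows.append({"construct": f"{gene}_g{k}", "gene": gene,
                             "class": cls})
    return pd.DataFrame(rows)


def make_dual_library(n_eg: int = 4, n_neg: int = 4,
                      guides_per_gene: int = 5) -> pd.DataFrame:
    """All ordered guide pairs over a small EG/NEG guide panel."""
    guides = []
    for cls, n in (("EG", n_eg), ("NEG", n_neg)):
        for g in range(n):
            gene = f"{cls}{g:02d}"
            for k in range(guides_per_gene):
                guides.append((f"{gene}_g{k}", gene, cls))
    rows = []
    for gh, geneh, clsh in guides:
        for gc_, genec, clsc in guides:
            rows.append({"construct": f"{gh}|{gc_}",
                         "guide_h": gh, "guide_c": gc_,
                         "gene_h": geneh, "gene_c": genec,
                         "class_h": clsh, "class_c": clsc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- scar SAM

@dataclass
class ScarMixConfig:
    rng_seed: int = 15
    n_fragments: int = 2000
    read_len: int = 150
    amplicon_len: int = 300
    cut_h: int = 100
    cut_c: int = 200
    proportions: dict = field(default_factory=lambda: {
        "no_edit": 0.10, "h_indel": 0.20, "c_indel": 0.20,
        "dual_indel": 0.10, "dsb_dsb": 0.30, "non_dsb_dsb": 0.10,
    })


def _small_indel(rng: np.random.Generator, cut: int) -> Edit:
    if rng.random() < 0.5:
        return Edit("D", cut, int(rng.integers(1, 5)))
    return Edit("I", cut, int(rng.integers(1, 4)))


def _edits_for_class(rng: np.random.Generator, label: str,
                     cut_h: int, cut_c: int) -> list[Edit]:
    if label == "no_edit":
        return []
    if label == "h_indel":
        return [_small_indel(rng, cut_h)]
    if label == "c_indel":
        return [_small_indel(rng, cut_c)]
    if label == "dual_indel":
        return [_small_indel(rng, cut_h), _small_indel(rng, cut_c)]
    if label == "dsb_dsb":
        return [Edit("D", cut_h, cut_c - cut_h)]
    if label == "non_dsb_dsb":
        a = int(rng.integers(0, 4))
        b = int(rng.integers(0, 4))
        if a == 0 and b == 0:
            a = 1
        return [Edit("D", cut_h - a, cut_c - cut_h + a + b)]
    raise ConfigError(f"unknown scar class {label!r}")


def _apply_edits(seq: str, edits: list[Edit], rng: np.random.Generator) -> str:
    out = []
    pos = 0
    for e in sorted(edits, key=lambda x: x.start):
        out.append(seq[pos:e.start])
        if e.kind == "D":
            pos = e.start + e.length
        else:
            out.append("".join(rng.choice(list("ACGT"), size=e.length)))
            pos = e.start
    out.append(seq[pos:])
    return "".join(out)


def _mirror_edits(edits: list[Edit], ref_len: int) -> list[Edit]:
    out = []
    for e in edits:
        if e.kind == "D":
            out.append(Edit("D", ref_len - (e.start + e.length), e.length))
        else:
            out.append(Edit("I", ref_len - e.start, e.length))
    return out


def _forward_cigar(edits: list[Edit], ref_len: int, budget: int):
    """CIGAR tuples for a read starting at ref 0 consuming ``budget`` query."""
    cig: list[tuple[int, int]] = []
    ref = 0
    b = budget
    for e in sorted(edits, key=lambda x: (x.start, x.kind)):
        gap = e.start - ref
        t = min(gap, b)
        if t > 0:
            cig.append((0, t))
            ref += t
            b -= t
        if b == 0 or ref < e.start:
            break
        if e.kind == "D":
            cig.append((2, e.length))
            ref += e.length
        else:
            t = min(e.length, b)
            cig.append((1, t))
            b -= t
            if b == 0:
                break
    if b > 0:
        t = min(ref_len - ref, b)
        cig.append((0, t))
        ref += t
        b -= t
    while cig and cig[-1][0] == 2:      # never end on a deletion
        ref -= cig[-1][1]
        cig.pop()
    # merge adjacent same-op runs
    merged: list[tuple[int, int]] = []
    for op, ln in cig:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged, ref


def make_scar_sam(sam_path, config: ScarMixConfig | None = None):
    """Write an amplicon SAM of planted scar read pairs; return the truth.

    Returns (AmpliconSpec, truth dict) where truth maps fragment id to its
    planted class (and subclass for fragment deletions).
    """
    config = config or ScarMixConfig()
    rng = np.random.default_rng(config.rng_seed)
    amp_seq = "".join(rng.choice(list("ACGT"), size=config.amplicon_len))
    amplicon = AmpliconSpec(amplicon_id="amp1", sequence=amp_seq,
                            cut_h=config.cut_h, cut_c=config.cut_c)
    labels = list(config.proportions)
    probs = np.array([config.proportions[k] for k in labels], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ConfigError("scar class proportions must sum to 1")
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": "amp1", "LN": config.amplicon_len}]}
    truth: dict[str, dict] = {}
    L = config.amplicon_len
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i in range(config.n_fragments):
            label = labels[int(rng.choice(len(labels), p=probs))]
            edits = _edits_for_class(rng, label, config.cut_h, config.cut_c)
            frag = _apply_edits(amp_seq, edits, rng)
            name = f"frag{i:05d}"
            scar_class = ("fragment_deletion"
                          if label in ("dsb_dsb", "non_dsb_dsb") else label)
            truth[name] = {"class": scar_class,
                           "subclass": label if scar_class == "fragment_deletion"
                           else None}
            rl = min(config.read_len, len(frag))
            cig1, _ = _forward_cigar(edits, L, rl)
            mirr = _mirror_edits(edits, L)
            cig2m, ref2 = _forward_cigar(mirr, L, rl)
            cig2 = list(reversed(cig2m))
            r1 = pysam.AlignedSegment()
            r1.query_name = name
            r1.query_sequence = frag[:rl]
            r1.flag = 0x1 | 0x2 | 0x40
            r1.reference_id = 0
            r1.reference_start = 0
            r1.mapping_quality = 60
            r1.cigartuples = cig1
            r2 = pysam.AlignedSegment()
            r2.query_name = name
            r2.query_sequence = frag[-rl:]   # SEQ is reference-oriented
            r2.flag = 0x1 | 0x2 | 0x80 | 0x10
            r2.reference_id = 0
            r2.reference_start = L - ref2
            r2.mapping_quality = 60
            r2.cigartuples = cig2
            out.write(r1)
            out.write(r2)
    return amplicon, truth


def write_fasta(genome: dict[str, str], path, width: int = 60):
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth(truth: dict, path):
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
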