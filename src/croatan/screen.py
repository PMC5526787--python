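"""Pooled-screen depletion analysis: filtering, log-fold-changes, hit calls.

The module starts at a long-format count table (construct, replicate,
timepoint, count). Counts are scaled to counts-per-million within each
sample, log2 ratios of final over reference abundance are computed per
replicate with a pseudocount, and gene-level "hits" are called with the
two-construct rule: a gene is depleted at stringency q when at least two of
its constructs fall in the most-depleted q-fraction of all constructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultError, ValidationError

REQUIRED_COUNT_COLS = {"construct", "replicate", "timepoint", "count"}


def _check_table(counts: pd.DataFrame):
    if missing := REQUIRED_COUNT_COLS - set(counts.columns):
        raise ValidationError(f"count table missing columns {sorted(missing)}")
    if (counts["count"] < 0).any():
        raise ValidationError("negative counts")
    tps = set(counts["timepoint"])
    if not {"reference", "final"} <= tps:
        raise ValidationError("count table needs 'reference' and 'final' timepoints")


def filter_min_reference(counts: pd.DataFrame, threshold: int = 50) -> pd.DataFrame:
    """Drop constructs whose reference count is below ``threshold``, per replicate."""
    _check_table(counts)
    ref = counts[counts["timepoint"] == "reference"]
    keep = ref[ref["count"] >= threshold][["construct", "replicate"]]
    out = counts.merge(keep, on=["construct", "replicate"], how="inner")
    if out.empty:
        raise EmptyResultError(
            f"no construct passes the reference-count threshold of {threshold}"
        )
    return out.reset_index(drop=True)


@dataclass
class DepletionResult:
    per_replicate: pd.DataFrame     # construct, replicate, lfc, zscore
    mean_lfc: pd.Series             # replicate-averaged LFC by construct
    config: dict = field(default_factory=dict)
    gene_percentiles: Optional[pd.DataFrame] = None


def log_fold_change(counts: pd.DataFrame, pseudocount: float = 1.0,
                    z_stratum: str = "replicate") -> DepletionResult:
    """Per-replicate CPM log2 ratios (final/reference) with z-scores.

    ``z_stratum`` controls where z-scores are standardized: per replicate
    (default) or over the whole screen ("screen").
    """
    _check_table(counts)
    df = counts.copy()
    totals = df.groupby(["replicate", "timepoint"])["count"].transform("sum")
    df["cpm"] = df["count"] / totals * 1e6
    wide = df.pivot_table(index=["construct", "replicate"], columns="timepoint",
                          values="cpm", aggfunc="sum")
    if "reference" not in wide.columns or wide["reference"].isna().any():
        raise ValidationError("constructs missing a matched reference sample")
    if wide["final"].isna().any():
        raise ValidationError("constructs missing a matched final sample")
    wide = wide.reset_index()
    wide["lfc"] = np.log2((wide["final"] + pseudocount)
                          / (wide["reference"] + pseudocount))
    if z_stratum == "replicate":
        grp = wide.groupby("replicate")["lfc"]
        wide["zscore"] = (wide["lfc"] - grp.transform("mean")) / grp.transform("std")
    elif z_stratum == "screen":
        wide["zscore"] = (wide["lfc"] - wide["lfc"].mean()) / wide["lfc"].std()
    else:
        raise ValidationError(f"unknown z stratum {z_stratum!r}")
    mean_lfc = wide.groupby("construct")["lfc"].mean()
    return DepletionResult(
        per_replicate=wide[["construct", "replicate", "lfc", "zscore"]],
        mean_lfc=mean_lfc,
        config={"pseudocount": pseudocount, "normalization": "cpm",
                "z_stratum": z_stratum, "z_order": "z-after-lfc-per-replicate"},
    )


def gene_percentile(result: DepletionResult,
                    guide_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Within-gene depletion percentile of each guide's mean LFC.

    The most-depleted guide (lowest LFC) gets the highest percentile;
    midpoint convention, ties averaged. Singleton genes are flagged and
    excluded.
    """
    df = result.mean_lfc.rename("lfc").rename_axis("construct").reset_index()
    df["gene"] = df["construct"].map(guide_to_gene)
    df = df.dropna(subset=["gene"])
    sizes = df.groupby("gene")["construct"].transform("size")
    singles = df[sizes < 2]
    if len(singles):
        warnings.warn(f"excluding {len(singles)} singleton-gene guide(s)")
    df = df[sizes >= 2].copy()

    def pct(x: pd.Series) -> pd.Series:
        r = (-x).rank(method="average")
        return (r - 0.5) / len(x) * 100.0

    df["depletion_percentile"] = df.groupby("gene", group_keys=False)["lfc"].apply(pct)
    result.gene_percentiles = df.reset_index(drop=True)
    return result.gene_percentiles


def group_tests(values: Mapping[str, Sequence[float]],
                matched: bool = False) -> dict:
    """Nonparametric comparisons among named groups of depletion values.

    Two groups -> Wilcoxon rank-sum; k matched groups -> Friedman. When the
    group labels are orderable, Spearman rho of label order vs. value is
    reported too. Groups with n < 2 are excluded with a warning.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    dropped = [k for k, v in groups.items() if len(v) < 2]
    if dropped:
        warnings.warn(f"excluding group(s) with n<2: {dropped}")
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValidationError("need at least two groups of size >= 2")
    report: dict = {"n": {k: int(len(v)) for k, v in groups.items()}}
    keys = sorted(groups)
    if len(groups) == 2:
        a, b = (groups[k] for k in keys)
        stat, p = stats.ranksums(a, b)
        report["test"] = "ranksum"
        report["statistic"], report["p_value"] = float(stat), float(p)
    elif matched:
        stat, p = stats.friedmanchisquare(*(groups[k] for k in keys))
        report["test"] = "friedman"
        report["statistic"], report["p_value"] = float(stat), float(p)
    else:
        stat, p = stats.kruskal(*(groups[k] for k in keys))
        report["test"] = "kruskal"
        report["statistic"], report["p_value"] = float(stat), float(p)
    # monotone association across ordered group labels
    xs = np.concatenate([np.full(len(groups[k]), i) for i, k in enumerate(keys)])
    ys = np.concatenate([groups[k] for k in keys])
    rho, rho_p = stats.spearmanr(xs, ys)
    report["spearman_rho"], report["spearman_p"] = float(rho), float(rho_p)
    return report


def spearman_association(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    rho, p = stats.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(rho), float(p)


def dual_construct_decomposition(result: DepletionResult,
                                 construct_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-EG-guide mean LFC with NEG partners vs. same-gene partners.

    ``construct_meta`` needs columns construct, guide_h, guide_c, gene_h,
    gene_c, class_h, class_c. Guides lacking either partner class are
    excluded. Returns one row per EG guide with the two partner-class means
    and attaches a paired Wilcoxon p-value in ``attrs`` when possible.
    """
    need = {"construct", "guide_h", "guide_c", "gene_h", "gene_c",
            "class_h", "class_c"}
    if missing := need - set(construct_meta.columns):
        raise ValidationError(f"construct metadata missing {sorted(missing)}")
    lfc = result.mean_lfc
    meta = construct_meta[construct_meta["construct"].isin(lfc.index)]
    if meta.empty:
        return pd.DataFrame(columns=["guide", "gene", "neg_partner_mean",
                                     "same_gene_partner_mean", "n_neg", "n_same"])
    rows = []
    eg_guides = sorted(
        set(meta.loc[meta["class_h"] == "EG", "guide_h"])
        | set(meta.loc[meta["class_c"] == "EG", "guide_c"])
    )
    for guide in eg_guides:
        as_h = meta[meta["guide_h"] == guide]
        as_c = meta[meta["guide_c"] == guide]
        gene = pd.concat([as_h["gene_h"], as_c["gene_c"]]).iloc[0]
        neg = pd.concat([
            as_h[as_h["class_c"] == "NEG"],
            as_c[as_c["class_h"] == "NEG"],
        ])["construct"]
        same = pd.concat([
            as_h[(as_h["gene_c"] == gene) & (as_h["guide_c"] != guide)],
            as_c[(as_c["gene_h"] == gene) & (as_c["guide_h"] != guide)],
        ])["construct"]
        if neg.empty or same.empty:
            continue
        rows.append({
            "guide": guide, "gene": gene,
            "neg_partner_mean": float(lfc[neg].mean()),
            "same_gene_partner_mean": float(lfc[same].mean()),
            "n_neg": int(len(neg)), "n_same": int(len(same)),
        })
    out = pd.DataFrame(rows, columns=["guide", "gene", "neg_partner_mean",
                                      "same_gene_partner_mean", "n_neg", "n_same"])
    if len(out) >= 2:
        try:
            stat, p = stats.wilcoxon(out["neg_partner_mean"],
                                     out["same_gene_partner_mean"])
            out.attrs["wilcoxon_p"] = float(p)
        except ValueError:  # all-zero differences
            out.attrs["wilcoxon_p"] = 1.0
    return out


def gene_hits(result: DepletionResult, construct_to_gene: Mapping[str, str],
              labels: Optional[Mapping[str, str]] = None,
              stringency_quantiles: Sequence[int] = (10, 20, 30, 40, 50),
              min_constructs: int = 2) -> pd.DataFrame:
    """Gene hit calls and TPR/FPR across depletion stringencies.

    At stringency q, the q% most-depleted constructs (lowest mean LFC) are
    flagged; a gene is a hit when >= ``min_constructs`` of its constructs
    are flagged. With EG/NEG labels, TPR is the hit fraction among essential
    genes and FPR among non-essential ones; unlabeled genes are still
    called but do not enter the rates.
    """
    lfc = result.mean_lfc.rename("lfc").rename_axis("construct").reset_index()
    lfc["gene"] = lfc["construct"].map(construct_to_gene)
    lfc = lfc.dropna(subset=["gene"])
    rows = []
    for q in stringency_quantiles:
        cutoff = np.percentile(lfc["lfc"], q)
        flagged = lfc[lfc["lfc"] <= cutoff]
        hit_counts = flagged.groupby("gene")["construct"].size()
        for gene, n_total in lfc.groupby("gene")["construct"].size().items():
            n_hit = int(hit_counts.get(gene, 0))
            rows.append({
                "stringency_pct": q, "gene": gene,
                "n_constructs": int(n_total), "n_depleted": n_hit,
                "hit": n_hit >= min_constructs,
                "label": labels.get(gene, "") if labels else "",
            })
    table = pd.DataFrame(rows)
    if labels:
        rates = []
        for q, sub in table.groupby("stringency_pct"):
            eg = sub[sub["label"] == "EG"]
            neg = sub[sub["label"] == "NEG"]
            rates.append({
                "stringency_pct": q,
                "tpr": float(eg["hit"].mean()) if len(eg) else np.nan,
                "fpr": float(neg["hit"].mean()) if len(neg) else np.nan,
            })
        table.attrs["rates"] = pd.DataFrame(rates)
    return table
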