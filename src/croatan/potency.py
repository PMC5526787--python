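"""Stringency-laddered random-forest potency scoring.

Two ensembles are trained, one per efficacy data source (a FACS-depletion
"doench-like" table and a mutation-rate "chari-like" table). Each ensemble is
a ladder of ten random forests sharing features and labels but trained with
incrementally increasing penalties for false-positive calls (calling a weak
guide potent). A target's per-ensemble score is the highest rung whose forest
calls it potent; the combined score is the minimum over the two ensembles, so
a guide must clear a stringency level in BOTH data sources to hold it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigError, TrainingError, ValidationError

DEFAULT_PENALTIES = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0)

_BASES = "ACGT"
ALL_3MERS = ["".join(p) for p in itertools.product(_BASES, repeat=3)]
_KMER_INDEX = {k: i for i, k in enumerate(ALL_3MERS)}
N_POSITIONS = 28
FEATURE_CODEC_VERSION = "positional-3mer-v1"


def featurize_3mers(context30: str) -> list[str]:
    """Decompose a 30-nt context into its 28 overlapping positional 3-mers."""
    s = context30.upper()
    if len(s) != 30:
        raise ValidationError(f"context must be 30 nt, got {len(s)}")
    if set(s) - set(_BASES):
        raise ValidationError(f"non-ACGT base in context: {s}")
    return [s[i:i + 3] for i in range(N_POSITIONS)]


def encode_contexts(contexts, mode: str = "positional") -> np.ndarray:
    """One-hot matrix for a list of 30-nt contexts.

    positional: 28 positions x 64 3-mer identities (the default codec).
    bag: 64 counts of 3-mer occurrences, position-free (comparison mode).
    """
    contexts = list(contexts)
    if mode == "positional":
        X = np.zeros((len(contexts), N_POSITIONS * 64), dtype=np.float32)
        for r, ctx in enumerate(contexts):
            for i, kmer in enumerate(featurize_3mers(ctx)):
                X[r, i * 64 + _KMER_INDEX[kmer]] = 1.0
    elif mode == "bag":
        X = np.zeros((len(contexts), 64), dtype=np.float32)
        for r, ctx in enumerate(contexts):
            for kmer in featurize_3mers(ctx):
                X[r, _KMER_INDEX[kmer]] += 1.0
    else:
        raise ConfigError(f"unknown feature mode {mode!r}")
    return X


def within_gene_percentiles(df: pd.DataFrame, value_col: str = "efficacy",
                            per_gene: bool = True) -> pd.Series:
    """Midpoint percentile rank of ``value_col``, by gene (or globally)."""
    def pct(x: pd.Series) -> pd.Series:
        r = x.rank(method="average")
        return (r - 0.5) / len(x) * 100.0

    if per_gene:
        return df.groupby("gene_id", group_keys=False)[value_col].apply(pct)
    return pct(df[value_col])


def label_records(records: pd.DataFrame, per_gene: bool = True,
                  min_guides: int = 3):
    """Split efficacy records into potent / weak / discarded training sets.

    Guides at or above the 60th within-gene percentile are potent, at or
    below the 40th weak; the middle 20% is discarded. Genes with fewer than
    ``min_guides`` guides are dropped with a warning.
    """
    df = records.copy()
    sizes = df.groupby("gene_id")["context30"].transform("size")
    small = df.loc[sizes < min_guides, "gene_id"].unique()
    if len(small):
        warnings.warn(f"excluding {len(small)} gene(s) with < {min_guides} guides")
        df = df[sizes >= min_guides].copy()
    if "efficacy_percentile" not in df.columns or df["efficacy_percentile"].isna().any():
        df["efficacy_percentile"] = within_gene_percentiles(df, per_gene=per_gene)
    bad = ~df["efficacy_percentile"].between(0, 100)
    if bad.any():
        raise ValidationError("efficacy percentiles outside [0,100]")
    potent = df[df["efficacy_percentile"] >= 60]
    weak = df[df["efficacy_percentile"] <= 40]
    discarded = df[(df["efficacy_percentile"] > 40) & (df["efficacy_percentile"] < 60)]
    return potent, weak, discarded


@dataclass
class EnsembleConfig:
    penalties: tuple = DEFAULT_PENALTIES
    trees_per_forest: int = 1000
    rng_seed: int = 17
    feature_mode: str = "positional"
    per_gene_percentiles: bool = True

    def validate(self):
        if len(self.penalties) != 10:
            raise ConfigError("penalty ladder must have exactly 10 rungs")
        if any(b <= a for a, b in zip(self.penalties, self.penalties[1:])):
            raise ConfigError("penalty ladder must be strictly increasing")


@dataclass
class StringencyEnsemble:
    dataset_tag: str
    forests: list = field(default_factory=list)
    penalties: tuple = DEFAULT_PENALTIES
    trees_per_forest: int = 1000
    feature_codec_version: str = FEATURE_CODEC_VERSION
    feature_mode: str = "positional"
    rng_seed: int = 17

    def score(self, context30: str) -> int:
        return ensemble_score(self, context30)

    def score_many(self, contexts) -> np.ndarray:
        X = encode_contexts(contexts, mode=self.feature_mode)
        calls = np.stack([f.predict(X) for f in self.forests], axis=1)
        idx = np.arange(1, len(self.forests) + 1)
        return (calls * idx).max(axis=1).astype(int)


def train_ensemble(records: pd.DataFrame, dataset_tag: str,
                   config: EnsembleConfig | None = None) -> StringencyEnsemble:
    """Train the 10-forest stringency ladder on labelled efficacy records.

    The rung-k forest is trained with class weights making a false positive
    (weak called potent) cost ``penalties[k-1]`` relative to a unit-cost
    false negative. All other hyperparameters are scikit-learn defaults.
    """
    config = config or EnsembleConfig()
    config.validate()
    potent, weak, _ = label_records(records, per_gene=config.per_gene_percentiles)
    if len(potent) == 0 or len(weak) == 0:
        raise TrainingError("need both potent and weak guides to train")
    contexts = pd.concat([potent["context30"], weak["context30"]])
    y = np.r_[np.ones(len(potent), dtype=int), np.zeros(len(weak), dtype=int)]
    X = encode_contexts(contexts, mode=config.feature_mode)
    forests = []
    for k, penalty in enumerate(config.penalties, start=1):
        rf = RandomForestClassifier(
            n_estimators=config.trees_per_forest,
            class_weight={0: float(penalty), 1: 1.0},
            oob_score=True,
            bootstrap=True,
            random_state=config.rng_seed + k,
            n_jobs=1,
        )
        rf.fit(X, y)
        forests.append(rf)
    return StringencyEnsemble(
        dataset_tag=dataset_tag, forests=forests, penalties=tuple(config.penalties),
        trees_per_forest=config.trees_per_forest, feature_mode=config.feature_mode,
        rng_seed=config.rng_seed,
    )


def ensemble_score(ensemble: StringencyEnsemble, context30: str) -> int:
    """Highest 1-based rung whose forest calls the target potent; 0 if none."""
    X = encode_contexts([context30], mode=ensemble.feature_mode)
    score = 0
    for k, rf in enumerate(ensemble.forests, start=1):
        if rf.predict(X)[0] == 1:
            score = k
    return score


def combined_forest_score(doench_score: int, chari_score: int) -> int:
    """Highest stringency level passed in BOTH random-forest sets."""
    for s in (doench_score, chari_score):
        if not 0 <= s <= 10:
            raise ValidationError(f"forest score {s} outside 0-10")
    return min(doench_score, chari_score)


def oob_percentile_report(ensemble: StringencyEnsemble,
                          records: pd.DataFrame) -> pd.DataFrame:
    """Out-of-bag ladder scores vs. efficacy percentiles for training records.

    Each record's OOB call on rung k uses only the trees that did not see it
    in their bootstrap sample. Returns one row per labelled training guide
    plus Spearman rho/p in ``DataFrame.attrs``.
    """
    if not all(getattr(rf, "bootstrap", False) and hasattr(rf, "oob_decision_function_")
               for rf in ensemble.forests):
        raise TrainingError("out-of-bag report requires bagging-enabled forests")
    if len(records) < 2:
        raise ValidationError("need >= 2 records for within-gene percentiles")
    potent, weak, _ = label_records(records)
    df = pd.concat([potent, weak]).reset_index(drop=True)
    scores = np.zeros(len(df), dtype=int)
    for k, rf in enumerate(ensemble.forests, start=1):
        oob = rf.oob_decision_function_
        call = np.zeros(len(df), dtype=bool)
        ok = ~np.isnan(oob[:, 0])
        call[ok] = oob[ok, list(rf.classes_).index(1)] > 0.5
        scores[call] = k
    out = pd.DataFrame({
        "context30": df["context30"].values,
        "gene_id": df["gene_id"].values,
        "oob_score": scores,
        "efficacy_percentile": df["efficacy_percentile"].values,
    })
    rho, p = stats.spearmanr(out["oob_score"], out["efficacy_percentile"])
    out.attrs["spearman_rho"] = float(rho)
    out.attrs["spearman_p"] = float(p)
    return out


def save_ensembles(path, ensembles: dict[str, StringencyEnsemble]):
    """Serialize a bundle of trained ensembles with a manifest."""
    bundle = {
        "manifest": {
            tag: {
                "penalties": list(e.penalties),
                "rng_seed": e.rng_seed,
                "trees_per_forest": e.trees_per_forest,
                "feature_codec_version": e.feature_codec_version,
                "feature_mode": e.feature_mode,
            }
            for tag, e in ensembles.items()
        },
        "ensembles": ensembles,
    }
    joblib.dump(bundle, path)


def load_ensembles(path) -> dict[str, StringencyEnsemble]:
    return joblib.load(path)["ensembles"]
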