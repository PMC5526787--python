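"""Microhomology enumeration and frameshift-likelihood prediction.

Cas9 blunt double-strand breaks are partly resolved by microhomology-guided
end joining: a short exact repeat with one copy on each side of the break
anneals, deleting the intervening segment plus one repeat copy. The relative
likelihood of each such resolution is modelled linearly from the repeat's
length, GC fraction and distance to the break; the frameshift-mutation (FSM)
likelihood of a target is the predicted-likelihood mass on resolutions whose
deletion length is not a multiple of 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, ValidationError

PREDICTORS = ("length", "gc_fraction", "distance")


@dataclass(frozen=True)
class MicrohomologyPair:
    homology_seq: str
    length: int
    gc_fraction: float
    dist_upstream: int
    dist_downstream: int

    @property
    def deletion_length(self) -> int:
        return self.dist_upstream + self.dist_downstream + self.length

    @property
    def is_frameshift(self) -> bool:
        return self.deletion_length % 3 != 0


def _gc(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq) if seq else 0.0


def enumerate_microhomologies(context_seq: str, cut_index: int,
                              min_len: int = 2, window: int = 30
                              ) -> list[MicrohomologyPair]:
    """All maximal exact repeats flanking the cut within ``window`` nt.

    The upstream copy must end at or before the cut boundary, the downstream
    copy begin at or after it, and both copies must lie entirely inside the
    search window. Sub-repeats of a longer repeat at the same locus pair are
    suppressed (only maximal extensions are reported).
    """
    s = context_seq.upper()
    n = len(s)
    if not 0 <= cut_index <= n:
        raise ValidationError("cut_index outside context sequence")
    lo = max(0, cut_index - window)
    hi = min(n, cut_index + window)
    pairs: list[MicrohomologyPair] = []
    for u in range(lo, cut_index):          # upstream copy start
        for d in range(cut_index, hi):      # downstream copy start
            # maximality to the left: previous bases must differ (or be out of range)
            if u > lo and d > cut_index and s[u - 1] == s[d - 1]:
                continue
            L = 0
            max_len = min(cut_index - u, hi - d)
            while L < max_len and s[u + L] == s[d + L]:
                L += 1
            if L < min_len:
                continue
            homology = s[u:u + L]
            pairs.append(MicrohomologyPair(
                homology_seq=homology,
                length=L,
                gc_fraction=_gc(homology),
                dist_upstream=cut_index - (u + L),
                dist_downstream=d - cut_index,
            ))
    pairs.sort(key=lambda p: (p.dist_upstream + p.dist_downstream, -p.length,
                              p.homology_seq))
    return pairs


@dataclass
class RepairModel:
    intercept: float
    coefficients: dict[str, float]
    fit_diagnostics: dict = field(default_factory=dict)
    hej_cutoff: Optional[float] = None
    distance_mode: str = "sum"  # or "min"

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "fit_diagnostics": self.fit_diagnostics,
                "hej_cutoff": self.hej_cutoff,
                "distance_mode": self.distance_mode,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RepairModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def fit_repair_model(resolution_table: pd.DataFrame,
                     distance_mode: str = "sum") -> RepairModel:
    """OLS fit of observed resolution frequency on (length, GC, distance).

    The table needs columns length, gc_fraction, distance, frequency and at
    least 10 rows. A rank-deficient design raises :class:`FitError` naming
    the collinear predictor(s).
    """
    required = set(PREDICTORS) | {"frequency"}
    missing = required - set(resolution_table.columns)
    if missing:
        raise ValidationError(f"resolution table missing columns {sorted(missing)}")
    if len(resolution_table) < 10:
        raise ValidationError("need >= 10 resolution observations")
    X = resolution_table[list(PREDICTORS)].astype(float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.values) < Xc.shape[1]:
        degenerate = [c for c in PREDICTORS if X[c].nunique() == 1]
        raise FitError(
            "rank-deficient design; collinear/constant predictor(s): "
            f"{degenerate or list(PREDICTORS)}"
        )
    res = sm.OLS(resolution_table["frequency"].astype(float), Xc).fit()
    return RepairModel(
        intercept=float(res.params["const"]),
        coefficients={c: float(res.params[c]) for c in PREDICTORS},
        fit_diagnostics={
            "r_squared": float(res.rsquared),
            "resid_std": float(np.std(res.resid, ddof=Xc.shape[1])),
            "nobs": int(res.nobs),
        },
        distance_mode=distance_mode,
    )


def predict_resolution(model: RepairModel, pair: MicrohomologyPair) -> float:
    """Predicted (non-negative) resolution likelihood for one repeat pair."""
    if model.distance_mode == "sum":
        dist = pair.dist_upstream + pair.dist_downstream
    elif model.distance_mode == "min":
        dist = min(pair.dist_upstream, pair.dist_downstream)
    else:
        raise ValidationError(f"unknown distance mode {model.distance_mode!r}")
    raw = (model.intercept
           + model.coefficients["length"] * pair.length
           + model.coefficients["gc_fraction"] * pair.gc_fraction
           + model.coefficients["distance"] * dist)
    return max(0.0, raw)


@dataclass
class FsmAssessment:
    fsm_likelihood: Optional[float]
    hej_sum: float
    passes_fsm_test: bool


def hej_sum(model: RepairModel, context_seq: str, cut_index: int,
            min_len: int = 2, window: int = 30) -> float:
    pairs = enumerate_microhomologies(context_seq, cut_index, min_len, window)
    return float(sum(predict_resolution(model, p) for p in pairs))


def assess_fsm(model: RepairModel, context_seq: str, cut_index: int,
               fsm_threshold: float = 0.66, min_len: int = 2,
               window: int = 30) -> FsmAssessment:
    """FSM likelihood and threshold test for one cut site.

    The FSM likelihood is the fraction of total predicted resolution score
    carried by deletions whose length is not divisible by 3. The test passes
    only if that fraction strictly exceeds ``fsm_threshold`` AND the
    unnormalized likelihood sum clears the model's lower-limit HEJ cutoff
    (homology-guided repair must be plausible at all).
    """
    pairs = enumerate_microhomologies(context_seq, cut_index, min_len, window)
    scores = np.array([predict_resolution(model, p) for p in pairs])
    total = float(scores.sum())
    if total == 0.0:
        return FsmAssessment(fsm_likelihood=None, hej_sum=0.0,
                             passes_fsm_test=False)
    fsm_mass = float(scores[[p.is_frameshift for p in pairs]].sum())
    fsm_like = fsm_mass / total
    cutoff_ok = model.hej_cutoff is None or total >= model.hej_cutoff
    return FsmAssessment(
        fsm_likelihood=fsm_like,
        hej_sum=total,
        passes_fsm_test=(fsm_like > fsm_threshold) and cutoff_ok,
    )


def compute_hej_cutoff(model: RepairModel, background_contexts: Sequence[tuple[str, int]],
                       min_len: int = 2, window: int = 30) -> float:
    """Median HEJ likelihood sum over background (context, cut_index) sites.

    The intended background is coding-sequence Cas9 cut sites; the median is
    stored on the model as its lower-limit cutoff.
    """
    if not background_contexts:
        raise ValidationError("empty background for HEJ cutoff")
    sums = [hej_sum(model, ctx, cut, min_len, window)
            for ctx, cut in background_contexts]
    cutoff = float(np.median(sums))
    model.hej_cutoff = cutoff
    return cutoff
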