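"""Cut-site conservation scoring from per-residue deleteriousness profiles.

Profiles follow the PROVEAN convention (more negative = substitution more
deleterious = residue more conserved). The score of a cut is the mean
absolute profile value over a small amino-acid window around the codon the
cut falls in; a guide passes the conservation test when its score strictly
exceeds the median score of a background collection of coding cut sites.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError


def read_profiles(path) -> dict[str, np.ndarray]:
    """Read a TSV of (protein_id, residue_index, score) into per-protein arrays."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "residue_index", "score"}
    if missing := required - set(df.columns):
        raise ValidationError(f"profile TSV missing columns {sorted(missing)}")
    profiles: dict[str, np.ndarray] = {}
    for pid, sub in df.groupby("protein_id"):
        sub = sub.sort_values("residue_index")
        idx = sub["residue_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValidationError(f"profile {pid}: residue indices not 0..n-1")
        scores = sub["score"].to_numpy(dtype=float)
        if not np.isfinite(scores).all():
            raise ValidationError(f"profile {pid}: non-finite score")
        profiles[pid] = scores
    return profiles


def conservation_score(profile: np.ndarray, cut_aa_index: Optional[int],
                       flank_aa: int = 2) -> Optional[float]:
    """Windowed mean |deleteriousness| around the cut codon.

    Returns None (undefined; the guide fails the conservation test) when the
    cut is outside the coding sequence. The window is truncated at protein
    ends.
    """
    scores = np.asarray(profile, dtype=float)
    if cut_aa_index is None:
        return None
    if not 0 <= cut_aa_index < len(scores):
        return None
    lo = max(0, cut_aa_index - flank_aa)
    hi = min(len(scores), cut_aa_index + flank_aa + 1)
    return float(np.abs(scores[lo:hi]).mean())


def conservation_threshold(background_scores: Iterable[float]) -> float:
    """Median of background cut-site conservation scores (the pass cutoff)."""
    vals = np.asarray([s for s in background_scores if s is not None], dtype=float)
    if vals.size == 0:
        raise ValidationError("empty conservation background")
    return float(np.median(vals))


def passes_conservation(score: Optional[float], threshold: float) -> bool:
    """Strict-inequality test; undefined (non-coding) scores fail."""
    return score is not None and score > threshold


def score_sites(profiles: Mapping[str, np.ndarray], site_protein: Mapping[str, str],
                site_aa_index: Mapping[str, Optional[int]],
                flank_aa: int = 2) -> dict[str, Optional[float]]:
    """Conservation scores for a batch of sites keyed by site id."""
    out: dict[str, Optional[float]] = {}
    for site_id, pid in site_protein.items():
        prof = profiles.get(pid)
        aa = site_aa_index.get(site_id)
        out[site_id] = None if prof is None else conservation_score(prof, aa, flank_aa)
    return out
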