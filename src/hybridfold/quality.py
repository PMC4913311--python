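"""Model-quality utilities: decoy z-scores, quality bands, score smoothing.

The global quality of a sequence–structure model is summarised as a z-score
of its energy-like score against scores of decoys obtained by randomly
permuting the amino-acid positions (50 decoys by default); more negative is
better.  The z-score maps onto four reporting bands: poor (z > -1), medium
(-2 <= z <= -1), reliable (-4 <= z < -2) and native-like (z < -4); exact
boundaries are assigned to the better band.  Per-residue scores are
smoothed with a centred 15-residue moving mean (truncated at the chain
ends) before display against the pseudo-energy threshold of 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QUALITY_CATEGORIES",
    "DEFAULT_N_DECOYS",
    "SMOOTHING_WINDOW",
    "QualityReport",
    "permute_sequence_decoy",
    "zscore_from_decoys",
    "classify_quality",
    "smooth_scores",
    "quality_report",
]

QUALITY_CATEGORIES = ("poor", "medium", "reliable", "native-like")
DEFAULT_N_DECOYS = 50
SMOOTHING_WINDOW = 15


@dataclass
class QualityReport:
    global_score: float
    decoy_scores: list[float]
    zscore: float
    category: str
    smoothed_residue_scores: np.ndarray
    threshold: float = 0.0  # pseudo-energy threshold marking poor local regions


def permute_sequence_decoy(sequence: str, seed: int) -> str:
    """A uniformly random permutation of the residue labels; seed-deterministic."""
    rng = np.random.default_rng(seed)
    chars = list(sequence)
    rng.shuffle(chars)
    return "".join(chars)


def zscore_from_decoys(model_score: float, decoy_scores) -> float:
    """z = (model - mean(decoys)) / sd(decoys), sample (n-1) standard deviation."""
    decoys = np.asarray(list(decoy_scores), dtype=float)
    if decoys.size < 2:
        raise ValueError("need at least 2 decoy scores")
    sd = decoys.std(ddof=1)
    if sd == 0:
        raise ValueError("decoy scores have zero variance")
    return float((model_score - decoys.mean()) / sd)


def classify_quality(z: float) -> str:
    """Map a decoy z-score to its reporting band (boundaries to the better band)."""
    if z <= -4:
        return "native-like"
    if z <= -2:
        return "reliable"
    if z <= -1:
        return "medium"
    return "poor"


def smooth_scores(values, window: int = SMOOTHING_WINDOW):
    """Centred moving mean with the window truncated at the ends.

    Output length equals input length; a window spanning the whole vector
    reproduces the global mean everywhere.
    """
    v = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(v)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = v[lo:hi].mean()
    return out


def quality_report(
    model_score: float,
    residue_scores,
    decoy_scores,
    window: int = SMOOTHING_WINDOW,
) -> QualityReport:
    """Assemble the global/local quality summary from precomputed scores."""
    z = zscore_from_decoys(model_score, decoy_scores)
    return QualityReport(
        global_score=float(model_score),
        decoy_scores=[float(x) for x in decoy_scores],
        zscore=z,
        category=classify_quality(z),
        smoothed_residue_scores=smooth_scores(residue_scores, window=window),
    )
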