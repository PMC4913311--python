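"""Profile–profile alignment: column scoring, affine-gap DP, correlation score.

The match score of two hybrid-profile columns is a sum of per-component
co-emission log-odds (amino acids, Protein Blocks, solvent-accessibility
classes), each floored at ``s_min`` and weighted:

    S(q, t) = sum_c  w_c * max(s_min, log2( sum_a q_c(a) t_c(a) / f_c(a) ))

Gap penalties are position specific: a column observed to be often gapped in
the underlying alignment is cheap to gap again.  A gap opposite profile
position i costs ``gap_open * (1 - g_i)`` to open and ``gap_ext * (1 - g_i)``
to extend, charged at the position being consumed opposite the gap.

Three alignment modes are supported:

``global``
    both profiles consumed end to end, terminal gaps charged;
``local``
    Smith–Waterman: best-scoring subalignment, never below zero;
``gloloc``
    the template is consumed end to end while the query's unaligned flanks
    are free — the mode of choice when templates are single domains.

After traceback a correlation bonus rewards clustering of well-scoring
columns: S_corr = sum_l S_l * sum_{j=1..min(d, L-l)} S_{l+j}, added to the
raw score with weight ``w_corr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .profiles import AA_BACKGROUND, PB_BACKGROUND, HybridProfile

__all__ = [
    "ScoringParams",
    "AlignmentResult",
    "column_score",
    "column_score_matrix",
    "gap_penalties",
    "correlation_score",
    "align",
    "alignment_stats",
]

MODES = ("gloloc", "local", "global")
_NEG = -np.inf


@dataclass
class ScoringParams:
    """Weights, backgrounds and gap model of the hybrid scoring system."""

    w_aa: float = 1.0
    w_pb: float = 1.0
    w_sa: float = 0.5
    s_min: float = -10.0  # bits, per-component score floor
    gap_open: float = 3.0  # bits
    gap_ext: float = 0.3  # bits
    corr_window: int = 4  # d, forward window of the correlation score
    w_corr: float = 0.1
    mode: str = "gloloc"
    aa_background: np.ndarray = field(default_factory=lambda: AA_BACKGROUND.copy())
    pb_background: np.ndarray = field(default_factory=lambda: PB_BACKGROUND.copy())
    sa_background: np.ndarray = field(default_factory=lambda: np.full(10, 0.1))

    def __post_init__(self):
        if min(self.w_aa, self.w_pb, self.w_sa) < 0:
            raise ValueError("component weights must be non-negative")
        if not self.gap_open >= self.gap_ext >= 0:
            raise ValueError("need gap_open >= gap_ext >= 0")
        if self.corr_window < 0:
            raise ValueError("correlation window must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for name in ("aa_background", "pb_background", "sa_background"):
            bg = np.asarray(getattr(self, name), dtype=float)
            if (bg <= 0).any():
                raise ValueError(f"{name} must be strictly positive")
            setattr(self, name, bg)

    @classmethod
    def from_yaml(cls, path) -> "ScoringParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for k in ("aa_background", "pb_background", "sa_background"):
            data[k] = [float(x) for x in data[k]]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class AlignmentResult:
    """A scored query–template alignment.

    ``columns`` is a list of (query_index, template_index) pairs, 0-based,
    with ``None`` on the gapped side.  ``position_scores`` has one entry per
    alignment column (zero at gap columns).  Bounds are 1-based inclusive
    over matched columns; identity and coverage are percentages.
    """

    query_id: str
    template_id: str
    mode: str
    columns: list[tuple[int | None, int | None]]
    position_scores: np.ndarray
    score_raw: float
    score_corr: float
    score_total: float
    query_start: int
    query_end: int
    template_start: int
    template_end: int
    identity: float
    coverage: float

    @property
    def n_matched(self) -> int:
        return sum(1 for q, t in self.columns if q is not None and t is not None)


def _component_scores(q, t, bg, w, s_min):
    with np.errstate(divide="ignore"):
        co = np.log2((q / bg[None, :]) @ t.T)
    return w * np.maximum(co, s_min)


def column_score_matrix(
    query: HybridProfile, template: HybridProfile, params: ScoringParams
) -> np.ndarray:
    """All-vs-all hybrid column scores in bits, shape (len(query), len(template))."""
    s = _component_scores(query.aa, template.aa, params.aa_background, params.w_aa, params.s_min)
    s += _component_scores(query.pb, template.pb, params.pb_background, params.w_pb, params.s_min)
    s += _component_scores(query.sa, template.sa, params.sa_background, params.w_sa, params.s_min)
    return s


def column_score(
    query: HybridProfile, template: HybridProfile, i: int, j: int, params: ScoringParams
) -> float:
    """Hybrid match score (bits) of query column i vs template column j (0-based)."""
    qi = HybridProfile(
        identifier="c", sequence="X", aa=query.aa[i : i + 1], gap=query.gap[i : i + 1],
        pb=query.pb[i : i + 1], sa=query.sa[i : i + 1],
    )
    tj = HybridProfile(
        identifier="c", sequence="X", aa=template.aa[j : j + 1], gap=template.gap[j : j + 1],
        pb=template.pb[j : j + 1], sa=template.sa[j : j + 1],
    )
    return float(column_score_matrix(qi, tj, params)[0, 0])


def gap_penalties(profile: HybridProfile, params: ScoringParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-position (open, extend) penalties: gamma * (1 - gap probability)."""
    keep = 1.0 - np.asarray(profile.gap, dtype=float)
    return params.gap_open * keep, params.gap_ext * keep


def correlation_score(position_scores, d: int) -> float:
    """Forward-window pairwise-product correlation score.

    S_corr = sum_l S_l * sum_{j=1..min(d, L-l)} S_{l+j}; zero when d = 0 or
    fewer than two positions.
    """
    s = np.asarray(position_scores, dtype=float)
    if d < 0:
        raise ValueError("window must be >= 0")
    total = 0.0
    for j in range(1, min(d, len(s) - 1) + 1):
        total += float(s[:-j] @ s[j:])
    return total


def alignment_stats(
    columns: list[tuple[int | None, int | None]],
    query_seq: str,
    template_seq: str,
) -> tuple[float, float, tuple[int, int, int, int]]:
    """(identity %, query coverage %, 1-based bounds) of an alignment.

    Identity is over matched (gap-free) columns; coverage counts matched
    query positions against the full query length.  An alignment with no
    matched columns reports zeros.
    """
    matched = [(q, t) for q, t in columns if q is not None and t is not None]
    if not matched:
        return 0.0, 0.0, (0, 0, 0, 0)
    ident = sum(1 for q, t in matched if query_seq[q] == template_seq[t])
    identity = 100.0 * ident / len(matched)
    coverage = 100.0 * len(matched) / len(query_seq)
    bounds = (
        matched[0][0] + 1,
        matched[-1][0] + 1,
        matched[0][1] + 1,
        matched[-1][1] + 1,
    )
    return identity, coverage, bounds


# traceback pointer codes
_FROM_M, _FROM_Y, _FROM_X, _FROM_START = 0, 1, 2, 3


def align(query: HybridProfile, template: HybridProfile, params: ScoringParams) -> AlignmentResult:
    """Optimal profile–profile alignment under the selected mode.

    Three-state (match / template-gap / query-gap) affine dynamic
    programming with position-specific penalties.  Traceback ties prefer
    match over delete (gap in query) over insert (gap in template), giving a
    deterministic alignment.
    """
    n, m = len(query), len(template)
    if n == 0 or m == 0:
        raise ValueError("empty profile")
    mode = params.mode
    S = column_score_matrix(query, template, params)
    qopen, qext = gap_penalties(query, params)  # charged when query pos sits opposite a gap
    topen, text = gap_penalties(template, params)  # charged when template pos is skipped

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in template: consumes query i
    Y = np.full((n + 1, m + 1), _NEG)  # gap in query: consumes template j
    ptr_m = np.full((n + 1, m + 1), -1, dtype=np.int8)
    ptr_x = np.full((n + 1, m + 1), -1, dtype=np.int8)
    ptr_y = np.full((n + 1, m + 1), -1, dtype=np.int8)

    if mode == "global":
        M[0, 0] = 0.0
        ptr_m[0, 0] = _FROM_START
        for i in range(1, n + 1):
            X[i, 0] = M[0, 0] - qopen[0] if i == 1 else X[i - 1, 0] - qext[i - 1]
            ptr_x[i, 0] = _FROM_M if i == 1 else _FROM_X
        for j in range(1, m + 1):
            Y[0, j] = M[0, 0] - topen[0] if j == 1 else Y[0, j - 1] - text[j - 1]
            ptr_y[0, j] = _FROM_M if j == 1 else _FROM_Y
    elif mode == "gloloc":
        # free start anywhere along the query, template column 0
        M[:, 0] = 0.0
        ptr_m[:, 0] = _FROM_START
        for j in range(1, m + 1):  # leading template deletions from the (0, 0) start
            Y[0, j] = M[0, 0] - topen[0] if j == 1 else Y[0, j - 1] - text[j - 1]
            ptr_y[0, j] = _FROM_M if j == 1 else _FROM_Y
    # local: no boundary states; fresh starts handled in the M recurrence

    local = mode == "local"
    for i in range(1, n + 1):
        Si = S[i - 1]
        for j in range(1, m + 1):
            # match state: preference M > Y > X (> fresh start) on ties
            best, code = M[i - 1, j - 1], _FROM_M
            if Y[i - 1, j - 1] > best:
                best, code = Y[i - 1, j - 1], _FROM_Y
            if X[i - 1, j - 1] > best:
                best, code = X[i - 1, j - 1], _FROM_X
            if local and 0.0 > best:
                best, code = 0.0, _FROM_START
            M[i, j] = Si[j - 1] + best
            ptr_m[i, j] = code

            # gap in template (insert): consume query position i
            best, code = M[i - 1, j] - qopen[i - 1], _FROM_M
            cand = Y[i - 1, j] - qopen[i - 1]
            if cand > best:
                best, code = cand, _FROM_Y
            cand = X[i - 1, j] - qext[i - 1]
            if cand > best:
                best, code = cand, _FROM_X
            X[i, j] = best
            ptr_x[i, j] = code

            # gap in query (delete): consume template position j
            best, code = M[i, j - 1] - topen[j - 1], _FROM_M
            cand = X[i, j - 1] - topen[j - 1]
            if cand > best:
                best, code = cand, _FROM_X
            cand = Y[i, j - 1] - text[j - 1]
            if cand > best:
                best, code = cand, _FROM_Y
            Y[i, j] = best
            ptr_y[i, j] = code

    # select the end cell/state per mode (preference M > Y > X on ties)
    if mode == "global":
        end_i, end_j = n, m
        end_state, best = "M", M[n, m]
        if Y[n, m] > best:
            end_state, best = "Y", Y[n, m]
        if X[n, m] > best:
            end_state, best = "X", X[n, m]
    elif mode == "gloloc":
        end_j = m
        end_i, end_state, best = 0, "M", M[0, m]
        for i in range(n + 1):
            for state, val in (("M", M[i, m]), ("Y", Y[i, m]), ("X", X[i, m])):
                if val > best:
                    end_i, end_state, best = i, state, val
    else:  # local
        end_i, end_j, end_state, best = 0, 0, "E", 0.0  # empty alignment
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if M[i, j] > best:
                    end_i, end_j, end_state, best = i, j, "M", M[i, j]

    score_raw = float(best)

    # traceback (start cells carry the _FROM_START pointer and stop the walk)
    decode = {_FROM_M: "M", _FROM_Y: "Y", _FROM_X: "X"}
    columns: list[tuple[int | None, int | None]] = []
    scores: list[float] = []
    i, j, state = end_i, end_j, end_state
    while state != "E":
        if state == "M":
            if i == 0 or j == 0:  # boundary start cell, nothing to emit
                break
            columns.append((i - 1, j - 1))
            scores.append(float(S[i - 1, j - 1]))
            code = ptr_m[i, j]
            i, j = i - 1, j - 1
            if code == _FROM_START:
                break
            state = decode[code]
        elif state == "X":
            columns.append((i - 1, None))
            scores.append(0.0)
            code = ptr_x[i, j]
            i -= 1
            state = decode[code]
        else:  # Y
            columns.append((None, j - 1))
            scores.append(0.0)
            code = ptr_y[i, j]
            j -= 1
            state = decode[code]
    columns.reverse()
    scores.reverse()

    pos_scores = np.array(scores, dtype=float)
    s_corr = correlation_score(pos_scores, params.corr_window)
    identity, coverage, bounds = alignment_stats(columns, query.sequence, template.sequence)
    return AlignmentResult(
        query_id=query.identifier,
        template_id=template.identifier,
        mode=mode,
        columns=columns,
        position_scores=pos_scores,
        score_raw=score_raw,
        score_corr=s_corr,
        score_total=score_raw + params.w_corr * s_corr,
        query_start=bounds[0],
        query_end=bounds[1],
        template_start=bounds[2],
        template_end=bounds[3],
        identity=identity,
        coverage=coverage,
    )
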