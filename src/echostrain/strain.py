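"""Endocardial length series, ED/ES detection and strain computation.

Global longitudinal strain (GLS) is the percent change of endocardial
contour length from end-diastole (maximal length) to end-systole
(minimal length); shortening is negative by clinical convention.

Three estimators are provided, mirroring the hybridisation experiment:

``dp``
    Selects an alternating ED/ES frame sequence by exact dynamic
    programming, maximising the accumulated length drop minus a switch
    penalty; globally optimal, no peak-prominence tuning, and applied to
    the raw (unsmoothed) length series.
``pairwise_extrema``
    Local maxima/minima from ``scipy.signal.find_peaks`` (prominence and
    distance must be tuned), each ED paired with the following ES,
    per-pair strains averaged.
``mean_length``
    The same extrema, but ED and ES lengths are averaged separately and
    a single strain is computed from the two means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .contours import ContourSequence, N_POINTS

__all__ = [
    "LengthSeries",
    "CyclePair",
    "StrainResult",
    "DPConfig",
    "contour_length",
    "length_series",
    "detect_ed_es_dp",
    "detect_ed_es_peaks",
    "pair_extrema",
    "strain_pairwise",
    "strain_mean_length",
    "strain_dp",
    "relative_difference",
    "average_gls",
]


@dataclass
class LengthSeries:
    """Per-frame endocardial contour length."""

    lengths: np.ndarray
    frame_rate: float | None = None
    unit: str = "px"

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 1 or len(self.lengths) == 0:
            raise ValueError("lengths must be a nonempty 1-D array")
        if np.any(self.lengths <= 0):
            raise ValueError("contour lengths must be positive")

    def __len__(self):
        return len(self.lengths)


@dataclass(frozen=True)
class CyclePair:
    """One cardiac cycle's keyframes (ED strictly before ES)."""

    ed_frame: int
    es_frame: int

    def __post_init__(self):
        if not self.ed_frame < self.es_frame:
            raise ValueError("ed_frame must precede es_frame")


@dataclass
class StrainResult:
    pairs: list
    per_cycle_strain: list
    gls: float
    algorithm: str
    params: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# lengths


def contour_length(points, spacing: float = 1.0) -> float:
    """Sum of the 48 consecutive segment lengths, times mm/px spacing."""
    pts = np.asarray(points, dtype=float)
    if pts.shape != (N_POINTS, 2):
        raise ValueError(f"expected ({N_POINTS}, 2) points, got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("contour points must be finite")
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * spacing)


def length_series(cs: ContourSequence, spacing: float = 1.0,
                  frame_rate: float | None = None) -> LengthSeries:
    """Per-frame contour length; deliberately unsmoothed."""
    lengths = [contour_length(p, spacing) for p in cs.points]
    return LengthSeries(np.asarray(lengths), frame_rate,
                        unit="mm" if spacing != 1.0 else "px")


# ----------------------------------------------------------------------
# dynamic-programming ED/ES detection


@dataclass
class DPConfig:
    """Parameters of the DP detector.

    switch_penalty: cost lambda charged per selected keyframe; ``None``
        resolves to 0.5 * median(|frame-to-frame length change|) * d_min,
        which scales with both measurement noise and series units.
    min_duration: minimum frame gap d_min between consecutive keyframes;
        ``None`` resolves to 0.15 s at the series frame rate (a lower
        bound on how fast a phase can be traversed), falling back to 3
        frames when the rate is unknown.
    """

    switch_penalty: float | None = None
    min_duration: int | None = None

    def resolve(self, ls: LengthSeries):
        d_min = self.min_duration
        if d_min is None:
            d_min = int(round(0.15 * ls.frame_rate)) if ls.frame_rate else 3
        d_min = max(1, d_min)
        lam = self.switch_penalty
        if lam is None:
            steps = np.abs(np.diff(ls.lengths))
            lam = 0.5 * float(np.median(steps)) * d_min if len(steps) else 0.0
        return lam, d_min


def detect_ed_es_dp(ls: LengthSeries, cfg: DPConfig | None = None) -> list:
    """Globally optimal ED/ES pairs by two-state dynamic programming.

    Selects an alternating sequence ED, ES, ED, ES, ... (consecutive
    keyframes at least d_min frames apart) maximising::

        sum over pairs (L[ED] - L[ES])  -  lambda * (number of keyframes)

    and returns the pairs of the best strictly-positive-score sequence
    (a constant series admits none).  Ties resolve to the earliest
    frame.  The optimum is exact: the score of a prefix ending in an ED
    (or ES) at frame t depends only on t, so a two-state recurrence with
    running prefix maxima explores every admissible labelling.
    """
    if cfg is None:
        cfg = DPConfig()
    lam, d_min = cfg.resolve(ls)
    L = ls.lengths
    n = len(L)
    neg = -np.inf
    dp_ed = np.full(n, neg)  # best score of a chain ending with ED at t
    dp_es = np.full(n, neg)  # ... ending with ES at t (complete chain)
    prev_ed = np.full(n, -1, dtype=int)  # ES index preceding an ED (-1: chain start)
    prev_es = np.full(n, -1, dtype=int)  # ED index preceding an ES
    best_ed_up_to = neg  # max dp_ed[s] for s <= t - d_min, earliest argmax
    best_ed_idx = -1
    best_es_up_to = neg
    best_es_idx = -1
    for t in range(n):
        s = t - d_min
        if s >= 0:
            if dp_ed[s] > best_ed_up_to:
                best_ed_up_to, best_ed_idx = dp_ed[s], s
            if dp_es[s] > best_es_up_to:
                best_es_up_to, best_es_idx = dp_es[s], s
        if best_es_up_to > 0.0:  # attach to a prior complete chain
            dp_ed[t] = L[t] - lam + best_es_up_to
            prev_ed[t] = best_es_idx
        else:
            dp_ed[t] = L[t] - lam
        if best_ed_up_to > neg:
            dp_es[t] = -L[t] - lam + best_ed_up_to
            prev_es[t] = best_ed_idx
    if not np.any(dp_es > 0.0):
        return []
    end = int(np.argmax(dp_es))  # np.argmax returns the earliest maximiser
    pairs = []
    t = end
    while t >= 0:
        ed = prev_es[t]
        pairs.append(CyclePair(int(ed), int(t)))
        t = prev_ed[ed]
    return pairs[::-1]


def detect_ed_es_peaks(ls: LengthSeries, prominence: float,
                       min_distance: int):
    """ED/ES candidates as prominence-filtered local maxima/minima."""
    if prominence <= 0 or min_distance <= 0:
        raise ValueError("prominence and min_distance must be positive")
    ed, _ = find_peaks(ls.lengths, prominence=prominence,
                       distance=min_distance)
    es, _ = find_peaks(-ls.lengths, prominence=prominence,
                       distance=min_distance)
    return list(ed), list(es)


def pair_extrema(ed_list, es_list) -> list:
    """Pair each ED with the first following ES (before the next ED)."""
    eds, ess = sorted(ed_list), sorted(es_list)
    pairs = []
    for i, ed in enumerate(eds):
        limit = eds[i + 1] if i + 1 < len(eds) else np.inf
        nxt = [s for s in ess if ed < s < limit]
        if nxt:  # an ED without an ES in its cycle contributes no pair
            pairs.append(CyclePair(int(ed), int(nxt[0])))
    return pairs


# ----------------------------------------------------------------------
# strain estimators


def _pair_strains(ls: LengthSeries, pairs) -> np.ndarray:
    led = ls.lengths[[p.ed_frame for p in pairs]]
    les = ls.lengths[[p.es_frame for p in pairs]]
    return 100.0 * (les - led) / led


def strain_pairwise(ls: LengthSeries, pairs,
                    algorithm: str = "pairwise_extrema") -> StrainResult:
    """Per-pair strain 100 (L_ES - L_ED)/L_ED, averaged across pairs."""
    if not pairs:
        raise ValueError("no ED/ES pairs: strain undefined")
    strains = _pair_strains(ls, pairs)
    return StrainResult(list(pairs), strains.tolist(),
                        float(strains.mean()), algorithm)


def strain_mean_length(ls: LengthSeries, ed_list, es_list) -> StrainResult:
    """Strain of the averaged ED length against the averaged ES length."""
    if not len(ed_list) or not len(es_list):
        raise ValueError("need at least one ED and one ES frame")
    led = float(np.mean(ls.lengths[list(ed_list)]))
    les = float(np.mean(ls.lengths[list(es_list)]))
    gls = 100.0 * (les - led) / led
    pairs = [CyclePair(int(e), int(s))
             for e, s in zip(sorted(ed_list), sorted(es_list)) if e < s]
    return StrainResult(pairs, [], gls, "mean_length")


def strain_dp(ls: LengthSeries, cfg: DPConfig | None = None) -> StrainResult:
    """DP detection followed by per-pair strain averaging (end to end)."""
    pairs = detect_ed_es_dp(ls, cfg)
    if not pairs:
        raise ValueError("no cardiac cycles detected")
    res = strain_pairwise(ls, pairs, algorithm="dp")
    lam, d_min = (cfg or DPConfig()).resolve(ls)
    res.params = {"switch_penalty": lam, "min_duration": d_min}
    return res


def relative_difference(model_gls: float, expert_gls: float) -> float:
    """(model - expert) / expert; undefined for a zero expert value."""
    if expert_gls == 0:
        raise ValueError("relative difference undefined for zero expert GLS")
    return (model_gls - expert_gls) / expert_gls


def average_gls(view_gls) -> float:
    """Mean GLS across apical views (A4C, A2C, A3C)."""
    vals = np.asarray(list(view_gls), dtype=float)
    if len(vals) == 0:
        raise ValueError("need at least one per-view GLS value")
    return float(vals.mean())
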