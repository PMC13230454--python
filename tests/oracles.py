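"""Independent oracles used by the test-suite.

Each function recomputes a quantity by a route unrelated to the
implementation it checks: exhaustive enumeration for the DP detector,
raw ANOVA mean squares for the ICC, pairwise concordance for the AUC,
and point-in-polygon tests for rasterisation.
"""

import numpy as np


def enumerate_best_chain(lengths, lam, d_min):
    """Exhaustive search over all admissible alternating ED/ES chains.

    A chain is ED1 < ES1 < ED2 < ES2 < ... with consecutive keyframes at
    least d_min frames apart; its score is sum(L[ED]-L[ES]) - 2*lam per
    pair.  Returns (best_score, best_pairs) with 0.0 / [] for the empty
    chain; the first-found optimum (lexicographically earliest chain) is
    kept on exact ties.
    """
    L = np.asarray(lengths, dtype=float)
    n = len(L)
    best = {"score": 0.0, "pairs": []}

    def extend(start, score, pairs):
        for ed in range(start, n):
            base = score + L[ed] - 2 * lam
            for es in range(ed + d_min, n):
                s2 = base - L[es]
                chain = pairs + [(ed, es)]
                if s2 > best["score"] + 1e-12:
                    best["score"], best["pairs"] = s2, chain
                extend(es + d_min, s2, chain)

    extend(0, 0.0, [])
    return best["score"], best["pairs"]


def icc_a1_mean_squares(x, y):
    """ICC(A,1) from the raw two-way ANOVA decomposition (k = 2 raters)."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def auc_concordance(scores, labels):
    """AUC as the fraction of concordant positive/negative score pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def rasterize_by_point_in_polygon(vertices, shape):
    """Boolean mask of pixel centres inside a polygon (shapely route)."""
    from shapely.geometry import Point, Polygon

    poly = Polygon([(float(x), float(y)) for x, y in vertices])
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if poly.contains(Point(c, r)):
                mask[r, c] = True
    return mask


def shifted_window_allowed_pairs(grid, window, shift):
    """Brute-force legality of token pairs under cyclic-shift attention.

    After rolling the grid by -shift, tokens sharing a window may
    interact iff on every axis they originate from the same side of the
    wrap boundary (pre-roll coordinate < shift means wrapped).
    """
    gt, gh, gw = grid
    coords = [(t, h, w) for t in range(gt) for h in range(gh)
              for w in range(gw)]

    def window_of(post):
        return tuple(p // ws for p, ws in zip(post, window))

    def wrapped(post):
        return tuple(((p + s) % g) < s
                     for p, s, g in zip(post, shift, grid))

    allowed = {}
    for i in coords:
        for j in coords:
            same_window = window_of(i) == window_of(j)
            same_side = wrapped(i) == wrapped(j)
            allowed[i, j] = same_window and same_side
    return allowed
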