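"""Independent brute-force oracles for the detector and vote rules.

Each oracle applies the stated rule of the corresponding operation with the
most naive possible code (pure-Python scans and nested loops, no shared
helpers with the package), so that agreement between the two routes checks
the optimised implementations rather than restating them.
"""

from __future__ import annotations

import itertools
import math


def oracle_macd(times, bsi_values, window, persistence):
    """Naive scan for the first persistent >=0 -> <0 crossing of the
    trailing moving average."""
    n = len(bsi_values)
    if n < window:
        return None
    ma, ma_t = [], []
    for i in range(window - 1, n):
        ma.append(sum(bsi_values[i - window + 1 : i + 1]) / window)
        ma_t.append(times[i])
    for i in range(1, len(ma)):
        if not (ma[i] < 0 <= ma[i - 1]):
            continue
        t0 = ma_t[i]
        if ma_t[-1] < t0 + persistence:
            continue
        ok = True
        for j in range(i + 1, len(ma)):
            if t0 < ma_t[j] <= t0 + persistence and not ma[j] < 0:
                ok = False
                break
        if ok:
            return int(math.floor(t0))
    return None


def oracle_vct(years, values, threshold, consecutive=2, prior_consecutive=3):
    """Naive state scan: last confirmed non-forest run, then the onset of
    the eventually-confirmed forest state."""
    obs = [(y, v) for y, v in zip(years, values) if not math.isnan(v)]
    if not obs:
        return None
    # last index ending a run of prior_consecutive years >= threshold
    nonforest_end = None
    for i in range(len(obs) - prior_consecutive + 1):
        if all(obs[i + k][1] >= threshold for k in range(prior_consecutive)):
            nonforest_end = i + prior_consecutive - 1
    if nonforest_end is None:
        return None
    confirmed = False
    for i in range(nonforest_end + 1, len(obs) - consecutive + 1):
        if all(obs[i + k][1] < threshold for k in range(consecutive)):
            confirmed = True
            break
    if not confirmed:
        return None
    for i in range(nonforest_end + 1, len(obs)):
        if obs[i][1] < threshold:
            return int(obs[i][0])
    return None


def _interp_sse(years, values, vertices):
    """SSE of piecewise-linear interpolation through vertex points,
    computed point by point in pure Python."""
    sse = 0.0
    for j, (x, y) in enumerate(zip(years, values)):
        for a, b in zip(vertices[:-1], vertices[1:]):
            if years[a] <= x <= years[b]:
                x0, x1 = years[a], years[b]
                y0, y1 = values[a], values[b]
                yy = y0 if x1 == x0 else y0 + (y1 - y0) * (x - x0) / (x1 - x0)
                sse += (y - yy) ** 2
                break
    return sse


def oracle_lt(
    years,
    values,
    max_segments=6,
    recovery_threshold=0.4,
    despike_threshold=0.9,
):
    """Naive re-application of the LT rule: despike, greedy bottom-up vertex
    removal with from-scratch SSE recomputation, then the longest
    qualifying recovery segment; establishment is the year after its base
    vertex."""
    pairs = [(y, v) for y, v in zip(years, values) if not math.isnan(v)]
    if len(pairs) < 6:
        return None
    ys = [p[0] for p in pairs]
    vs = [p[1] for p in pairs]
    # despike
    out = list(vs)
    for i in range(1, len(vs) - 1):
        left = vs[i] - vs[i - 1]
        right = vs[i + 1] - vs[i]
        peak = max(abs(left), abs(right))
        if peak and abs(vs[i + 1] - vs[i - 1]) < (1.0 - despike_threshold) * peak:
            out[i] = 0.5 * (vs[i - 1] + vs[i + 1])
    vs = out
    vertices = list(range(len(ys)))
    while len(vertices) - 1 > max_segments and len(vertices) > 2:
        base = _interp_sse(ys, vs, vertices)
        best_cost, best_k = None, None
        for k in range(1, len(vertices) - 1):
            trial = vertices[:k] + vertices[k + 1 :]
            cost = _interp_sse(ys, vs, trial) - base
            if best_cost is None or cost < best_cost - 1e-12:
                best_cost, best_k = cost, k
        vertices.pop(best_k)
    best_len, best_year = 0, None
    for a, b in zip(vertices[:-1], vertices[1:]):
        gain = vs[b] - vs[a]
        length = ys[b] - ys[a]
        if gain > recovery_threshold and length > best_len:
            best_len, best_year = length, ys[a] + 1
    return best_year


def oracle_vote(years, m, tolerance=1):
    """Brute-force the largest mutually-coherent subset over all subsets."""
    detected = [y for y in years if y]
    best = None  # (size, year)
    for r in range(1, len(detected) + 1):
        for combo in itertools.combinations(detected, r):
            s = sorted(combo)
            k = len(s)
            med = s[k // 2] if k % 2 else (s[k // 2 - 1] + s[k // 2]) / 2.0
            if all(abs(y - med) <= tolerance for y in s):
                year = int(math.floor(med))
                cand = (r, -year)
                if best is None or cand > best:
                    best = cand
    if best and best[0] >= m:
        return -best[1]
    return None
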