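"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by exhaustive scanning rather than by
the incremental algorithms in the package.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_clean(t, xy, T_v=15.0, T_d=5.0):
    """Re-scan-from-the-start cleaning: delete the first offending record,
    then re-examine the whole history, until no consecutive pair offends."""
    idx = list(range(len(t)))
    changed = True
    while changed:
        changed = False
        for k in range(len(idx) - 1):
            a, b = idx[k], idx[k + 1]
            dt = t[b] - t[a]
            dx = xy[b][0] - xy[a][0]
            dy = xy[b][1] - xy[a][1]
            dist = math.hypot(dx, dy)
            bad = False
            if dt == 0:
                bad = True  # duplicate or simultaneous reading elsewhere
            elif dist > T_d or dist / dt > T_v:
                bad = True
            if bad:
                del idx[k + 1]
                changed = True
                break
    return idx


def oracle_segment(t, T_s):
    """Brute-force splitter: cut after every gap exceeding T_s."""
    groups = [[0]] if len(t) else []
    for i in range(1, len(t)):
        if t[i] - t[i - 1] > T_s:
            groups.append([i])
        else:
            groups[-1].append(i)
    return [g for g in groups if len(g) >= 2]


def _collapse(seq):
    out = []
    for s in seq:
        if not out or out[-1] != s:
            out.append(s)
    return out


def _is_pacing_window(w):
    return len(w) >= 4 and len(set(w)) == 2 and all(w[i] == w[i % 2] for i in range(len(w)))


def _lapping_window_ok(w):
    for p in range(3, (len(w) - 1) // 2 + 1):
        if (
            len(set(w[:p])) == p
            and len(w) >= 2 * p + 1
            and all(w[i] == w[i % p] for i in range(len(w)))
        ):
            return True
    return False


def _turns(coords_list, min_deg):
    pts = np.asarray(coords_list, float)
    if len(pts) < 3:
        return 0
    v = np.diff(pts, axis=0)
    n = np.hypot(v[:, 0], v[:, 1])
    count = 0
    for k in range(len(v) - 1):
        if n[k] == 0 or n[k + 1] == 0:
            continue
        c = float(np.dot(v[k], v[k + 1]) / (n[k] * n[k + 1]))
        ang = math.degrees(math.acos(max(-1.0, min(1.0, c))))
        if ang >= min_deg - 1e-9:
            count += 1
    return count


def oracle_patterns(locations, coords=None):
    """Exhaustive-window pattern counting with the same greedy policy:
    left-to-right, longest window first, pacing preferred on ties."""
    seq = _collapse(list(locations))
    n = len(seq)
    consumed = [False] * n
    pacing = lapping = random_ = 0
    i = 0
    while i < n - 1:
        best_pacing = 0
        best_lapping = 0
        for j in range(i + 2, n + 1):  # all windows seq[i:j]
            w = seq[i:j]
            if _is_pacing_window(w):
                best_pacing = max(best_pacing, len(w) - 1)
            if _lapping_window_ok(w):
                best_lapping = max(best_lapping, len(w) - 1)
        if best_pacing >= 3 and best_pacing >= best_lapping:
            pacing += 1
            moves = best_pacing
        elif best_lapping > 0:
            lapping += 1
            moves = best_lapping
        else:
            i += 1
            continue
        for k in range(i, i + moves + 1):
            consumed[k] = True
        i += moves + 1
    if coords is not None:
        coords = dict(coords)
        runs, cur = [], []
        for k in range(n):
            if consumed[k]:
                if cur:
                    runs.append(cur)
                cur = []
            else:
                cur.append(seq[k])
        if cur:
            runs.append(cur)
        for run in runs:
            if len(set(run)) >= 5 and _turns([coords[x] for x in run], 45.0) >= 2:
                random_ += 1
    return {"pacing": pacing, "lapping": lapping, "random": random_}
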