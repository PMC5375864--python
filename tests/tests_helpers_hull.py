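"""Brute-force oracles shared between test modules."""

import numpy as np


def brute_force_hull(wl, vals):
    """O(n^3) upper-hull oracle: at each band, the maximum over all chords
    spanning it (and the point itself)."""
    n = len(wl)
    out = np.array(vals, dtype=float)
    for k in range(n):
        for i in range(0, k + 1):
            for j in range(k, n):
                if i == j:
                    continue
                t = (wl[k] - wl[i]) / (wl[j] - wl[i])
                out[k] = max(out[k], vals[i] + t * (vals[j] - vals[i]))
    return out


def brute_force_spearman(x, y):
    """Rank correlation computed from first principles with average ranks."""

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        sorted_v = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
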