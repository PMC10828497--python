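"""Independent brute-force reference implementations.

Deliberately literal double-loop versions of the nonlinear HRV metrics,
kept free of any code sharing with the package so they can serve as
oracles for equivalence tests on short series.
"""

from __future__ import annotations

import math

import numpy as np


def apen_brute(x, m: int, r: float) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            count = 0
            for b in templates:
                if max(abs(a - b)) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_brute(x, m: int, r: float) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)

    def matches(mm):
        templates = [x[i : i + mm] for i in range(n - m)]
        count = 0
        for i in range(len(templates)):
            for j in range(len(templates)):
                if i != j and max(abs(templates[i] - templates[j])) <= r:
                    count += 1
        return count

    b = matches(m)
    a = matches(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def dfa_brute(x, lo: int, hi: int) -> float:
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    sizes = list(range(lo, hi + 1))
    logs, logf = [], []
    for s in sizes:
        nb = len(y) // s
        sq = 0.0
        for b in range(nb):
            seg = y[b * s : (b + 1) * s]
            t = np.arange(s, dtype=float)
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            sq += float(np.sum(resid**2))
        logs.append(math.log(s))
        logf.append(0.5 * math.log(sq / (nb * s)))
    return float(np.polyfit(logs, logf, 1)[0])


def _embed_brute(x, m, tau):
    n = len(x) - (m - 1) * tau
    return [np.array([x[i + k * tau] for k in range(m)]) for i in range(n)]


def corr_sums_brute(x, radii, m: int, tau: int):
    vecs = _embed_brute(np.asarray(x, dtype=float), m, tau)
    nv = len(vecs)
    dists = []
    for i in range(nv):
        for j in range(i + 1, nv):
            dists.append(math.sqrt(float(np.sum((vecs[i] - vecs[j]) ** 2))))
    out = []
    for r in radii:
        out.append(sum(1 for d in dists if d <= r) / len(dists))
    return np.asarray(out)


def rpa_brute(x, m: int, tau: int, r: float, lmin: int = 2):
    """(REC %, DET %, Lmean, Lmax, ShanEn) by explicit matrix scan."""
    vecs = _embed_brute(np.asarray(x, dtype=float), m, tau)
    nv = len(vecs)
    rec_mat = np.zeros((nv, nv), dtype=bool)
    for i in range(nv):
        for j in range(nv):
            d = math.sqrt(float(np.sum((vecs[i] - vecs[j]) ** 2)))
            rec_mat[i, j] = d <= r
    n_recurrent = int(rec_mat.sum()) - nv
    rec = 100.0 * n_recurrent / (nv * nv - nv)
    if n_recurrent == 0:
        nan = float("nan")
        return rec, nan, nan, nan, nan
    lines = []
    for k in range(1, nv):
        run = 0
        for i in range(nv - k):
            if rec_mat[i, i + k]:
                run += 1
            else:
                if run:
                    lines.append(run)
                run = 0
        if run:
            lines.append(run)
    long_lines = [l for l in lines if l >= lmin]
    det = 100.0 * 2.0 * sum(long_lines) / n_recurrent
    if not long_lines:
        nan = float("nan")
        return rec, det, nan, nan, nan
    counts = {}
    for l in long_lines:
        counts[l] = counts.get(l, 0) + 1
    total = sum(counts.values())
    shanen = -sum((c / total) * math.log(c / total) for c in counts.values())
    return (
        rec,
        det,
        float(np.mean(long_lines)),
        float(max(long_lines)),
        float(shanen),
    )


def prsa_brute(rr):
    """(DC, DCmod, AC, ACmod) by explicit anchor scanning."""
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    out = []
    for direction in ("dec", "acc"):
        four, two = [], []
        for i in range(1, n):
            if direction == "dec":
                is_anchor = rr[i] > rr[i - 1]
            else:
                is_anchor = rr[i] < rr[i - 1]
            if not is_anchor:
                continue
            if abs(rr[i] - rr[i - 1]) > 0.05 * rr[i - 1]:
                continue
            two.append((rr[i] - rr[i - 1]) / 2.0)
            if 2 <= i <= n - 2:
                four.append((rr[i] + rr[i + 1] - rr[i - 1] - rr[i - 2]) / 4.0)
        out.append(float(np.mean(four)) if four else float("nan"))
        out.append(float(np.mean(two)) if two else float("nan"))
    return tuple(out)
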