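"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops directly from the published
definitions, deliberately sharing no code with the package implementation.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def _clusters(x, labels):
    return {q: x[np.asarray(labels) == q] for q in sorted(set(labels))}


def _centroid(pts):
    return pts.mean(axis=0)


def _dist(a, b):
    return math.dist(list(a), list(b))


def _all_pairs(x, labels):
    n = len(x)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = _dist(x[i], x[j])
            (within if labels[i] == labels[j] else between).append(d)
    return within, between


def ball_hall(x, labels):
    cl = _clusters(x, labels)
    vals = []
    for pts in cl.values():
        g = _centroid(pts)
        vals.append(sum(_dist(p, g) ** 2 for p in pts) / len(pts))
    return sum(vals) / len(vals)


def banfield_raftery(x, labels):
    total = 0.0
    for pts in _clusters(x, labels).values():
        g = _centroid(pts)
        tr = sum(_dist(p, g) ** 2 for p in pts)
        total += len(pts) * math.log(tr / len(pts))
    return total


def c_index(x, labels):
    within, between = _all_pairs(x, labels)
    alld = sorted(within + between)
    nw = len(within)
    s_w = sum(within)
    s_min = sum(alld[:nw])
    s_max = sum(alld[-nw:])
    return (s_w - s_min) / (s_max - s_min)


def calinski_harabasz(x, labels):
    n, k = len(x), len(set(labels))
    g = _centroid(x)
    cl = _clusters(x, labels)
    wgss = sum(
        sum(_dist(p, _centroid(pts)) ** 2 for p in pts) for pts in cl.values()
    )
    bgss = sum(len(pts) * _dist(_centroid(pts), g) ** 2 for pts in cl.values())
    return (bgss / (k - 1)) / (wgss / (n - k))


def davies_bouldin(x, labels):
    cl = _clusters(x, labels)
    ids = sorted(cl)
    delta = {
        q: sum(_dist(p, _centroid(cl[q])) for p in cl[q]) / len(cl[q]) for q in ids
    }
    total = 0.0
    for q in ids:
        total += max(
            (delta[q] + delta[r]) / _dist(_centroid(cl[q]), _centroid(cl[r]))
            for r in ids
            if r != q
        )
    return total / len(ids)


def dunn(x, labels):
    within, between = _all_pairs(x, labels)
    return min(between) / max(within)


def silhouette(x, labels):
    n = len(x)
    ids = sorted(set(labels))
    total = 0.0
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = sum(_dist(x[i], x[j]) for j in same) / len(same) if same else 0.0
        b = min(
            sum(_dist(x[i], x[j]) for j in range(n) if labels[j] == q)
            / sum(1 for j in range(n) if labels[j] == q)
            for q in ids
            if q != labels[i]
        )
        total += 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return total / n


def xie_beni(x, labels):
    cl = _clusters(x, labels)
    ids = sorted(cl)
    wgss = sum(
        sum(_dist(p, _centroid(pts)) ** 2 for p in pts) for pts in cl.values()
    )
    min_sep = min(
        _dist(_centroid(cl[q]), _centroid(cl[r])) ** 2
        for q, r in itertools.combinations(ids, 2)
    )
    return wgss / (len(x) * min_sep)


def mcclain_rao(x, labels):
    within, between = _all_pairs(x, labels)
    return (sum(within) / len(within)) / (sum(between) / len(between))


def ratkowsky_lance(x, labels):
    x = np.asarray(x, float)
    k = len(set(labels))
    g = x.mean(axis=0)
    cl = _clusters(x, labels)
    rs = []
    for j in range(x.shape[1]):
        tss = sum((x[i, j] - g[j]) ** 2 for i in range(len(x)))
        bgss = sum(
            len(pts) * (_centroid(pts)[j] - g[j]) ** 2 for pts in cl.values()
        )
        rs.append(math.sqrt(bgss / tss))
    return (sum(rs) / len(rs)) / math.sqrt(k)


def scott_symons(x, labels):
    total = 0.0
    for pts in _clusters(x, labels).values():
        nq = len(pts)
        g = _centroid(pts)
        w = np.zeros((pts.shape[1], pts.shape[1]))
        for p in pts:
            d = (p - g)[:, None]
            w += d @ d.T
        total += nq * math.log(np.linalg.det(w / nq))
    return total


def marriot(x, labels):
    k = len(set(labels))
    p = x.shape[1]
    w = np.zeros((p, p))
    for pts in _clusters(x, labels).values():
        g = _centroid(pts)
        for pt in pts:
            d = (pt - g)[:, None]
            w += d @ d.T
    return k**2 * np.linalg.det(w)


def trace_w(x, labels):
    return sum(
        sum(_dist(p, _centroid(pts)) ** 2 for p in pts)
        for pts in _clusters(x, labels).values()
    )


def trace_wib(x, labels):
    p = x.shape[1]
    g = _centroid(x)
    w = np.zeros((p, p))
    t = np.zeros((p, p))
    for pt in x:
        d = (pt - g)[:, None]
        t += d @ d.T
    for pts in _clusters(x, labels).values():
        gq = _centroid(pts)
        for pt in pts:
            d = (pt - gq)[:, None]
            w += d @ d.T
    b = t - w
    return float(np.trace(np.linalg.inv(w) @ b))


def det_ratio(x, labels):
    p = x.shape[1]
    g = _centroid(x)
    w = np.zeros((p, p))
    t = np.zeros((p, p))
    for pt in x:
        d = (pt - g)[:, None]
        t += d @ d.T
    for pts in _clusters(x, labels).values():
        gq = _centroid(pts)
        for pt in pts:
            d = (pt - gq)[:, None]
            w += d @ d.T
    return float(np.linalg.det(t) / np.linalg.det(w))


def log_ss_ratio(x, labels):
    g = _centroid(x)
    tss = sum(_dist(pt, g) ** 2 for pt in x)
    wgss = trace_w(x, labels)
    return math.log((tss - wgss) / wgss)


def pbm(x, labels):
    cl = _clusters(x, labels)
    ids = sorted(cl)
    k = len(ids)
    g = _centroid(x)
    e1 = sum(_dist(pt, g) for pt in x)
    ek = sum(sum(_dist(p, _centroid(pts)) for p in pts) for pts in cl.values())
    dk = max(
        _dist(_centroid(cl[q]), _centroid(cl[r]))
        for q, r in itertools.combinations(ids, 2)
    )
    return ((1.0 / k) * (e1 / ek) * dk) ** 2


def point_biserial(x, labels):
    within, between = _all_pairs(x, labels)
    alld = within + between
    nt = len(alld)
    sd = np.std(alld)
    mw = sum(within) / len(within)
    mb = sum(between) / len(between)
    return (mb - mw) * math.sqrt(len(within) * len(between)) / nt / sd


def _concordance(x, labels):
    within, between = _all_pairs(x, labels)
    s_plus = s_minus = 0
    for w in within:
        for b in between:
            if w < b:
                s_plus += 1
            elif w > b:
                s_minus += 1
    return s_plus, s_minus, len(within), len(between)


def gamma(x, labels):
    s_plus, s_minus, _, _ = _concordance(x, labels)
    return (s_plus - s_minus) / (s_plus + s_minus)


def g_plus(x, labels):
    s_plus, s_minus, nw, nb = _concordance(x, labels)
    nt = nw + nb
    return 2.0 * s_minus / (nt * (nt - 1))


def tau(x, labels):
    s_plus, s_minus, nw, nb = _concordance(x, labels)
    nt = nw + nb
    return (s_plus - s_minus) / math.sqrt(nb * nw * (nt * (nt - 1) / 2.0))


def _scat(x, labels):
    var_tot = np.var(x, axis=0)
    cl = _clusters(x, labels)
    norms = [np.linalg.norm(np.var(pts, axis=0)) for pts in cl.values()]
    return (sum(norms) / len(norms)) / np.linalg.norm(var_tot)


def sd_index(x, labels):
    cl = _clusters(x, labels)
    ids = sorted(cl)
    cents = {q: _centroid(cl[q]) for q in ids}
    dists = [
        _dist(cents[q], cents[r]) for q, r in itertools.combinations(ids, 2)
    ]
    dis = (max(dists) / min(dists)) * sum(
        1.0 / sum(_dist(cents[q], cents[r]) for r in ids if r != q) for q in ids
    )
    return _scat(x, labels) + dis


def s_dbw(x, labels):
    cl = _clusters(x, labels)
    ids = sorted(cl)
    cents = {q: _centroid(cl[q]) for q in ids}
    radius = sum(
        math.sqrt(np.linalg.norm(np.var(cl[q], axis=0))) for q in ids
    ) / len(ids)

    def density(point, pts):
        return sum(1 for p in pts if _dist(p, point) <= radius)

    total, pairs = 0.0, 0
    for q, r in itertools.combinations(ids, 2):
        union = np.vstack([cl[q], cl[r]])
        dq, dr = density(cents[q], union), density(cents[r], union)
        mid = (cents[q] + cents[r]) / 2.0
        total += density(mid, union) / max(dq, dr)
        pairs += 1
    return _scat(x, labels) + total / pairs


def wemmert_gancarski(x, labels):
    cl = _clusters(x, labels)
    ids = sorted(cl)
    cents = {q: _centroid(cl[q]) for q in ids}
    n = len(x)
    total = 0.0
    for q in ids:
        s = 0.0
        for p in cl[q]:
            d_own = _dist(p, cents[q])
            d_other = min(_dist(p, cents[r]) for r in ids if r != q)
            s += d_own / d_other if d_other > 0 else (1.0 if d_own == 0 else np.inf)
        total += max(0.0, len(cl[q]) - s)
    return total / n


ORACLES = {
    "ball_hall": ball_hall,
    "banfield_raftery": banfield_raftery,
    "c_index": c_index,
    "calinski_harabasz": calinski_harabasz,
    "davies_bouldin": davies_bouldin,
    "dunn": dunn,
    "silhouette": silhouette,
    "xie_beni": xie_beni,
    "mcclain_rao": mcclain_rao,
    "ratkowsky_lance": ratkowsky_lance,
    "scott_symons": scott_symons,
    "marriot": marriot,
    "trace_w": trace_w,
    "trace_wib": trace_wib,
    "det_ratio": det_ratio,
    "hartigan": trace_w,  # the Hartigan curve is built from trace(W)
    "pbm": pbm,
    "point_biserial": point_biserial,
    "gamma": gamma,
    "g_plus": g_plus,
    "tau": tau,
    "sd_index": sd_index,
    "s_dbw": s_dbw,
    "wemmert_gancarski": wemmert_gancarski,
    "log_ss_ratio": log_ss_ratio,
}


def adjusted_rand(a, b):
    """ARI from the contingency table, straight from the definition."""
    a, b = list(a), list(b)
    n = len(a)
    ua, ub = sorted(set(a)), sorted(set(b))
    cont = [[sum(1 for i in range(n) if a[i] == x and b[i] == y) for y in ub] for x in ua]

    def comb2(m):
        return m * (m - 1) / 2.0

    sum_ij = sum(comb2(c) for row in cont for c in row)
    sum_a = sum(comb2(sum(row)) for row in cont)
    sum_b = sum(comb2(sum(cont[i][j] for i in range(len(ua)))) for j in range(len(ub)))
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def best_alignment_exhaustive(ref, other):
    """Best relabeling of `other` by exhaustive search over all k! bijections."""
    ref, other = list(ref), list(other)
    ks = sorted(set(ref) | set(other))
    best, best_agree = None, -1
    for perm in itertools.permutations(ks):
        mapping = dict(zip(ks, perm))
        relabeled = [mapping[o] for o in other]
        agree = sum(1 for r, o in zip(ref, relabeled) if r == o)
        if agree > best_agree:
            best, best_agree = relabeled, agree
    return best, best_agree
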