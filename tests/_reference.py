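"""Independent brute-force reference implementation used as a test oracle.

Pure-Python loops only (math/statistics), no numpy/scipy, so every stage of
the pipeline can be cross-checked entry-for-entry against an implementation
that shares no code with the package.

Numerical note: the spearman distance is evaluated here through the same
algebraic form as the package (centered average ranks, exact half-integer
sums), so even exactly tied distances sort identically under the ascending
index tie rule.  Median, norm and bin arithmetic likewise use operation
orders whose float results coincide with the package's for the small sizes
tested.
"""

from __future__ import annotations

import math
from statistics import median


# ---------------------------------------------------------------- distances

def average_ranks(v):
    """Average (fractional) ranks, 1-based, ties share the mean rank."""
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def euclidean(u, v):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))


def cosine(u, v):
    num = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return 1.0 - num / (nu * nv)


def spearman_distances(X):
    """Full C×C spearman rank-correlation distance matrix."""
    n_genes = len(X[0])
    mean = (n_genes + 1) / 2.0
    Rc = [[r - mean for r in average_ranks(row)] for row in X]
    ss = [sum(x * x for x in row) for row in Rc]
    C = len(X)
    D = [[0.0] * C for _ in range(C)]
    for i in range(C):
        for j in range(C):
            num = sum(a * b for a, b in zip(Rc[i], Rc[j]))
            D[i][j] = 1.0 - num / math.sqrt(ss[i] * ss[j])
    return D


def knn(X, k, metric):
    """k nearest neighbors by exhaustive all-pairs sort, ties by index."""
    C = len(X)
    if metric == "spearman":
        D = spearman_distances(X)
        dist = lambda c, j: D[c][j]
    elif metric == "euclidean":
        dist = lambda c, j: euclidean(X[c], X[j])
    else:
        dist = lambda c, j: cosine(X[c], X[j])
    out = []
    for c in range(C):
        cand = sorted((dist(c, j), j) for j in range(C) if j != c)
        out.append([j for _, j in cand[:k]])
    return out


# ------------------------------------------------------------ differentials

def differentials(X, S, nn):
    """d[c][g] = tuple of per-dimension medians, or None if undefined."""
    C, G, P = len(X), len(X[0]), len(S[0])
    d = [[None] * G for _ in range(C)]
    for c in range(C):
        for g in range(G):
            if X[c][g] == 0:
                continue
            comps = []
            ok = True
            for p in range(P):
                quots = [
                    (X[c][g] - X[n][g]) / (S[n][p] - S[c][p])
                    for n in nn[c]
                    if S[n][p] != S[c][p]
                ]
                if not quots:
                    ok = False
                    break
                comps.append(median(quots))
            if ok:
                d[c][g] = tuple(comps)
    return d


def scores(d):
    return [
        [None if v is None else math.sqrt(sum(q * q for q in v)) for v in row]
        for row in d
    ]


def ranks(sc):
    """Descending competition (min) ranks among defined scores per cell."""
    out = []
    for row in sc:
        rr = []
        for v in row:
            if v is None:
                rr.append(None)
            else:
                rr.append(1 + sum(1 for w in row if w is not None and w > v))
        out.append(rr)
    return out


# ---------------------------------------------------------------- relevance

def local_relevance(rk, cells, cutoff, inclusive=False):
    G = len(rk[0])
    out = []
    for g in range(G):
        hits = 0
        for c in cells:
            r = rk[c][g]
            if r is not None and (r <= cutoff if inclusive else r < cutoff):
                hits += 1
        out.append(hits / len(cells))
    return out


def bin_assign(S, nx, ny):
    C = len(S)
    P = len(S[0])

    def axis(p, n):
        vals = [S[c][p] for c in range(C)]
        lo, hi = min(vals), max(vals)
        if hi == lo:
            return [0] * C
        w = (hi - lo) / n
        return [min(n - 1, max(0, int(math.floor((v - lo) / w)))) for v in vals]

    bx = axis(0, nx)
    by = axis(1, ny) if P >= 2 else [0] * C
    return bx, by


def binned_local_relevance(rk, bx, by, nx, ny, cutoff, inclusive=False):
    """dict (bin_x, bin_y) -> (n_cells, [LR per gene] or None if empty)."""
    out = {}
    for i in range(nx):
        for j in range(ny):
            cells = [c for c in range(len(rk)) if bx[c] == i and by[c] == j]
            if cells:
                out[(i, j)] = (len(cells), local_relevance(rk, cells, cutoff, inclusive))
            else:
                out[(i, j)] = (0, None)
    return out


# ---------------------------------------------------------------- map

def initial_labels(sc, pool, gene_ids):
    """Most relevant pool gene per cell; ties to the lex smallest gene id."""
    pool_sorted = sorted(pool)
    cols = [gene_ids.index(g) for g in pool_sorted]
    labels = []
    for row in sc:
        best, best_v = None, None
        for g, col in zip(pool_sorted, cols):
            v = row[col]
            if v is None:
                continue
            if best_v is None or v > best_v:
                best, best_v = g, v
        labels.append(best)
    return labels


def smooth(labels, nn, pool, steps):
    pool_sorted = sorted(pool)
    cur = list(labels)
    for _ in range(steps):
        new = []
        for c in range(len(cur)):
            counts = {g: 0 for g in pool_sorted}
            total = 0
            for n in nn[c]:
                if cur[n] is not None:
                    counts[cur[n]] += 1
                    total += 1
            if total == 0:
                new.append(cur[c])
            else:
                # highest count, ties to the lexicographically smallest gene
                best = sorted(pool_sorted, key=lambda g: (-counts[g], g))[0]
                new.append(best)
        cur = new
    return cur


# ---------------------------------------------------------------- RBO

def rbo_ext(a, b, p):
    """Extrapolated RBO by explicit depth-by-depth summation."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    s, l = len(short), len(long_)
    x_s = len(set(short) & set(long_[:s]))
    total = 0.0
    for d in range(1, l + 1):
        if d <= s:
            x = len(set(short[:d]) & set(long_[:d]))
        else:
            # the short list is exhausted; extrapolate its agreement rate
            x = len(set(short) & set(long_[:d])) + (d - s) * x_s / s
        total += (1 - p) * p ** (d - 1) * (x / d)
    x_l = len(set(short) & set(long_))
    final = (x_l - x_s) / l + x_s / s
    return total + p**l * final


def rbo_truncated(a, b, p, depth):
    total = 0.0
    for d in range(1, depth + 1):
        x = len(set(a[: min(d, len(a))]) & set(b[: min(d, len(b))]))
        total += (1 - p) * p ** (d - 1) * (x / d)
    return total
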