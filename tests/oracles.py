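"""Independent brute-force oracles shared by unit and acceptance tests.

Everything here is written as literal loop transcriptions of the defining
formulas, deliberately independent of the package implementations.
"""

import numpy as np


def gat_oracle(h, edges, layer):
    wl, wr, a = layer.Wl.data, layer.Wr.data, layer.a.data
    slope = layer.leaky_slope

    def lrelu(v):
        return np.where(v > 0, v, slope * v)

    def elu(v):
        return np.where(v > 0, v, np.exp(v) - 1)

    n = len(h)
    out = np.zeros((n, wl.shape[1]))
    for i in range(n):
        nbrs = [int(s) for s, d in zip(*edges) if d == i]
        if not nbrs:
            out[i] = elu(h[i] @ wr)
            continue
        scores = np.array([a @ lrelu(h[i] @ wl + h[j] @ wr) for j in nbrs])
        alpha = np.exp(scores - scores.max())
        alpha = alpha / alpha.sum()
        out[i] = elu(sum(alpha[k] * (h[j] @ wr)
                         for k, j in enumerate(nbrs)))
    return out


def transformer_oracle(x, layer):
    n, d = x.shape
    H, dh = layer.n_heads, layer.d_head
    heads = []
    for hh in range(H):
        sl = slice(hh * dh, (hh + 1) * dh)
        q, k, v = (x @ layer.Wq.data[:, sl], x @ layer.Wk.data[:, sl],
                   x @ layer.Wv.data[:, sl])
        o = np.zeros((n, dh))
        for i in range(n):
            scores = np.array([q[i] @ k[j] for j in range(n)]) / np.sqrt(dh)
            w = np.exp(scores - scores.max())
            w = w / w.sum()
            o[i] = sum(w[j] * v[j] for j in range(n))
        heads.append(o)
    mh = np.concatenate(heads, axis=1) @ layer.Wo.data

    def ln(z, lnl):
        mu = z.mean(axis=-1, keepdims=True)
        var = ((z - mu) ** 2).mean(axis=-1, keepdims=True)
        return lnl.gamma.data * (z - mu) / np.sqrt(var + lnl.eps) + \
            lnl.beta.data

    z = ln(x + mh, layer.ln1)
    ff = np.maximum(z @ layer.ff1.W.data + layer.ff1.b.data, 0)
    return ln(z + ff @ layer.ff2.W.data + layer.ff2.b.data, layer.ln2)


def rbf_weights_oracle(coords, l):
    n = len(coords)
    w0 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                w0[i, j] = np.exp(-((coords[i] - coords[j]) ** 2).sum()
                                  / (2 * l * l))
    return w0 * n / w0.sum()


def moran_oracle(x, y, w):
    n = len(x)
    xb, yb = x.mean(), y.mean()
    num = sum(w[i, j] * (x[i] - xb) * (y[j] - yb)
              for i in range(n) for j in range(n))
    return num / np.sqrt(((x - xb) ** 2).sum() * ((y - yb) ** 2).sum())


def mse_oracle(p, y):
    n, t = p.shape
    return sum((p[i, j] - y[i, j]) ** 2 for i in range(n)
               for j in range(t)) / (n * t)


def pearson_oracle(x, y):
    xb, yb = x.mean(), y.mean()
    num = sum((a - xb) * (b - yb) for a, b in zip(x, y))
    return num / np.sqrt(sum((a - xb) ** 2 for a in x)) / \
        np.sqrt(sum((b - yb) ** 2 for b in y))


def jsd_oracle(p, q):
    pn, qn = p / p.sum(), q / q.sum()
    m = (pn + qn) / 2
    kl_pm = sum(a * np.log2(a / b) for a, b in zip(pn, m) if a > 0)
    kl_qm = sum(a * np.log2(a / b) for a, b in zip(qn, m) if a > 0)
    return 0.5 * kl_pm + 0.5 * kl_qm


def cindex_oracle(s, t, c):
    num = den = 0.0
    n = len(s)
    for i in range(n):
        for j in range(n):
            if t[i] < t[j] and c[i] == 0:
                den += 1
                if s[i] < s[j]:
                    num += 1
                elif s[i] == s[j]:
                    num += 0.5
    return num / den


def km_oracle(t, c):
    """Product-limit estimate at each distinct observed event time."""
    uniq = sorted(set(t[i] for i in range(len(t)) if c[i] == 0))
    s, out = 1.0, []
    for u in uniq:
        at_risk = sum(1 for v in t if v >= u)
        deaths = sum(1 for v, cc in zip(t, c) if v == u and cc == 0)
        s *= 1 - deaths / at_risk
        out.append((u, s))
    return out


def knn_edges_oracle(coords, k):
    n = len(coords)
    edges = set()
    for i in range(n):
        d = sorted((np.hypot(*(coords[i] - coords[j])), j)
                   for j in range(n) if j != i)
        for _, j in d[:k]:
            edges.add((min(i, j), max(i, j)))
    return edges


def bfs_oracle(adj, centers, hops):
    dist = {c: 0 for c in centers}
    frontier = list(centers)
    for h in range(hops):
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = h + 1
                    nxt.append(v)
        frontier = nxt
    return dist
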