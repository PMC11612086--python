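"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity with explicit loops or exhaustive
enumeration and share no code with the package internals.
"""

import itertools
import math

import numpy as np
from scipy.special import erf
from scipy.stats import binom


def oracle_layernorm(row, g, b, eps=1e-5):
    mu = sum(row) / len(row)
    var = sum((v - mu) ** 2 for v in row) / len(row)
    return np.array([(v - mu) / math.sqrt(var + eps) for v in row]) * g + b


def oracle_gelu(x):
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def oracle_encoder(tokens, params, prefix, cfg):
    """Explicit-loop pre-norm transformer encoder for a single sample (T, D)."""
    x = np.asarray(tokens, dtype=np.float64).copy()
    T, D = x.shape
    H, dh = cfg.n_heads, cfg.head_dim
    for l in range(cfg.depth):
        p = f"{prefix}blocks.{l}."
        h = np.stack([oracle_layernorm(x[t], params[p + "ln1.g"], params[p + "ln1.b"])
                      for t in range(T)])
        q = h @ params[p + "Wq"] + params[p + "bq"]
        k = h @ params[p + "Wk"] + params[p + "bk"]
        v = h @ params[p + "Wv"] + params[p + "bv"]
        out = np.zeros((T, H * dh))
        for head in range(H):
            sl = slice(head * dh, (head + 1) * dh)
            for t in range(T):
                scores = []
                for u in range(T):
                    scores.append(float(np.dot(q[t, sl], k[u, sl])) / math.sqrt(dh))
                mx = max(scores)
                w = [math.exp(s - mx) for s in scores]
                Z = sum(w)
                acc = np.zeros(dh)
                for u in range(T):
                    acc += (w[u] / Z) * v[u, sl]
                out[t, sl] = acc
        x = x + out @ params[p + "Wo"] + params[p + "bo"]
        h2 = np.stack([oracle_layernorm(x[t], params[p + "ln2.g"], params[p + "ln2.b"])
                       for t in range(T)])
        m = oracle_gelu(h2 @ params[p + "W1"] + params[p + "b1"]) @ params[p + "W2"] \
            + params[p + "b2"]
        x = x + m
    return np.stack([oracle_layernorm(x[t], params[prefix + "final_ln.g"],
                                      params[prefix + "final_ln.b"]) for t in range(T)])


def oracle_auc(y, s):
    """All-pairs concordance count with ties worth 1/2."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def oracle_anova_f_two_group(x, labels):
    """Squared pooled-variance t statistic for two groups."""
    x = np.asarray(x, dtype=float)
    g = np.asarray(labels)
    a, b = x[g == np.unique(g)[0]], x[g == np.unique(g)[1]]
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t * t


def oracle_mcnemar_exact(b, c):
    """Two-sided exact binomial McNemar p from discordant counts."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    p = 2 * binom.cdf(k, n, 0.5)
    if b == c:
        p -= binom.pmf(k, n, 0.5)  # do not double-count the center
    return min(p, 1.0)


def oracle_mannwhitney_exact(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments (feasible for <= 10 observations, tie-free)."""
    x, y = list(x), list(y)
    nx = len(x)
    pooled = x + y
    def ustat(xs, ys):
        return sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys)
    u_obs = ustat(x, y)
    mean_u = nx * len(y) / 2.0
    dev = abs(u_obs - mean_u)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = ustat(xs, ys)
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


def reconstruct_confusion(n_total, targets, tol=5e-4):
    """Brute-force search for integer confusion matrices matching printed
    accuracy/sensitivity/specificity/PPV/NPV values."""
    hits = []
    for tp in range(n_total + 1):
        for fn in range(n_total + 1 - tp):
            for fp in range(n_total + 1 - tp - fn):
                tn = n_total - tp - fn - fp
                try:
                    vals = {
                        "accuracy": (tp + tn) / n_total,
                        "sensitivity": tp / (tp + fn),
                        "specificity": tn / (tn + fp),
                        "ppv": tp / (tp + fp),
                        "npv": tn / (tn + fn),
                    }
                except ZeroDivisionError:
                    continue
                if all(abs(vals[k] - v) < tol for k, v in targets.items()):
                    hits.append((tp, fn, fp, tn))
    return hits
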