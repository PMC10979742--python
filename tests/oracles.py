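"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain Python loops over nested
lists (with `math` scalar functions), independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import math


def _matvec(M, x):
    n = len(x)
    return [sum(M[i][j] * x[j] for j in range(n)) for i in range(n)]


def plain_loop_develop(
    matrices,
    cue,
    model: str,
    steps: int,
    ema_alpha: float = 1.0 / 3.0,
    gains=(0.65, 0.65, 0.65, 0.65),
):
    """Step-by-step recursion of the developmental map using nothing but
    Python loops.  Returns the list of per-step states.

    ``matrices`` is the (E, F, G, H, J, P) ensemble as nested lists; ``cue``
    is a list (ignored for the NoCue model).
    """
    E, F, G, H, J, P = matrices
    n = len(E)
    gf, gg, gh, gp = gains
    a = ema_alpha
    f = [0.0] * n
    g = [1.0] * n
    h = [0.0] * n
    p = [0.0] * n
    p_ema = [0.0] * n
    v = [1.0] * n
    out = []
    for _ in range(steps):
        if model == "full":
            drive = _matvec(E, [cue[j] - p_ema[j] for j in range(n)])
        else:
            drive = [-x for x in _matvec(E, p_ema)]
        gg_prev = _matvec(G, g)
        f = [(2.0 / math.pi) * math.atan(gf * (gg_prev[i] + drive[i]))
             for i in range(n)]
        ff = _matvec(F, f)
        g = [(2.0 / math.pi) * math.atan(gg * ff[i]) for i in range(n)]
        hh = _matvec(H, g)
        jh = _matvec(J, h)
        h = [(2.0 / math.pi) * math.atan(gh * (hh[i] + jh[i])) for i in range(n)]
        pp = _matvec(P, h)
        p = [math.tanh(gp * pp[i]) for i in range(n)]
        v = [(1.0 - a) * (v[i] + a * (p_ema[i] - p[i]) ** 2) for i in range(n)]
        p_ema = [a * p[i] + (1.0 - a) * p_ema[i] for i in range(n)]
        out.append(
            {"f": f[:], "g": g[:], "h": h[:], "p": p[:],
             "p_ema": p_ema[:], "v": v[:], "total_v": sum(v)}
        )
    return out


def brute_cross_covariance(phenos, covars):
    """Double-loop divisor-N cross-covariance of (N,T) and (N,M) lists."""
    n = len(phenos)
    t = len(phenos[0])
    m = len(covars[0])
    pbar = [sum(row[i] for row in phenos) / n for i in range(t)]
    xbar = [sum(row[j] for row in covars) / n for j in range(m)]
    return [
        [
            sum((phenos[k][i] - pbar[i]) * (covars[k][j] - xbar[j])
                for k in range(n)) / n
            for j in range(m)
        ]
        for i in range(t)
    ]


def brute_total_variance(vectors):
    """Sum over positions of the divisor-N variance across vectors."""
    n = len(vectors)
    m = len(vectors[0])
    total = 0.0
    for j in range(m):
        col = [vectors[k][j] for k in range(n)]
        mean = sum(col) / n
        total += sum((x - mean) ** 2 for x in col) / n
    return total
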