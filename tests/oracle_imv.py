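"""Hand-unrolled scalar-loop reference implementation of the IMV-LSTM
forward pass, written independently of the vectorized model code.

Everything here works one variable, one timestep and one hidden unit at a
time using explicit Python loops and ``math`` scalars, so it cannot share a
broadcasting or reshaping mistake with the einsum-based implementation.
"""

import math


def _sig(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def unrolled_forward(params: dict, window) -> tuple[float, list, list]:
    """Single-window reference forward. ``window`` is a T x V nested list.

    Returns (probability, alpha as V x T nested list, beta as list of V).
    """
    T = len(window)
    V = len(window[0])
    d = len(params["b"][0])
    shared = "Wg" in params
    D = V * d

    h = [[0.0] * d for _ in range(V)]
    if shared:
        c = [0.0] * D
    else:
        c = [[0.0] * d for _ in range(V)]
    hs = []  # h at each step, deep-copied

    for t in range(T):
        x = window[t]
        # candidate update, variable by variable
        j = [[0.0] * d for _ in range(V)]
        for v in range(V):
            for a in range(d):
                acc = params["b"][v][a] + params["U"][v][a] * x[v]
                for e in range(d):
                    acc += params["W"][v][a][e] * h[v][e]
                j[v][a] = math.tanh(acc)
        if shared:
            z = [h[v][a] for v in range(V) for a in range(d)] + list(x)
            gates = []
            for r in range(3 * D):
                acc = params["bg"][r]
                for cidx in range(D + V):
                    acc += params["Wg"][r][cidx] * z[cidx]
                gates.append(_sig(acc))
            jf = [j[v][a] for v in range(V) for a in range(d)]
            c_new = [gates[D + r] * c[r] + gates[r] * jf[r] for r in range(D)]
            h_flat = [gates[2 * D + r] * math.tanh(c_new[r]) for r in range(D)]
            h = [[h_flat[v * d + a] for a in range(d)] for v in range(V)]
            c = c_new
        else:
            h_new = [[0.0] * d for _ in range(V)]
            c_new = [[0.0] * d for _ in range(V)]
            for v in range(V):
                pre = []
                for r in range(3 * d):
                    acc = params["bg"][v][r] + params["Wgx"][v][r] * x[v]
                    for e in range(d):
                        acc += params["Wgh"][v][r][e] * h[v][e]
                    pre.append(_sig(acc))
                for a in range(d):
                    gi, gf, go = pre[a], pre[d + a], pre[2 * d + a]
                    c_new[v][a] = gf * c[v][a] + gi * j[v][a]
                    h_new[v][a] = go * math.tanh(c_new[v][a])
            h, c = h_new, c_new
        hs.append([[h[v][a] for a in range(d)] for v in range(V)])

    # temporal attention per variable
    alpha = [[0.0] * T for _ in range(V)]
    g = [[0.0] * d for _ in range(V)]
    for v in range(V):
        scores = []
        for t in range(T):
            acc_out = 0.0
            for a in range(d):
                acc = params["fa"][v][a]
                for e in range(d):
                    acc += params["Fa"][v][a][e] * hs[t][v][e]
                acc_out += params["ua"][v][a] * math.tanh(acc)
            scores.append(acc_out)
        mx = max(scores)
        exps = [math.exp(s - mx) for s in scores]
        tot = sum(exps)
        for t in range(T):
            alpha[v][t] = exps[t] / tot
            for a in range(d):
                g[v][a] += alpha[v][t] * hs[t][v][a]

    # variable attention over [g_v; h_T[v]]
    svals = []
    for v in range(V):
        concat = g[v] + hs[T - 1][v]
        acc_out = 0.0
        for a in range(d):
            acc = params["fb"][a]
            for e in range(2 * d):
                acc += params["Fb"][a][e] * concat[e]
            acc_out += params["ub"][a] * math.tanh(acc)
        svals.append(acc_out)
    mx = max(svals)
    exps = [math.exp(s - mx) for s in svals]
    tot = sum(exps)
    beta = [e / tot for e in exps]

    # mixture-of-experts output over [g_v; h_T[v]]
    p = 0.0
    for v in range(V):
        concat = g[v] + hs[T - 1][v]
        acc = params["bh"][v]
        for a in range(2 * d):
            acc += params["Wh"][v][a] * concat[a]
        p += beta[v] * _sig(acc)
    return p, alpha, beta
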