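"""Independent scalar-loop reference implementations.

These are deliberately naive (explicit Python loops, no vectorization, no
code shared with the package) so that agreement with the package is
meaningful.  They operate on single samples only.
"""

import math


def qfm_oracle(z, W, b, U, V, W0, b0, eps, alt_phase_interaction=False):
    """Quantum feature map, one vector at a time, all loops."""
    P = len(b)
    d = len(z)
    r = len(U[0])
    theta = [sum(W[p][j] * z[j] for j in range(d)) + b[p] for p in range(P)]
    c = [math.cos(t) for t in theta]
    s = [math.sin(t) for t in theta]
    if alt_phase_interaction:
        h1 = [math.cos(sum(theta[p] * U[p][k] for p in range(P))) for k in range(r)]
    else:
        h1 = [sum(c[p] * U[p][k] for p in range(P)) for k in range(r)]
    h2 = [math.sin(sum(z[j] * V[j][k] for j in range(d))) for k in range(r)]
    h = [h1[k] * h2[k] for k in range(r)]
    ft = c + s + h
    f = [sum(W0[p][q] * ft[q] for q in range(2 * P + r)) + b0[p] for p in range(P)]
    norm = math.sqrt(sum(v * v for v in f))
    return [v / (norm + eps) for v in f]


def _softmax_row(row):
    m = max(row)
    e = [math.exp(v - m) for v in row]
    t = sum(e)
    return [v / t for v in e]


def mha_oracle(T, WQ, WK, WV, WO, n_heads):
    """Multi-head attention over an L x P token list, all loops."""
    L = len(T)
    P = len(T[0])
    dk = P // n_heads
    concat = [[0.0] * P for _ in range(L)]
    for head in range(n_heads):
        cols = range(head * dk, (head + 1) * dk)
        Q = [[sum(T[i][p] * WQ[p][c] for p in range(P)) for c in cols] for i in range(L)]
        K = [[sum(T[i][p] * WK[p][c] for p in range(P)) for c in cols] for i in range(L)]
        V = [[sum(T[i][p] * WV[p][c] for p in range(P)) for c in cols] for i in range(L)]
        for i in range(L):
            scores = [sum(Q[i][k] * K[j][k] for k in range(dk)) / math.sqrt(dk)
                      for j in range(L)]
            att = _softmax_row(scores)
            for k in range(dk):
                concat[i][head * dk + k] = sum(att[j] * V[j][k] for j in range(L))
    return [[sum(concat[i][p] * WO[p][q] for p in range(P)) for q in range(P)]
            for i in range(L)]


def classify_oracle(attended, W1, b1, W2, b2, pooling="mean"):
    """Pool -> hidden ReLU -> softmax, loops; dropout inactive (inference)."""
    L = len(attended)
    P = len(attended[0])
    if pooling == "mean":
        pooled = [sum(attended[i][p] for i in range(L)) / L for p in range(P)]
    else:
        pooled = [attended[i][p] for i in range(L) for p in range(P)]
    hidden = len(b1)
    K = len(b2)
    hid = [sum(pooled[j] * W1[j][m] for j in range(len(pooled))) + b1[m]
           for m in range(hidden)]
    act = [max(v, 0.0) for v in hid]
    logits = [sum(act[m] * W2[m][k] for m in range(hidden)) + b2[k] for k in range(K)]
    return _softmax_row(logits)


def fusion_oracle(zA, zB, model):
    """Composition of the stage oracles using the model's parameters."""
    dH = min(len(zA), len(zB))
    zH = [zA[i] * zB[i] for i in range(dH)]
    tokens = []
    for z, p in ((zA, model.qfm_a), (zB, model.qfm_b), (zH, model.qfm_h)):
        tokens.append(qfm_oracle(list(z), p.W.tolist(), p.b.tolist(), p.U.tolist(),
                                 p.V.tolist(), p.W0.tolist(), p.b0.tolist(), p.eps,
                                 p.alt_phase_interaction))
    att = mha_oracle(tokens, model.mha.WQ.tolist(), model.mha.WK.tolist(),
                     model.mha.WV.tolist(), model.mha.WO.tolist(),
                     model.mha.n_heads)
    return classify_oracle(att, model.head.W1.tolist(), model.head.b1.tolist(),
                           model.head.W2.tolist(), model.head.b2.tolist(),
                           model.config.pooling)
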