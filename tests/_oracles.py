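"""Independent brute-force oracles for the collapsed mixture likelihoods.

Everything here is computed with direct rising-factorial products and
explicit enumeration — no log-gamma, no sharing of code with the
implementation under test.  Valid only for small instances.
"""

from itertools import product

import numpy as np


def rising(a: float, n: int) -> float:
    """Rising factorial a^(n) = a (a+1) ... (a+n-1)."""
    out = 1.0
    for i in range(n):
        out *= a + i
    return out


def dm_prob(x, beta) -> float:
    """DM pmf of a count vector by direct products (with multinomial coefficient)."""
    import math

    x = np.asarray(x, dtype=int)
    beta = np.asarray(beta, dtype=float)
    N = int(x.sum())
    coeff = math.factorial(N)
    for xv in x:
        coeff //= math.factorial(int(xv))
    num = 1.0
    for xv, bv in zip(x, beta):
        num *= rising(bv, int(xv))
    return coeff * num / rising(float(beta.sum()), N)


def dm_seq_prob(x, beta) -> float:
    """Probability of one particular sequence with counts x (no coefficient)."""
    x = np.asarray(x, dtype=int)
    beta = np.asarray(beta, dtype=float)
    num = 1.0
    for xv, bv in zip(x, beta):
        num *= rising(bv, int(xv))
    return num / rising(float(beta.sum()), int(x.sum()))


def count_matrix(corpus, stream):
    """(M, V) per-segment count matrix for one stream."""
    V = corpus.schema.vocab_size(stream)
    M = corpus.M
    X = np.zeros((M, V), dtype=int)
    for m, seg in enumerate(corpus.segments):
        np.add.at(X[m], seg.tokens[stream], 1)
    return X


def joint_prob(corpus, z, alpha, beta_by_stream, K) -> float:
    """P(Z, all streams) by direct products: cluster prior times per-cluster DM terms."""
    z = np.asarray(z, dtype=int)
    M = len(z)
    alpha = np.asarray(alpha, dtype=float)
    tau = np.bincount(z, minlength=K)
    pz = 1.0
    for k in range(K):
        pz *= rising(alpha[k], int(tau[k]))
    pz /= rising(float(alpha.sum()), M)
    pw = 1.0
    for stream, beta in beta_by_stream.items():
        X = count_matrix(corpus, stream)
        for k in range(K):
            xk = X[z == k].sum(axis=0)
            pw *= dm_seq_prob(xk, beta[k])
    return pz * pw


def conditional(corpus, z, m, alpha, beta_by_stream, K) -> np.ndarray:
    """Exact P(z_m = k | Z\\m, data) by enumerating the K joint numerators."""
    z = np.array(z, dtype=int)
    probs = np.zeros(K)
    for k in range(K):
        z[m] = k
        probs[k] = joint_prob(corpus, z, alpha, beta_by_stream, K)
    return probs / probs.sum()


def marginal(corpus, alpha, beta_by_stream, K) -> float:
    """P(all streams) by summing the joint over every assignment vector."""
    total = 0.0
    for z in product(range(K), repeat=corpus.M):
        total += joint_prob(corpus, np.array(z), alpha, beta_by_stream, K)
    return total


def all_count_vectors(N, V):
    """Every non-negative integer vector of length V summing to N."""
    if V == 1:
        yield (N,)
        return
    for first in range(N + 1):
        for rest in all_count_vectors(N - first, V - 1):
            yield (first, *rest)
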