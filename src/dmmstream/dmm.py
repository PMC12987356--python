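"""Dirichlet multinomial mixture (DMM) over multiple token streams.

The model: each segment m carries a latent activity z_m ~ Cat(theta),
theta ~ Dir(alpha).  Given z_m = k, the words of each stream are drawn
i.i.d. from a categorical phi_k(stream) with phi_k(stream) ~
Dir(beta_k(stream)), streams conditionally independent given z_m.
Integrating theta and every phi out (collapsing) leaves count tables
(tau, omega) as sufficient statistics and yields a Gibbs sampler whose
per-segment conditional is

    P(z_m = k | rest)  propto  (tau_k^{\\m} + alpha_k)
        * prod_streams  prod_v prod_{l=1..N_m(v)} (omega_{k,v}^{\\m} + beta_{k,v} + l - 1)
                        / prod_{n=1..N_m} (omega_{k,.}^{\\m} + beta_{k,.} + n - 1)

All probability arithmetic is done in log space: the rising-factorial
products are evaluated as differences of log-gamma, which stays finite
for the large vocabularies and counts where direct products overflow.

Collapsing the Dirichlet makes the per-cluster word-count distribution a
Dirichlet multinomial, whose heavy (power-law) tail captures burstiness:
a word seen once in an activity becomes much more likely to recur there.
With beta < 1 this effect is strong, which is the regime these defaults
target.

Per full sweep the sampler touches each segment once; one segment update
costs O(K * L * S) where L is the stream count and S the number of
tokens in the segment, and the count tables take O(K * L * V) memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .corpus import Corpus, DmmModelState, Segment, recompute_counts
from .errors import ConfigError, IntegrityError

DEFAULT_ALPHA = 1.0
DEFAULT_BETA = 0.1


# ---------------------------------------------------------------------------
# Hyperparameters and configuration


@dataclass
class Hyperparameters:
    """Dirichlet concentrations: alpha over clusters, beta per stream.

    Scalars expand to symmetric vectors/matrices.  ``beta`` may be a
    single scalar (every stream symmetric at that value), a mapping
    stream -> scalar, or a mapping stream -> (K, V) matrix.

    Defaults (alpha=1.0, beta=0.1) put the emission prior in the sparse
    regime (beta < 1) where the collapsed likelihood rewards bursty
    word reuse.
    """

    alpha: float | np.ndarray = DEFAULT_ALPHA
    beta: float | Mapping[str, float | np.ndarray] = DEFAULT_BETA

    def expand(self, K: int, vocab_sizes: Mapping[str, int]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Materialize (alpha vector length K, beta dict of K x V matrices)."""
        alpha = np.asarray(self.alpha, dtype=np.float64)
        if alpha.ndim == 0:
            alpha = np.full(K, float(alpha))
        if alpha.shape != (K,):
            raise ConfigError(f"alpha must be scalar or length {K}")
        if (alpha <= 0).any():
            raise ConfigError("alpha entries must be > 0")
        beta: dict[str, np.ndarray] = {}
        for s, V in vocab_sizes.items():
            if isinstance(self.beta, Mapping):
                b = np.asarray(self.beta[s], dtype=np.float64)
            else:
                b = np.asarray(self.beta, dtype=np.float64)
            if b.ndim == 0:
                b = np.full((K, V), float(b))
            elif b.shape != (K, V):
                raise ConfigError(f"beta for stream {s!r} must be scalar or shape ({K}, {V})")
            if (b <= 0).any():
                raise ConfigError("beta entries must be > 0")
            beta[s] = b
        return alpha, beta


@dataclass
class GibbsConfig:
    """Sampler settings: maximum clusters K, full sweeps, RNG seed."""

    K: int
    iterations: int = 50
    seed: int = 0
    record_history: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")


@dataclass
class FitResult:
    """Outcome of a Gibbs run: final state plus optional per-sweep history."""

    state: DmmModelState
    estimated_clusters: int
    history: list[np.ndarray] = field(default_factory=list)
    log_joint_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Dirichlet multinomial primitives


def _check_dm_args(x: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    beta = np.asarray(beta, dtype=np.float64)
    if x.shape != beta.shape:
        raise ConfigError("count vector and beta must have the same length")
    if (x < 0).any() or not np.issubdtype(np.asarray(x).dtype, np.number):
        raise ConfigError("counts must be non-negative")
    if np.any(x != np.floor(x)):
        raise ConfigError("counts must be integers")
    if (beta <= 0).any():
        raise ConfigError("beta entries must be > 0")
    return np.asarray(x, dtype=np.float64), beta


def dm_log_pmf(x: Sequence[int] | np.ndarray, beta: Sequence[float] | np.ndarray) -> float:
    """Log pmf of the Dirichlet multinomial over count vectors.

    ``DM(x | beta) = Gamma(N+1) Gamma(b.) / Gamma(b.+N)
    * prod_v Gamma(x_v+beta_v) / (Gamma(x_v+1) Gamma(beta_v))`` with
    ``N = sum_v x_v`` and ``b. = sum_v beta_v``.  Finite for all valid
    inputs; sums to 1 over all count vectors with total N.
    """
    x, beta = _check_dm_args(x, beta)
    N = x.sum()
    b_tot = beta.sum()
    return float(
        gammaln(N + 1.0)
        + gammaln(b_tot)
        - gammaln(b_tot + N)
        + np.sum(gammaln(x + beta) - gammaln(x + 1.0) - gammaln(beta))
    )


def dm_sequence_log_prob(x: Sequence[int] | np.ndarray, beta: Sequence[float] | np.ndarray) -> float:
    """Log probability of one particular word *sequence* with counts ``x``.

    This is ``log B(x + beta) - log B(beta)`` — the pmf without the
    multinomial coefficient, i.e. ``dm_log_pmf`` minus
    ``log N! / prod_v x_v!``.
    """
    x, beta = _check_dm_args(x, beta)
    N = x.sum()
    b_tot = beta.sum()
    return float(gammaln(b_tot) - gammaln(b_tot + N) + np.sum(gammaln(x + beta) - gammaln(beta)))


def joint_log_prob(
    corpus: Corpus,
    assignments: Sequence[int] | np.ndarray,
    hyper: Hyperparameters,
    K: int | None = None,
) -> float:
    """Collapsed log joint ``log P(Z, all streams | alpha, beta)``.

    ``log B(tau + alpha) - log B(alpha) + sum_streams sum_k
    [log B(omega_k + beta_k) - log B(beta_k)]``.  Invariant under word
    order within segments and under joint permutation of segments and
    assignments.
    """
    z = np.asarray(assignments, dtype=np.int64)
    if len(z) != corpus.M:
        raise ConfigError("assignments length must equal number of segments")
    if K is None:
        K = int(z.max()) + 1 if z.size else 1
    vocab_sizes = {s: corpus.schema.vocab_size(s) for s in corpus.schema.streams}
    alpha, beta = Hyperparameters(hyper.alpha, hyper.beta).expand(K, vocab_sizes)
    tau, omega = recompute_counts(corpus, z, K)
    total = _log_beta_vec(tau + alpha) - _log_beta_vec(alpha)
    for s in corpus.schema.streams:
        b = beta[s]
        ob = omega[s] + b
        total += float(
            np.sum(gammaln(ob)) - np.sum(gammaln(ob.sum(axis=1)))
            - np.sum(gammaln(b)) + np.sum(gammaln(b.sum(axis=1)))
        )
    return float(total)


def _log_beta_vec(v: np.ndarray) -> float:
    return float(np.sum(gammaln(v)) - gammaln(v.sum()))


# ---------------------------------------------------------------------------
# Preprocessed corpus views (sparse per-segment counts)


class _StreamData:
    """Per-stream unique-word/count arrays for every segment."""

    __slots__ = ("name", "V", "idx", "cnt", "totals")

    def __init__(self, corpus: Corpus, name: str):
        self.name = name
        self.V = corpus.schema.vocab_size(name)
        self.idx: list[np.ndarray] = []
        self.cnt: list[np.ndarray] = []
        self.totals = np.zeros(corpus.M, dtype=np.int64)
        for m, seg in enumerate(corpus.segments):
            u, c = np.unique(seg.tokens[name], return_counts=True)
            self.idx.append(u.astype(np.int64))
            self.cnt.append(c.astype(np.float64))
            self.totals[m] = seg.tokens[name].size


def _segment_counts(segment: Segment, streams: Sequence[str]) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    out = {}
    for s in streams:
        toks = segment.tokens.get(s, np.zeros(0, dtype=np.int64))
        u, c = np.unique(toks, return_counts=True)
        out[s] = (u.astype(np.int64), c.astype(np.float64), int(toks.size))
    return out


def _conditional_logw(
    tau_ex: np.ndarray,
    alpha: np.ndarray,
    omega: Mapping[str, np.ndarray],
    omega_tot: Mapping[str, np.ndarray],
    beta: Mapping[str, np.ndarray],
    beta_tot: Mapping[str, np.ndarray],
    seg_counts: Mapping[str, tuple[np.ndarray, np.ndarray, int]],
) -> np.ndarray:
    """Unnormalized log conditional over K clusters for one segment."""
    logw = np.log(tau_ex + alpha)
    for s, (idx, cnt, N) in seg_counts.items():
        if N == 0:
            continue
        A = omega[s][:, idx] + beta[s][:, idx]
        logw += np.sum(gammaln(A + cnt) - gammaln(A), axis=1)
        T = omega_tot[s] + beta_tot[s]
        logw -= gammaln(T + N) - gammaln(T)
    return logw


def gibbs_conditional(m: int, state: DmmModelState, corpus: Corpus) -> np.ndarray:
    """Normalized full conditional P(z_m = k | Z\\m, data) for segment m.

    Segment m's own contributions are removed from the count tables
    before evaluating the collapsed conditional.
    """
    if not 0 <= m < corpus.M:
        raise ConfigError(f"segment index {m} out of range")
    seg = corpus.segments[m]
    k_old = int(state.assignments[m])
    seg_counts = _segment_counts(seg, corpus.schema.streams)

    tau_ex = state.tau.astype(np.float64).copy()
    tau_ex[k_old] -= 1.0
    omega_ex: dict[str, np.ndarray] = {}
    omega_tot_ex: dict[str, np.ndarray] = {}
    beta_tot = {s: state.beta[s].sum(axis=1) for s in state.beta}
    for s in corpus.schema.streams:
        o = state.omega[s].astype(np.float64).copy()
        idx, cnt, _ = seg_counts[s]
        o[k_old, idx] -= cnt
        omega_ex[s] = o
        omega_tot_ex[s] = o.sum(axis=1)

    logw = _conditional_logw(tau_ex, state.alpha, omega_ex, omega_tot_ex, state.beta, beta_tot, seg_counts)
    p = np.exp(logw - logsumexp(logw))
    return p / p.sum()


# ---------------------------------------------------------------------------
# Fitting


def fit(
    corpus: Corpus,
    hyper: Hyperparameters | None = None,
    config: GibbsConfig | None = None,
    init_state: DmmModelState | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Collapsed Gibbs sampling over segment assignments.

    Initializes each z_m uniformly at random from the seeded generator
    (unless ``init_state`` resumes a previous run), then performs
    ``config.iterations`` full sweeps resampling each segment in corpus
    order with incrementally maintained count tables.  The final
    clustering is the assignment vector after the last sweep; no
    posterior averaging, so cluster identities stay stable across the
    run.  Identical (corpus, hyper, config) gives bit-identical results.

    ``rng`` may be passed to continue an existing generator stream, in
    which case a save/load/resume run reproduces an uninterrupted one.
    """
    if hyper is None:
        hyper = Hyperparameters()
    if config is None:
        raise ConfigError("GibbsConfig is required (at minimum K)")
    vocab_sizes = {s: corpus.schema.vocab_size(s) for s in corpus.schema.streams}
    K = config.K
    alpha, beta = hyper.expand(K, vocab_sizes)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    M = corpus.M
    streams = [_StreamData(corpus, s) for s in corpus.schema.streams]

    if init_state is None:
        z = rng.integers(0, K, size=M)
    else:
        init_state.validate(corpus)
        if init_state.K != K:
            raise ConfigError("init_state.K differs from config.K")
        z = init_state.assignments.copy()
    tau = np.bincount(z, minlength=K).astype(np.int64)
    omega = {sd.name: np.zeros((K, sd.V), dtype=np.float64) for sd in streams}
    omega_tot = {sd.name: np.zeros(K, dtype=np.float64) for sd in streams}
    for sd in streams:
        o = omega[sd.name]
        for m in range(M):
            o[z[m], sd.idx[m]] += sd.cnt[m]
        omega_tot[sd.name] = o.sum(axis=1)
    beta_tot = {s: beta[s].sum(axis=1) for s in beta}

    tau_f = tau.astype(np.float64)
    history: list[np.ndarray] = []
    log_joint_trace: list[float] = []
    hyper_expanded = Hyperparameters(alpha=alpha, beta=beta)

    for _ in range(config.iterations):
        for m in range(M):
            k_old = z[m]
            tau_f[k_old] -= 1.0
            for sd in streams:
                idx, cnt = sd.idx[m], sd.cnt[m]
                omega[sd.name][k_old, idx] -= cnt
                omega_tot[sd.name][k_old] -= sd.totals[m]

            logw = np.log(tau_f + alpha)
            for sd in streams:
                idx, cnt, N = sd.idx[m], sd.cnt[m], sd.totals[m]
                if N == 0:
                    continue
                A = omega[sd.name][:, idx] + beta[sd.name][:, idx]
                logw += np.sum(gammaln(A + cnt) - gammaln(A), axis=1)
                T = omega_tot[sd.name] + beta_tot[sd.name]
                logw -= gammaln(T + N) - gammaln(T)

            logw -= logw.max()
            p = np.exp(logw)
            cp = np.cumsum(p)
            k_new = int(np.searchsorted(cp, rng.random() * cp[-1], side="right"))
            if k_new >= K:  # guard against roundoff at the upper edge
                k_new = K - 1

            z[m] = k_new
            tau_f[k_new] += 1.0
            for sd in streams:
                idx, cnt = sd.idx[m], sd.cnt[m]
                omega[sd.name][k_new, idx] += cnt
                omega_tot[sd.name][k_new] += sd.totals[m]

        if config.record_history:
            history.append(z.copy())
            log_joint_trace.append(joint_log_prob(corpus, z, hyper_expanded, K=K))

    tau_final = np.bincount(z, minlength=K).astype(np.int64)
    state = DmmModelState(
        K=K,
        alpha=alpha,
        beta=beta,
        tau=tau_final,
        omega={s: np.rint(omega[s]).astype(np.int64) for s in omega},
        assignments=z,
        seed=config.seed,
        iterations_run=(0 if init_state is None else init_state.iterations_run) + config.iterations,
        schema=corpus.schema,
    )
    state.validate(corpus)
    return FitResult(
        state=state,
        estimated_clusters=estimated_cluster_count(state),
        history=history,
        log_joint_trace=log_joint_trace,
    )


def estimated_cluster_count(state: DmmModelState) -> int:
    """Number of non-empty clusters (tau_k > 0).

    With K chosen generously the sampler leaves surplus clusters empty,
    so this is the automatically determined effective cluster count.
    """
    return int(np.count_nonzero(state.tau))


# ---------------------------------------------------------------------------
# Held-out assignment


def assign(
    segment: Segment,
    state: DmmModelState,
    mode: str = "map",
    iterations: int = 50,
    seed: int = 0,
) -> int:
    """Cluster a held-out segment against fitted count tables.

    ``map``: argmax of the held-out conditional (training counts, no
    decrement; the segment is not part of the tables).  Ties break to
    the lowest cluster index.  ``gibbs``: ``iterations`` resampling
    steps where the segment's own counts are added and removed around
    each draw; returns the final draw.  Deterministic given ``seed``.

    Token ids must lie inside the model's vocabularies; an all-empty
    segment is assigned from the cluster-size prior alone.
    """
    if mode not in ("map", "gibbs"):
        raise ConfigError(f"unknown assignment mode {mode!r}")
    streams = state.streams
    seg_counts = _segment_counts(segment, streams)
    for s, (idx, _, _) in seg_counts.items():
        if idx.size and (idx.min() < 0 or idx.max() >= state.beta[s].shape[1]):
            raise IntegrityError(f"segment token id out of model vocabulary for stream {s!r}")
    tau = state.tau.astype(np.float64)
    beta_tot = {s: state.beta[s].sum(axis=1) for s in streams}
    omega = {s: state.omega[s].astype(np.float64) for s in streams}
    omega_tot = {s: omega[s].sum(axis=1) for s in streams}

    logw = _conditional_logw(tau, state.alpha, omega, omega_tot, state.beta, beta_tot, seg_counts)
    if mode == "map":
        return int(np.argmax(logw))

    # gibbs: attach the segment to the tables, then resample its (and
    # only its) assignment with its counts removed around each draw.
    rng = np.random.default_rng(seed)
    k = _sample_from_logw(logw, rng)
    _add_segment(tau, omega, omega_tot, seg_counts, k, +1.0)
    for _ in range(iterations):
        _add_segment(tau, omega, omega_tot, seg_counts, k, -1.0)
        logw = _conditional_logw(tau, state.alpha, omega, omega_tot, state.beta, beta_tot, seg_counts)
        k = _sample_from_logw(logw, rng)
        _add_segment(tau, omega, omega_tot, seg_counts, k, +1.0)
    return int(k)


def _add_segment(tau, omega, omega_tot, seg_counts, k, sign):
    tau[k] += sign
    for s, (idx, cnt, N) in seg_counts.items():
        omega[s][k, idx] += sign * cnt
        omega_tot[s][k] += sign * N


def _sample_from_logw(logw: np.ndarray, rng: np.random.Generator) -> int:
    p = np.exp(logw - logw.max())
    cp = np.cumsum(p)
    k = int(np.searchsorted(cp, rng.random() * cp[-1], side="right"))
    return min(k, len(logw) - 1)


def drop_out_of_vocabulary(
    tokens: Mapping[str, Sequence[str]], schema,
) -> tuple[dict[str, np.ndarray], int]:
    """Map string tokens to model word ids, dropping unknown words.

    Returns the integer token dict plus the number of dropped
    occurrences (the model carries no probability for unseen words).
    """
    mapped: dict[str, np.ndarray] = {}
    dropped = 0
    for s in schema.streams:
        ids = schema.word_ids(s)
        seq = [ids[w] for w in tokens.get(s, []) if w in ids]
        dropped += len(tokens.get(s, [])) - len(seq)
        mapped[s] = np.asarray(seq, dtype=np.int64)
    return mapped, dropped
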