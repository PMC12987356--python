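"""Burstiness diagnostics for token streams.

The question the diagnostic answers: do word counts within an activity
decay like a multinomial (exponentially — a straight line on semi-log
axes) or like a power law (a straight line on log-log axes)?  Bursty
data show the latter: a word that appears once in an activity tends to
appear again, inflating the tail of its count distribution far beyond
what its overall frequency predicts.

Procedure: for every word, the empirical probability of appearing
exactly x times within a counting unit is computed; words are split by
overall frequency into three groups (frequent / average / rare), the
per-word probabilities are averaged within each group, and each group's
curve is fitted on log-log axes.  A matched multinomial reference —
same per-word mean frequencies, same unit sizes — is simulated for
comparison: its curves fit better on semi-log axes and carry strictly
less tail mass.

The counting unit is either each labeled segment ("segment", the
default) or all segments of one activity pooled ("activity-block");
both readings of "count within an activity" are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import Corpus
from .dmm import dm_log_pmf
from .errors import ConfigError


@dataclass
class CountDistribution:
    """Per-word occurrence counts across counting units.

    ``matrix[i, v]`` is the number of times word v occurs in unit i;
    the per-word pmf over x is the column-wise empirical distribution.
    """

    words: list[str]
    unit_groups: list[str]       # stratum (label or cluster) of each unit
    matrix: np.ndarray           # (n_units, V) int

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    def pmf(self, v: int) -> tuple[np.ndarray, np.ndarray]:
        """Support and probabilities of word v's count distribution (sums to 1)."""
        counts = np.bincount(self.matrix[:, v])
        support = np.nonzero(counts)[0]
        return support, counts[support] / self.n_units

    def word_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def count_distribution(
    corpus: Corpus,
    stream: str | None = None,
    grouping: str = "by-label",
    unit: str = "segment",
    assignments: Sequence[int] | None = None,
) -> CountDistribution:
    """Occurrence-count matrix of one stream's words over counting units.

    ``grouping`` names the stratifier: ground-truth labels or cluster
    assignments.  ``unit="segment"`` counts within each stratified
    segment; ``unit="activity-block"`` pools all segments sharing a
    stratum into one block each.
    """
    if grouping not in ("by-label", "by-cluster"):
        raise ConfigError(f"unknown grouping {grouping!r}")
    if unit not in ("segment", "activity-block"):
        raise ConfigError(f"unknown counting unit {unit!r}")
    if stream is None:
        stream = corpus.schema.streams[0]
    V = corpus.schema.vocab_size(stream)

    if grouping == "by-label":
        strata = [seg.label for seg in corpus.segments]
        if all(s is None for s in strata):
            raise ConfigError("grouping by label requires labeled segments")
    else:
        if assignments is None:
            raise ConfigError("grouping by cluster requires an assignments vector")
        strata = [str(k) for k in assignments]

    rows: list[np.ndarray] = []
    groups: list[str] = []
    if unit == "segment":
        for seg, stratum in zip(corpus.segments, strata):
            if stratum is None:
                continue
            row = np.zeros(V, dtype=np.int64)
            np.add.at(row, seg.tokens[stream], 1)
            rows.append(row)
            groups.append(str(stratum))
    else:
        block: dict[str, np.ndarray] = {}
        for seg, stratum in zip(corpus.segments, strata):
            if stratum is None:
                continue
            row = block.setdefault(str(stratum), np.zeros(V, dtype=np.int64))
            np.add.at(row, seg.tokens[stream], 1)
        for stratum in block:
            rows.append(block[stratum])
            groups.append(stratum)
    return CountDistribution(
        words=list(corpus.schema.vocabularies[stream]),
        unit_groups=groups,
        matrix=np.stack(rows),
    )


@dataclass
class GroupCurve:
    """Averaged count-probability curve for one frequency group.

    Raw support points are kept for plotting and tail masses; the slope
    and goodness-of-fit numbers come from logarithmically binned points,
    the standard practice for heavy-tailed pmfs (it equalizes sampling
    noise across decades instead of letting the sparse deep tail
    dominate the fit).
    """

    name: str
    members: list[str]
    x: np.ndarray                # support (x >= 1) with positive averaged probability
    p: np.ndarray                # averaged empirical P(count = x)
    x_binned: np.ndarray         # geometric bin centers
    p_binned: np.ndarray         # bin-averaged probability
    slope: float                 # least-squares slope of log p vs log x (binned)
    r2_loglog: float
    r2_semilog: float

    def tail_mass(self, threshold: int = 10) -> float:
        """Averaged probability of a count >= threshold."""
        return float(self.p[self.x >= threshold].sum())


@dataclass
class BurstinessReport:
    """Frequency-grouped count-probability curves plus a multinomial reference."""

    groups: dict[str, GroupCurve]
    reference: dict[str, GroupCurve] | None = None
    group_sizes: tuple[int, int, int] = (0, 0, 0)

    def to_json_obj(self) -> dict:
        def enc(curves):
            return {
                name: {
                    "x": c.x.tolist(),
                    "p": c.p.tolist(),
                    "slope": c.slope,
                    "r2_loglog": c.r2_loglog,
                    "r2_semilog": c.r2_semilog,
                    "tail_mass_ge_10": c.tail_mass(10),
                    "n_members": len(c.members),
                }
                for name, c in curves.items()
            }

        obj = {"group_sizes": list(self.group_sizes), "groups": enc(self.groups)}
        if self.reference is not None:
            obj["reference_multinomial"] = enc(self.reference)
        return obj


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of y on x."""
    if len(x) < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def _log_bin(x: np.ndarray, p: np.ndarray, ratio: float = 1.6) -> tuple[np.ndarray, np.ndarray]:
    """Average the curve within geometric bins [1, r), [r, r^2), ..."""
    edges = [1.0]
    while edges[-1] <= x.max():
        edges.append(edges[-1] * ratio)
    bx, bp = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (x >= lo) & (x < hi)
        if m.any():
            bx.append(float(np.exp(np.mean(np.log(x[m])))))
            bp.append(float(p[m].mean()))
    return np.asarray(bx), np.asarray(bp)


def _group_curve(name: str, members_idx: np.ndarray, dist: CountDistribution) -> GroupCurve:
    sub = dist.matrix[:, members_idx]
    max_count = int(sub.max()) if sub.size else 0
    # averaged P(count = x) over the group's words, for x >= 1
    avg = np.zeros(max_count + 1)
    for j in range(sub.shape[1]):
        counts = np.bincount(sub[:, j], minlength=max_count + 1)
        avg += counts / dist.n_units
    avg /= max(sub.shape[1], 1)
    x = np.arange(1, max_count + 1)
    mask = avg[1:] > 0
    x, p = x[mask], avg[1:][mask]
    if len(x):
        bx, bp = _log_bin(x.astype(float), p)
        slope, r2_loglog = _fit_line(np.log(bx), np.log(bp))
        _, r2_semilog = _fit_line(bx, np.log(bp))
    else:
        bx = bp = np.zeros(0)
        slope = r2_loglog = r2_semilog = float("nan")
    return GroupCurve(
        name=name,
        members=[dist.words[i] for i in members_idx],
        x=x,
        p=p,
        x_binned=bx,
        p_binned=bp,
        slope=slope,
        r2_loglog=r2_loglog,
        r2_semilog=r2_semilog,
    )


def frequency_groups(
    dist: CountDistribution, group_sizes: tuple[int, int, int]
) -> dict[str, np.ndarray]:
    """Partition word indices into frequent / average / rare rank groups.

    Words are ranked by total frequency (descending; ties broken by
    word string so the split is deterministic).  The frequent group is
    the top ``n_frequent`` ranks, the rare group the bottom ``n_rare``,
    and the average group a band of ``n_average`` ranks centered on the
    median rank.
    """
    n_freq, n_avg, n_rare = group_sizes
    V = len(dist.words)
    if n_freq + n_avg + n_rare > V:
        raise ConfigError("group sizes exceed vocabulary size")
    totals = dist.word_totals()
    order = sorted(range(V), key=lambda i: (-totals[i], dist.words[i]))
    order = np.asarray(order)
    mid = V // 2
    start = max(n_freq, min(mid - n_avg // 2, V - n_rare - n_avg))
    if start < n_freq or start + n_avg > V - n_rare:
        raise ConfigError("average-frequency band overlaps the frequent or rare group")
    return {
        "frequent": order[:n_freq],
        "average": order[start : start + n_avg],
        "rare": order[V - n_rare :] if n_rare else order[:0],
    }


def vocabulary_curve(dist: CountDistribution) -> GroupCurve:
    """Averaged count-probability curve over the entire vocabulary."""
    return _group_curve("all", np.arange(len(dist.words)), dist)


def matched_multinomial(dist: CountDistribution, seed: int = 0) -> CountDistribution:
    """Simulate the null: same per-word mean frequencies, same unit sizes, no burstiness.

    Each unit's tokens are redrawn i.i.d. from the global word-frequency
    distribution, so counts are multinomial with matched means.
    """
    rng = np.random.default_rng(seed)
    totals = dist.word_totals().astype(np.float64)
    if totals.sum() == 0:
        raise ConfigError("empty count matrix")
    p = totals / totals.sum()
    unit_sizes = dist.matrix.sum(axis=1)
    matrix = np.stack([rng.multinomial(int(n), p) for n in unit_sizes])
    return CountDistribution(words=list(dist.words), unit_groups=list(dist.unit_groups), matrix=matrix)


def burstiness_report(
    dist: CountDistribution,
    group_sizes: tuple[int, int, int],
    reference_seed: int | None = 0,
) -> BurstinessReport:
    """Frequency-grouped averaged count-probability curves with log-log fits.

    ``reference_seed`` controls the matched-multinomial simulation;
    pass None to skip the reference.
    """
    groups_idx = frequency_groups(dist, group_sizes)
    groups = {name: _group_curve(name, idx, dist) for name, idx in groups_idx.items() if len(idx)}
    reference = None
    if reference_seed is not None:
        ref_dist = matched_multinomial(dist, seed=reference_seed)
        reference = {
            name: _group_curve(name, idx, ref_dist) for name, idx in groups_idx.items() if len(idx)
        }
    return BurstinessReport(groups=groups, reference=reference, group_sizes=tuple(group_sizes))


def dm_power_law_slope(
    beta_v: float,
    beta_total: float,
    fixed_other_count: int = 0,
    x_min: int = 1000,
    x_max: int = 10000,
    n_points: int = 25,
) -> float:
    """Tail exponent of the DM count pmf for one word.

    Holding the other words' counts fixed, P(x_v) from the DM pmf
    behaves as O(x_v^(beta_v - beta_total)) for large x_v; this
    measures the realized log-log slope over [x_min, x_max].  A large
    fixed background count N' delays the asymptote (the local slope is
    scaled by roughly x/(x+N')), so the default holds the other counts
    at zero.
    """
    if beta_total <= beta_v:
        raise ConfigError("beta_total must exceed beta_v")
    beta = np.array([beta_v, beta_total - beta_v])
    xs = np.unique(np.geomspace(x_min, x_max, n_points).astype(np.int64))
    logp = np.array([dm_log_pmf(np.array([x, fixed_other_count]), beta) for x in xs])
    slope, _ = _fit_line(np.log(xs.astype(float)), logp)
    return slope


def plot_burstiness(report: BurstinessReport, path: str) -> str:
    """Log-log plot of the grouped curves (reference dashed), written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    colors = {"frequent": "C0", "average": "C1", "rare": "C2"}
    for name, curve in report.groups.items():
        ax.loglog(curve.x, curve.p, "o-", ms=3, color=colors.get(name), label=name)
    if report.reference:
        for name, curve in report.reference.items():
            ax.loglog(curve.x, curve.p, "--", lw=1, color=colors.get(name), alpha=0.6)
    ax.set_xlabel("count x within unit")
    ax.set_ylabel("averaged P(count = x)")
    ax.legend(title="frequency group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
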