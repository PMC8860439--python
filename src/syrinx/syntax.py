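"""Behavioral statistics on annotated song: transition matrices, branch-point
stability, and probabilistic suffix trees (PSTs).

Bigram counts within bouts (never across bouts) are row-normalized into a
first-order Markov transition matrix; end of song is an explicit outcome
symbol, and probabilities below a floor (default 0.002) are zeroed after
normalization without renormalizing.  Branch-point stability across two
days is assessed with a permutation test on the day labels of pooled
transition outcomes.  PSTs are variable-order Markov models whose nodes
are history suffixes; a node enters the tree only if its history occurs
with frequency at least ``p_min``, selected by cross-validated held-out
negative log-likelihood.

For canaries, analyses run on phrase sequences (runs of one syllable type
collapsed to a single symbol, :func:`collapse_repeats`); for Bengalese
finches they run on raw syllable sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_song import END

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "collapse_repeats",
    "branch_outcomes",
    "branchpoint_permutation_test",
    "bonferroni",
    "PSTConfig",
    "PSTNode",
    "PST",
    "fit_pst",
    "pst_negative_log_likelihood",
    "cross_validate_pmin",
]

#: reserved start-of-song symbol prepended to every sequence (single char,
#: so suffix contexts like "^A" remain well-formed strings)
START = "^"


@dataclass
class TransitionMatrix:
    """First-order Markov transition matrix with an END outcome column."""

    labels: list[str]           # row labels ('from')
    to_labels: list[str]        # column labels ('to'), includes END
    counts: np.ndarray          # integer bigram counts
    p: np.ndarray               # row-stochastic before flooring

    def prob(self, from_label: str, to_label: str) -> float:
        return float(
            self.p[self.labels.index(from_label), self.to_labels.index(to_label)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.labels, columns=self.to_labels)


def collapse_repeats(sequence: list[str]) -> list[str]:
    """Collapse runs of a repeated symbol to one symbol per run (phrase
    sequence of a canary bout)."""
    out: list[str] = []
    for sym in sequence:
        if not out or out[-1] != sym:
            out.append(sym)
    return out


def transition_matrix(
    sequences: list[list[str]], prob_floor: float = 0.002
) -> TransitionMatrix:
    """Bigram transition matrix over bout label sequences.

    Counts consecutive pairs within each bout plus one END event per
    non-empty bout; rows are normalized to probabilities, then entries
    below ``prob_floor`` are set to zero.  Rows are *not* renormalized
    after flooring.
    """
    labels = sorted({sym for seq in sequences for sym in seq})
    to_labels = labels + [END]
    idx = {lab: i for i, lab in enumerate(labels)}
    jdx = {lab: j for j, lab in enumerate(to_labels)}
    counts = np.zeros((len(labels), len(to_labels)), dtype=np.int64)
    for seq in sequences:
        for a, b in zip(seq, seq[1:]):
            counts[idx[a], jdx[b]] += 1
        if seq:
            counts[idx[seq[-1]], jdx[END]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        p = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    p = np.where(p < prob_floor, 0.0, p)
    return TransitionMatrix(labels=labels, to_labels=to_labels, counts=counts, p=p)


def branch_outcomes(sequences: list[list[str]], branch_label: str) -> list[str]:
    """Outcome symbols following every occurrence of ``branch_label``
    (END when the branch syllable ends the bout)."""
    outcomes = []
    for seq in sequences:
        for k, sym in enumerate(seq):
            if sym == branch_label:
                outcomes.append(seq[k + 1] if k + 1 < len(seq) else END)
    return outcomes


def branchpoint_permutation_test(
    outcomes_day1: list[str],
    outcomes_day2: list[str],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test for stability of a branch point across two days.

    The statistic is the maximum absolute difference, across outcome
    classes, between the two days' outgoing probability vectors.  The null
    distribution permutes the day labels of the pooled outcomes; this is
    realized exactly by drawing day-1 outcome counts from the multivariate
    hypergeometric distribution on the pooled counts.  Returns
    ``(observed_statistic, p_value)`` with the permutation convention
    ``p = (1 + #{perm >= obs}) / (n_perm + 1)``, so p is never 0.
    """
    if not outcomes_day1 or not outcomes_day2:
        raise ValueError("the branch point must occur at least once on each day")
    if rng is None:
        rng = np.random.default_rng()
    classes = sorted(set(outcomes_day1) | set(outcomes_day2))
    c1 = np.array([outcomes_day1.count(c) for c in classes], dtype=np.int64)
    c2 = np.array([outcomes_day2.count(c) for c in classes], dtype=np.int64)
    n1, n2 = c1.sum(), c2.sum()
    observed = float(np.max(np.abs(c1 / n1 - c2 / n2)))
    pooled = c1 + c2
    draws = rng.multivariate_hypergeometric(pooled, int(n1), size=n_perm)
    perm1 = draws / n1
    perm2 = (pooled - draws) / n2
    perm_stats = np.abs(perm1 - perm2).max(axis=1)
    p = (1 + int((perm_stats >= observed - 1e-12).sum())) / (n_perm + 1)
    return observed, float(p)


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni correction across (branch point, day pair) tests."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


# ---- probabilistic suffix trees -------------------------------------------


@dataclass(frozen=True)
class PSTConfig:
    """p_min: minimum history frequency for a node; max_depth: longest
    history; gain_threshold: minimum frequency-weighted KL divergence of a
    child's next-symbol distribution from its parent's (0 = grow on
    frequency alone)."""

    p_min: float = 0.01
    max_depth: int = 5
    gain_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_min < 1.0:
            raise ValueError("p_min must be in (0, 1)")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


@dataclass
class PSTNode:
    """One suffix node: its context (most recent symbol last), the fraction
    of transitions whose history ends with that context, and the
    next-symbol distribution (including END)."""

    context: str
    frequency: float
    next_dist: dict[str, float]


@dataclass
class PST:
    """Rooted suffix tree: context string -> node; root context is ""."""

    nodes: dict[str, PSTNode]
    alphabet: list[str]
    n_transitions: int
    config: PSTConfig = field(default_factory=PSTConfig)

    @property
    def depth(self) -> int:
        return max(len(ctx) for ctx in self.nodes)

    def deepest_context(self, history: str) -> PSTNode:
        """Node of the longest suffix of ``history`` present in the tree."""
        for k in range(min(len(history), self.depth), -1, -1):
            node = self.nodes.get(history[len(history) - k:])
            if node is not None:
                return node
        raise AssertionError("root context missing")

    def to_json_dict(self) -> dict:
        return {
            "alphabet": self.alphabet,
            "n_transitions": self.n_transitions,
            "nodes": {
                ctx: {"frequency": n.frequency, "next_dist": n.next_dist}
                for ctx, n in self.nodes.items()
            },
        }


def _histories_and_transitions(sequences: list[list[str]]):
    """Each bout contributes transitions (history, next) with the history
    starting at the reserved start symbol and the last next being END."""
    transitions = []
    for seq in sequences:
        history = START
        for sym in seq:
            transitions.append((history, sym))
            history += sym
        transitions.append((history, END))
    return transitions


def _kl(p: dict[str, float], q: dict[str, float], symbols: list[str]) -> float:
    out = 0.0
    for s in symbols:
        ps = p.get(s, 0.0)
        if ps > 0:
            qs = max(q.get(s, 0.0), 1e-12)
            out += ps * np.log(ps / qs)
    return out


def fit_pst(sequences: list[list[str]], cfg: PSTConfig = PSTConfig()) -> PST:
    """Grow a probabilistic suffix tree by iterative addition of nodes.

    Starting from the root (zero-order next-symbol frequencies), a
    candidate node extends an existing context by one earlier symbol and
    is added iff its history frequency is at least ``p_min`` *and* the
    frequency-weighted KL divergence of its next-symbol distribution from
    its parent's exceeds ``gain_threshold``.  A ``p_min`` so high that no
    candidate survives yields a valid depth-0 tree.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    for seq in sequences:
        if any(len(sym) != 1 or sym == START for sym in seq):
            raise ValueError(
                f"symbols must be single characters other than {START!r}"
            )
    transitions = _histories_and_transitions(sequences)
    total = len(transitions)
    alphabet = sorted({sym for seq in sequences for sym in seq})
    out_symbols = alphabet + [END]

    # count (history-suffix, next) pairs once, for every suffix length that
    # could become a node; turns candidate scoring into dict lookups
    ctx_next: dict[str, dict[str, int]] = {}
    for history, nxt in transitions:
        hlen = len(history)
        for k_len in range(0, min(hlen, cfg.max_depth) + 1):
            ctx = history[hlen - k_len:]
            bucket = ctx_next.setdefault(ctx, {})
            bucket[nxt] = bucket.get(nxt, 0) + 1

    def stats_for(ctx: str):
        counts = ctx_next.get(ctx)
        if not counts:
            return 0.0, {}
        n = sum(counts.values())
        return n / total, {s: c / n for s, c in counts.items()}

    root_freq, root_dist = stats_for("")
    nodes = {"": PSTNode(context="", frequency=root_freq, next_dist=root_dist)}
    frontier = [""]
    extension_symbols = alphabet + [START]
    while frontier:
        ctx = frontier.pop(0)
        if len(ctx) >= cfg.max_depth:
            continue
        for sym in extension_symbols:
            child_ctx = sym + ctx
            if child_ctx in nodes or START in child_ctx[1:]:
                continue
            freq, dist = stats_for(child_ctx)
            if freq < cfg.p_min or not dist:
                continue
            gain = freq * _kl(dist, nodes[ctx].next_dist, out_symbols)
            if gain <= cfg.gain_threshold:
                continue
            nodes[child_ctx] = PSTNode(
                context=child_ctx, frequency=freq, next_dist=dist
            )
            frontier.append(child_ctx)
    return PST(nodes=nodes, alphabet=alphabet, n_transitions=total, config=cfg)


def pst_negative_log_likelihood(pst: PST, sequences: list[list[str]]) -> float:
    """Mean negative log-likelihood per transition of held-out bouts.

    Each transition is scored by the deepest matching suffix node.
    Zero-probability (or unseen) outcomes are handled by additive
    smoothing with epsilon = 1 / (training transitions), so scores stay
    finite for held-out novelties.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    eps = 1.0 / pst.n_transitions
    n_out = len(pst.alphabet) + 1  # + END
    nll = 0.0
    count = 0
    for history, nxt in _histories_and_transitions(sequences):
        node = pst.deepest_context(history)
        p = node.next_dist.get(nxt, 0.0)
        p_smooth = (p + eps) / (1.0 + n_out * eps)
        nll -= np.log(p_smooth)
        count += 1
    return nll / count


def cross_validate_pmin(
    sequences: list[list[str]],
    pmin_grid: list[float],
    k: int = 10,
    rng: np.random.Generator | None = None,
    cfg: PSTConfig = PSTConfig(),
) -> tuple[pd.DataFrame, float]:
    """Select ``p_min`` by 10-fold cross-validated held-out NLL.

    For each grid value, the bouts are randomly split 90/10 into training
    and test sets ``k`` times; a PST is fit on the training songs and the
    mean test negative log-likelihood per transition is recorded.  Returns
    the (p_min, mean NLL) table and the argmin of the mean NLL.
    """
    if len(sequences) < 20:
        raise ValueError("need at least 20 sequences for 90/10 cross-validation")
    if any(p >= 1.0 for p in pmin_grid):
        raise ValueError("p_min grid values must be < 1")
    if rng is None:
        rng = np.random.default_rng()
    n = len(sequences)
    n_test = max(1, n // 10)
    splits = []
    for _ in range(k):
        perm = rng.permutation(n)
        splits.append((perm[n_test:], perm[:n_test]))
    rows = []
    for p_min in pmin_grid:
        run_cfg = PSTConfig(
            p_min=p_min, max_depth=cfg.max_depth, gain_threshold=cfg.gain_threshold
        )
        nlls = []
        for train_idx, test_idx in splits:
            pst = fit_pst([sequences[i] for i in train_idx], run_cfg)
            nlls.append(
                pst_negative_log_likelihood(pst, [sequences[i] for i in test_idx])
            )
        rows.append({"p_min": p_min, "mean_nll": float(np.mean(nlls))})
    table = pd.DataFrame(rows)
    pmin_opt = float(table.loc[table["mean_nll"].idxmin(), "p_min"])
    return table, pmin_opt
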