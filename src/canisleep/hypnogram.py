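"""Sleep-architecture quantification from scored hypnograms.

Four analyses: the percentage of recording time spent in each behavioural
state, state latencies (time to first epoch of a state, censored at the
total recording duration when the state never occurs), the Lempel-Ziv
production complexity of the state sequence, and the first-order
transition-probability matrix between consecutive epochs. All epochs
enter these analyses, including artifact-flagged ones; the artifact flags
only matter for EEG-signal metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Hypnogram, N_STATES, STATE_NAMES
from .stats import paired_wilcoxon


def lzc_sequence(seq: Sequence[int] | str | np.ndarray) -> int:
    """Lempel-Ziv production complexity of a symbol sequence.

    Implements the Kaspar-Schuster counting algorithm: the number of
    phrases in the exhaustive production history, where each phrase is the
    shortest extension of the parsed prefix that cannot be copied from the
    already-seen text. Works over any finite alphabet (hypnogram states or
    a binarized signal alike). A constant sequence of length >= 2 has
    complexity 2; complexity grows toward n / log_k(n) for random text.
    """
    vals = seq.tolist() if isinstance(seq, np.ndarray) else list(seq)
    n = len(vals)
    if n == 0:
        raise ValueError("empty sequence")
    sym: dict = {}
    for v in vals:
        sym.setdefault(v, len(sym))
    if len(sym) > 256:
        raise ValueError("alphabet larger than 256 symbols")
    b = bytes(sym[v] for v in vals)
    # exhaustive history: each phrase is the shortest extension of the
    # parsed text not reproducible (as a substring) from what precedes
    # its last symbol; the final phrase may remain reproducible
    c = 0
    j = 0
    while j < n:
        k = 1
        while j + k <= n and b[j:j + k] in b[:j + k - 1]:
            k += 1
        c += 1
        if j + k > n:
            break
        j += k
    return c


def lzc_normalized(seq: Sequence[int] | np.ndarray, n_symbols: int) -> float:
    """Normalized LZ complexity c(n) * log_k(n) / n for alphabet size k."""
    s = np.asarray(list(seq))
    n = s.size
    if n < 2:
        raise ValueError("need length >= 2 to normalize")
    return lzc_sequence(s) * (np.log(n) / np.log(n_symbols)) / n


def percent_time(hyp: Hypnogram) -> np.ndarray:
    """Percentage of epochs spent in each state (length-4 vector, sums to
    100). Every scored epoch counts, artifact-flagged or not."""
    if len(hyp) == 0:
        raise ValueError("empty hypnogram")
    counts = np.bincount(hyp.states, minlength=N_STATES)
    return 100.0 * counts / len(hyp)


def latency(hyp: Hypnogram, state: int,
            total_min: float | None = None) -> tuple[float, bool]:
    """Minutes until the first epoch of ``state``; censored at the total
    recording duration when the state never occurs.

    Follows the study convention of assigning the full recording length
    (120 min for the 2-h sessions) as the latency of a never-entered state.
    """
    if total_min is None:
        total_min = hyp.duration_min
    if total_min <= 0:
        raise ValueError("total_min must be positive")
    hits = np.flatnonzero(hyp.states == state)
    if hits.size == 0:
        return float(total_min), True
    return float(hits[0] * hyp.epoch_length_s / 60.0), False


@dataclass
class TransitionMatrix:
    """First-order state-transition counts and row-normalized probabilities.

    ``probs[i, j]`` is P(state j at epoch t+1 | state i at epoch t); the
    diagonal is the probability of remaining in a state. Rows for states
    never occupied (before the last epoch) are undefined and stored NaN.
    """

    counts: np.ndarray
    probs: np.ndarray

    @property
    def defined_rows(self) -> np.ndarray:
        return self.counts.sum(axis=1) > 0


def transition_matrix(hyp: Hypnogram) -> TransitionMatrix:
    """Estimate the 4x4 transition matrix from consecutive epoch pairs."""
    if len(hyp) < 2:
        raise ValueError("need at least 2 epochs")
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    np.add.at(counts, (hyp.states[:-1], hyp.states[1:]), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_sums
    probs[row_sums[:, 0] == 0] = np.nan
    return TransitionMatrix(counts=counts, probs=probs)


@dataclass
class ArchitectureSummary:
    """Per-session sleep-architecture metrics."""

    percent_time: np.ndarray              # (4,) %
    latency_min: np.ndarray               # (4,) minutes
    censored: np.ndarray                  # (4,) bool
    hypnogram_lzc: int
    transitions: TransitionMatrix


def summarize_architecture(hyp: Hypnogram,
                           total_min: float | None = None,
                           ) -> ArchitectureSummary:
    lat = np.empty(N_STATES)
    cen = np.empty(N_STATES, dtype=bool)
    for s in range(N_STATES):
        lat[s], cen[s] = latency(hyp, s, total_min)
    return ArchitectureSummary(
        percent_time=percent_time(hyp),
        latency_min=lat,
        censored=cen,
        hypnogram_lzc=lzc_sequence(hyp.states),
        transitions=transition_matrix(hyp),
    )


def architecture_table(summaries: Mapping[str, Mapping[str, ArchitectureSummary]],
                       ) -> pd.DataFrame:
    """Tidy per-session table (subject, condition, metric, state, value)."""
    rows = []
    for cond, per_subject in summaries.items():
        for subj, summ in per_subject.items():
            for s in range(N_STATES):
                rows.append((subj, cond, "percent_time", STATE_NAMES[s],
                             summ.percent_time[s]))
                rows.append((subj, cond, "latency_min", STATE_NAMES[s],
                             summ.latency_min[s]))
            rows.append((subj, cond, "hypnogram_lzc", "", summ.hypnogram_lzc))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "metric",
                                       "state", "value"])


def transition_table(summaries: Mapping[str, Mapping[str, ArchitectureSummary]],
                     ) -> pd.DataFrame:
    rows = []
    for cond, per_subject in summaries.items():
        for subj, summ in per_subject.items():
            tm = summ.transitions
            for i in range(N_STATES):
                for j in range(N_STATES):
                    rows.append((subj, cond, STATE_NAMES[i], STATE_NAMES[j],
                                 int(tm.counts[i, j]), tm.probs[i, j]))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "from_state",
                                       "to_state", "count", "prob"])


def compare_architecture(control: Mapping[str, ArchitectureSummary],
                         trazodone: Mapping[str, ArchitectureSummary],
                         ) -> pd.DataFrame:
    """Paired two-sided Wilcoxon tests on every architecture metric.

    Tests percent-time and latency per state (censored latencies enter at
    their censored value), hypnogram LZC, and each transition-probability
    cell (over subjects where the cell is defined in both conditions;
    undefined cells are never imputed). Returns a tidy result table.
    """
    common = sorted(set(control) & set(trazodone))
    if len(common) < 2:
        raise ValueError("need >= 2 subjects recorded in both conditions")

    rows = []

    def add(metric: str, state: str, x: np.ndarray, y: np.ndarray) -> None:
        valid = ~(np.isnan(x) | np.isnan(y))
        if valid.sum() < 2:
            return
        res = paired_wilcoxon(x[valid], y[valid])
        rows.append((metric, state, res.statistic, res.p_value, res.n_used,
                     res.method, res.degenerate))

    for s in range(N_STATES):
        add("percent_time", STATE_NAMES[s],
            np.array([control[d].percent_time[s] for d in common]),
            np.array([trazodone[d].percent_time[s] for d in common]))
        add("latency_min", STATE_NAMES[s],
            np.array([control[d].latency_min[s] for d in common]),
            np.array([trazodone[d].latency_min[s] for d in common]))
    add("hypnogram_lzc", "",
        np.array([control[d].hypnogram_lzc for d in common], dtype=float),
        np.array([trazodone[d].hypnogram_lzc for d in common], dtype=float))
    for i in range(N_STATES):
        for j in range(N_STATES):
            add("transition_prob", f"{STATE_NAMES[i]}->{STATE_NAMES[j]}",
                np.array([control[d].transitions.probs[i, j] for d in common]),
                np.array([trazodone[d].transitions.probs[i, j] for d in common]))
    return pd.DataFrame(rows, columns=["metric", "state", "statistic", "p_value",
                                       "n_used", "method", "degenerate"])
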