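"""Brain-state dynamics: random walks, dwell times, transition statistics.

A Metropolis–Hastings random walk on the pattern hypercube — propose one
of the N single-flip neighbours uniformly, accept with
``min[1, exp(E(current) − E(proposed))]`` — has the model's Boltzmann
distribution as its stationary law and serves as a long surrogate
trajectory of the group-level brain dynamics.  Trajectories (simulated
or empirical binarized data) are classified into brain states via the
basin map, and summarized by dwell times, pairwise transition
frequencies and the frequencies of *indirect* transitions: passages
between two designated states through a prescribed sequence of
intermediate state sets (e.g. A–C/D–B, A–[C/D–E/F]–B, A–C–F–B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .binarize import BinaryTimeSeries
from .landscape import BasinMap, EnergyLandscape
from .mem import MEMParameters, _all_energies
from .patterns import series_to_codes

__all__ = [
    "PatternTrajectory",
    "StateSequence",
    "PathTemplate",
    "TransitionSummary",
    "metropolis_random_walk",
    "patterns_to_states",
    "compress_runs",
    "transition_statistics",
    "count_path_transitions",
    "subject_dynamics",
    "parse_template",
]


@dataclass
class PatternTrajectory:
    """Sequence of visited pattern codes from a random walk.

    The first ``burn_in`` steps have already been discarded; consecutive
    codes differ by exactly one bit (accepted flip) or are equal
    (rejected proposal).
    """

    codes: np.ndarray
    n_nodes: int
    seed: int | None
    n_steps: int
    burn_in: int

    def __len__(self) -> int:
        return self.codes.shape[0]


@dataclass
class StateSequence:
    """Basin (brain-state) labels along a trajectory.

    ``labels`` holds uppercase state letters; patterns that could not be
    assigned to a basin were dropped, their count kept in ``n_dropped``.
    """

    labels: np.ndarray
    source: str  # "simulated" or "empirical"
    subject_id: str | None = None
    n_dropped: int = 0
    state_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class PathTemplate:
    """An indirect-transition template X–B1–…–Bk–Y.

    ``endpoints`` is the ordered pair (X, Y); ``interior_blocks`` is an
    ordered tuple of state sets.  With the default ``ordered=True``
    semantics the interior of a match must decompose exactly into one
    nonempty run-group per block, in order; with ``ordered=False`` the
    interior may interleave freely as long as it stays within the union
    of the blocks and visits every block at least once.  Matches are
    counted in both directions: X→Y with the blocks in order and Y→X
    with the blocks reversed.
    """

    endpoints: tuple[str, str]
    interior_blocks: tuple[frozenset, ...]
    name: str = ""
    ordered: bool = True

    def __post_init__(self) -> None:
        x, y = self.endpoints
        if x == y:
            raise ValueError("endpoints must be two distinct states")
        for block in self.interior_blocks:
            if not block:
                raise ValueError("interior blocks must be nonempty sets")
            if x in block or y in block:
                raise ValueError("endpoints may not appear in interior blocks")
        if not self.name:
            object.__setattr__(self, "name", template_name(self))


def template_name(template: PathTemplate) -> str:
    blocks = ["/".join(sorted(b)) for b in template.interior_blocks]
    x, y = template.endpoints
    prefix = "" if template.ordered else "~"
    if len(blocks) == 1:
        return f"{prefix}{x}-{blocks[0]}-{y}"
    return f"{prefix}{x}-[" + "-".join(blocks) + f"]-{y}"


def parse_template(text: str) -> PathTemplate:
    """Parse ``"A|C,D|B"`` → endpoints (A, B), one interior block {C, D}.

    Pipe-separated fields: first and last are the endpoint states, each
    middle field is a comma-separated state set forming one ordered
    interior block (``"A|C,D|E,F|B"`` has two blocks).  A ``~`` prefix
    (``"~A|C,D|E,F|B"``) selects the unordered visit-all-blocks
    semantics.
    """
    ordered = True
    if text.startswith("~"):
        ordered = False
        text = text[1:]
    parts = [p.strip() for p in text.split("|")]
    if len(parts) < 3:
        raise ValueError("template needs endpoints and at least one interior block")
    blocks = tuple(
        frozenset(s.strip() for s in part.split(",") if s.strip())
        for part in parts[1:-1]
    )
    return PathTemplate(
        endpoints=(parts[0], parts[-1]), interior_blocks=blocks, ordered=ordered
    )


@dataclass
class TransitionSummary:
    """Dwell-time, transition-frequency and path-count statistics."""

    states: list[str]
    transition_counts: np.ndarray  # (K, K), diagonal zero
    transition_freq: np.ndarray  # counts / (sequence length - 1)
    dwell_times: dict[str, list[int]]
    mean_dwell: dict[str, float]
    path_counts: dict[str, int]
    path_freq: dict[str, float]
    n_observations: int  # uncompressed sequence length

    def to_dict(self) -> dict:
        return {
            "states": self.states,
            "transition_counts": self.transition_counts.tolist(),
            "transition_freq": self.transition_freq.tolist(),
            "mean_dwell": self.mean_dwell,
            "path_counts": self.path_counts,
            "path_freq": self.path_freq,
            "n_observations": self.n_observations,
        }


# ---------------------------------------------------------------------------
# random walk


def metropolis_random_walk(
    params: MEMParameters | EnergyLandscape,
    n_steps: int = 100_000,
    burn_in: int = 100,
    seed: int | np.random.Generator | None = None,
    initial: int | None = None,
) -> PatternTrajectory:
    """Metropolis–Hastings single-flip random walk over patterns.

    Starting from a uniformly random pattern (or ``initial``), each step
    proposes one of the N single-flip neighbours uniformly at random and
    moves there with probability ``min[1, exp(E(current) − E(proposed))]``
    — downhill moves are always accepted, uphill moves sometimes, so the
    walk samples the Boltzmann distribution while escaping local minima.
    The first ``burn_in`` visited patterns are discarded, leaving
    ``n_steps − burn_in`` entries.
    """
    if isinstance(params, EnergyLandscape):
        energies = params.energies
        n = params.n_nodes
    else:
        energies = _all_energies(params)
        n = params.n_nodes
    if burn_in < 0 or n_steps <= burn_in:
        raise ValueError("need n_steps > burn_in >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    current = int(rng.integers(0, 2**n)) if initial is None else int(initial)
    flips = rng.integers(0, n, size=n_steps)
    uniforms = rng.random(size=n_steps)

    E = energies.tolist()  # plain floats: faster scalar access in the loop
    out = np.empty(n_steps, dtype=np.int64)
    exp = math.exp
    for t in range(n_steps):
        proposal = current ^ (1 << int(flips[t]))
        dE = E[current] - E[proposal]
        if dE >= 0.0 or uniforms[t] < exp(dE):
            current = proposal
        out[t] = current
    return PatternTrajectory(
        codes=out[burn_in:],
        n_nodes=n,
        seed=seed if isinstance(seed, int) else None,
        n_steps=n_steps,
        burn_in=burn_in,
    )


# ---------------------------------------------------------------------------
# state classification and counting


def patterns_to_states(
    data: PatternTrajectory | BinaryTimeSeries | np.ndarray,
    basins: BasinMap,
    source: str | None = None,
    subject_id: str | None = None,
    drop_ambiguous: bool = False,
) -> StateSequence:
    """Map visited patterns to brain-state labels via the basin map.

    Unassigned patterns (no strictly descending neighbour) are always
    dropped; with ``drop_ambiguous`` the saddle-flagged patterns (tied
    steepest descent) are dropped as well.
    """
    if isinstance(data, PatternTrajectory):
        codes = data.codes
        source = source or "simulated"
    else:
        values = data.values if isinstance(data, BinaryTimeSeries) else np.asarray(data)
        if isinstance(data, BinaryTimeSeries) and subject_id is None:
            subject_id = data.subject_id
        codes = series_to_codes(values)
        source = source or "empirical"
    assignment = basins.assignment[codes]
    keep = assignment >= 0
    if drop_ambiguous:
        keep &= ~basins.ambiguous[codes]
    n_dropped = int((~keep).sum())
    lookup = np.array([m.state_label for m in basins.minima], dtype=object)
    labels = lookup[assignment[keep]]
    return StateSequence(
        labels=labels,
        source=source,
        subject_id=subject_id,
        n_dropped=n_dropped,
        state_labels=list(basins.state_labels),
    )


def compress_runs(seq: StateSequence | Sequence[str]) -> list[tuple[str, int]]:
    """Merge consecutive identical labels into (label, duration) runs."""
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq, dtype=object)
    if len(labels) == 0:
        raise ValueError("cannot compress an empty state sequence")
    runs: list[tuple[str, int]] = []
    current = labels[0]
    count = 1
    for lab in labels[1:]:
        if lab == current:
            count += 1
        else:
            runs.append((current, count))
            current, count = lab, 1
    runs.append((current, count))
    return runs


def transition_statistics(
    seq: StateSequence,
    templates: Iterable[PathTemplate] = (),
) -> TransitionSummary:
    """Dwell times, transition counts/frequencies and path-template counts.

    Transition counts tally label changes between consecutive entries of
    the uncompressed sequence; frequencies divide by (length − 1) so that
    short empirical and long simulated sequences are comparable.
    """
    if len(seq) < 2:
        raise ValueError("need a sequence of length >= 2")
    states = seq.state_labels or sorted(set(seq.labels))
    index = {s: i for i, s in enumerate(states)}
    runs = compress_runs(seq)
    K = len(states)
    counts = np.zeros((K, K), dtype=np.int64)
    for (a, _), (b, _) in zip(runs[:-1], runs[1:]):
        counts[index[a], index[b]] += 1
    denom = len(seq) - 1
    dwell: dict[str, list[int]] = {s: [] for s in states}
    for label, duration in runs:
        dwell[label].append(duration)
    mean_dwell = {
        s: (float(np.mean(d)) if d else 0.0) for s, d in dwell.items()
    }
    path_counts = {}
    path_freq = {}
    for template in templates:
        c, f = count_path_transitions(seq, template, _runs=runs)
        path_counts[template.name] = c
        path_freq[template.name] = f
    return TransitionSummary(
        states=states,
        transition_counts=counts,
        transition_freq=counts / denom,
        dwell_times=dwell,
        mean_dwell=mean_dwell,
        path_counts=path_counts,
        path_freq=path_freq,
        n_observations=len(seq),
    )


def _blocks_match(labels: list[str], blocks: Sequence[frozenset]) -> bool:
    """Exact decomposition check for template interiors.

    True iff the run labels can be split into ``len(blocks)`` contiguous
    nonempty groups where group ``g`` is drawn entirely from
    ``blocks[g]``, in order.  Dynamic program over the invariant
    "after consuming the first i runs, the runs exactly fill the first g
    blocks (each nonempty)"; correct also when adjacent block sets
    overlap, where a greedy scan could fail.
    """
    k = len(blocks)
    if len(labels) < k:
        return False
    reachable = {0}
    for lab in labels:
        nxt = set()
        for g in reachable:
            if g >= 1 and lab in blocks[g - 1]:
                nxt.add(g)  # run continues block g-1
            if g < k and lab in blocks[g]:
                nxt.add(g + 1)  # run opens block g
        reachable = nxt
        if not reachable:
            return False
    return k in reachable


def count_path_transitions(
    seq: StateSequence,
    template: PathTemplate,
    _runs: list[tuple[str, int]] | None = None,
) -> tuple[int, float]:
    """Count indirect transitions matching a path template.

    Operates on the compressed run sequence: a match is a segment running
    from an endpoint run to the next endpoint run (one endpoint each,
    in either direction), whose interior runs decompose exactly into the
    template's ordered blocks — each block contributing at least one run,
    in order (reversed when traversed Y→X).  The frequency divides the
    count by (uncompressed length − 1).
    """
    states = set(seq.state_labels or set(seq.labels))
    x, y = template.endpoints
    for s in (x, y, *(s for b in template.interior_blocks for s in b)):
        if states and s not in states:
            raise ValueError(f"template state {s!r} not in the label set {sorted(states)}")
    runs = _runs if _runs is not None else compress_runs(seq)
    labels = [r[0] for r in runs]
    endpoint_idx = [i for i, lab in enumerate(labels) if lab in (x, y)]
    blocks = template.interior_blocks
    count = 0
    for i, j in zip(endpoint_idx[:-1], endpoint_idx[1:]):
        if labels[i] == labels[j]:
            continue
        interior = labels[i + 1 : j]
        if template.ordered:
            oriented = blocks if labels[i] == x else tuple(reversed(blocks))
            matched = _blocks_match(interior, oriented)
        else:
            union = frozenset().union(*blocks)
            matched = (
                len(interior) > 0
                and all(lab in union for lab in interior)
                and all(any(lab in b for lab in interior) for b in blocks)
            )
        if matched:
            count += 1
    freq = count / (len(seq) - 1) if len(seq) > 1 else 0.0
    return count, freq


def subject_dynamics(
    series: BinaryTimeSeries | np.ndarray,
    basins: BasinMap,
    templates: Iterable[PathTemplate] = (),
    subject_id: str | None = None,
) -> TransitionSummary:
    """Per-subject empirical dynamics features.

    Classifies the subject's binarized patterns into brain states under
    the group-level basin map and returns the transition summary with
    path-template counts — the features used for symptom correlations.
    """
    seq = patterns_to_states(series, basins, source="empirical", subject_id=subject_id)
    return transition_statistics(seq, templates=templates)
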