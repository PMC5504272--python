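"""Random-walk dynamics on the energy landscape and dynamics indices.

A Metropolis-Hastings chain moves between Hamming-1 neighbour patterns and
has the Boltzmann distribution of the fitted model as its stationary law.
Simulated trajectories -- and, through the same code path, empirical
binarized volume sequences -- are summarized as stays in and transitions
between the labelled brain states, yielding the three indices of interest:
intermediate-state frequency, indirect-transition frequency and duration
of the major states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import BrainStatePartition, EnergyLandscape

__all__ = [
    "StateTrajectory",
    "DynamicsIndices",
    "metropolis_walk",
    "acceptance_matrix",
    "to_state_sequence",
    "classify_transitions",
    "summarize_dynamics",
    "running_cv",
]


@dataclass
class StateTrajectory:
    """Sequence of brain-state indices with their label set.

    ``states[t]`` indexes into ``labels``; ``source`` records whether the
    sequence came from simulation or from empirical volumes, and ``seed``
    the generator seed when simulated.
    """

    states: np.ndarray
    labels: tuple[str, ...]
    source: str = "simulated"
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.states)

    @property
    def label_sequence(self) -> list[str]:
        return [self.labels[i] for i in self.states]


@dataclass
class DynamicsIndices:
    """Stay/transition summary of a state trajectory.

    Frequencies are percentages of retained steps; transition counts are
    also reported normalized per step and per label change (the two
    plausible normalizations).  Major-state durations are the lengths of
    maximal constant runs within the major states, in steps (volumes for
    empirical data).
    """

    appearance_freq: dict[str, float]
    intermediate_freq: float
    transition_matrix: np.ndarray
    direct_count: int
    indirect_count: int
    direct_freq: float  # % of steps
    indirect_freq: float  # % of steps
    direct_freq_per_change: float
    indirect_freq_per_change: float
    major_run_lengths: list[int] = field(default_factory=list)
    mean_major_duration: float = np.nan
    n_steps: int = 0


def acceptance_matrix(ls: EnergyLandscape) -> np.ndarray:
    """(2**K, K) Metropolis acceptance probabilities for each bit flip.

    Entry ``[v, i]`` = min(1, exp(E(v) - E(v with bit i flipped))).
    """
    nbr = ls.neighbour_table()
    return np.minimum(1.0, np.exp(ls.energies[:, None] - ls.energies[nbr]))


def metropolis_walk(
    ls: EnergyLandscape,
    n_steps: int,
    seed: int,
    burn_in: int = 100,
    initial: int | None = None,
) -> np.ndarray:
    """Metropolis-Hastings random walk on the hypercube landscape.

    Starts at a uniformly random pattern (or ``initial``); each step
    proposes one of the K neighbours uniformly and accepts with
    min(1, exp(E_current - E_proposed)); a rejected proposal repeats the
    current pattern.  The first ``burn_in`` steps are discarded, so the
    returned code sequence has length ``n_steps - burn_in``.  Fully
    reproducible from ``seed``.
    """
    if n_steps <= burn_in:
        raise ValueError(f"n_steps={n_steps} must exceed burn_in={burn_in}")
    rng = np.random.default_rng(seed)
    code = int(rng.integers(ls.n_patterns)) if initial is None else int(initial)
    accept = acceptance_matrix(ls)
    flips = rng.integers(0, ls.k, size=n_steps)
    unif = rng.random(n_steps)
    out = np.empty(n_steps, dtype=np.int64)
    for t in range(n_steps):
        i = flips[t]
        if unif[t] < accept[code, i]:
            code ^= 1 << i
        out[t] = code
    return out[burn_in:]


def to_state_sequence(
    codes: np.ndarray, partition: BrainStatePartition, source: str = "simulated",
    seed: int | None = None,
) -> StateTrajectory:
    """Map a pattern-code sequence to its basin's brain-state sequence.

    Works identically for simulated walks and for empirical binarized
    volumes (direct counting): each pattern is replaced by the state label
    of the basin it belongs to.
    """
    codes = np.asarray(codes)
    if codes.min(initial=0) < 0 or codes.max(initial=0) >= len(partition.pattern_state):
        raise ValueError("pattern code out of range for this partition")
    return StateTrajectory(
        states=partition.pattern_state[codes],
        labels=partition.labels,
        source=source,
        seed=seed,
    )


def _runs(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (values, lengths) of maximal constant runs."""
    if len(states) == 0:
        return np.array([], dtype=states.dtype), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(states)]))
    return states[starts], ends - starts


def classify_transitions(
    st: StateTrajectory,
) -> tuple[np.ndarray, int, int]:
    """Count state transitions, split into direct and indirect.

    Returns (n_states x n_states transition count matrix over consecutive
    label changes, direct count, indirect count).  A direct transition is a
    single-step change between the two major states.  An indirect
    transition is a completed passage major_a -> (one or more consecutive
    intermediate steps) -> major_b with b != a; an excursion into the
    intermediate state that returns to the same major state counts as no
    transition, and a trajectory ending inside the intermediate state
    contributes none either.
    """
    n = len(st.labels)
    mat = np.zeros((n, n), dtype=np.int64)
    s = st.states
    if len(s) >= 2:
        a, b = s[:-1], s[1:]
        changed = a != b
        np.add.at(mat, (a[changed], b[changed]), 1)

    majors = set()
    minors = set()
    for i, lab in enumerate(st.labels):
        (majors if lab.startswith("major") else minors).add(i)

    direct = 0
    indirect = 0
    vals, _ = _runs(s)
    last_major: int | None = None
    via_intermediate = False
    for v in vals:
        if v in majors:
            if last_major is not None and v != last_major:
                if via_intermediate:
                    indirect += 1
                else:
                    direct += 1
            last_major = int(v)
            via_intermediate = False
        else:
            via_intermediate = True
    return mat, direct, indirect


def summarize_dynamics(st: StateTrajectory) -> DynamicsIndices:
    """All dynamics indices of a state trajectory.

    Appearance frequencies are percentages of the retained steps and sum
    to 100; the intermediate-state frequency pools the minor states;
    major-state durations are maximal constant-run lengths within either
    major state.
    """
    if len(st) < 1:
        raise ValueError("trajectory must contain at least one step")
    n = len(st.labels)
    counts = np.bincount(st.states, minlength=n)
    total = len(st)
    freq = {lab: 100.0 * counts[i] / total for i, lab in enumerate(st.labels)}
    minor_idx = [i for i, lab in enumerate(st.labels) if lab.startswith("minor")]
    intermediate = float(sum(100.0 * counts[i] / total for i in minor_idx))

    mat, direct, indirect = classify_transitions(st)
    n_changes = int(mat.sum())
    per_change = (lambda c: c / n_changes if n_changes else 0.0)
    steps = max(total - 1, 1)

    major_idx = {i for i, lab in enumerate(st.labels) if lab.startswith("major")}
    vals, lens = _runs(st.states)
    run_lengths = [int(l) for v, l in zip(vals, lens) if v in major_idx]
    mean_dur = float(np.mean(run_lengths)) if run_lengths else np.nan

    return DynamicsIndices(
        appearance_freq=freq,
        intermediate_freq=intermediate,
        transition_matrix=mat,
        direct_count=direct,
        indirect_count=indirect,
        direct_freq=100.0 * direct / steps,
        indirect_freq=100.0 * indirect / steps,
        direct_freq_per_change=per_change(direct),
        indirect_freq_per_change=per_change(indirect),
        major_run_lengths=run_lengths,
        mean_major_duration=mean_dur,
        n_steps=total,
    )


def running_cv(
    ls: EnergyLandscape,
    partition: BrainStatePartition,
    n_steps: int = 100_000,
    checkpoints: np.ndarray | None = None,
    n_runs: int = 5,
    seed: int = 0,
    burn_in: int = 100,
    window_fraction: float = 0.5,
) -> dict[str, float]:
    """Convergence diagnostic for the simulated dynamics indices.

    For each run, the indirect-transition frequency and mean major-state
    duration are re-estimated cumulatively at each checkpoint (numbers of
    retained steps); the coefficient of variation of each index over the
    checkpoints in the trailing ``window_fraction`` of the schedule is
    averaged across runs.  A CV near zero indicates the walk length
    suffices.  Indices whose checkpoint mean is zero have an undefined CV
    and are reported as NaN with the ``*_defined`` flag set to False.
    """
    retained = n_steps - burn_in
    if checkpoints is None:
        checkpoints = np.unique(
            np.linspace(retained // 10, retained, 10).astype(int)
        )
    checkpoints = np.asarray(checkpoints, dtype=int)
    if checkpoints.min() <= 0 or checkpoints.max() > retained:
        raise ValueError("checkpoints must lie within (0, n_steps - burn_in]")

    lo = int(np.ceil(len(checkpoints) * (1 - window_fraction)))
    cvs: dict[str, list[float]] = {"indirect_freq": [], "mean_major_duration": []}
    defined = {"indirect_freq": True, "mean_major_duration": True}
    rng = np.random.default_rng(seed)
    for _ in range(n_runs):
        walk = metropolis_walk(ls, n_steps, int(rng.integers(2**31)), burn_in)
        est = {k: [] for k in cvs}
        for cp in checkpoints:
            st = to_state_sequence(walk[:cp], partition)
            ix = summarize_dynamics(st)
            est["indirect_freq"].append(ix.indirect_freq)
            est["mean_major_duration"].append(ix.mean_major_duration)
        for k, series in est.items():
            window = np.asarray(series[lo:], dtype=float)
            m = np.nanmean(window)
            if not np.isfinite(m) or m == 0.0:
                defined[k] = False
                cvs[k].append(np.nan)
            else:
                cvs[k].append(float(np.nanstd(window) / m))
    out: dict[str, float] = {}
    for k, v in cvs.items():
        out[k] = float(np.nanmean(v)) if defined[k] else float("nan")
        out[f"{k}_defined"] = defined[k]
    return out
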