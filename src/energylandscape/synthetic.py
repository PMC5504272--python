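"""Synthetic ground-truth cohorts for end-to-end pipeline testing.

The generator emulates the structure of a two-group resting-state study at
the network level: K=7 binary network activities with planted pairwise-MEM
statistics whose landscapes contain two major states (two minima each) and
two shallow minor states; a TD-like and an ASD-like parameter set that
share the six minima but differ in minor-basin depth; continuous surrogate
signals whose mean-threshold binarization recovers the binary patterns;
and behavioural scores (ADOS-like, FIQ-like) planted with configurable
correlations to each participant's true dynamics indices.

Default cohort sizes (26 TD-like, 24 ASD-like) and series length (240
volumes, an ~8 min scan at TR = 2 s) mirror a single-site resting-state
cohort.  Every stochastic output is reproducible from (master seed,
participant index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._planted import H_ASD, H_TD, J_ASD, J_TD, PLANTED_GROUPING, PLANTED_MINIMA
from .cohort import CohortDataset, Participant
from .dynamics import metropolis_walk, summarize_dynamics, to_state_sequence
from .landscape import (
    BrainStatePartition,
    assign_basins,
    build_disconnectivity_graph,
    build_landscape,
    find_local_minima,
)
from .mem import MEMParams, all_patterns, boltzmann_distribution
from .preprocess import BinaryTimeSeries, NetworkTimeSeries

__all__ = [
    "NETWORKS",
    "PlantedCohortConfig",
    "planted_params",
    "planted_partition",
    "sample_mem_series",
    "lift_to_continuous",
    "build_cohort",
]

#: canonical network order; defines pattern-code bit order
NETWORKS = ("DMN", "FPN", "SAN", "ATN", "SMN", "AUD", "VIS")


@dataclass
class PlantedCohortConfig:
    """Study conditions of the synthetic cohort.

    Behavioural planting: ADOS-like severity correlates negatively with
    the true indirect-transition frequency (strongly in the ASD-like
    group); FIQ-like scores correlate with the indirect-transition
    frequency in the TD-like group but with the major-state duration in
    the ASD-like group.  Score scales follow the demographic table of a
    typical high-functioning adult cohort.
    """

    n_td: int = 26
    n_asd: int = 24
    n_timepoints: int = 240
    sampling_mode: str = "markov"  # temporal autocorrelation, like fMRI
    noise_sd: float = 0.1
    participant_jitter_h: float = 0.04
    participant_jitter_j: float = 0.02
    true_index_steps: int = 10_000
    ados_corr_asd: float = -0.47
    ados_corr_td: float = -0.30
    fiq_corr_td: float = 0.46
    fiq_corr_asd: float = 0.55
    ados_mean_asd: float = 12.8
    ados_sd_asd: float = 3.6
    ados_mean_td: float = 1.2
    ados_sd_td: float = 1.4
    fiq_mean: float = 110.0
    fiq_sd: float = 13.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_td < 1 or self.n_asd < 1 or self.n_timepoints < 2:
            raise ValueError("cohort sizes and series length must be positive")
        if self.sampling_mode not in ("iid", "markov"):
            raise ValueError(f"unknown sampling mode {self.sampling_mode!r}")


def planted_params(group_kind: str, config: PlantedCohortConfig | None = None) -> MEMParams:
    """The frozen planted MEM parameters for a group kind.

    ``td_like`` has deep minor basins; ``asd_like`` shares the same six
    local minima but with raised, trimmed minor basins.  See
    :mod:`energylandscape._planted` for the calibration.
    """
    if group_kind == "td_like":
        return MEMParams(h=H_TD.copy(), J=J_TD.copy())
    if group_kind == "asd_like":
        return MEMParams(h=H_ASD.copy(), J=J_ASD.copy())
    raise ValueError(f"group_kind must be 'td_like' or 'asd_like', got {group_kind!r}")


def planted_partition(group_kind: str) -> BrainStatePartition:
    """Ground-truth brain-state partition of a planted landscape."""
    ls = build_landscape(planted_params(group_kind))
    minima = find_local_minima(ls)
    assert sorted(minima) == sorted(PLANTED_MINIMA)
    tree = build_disconnectivity_graph(ls, minima)
    basins = assign_basins(ls, minima)
    from .landscape import define_brain_states

    return define_brain_states(tree, basins, grouping=PLANTED_GROUPING)


def sample_mem_series(
    params: MEMParams,
    t: int,
    seed: int,
    mode: str = "iid",
    network_names: tuple[str, ...] | None = None,
    participant_id: str = "",
    burn_in: int = 100,
) -> BinaryTimeSeries:
    """Draw a T x K +/-1 series from the model.

    ``iid`` draws T patterns exactly from the enumerated Boltzmann
    distribution (a categorical over the 2**K patterns -- no MCMC error or
    burn-in concerns).  ``markov`` runs the Metropolis chain and records
    every retained step, adding the temporal autocorrelation of real
    scans.
    """
    if network_names is None:
        network_names = NETWORKS if params.k == len(NETWORKS) else tuple(
            f"N{i+1}" for i in range(params.k)
        )
    patterns = all_patterns(params.k)
    if mode == "iid":
        p = boltzmann_distribution(params)
        rng = np.random.default_rng(seed)
        codes = rng.choice(len(p), size=t, p=p)
    elif mode == "markov":
        ls = build_landscape(params)
        codes = metropolis_walk(ls, t + burn_in, seed=seed, burn_in=burn_in)
    else:
        raise ValueError(f"mode must be 'iid' or 'markov', got {mode!r}")
    return BinaryTimeSeries(
        values=patterns[codes],
        network_names=network_names,
        participant_id=participant_id,
    )


def lift_to_continuous(
    bts: BinaryTimeSeries, noise_sd: float, seed: int
) -> NetworkTimeSeries:
    """Continuous surrogate signal: the +/-1 activity plus Gaussian noise.

    For ``noise_sd`` well below 1 the per-network temporal mean stays
    close to 0 and mean-threshold binarization recovers the input series
    (exactly at ``noise_sd=0``, with a small error rate below roughly
    noise_sd/2 otherwise).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    values = bts.values.astype(float) + rng.normal(0.0, noise_sd, bts.values.shape)
    return NetworkTimeSeries(
        values=values,
        network_names=bts.network_names,
        participant_id=bts.participant_id,
    )


def _jittered_params(base: MEMParams, config: PlantedCohortConfig, rng) -> MEMParams:
    dh = rng.normal(0.0, config.participant_jitter_h, base.k)
    dj = rng.normal(0.0, config.participant_jitter_j, (base.k, base.k))
    dj = 0.5 * (dj + dj.T)
    np.fill_diagonal(dj, 0.0)
    return MEMParams(h=base.h + dh, J=base.J + dj)


def _true_indices(
    params: MEMParams, partition: BrainStatePartition, config: PlantedCohortConfig, seed: int
) -> dict[str, float]:
    """Long-reference-walk dynamics indices on a participant's own
    landscape, mapped through the group's planted state partition."""
    ls = build_landscape(params)
    walk = metropolis_walk(ls, config.true_index_steps + 100, seed=seed, burn_in=100)
    ix = summarize_dynamics(to_state_sequence(walk, partition))
    return {
        "indirect_freq": ix.indirect_freq,
        "direct_freq": ix.direct_freq,
        "intermediate_freq": ix.intermediate_freq,
        "mean_major_duration": ix.mean_major_duration,
    }


def _planted_scores(
    true_idx: list[dict[str, float]],
    group: str,
    config: PlantedCohortConfig,
    rng,
) -> list[dict[str, float]]:
    """Scores as linear-plus-noise functions of the true indices.

    Built on z-scales so the within-group correlation with the chosen true
    index equals the configured value up to sampling error; attenuation by
    index-estimation error downstream is therefore itself measurable.
    """

    def zscore(v):
        v = np.asarray(v, dtype=float)
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    def mix(z, rho):
        eps = rng.normal(size=len(z))
        return rho * z + np.sqrt(max(0.0, 1 - rho**2)) * zscore(eps)

    z_ind = zscore([d["indirect_freq"] for d in true_idx])
    z_dur = zscore([d["mean_major_duration"] for d in true_idx])
    if group == "td":
        ados = config.ados_mean_td + config.ados_sd_td * mix(z_ind, config.ados_corr_td)
        ados = np.clip(ados, 0.0, None)
        fiq = config.fiq_mean + config.fiq_sd * mix(z_ind, config.fiq_corr_td)
    else:
        ados = config.ados_mean_asd + config.ados_sd_asd * mix(z_ind, config.ados_corr_asd)
        fiq = config.fiq_mean + config.fiq_sd * mix(z_dur, config.fiq_corr_asd)
    return [{"ados": float(a), "fiq": float(q)} for a, q in zip(ados, fiq)]


def build_cohort(config: PlantedCohortConfig | None = None) -> CohortDataset:
    """Generate the full synthetic two-group cohort.

    Per participant: group parameters with small per-participant jitter, a
    binary series sampled under the configured mode, a lifted continuous
    series, true dynamics indices from a long reference walk, and planted
    behavioural scores.  The ground-truth record (parameters, true
    indices, planted partitions and effect sizes) travels with the
    dataset.
    """
    if config is None:
        config = PlantedCohortConfig()
    partitions = {
        "td": planted_partition("td_like"),
        "asd": planted_partition("asd_like"),
    }
    base = {"td": planted_params("td_like"), "asd": planted_params("asd_like")}

    participants: list[Participant] = []
    truth_records: dict[str, dict] = {}
    index = 0
    per_group_truth: dict[str, list[dict[str, float]]] = {"td": [], "asd": []}
    per_group_members: dict[str, list[Participant]] = {"td": [], "asd": []}
    for group, n in (("td", config.n_td), ("asd", config.n_asd)):
        for i in range(n):
            pid = f"s{config.master_seed}_{group}{i+1:03d}"
            rng = np.random.default_rng([config.master_seed, index])
            params_p = _jittered_params(base[group], config, rng)
            bts = sample_mem_series(
                params_p,
                config.n_timepoints,
                seed=int(rng.integers(2**31)),
                mode=config.sampling_mode,
                participant_id=pid,
            )
            net_ts = lift_to_continuous(
                bts, config.noise_sd, seed=int(rng.integers(2**31))
            )
            true_idx = _true_indices(
                params_p, partitions[group], config, seed=int(rng.integers(2**31))
            )
            p = Participant(
                participant_id=pid,
                group=group,
                continuous=net_ts,
                binary=bts,
                truth={"params_h": params_p.h.tolist(),
                       "params_J": params_p.J.tolist(),
                       "true_indices": true_idx},
            )
            participants.append(p)
            per_group_truth[group].append(true_idx)
            per_group_members[group].append(p)
            truth_records[pid] = p.truth
            index += 1

    score_rng = np.random.default_rng([config.master_seed, 10_000_019])
    for group in ("td", "asd"):
        scores = _planted_scores(per_group_truth[group], group, config, score_rng)
        for p, sc in zip(per_group_members[group], scores):
            p.scores = sc
            truth_records[p.participant_id]["scores"] = sc

    ground_truth = {
        "planted_minima": list(PLANTED_MINIMA),
        "planted_grouping": {str(k): v for k, v in PLANTED_GROUPING.items()},
        "config": {
            k: getattr(config, k)
            for k in (
                "n_td", "n_asd", "n_timepoints", "sampling_mode", "noise_sd",
                "participant_jitter_h", "participant_jitter_j",
                "ados_corr_asd", "ados_corr_td", "fiq_corr_td", "fiq_corr_asd",
                "master_seed",
            )
        },
        "participants": truth_records,
    }
    return CohortDataset(
        participants=participants,
        network_names=NETWORKS,
        metadata={"master_seed": config.master_seed, "synthetic": True},
        ground_truth=ground_truth,
    )
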