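"""From region-level continuous signals to per-network binary activity.

ROI time series are averaged within their assigned large-scale networks,
then each network's continuous signal is binarized per participant against
its own temporal mean (+1 strictly above the mean, -1 otherwise), which
approximately balances the active/inactive counts.  The module also
provides the binary similarity index used to validate the network
summaries, and the seed-based split of the default-mode network into
vmPFC- and PCC-dominated ROI groups used by the finer parcellation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NetworkTimeSeries",
    "BinaryTimeSeries",
    "RoiAssignment",
    "average_network_activity",
    "binarize_mean_threshold",
    "binary_similarity",
    "split_dmn_by_seed",
    "fisher_z",
]

logger = logging.getLogger(__name__)

#: |r| is clamped below 1 by this margin before atanh, to avoid infinities
_Z_CLAMP = 1e-12


@dataclass
class NetworkTimeSeries:
    """T x K matrix of continuous per-network activity.

    Column order is fixed by ``network_names`` and preserved through the
    whole pipeline (it defines the bit order of pattern codes downstream).
    """

    values: np.ndarray
    network_names: tuple[str, ...]
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.network_names = tuple(self.network_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x K matrix")
        t, k = self.values.shape
        if t < 2 or k < 2:
            raise ValueError(f"need T >= 2 and K >= 2, got {self.values.shape}")
        if k != len(self.network_names):
            raise ValueError("one name per network column is required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite values in time series")

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryTimeSeries:
    """T x K matrix of +/-1 network activities (sigma_i^t)."""

    values: np.ndarray
    network_names: tuple[str, ...]
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.network_names = tuple(self.network_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x K matrix")
        if self.values.shape[1] != len(self.network_names):
            raise ValueError("one name per network column is required")
        if not np.all(np.isin(self.values, (-1, 1))):
            raise ValueError("every entry must be exactly -1 or +1")
        self.values = self.values.astype(np.int8)

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


class RoiAssignment:
    """Mapping of ROI identifiers to network labels.

    Every ROI maps to exactly one network and every network owns at least
    one ROI.  ``network_order`` fixes the output column order; when not
    given, networks appear in first-encounter order of the mapping.
    """

    def __init__(
        self,
        mapping: Mapping[str, str],
        network_order: Sequence[str] | None = None,
    ) -> None:
        self.roi_to_network = dict(mapping)
        if not self.roi_to_network:
            raise ValueError("empty ROI assignment")
        seen: list[str] = []
        for net in self.roi_to_network.values():
            if net not in seen:
                seen.append(net)
        if network_order is None:
            network_order = seen
        else:
            missing = set(seen) - set(network_order)
            if missing:
                raise ValueError(f"network_order omits networks: {sorted(missing)}")
        self.networks = tuple(network_order)
        for net in self.networks:
            if net not in seen:
                raise ValueError(f"network {net!r} has no assigned ROI")

    @classmethod
    def from_tsv(cls, path) -> "RoiAssignment":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("assignment table needs columns (roi_id, network)")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def rois_of(self, network: str) -> list[str]:
        return [r for r, n in self.roi_to_network.items() if n == network]


def average_network_activity(
    roi_ts: pd.DataFrame, assignment: RoiAssignment, participant_id: str = ""
) -> NetworkTimeSeries:
    """Average ROI signals within each network, per time point.

    ``roi_ts`` is a T x R DataFrame whose columns are ROI identifiers; every
    column must appear in the assignment.
    """
    unassigned = [c for c in roi_ts.columns if c not in assignment.roi_to_network]
    if unassigned:
        raise ValueError(f"ROIs not in assignment: {unassigned}")
    cols = []
    for net in assignment.networks:
        rois = [r for r in assignment.rois_of(net) if r in roi_ts.columns]
        if not rois:
            raise ValueError(f"network {net!r} has no ROI columns in the input")
        cols.append(roi_ts[rois].to_numpy(dtype=float).mean(axis=1))
    return NetworkTimeSeries(
        values=np.column_stack(cols),
        network_names=assignment.networks,
        participant_id=participant_id,
    )


def binarize_mean_threshold(net_ts: NetworkTimeSeries) -> BinaryTimeSeries:
    """Binarize each network against its own temporal mean.

    Entries strictly above the network's mean become +1 (active), entries
    at or below it become -1 (inactive); the tie rule at the exact mean is
    deterministic and measure-zero for continuous signals.  Binarization is
    per participant and per network, before any concatenation across
    participants.  A constant network yields all -1 and a logged warning.
    """
    means = net_ts.values.mean(axis=0)
    for j, name in enumerate(net_ts.network_names):
        if np.ptp(net_ts.values[:, j]) == 0.0:
            logger.warning(
                "network %s of participant %s is constant; binarized to all -1",
                name,
                net_ts.participant_id or "<unknown>",
            )
    binary = np.where(net_ts.values > means, 1, -1).astype(np.int8)
    return BinaryTimeSeries(
        values=binary,
        network_names=net_ts.network_names,
        participant_id=net_ts.participant_id,
    )


def binary_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Fraction of time points at which two binary series agree.

    Accepts +/-1 series (converted internally to the 1/0 coding of the
    similarity formula); equals 1 - Hamming distance / N_T.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    xb = (x > 0).astype(int)
    yb = (y > 0).astype(int)
    return float(np.mean(xb == yb))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform atanh(r) with |r| clamped below 1."""
    return np.arctanh(np.clip(r, -1 + _Z_CLAMP, 1 - _Z_CLAMP))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("zero-variance series in correlation")
    return float(np.corrcoef(a, b)[0, 1])


def split_dmn_by_seed(
    roi_ts_per_participant: Sequence[pd.DataFrame],
    dmn_rois: Sequence[str],
    vmpfc_series: Sequence[np.ndarray],
    pcc_series: Sequence[np.ndarray],
) -> tuple[list[str], list[str]]:
    """Split DMN ROIs into vmPFC- and PCC-dominated groups.

    Per participant, each DMN ROI's Pearson correlation with the vmPFC and
    PCC seed series is Fisher z-transformed; the z-scores are averaged
    across participants and the ROI joins the vmPFC-DMN group when its
    average vmPFC coupling exceeds its average PCC coupling, otherwise the
    PCC-DMN group.  Returns (vmpfc_rois, pcc_rois); the two groups are
    disjoint and their union is ``dmn_rois``.
    """
    if len(roi_ts_per_participant) < 1:
        raise ValueError("need at least one participant")
    if not (len(roi_ts_per_participant) == len(vmpfc_series) == len(pcc_series)):
        raise ValueError("per-participant inputs must have equal lengths")
    z_vmpfc = {roi: [] for roi in dmn_rois}
    z_pcc = {roi: [] for roi in dmn_rois}
    for df, vm, pc in zip(roi_ts_per_participant, vmpfc_series, pcc_series):
        vm = np.asarray(vm, dtype=float)
        pc = np.asarray(pc, dtype=float)
        for roi in dmn_rois:
            series = df[roi].to_numpy(dtype=float)
            z_vmpfc[roi].append(fisher_z(_pearson(series, vm)))
            z_pcc[roi].append(fisher_z(_pearson(series, pc)))
    vmpfc_group, pcc_group = [], []
    for roi in dmn_rois:
        if np.mean(z_vmpfc[roi]) > np.mean(z_pcc[roi]):
            vmpfc_group.append(roi)
        else:
            pcc_group.append(roi)
    return vmpfc_group, pcc_group
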