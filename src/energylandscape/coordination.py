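"""Network-level functional connectivity and module segregation strength.

Functional connectivity (FC) between two networks is the Pearson
correlation of their continuous average time series; averages of FC values
are always taken on the Fisher z scale.  The functional segregation
strength of a two-module partition of the networks is the mean z-FC over
within-module pairs (both modules pooled) minus the mean z-FC over
across-module pairs: the wider this gap, the more segregated the modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import NetworkTimeSeries, fisher_z

__all__ = ["FCMatrix", "ModuleSpec", "network_fc", "segregation_strength"]


@dataclass
class FCMatrix:
    """K x K Pearson FC and its Fisher z transform for one participant."""

    r: np.ndarray
    z: np.ndarray
    network_names: tuple[str, ...]
    participant_id: str = ""


@dataclass
class ModuleSpec:
    """Disjoint two-module partition of the K networks.

    The canonical intermediate-state modules are DMN/SMN/Auditory vs
    FPN/SAN/ATN/Visual; the major-state modules are DMN/Visual vs the
    rest.
    """

    module_a: tuple[str, ...]
    module_b: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        self.module_a = tuple(self.module_a)
        self.module_b = tuple(self.module_b)
        if set(self.module_a) & set(self.module_b):
            raise ValueError("modules must be disjoint")
        if not self.module_a or not self.module_b:
            raise ValueError("both modules must be non-empty")

    def validate_against(self, names: Sequence[str]) -> None:
        union = set(self.module_a) | set(self.module_b)
        if union != set(names):
            raise ValueError(
                f"module spec {self.name!r} does not cover exactly the "
                f"networks {tuple(names)}"
            )


def network_fc(net_ts: NetworkTimeSeries) -> FCMatrix:
    """Pairwise Pearson FC between the network time series."""
    if net_ts.t < 3:
        raise ValueError("need T >= 3 time points for correlation")
    stds = net_ts.values.std(axis=0)
    flat = [n for n, s in zip(net_ts.network_names, stds) if s == 0.0]
    if flat:
        raise ValueError(f"constant network time series: {flat}")
    r = np.corrcoef(net_ts.values, rowvar=False)
    z = fisher_z(r)
    return FCMatrix(
        r=r, z=z, network_names=net_ts.network_names,
        participant_id=net_ts.participant_id,
    )


def segregation_strength(fc: FCMatrix, spec: ModuleSpec) -> float:
    """Mean within-module z-FC minus mean across-module z-FC.

    Within-module pairs from both modules are pooled without per-module
    weighting; the diagonal is excluded.  Raises when the partition has no
    within-module pair at all (both modules of size 1).
    """
    spec.validate_against(fc.network_names)
    idx = {n: i for i, n in enumerate(fc.network_names)}
    a = [idx[n] for n in spec.module_a]
    b = [idx[n] for n in spec.module_b]
    within = [
        fc.z[i, j]
        for group in (a, b)
        for gi, i in enumerate(group)
        for j in group[gi + 1:]
    ]
    if not within:
        raise ValueError("module spec yields no within-module pairs")
    across = [fc.z[i, j] for i in a for j in b]
    return float(np.mean(within) - np.mean(across))
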