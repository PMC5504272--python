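"""Readers and writers: cohort directories, landscape tables, trees.

A cohort lives in a directory with a ``manifest.json`` (participant ids,
group labels, scores, seeds), one TSV per participant (rows = time points,
columns = networks, header row of labels) and, for synthetic cohorts, a
``ground_truth.json``.  Landscapes export as TSV (one row per pattern);
disconnectivity trees as Newick with merge energies annotated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortDataset, Participant
from .landscape import BasinMap, BrainStatePartition, EnergyLandscape
from .mem import pattern_decode
from .preprocess import NetworkTimeSeries

__all__ = [
    "write_cohort",
    "read_cohort",
    "landscape_table",
    "write_landscape",
    "write_indices_table",
]


def write_cohort(cohort: CohortDataset, path) -> None:
    """Write a cohort directory: manifest, per-participant TSVs, truth."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "network_names": list(cohort.network_names),
        "metadata": cohort.metadata,
        "participants": [],
    }
    for p in cohort.participants:
        if p.continuous is None:
            raise ValueError(
                f"participant {p.participant_id} has no continuous series to write"
            )
        fname = f"{p.participant_id}.tsv"
        df = pd.DataFrame(p.continuous.values, columns=list(p.continuous.network_names))
        df.to_csv(path / fname, sep="\t", index=False, float_format="%.6g")
        manifest["participants"].append(
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "file": fname,
                "scores": p.scores,
            }
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if cohort.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(cohort.ground_truth, indent=2)
        )


def read_cohort(path) -> CohortDataset:
    """Load a cohort directory written by :func:`write_cohort`.

    Validates shapes and numeric content; errors name the offending file
    (and cell, for malformed numbers).
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    names = tuple(manifest["network_names"])
    participants = []
    for entry in manifest["participants"]:
        f = path / entry["file"]
        if not f.exists():
            raise FileNotFoundError(f"participant file missing: {f}")
        df = pd.read_csv(f, sep="\t")
        if tuple(df.columns) != names:
            raise ValueError(
                f"{f}: columns {tuple(df.columns)} do not match manifest "
                f"networks {names}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(df.apply(pd.to_numeric, errors="coerce").to_numpy()))
            r, c = (bad[0] + [2, 1]) if len(bad) else (0, 0)  # 1-based, header row
            raise ValueError(f"{f}: non-numeric or missing cell at row {r}, column {c}")
        participants.append(
            Participant(
                participant_id=entry["participant_id"],
                group=entry["group"],
                continuous=NetworkTimeSeries(
                    values=values.astype(float),
                    network_names=names,
                    participant_id=entry["participant_id"],
                ),
                scores=entry.get("scores", {}),
            )
        )
    truth_path = path / "ground_truth.json"
    ground_truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return CohortDataset(
        participants=participants,
        network_names=names,
        metadata=manifest.get("metadata", {}),
        ground_truth=ground_truth,
    )


def landscape_table(
    ls: EnergyLandscape,
    basins: BasinMap | None = None,
    partition: BrainStatePartition | None = None,
) -> pd.DataFrame:
    """One row per pattern: code, bit string, energy, minimum flag,
    basin and state label."""
    n = ls.n_patterns
    rows = {
        "code": np.arange(n),
        "bits": ["".join("1" if b > 0 else "0" for b in pattern_decode(c, ls.k)) for c in range(n)],
        "energy": ls.energies,
    }
    if basins is not None:
        rows["basin"] = basins.basin_of
        rows["is_minimum"] = [c in basins.basin_sizes for c in range(n)]
    if partition is not None:
        rows["state"] = [partition.labels[i] for i in partition.pattern_state]
    return pd.DataFrame(rows)


def write_landscape(ls, basins, partition, tree, out_dir, prefix: str) -> None:
    """Write the landscape TSV and the disconnectivity tree Newick."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    landscape_table(ls, basins, partition).to_csv(
        out_dir / f"{prefix}_landscape.tsv", sep="\t", index=False, float_format="%.8g"
    )
    (out_dir / f"{prefix}_tree.nwk").write_text(tree.to_newick() + "\n")


def write_indices_table(df: pd.DataFrame, path) -> None:
    """Per-participant dynamics-index table as TSV."""
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
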