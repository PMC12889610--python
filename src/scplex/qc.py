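"""Per-channel QC and per-cell peptide-input estimation.

A multiplexed single-cell experiment carries three kinds of channels: bridge
channels with a known bulk peptide input (the quantitative anchor), blank
channels that measure background/interference, and single-cell channels. The
summed reporter intensity of a channel scales with its peptide input, so the
ratio of a cell's sum to the bridge sum of its batch back-calculates the
cell's peptide input in picograms:

    input_pg(cell) = bridge_pg * sum(cell) / median(bridge sums of the batch)

with ``bridge_pg`` the input of a single bridge channel (when a batch carries
several bridge channels the reference is the median of their sums, each at
the per-channel input, not the pooled total).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .quant_io import PlexDesign, QuantMatrix

__all__ = [
    "ChannelSummary",
    "channel_sums",
    "fold_differences",
    "estimate_input",
    "completeness",
    "sensitivity_curve",
]


@dataclass
class ChannelSummary:
    """Per-sample summed intensity, identification count and estimated input.

    ``table`` has one row per sample: ``sum`` (linear summed reporter
    intensity over observed features), ``n_identified`` (observed feature
    count), ``role``, ``batch``, ``all_missing`` flag and, after
    :func:`estimate_input`, ``input_pg`` for single-cell samples.
    """

    table: pd.DataFrame

    def role_median(self, role: str, column: str = "sum") -> float:
        sub = self.table[self.table["role"] == role]
        sub = sub[~sub["all_missing"]]
        if sub.empty:
            return float("nan")
        return float(sub[column].median())


def channel_sums(qm: QuantMatrix, meta: pd.DataFrame) -> ChannelSummary:
    """Sum observed reporter intensities and count identifications per sample."""
    if qm.scale != "linear":
        raise ValueError("channel_sums expects a linear-scale matrix")
    sums = qm.values.sum(axis=0, skipna=True)
    counts = qm.mask.sum(axis=0)
    table = pd.DataFrame(
        {
            "sum": sums,
            "n_identified": counts.astype(int),
            "all_missing": counts == 0,
        }
    )
    table = table.join(meta[["batch", "channel", "role"]], how="left")
    if table["role"].isna().any():
        missing = list(table.index[table["role"].isna()])[:5]
        raise ValueError(f"samples without metadata: {missing}")
    table.index.name = "sample_id"
    return ChannelSummary(table=table)


def fold_differences(summary: ChannelSummary) -> dict[str, float]:
    """Median-sum fold differences between channel roles.

    Returns ``bridge_vs_cell`` and ``cell_vs_blank``; a ratio is ``NaN``
    (undefined, not an error) when the corresponding role is absent by
    design, but a zero denominator median among present roles is an error.
    """
    med = {role: summary.role_median(role) for role in ("bridge", "blank", "single_cell")}
    present = set(summary.table["role"])
    out: dict[str, float] = {}
    for key, num_role, den_role in (
        ("bridge_vs_cell", "bridge", "single_cell"),
        ("cell_vs_blank", "single_cell", "blank"),
    ):
        if num_role not in present or den_role not in present:
            out[key] = float("nan")
            continue
        if not med[den_role] > 0:
            raise ValueError(f"median {den_role} sum is zero; fold {key} undefined")
        out[key] = med[num_role] / med[den_role]
    return out


def estimate_input(
    summary: ChannelSummary, designs: Sequence[PlexDesign] | PlexDesign
) -> pd.Series:
    """Back-calculate per-cell peptide input (pg) from the bridge channels.

    For each batch the bridge reference is the median of the bridge-channel
    sums, anchored at a single bridge channel's pg input. The returned series
    covers single-cell samples; the estimate is also written into the
    summary table (``input_pg`` column).
    """
    if isinstance(designs, PlexDesign):
        designs = [designs]
    by_batch = {d.batch_id: d for d in designs}
    table = summary.table
    estimates = pd.Series(np.nan, index=table.index, name="input_pg")
    for batch, sub in table.groupby("batch"):
        design = by_batch.get(batch)
        if design is None:
            raise ValueError(f"no plex design for batch {batch!r}")
        bridge_rows = sub[sub["role"] == "bridge"]
        if bridge_rows.empty:
            raise ValueError(f"batch {batch!r} has no bridge channel")
        pgs = {design.bridge_pg[ch] for ch in bridge_rows["channel"]}
        if len(pgs) != 1:
            raise ValueError(f"batch {batch!r}: bridge channels with unequal pg inputs")
        bridge_pg = pgs.pop()
        bridge_ref = float(bridge_rows["sum"].median())
        if not bridge_ref > 0:
            raise ValueError(f"batch {batch!r}: bridge reference sum is zero")
        cells = sub[sub["role"] == "single_cell"]
        estimates.loc[cells.index] = bridge_pg * cells["sum"] / bridge_ref
    table["input_pg"] = estimates
    return estimates.dropna()


def completeness(qm: QuantMatrix, samples: Sequence[str] | None = None) -> float:
    """Fraction of observed cells among features with at least one observation.

    The denominator counts only features observed in at least one of the
    selected samples times the number of samples, so all-missing features do
    not deflate the value.
    """
    mask = qm.mask
    if samples is not None:
        samples = list(samples)
        if len(samples) == 0:
            raise ValueError("empty sample subset")
        mask = mask.loc[:, samples]
    arr = mask.to_numpy()
    informative = arr.any(axis=1)
    denom = int(informative.sum()) * arr.shape[1]
    if denom == 0:
        return float("nan")
    return float(arr[informative].sum()) / denom


def sensitivity_curve(
    id_sets: Sequence[set[str]],
    n_permutations: int = 100,
    seed: int = 0,
) -> dict[str, object]:
    """Cumulative and local sensitivity over a collection of runs.

    The cumulative curve gives the expected number of unique features after
    sampling ``k`` runs, averaged over ``n_permutations`` random run orders
    (seed-controlled). Total sensitivity is the union over all runs; mean
    local sensitivity the mean per-run set size.
    """
    runs = [set(s) for s in id_sets]
    if len(runs) == 0:
        raise ValueError("need at least one run")
    rng = np.random.default_rng(seed)
    n = len(runs)
    curve = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        seen: set[str] = set()
        for k, idx in enumerate(order):
            seen |= runs[idx]
            curve[k] += len(seen)
    curve /= n_permutations
    union = set().union(*runs)
    return {
        "cumulative": curve,
        "total_sensitivity": len(union),
        "mean_local_sensitivity": float(np.mean([len(s) for s in runs])),
    }
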