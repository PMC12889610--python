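"""Core data model and I/O for multiplexed reporter-ion quantification.

The central container is :class:`QuantMatrix`, a features × samples intensity
table with an explicit missingness convention (``NaN`` means *not quantified*,
which is distinct from an observed zero), a feature level tag
(``peptide``/``protein``) and a scale tag (``linear``/``log2``). Sample
annotations live in a plain :class:`pandas.DataFrame` (see
:func:`read_sample_meta`) and the plex layout of each multiplexed batch in
:class:`PlexDesign`.

Reporter-ion intensities are stored on the linear scale; all statistical
modeling downstream happens on log2 intensities, where observed zeros are
treated as missing (a zero reporter intensity carries no usable quantitative
information on the log scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("bridge", "blank", "single_cell")

__all__ = [
    "ROLES",
    "PlexDesign",
    "QuantMatrix",
    "read_quant_table",
    "write_quant_table",
    "read_sample_meta",
    "write_sample_meta",
    "read_plex_designs",
    "write_plex_designs",
    "validate_design",
    "rollup_to_protein",
]


@dataclass
class PlexDesign:
    """Channel layout of one multiplexed (e.g. TMTpro) batch.

    Parameters
    ----------
    batch_id:
        Identifier shared with the sample metadata ``batch`` column.
    channels:
        Ordered channel names, e.g. ``["126", "127N", ..., "135ND"]``.
    roles:
        Role per channel, each one of ``bridge`` (known bulk peptide input,
        the quantitative anchor of the plex), ``blank`` (labeled but empty)
        or ``single_cell``.
    bridge_pg:
        Peptide input in picograms for each bridge channel.
    reporter_mass:
        Optional nominal reporter ion mass per channel.
    adjacency:
        Optional list of channel-name pairs that are isotopically adjacent.
    """

    batch_id: str
    channels: list[str]
    roles: dict[str, str]
    bridge_pg: dict[str, float] = field(default_factory=dict)
    reporter_mass: dict[str, float] = field(default_factory=dict)
    adjacency: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channel names in batch {self.batch_id!r}")
        for ch, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for channel {ch!r}")
        missing = set(self.channels) - set(self.roles)
        if missing:
            raise ValueError(f"channels without a role in batch {self.batch_id!r}: {sorted(missing)}")
        for ch in self.bridge_channels:
            pg = self.bridge_pg.get(ch)
            if pg is None or not pg > 0:
                raise ValueError(
                    f"bridge channel {ch!r} in batch {self.batch_id!r} needs bridge_pg > 0"
                )

    @property
    def bridge_channels(self) -> list[str]:
        return [c for c in self.channels if self.roles[c] == "bridge"]

    @property
    def blank_channels(self) -> list[str]:
        return [c for c in self.channels if self.roles[c] == "blank"]

    @property
    def cell_channels(self) -> list[str]:
        return [c for c in self.channels if self.roles[c] == "single_cell"]

    def role_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for role in self.roles.values():
            counts[role] += 1
        return counts


@dataclass
class QuantMatrix:
    """Features × samples intensity matrix with explicit missingness.

    ``values`` is a :class:`pandas.DataFrame` whose index holds feature ids
    and whose columns hold sample ids; ``NaN`` marks a missing (unquantified)
    cell. ``level`` is ``"peptide"`` or ``"protein"``; ``scale`` is
    ``"linear"`` or ``"log2"``. On the linear scale intensities must be
    non-negative. ``protein_map`` optionally maps peptide ids to protein ids.
    """

    values: pd.DataFrame
    level: str = "protein"
    scale: str = "linear"
    protein_map: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "protein"):
            raise ValueError(f"level must be 'peptide' or 'protein', got {self.level!r}")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if self.scale == "linear" and np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed on the linear scale")

    # -- basic accessors ----------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-mask (True where a value was quantified)."""
        return self.values.notna()

    @property
    def n_observed(self) -> int:
        return int(self.mask.to_numpy().sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "QuantMatrix":
        return replace(self, values=self.values.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "QuantMatrix":
        return replace(self, values=self.values.loc[list(feature_ids)])

    # -- scale conversion ---------------------------------------------------
    def to_log2(self) -> "QuantMatrix":
        """Log2-transform a linear matrix; observed zeros become missing."""
        if self.scale == "log2":
            return self
        vals = self.values.where(self.values > 0)
        return replace(self, values=np.log2(vals), scale="log2")

    def to_linear(self) -> "QuantMatrix":
        if self.scale == "linear":
            return self
        return replace(self, values=2.0 ** self.values, scale="linear")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NA_TOKENS = ["", "NA", "NaN", "nan"]


def read_quant_table(
    path: str | Path,
    level: str = "protein",
    dialect: str = "tsv",
    zero_as_missing: bool = False,
    feature_col: str | None = None,
) -> QuantMatrix:
    """Read a wide feature × sample intensity table (TSV or CSV).

    Empty cells and ``NA`` tokens become missing values; observed zeros are
    kept unless ``zero_as_missing`` is set (TMT export tools are inconsistent
    about whether zero means "not quantified").
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, na_values=_NA_TOKENS, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need one feature-id column and at least one sample column")
    fcol = feature_col or df.columns[0]
    if df[fcol].duplicated().any():
        dup = df.loc[df[fcol].duplicated(), fcol].iloc[0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    df = df.set_index(fcol)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric intensity cell ({exc})") from exc
    if zero_as_missing:
        df = df.where(df != 0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return QuantMatrix(values=df, level=level, scale="linear")


def write_quant_table(qm: QuantMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a :class:`QuantMatrix` as a wide table; missing cells become ``NA``."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    out = qm.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep, na_rep="NA")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, batch, channel, role."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "batch", "channel", "role"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return meta.set_index("sample_id")


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_plex_designs(designs: Iterable[PlexDesign], path: str | Path) -> None:
    payload = []
    for d in designs:
        payload.append(
            {
                "batch_id": d.batch_id,
                "channels": d.channels,
                "roles": d.roles,
                "bridge_pg": d.bridge_pg,
                "reporter_mass": d.reporter_mass,
                "adjacency": [list(p) for p in d.adjacency],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2))


def read_plex_designs(path: str | Path) -> list[PlexDesign]:
    payload = json.loads(Path(path).read_text())
    designs = []
    for d in payload:
        designs.append(
            PlexDesign(
                batch_id=d["batch_id"],
                channels=list(d["channels"]),
                roles=dict(d["roles"]),
                bridge_pg={k: float(v) for k, v in d.get("bridge_pg", {}).items()},
                reporter_mass={k: float(v) for k, v in d.get("reporter_mass", {}).items()},
                adjacency=[tuple(p) for p in d.get("adjacency", [])],
            )
        )
    return designs


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_design(
    designs: Sequence[PlexDesign] | PlexDesign,
    meta: pd.DataFrame,
    qm: QuantMatrix,
    require_bridge: bool = False,
) -> dict[str, int]:
    """Cross-check plex designs, sample metadata and a quant matrix.

    Every sample column must map to exactly one (batch, channel) in the
    designs, with a consistent role. Returns counts of samples per role.
    Set ``require_bridge`` when per-cell input estimation is planned: each
    batch must then carry at least one bridge channel with a known input.
    """
    if isinstance(designs, PlexDesign):
        designs = [designs]
    by_batch = {d.batch_id: d for d in designs}
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    pairs = meta[["batch", "channel"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0]
        raise ValueError(f"duplicate (batch, channel) pair in metadata: {dup}")

    unmatched = [s for s in qm.sample_ids if s not in meta.index]
    if unmatched:
        raise ValueError(f"samples without metadata: {unmatched[:5]}")

    counts = {r: 0 for r in ROLES}
    for sample_id in qm.sample_ids:
        row = meta.loc[sample_id]
        design = by_batch.get(row["batch"])
        if design is None:
            raise ValueError(f"sample {sample_id!r}: unknown batch {row['batch']!r}")
        if row["channel"] not in design.roles:
            raise ValueError(
                f"sample {sample_id!r}: unknown channel {row['channel']!r} in batch {row['batch']!r}"
            )
        role = design.roles[row["channel"]]
        if row["role"] != role:
            raise ValueError(
                f"sample {sample_id!r}: metadata role {row['role']!r} != design role {role!r}"
            )
        counts[role] += 1

    if require_bridge:
        batches_used = set(meta.loc[list(qm.sample_ids), "batch"])
        for b in sorted(batches_used):
            design = by_batch.get(b)
            if design is None or not design.bridge_channels:
                raise ValueError(
                    f"batch {b!r} has no bridge channel but input estimation was requested"
                )
    return counts


def rollup_to_protein(qm: QuantMatrix, protein_map: Mapping[str, str] | pd.Series | None = None) -> QuantMatrix:
    """Aggregate a peptide-level linear matrix to protein level.

    Protein intensity per sample is the sum of the observed peptide
    intensities of that protein; a protein with no observed peptide in a
    sample stays missing there.
    """
    if qm.level != "peptide":
        raise ValueError("rollup_to_protein expects a peptide-level matrix")
    if qm.scale != "linear":
        raise ValueError("rollup_to_protein expects a linear-scale matrix")
    pmap = protein_map if protein_map is not None else qm.protein_map
    if pmap is None:
        raise ValueError("no peptide-to-protein map available")
    pmap = pd.Series(pmap)
    groups = pmap.reindex(qm.feature_ids)
    if groups.isna().any():
        missing = list(qm.feature_ids[groups.isna()])[:5]
        raise ValueError(f"peptides without protein assignment: {missing}")
    sums = qm.values.groupby(groups).sum(min_count=1)
    sums = sums.sort_index()
    return QuantMatrix(values=sums, level="protein", scale="linear")
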