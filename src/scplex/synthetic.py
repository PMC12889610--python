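"""Synthetic multiplexed single-cell proteomes and reporter-ion acquisition.

This module generates ground-truth single-cell proteomes with known cell
types, per-cell peptide input (tens of picograms), planted marker proteins,
batch effects, and a permeabilization artifact (a random subset of cells
loses a fraction of its cytosolic protein content before isolation). It then
simulates multiplexed MS2 acquisition of those proteomes under two precursor
selection regimes:

``standard``
    data-dependent selection: the instrument spends its MS2 budget on
    candidate features sampled with intensity bias, where candidates include
    both real peptides and uninformative "noise" features (chemical
    background, unlabeled species) that waste budget.
``rtls``
    library-gated selection: each candidate is pre-screened against a
    spectral library with sensitivity τ (a real peptide passes with
    probability τ) and specificity σ (a noise feature is rejected with
    probability σ); only passing candidates consume budget.

Identified real peptides receive per-channel reporter intensities equal to
the true abundance times multiplicative lognormal noise, plus a small
channel-independent interference term proportional to the summed bridge
signal of that feature (low-m/z fragment interference, which makes empty
"blank" channels accumulate signal as the bridge input grows). Intensities
below a quantification limit are censored to missing, so peptide
observability increases with abundance.

All outputs are pure functions of their configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .quant_io import PlexDesign, QuantMatrix

__all__ = [
    "GroundTruthConfig",
    "GroundTruthDataset",
    "AcquisitionConfig",
    "AcquisitionResult",
    "ReferenceExpression",
    "generate_truth",
    "simulate_acquisition",
    "generate_reference",
]

DEFAULT_TYPE_PROPORTIONS: dict[str, float] = {
    # coarse PBMC composition with a rare granulocyte contaminant
    "monocyte": 0.36,
    "cd4_t": 0.25,
    "cd8_t": 0.15,
    "nk": 0.12,
    "b": 0.10,
    "granulocyte": 0.02,
}


@dataclass
class GroundTruthConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a TMTpro 32-plex design: 2 bridge channels at 150 pg
    each, 3 blank channels, 27 single cells per batch; a median single-cell
    peptide input of 14.2 pg; and a permeabilization artifact in which 15% of
    cells retain only ``permeabilization_lambda`` of their cytosolic protein
    content.
    """

    n_batches: int = 24
    n_bridge: int = 2
    n_blank: int = 3
    n_cells_per_batch: int = 27
    n_proteins: int = 800
    mean_peptides_per_protein: float = 3.0
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    marker_fraction: float = 0.04
    marker_log2_effect: float = 2.0
    # per-cell peptide input, lognormal on the natural-log scale
    cell_input_median_pg: float = 14.2
    cell_input_sigma: float = 0.45
    bridge_pg: float = 150.0
    # batch effects on the log2 scale: additive location sd, multiplicative scale sd
    batch_location_sd: float = 0.5
    batch_scale_sd: float = 0.2
    # permeabilization artifact
    permeabilized_fraction: float = 0.15
    cytosolic_fraction: float = 0.6
    permeabilization_lambda: float = 0.4
    # bridge-signal interference into every channel. The default puts the
    # observed blank-channel sums a few-hundred-fold below the single-cell
    # channels (after the quantification limit censors most of the leak),
    # the background level typical of blank TMT channels in this design.
    interference_eps: float = 3.5e-4
    # protein/peptide abundance model (log2 scale)
    protein_base_sd: float = 1.5
    peptide_propensity_sd: float = 1.0
    cell_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_batches", "n_bridge", "n_blank", "n_cells_per_batch", "n_proteins"):
            if getattr(self, name) < 0 or (name in ("n_batches", "n_proteins") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        fracs = {
            "marker_fraction": self.marker_fraction,
            "permeabilized_fraction": self.permeabilized_fraction,
            "cytosolic_fraction": self.cytosolic_fraction,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if not 0.0 <= self.permeabilization_lambda < 1.0:
            raise ValueError("permeabilization_lambda must be in [0, 1)")
        if self.cell_input_median_pg <= 0 or self.bridge_pg <= 0:
            raise ValueError("pg amounts must be positive")
        if self.interference_eps < 0:
            raise ValueError("interference_eps must be non-negative")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"type proportions must sum to 1, got {total}")
        if len(self.type_proportions) < 1:
            raise ValueError("need at least one cell type")

    @property
    def plex_size(self) -> int:
        return self.n_bridge + self.n_blank + self.n_cells_per_batch

    @property
    def cell_types(self) -> list[str]:
        return list(self.type_proportions)


@dataclass
class GroundTruthDataset:
    """Latent quantities the pipeline is meant to estimate.

    ``abundance`` holds true linear peptide abundances (features × cells) in
    picogram units: each cell's column sums to its realized peptide input.
    ``type_profiles_log2`` holds the noise-free protein-level log2 profile
    per cell type; planted markers exceed all other types by exactly
    ``marker_log2_effect`` there by construction.
    """

    config: GroundTruthConfig
    cells: pd.DataFrame  # index cell/sample id: type, batch, channel, input pg, permeabilized
    features: pd.DataFrame  # index peptide id: protein_id, marker_type, cytosolic
    abundance: pd.DataFrame  # peptides × cells, linear pg units
    bridge_abundance: pd.Series  # per-peptide bridge-channel abundance (one channel)
    type_profiles_log2: pd.DataFrame  # proteins × types
    batch_location: pd.DataFrame  # peptides × batches, additive log2 batch effect
    batch_scale: pd.DataFrame  # peptides × batches, multiplier on reporter noise sd
    designs: list[PlexDesign]

    @property
    def sample_meta(self) -> pd.DataFrame:
        """Sample metadata covering every channel (bridge, blank, single cell)."""
        rows = []
        for d in self.designs:
            for ch in d.channels:
                rows.append(
                    {
                        "sample_id": f"{d.batch_id}_{ch}",
                        "batch": d.batch_id,
                        "channel": ch,
                        "role": d.roles[ch],
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")


def _make_designs(config: GroundTruthConfig) -> list[PlexDesign]:
    designs = []
    for b in range(config.n_batches):
        batch_id = f"batch{b:02d}"
        channels: list[str] = []
        roles: dict[str, str] = {}
        bridge_pg: dict[str, float] = {}
        for i in range(config.n_bridge):
            name = f"bridge{i + 1}"
            channels.append(name)
            roles[name] = "bridge"
            bridge_pg[name] = config.bridge_pg
        for i in range(config.n_cells_per_batch):
            name = f"sc{i + 1:02d}"
            channels.append(name)
            roles[name] = "single_cell"
        for i in range(config.n_blank):
            name = f"blank{i + 1}"
            channels.append(name)
            roles[name] = "blank"
        designs.append(
            PlexDesign(batch_id=batch_id, channels=channels, roles=roles, bridge_pg=bridge_pg)
        )
    return designs


def generate_truth(config: GroundTruthConfig) -> GroundTruthDataset:
    """Draw a ground-truth cohort from the generative model.

    The model: each protein has a lognormal baseline abundance; each peptide
    of a protein carries a multiplicative ionization propensity; each cell
    type up-regulates a disjoint set of marker proteins by
    ``marker_log2_effect`` log2 units; each cell adds protein-level
    biological noise and its relative proteome is scaled so the peptide
    abundances sum to the cell's drawn peptide input (pg). Permeabilized
    cells then lose ``1 - λ`` of every cytosolic peptide, which lowers their
    realized input. The bridge channel carries the expected pooled proteome
    scaled to ``bridge_pg``.
    """
    rng = np.random.default_rng(config.seed)
    types = config.cell_types
    n_prot = config.n_proteins

    protein_ids = np.array([f"P{i:04d}" for i in range(n_prot)])
    base_log2 = rng.normal(0.0, config.protein_base_sd, size=n_prot)

    # peptides per protein: 1 + Poisson(mean - 1), at least one peptide each
    lam = max(config.mean_peptides_per_protein - 1.0, 0.0)
    n_pep = 1 + rng.poisson(lam, size=n_prot)
    pep_protein_idx = np.repeat(np.arange(n_prot), n_pep)
    n_peptides = int(n_pep.sum())
    peptide_ids = np.array(
        [f"{protein_ids[p]}_pep{j + 1}" for p, cnt in enumerate(n_pep) for j in range(cnt)]
    )
    propensity = rng.normal(0.0, config.peptide_propensity_sd, size=n_peptides)

    cytosolic_prot = rng.random(n_prot) < config.cytosolic_fraction

    # disjoint marker sets, one per type
    n_markers = int(round(config.marker_fraction * n_prot))
    marker_type = np.full(n_prot, "", dtype=object)
    if n_markers * len(types) > n_prot:
        raise ValueError("marker_fraction too large for disjoint marker sets")
    perm = rng.permutation(n_prot)
    for t_idx, t in enumerate(types):
        marker_type[perm[t_idx * n_markers : (t_idx + 1) * n_markers]] = t

    # noise-free protein log2 profile per type
    profiles = np.tile(base_log2[:, None], (1, len(types)))
    for t_idx, t in enumerate(types):
        profiles[marker_type == t, t_idx] += config.marker_log2_effect
    type_profiles_log2 = pd.DataFrame(profiles, index=protein_ids, columns=types)

    # cells
    n_cells = config.n_batches * config.n_cells_per_batch
    if n_cells == 0:
        raise ValueError("layout contains zero single-cell channels")
    props = np.array([config.type_proportions[t] for t in types])
    cell_types = rng.choice(types, size=n_cells, p=props)
    drawn_input = config.cell_input_median_pg * np.exp(
        rng.normal(0.0, config.cell_input_sigma, size=n_cells)
    )
    permeabilized = rng.random(n_cells) < config.permeabilized_fraction

    # per-cell protein-level biological noise
    cell_noise = rng.normal(0.0, config.cell_noise_sd, size=(n_prot, n_cells))

    designs = _make_designs(config)
    batch_ids = np.repeat([d.batch_id for d in designs], config.n_cells_per_batch)
    channels = np.tile(
        [f"sc{i + 1:02d}" for i in range(config.n_cells_per_batch)], config.n_batches
    )
    cell_ids = np.array([f"{b}_{c}" for b, c in zip(batch_ids, channels)])

    # peptide-level log2 abundance, then column-normalize to the drawn input
    type_idx = np.array([types.index(t) for t in cell_types])
    prot_log2 = profiles[:, type_idx] + cell_noise  # proteins × cells
    pep_log2 = prot_log2[pep_protein_idx, :] + propensity[:, None]
    abundance = 2.0 ** pep_log2
    abundance *= drawn_input / abundance.sum(axis=0)

    cytosolic_pep = cytosolic_prot[pep_protein_idx]
    if permeabilized.any():
        abundance[np.ix_(cytosolic_pep, permeabilized)] *= config.permeabilization_lambda
    realized_input = abundance.sum(axis=0)

    # bridge: expected pooled proteome (type-proportion weighted), scaled to bridge_pg
    pooled = (2.0 ** profiles) @ props
    bridge_pep = (2.0 ** propensity) * pooled[pep_protein_idx]
    bridge_pep *= config.bridge_pg / bridge_pep.sum()

    # batch effects per feature
    batch_names = [d.batch_id for d in designs]
    batch_location = pd.DataFrame(
        rng.normal(0.0, config.batch_location_sd, size=(n_peptides, config.n_batches)),
        index=peptide_ids,
        columns=batch_names,
    )
    batch_scale = pd.DataFrame(
        2.0 ** rng.normal(0.0, config.batch_scale_sd, size=(n_peptides, config.n_batches)),
        index=peptide_ids,
        columns=batch_names,
    )

    cells = pd.DataFrame(
        {
            "cell_type": cell_types,
            "batch": batch_ids,
            "channel": channels,
            "drawn_input_pg": drawn_input,
            "input_pg": realized_input,
            "permeabilized": permeabilized,
        },
        index=pd.Index(cell_ids, name="sample_id"),
    )
    features = pd.DataFrame(
        {
            "protein_id": protein_ids[pep_protein_idx],
            "marker_type": marker_type[pep_protein_idx],
            "cytosolic": cytosolic_pep,
        },
        index=pd.Index(peptide_ids, name="peptide_id"),
    )
    return GroundTruthDataset(
        config=config,
        cells=cells,
        features=features,
        abundance=pd.DataFrame(abundance, index=peptide_ids, columns=cell_ids),
        bridge_abundance=pd.Series(bridge_pep, index=peptide_ids),
        type_profiles_log2=type_profiles_log2,
        batch_location=batch_location,
        batch_scale=batch_scale,
        designs=designs,
    )


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionConfig:
    """Precursor-selection and reporter-noise model for one acquisition.

    ``ms2_budget`` caps the number of quantitative MS2 scans per run (one run
    per batch). Candidate real peptides are detected with probability
    logistic in log10 total precursor abundance (slope per decade, midpoint
    in log10 pg). ``noise_fraction`` is the fraction of the candidate pool
    made up of noise features. In ``rtls`` mode candidates are pre-screened:
    a real peptide passes with probability ``screen_sensitivity`` and a noise
    feature passes with probability ``1 - screen_specificity``.
    """

    mode: str = "standard"
    ms2_budget: int = 1500
    noise_fraction: float = 0.2
    screen_sensitivity: float = 0.95
    screen_specificity: float = 0.95
    # midpoint sits near the median per-run total precursor abundance of the
    # default cohort (~0.05 pg), so roughly two thirds of real peptides are
    # selectable candidates in a run and observability rises with abundance
    observability_slope: float = 1.5
    observability_midpoint_log10: float = -1.3
    reporter_cv: float = 0.15
    quant_limit: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "rtls"):
            raise ValueError(f"mode must be 'standard' or 'rtls', got {self.mode!r}")
        if self.ms2_budget < 0:
            raise ValueError("ms2_budget must be non-negative")
        for name in ("noise_fraction", "screen_sensitivity", "screen_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reporter_cv < 0 or self.quant_limit < 0:
            raise ValueError("reporter_cv and quant_limit must be non-negative")


@dataclass
class AcquisitionResult:
    quant: QuantMatrix  # peptide-level, linear, NaN = not quantified
    sample_meta: pd.DataFrame
    identified: dict[str, set[str]]  # per run (batch id): identified peptide ids

    @property
    def id_sets(self) -> list[set[str]]:
        return [self.identified[b] for b in sorted(self.identified)]


def detection_probability(total_abundance: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    """Probability that a peptide becomes a selectable candidate in a run."""
    with np.errstate(divide="ignore"):
        log10_ab = np.log10(np.maximum(total_abundance, 1e-300))
    return expit(acq.observability_slope * (log10_ab - acq.observability_midpoint_log10))


def _weighted_sample_without_replacement(
    weights: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of ``n`` items sampled without replacement, P ∝ weight (Gumbel keys)."""
    if n >= weights.size:
        return np.arange(weights.size)
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    return np.argpartition(-keys, n)[:n]


def simulate_acquisition(
    truth: GroundTruthDataset, acq: AcquisitionConfig
) -> AcquisitionResult:
    """Simulate one multiplexed LC-MS2 run per batch.

    Returns a peptide-level linear :class:`QuantMatrix` over all channels of
    all batches (missing where a peptide was not identified in that run or
    fell below the quantification limit), plus the per-run identified
    peptide sets used for sensitivity curves.
    """
    if truth.abundance.shape[0] == 0 or truth.abundance.shape[1] == 0:
        raise ValueError("empty ground-truth dataset")
    config = truth.config
    peptide_ids = truth.abundance.index.to_numpy()
    n_features = peptide_ids.size
    bridge = truth.bridge_abundance.to_numpy()
    eps = config.interference_eps
    sigma_base = float(np.sqrt(np.log1p(acq.reporter_cv**2)))

    meta = truth.sample_meta
    columns: dict[str, np.ndarray] = {}
    identified: dict[str, set[str]] = {}

    for b_idx, design in enumerate(truth.designs):
        batch = design.batch_id
        # independent child streams; the detection stream consumes a fixed
        # number of draws so identified sets stay coupled across configs that
        # differ only in abundance scale (matched-seed comparisons)
        det_rng = np.random.default_rng([acq.seed, b_idx, 0])
        screen_rng = np.random.default_rng([acq.seed, b_idx, 1])
        select_rng = np.random.default_rng([acq.seed, b_idx, 2])
        noise_rng = np.random.default_rng([acq.seed, b_idx, 3])

        cell_cols = [f"{batch}_{c}" for c in design.cell_channels]
        cell_ab = truth.abundance[cell_cols].to_numpy()  # features × cells
        n_bridge = len(design.bridge_channels)
        total = cell_ab.sum(axis=1) + n_bridge * bridge

        u = det_rng.random(n_features)
        real_cand = np.flatnonzero(u < detection_probability(total, acq))
        n_real = real_cand.size
        nf = acq.noise_fraction
        n_noise = int(round(nf / (1.0 - nf) * n_real)) if nf < 1.0 else n_real

        cand_intensity = total[real_cand]
        if n_noise > 0 and n_real > 0:
            noise_intensity = noise_rng.choice(cand_intensity, size=n_noise, replace=True)
        else:
            noise_intensity = np.empty(0)
        pool_intensity = np.concatenate([cand_intensity, noise_intensity])
        is_real = np.concatenate(
            [np.ones(n_real, dtype=bool), np.zeros(n_noise, dtype=bool)]
        )

        if acq.mode == "rtls":
            pass_p = np.where(is_real, acq.screen_sensitivity, 1.0 - acq.screen_specificity)
            passed = screen_rng.random(pool_intensity.size) < pass_p
            pool_intensity = pool_intensity[passed]
            is_real_pool = is_real[passed]
            real_pool_idx = real_cand[passed[:n_real]]
        else:
            is_real_pool = is_real
            real_pool_idx = real_cand

        chosen = _weighted_sample_without_replacement(
            pool_intensity, acq.ms2_budget, select_rng
        )
        chosen_real = chosen[is_real_pool[chosen]]
        # map back to feature indices: positions of real items in the pool
        real_positions = np.flatnonzero(is_real_pool)
        pos_to_feature = dict(zip(real_positions, real_pool_idx))
        ident_idx = np.sort(np.array([pos_to_feature[p] for p in chosen_real], dtype=int))
        identified[batch] = set(peptide_ids[ident_idx])

        # reporter intensities for identified features, all channels of the batch
        loc = 2.0 ** truth.batch_location[batch].to_numpy()
        scale = truth.batch_scale[batch].to_numpy()
        sig = sigma_base * scale[ident_idx]
        leak = eps * (n_bridge * bridge[ident_idx]) * loc[ident_idx]

        def _noisy(base: np.ndarray) -> np.ndarray:
            z = noise_rng.standard_normal(base.shape)
            s = sig if base.ndim == 1 else sig[:, None]
            return base * np.exp(s * z - 0.5 * s**2)

        batch_cols: dict[str, np.ndarray] = {}
        for ch in design.channels:
            col = np.full(n_features, np.nan)
            role = design.roles[ch]
            if role == "bridge":
                signal = _noisy(bridge[ident_idx] * loc[ident_idx])
            elif role == "blank":
                signal = np.zeros(ident_idx.size)
            else:
                ab = truth.abundance[f"{batch}_{ch}"].to_numpy()[ident_idx]
                signal = _noisy(ab * loc[ident_idx])
            vals = signal + leak
            vals[vals < acq.quant_limit] = np.nan
            col[ident_idx] = vals
            batch_cols[f"{batch}_{ch}"] = col
        columns.update(batch_cols)

    values = pd.DataFrame(columns, index=peptide_ids)
    values = values.loc[:, [f"{d.batch_id}_{c}" for d in truth.designs for c in d.channels]]
    # keep only features identified somewhere
    values = values.loc[values.notna().any(axis=1)]
    qm = QuantMatrix(
        values=values,
        level="peptide",
        scale="linear",
        protein_map=truth.features["protein_id"].reindex(values.index),
    )
    return AcquisitionResult(quant=qm, sample_meta=meta, identified=identified)


# ---------------------------------------------------------------------------
# Reference expression (transcriptome stand-in for label transfer)
# ---------------------------------------------------------------------------


@dataclass
class ReferenceExpression:
    """Gene × reference-cell expression with per-cell type labels.

    A configurable fraction of gene ids coincides with proteome feature ids;
    on those shared features the per-type expression profile tracks the
    protein profile (plus modality noise), which is what makes label
    transfer possible.
    """

    values: pd.DataFrame  # genes × reference cells, log2-like scale
    labels: pd.Series  # per reference cell
    shared_ids: list[str]

    def __post_init__(self) -> None:
        if self.labels.nunique() < 2:
            raise ValueError("reference must contain at least two cell types")
        if set(self.labels.index) != set(self.values.columns):
            raise ValueError("every reference cell needs a label")


def generate_reference(
    truth: GroundTruthDataset,
    overlap_fraction: float = 0.3,
    n_reference_cells: int = 1500,
    seed: int = 0,
    exclude_types: Sequence[str] = ("granulocyte",),
    n_genes: int = 2000,
    modality_offset_sd: float = 0.3,
    rna_noise_sd: float = 0.8,
) -> ReferenceExpression:
    """Build a reference atlas stand-in from the ground truth.

    Reference cell types correspond one-to-one to truth types, optionally
    minus ``exclude_types`` (a rare contaminating type is typically absent
    from curated atlases). ``overlap_fraction`` of the proteome's protein ids
    appear as gene ids; remaining genes are reference-only.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    types = [t for t in truth.config.cell_types if t not in set(exclude_types)]
    if len(types) < 2:
        raise ValueError("need at least two reference types")
    if n_reference_cells < len(types):
        raise ValueError("n_reference_cells must be at least the number of types")

    rng = np.random.default_rng(seed)
    protein_ids = truth.type_profiles_log2.index.to_numpy()
    n_shared = int(round(overlap_fraction * protein_ids.size))
    shared = np.sort(rng.choice(protein_ids, size=n_shared, replace=False))
    n_extra = max(n_genes - n_shared, 0)
    extra = np.array([f"G{i:04d}" for i in range(n_extra)])
    genes = np.concatenate([shared, extra])

    # per-type mean expression: protein profile (+ per-gene modality offset)
    # on shared genes, independent type structure elsewhere
    prof = np.empty((genes.size, len(types)))
    prof[:n_shared] = truth.type_profiles_log2.loc[shared, types].to_numpy()
    prof[:n_shared] += rng.normal(0.0, modality_offset_sd, size=(n_shared, 1))
    base_extra = rng.normal(0.0, 1.5, size=(n_extra, 1))
    prof[n_shared:] = base_extra + rng.normal(0.0, 0.5, size=(n_extra, len(types)))

    props = np.array([truth.config.type_proportions[t] for t in types])
    props = props / props.sum()
    cell_types = rng.choice(types, size=n_reference_cells, p=props)
    t_idx = np.array([types.index(t) for t in cell_types])
    expr = prof[:, t_idx] + rng.normal(0.0, rna_noise_sd, size=(genes.size, n_reference_cells))

    cell_ids = pd.Index([f"ref{i:05d}" for i in range(n_reference_cells)], name="cell_id")
    return ReferenceExpression(
        values=pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=cell_ids),
        labels=pd.Series(cell_types, index=cell_ids, name="cell_type"),
        shared_ids=list(shared),
    )
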