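"""Synthetic inputs with known ground truth.

Every data modality the analysis consumes can be generated here: a
cell-type methylation reference atlas, bulk tumor beta matrices mixed from
it, zero-inflated single-cell expression with planted gene modules, and
Visium-style spatial samples (hexagonal spot lattice, spot expression
driven by a latent cell composition, scattered nucleus positions).

All generators are pure functions of their arguments including the seed:
calling one twice with identical arguments returns bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COMPONENT_NAMES",
    "NEURAL_COMPONENT",
    "VISIUM_CELL_TYPES",
    "NEURAL_LINEAGE_TYPES",
    "ReferenceAtlas",
    "BulkCohort",
    "SpatialSample",
    "make_reference_atlas",
    "make_bulk_cohort",
    "make_single_cell_profiles",
    "make_visium_sample",
]

#: Name of the reference component whose proportion is the neural score.
NEURAL_COMPONENT = "cortical neurons"

#: 25 cell-type components, mirroring the structure of a whole-body
#: reference methylome atlas with a single neuronal entry.
DEFAULT_COMPONENT_NAMES: tuple[str, ...] = (
    NEURAL_COMPONENT,
    "monocytes",
    "B cells",
    "CD4 T cells",
    "CD8 T cells",
    "NK cells",
    "neutrophils",
    "eosinophils",
    "erythrocyte progenitors",
    "adipocytes",
    "hepatocytes",
    "lung epithelium",
    "pancreatic beta cells",
    "pancreatic acinar cells",
    "pancreatic duct cells",
    "vascular endothelium",
    "colon epithelium",
    "cardiomyocytes",
    "bladder epithelium",
    "breast epithelium",
    "head and neck epithelium",
    "prostate epithelium",
    "thyroid epithelium",
    "upper GI epithelium",
    "uterus cervix epithelium",
)

#: Cell types populating synthetic spatial samples.
VISIUM_CELL_TYPES: tuple[str, ...] = (
    "NPC-like",
    "AC-like",
    "OPC-like",
    "oligodendrocyte",
    "neuron",
    "immune",
    "MES-like",
)

#: The neural-lineage subset whose total abundance tracks the neural score.
NEURAL_LINEAGE_TYPES: tuple[str, ...] = VISIUM_CELL_TYPES[:5]

#: Published low/high-neural cutoff on the neural proportion.
NEURAL_CUTOFF = 0.41

# Dirichlet concentration: total mass 10, with the neuronal component's mass
# chosen so the marginal Beta median sits at the 0.41 cutoff, i.e. simulated
# cohorts straddle the low/high boundary the way a dichotomized cohort does.
_TOTAL_CONCENTRATION = 10.0
_NEURAL_CONCENTRATION = NEURAL_CUTOFF * (_TOTAL_CONCENTRATION - 2.0 / 3.0) + 1.0 / 3.0


def default_concentration(component_names: Sequence[str]) -> np.ndarray:
    """Dirichlet concentration spanning the 0.41 cutoff on the neural axis."""
    names = list(component_names)
    conc = np.full(
        len(names),
        (_TOTAL_CONCENTRATION - _NEURAL_CONCENTRATION) / max(len(names) - 1, 1),
    )
    if NEURAL_COMPONENT in names:
        conc[names.index(NEURAL_COMPONENT)] = _NEURAL_CONCENTRATION
    return conc


@dataclasses.dataclass(frozen=True)
class ReferenceAtlas:
    """CpG x cell-type beta matrix used as the deconvolution basis."""

    betas: pd.DataFrame  # index: CpG ids, columns: component names

    def __post_init__(self) -> None:
        values = self.betas.to_numpy()
        if values.size and (values.min() < 0 or values.max() > 1):
            raise ValueError("atlas betas must lie in [0, 1]")
        if self.betas.columns.has_duplicates:
            raise ValueError("component names must be unique")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def component_names(self) -> list[str]:
        return list(self.betas.columns)


@dataclasses.dataclass(frozen=True)
class BulkCohort:
    """Bulk beta matrix plus (synthetic-only) ground truth."""

    betas: pd.DataFrame  # index: CpG ids, columns: sample ids
    truth_proportions: pd.DataFrame | None = None  # sample x component
    truth_labels: pd.Series | None = None  # "low" / "high" per sample

    def __post_init__(self) -> None:
        values = self.betas.to_numpy()
        if values.size and (values.min() < 0 or values.max() > 1):
            raise ValueError("bulk betas must lie in [0, 1]")
        if self.truth_proportions is not None:
            sums = self.truth_proportions.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("truth proportion rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.columns)


@dataclasses.dataclass(frozen=True)
class SpatialSample:
    """Visium-style spatial sample with ground truth."""

    coords: pd.DataFrame  # index: spot ids, columns: x, y (micrometres)
    expression: pd.DataFrame  # spot x gene, non-negative
    nucleus_positions: pd.DataFrame  # columns: x, y, spot (home spot id)
    truth_score: float
    truth_spot_composition: pd.DataFrame  # spot x cell type, simplex rows

    @property
    def spot_ids(self) -> list[str]:
        return list(self.coords.index)


def make_reference_atlas(
    n_cpgs: int,
    component_names: Sequence[str] = DEFAULT_COMPONENT_NAMES,
    block_width: int = 10,
    seed: int = 0,
) -> ReferenceAtlas:
    """Build an identifiable synthetic reference atlas.

    Each component owns a disjoint block of ``block_width`` CpGs that is
    hypomethylated (beta 0.1) in that component and hypermethylated
    (beta 0.9) in every other component; the remaining CpGs carry a shared
    uniform baseline and no compositional information.
    """
    names = list(component_names)
    if len(set(names)) != len(names):
        raise ValueError("component names must be unique")
    if block_width < 1 or n_cpgs < 1:
        raise ValueError("n_cpgs and block_width must be positive")
    if n_cpgs < block_width * len(names):
        raise ValueError(
            f"need at least {block_width * len(names)} CpGs for "
            f"{len(names)} blocks of width {block_width}, got {n_cpgs}"
        )
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(0.2, 0.8, size=n_cpgs)
    betas = np.tile(baseline[:, None], (1, len(names)))
    for k in range(len(names)):
        block = slice(k * block_width, (k + 1) * block_width)
        betas[block, :] = 0.9
        betas[block, k] = 0.1
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpgs)]
    return ReferenceAtlas(pd.DataFrame(betas, index=cpg_ids, columns=names))


def make_bulk_cohort(
    atlas: ReferenceAtlas,
    n_samples: int,
    concentration: Sequence[float] | None = None,
    noise_sd: float = 0.005,
    seed: int = 0,
    cutoff: float = NEURAL_CUTOFF,
) -> BulkCohort:
    """Mix bulk beta profiles from an atlas with Dirichlet-drawn proportions.

    betas = atlas @ proportions + Gaussian noise truncated to [0, 1] by
    clipping. Truth labels compare the neuronal component's proportion to
    ``cutoff`` (ties -> high).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    names = atlas.component_names
    if concentration is None:
        conc = default_concentration(names)
    else:
        conc = np.asarray(concentration, dtype=float)
    if conc.shape != (len(names),):
        raise ValueError("concentration length must equal number of components")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(conc, size=n_samples)  # sample x component
    mix = atlas.betas.to_numpy() @ props.T  # CpG x sample
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    mix = np.clip(mix, 0.0, 1.0)
    sample_ids = [f"sample{j:04d}" for j in range(n_samples)]
    betas = pd.DataFrame(mix, index=atlas.cpg_ids, columns=sample_ids)
    truth = pd.DataFrame(props, index=sample_ids, columns=names)
    labels = None
    if NEURAL_COMPONENT in names:
        neural = truth[NEURAL_COMPONENT].to_numpy()
        labels = pd.Series(
            np.where(neural >= cutoff, "high", "low"), index=sample_ids, name="label"
        )
    return BulkCohort(betas=betas, truth_proportions=truth, truth_labels=labels)


def make_single_cell_profiles(
    n_cells: int,
    gene_panel: Sequence[str],
    module_sets: Mapping[str, Sequence[str]],
    cell_type_of_cell: Sequence[str],
    dropout_rate: float = 0.3,
    seed: int = 0,
    module_targets: Mapping[str, str] | None = None,
    background_scale: float = 0.3,
    module_effect: float = 1.5,
) -> pd.DataFrame:
    """Zero-inflated single-cell expression with planted module genes.

    Returns a gene x cell matrix on a log-normalized scale (non-negative).
    Cells of the type a module targets express that module's genes at an
    elevated level; every entry is then independently zeroed with
    probability ``dropout_rate`` (the dropout layer of zero inflation).
    ``module_targets`` maps module name -> targeted cell type; by default a
    module targets the cell type sharing its name.
    """
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must lie in [0, 1]")
    if len(cell_type_of_cell) != n_cells:
        raise ValueError("cell_type_of_cell must have one entry per cell")
    genes = list(gene_panel)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for module, members in module_sets.items():
        missing = [g for g in members if g not in gene_pos]
        if missing:
            raise KeyError(
                f"module {module!r} gene(s) absent from panel: {missing}"
            )
    targets = dict(module_targets or {m: m for m in module_sets})
    rng = np.random.default_rng(seed)
    expr = rng.exponential(background_scale, size=(len(genes), n_cells))
    cell_types = np.asarray(cell_type_of_cell)
    for module, members in module_sets.items():
        target = targets.get(module, module)
        cells = np.flatnonzero(cell_types == target)
        rows = [gene_pos[g] for g in members]
        if cells.size and rows:
            expr[np.ix_(rows, cells)] += module_effect
    if dropout_rate > 0:
        keep = rng.random(expr.shape) >= dropout_rate
        expr = expr * keep
    columns = [f"cell{i:05d}" for i in range(n_cells)]
    return pd.DataFrame(expr, index=genes, columns=columns)


def hexagonal_lattice(n_rows: int, n_cols: int, pitch_um: float) -> pd.DataFrame:
    """Spot coordinates on a hexagonal lattice (odd rows offset by pitch/2)."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    if pitch_um <= 0:
        raise ValueError("pitch_um must be positive")
    ids, xs, ys = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            ids.append(f"spot_{r:03d}_{c:03d}")
            xs.append(c * pitch_um + (pitch_um / 2.0 if r % 2 else 0.0))
            ys.append(r * pitch_um * math.sqrt(3.0) / 2.0)
    return pd.DataFrame({"x": xs, "y": ys}, index=ids)


def make_visium_sample(
    n_rows: int,
    n_cols: int,
    pitch_um: float = 100.0,
    truth_score: float = 0.5,
    n_genes: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    mean_nuclei: float = 4.0,
) -> SpatialSample:
    """Generate a Visium-style spatial sample tied to a neural score.

    Spots sit on a hexagonal lattice with the given pitch. Each spot
    carries a latent composition over seven cell types. The *total*
    abundance of the five neural-lineage types is an exact affine function
    of ``truth_score`` (0.15 + 0.7 * score); smooth sinusoidal spatial
    fields redistribute abundance within the neural-lineage group and
    within the non-neural group but never across them, so at
    ``noise_sd=0`` the expression carries a noise-free score signal while
    still varying from spot to spot. Expression is composition times a
    cell-type signature matrix plus optional Gaussian noise, clipped at 0.
    Nucleus positions are scattered in a disk around each spot centre
    (at least one nucleus per spot).
    """
    if not 0.0 <= truth_score <= 1.0:
        raise ValueError("truth_score must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    coords = hexagonal_lattice(n_rows, n_cols, pitch_um)
    n_spots = len(coords)
    rng = np.random.default_rng(seed)

    types = VISIUM_CELL_TYPES
    n_neural = len(NEURAL_LINEAGE_TYPES)
    neural_total = 0.15 + 0.7 * truth_score

    # Smooth spatial fields: one long-wavelength plane wave per cell type.
    xy = coords.to_numpy()
    wavelength = 8.0 * pitch_um
    logits = np.empty((n_spots, len(types)))
    base_logits = rng.normal(0.0, 0.3, size=len(types))
    for t in range(len(types)):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        wave = np.sin(
            2.0 * math.pi * (xy[:, 0] * math.cos(theta) + xy[:, 1] * math.sin(theta))
            / wavelength
            + phase
        )
        logits[:, t] = base_logits[t] + 0.6 * wave

    def softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    comp = np.empty((n_spots, len(types)))
    comp[:, :n_neural] = neural_total * softmax(logits[:, :n_neural])
    comp[:, n_neural:] = (1.0 - neural_total) * softmax(logits[:, n_neural:])

    # Cell-type expression signatures: gamma background plus marker blocks.
    signatures = rng.gamma(2.0, 0.25, size=(len(types), n_genes))
    block = max(n_genes // (2 * len(types)), 1)
    for t in range(len(types)):
        lo = (t * block) % n_genes
        signatures[t, lo : lo + block] += 2.5

    expression = comp @ signatures * 10.0
    if noise_sd > 0:
        expression = expression + rng.normal(0.0, noise_sd, size=expression.shape)
    expression = np.clip(expression, 0.0, None)
    gene_names = [f"gene{g:04d}" for g in range(n_genes)]
    expression_df = pd.DataFrame(expression, index=coords.index, columns=gene_names)

    # Nuclei: >= 1 per spot, uniform in a disk of radius 0.275 * pitch.
    counts = 1 + rng.poisson(mean_nuclei, size=n_spots)
    radius = 0.275 * pitch_um
    rows = []
    for j, spot in enumerate(coords.index):
        angles = rng.uniform(0.0, 2.0 * math.pi, size=counts[j])
        radii = radius * np.sqrt(rng.random(counts[j]))
        for a, r in zip(angles, radii):
            rows.append(
                (xy[j, 0] + r * math.cos(a), xy[j, 1] + r * math.sin(a), spot)
            )
    nuclei = pd.DataFrame(rows, columns=["x", "y", "spot"])

    truth_comp = pd.DataFrame(comp, index=coords.index, columns=list(types))
    return SpatialSample(
        coords=coords,
        expression=expression_df,
        nucleus_positions=nuclei,
        truth_score=float(truth_score),
        truth_spot_composition=truth_comp,
    )
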