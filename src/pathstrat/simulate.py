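"""Synthetic cohorts with planted, recoverable structure.

The generator emulates the kind of preprocessed data the analysis pipeline
consumes: a bulk log2 expression cohort with ``k`` latent clusters, each
defined by a coordinated shift of a planted gene *program*, cluster-dependent
exponential survival, a gene-set collection containing redundant planted sets
plus size-matched decoys, and a single-cell matrix with planted cell states.

Redundancy is deliberate: each cluster's program is represented by several
overlapping gene sets (random subsets of the program pool), which is what
makes overlap-based signature synthesis meaningful — real pathway collections
are highly redundant in exactly this way.

All generators are pure functions of their configuration: a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, SurvivalTable

logger = logging.getLogger("pathstrat")

#: inclusion probability of a program gene in each planted set
_SET_INCLUSION = 0.8


@dataclass
class SimulationConfig:
    """Parameters of the bulk-cohort generator.

    effect is the mean log2 shift of program genes in their own cluster's
    samples; hazard_by_cluster gives the exponential event rate per cluster
    (per month); censor_rate is the probability a subject is censored.
    down_fraction is the fraction of clusters whose program is down- rather
    than up-shifted.
    """

    n_genes: int = 2000
    n_samples: int = 60
    k_clusters: int = 3
    programs_per_cluster: int = 8
    program_size: int = 50
    effect: float = 2.0
    noise_sd: float = 1.0
    hazard_by_cluster: tuple[float, ...] = (0.04, 0.07, 0.10)
    censor_rate: float = 0.2
    seed: int = 0
    n_decoys: int = 40
    down_fraction: float = 0.0

    def __post_init__(self):
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.program_size < 2:
            raise ValueError("program_size must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.hazard_by_cluster) != self.k_clusters:
            raise ValueError("hazard_by_cluster must have one rate per cluster")
        if any(h <= 0 for h in self.hazard_by_cluster):
            raise ValueError("hazards must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.program_size * self.programs_per_cluster * self.k_clusters > self.n_genes:
            raise ValueError(
                "program_size * programs_per_cluster * k_clusters exceeds n_genes"
            )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    labels: dict[str, int]                     # sample (or cell) -> cluster/state index
    planted_sets: dict[int, list[GeneSet]] = field(default_factory=dict)
    program_genes: dict[int, list[str]] = field(default_factory=dict)
    survival_params: tuple[float, ...] = ()
    directions: dict[int, int] = field(default_factory=dict)   # cluster -> +1 / -1
    state_names: dict[int, str] = field(default_factory=dict)  # single-cell states
    overlapping_states: bool = False

    def label_vector(self, ids: list[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_bulk(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SurvivalTable, GeneSetCollection, SyntheticTruth]:
    """Generate a bulk cohort, survival table, gene-set collection, and truth.

    Baseline expression of gene g is Normal(mu_g, noise_sd) with gene means
    mu_g drawn once from Normal(7, 1.5) (typical log2 microarray/RNA-seq
    intensities).  Each cluster owns a disjoint program pool of
    ``program_size`` genes shifted by +/- ``effect`` in that cluster's
    samples.  The collection holds ``programs_per_cluster`` overlapping
    planted sets per cluster plus ``n_decoys`` size-matched random decoys.
    Survival times are Exponential(hazard of cluster) with independent
    uniform right-censoring.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    samples = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]

    # near-equal cluster assignment in sample order
    labels = np.repeat(np.arange(cfg.k_clusters), int(np.ceil(cfg.n_samples / cfg.k_clusters)))[
        : cfg.n_samples
    ]

    mu = rng.normal(7.0, 1.5, size=cfg.n_genes)
    X = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))

    n_down = int(round(cfg.down_fraction * cfg.k_clusters))
    directions = {c: (-1 if c < n_down else 1) for c in range(cfg.k_clusters)}

    program_genes: dict[int, list[str]] = {}
    planted_sets: dict[int, list[GeneSet]] = {}
    set_size = max(2, int(round(_SET_INCLUSION * cfg.program_size)))
    all_sets: list[GeneSet] = []
    for c in range(cfg.k_clusters):
        pool_idx = np.arange(c * cfg.program_size, (c + 1) * cfg.program_size)
        pool = [genes[i] for i in pool_idx]
        program_genes[c] = pool
        X[np.ix_(pool_idx, np.flatnonzero(labels == c))] += directions[c] * cfg.effect
        planted_sets[c] = []
        for p in range(cfg.programs_per_cluster):
            members = rng.choice(pool, size=set_size, replace=False)
            gs = GeneSet(
                name=f"PLANTED_C{c + 1}_{p + 1:02d}",
                description=f"planted program, cluster {c + 1}",
                genes=tuple(sorted(members)),
            )
            planted_sets[c].append(gs)
            all_sets.append(gs)
    for d in range(cfg.n_decoys):
        members = rng.choice(genes, size=set_size, replace=False)
        all_sets.append(
            GeneSet(name=f"DECOY_{d + 1:03d}", description="decoy", genes=tuple(sorted(members)))
        )

    hazards = np.asarray(cfg.hazard_by_cluster, dtype=float)
    t_event = rng.exponential(1.0 / hazards[labels])
    censored = rng.random(cfg.n_samples) < cfg.censor_rate
    t_obs = np.where(censored, rng.uniform(0.0, t_event), t_event)
    clinical = SurvivalTable(
        data=pd.DataFrame(
            {
                "sample": samples,
                "time": t_obs,
                "event": (~censored).astype(int),
                "group": labels,
            }
        )
    )

    matrix = ExpressionMatrix(values=pd.DataFrame(X, index=genes, columns=samples))
    collection = GeneSetCollection(sets=all_sets, label="synthetic")
    truth = SyntheticTruth(
        labels=dict(zip(samples, labels.tolist())),
        planted_sets=planted_sets,
        program_genes=program_genes,
        survival_params=tuple(hazards.tolist()),
        directions=directions,
    )
    return matrix, clinical, collection, truth


def simulate_single_cell(
    n_cells: int,
    states: list[tuple[str, GeneSet, float]],
    noise_sd: float = 1.0,
    dropout: float = 0.0,
    seed: int = 0,
    n_genes: int = 500,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a single-cell log-expression matrix with planted cell states.

    Each state is a (name, program gene set, effect) triple; cells are split
    near-equally across states and the state's program genes are shifted by
    ``effect`` in its cells.  Entries are then zeroed independently at rate
    ``dropout``.  The gene universe is the union of program genes padded with
    background genes up to ``n_genes``.
    """
    if not states:
        raise ValueError("at least one state is required")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)

    program_union: list[str] = []
    seen: set[str] = set()
    overlap = False
    for _, gs, _ in states:
        for g in gs.genes:
            if g in seen:
                overlap = True
            else:
                seen.add(g)
                program_union.append(g)
    if overlap:
        logger.warning("program genes overlap across states; recorded in truth")
    background = [f"BG{i:05d}" for i in range(1, max(0, n_genes - len(program_union)) + 1)]
    genes = program_union + background
    cells = [f"CELL{i:04d}" for i in range(1, n_cells + 1)]

    state_of_cell = np.repeat(np.arange(len(states)), int(np.ceil(n_cells / len(states))))[:n_cells]
    gene_index = {g: i for i, g in enumerate(genes)}

    # homogeneous baseline: per-cell scores are background-relative, so
    # gene-specific baseline offsets would only add a fixed per-set bias
    X = 2.0 + rng.normal(0.0, noise_sd, size=(len(genes), n_cells))
    for s, (_, gs, effect) in enumerate(states):
        idx = [gene_index[g] for g in gs.genes]
        X[np.ix_(idx, np.flatnonzero(state_of_cell == s))] += effect
    if dropout > 0:
        X[rng.random(X.shape) < dropout] = 0.0

    truth = SyntheticTruth(
        labels=dict(zip(cells, state_of_cell.tolist())),
        planted_sets={s: [gs] for s, (_, gs, _) in enumerate(states)},
        program_genes={s: list(gs.genes) for s, (_, gs, _) in enumerate(states)},
        state_names={s: name for s, (name, _, _) in enumerate(states)},
        overlapping_states=overlap,
    )
    return ExpressionMatrix(values=pd.DataFrame(X, index=genes, columns=cells)), truth


def make_collection(pool: list[str], n_sets: int, size: int, seed: int = 0) -> GeneSetCollection:
    """Random gene-set collection: ``n_sets`` subsets of ``pool`` of the given size."""
    if size > len(pool):
        raise ValueError("set size exceeds pool length")
    rng = np.random.default_rng(seed)
    pool = [g.upper() for g in pool]
    sets = [
        GeneSet(
            name=f"SET{i + 1:04d}",
            description="random",
            genes=tuple(sorted(rng.choice(pool, size=size, replace=False))),
        )
        for i in range(n_sets)
    ]
    return GeneSetCollection(sets=sets, label="random")
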