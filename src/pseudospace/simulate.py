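"""Paired SC/ST simulator with a shared population structure.

A gamma-Poisson (negative-binomial marginal) count generator in the style of
Splatter: gene baseline means are gamma-distributed, cell populations get
differentially expressed (DE) genes at rate ``de_prob_major`` with log-normal
fold changes, and designated *spatial subclusters* are carved out of a parent
population, inheriting its DE genes and adding extras only at rate
``de_prob_sub`` — transcriptomically near-identical to the parent by design,
but placed at their own spatial centers. The single-cell and spatial
modalities draw from the same population mixture; a multiplicative per-gene
log-normal batch factor applied to the single-cell batch emulates the
technical shift between the two assays. Every group's cells scatter
isotropically (Normal, sd ``spatial_sd``) around a center sampled uniformly
in a ``field_size`` x ``field_size`` square; the single-cell coordinates are
kept only as ground truth for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset, SpatialReference

__all__ = ["SimConfig", "SimulatedPair", "simulate_paired", "assign_coordinates"]


@dataclass
class SimConfig:
    """Study conditions of the paired simulation.

    Defaults follow the benchmark design: 5000 genes, two batches, DE
    probability 0.2 for populations vs 0.01 for spatial subclusters, spatial
    centers uniform in a 20 x 20 field with per-cell Normal(center, 1)
    placement, and cell counts in the middle of the 500-1500 range.
    """

    n_genes: int = 5000
    n_sc: int = 800
    n_st: int = 800
    n_pops: int = 5
    n_spatial_subclusters: int = 0
    de_prob_major: float = 0.2
    de_prob_sub: float = 0.01
    de_log2fc_mean: float = 1.0
    de_log2fc_sd: float = 0.4
    batch_log2fc_sd: float = 0.25
    libsize_log_mean: float = float(np.log(1e4))
    libsize_log_sd: float = 0.25
    mean_shape: float = 0.6       # gamma shape of gene baseline means
    mean_rate: float = 0.3        # gamma rate of gene baseline means
    field_size: float = 20.0
    spatial_sd: float = 1.0
    #: a subcluster center is re-drawn until it lies at least this far from
    #: its parent population's center — subclusters are spatially separated
    #: from their parent by construction, that being their defining feature
    min_subcluster_separation: float = 5.0
    pop_proportions: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.de_prob_major, self.de_prob_sub):
            if not 0.0 <= p <= 1.0:
                raise ValueError("DE probabilities must lie in [0, 1]")
        if self.n_pops < 1:
            raise ValueError("need at least one population")
        if self.n_spatial_subclusters < 0:
            raise ValueError("n_spatial_subclusters must be >= 0")
        if self.pop_proportions is not None:
            if len(self.pop_proportions) != self.n_pops:
                raise ValueError("pop_proportions length must equal n_pops")
            if abs(sum(self.pop_proportions) - 1.0) > 1e-8:
                raise ValueError("pop_proportions must sum to 1")


@dataclass
class SimulatedPair:
    """A simulated SC dataset + ST reference with full ground truth."""

    sc: ExpressionDataset              # labels = group-level truth
    st: SpatialReference               # expr.labels = group-level truth
    truth_coords_sc: np.ndarray        # n_sc x 2, evaluation-only
    sc_populations: list[str] = field(default_factory=list)
    st_populations: list[str] = field(default_factory=list)
    group_centers: dict[str, np.ndarray] = field(default_factory=dict)
    de_masks: dict[str, np.ndarray] = field(default_factory=dict)


def assign_coordinates(
    labels,
    field_size: float = 20.0,
    spatial_sd: float = 1.0,
    seed: int = 0,
    centers: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Place cells around per-label spatial centers.

    One center per distinct label is drawn uniformly in
    ``[0, field_size]^2`` (unless ``centers`` provides them); each cell's
    position is Normal(center, spatial_sd * I). Returns ``(coords, centers)``.
    """
    labels = list(map(str, labels))
    if not labels:
        raise ValueError("need at least one label")
    rng = np.random.default_rng(seed)
    distinct = sorted(set(labels))
    if centers is None:
        centers = {
            lab: rng.uniform(0.0, field_size, size=2) for lab in distinct
        }
    coords = np.empty((len(labels), 2))
    for i, lab in enumerate(labels):
        coords[i] = centers[lab] + rng.normal(0.0, spatial_sd, size=2)
    return coords, centers


def _allocate(n_cells: int, groups: list[str], weights: np.ndarray) -> list[str]:
    """Deterministic largest-remainder allocation of cells to groups."""
    raw = weights * n_cells
    counts = np.floor(raw).astype(int)
    short = n_cells - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    out: list[str] = []
    for g, c in zip(groups, counts):
        out.extend([g] * int(c))
    return out


def simulate_paired(cfg: SimConfig | None = None, **overrides) -> SimulatedPair:
    """Generate one paired SC/ST dataset under ``cfg``.

    Group mean profiles are ``base_mean * pop_factor * sub_factor`` with
    log-normal DE fold factors; counts are Poisson with per-cell library-size
    factors, giving negative-binomial marginals across cells. Identical
    configs (including the seed) reproduce identical pairs.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either cfg or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)

    if cfg.n_spatial_subclusters > 0 and cfg.n_pops < 1:
        raise ValueError("subclusters need at least one parent population")
    if cfg.n_spatial_subclusters > min(cfg.n_sc, cfg.n_st):
        raise ValueError("more subclusters than cells")

    base_mean = rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=cfg.n_genes)
    base_mean = np.maximum(base_mean, 1e-8)

    def de_factor(prob: float) -> tuple[np.ndarray, np.ndarray]:
        mask = rng.random(cfg.n_genes) < prob
        log2fc = rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd, cfg.n_genes)
        signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)
        fac = np.where(mask, 2.0 ** (signs * log2fc), 1.0)
        return fac, mask

    pops = [f"Pop{p + 1}" for p in range(cfg.n_pops)]
    pop_factors: dict[str, np.ndarray] = {}
    de_masks: dict[str, np.ndarray] = {}
    for pop in pops:
        pop_factors[pop], de_masks[pop] = de_factor(cfg.de_prob_major)

    # carve subclusters out of parent populations (round-robin)
    group_profiles: dict[str, np.ndarray] = {}
    group_parent: dict[str, str] = {}
    sub_of: dict[str, list[str]] = {p: [] for p in pops}
    for s in range(cfg.n_spatial_subclusters):
        parent = pops[s % cfg.n_pops]
        name = f"{parent}-sub{len(sub_of[parent]) + 1}"
        extra, extra_mask = de_factor(cfg.de_prob_sub)
        group_profiles[name] = base_mean * pop_factors[parent] * extra
        group_parent[name] = parent
        de_masks[name] = de_masks[parent] | extra_mask
        sub_of[parent].append(name)
    for pop in pops:
        group_profiles[pop] = base_mean * pop_factors[pop]
        group_parent[pop] = pop

    # group weights: equal across populations; a carved population's share
    # is split equally between its core and its subclusters
    pop_w = (
        np.asarray(cfg.pop_proportions, dtype=float)
        if cfg.pop_proportions is not None
        else np.full(cfg.n_pops, 1.0 / cfg.n_pops)
    )
    groups: list[str] = []
    weights: list[float] = []
    for pop, w in zip(pops, pop_w):
        members = [pop] + sub_of[pop]
        for gname in members:
            groups.append(gname)
            weights.append(w / len(members))
    weights_arr = np.asarray(weights)

    batch_fac = 2.0 ** rng.normal(0.0, cfg.batch_log2fc_sd, cfg.n_genes)

    def sample_counts(n_cells: int, is_sc: bool) -> tuple[np.ndarray, list[str]]:
        cell_groups = _allocate(n_cells, groups, weights_arr)
        libsize = np.exp(
            rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, n_cells)
        )
        counts = np.empty((n_cells, cfg.n_genes))
        for i, gname in enumerate(cell_groups):
            prof = group_profiles[gname]
            if is_sc:
                prof = prof * batch_fac
            p = prof / prof.sum()
            counts[i] = rng.poisson(libsize[i] * p)
        return counts, cell_groups

    sc_counts, sc_groups = sample_counts(cfg.n_sc, is_sc=True)
    st_counts, st_groups = sample_counts(cfg.n_st, is_sc=False)

    coord_seed = int(rng.integers(0, 2**31 - 1))
    center_rng = np.random.default_rng(coord_seed)
    centers: dict[str, np.ndarray] = {}
    for gname in groups:
        center = center_rng.uniform(0.0, cfg.field_size, size=2)
        parent = group_parent[gname]
        if gname != parent:  # subcluster: enforce spatial separation
            for _ in range(1000):
                if (np.linalg.norm(center - centers[parent])
                        >= cfg.min_subcluster_separation):
                    break
                center = center_rng.uniform(0.0, cfg.field_size, size=2)
        centers[gname] = center

    st_coords, _ = assign_coordinates(
        st_groups, cfg.field_size, cfg.spatial_sd, seed=coord_seed + 2,
        centers=centers,
    )
    sc_coords, _ = assign_coordinates(
        sc_groups, cfg.field_size, cfg.spatial_sd,
        seed=coord_seed + 1, centers=centers,
    )

    width = len(str(max(cfg.n_sc, cfg.n_st)))
    gene_names = [f"G{j + 1:0{len(str(cfg.n_genes))}d}" for j in range(cfg.n_genes)]
    sc = ExpressionDataset(
        matrix=sc_counts,
        gene_names=gene_names,
        obs_ids=[f"SC_{i + 1:0{width}d}" for i in range(cfg.n_sc)],
        labels=sc_groups,
        layer_tag="counts",
    )
    st_expr = ExpressionDataset(
        matrix=st_counts,
        gene_names=gene_names,
        obs_ids=[f"ST_{i + 1:0{width}d}" for i in range(cfg.n_st)],
        labels=st_groups,
        layer_tag="counts",
    )
    return SimulatedPair(
        sc=sc,
        st=SpatialReference(expr=st_expr, coords=st_coords),
        truth_coords_sc=sc_coords,
        sc_populations=[group_parent[g] for g in sc_groups],
        st_populations=[group_parent[g] for g in st_groups],
        group_centers=centers,
        de_masks=de_masks,
    )
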