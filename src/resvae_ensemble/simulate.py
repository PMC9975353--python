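"""Synthetic regulatory-trajectory generators with exact ground truth.

Two designs:

* a bifurcating trajectory — seven populations (sA -> sB -> sBmid
  forking into sC -> sEndC and sD -> sEndD), 35 transcription factors
  organised into named modules (Burn1-4, A, B1-B14, D6) regulating 500
  target genes, plus 20 unregulated housekeeping genes;
* a myeloid-differentiation model — a progenitor population and four
  terminal fates (Mk, Ery, Granu, Mono) driven by 11 named regulators
  with the classical fate associations (EKLF->Ery, Fli-1->Mk,
  GATA-1->Ery/Mk, PU.1/cJun/EgrNab/C/EBPa->Mono, Gfi-1->Granu, ...).

Module activities are smooth windows over pseudotime with hard
branch-antagonistic gating (a cell on the C branch receives exactly
zero input from D-branch modules); counts are negative binomial via
gamma-Poisson mixing, so the per-gene variance exceeds the mean.
Cluster assignments come in hard (population label) and soft (Gaussian
kernel similarity to the population archetype centroids) forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ClusterAssignment, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "MyeloidConfig",
    "RegulatoryGroundTruth",
    "BIFURCATION_POPULATIONS",
    "MYELOID_REGULATORS",
    "MYELOID_FATE_REGULATORS",
    "simulate_bifurcation",
    "simulate_myeloid",
    "split_cluster_partitions",
]

BIFURCATION_POPULATIONS = ("sA", "sB", "sBmid", "sC", "sD", "sEndC", "sEndD")

# (t_start, t_end, branch); trunk cells carry branch "" and fork at t=0.5
_POP_SEGMENTS: dict[str, tuple[float, float, str]] = {
    "sA": (0.0, 0.2, ""),
    "sB": (0.2, 0.35, ""),
    "sBmid": (0.35, 0.5, ""),
    "sC": (0.5, 0.75, "C"),
    "sEndC": (0.75, 1.0, "C"),
    "sD": (0.5, 0.75, "D"),
    "sEndD": (0.75, 1.0, "D"),
}

# module -> (n_tfs, active populations); sizes total 35
_MODULE_TABLE: dict[str, tuple[int, tuple[str, ...]]] = {
    "Burn1": (2, ("sA",)),
    "Burn2": (2, ("sA",)),
    "Burn3": (2, ("sA",)),
    "Burn4": (2, ("sA",)),
    "A": (3, ("sB", "sBmid")),
    "B1": (2, ("sB", "sBmid")),
    "B2": (2, ("sC", "sEndC")),
    "B3": (2, ("sD", "sEndD")),
    "B4": (2, ("sA",)),
    "B5": (2, ("sA",)),
    "B6": (2, ("sC", "sEndC")),
    "B7": (2, ("sD", "sEndD")),
    "B8": (2, ("sC", "sEndC", "sD", "sEndD")),
    "B9": (1, ("sC", "sEndC")),
    "B10": (1, ("sC", "sEndC")),
    "B11": (1, ("sC", "sEndC")),
    "B12": (1, ("sD", "sEndD")),
    "B13": (1, ("sD", "sEndD")),
    "B14": (1, ("sD", "sEndD")),
    "D6": (2, ("sD", "sEndD")),
}

MYELOID_REGULATORS = (
    "EKLF",
    "Fli-1",
    "GATA-1",
    "GATA-2",
    "PU.1",
    "cJun",
    "EgrNab",
    "C/EBPa",
    "Gfi-1",
    "SCL",
    "FOG-1",
)

# fate associations of the 11 regulators in the myeloid model
MYELOID_FATE_REGULATORS: dict[str, tuple[str, ...]] = {
    "Prog": ("GATA-2", "SCL"),
    "Ery": ("EKLF", "GATA-1", "SCL", "FOG-1"),
    "Mk": ("Fli-1", "GATA-1", "FOG-1"),
    "Mono": ("PU.1", "cJun", "EgrNab", "C/EBPa"),
    "Granu": ("Gfi-1",),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the bifurcation generator.

    Defaults reproduce the stated design: 7 populations x 200 cells,
    35 TFs, 500 regulated targets, 20 housekeeping genes, negative
    binomial counts with dispersion (NB size) 10.
    """

    n_cells_per_population: int = 200
    n_targets: int = 500
    n_housekeeping: int = 20
    dispersion: float = 10.0
    tf_scale: float = 50.0
    target_scale: float = 25.0
    housekeeping_mean: float = 10.0
    base_mean: float = 0.5
    ramp_width: float = 0.04
    soft_bandwidth: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_population <= 0:
            raise ValueError("n_cells_per_population must be positive")
        if self.n_targets <= 0 or self.n_housekeeping <= 0:
            raise ValueError("feature counts must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name in ("tf_scale", "target_scale", "housekeeping_mean", "base_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_tfs(self) -> int:
        return sum(n for n, _ in _MODULE_TABLE.values())


@dataclass
class RegulatoryGroundTruth:
    """What the generator actually wired, for scoring recovery.

    ``population_modules`` maps each population to its active modules;
    ``feature_roles`` tags every feature as tf/target/housekeeping;
    ``tf_module`` names each TF's module; ``edges`` maps each target to
    its (tf, weight) regulators. Housekeeping features never appear in
    ``edges`` values.
    """

    population_modules: dict[str, set[str]]
    feature_roles: dict[str, str]
    tf_module: dict[str, str]
    edges: dict[str, list[tuple[str, float]]]
    cell_pseudotime: np.ndarray | None = None
    cell_branch: np.ndarray | None = None

    def active_tfs(self, population: str) -> list[str]:
        """TFs whose module is active in ``population``."""
        if population not in self.population_modules:
            raise KeyError(f"unknown population {population!r}")
        mods = self.population_modules[population]
        return sorted(t for t, m in self.tf_module.items() if m in mods)

    def housekeeping(self) -> list[str]:
        return sorted(f for f, r in self.feature_roles.items() if r == "housekeeping")


def _module_activity(
    t: np.ndarray, branch: np.ndarray, populations: tuple[str, ...], ramp: float
) -> np.ndarray:
    """Smooth pseudotime window over the union of active segments,
    gated hard by branch compatibility."""
    segs = [_POP_SEGMENTS[p] for p in populations]
    t0 = min(s[0] for s in segs)
    t1 = max(s[1] for s in segs)
    act = np.ones_like(t)
    below, above = t < t0, t > t1
    act[below] = np.exp(-(((t[below] - t0) / ramp) ** 2))
    act[above] = np.exp(-(((t[above] - t1) / ramp) ** 2))
    branches = {s[2] for s in segs}
    if branches != {""}:
        # branch-specific module: zero on incompatible branches and,
        # for cells still on the trunk, before the fork
        compatible = np.isin(branch, sorted(branches - {""}))
        act = np.where(compatible, act, 0.0)
    return act


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(float)


def _soft_weights(
    coords: np.ndarray, centroids: np.ndarray, bandwidth: float
) -> np.ndarray:
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    k = np.exp(-d2 / (2.0 * bandwidth**2))
    return k / k.sum(axis=1, keepdims=True)


def simulate_bifurcation(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, ClusterAssignment, ClusterAssignment, RegulatoryGroundTruth]:
    """Bifurcating-trajectory counts with hard and soft assignments.

    Returns ``(counts, hard, soft, truth)``. Cells are laid out on
    pseudotime within their population segment; TF means follow their
    module's activity window, target means are weighted sums of their
    1-3 regulators' activities, housekeeping means are constant.
    """
    rng = np.random.default_rng(config.seed)
    n_pop = config.n_cells_per_population

    pops, ts, branches = [], [], []
    for p in BIFURCATION_POPULATIONS:
        t0, t1, br = _POP_SEGMENTS[p]
        ts.append(rng.uniform(t0, t1, size=n_pop))
        pops.extend([p] * n_pop)
        branches.extend([br] * n_pop)
    t = np.concatenate(ts)
    branch = np.asarray(branches)
    populations = np.asarray(pops)
    n_cells = t.size

    # module activity per cell
    activity = {
        mod: _module_activity(t, branch, active, config.ramp_width)
        for mod, (_, active) in _MODULE_TABLE.items()
    }

    tf_ids, tf_module = [], {}
    tf_activity = []
    for mod, (size, _) in _MODULE_TABLE.items():
        for i in range(1, size + 1):
            name = f"TF_{mod}_{i}"
            tf_ids.append(name)
            tf_module[name] = mod
            tf_activity.append(activity[mod])
    tf_activity = np.stack(tf_activity, axis=1)  # cells x tfs

    width = len(str(config.n_targets))
    target_ids = [f"G{i:0{width}d}" for i in range(1, config.n_targets + 1)]
    edges: dict[str, list[tuple[str, float]]] = {}
    target_activity = np.zeros((n_cells, config.n_targets))
    for j, g in enumerate(target_ids):
        k = int(rng.integers(1, 4))
        regs = rng.choice(len(tf_ids), size=k, replace=False)
        w = rng.uniform(0.5, 1.0, size=k)
        w = w / w.sum()
        edges[g] = [(tf_ids[r], float(wi)) for r, wi in zip(regs, w)]
        target_activity[:, j] = tf_activity[:, regs] @ w

    hk_ids = [f"HK_{i:02d}" for i in range(1, config.n_housekeeping + 1)]

    mean = np.concatenate(
        [
            config.base_mean + config.tf_scale * tf_activity,
            config.base_mean + config.target_scale * target_activity,
            np.full((n_cells, config.n_housekeeping), config.housekeeping_mean),
        ],
        axis=1,
    )
    counts = _nb_counts(rng, mean, config.dispersion)

    feature_ids = tf_ids + target_ids + hk_ids
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    data = ExpressionMatrix(values=counts, feature_ids=feature_ids, cell_ids=cell_ids)

    hard = ClusterAssignment.from_labels(
        populations, cell_ids, cluster_ids=list(BIFURCATION_POPULATIONS)
    )

    # archetype centroids in (pseudotime, branch-offset) coordinates
    def _coord(tv: np.ndarray, br: np.ndarray) -> np.ndarray:
        offset = np.where(br == "C", 1.0, np.where(br == "D", -1.0, 0.0))
        return np.stack([tv, offset * np.maximum(tv - 0.5, 0.0)], axis=1)

    centroids = []
    for p in BIFURCATION_POPULATIONS:
        t0, t1, br = _POP_SEGMENTS[p]
        mid = 0.5 * (t0 + t1)
        centroids.append(_coord(np.array([mid]), np.array([br]))[0])
    soft_w = _soft_weights(_coord(t, branch), np.asarray(centroids), config.soft_bandwidth)
    soft = ClusterAssignment(
        weights=soft_w,
        cluster_ids=list(BIFURCATION_POPULATIONS),
        cell_ids=cell_ids,
        is_hard=False,
    )

    roles = {f: "tf" for f in tf_ids}
    roles.update({f: "target" for f in target_ids})
    roles.update({f: "housekeeping" for f in hk_ids})
    truth = RegulatoryGroundTruth(
        population_modules={
            p: {m for m, (_, active) in _MODULE_TABLE.items() if p in active}
            for p in BIFURCATION_POPULATIONS
        },
        feature_roles=roles,
        tf_module=tf_module,
        edges=edges,
        cell_pseudotime=t,
        cell_branch=branch,
    )
    return data, hard, soft, truth


@dataclass(frozen=True)
class MyeloidConfig:
    """Knobs of the myeloid-differentiation generator."""

    n_cells_per_fate: int = 150
    n_noise_features: int = 0
    dispersion: float = 10.0
    scale: float = 40.0
    progenitor_scale: float = 15.0
    base_mean: float = 0.5
    noise_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_fate < 10:
            raise ValueError("need at least 10 cells per fate")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def simulate_myeloid(
    config: MyeloidConfig = MyeloidConfig(),
) -> tuple[ExpressionMatrix, ClusterAssignment, RegulatoryGroundTruth]:
    """Myeloid model: progenitors plus four fates over 11 regulators.

    A regulator's mean is high in its associated fate(s), intermediate
    in progenitors for the progenitor-associated regulators, and basal
    elsewhere. Optional unassociated noise features can be appended.
    """
    rng = np.random.default_rng(config.seed)
    fates = list(MYELOID_FATE_REGULATORS)  # Prog + 4 terminal fates
    n = config.n_cells_per_fate
    labels = [f for f in fates for _ in range(n)]
    n_cells = len(labels)

    mean = np.full((n_cells, len(MYELOID_REGULATORS)), config.base_mean)
    for fi, fate in enumerate(fates):
        rows = slice(fi * n, (fi + 1) * n)
        scale = config.progenitor_scale if fate == "Prog" else config.scale
        for reg in MYELOID_FATE_REGULATORS[fate]:
            mean[rows, MYELOID_REGULATORS.index(reg)] = scale
    feature_ids = list(MYELOID_REGULATORS)
    if config.n_noise_features:
        noise = np.full((n_cells, config.n_noise_features), config.noise_mean)
        mean = np.concatenate([mean, noise], axis=1)
        feature_ids += [f"noise_{i:02d}" for i in range(1, config.n_noise_features + 1)]

    counts = _nb_counts(rng, mean, config.dispersion)
    cell_ids = [f"mcell_{i:05d}" for i in range(n_cells)]
    data = ExpressionMatrix(values=counts, feature_ids=feature_ids, cell_ids=cell_ids)
    assignment = ClusterAssignment.from_labels(labels, cell_ids, cluster_ids=fates)

    roles = {f: "tf" for f in MYELOID_REGULATORS}
    roles.update(
        {f: "housekeeping" for f in feature_ids if f.startswith("noise_")}
    )
    truth = RegulatoryGroundTruth(
        population_modules={f: set(MYELOID_FATE_REGULATORS[f]) for f in fates},
        feature_roles=roles,
        tf_module={r: r for r in MYELOID_REGULATORS},  # one regulator per "module"
        edges={},
    )
    return data, assignment, truth


def split_cluster_partitions(assignment: ClusterAssignment, seed: int = 0) -> ClusterAssignment:
    """Randomly halve every cluster into ``<id>_1`` / ``<id>_2``.

    The partition sizes differ by at most one cell; the cluster count
    doubles. Used as a self-consistency diagnostic: partitions of a
    homogeneous cluster should yield near-identical feature sets.
    """
    if not assignment.is_hard:
        raise ValueError("partition splitting requires a hard assignment")
    rng = np.random.default_rng(seed)
    labels = assignment.hard_labels()
    new_labels = np.empty(len(labels), dtype=object)
    for c in assignment.cluster_ids:
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"cluster {c!r} has fewer than 2 cells; cannot split")
        idx = rng.permutation(idx)
        half = idx.size // 2 + idx.size % 2
        new_labels[idx[:half]] = f"{c}_1"
        new_labels[idx[half:]] = f"{c}_2"
    new_ids = [f"{c}_{k}" for c in assignment.cluster_ids for k in (1, 2)]
    return ClusterAssignment.from_labels(list(new_labels), assignment.cell_ids, cluster_ids=new_ids)
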