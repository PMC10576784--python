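"""Seeded generators for synthetic assay pairs and perturbation graphs.

The generators emulate the statistical structure the analysis assumes: a
congeneric series with true dGs spanning a few kcal/mol, measured by two
assays that may disagree by an additive offset and by per-measurement noise
(Gaussian or heavy-tailed Student-t) applied on the dG (log-concentration)
scale, with optional detection-limit censoring that clamps concentrations to
the limit and flags them lt/gt; and connected perturbation graphs built as a
random spanning tree plus extra cycle-closing chords whose edge ddGs carry
Gaussian noise.  All randomness flows from the config seed; identical
configs produce bit-identical output.

Default conditions: series of 50 compounds, true dGs uniform over a
5 kcal/mol dynamic range centered at -10 kcal/mol (tens of nM), per-assay
Gaussian noise of 0.45 kcal/mol — two such assays disagree by ~0.64 kcal/mol
per compound, i.e. pairwise RMSEs near the ~0.9 kcal/mol regime observed
between real assays — and no offset or censoring unless configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .affinity import (
    DEFAULT_THERMO,
    AffinityMeasurement,
    Qualifier,
    ThermoConstants,
)
from .exceptions import RbfeError
from .graph import Edge, PerturbationGraph
from .survey import AssaySeries


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise on the dG scale (kcal/mol).

    ``kind`` is 'gaussian' (sd = ``scale``) or 'student_t' (Student-t with
    ``df`` degrees of freedom and scale = ``scale``); scale 0 disables
    noise.
    """

    kind: str = "gaussian"
    scale: float = 0.45
    df: float = 6.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "student_t"):
            raise RbfeError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0 or self.df <= 0:
            raise RbfeError("noise scale must be >= 0 and df > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.scale == 0:
            return np.zeros(n)
        if self.kind == "gaussian":
            return rng.normal(0.0, self.scale, size=n)
        return self.scale * rng.standard_t(self.df, size=n)


@dataclass(frozen=True)
class SeriesSimConfig:
    """Conditions for a simulated two-assay measurement of one series."""

    n_compounds: int = 50
    dg_range: float = 5.0  # span (uniform) or sd (normal) of true dGs
    dg_distribution: str = "uniform"
    dg_center: float = -10.0
    assay_offsets: Tuple[float, float] = (0.0, 0.0)
    noise: Tuple[NoiseModel, NoiseModel] = (NoiseModel(), NoiseModel())
    censor_limits: Tuple[
        Optional[Tuple[float, float]], Optional[Tuple[float, float]]
    ] = (None, None)  # molar (lower, upper) per assay
    measure_types: Tuple[str, str] = ("Kd", "Ki")
    categories: Tuple[str, str] = ("binding", "functional")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2:
            raise RbfeError("n_compounds must be >= 2")
        if self.dg_distribution not in ("uniform", "normal"):
            raise RbfeError(f"unknown dG distribution {self.dg_distribution!r}")
        if self.dg_range <= 0:
            raise RbfeError("dg_range must be > 0")


@dataclass(frozen=True)
class GraphSimConfig:
    """Conditions for a simulated perturbation graph."""

    n_nodes: int = 30
    extra_cycle_edges: int = 15
    edge_noise_sd: float = 0.4
    edge_se_reported: bool = False
    dg_range: float = 5.0
    dg_center: float = -10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise RbfeError("n_nodes must be >= 2")
        max_extra = self.n_nodes * (self.n_nodes - 1) // 2 - (self.n_nodes - 1)
        if not 0 <= self.extra_cycle_edges <= max_extra:
            raise RbfeError(
                f"extra_cycle_edges must be in [0, {max_extra}] for "
                f"{self.n_nodes} nodes"
            )
        if self.edge_noise_sd < 0:
            raise RbfeError("edge_noise_sd must be >= 0")


def _compound_ids(n: int) -> List[str]:
    width = max(3, len(str(n)))
    return [f"L{i + 1:0{width}d}" for i in range(n)]


def _true_dgs(cfg, rng: np.random.Generator, n: int) -> np.ndarray:
    if getattr(cfg, "dg_distribution", "uniform") == "normal":
        return cfg.dg_center + rng.normal(0.0, cfg.dg_range, size=n)
    half = cfg.dg_range / 2.0
    return cfg.dg_center + rng.uniform(-half, half, size=n)


def simulate_assay_pair(
    cfg: SeriesSimConfig, thermo: ThermoConstants = DEFAULT_THERMO
) -> Tuple[Dict[str, object], AssaySeries, AssaySeries]:
    """Draw one series and its two noisy assay measurements.

    Returns ``(truth, series_a, series_b)``.  ``truth`` records the true
    dGs and each assay's measured (pre-censoring) dGs keyed by compound id,
    so tests can check recovery.  Measured dG = true + offset + noise;
    concentrations are X = exp(dG/kT); values beyond a censor limit are
    clamped to the limit with qualifier lt/gt.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = _compound_ids(cfg.n_compounds)
    true_dg = _true_dgs(cfg, rng, cfg.n_compounds)

    series = []
    measured_dgs = []
    for side in (0, 1):
        noise = cfg.noise[side].sample(rng, cfg.n_compounds)
        dg = true_dg + cfg.assay_offsets[side] + noise
        measured_dgs.append(dg)
        conc = np.exp(dg / thermo.kt)
        limits = cfg.censor_limits[side]
        measurements = []
        for cid, x in zip(ids, conc):
            qual = Qualifier.EQ
            if limits is not None:
                lo, hi = limits
                if x < lo:
                    x, qual = lo, Qualifier.LT
                elif x > hi:
                    x, qual = hi, Qualifier.GT
            measurements.append(
                AffinityMeasurement(cid, cfg.measure_types[side], float(x), qual)
            )
        series.append(
            AssaySeries(
                assay_id=f"assay_{'AB'[side]}",
                category=cfg.categories[side],
                measurements=measurements,
                source_tag="synthetic",
            )
        )

    truth = {
        "true_dg": dict(zip(ids, map(float, true_dg))),
        "measured_dg_a": dict(zip(ids, map(float, measured_dgs[0]))),
        "measured_dg_b": dict(zip(ids, map(float, measured_dgs[1]))),
    }
    return truth, series[0], series[1]


def simulate_graph(
    cfg: GraphSimConfig,
) -> Tuple[Dict[str, object], PerturbationGraph, Dict[str, float]]:
    """Draw a connected perturbation graph with noisy edge predictions.

    A random spanning tree guarantees connectivity; ``extra_cycle_edges``
    chords close cycles.  Edge ddg_pred = (true dG_a - true dG_b) + noise.
    Experimental dGs are exported exactly equal to the truth, so any
    residual error is attributable to the edge noise.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = _compound_ids(cfg.n_nodes)
    true_dg = _true_dgs(cfg, rng, cfg.n_nodes)
    dg = dict(zip(ids, map(float, true_dg)))

    # random spanning tree: attach each node to a random earlier node
    order = rng.permutation(cfg.n_nodes)
    tree_pairs = [
        (order[int(rng.integers(0, i))], order[i]) for i in range(1, cfg.n_nodes)
    ]
    used = {tuple(sorted(p)) for p in tree_pairs}
    all_pairs = [
        (i, j)
        for i in range(cfg.n_nodes)
        for j in range(i + 1, cfg.n_nodes)
        if (i, j) not in used
    ]
    chord_idx = rng.choice(len(all_pairs), size=cfg.extra_cycle_edges, replace=False)
    pairs = tree_pairs + [all_pairs[int(k)] for k in sorted(chord_idx)]

    noise = (
        rng.normal(0.0, cfg.edge_noise_sd, size=len(pairs))
        if cfg.edge_noise_sd > 0
        else np.zeros(len(pairs))
    )
    edges = []
    for (ia, ib), eps in zip(pairs, noise):
        a, b = ids[int(ia)], ids[int(ib)]
        se = cfg.edge_noise_sd if (cfg.edge_se_reported and cfg.edge_noise_sd > 0) else None
        edges.append(Edge(a, b, dg[a] - dg[b] + float(eps), se))

    graph = PerturbationGraph(edges=edges, exp_dg=dict(dg))
    truth = {
        "true_dg": dict(dg),
        "n_tree_edges": cfg.n_nodes - 1,
        "n_chords": cfg.extra_cycle_edges,
    }
    return truth, graph, dict(dg)
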