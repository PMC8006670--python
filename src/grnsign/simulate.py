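"""Synthetic signed networks and GRN-driven expression compendia.

Stands in for an experimental network, a public expression compendium and a
kinetic simulator: it generates a signed directed acyclic network, then
simulates steady-state log-scale expression through it with a linear-
Gaussian propagation model,

    x_v = b_v + sum_u sign(u->v) * w(u->v) * x_u + eps,   eps ~ N(0, sigma),

under a schedule of experimental conditions.  Knockouts clamp the affected
gene low (-2 z-units), overexpression clamps it high (+2), stress shifts
basal levels of a subset of root regulators, and wild-type groups are
unclamped.  Each non-wild-type group forms a perturbed contrast against its
dataset's wild-type reference; extra wild-type groups form unperturbed
baseline-vs-baseline contrasts.  The noiseless (sigma = 0) solve of the
same system provides the ground-truth label sign per (gene, contrast).

Weights are positive and signs explicit, so in a network where every gene
has at most one regulator the noiseless world is sign-consistent by
construction; with multiple regulators, interfering paths can contradict
individual edges even without noise, which is exactly the ambiguity the
consistency analysis probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .contrasts import ContrastDefinition, write_contrast_definitions
from .expression import ExpressionCompendium, write_compendium
from .network import (
    ACTIVATION,
    REPRESSION,
    Edge,
    RegulatoryNetwork,
    degree_profile,
    topological_order,
    write_edge_list,
)

WILDTYPE = "wildtype"
KNOCKOUT = "knockout"
DOUBLE_KNOCKOUT = "double_knockout"
OVEREXPRESSION = "overexpression"
STRESS = "stress"

CONDITION_KINDS = (WILDTYPE, KNOCKOUT, DOUBLE_KNOCKOUT, OVEREXPRESSION, STRESS)


@dataclass(frozen=True)
class ConditionGroup:
    """One experimental group: a condition applied to genes, with replicates."""

    group_id: str
    dataset: str
    kind: str
    genes: tuple[str, ...] = ()
    n_replicates: int = 3
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.kind not in CONDITION_KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults describe the canonical positive-control world: a 60-gene forest
    (12 TFs, 48 targets, every gene at most one regulator), an even
    activation/repression mix, regulatory weights U(0.5, 1.5), basal levels
    U(-1, 1), measurement noise sigma = 0.3 z-units, clamps at +/-2, and a
    3-dataset schedule of knockout / overexpression / double-knockout /
    stress cases plus wild-type-vs-wild-type baselines.
    """

    n_tfs: int = 12
    n_targets: int = 48
    mean_in_degree: float = 1.0  # 1.0 => forest (each non-root gene one regulator)
    tf_parent_prob: float = 0.4  # chance a TF is itself regulated by an earlier TF
    activation_fraction: float = 0.5
    weight_range: tuple[float, float] = (0.5, 1.5)
    basal_range: tuple[float, float] = (-1.0, 1.0)
    noise_sd: float = 0.3
    case_noise_multiplier: float = 1.0  # extra noise on non-wild-type samples
    clamp_low: float = -2.0
    clamp_high: float = 2.0
    stress_n_genes: int = 3
    stress_shift: float = 1.5
    dataset_effect_sd: float = 0.5
    n_datasets: int = 3
    replicates: int = 3
    n_knockout: int = 2  # per dataset
    n_overexpression: int = 1
    n_double_knockout: int = 1
    n_stress: int = 1
    n_extra_wildtype: int = 2  # unperturbed baseline contrasts per dataset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_targets < 0:
            raise ValueError("need at least one TF and a non-negative target count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mean_in_degree < 0 or self.mean_in_degree > self.n_tfs:
            raise ValueError("mean_in_degree must lie in [0, n_tfs]")


@dataclass
class SyntheticWorld:
    """A generated network plus the compendium it drives, with ground truth."""

    network: RegulatoryNetwork
    weights: dict[tuple[str, str], float]
    basal: dict[str, float]
    schedule: list[ConditionGroup]
    compendium: ExpressionCompendium
    contrasts: list[ContrastDefinition]
    ground_truth: pd.DataFrame  # gene x contrast labels of the noiseless system
    config: SimulationConfig


# -- network generation ----------------------------------------------------


def generate_network(
    config: SimulationConfig,
    rng: np.random.Generator,
    template: Optional[RegulatoryNetwork] = None,
) -> tuple[RegulatoryNetwork, dict[tuple[str, str], float], dict[str, float]]:
    """Generate a signed DAG with weights and basal levels.

    Layered wiring: TFs get an implicit order, each TF optionally regulated
    by one earlier TF; each target draws its regulator count (>=1, mean
    ``mean_in_degree``) and its regulators uniformly among the TFs.  With a
    ``template`` network, its edge topology is copied verbatim (so the
    degree profile matches the template exactly) and only signs and weights
    are redrawn.
    """
    if template is not None:
        edges = [
            Edge(e.regulator, e.target, _draw_sign(config, rng)) for e in sorted(template.edges)
        ]
        net = RegulatoryNetwork(set(template.nodes), edges)
    else:
        tfs = [f"TF{i:03d}" for i in range(config.n_tfs)]
        tgts = [f"G{i:03d}" for i in range(config.n_targets)]
        edges = []
        for i, tf in enumerate(tfs[1:], start=1):
            if rng.random() < config.tf_parent_prob:
                parent = tfs[rng.integers(0, i)]
                edges.append(Edge(parent, tf, _draw_sign(config, rng)))
        for g in tgts:
            if config.mean_in_degree <= 1.0:
                k = 1 if rng.random() < config.mean_in_degree else 0
            else:
                k = 1 + rng.poisson(config.mean_in_degree - 1.0)
            k = min(k, config.n_tfs)
            if k == 0:
                continue
            regs = rng.choice(config.n_tfs, size=k, replace=False)
            for r in regs:
                edges.append(Edge(tfs[r], g, _draw_sign(config, rng)))
        net = RegulatoryNetwork(set(tfs) | set(tgts), edges)
    weights = {
        (e.regulator, e.target): float(rng.uniform(*config.weight_range)) for e in net.edges
    }
    basal = {g: float(rng.uniform(*config.basal_range)) for g in sorted(net.nodes)}
    return net, weights, basal


def _draw_sign(config: SimulationConfig, rng: np.random.Generator) -> int:
    return ACTIVATION if rng.random() < config.activation_fraction else REPRESSION


# -- schedule --------------------------------------------------------------


def build_schedule(
    net: RegulatoryNetwork,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ConditionGroup]:
    """Assign condition groups (with perturbation targets) to datasets.

    Perturbed genes are drawn among the regulators, so perturbations
    propagate; every dataset gets one wild-type reference group plus its
    share of case groups and extra wild-type baselines.
    """
    tfs = sorted(net.regulators())
    if not tfs:
        raise ValueError("network has no regulators to perturb")
    roots = sorted(g for g, d in degree_profile(net).in_degree.items() if d == 0)
    reach = _reachable_sets(net)
    schedule: list[ConditionGroup] = []
    for d in range(config.n_datasets):
        ds = f"DS{d:02d}"
        schedule.append(
            ConditionGroup(f"{ds}_wt_ref", ds, WILDTYPE, (), config.replicates, is_reference=True)
        )
        specs = (
            [(KNOCKOUT, 1)] * config.n_knockout
            + [(OVEREXPRESSION, 1)] * config.n_overexpression
            + [(DOUBLE_KNOCKOUT, 2)] * config.n_double_knockout
            + [(STRESS, 0)] * config.n_stress
        )
        for i, (kind, n_genes) in enumerate(specs):
            if kind == STRESS:
                pool = roots if roots else tfs
                k = min(config.stress_n_genes, len(pool))
                genes = tuple(sorted(rng.choice(pool, size=k, replace=False)))
            elif kind == DOUBLE_KNOCKOUT and len(tfs) >= 2:
                genes = _independent_pair(tfs, reach, rng)
            else:
                genes = tuple(sorted(rng.choice(tfs, size=min(n_genes, len(tfs)), replace=False)))
            schedule.append(ConditionGroup(f"{ds}_{kind}_{i}", ds, kind, genes, config.replicates))
        for i in range(config.n_extra_wildtype):
            schedule.append(ConditionGroup(f"{ds}_wt_case_{i}", ds, WILDTYPE, (), config.replicates))
    return schedule


def _reachable_sets(net: RegulatoryNetwork) -> dict[str, set[str]]:
    """Gene -> set of genes reachable downstream (the gene's regulon closure)."""
    children: dict[str, list[str]] = {}
    for e in net.edges:
        children.setdefault(e.regulator, []).append(e.target)
    reach: dict[str, set[str]] = {}
    for g in reversed(topological_order(net)):
        r: set[str] = set()
        for c in children.get(g, []):
            r.add(c)
            r |= reach.get(c, set())
        reach[g] = r
    return reach


def _independent_pair(
    tfs: list[str], reach: dict[str, set[str]], rng: np.random.Generator
) -> tuple[str, ...]:
    """Two regulators with no directed path between them.

    A double perturbation where one gene sits downstream of the other would
    clamp away the propagated signal and manufacture a spurious ground-truth
    contradiction; independent regulators are the clean design.  Falls back
    to an arbitrary pair if the network admits none.
    """
    for _ in range(100):
        a, b = rng.choice(tfs, size=2, replace=False)
        if b not in reach.get(a, set()) and a not in reach.get(b, set()):
            return tuple(sorted((str(a), str(b))))
    return tuple(sorted(str(g) for g in rng.choice(tfs, size=2, replace=False)))


# -- expression simulation -------------------------------------------------


def _solve_group(
    order: list[str],
    parents: dict[str, list[tuple[str, int, float]]],
    basal: dict[str, float],
    group: ConditionGroup,
    config: SimulationConfig,
    noise: Optional[dict[str, np.ndarray]],
    stress_shift: dict[str, float],
) -> dict[str, np.ndarray]:
    """Propagate expression in topological order for one group's replicates.

    ``noise`` maps gene -> per-replicate eps vector (None for the noiseless
    solve).  Clamped genes take their clamp value exactly.
    """
    n_rep = group.n_replicates if noise is not None else 1
    clamp: dict[str, float] = {}
    if group.kind in (KNOCKOUT, DOUBLE_KNOCKOUT):
        clamp = {g: config.clamp_low for g in group.genes}
    elif group.kind == OVEREXPRESSION:
        clamp = {g: config.clamp_high for g in group.genes}
    x: dict[str, np.ndarray] = {}
    for g in order:
        if g in clamp:
            x[g] = np.full(n_rep, clamp[g])
            continue
        val = np.full(n_rep, basal[g] + stress_shift.get(g, 0.0))
        for (u, sign, w) in parents.get(g, []):
            val = val + sign * w * x[u]
        if noise is not None:
            val = val + noise[g]
        x[g] = val
    return x


def simulate_expression(
    net: RegulatoryNetwork,
    weights: dict[tuple[str, str], float],
    basal: dict[str, float],
    schedule: list[ConditionGroup],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[ExpressionCompendium, list[ContrastDefinition], pd.DataFrame]:
    """Simulate the compendium, derive contrasts, and solve the ground truth.

    Noise propagates through the network (it enters each gene's equation).
    A per-(dataset, gene) offset emulating platform/batch effects is added
    after propagation; it cancels within every contrast and is removed by
    per-dataset z-scoring.  Ground-truth labels come from the noiseless,
    offset-free solve: sign of the case-vs-reference difference where it is
    non-zero.
    """
    order = topological_order(net)  # raises on cycles
    genes = sorted(net.nodes)
    parents: dict[str, list[tuple[str, int, float]]] = {}
    for e in net.edges:
        parents.setdefault(e.target, []).append(
            (e.regulator, e.sign, weights[(e.regulator, e.target)])
        )

    datasets = sorted({g.dataset for g in schedule})
    offsets = {
        ds: {g: float(rng.normal(0.0, config.dataset_effect_sd)) for g in genes}
        for ds in datasets
    }

    stress_shifts: dict[str, dict[str, float]] = {}
    for grp in schedule:
        if grp.kind == STRESS:
            stress_shifts[grp.group_id] = {
                g: float(config.stress_shift * rng.choice([-1.0, 1.0])) for g in grp.genes
            }

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    group_samples: dict[str, list[str]] = {}
    noiseless: dict[str, dict[str, float]] = {}
    for grp in schedule:
        shift = stress_shifts.get(grp.group_id, {})
        sd = config.noise_sd * (1.0 if grp.kind == WILDTYPE else config.case_noise_multiplier)
        noise = {g: rng.normal(0.0, sd, size=grp.n_replicates) for g in order}
        x = _solve_group(order, parents, basal, grp, config, noise, shift)
        x0 = _solve_group(order, parents, basal, grp, config, None, shift)
        noiseless[grp.group_id] = {g: float(x0[g][0]) for g in genes}
        off = offsets[grp.dataset]
        samples = [f"{grp.group_id}_r{i}" for i in range(grp.n_replicates)]
        group_samples[grp.group_id] = samples
        platform = "microarray" if datasets.index(grp.dataset) % 2 == 0 else "rnaseq"
        for i, s in enumerate(samples):
            columns[s] = np.array([x[g][i] + off[g] for g in genes])
            meta_rows.append({"sample": s, "dataset": grp.dataset, "platform": platform})

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    comp = ExpressionCompendium(values, meta)

    # contrasts: each non-reference group vs its dataset's wild-type reference
    refs = {g.dataset: g for g in schedule if g.is_reference}
    defs: list[ContrastDefinition] = []
    gt_cols: dict[str, np.ndarray] = {}
    for grp in schedule:
        if grp.is_reference:
            continue
        ref = refs.get(grp.dataset)
        if ref is None:
            raise ValueError(f"dataset {grp.dataset!r} has no wild-type reference group")
        cid = f"c_{grp.group_id}"
        defs.append(
            ContrastDefinition(
                contrast_id=cid,
                dataset=grp.dataset,
                reference=tuple(group_samples[ref.group_id]),
                case=tuple(group_samples[grp.group_id]),
                perturbed=grp.kind != WILDTYPE,
            )
        )
        delta0 = np.array(
            [noiseless[grp.group_id][g] - noiseless[ref.group_id][g] for g in genes]
        )
        gt_cols[cid] = np.where(np.abs(delta0) > 1e-9, np.sign(delta0), 0.0).astype(np.int8)
    ground_truth = pd.DataFrame(gt_cols, index=genes, dtype=np.int8)
    return comp, defs, ground_truth


# -- convenience worlds ----------------------------------------------------


def make_world(config: SimulationConfig, template: Optional[RegulatoryNetwork] = None) -> SyntheticWorld:
    """Generate network, schedule and compendium from one config and seed."""
    rng = np.random.default_rng(config.seed)
    net, weights, basal = generate_network(config, rng, template=template)
    schedule = build_schedule(net, config, rng)
    comp, defs, gt = simulate_expression(net, weights, basal, schedule, config, rng)
    return SyntheticWorld(net, weights, basal, schedule, comp, defs, gt, config)


def consistent_world(seed: int = 0, **overrides) -> SyntheticWorld:
    """The canonical positive-control world (forest topology, see config)."""
    return make_world(replace(SimulationConfig(seed=seed), **overrides))


def contrast_rich_world(seed: int = 0, **overrides) -> SyntheticWorld:
    """A world with 30 perturbed and 30 unperturbed contrasts (3 datasets).

    Perturbation conditions carry twice the measurement noise of wild-type
    samples, emulating the broader physiological response a perturbation
    drags along beyond the regulatory cascade itself.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_datasets=3,
        n_knockout=5,
        n_overexpression=2,
        n_double_knockout=2,
        n_stress=1,
        n_extra_wildtype=10,
        replicates=2,
        case_noise_multiplier=2.0,
    )
    return make_world(replace(cfg, **overrides))


def decouple(world: SyntheticWorld, seed: int) -> SyntheticWorld:
    """Regenerate expression with all regulatory weights zeroed.

    The network then has no influence on expression (pure basal + noise):
    the negative-control world whose observed inconsistency load should sit
    inside the null distributions.  Because a zero-weight network also makes
    the choice of perturbed gene arbitrary, the schedule's perturbation
    targets are redrawn uniformly over all genes; keeping them on the
    original TFs would leave the strongly-labeled rows preferentially on
    high-out-degree nodes, a residual network-expression association the
    negative control is meant to exclude.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(world.network.nodes)
    schedule = [
        replace(
            grp,
            genes=tuple(sorted(rng.choice(genes, size=len(grp.genes), replace=False)))
            if grp.genes
            else (),
        )
        for grp in world.schedule
    ]
    zero_w = {k: 0.0 for k in world.weights}
    comp, defs, gt = simulate_expression(
        world.network, zero_w, world.basal, schedule, world.config, rng
    )
    return SyntheticWorld(
        world.network, zero_w, world.basal, schedule, comp, defs, gt, world.config
    )


# -- IO --------------------------------------------------------------------


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    """Emit the exact file formats the pipeline consumes, plus ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(world.network, out / "network.tsv")
    write_compendium(world.compendium, out / "expression.tsv", out / "samples.tsv")
    write_contrast_definitions(world.contrasts, out / "contrasts.tsv")
    world.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index_label="gene")
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(world.config).items()}
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
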