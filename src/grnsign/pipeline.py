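"""End-to-end orchestration: normalize -> contrast -> label -> assess ->
nulls -> correlations -> perturbed-vs-unperturbed comparison.

Every stage writes its table to the output directory, so any later stage
can be resumed from disk, and one JSON run report collects the summary
numbers (threshold, achieved fraction, global load, mGlobal for both nulls,
mEdge, per-category mean correlations, Mann-Whitney comparisons, dropped
genes/edges and all seeds).  Reruns with the same inputs and master seed
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .consistency import InconsistencyReport, assess
from .contrasts import (
    ContrastDefinition,
    calibrate_threshold,
    compute_contrasts,
    label_genes,
    read_contrast_definitions,
    write_label_matrix,
)
from .correlation import GroupComparison, mann_whitney_u, pair_correlations
from .expression import ExpressionCompendium, quantile_normalize, read_compendium, zscore_by_dataset
from .network import RegulatoryNetwork, read_edge_list
from .nulls import EDGE_SHUFFLE, PROFILE_SHUFFLE, null_distribution, percentile_of

log = logging.getLogger("grnsign")

# named substreams of the master seed, so each randomized stage is
# independently reproducible
_SUBSTREAM = {"profile_null": 1, "edge_null": 2}


@dataclass
class RunConfig:
    network_path: str
    expression_path: str
    samples_path: str
    contrasts_path: str
    out_dir: str
    fraction: float = 0.5
    n_iterations: int = 200
    null_methods: tuple[str, ...] = (PROFILE_SHUFFLE, EDGE_SHUFFLE)
    correlation_methods: tuple[str, ...] = ("pearson", "spearman")
    seed: int = 0
    quantile: bool = False
    zscore: bool = True
    permissive: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def substream_seed(master: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the master seed."""
    offset = _SUBSTREAM.get(name, 0)
    return int(np.random.SeedSequence([master, offset]).generate_state(1)[0] % (2**31))


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = read_edge_list(config.network_path, permissive=config.permissive).expand_operons()
    comp = read_compendium(config.expression_path, config.samples_path)
    defs = read_contrast_definitions(config.contrasts_path)
    return analyze(net, comp, defs, config, out)


def analyze(
    net: RegulatoryNetwork,
    comp: ExpressionCompendium,
    defs: list[ContrastDefinition],
    config: RunConfig,
    out: Optional[Path] = None,
) -> dict:
    overlap = net.nodes & set(comp.values.index)
    if not overlap:
        raise ValueError("no gene id overlap between network and compendium")
    log.info("network: %d nodes, %d edges; compendium: %d genes x %d samples; overlap %d genes",
             len(net.nodes), net.n_edges, comp.values.shape[0], comp.values.shape[1], len(overlap))

    if config.quantile:
        comp = quantile_normalize(comp)
    if config.zscore:
        comp = zscore_by_dataset(comp)

    deltas = compute_contrasts(comp, defs)
    cal = calibrate_threshold(deltas, config.fraction)
    labels = label_genes(deltas, cal.t)
    log.info("threshold t=%.4f (target fraction %.3f, achieved %.3f) over %d contrasts",
             cal.t, cal.target_fraction, cal.achieved_fraction, len(defs))

    report = assess(net, labels)
    log.info("global inconsistency load %d over nPairs=%d (mEdge=%.3f); splits %s",
             report.global_count, report.n_pairs, report.m_edge, report.splits)

    nulls = {}
    for method in config.null_methods:
        name = "profile_null" if method == PROFILE_SHUFFLE else "edge_null"
        nd = null_distribution(
            net, deltas, cal.t, method,
            n_iterations=config.n_iterations,
            seed=substream_seed(config.seed, name),
        )
        nulls[method] = nd
        log.info("%s null: mGlobal=%.2f over %d iterations; observed at percentile %.1f",
                 method, nd.m_global, nd.n_iterations,
                 percentile_of(report.global_count, nd.loads))

    correlations = {}
    for method in config.correlation_methods:
        summary = pair_correlations(net, comp, method=method)
        correlations[method] = summary
        log.info("%s mc per category: %s", method,
                 {k: (None if v is None else round(v, 4)) for k, v in summary.mc.items()})

    comparison = summarize_contrast_groups(report, defs)

    run_report = {
        "config": {
            "fraction": config.fraction,
            "n_iterations": config.n_iterations,
            "seed": config.seed,
            "quantile": config.quantile,
            "zscore": config.zscore,
        },
        "n_contrasts": len(defs),
        "threshold": {"t": cal.t, "target_fraction": cal.target_fraction,
                      "achieved_fraction": cal.achieved_fraction},
        "consistency": report.to_dict(),
        "nulls": {m: nd.to_dict(observed=report.global_count) for m, nd in nulls.items()},
        "correlations": {m: {"mc": s.mc, "n_pairs": s.n_pairs} for m, s in correlations.items()},
        "group_comparison": comparison,
    }

    if out is not None:
        write_label_matrix(labels, out / "labels.tsv")
        deltas.to_csv(out / "contrast_deltas.tsv", sep="\t", index_label="gene")
        report.per_edge.to_csv(out / "edges.tsv", sep="\t", index=False)
        report.per_contrast.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        for m, nd in nulls.items():
            name = "null_profiles.json" if m == PROFILE_SHUFFLE else "null_edges.json"
            (out / name).write_text(
                json.dumps(nd.to_dict(observed=report.global_count), indent=2, sort_keys=True) + "\n"
            )
        for m, s in correlations.items():
            s.pairs.to_csv(out / f"pairs_{m}.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(run_report, indent=2, sort_keys=True) + "\n")
    return run_report


def summarize_contrast_groups(
    report: InconsistencyReport, defs: list[ContrastDefinition]
) -> dict:
    """Perturbed-vs-unperturbed Mann-Whitney comparisons.

    Two comparisons across contrasts: the per-contrast inconsistency load and
    the per-contrast deregulated-gene count.
    """
    perturbed = {d.contrast_id for d in defs if d.perturbed}
    unperturbed = {d.contrast_id for d in defs if not d.perturbed}
    if not perturbed or not unperturbed:
        raise ValueError(
            f"need both groups: {len(perturbed)} perturbed vs {len(unperturbed)} unperturbed contrasts"
        )
    pc = report.per_contrast.set_index("contrast")

    def compare(column: str) -> dict:
        x = pc.loc[sorted(perturbed), column].tolist()
        y = pc.loc[sorted(unperturbed), column].tolist()
        gc: GroupComparison = mann_whitney_u(x, y)
        return {
            **gc.to_dict(),
            "perturbed_mean": float(np.mean(x)),
            "unperturbed_mean": float(np.mean(y)),
        }

    return {
        "inconsistency_load": compare("n_incons"),
        "deregulated_genes": compare("n_deregulated"),
    }
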