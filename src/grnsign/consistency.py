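"""Conservative sign-consistency assessment of a network against labels.

For each regulatory edge u -s-> v and each contrast, the expected target
behavior is sign(v) = s * sign(u): activation propagates the regulator's
direction, repression inverts it.  The model is conservative: a verdict of
"inconsistent" requires both endpoints to be labeled changed (non-zero) with
the target contradicting the expectation; an "unchanged" label on either
endpoint yields "indeterminate" and never counts against the network.
The global inconsistency load is the total number of inconsistent
(edge, contrast) cases; mEdge is the mean per-edge inconsistency count
(sum of per-edge counts divided by the number of assessed pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .network import ACTIVATION, Edge, RegulatoryNetwork, degree_profile

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
INDETERMINATE = "indeterminate"

_SPLIT_KEYS = ("activation", "repression", "activation_single", "repression_single")


def edge_consistency(label_u: int, sign: int, label_v: int) -> str:
    """Verdict for one edge in one contrast (conservative truth table)."""
    if label_u not in (-1, 0, 1) or label_v not in (-1, 0, 1):
        raise ValueError(f"labels must be in {{-1, 0, 1}}, got ({label_u}, {label_v})")
    if sign not in (-1, 1):
        raise ValueError(f"edge sign must be +1 or -1, got {sign}")
    if label_u == 0 or label_v == 0:
        return INDETERMINATE
    return CONSISTENT if label_v == sign * label_u else INCONSISTENT


@dataclass
class InconsistencyReport:
    """Aggregated inconsistency counts for one (network, label-matrix) pair.

    ``global_count`` = sum of ``per_edge`` = sum of ``per_contrast``;
    the activation/repression splits partition it.  ``n_pairs`` counts the
    assessed edges (edges with expression for both endpoints); ``m_edge`` is
    global_count / n_pairs.
    """

    global_count: int
    n_pairs: int
    m_edge: float
    per_edge: pd.DataFrame  # regulator, target, role, single, n_incons, n_consistent
    per_contrast: pd.DataFrame  # contrast, n_incons, n_deregulated
    splits: dict[str, int]
    dropped_genes: list[str] = field(default_factory=list)
    dropped_edges: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "global": self.global_count,
            "n_pairs": self.n_pairs,
            "m_edge": self.m_edge,
            "splits": dict(self.splits),
            "per_contrast_incons": self.per_contrast["n_incons"].tolist(),
            "n_dropped_genes": len(self.dropped_genes),
            "n_dropped_edges": len(self.dropped_edges),
        }


def assess(
    net: RegulatoryNetwork,
    labels: pd.DataFrame,
    single_only: bool = False,
    role_filter: Optional[int] = None,
) -> InconsistencyReport:
    """Apply the conservative model to every (edge, contrast) pair.

    ``labels`` is a gene × contrast matrix over {-1, 0, 1}.  Edges whose
    regulator or target has no expression row are excluded from n_pairs and
    listed in ``dropped_edges``; network genes absent from the labels are
    listed in ``dropped_genes``.  ``single_only`` restricts assessment to
    targets with a single regulator; ``role_filter`` (+1 or -1) to one role.
    Each edge is assessed independently (no multi-regulator combination
    logic).
    """
    if labels.shape[1] == 0 or labels.shape[0] == 0:
        raise ValueError("empty label matrix")

    gene_pos = {g: i for i, g in enumerate(labels.index)}
    in_deg = degree_profile(net).in_degree

    dropped_genes = sorted(g for g in net.nodes if g not in gene_pos)
    edges: list[Edge] = []
    dropped_edges: list[tuple[str, str]] = []
    for e in net.edges:
        if e.regulator not in gene_pos or e.target not in gene_pos:
            dropped_edges.append((e.regulator, e.target))
            continue
        if single_only and in_deg[e.target] != 1:
            continue
        if role_filter is not None and e.sign != role_filter:
            continue
        edges.append(e)

    L = labels.to_numpy(dtype=np.int8)
    n_contrasts = L.shape[1]
    if edges:
        reg_idx = np.array([gene_pos[e.regulator] for e in edges])
        tgt_idx = np.array([gene_pos[e.target] for e in edges])
        signs = np.array([e.sign for e in edges], dtype=np.int8)
        lu = L[reg_idx, :]
        lv = L[tgt_idx, :]
        determinate = (lu != 0) & (lv != 0)
        incons = determinate & (lv != signs[:, None] * lu)
        cons = determinate & ~incons
        per_edge_incons = incons.sum(axis=1)
        per_edge_cons = cons.sum(axis=1)
        per_contrast_incons = incons.sum(axis=0)
    else:
        per_edge_incons = np.zeros(0, dtype=int)
        per_edge_cons = np.zeros(0, dtype=int)
        per_contrast_incons = np.zeros(n_contrasts, dtype=int)

    single = np.array([in_deg[e.target] == 1 for e in edges], dtype=bool)
    act = np.array([e.sign == ACTIVATION for e in edges], dtype=bool)
    splits = {
        "activation": int(per_edge_incons[act].sum()) if edges else 0,
        "repression": int(per_edge_incons[~act].sum()) if edges else 0,
        "activation_single": int(per_edge_incons[act & single].sum()) if edges else 0,
        "repression_single": int(per_edge_incons[~act & single].sum()) if edges else 0,
    }

    per_edge = pd.DataFrame(
        {
            "regulator": [e.regulator for e in edges],
            "target": [e.target for e in edges],
            "role": ["activation" if e.sign == ACTIVATION else "repression" for e in edges],
            "single": single.astype(int) if edges else [],
            "n_incons": per_edge_incons,
            "n_consistent": per_edge_cons,
        }
    )
    per_contrast = pd.DataFrame(
        {
            "contrast": list(labels.columns),
            "n_incons": per_contrast_incons,
            "n_deregulated": (L != 0).sum(axis=0),
        }
    )

    global_count = int(per_edge_incons.sum())
    n_pairs = len(edges)
    m_edge = global_count / n_pairs if n_pairs else float("nan")
    return InconsistencyReport(
        global_count=global_count,
        n_pairs=n_pairs,
        m_edge=m_edge,
        per_edge=per_edge,
        per_contrast=per_contrast,
        splits=splits,
        dropped_genes=dropped_genes,
        dropped_edges=dropped_edges,
    )
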