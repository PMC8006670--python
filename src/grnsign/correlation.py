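"""TF-target expression correlation summaries and group comparisons.

For every regulator-target pair the correlation of the two expression
profiles is computed across all samples of the combined z-scored compendium
(Pearson, or Spearman via rank transform).  Pairs are summarized per
category — all possible TF x gene pairs, known interactions, activations,
repressions, and the single-regulator restrictions of the last two — by the
mean correlation mc = sum(cPairs) / nPairs.  Under a consistent network,
activations should show positive and repressions negative mc; a network
uninformative about expression shows both near zero.

The Mann-Whitney U test compares per-contrast statistics (inconsistency
loads, deregulated-gene counts) between perturbed and unperturbed contrasts:
exact enumeration of all arrangements for small samples (combined n <= 16),
tie-corrected normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .expression import ExpressionCompendium
from .network import ACTIVATION, RegulatoryNetwork, degree_profile

CATEGORIES = (
    "all_possible_pairs",
    "known_pairs",
    "activation",
    "repression",
    "activation_single",
    "repression_single",
)

EXACT_MAX_N = 16  # combined sample size at or below which U is enumerated exactly


@dataclass
class CorrelationSummary:
    """Per-pair correlations plus per-category means.

    ``pairs``: DataFrame (regulator, target, role, single, known, r) for the
    known interactions (and, if requested, all possible TF x gene pairs).
    ``mc``: category -> mean correlation, None where a category has no valid
    pair.  ``n_pairs``: category -> count of valid pairs.  Pairs involving a
    constant or absent profile are skipped and counted.
    """

    method: str
    pairs: pd.DataFrame
    mc: dict[str, Optional[float]]
    n_pairs: dict[str, int]
    n_skipped_constant: int
    n_skipped_missing: int


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows -> zero mean, unit norm; returns (standardized, valid_mask)."""
    mu = mat.mean(axis=1, keepdims=True)
    centered = mat - mu
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    valid = norms[:, 0] > 0
    safe = np.where(norms > 0, norms, 1.0)
    return centered / safe, valid


def all_possible_pairs(net: RegulatoryNetwork, comp: ExpressionCompendium) -> pd.DataFrame:
    """Cartesian product of the network's TFs with the compendium's genes.

    Self-pairs are excluded; known interactions are flagged.
    """
    tfs = sorted(net.regulators())
    genes = list(comp.values.index)
    known = {(e.regulator, e.target) for e in net.edges}
    rows = [
        {"regulator": tf, "target": g, "known": (tf, g) in known}
        for tf in tfs
        for g in genes
        if tf != g
    ]
    return pd.DataFrame(rows, columns=["regulator", "target", "known"])


def pair_correlations(
    net: RegulatoryNetwork,
    comp: ExpressionCompendium,
    method: str = "pearson",
    include_all_possible: bool = True,
) -> CorrelationSummary:
    """Correlate each TF-target pair's profiles across all samples."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    mat = comp.values.to_numpy(dtype=float)
    if method == "spearman":
        mat = rankdata(mat, axis=1)
    Z, valid = _standardize_rows(mat)
    pos = {g: i for i, g in enumerate(comp.values.index)}
    in_deg = degree_profile(net).in_degree

    def corr(u: str, v: str) -> Optional[float]:
        iu, iv = pos.get(u), pos.get(v)
        if iu is None or iv is None:
            return None
        if not (valid[iu] and valid[iv]):
            return math.nan
        return float(np.clip(Z[iu] @ Z[iv], -1.0, 1.0))

    n_missing = n_constant = 0
    rows = []
    for e in net.edges:
        r = corr(e.regulator, e.target)
        if r is None:
            n_missing += 1
            continue
        if math.isnan(r):
            n_constant += 1
            continue
        rows.append(
            {
                "regulator": e.regulator,
                "target": e.target,
                "role": "activation" if e.sign == ACTIVATION else "repression",
                "single": int(in_deg[e.target] == 1),
                "known": True,
                "r": r,
            }
        )
    pairs = pd.DataFrame(rows, columns=["regulator", "target", "role", "single", "known", "r"])

    mc: dict[str, Optional[float]] = {}
    n_pairs: dict[str, int] = {}

    def record(cat: str, values: Sequence[float]) -> None:
        n_pairs[cat] = len(values)
        mc[cat] = float(np.mean(values)) if len(values) else None

    record("known_pairs", pairs["r"].tolist())
    for role in ("activation", "repression"):
        sub = pairs[pairs["role"] == role]
        record(role, sub["r"].tolist())
        record(f"{role}_single", sub[sub["single"] == 1]["r"].tolist())

    if include_all_possible:
        tfs = sorted(g for g in net.regulators() if g in pos and valid[pos[g]])
        n_constant += sum(1 for g in net.regulators() if g in pos and not valid[pos[g]])
        n_missing += sum(1 for g in net.regulators() if g not in pos)
        vals: list[float] = []
        if tfs:
            tf_idx = np.array([pos[g] for g in tfs])
            R = Z[tf_idx] @ Z[valid].T  # |TF| x |valid genes|
            valid_genes = [g for g in comp.values.index if valid[pos[g]]]
            for i, tf in enumerate(tfs):
                for j, g in enumerate(valid_genes):
                    if tf != g:
                        vals.append(float(np.clip(R[i, j], -1.0, 1.0)))
        record("all_possible_pairs", vals)
    else:
        mc["all_possible_pairs"] = None
        n_pairs["all_possible_pairs"] = 0

    return CorrelationSummary(
        method=method,
        pairs=pairs,
        mc=mc,
        n_pairs=n_pairs,
        n_skipped_constant=n_constant,
        n_skipped_missing=n_missing,
    )


# -- Mann-Whitney U --------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney U comparison of two value groups."""

    u: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" or "normal"

    def to_dict(self) -> dict:
        return {"U": self.u, "p": self.p_value, "n1": self.n1, "n2": self.n2, "method": self.method}


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midranks for ties.

    Combined n <= 16: exact two-sided p by enumerating all C(n1+n2, n1)
    assignments of the (mid)ranks, counting arrangements whose U deviates
    from the mean n1*n2/2 at least as much as the observed U.  Larger
    samples: normal approximation with tie-corrected variance and a 0.5
    continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u_obs = _u_from_ranks(ranks[:n1].sum(), n1)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_MAX_N:
        dev_obs = abs(u_obs - mu) - 1e-12
        total = extreme = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = _u_from_ranks(ranks[list(idx)].sum(), n1)
            total += 1
            if abs(u - mu) >= dev_obs:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        n = n1 + n2
        _, counts = np.unique(combined, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:  # all values tied
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
        method = "normal"
    return GroupComparison(u=float(u_obs), p_value=float(max(p, np.finfo(float).tiny)), n1=n1, n2=n2, method=method)
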