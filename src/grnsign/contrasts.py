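"""Expression contrasts, threshold calibration and ternary labeling.

A contrast compares a case condition against its reference (control) within
one experiment: delta = mean(case) - mean(reference), in z-units.  A single
global threshold t, calibrated so that a target fraction of all pooled
|delta| values exceeds it, turns deltas into ternary labels: upregulated
(+1), downregulated (-1) or unchanged (0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionCompendium


@dataclass(frozen=True)
class ContrastDefinition:
    """A case-vs-reference comparison within one dataset.

    ``perturbed`` marks case conditions that are experimental perturbations
    (stress, knockout, double knockout, overexpression) rather than a second
    baseline.
    """

    contrast_id: str
    dataset: str
    reference: tuple[str, ...]
    case: tuple[str, ...]
    perturbed: bool

    def __post_init__(self) -> None:
        if not self.reference or not self.case:
            raise ValueError(f"contrast {self.contrast_id!r}: reference and case must be non-empty")
        overlap = set(self.reference) & set(self.case)
        if overlap:
            raise ValueError(
                f"contrast {self.contrast_id!r}: reference and case share samples {sorted(overlap)}"
            )


@dataclass(frozen=True)
class ThresholdCalibration:
    """Label threshold t with the deregulated fraction it targets/achieves."""

    t: float
    target_fraction: float
    achieved_fraction: float


def validate_contrasts(defs: list[ContrastDefinition], comp: ExpressionCompendium) -> None:
    ds_of = comp.sample_meta["dataset"]
    ids = set()
    for d in defs:
        if d.contrast_id in ids:
            raise ValueError(f"duplicate contrast id {d.contrast_id!r}")
        ids.add(d.contrast_id)
        for s in (*d.reference, *d.case):
            if s not in comp.values.columns:
                raise ValueError(f"contrast {d.contrast_id!r}: unknown sample {s!r}")
        datasets = {ds_of[s] for s in (*d.reference, *d.case)}
        if datasets != {d.dataset}:
            raise ValueError(
                f"contrast {d.contrast_id!r}: samples span datasets {sorted(datasets)}, "
                f"expected only {d.dataset!r}"
            )


def compute_contrasts(
    comp: ExpressionCompendium,
    defs: list[ContrastDefinition],
    sign_convention: str = "case-minus-reference",
) -> pd.DataFrame:
    """Gene × contrast matrix of deltas.

    Default convention: delta = mean(case) - mean(reference), so +1 later
    reads "upregulated in the case condition".  All downstream inconsistency
    counts are invariant to a global sign flip.
    """
    if sign_convention not in ("case-minus-reference", "reference-minus-case"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    validate_contrasts(defs, comp)
    cols = {}
    for d in defs:
        delta = comp.values[list(d.case)].mean(axis=1) - comp.values[list(d.reference)].mean(axis=1)
        if sign_convention == "reference-minus-case":
            delta = -delta
        cols[d.contrast_id] = delta
    cm = pd.DataFrame(cols, index=comp.values.index)
    if not np.isfinite(cm.to_numpy()).all():
        raise ValueError("non-finite contrast values")
    return cm


def calibrate_threshold(cm: pd.DataFrame, f: float = 0.5) -> ThresholdCalibration:
    """Pick t as the (1-f)-quantile of pooled |delta| (linear interpolation).

    f is the fraction of gene-contrast values assumed deregulated; the
    achieved fraction |delta| > t is reported (it can deviate from f when the
    delta multiset is discrete).
    """
    if not 0 < f < 1:
        raise ValueError(f"target fraction must lie in (0, 1), got {f}")
    absd = np.abs(cm.to_numpy(dtype=float)).ravel()
    if absd.size == 0:
        raise ValueError("empty contrast matrix")
    t = float(np.quantile(absd, 1.0 - f))
    achieved = float(np.mean(absd > t))
    return ThresholdCalibration(t=t, target_fraction=f, achieved_fraction=achieved)


def label_genes(cm: pd.DataFrame, t: float) -> pd.DataFrame:
    """Ternary labels: sign(delta) where |delta| > t (strict), else 0."""
    if t < 0:
        raise ValueError(f"threshold must be non-negative, got {t}")
    arr = cm.to_numpy(dtype=float)
    labels = np.where(np.abs(arr) > t, np.sign(arr), 0.0).astype(np.int8)
    return pd.DataFrame(labels, index=cm.index, columns=cm.columns)


# -- IO --------------------------------------------------------------------


def read_contrast_definitions(path: str | Path) -> list[ContrastDefinition]:
    """Contrast TSV: contrast, dataset, reference_samples(;), case_samples(;), perturbed{0,1}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    defs = []
    for _, row in df.iterrows():
        defs.append(
            ContrastDefinition(
                contrast_id=row["contrast"],
                dataset=row["dataset"],
                reference=tuple(row["reference_samples"].split(";")),
                case=tuple(row["case_samples"].split(";")),
                perturbed=row["perturbed"].strip() in ("1", "true", "True"),
            )
        )
    return defs


def write_contrast_definitions(defs: list[ContrastDefinition], path: str | Path) -> None:
    rows = [
        {
            "contrast": d.contrast_id,
            "dataset": d.dataset,
            "reference_samples": ";".join(d.reference),
            "case_samples": ";".join(d.case),
            "perturbed": int(d.perturbed),
        }
        for d in defs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_label_matrix(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index_label="gene")


def read_label_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(np.int8)
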