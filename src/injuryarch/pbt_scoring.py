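"""Pathogenesis-based transcript set (PBT) scoring.

A PBT score summarises a biopsy's expression of a curated probe set as
the geometric mean of the fold change of each member probe versus the
mean expression of that probe in a control (nephrectomy) population.  A
score of 1.0 means control-like expression; scores above 1 indicate
induction, below 1 loss.

The geometric mean is computed in log space, which ties exactly with
the product-root definition while avoiding overflow on long probe
lists.  The control baseline is the arithmetic mean of the linear-scale
control intensities per probe.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .formats import ExpressionMatrix, GeneSetCollection, ValidationError

__all__ = ["control_baseline", "pbt_score", "score_all"]


def _resolve_probes(expr: ExpressionMatrix, probes: Sequence[str]) -> list[str]:
    missing = [p for p in probes if p not in expr.values.index]
    if missing:
        raise KeyError(f"probes absent from expression matrix: {missing}")
    return list(probes)


def control_baseline(expr: ExpressionMatrix, probes: Sequence[str]) -> pd.Series:
    """Per-probe arithmetic mean of linear-scale control intensities."""
    if not expr.control_sample_ids:
        raise ValidationError("no control samples designated; cannot form baseline")
    probes = _resolve_probes(expr, probes)
    block = expr.values.loc[probes, expr.control_sample_ids]
    return block.mean(axis=1)


def pbt_score(
    expr: ExpressionMatrix,
    gene_set,
    sample_id: str,
    *,
    drop_missing: bool = False,
) -> float:
    """Geometric-mean fold change of one biopsy over one gene set.

    score = exp( mean over member probes of ln(intensity / baseline) )

    Probes absent from the matrix raise ``KeyError`` unless
    ``drop_missing`` is set, in which case they are excluded; an empty
    effective probe list is always an error.
    """
    probes = list(gene_set.probe_ids) if hasattr(gene_set, "probe_ids") else list(gene_set)
    if drop_missing:
        probes = [p for p in probes if p in expr.values.index]
    if not probes:
        raise ValidationError(
            f"gene set {getattr(gene_set, 'name', '?')!r}: empty effective probe list"
        )
    baseline = control_baseline(expr, probes)
    if sample_id not in expr.values.columns:
        raise KeyError(f"sample {sample_id!r} not in expression matrix")
    sample = expr.values.loc[probes, sample_id]
    logfc = np.log(sample.to_numpy(dtype=float)) - np.log(baseline.to_numpy(dtype=float))
    return float(np.exp(logfc.mean()))


def score_all(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    *,
    drop_missing: bool = False,
) -> pd.DataFrame:
    """Score every biopsy (non-control sample) against every set.

    Returns a DataFrame indexed by biopsy id with one column per gene
    set, in collection order.
    """
    biopsies = expr.biopsy_ids
    out = pd.DataFrame(index=pd.Index(biopsies, name="sample_id"), dtype=float)
    for gene_set in collection:
        probes = list(gene_set.probe_ids)
        if drop_missing:
            probes = [p for p in probes if p in expr.values.index]
            if not probes:
                raise ValidationError(
                    f"gene set {gene_set.name!r}: empty effective probe list"
                )
        baseline = control_baseline(expr, probes).to_numpy(dtype=float)
        block = expr.values.loc[probes, biopsies].to_numpy(dtype=float)
        logfc = np.log(block) - np.log(baseline)[:, None]
        out[gene_set.name] = np.exp(logfc.mean(axis=0))
    return out
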