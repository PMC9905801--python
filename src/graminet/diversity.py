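"""Rarefaction, alpha-diversity indices, and Bray-Curtis beta-diversity.

All logarithms are natural.  Pielou evenness is undefined (NaN) for samples
with a single taxon and is excluded from downstream correlations rather than
coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import CountTable, DistanceMatrix, ValidationError


@dataclass
class RarefactionReport:
    depth: int
    retained: list[str]
    dropped: list[str]


def rarefy_table(table: CountTable, depth: int, seed: int) -> tuple[CountTable, RarefactionReport]:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples whose total count is below the depth are dropped and reported.
    One draw per sample (no averaging over repeated rarefactions).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValidationError(f"all samples have fewer than {depth} reads")
    rows = []
    for i in np.flatnonzero(keep):
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth, method="marginals"))
    samples = [s for s, k in zip(table.samples, keep) if k]
    dropped = [s for s, k in zip(table.samples, keep) if not k]
    out = CountTable(samples, list(table.taxa), np.array(rows), table.domain)
    return out, RarefactionReport(depth, samples, dropped)


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Observed richness, Shannon (nats), Pielou, and Margalef per sample."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    shannon = np.zeros(len(totals))
    for i, row in enumerate(counts):
        p = row[row > 0] / totals[i]
        shannon[i] = -np.sum(p * np.log(p))
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(richness > 1, shannon / np.log(richness), np.nan)
        margalef = np.where(
            totals > 1, (richness - 1) / np.log(totals), 0.0
        )
    margalef = np.where(richness == 1, 0.0, margalef)
    return pd.DataFrame(
        {
            "richness": richness,
            "shannon": shannon,
            "pielou": pielou,
            "margalef": margalef,
        },
        index=pd.Index(table.samples, name="sample_id"),
    )


def bray_curtis_matrix(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = 1 - 2*sum(min)/(sum_i + sum_j)."""
    if table.n_samples < 2:
        raise ValidationError("need >= 2 samples for a distance matrix")
    if np.any(table.counts.sum(axis=1) == 0):
        raise ValidationError("zero-sum sample: filter before computing Bray-Curtis")
    vals = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.samples), vals, metric="braycurtis")
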