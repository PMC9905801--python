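"""Mantel and partial Mantel tests, and the sample-level network-connectivity
profile they are applied to.

"Connectivity" of a sample is the degree-weighted summed relative abundance
of network members present in that sample; pairwise Euclidean distances of
these scores give the connectivity divergence matrix that is tested against
productivity / diversity / soil divergence (optionally partialling out
other matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountTable, DistanceMatrix, ValidationError


@dataclass
class MantelResult:
    variable: str
    r: float
    p: float
    n_perm: int
    controlled: list[str] = field(default_factory=list)
    tail: str = "greater"
    degenerate: bool = False


def _check_pair(dm_a: DistanceMatrix, dm_b: DistanceMatrix) -> None:
    if dm_a.labels != dm_b.labels:
        raise ValidationError("distance matrices must share labels and order")
    if len(dm_a) < 4:
        raise ValidationError("need >= 4 samples")


def _tail_count(stat_perm: float, stat_obs: float, tail: str) -> bool:
    if tail == "greater":
        return stat_perm >= stat_obs
    if tail == "two-sided":
        return abs(stat_perm) >= abs(stat_obs)
    raise ValueError(f"unknown tail {tail!r}")


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "greater",
    variable: str = "",
) -> MantelResult:
    """Mantel test: Pearson correlation of condensed distances; permutation p
    by jointly permuting rows+columns of the second matrix."""
    _check_pair(dm_a, dm_b)
    n = len(dm_a)
    a = dm_a.condensed()
    bv = dm_b.values
    iu = np.triu_indices(n, k=1)
    b = bv[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        return MantelResult(variable, np.nan, np.nan, n_perm, tail=tail, degenerate=True)
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = bv[np.ix_(perm, perm)][iu]
        r_perm = np.corrcoef(a, bp)[0, 1]
        if _tail_count(r_perm, r_obs, tail):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(variable, r_obs, float(p), n_perm, tail=tail)


def _residualise(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(controls.shape[0]), controls])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    dm_control: "DistanceMatrix | list[DistanceMatrix]",
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "greater",
    variable: str = "",
    controlled_names: list[str] | None = None,
) -> MantelResult:
    """Partial Mantel by the residual method: correlate the control-matrix
    residuals of a and b; p from permuting dm_b's labels.  Several control
    matrices may be partialled out jointly."""
    controls = dm_control if isinstance(dm_control, list) else [dm_control]
    if controlled_names is None:
        controlled_names = [c.metric for c in controls]
    _check_pair(dm_a, dm_b)
    for cdm in controls:
        _check_pair(dm_a, cdm)
    n = len(dm_a)
    iu = np.triu_indices(n, k=1)
    a = dm_a.condensed()
    c = np.column_stack([cdm.condensed() for cdm in controls])
    bv = dm_b.values
    b = bv[iu]
    degenerate = bool(np.all(c.std(axis=0) == 0))
    if np.std(a) == 0 or np.std(b) == 0:
        return MantelResult(variable, np.nan, np.nan, n_perm,
                            controlled=controlled_names, tail=tail, degenerate=True)
    ra = _residualise(a, c)
    rb = _residualise(b, c)

    def _safe_corr(u, v):
        # a residual that is numerically zero (matrix fully explained by the
        # controls) carries no signal; report 0 rather than float noise
        if u.std() <= 1e-10 * max(a.std(), 1.0) or v.std() <= 1e-10 * max(b.std(), 1.0):
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    r_obs = _safe_corr(ra, rb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = _residualise(bv[np.ix_(perm, perm)][iu], c)
        r_perm = _safe_corr(ra, bp)
        if _tail_count(r_perm, r_obs, tail):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(variable, r_obs, float(p), n_perm,
                        controlled=controlled_names, tail=tail, degenerate=degenerate)


def sample_connectivity_profile(
    net,
    tables: list[CountTable],
    weighted: bool = True,
) -> tuple[pd.Series, DistanceMatrix]:
    """Per-sample connectivity score and its Euclidean divergence matrix.

    score(s) = sum over network nodes of degree(node) * relative abundance of
    the node's taxon in sample s (``weighted=False`` drops the abundance
    factor, counting degrees of taxa present in the sample).  Samples are the
    intersection of the tables' sample sets; samples containing no network
    taxon score 0.
    """
    degree = net.degrees()
    common: list[str] | None = None
    for t in tables:
        common = t.samples if common is None else [s for s in common if s in set(t.samples)]
    if not common:
        raise ValidationError("tables share no samples")
    scores = pd.Series(0.0, index=pd.Index(common, name="sample_id"))
    for t in tables:
        rel = t.relative_abundance()
        sub = t.select_samples(common)
        rel = sub.relative_abundance()
        for j, taxon in enumerate(sub.taxa):
            if taxon not in degree:
                continue
            if weighted:
                scores += degree[taxon] * rel[:, j]
            else:
                scores += degree[taxon] * (rel[:, j] > 0)
    arr = scores.to_numpy()
    vals = np.abs(arr[:, None] - arr[None, :])
    dm = DistanceMatrix(common, vals, metric="connectivity_euclidean")
    return scores, dm
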