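"""Three-way variance partitioning of community structure via constrained
correspondence analysis (chi-square metric, weighted least squares).

The partition runs the seven constrained ordinations (each block, each pair,
all three) and recovers unique, pairwise-shared, and triple-shared fractions
by inclusion-exclusion, so the eight fractions sum to the jointly explained
fraction exactly.  Fractions are unadjusted by default; Ezekiel-adjusted
values can be requested, in which case shared fractions may go negative
(flagged by convention, not an error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountTable, ValidationError


def _chi_square_transform(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (Q, row_weights) where Q is the chi-square standardised
    contribution matrix and total inertia = sum(Q**2)."""
    x = counts.astype(float)
    total = x.sum()
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (p - expected) / np.sqrt(expected)
    q[~np.isfinite(q)] = 0.0
    return q, r


def _drop_collinear(z: np.ndarray, names: list[str], tol: float = 1e-8) -> tuple[np.ndarray, list[str]]:
    """Greedy QR-based removal of linearly dependent columns."""
    keep: list[int] = []
    for j in range(z.shape[1]):
        cand = z[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear constraint {names[j]!r}")
    return z[:, keep], [names[j] for j in keep]


def cca_inertia(table: CountTable, constraints: pd.DataFrame) -> float:
    """Fraction of total chi-square inertia explained by the constraints.

    The community matrix is chi-square transformed and regressed on the
    row-weighted, weighted-centred constraints; the constrained inertia is
    the sum of squares of the fitted values (vegan's CCA algorithm).
    """
    if list(constraints.index) != list(table.samples):
        constraints = constraints.loc[table.samples]
    z_raw = constraints.to_numpy(dtype=float)
    if np.any(~np.isfinite(z_raw)):
        raise ValidationError("constraints contain missing values")
    if np.any(table.counts.sum(axis=1) == 0) or np.any(table.counts.sum(axis=0) == 0):
        raise ValidationError("zero-sum rows/columns: filter the table first")
    if constraints.shape[1] >= table.n_samples:
        raise ValidationError("more constraints than samples")
    q, r = _chi_square_transform(table.counts)
    total_inertia = float((q**2).sum())
    if total_inertia == 0:
        raise ValidationError("community matrix has no inertia")
    # weighted centring then row weighting by sqrt(r)
    wmean = (r[:, None] * z_raw).sum(axis=0) / r.sum()
    z = np.sqrt(r)[:, None] * (z_raw - wmean)
    z, kept = _drop_collinear(z, list(constraints.columns))
    if z.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(z, q, rcond=None)
    fitted = z @ beta
    return float((fitted**2).sum() / total_inertia)


def adjusted_fraction(fraction: float, n: int, n_constraints: int) -> float:
    """Ezekiel-style adjustment of an explained-inertia fraction."""
    if n - n_constraints - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - fraction) * (n - 1) / (n - n_constraints - 1)


@dataclass
class VpaResult:
    total_explained: float
    unique: dict[str, float]        # keys a, b, c
    shared_pair: dict[str, float]   # keys ab, ac, bc
    shared_triple: float            # abc
    residual: float
    block_names: dict[str, str] = field(default_factory=dict)
    adjusted: bool = False
    negative_fraction_flag: bool = False

    def fractions(self) -> dict[str, float]:
        out = {**self.unique, **self.shared_pair, "abc": self.shared_triple}
        return out


def vpa_three_way(
    table: CountTable,
    block_a: pd.DataFrame,
    block_b: pd.DataFrame,
    block_c: pd.DataFrame,
    names: tuple[str, str, str] = ("a", "b", "c"),
    adjusted: bool = False,
) -> VpaResult:
    """Partition community inertia among three explanatory blocks."""
    for blk in (block_a, block_b, block_c):
        if blk.shape[1] == 0:
            raise ValidationError("empty constraint block")
    n = table.n_samples

    def frac(*blocks: pd.DataFrame) -> float:
        joint = pd.concat(blocks, axis=1)
        f = cca_inertia(table, joint)
        if adjusted:
            f = adjusted_fraction(f, n, joint.shape[1])
        return f

    fa, fb, fc = frac(block_a), frac(block_b), frac(block_c)
    fab, fac, fbc = frac(block_a, block_b), frac(block_a, block_c), frac(block_b, block_c)
    fabc = frac(block_a, block_b, block_c)

    a = fabc - fbc
    b = fabc - fac
    c = fabc - fab
    ab = fac + fbc - fabc - fc
    ac = fab + fbc - fabc - fb
    bc = fab + fac - fabc - fa
    abc = fabc - a - b - c - ab - ac - bc
    result = VpaResult(
        total_explained=fabc,
        unique={"a": a, "b": b, "c": c},
        shared_pair={"ab": ab, "ac": ac, "bc": bc},
        shared_triple=abc,
        residual=1.0 - fabc,
        block_names={"a": names[0], "b": names[1], "c": names[2]},
        adjusted=adjusted,
        negative_fraction_flag=any(v < 0 for v in (ab, ac, bc, abc)),
    )
    return result
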