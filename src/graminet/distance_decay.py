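"""Distance-decay relationships (DDR): community dissimilarity regressed on
geographic distance or on divergence in grass productivity/diversity/soil
variables, with permutation significance and cross-group slope contrasts.

Pairwise points from a distance matrix are not independent, so the reported
significance comes from a Mantel-style matrix permutation; the naive OLS p
is reported alongside.  Upper-triangle vectorisation is row-major (i<j),
matching scipy's squareform convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import DistanceMatrix, SampleTable, ValidationError
from .group_stats import bh_adjust

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geographic_distance_matrix(frame: SampleTable) -> DistanceMatrix:
    """Pairwise haversine distances (km) between samples."""
    coords = frame.variables(["latitude", "longitude"])
    if coords.isna().any().any():
        raise ValidationError("missing coordinates")
    lat = np.radians(coords["latitude"].to_numpy())
    lon = np.radians(coords["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    vals = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return DistanceMatrix(frame.samples, vals, metric="haversine_km")


def variable_divergence_matrix(frame: SampleTable, variables: list[str]) -> DistanceMatrix:
    """Euclidean distance on z-scored metadata variables.

    Zero-variance variables are dropped with a warning (they carry no
    divergence signal and would divide by zero when standardised).
    """
    block = frame.variables(variables)
    keep = []
    for col in block.columns:
        sd = block[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            import warnings

            warnings.warn(f"dropping zero-variance variable {col!r}")
            continue
        keep.append(col)
    if not keep:
        raise ValidationError("no usable variables")
    z = (block[keep] - block[keep].mean()) / block[keep].std(ddof=1)
    arr = z.to_numpy()
    diff = arr[:, None, :] - arr[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(frame.samples, vals, metric="euclidean_z")


@dataclass
class DdrFit:
    organism_group: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_permutation: float
    p_ols: float
    n_pairs: int
    # retained for pooled slope contrasts
    x: np.ndarray | None = None
    y: np.ndarray | None = None


def fit_ddr(
    community_dm: DistanceMatrix,
    predictor_dm: DistanceMatrix,
    organism_group: str = "",
    predictor: str = "geographic",
    log10_predictor: bool = False,
    n_perm: int = 999,
    seed: int = 0,
) -> DdrFit:
    """OLS of community dissimilarity on a predictor distance over sample
    pairs, with slope significance from matrix permutation."""
    if community_dm.labels != predictor_dm.labels:
        raise ValidationError("matrices must share labels and order")
    n = len(community_dm)
    if n < 4:
        raise ValidationError("need >= 4 samples")
    y = community_dm.condensed()
    x = predictor_dm.condensed()
    if log10_predictor:
        x = np.log10(np.maximum(x, np.min(x[x > 0]) / 10.0))
    if np.std(x) == 0:
        raise ValidationError("predictor distances are constant; slope undefined")
    res = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    pv = predictor_dm.values
    iu = np.triu_indices(n, k=1)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = pv[np.ix_(perm, perm)][iu]
        if log10_predictor:
            xp = np.log10(np.maximum(xp, np.min(xp[xp > 0]) / 10.0))
        slope_perm = stats.linregress(xp, y).slope
        if abs(slope_perm) >= abs(res.slope):
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    return DdrFit(
        organism_group=organism_group,
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_permutation=float(p_perm),
        p_ols=float(res.pvalue),
        n_pairs=len(y),
        x=x,
        y=y,
    )


def compare_slopes(fits: list[DdrFit]) -> pd.DataFrame:
    """Pairwise DDR slope contrasts from a pooled group x predictor OLS.

    Fits must carry their pair data.  Returns one row per ordered pair with
    the slope difference, interaction t-test p, and BH-adjusted p.
    Delta(a, b) == -Delta(b, a).
    """
    if len(fits) < 2:
        raise ValidationError("need >= 2 fits to compare slopes")
    if any(f.x is None or f.y is None for f in fits):
        raise ValidationError("fits must retain pair data for slope contrasts")
    frames = []
    for f in fits:
        frames.append(pd.DataFrame({"x": f.x, "y": f.y, "group": f.organism_group}))
    data = pd.concat(frames, ignore_index=True)
    groups = [f.organism_group for f in fits]
    # design: per-group intercept and per-group slope (cell-means coding)
    X = []
    for g in groups:
        ind = (data["group"] == g).astype(float).to_numpy()
        X.append(ind)
    for g in groups:
        ind = (data["group"] == g).astype(float).to_numpy()
        X.append(ind * data["x"].to_numpy())
    X = np.column_stack(X)
    model = sm.OLS(data["y"].to_numpy(), X).fit()
    k = len(groups)
    rows = []
    for i, a in enumerate(groups):
        for j, b in enumerate(groups):
            if i >= j:
                continue
            contrast = np.zeros(2 * k)
            contrast[k + i] = 1.0
            contrast[k + j] = -1.0
            tt = model.t_test(contrast)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "slope_a": float(model.params[k + i]),
                    "slope_b": float(model.params[k + j]),
                    "delta": float(tt.effect[0]),
                    "p": float(tt.pvalue),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
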