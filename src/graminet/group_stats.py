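"""Group comparisons: Kruskal-Wallis with compact letters, Spearman
correlation screens, and PERMANOVA on a distance matrix.

The post-hoc behind the letter display is Dunn's test with Benjamini-
Hochberg correction (the omnibus test used for the published group letters
is unnamed; Kruskal-Wallis + Dunn is the documented choice here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import DistanceMatrix, ValidationError


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class LetterDisplay:
    variable: str
    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    letters: dict[str, str]
    kruskal_h: float
    kruskal_p: float
    pairwise_p: pd.DataFrame | None = None


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Pairwise Dunn z-tests on ranks with tie correction; raw two-sided p."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    n = len(values)
    ranks = stats.rankdata(values)
    # tie correction term
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / se
                p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def _letters_from_nonsig(labels: list[str], nonsig: set[tuple[str, str]],
                         order_stat: dict[str, float]) -> dict[str, str]:
    """Compact letter display via maximal cliques of the non-significance graph."""
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from(nonsig)
    cliques = list(nx.find_cliques(g))
    # letter 'a' goes to the clique containing the highest-ranked group
    cliques.sort(key=lambda c: (-max(order_stat[m] for m in c), sorted(c)))
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for member in clique:
            letters[member].append(alphabet[i % len(alphabet)])
    return {lab: "".join(sorted(ls)) for lab, ls in letters.items()}


def kruskal_letters(values, groups, variable: str = "", alpha: float = 0.05) -> LetterDisplay:
    """Kruskal-Wallis omnibus test followed, when significant, by Dunn/BH
    pairwise tests summarised as compact letters."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    group_values = [values[groups == g] for g in labels]
    if any(len(v) < 2 for v in group_values):
        raise ValidationError("every group needs >= 2 observations")
    means = {g: float(v.mean()) for g, v in zip(labels, group_values)}
    sds = {g: float(v.std(ddof=1)) for g, v in zip(labels, group_values)}
    try:
        h, p = stats.kruskal(*group_values)
    except ValueError:  # all values identical -> H degenerate
        h, p = 0.0, 1.0
    pairwise = None
    if np.isnan(p):
        p = 1.0
    if p < alpha:
        pairwise = dunn_test(values, groups)
        nonsig = {
            (r.group_a, r.group_b)
            for r in pairwise.itertuples()
            if r.p_adj >= alpha
        }
    else:
        nonsig = {(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]}
    letters = _letters_from_nonsig(labels, nonsig, means)
    return LetterDisplay(variable, labels, means, sds, letters, float(h), float(p), pairwise)


def spearman_matrix(x_block: pd.DataFrame, y_block: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p for every (x column, y column) pair.

    Constant columns yield NaN.  Pairs are evaluated on their jointly
    non-missing samples.
    """
    if len(x_block) != len(y_block):
        raise ValidationError("blocks must share samples")
    if len(x_block) < 4:
        raise ValidationError("need n >= 4")
    rho = pd.DataFrame(index=x_block.columns, columns=y_block.columns, dtype=float)
    pmat = rho.copy()
    for xc in x_block.columns:
        for yc in y_block.columns:
            x = x_block[xc].to_numpy(dtype=float)
            y = y_block[yc].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 4 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rho.loc[xc, yc] = np.nan
                pmat.loc[xc, yc] = np.nan
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rho.loc[xc, yc] = r
            pmat.loc[xc, yc] = p
    return rho, pmat


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    singleton_groups: list[str] = field(default_factory=list)


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    f = (ss_among / df_among) / (ss_within / df_within)
    return f, ss_among / ss_total


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F from the among/within partition of squared
    distances; permutation p with the +1 convention."""
    groups = np.asarray(groups)
    if len(groups) != len(dm):
        raise ValidationError("group labels must match distance matrix")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    singletons = [str(g) for g in labels if (groups == g).sum() == 1]
    d2 = dm.values**2
    f_obs, r2 = _permanova_f(d2, codes, len(labels))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_f(d2, perm, len(labels))
        if f_perm >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, singletons)
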