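"""Phylogenetic assemblage structure: MPD and SES-MPD.

Mean pairwise phylogenetic distance (MPD) among the species of each
assemblage, standardized against a taxon-shuffle null model that permutes
the tip labels of the cophenetic distance matrix while holding assemblage
richness fixed:

    SES = (MPD_obs - mean(MPD_null)) / sd(MPD_null)

Under this formula an assemblage drawn from a single clade (phylogenetic
clustering, low MPD) gets SES < 0 and one spread across clades
(overdispersion) gets SES > 0; see the methods note for the sign-labelling
conventions in use in the literature.

For trees with few tips the null is enumerated exactly: a uniform tip
permutation maps an assemblage of richness k to a uniform random k-subset
of tips, so the null distribution is the MPD over all C(n, k) subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

__all__ = ["SESResult", "cophenetic_distances", "mpd", "ses_mpd"]


@dataclass
class SESResult:
    """SES-MPD for one assemblage; ``ses`` is NaN when undefined
    (richness < 2 or a degenerate null with sd = 0)."""

    unit_id: str
    observed_mpd: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_null: int


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise tip-to-tip path-length distances as a labelled matrix."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    n = len(labels)
    mat = np.zeros((n, n))
    for i, li in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[li], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def mpd(community: set[str] | list[str], distances: pd.DataFrame) -> float:
    """Mean pairwise distance over unordered present-present pairs;
    NaN (undefined) for fewer than two species."""
    members = sorted(set(community))
    if len(members) < 2:
        return float("nan")
    missing = [s for s in members if s not in distances.index]
    if missing:
        raise ValueError(f"species missing from the tree: {missing}")
    sub = distances.loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def _mpd_from_indices(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def ses_mpd(
    matrix: pd.DataFrame,
    tree: dendropy.Tree | pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    exact_max_tips: int = 7,
) -> pd.DataFrame:
    """SES-MPD per assemblage under the taxon-shuffle null.

    ``matrix`` is a units-x-species incidence matrix; ``tree`` a dendropy
    tree (or a precomputed cophenetic distance matrix) covering every
    species column.  The shuffle pool is the full tip set of the tree.  With
    at most ``exact_max_tips`` tips the null is enumerated exactly
    (population sd over all richness-k subsets); otherwise ``n_null``
    seeded Monte-Carlo tip permutations are used, and the rank p-value is
    ``(#{null <= obs} + 1) / (n_null + 1)``.

    Returns a DataFrame indexed by unit id with the :class:`SESResult`
    fields.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    distances = tree if isinstance(tree, pd.DataFrame) else cophenetic_distances(tree)
    tips = list(distances.index)
    missing = [s for s in matrix.columns if s not in tips]
    if missing:
        raise ValueError(f"species missing from the tree: {missing}")
    d = distances.to_numpy()
    n_tips = len(tips)
    col_idx = {s: tips.index(s) for s in matrix.columns}

    exact = n_tips <= exact_max_tips
    perms = None
    if not exact:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n_tips) for _ in range(n_null)])

    exact_null_cache: dict[int, tuple[float, float, np.ndarray]] = {}
    results = []
    for unit in matrix.index:
        present = matrix.columns[matrix.loc[unit].to_numpy() > 0]
        k = len(present)
        obs = mpd(list(present), distances)
        if k < 2:
            results.append(
                SESResult(str(unit), obs, np.nan, np.nan, np.nan, np.nan, 0)
            )
            continue
        idx = np.array([col_idx[s] for s in present])
        if exact:
            if k not in exact_null_cache:
                vals = np.array(
                    [_mpd_from_indices(d, np.array(sub)) for sub in combinations(range(n_tips), k)]
                )
                exact_null_cache[k] = (float(vals.mean()), float(vals.std()), vals)
            null_mean, null_sd, vals = exact_null_cache[k]
            p = float((vals <= obs + 1e-12).mean())
            n_used = len(vals)
        else:
            vals = np.array([_mpd_from_indices(d, perm[idx]) for perm in perms])
            null_mean = float(vals.mean())
            null_sd = float(vals.std(ddof=1))
            p = float(((vals <= obs + 1e-12).sum() + 1) / (n_null + 1))
            n_used = n_null
        ses = (obs - null_mean) / null_sd if null_sd > 0 else float("nan")
        results.append(SESResult(str(unit), obs, null_mean, null_sd, ses, p, n_used))

    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "observed_mpd": r.observed_mpd,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "ses": r.ses,
                "p_value": r.p_value,
                "n_null": r.n_null,
            }
            for r in results
        ]
    ).set_index("unit_id")
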