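"""Probit Bayesian additive regression trees (BART) for occurrence modelling.

A sum-of-trees model with the standard regularizing priors, fit by
backfitting MCMC.  The binary outcome (presence / pseudoabsence) enters
through a probit link with latent-variable augmentation: a latent normal
``z_i ~ N(f(x_i), 1)`` is truncated above 0 for presences and below 0 for
absences, and the sum-of-trees ``f`` is updated tree by tree against the
latent residuals.  Tree moves are grow / prune / change proposals accepted
by Metropolis-Hastings with the leaf values integrated out analytically
(conjugate normal leaf prior).

Priors
------
* split probability at depth d: ``alpha * (1 + d) ** -beta`` (defaults
  0.95 and 2);
* splitting rule: variable uniform, cutpoint uniform over a per-variable
  quantile grid;
* leaf values: ``N(0, sigma_mu^2)`` with ``sigma_mu = 3 / (k * sqrt(m))``
  for ``m`` trees (``k = 2`` default), which shrinks the latent function
  into roughly (-3, 3), i.e. probabilities into (0.001, 0.999).

The move is drawn from fixed probabilities (grow 0.4 / prune 0.4 / change
0.2); a move that is structurally impossible in the current tree (pruning a
stump) counts as a rejected proposal.  Proposals creating an empty leaf are
rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .raster import RasterGrid

__all__ = [
    "BARTConfig",
    "DesignMatrix",
    "BARTModel",
    "PosteriorPrediction",
    "FitDiagnostics",
    "fit_bart",
    "predict_occurrence",
    "evaluate_model",
    "tss_threshold",
    "tss_at_threshold",
    "auc_score",
    "variable_importance",
    "select_covariates",
    "binarize",
]


@dataclass
class BARTConfig:
    """Sampler settings.  The field defaults are the reference settings of
    the modelling framework (200 trees, 1000 iterations, 20% burn-in);
    :meth:`test_size` gives a reduced configuration for fast runs."""

    n_trees: int = 200
    n_iterations: int = 1000
    burn_in_fraction: float = 0.2
    alpha: float = 0.95
    beta: float = 2.0
    k: float = 2.0
    n_cutpoints: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")

    @classmethod
    def test_size(cls, seed: int = 0, **kwargs) -> "BARTConfig":
        kwargs.setdefault("n_trees", 20)
        kwargs.setdefault("n_iterations", 200)
        return cls(seed=seed, **kwargs)

    @property
    def n_burn_in(self) -> int:
        return int(np.floor(self.n_iterations * self.burn_in_fraction))


@dataclass
class DesignMatrix:
    """Training data: covariate values per point and presence labels."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.X.isna().to_numpy().any():
            raise ValueError("missing covariate values in design matrix")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, names: list[str]) -> "DesignMatrix":
        return DesignMatrix(X=self.X[names].copy(), y=self.y.copy())


@dataclass
class PosteriorPrediction:
    """Posterior-mean probability map and 95% credible-interval width map."""

    mean_probability: RasterGrid
    ci_width: RasterGrid


@dataclass
class FitDiagnostics:
    auc: float
    tss: float
    threshold: float


class _Node:
    __slots__ = ("var", "cut", "left", "right", "mu", "idx")

    def __init__(self, idx: np.ndarray):
        self.var = None      # split variable index; None -> leaf
        self.cut = 0.0
        self.left = None
        self.right = None
        self.mu = 0.0
        self.idx = idx       # training-row indices reaching this leaf

    @property
    def is_leaf(self) -> bool:
        return self.var is None


def _collect(root: _Node):
    """Return (leaves with depth, prunable internals with depth).

    Prunable = internal node whose both children are leaves.
    """
    leaves, prunable = [], []
    stack = [(root, 0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf:
            leaves.append((node, d))
        else:
            if node.left.is_leaf and node.right.is_leaf:
                prunable.append((node, d))
            stack.append((node.left, d + 1))
            stack.append((node.right, d + 1))
    return leaves, prunable


class BARTModel:
    """Fitted probit BART: retained posterior draws of the tree ensemble."""

    def __init__(
        self,
        covariate_names: list[str],
        config: BARTConfig,
        draws: list[list[tuple]],
        train_f_draws: np.ndarray,
    ):
        self.covariate_names = covariate_names
        self.config = config
        self.draws = draws                  # frozen tree ensembles
        self.train_f_draws = train_f_draws  # (n_draws, n_train) latent means

    # -- prediction ---------------------------------------------------------
    def predict_probability_draws(
        self, X: np.ndarray, thin_draws: int | None = None
    ) -> np.ndarray:
        """Per-draw occurrence probabilities, shape (n_draws_used, n_points)."""
        X = np.asarray(X, dtype=float)
        draws = self.draws
        if thin_draws is not None and thin_draws < len(draws):
            sel = np.linspace(0, len(draws) - 1, thin_draws).round().astype(int)
            draws = [draws[i] for i in sel]
        out = np.empty((len(draws), len(X)))
        for d, trees in enumerate(draws):
            f = np.zeros(len(X))
            for tree in trees:
                f += _eval_frozen(tree, X)
            out[d] = ndtr(f)
        return out

    def train_probability(self) -> np.ndarray:
        """Posterior-mean in-sample occurrence probabilities."""
        return ndtr(self.train_f_draws).mean(axis=0)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """JSON-lines: a header line, then one line per posterior draw."""
        with open(path, "w") as fh:
            header = {
                "covariate_names": self.covariate_names,
                "config": vars(self.config),
                "n_draws": len(self.draws),
            }
            fh.write(json.dumps(header) + "\n")
            for trees in self.draws:
                fh.write(json.dumps(trees) + "\n")

    @classmethod
    def load(cls, path) -> "BARTModel":
        with open(path) as fh:
            header = json.loads(fh.readline())
            draws = [_listify(json.loads(line)) for line in fh]
        config = BARTConfig(**header["config"])
        return cls(header["covariate_names"], config, draws, np.zeros((0, 0)))


def _listify(trees):
    return [_tuplify(t) for t in trees]


def _tuplify(node):
    if node[0] == "L":
        return ("L", node[1])
    return ("S", node[1], node[2], _tuplify(node[3]), _tuplify(node[4]))


def _freeze(node: _Node):
    if node.is_leaf:
        return ("L", float(node.mu))
    return ("S", int(node.var), float(node.cut), _freeze(node.left), _freeze(node.right))


def _eval_frozen(tree, X: np.ndarray) -> np.ndarray:
    out = np.zeros(len(X))
    stack = [(tree, np.arange(len(X)))]
    while stack:
        node, idx = stack.pop()
        if node[0] == "L":
            out[idx] = node[1]
        else:
            mask = X[idx, node[1]] <= node[2]
            stack.append((node[3], idx[mask]))
            stack.append((node[4], idx[~mask]))
    return out


def fit_bart(design: DesignMatrix, config: BARTConfig | None = None) -> BARTModel:
    """Fit probit BART by backfitting MCMC; deterministic given the seed."""
    config = config or BARTConfig()
    X = design.X.to_numpy(dtype=float)
    y = design.y
    n, p = X.shape

    cutpoints = []
    for j in range(p):
        qs = np.unique(np.quantile(X[:, j], np.linspace(0, 1, config.n_cutpoints + 2)[1:-1]))
        # drop cutpoints that cannot separate anything
        qs = qs[(qs >= X[:, j].min()) & (qs < X[:, j].max())]
        cutpoints.append(qs)
    if all(len(c) == 0 for c in cutpoints):
        raise ValueError("zero-variance design: no covariate admits a split")

    rng = np.random.default_rng(config.seed)
    m = config.n_trees
    tau2 = (3.0 / (config.k * np.sqrt(m))) ** 2
    p_split = lambda d: config.alpha * (1.0 + d) ** (-config.beta)

    def leaf_ml(n_l: int, s_l: float) -> float:
        # marginal log-lik terms that depend on the partition (sigma = 1)
        return 0.5 * (-np.log1p(n_l * tau2) + tau2 * s_l**2 / (1.0 + n_l * tau2))

    trees = [_Node(np.arange(n)) for _ in range(m)]
    tree_pred = np.zeros((m, n))
    f = np.zeros(n)
    z = np.where(y == 1, 0.67, -0.67).astype(float)

    n_keep = config.n_iterations - config.n_burn_in
    draws: list[list[tuple]] = []
    train_f = np.empty((n_keep, n))

    eps = 1e-12
    for it in range(config.n_iterations):
        # latent truncated-normal draw
        u = rng.random(n)
        a = ndtr(-f)  # P(z < 0 | f)
        arg = np.where(y == 1, a + u * (1.0 - a), u * a)
        z = f + ndtri(np.clip(arg, eps, 1.0 - eps))

        for t in range(m):
            root = trees[t]
            resid = z - f + tree_pred[t]
            move = rng.choice(3, p=(0.4, 0.4, 0.2))
            leaves, prunable = _collect(root)
            accepted = False

            if move == 0:  # grow
                node, depth = leaves[rng.integers(len(leaves))]
                var = int(rng.integers(p))
                if len(cutpoints[var]) > 0:
                    cut = float(cutpoints[var][rng.integers(len(cutpoints[var]))])
                    go_left = X[node.idx, var] <= cut
                    nl = int(go_left.sum())
                    nr = len(node.idx) - nl
                    if nl > 0 and nr > 0:
                        r = resid[node.idx]
                        s = r.sum()
                        sl = r[go_left].sum()
                        ll = (
                            leaf_ml(nl, sl)
                            + leaf_ml(nr, s - sl)
                            - leaf_ml(len(node.idx), s)
                        )
                        pd_ = p_split(depth)
                        pd1 = p_split(depth + 1)
                        log_prior = np.log(pd_) + 2 * np.log(1 - pd1) - np.log(1 - pd_)
                        n_prunable_after = len(prunable) + (
                            1 if node is root else _grow_prunable_delta(root, node, prunable)
                        )
                        log_prop = np.log(0.4 / 0.4) + np.log(
                            len(leaves) / max(n_prunable_after, 1)
                        )
                        if np.log(rng.random() + eps) < ll + log_prior + log_prop:
                            node.var = var
                            node.cut = cut
                            node.left = _Node(node.idx[go_left])
                            node.right = _Node(node.idx[~go_left])
                            node.idx = None
                            accepted = True

            elif move == 1 and prunable:  # prune
                node, depth = prunable[rng.integers(len(prunable))]
                idx = np.concatenate([node.left.idx, node.right.idx])
                r = resid[idx]
                s = r.sum()
                ll = (
                    leaf_ml(len(idx), s)
                    - leaf_ml(len(node.left.idx), resid[node.left.idx].sum())
                    - leaf_ml(len(node.right.idx), resid[node.right.idx].sum())
                )
                pd_ = p_split(depth)
                pd1 = p_split(depth + 1)
                log_prior = -(np.log(pd_) + 2 * np.log(1 - pd1) - np.log(1 - pd_))
                n_leaves_after = len(leaves) - 1
                log_prop = np.log(len(prunable) / max(n_leaves_after, 1))
                if np.log(rng.random() + eps) < ll + log_prior + log_prop:
                    node.var = None
                    node.left = None
                    node.right = None
                    node.idx = idx
                    accepted = True

            elif move == 2 and prunable:  # change splitting rule
                node, _ = prunable[rng.integers(len(prunable))]
                var = int(rng.integers(p))
                if len(cutpoints[var]) > 0:
                    cut = float(cutpoints[var][rng.integers(len(cutpoints[var]))])
                    idx = np.concatenate([node.left.idx, node.right.idx])
                    go_left = X[idx, var] <= cut
                    nl = int(go_left.sum())
                    nr = len(idx) - nl
                    if nl > 0 and nr > 0:
                        r = resid[idx]
                        sl = r[go_left].sum()
                        s = r.sum()
                        ll_new = leaf_ml(nl, sl) + leaf_ml(nr, s - sl)
                        ll_old = leaf_ml(
                            len(node.left.idx), resid[node.left.idx].sum()
                        ) + leaf_ml(len(node.right.idx), resid[node.right.idx].sum())
                        if np.log(rng.random() + eps) < ll_new - ll_old:
                            node.var = var
                            node.cut = cut
                            node.left = _Node(idx[go_left])
                            node.right = _Node(idx[~go_left])
                            accepted = True

            del accepted
            # draw leaf values and refresh this tree's prediction
            new_pred = np.empty(n)
            for leaf, _d in _collect(root)[0]:
                r = resid[leaf.idx]
                n_l = len(leaf.idx)
                post_var = tau2 / (1.0 + n_l * tau2)
                post_mean = tau2 * r.sum() / (1.0 + n_l * tau2)
                leaf.mu = post_mean + np.sqrt(post_var) * rng.standard_normal()
                new_pred[leaf.idx] = leaf.mu
            f += new_pred - tree_pred[t]
            tree_pred[t] = new_pred

        if it >= config.n_burn_in:
            keep = it - config.n_burn_in
            draws.append([_freeze(tr) for tr in trees])
            train_f[keep] = f

    return BARTModel(design.covariate_names, config, draws, train_f)


def _grow_prunable_delta(root: _Node, grown: _Node, prunable) -> int:
    """Net change in prunable-node count if ``grown`` (a leaf) is split.

    The grown node becomes prunable (+1); its parent, if it was prunable,
    stops being prunable (-1).
    """
    parent = _find_parent(root, grown)
    if parent is not None and parent.left.is_leaf and parent.right.is_leaf:
        return 0
    return 1


def _find_parent(root: _Node, child: _Node) -> _Node | None:
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        if node.left is child or node.right is child:
            return node
        stack.extend([node.left, node.right])
    return None


# ---------------------------------------------------------------------------
# prediction on rasters


def predict_occurrence(
    model: BARTModel,
    covariate_grids: list[RasterGrid],
    thin_draws: int | None = None,
) -> PosteriorPrediction:
    """Posterior mean probability and 95% credible-interval width per cell.

    ``covariate_grids`` are matched to the training covariates by name; a
    mismatch raises with the missing names listed.
    """
    by_name = {g.name: g for g in covariate_grids}
    missing = [n for n in model.covariate_names if n not in by_name]
    if missing:
        raise ValueError(f"missing covariate layers: {missing}")
    geom = by_name[model.covariate_names[0]]
    X = np.column_stack(
        [by_name[n].data.ravel() for n in model.covariate_names]
    )
    probs = model.predict_probability_draws(X, thin_draws=thin_draws)
    mean = probs.mean(axis=0).reshape(geom.data.shape)
    lo, hi = np.percentile(probs, [2.5, 97.5], axis=0)
    width = (hi - lo).reshape(geom.data.shape)
    return PosteriorPrediction(
        mean_probability=geom.like(mean, name="mean_probability"),
        ci_width=geom.like(width, name="ci_width"),
    )


# ---------------------------------------------------------------------------
# evaluation


def auc_score(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic; ties get half credit."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(probabilities)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def tss_at_threshold(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float
) -> float:
    """TSS (sensitivity + specificity - 1) with rule presence iff p >= t."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = probabilities >= threshold
    pos = labels == 1
    sens = pred[pos].mean() if pos.any() else np.nan
    spec = (~pred[~pos]).mean() if (~pos).any() else np.nan
    return float(sens + spec - 1.0)


def tss_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Smallest candidate threshold maximizing TSS.

    Candidates are the sorted unique predicted values; the binarization
    rule is presence iff probability >= threshold.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    candidates = np.unique(np.asarray(probabilities, dtype=float))
    tss = np.array([tss_at_threshold(probabilities, labels, t) for t in candidates])
    return float(candidates[np.argmax(tss)])


def evaluate_model(probabilities: np.ndarray, labels: np.ndarray) -> FitDiagnostics:
    """AUC plus TSS at the TSS-maximizing threshold."""
    thr = tss_threshold(probabilities, labels)
    return FitDiagnostics(
        auc=auc_score(probabilities, labels),
        tss=tss_at_threshold(probabilities, labels, thr),
        threshold=thr,
    )


# ---------------------------------------------------------------------------
# covariate importance and selection


def variable_importance(model: BARTModel) -> pd.Series:
    """Percentage of splitting rules using each covariate, over all draws.

    Sums to 100; an ensemble with no splits at all reports a uniform split.
    """
    counts = np.zeros(len(model.covariate_names))

    def visit(node):
        if node[0] == "S":
            counts[node[1]] += 1
            visit(node[3])
            visit(node[4])

    for trees in model.draws:
        for tree in trees:
            visit(tree)
    total = counts.sum()
    if total == 0:
        pct = np.full(len(counts), 100.0 / len(counts))
    else:
        pct = 100.0 * counts / total
    return pd.Series(pct, index=model.covariate_names, name="importance_pct")


def _cv_auc(design: DesignMatrix, config: BARTConfig, n_folds: int, seed: int) -> float:
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    X = design.X.to_numpy(dtype=float)
    aucs = []
    for tr, te in skf.split(X, design.y):
        sub = DesignMatrix(X=design.X.iloc[tr], y=design.y[tr])
        model = fit_bart(sub, config)
        probs = model.predict_probability_draws(X[te]).mean(axis=0)
        aucs.append(auc_score(probs, design.y[te]))
    return float(np.mean(aucs))


def select_covariates(
    design: DesignMatrix,
    config: BARTConfig | None = None,
    tolerance: float = 0.01,
    n_folds: int = 4,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination of covariates by importance.

    Iteratively drops the lowest-importance covariate and re-estimates the
    stratified cross-validated AUC; stops when a drop would cost more than
    ``tolerance`` AUC.  Returns the retained names and the nested-model
    trace (one row per candidate model).
    """
    config = config or BARTConfig.test_size()
    current = list(design.covariate_names)
    cur_auc = _cv_auc(design.subset(current), config, n_folds, seed)
    rows = [{"n_covariates": len(current), "covariates": tuple(current), "cv_auc": cur_auc, "dropped": None}]
    while len(current) > 1:
        model = fit_bart(design.subset(current), config)
        imp = variable_importance(model)
        drop = imp.idxmin()
        cand = [c for c in current if c != drop]
        cand_auc = _cv_auc(design.subset(cand), config, n_folds, seed)
        rows.append(
            {"n_covariates": len(cand), "covariates": tuple(cand), "cv_auc": cand_auc, "dropped": drop}
        )
        if cur_auc - cand_auc > tolerance:
            rows[-1]["rejected"] = True
            break
        current, cur_auc = cand, cand_auc
    return current, pd.DataFrame(rows)


def binarize(prediction: PosteriorPrediction, threshold: float) -> RasterGrid:
    """Presence-absence map: cell = 1 iff mean probability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    grid = prediction.mean_probability
    return grid.like((grid.data >= threshold).astype(float), name="binary")
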