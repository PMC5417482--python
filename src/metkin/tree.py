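"""Relative-risk survival tree: recursive partitioning of censored survival
data with cross-validation pruning.

The method follows the full-likelihood relative-risk approach of LeBlanc &
Crowley: observed follow-up is first rescaled by the cohort-level
Nelson-Aalen cumulative hazard, ``e_i = H(t_i) - H(t0_i)`` (the subject's
expected number of events under the root baseline, honouring delayed entry),
after which a death count ``d_i`` over exposure ``e_i`` is an exponential /
Poisson problem.  Splits maximise the Poisson deviance reduction

    D(node) = 2 * sum_i [ d_i log(d_i / (lam e_i)) - (d_i - lam e_i) ],
    lam = sum d / sum e,

and each node's relative risk is its (shrunken) event rate relative to the
root: ``RR = lam_node / lam_root`` — an observed/expected ratio.  The grown
tree is pruned by cost-complexity cross-validation: the weakest-link
subtree sequence is scored by held-out deviance over seeded folds and the
subtree minimising the estimate (optionally within one standard error) is
returned.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TreeControl",
    "RiskTreeNode",
    "RiskTree",
    "grow_tree",
    "prune_tree",
    "fit_risk_tree",
    "predict_rr",
]


@dataclass(frozen=True)
class TreeControl:
    """Growth and pruning controls (rpart-like defaults)."""

    min_split: int = 20   # minimum subjects in a node to attempt a split
    min_bucket: int = 7   # minimum subjects in a child
    cp: float = 0.01      # minimum deviance gain as a fraction of root deviance
    max_depth: int = 10
    cv_folds: int = 10
    shrink_cv: float = 1.0  # coefficient of variation of the gamma prior on node rates
    one_se: bool = False    # 1-SE rule at pruning


@dataclass
class RiskTreeNode:
    n: int
    events: float
    exposure: float
    deviance: float
    rr: float                      # shrunken rate relative to the root rate
    depth: int = 0
    split_var: str | None = None
    split_threshold: float | None = None
    left: "RiskTreeNode | None" = None   # split_var <= threshold
    right: "RiskTreeNode | None" = None
    node_id: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        d = {"n": self.n, "events": self.events, "exposure": round(self.exposure, 6),
             "deviance": round(self.deviance, 6), "rr": round(self.rr, 6),
             "node_id": self.node_id}
        if not self.is_leaf:
            d["split"] = {"var": self.split_var, "threshold": self.split_threshold}
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


@dataclass
class RiskTree:
    """A fitted relative-risk tree plus the root-level transform it used."""

    root: RiskTreeNode
    covariates: list
    lambda_root: float
    event_times: np.ndarray = field(repr=False)
    cum_hazard: np.ndarray = field(repr=False)
    control: TreeControl = field(default_factory=TreeControl)
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def to_json(self, path=None):
        payload = {"covariates": self.covariates, "lambda_root": self.lambda_root,
                   "tree": self.root.to_dict()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def render(self) -> str:
        lines = []

        def walk(node: RiskTreeNode, indent: str):
            tag = f"RR={node.rr:.3f} (n={node.n}, events={node.events:.0f})"
            if node.is_leaf:
                lines.append(f"{indent}* {tag}")
            else:
                lines.append(f"{indent}{node.split_var} <= {node.split_threshold:.4g}? {tag}")
                walk(node.left, indent + "  ")
                walk(node.right, indent + "  ")

        walk(self.root, "")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# root-level time transform
# ---------------------------------------------------------------------------

def _nelson_aalen(time, event, entry=None):
    """Event times and cumulative-hazard values (step function, delayed entry)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    entry = np.zeros_like(time) if entry is None else np.asarray(entry, float)
    ts = np.unique(time[event == 1])
    jumps = np.empty_like(ts)
    for k, t in enumerate(ts):
        at_risk = np.sum((entry < t) & (time >= t))
        jumps[k] = np.sum((time == t) & (event == 1)) / at_risk
    return ts, np.cumsum(jumps)


def _eval_cumhaz(ts, ch, t):
    """H(t) for a right-continuous step function with jumps at `ts`."""
    idx = np.searchsorted(ts, np.asarray(t, float), side="right")
    return np.where(idx == 0, 0.0, ch[np.maximum(idx - 1, 0)])


def _exposures(tree_times, tree_ch, time, entry):
    e = _eval_cumhaz(tree_times, tree_ch, time) - _eval_cumhaz(tree_times, tree_ch, entry)
    return np.maximum(e, 0.0)


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------

def _poisson_deviance(d, e):
    """Total Poisson deviance of a node under its MLE rate."""
    d, e = np.asarray(d, float), np.asarray(e, float)
    E = e.sum()
    D = d.sum()
    if E <= 0 or D <= 0:
        return 0.0
    lam = D / E
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / (lam * np.maximum(e, 1e-300))), 0.0)
    return float(2.0 * (term - (d - lam * e)).sum())


def _best_split(X: pd.DataFrame, d, e, covariates, min_bucket):
    parent = _poisson_deviance(d, e)
    best = (None, None, 0.0)
    for cov in covariates:
        x = X[cov].to_numpy(float)
        order = np.argsort(x, kind="mergesort")
        xs, ds, es = x[order], d[order], e[order]
        uniq = np.unique(xs)
        if len(uniq) < 2:
            continue
        thresholds = (uniq[:-1] + uniq[1:]) / 2.0
        for thr in thresholds:
            mask = xs <= thr
            nl = int(mask.sum())
            if nl < min_bucket or len(xs) - nl < min_bucket:
                continue
            gain = parent - _poisson_deviance(ds[mask], es[mask]) - _poisson_deviance(ds[~mask], es[~mask])
            if gain > best[2] + 1e-12:
                best = (cov, float(thr), float(gain))
    return best


def _shrunken_rate(d_sum, e_sum, lam_root, k_cv):
    # gamma prior centred at the root rate with coefficient of variation k_cv
    alpha = 1.0 / k_cv**2
    return (alpha + d_sum) / (alpha / lam_root + e_sum) if (e_sum > 0 or alpha > 0) else lam_root


def _grow(X, d, e, covariates, control, lam_root, root_dev, depth, counter):
    node = RiskTreeNode(
        n=len(d), events=float(d.sum()), exposure=float(e.sum()),
        deviance=_poisson_deviance(d, e),
        rr=_shrunken_rate(d.sum(), e.sum(), lam_root, control.shrink_cv) / lam_root,
        depth=depth, node_id=counter[0],
    )
    counter[0] += 1
    if (len(d) < control.min_split or depth >= control.max_depth
            or node.events == 0 or node.deviance <= 0):
        return node
    var, thr, gain = _best_split(X, d, e, covariates, control.min_bucket)
    if var is None or gain < control.cp * max(root_dev, 1e-300):
        return node
    mask = X[var].to_numpy(float) <= thr
    node.split_var, node.split_threshold = var, thr
    node.left = _grow(X[mask], d[mask], e[mask], covariates, control, lam_root,
                      root_dev, depth + 1, counter)
    node.right = _grow(X[~mask], d[~mask], e[~mask], covariates, control, lam_root,
                       root_dev, depth + 1, counter)
    return node


def grow_tree(
    data: pd.DataFrame,
    covariates: list,
    control: TreeControl = TreeControl(),
    duration_col: str = "time",
    event_col: str = "event",
    entry_col: str | None = None,
) -> RiskTree:
    """Grow the full relative-risk tree (no pruning).

    `data` holds one row per subject with follow-up, event indicator,
    optional delayed-entry column and the candidate split covariates.  A node
    where every subject is censored, or whose best split gains less than
    ``cp`` times the root deviance, becomes a leaf.
    """
    if len(data) < 2:
        raise ValueError("too few subjects to grow a tree")
    time = data[duration_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    entry = data[entry_col].to_numpy(float) if entry_col else np.zeros_like(time)
    ts, ch = _nelson_aalen(time, event, entry)
    if len(ts) == 0:
        raise ValueError("no events: cannot grow a survival tree")
    e = _exposures(ts, ch, time, entry)
    d = event.astype(float)
    lam_root = d.sum() / e.sum()
    root_dev = _poisson_deviance(d, e)
    X = data[covariates].reset_index(drop=True)
    root = _grow(X, d, e, covariates, control, lam_root, root_dev, 0, [0])
    return RiskTree(root=root, covariates=list(covariates), lambda_root=float(lam_root),
                    event_times=ts, cum_hazard=ch, control=control)


# ---------------------------------------------------------------------------
# cost-complexity pruning with cross-validation
# ---------------------------------------------------------------------------

def _branch_stats(node):
    leaves = node.leaves()
    return sum(l.deviance for l in leaves), len(leaves)


def _weakest_link(node):
    """(g, node) of the internal node with smallest complexity parameter g."""
    best = None
    if node.is_leaf:
        return best
    r_branch, n_leaves = _branch_stats(node)
    g = (node.deviance - r_branch) / max(n_leaves - 1, 1)
    best = (g, node)
    for child in (node.left, node.right):
        cand = _weakest_link(child)
        if cand is not None and cand[0] < best[0]:
            best = cand
    return best


def _cc_sequence(root):
    """Nested subtree sequence with their critical complexity values."""
    seq = [(0.0, _copy.deepcopy(root))]
    work = _copy.deepcopy(root)
    while not work.is_leaf:
        g, node = _weakest_link(work)
        node.left = node.right = None
        node.split_var = node.split_threshold = None
        seq.append((max(g, 0.0), _copy.deepcopy(work)))
    return seq


def _route(node, row):
    while not node.is_leaf:
        node = node.left if row[node.split_var] <= node.split_threshold else node.right
    return node


def _holdout_deviance(tree_root, lam_root, X, d, e, shrink_cv):
    """Held-out Poisson deviance using the training tree's shrunken leaf rates."""
    total = 0.0
    for i in range(len(d)):
        leaf = _route(tree_root, X.iloc[i])
        lam = leaf.rr * lam_root
        di, ei = d[i], e[i]
        if lam <= 0:
            lam = 1e-10
        term = di * np.log(di / (lam * max(ei, 1e-300))) if di > 0 else 0.0
        total += 2.0 * (term - (di - lam * ei))
    return total


def prune_tree(tree: RiskTree, data: pd.DataFrame, seed: int = 0,
               duration_col: str = "time", event_col: str = "event",
               entry_col: str | None = None, one_se: bool | None = None) -> RiskTree:
    """Prune a grown tree by k-fold cross-validated deviance.

    The weakest-link sequence of the full tree defines candidate complexity
    values; each is scored by the held-out deviance of trees regrown on the
    training folds (fold assignment is seeded, so pruning is deterministic).
    The subtree minimising the cross-validated deviance is returned — with
    the 1-SE rule, the smallest subtree within one standard error of the
    minimum.
    """
    control = tree.control
    one_se = control.one_se if one_se is None else one_se
    seq = _cc_sequence(tree.root)
    if len(seq) == 1:
        return tree
    alphas = [a for a, _ in seq]
    # geometric means between consecutive critical values (rpart convention)
    evals = [0.0] + [float(np.sqrt(max(alphas[i], 1e-12) * max(alphas[i + 1], 1e-12)))
                     for i in range(len(alphas) - 1)] + [np.inf]
    evals = sorted(set(np.clip(evals, 0.0, np.finfo(float).max)))

    rng = np.random.default_rng(seed)
    k = min(control.cv_folds, len(data))
    folds = rng.permutation(len(data)) % k

    time = data[duration_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    entry = data[entry_col].to_numpy(float) if entry_col else np.zeros_like(time)
    X = data[tree.covariates].reset_index(drop=True)

    cv = np.zeros((k, len(evals)))
    for f in range(k):
        tr = folds != f
        if event[tr].sum() == 0:
            continue
        sub = data.loc[tr].reset_index(drop=True)
        try:
            full = grow_tree(sub, tree.covariates, control, duration_col, event_col, entry_col)
        except ValueError:
            continue
        e_val = _exposures(full.event_times, full.cum_hazard, time[~tr], entry[~tr])
        d_val = event[~tr].astype(float)
        Xv = X.loc[~tr].reset_index(drop=True)
        sub_seq = _cc_sequence(full.root)
        for j, a in enumerate(evals):
            pruned = _prune_at(sub_seq, a)
            cv[f, j] = _holdout_deviance(pruned, full.lambda_root, Xv, d_val, e_val,
                                         control.shrink_cv)
    total = cv.sum(axis=0)
    se = cv.std(axis=0, ddof=1) * np.sqrt(k) if k > 1 else np.zeros_like(total)
    jbest = int(np.argmin(total))
    if one_se:
        within = np.nonzero(total <= total[jbest] + se[jbest])[0]
        jbest = int(within[-1])  # larger alpha = smaller tree
    chosen_alpha = evals[jbest]
    pruned_root = _prune_at(seq, chosen_alpha)
    out = RiskTree(root=_copy.deepcopy(pruned_root), covariates=tree.covariates,
                   lambda_root=tree.lambda_root, event_times=tree.event_times,
                   cum_hazard=tree.cum_hazard, control=control)
    out.cv_table = pd.DataFrame({"alpha": evals, "cv_deviance": total, "se": se})
    return out


def _prune_at(seq, alpha):
    """Smallest subtree in the sequence whose critical value exceeds alpha."""
    chosen = seq[0][1]
    for a, sub in seq:
        if a <= alpha:
            chosen = sub
    return chosen


def fit_risk_tree(data, covariates, control: TreeControl = TreeControl(), seed: int = 0,
                  duration_col="time", event_col="event", entry_col=None) -> RiskTree:
    """Grow and cross-validation-prune a relative-risk tree in one call."""
    full = grow_tree(data, covariates, control, duration_col, event_col, entry_col)
    return prune_tree(full, data, seed, duration_col, event_col, entry_col)


def predict_rr(tree: RiskTree, X: pd.DataFrame):
    """Relative risk (leaf observed/expected ratio) for each subject.

    Raises ``KeyError`` if a split covariate is missing — there is no
    surrogate-split policy.
    """
    missing = [c for c in tree.covariates if c not in X.columns]
    if missing:
        raise KeyError(f"missing split covariates: {missing}")
    out = np.empty(len(X))
    for i in range(len(X)):
        out[i] = _route(tree.root, X.iloc[i]).rr
    return out
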