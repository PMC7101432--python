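"""Module-network learning: gene modules regulated by thresholded image features.

The model class assumes the cohort expression of every gene in a module is
generated by a shared regulator tree: a depth <= 2 threshold tree over
normalized (0-1) radiomic features that partitions the patients into at most
4 subgroups (leaves), each with its own Gaussian expression distribution.
Leaf distributions carry a conjugate normal-gamma prior, so the Bayesian
score of a tree is available in closed form as a sum of leaf log marginal
likelihoods. Learning alternates tree search (M-step, greedy over features
and candidate thresholds at midpoints of consecutive distinct values) and
gene reassignment (E-step, each probe moving to the module with the highest
leave-that-probe-out posterior-predictive likelihood) for at most
``max_iter`` iterations; the total score is non-decreasing by construction
and is asserted so.

`ModuleNetwork` is the model object (built from a probes x patients
expression frame and a patients x features regulator frame); ``fit`` returns
a :class:`ModuleNetworkResults` carrying assignments, trees, scores, an
iteration log, and Table-style summaries with thresholds displayed as
percentages of each feature's cohort range.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from sklearn.cluster import KMeans

__all__ = [
    "ScorePrior",
    "Split",
    "RegulatorTree",
    "ModuleNetwork",
    "ModuleNetworkResults",
    "leaf_log_marginal",
    "tree_score",
    "learn_regulator_tree",
    "fit_module_network",
    "format_group_sizes",
    "parse_group_sizes",
    "threshold_to_percent",
]


@dataclass(frozen=True)
class ScorePrior:
    """Normal-gamma hyperparameters (mu0, lambda0, alpha0, beta0)."""

    mu0: float = 0.0
    lam0: float = 1.0
    a0: float = 1.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        if self.lam0 <= 0 or self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("lambda0, alpha0, beta0 must be positive")


def _log_marginal_stats(n: float, sx: float, sxx: float, prior: ScorePrior) -> float:
    """Closed-form normal-gamma log marginal from sufficient statistics."""
    if n == 0:
        return 0.0
    mean = sx / n
    ss = max(sxx - sx * sx / n, 0.0)
    lam_n = prior.lam0 + n
    a_n = prior.a0 + n / 2.0
    b_n = prior.b0 + 0.5 * ss + prior.lam0 * n * (mean - prior.mu0) ** 2 / (2.0 * lam_n)
    return float(
        -(n / 2.0) * np.log(2 * np.pi)
        + 0.5 * (np.log(prior.lam0) - np.log(lam_n))
        + prior.a0 * np.log(prior.b0)
        - a_n * np.log(b_n)
        + special.gammaln(a_n)
        - special.gammaln(prior.a0)
    )


def _posterior(n: float, sx: float, sxx: float, prior: ScorePrior) -> ScorePrior:
    """Normal-gamma posterior hyperparameters after observing the statistics."""
    if n == 0:
        return prior
    mean = sx / n
    ss = max(sxx - sx * sx / n, 0.0)
    lam_n = prior.lam0 + n
    return ScorePrior(
        mu0=(prior.lam0 * prior.mu0 + sx) / lam_n,
        lam0=lam_n,
        a0=prior.a0 + n / 2.0,
        b0=prior.b0 + 0.5 * ss + prior.lam0 * n * (mean - prior.mu0) ** 2 / (2.0 * lam_n),
    )


def leaf_log_marginal(values: np.ndarray, prior: ScorePrior = ScorePrior()) -> float:
    """Log marginal likelihood of i.i.d. Gaussian observations under a
    normal-gamma prior on (mean, precision); empty input scores 0."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        return 0.0
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return _log_marginal_stats(x.size, float(x.sum()), float((x * x).sum()), prior)


# ------------------------------------------------------------------- trees

@dataclass(frozen=True)
class Split:
    feature: str
    threshold: float  # on the 0-1 normalized scale


@dataclass
class RegulatorTree:
    """Depth <= 2 threshold tree over normalized regulator features.

    The root splits patients into a left group (feature value < threshold)
    and a right group (value >= threshold); each side may carry one further
    split, for at most 4 leaves. ``leaf_sets`` orders leaves left block
    first: [LL, LR][RL, RR], collapsing unsplit sides to a single leaf —
    matching the "[a|b][c|d]" group-size notation.
    """

    root: Split | None = None
    left: Split | None = None
    right: Split | None = None

    def __post_init__(self) -> None:
        if self.root is None and (self.left is not None or self.right is not None):
            raise ValueError("child splits require a root split")

    @property
    def depth(self) -> int:
        if self.root is None:
            return 0
        return 2 if (self.left is not None or self.right is not None) else 1

    @property
    def n_leaves(self) -> int:
        if self.root is None:
            return 1
        return 2 + (self.left is not None) + (self.right is not None)

    @property
    def features(self) -> list[str]:
        out = []
        for s in (self.root, self.left, self.right):
            if s is not None:
                out.append(s.feature)
        return out

    def leaf_sets(self, regulators: pd.DataFrame) -> list[np.ndarray]:
        """Partition patient indices (positional) into ordered leaves."""
        idx = np.arange(len(regulators))
        if self.root is None:
            return [idx]
        rv = regulators[self.root.feature].to_numpy(dtype=float)
        left_idx = idx[rv < self.root.threshold]
        right_idx = idx[rv >= self.root.threshold]
        leaves = []
        for side_idx, split in ((left_idx, self.left), (right_idx, self.right)):
            if split is None:
                leaves.append(side_idx)
            else:
                sv = regulators[split.feature].to_numpy(dtype=float)[side_idx]
                leaves.append(side_idx[sv < split.threshold])
                leaves.append(side_idx[sv >= split.threshold])
        return leaves

    def group_sizes(self, regulators: pd.DataFrame) -> list[list[int]]:
        """Leaf sizes grouped by root side, e.g. [[15, 24], [6]]."""
        leaves = self.leaf_sets(regulators)
        if self.root is None:
            return [[len(leaves[0])]]
        n_left = 2 if self.left is not None else 1
        return [[len(l) for l in leaves[:n_left]], [len(l) for l in leaves[n_left:]]]

    def to_dict(self, feature_ranges: pd.DataFrame | None = None) -> dict:
        def enc(s: Split | None) -> dict | None:
            if s is None:
                return None
            d = {
                "feature": s.feature,
                "threshold": s.threshold,
                "threshold_pct": threshold_to_percent(s.threshold),
            }
            if feature_ranges is not None and s.feature in feature_ranges.index:
                lo = feature_ranges.loc[s.feature, "min"]
                hi = feature_ranges.loc[s.feature, "max"]
                d["threshold_raw"] = float(lo + s.threshold * (hi - lo))
            return d

        return {"root": enc(self.root), "left": enc(self.left), "right": enc(self.right)}

    @classmethod
    def from_dict(cls, d: dict) -> "RegulatorTree":
        def dec(e: dict | None) -> Split | None:
            return None if e is None else Split(e["feature"], float(e["threshold"]))

        return cls(dec(d.get("root")), dec(d.get("left")), dec(d.get("right")))


def threshold_to_percent(threshold: float) -> str:
    """Render a normalized threshold as a percentage of the feature range."""
    return f"{100 * threshold:.1f}%"


def format_group_sizes(sizes: list[list[int]]) -> str:
    """Render leaf sizes as the bracketed notation, e.g. [[15,24],[6]] -> '[15|24][06]'."""
    return "".join("[" + "|".join(f"{n:02d}" for n in block) + "]" for block in sizes)


def parse_group_sizes(text: str) -> list[list[int]]:
    """Inverse of :func:`format_group_sizes`."""
    blocks = re.findall(r"\[([0-9|]+)\]", text)
    if not blocks or "".join(f"[{b}]" for b in blocks) != text.replace(" ", ""):
        raise ValueError(f"malformed group-size string: {text!r}")
    return [[int(x) for x in b.split("|")] for b in blocks]


def tree_score(
    values: np.ndarray,
    tree: RegulatorTree,
    regulators: pd.DataFrame,
    prior: ScorePrior = ScorePrior(),
) -> float:
    """Bayesian score of a tree: sum of leaf log marginals over all
    (probe, patient-in-leaf) expression values pooled per leaf."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(regulators):
        raise ValueError("expression columns must match regulator rows")
    leaves = tree.leaf_sets(regulators)
    covered = np.concatenate(leaves) if leaves else np.array([], dtype=int)
    if sorted(covered.tolist()) != list(range(len(regulators))):
        raise ValueError("tree leaves do not partition the cohort")
    total = 0.0
    for leaf in leaves:
        x = values[:, leaf].ravel()
        total += leaf_log_marginal(x, prior)
    return total


# ------------------------------------------------------------ tree search

def _leaf_stat_arrays(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient (column) sums and sums of squares over the module's probes."""
    return values.sum(axis=0), (values * values).sum(axis=0)


def _score_subset(idx: np.ndarray, P: int, s1: np.ndarray, s2: np.ndarray, prior: ScorePrior) -> float:
    return _log_marginal_stats(P * len(idx), float(s1[idx].sum()), float(s2[idx].sum()), prior)


def _best_split(
    idx: np.ndarray,
    P: int,
    s1: np.ndarray,
    s2: np.ndarray,
    reg: np.ndarray,
    feature_names: list[str],
    min_leaf: int,
    prior: ScorePrior,
) -> tuple[float, Split, np.ndarray, np.ndarray] | None:
    """Best single split of patient subset ``idx``; None when nothing improves.

    Candidate thresholds are midpoints between consecutive distinct sorted
    feature values within the subset. Ties are broken by feature column
    order, then by ascending threshold (first strict improvement kept).
    """
    base = _score_subset(idx, P, s1, s2, prior)
    best: tuple[float, Split, np.ndarray, np.ndarray] | None = None
    for f_col, fname in enumerate(feature_names):
        v = reg[idx, f_col]
        uniq = np.unique(v)
        if len(uniq) < 2:
            continue
        for t in (uniq[:-1] + uniq[1:]) / 2.0:
            left = idx[v < t]
            right = idx[v >= t]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            sc = _score_subset(left, P, s1, s2, prior) + _score_subset(right, P, s1, s2, prior)
            if sc > base and (best is None or sc > best[0]):
                best = (sc, Split(fname, float(t)), left, right)
    return best


def learn_regulator_tree(
    values: np.ndarray,
    regulators: pd.DataFrame,
    max_depth: int = 2,
    min_leaf: int = 4,
    prior: ScorePrior = ScorePrior(),
) -> RegulatorTree:
    """Greedy regulator-tree search for one module.

    The root split is chosen over every (feature, candidate threshold) pair
    to maximize the Bayesian score, accepted only on strict improvement over
    the unsplit tree; each side is then split once more under the same rule
    when ``max_depth`` = 2. Leaves always keep at least ``min_leaf``
    patients. Returns the trivial tree when nothing improves.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    P = values.shape[0]
    if values.shape[1] != len(regulators):
        raise ValueError("expression columns must match regulator rows")
    if len(regulators) < 2 * min_leaf:
        return RegulatorTree()
    s1, s2 = _leaf_stat_arrays(values)
    reg = regulators.to_numpy(dtype=float)
    names = list(regulators.columns)
    idx = np.arange(len(regulators))
    root = _best_split(idx, P, s1, s2, reg, names, min_leaf, prior)
    if root is None:
        return RegulatorTree()
    _, root_split, left, right = root
    left_split = right_split = None
    if max_depth >= 2:
        lb = _best_split(left, P, s1, s2, reg, names, min_leaf, prior)
        if lb is not None:
            left_split = lb[1]
        rb = _best_split(right, P, s1, s2, reg, names, min_leaf, prior)
        if rb is not None:
            right_split = rb[1]
    return RegulatorTree(root_split, left_split, right_split)


# ------------------------------------------------------------------ model

class ModuleNetwork:
    """Module-network model of expression regulated by radiomic features.

    Parameters
    ----------
    expression : DataFrame, probes x patients
        Typically the paired tumor - normal log2 ratios of the retained
        probes. Centered per probe by default (``center=True``), the
        module-network convention.
    regulators : DataFrame, patients x features
        Normalized to [0, 1] per feature across the cohort.
    K : int
        Initial number of modules; empty modules are pruned from the output.
    max_iter, max_depth, min_leaf : int
        EM iteration cap, tree depth cap and smallest allowed patient
        subgroup.
    prior : ScorePrior
        Normal-gamma hyperparameters of the Bayesian score.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        regulators: pd.DataFrame,
        K: int = 50,
        max_iter: int = 30,
        max_depth: int = 2,
        min_leaf: int = 4,
        prior: ScorePrior | None = None,
        center: bool = True,
    ) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        if list(expression.columns) != list(regulators.index):
            raise ValueError("expression columns must equal regulator rows (patients)")
        reg = regulators.to_numpy(dtype=float)
        if np.isnan(reg).any():
            raise ValueError("regulators contain missing values")
        if reg.min() < 0 or reg.max() > 1:
            raise ValueError("regulators must be normalized to [0, 1]")
        x = expression.to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("expression contains non-finite values")
        if center:
            x = x - x.mean(axis=1, keepdims=True)
        self.expression = pd.DataFrame(x, index=expression.index, columns=expression.columns)
        self.regulators = regulators.astype(float)
        self.K = int(K)
        self.max_iter = int(max_iter)
        self.max_depth = int(max_depth)
        self.min_leaf = int(min_leaf)
        self.prior = prior or ScorePrior()

    # -- internal E-step helpers ------------------------------------------

    def _probe_leaf_stats(self, row: np.ndarray, leaves: list[np.ndarray]) -> list[tuple[float, float, float]]:
        return [
            (float(len(l)), float(row[l].sum()), float((row[l] ** 2).sum())) for l in leaves
        ]

    def _predictive(
        self,
        probe_stats: list[tuple[float, float, float]],
        module_stats: list[tuple[float, float, float]],
    ) -> float:
        """Log posterior-predictive of a probe's leaf values given the module's
        other members (module_stats excludes the probe)."""
        total = 0.0
        for (pn, psx, psxx), (mn, msx, msxx) in zip(probe_stats, module_stats):
            post = _posterior(mn, msx, msxx, self.prior)
            total += _log_marginal_stats(pn, psx, psxx, post)
        return total

    def fit(self, seed: int = 0) -> "ModuleNetworkResults":
        """Run the EM loop and return the fitted results object."""
        x = self.expression.to_numpy(dtype=float)
        n_probes, n_patients = x.shape
        k = min(self.K, n_probes)
        if n_probes > 1 and k > 1:
            km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
            assign = km.fit_predict(x)
        else:
            assign = np.zeros(n_probes, dtype=int)
        assign = assign.astype(int)

        trees: list[RegulatorTree] = [RegulatorTree() for _ in range(self.K)]
        leaves: list[list[np.ndarray]] = [t.leaf_sets(self.regulators) for t in trees]
        log: list[dict] = []
        prev_score = -np.inf
        n_iter = 0
        converged = False

        def module_values(m: int) -> np.ndarray:
            return x[assign == m]

        def total_score() -> float:
            return sum(
                tree_score(module_values(m), trees[m], self.regulators, self.prior)
                for m in range(self.K)
                if np.any(assign == m)
            )

        for it in range(1, self.max_iter + 1):
            n_iter = it
            # M-step: re-learn each nonempty module's tree, keep the better
            for m in range(self.K):
                vals = module_values(m)
                if vals.shape[0] == 0:
                    trees[m] = RegulatorTree()
                    leaves[m] = trees[m].leaf_sets(self.regulators)
                    continue
                new = learn_regulator_tree(vals, self.regulators, self.max_depth,
                                           self.min_leaf, self.prior)
                old_sc = tree_score(vals, trees[m], self.regulators, self.prior)
                new_sc = tree_score(vals, new, self.regulators, self.prior)
                if new_sc > old_sc:
                    trees[m] = new
                leaves[m] = trees[m].leaf_sets(self.regulators)

            # E-step: sequential greedy reassignment by leave-one-out predictive
            mstats: list[list[tuple[float, float, float]]] = []
            for m in range(self.K):
                vals = module_values(m)
                stats = []
                for l in leaves[m]:
                    sub = vals[:, l]
                    stats.append((float(sub.size), float(sub.sum()), float((sub**2).sum())))
                mstats.append(stats)

            n_changed = 0
            for g in range(n_probes):
                row = x[g]
                cur = assign[g]
                probe_stats = {m: self._probe_leaf_stats(row, leaves[m]) for m in range(self.K)}
                # remove g from its module's stats
                mstats[cur] = [
                    (mn - pn, msx - psx, msxx - psxx)
                    for (mn, msx, msxx), (pn, psx, psxx) in zip(mstats[cur], probe_stats[cur])
                ]
                preds = np.array(
                    [self._predictive(probe_stats[m], mstats[m]) for m in range(self.K)]
                )
                # best module; exact ties broken at the lowest module index
                best_m = int(np.flatnonzero(preds >= preds.max() - 1e-12).min())
                if best_m != cur:
                    n_changed += 1
                assign[g] = best_m
                mstats[best_m] = [
                    (mn + pn, msx + psx, msxx + psxx)
                    for (mn, msx, msxx), (pn, psx, psxx) in zip(mstats[best_m], probe_stats[best_m])
                ]

            # merge moves: pooling two modules whose genes share one tree's
            # leaf distributions raises the marginal score (shared parameters
            # explain both); accept only strict improvements, so the total
            # score stays monotone and genuinely distinct modules never merge.
            n_merged = 0
            improved = True
            while improved:
                improved = False
                occupied = [m for m in range(self.K) if np.any(assign == m)]
                part_scores = {
                    m: tree_score(module_values(m), trees[m], self.regulators, self.prior)
                    for m in occupied
                }
                best_gain, best_pair = 1e-9, None
                def merged_candidates(m1: int, m2: int, pooled: np.ndarray):
                    cands = [trees[m1], trees[m2],
                             learn_regulator_tree(pooled, self.regulators,
                                                  self.max_depth, self.min_leaf, self.prior)]
                    scores = [tree_score(pooled, t, self.regulators, self.prior) for t in cands]
                    best = int(np.argmax(scores))
                    return scores[best], cands[best]

                for a_i, m1 in enumerate(occupied):
                    for m2 in occupied[a_i + 1:]:
                        pooled = x[(assign == m1) | (assign == m2)]
                        sc, _ = merged_candidates(m1, m2, pooled)
                        gain = sc - part_scores[m1] - part_scores[m2]
                        if gain > best_gain:
                            best_gain, best_pair = gain, (m1, m2)
                if best_pair is not None:
                    m1, m2 = best_pair
                    pooled = x[(assign == m1) | (assign == m2)]
                    _, best_tree = merged_candidates(m1, m2, pooled)
                    trees[m1] = best_tree
                    leaves[m1] = best_tree.leaf_sets(self.regulators)
                    assign[assign == m2] = m1
                    trees[m2] = RegulatorTree()
                    leaves[m2] = trees[m2].leaf_sets(self.regulators)
                    n_merged += 1
                    improved = True

            score = total_score()
            log.append({"iteration": it, "score": score, "n_reassigned": n_changed,
                        "n_merged": n_merged})
            if score < prev_score - 1e-6 * (1 + abs(prev_score)):
                raise AssertionError(
                    f"Bayesian score decreased at iteration {it}: {prev_score} -> {score}"
                )
            prev_score = score
            if n_changed == 0 and n_merged == 0:
                converged = True
                break

        # prune empty modules and renumber 1..M by first-probe order
        occupied = [m for m in range(self.K) if np.any(assign == m)]
        order = sorted(occupied, key=lambda m: int(np.argmax(assign == m)))
        relabel = {m: i + 1 for i, m in enumerate(order)}
        final_assign = pd.Series(
            [relabel[m] for m in assign], index=self.expression.index, name="module"
        )
        final_trees = {relabel[m]: trees[m] for m in order}
        return ModuleNetworkResults(
            model=self,
            assignment=final_assign,
            trees=final_trees,
            score=prev_score,
            iteration_log=pd.DataFrame(log),
            n_iter=n_iter,
            converged=converged,
            seed=int(seed),
        )


@dataclass
class ModuleNetworkResults:
    """Fitted module network: assignments, regulator trees and diagnostics."""

    model: ModuleNetwork
    assignment: pd.Series  # probe -> module label (1..M)
    trees: dict[int, RegulatorTree]
    score: float
    iteration_log: pd.DataFrame
    n_iter: int
    converged: bool
    seed: int

    @property
    def n_modules(self) -> int:
        return len(self.trees)

    def module_probes(self, module: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    def leaf_patient_ids(self, module: int) -> list[list[str]]:
        reg = self.model.regulators
        return [[str(reg.index[i]) for i in leaf] for leaf in self.trees[module].leaf_sets(reg)]

    def leaf_means(self, module: int) -> list[float]:
        """Posterior-mean expression per leaf (pooled over the module's probes)."""
        x = self.model.expression.loc[self.module_probes(module)].to_numpy()
        out = []
        for leaf in self.trees[module].leaf_sets(self.model.regulators):
            sub = x[:, leaf]
            post = _posterior(sub.size, float(sub.sum()), float((sub**2).sum()), self.model.prior)
            out.append(post.mu0)
        return out

    def module_table(self, feature_ranges: pd.DataFrame | None = None) -> pd.DataFrame:
        """Tabular model view: one row per module with up to three regulators,
        percent thresholds and the bracketed subgroup sizes."""
        rows = []
        reg = self.model.regulators
        for m in sorted(self.trees):
            tree = self.trees[m]
            splits = [tree.root, tree.left, tree.right]
            row: dict[str, object] = {"module": m, "n_probes": int((self.assignment == m).sum())}
            for i, s in enumerate(splits, start=1):
                row[f"regulator{i}"] = s.feature if s else ""
                row[f"threshold{i}_pct"] = threshold_to_percent(s.threshold) if s else ""
            row["group_sizes"] = format_group_sizes(tree.group_sizes(reg))
            rows.append(row)
        return pd.DataFrame(rows).set_index("module")

    def summary(self) -> str:
        sizes = self.assignment.value_counts()
        lines = [
            "Module network results",
            "======================",
            f"Probes: {len(self.assignment)}   Patients: {len(self.model.regulators)}",
            f"Modules: {self.n_modules} (sizes {int(sizes.min())}-{int(sizes.max())}, "
            f"mean {sizes.mean():.1f} +/- {sizes.std(ddof=0):.1f})",
            f"Total Bayesian score: {self.score:.4f}",
            f"Iterations: {self.n_iter} ({'converged' if self.converged else 'max_iter reached'})",
            "",
            self.module_table().to_string(),
        ]
        return "\n".join(lines)

    def to_json(self, path: str | None = None, feature_ranges: pd.DataFrame | None = None) -> str:
        payload = {
            "seed": self.seed,
            "score": self.score,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "prior": vars(self.model.prior),
            "assignment": {str(p): int(m) for p, m in self.assignment.items()},
            "modules": {
                str(m): {
                    "tree": t.to_dict(feature_ranges),
                    "leaf_patients": self.leaf_patient_ids(m),
                    "leaf_means": self.leaf_means(m),
                    "group_sizes": format_group_sizes(t.group_sizes(self.model.regulators)),
                }
                for m, t in self.trees.items()
            },
            "iteration_log": self.iteration_log.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_module_network(
    expression: pd.DataFrame,
    regulators: pd.DataFrame,
    K: int = 50,
    max_iter: int = 30,
    min_leaf: int = 4,
    seed: int = 0,
    prior: ScorePrior | None = None,
    max_depth: int = 2,
) -> ModuleNetworkResults:
    """Convenience wrapper: build a :class:`ModuleNetwork` and fit it."""
    return ModuleNetwork(
        expression, regulators, K=K, max_iter=max_iter, max_depth=max_depth,
        min_leaf=min_leaf, prior=prior,
    ).fit(seed=seed)
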