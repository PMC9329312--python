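"""Random survival forest with log-rank splitting and Nelson-Aalen leaves.

Each tree is grown on a with-replacement bootstrap of the patients.  At every
node, ``mtry`` candidate predictors are drawn uniformly without replacement
and every midpoint between consecutive distinct values of each candidate is
scored with the standardized log-rank statistic; the best (predictor,
threshold) pair splits the node.  Terminal nodes store the Nelson-Aalen
cumulative-hazard estimate of their in-bag members, evaluated on a single
event-time grid shared by the whole forest (the sorted distinct event times of
the training data).  Tied event times follow the Breslow convention both in
the Nelson-Aalen increments and in the hypergeometric log-rank variance.

Ensemble prediction averages the terminal cumulative-hazard functions over
trees; survival is S(t) = exp(-H(t)).  Out-of-bag (OOB) bookkeeping supports
unbiased error estimation, permutation variable importance (VIMP) and minimal
depth.  The scalar risk score used throughout is *ensemble mortality*: the sum
of the (OOB or full) ensemble cumulative hazard over the event-time grid.

All randomness descends from a single seed through ``numpy`` SeedSequence
spawning, so a fit is bit-reproducible and trees are independent given their
seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ForestConfig",
    "HazardCurve",
    "SurvivalTree",
    "SurvivalForest",
    "logrank_split_statistic",
    "nelson_aalen",
    "kaplan_meier",
    "grow_tree",
    "fit_forest",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the survival forest.

    mtry defaults to ceil(sqrt(p)) when left as None.  ``min_node_size`` is
    the smallest node that may still be split; ``min_node_events`` the minimum
    number of in-bag events a node needs before a split is attempted.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 15
    min_node_events: int = 3

    def resolve_mtry(self, n_predictors: int) -> int:
        if self.mtry is not None:
            return max(1, min(self.mtry, n_predictors))
        return max(1, int(np.ceil(np.sqrt(n_predictors))))


# ---------------------------------------------------------------------------
# hazard curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HazardCurve:
    """Cumulative hazard H on a strictly increasing time grid; S = exp(-H)."""

    times: np.ndarray
    chf: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.chf, dtype=float)
        if t.ndim != 1 or h.shape != t.shape:
            raise ValueError("times and chf must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(h < 0) or np.any(np.diff(h) < -1e-12):
            raise ValueError("cumulative hazard must be non-negative and non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "chf", h)

    @property
    def survival(self) -> np.ndarray:
        return np.exp(-self.chf)

    def at(self, t: float) -> float:
        """Right-continuous step-function value H(t); H(t) = 0 before the grid."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.chf[idx])

    def survival_at(self, t: float) -> float:
        return float(np.exp(-self.at(t)))


def nelson_aalen(times: np.ndarray, events: np.ndarray, grid: np.ndarray | None = None) -> HazardCurve:
    """Nelson-Aalen cumulative hazard H(t) = sum_{t_k <= t} d_k / n_k.

    ``grid`` (strictly increasing) evaluates the step function on an external
    time grid; by default the grid is the sample's own distinct event times.
    With no events the curve is identically zero.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    event_times = np.unique(times[events == 1])
    if grid is None:
        grid = event_times if event_times.size else np.array([float(np.max(times))])
    grid = np.asarray(grid, dtype=float)
    increments = np.zeros_like(grid)
    for tk in event_times:
        d_k = int(np.sum((times == tk) & (events == 1)))
        n_k = int(np.sum(times >= tk))
        idx = np.searchsorted(grid, tk)  # event times off-grid fold onto the next grid point
        if idx < grid.size:
            increments[idx] += d_k / n_k
    return HazardCurve(grid, np.cumsum(increments))


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate on the sample's distinct event times.

    Returns ``(event_times, S)`` with S(t_k) = prod_{j<=k} (1 - d_j / n_j).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = np.unique(times[events == 1])
    surv = np.ones_like(event_times, dtype=float)
    s = 1.0
    for i, tk in enumerate(event_times):
        d_k = int(np.sum((times == tk) & (events == 1)))
        n_k = int(np.sum(times >= tk))
        s *= 1.0 - d_k / n_k
        surv[i] = s
    return event_times, surv


# ---------------------------------------------------------------------------
# log-rank split statistic
# ---------------------------------------------------------------------------


def logrank_split_statistic(
    times: np.ndarray, events: np.ndarray, left_membership: np.ndarray
) -> float:
    """Absolute standardized log-rank statistic for a proposed binary split.

    |sum_k (d_{k,L} - d_k Y_{k,L} / Y_k)| / sqrt(sum_k V_k) with the
    hypergeometric variance V_k = (Y_{k,L}/Y_k)(1 - Y_{k,L}/Y_k)
    ((Y_k - d_k)/(Y_k - 1)) d_k.  Zero variance (no events, or a degenerate
    grouping) yields 0 by convention.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    left = np.asarray(left_membership, dtype=bool)
    if not left.any() or left.all():
        raise ValueError("both sides of the split must be non-empty")
    num = 0.0
    var = 0.0
    for tk in np.unique(times[events == 1]):
        at_risk = times >= tk
        d_k = int(np.sum((times == tk) & (events == 1)))
        y_k = int(np.sum(at_risk))
        y_l = int(np.sum(at_risk & left))
        d_l = int(np.sum((times == tk) & (events == 1) & left))
        num += d_l - d_k * y_l / y_k
        if y_k > 1:
            var += (y_l / y_k) * (1 - y_l / y_k) * ((y_k - d_k) / (y_k - 1)) * d_k
    if var <= 0:
        return 0.0
    return abs(num) / np.sqrt(var)


def _best_split_all_thresholds(
    x: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, float]:
    """Best (statistic, threshold) over all midpoint thresholds of predictor x.

    Vectorized over split positions: members sorted by x; prefix cumulative
    at-risk and event counts against the node's distinct event times give the
    log-rank numerator and variance for every candidate split at once.
    Returns (0.0, nan) when no admissible split exists.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ts = times[order]
    es = events[order]
    # candidate split positions: boundaries between distinct consecutive xs
    boundary = np.nonzero(np.diff(xs) > 0)[0]  # left side = xs[: b + 1]
    if boundary.size == 0:
        return 0.0, np.nan
    tk = np.unique(ts[es == 1])
    if tk.size == 0:
        return 0.0, np.nan
    at_risk = ts[:, None] >= tk[None, :]  # (n, K)
    death = (ts[:, None] == tk[None, :]) & (es[:, None] == 1)
    y_left = np.cumsum(at_risk, axis=0)[boundary]  # (B, K)
    d_left = np.cumsum(death, axis=0)[boundary]
    y_k = at_risk.sum(axis=0).astype(float)  # (K,)
    d_k = death.sum(axis=0).astype(float)
    num = (d_left - d_k[None, :] * y_left / y_k[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = y_left / y_k[None, :]
        vterm = frac * (1 - frac) * ((y_k - d_k) / np.maximum(y_k - 1, 1))[None, :] * d_k[None, :]
    var = vterm.sum(axis=1)
    stat = np.where(var > 0, np.abs(num) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    best = int(np.argmax(stat))
    if stat[best] <= 0:
        return 0.0, np.nan
    b = boundary[best]
    threshold = 0.5 * (xs[b] + xs[b + 1])
    return float(stat[best]), float(threshold)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class SurvivalTree:
    """One log-rank-split survival tree in flat array form.

    ``feature[i] == -1`` marks a terminal node; ``leaf_slot`` maps terminal
    nodes to rows of ``leaf_chf``, the Nelson-Aalen cumulative hazards of the
    in-bag members on the forest's shared event-time grid.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    depth: np.ndarray
    leaf_slot: np.ndarray
    leaf_chf: np.ndarray  # (n_leaves, K)
    in_bag_idx: np.ndarray  # bootstrap draw, with multiplicity
    oob_idx: np.ndarray
    first_split_depth: dict[int, int] = field(default_factory=dict)
    max_depth: int = 0

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    @property
    def features_used(self) -> np.ndarray:
        return np.unique(self.feature[self.feature >= 0])

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf-slot index for each row of X (vectorized descent)."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            f = self.feature[node]
            active = f >= 0
            if not active.any():
                break
            rows = np.nonzero(active)[0]
            nd = node[rows]
            go_left = X[rows, self.feature[nd]] <= self.threshold[nd]
            node[rows] = np.where(go_left, self.left[nd], self.right[nd])
        return self.leaf_slot[node]

    def predict_chf(self, X: np.ndarray) -> np.ndarray:
        return self.leaf_chf[self.apply(X)]


def grow_tree(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    config: ForestConfig,
    rng: np.random.Generator,
    grid: np.ndarray,
    in_bag_idx: np.ndarray | None = None,
    oob_idx: np.ndarray | None = None,
) -> SurvivalTree:
    """Grow one survival tree on (already bootstrapped) member rows.

    ``in_bag_idx``/``oob_idx`` are bookkeeping only; X, times, events are the
    in-bag sample (with bootstrap multiplicity materialized as repeated rows).
    Tie-breaking between equal-statistic splits is by first encounter in the
    seeded random candidate order, so growth is deterministic given the rng.
    """
    n, p = X.shape
    mtry = config.resolve_mtry(p)

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    depth: list[int] = []
    leaf_slot: list[int] = []
    leaf_curves: list[np.ndarray] = []
    first_split_depth: dict[int, int] = {}

    def new_node(d: int) -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        depth.append(d)
        leaf_slot.append(-1)
        return len(feature) - 1

    def make_leaf(node_id: int, members: np.ndarray) -> None:
        curve = nelson_aalen(times[members], events[members], grid=grid)
        leaf_slot[node_id] = len(leaf_curves)
        leaf_curves.append(curve.chf)

    root = new_node(0)
    stack: list[tuple[int, np.ndarray]] = [(root, np.arange(n))]
    while stack:
        node_id, members = stack.pop()
        d = depth[node_id]
        t_m = times[members]
        e_m = events[members]
        if (
            members.size < config.min_node_size
            or int(e_m.sum()) < config.min_node_events
        ):
            make_leaf(node_id, members)
            continue
        candidates = rng.choice(p, size=mtry, replace=False)
        best_stat, best_feat, best_thr = 0.0, -1, np.nan
        for f in candidates:
            stat, thr = _best_split_all_thresholds(X[members, f], t_m, e_m)
            if stat > best_stat:  # strict: first encountered equal stat wins
                best_stat, best_feat, best_thr = stat, int(f), thr
        if best_feat < 0:
            make_leaf(node_id, members)
            continue
        go_left = X[members, best_feat] <= best_thr
        feature[node_id] = best_feat
        threshold[node_id] = best_thr
        if best_feat not in first_split_depth or d < first_split_depth[best_feat]:
            first_split_depth[best_feat] = d
        lid = new_node(d + 1)
        rid = new_node(d + 1)
        left[node_id] = lid
        right[node_id] = rid
        stack.append((lid, members[go_left]))
        stack.append((rid, members[~go_left]))

    return SurvivalTree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        depth=np.asarray(depth, dtype=np.int64),
        leaf_slot=np.asarray(leaf_slot, dtype=np.int64),
        leaf_chf=np.asarray(leaf_curves, dtype=float),
        in_bag_idx=np.asarray(in_bag_idx if in_bag_idx is not None else np.arange(n)),
        oob_idx=np.asarray(oob_idx if oob_idx is not None else [], dtype=np.int64),
        first_split_depth=first_split_depth,
        max_depth=int(max(depth)),
    )


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------


@dataclass
class SurvivalForest:
    """Bootstrap ensemble of survival trees on a shared event-time grid."""

    trees: list[SurvivalTree]
    grid: np.ndarray
    predictor_names: list[str]
    config: ForestConfig
    seed: int
    X_train: np.ndarray
    times_train: np.ndarray
    events_train: np.ndarray

    # -- prediction ---------------------------------------------------------

    def predict_chf(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Ensemble cumulative hazard, rows x grid; mean over trees."""
        X = self._as_array(X)
        if not np.isfinite(X).all():
            raise ValueError("feature rows contain missing or non-finite values")
        acc = np.zeros((X.shape[0], self.grid.size))
        for tree in self.trees:
            acc += tree.predict_chf(X)
        return acc / len(self.trees)

    def predict_survival(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        return np.exp(-self.predict_chf(X))

    def predict_curve(self, feature_row: np.ndarray | pd.Series) -> HazardCurve:
        row = np.asarray(feature_row, dtype=float).reshape(1, -1)
        return HazardCurve(self.grid, self.predict_chf(row)[0])

    def predict_mortality(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Ensemble mortality: CHF summed over the event-time grid (risk score)."""
        return self.predict_chf(X).sum(axis=1)

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != len(self.predictor_names):
            raise ValueError(
                f"expected {len(self.predictor_names)} predictors, got {X.shape[1]}"
            )
        return X

    # -- OOB machinery ------------------------------------------------------

    def _oob_chf_sums(self) -> tuple[np.ndarray, np.ndarray]:
        """Summed (not yet averaged) OOB CHF per training row, plus tree counts."""
        n = self.X_train.shape[0]
        sums = np.zeros((n, self.grid.size))
        counts = np.zeros(n)
        for tree in self.trees:
            if tree.oob_idx.size == 0:
                continue
            sums[tree.oob_idx] += tree.predict_chf(self.X_train[tree.oob_idx])
            counts[tree.oob_idx] += 1
        return sums, counts

    def oob_mortality(self) -> np.ndarray:
        """OOB ensemble mortality per training row; NaN if never out-of-bag."""
        sums, counts = self._oob_chf_sums()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums.sum(axis=1) / counts, np.nan)

    def oob_concordance(self) -> float:
        """Harrell's C of the OOB mortality risk against the training outcome."""
        from .evaluate import harrell_c

        risk = self.oob_mortality()
        keep = ~np.isnan(risk)
        return harrell_c(self.times_train[keep], self.events_train[keep], risk[keep])

    def oob_error(self) -> float:
        """OOB prediction error, 1 - Harrell's C."""
        return 1.0 - self.oob_concordance()

    # -- variable importance ------------------------------------------------

    def permutation_vimp(
        self,
        predictor: int | str,
        rng: np.random.Generator | None = None,
        repeats: int = 1,
        seed: int | None = None,
    ) -> float:
        """Permutation VIMP of one predictor.

        The predictor's OOB values are permuted within each tree's OOB set,
        OOB mortality recomputed, and the increase in OOB error (1 - C)
        over the unpermuted baseline returned (averaged over ``repeats``).
        Trees that never split on the predictor contribute their baseline
        predictions unchanged, so an entirely unused predictor scores 0.
        """
        return self.permutation_vimp_all(
            predictors=[predictor], rng=rng, repeats=repeats, seed=seed
        )[0]

    def permutation_vimp_all(
        self,
        predictors: Sequence[int | str] | None = None,
        rng: np.random.Generator | None = None,
        repeats: int = 1,
        seed: int | None = None,
    ) -> np.ndarray:
        """Permutation VIMP for many predictors, sharing baseline bookkeeping."""
        from .evaluate import harrell_c

        if rng is None:
            rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        idxs = [self._predictor_index(p) for p in (
            predictors if predictors is not None else range(len(self.predictor_names))
        )]
        base_sums, counts = self._oob_chf_sums()
        keep = counts > 0
        t_keep = self.times_train[keep]
        e_keep = self.events_train[keep]
        base_risk = (base_sums.sum(axis=1) / np.where(counts > 0, counts, 1))[keep]
        base_err = 1.0 - harrell_c(t_keep, e_keep, base_risk)
        # per-tree baseline OOB contributions, only for trees using a predictor
        tree_uses = [set(tree.features_used.tolist()) for tree in self.trees]
        base_contrib: dict[int, np.ndarray] = {}
        wanted = set(idxs)
        for ti, tree in enumerate(self.trees):
            if tree.oob_idx.size and (tree_uses[ti] & wanted):
                base_contrib[ti] = tree.predict_chf(self.X_train[tree.oob_idx])
        out = np.zeros(len(idxs))
        for j, pidx in enumerate(idxs):
            using = [ti for ti in range(len(self.trees)) if pidx in tree_uses[ti]]
            if not using:
                out[j] = 0.0
                continue
            acc = 0.0
            for _ in range(repeats):
                sums = base_sums.copy()
                for ti in using:
                    tree = self.trees[ti]
                    if tree.oob_idx.size == 0:
                        continue
                    Xp = self.X_train[tree.oob_idx].copy()
                    Xp[:, pidx] = Xp[rng.permutation(Xp.shape[0]), pidx]
                    sums[tree.oob_idx] += tree.predict_chf(Xp) - base_contrib[ti]
                risk = (sums.sum(axis=1) / np.where(counts > 0, counts, 1))[keep]
                acc += (1.0 - harrell_c(t_keep, e_keep, risk)) - base_err
            out[j] = acc / repeats
        return out

    def minimal_depth(self, predictor: int | str) -> float:
        """Average depth of the predictor's first split across trees.

        Trees never splitting on the predictor contribute their own maximal
        depth + 1, so unused predictors attain the largest possible value.
        """
        pidx = self._predictor_index(predictor)
        vals = [
            tree.first_split_depth.get(pidx, tree.max_depth + 1)
            for tree in self.trees
        ]
        return float(np.mean(vals))

    def minimal_depth_all(self) -> np.ndarray:
        p = len(self.predictor_names)
        acc = np.zeros(p)
        for tree in self.trees:
            vals = np.full(p, tree.max_depth + 1, dtype=float)
            for f, d in tree.first_split_depth.items():
                vals[f] = d
            acc += vals
        return acc / len(self.trees)

    def _predictor_index(self, predictor: int | str) -> int:
        if isinstance(predictor, str):
            try:
                return self.predictor_names.index(predictor)
            except ValueError:
                raise KeyError(f"unknown predictor {predictor!r}") from None
        if not 0 <= predictor < len(self.predictor_names):
            raise KeyError(f"predictor index {predictor} out of range")
        return int(predictor)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Serialize the fitted forest to a single versioned JSON file."""
        payload = {
            "schema": "kinotox.forest/1",
            "seed": self.seed,
            "config": {
                "n_trees": self.config.n_trees,
                "mtry": self.config.mtry,
                "min_node_size": self.config.min_node_size,
                "min_node_events": self.config.min_node_events,
            },
            "grid": self.grid.tolist(),
            "predictor_names": self.predictor_names,
            "X_train": self.X_train.tolist(),
            "times_train": self.times_train.tolist(),
            "events_train": self.events_train.tolist(),
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": [None if np.isnan(x) else x for x in t.threshold],
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "depth": t.depth.tolist(),
                    "leaf_slot": t.leaf_slot.tolist(),
                    "leaf_chf": t.leaf_chf.tolist(),
                    "in_bag_idx": t.in_bag_idx.tolist(),
                    "oob_idx": t.oob_idx.tolist(),
                    "first_split_depth": {str(k): v for k, v in t.first_split_depth.items()},
                    "max_depth": t.max_depth,
                }
                for t in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurvivalForest":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != "kinotox.forest/1":
            raise ValueError("unrecognized forest schema")
        cfg = ForestConfig(**payload["config"])
        trees = [
            SurvivalTree(
                feature=np.asarray(t["feature"], dtype=np.int64),
                threshold=np.asarray(
                    [np.nan if x is None else x for x in t["threshold"]], dtype=float
                ),
                left=np.asarray(t["left"], dtype=np.int64),
                right=np.asarray(t["right"], dtype=np.int64),
                depth=np.asarray(t["depth"], dtype=np.int64),
                leaf_slot=np.asarray(t["leaf_slot"], dtype=np.int64),
                leaf_chf=np.asarray(t["leaf_chf"], dtype=float),
                in_bag_idx=np.asarray(t["in_bag_idx"], dtype=np.int64),
                oob_idx=np.asarray(t["oob_idx"], dtype=np.int64),
                first_split_depth={int(k): v for k, v in t["first_split_depth"].items()},
                max_depth=int(t["max_depth"]),
            )
            for t in payload["trees"]
        ]
        return cls(
            trees=trees,
            grid=np.asarray(payload["grid"], dtype=float),
            predictor_names=list(payload["predictor_names"]),
            config=cfg,
            seed=int(payload["seed"]),
            X_train=np.asarray(payload["X_train"], dtype=float),
            times_train=np.asarray(payload["times_train"], dtype=float),
            events_train=np.asarray(payload["events_train"], dtype=np.int64),
        )


def fit_forest(
    features: pd.DataFrame | np.ndarray,
    times: np.ndarray | Sequence[float],
    events: np.ndarray | Sequence[int],
    config: ForestConfig | None = None,
    seed: int = 0,
) -> SurvivalForest:
    """Fit a random survival forest.

    Each tree is grown on an n-out-of-n bootstrap WITH replacement; rows never
    drawn form the tree's out-of-bag set.  The shared event-time grid is the
    sorted distinct event times of the training sample.  Refuses to fit when
    the outcome has no events.
    """
    config = config or ForestConfig()
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=np.int64)
    n = X.shape[0]
    if times.shape != (n,) or events.shape != (n,):
        raise ValueError("times/events must align with feature rows")
    if events.sum() == 0:
        raise ValueError(
            "outcome has zero events; a survival forest cannot be fitted on an "
            "all-censored sample"
        )
    grid = np.unique(times[events == 1])
    ss = np.random.SeedSequence(seed)
    trees: list[SurvivalTree] = []
    for child in ss.spawn(config.n_trees):
        rng = np.random.default_rng(child)
        in_bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        trees.append(
            grow_tree(
                X[in_bag],
                times[in_bag],
                events[in_bag],
                config,
                rng,
                grid,
                in_bag_idx=in_bag,
                oob_idx=oob,
            )
        )
    return SurvivalForest(
        trees=trees,
        grid=grid,
        predictor_names=names,
        config=config,
        seed=seed,
        X_train=X,
        times_train=times,
        events_train=events,
    )
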