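"""Connectome-based predictive modeling (CPM).

Predicts a behavioral score from functional-connectivity edges: within each
leave-one-out fold, edges whose Pearson correlation with behavior passes the
selection threshold (p < alpha, default 0.01) form positive and negative
masks; per-subject mask strengths (sums of edge weights) plus a head-motion
covariate enter an OLS model fitted on the training subjects and evaluated on
the held-out subject.  Prediction quality is the Spearman correlation of
predicted vs observed scores; inference uses a permutation test that reruns
the whole cross-validated pipeline under shuffled behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = ["EdgeMask", "CPM", "CPMResults", "select_edges", "strength",
           "summarize_network", "upper_tri_edges"]

SYMMETRY_TOL = 1e-6


def upper_tri_edges(n_nodes: int) -> list[tuple[int, int]]:
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


@dataclass(frozen=True)
class EdgeMask:
    """A signed set of unordered node pairs (strict upper triangle)."""

    sign: str  # "positive" or "negative"
    edges: frozenset[tuple[int, int]]

    def __post_init__(self):
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        for i, j in self.edges:
            if not i < j:
                raise ValueError(f"edge ({i},{j}) not in strict upper triangle")

    def __len__(self) -> int:
        return len(self.edges)


def _extract_edge_matrix(matrices: Sequence[np.ndarray]) -> tuple[np.ndarray, int]:
    """Stack upper-triangle edge vectors; symmetrize by averaging when the
    asymmetry is within tolerance, reject otherwise."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    n_nodes = mats[0].shape[0]
    rows = []
    for k, m in enumerate(mats):
        if m.shape != (n_nodes, n_nodes):
            raise DataError(f"matrix {k} has shape {m.shape}, expected "
                            f"({n_nodes}, {n_nodes})")
        asym = np.max(np.abs(m - m.T))
        if asym > SYMMETRY_TOL:
            raise DataError(f"matrix {k} asymmetric beyond tolerance "
                            f"({asym:.2e})")
        m = 0.5 * (m + m.T)
        iu = np.triu_indices(n_nodes, k=1)
        rows.append(m[iu])
    return np.vstack(rows), n_nodes


def _corr_with(Ec: np.ndarray, enorm: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of pre-centered edge columns with a behavior vector."""
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise DataError("behavior is constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ec.T @ yc) / (enorm * ynorm)
    r[~np.isfinite(r)] = 0.0  # constant edges: skipped
    return r


def _r_crit(n: int, alpha: float) -> float:
    """Critical |r| equivalent to a two-sided p < alpha at n-2 df."""
    df = n - 2
    t = stats.t.isf(alpha / 2.0, df)
    return t / np.sqrt(df + t * t)


def select_edges(matrices: Sequence[np.ndarray], behavior: np.ndarray,
                 alpha: float = 0.01) -> tuple[EdgeMask, EdgeMask]:
    """Correlate every upper-triangle edge with behavior; edges with p < alpha
    enter the mask matching the correlation sign."""
    behavior = np.asarray(behavior, dtype=float)
    if len(matrices) < 4:
        raise DataError("edge selection needs >= 4 subjects")
    if np.ptp(behavior) == 0:
        raise DataError("behavior is constant")
    E, n_nodes = _extract_edge_matrix(matrices)
    Ec = E - E.mean(axis=0)
    enorm = np.linalg.norm(Ec, axis=0)
    r = _corr_with(Ec, enorm, behavior)
    crit = _r_crit(len(matrices), alpha)
    edges = upper_tri_edges(n_nodes)
    pos = frozenset(e for e, ri in zip(edges, r) if ri > crit)
    neg = frozenset(e for e, ri in zip(edges, r) if ri < -crit)
    return EdgeMask("positive", pos), EdgeMask("negative", neg)


def strength(matrix: np.ndarray, mask: EdgeMask) -> float:
    """Sum of edge weights over the mask, each unordered pair counted once."""
    m = np.asarray(matrix, dtype=float)
    if len(mask) == 0:
        warnings.warn("empty mask: strength is 0")
        return 0.0
    for i, j in mask.edges:
        if j >= m.shape[0]:
            raise DataError(f"mask edge ({i},{j}) outside matrix")
    return float(sum(m[i, j] for i, j in mask.edges))


@dataclass
class CPMResults:
    """Cross-validated predictions plus masks and fold models."""

    predicted: np.ndarray
    observed: np.ndarray
    rho: float
    p_parametric: float
    pos_mask: EdgeMask
    neg_mask: EdgeMask
    fold_models: list[dict]
    empty_folds: list[int]
    alpha: float
    p_permutation: float | None = None
    _model: "CPM | None" = field(default=None, repr=False)

    def permutation_test(self, n_perm: int = 1000, seed: int | None = None) -> float:
        """Permutation p-value for the predicted-observed Spearman rho.

        Behavior is shuffled across subjects and the full leave-one-out
        pipeline rerun per permutation; p = (1 + #{null rho >= observed}) /
        (n_perm + 1).
        """
        if self._model is None:
            raise RuntimeError("results are detached from their model")
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(self._model.behavior)
            pred = self._model._loo_predict(yp, want_masks=False)[0]
            null_rho = _spearman(pred, yp)
            if null_rho >= self.rho:
                count += 1
        self.p_permutation = (1 + count) / (n_perm + 1)
        return self.p_permutation

    def summary(self) -> str:
        lines = [
            "Connectome-based predictive model (leave-one-out CV)",
            f"  subjects: {len(self.observed)}   edge-selection alpha: {self.alpha}",
            f"  Spearman rho (predicted vs observed): {self.rho:.3f} "
            f"(parametric p = {self.p_parametric:.4g})",
            f"  final positive mask: {len(self.pos_mask)} edge(s); "
            f"final negative mask: {len(self.neg_mask)} edge(s)",
        ]
        if self.p_permutation is not None:
            lines.append(f"  permutation p = {self.p_permutation:.4g}")
        if self.empty_folds:
            lines.append(f"  folds with both masks empty: {self.empty_folds}")
        return "\n".join(lines)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.linalg.norm(ra) * np.linalg.norm(rb)
    return float(ra @ rb / denom) if denom > 0 else 0.0


class CPM:
    """Connectome-based predictive model.

    Parameters
    ----------
    matrices : sequence of (n_nodes, n_nodes) arrays, or bundles with a
        ``matrix`` attribute.
    behavior : per-subject score to predict.
    motion : per-subject nuisance covariate (mean framewise displacement);
        optional.
    node_labels : node -> network-name mapping used by network summaries.
    alpha : edge-selection threshold (per-edge correlation p-value).
    """

    def __init__(self, matrices, behavior, motion=None, node_labels=None,
                 alpha: float = 0.01):
        mats = [getattr(m, "matrix", m) for m in matrices]
        if motion is None and all(hasattr(m, "motion") for m in matrices):
            motion = [m.motion for m in matrices]
        if node_labels is None and hasattr(matrices[0], "node_labels"):
            node_labels = matrices[0].node_labels
        self.E, self.n_nodes = _extract_edge_matrix(mats)
        self.behavior = np.asarray(behavior, dtype=float)
        n = len(self.behavior)
        if self.E.shape[0] != n:
            raise DataError("behavior length does not match subject count")
        if n < 10:
            raise DataError("leave-one-out CPM needs >= 10 subjects")
        self.motion = (np.asarray(motion, dtype=float) if motion is not None
                       else None)
        if self.motion is not None and len(self.motion) != n:
            raise DataError("motion length does not match subject count")
        self.node_labels = dict(node_labels) if node_labels is not None else None
        self.alpha = float(alpha)
        self.edges = upper_tri_edges(self.n_nodes)
        self._folds = self._prepare_folds()

    # -- fold workspace -----------------------------------------------------
    #
    # Leave-one-out statistics are derived from full-cohort column sums, so
    # each fold costs two matrix-vector products over E instead of a centered
    # copy of the training matrix (which would be prohibitive at atlas scale).

    def _prepare_folds(self) -> list[dict]:
        n = len(self.behavior)
        S = self.E.sum(axis=0)
        Q = (self.E ** 2).sum(axis=0)
        folds = []
        for held in range(n):
            mean_f = (S - self.E[held]) / (n - 1)
            ss = Q - self.E[held] ** 2 - (n - 1) * mean_f ** 2
            enorm = np.sqrt(np.clip(ss, 0.0, None))
            folds.append(dict(held=held, enorm=enorm))
        return folds

    def _loo_predict(self, y: np.ndarray, want_masks: bool = True):
        n = len(y)
        crit = _r_crit(n - 1, self.alpha)
        predicted = np.empty(n)
        masks: list[tuple[np.ndarray, np.ndarray]] = []
        fold_models: list[dict] = []
        empty_folds: list[int] = []
        y_sum = y.sum()
        for f in self._folds:
            held = f["held"]
            y_mean = (y_sum - y[held]) / (n - 1)
            w = y - y_mean
            w[held] = 0.0          # E.T @ w then sums over the training fold
            ynorm = np.linalg.norm(w)
            if ynorm == 0:
                raise DataError("behavior constant within a training fold")
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (self.E.T @ w) / (f["enorm"] * ynorm)
            r[~np.isfinite(r)] = 0.0
            sel_pos = r > crit
            sel_neg = r < -crit
            train = np.arange(n) != held
            cols = [np.ones(n - 1)]
            test_cols = [1.0]
            if sel_pos.any() or sel_neg.any():
                sp = self.E @ sel_pos
                sn = self.E @ sel_neg
                cols += [sp[train], sn[train]]
                test_cols += [float(sp[held]), float(sn[held])]
            else:
                empty_folds.append(held)
            if self.motion is not None:
                cols.append(self.motion[train])
                test_cols.append(float(self.motion[held]))
            D = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(D, y[train], rcond=None)
            predicted[held] = float(np.asarray(test_cols) @ coef)
            if want_masks:
                masks.append((sel_pos, sel_neg))
                fold_models.append(dict(held=held, coef=coef,
                                        n_pos=int(sel_pos.sum()),
                                        n_neg=int(sel_neg.sum())))
        return predicted, masks, fold_models, empty_folds

    # -- public API -----------------------------------------------------------

    def fit(self) -> CPMResults:
        """Run leave-one-out cross-validation and score the predictions."""
        y = self.behavior
        if np.ptp(y) == 0:
            raise DataError("behavior is constant")
        predicted, masks, fold_models, empty = self._loo_predict(y)
        rho, p = stats.spearmanr(predicted, y)
        pos_all = np.logical_and.reduce([m[0] for m in masks])
        neg_all = np.logical_and.reduce([m[1] for m in masks])
        pos_mask = EdgeMask("positive", frozenset(
            e for e, s in zip(self.edges, pos_all) if s))
        neg_mask = EdgeMask("negative", frozenset(
            e for e, s in zip(self.edges, neg_all) if s))
        return CPMResults(predicted=predicted, observed=y.copy(),
                          rho=float(rho), p_parametric=float(p),
                          pos_mask=pos_mask, neg_mask=neg_mask,
                          fold_models=fold_models, empty_folds=empty,
                          alpha=self.alpha, _model=self)


def summarize_network(mask: EdgeMask, node_labels: Mapping[int, str]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node degrees and network-pair composition of a predictive mask.

    Returns ``(degrees, network_pairs)``: per-node degree (only nodes with at
    least one mask edge), and a symmetric network-by-network frame of edge
    counts with the percentage each unordered network pair contributes to the
    mask.
    """
    degrees: dict[int, int] = {}
    for i, j in mask.edges:
        for node in (i, j):
            if node not in node_labels:
                raise DataError(f"node {node} has no network label")
            degrees[node] = degrees.get(node, 0) + 1
    deg = pd.DataFrame(sorted(degrees.items()),
                       columns=["node", "degree"]) if degrees else \
        pd.DataFrame(columns=["node", "degree"])
    if len(deg):
        deg["network"] = deg["node"].map(node_labels)

    networks = sorted(set(node_labels.values()))
    counts = pd.DataFrame(0, index=networks, columns=networks, dtype=int)
    for i, j in mask.edges:
        a, b = sorted((node_labels[i], node_labels[j]))
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    total = len(mask)
    pct = pd.DataFrame(0.0, index=networks, columns=networks)
    if total:
        for a in networks:
            for b in networks:
                # percentage of the unordered pair; diagonal counted once
                pct.loc[a, b] = 100.0 * counts.loc[a, b] / total
    pairs = counts.copy()
    pairs.attrs["percentage"] = pct
    pairs.attrs["n_links"] = total
    pairs.attrs["n_nodes"] = len(degrees)
    return deg, pairs
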