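"""Connectome-based predictive modeling (CPM).

The model has three stages.  Feature selection: every edge is correlated
(Pearson) with the behavioral change score across training subjects, and
edges with two-sided p below ``alpha_edge`` (default .01) are split into a
positive and a negative set by the sign of r.  Model construction: the
selected edge strengths are summed into a single network-strength scalar
per subject and an ordinary least-squares line y ~ strength is fitted.
Model evaluation: leave-one-out cross-validation (LOOCV) repeats selection
and fitting with one subject held out, predicts that subject, and scores
the full prediction vector against the observed scores with a Spearman
correlation; significance comes from permuting the behavioral scores and
re-running the entire LOOCV per permutation.

Edges selected in at least half the LOOCV folds form the "robust" network,
which can be cross-tabulated against canonical functional networks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import AtlasLabels, ConnectomeError, EdgeIndexMap

__all__ = [
    "EdgeBehaviorCorrelation",
    "EdgeMasks",
    "CPMFold",
    "CPMResult",
    "PermutationResult",
    "RobustNetwork",
    "correlate_edges",
    "select_edges",
    "network_strength",
    "run_loocv",
    "evaluate_spearman",
    "permutation_test",
    "robust_edges",
    "overlap_with_networks",
    "save_cpm_bundle",
]

logger = logging.getLogger(__name__)

Tail = Literal["positive", "negative"]

#: edge-selection significance threshold (two-sided, per edge)
DEFAULT_ALPHA_EDGE = 0.01
#: permutation count used for inference at full scale
DEFAULT_PERMUTATIONS = 5000
#: an edge is robust if selected in at least this fraction of LOOCV folds
DEFAULT_ROBUST_THRESHOLD = 0.5

_TINY_P = np.finfo(float).tiny


@dataclass
class EdgeBehaviorCorrelation:
    """Per-edge Pearson r with behavior and its two-sided p (t transform)."""

    r: np.ndarray
    p: np.ndarray
    n: int


@dataclass
class EdgeMasks:
    """Linear edge indices of the positive- and negative-tail selections."""

    positive: np.ndarray
    negative: np.ndarray

    def for_tail(self, tail: Tail) -> np.ndarray:
        return self.positive if tail == "positive" else self.negative


@dataclass
class CPMFold:
    held_out: int                 # subject position in the cohort
    mask: np.ndarray              # edges selected on the training subjects
    slope: float
    intercept: float
    prediction: float
    empty_mask: bool              # no edge passed selection; mean fallback used


@dataclass
class CPMResult:
    tail: Tail
    observed: np.ndarray
    predicted: np.ndarray
    rho: float
    p_parametric: float
    selection_frequency: np.ndarray   # per edge, fraction of folds
    folds: list[CPMFold] = field(default_factory=list)
    alpha_edge: float = DEFAULT_ALPHA_EDGE

    @property
    def n_subjects(self) -> int:
        return self.observed.size


@dataclass
class PermutationResult:
    b: int
    observed_rho: float
    count_ge: int                 # permuted rho >= observed rho
    p_value: float
    permuted_rho: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class RobustNetwork:
    tail: Tail
    edges: np.ndarray             # linear edge indices
    frequencies: np.ndarray       # selection frequency of each robust edge
    threshold: float = DEFAULT_ROBUST_THRESHOLD


def _validate_xy(x: np.ndarray, y: np.ndarray, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2:
        raise ValueError("edge matrix must be 2-D (subjects x edges)")
    if y.shape != (x.shape[0],):
        raise ValueError("behavior vector length must equal number of subjects")
    if x.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} subjects, got {x.shape[0]}")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("edge matrix and behavior must be finite (no NaN/inf)")
    if np.ptp(y) == 0:
        raise ValueError("behavior vector is constant")
    return x, y


def correlate_edges(edges: np.ndarray, y: np.ndarray) -> EdgeBehaviorCorrelation:
    """Pearson r and two-sided p of every edge against the behavior score.

    p comes from the exact t transform ``t = r * sqrt((n-2)/(1-r^2))`` with
    n - 2 degrees of freedom.  A zero-variance edge cannot carry a
    correlation; it is assigned r = 0, p = 1 with a logged warning rather
    than an error, because label permutations can create degenerate folds.
    """
    x, y = _validate_xy(edges, y, min_n=4)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    syy = yc @ yc
    sxy = xc.T @ yc
    dead = sxx <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    if dead.any():
        k = int(dead.sum())
        warnings.warn(f"{k} zero-variance edge(s) assigned r=0, p=1", RuntimeWarning)
        r[dead] = 0.0
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, _TINY_P, 1.0)
    p[dead] = 1.0
    return EdgeBehaviorCorrelation(r=r, p=p, n=n)


def select_edges(
    corr: EdgeBehaviorCorrelation, alpha_edge: float = DEFAULT_ALPHA_EDGE
) -> EdgeMasks:
    """Split edges with p < alpha_edge into positive/negative sets by sign of r."""
    pos = np.flatnonzero((corr.p < alpha_edge) & (corr.r > 0))
    neg = np.flatnonzero((corr.p < alpha_edge) & (corr.r < 0))
    return EdgeMasks(positive=pos, negative=neg)


def network_strength(edges: np.ndarray, mask: np.ndarray) -> float | np.ndarray:
    """Sum of edge strengths over a mask; an empty mask sums to 0.

    ``edges`` may be a single subject's edge vector or a subjects x edges
    matrix (then one strength per subject is returned).
    """
    edges = np.asarray(edges, dtype=float)
    mask = np.asarray(mask, dtype=np.int64)
    if mask.size and (mask.min() < 0 or mask.max() >= edges.shape[-1]):
        raise ValueError("mask contains out-of-range edge indices")
    if edges.ndim == 1:
        return float(edges[mask].sum())
    return edges[:, mask].sum(axis=1)


def _r_critical(alpha_edge: float, df: int) -> float:
    """|r| threshold equivalent to two-sided p < alpha at df degrees of freedom."""
    tcrit = stats.t.isf(alpha_edge / 2.0, df)
    return float(tcrit / np.sqrt(tcrit * tcrit + df))


def _loocv(
    x: np.ndarray,
    y: np.ndarray,
    alpha_edge: float,
    tail: Tail,
    collect_folds: bool,
) -> tuple[np.ndarray, np.ndarray, list[CPMFold]]:
    """One full LOOCV pass: per-fold selection, OLS fit, held-out prediction.

    Selection at two-sided p < alpha is applied as |r| > r_crit, the exact
    inverse of the t transform at the fold's degrees of freedom.  When fold
    records are collected (a single analysis run) every fold recomputes its
    statistics directly on the n-1 training subjects, so a held-out
    subject's prediction is bit-for-bit independent of its own score.  The
    permutation path instead downdates cohort-level sums (algebraically
    identical, one order of magnitude faster).
    """
    if collect_folds:
        return _loocv_exact(x, y, alpha_edge, tail)
    n, n_edges = x.shape
    m = n - 1                       # training-set size, identical in every fold
    if m < 4:
        raise ValueError("need at least 5 subjects for LOOCV")
    rcrit = _r_critical(alpha_edge, m - 2)
    s_x = x.sum(axis=0)
    s_xx = np.einsum("ij,ij->j", x, x)
    t_xy = x.T @ y
    s_y = float(y.sum())
    s_yy = float(y @ y)

    preds = np.empty(n)
    counts = np.zeros(n_edges)
    folds: list[CPMFold] = []
    for i in range(n):
        xi = x[i]
        yi = y[i]
        sx = s_x - xi
        sxx = s_xx - xi * xi
        sy = s_y - yi
        syy = s_yy - yi * yi
        sxy = t_xy - xi * yi
        train_mean = sy / m
        vary = m * syy - sy * sy
        if vary <= 0:               # training y constant (only possible under permutation)
            preds[i] = train_mean
            if collect_folds:
                folds.append(CPMFold(i, np.empty(0, np.int64), np.nan, np.nan, train_mean, True))
            continue
        num = m * sxy - sx * sy
        varx = np.maximum(m * sxx - sx * sx, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / np.sqrt(varx * vary)
        r[varx <= 0] = 0.0          # zero-variance edges never selected
        if tail == "positive":
            mask = np.flatnonzero(r > rcrit)
        else:
            mask = np.flatnonzero(r < -rcrit)
        counts[mask] += 1

        if mask.size == 0:
            preds[i] = train_mean
            slope = intercept = np.nan
            empty = True
        else:
            s = x[:, mask].sum(axis=1)
            s_i = float(s[i])
            ssum = float(s.sum()) - s_i
            ssq = float(s @ s) - s_i * s_i
            scov = float(s @ y) - s_i * yi
            denom = m * ssq - ssum * ssum
            if denom <= 0:          # constant strengths; fall back to the mean
                preds[i] = train_mean
                slope = intercept = np.nan
                empty = True
            else:
                slope = (m * scov - ssum * sy) / denom
                intercept = (sy - slope * ssum) / m
                preds[i] = intercept + slope * s_i
                empty = False
        if collect_folds:
            folds.append(CPMFold(i, mask, slope, intercept, float(preds[i]), empty))
    return preds, counts / n, folds


def _loocv_exact(
    x: np.ndarray, y: np.ndarray, alpha_edge: float, tail: Tail
) -> tuple[np.ndarray, np.ndarray, list[CPMFold]]:
    """Fold-record LOOCV: per-fold statistics computed on the training
    subset itself (see :func:`_loocv`)."""
    n, n_edges = x.shape
    m = n - 1
    if m < 4:
        raise ValueError("need at least 5 subjects for LOOCV")
    rcrit = _r_critical(alpha_edge, m - 2)
    preds = np.empty(n)
    counts = np.zeros(n_edges)
    folds: list[CPMFold] = []
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        xt = x[keep]
        yt = y[keep]
        keep[i] = True
        train_mean = float(yt.mean())
        yc = yt - train_mean
        vary = float(yc @ yc)
        if vary <= 0:
            preds[i] = train_mean
            folds.append(CPMFold(i, np.empty(0, np.int64), np.nan, np.nan, train_mean, True))
            continue
        xc = xt - xt.mean(axis=0)
        varx = np.einsum("ij,ij->j", xc, xc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc.T @ yc) / np.sqrt(varx * vary)
        r[varx <= 0] = 0.0
        mask = np.flatnonzero(r > rcrit if tail == "positive" else r < -rcrit)
        counts[mask] += 1
        if mask.size == 0:
            preds[i] = train_mean
            folds.append(CPMFold(i, mask, np.nan, np.nan, train_mean, True))
            continue
        s = xt[:, mask].sum(axis=1)
        sc = s - s.mean()
        denom = float(sc @ sc)
        if denom <= 0:
            preds[i] = train_mean
            folds.append(CPMFold(i, mask, np.nan, np.nan, train_mean, True))
            continue
        slope = float(sc @ yc) / denom
        intercept = train_mean - slope * float(s.mean())
        preds[i] = intercept + slope * float(x[i, mask].sum())
        folds.append(CPMFold(i, mask, slope, intercept, float(preds[i]), False))
    return preds, counts / n, folds


def evaluate_spearman(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """Average-rank Spearman rho and its two-sided p (t approximation)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("prediction and observation vectors must have equal length")
    if pred.size < 5:
        raise ValueError("need at least 5 paired values")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(pred, obs)
    return float(rho), float(p)


def _spearman_stat(pred: np.ndarray, obs: np.ndarray) -> float:
    """rho for permutation counting; a constant vector contributes rho = 0."""
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return 0.0
    ra = stats.rankdata(pred)
    rb = stats.rankdata(obs)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def run_loocv(
    edges: np.ndarray,
    y: np.ndarray,
    alpha_edge: float = DEFAULT_ALPHA_EDGE,
    tail: Tail = "positive",
) -> CPMResult:
    """Leave-one-out CPM for one tail.

    Each subject is predicted by a model whose edge selection and OLS fit
    saw only the other n - 1 subjects; if no edge passes selection in a
    fold, that fold predicts the training mean of y (and is flagged).
    Selection frequencies are accumulated over the n folds.
    """
    x, y = _validate_xy(edges, y, min_n=5)
    if tail not in ("positive", "negative"):
        raise ValueError(f"tail must be 'positive' or 'negative', got {tail!r}")
    preds, freq, folds = _loocv(x, y, alpha_edge, tail, collect_folds=True)
    n_empty = sum(f.empty_mask for f in folds)
    if n_empty:
        logger.info("%d of %d LOOCV folds had an empty %s mask", n_empty, len(folds), tail)
    rho, p = evaluate_spearman(preds, y) if np.ptp(preds) > 0 else (0.0, 1.0)
    return CPMResult(
        tail=tail,
        observed=y.copy(),
        predicted=preds,
        rho=rho,
        p_parametric=p,
        selection_frequency=freq,
        folds=folds,
        alpha_edge=alpha_edge,
    )


def permutation_test(
    edges: np.ndarray,
    y: np.ndarray,
    alpha_edge: float = DEFAULT_ALPHA_EDGE,
    tail: Tail = "positive",
    b: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.SeedSequence = 0,
    observed: CPMResult | None = None,
    add_one: bool = True,
    keep_null: bool = False,
) -> PermutationResult:
    """Permutation significance of the LOOCV Spearman rho.

    Each of the ``b`` permutations shuffles the behavior labels and reruns
    the complete LOOCV, fold-wise edge selection included.  The p-value is
    the add-one estimate (1 + #{rho_perm >= rho_obs}) / (1 + b), which is
    never zero; ``add_one=False`` gives the plain proportion instead.
    Permutations are drawn uniformly with replacement from the permutation
    group (duplicates are possible and harmless).
    """
    if b < 1:
        raise ValueError("need at least 1 permutation")
    x, y = _validate_xy(edges, y, min_n=5)
    if observed is None:
        observed = run_loocv(x, y, alpha_edge=alpha_edge, tail=tail)
    rho_obs = observed.rho
    rng = np.random.default_rng(seed)
    rhos = np.empty(b)
    for k in range(b):
        yp = rng.permutation(y)
        preds, _, _ = _loocv(x, yp, alpha_edge, tail, collect_folds=False)
        rhos[k] = _spearman_stat(preds, yp)
    count = int((rhos >= rho_obs).sum())
    p = (1 + count) / (1 + b) if add_one else count / b
    return PermutationResult(
        b=b,
        observed_rho=rho_obs,
        count_ge=count,
        p_value=p,
        permuted_rho=rhos if keep_null else np.empty(0),
    )


def robust_edges(
    result: CPMResult, threshold: float = DEFAULT_ROBUST_THRESHOLD
) -> RobustNetwork:
    """Edges selected in at least ``threshold`` of the LOOCV folds (inclusive)."""
    if not (0 < threshold <= 1):
        raise ValueError(f"robustness threshold must be in (0, 1], got {threshold}")
    idx = np.flatnonzero(result.selection_frequency >= threshold)
    return RobustNetwork(
        tail=result.tail,
        edges=idx,
        frequencies=result.selection_frequency[idx],
        threshold=threshold,
    )


def overlap_with_networks(
    net: RobustNetwork, labels: AtlasLabels, emap: EdgeIndexMap
) -> pd.DataFrame:
    """Counts of robust edges within and between canonical networks.

    Returns a symmetric K x K DataFrame over the atlas's networks; the
    diagonal holds within-network edges and the total over the upper
    triangle plus diagonal equals the number of robust edges.
    """
    networks = labels.networks
    pos = {name: k for k, name in enumerate(networks)}
    counts = np.zeros((len(networks), len(networks)), dtype=np.int64)
    rows, cols = emap.pairs()
    if net.edges.size:
        lab_i = labels.network_of(rows[net.edges])
        lab_j = labels.network_of(cols[net.edges])
        for a, b in zip(lab_i, lab_j):
            ia, ib = pos[a], pos[b]
            counts[ia, ib] += 1
            if ia != ib:
                counts[ib, ia] += 1
    return pd.DataFrame(counts, index=networks, columns=networks)


# ---------------------------------------------------------------------------
# results bundle


def save_cpm_bundle(
    outdir: str | Path,
    results: dict[str, CPMResult],
    emap: EdgeIndexMap,
    subject_ids: Sequence[str] | None = None,
    permutations: dict[str, PermutationResult] | None = None,
    robust: dict[str, RobustNetwork] | None = None,
    overlaps: dict[str, pd.DataFrame] | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write the CPM results bundle (predictions, frequencies, robust edges,
    overlap matrices, run metadata) as plain CSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows_i, cols_j = emap.pairs()

    pred_rows = []
    freq_rows = []
    robust_rows = []
    for tail, res in results.items():
        ids = subject_ids if subject_ids is not None else [str(k) for k in range(res.n_subjects)]
        for sid, o, p in zip(ids, res.observed, res.predicted):
            pred_rows.append({"subject_id": sid, "tail": tail, "observed": o, "predicted": p})
        nz = np.flatnonzero(res.selection_frequency > 0)
        for k in nz:
            freq_rows.append(
                {
                    "edge_index": int(k),
                    "node_i": int(rows_i[k]),
                    "node_j": int(cols_j[k]),
                    "frequency": float(res.selection_frequency[k]),
                    "tail": tail,
                }
            )
        if robust and tail in robust:
            rn = robust[tail]
            for k, f in zip(rn.edges, rn.frequencies):
                robust_rows.append(
                    {
                        "edge_index": int(k),
                        "node_i": int(rows_i[k]),
                        "node_j": int(cols_j[k]),
                        "frequency": float(f),
                        "tail": tail,
                    }
                )
    pd.DataFrame(pred_rows).to_csv(outdir / "predictions.csv", index=False)
    pd.DataFrame(freq_rows).to_csv(outdir / "edge_frequencies.csv", index=False)
    pd.DataFrame(robust_rows).to_csv(outdir / "robust_edges.csv", index=False)
    if overlaps:
        for tail, om in overlaps.items():
            om.to_csv(outdir / f"overlap_{tail}.csv")

    meta = dict(metadata or {})
    meta.setdefault("n_nodes", emap.n_nodes)
    for tail, res in results.items():
        entry = {
            "spearman_rho": res.rho,
            "p_parametric": res.p_parametric,
            "alpha_edge": res.alpha_edge,
            "n_subjects": res.n_subjects,
        }
        if permutations and tail in permutations:
            pr = permutations[tail]
            entry.update({"permutations": pr.b, "p_permutation": pr.p_value})
        meta[f"model_{tail}"] = entry
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return outdir
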