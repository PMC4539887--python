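"""Late integration of per-view patient clusterings.

The per-view hard clusterings, encoded as membership matrices, are combined
into *meta-clusters* in two ways:

* **MF** — the transposed memberships are stacked vertically into a
  clusters x patients matrix X and factorized as X ≈ PH with P, H >= 0 by
  multiplicative updates minimizing the Frobenius reconstruction error.
  Columns of H give soft meta-cluster memberships of the patients; P maps
  single-view clusters onto meta-clusters.

* **GLI** — a consensus model: find a row-stochastic patient membership B
  (n x k) and non-negative mapping P (k x l) minimizing the generalized
  Kullback-Leibler divergence GI(M || BP), where M (n x l) is the horizontal
  concatenation of the view memberships.

Because the rows of P (MF) carry a view index, the mass of each meta-cluster
column of P can be split by view: the column-normalized per-view mass is the
*contribution matrix* T, quantifying how much each view determines each
meta-cluster.

Semi-supervised mode adds the class-label indicator matrix as one extra
(prior) view before integrating.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import LabelVector, MultiViewDataset, ValidationError
from .patients import Membership

__all__ = [
    "StackedMembership",
    "MetaClustering",
    "stack_memberships",
    "mf_integrate",
    "gli_integrate",
    "view_contributions",
    "integrate",
    "generalized_kl",
]

log = logging.getLogger("mvda")

_EPS = 1e-12


@dataclass
class StackedMembership:
    """Vertically stacked transposed membership matrices (clusters x patients)."""

    X: np.ndarray  # (l, n) non-negative
    row_view: np.ndarray  # view index per row
    view_names: list[str]
    row_labels: list[str]
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.row_view = np.asarray(self.row_view, dtype=int)
        if self.X.shape != (len(self.row_labels), len(self.patient_ids)):
            raise ValidationError("stacked matrix shape mismatch")
        if self.row_view.shape[0] != self.X.shape[0]:
            raise ValidationError("row_view length mismatch")

    @property
    def n_views(self) -> int:
        return len(self.view_names)


def stack_memberships(
    memberships: list[Membership],
    prior: Membership | None = None,
    prior_weight: float = 1.0,
) -> StackedMembership:
    """Stack per-view memberships (and an optional prior view) into X.

    Every column of X sums to the number of stacked views because each
    patient sits in exactly one cluster per view; the prior rows are scaled
    by ``prior_weight``.
    """
    if not memberships:
        raise ValidationError("no memberships to stack")
    ref = memberships[0].patient_ids
    entries = list(memberships)
    if prior is not None:
        entries.append(prior)
    blocks, row_view, row_labels, names = [], [], [], []
    for vi, m in enumerate(entries):
        if m.patient_ids != ref:
            raise ValidationError(
                f"membership {m.view_name!r} is over a different patient set"
            )
        block = m.matrix.T.astype(float)
        if prior is not None and m is prior:
            block = block * prior_weight
        blocks.append(block)
        row_view.extend([vi] * m.n_clusters)
        row_labels.extend(m.cluster_ids)
        names.append(m.view_name)
    return StackedMembership(
        X=np.vstack(blocks),
        row_view=np.array(row_view),
        view_names=names,
        row_labels=row_labels,
        patient_ids=list(ref),
    )


@dataclass
class MetaClustering:
    """Result of late integration."""

    method: str  # "MF" or "GLI"
    k: int  # requested meta-cluster count
    P: np.ndarray
    H_or_B: np.ndarray
    partition: np.ndarray  # meta-cluster index per patient (compacted labels)
    contributions: pd.DataFrame  # views x meta-clusters, columns sum to 1
    objective_history: list[float]
    converged: bool
    patient_ids: list[str]
    k_effective: int = 0
    mode: str = "unsupervised"

    def __post_init__(self) -> None:
        if self.k_effective == 0:
            self.k_effective = len(set(self.partition.tolist()))


def _compact_partition(raw: np.ndarray, k: int, what: str) -> tuple[np.ndarray, list[int]]:
    used = sorted(set(raw.tolist()))
    if len(used) < k:
        log.info("%s: %d of %d meta-clusters are empty and were dropped", what, k - len(used), k)
    lut = {u: i for i, u in enumerate(used)}
    return np.array([lut[r] for r in raw]), used


def view_contributions(
    P: np.ndarray,
    row_view: np.ndarray,
    view_names: list[str],
    columns: list | None = None,
) -> pd.DataFrame:
    """Per-view contribution to each meta-cluster, from the projection P.

    Each row of P (one single-view cluster) is first normalized to a
    distribution over meta-clusters, measuring how *dedicated* that cluster
    is to each meta-cluster: a cluster coinciding with a meta-cluster puts
    all its mapping mass there, a cluster whose patients scatter over many
    meta-clusters dilutes it.  View h's raw contribution to meta-cluster f
    is the dedication of its best-aligned cluster, ``max_r P_norm[r, f]``
    over the view's rows; columns are then normalized to sum to 1.  A
    meta-cluster that only view h's clustering isolates therefore gets
    ``T[h, f] -> 1`` — the "one view contributes 100 %" situation.
    An all-zero column yields a uniform contribution and a warning.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValidationError("P must be non-negative")
    row_sum = P.sum(axis=1, keepdims=True)
    row_sum[row_sum == 0] = 1.0  # zero rows stay zero
    P = P / row_sum
    n_views = len(view_names)
    k = P.shape[1]
    T = np.zeros((n_views, k))
    for h in range(n_views):
        rows = P[row_view == h, :]
        if rows.shape[0]:
            T[h] = rows.max(axis=0)
    col = T.sum(axis=0)
    zero = col <= 0
    if np.any(zero):
        warnings.warn("all-zero P column; contribution set uniform", RuntimeWarning)
        T[:, zero] = 1.0 / n_views
        col[zero] = 1.0
    T = T / col
    return pd.DataFrame(
        T,
        index=view_names,
        columns=columns if columns is not None else [f"meta{j + 1}" for j in range(k)],
    )


def _frobenius_mu(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Multiplicative updates for X ≈ PH under squared Frobenius error."""
    l, n = X.shape
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    P = scale * rng.random((l, k)) + _EPS
    H = scale * rng.random((k, n)) + _EPS
    history = [float(np.linalg.norm(X - P @ H) ** 2)]
    converged = False
    for _ in range(max_iter):
        H *= (P.T @ X) / (P.T @ P @ H + _EPS)
        P *= (X @ H.T) / (P @ H @ H.T + _EPS)
        obj = float(np.linalg.norm(X - P @ H) ** 2)
        history.append(obj)
        if history[-2] - obj <= tol * max(history[0], 1.0):
            converged = True
            break
    return P, H, history, converged


def mf_integrate(
    stacked: StackedMembership,
    k_range: list[int] | int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
    n_restarts: int = 10,
) -> MetaClustering:
    """Non-negative factorization X ≈ PH with model selection over k.

    For each k the best of ``n_restarts`` seeded runs (lowest reconstruction
    error) is kept; across k the factorization with the sharpest patient
    memberships wins — sharpness is the mean over patients of the largest
    column-normalized entry of H, so a crisp partition scores 1.  Ties go to
    the smaller k.
    """
    X = stacked.X
    l, n = X.shape
    ks = [k_range] if np.isscalar(k_range) else sorted(set(int(k) for k in k_range))
    for k in ks:
        if not (1 <= k <= l):
            raise ValidationError(f"k={k} outside [1, {l}]")
    rng_master = np.random.default_rng(seed)
    best = None  # (neg_sharpness, k, P, H, history, converged)
    for k in ks:
        k_best = None
        for _ in range(n_restarts):
            rng = np.random.default_rng(rng_master.integers(2**31))
            P, H, hist, conv = _frobenius_mu(X, k, rng, max_iter, tol)
            if k_best is None or hist[-1] < k_best[2][-1]:
                k_best = (P, H, hist, conv)
        P, H, hist, conv = k_best
        if not conv:
            log.warning("MF at k=%d did not converge in %d iterations", k, max_iter)
        hn = H / (H.sum(axis=0, keepdims=True) + _EPS)
        sharpness = float(hn.max(axis=0).mean())
        key = (-sharpness, k)
        if best is None or key < best[0]:
            best = (key, k, P, H, hist, conv)
    _, k, P, H, hist, conv = best
    # fix the diagonal gauge: scale each meta-cluster so its H row peaks at 1
    # (leaves indicator factorizations untouched; X = PH is preserved)
    d = H.max(axis=1)
    d[d == 0] = 1.0
    P = P * d[None, :]
    H = H / d[:, None]
    raw = H.argmax(axis=0)
    partition, used = _compact_partition(raw, k, "MF")
    contrib = view_contributions(
        P[:, used], stacked.row_view, stacked.view_names,
        columns=[f"meta{u + 1}" for u in used],
    )
    return MetaClustering(
        method="MF",
        k=k,
        P=P,
        H_or_B=H,
        partition=partition,
        contributions=contrib,
        objective_history=hist,
        converged=conv,
        patient_ids=stacked.patient_ids,
    )


def generalized_kl(X: np.ndarray, Y: np.ndarray) -> float:
    """GI(X || Y) = sum( X log(X/Y) - X + Y ), with 0 log 0 = 0."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    ratio = np.log((X + _EPS) / (Y + _EPS))
    return float(np.sum(np.where(X > 0, X * ratio, 0.0) - X + Y))


def gli_integrate(
    stacked: StackedMembership,
    k: int | list[int],
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
    n_restarts: int = 10,
) -> MetaClustering:
    """Consensus clustering minimizing GI(M || BP) with row-stochastic B.

    M (n x l) is the horizontally stacked membership; B (n x k) holds the
    consensus memberships and P (k x l) maps meta-clusters back onto the
    single-view clusters.  Multiplicative KL updates alternate with a row
    normalization of B; since the normalization can locally raise the
    objective, the best iterate seen is kept and its trajectory reported as
    a best-so-far (non-increasing) history.
    """
    M = stacked.X.T  # n x l
    n, l = M.shape
    ks = [k] if np.isscalar(k) else sorted(set(int(v) for v in k))
    for kk in ks:
        if not (2 <= kk <= l):
            raise ValidationError(f"k={kk} outside [2, {l}]")
    rng_master = np.random.default_rng(seed)
    overall = None
    for kk in ks:
        best = None  # (best_obj, B, P, history, converged)
        for _ in range(n_restarts):
            rng = np.random.default_rng(rng_master.integers(2**31))
            B = rng.random((n, kk)) + _EPS
            B /= B.sum(axis=1, keepdims=True)
            P = rng.random((kk, l)) + _EPS
            best_obj = generalized_kl(M, B @ P)
            best_BP = (B.copy(), P.copy())
            history = [best_obj]
            converged = False
            stall = 0
            for _ in range(max_iter):
                Y = B @ P + _EPS
                B *= ((M / Y) @ P.T) / (P.sum(axis=1)[None, :] + _EPS)
                B /= B.sum(axis=1, keepdims=True) + _EPS
                Y = B @ P + _EPS
                P *= (B.T @ (M / Y)) / (B.sum(axis=0)[:, None] + _EPS)
                obj = generalized_kl(M, B @ P)
                if obj < best_obj - tol * max(history[0], 1.0):
                    stall = 0
                else:
                    stall += 1
                if obj < best_obj:
                    best_obj = obj
                    best_BP = (B.copy(), P.copy())
                history.append(best_obj)  # best-so-far trajectory
                if stall >= 5:
                    converged = True
                    break
            if best is None or best_obj < best[0]:
                best = (best_obj, *best_BP, history, converged)
        obj, B, P, history, conv = best
        if overall is None or obj < overall[0]:
            overall = (obj, kk, B, P, history, conv)
    obj, kk, B, P, history, conv = overall
    if not conv:
        log.warning("GLI at k=%d did not converge in %d iterations", kk, max_iter)
    raw = B.argmax(axis=1)
    partition, used = _compact_partition(raw, kk, "GLI")
    contrib = view_contributions(
        P.T[:, used], stacked.row_view, stacked.view_names,
        columns=[f"meta{u + 1}" for u in used],
    )
    return MetaClustering(
        method="GLI",
        k=kk,
        P=P,
        H_or_B=B,
        partition=partition,
        contributions=contrib,
        objective_history=history,
        converged=conv,
        patient_ids=stacked.patient_ids,
    )


def integrate(
    dataset: MultiViewDataset,
    memberships: list[Membership],
    method: str = "MF",
    mode: str = "unsupervised",
    k_range: list[int] | int | None = None,
    seed: int = 0,
    prior_weight: float = 1.0,
    **kwargs,
) -> MetaClustering:
    """Dispatch stacking (optionally with the class prior) and integration.

    ``mode="semi_supervised"`` appends the exact class-indicator membership
    as one extra view, which anchors the meta-clusters to the known classes.
    """
    if method not in ("MF", "GLI"):
        raise ValidationError(f"unknown integration method {method!r}")
    if mode not in ("unsupervised", "semi_supervised"):
        raise ValidationError(f"unknown mode {mode!r}")
    prior = None
    if mode == "semi_supervised":
        if dataset.labels is None:
            raise ValidationError("semi-supervised integration requires labels")
        prior = Membership.from_partition(
            dataset.labels.as_codes(), dataset.patient_ids, "prior"
        )
    stacked = stack_memberships(memberships, prior=prior, prior_weight=prior_weight)
    if k_range is None:
        lo = max(m.n_clusters for m in memberships)
        k_range = list(range(max(2, lo), min(stacked.X.shape[0] - 1, 2 * lo) + 1))
    if method == "MF":
        meta = mf_integrate(stacked, k_range, seed=seed, **kwargs)
    else:
        meta = gli_integrate(stacked, k_range, seed=seed, **kwargs)
    meta.mode = mode
    return meta
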