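"""Expression-pattern clustering of phosphosites by fuzzy c-means.

The workflow follows the soft-clustering convention for omics time/condition
profiles: sites are screened by sample standard deviation (default SD > 0.5
on log2 ratios, keeping only sites that actually move), collapsed to
per-group mean profiles in a fixed group order, standardized per row to mean
0 / SD 1 (so cluster shapes, not magnitudes, drive the grouping), and
clustered with fuzzy c-means (default c = 5 clusters).

The fuzzifier m defaults to the Schwämmle-Jensen estimate used by the Mfuzz
package, m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N -
0.1134) with N profiles and D dimensions, falling back to a fixed value on
request.  Memberships follow the standard update u_jk = 1 / sum_l
(d_jk/d_jl)^(2/(m-1)); a point coincident with a center gets membership 1
there by the limit convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RatioMatrix, SampleDesign

logger = logging.getLogger("phosphonet")

SD_THRESHOLD = 0.5
N_CLUSTERS = 5


def filter_by_sd(matrix: RatioMatrix, threshold: float = SD_THRESHOLD) -> list[str]:
    """Sites whose sample SD (ddof=1, present values) exceeds ``threshold``."""
    if matrix.stage != "log2":
        raise ValueError("filter_by_sd expects a log2 matrix")
    sd = matrix.values.std(axis=1, ddof=1, skipna=True)
    keep = sd[(matrix.values.notna().sum(axis=1) >= 2) & (sd > threshold)]
    return list(keep.index)


def group_profiles(matrix: RatioMatrix, design: SampleDesign) -> pd.DataFrame:
    """Per-group mean profiles (columns in design.group_order).

    A site with any group entirely missing is dropped with a logged count.
    """
    cols = {}
    for g in design.group_order:
        cols[g] = matrix.values[design.samples_of(g)].mean(axis=1, skipna=True)
    prof = pd.DataFrame(cols)[design.group_order]
    complete = prof.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("group_profiles: dropped %d sites with an all-missing group", n_dropped)
    return prof.loc[complete]


def standardize_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    """Rescale each row to mean 0, SD 1 (ddof=1); zero-SD rows are dropped."""
    mean = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("standardize_rows: dropped %d constant rows", int((~keep).sum()))
    p = profiles.loc[keep]
    return p.sub(mean[keep], axis=0).div(sd[keep], axis=0)


def mfuzz_fuzzifier(n: int, d: int) -> float:
    """Fuzzifier estimate for N profiles in D dimensions (Schwämmle & Jensen)."""
    return float(
        1.0
        + (1418.0 / n + 22.05) * d**-2.0
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


@dataclass
class FuzzyClustering:
    memberships: pd.DataFrame  # sites x clusters, rows sum to 1
    centers: pd.DataFrame      # clusters x groups
    fuzzifier: float
    n_iter: int
    converged: bool
    objective: float
    objective_trace: list[float]  # objective after each iteration (best restart)

    @property
    def hard_assignment(self) -> pd.Series:
        # argmax; pandas idxmax takes the first (lowest cluster index) on ties
        return self.memberships.idxmax(axis=1)


def _memberships(data: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    u = np.zeros((data.shape[0], centers.shape[0]))
    any_zero = zero.any(axis=1)
    if any_zero.any():
        # coincident point: full membership to (the first) coincident center
        for j in np.where(any_zero)[0]:
            u[j, np.argmax(zero[j])] = 1.0
    rest = ~any_zero
    if rest.any():
        inv = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _objective(data: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float((u**m * d2).sum())


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = N_CLUSTERS,
    m: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 10,
    seed: int = 0,
) -> FuzzyClustering:
    """Fuzzy c-means with Euclidean distance and random-row initialization.

    Alternates membership and center updates until the largest center shift
    falls below ``tol``; the best of ``n_restarts`` runs by objective value is
    returned.  Deterministic under a fixed seed.
    """
    data = profiles.to_numpy(dtype=float)
    n, d = data.shape
    if n < c:
        raise ValueError(f"need at least c={c} rows, got {n}")
    if m is None:
        m = mfuzz_fuzzifier(n, d)
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray, int, bool, list[float]] | None = None
    for _ in range(max(1, n_restarts)):
        centers = data[rng.choice(n, size=c, replace=False)].copy()
        converged = False
        trace: list[float] = []
        for it in range(1, max_iter + 1):
            u = _memberships(data, centers, m)
            um = u**m
            denom = um.sum(axis=0)
            # a cluster losing all mass keeps its previous center
            new_centers = np.where(
                denom[:, None] > 0, (um.T @ data) / np.maximum(denom, 1e-300)[:, None], centers
            )
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            trace.append(_objective(data, centers, _memberships(data, centers, m), m))
            if shift < tol:
                converged = True
                break
        u = _memberships(data, centers, m)
        obj = _objective(data, centers, u, m)
        if best is None or obj < best[0]:
            best = (obj, u, centers, it, converged, trace)

    obj, u, centers, n_iter, converged, trace = best
    cluster_ids = [f"C{i + 1}" for i in range(c)]
    return FuzzyClustering(
        memberships=pd.DataFrame(u, index=profiles.index, columns=cluster_ids),
        centers=pd.DataFrame(centers, index=cluster_ids, columns=profiles.columns),
        fuzzifier=float(m),
        n_iter=n_iter,
        converged=converged,
        objective=obj,
        objective_trace=trace,
    )


def assign_and_summarize(
    clustering: FuzzyClustering,
    profiles: pd.DataFrame,
    min_membership: float = 0.0,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Hard cluster assignment and per-cluster mean profile.

    Sites whose maximal membership falls below ``min_membership`` stay
    unassigned.  The member lists are what per-cluster enrichment takes as
    foreground.
    """
    hard = clustering.hard_assignment
    maxu = clustering.memberships.max(axis=1)
    assigned = hard[maxu >= min_membership]
    members = {
        c: sorted(assigned.index[assigned == c]) for c in clustering.memberships.columns
    }
    mean_profiles = pd.DataFrame(
        {
            c: profiles.loc[ids].mean(axis=0) if ids else pd.Series(np.nan, index=profiles.columns)
            for c, ids in members.items()
        }
    ).T
    return members, mean_profiles
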