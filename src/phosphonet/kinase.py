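"""Kinase-substrate prediction and kinase-activity inference.

Substrate prediction uses transparent position-specific scoring matrices
(PSSMs) over the short linear motif around each phosphosite: a window's score
for a kinase is the sum of the matrix weights at each offset for the residue
observed there (pad characters contribute 0), and the site is called a
substrate when the score reaches the kinase's threshold.  A site may be a
substrate of several kinases.

Kinase activity is scored by preranked GSEA over the per-comparison ranking
of sites by log2 fold change.  The enrichment score (ES) is the maximal
deviation of the weighted Kolmogorov-Smirnov running statistic: walking down
the ranking, hitting one of the kinase's substrates increments the running
sum by |metric|^p normalized by the total over hits, and a miss decrements it
by 1/(N - N_hits).  Significance comes from a permutation null of random
same-size site sets; the normalized enrichment score NES = ES / mean(|null
ES| of the same sign) is the kinase activity score, positive for activated
and negative for inhibited kinases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import AMINO_ACIDS, PAD_CHAR
from .simulate import MotifSpec

logger = logging.getLogger("phosphonet")

MIN_SET_SIZE = 3
N_PERM = 1000

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class KinasePSSM:
    """Log-odds weights per (offset, residue) with a per-kinase call threshold."""

    kinase_id: str
    weights: pd.DataFrame  # index: offsets -h..+h, columns: 20 residues
    score_threshold: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError(f"PSSM of {self.kinase_id} contains non-finite weights")

    @property
    def halfwidth(self) -> int:
        return int(max(abs(o) for o in self.weights.index))

    def score(self, window: str) -> float:
        h = len(window) // 2
        total = 0.0
        for off in self.weights.index:
            if abs(off) > h:
                raise ValueError(
                    f"PSSM {self.kinase_id} offset {off} incompatible with window length {len(window)}"
                )
            res = window[h + off]
            if res == PAD_CHAR:
                continue
            total += float(self.weights.loc[off, res])
        return total


def pssm_from_motif_spec(
    kinase_id: str, spec: MotifSpec, h: int = 6, weight: float = 4.0,
    threshold_fraction: float = 0.75,
) -> KinasePSSM:
    """Build a sparse PSSM from a consensus motif.

    Consensus positions get ``weight``; everything else 0.  The call threshold
    defaults to 75% of the maximal score, so windows matching most consensus
    positions are called substrates while random windows (expected score ~0)
    are not.
    """
    mat = pd.DataFrame(0.0, index=range(-h, h + 1), columns=list(AMINO_ACIDS))
    for off, res in spec.consensus.items():
        mat.loc[off, res] = weight
    max_score = weight * len(spec.consensus)
    return KinasePSSM(kinase_id, mat, score_threshold=threshold_fraction * max_score)


def score_substrates(
    windows: pd.DataFrame, pssms: list[KinasePSSM]
) -> dict[str, dict[str, float]]:
    """Assign sites to kinases by PSSM score.

    ``windows`` is a site table with ``site_id`` and ``window`` columns.
    Returns {kinase_id: {site_id: score}} keeping only sites whose score
    reaches the kinase's threshold.
    """
    if not len(windows):
        return {k.kinase_id: {} for k in pssms}
    length = {len(w) for w in windows["window"]}
    if len(length) != 1:
        raise ValueError("windows must share one length")
    (L,) = length
    h = L // 2
    # integer-encode windows once; X -> -1 (contributes nothing)
    enc = np.full((len(windows), L), -1, dtype=np.int64)
    for i, w in enumerate(windows["window"]):
        for j, ch in enumerate(w):
            enc[i, j] = _AA_INDEX.get(ch, -1)
    site_ids = windows["site_id"].to_numpy()

    out: dict[str, dict[str, float]] = {}
    for pssm in pssms:
        if pssm.halfwidth > h:
            raise ValueError(
                f"PSSM {pssm.kinase_id} half-width {pssm.halfwidth} exceeds window half-width {h}"
            )
        wmat = np.zeros((L, 21))  # last row = pad, weight 0
        for off in pssm.weights.index:
            wmat[h + off, :20] = pssm.weights.loc[off].to_numpy()
        scores = wmat[np.arange(L)[None, :], enc].sum(axis=1)
        hits = scores >= pssm.score_threshold
        out[pssm.kinase_id] = {
            str(s): float(v) for s, v in zip(site_ids[hits], scores[hits])
        }
    return out


def substrate_sets_to_gmt(ks_map: dict[str, dict[str, float]]) -> dict[str, tuple[str, set[str]]]:
    return {
        k: (f"predicted substrates of {k}", set(sites))
        for k, sites in ks_map.items()
        if sites
    }


def rank_sites(diff: pd.DataFrame) -> pd.DataFrame:
    """Rank tested sites by log2 fold change, descending; ties by site_id.

    Untested sites (missing p) are excluded with a logged count.
    """
    tested = diff[diff["tested"]].copy()
    n_skipped = len(diff) - len(tested)
    if n_skipped:
        logger.info("rank_sites: excluded %d untested sites", n_skipped)
    tested = tested.sort_values(
        ["log2_fc", "site_id"], ascending=[False, True], kind="mergesort"
    )
    return tested[["site_id", "log2_fc"]].rename(columns={"log2_fc": "metric"}).reset_index(drop=True)


def enrichment_score(
    metrics: np.ndarray, hit_mask: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """ES of one ranked list: signed maximal deviation of the running sum.

    ``metrics`` must already be in ranking order.  Hit steps are
    |metric|^p / sum over hits of |metric|^p; miss steps are -1/(N - N_hits).
    If every hit metric is 0 (weighted total 0), hits fall back to equal
    weights.  ES is bounded in [-1, 1]; when the maximal positive and
    negative deviations tie in magnitude, the earlier rank wins.
    """
    n = len(metrics)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        return 0.0
    w = np.abs(metrics) ** weight_exponent
    w = np.where(hit_mask, w, 0.0)
    total = w.sum()
    if total == 0:
        w = hit_mask.astype(float)
        total = float(n_hits)
    steps = np.where(hit_mask, w / total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    absr = np.abs(running)
    mx = absr.max()
    # exact magnitude ties (up to float noise) resolve to the earliest rank
    i = int(np.argmax(absr >= mx - 1e-12 * max(1.0, mx)))
    return float(running[i])


def ksea(
    ranked: pd.DataFrame,
    substrate_sets: dict[str, set[str]] | dict[str, dict[str, float]],
    weight_exponent: float = 1.0,
    n_perm: int = N_PERM,
    min_set_size: int = MIN_SET_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA kinase-activity scores.

    ``ranked`` comes from :func:`rank_sites`.  Substrate sets are intersected
    with the ranking; kinases with fewer than ``min_set_size`` ranked
    substrates are skipped.  The permutation null draws ``n_perm`` random
    site sets of the same size without replacement (site-label permutation,
    one independent seeded stream per kinase so results do not depend on
    kinase iteration order).  Returns one row per scored kinase: ES, NES,
    permutation p (add-one corrected, same-sign null), Benjamini-Hochberg q,
    substrate count and direction.
    """
    if not len(ranked):
        raise ValueError("empty ranking")
    site_ids = ranked["site_id"].to_numpy()
    metrics = ranked["metric"].to_numpy(dtype=float)
    n = len(site_ids)
    pos = {s: i for i, s in enumerate(site_ids)}

    rows = []
    for ki, kinase in enumerate(sorted(substrate_sets)):
        members = substrate_sets[kinase]
        idx = np.array(sorted(pos[s] for s in members if s in pos), dtype=int)
        if len(idx) < min_set_size:
            logger.info("ksea: kinase %s skipped (%d ranked substrates)", kinase, len(idx))
            continue
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es = enrichment_score(metrics, hit, weight_exponent)

        rng = np.random.default_rng([seed, ki])
        null = np.empty(n_perm)
        k = len(idx)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            null[b] = enrichment_score(metrics, mask, weight_exponent)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign):
            nes = es / np.mean(np.abs(same_sign))
            perm_p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + len(same_sign))
        else:
            denom = np.mean(np.abs(null)) if np.abs(null).sum() else 1.0
            nes = es / denom
            perm_p = 1.0 / (1 + n_perm)
        rows.append(
            dict(kinase=kinase, es=es, nes=float(nes), perm_p=float(perm_p),
                 n_substrates=int(len(idx)),
                 direction="activated" if es > 0 else ("inhibited" if es < 0 else "none"))
        )
    res = pd.DataFrame(
        rows, columns=["kinase", "es", "nes", "perm_p", "n_substrates", "direction"]
    )
    if len(res):
        res["q_value"] = multipletests(res["perm_p"].to_numpy(), method="fdr_bh")[1]
    else:
        res["q_value"] = pd.Series(dtype=float)
    return res


def top_kinases(activities: pd.DataFrame, k: int = 10) -> tuple[list[str], list[str]]:
    """Top-k activated (NES descending) and top-k inhibited (NES ascending).

    Ties break by kinase id; if fewer than k are available, all are returned
    with a warning.
    """
    act = activities[activities["nes"] > 0].sort_values(
        ["nes", "kinase"], ascending=[False, True], kind="mergesort"
    )
    inh = activities[activities["nes"] < 0].sort_values(
        ["nes", "kinase"], ascending=[True, True], kind="mergesort"
    )
    if len(act) < k or len(inh) < k:
        logger.warning(
            "top_kinases: only %d activated / %d inhibited available (k=%d)",
            len(act), len(inh), k,
        )
    return list(act["kinase"].head(k)), list(inh["kinase"].head(k))
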