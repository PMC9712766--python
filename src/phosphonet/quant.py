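"""Quantification pipeline and differential statistics.

The relative quantification chain mirrors standard label-free practice:

1. **Centering** — each site's intensity is divided by its mean over the
   samples in which it was observed, R_ij = I_ij / mean_i(I_ij), so every row
   of the centred matrix has mean 1 over present values.
2. **Protein correction** — a site's ratio is divided by its parent protein's
   ratio, removing protein-abundance changes from the modification signal.
   Sites whose protein was not quantified pass through unchanged and are
   flagged.
3. **log2 transform** — ratios are log2-transformed so that the downstream
   t statistics operate on approximately normal values.

Differential testing is a classic pooled-variance (Student) two-sample t test
per site, two- or one-tailed, with the conventional significance gate
p < 0.05 and linear fold change >= 1.5 (or <= 1/1.5).  Welch's unequal
variance form is available behind a flag.  No imputation is performed; sites
with too few present values per group are reported as untested rather than
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import RatioMatrix, SampleDesign

logger = logging.getLogger("phosphonet")

P_THRESHOLD = 0.05
FC_THRESHOLD = 1.5


def center_normalize(intensities: pd.DataFrame) -> RatioMatrix:
    """Divide each row by its mean over present values (centering).

    Rows that are entirely missing, or whose mean over present values is not
    strictly positive, are dropped with a logged warning.  Missing entries
    stay missing.
    """
    vals = intensities.astype(float)
    row_means = vals.mean(axis=1, skipna=True)
    keep = row_means.notna() & (row_means > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "center_normalize: dropped %d rows with no positive present values", n_dropped
        )
    vals = vals.loc[keep]
    centered = vals.div(row_means.loc[keep], axis=0)
    return RatioMatrix(centered, stage="centered")


def protein_correct(
    site_ratios: RatioMatrix, protein_ratios: RatioMatrix, site_table: pd.DataFrame
) -> RatioMatrix:
    """Divide each site's centred ratio by its parent protein's centred ratio.

    A protein ratio of exactly 0 makes the corrected value missing (counted
    and logged).  Sites whose protein has no quantified row pass through
    uncorrected and are listed in ``uncorrected``.
    """
    if site_ratios.stage != "centered" or protein_ratios.stage != "centered":
        raise ValueError("protein_correct expects centred site and protein matrices")
    site_vals = site_ratios.values
    prot_vals = protein_ratios.values
    parent = site_table.set_index("site_id")["protein_id"]

    corrected = site_vals.copy()
    uncorrected: list[str] = []
    n_zero = 0
    for site_id in site_vals.index:
        pid = parent.get(site_id)
        if pid is None or pid not in prot_vals.index:
            uncorrected.append(site_id)
            continue
        denom = prot_vals.loc[pid, site_vals.columns].to_numpy(dtype=float)
        zero = denom == 0
        n_zero += int(zero.sum())
        denom = np.where(zero, np.nan, denom)
        corrected.loc[site_id] = site_vals.loc[site_id].to_numpy(dtype=float) / denom
    if uncorrected:
        logger.warning(
            "protein_correct: %d sites lack protein quantification and pass through",
            len(uncorrected),
        )
    if n_zero:
        logger.warning("protein_correct: %d zero protein ratios set corrected values missing", n_zero)
    return RatioMatrix(corrected, stage="protein_corrected", uncorrected=tuple(uncorrected))


def log2_transform(ratios: RatioMatrix) -> RatioMatrix:
    """Elementwise log2; non-positive values become missing with a warning."""
    if ratios.stage not in ("centered", "protein_corrected"):
        raise ValueError("log2_transform expects a centred or protein-corrected matrix")
    vals = ratios.values.astype(float)
    nonpos = (vals <= 0).to_numpy() & ~np.isnan(vals.to_numpy())
    if nonpos.any():
        logger.warning("log2_transform: %d non-positive values set missing", int(nonpos.sum()))
        vals = vals.mask(vals <= 0)
    return RatioMatrix(np.log2(vals), stage="log2", uncorrected=ratios.uncorrected)


@dataclass(frozen=True)
class Comparison:
    group_a: str
    group_b: str

    @property
    def label(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


def _pooled_t(
    a: np.ndarray, b: np.ndarray, tails: str, welch: bool
) -> tuple[float, float, float, bool]:
    """Pooled-variance (or Welch) two-sample t.  Returns (t, df, p, degenerate).

    ``tails="one"`` tests mean(a) > mean(b).  Zero pooled variance is handled
    by convention: equal means give p = 1, unequal means p = 0 (flagged as
    degenerate).
    """
    na, nb = len(a), len(b)
    diff = a.mean() - b.mean()
    if welch:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / na + vb / nb
        if se2 == 0:
            if diff == 0:
                return 0.0, float(na + nb - 2), 1.0, False
            return np.inf * np.sign(diff), float(na + nb - 2), 0.0, True
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            if diff == 0:
                return 0.0, df, 1.0, False
            return np.inf * np.sign(diff), df, 0.0, True
        t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    if tails == "two":
        p = 2 * stats.t.sf(abs(t), df)
    elif tails == "one":
        p = stats.t.sf(t, df)
    else:
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    return float(t), float(df), float(p), False


def differential_test(
    log2_matrix: RatioMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    tails: str = "two",
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    min_per_group: int = 2,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-site two-sample t test between two groups on log2 ratios.

    Returns one row per site with columns ``site_id, comparison, log2_fc, fc,
    t, df, p_value, q_value, n_a, n_b, significant, direction, tested,
    degenerate``.  The fold change is mean(log2 A) - mean(log2 B) expressed on
    the linear scale; q_value is the Benjamini-Hochberg adjustment over tested
    sites (reported alongside; the significance gate uses the raw p).
    """
    if log2_matrix.stage != "log2":
        raise ValueError("differential_test expects a log2 matrix")
    samples_a = design.samples_of(group_a)
    samples_b = design.samples_of(group_b)
    vals = log2_matrix.values
    missing_cols = set(samples_a + samples_b) - set(vals.columns)
    if missing_cols:
        raise ValueError(f"samples not in matrix: {sorted(missing_cols)}")
    comp = Comparison(group_a, group_b)

    rows = []
    for site_id in vals.index:
        a = vals.loc[site_id, samples_a].dropna().to_numpy(dtype=float)
        b = vals.loc[site_id, samples_b].dropna().to_numpy(dtype=float)
        na, nb = len(a), len(b)
        if na < min_per_group or nb < min_per_group:
            rows.append(
                dict(site_id=site_id, log2_fc=np.nan, t=np.nan, df=np.nan, p_value=np.nan,
                     n_a=na, n_b=nb, tested=False, degenerate=False)
            )
            continue
        t, df, p, degen = _pooled_t(a, b, tails=tails, welch=welch)
        rows.append(
            dict(site_id=site_id, log2_fc=float(a.mean() - b.mean()), t=t, df=df, p_value=p,
                 n_a=na, n_b=nb, tested=True, degenerate=degen)
        )
    res = pd.DataFrame(rows)
    n_untested = int((~res["tested"]).sum())
    if n_untested:
        logger.info("differential_test %s: %d sites untested (too few values)", comp.label, n_untested)
    res["comparison"] = comp.label
    res["fc"] = 2.0 ** res["log2_fc"]
    res["q_value"] = np.nan
    tested = res["tested"].to_numpy()
    if tested.any():
        res.loc[tested, "q_value"] = multipletests(
            res.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    res["significant"] = (
        tested
        & (res["p_value"] < p_threshold)
        & ((res["fc"] >= fc_threshold) | (res["fc"] <= 1 / fc_threshold))
    )
    res["direction"] = np.where(res["log2_fc"] > 0, "up", "down")
    res.loc[res["log2_fc"] == 0, "direction"] = "none"
    cols = ["site_id", "comparison", "log2_fc", "fc", "t", "df", "p_value", "q_value",
            "n_a", "n_b", "significant", "direction", "tested", "degenerate"]
    return res[cols]


def significant_sites(
    results: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> tuple[set[str], set[str]]:
    """Partition significant sites into (up, down) sets.

    up: p < p_threshold and FC >= fc_threshold;
    down: p < p_threshold and FC <= 1/fc_threshold.  The sets are disjoint.
    """
    if results["comparison"].nunique() > 1:
        raise ValueError("significant_sites expects results from a single comparison")
    ok = results["tested"] & (results["p_value"] < p_threshold)
    up = set(results.loc[ok & (results["fc"] >= fc_threshold), "site_id"])
    down = set(results.loc[ok & (results["fc"] <= 1 / fc_threshold), "site_id"])
    return up, down


def overlap_sets(named_sets: dict[str, set[str]]) -> dict[frozenset[str], set[str]]:
    """Exact Venn partition of >=2 named sets.

    Returns {frozenset of set names: ids belonging to exactly those sets};
    empty regions are included with empty id sets, and region counts sum to
    the size of the union.
    """
    if len(named_sets) < 2:
        raise ValueError("overlap_sets needs at least two sets")
    names = list(named_sets)
    universe = set().union(*named_sets.values())
    regions: dict[frozenset[str], set[str]] = {}
    # all non-empty name combinations
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = set()
    for item in universe:
        membership = frozenset(n for n in names if item in named_sets[n])
        regions[membership].add(item)
    return regions
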