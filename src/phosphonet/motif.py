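"""Sequence-window extraction and motif-x style iterative motif discovery.

A motif is discovered one position-residue constraint at a time: at each step
every (offset, residue) pair is scored by the one-sided binomial tail
P[X >= k] with k = foreground occurrences, n = foreground size and p = the
background frequency of that residue at that offset.  The most significant
pair passing both thresholds (minimum occurrence count and maximum p) is
fixed, both window sets are restricted to matching windows, and the search
recurses.  When no further constraint qualifies, the accumulated constraints
form a motif; its matching windows are removed from both sets and the whole
procedure restarts, so emitted motifs have disjoint foreground support.

The default thresholds are the conventional motif-x settings for
phosphoproteomic data: at least 20 foreground occurrences and a binomial
p below 1e-6 per constraint.

Pad characters ("X", beyond protein termini) never count as residue matches
and are excluded from the background frequency denominator at their offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AMINO_ACIDS, PAD_CHAR

logger = logging.getLogger("phosphonet")

MIN_COUNT = 20
P_MAX = 1e-6


def extract_windows(
    site_table: pd.DataFrame, seqs: dict[str, str], h: int = 6
) -> pd.DataFrame:
    """Extract the +-h sequence window around each site (X-padded at termini).

    Returns the site table with a ``window`` column (length 2h+1).  A mismatch
    between the table's residue letter and the sequence is an error naming the
    site.
    """
    windows = []
    for r in site_table.itertuples():
        seq = seqs.get(r.protein_id)
        if seq is None:
            raise KeyError(f"no sequence for protein {r.protein_id!r} (site {r.site_id})")
        pos = int(r.position)
        if not 1 <= pos <= len(seq):
            raise ValueError(f"site {r.site_id}: position {pos} outside sequence")
        if seq[pos - 1] != r.residue:
            raise ValueError(
                f"site {r.site_id}: sequence residue {seq[pos - 1]!r} at position "
                f"{pos} does not match table residue {r.residue!r}"
            )
        left = seq[max(0, pos - 1 - h) : pos - 1]
        right = seq[pos : pos + h]
        windows.append(
            PAD_CHAR * (h - len(left)) + left + seq[pos - 1] + right + PAD_CHAR * (h - len(right))
        )
    out = site_table.copy()
    out["window"] = windows
    return out


@dataclass
class Motif:
    """An emitted motif: ordered position constraints plus its statistics."""

    center: str
    constraints: dict[int, str]
    binomial_p: list[float] = field(default_factory=list)
    fg_matches: int = 0
    fg_total: int = 0
    bg_matches: int = 0
    bg_total: int = 0

    @property
    def fold_enrichment(self) -> float:
        fg_rate = self.fg_matches / self.fg_total if self.fg_total else np.nan
        bg_rate = self.bg_matches / self.bg_total if self.bg_total else np.nan
        return fg_rate / bg_rate if bg_rate else np.inf

    @property
    def pattern(self) -> str:
        """Constraints serialized as e.g. ``"K@-3,P@+1"`` (offset-sorted)."""
        return ",".join(f"{res}@{off:+d}" for off, res in sorted(self.constraints.items()))


def binomial_tail(k: int, n: int, p: float) -> float:
    """One-sided upper binomial tail P[X >= k] for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def _window_array(windows: list[str], h: int) -> np.ndarray:
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype="S1")
    return arr.reshape(len(windows), 2 * h + 1).astype("U1")


def _best_pair(
    fg: np.ndarray, bg: np.ndarray, h: int, min_count: int, p_max: float,
    fixed: set[int],
) -> tuple[float, int, int, str] | None:
    """Most significant (offset, residue) candidate, or None.

    Ties on p are broken toward the larger foreground count, then the smaller
    offset magnitude, then the alphabetically first residue — a fixed total
    order that makes the search deterministic.
    """
    n_fg = fg.shape[0]
    best: tuple[float, int, int, str] | None = None  # (p, -k, |off|, residue); offset kept aside
    best_off = 0
    for off in range(-h, h + 1):
        if off == 0 or off in fixed:
            continue
        col_fg = fg[:, h + off]
        col_bg = bg[:, h + off]
        bg_valid = col_bg != PAD_CHAR
        n_bg_valid = int(bg_valid.sum())
        if n_bg_valid == 0:
            continue
        for res in AMINO_ACIDS:
            k = int((col_fg == res).sum())
            if k < min_count:
                continue
            p_bg = int((col_bg[bg_valid] == res).sum()) / n_bg_valid
            pval = binomial_tail(k, n_fg, p_bg)
            if pval >= p_max:
                continue
            key = (pval, -k, abs(off), res)
            if best is None or key < best:
                best = key
                best_off = off
    if best is None:
        return None
    pval, neg_k, _, res = best
    return pval, -neg_k, best_off, res


def _match_mask(arr: np.ndarray, h: int, off: int, res: str) -> np.ndarray:
    return arr[:, h + off] == res


def motifx(
    foreground: list[str],
    background: list[str],
    center: str,
    min_count: int = MIN_COUNT,
    p_max: float = P_MAX,
) -> list[Motif]:
    """Iterative motif-x over fixed-width phosphosite windows.

    Both window lists must share one odd length and are restricted to windows
    whose centre is ``center`` before searching.  Returns motifs in discovery
    order; the reported counts refer to the window sets at the start of each
    motif's discovery round.
    """
    if not foreground:
        return []
    lengths = {len(w) for w in foreground} | {len(w) for w in background}
    if len(lengths) != 1:
        raise ValueError(f"foreground/background window lengths differ: {sorted(lengths)}")
    (length,) = lengths
    if length % 2 != 1:
        raise ValueError("window length must be odd")
    h = length // 2
    fg_list = [w for w in foreground if w[h] == center]
    bg_list = [w for w in background if w[h] == center]
    if not fg_list:
        return []
    if len(bg_list) < len(fg_list):
        logger.warning(
            "motifx: background (%d) smaller than foreground (%d)", len(bg_list), len(fg_list)
        )
    fg_all = _window_array(fg_list, h)
    bg_all = _window_array(bg_list, h) if bg_list else np.empty((0, length), dtype="U1")

    motifs: list[Motif] = []
    while fg_all.shape[0] >= min_count:
        fg = fg_all
        bg = bg_all
        round_fg_total = fg.shape[0]
        round_bg_total = bg.shape[0]
        constraints: dict[int, str] = {}
        pvals: list[float] = []
        while True:
            cand = _best_pair(fg, bg, h, min_count, p_max, set(constraints))
            if cand is None:
                break
            pval, _k, off, res = cand
            constraints[off] = res
            pvals.append(pval)
            fg = fg[_match_mask(fg, h, off, res)]
            bg = bg[_match_mask(bg, h, off, res)]
        if not constraints:
            break
        motifs.append(
            Motif(
                center=center,
                constraints=constraints,
                binomial_p=pvals,
                fg_matches=fg.shape[0],
                fg_total=round_fg_total,
                bg_matches=bg.shape[0],
                bg_total=round_bg_total,
            )
        )
        # remove the emitted motif's support from both sets and restart
        keep_fg = np.ones(fg_all.shape[0], dtype=bool)
        keep_bg = np.ones(bg_all.shape[0], dtype=bool)
        for off, res in constraints.items():
            keep_fg &= ~_match_mask(fg_all, h, off, res)
            keep_bg &= ~_match_mask(bg_all, h, off, res)
        fg_all = fg_all[keep_fg]
        bg_all = bg_all[keep_bg]
    return motifs


def motif_report(motifs: list[Motif]) -> pd.DataFrame:
    rows = [
        {
            "center": m.center,
            "pattern": m.pattern,
            "n_constraints": len(m.constraints),
            "fg_matches": m.fg_matches,
            "fg_total": m.fg_total,
            "bg_matches": m.bg_matches,
            "bg_total": m.bg_total,
            "fold_enrichment": m.fold_enrichment,
            "max_constraint_p": max(m.binomial_p) if m.binomial_p else np.nan,
        }
        for m in motifs
    ]
    return pd.DataFrame(
        rows,
        columns=["center", "pattern", "n_constraints", "fg_matches", "fg_total",
                 "bg_matches", "bg_total", "fold_enrichment", "max_constraint_p"],
    )
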