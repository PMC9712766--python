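"""Fisher exact term enrichment against the identified background.

Each term yields a 2x2 table — foreground hits (a), foreground non-hits (b),
background-only hits (c), background-only non-hits (d) — tested with the
two-tailed Fisher exact test (probability-mass method: the p-value sums the
probabilities of all tables, at the observed margins, no more probable than
the observed one).  The universe defaults to all identified proteins (or
sites); terms with no members inside the universe are skipped.  Raw p < 0.05
is the conventional significance gate; Benjamini-Hochberg q-values are
reported alongside.

Site-level foregrounds can be collapsed to protein level for protein-keyed
annotations (each protein counts once regardless of how many of its sites
changed).
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("phosphonet")

P_THRESHOLD = 0.05


def sites_to_proteins(site_ids: set[str], site_table: pd.DataFrame) -> set[str]:
    """Collapse a set of site ids to their parent protein ids."""
    by_site = site_table.set_index("site_id")["protein_id"]
    missing = site_ids - set(by_site.index)
    if missing:
        raise KeyError(f"sites not in table: {sorted(missing)[:5]}")
    return {by_site[s] for s in site_ids}


def fisher_enrich(
    foreground: set[str],
    universe: set[str],
    terms: dict[str, tuple[str, set[str]]],
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Two-tailed Fisher enrichment of ``foreground`` against ``universe``.

    Returns one row per tested term with the 2x2 counts, odds ratio, p, BH q,
    direction (enriched when the foreground hit rate exceeds the background
    rate) and the ``significant`` flag at raw p < ``p_threshold``.
    """
    offenders = foreground - universe
    if offenders:
        raise ValueError(f"foreground ids outside universe: {sorted(offenders)[:10]}")
    n_fg = len(foreground)
    rows = []
    for term_id in sorted(terms):
        name, members = terms[term_id]
        in_universe = members & universe
        if not in_universe:
            continue
        a = len(in_universe & foreground)
        b = n_fg - a
        c = len(in_universe) - a
        d = len(universe) - n_fg - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        fg_rate = a / n_fg if n_fg else 0.0
        bg_rate = c / (len(universe) - n_fg) if len(universe) > n_fg else 0.0
        rows.append(
            dict(term_id=term_id, term_name=name, a=a, b=b, c=c, d=d,
                 odds_ratio=float(odds), p_value=float(p),
                 direction="enriched" if fg_rate >= bg_rate else "depleted")
        )
    res = pd.DataFrame(
        rows, columns=["term_id", "term_name", "a", "b", "c", "d",
                       "odds_ratio", "p_value", "direction"]
    )
    if len(res):
        res["q_value"] = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
        res["significant"] = res["p_value"] < p_threshold
    else:
        res["q_value"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
    return res
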