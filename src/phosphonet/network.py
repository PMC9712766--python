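"""Typed kinase-regulated network construction.

Two networks are built per comparison:

* the **kinase-substrate regulatory network** — kinases with significant
  activity (non-zero NES, permutation p below the gate) connected to their
  significantly differential substrate sites; and
* the **quadripartite network** — top activated and inhibited kinases (top 10
  each by NES), their significant substrate sites, those sites' parent
  proteins, and the enriched annotation terms (p < 0.05) containing those
  proteins.  A selected kinase that catalyzes no significant site is skipped
  entirely.

Nodes carry ``node_type`` (kinase / phosphosite / protein / pathway) plus
direction and score attributes; edges are typed and directed along the causal
reading kinase -> site -> protein -> pathway (catalyzes, site_of, member_of).
Construction is purely set algebra: identical inputs give identical networks.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .quant import significant_sites

logger = logging.getLogger("phosphonet")

NODE_TYPES = ("kinase", "phosphosite", "protein", "pathway")
EDGE_TYPES = {
    ("kinase", "phosphosite"): "catalyzes",
    ("phosphosite", "protein"): "site_of",
    ("protein", "pathway"): "member_of",
}
PERM_P_GATE = 0.05
TOP_K = 10


def validate_network(net: nx.DiGraph) -> None:
    """Check node/edge typing invariants."""
    for n, d in net.nodes(data=True):
        if d.get("node_type") not in NODE_TYPES:
            raise ValueError(f"node {n!r} has invalid node_type {d.get('node_type')!r}")
    for u, v, d in net.edges(data=True):
        tu = net.nodes[u]["node_type"]
        tv = net.nodes[v]["node_type"]
        expected = EDGE_TYPES.get((tu, tv))
        if expected is None or d.get("edge_type") != expected:
            raise ValueError(
                f"edge {u}->{v} ({d.get('edge_type')!r}) inconsistent with "
                f"node types {tu}->{tv}"
            )
    for n, d in net.nodes(data=True):
        if d["node_type"] == "pathway" and net.in_degree(n) == 0:
            raise ValueError(f"orphan pathway node {n!r}")


def kinase_substrate_network(
    activities: pd.DataFrame,
    diff: pd.DataFrame,
    ks_map: dict[str, dict[str, float]] | dict[str, set[str]],
    perm_p_gate: float = PERM_P_GATE,
) -> nx.DiGraph:
    """Significant kinases wired to their significantly differential substrates.

    A kinase enters only if it passes the activity gate (NES != 0 and
    permutation p < ``perm_p_gate``) and has at least one significant
    substrate site.
    """
    up, down = significant_sites(diff)
    sig = up | down
    lfc = diff.set_index("site_id")["log2_fc"]
    net = nx.DiGraph()
    passing = activities[(activities["nes"] != 0) & (activities["perm_p"] < perm_p_gate)]
    for row in passing.itertuples():
        substrates = sorted(set(ks_map.get(row.kinase, ())) & sig)
        if not substrates:
            continue
        net.add_node(
            row.kinase, node_type="kinase", nes=float(row.nes),
            direction="up" if row.nes > 0 else "down", perm_p=float(row.perm_p),
        )
        for site in substrates:
            if site not in net:
                net.add_node(
                    site, node_type="phosphosite", log2_fc=float(lfc[site]),
                    direction="up" if site in up else "down",
                )
            net.add_edge(row.kinase, site, edge_type="catalyzes")
    if net.number_of_nodes() == 0:
        logger.warning("kinase_substrate_network: empty network")
    validate_network(net)
    return net


def quadripartite_network(
    top: tuple[list[str], list[str]],
    activities: pd.DataFrame,
    diff: pd.DataFrame,
    ks_map: dict[str, dict[str, float]] | dict[str, set[str]],
    site_table: pd.DataFrame,
    enrich: pd.DataFrame,
    p_threshold: float = 0.05,
) -> nx.DiGraph:
    """Kinase -> phosphosite -> protein -> pathway four-layer network.

    ``top`` is the (activated, inhibited) kinase selection; kinases without
    any significant substrate site are skipped.  Pathway nodes are enriched
    terms (p < ``p_threshold``) containing at least one included protein.
    """
    up, down = significant_sites(diff)
    sig = up | down
    lfc = diff.set_index("site_id")["log2_fc"]
    nes = activities.set_index("kinase")["nes"]
    parent = site_table.set_index("site_id")["protein_id"]

    net = nx.DiGraph()
    selected = list(dict.fromkeys(top[0] + top[1]))
    included_proteins: set[str] = set()
    for kinase in selected:
        substrates = sorted(set(ks_map.get(kinase, ())) & sig)
        if not substrates:
            logger.info("quadripartite_network: kinase %s skipped (no significant substrate)", kinase)
            continue
        kin_nes = float(nes.get(kinase, 0.0))
        net.add_node(
            kinase, node_type="kinase", nes=kin_nes,
            direction="up" if kin_nes > 0 else "down",
        )
        for site in substrates:
            if site not in net:
                net.add_node(
                    site, node_type="phosphosite", log2_fc=float(lfc[site]),
                    direction="up" if site in up else "down",
                )
            net.add_edge(kinase, site, edge_type="catalyzes")
            pid = parent[site]
            if pid not in net:
                net.add_node(pid, node_type="protein")
            net.add_edge(site, pid, edge_type="site_of")
            included_proteins.add(pid)

    if len(enrich):
        enriched = enrich[enrich["p_value"] < p_threshold]
        terms_added = 0
        for row in enriched.itertuples():
            members = getattr(row, "members", None)
            if members is None:
                raise ValueError(
                    "enrichment table must carry a 'members' column of term member sets"
                )
            linked = sorted(set(members) & included_proteins)
            if not linked:
                continue
            net.add_node(
                row.term_id, node_type="pathway", term_name=row.term_name,
                p_value=float(row.p_value), source=getattr(row, "source", "annotation"),
            )
            for pid in linked:
                net.add_edge(pid, row.term_id, edge_type="member_of")
            terms_added += 1
        if terms_added == 0:
            logger.warning("quadripartite_network: no enriched terms linked")
    validate_network(net)
    return net


def attach_members(enrich: pd.DataFrame, terms: dict[str, tuple[str, set[str]]]) -> pd.DataFrame:
    """Add each enrichment row's member set (needed for network construction)."""
    out = enrich.copy()
    out["members"] = [
        frozenset(terms[t][1]) if t in terms else frozenset() for t in out["term_id"]
    ]
    return out
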