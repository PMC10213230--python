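"""Zi-Pi topological roles and putative keystone taxa.

Zi is the within-module degree z-score and Pi the among-module
participation coefficient.  Roles follow the classic threshold table
(Zi 2.5, Pi 0.62): peripherals sit at or below both thresholds,
connectors exceed Pi only, module hubs exceed Zi only, and network hubs
exceed both.  Non-peripheral nodes are the putative keystone taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import parse_taxonomy_string
from .topology import ModulePartition, _g

ZI_CUT = 2.5
PI_CUT = 0.62

ROLE_ORDER = ("network hub", "module hub", "connector", "peripheral")


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    role: str | None = None
    taxonomy: str = ""


def zi_pi(net, modules: ModulePartition) -> list[NodeRole]:
    """Within-module connectivity Zi and among-module connectivity Pi.

    Zi = (k_is - mean(k_js)) / sd(k_js) over nodes j of i's module s
    (population sd, Zi = 0 when sd = 0); Pi = 1 - sum_t (k_it / k_i)^2.
    """
    g = _g(net)
    missing = [n for n in g.nodes if n not in modules.membership]
    if missing:
        raise ValidationError(f"nodes without module assignment: {missing[:5]}")
    member = modules.membership
    # within-module degree of every node
    k_within = {}
    k_by_module = {}
    for node in g.nodes:
        s = member[node]
        kis = sum(1 for nb in g[node] if member[nb] == s)
        k_within[node] = kis
        k_by_module.setdefault(s, []).append(kis)
    stats = {s: (float(np.mean(v)), float(np.std(v)))
             for s, v in k_by_module.items()}
    roles = []
    for node in g.nodes:
        s = member[node]
        mean_k, sd_k = stats[s]
        zi = (k_within[node] - mean_k) / sd_k if sd_k > 0 else 0.0
        k_i = g.degree(node)
        per_module = {}
        for nb in g[node]:
            t = member[nb]
            per_module[t] = per_module.get(t, 0) + 1
        pi = 1.0 - sum((k / k_i) ** 2 for k in per_module.values())
        roles.append(NodeRole(str(node), float(zi), float(pi)))
    return roles


def classify_roles(nodes: list[NodeRole], z_cut: float = ZI_CUT,
                   p_cut: float = PI_CUT) -> list[NodeRole]:
    """Assign topological roles; boundary values belong to the <= branch
    (a node at exactly (2.5, 0.62) is peripheral)."""
    for nd in nodes:
        if nd.zi <= z_cut:
            nd.role = "connector" if nd.pi > p_cut else "peripheral"
        else:
            nd.role = "network hub" if nd.pi > p_cut else "module hub"
    return nodes


def keystone_table(roles: list[NodeRole],
                   taxonomy: dict[str, str] | None = None) -> pd.DataFrame:
    """Report rows for all non-peripheral (putative keystone) nodes,
    sorted by role then Zi descending."""
    taxonomy = taxonomy or {}
    rows = []
    for nd in roles:
        if nd.role is None:
            raise ValidationError("roles must be classified first")
        if nd.role == "peripheral":
            continue
        tax = taxonomy.get(nd.node, nd.taxonomy)
        ranks = parse_taxonomy_string(tax)
        lowest = next((ranks[r] for r in reversed(
            ("kingdom", "phylum", "class", "order", "family", "genus"))
            if ranks[r]), "")
        rows.append({"node": nd.node, "Zi": nd.zi, "Pi": nd.pi,
                     "role": nd.role, "phylum": ranks["phylum"],
                     "lowest_rank": lowest})
    df = pd.DataFrame(rows, columns=["node", "Zi", "Pi", "role", "phylum",
                                     "lowest_rank"])
    if len(df):
        df["_order"] = df["role"].map({r: i for i, r in enumerate(ROLE_ORDER)})
        df = df.sort_values(["_order", "Zi"], ascending=[True, False]) \
               .drop(columns="_order").reset_index(drop=True)
    return df
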