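"""Per-subtype metabolite correlation networks and pathway enrichment.

Within one subtype's samples, all metabolite pairs are tested by Spearman
correlation; after Benjamini-Hochberg adjustment over every pair, edges with
q < alpha (default 0.001) are kept and metabolites without any significant
edge are dropped.  Enrichment of the network's metabolites in a pathway
catalog is over-representation analysis: hits vs the hypergeometric null,
enrichment ratio = hits / expected hits, BH across pathways.  The background
is the full set of annotated metabolites in the cohort matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PathwayCatalog

log = logging.getLogger("subtyper.networks")


@dataclass
class CorrelationNetwork:
    subtype: str
    graph: nx.Graph
    edges: pd.DataFrame  # metabolite_a, metabolite_b, rho, sign, p, q

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edges(self, path) -> None:
        self.edges.to_csv(path, index=False)


def subtype_correlation_network(
    data: pd.DataFrame,
    subtype: str = "",
    alpha: float = 0.001,
    adjusted: bool = True,
) -> CorrelationNetwork:
    """Build the significant-correlation network for one subtype's samples.

    `data` is samples x metabolites restricted to the subtype; needs >= 5
    samples.  With `adjusted` (default) the alpha cut applies to BH-adjusted
    p-values, otherwise to raw p-values.
    """
    if len(data) < 5:
        raise ValueError("correlation network needs >= 5 samples")
    cols = list(data.columns)
    m = len(cols)
    rho_mat, p_mat = stats.spearmanr(data.to_numpy(dtype=float))
    if m == 2:  # spearmanr returns scalars for two columns
        rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
        p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
    iu = np.triu_indices(m, k=1)
    rows = pd.DataFrame({
        "metabolite_a": np.asarray(cols)[iu[0]],
        "metabolite_b": np.asarray(cols)[iu[1]],
        "rho": rho_mat[iu],
        "p": p_mat[iu],
    })
    rows = rows.dropna(subset=["p"])
    rows["q"] = multipletests(rows["p"], method="fdr_bh")[1] if len(rows) else []
    crit = rows["q"] if adjusted else rows["p"]
    edges = rows[crit < alpha].copy()
    edges["sign"] = np.where(edges["rho"] >= 0, "positive", "negative")
    g = nx.Graph()
    for rec in edges.itertuples(index=False):
        g.add_edge(rec.metabolite_a, rec.metabolite_b,
                   rho=float(rec.rho), sign=rec.sign, q=float(rec.q))
    return CorrelationNetwork(subtype=subtype, graph=g,
                              edges=edges.reset_index(drop=True))


def quantitative_enrichment(
    network_metabolites: list[str] | set[str],
    catalog: PathwayCatalog,
    background: list[str] | set[str],
) -> pd.DataFrame:
    """Over-representation of network metabolites per pathway.

    hits = |network ∩ pathway|, expected = pathway_size * |network| / |bg|,
    ratio = hits / expected, p = hypergeometric upper tail, q = BH across
    pathways.  Pathways with no background overlap are skipped.
    """
    bg = set(background)
    net = set(network_metabolites) & bg
    if not bg:
        raise ValueError("empty background")
    if len(catalog) == 0:
        raise ValueError("empty pathway catalog")
    M, n_net = len(bg), len(net)
    rows = []
    for pid, entry in sorted(catalog.items()):
        members = entry["members"] & bg
        if not members:
            log.info("pathway %s skipped: no background overlap", pid)
            continue
        K = len(members)
        hits = len(net & members)
        expected = K * n_net / M
        ratio = hits / expected if expected > 0 else 0.0
        p = float(stats.hypergeom.sf(hits - 1, M, K, n_net)) if hits > 0 else 1.0
        rows.append({"pathway": pid, "name": entry["name"], "hits": hits,
                     "set_size": K, "ratio": ratio, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
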