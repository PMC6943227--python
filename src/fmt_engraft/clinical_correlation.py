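"""Correlation of microbiota change with clinical change.

Per recipient, the change in each taxon's relative abundance and in each
clinical index between baseline and an early post-FMT visit (day 3 by
default) is computed; every (taxon, index) pair is tested with the
tie-corrected Spearman rank correlation; Benjamini–Hochberg adjustment
controls the false-discovery rate; pairs with q below a threshold (strict
``q < 0.05`` by default) form a bipartite network with |rho| edge weights.

Pairs with fewer than four complete observations are skipped rather than
imputed — rank p-values below n = 4 are vacuous, and these cohorts top out
at ~15 recipients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedInputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DeltaTable:
    """Per-recipient changes: taxa and clinical indexes side by side.

    ``taxon`` and ``clinical`` are recipients x variables frames of
    value(t2) - value(t1); a delta exists only where both visits exist.
    """

    taxon: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.taxon.index.equals(self.clinical.index):
            raise ValidationError("taxon and clinical deltas must share the recipient index")


def build_deltas(
    abundance,
    clinical,
    manifest,
    t1: int = 0,
    t2: int = 3,
) -> DeltaTable:
    """Delta matrix between two visit days, pairwise-complete.

    Recipients missing either abundance sample are dropped entirely (their
    whole profile is missing); clinical deltas are NaN per index where a
    visit lacks that measurement.
    """
    taxon_rows = {}
    for pair in manifest.pairs():
        s1 = manifest.sample_for(pair.recipient, t1)
        s2 = manifest.sample_for(pair.recipient, t2)
        if s1 is None or s2 is None:
            logger.info("recipient %s lacks day %d or %d; excluded", pair.recipient, t1, t2)
            continue
        taxon_rows[pair.recipient] = abundance.data[s2] - abundance.data[s1]
    if not taxon_rows:
        raise UndefinedInputError(f"no recipient has both day {t1} and day {t2} samples")
    taxon = pd.DataFrame(taxon_rows).T
    taxon.index.name = "recipient"

    w1 = clinical.wide(t1)
    w2 = clinical.wide(t2)
    indexes = sorted(set(w1.columns) | set(w2.columns))
    clin = (
        w2.reindex(index=taxon.index, columns=indexes)
        - w1.reindex(index=taxon.index, columns=indexes)
    )
    return DeltaTable(taxon=taxon, clinical=clin)


def _spearman_fast(taxon: np.ndarray, clin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs tie-corrected Spearman rho and two-sided t-approx p.

    Complete-data fast path: rank each column, then Pearson correlation of
    the rank matrices (exactly the tie-corrected Spearman statistic).
    """
    n = taxon.shape[0]
    rt = scipy.stats.rankdata(taxon, axis=0)
    rc = scipy.stats.rankdata(clin, axis=0)
    rt = rt - rt.mean(axis=0)
    rc = rc - rc.mean(axis=0)
    st = np.sqrt((rt**2).sum(axis=0))
    sc = np.sqrt((rc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rt.T @ rc) / np.outer(st, sc)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = np.nan
    p[np.isinf(t)] = 0.0
    return rho, p


def spearman_all_pairs(deltas: DeltaTable, min_n: int = 4) -> pd.DataFrame:
    """Spearman rho and p for every (taxon, clinical index) delta pair.

    Pairs with fewer than ``min_n`` complete observations, or a constant
    column, are skipped with a recorded reason (``skip_reason`` column,
    rho/p NaN).
    """
    tx = deltas.taxon
    cl = deltas.clinical
    rows = []
    complete = not tx.isna().any().any() and not cl.isna().any().any()
    if complete and len(tx) >= min_n:
        rho_m, p_m = _spearman_fast(tx.to_numpy(dtype=float), cl.to_numpy(dtype=float))
        for i, taxon in enumerate(tx.columns):
            const_t = tx[taxon].nunique() < 2
            for j, index in enumerate(cl.columns):
                if const_t or cl[index].nunique() < 2:
                    rows.append(
                        {
                            "taxon_id": taxon,
                            "index_name": index,
                            "rho": np.nan,
                            "p": np.nan,
                            "n": len(tx),
                            "skip_reason": "constant column",
                        }
                    )
                else:
                    rows.append(
                        {
                            "taxon_id": taxon,
                            "index_name": index,
                            "rho": float(rho_m[i, j]),
                            "p": float(p_m[i, j]),
                            "n": len(tx),
                            "skip_reason": "",
                        }
                    )
    else:
        for taxon in tx.columns:
            for index in cl.columns:
                both = pd.concat([tx[taxon], cl[index]], axis=1).dropna()
                n = len(both)
                if n < min_n:
                    rows.append(
                        {
                            "taxon_id": taxon,
                            "index_name": index,
                            "rho": np.nan,
                            "p": np.nan,
                            "n": n,
                            "skip_reason": f"fewer than {min_n} complete observations",
                        }
                    )
                    continue
                a, b = both.iloc[:, 0], both.iloc[:, 1]
                if a.nunique() < 2 or b.nunique() < 2:
                    rows.append(
                        {
                            "taxon_id": taxon,
                            "index_name": index,
                            "rho": np.nan,
                            "p": np.nan,
                            "n": n,
                            "skip_reason": "constant column",
                        }
                    )
                    continue
                rho, p = scipy.stats.spearmanr(a, b)
                rows.append(
                    {
                        "taxon_id": taxon,
                        "index_name": index,
                        "rho": float(rho),
                        "p": float(p),
                        "n": n,
                        "skip_reason": "",
                    }
                )
    return pd.DataFrame(rows, columns=["taxon_id", "index_name", "rho", "p", "n", "skip_reason"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("need at least one p-value")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_edges(pairs: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Attach BH q-values and keep pairs with q strictly below ``q_max``."""
    tested = pairs[pairs["skip_reason"] == ""].copy()
    if tested.empty:
        return tested.assign(q=pd.Series(dtype=float), sign=pd.Series(dtype=str))
    tested["q"] = bh_adjust(tested["p"].to_numpy())
    tested["sign"] = np.where(tested["rho"] >= 0, "positive", "negative")
    return tested[tested["q"] < q_max].reset_index(drop=True)


def build_network(edges: pd.DataFrame, q_max: float = 0.05) -> nx.Graph:
    """Bipartite taxon–clinical graph of significant correlations.

    Nodes carry kind='taxon'|'clinical'; edges carry rho, p, q, sign and
    weight=|rho|.  Edges with q >= q_max (including exactly q_max) are
    excluded; an empty graph is valid.
    """
    g = nx.Graph()
    if edges.empty:
        return g
    if "q" not in edges.columns:
        raise ValidationError("edges must carry q-values; run significant_edges first")
    kept = edges[edges["q"] < q_max]
    for _, row in kept.iterrows():
        taxon = str(row["taxon_id"])
        index = str(row["index_name"])
        g.add_node(taxon, kind="taxon")
        g.add_node(index, kind="clinical")
        g.add_edge(
            taxon,
            index,
            rho=float(row["rho"]),
            p=float(row["p"]),
            q=float(row["q"]),
            sign=str(row["sign"]),
            weight=float(abs(row["rho"])),
        )
    return g


def correlate_cohort(
    abundance,
    clinical,
    manifest,
    t1: int = 0,
    t2: int = 3,
    q_max: float = 0.05,
    min_n: int = 4,
) -> dict:
    """End-to-end delta correlation: deltas -> Spearman -> BH -> network."""
    deltas = build_deltas(abundance, clinical, manifest, t1, t2)
    pairs = spearman_all_pairs(deltas, min_n=min_n)
    edges = significant_edges(pairs, q_max=q_max)
    graph = build_network(edges, q_max=q_max)
    return {
        "deltas": deltas,
        "pairs": pairs,
        "edges": edges,
        "graph": graph,
        "n_tested": int((pairs["skip_reason"] == "").sum()),
        "n_significant": len(edges),
    }
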