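"""Hypergeometric term enrichment with BH adjustment, z-scores, and
redundancy pruning.

For each term with K annotated genes in a universe of N, of which the DEG set
covers n genes and k fall in the term, the enrichment p-value is the
hypergeometric upper tail P(X >= k). The per-term z-score follows the bubble
plot convention z = (n_up - n_down) / sqrt(k) (0 when k = 0), summarizing the
direction balance of the term's DEG members. Terms whose DEG-member overlap
with a more significant term exceeds a fraction of the smaller term are
pruned as redundant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError
from .deg import bh_adjust


def enrich(
    deg_genes: dict[str, int],
    annotation: dict[str, list[str]],
    universe: list[str],
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Enrichment table over all annotated terms.

    Parameters
    ----------
    deg_genes
        Gene id -> sign (+1 up / -1 down).
    annotation
        Term id -> member gene ids.
    universe
        All genes eligible for annotation (the tested background).
    categories
        Optional term id -> category (BP/CC/MF/other).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ConfigurationError("empty universe")
    if not deg_genes:
        raise ConfigurationError("empty DEG set")
    stray = set(deg_genes) - universe_set
    if stray:
        raise ConfigurationError(f"DEG genes outside universe: {sorted(stray)[:5]}")

    N = len(universe_set)
    deg_set = set(deg_genes)
    n = len(deg_set)
    categories = categories or {}

    rows = []
    for term, members in annotation.items():
        members_in = [g for g in dict.fromkeys(members) if g in universe_set]
        K = len(members_in)
        hits = [g for g in members_in if g in deg_set]
        k = len(hits)
        if k == 0:
            p, z = 1.0, 0.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            n_up = sum(1 for g in hits if deg_genes[g] > 0)
            z = (2 * n_up - k) / np.sqrt(k)
        rows.append(
            {
                "term_id": term,
                "category": categories.get(term, "other"),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "z": z,
                "member_degs": ",".join(f"{g}:{'up' if deg_genes[g] > 0 else 'down'}" for g in hits),
                "pruned": False,
            }
        )
    table = pd.DataFrame(rows).set_index("term_id")
    table["adj_p"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


def _deg_members(row) -> set[str]:
    if not row["member_degs"]:
        return set()
    return {entry.split(":")[0] for entry in row["member_degs"].split(",")}


def prune_redundant(
    table: pd.DataFrame, overlap_frac: float = 0.75, adj_p_cut: float = 0.01
) -> pd.DataFrame:
    """Mark redundant significant terms as pruned.

    Greedy by significance: terms with adj_p < ``adj_p_cut`` are visited in
    order of (adj_p, larger term size K last, term_id); a term is pruned when
    its DEG-member overlap with an already-kept term exceeds ``overlap_frac``
    of the smaller member set. The surviving set contains no violating pair,
    so re-running is a no-op.
    """
    if not 0.0 < overlap_frac <= 1.0:
        raise ConfigurationError("overlap_frac must lie in (0, 1]")
    out = table.copy()
    out["pruned"] = False
    sig = out[out["adj_p"] < adj_p_cut]
    order = sig.reset_index().sort_values(["adj_p", "K", "term_id"])["term_id"]
    kept: list[tuple[str, set[str]]] = []
    for term in order:
        members = _deg_members(out.loc[term])
        redundant = False
        for _, kept_members in kept:
            denom = min(len(members), len(kept_members))
            if denom == 0:
                continue
            if len(members & kept_members) / denom > overlap_frac:
                redundant = True
                break
        if redundant:
            out.loc[term, "pruned"] = True
        else:
            kept.append((term, members))
    return out
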