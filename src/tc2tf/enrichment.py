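"""Sub-clustering of differential genes and Fisher TFBS enrichment.

Differential genes are split into K sub-clusters (default 3) by complete-
linkage hierarchical clustering on 1 - Pearson correlation over their late
time-point samples. For each motif and each gene set (the full differential
set and every sub-cluster), a one-sided Fisher's exact test compares the
promoter hit frequency in the set against all other promoter-bearing genes
on the array, with Benjamini-Hochberg correction across motifs within each
gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from tc2tf.diffexp import bh_adjust


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson correlation between gene rows.

    Requires >= 2 samples and positive per-gene variance (a zero-variance
    gene has no defined correlation and is reported by name).
    """
    X = profiles.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene")
    sd = X.std(axis=1)
    if (sd == 0).any():
        gene = profiles.index[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance gene {gene!r}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def hcluster_cut(distance: pd.DataFrame, k: int = 3) -> pd.Series:
    """Complete-linkage agglomerative clustering cut to exactly k clusters.

    Labels are renumbered 1..k by first occurrence in the input gene order,
    so the labelling is invariant to the dendrogram's internal numbering.
    """
    n = len(distance)
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n == 1:
        return pd.Series([1], index=distance.index, name="subcluster")
    condensed = squareform(distance.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels.append(relabel[c])
    return pd.Series(labels, index=distance.index, name="subcluster")


@dataclass
class EnrichmentResult:
    """One motif x gene-set Fisher enrichment record.

    a/b: set genes with/without a hit; c/d: background genes with/without.
    ``p`` is the one-sided (enrichment) Fisher exact p; ``q`` is filled by
    enrich_all after BH correction within the gene set's motif family.
    """

    motif_id: str
    gene_set: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float = float("nan")


def _upper_tail_p(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X hypergeometric with the table's margins."""
    total = a + b + c + d
    hit_margin = a + c
    set_size = a + b
    return float(hypergeom.sf(a - 1, total, hit_margin, set_size))


def fisher_enrichment(hit_table: pd.DataFrame, gene_set: list[str],
                      background_set: list[str], motif: str,
                      gene_set_label: str = "set",
                      alternative: str = "greater") -> EnrichmentResult:
    """One-sided Fisher's exact enrichment of motif hits in a gene set.

    The one-sided p equals the hypergeometric upper-tail probability of
    observing >= a hits in the set given the table margins. ``alternative=
    'two-sided'`` is available for users wanting a non-directional test.
    """
    set_s, bg_s = set(gene_set), set(background_set)
    if not set_s or not bg_s:
        raise ValueError("gene_set and background_set must be non-empty")
    if set_s & bg_s:
        raise ValueError("gene_set and background_set overlap")
    col = hit_table[motif]
    a = int(col.loc[list(set_s)].sum())
    b = len(set_s) - a
    c = int(col.loc[list(bg_s)].sum())
    d = len(bg_s) - c
    if alternative == "greater":
        p = _upper_tail_p(a, b, c, d)
    elif alternative == "two-sided":
        from scipy.stats import fisher_exact
        p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentResult(motif_id=motif, gene_set=gene_set_label,
                            a=a, b=b, c=c, d=d, odds_ratio=odds, p=p)


def enrich_all(hit_table: pd.DataFrame, subclusters: pd.Series,
               background_set: list[str],
               alternative: str = "greater",
               bh_scope: str = "per_set") -> pd.DataFrame:
    """Enrichment of every motif in the full set and each sub-cluster.

    The background for the full differential set is ``background_set`` (all
    other promoter-bearing genes); for a sub-cluster it additionally includes
    the differential genes outside that cluster, i.e. always "all other
    genes". BH is applied across motifs within each gene set (or globally
    with ``bh_scope='global'``); rows are sorted by gene set, then raw p.
    """
    if bh_scope not in ("per_set", "global"):
        raise ValueError("bh_scope must be 'per_set' or 'global'")
    de_genes = subclusters.index.tolist()
    missing = set(de_genes) - set(hit_table.index)
    if missing:
        raise ValueError(f"genes absent from hit table: {sorted(missing)[:5]}")
    sets: list[tuple[str, list[str], list[str]]] = [
        ("all", de_genes, list(background_set))]
    for c in sorted(subclusters.unique()):
        members = subclusters.index[subclusters == c].tolist()
        others = [g for g in de_genes if g not in set(members)]
        sets.append((f"cluster{c}", members, list(background_set) + others))
    rows = []
    for label, genes, bg in sets:
        for motif in hit_table.columns:
            res = fisher_enrichment(hit_table, genes, bg, motif,
                                    gene_set_label=label,
                                    alternative=alternative)
            rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if bh_scope == "per_set":
        out["q"] = np.nan
        for label in out["gene_set"].unique():
            mask = out["gene_set"] == label
            out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    else:
        out["q"] = bh_adjust(out["p"].to_numpy())
    set_order = {label: i for i, (label, _, _) in enumerate(sets)}
    out = out.sort_values(by=["gene_set", "p", "motif_id"],
                          key=lambda col: col.map(set_order)
                          if col.name == "gene_set" else col,
                          kind="mergesort").reset_index(drop=True)
    return out


def promoter_mapped_genes(genes: list[str], probe_map: pd.DataFrame,
                          promoters: dict[str, str]) -> list[str]:
    """Filter to genes with an unambiguous probe mapping and a promoter.

    Mirrors the selection step between differential testing and promoter
    analysis: a gene survives only if at least one probe maps to it
    unambiguously and its promoter sequence is available.
    """
    ok = probe_map.loc[~probe_map["ambiguous"], "gene_id"]
    unambiguous = set(ok) - {""}
    return [g for g in genes if g in unambiguous and g in promoters]
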