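"""Rank-score filtering of responsive genes and profile clustering.

Each gene's response in one replicate is summarized by two numbers computed
on absolute log2 fold change: the time-averaged mean FE_mean and the peak
FE_peak. Both are normalized to their across-gene maximum within the
replicate and combined into the rank score

    s = sqrt(FE_mean_norm^2 + FE_peak_norm^2)  in [0, sqrt(2)].

Ranking is performed separately per biological replicate; genes common to
the per-replicate top-k lists form the responsive set, which is k-means
clustered on signed mean profiles, and the other genotype's profiles are
superimposed cluster by cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from tc2tf.preprocess import FoldChangeCube

logger = logging.getLogger(__name__)


def rank_genes(cube: FoldChangeCube, genotype: str = "wt"
               ) -> dict[int, pd.DataFrame]:
    """Per-replicate rank tables, sorted by rank score descending.

    Ties on s are broken by FE_peak descending, then gene id ascending, so
    the ordering is deterministic. Normalization maxima are per replicate.
    """
    if genotype not in cube.data.coords["genotype"].values:
        raise ValueError(f"genotype {genotype!r} not in cube")
    absfc = cube.abs().sel(genotype=genotype)  # gene x time x replicate
    genes = cube.genes
    if len(genes) == 0:
        raise ValueError("empty gene set")
    out: dict[int, pd.DataFrame] = {}
    for rep in cube.replicates:
        block = absfc.sel(replicate=rep).to_numpy()  # gene x time
        fe_mean = block.mean(axis=1)
        fe_peak = block.max(axis=1)
        max_mean = fe_mean.max()
        max_peak = fe_peak.max()
        mean_norm = fe_mean / max_mean if max_mean > 0 else np.zeros_like(fe_mean)
        peak_norm = fe_peak / max_peak if max_peak > 0 else np.zeros_like(fe_peak)
        score = np.sqrt(mean_norm ** 2 + peak_norm ** 2)
        table = pd.DataFrame({
            "gene_id": genes, "replicate": rep,
            "fe_mean": fe_mean, "fe_peak": fe_peak,
            "fe_mean_norm": mean_norm, "fe_peak_norm": peak_norm,
            "score": score,
        })
        table = table.sort_values(
            by=["score", "fe_peak", "gene_id"],
            ascending=[False, False, True], kind="mergesort",
        ).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        out[rep] = table
    return out


def intersect_top_k(rank_tables: dict[int, pd.DataFrame], k: int) -> list[str]:
    """Genes common to the top-k of every replicate's rank list (sorted)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if not rank_tables:
        raise ValueError("no rank tables")
    shortest = min(len(t) for t in rank_tables.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest rank list length {shortest}")
    sets = [set(t["gene_id"].iloc[:k]) for t in rank_tables.values()]
    common = set.intersection(*sets)
    return sorted(common)


@dataclass
class ClusterAssignment:
    """k-means cluster labels (1..k) with per-cluster mean profiles."""

    labels: pd.Series           # gene_id -> cluster label
    centers: pd.DataFrame       # cluster x time, signed mean log2 FC
    inertia: float

    @property
    def k(self) -> int:
        return len(self.centers)

    def genes_in(self, cluster: int) -> list[str]:
        return self.labels.index[self.labels == cluster].tolist()


def mean_profiles(cube: FoldChangeCube, genes: list[str], genotype: str
                  ) -> pd.DataFrame:
    """Signed log2 FC averaged over replicates: gene x non-zero time."""
    sub = cube.data.sel(genotype=genotype, gene=genes)
    prof = sub.mean(dim="replicate")
    return pd.DataFrame(prof.to_numpy(), index=genes, columns=cube.times)


def kmeans_profiles(genes: list[str], cube: FoldChangeCube, k: int = 6,
                    n_restarts: int = 10, seed: int = 0,
                    genotype: str = "wt") -> ClusterAssignment:
    """Cluster signed mean profiles with Lloyd k-means, best of n_restarts.

    Cluster labels are renumbered 1..k by decreasing cluster size (ties by
    first gene occurrence) so the labelling is reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes {len(genes)}")
    profiles = mean_profiles(cube, genes, genotype)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    raw = km.fit_predict(profiles.to_numpy())
    # stable relabeling: by size desc, then first occurrence
    order = sorted(range(k), key=lambda c: (-(raw == c).sum(),
                                            int(np.argmax(raw == c))))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=profiles.index,
                       name="cluster")
    centers = pd.DataFrame(km.cluster_centers_[order],
                           index=range(1, k + 1), columns=profiles.columns)
    return ClusterAssignment(labels=labels, centers=centers,
                             inertia=float(km.inertia_))


def superimpose(assignment: ClusterAssignment, cube: FoldChangeCube,
                other_genotype: str = "ko", base_genotype: str = "wt"
                ) -> pd.DataFrame:
    """Per-cluster mean +- sd profiles for both genotypes, tidy format.

    Genes absent from the other genotype are dropped with a logged warning.
    Columns: cluster, genotype, time_h, mean, sd, n.
    """
    available = set(cube.genes)
    rows = []
    for cluster in range(1, assignment.k + 1):
        genes = assignment.genes_in(cluster)
        usable = [g for g in genes if g in available]
        dropped = set(genes) - set(usable)
        if dropped:
            logger.warning("cluster %d: %d genes missing in genotype %s, "
                           "dropped", cluster, len(dropped), other_genotype)
        if not usable:
            continue
        for genotype in (base_genotype, other_genotype):
            prof = cube.data.sel(genotype=genotype, gene=usable)
            per_gene = prof.mean(dim="replicate")  # gene x time
            for t in cube.times:
                vals = per_gene.sel(time_h=t).to_numpy()
                rows.append({
                    "cluster": cluster, "genotype": genotype, "time_h": t,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals)})
    return pd.DataFrame(rows)
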