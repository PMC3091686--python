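"""Quantile normalization and control-referenced fold-change computation.

The pipeline works on log2 intensities throughout. Normalization forces all
sample columns onto the identical value multiset (the across-column mean of
order statistics), and fold change is computed per replicate against the t=0
control of the same genotype and replicate, then collapsed from probes to
genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from tc2tf.io_formats import GENOTYPES, FormatError, validate_design


@dataclass
class ExpressionDataset:
    """Probe x sample log2 intensity matrix plus design and probe->gene map.

    ``values`` columns correspond one-to-one to ``design`` rows (keyed by
    sample_id); ``probe_map`` has one row per probe with ``gene_id`` (empty
    when unmapped) and an ``ambiguous`` flag for probes hitting more than one
    gene.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    probe_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        if set(self.values.columns) != set(self.design["sample_id"]):
            raise ValueError("expression columns and design sample_ids differ")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        known = set(self.probe_map["probe_id"])
        missing = set(self.values.index) - known
        if missing:
            raise ValueError(
                f"probes absent from probe map: {sorted(missing)[:5]}")

    @property
    def time_grid(self) -> list[float]:
        return sorted(set(self.design["time_h"]))

    @property
    def replicates(self) -> list[int]:
        return sorted(set(self.design["replicate"]))

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(values=values, design=self.design,
                                 probe_map=self.probe_map)


@dataclass
class FoldChangeCube:
    """Signed log2 fold change vs the replicate-matched t=0 control.

    ``data`` is a labelled array with dims (genotype, gene, time_h, replicate)
    over the non-zero time points.
    """

    data: xr.DataArray

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.data.coords["gene"].values]

    @property
    def times(self) -> list[float]:
        return [float(t) for t in self.data.coords["time_h"].values]

    @property
    def replicates(self) -> list[int]:
        return [int(r) for r in self.data.coords["replicate"].values]

    def abs(self) -> xr.DataArray:
        return np.abs(self.data)

    def to_tidy(self) -> pd.DataFrame:
        df = self.data.to_dataframe("log2fc").reset_index()
        return df[["gene", "genotype", "time_h", "replicate", "log2fc"]]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean of order statistics.

    After normalization every column holds the identical sorted value
    multiset; within-column rank order is preserved and ties receive the mean
    of the tied reference quantiles.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one column")
    if not np.isfinite(X).all():
        raise ValueError("missing or non-finite values")
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        # runs of tied values share the mean of their reference quantiles
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        csum = np.concatenate(([0.0], np.cumsum(ref)))
        run_means = (csum[ends] - csum[starts]) / (ends - starts)
        assigned = np.repeat(run_means, ends - starts)
        out[order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _sample_lookup(design: pd.DataFrame) -> dict[tuple[str, float, int], str]:
    lut: dict[tuple[str, float, int], str] = {}
    for row in design.itertuples(index=False):
        lut[(row.genotype, float(row.time_h), int(row.replicate))] = row.sample_id
    return lut


def fold_change_cube(dataset: ExpressionDataset) -> FoldChangeCube:
    """Compute the gene x time x replicate signed log2 fold-change cube.

    Probes with an ambiguous or missing gene mapping are dropped; multiple
    probes per gene are collapsed by keeping, per (gene, genotype, replicate),
    the probe whose time series attains the largest |log2 FC| (ties broken by
    probe id).
    """
    pm = dataset.probe_map.set_index("probe_id")
    keep = [p for p in dataset.values.index
            if p in pm.index and not pm.loc[p, "ambiguous"] and pm.loc[p, "gene_id"]]
    if not keep:
        raise ValueError("no unambiguously mapped probes")
    values = dataset.values.loc[keep]
    gene_of = pm.loc[keep, "gene_id"]

    genotypes = [g for g in GENOTYPES if g in set(dataset.design["genotype"])]
    times = [t for t in dataset.time_grid if t != 0]
    if not times:
        raise ValueError("design has no non-zero time points")
    reps = dataset.replicates
    lut = _sample_lookup(dataset.design)
    for gt in genotypes:
        for rep in reps:
            if (gt, 0.0, rep) not in lut:
                raise ValueError(
                    f"missing t=0 control for (genotype={gt}, replicate={rep})")

    # probe-level fold changes: (probe, genotype, time, rep)
    probe_fc = np.full((len(keep), len(genotypes), len(times), len(reps)), np.nan)
    for a, gt in enumerate(genotypes):
        for c, rep in enumerate(reps):
            ctrl = values[lut[(gt, 0.0, rep)]].to_numpy()
            for b, t in enumerate(times):
                key = (gt, float(t), rep)
                if key not in lut:
                    raise ValueError(
                        f"missing sample for (genotype={gt}, time_h={t}, "
                        f"replicate={rep})")
                probe_fc[:, a, b, c] = values[lut[key]].to_numpy() - ctrl

    genes = sorted(set(gene_of))
    gene_fc = np.empty((len(genotypes), len(genes), len(times), len(reps)))
    probe_index = pd.Index(keep)
    for gi, gene in enumerate(genes):
        rows = np.flatnonzero((gene_of == gene).to_numpy())
        if len(rows) == 1:
            gene_fc[:, gi] = probe_fc[rows[0]].copy()
            continue
        # deterministic representative: max over time of |FC|, tie -> probe id
        block = probe_fc[rows]  # (nprobe, gt, time, rep)
        peak = np.abs(block).max(axis=2)  # (nprobe, gt, rep)
        order = np.argsort(probe_index[rows])  # lexicographic probe ids
        for a in range(len(genotypes)):
            for c in range(len(reps)):
                cand = order[np.argmax(peak[order, a, c])]
                gene_fc[a, gi, :, c] = block[cand, a, :, c]

    data = xr.DataArray(
        gene_fc,
        dims=("genotype", "gene", "time_h", "replicate"),
        coords={"genotype": genotypes, "gene": genes,
                "time_h": times, "replicate": reps},
        name="log2fc",
    )
    return FoldChangeCube(data=data)


def subtract_offset(matrix: pd.DataFrame, offset: float) -> pd.DataFrame:
    """Constant-offset subtraction for linear-scale input (clipped at a floor).

    A plain additive background adjustment offered for users whose input
    carries a uniform offset; applied on the linear scale before the log2
    transform.
    """
    linear = np.power(2.0, matrix) - offset
    floor = np.maximum(linear, 2.0 ** -10)
    return pd.DataFrame(np.log2(floor), index=matrix.index,
                        columns=matrix.columns)
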