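"""Synthetic expression kinetics and promoter/motif fixtures with ground truth.

The generator emulates the statistical structure of a two-genotype (wild type
vs knockout) stimulation time course in which all responsive genes share a
receptor-independent early response, while only the wild type maintains the
altered level through late time points — in the knockout the response decays
back to baseline between 12 and 24 h. Promoters are i.i.d. background DNA
with motif instances planted at configurable frequency, so the downstream
scanning and enrichment stages can be validated against known truth.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Collection, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tc2tf.io_formats import (PwmRecord, write_design_tsv, write_expression_tsv,
                              write_fasta, write_probe_map_tsv,
                              write_transfac)
from tc2tf.preprocess import ExpressionDataset

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Late-phase retention of the sustained wild-type response, as a fraction of
#: the peak amplitude, anchored at (1x, 2x) the decay time point. A mild
#: decline that stays >= 0.8 of the peak.
SUSTAINED_RETENTION = (0.9, 0.8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the expression simulator.

    Defaults describe the emulated study conditions: a 0/6/12/24/48 h grid,
    three biological replicates per genotype, ~7.5% responsive genes with a
    2.0 log2-unit peak response, Gaussian log-scale noise of 0.3 sd, and the
    knockout decay completing at 24 h.
    """

    n_genes: int = 2000
    time_grid_h: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 48.0)
    n_replicates: int = 3
    frac_responsive: float = 0.075
    frac_sustained_of_responsive: float = 0.6
    frac_repressed_of_responsive: float = 0.4
    amplitude_log2: float = 2.0
    noise_sd_log2: float = 0.3
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.5
    interaction_time_h: float = 24.0
    frac_ambiguous_probes: float = 0.01
    frac_duplicate_probes: float = 0.02
    frac_missing_promoter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_responsive", "frac_sustained_of_responsive",
                     "frac_repressed_of_responsive", "frac_ambiguous_probes",
                     "frac_duplicate_probes", "frac_missing_promoter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        grid = tuple(float(t) for t in self.time_grid_h)
        if grid[0] != 0.0 or sorted(grid) != list(grid) or len(set(grid)) != len(grid):
            raise ValueError("time_grid_h must be increasing and start at 0")
        if len(grid) < 2:
            raise ValueError("time grid needs at least one non-zero point")
        if self.amplitude_log2 <= 0:
            raise ValueError("amplitude_log2 must be positive")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be non-negative")
        if self.interaction_time_h not in grid:
            raise ValueError("interaction_time_h must lie on the time grid")
        n_resp = int(round(self.frac_responsive * self.n_genes))
        if self.frac_responsive > 0 and n_resp == 0:
            raise ValueError(
                "n_genes too small to honor frac_responsive")
        if n_resp:
            n_sust = int(round(self.frac_sustained_of_responsive * n_resp))
            if self.frac_sustained_of_responsive > 0 and n_sust == 0:
                raise ValueError(
                    "n_genes too small to honor frac_sustained_of_responsive")


@dataclass
class TruthLabels:
    """Ground truth of a simulated dataset.

    ``classes`` holds one row per gene (gene_id, klass, direction);
    ``trajectories`` maps genotype -> gene x non-zero-time true mean log2 FC;
    ``planted`` records exact planted motif instances (filled by
    generate_promoters).
    """

    classes: pd.DataFrame
    trajectories: dict[str, pd.DataFrame] = field(default_factory=dict)
    planted: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "motif_id", "position", "strand", "instance"]))

    def genes_of_class(self, klass: str) -> list[str]:
        mask = self.classes["klass"] == klass
        return self.classes.loc[mask, "gene_id"].tolist()


def _response_shape(klass: str, genotype: str, times: np.ndarray,
                    decay_time: float) -> np.ndarray:
    """Unit-amplitude response at the non-zero grid times.

    Early phase (t <= 12 h) is at full amplitude for every responsive gene in
    both genotypes. Transient genes — and the knockout copy of sustained
    genes — then decay linearly to baseline by ``decay_time``. The sustained
    wild-type response declines only mildly and stays >= 0.8 of the peak.
    """
    if klass == "nonresponsive":
        return np.zeros_like(times)
    early_end = min(12.0, decay_time / 2.0)
    if klass == "sustained" and genotype == "wt":
        xp = [early_end, decay_time, 2.0 * decay_time]
        fp = [1.0, SUSTAINED_RETENTION[0], SUSTAINED_RETENTION[1]]
    else:  # transient in either genotype, or sustained in the knockout
        xp = [early_end, decay_time]
        fp = [1.0, 0.0]
    out = np.interp(times, xp, fp, left=1.0, right=fp[-1])
    out[times <= 0] = 0.0
    return out


def true_trajectories(classes: pd.DataFrame, times: Sequence[float],
                      amplitude: float, decay_time: float
                      ) -> dict[str, pd.DataFrame]:
    times = np.asarray([t for t in times if t > 0], dtype=float)
    out = {}
    for genotype in ("wt", "ko"):
        rows = []
        for row in classes.itertuples(index=False):
            sign = {"up": 1.0, "down": -1.0, "none": 0.0}[row.direction]
            shape = _response_shape(row.klass, genotype, times, decay_time)
            rows.append(sign * amplitude * shape)
        out[genotype] = pd.DataFrame(np.asarray(rows),
                                     index=classes["gene_id"], columns=times)
    return out


def _assign_classes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = max(4, len(str(config.n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    n_resp = int(round(config.frac_responsive * config.n_genes))
    n_sust = int(round(config.frac_sustained_of_responsive * n_resp))
    responsive = rng.choice(config.n_genes, size=n_resp, replace=False)
    klass = np.array(["nonresponsive"] * config.n_genes, dtype=object)
    klass[responsive[:n_sust]] = "sustained"
    klass[responsive[n_sust:]] = "transient"
    direction = np.array(["none"] * config.n_genes, dtype=object)
    for idx in (responsive[:n_sust], responsive[n_sust:]):
        n_down = int(round(config.frac_repressed_of_responsive * len(idx)))
        shuffled = rng.permutation(idx)
        direction[shuffled[:n_down]] = "down"
        direction[shuffled[n_down:]] = "up"
    return pd.DataFrame({"gene_id": genes, "klass": klass,
                         "direction": direction})


def generate_expression_dataset(config: SimConfig
                                ) -> tuple[ExpressionDataset, TruthLabels]:
    """Simulate a probe x sample log2 intensity matrix with known kinetics.

    Log2 intensity = per-gene baseline + genotype-specific true trajectory +
    i.i.d. Gaussian noise. One t=0 control per (genotype, replicate). A small
    fraction of extra probes is flagged ambiguous and a fraction of genes
    carries a second (attenuated) probe, to exercise the downstream mapping
    and collapsing filters.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_class, rng_base, rng_noise, rng_extra = (
        np.random.default_rng(s) for s in root.spawn(4))

    classes = _assign_classes(config, rng_class)
    genes = classes["gene_id"].tolist()
    times = [float(t) for t in config.time_grid_h]
    nonzero = [t for t in times if t > 0]
    traj = true_trajectories(classes, times, config.amplitude_log2,
                             config.interaction_time_h)

    baseline = rng_base.normal(config.baseline_mean_log2,
                               config.baseline_sd_log2, size=config.n_genes)

    design_rows = []
    for genotype in ("wt", "ko"):
        for rep in range(1, config.n_replicates + 1):
            for t in times:
                design_rows.append({
                    "sample_id": f"{genotype}_t{int(t):02d}_r{rep}",
                    "genotype": genotype, "time_h": t, "replicate": rep})
    design = pd.DataFrame(design_rows)

    # gene-level signal per sample
    signal = np.empty((config.n_genes, len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        if row.time_h == 0:
            signal[:, j] = baseline
        else:
            signal[:, j] = baseline + traj[row.genotype][row.time_h].to_numpy()

    # probes: one primary per gene, optional attenuated duplicates,
    # plus ambiguous decoys carrying baseline-level noise only
    n_dup = int(round(config.frac_duplicate_probes * config.n_genes))
    dup_idx = rng_extra.choice(config.n_genes, size=n_dup, replace=False)
    n_amb = int(round(config.frac_ambiguous_probes * config.n_genes))

    probe_ids = [f"p_{g}" for g in genes]
    probe_gene = list(genes)
    probe_signal = [signal]
    if n_dup:
        probe_ids += [f"p_{genes[i]}_b" for i in dup_idx]
        probe_gene += [genes[i] for i in dup_idx]
        attenuated = baseline[dup_idx, None] + 0.6 * (signal[dup_idx]
                                                      - baseline[dup_idx, None])
        probe_signal.append(attenuated)
    amb_flags = [False] * len(probe_ids)
    if n_amb:
        amb_targets = rng_extra.choice(config.n_genes, size=n_amb, replace=False)
        probe_ids += [f"amb_{i + 1:04d}" for i in range(n_amb)]
        probe_gene += [genes[i] for i in amb_targets]
        amb_flags += [True] * n_amb
        probe_signal.append(np.repeat(
            rng_extra.normal(config.baseline_mean_log2,
                             config.baseline_sd_log2, size=(n_amb, 1)),
            len(design), axis=1))

    full_signal = np.vstack(probe_signal)
    noise = rng_noise.normal(0.0, config.noise_sd_log2, size=full_signal.shape)
    values = pd.DataFrame(full_signal + noise, index=pd.Index(probe_ids, name="probe_id"),
                          columns=design["sample_id"])
    probe_map = pd.DataFrame({"probe_id": probe_ids, "gene_id": probe_gene,
                              "ambiguous": amb_flags})
    dataset = ExpressionDataset(values=values, design=design,
                                probe_map=probe_map)
    truth = TruthLabels(classes=classes, trajectories=traj)
    return dataset, truth


def generate_interaction_dataset(n_genes: int = 2000, n_planted: int = 100,
                                 delta_log2: float = 1.5,
                                 noise_sd_log2: float = 0.3,
                                 time_grid_h: Sequence[float] = (0, 6, 12, 24, 48),
                                 n_replicates: int = 3,
                                 interaction_time_h: float = 24.0,
                                 baseline_mean_log2: float = 8.0,
                                 baseline_sd_log2: float = 1.5,
                                 seed: int = 0
                                 ) -> tuple[ExpressionDataset, list[str]]:
    """Dataset with a genotype x time interaction planted at one time point only.

    The first ``n_planted`` genes (after shuffling) respond identically in
    both genotypes everywhere except at ``interaction_time_h``, where the
    knockout is shifted by ``delta_log2``. Returns the dataset and the list
    of planted gene ids. Used to probe the specificity of the per-time
    interaction contrast.
    """
    root = np.random.SeedSequence(seed)
    rng_pick, rng_base, rng_noise = (np.random.default_rng(s)
                                     for s in root.spawn(3))
    width = max(4, len(str(n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    planted_idx = rng_pick.choice(n_genes, size=n_planted, replace=False)
    planted = [genes[i] for i in sorted(planted_idx)]

    times = [float(t) for t in time_grid_h]
    design_rows = []
    for genotype in ("wt", "ko"):
        for rep in range(1, n_replicates + 1):
            for t in times:
                design_rows.append({
                    "sample_id": f"{genotype}_t{int(t):02d}_r{rep}",
                    "genotype": genotype, "time_h": t, "replicate": rep})
    design = pd.DataFrame(design_rows)

    baseline = rng_base.normal(baseline_mean_log2, baseline_sd_log2,
                               size=n_genes)
    signal = np.repeat(baseline[:, None], len(design), axis=1)
    is_planted = np.zeros(n_genes, dtype=bool)
    is_planted[planted_idx] = True
    for j, row in enumerate(design.itertuples(index=False)):
        if row.genotype == "ko" and row.time_h == interaction_time_h:
            signal[is_planted, j] += delta_log2
    noise = rng_noise.normal(0.0, noise_sd_log2, size=signal.shape)
    values = pd.DataFrame(signal + noise,
                          index=pd.Index([f"p_{g}" for g in genes],
                                         name="probe_id"),
                          columns=design["sample_id"])
    probe_map = pd.DataFrame({"probe_id": values.index,
                              "gene_id": genes,
                              "ambiguous": False})
    dataset = ExpressionDataset(values=values, design=design,
                                probe_map=probe_map)
    return dataset, planted


# ---------------------------------------------------------------------------
# Motif and promoter generation
# ---------------------------------------------------------------------------

def _ic_of_p(p: float) -> float:
    """Per-position information content (bits) with one dominant base at
    probability p and the rest uniform."""
    rest = (1.0 - p) / 3.0
    terms = [p] + [rest] * 3
    h = -sum(q * np.log2(q) for q in terms if q > 0)
    return 2.0 - h


def generate_pwm_library(n_motifs: int, length_range: tuple[int, int] = (8, 12),
                         information_content_range: tuple[float, float] = (1.0, 1.8),
                         seed: int = 0, total_count: float = 100.0
                         ) -> list[PwmRecord]:
    """Random count matrices with controlled per-position information content.

    Each position has one dominant base whose probability is solved so the
    position's information content matches a draw from the requested range
    (0 bits = uniform, 2 bits = deterministic base).
    """
    lo, hi = information_content_range
    if not (0.0 <= lo <= hi <= 2.0):
        raise ValueError("information content must lie in [0, 2] bits "
                         "for a 4-letter alphabet")
    if length_range[0] < 4:
        raise ValueError("motif length must be >= 4")
    rng = np.random.default_rng(seed)
    records = []
    for m in range(n_motifs):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        counts = np.zeros((4, L))
        for j in range(L):
            target = float(rng.uniform(lo, hi))
            if target <= 1e-12:
                p = 0.25
            elif target >= 2.0 - 1e-12:
                p = 1.0
            else:
                p = brentq(lambda q: _ic_of_p(q) - target, 0.25 + 1e-12,
                           1.0 - 1e-12)
            dom = int(rng.integers(0, 4))
            probs = np.full(4, (1.0 - p) / 3.0)
            probs[dom] = p
            # real count matrices have uneven non-dominant counts; perfectly
            # symmetric ones collapse window scores onto a coarse lattice
            # (score = number of consensus matches), which breaks the
            # near-continuity that permutation calibration relies on. The
            # jitter vanishes at both entropy extremes so those stay exact.
            jitter_sd = 0.25 * target * (2.0 - target)
            if jitter_sd > 0 and p < 1.0:
                others = np.array([i for i in range(4) if i != dom])
                w = probs[others] * np.exp(rng.normal(0.0, jitter_sd, 3))
                probs[others] = w * (1.0 - p) / w.sum()
            counts[:, j] = np.round(probs * total_count, 3)
        counts[:, counts.sum(axis=0) == 0] = total_count / 4.0  # degenerate guard
        records.append(PwmRecord(motif_id=f"M{m + 1:03d}",
                                 name=f"synthetic_motif_{m + 1}",
                                 counts=counts))
    return records


@dataclass(frozen=True)
class PlantingRule:
    """Plant ``motif_id`` into each promoter of ``genes`` with ``probability``."""

    motif_id: str
    genes: frozenset[str]
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("planting probability outside [0, 1]")


def _sample_instance(pwm: PwmRecord, rng: np.random.Generator) -> str:
    probs = pwm.counts / pwm.counts.sum(axis=0, keepdims=True)
    letters = [BASES[rng.choice(4, p=probs[:, j])] for j in range(pwm.length)]
    return "".join(letters)


def generate_promoters(gene_ids: Iterable[str], pwm_library: Sequence[PwmRecord],
                       planting_plan: Sequence[PlantingRule] = (),
                       length: int = 4000,
                       background_freqs: Sequence[float] | None = None,
                       seed: int = 0
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Background promoters with motif instances planted at known positions.

    Each promoter is i.i.d. background sequence; for every planting rule that
    covers the gene and fires (Bernoulli with the rule's probability), 1-3
    instances sampled from the motif's count-proportional distribution are
    written at random non-overlapping positions on a random strand. Returns
    the FASTA mapping and a table of exact planted instances.
    """
    bg = np.full(4, 0.25) if background_freqs is None else np.asarray(
        background_freqs, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background_freqs must be 4 positive values summing to 1")
    by_id = {p.motif_id: p for p in pwm_library}
    for rule in planting_plan:
        if rule.motif_id not in by_id:
            raise ValueError(f"unknown motif {rule.motif_id!r} in planting plan")
        if by_id[rule.motif_id].length > length:
            raise ValueError(
                f"motif {rule.motif_id!r} longer than promoter length {length}")
    rng = np.random.default_rng(seed)
    promoters: dict[str, str] = {}
    planted_rows = []
    for gene in gene_ids:
        seq = list(rng.choice(BASES, size=length, p=bg))
        occupied: list[tuple[int, int]] = []
        for rule in planting_plan:
            if gene not in rule.genes or rng.random() >= rule.probability:
                continue
            pwm = by_id[rule.motif_id]
            for _ in range(int(rng.integers(1, 4))):
                instance = _sample_instance(pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                written = instance if strand == "+" else reverse_complement(instance)
                for _attempt in range(100):
                    pos = int(rng.integers(0, length - pwm.length + 1))
                    span = (pos, pos + pwm.length)
                    if all(span[1] <= a or span[0] >= b for a, b in occupied):
                        seq[span[0]:span[1]] = list(written)
                        occupied.append(span)
                        planted_rows.append({
                            "gene_id": gene, "motif_id": rule.motif_id,
                            "position": pos, "strand": strand,
                            "instance": instance})
                        break
        promoters[gene] = "".join(seq)
    planted = pd.DataFrame(planted_rows, columns=["gene_id", "motif_id",
                                                  "position", "strand",
                                                  "instance"])
    return promoters, planted


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(outdir: str | Path, config: SimConfig,
                         n_motifs: int = 4, promoter_length: int = 4000,
                         planted_motif_prob: float = 0.75,
                         background_motif_prob: float = 0.20,
                         n_perm_note: int | None = None) -> dict[str, Path]:
    """Generate and write the full fixture bundle for a pipeline run.

    Writes expression/design/probe-map TSVs, promoter FASTA, a TRANSFAC motif
    library, and a JSON-lines truth table. The first motif of the library is
    planted into the promoters of sustained genes at ``planted_motif_prob``
    and into all other promoters at ``background_motif_prob``, so the
    enrichment stage has a recoverable signal.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_expression_dataset(config)
    root = np.random.SeedSequence(config.seed + 1)
    s_pwm, s_prom, s_drop = root.spawn(3)

    motifs = generate_pwm_library(n_motifs, seed=int(s_pwm.generate_state(1)[0]
                                                     % 2**31))
    genes = truth.classes["gene_id"].tolist()
    sustained = frozenset(truth.genes_of_class("sustained"))
    others = frozenset(genes) - sustained
    plan = [
        PlantingRule(motifs[0].motif_id, sustained, planted_motif_prob),
        PlantingRule(motifs[0].motif_id, others, background_motif_prob),
    ]
    rng_drop = np.random.default_rng(s_drop)
    n_drop = int(round(config.frac_missing_promoter * len(genes)))
    dropped = set(rng_drop.choice(genes, size=n_drop, replace=False))
    with_prom = [g for g in genes if g not in dropped]
    promoters, planted = generate_promoters(
        with_prom, motifs, plan, length=promoter_length,
        seed=int(s_prom.generate_state(1)[0] % 2**31))
    truth.planted = planted

    params = {"seed": config.seed, "n_genes": config.n_genes}
    paths = {
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "promoters": outdir / "promoters.fasta",
        "motifs": outdir / "motifs.transfac",
        "truth": outdir / "truth.jsonl",
    }
    write_expression_tsv(dataset.values, paths["expression"], params=params)
    write_design_tsv(dataset.design, paths["design"], params=params)
    write_probe_map_tsv(dataset.probe_map, paths["probe_map"], params=params)
    write_fasta(promoters, paths["promoters"])
    write_transfac(motifs, paths["motifs"])
    with open(paths["truth"], "w") as fh:
        for row in truth.classes.itertuples(index=False):
            fh.write(pd.Series({"gene_id": row.gene_id, "klass": row.klass,
                                "direction": row.direction}).to_json() + "\n")
        for row in planted.itertuples(index=False):
            fh.write(pd.Series(row._asdict()).to_json() + "\n")
    return paths
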