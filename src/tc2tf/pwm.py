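"""Log-odds PWM scanning with permutation-calibrated per-promoter p-values.

A count matrix is converted to log2-odds weights against a background base
composition with a pseudocount split by background. The per-promoter
statistic is the maximum window score over both strands; its null
distribution is obtained by rescoring composition-preserving random letter
shuffles of the same promoter, and the p-value uses the add-one estimator

    p = (1 + #{null best-scores >= observed}) / (n_perm + 1),

so p is bounded below by 1/(n_perm + 1) and never exactly zero. A promoter
is a hit for a motif when p < alpha (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tc2tf.io_formats import PwmRecord
from tc2tf.simulate import reverse_complement  # re-exported convenience

_CODE = np.full(256, 4, dtype=np.int8)
for i, ch in enumerate("ACGT"):
    _CODE[ord(ch)] = i
    _CODE[ord(ch.lower())] = i

#: finite stand-in for -inf so N-containing windows can never win
_NEG = np.float64(-1e30)


@dataclass
class LogOddsPwm:
    """Log2-odds weights of a count matrix against a background model.

    weight(a, j) = log2((count(a,j) + beta*b_a) / ((n_j + beta) * b_a)).
    Row 5 of the internal scoring matrix (index 4, the N code) is a large
    negative constant, so any window containing N scores below every
    N-free window.
    """

    motif_id: str
    weights: np.ndarray            # 4 x L
    background: np.ndarray
    pseudocount: float

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    def scoring_matrix(self) -> np.ndarray:
        W = np.vstack([self.weights, np.full(self.length, _NEG)])
        return W

    def scoring_matrix_rc(self) -> np.ndarray:
        # complement swaps A<->T and C<->G (rows 0<->3, 1<->2), reverse positions
        W = self.weights[[3, 2, 1, 0], ::-1]
        return np.vstack([W, np.full(self.length, _NEG)])


def build_logodds(pwm: PwmRecord, background=(0.25, 0.25, 0.25, 0.25),
                  pseudocount: float = 1.0) -> LogOddsPwm:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    if (bg <= 0).any():
        raise ValueError("zero background frequency")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = pwm.counts
    n_j = counts.sum(axis=0)
    weights = np.log2((counts + pseudocount * bg[:, None])
                      / ((n_j + pseudocount)[None, :] * bg[:, None]))
    return LogOddsPwm(motif_id=pwm.motif_id, weights=weights,
                      background=bg, pseudocount=float(pseudocount))


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes (A=0, C=1, G=2, T=3, N=4); case-blind."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def _window_scores(codes: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Scores of all length-L windows for a batch of coded sequences.

    ``codes`` is (P, seqlen), ``W`` a 5 x L scoring matrix; returns
    (P, seqlen - L + 1) float64 scores.
    """
    P, n = codes.shape
    L = W.shape[1]
    n_win = n - L + 1
    if n_win < 1:
        raise ValueError(f"sequence length {n} shorter than motif length {L}")
    scores = np.zeros((P, n_win))
    for j in range(L):
        scores += W[codes[:, j:j + n_win], j]
    return scores


def best_score(sequence: str, pwm: LogOddsPwm
               ) -> tuple[float, int, str]:
    """Maximum log2-odds window score over both strands.

    Returns (score, 0-based forward position of the window start, strand).
    Ties break toward the smaller position, then the + strand. Windows
    containing N never beat an N-free window.
    """
    codes = encode(sequence)[None, :]
    fwd = _window_scores(codes, pwm.scoring_matrix())[0]
    rev = _window_scores(codes, pwm.scoring_matrix_rc())[0]
    best = max(fwd.max(), rev.max())
    # the two strands sum weights in different orders, so true ties can
    # differ in the last bits; compare with a small tolerance
    tol = 1e-9
    fwd_hits = np.flatnonzero(fwd >= best - tol)
    rev_hits = np.flatnonzero(rev >= best - tol)
    pos_f = int(fwd_hits[0]) if len(fwd_hits) else None
    pos_r = int(rev_hits[0]) if len(rev_hits) else None
    if pos_f is not None and (pos_r is None or pos_f <= pos_r):
        return float(best), pos_f, "+"
    return float(best), pos_r, "-"


def _best_of_batch(codes: np.ndarray, pwm: LogOddsPwm) -> np.ndarray:
    fwd = _window_scores(codes, pwm.scoring_matrix())
    rev = _window_scores(codes, pwm.scoring_matrix_rc())
    return np.maximum(fwd.max(axis=1), rev.max(axis=1))


def _dinucleotide_shuffle(codes: np.ndarray, rng: np.random.Generator
                          ) -> np.ndarray:
    """Altschul-Erikson shuffle preserving dinucleotide composition."""
    n = len(codes)
    if n < 3:
        return codes.copy()
    edges: dict[int, list[int]] = {}
    for i in range(n - 1):
        edges.setdefault(int(codes[i]), []).append(int(codes[i + 1]))
    last = int(codes[-1])
    for _ in range(200):
        trial = {a: rng.permutation(nbrs).tolist() for a, nbrs in edges.items()}
        # keep one edge into the terminal vertex last for each source
        out = [int(codes[0])]
        counters = {a: 0 for a in trial}
        ok = True
        cur = out[0]
        for _step in range(n - 1):
            nbrs = trial.get(cur)
            if nbrs is None or counters[cur] >= len(nbrs):
                ok = False
                break
            nxt = nbrs[counters[cur]]
            counters[cur] += 1
            out.append(nxt)
            cur = nxt
        if ok and len(out) == n and cur == last:
            return np.asarray(out, dtype=np.int8)
    # fall back to a plain letter shuffle if no Eulerian walk was found
    return rng.permutation(codes)


def _null_batch(codes: np.ndarray, n_perm: int, rng: np.random.Generator,
                shuffle: str) -> np.ndarray:
    if shuffle == "mono":
        tiled = np.tile(codes, (n_perm, 1))
        return rng.permuted(tiled, axis=1)
    if shuffle == "di":
        return np.stack([_dinucleotide_shuffle(codes, rng)
                         for _ in range(n_perm)])
    raise ValueError("shuffle must be 'mono' or 'di'")


def permutation_pvalue(sequence: str, pwm: LogOddsPwm, n_perm: int = 1000,
                       seed: int = 0, alpha: float = 0.1,
                       shuffle: str = "mono") -> dict:
    """Permutation-calibrated best-score p-value for one promoter and motif.

    The null statistic is the best score of a composition-preserving random
    letter shuffle of the promoter, repeated n_perm times.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    codes = encode(sequence)
    obs, pos, strand = best_score(sequence, pwm)
    null = _best_of_batch(_null_batch(codes, n_perm, rng, shuffle), pwm)
    p = (1.0 + int((null >= obs).sum())) / (n_perm + 1.0)
    return {"motif_id": pwm.motif_id, "best_score": obs,
            "best_position": pos, "best_strand": strand,
            "perm_p": p, "n_perm": n_perm, "significant": p < alpha}


def build_hit_table(promoters: dict[str, str],
                    motifs: list[PwmRecord] | list[LogOddsPwm],
                    alpha: float = 0.1, n_perm: int = 1000, seed: int = 0,
                    background=(0.25, 0.25, 0.25, 0.25),
                    pseudocount: float = 1.0,
                    shuffle: str = "mono"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x motif boolean hit table plus the full scan result table.

    One batch of sequence shuffles is drawn per promoter (seeded from
    ``seed``) and scored against every motif, so all motifs share the same
    null sequences for a given promoter — a valid Monte-Carlo null that cuts
    the shuffling cost by the number of motifs.
    """
    if not motifs:
        raise ValueError("empty motif list")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    lodds = [m if isinstance(m, LogOddsPwm)
             else build_logodds(m, background=background,
                                pseudocount=pseudocount)
             for m in motifs]
    genes = list(promoters)
    seeds = np.random.SeedSequence(seed).spawn(len(genes))
    rows = []
    hits = np.zeros((len(genes), len(lodds)), dtype=bool)
    for gi, gene in enumerate(genes):
        rng = np.random.default_rng(seeds[gi])
        codes = encode(promoters[gene])
        null_codes = _null_batch(codes, n_perm, rng, shuffle)
        for mi, lo in enumerate(lodds):
            obs, pos, strand = best_score(promoters[gene], lo)
            null = _best_of_batch(null_codes, lo)
            p = (1.0 + int((null >= obs).sum())) / (n_perm + 1.0)
            sig = p < alpha
            hits[gi, mi] = sig
            rows.append({"gene_id": gene, "motif_id": lo.motif_id,
                         "best_score": obs, "best_position": pos,
                         "best_strand": strand, "perm_p": p,
                         "n_perm": n_perm, "significant": sig})
    hit_table = pd.DataFrame(hits, index=pd.Index(genes, name="gene_id"),
                             columns=[lo.motif_id for lo in lodds])
    return hit_table, pd.DataFrame(rows)
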