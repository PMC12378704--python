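"""Permutation-based significance and candidate selection.

For every aligned candidate row the null distribution of the positive-sum
score is obtained by shuffling the row's nucleotides uniformly at random
and re-inserting them into the row's own non-gap columns (the gap
structure is held fixed), then rescoring. From B such permutations:

* z = (S_obs - mean_null) / sd_null — the ranking key;
* a one-tailed t p-value with t = (S_obs - mean_null) / (sd_null / sqrt(B))
  on B-1 degrees of freedom — the significance filter (deliberately
  aggressive: the sd is scaled by sqrt(B), so almost any above-null score
  is called significant);
* an empirical permutation p-value (1 + #{null >= S_obs}) / (B + 1) — the
  calibrated tail probability at the resolution of B, exposed alongside.

p-values are Benjamini-Hochberg adjusted across all candidates, and the
final set is the top fraction of ALL scanned candidates ranked by z among
those passing the q threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pssm import _BASE_INDEX, PSSM, SeqScore, score_aligned_row
from .scanner import MotifMatch


@dataclass
class NullDistribution:
    """Summary of the permutation null for one row."""

    B: int
    mean: float
    sd: float
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("need at least 2 permutations")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class ScoredCandidate:
    match: MotifMatch
    score: SeqScore
    null: NullDistribution
    p: float
    p_empirical: float
    q: float = math.nan
    z: float = 0.0
    selected: bool = False


def shuffle_sequence(seq: str, rng: np.random.Generator | int) -> str:
    """Uniform random permutation of the characters of ``seq``."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


def permutation_test(
    pssm: PSSM,
    row: str,
    B: int = 1000,
    rng: np.random.Generator | int = 0,
    keep_null: bool = False,
) -> tuple[float, float, NullDistribution, float]:
    """Permutation null for one gapped row.

    Returns ``(p, z, null, p_empirical)`` where ``p`` is the one-tailed
    t p-value described in the module docstring. Degenerate nulls
    (sd = 0, e.g. homopolymer rows) give z = 0 and p = 1 unless the
    observed score exceeds the null mean, in which case p = 1/(B+1).
    """
    if len(row) != pssm.width:
        raise ValueError(f"row width {len(row)} != PSSM width {pssm.width}")
    if B < 2:
        raise ValueError("need at least 2 permutations")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng

    obs = score_aligned_row(pssm, row)
    cols = np.array([i for i, c in enumerate(row) if c != "-"], dtype=int)
    chars = np.array([_BASE_INDEX[row[i]] for i in cols], dtype=int)
    n = len(cols)
    pos = np.clip(pssm.scores, 0.0, None)

    if n == 0:
        null = NullDistribution(B, 0.0, 0.0)
        return 1.0, 0.0, null, 1.0

    # B independent in-row shuffles, vectorized: argsort of uniform noise
    perm = np.argsort(rng.random((B, n)), axis=1)
    shuffled = chars[perm]                      # (B, n) base indices
    null_scores = pos[cols[None, :], shuffled].sum(axis=1)

    mean = float(null_scores.mean())
    sd = float(null_scores.std(ddof=1))
    if sd < 1e-9 * max(1.0, abs(mean)):  # all permutations score identically
        sd = 0.0
    p_emp = float((1 + (null_scores >= obs.value).sum()) / (B + 1))
    null = NullDistribution(B, mean, sd, null_scores if keep_null else None)

    if sd == 0.0:
        if obs.value <= mean:
            return 1.0, 0.0, null, p_emp
        return 1.0 / (B + 1), 0.0, null, p_emp

    z = (obs.value - mean) / sd
    t = (obs.value - mean) / (sd / math.sqrt(B))
    p = float(stats.t.sf(t, df=B - 1))
    return p, float(z), null, p_emp


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_candidates(
    candidates: list[ScoredCandidate],
    q_threshold: float = 0.05,
    top_frac: float = 0.05,
) -> list[ScoredCandidate]:
    """Keep the floor(top_frac * N_total) highest-z among q < q_threshold.

    N_total is the number of ALL scanned candidates, so the q filter can
    only shrink the selection below the nominal top fraction. Ties in z
    break by score, then by genomic coordinate. Sets ``selected`` in place
    and returns the selected subset sorted by descending z.
    """
    n_keep = math.floor(top_frac * len(candidates))
    passing = [c for c in candidates if c.q < q_threshold]
    passing.sort(
        key=lambda c: (-c.z, -c.score.value, c.match.chrom, c.match.start)
    )
    chosen = passing[:n_keep]
    chosen_ids = {id(c) for c in chosen}
    for c in candidates:
        c.selected = id(c) in chosen_ids
    return chosen


def score_candidates(
    pssm_by_group: dict,
    rows_by_group: dict,
    matches_by_group: dict,
    B: int = 1000,
    seed: int = 0,
) -> list[ScoredCandidate]:
    """Run the permutation test for every row of every alignment group,
    then BH-adjust t p-values globally across groups.

    ``rows_by_group`` maps group key -> list of gapped rows; ``matches_by_group``
    maps the same keys to the corresponding MotifMatch objects. Each row
    gets an independent child seed so results do not depend on group
    iteration order.
    """
    root = np.random.default_rng(seed)
    out: list[ScoredCandidate] = []
    for key in sorted(rows_by_group):
        pssm = pssm_by_group[key]
        for match, row in zip(matches_by_group[key], rows_by_group[key]):
            rng = np.random.default_rng(root.integers(2**31))
            p, z, null, p_emp = permutation_test(pssm, row, B=B, rng=rng)
            obs = score_aligned_row(pssm, row)
            out.append(ScoredCandidate(match, obs, null, p, p_emp, z=z))
    if out:
        q = bh_adjust([c.p for c in out])
        for c, qi in zip(out, q):
            c.q = float(qi)
    return out


def candidates_to_frame(candidates: list[ScoredCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.match.chrom for c in candidates],
            "start": [c.match.start for c in candidates],
            "end": [c.match.end for c in candidates],
            "strand": [c.match.strand for c in candidates],
            "seq": [c.match.seq for c in candidates],
            "score": [c.score.value for c in candidates],
            "null_mean": [c.null.mean for c in candidates],
            "null_sd": [c.null.sd for c in candidates],
            "p": [c.p for c in candidates],
            "p_empirical": [c.p_empirical for c in candidates],
            "q": [c.q for c in candidates],
            "z": [c.z for c in candidates],
            "selected": [c.selected for c in candidates],
        }
    )
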