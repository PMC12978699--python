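"""Exact null-model statistics for observed cyst fragmentation patterns.

The observed data are 7- to 10-cell cysts scored for whether the gap in
their stabilized-microtubule network predicts release of a 6-cell cyst.
Under the random-breakage null, each cyst is an independent Bernoulli trial
whose success probability is the fraction of its bridges that release a
6-cell fragment.  The pooled test applies the canonical 8-cell value 2/7 to
every cyst (the published procedure); the exact test uses per-cyst
probabilities under a stated partial-round topology, via the
Poisson-binomial distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from cystkit.fragmentation import p_six
from cystkit.topology import PartialRoundPolicy, canonical_cyst, partial_cyst

TestMode = Literal["pooled_binomial", "exact_poisson_binomial"]


def binom_pmf(k: int, n: int, p: float) -> float:
    """Exact binomial point probability C(n,k) p^k (1-p)^(n-k), via log space."""
    _check_binom_args(k, n, p)
    return float(np.exp(sps.binom.logpmf(k, n, p)))


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    _check_binom_args(k, n, p)
    return float(sps.binom.sf(k - 1, n, p))


def _check_binom_args(k: int, n: int, p: float) -> None:
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")


def poisson_binom_pmf(probabilities: Sequence[float]) -> np.ndarray:
    """Exact distribution of a sum of independent Bernoulli trials.

    Returns the pmf over 0..n by iterative convolution; the empty list gives
    a point mass at 0.
    """
    probs = [float(p) for p in probabilities]
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    dist = np.array([1.0])
    for p in probs:
        nxt = np.zeros(len(dist) + 1)
        nxt[:-1] += dist * (1.0 - p)
        nxt[1:] += dist * p
        dist = nxt
    return dist


@dataclass
class BreakageSample:
    """Observed cysts: (cyst size, does the MT gap predict a 6-cell cyst)."""

    records: list[tuple[int, bool]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("sample needs at least one record")
        for size, _ in self.records:
            if size < 2:
                raise ValueError(f"cyst size {size} < 2")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def k(self) -> int:
        return sum(1 for _, six in self.records if six)

    @classmethod
    def from_counts(cls, size_counts: dict[int, int], k: int) -> "BreakageSample":
        """Sample from per-size cyst counts with ``k`` six-cell predictions.

        The ``k`` successes are assigned to the largest cysts first; the
        pooled test depends only on (n, k) and the exact test only on the
        size multiset and k, so the assignment does not affect results.
        """
        sizes = sorted(
            (s for s, c in size_counts.items() for _ in range(c)), reverse=True
        )
        if not 0 <= k <= len(sizes):
            raise ValueError("k outside 0..n")
        records = [(s, i < k) for i, s in enumerate(sizes)]
        return cls(records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BreakageSample":
        """Read records from columns ``cyst_size`` and ``six_predicted``."""
        return cls(
            [
                (int(r.cyst_size), bool(r.six_predicted))
                for r in df.itertuples(index=False)
            ]
        )


@dataclass
class NullTestResult:
    """Outcome of a random-breakage null test."""

    mode: TestMode
    k: int
    n: int
    point_prob: float
    upper_tail_prob: float
    p_success: Optional[float] = None
    per_record_p: Optional[list[float]] = None

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "k": self.k,
            "n": self.n,
            "point_prob": self.point_prob,
            "upper_tail_prob": self.upper_tail_prob,
        }
        if self.p_success is not None:
            out["p_success"] = self.p_success
        if self.per_record_p is not None:
            out["per_record_p"] = self.per_record_p
        return out


def published_sample() -> BreakageSample:
    """The published 15-cyst sample: sizes 7x3, 8x8, 9x1, 10x3; 13 six-cell
    predictions."""
    return BreakageSample.from_counts({7: 3, 8: 8, 9: 1, 10: 3}, k=13)


def breakage_null_test(
    sample: BreakageSample,
    topology_policy: PartialRoundPolicy = "leaf_first",
    mode: TestMode = "pooled_binomial",
    rng: Optional[np.random.Generator] = None,
) -> NullTestResult:
    """Test observed six-cell-prediction counts against random breakage.

    ``pooled_binomial`` applies the canonical 8-cell success probability
    2/7 to every cyst regardless of its size — the published procedure.
    ``exact_poisson_binomial`` gives each cyst its own success probability
    from the partial-round topology of its size (``topology_policy``;
    ``random_subset`` requires ``rng``) and evaluates the exact
    Poisson-binomial distribution.  Both report the point probability at k
    and the upper tail P(X >= k).
    """
    k, n = sample.k, sample.n
    if mode == "pooled_binomial":
        p = float(Fraction(p_six(canonical_cyst(3))))
        return NullTestResult(
            mode=mode,
            k=k,
            n=n,
            point_prob=binom_pmf(k, n, p),
            upper_tail_prob=binom_upper_tail(k, n, p),
            p_success=p,
        )
    if mode == "exact_poisson_binomial":
        cache: dict[int, float] = {}
        per_p: list[float] = []
        for size, _ in sample.records:
            if size not in cache:
                g = partial_cyst(size, policy=topology_policy, rng=rng)
                cache[size] = float(p_six(g))
            per_p.append(cache[size])
        pmf = poisson_binom_pmf(per_p)
        return NullTestResult(
            mode=mode,
            k=k,
            n=n,
            point_prob=float(pmf[k]),
            upper_tail_prob=float(pmf[k:].sum()),
            per_record_p=per_p,
        )
    raise ValueError(f"unknown mode {mode!r}")


def power_curve(
    truth: Literal["programmed", "random"],
    n_cysts: int,
    miscall_rate: float,
    replicates: int,
    rng: np.random.Generator,
    alphas: Sequence[float] = (0.05, 1e-4),
    size_mix: Optional[dict[int, int]] = None,
    mode: TestMode = "pooled_binomial",
) -> pd.DataFrame:
    """Rejection frequency of the null test over simulated datasets.

    Each replicate draws a fresh MT-gap dataset of ``n_cysts`` cysts
    (default: all canonical 8-cell) under the given ground truth, runs the
    null test, and scores rejection as upper_tail_prob <= alpha.  Returns a
    tidy table (alpha, rejections, replicates, rejection_rate).
    """
    from cystkit.synthetic import make_mt_gap_dataset

    if replicates < 0:
        raise ValueError("replicates must be >= 0")
    if size_mix is None:
        size_mix = {8: n_cysts}
    if sum(size_mix.values()) != n_cysts:
        raise ValueError("size_mix counts must sum to n_cysts")
    alphas = list(alphas)
    hits = np.zeros(len(alphas), dtype=int)
    # leaf_first topologies are shared across replicates, so whether a given
    # gap bridge releases a 6-cell fragment can be memoized per size
    six_memo: dict[tuple[int, tuple[int, int]], bool] = {}
    for _ in range(replicates):
        records = make_mt_gap_dataset(
            size_mix, truth=truth, miscall_rate=miscall_rate, rng=rng
        )
        rec_tuples = []
        for r in records:
            key = (r.cyst_size, r.gap_edge.endpoints)
            if key not in six_memo:
                six_memo[key] = r.six_predicted
            rec_tuples.append((r.cyst_size, six_memo[key]))
        sample = BreakageSample(rec_tuples)
        res = breakage_null_test(sample, mode=mode)
        for i, a in enumerate(alphas):
            if res.upper_tail_prob <= a:
                hits[i] += 1
    return pd.DataFrame(
        {
            "alpha": alphas,
            "rejections": hits,
            "replicates": replicates,
            "rejection_rate": (hits / replicates) if replicates else np.nan,
        }
    )
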