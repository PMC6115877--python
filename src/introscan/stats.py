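"""Site-pattern statistics for four-taxon introgression tests.

The quartet is ordered (P1, P2, P3, O).  At site *i* the derived-allele
frequencies are (p1, p2, p3, p4), polarized so the outgroup allele is
ancestral.  The frequency-weighted pattern counts are

    C_ABBA(i) = (1 - p1) * p2 * p3 * (1 - p4)
    C_BABA(i) = p1 * (1 - p2) * p3 * (1 - p4)

and Patterson's D over a set of sites is

    D = (sum C_ABBA - sum C_BABA) / (sum C_ABBA + sum C_BABA).

Under lineage sorting alone the two patterns are equally frequent and D is
centred on zero; an excess of ABBA (D > 0) indicates P2-P3 gene flow.
f_d divides the same numerator by its value under complete introgression
(the per-site donor P_D, the larger of p2 and p3, substituted at both inner
positions), bounding the admixture fraction.  d_xy is the mean pairwise
divergence between two taxa and is reduced, relative to the scaffold
background, inside genuinely introgressed tracts but not at loci that are
merely topology-discordant through incomplete lineage sorting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PatternWeights",
    "DResult",
    "FdResult",
    "DxyResult",
    "ScaffoldBackground",
    "site_weights",
    "pattern_weights",
    "d_statistic",
    "d_ztest",
    "fd_statistic",
    "dxy",
    "dxy_ztest",
]


@dataclass(frozen=True)
class PatternWeights:
    """Summed frequency-weighted ABBA/BABA counts over a site set."""

    abba: float
    baba: float
    n_informative: int

    @property
    def total(self) -> float:
        return self.abba + self.baba

    @property
    def gap(self) -> float:
        """|ABBA - BABA| on the frequency-weighted scale (equals the raw
        pattern-count gap for haploid inputs where every weight is 0 or 1)."""
        return abs(self.abba - self.baba)


@dataclass(frozen=True)
class DResult:
    """Patterson's D with (optionally) its block-based standard error.

    ``d`` is None when no informative sites were supplied.  ``se``/``z``/``p``
    are None unless a z-test was run and was estimable.  ``degenerate`` marks
    a zero-variance case with d != 0, where p is reported as 0.0 by
    convention.
    """

    d: Optional[float]
    weights: PatternWeights
    se: Optional[float] = None
    z: Optional[float] = None
    p: Optional[float] = None
    degenerate: bool = False
    n_blocks_used: int = 0

    @property
    def defined(self) -> bool:
        return self.d is not None


@dataclass(frozen=True)
class FdResult:
    """f_d admixture-fraction estimate for a site set.

    fd is defined only when both the observed numerator S(P1,P2,P3,O) and the
    complete-introgression denominator S(P1,PD,PD,O) are positive; windows
    with a BABA excess (s_num <= 0) can never pass an f_d filter and are
    reported as undefined.
    """

    s_num: float
    s_den: float
    fd: Optional[float]

    @property
    def defined(self) -> bool:
        return self.fd is not None


@dataclass(frozen=True)
class DxyResult:
    """Mean pairwise divergence between two taxa over a region."""

    dxy: Optional[float]
    n_sites: int
    mode: str = "bp"  # divisor semantics: "bp" or "aligned_sites"

    @property
    def defined(self) -> bool:
        return self.dxy is not None


@dataclass(frozen=True)
class ScaffoldBackground:
    """Scaffold-level d_xy background: mean and spread of per-window d_xy.

    ``se`` is the sample standard deviation of d_xy across full-size windows
    on the scaffold — the scale on which a single window varies — so that
    (window - mean) / se is a one-sample z-score of the window against the
    window population.
    """

    scaffold: str
    mean_dxy: float
    se: float
    n_windows: int

    @property
    def usable(self) -> bool:
        return self.n_windows >= 2 and self.se > 0


def _as_freq_array(sites) -> np.ndarray:
    """Coerce input to an (n, 4) float array of (p1, p2, p3, p4)."""
    if hasattr(sites, "freqs"):  # PolarizedSiteTable
        arr = np.asarray(sites.freqs, dtype=float)
    else:
        arr = np.asarray(
            [
                (s.p1, s.p2, s.p3, s.p4) if hasattr(s, "p1") else tuple(s)
                for s in sites
            ]
            if not isinstance(sites, np.ndarray)
            else sites,
            dtype=float,
        )
    if arr.size == 0:
        return arr.reshape(0, 4)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expected an (n, 4) array of quartet frequencies")
    return arr


def site_weights(p1: float, p2: float, p3: float, p4: float) -> tuple[float, float]:
    """Per-site (C_ABBA, C_BABA) weights from derived-allele frequencies."""
    c_abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    c_baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return c_abba, c_baba


def _weights_arrays(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p1, p2, p3, p4 = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    return (1 - p1) * p2 * p3 * (1 - p4), p1 * (1 - p2) * p3 * (1 - p4)


def pattern_weights(sites) -> PatternWeights:
    """Sum C_ABBA and C_BABA over a site set."""
    arr = _as_freq_array(sites)
    ca, cb = _weights_arrays(arr)
    return PatternWeights(
        abba=float(ca.sum()),
        baba=float(cb.sum()),
        n_informative=int(np.count_nonzero(ca + cb > 0)),
    )


def d_statistic(sites) -> DResult:
    """Patterson's D over a site set; undefined when ABBA + BABA = 0."""
    w = pattern_weights(sites)
    if w.total > 0:
        return DResult(d=(w.abba - w.baba) / w.total, weights=w)
    return DResult(d=None, weights=w)


def d_ztest(sites, n_blocks: int = 20) -> DResult:
    """Patterson's D with a contiguous-block z-test of the symmetric null.

    Sites (assumed sorted by position) are partitioned into ``n_blocks``
    contiguous blocks of near-equal site count.  With per-block numerator
    sums s_j = ABBA_j - BABA_j, the null hypothesis of no introgression
    makes each block's sign exchangeable, so the numerator S = sum(s_j) has
    exact null variance sum(s_j**2).  The reported standard error is that
    null SD on the D scale,

        se = sqrt(sum s_j**2) / (ABBA + BABA),    z = d / se,

    with a two-sided standard-normal p.  This block-variance form stays
    calibrated down to small per-window tail probabilities where the
    delete-one jackknife of the ratio (whose SE is itself noisy when
    informative sites are sparse and clustered) is strongly anticonservative.
    Fewer than two blocks containing informative sites leaves se/z/p
    undefined with the flag implied by ``n_blocks_used`` = 0.  A zero
    standard error with d == 0 gives p = 1; the degenerate se = 0, d != 0
    case (impossible for this estimator, kept for contract compatibility)
    would report p = 0 with ``degenerate`` set.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    arr = _as_freq_array(sites)
    ca, cb = _weights_arrays(arr)
    total_a, total_b = float(ca.sum()), float(cb.sum())
    w = PatternWeights(
        abba=total_a, baba=total_b, n_informative=int(np.count_nonzero(ca + cb > 0))
    )
    if total_a + total_b == 0:
        return DResult(d=None, weights=w)
    d = (total_a - total_b) / (total_a + total_b)

    n_blocks = min(n_blocks, arr.shape[0])
    if n_blocks < 2:
        return DResult(d=d, weights=w)
    block_a = np.array([c.sum() for c in np.array_split(ca, n_blocks)])
    block_b = np.array([c.sum() for c in np.array_split(cb, n_blocks)])
    informative_blocks = int(np.count_nonzero(block_a + block_b > 0))
    if informative_blocks < 2:
        return DResult(d=d, weights=w)

    s = block_a - block_b
    null_sd = float(np.sqrt(np.sum(s**2)))
    se = null_sd / (total_a + total_b)
    m = int(n_blocks)
    if se == 0.0:
        if d == 0.0:
            return DResult(d=d, weights=w, se=0.0, z=0.0, p=1.0, n_blocks_used=m)
        return DResult(
            d=d, weights=w, se=0.0, z=None, p=0.0, degenerate=True, n_blocks_used=m
        )
    z = d / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DResult(d=d, weights=w, se=se, z=float(z), p=p, n_blocks_used=m)


def fd_statistic(sites) -> FdResult:
    """f_d over a site set.

    Numerator: sum of (C_ABBA - C_BABA).  Denominator: the same sum with the
    per-site donor frequency P_D = max(p2, p3) substituted for both P2 and
    P3.  fd is undefined unless both sums are positive.
    """
    arr = _as_freq_array(sites)
    if arr.shape[0] == 0:
        return FdResult(s_num=0.0, s_den=0.0, fd=None)
    ca, cb = _weights_arrays(arr)
    p1, p4 = arr[:, 0], arr[:, 3]
    pd_ = np.maximum(arr[:, 1], arr[:, 2])
    den = (1 - p1) * pd_ * pd_ * (1 - p4) - p1 * (1 - pd_) * pd_ * (1 - p4)
    s_num = float((ca - cb).sum())
    s_den = float(den.sum())
    fd = s_num / s_den if (s_num > 0 and s_den > 0) else None
    return FdResult(s_num=s_num, s_den=s_den, fd=fd)


def dxy(
    freqs_x: Sequence[float],
    freqs_y: Sequence[float],
    n: int,
    mode: str = "bp",
) -> DxyResult:
    """Mean pairwise divergence d_xy = (1/n) * sum[px(1-py) + py(1-px)].

    ``freqs_x``/``freqs_y`` are the variant-site frequencies of the two taxa
    over the region; ``n`` is the divisor — the number of retained aligned
    sites when alignment input is available (mode "aligned_sites"), else the
    region length in bp with monomorphic positions contributing 0 (mode
    "bp").  n = 0 yields an undefined result.
    """
    fx = np.asarray(freqs_x, dtype=float)
    fy = np.asarray(freqs_y, dtype=float)
    if fx.shape != fy.shape:
        raise ValueError("frequency sequences must have equal length")
    if n < 1:
        return DxyResult(dxy=None, n_sites=int(n), mode=mode)
    num = float((fx * (1 - fy) + fy * (1 - fx)).sum())
    return DxyResult(dxy=num / n, n_sites=int(n), mode=mode)


def dxy_ztest(
    window_dxy: "DxyResult | float", background: ScaffoldBackground
) -> tuple[Optional[float], Optional[float]]:
    """One-sided (lower-tail) z-test of a window's d_xy against the scaffold
    background: introgression requires significantly LOWER divergence.

    Returns (z, p); (None, None) when the window d_xy is undefined or the
    background is unusable (se = 0 or fewer than 2 windows).
    """
    value = window_dxy.dxy if isinstance(window_dxy, DxyResult) else window_dxy
    if value is None or not background.usable:
        return None, None
    z = (value - background.mean_dxy) / background.se
    return float(z), float(sps.norm.cdf(z))
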