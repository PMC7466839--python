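"""Windowed co-occurrence statistics for tandem repeats, indels and SNPs.

Events and tandem repeats are binned into non-overlapping 150 bp windows
along the reference, and their association is quantified with Spearman
rank correlations (with the Akoglu strength labels), plus Mann-Whitney U
tests comparing mutation counts between tandem-present and
tandem-absent windows.  Small samples use exact enumeration null
distributions; larger samples use the t approximation (Spearman) or the
tie-corrected normal approximation with continuity correction
(Mann-Whitney).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WindowTable",
    "CorrelationResult",
    "MWUResult",
    "bin_counts",
    "spearman",
    "strength_label",
    "mann_whitney",
    "association_report",
]


@dataclass
class WindowTable:
    """Per-window counts of tandems, indels, SNPs and substitution blocks."""

    ref_len: int
    width: int
    table: pd.DataFrame  # columns: bin, start, end, tandems, indels, snps, substitutions

    def counts(self, column: str) -> np.ndarray:
        return self.table[column].to_numpy()


def _bin_of(pos: int, w: int) -> int:
    return (pos + w - 1) // w  # ceil(pos / w), 1-based bins


def bin_counts(events, tandems, ref_len: int, w: int = 150) -> WindowTable:
    """Assign events (by anchor) and tandems (by midpoint) to w-bp bins.

    Bin ``b`` covers ``[(b-1)w + 1, min(bw, ref_len)]``; the short final
    bin is retained so column sums equal the pooled event totals.
    """
    nbins = (ref_len + w - 1) // w
    cols = {
        "tandems": np.zeros(nbins, dtype=int),
        "indels": np.zeros(nbins, dtype=int),
        "snps": np.zeros(nbins, dtype=int),
        "substitutions": np.zeros(nbins, dtype=int),
    }
    for t in tandems:
        mid = (t.start + t.end) // 2
        if not 1 <= mid <= ref_len:
            raise ValueError(f"tandem midpoint {mid} outside [1, {ref_len}]")
        cols["tandems"][_bin_of(mid, w) - 1] += 1
    for e in events:
        pos = max(1, e.ref_pos)  # indels normalised to the origin anchor at 0
        if pos > ref_len:
            raise ValueError(f"event position {pos} outside [1, {ref_len}]")
        b = _bin_of(pos, w) - 1
        if e.kind in ("insertion", "deletion"):
            cols["indels"][b] += 1
        elif e.kind == "SNP":
            cols["snps"][b] += 1
        elif e.kind == "substitution_block":
            cols["substitutions"][b] += 1
        else:
            raise ValueError(f"unknown event kind {e.kind!r}")
    starts = np.arange(nbins) * w + 1
    ends = np.minimum(starts + w - 1, ref_len)
    table = pd.DataFrame(
        {"bin": np.arange(1, nbins + 1), "start": starts, "end": ends, **cols}
    )
    return WindowTable(ref_len=ref_len, width=w, table=table)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    strength: str


def strength_label(rho: float) -> str:
    """Correlation strength bands on \\|rho\\| (Akoglu-style)."""
    a = abs(rho)
    if a > 1:
        raise ValueError("|rho| must be <= 1")
    if a < 0.1:
        return "none"
    if a < 0.2:
        return "very weak"
    if a < 0.3:
        return "weak"
    if a < 0.4:
        return "moderate"
    if a < 0.7:
        return "strong"
    return "very strong"


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(rx @ ry) / denom


def spearman(x, y, exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rank correlation with ties handled by average ranks.

    The two-sided p-value comes from full permutation enumeration for
    ``n <= exact_max_n`` and from the t approximation with ``n - 2``
    degrees of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _rank(x), _rank(y)
    rho = _rho_of_ranks(rx, ry)
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        obs = abs(float(rxc @ ryc))
        count = 0
        total = 0
        perm_iter = itertools.permutations(range(n))
        while True:
            block = list(itertools.islice(perm_iter, 200_000))
            if not block:
                break
            P = np.array(block, dtype=np.int16)
            dots = np.abs(rxc[P] @ ryc)
            count += int(np.sum(dots >= obs - 1e-9))
            total += len(block)
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=p, n=n, strength=strength_label(rho))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass
class MWUResult:
    U: float
    p_value: float
    n_present: int
    n_absent: int
    median_present: float
    median_absent: float


def mann_whitney(values_present, values_absent, exact_max_total: int = 12) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    For ``n1 + n2 <= exact_max_total`` the p-value is exact, enumerating
    every assignment of the pooled observations to the two groups and
    measuring the deviation of U from its null mean (ties are thereby
    handled exactly).  Larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(values_present, dtype=float)
    b = np.asarray(values_absent, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _rank(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2  # number of (present > absent) wins, ties as 1/2
    mean_u = n1 * n2 / 2
    if n1 + n2 <= exact_max_total:
        obs_dev = abs(u1 - mean_u)
        count = total = 0
        idx = range(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            rsum = float(ranks[list(comb)].sum())
            u = rsum - n1 * (n1 + 1) / 2
            if abs(u - mean_u) >= obs_dev - 1e-9:
                count += 1
            total += 1
        p = count / total
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            dev = abs(u1 - mean_u)
            z = max(0.0, dev - 0.5) / math.sqrt(sigma2)
            p = float(2 * sps.norm.sf(z))
    return MWUResult(
        U=float(u1),
        p_value=min(1.0, p),
        n_present=n1,
        n_absent=n2,
        median_present=float(np.median(a)),
        median_absent=float(np.median(b)),
    )


# ---------------------------------------------------------------------------
# Association report
# ---------------------------------------------------------------------------


@dataclass
class AssociationReport:
    correlations: dict[str, CorrelationResult]
    mwu: dict[str, MWUResult]
    alpha: float
    note: str = field(
        default="p-values are reported without multiple-testing correction"
    )

    def significant(self, pair: str) -> bool:
        return self.correlations[pair].p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "note": self.note,
            "correlations": {
                k: {
                    "rho": c.rho,
                    "p_value": c.p_value,
                    "n": c.n,
                    "strength": c.strength,
                    "significant": c.p_value < self.alpha,
                }
                for k, c in self.correlations.items()
            },
            "mann_whitney": {
                k: {
                    "U": m.U,
                    "p_value": m.p_value,
                    "n_present": m.n_present,
                    "n_absent": m.n_absent,
                    "median_present": m.median_present,
                    "median_absent": m.median_absent,
                    "significant": m.p_value < self.alpha,
                }
                for k, m in self.mwu.items()
            },
        }


def association_report(wt: WindowTable, alpha: float = 0.01) -> AssociationReport:
    """All pairwise correlations plus the tandem presence/absence tests.

    Computes the three Spearman correlations (tandem-indel, tandem-SNP,
    indel-SNP) with strength labels and significance flags at ``alpha``,
    and the two Mann-Whitney tests of indel and SNP counts in
    tandem-present vs tandem-absent windows.  No multiple-testing
    correction is applied (noted in the output).
    """
    t = wt.counts("tandems")
    ind = wt.counts("indels")
    snp = wt.counts("snps")
    correlations = {
        "tandem-indel": spearman(t, ind),
        "tandem-snp": spearman(t, snp),
        "indel-snp": spearman(ind, snp),
    }
    present = t > 0
    if present.any() and (~present).any():
        mwu = {
            "indels": mann_whitney(ind[present], ind[~present]),
            "snps": mann_whitney(snp[present], snp[~present]),
        }
    else:
        raise ValueError("tandem presence/absence groups are degenerate")
    return AssociationReport(correlations=correlations, mwu=mwu, alpha=alpha)
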