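"""Gene-set enrichment of a ranked disease signature.

Two statistics are provided:

* a signed two-sample Kolmogorov–Smirnov enrichment of a transcription-factor
  target set within a ranked gene list (the rank positions of targets are
  compared against those of non-targets; the signed maximal ECDF deviation is
  the enrichment score, positive when targets concentrate among up-regulated
  genes), and
* a Fisher's exact test for over-representation of a pathway family among
  user-flagged enriched pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "FisherResult",
    "signed_ks_scan",
    "ks_target_enrichment",
    "fisher_overrepresentation",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return gene in self.members


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    p_value: float
    n_targets_in_signature: int
    n_signature: int


@dataclass
class FisherResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: np.ndarray


def signed_ks_scan(in_set: np.ndarray) -> float:
    """Signed maximal deviation between set and complement rank ECDFs.

    ``in_set`` is a boolean array over an ordered gene list (index 0 = most
    up-regulated).  Walking down the list, the running difference between the
    fraction of set members seen and the fraction of non-members seen is
    tracked; the value returned is the deviation of largest magnitude, signed:
    positive when set members concentrate at the top of the list.
    """
    in_set = np.asarray(in_set, dtype=bool)
    m = int(in_set.sum())
    n = int((~in_set).sum())
    if m == 0 or n == 0:
        raise ValueError("both the set and its complement must be non-empty")
    # integer arithmetic scaled by m*n keeps the +/-1 limits exact
    cum_in = np.cumsum(in_set.astype(np.int64))
    pos = np.arange(1, in_set.size + 1, dtype=np.int64)
    diff = cum_in * n - (pos - cum_in) * m
    d_plus = max(int(diff.max()), 0)
    d_minus = max(int(-diff.min()), 0)
    scaled = d_plus if d_plus >= d_minus else -d_minus
    return scaled / (m * n)


def _ks_pvalue(pos_set: np.ndarray, pos_rest: np.ndarray) -> float:
    method = "exact" if (len(pos_set) + len(pos_rest)) <= 30 else "asymp"
    return float(stats.ks_2samp(pos_set, pos_rest, method=method).pvalue)


def ks_target_enrichment(ranked, targets: GeneSet, domain: str = "top") -> EnrichmentResult:
    """Signed KS enrichment of ``targets`` in a ranked signature.

    ``ranked`` may be a ``RankedSignature`` or any ordered gene list (rank 1 =
    greatest up-regulation). With ``domain="top"`` (default) the test domain
    is the union of the up- and down-regulated query sets of the signature,
    kept in log2FC order; ``domain="full"`` scans the whole ranked list.
    ES > 0 means the targets skew toward the up-regulated end; the p-value is
    the two-sided two-sample KS probability comparing target and non-target
    rank positions.
    """
    genes = _domain_genes(ranked, domain)
    in_set = np.array([g in targets for g in genes], dtype=bool)
    m = int(in_set.sum())
    if m == 0:
        raise ValueError(
            f"no member of gene set {targets.name!r} occurs in the ranked domain"
        )
    if m == len(genes):
        raise ValueError(
            f"gene set {targets.name!r} covers the whole ranked domain; "
            "the two-sample comparison is undefined"
        )
    es = signed_ks_scan(in_set)
    positions = np.arange(1, len(genes) + 1, dtype=float)
    p = _ks_pvalue(positions[in_set], positions[~in_set])
    return EnrichmentResult(
        set_name=targets.name,
        es=es,
        p_value=p,
        n_targets_in_signature=m,
        n_signature=len(genes),
    )


def _domain_genes(ranked, domain: str) -> list:
    if domain not in ("top", "full"):
        raise ValueError(f"domain must be 'top' or 'full', got {domain!r}")
    if hasattr(ranked, "genes") and hasattr(ranked, "up_set"):
        if domain == "full":
            return list(ranked.genes)
        query = set(ranked.up_set) | set(ranked.down_set)
        return [g for g in ranked.genes if g in query]
    return list(ranked)


def fisher_overrepresentation(flags: pd.DataFrame) -> FisherResult:
    """Fisher's exact over-representation of a pathway family among enriched pathways.

    ``flags`` has one row per pathway with boolean columns ``enriched`` and
    ``in_family``. The 2×2 table is (enriched × in-family); the p-value is the
    exact two-sided hypergeometric probability, the odds ratio is the sample
    cross-product ratio, and the 95% CI uses the log-odds-ratio normal
    approximation (unbounded, with a warning, when any cell is zero).
    """
    enriched = np.asarray(flags["enriched"], dtype=bool)
    fam = np.asarray(flags["in_family"], dtype=bool)
    a = int(np.sum(enriched & fam))
    b = int(np.sum(enriched & ~fam))
    c = int(np.sum(~enriched & fam))
    d = int(np.sum(~enriched & ~fam))
    table = np.array([[a, b], [c, d]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if min(a, b, c, d) == 0:
        warnings.warn(
            "zero cell in the 2x2 table: odds ratio CI is unbounded",
            stacklevel=2,
        )
        orat = np.inf if b * c == 0 and a * d > 0 else (0.0 if a * d == 0 else np.nan)
        return FisherResult(orat, 0.0, np.inf, p, table)
    orat = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orat) + np.array([-1, 1]) * 1.959963984540054 * se)
    return FisherResult(float(orat), float(lo), float(hi), p, table)
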