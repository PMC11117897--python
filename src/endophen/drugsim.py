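"""Connectivity-style drug-signature similarity scoring (DGES).

Each drug's transcriptional response is a ranked gene list per cell line
(rank 1 = most up-regulated by the drug). Per-cell-line rankings are merged
into a prototype ranked list by a Spearman-agreement-weighted rank average.
The similarity between a disease signature (up/down query gene sets) and a
drug is the DGES score: the mean of the signed running-sum enrichment of the
up set and the negated enrichment of the down set, so that

* score → +1 : the drug mimics the disease signature,
* score → −1 : the drug reverses it.

Scanning a library yields per-drug z-scores (standardised over the library),
two-tailed normal p-values and percentile ranks; the reversed disease
signature is obtained by swapping the up and down query sets, which negates
every score exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import GeneSet, signed_ks_scan

__all__ = [
    "DrugSignature",
    "PrototypeRankedList",
    "DGESResult",
    "merge_signatures",
    "connectivity_es",
    "dges",
    "reverse_signature",
    "library_scan",
]


@dataclass
class DrugSignature:
    """Per-cell-line ranked transcriptional responses of one drug."""

    name: str
    rankings: dict  # cell_line -> list of genes, rank 1 first

    def __post_init__(self) -> None:
        if not self.rankings:
            raise ValueError(f"drug {self.name!r} has no rankings")
        universes = {cl: frozenset(r) for cl, r in self.rankings.items()}
        ref = next(iter(universes.values()))
        for cl, u in universes.items():
            if u != ref:
                diff = sorted(ref.symmetric_difference(u))
                raise ValueError(
                    f"drug {self.name!r}: cell line {cl!r} ranks a different "
                    f"gene universe (symmetric difference: {diff[:10]}...)"
                )
        for cl, r in self.rankings.items():
            if len(r) != len(ref):
                raise ValueError(f"drug {self.name!r}: ranking for {cl!r} has duplicates")


@dataclass
class PrototypeRankedList:
    """Consensus (merged) ranking of a drug across cell lines."""

    name: str
    ranking: list
    weights: dict = field(default_factory=dict)


@dataclass
class DGESResult:
    """Library-scan result table plus boxplot summary of the score distribution."""

    table: pd.DataFrame
    boxplot: dict


def merge_signatures(drug: DrugSignature | dict, name: str = "drug") -> PrototypeRankedList:
    """Merge per-cell-line rankings into a prototype ranked list.

    Each cell line is weighted by the (zero-clamped) mean Spearman correlation
    of its ranking with the other cell lines' rankings, so discordant lines
    contribute nothing; if every weight clamps to zero — or with a single
    cell line — uniform weights are used. The merged ranking orders genes by
    their weighted average rank, ties broken by gene identifier.
    """
    if isinstance(drug, dict):
        drug = DrugSignature(name=name, rankings=drug)
    cell_lines = sorted(drug.rankings)
    genes = sorted(drug.rankings[cell_lines[0]])
    gene_ix = {g: i for i, g in enumerate(genes)}
    R = np.empty((len(cell_lines), len(genes)))
    for i, cl in enumerate(cell_lines):
        for rank, g in enumerate(drug.rankings[cl], start=1):
            R[i, gene_ix[g]] = rank
    if len(cell_lines) == 1:
        weights = np.array([1.0])
    else:
        corr = np.corrcoef(R)  # Pearson on ranks == Spearman (no ties)
        np.fill_diagonal(corr, np.nan)
        weights = np.maximum(np.nanmean(corr, axis=1), 0.0)
        if weights.sum() <= 0:
            weights = np.ones(len(cell_lines))
        weights = weights / weights.sum()
    avg = weights @ R
    order = np.lexsort((np.array(genes, dtype=object), avg))
    return PrototypeRankedList(
        name=drug.name,
        ranking=[genes[i] for i in order],
        weights={cl: float(w) for cl, w in zip(cell_lines, weights)},
    )


def connectivity_es(ranking: list, query: GeneSet | set) -> float:
    """Signed running-sum enrichment of a query set in a drug ranking.

    Scanning from rank 1 (the drug's most up-regulated gene), the running
    difference between the query ECDF and the non-query ECDF is tracked; the
    signed maximal deviation is returned. +1 when the query occupies the very
    top of the ranking, −1 when it occupies the bottom.
    """
    members = query.members if isinstance(query, GeneSet) else frozenset(query)
    if not members:
        raise ValueError("query set is empty")
    universe = set(ranking)
    outside = members - universe
    if outside:
        raise ValueError(f"query genes outside the ranked universe: {sorted(outside)[:10]}")
    in_set = np.fromiter((g in members for g in ranking), dtype=bool, count=len(ranking))
    return signed_ks_scan(in_set)


def dges(drug: PrototypeRankedList, up: GeneSet | set, down: GeneSet | set) -> float:
    """DGES similarity between a disease up/down signature and one drug.

    ``(ES_up − ES_down) / 2``: positive when the drug up-regulates the
    disease's up genes and down-regulates its down genes (a mimicker),
    negative for a reverser.
    """
    up_m = up.members if isinstance(up, GeneSet) else frozenset(up)
    down_m = down.members if isinstance(down, GeneSet) else frozenset(down)
    if up_m & down_m:
        raise ValueError(f"up and down query sets overlap: {sorted(up_m & down_m)[:10]}")
    ranking = drug.ranking if isinstance(drug, PrototypeRankedList) else list(drug)
    return 0.5 * (connectivity_es(ranking, up_m) - connectivity_es(ranking, down_m))


def reverse_signature(up, down):
    """Reversed disease signature: swap the up and down query sets.

    Guarantees ``dges(drug, *reversed) == -dges(drug, up, down)`` exactly.
    """
    up_m = up.members if isinstance(up, GeneSet) else frozenset(up)
    down_m = down.members if isinstance(down, GeneSet) else frozenset(down)
    if up_m & down_m:
        raise ValueError("up and down query sets overlap")
    return down, up


def library_scan(
    library: list,
    up: GeneSet | set,
    down: GeneSet | set,
) -> DGESResult:
    """Score every drug in a library against a disease signature.

    Per drug: DGES score, library z-score, two-tailed standard-normal p-value
    of the z, percentile rank of the score within the library and a top-1%
    flag. The returned boxplot summary (Q1, median, Q3, whiskers at 1.5·IQR)
    describes the library score distribution.
    """
    if len(library) < 3:
        raise ValueError("library must contain at least 3 drugs")
    names, scores = [], []
    for drug in library:
        names.append(drug.name)
        scores.append(dges(drug, up, down))
    scores = np.asarray(scores)
    sd = scores.std()  # population sd: z-scores have mean 0, sd 1 exactly
    if sd == 0:
        raise ValueError("library scores have zero spread; z-scores undefined")
    z = (scores - scores.mean()) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    pct = 100.0 * stats.rankdata(scores, method="average") / len(scores)
    table = pd.DataFrame(
        {
            "drug": names,
            "score": scores,
            "z": z,
            "p": p,
            "percentile": pct,
            "top_1pct": pct > 99.0,
        }
    ).set_index("drug")
    q1, med, q3 = np.percentile(scores, [25, 50, 75])
    iqr = q3 - q1
    boxplot = {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }
    return DGESResult(table=table, boxplot=boxplot)
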