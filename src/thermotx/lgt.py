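"""Lateral-gene-transfer detection from tabular homology hits.

The approach follows the Close/Distal bit-score scoring scheme of
HGTector-style screens.  For each query gene, retained hits are grouped by
the taxonomic affiliation of the subject into Self (own genus), Close
(either the sister genus or the whole order, two presets) and Distal
(everything else).  Each hit contributes its bit score normalized by the
query's best self-group bit score, and contributions are summed per group.

Genes that lack close-relative homologs populate a "zero peak" in the
Close-score distribution; the transfer cutoff is the median of the scores
lying between that peak and the first local minimum of a Gaussian kernel
density estimate.  A gene is putatively transferred when its Close score
is below the Close cutoff AND its Distal score is above the Distal cutoff
(both strict).

Transfer recentness: a transferred gene with no retained non-self hit in
the home phylum is a recent acquisition (label ``K``); one whose
order-level and sister-genus Close scores differ by less than 1 is shared
with the sister genus (label ``K+M``), with K taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import ConfigError, DataError, NumericalError

HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_len",
    "evalue", "bitscore", "qcov", "lineage",
]


@dataclass(frozen=True)
class GroupDefinition:
    """Taxon label sets defining the Self and Close groups.

    Membership is decided by label matching against the subject's lineage
    path; everything that is neither Self nor Close is Distal.
    """

    self_taxa: frozenset[str]
    close_taxa: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "self_taxa", frozenset(self.self_taxa))
        object.__setattr__(self, "close_taxa", frozenset(self.close_taxa))
        if self.self_taxa & self.close_taxa:
            raise ConfigError("Self and Close taxa must be disjoint")


#: sister-genus preset (Close = Mesotoga)
SISTER_GROUPS = GroupDefinition(
    self_taxa=frozenset({"Kosmotoga"}), close_taxa=frozenset({"Mesotoga"})
)
#: order-level preset (Close = the rest of the order)
ORDER_GROUPS = GroupDefinition(
    self_taxa=frozenset({"Kosmotoga"}), close_taxa=frozenset({"Thermotogales"})
)
#: phylum label used for the recentness rule
DEFAULT_PHYLUM = "Thermotogae"


def filter_hits(
    hits: pd.DataFrame,
    max_per_query: int = 500,
    max_evalue: float = 1e-5,
    min_coverage: float = 0.7,
) -> pd.DataFrame:
    """Apply the hit-retention rules.

    Per query: drop hits with E-value >= ``max_evalue`` or coverage below
    ``min_coverage`` (>= keeps the boundary), then keep the
    ``max_per_query`` highest bit scores, breaking ties by subject id for
    a stable, order-independent result.
    """
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise DataError(f"hit table missing columns: {missing}")
    for col in ("evalue", "bitscore", "qcov"):
        vals = pd.to_numeric(hits[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise DataError(f"malformed {col} in hit table at row {line}")
    if (hits["lineage"].astype(str).str.strip() == "").any():
        raise DataError("hit with empty lineage")
    kept = hits[(hits["evalue"] < max_evalue) & (hits["qcov"] >= min_coverage)]
    kept = kept.sort_values(
        ["query_id", "bitscore", "subject_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return kept.groupby("query_id", sort=True).head(max_per_query).reset_index(drop=True)


def _lineage_labels(lineage: str) -> set[str]:
    return {p.strip() for p in str(lineage).split(";") if p.strip()}


def _group_of(labels: set[str], groups: GroupDefinition) -> str:
    if labels & groups.self_taxa:
        return "self"
    if labels & groups.close_taxa:
        return "close"
    return "distal"


def compute_group_scores(
    gene_hits: pd.DataFrame, groups: GroupDefinition, query_id: str | None = None
) -> dict:
    """Self/Close/Distal scores for one gene's retained hits.

    Normalizer: the query's hit to itself (subject_id == query id) if
    present, otherwise the best self-group bit score, otherwise 1.0 with
    ``no_self_hit`` flagged.  The self-match itself is excluded from all
    sums.
    """
    if len(gene_hits) == 0:
        return {
            "self_score": 0.0, "close_score": 0.0, "distal_score": 0.0,
            "no_self_hit": True, "no_hits": True,
        }
    qid = query_id if query_id is not None else gene_hits["query_id"].iloc[0]
    is_self_match = gene_hits["subject_id"] == qid
    labels = gene_hits["lineage"].map(_lineage_labels)
    grp = labels.map(lambda s: _group_of(s, groups))

    self_bits = gene_hits.loc[(grp == "self"), "bitscore"]
    self_match_bits = gene_hits.loc[is_self_match, "bitscore"]
    if len(self_match_bits):
        norm = float(self_match_bits.max())
        flagged = False
    elif len(self_bits):
        norm = float(self_bits.max())
        flagged = False
    else:
        norm = 1.0
        flagged = True

    use = ~is_self_match
    contrib = gene_hits.loc[use, "bitscore"].to_numpy(dtype=float) / norm
    g = grp[use].to_numpy()
    return {
        "self_score": float(contrib[g == "self"].sum()),
        "close_score": float(contrib[g == "close"].sum()),
        "distal_score": float(contrib[g == "distal"].sum()),
        "no_self_hit": flagged,
        "no_hits": False,
    }


def score_table(hits: pd.DataFrame, groups: GroupDefinition) -> pd.DataFrame:
    """Per-gene Self/Close/Distal scores over a filtered hit table."""
    rows = []
    for qid, sub in hits.groupby("query_id", sort=True):
        rec = compute_group_scores(sub, groups, query_id=qid)
        rec["gene_id"] = qid
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass(frozen=True)
class CutoffDiagnostics:
    cutoff: float
    peak: float
    minimum: float
    bandwidth: float
    used_fallback: bool
    n_between: int


def estimate_cutoffs(
    scores, min_genes: int = 50, grid_size: int = 512
) -> CutoffDiagnostics:
    """Density-derived transfer cutoff for a score distribution.

    Gaussian KDE (Silverman bandwidth) on a ``grid_size``-point grid from 0
    to the maximum score; the landmark pair is the density peak nearest
    zero and the first local minimum after it; the cutoff is the median of
    the score values lying between the two landmarks (midpoint fallback,
    flagged, when fewer than 5 points lie between).  A unimodal
    distribution (no local minimum after the zero peak) raises
    :class:`NumericalError`.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < min_genes:
        raise DataError(f"need at least {min_genes} scores, got {len(x)}")
    if np.std(x) == 0:
        raise NumericalError("constant score distribution has no cutoff")
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(0.0, float(x.max()), grid_size)
    dens = kde(grid)

    d = dens
    interior_max = np.flatnonzero(
        (d[1:-1] >= d[:-2]) & (d[1:-1] >= d[2:])
    ) + 1
    peaks = list(interior_max)
    if d[0] > d[1]:
        peaks = [0] + peaks
    if not peaks:
        raise NumericalError("no density peak found")
    peak_idx = min(peaks, key=lambda i: grid[i])

    minima = np.flatnonzero(
        (d[1:-1] <= d[:-2]) & (d[1:-1] <= d[2:])
    ) + 1
    after = [i for i in minima if i > peak_idx and d[i] < d[peak_idx]]
    if not after:
        raise NumericalError(
            "score distribution is unimodal: no local minimum after the zero "
            "peak, cannot place a transfer cutoff"
        )
    min_idx = after[0]

    lo, hi = grid[peak_idx], grid[min_idx]
    between = x[(x > lo) & (x < hi)]
    if len(between) >= 5:
        cutoff = float(np.median(between))
        fallback = False
    else:
        cutoff = float(0.5 * (lo + hi))
        fallback = True
    return CutoffDiagnostics(
        cutoff=cutoff, peak=float(lo), minimum=float(hi),
        bandwidth=float(kde.factor * np.std(x)), used_fallback=fallback,
        n_between=int(len(between)),
    )


def classify_transferred(
    scores: pd.DataFrame, close_cutoff: float, distal_cutoff: float
) -> pd.Series:
    """Transferred iff close < close_cutoff and distal > distal_cutoff."""
    if not (np.isfinite(close_cutoff) and np.isfinite(distal_cutoff)):
        raise ConfigError("cutoffs must be finite")
    return (scores["close_score"] < close_cutoff) & (
        scores["distal_score"] > distal_cutoff
    )


def assign_transfer_lineage(
    transferred_genes,
    hits: pd.DataFrame,
    close_order: pd.Series,
    close_sister: pd.Series,
    groups: GroupDefinition = ORDER_GROUPS,
    phylum_label: str = DEFAULT_PHYLUM,
) -> pd.Series:
    """Recentness labels for transferred genes.

    ``K``: no retained non-self-group hit whose lineage contains the
    phylum label (a transfer into the genome itself).  ``K+M``: the
    order-level and sister-genus Close scores differ by less than 1
    (transfer into the common ancestor with the sister genus).  K takes
    precedence; all other transferred genes are ``transferred_unlabeled``.
    """
    if close_order is None or close_sister is None:
        raise DataError("both group-definition runs are required")
    labels = {}
    lineage_sets = hits["lineage"].map(_lineage_labels)
    in_phylum = lineage_sets.map(lambda s: phylum_label in s)
    in_self = lineage_sets.map(lambda s: bool(s & groups.self_taxa))
    phylum_hits = hits[in_phylum & ~in_self].groupby("query_id").size()
    for gene in transferred_genes:
        if phylum_hits.get(gene, 0) == 0:
            labels[gene] = "K"
        elif abs(float(close_order.get(gene, 0.0)) - float(close_sister.get(gene, 0.0))) < 1.0:
            labels[gene] = "K+M"
        else:
            labels[gene] = "transferred_unlabeled"
    return pd.Series(labels, name="recentness")


@dataclass
class LgtResult:
    """Full output of the LGT screen."""

    scores: pd.DataFrame          # per-gene scores from both runs + calls
    close_cutoff: float
    distal_cutoff: float
    close_diag: CutoffDiagnostics
    distal_diag: CutoffDiagnostics


def run_lgt_screen(
    raw_hits: pd.DataFrame,
    order_groups: GroupDefinition = ORDER_GROUPS,
    sister_groups: GroupDefinition = SISTER_GROUPS,
    phylum_label: str = DEFAULT_PHYLUM,
    max_per_query: int = 500,
    max_evalue: float = 1e-5,
    min_coverage: float = 0.7,
    min_genes: int = 50,
) -> LgtResult:
    """Filter hits, score both Close presets, derive cutoffs, call transfers.

    Transfer calls use the order-level run (its Close group covers every
    close relative); the sister-genus run supplies the second Close score
    for the recentness rule.
    """
    hits = filter_hits(raw_hits, max_per_query, max_evalue, min_coverage)
    order_scores = score_table(hits, order_groups)
    sister_scores = score_table(hits, sister_groups)

    close_diag = estimate_cutoffs(order_scores["close_score"].to_numpy(), min_genes)
    distal_diag = estimate_cutoffs(order_scores["distal_score"].to_numpy(), min_genes)

    transferred = classify_transferred(
        order_scores, close_diag.cutoff, distal_diag.cutoff
    )
    recent = assign_transfer_lineage(
        order_scores.index[transferred], hits,
        order_scores["close_score"], sister_scores["close_score"],
        groups=order_groups, phylum_label=phylum_label,
    )
    out = pd.DataFrame(
        {
            "self_score": order_scores["self_score"],
            "close_score_run1": sister_scores["close_score"],
            "close_score_run2": order_scores["close_score"],
            "distal_score": order_scores["distal_score"],
            "transferred": transferred,
            "recentness": recent.reindex(order_scores.index, fill_value="none"),
        }
    )
    return LgtResult(
        scores=out,
        close_cutoff=close_diag.cutoff,
        distal_cutoff=distal_diag.cutoff,
        close_diag=close_diag,
        distal_diag=distal_diag,
    )
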