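"""Differential expression by the two-group negative-binomial exact test.

Pairwise comparisons of each sub-/supra-optimal temperature against the
65 C reference condition:

* RPKM (reads per kilobase of transcript per million mapped reads) for
  reporting and fold changes,
* a single common NB dispersion phi (var = mu + phi mu^2) estimated across
  genes by a pooled moment estimator,
* the Robinson-Smyth style exact test on counts: library sizes are scaled
  to their geometric mean, counts are summed per condition into
  pseudo-totals, and the two-sided p-value conditions on the gene's total,
  accumulating all outcomes whose conditional probability does not exceed
  the observed one,
* Benjamini-Hochberg FDR within each comparison,
* the three responsiveness criteria: FDR < 0.05, fold change >= 2 on mean
  RPKM, and more than 20 reads in at least one of the two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionExperiment
from .errors import ConfigError, DataError

REFERENCE_TEMPERATURE = 65.0


@dataclass(frozen=True)
class ResponsivenessCriteria:
    """Thresholds for calling a gene temperature-responsive.

    ``min_fold_change`` is inclusive (>=), ``min_reads`` strict (>), and
    ``max_fdr`` strict (<).
    """

    min_fold_change: float = 2.0
    min_reads: int = 20
    max_fdr: float = 0.05
    rpkm_pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.min_fold_change <= 0 or self.min_reads <= 0 or self.max_fdr <= 0:
            raise ConfigError("criteria thresholds must be positive")


def compute_rpkm(experiment: ExpressionExperiment) -> pd.DataFrame:
    """RPKM = 1e9 * count / (gene length in nt * mapped reads in sample)."""
    lengths = experiment.genes["length_nt"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise DataError("gene lengths must be positive for RPKM")
    counts = experiment.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise DataError("sample totals must be positive for RPKM")
    rpkm = 1.0e9 * counts / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(rpkm, index=experiment.counts.index,
                        columns=experiment.counts.columns)


def estimate_dispersion(counts: np.ndarray, groups: np.ndarray) -> float:
    """Common NB dispersion across genes by a pooled moment estimator.

    ``counts`` is genes x samples, ``groups`` a label per sample; within-
    group scatter is pooled over genes and equated to its NB expectation
    E[SS_g] = df_g * (mu_g + phi mu_g^2).  The estimate is refined twice to
    correct the plug-in bias of using the sample mean for mu, and clipped
    at 0, so under-dispersed (sub-Poisson) data report phi = 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise DataError("need a genes x samples matrix with >=2 samples")
    if counts.sum() <= 0:
        raise DataError("all-zero count matrix")
    groups = np.asarray(groups)
    ss = np.zeros(counts.shape[0])
    dfm = np.zeros(counts.shape[0])
    dfm2 = np.zeros(counts.shape[0])
    means = []
    ns = []
    for g in np.unique(groups):
        sub = counts[:, groups == g]
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        dfm += (n - 1) * m
        dfm2 += (n - 1) * m * m
        means.append(m)
        ns.append(n)
    if not means:
        raise DataError("no group with at least 2 replicates")
    phi = 0.0
    for _ in range(3):
        # E[m^2] = mu^2 + (mu + phi mu^2)/n : subtract the mean's own noise
        correction = 0.0
        for m, n in zip(means, ns):
            correction += ((n - 1) * (m + phi * m * m) / n).sum()
        denom = dfm2.sum() - correction
        if denom <= 0:
            return 0.0
        phi = max(0.0, (ss.sum() - dfm.sum()) / denom)
    return float(phi)


def exact_test_two_group(
    y1, y2, n1: int, n2: int, dispersion: float
) -> np.ndarray:
    """Two-sided conditional exact p-values for per-group pseudo-totals.

    ``y1``/``y2`` are the (normalized, rounded) count totals of the two
    conditions, ``n1``/``n2`` the numbers of samples summed into them.
    The group totals are modelled NB(n_g * lambda, size n_g / phi) with
    lambda the per-sample mean (y1+y2)/(n1+n2); conditioning on the gene
    total s, the p-value sums the probabilities of all splits k in [0, s]
    whose conditional probability does not exceed the observed one, capped
    at 1.  With phi = 0 the group totals are Poisson and the conditional
    law is Binomial(s, n1/(n1+n2)).
    """
    if dispersion < 0:
        raise ConfigError("dispersion must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ConfigError("both groups need at least one sample")
    y1 = np.atleast_1d(np.asarray(y1, dtype=float))
    y2 = np.atleast_1d(np.asarray(y2, dtype=float))
    if (y1 < 0).any() or (y2 < 0).any():
        raise DataError("negative counts")
    p_out = np.ones(len(y1))
    for i, (a, b) in enumerate(zip(y1, y2)):
        s = int(round(a + b))
        if s == 0:
            p_out[i] = 1.0
            continue
        obs = int(round(a))
        k = np.arange(s + 1)
        lam = s / (n1 + n2)
        if dispersion == 0:
            logp = (stats.poisson.logpmf(k, n1 * lam)
                    + stats.poisson.logpmf(s - k, n2 * lam))
        else:
            size1 = n1 / dispersion
            size2 = n2 / dispersion
            mu1 = n1 * lam
            mu2 = n2 * lam
            logp = (stats.nbinom.logpmf(k, size1, size1 / (size1 + mu1))
                    + stats.nbinom.logpmf(s - k, size2, size2 / (size2 + mu2)))
        logp -= logsumexp(logp)
        prob = np.exp(logp)
        keep = prob <= prob[obs] * (1.0 + 1e-12)
        p_out[i] = min(1.0, float(prob[keep].sum()))
    return p_out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_responsive(
    q: float,
    fold_change: float,
    max_group_reads: float,
    mean_rpkm_test: float,
    mean_rpkm_ref: float,
    criteria: ResponsivenessCriteria = ResponsivenessCriteria(),
) -> tuple[bool, str]:
    """Apply the three responsiveness criteria; returns (flag, direction)."""
    responsive = (
        q < criteria.max_fdr
        and fold_change >= criteria.min_fold_change
        and max_group_reads > criteria.min_reads
    )
    direction = "up" if mean_rpkm_test > mean_rpkm_ref else "down"
    return bool(responsive), direction


def _group_pseudototals(counts: np.ndarray, cols1, cols2):
    """Scale both groups' libraries to their geometric mean, then sum.

    Rounding is half-to-even (numpy rint), documented and fixed.
    """
    sub = counts[:, list(cols1) + list(cols2)]
    libs = sub.sum(axis=0)
    if (libs <= 0).any():
        raise DataError("zero library size in comparison")
    geo = np.exp(np.mean(np.log(libs)))
    scaled = sub * (geo / libs)[None, :]
    k1 = len(cols1)
    y1 = np.rint(scaled[:, :k1].sum(axis=1))
    y2 = np.rint(scaled[:, k1:].sum(axis=1))
    return y1, y2, scaled


def de_comparison(
    experiment: ExpressionExperiment,
    test_temperature: float,
    reference_temperature: float = REFERENCE_TEMPERATURE,
    criteria: ResponsivenessCriteria = ResponsivenessCriteria(),
    dispersion: float | None = None,
    min_reads_per: str = "condition",
) -> pd.DataFrame:
    """One pairwise comparison (test temperature vs 65 C reference).

    Returns a per-gene table: mean RPKM per condition, fold change and
    direction, the per-condition read maximum, exact-test p, BH q (within
    this comparison), and the responsive flag.

    ``min_reads_per`` selects the reading of the ">20 reads" criterion:
    ``"condition"`` (default) sums raw reads within each condition,
    ``"sample"`` uses the maximum single-sample count.
    """
    if min_reads_per not in ("condition", "sample"):
        raise ConfigError("min_reads_per must be 'condition' or 'sample'")
    cols_test = experiment.samples_at(test_temperature)
    cols_ref = experiment.samples_at(reference_temperature)
    if not cols_test or not cols_ref:
        raise DataError(
            f"no samples at {test_temperature:g} C or {reference_temperature:g} C"
        )
    counts = experiment.counts.to_numpy(dtype=float)
    all_cols = list(experiment.counts.columns)
    i_test = [all_cols.index(c) for c in cols_test]
    i_ref = [all_cols.index(c) for c in cols_ref]

    y1, y2, scaled = _group_pseudototals(counts, i_test, i_ref)
    if dispersion is None:
        groups = np.array([0] * len(i_test) + [1] * len(i_ref))
        dispersion = estimate_dispersion(scaled, groups)
    p = exact_test_two_group(y1, y2, len(i_test), len(i_ref), dispersion)
    q = bh_fdr(p)

    rpkm = compute_rpkm(experiment)
    mean_test = rpkm[cols_test].mean(axis=1).to_numpy()
    mean_ref = rpkm[cols_ref].mean(axis=1).to_numpy()
    pc = criteria.rpkm_pseudocount
    hi = np.maximum(mean_test, mean_ref) + pc
    lo = np.minimum(mean_test, mean_ref) + pc
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))

    raw_test = counts[:, i_test]
    raw_ref = counts[:, i_ref]
    if min_reads_per == "condition":
        max_reads = np.maximum(raw_test.sum(axis=1), raw_ref.sum(axis=1))
    else:
        max_reads = np.maximum(raw_test.max(axis=1), raw_ref.max(axis=1))

    flags = []
    directions = []
    for i in range(len(p)):
        f, d = call_responsive(q[i], fold[i], max_reads[i],
                               mean_test[i], mean_ref[i], criteria)
        flags.append(f)
        directions.append(d)

    return pd.DataFrame(
        {
            "test_temperature_C": test_temperature,
            "reference_temperature_C": reference_temperature,
            "mean_rpkm_test": mean_test,
            "mean_rpkm_ref": mean_ref,
            "fold_change": fold,
            "direction": directions,
            "max_group_reads": max_reads,
            "p": p,
            "q": q,
            "responsive": flags,
            "dispersion": dispersion,
        },
        index=experiment.counts.index,
    )


def de_all_comparisons(
    experiment: ExpressionExperiment,
    reference_temperature: float = REFERENCE_TEMPERATURE,
    criteria: ResponsivenessCriteria = ResponsivenessCriteria(),
    min_reads_per: str = "condition",
) -> dict[float, pd.DataFrame]:
    """Run every non-reference temperature against the reference."""
    out = {}
    for t in experiment.temperatures:
        if t == reference_temperature:
            continue
        out[float(t)] = de_comparison(
            experiment, float(t), reference_temperature, criteria,
            min_reads_per=min_reads_per,
        )
    return out


def updown_summary(de_tables: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Up/down-regulated counts per comparison plus a pooled row.

    A gene contributes once per comparison in which it is responsive, so
    the pooled row is the column sum of the per-comparison rows.
    """
    rows = []
    for t in sorted(de_tables):
        tab = de_tables[t]
        resp = tab[tab["responsive"]]
        rows.append(
            {
                "comparison": f"{t:g}v{tab['reference_temperature_C'].iloc[0]:g}",
                "up": int((resp["direction"] == "up").sum()),
                "down": int((resp["direction"] == "down").sum()),
                "responsive": int(len(resp)),
            }
        )
    pooled = {
        "comparison": "pooled",
        "up": sum(r["up"] for r in rows),
        "down": sum(r["down"] for r in rows),
        "responsive": sum(r["responsive"] for r in rows),
    }
    return pd.DataFrame(rows + [pooled])


def responsive_union(de_tables: dict[float, pd.DataFrame]) -> pd.Index:
    """Genes responsive in at least one comparison (each counted once)."""
    ids: set[str] = set()
    for tab in de_tables.values():
        ids.update(tab.index[tab["responsive"]])
    return pd.Index(sorted(ids), name="gene_id")


def pca_samples(log_expression: pd.DataFrame):
    """Centered PCA of samples from a genes x samples expression matrix.

    Returns ``(coordinates, loadings, variance_fractions)``: sample
    coordinates (samples x components), gene loadings (genes x components,
    scaled by the singular values so vector length ranks correlation
    strength), and the fractions of variance explained (summing to 1).
    """
    x = log_expression.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < 2:
        raise DataError("PCA needs at least 2 samples")
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(xc):
        raise DataError("constant expression matrix has no principal components")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ncomp = min(x.shape[0] - 1, len(s))
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    coords = pd.DataFrame(
        u * s, index=log_expression.columns,
        columns=[f"PC{i+1}" for i in range(ncomp)],
    )
    loadings = pd.DataFrame(
        (vt.T * s) / np.sqrt(max(x.shape[0] - 1, 1)),
        index=log_expression.index,
        columns=coords.columns,
    )
    var = s**2
    frac = var / var.sum()
    return coords, loadings, frac
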