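"""Observed-vs-expected representation of responsive genes across COG
functional categories.

Under random assignment, each category would contain the same fraction of
temperature-responsive genes as the genome at large; the table reports the
observed count, that expectation, and two flavours of the difference:

* ``diff_percent`` (primary): 100 * (observed - expected) / expected,
* ``diff_points``: the difference in percentage-point shares of the
  responsive vs genome category-incidence totals.

Genes assigned to more than one category are counted in every category
they carry; unassigned genes travel under the pseudo-category ``NC``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError


def _category_sets(cog_series: pd.Series) -> pd.Series:
    """Parse semicolon-separated category strings into sets (NC if empty)."""
    def parse(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return {"NC"}
        return {c.strip() for c in str(v).split(";") if c.strip()}
    return cog_series.map(parse)


def enrichment_table(
    responsive_genes,
    genome_cogs: pd.Series,
    permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-category enrichment of a responsive gene set.

    Parameters
    ----------
    responsive_genes
        Iterable of gene ids; must be a subset of ``genome_cogs``' index.
    genome_cogs
        Semicolon-separated COG category string per genome gene
        (index = gene id).
    permutations
        If > 0, adds a two-sided permutation p-value per category from
        seeded gene-label shuffles.  This is a convenience extra, not part
        of the original descriptive analysis.
    """
    responsive = list(responsive_genes)
    missing = [g for g in responsive if g not in genome_cogs.index]
    if missing:
        raise DataError(f"responsive gene(s) absent from genome table: {missing[:5]}")

    sets = _category_sets(genome_cogs)
    categories = sorted(set().union(*sets))
    genome_counts = {c: 0 for c in categories}
    for s in sets:
        for c in s:
            genome_counts[c] += 1
    resp_sets = sets.loc[responsive]
    observed = {c: 0 for c in categories}
    for s in resp_sets:
        for c in s:
            observed[c] += 1

    n_genome = len(genome_cogs)
    n_resp = len(responsive)
    frac = n_resp / n_genome
    genome_incidence = sum(genome_counts.values())
    resp_incidence = sum(observed.values())

    rows = []
    for c in categories:
        exp = genome_counts[c] * frac
        obs = observed[c]
        if exp > 0:
            diff = 100.0 * (obs - exp) / exp
            flagged = False
        elif obs == 0:
            diff = 0.0
            flagged = False
        else:
            diff = float("inf")
            flagged = True
        share_obs = obs / resp_incidence if resp_incidence else 0.0
        share_exp = genome_counts[c] / genome_incidence if genome_incidence else 0.0
        rows.append(
            {
                "category": c,
                "genome_count": genome_counts[c],
                "observed": obs,
                "expected": exp,
                "diff_percent": diff,
                "diff_points": 100.0 * (share_obs - share_exp),
                "flagged": flagged,
            }
        )
    table = pd.DataFrame(rows).set_index("category")

    if permutations > 0 and n_resp > 0:
        rng = np.random.default_rng(seed)
        all_ids = np.array(genome_cogs.index)
        obs_vec = table["observed"].to_numpy()
        extreme = np.zeros(len(table), dtype=int)
        dev_obs = np.abs(obs_vec - table["expected"].to_numpy())
        for _ in range(permutations):
            draw = rng.choice(all_ids, size=n_resp, replace=False)
            counts = {c: 0 for c in categories}
            for s in sets.loc[draw]:
                for c in s:
                    counts[c] += 1
            dev = np.abs(
                np.array([counts[c] for c in categories])
                - table["expected"].to_numpy()
            )
            extreme += dev >= dev_obs - 1e-12
        table["perm_p"] = (extreme + 1) / (permutations + 1)
    return table
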