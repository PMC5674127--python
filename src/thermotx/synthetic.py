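"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline is testable without any download
because this module fabricates all of its inputs:

* a temperature-gradient RNA-seq experiment (negative-binomial counts over
  4 temperatures x 2 replicates, with planted temperature-responsive,
  growth-rate-linear and null genes),
* three-phase (lag / exponential / stationary) OD600 growth curves whose
  exponential rate follows a square-root cardinal-temperature model,
* tabular homology hits with Self/Close/Distal structure and a planted
  fraction of laterally transferred genes (the "zero peak" of the Close
  score distribution),
* annotated genome pairs with controlled coding fraction and controlled
  nucleotide divergence for ANI testing.

All generators are pure functions of (config, seed): the same seed gives
bit-identical output (numpy PCG64 via ``default_rng``).

The defaults mirror the study design this toolkit was built around:
temperatures 30/40/65/77 C with growth rates 0.006/0.087/0.274/0.107 h^-1,
two replicate libraries per temperature, and ~3 million mapped reads per
library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import COG_CATEGORIES, ExpressionExperiment, empty_truth
from .errors import ConfigError
from .growth import GrowthCurve, RatkowskyParams

DEFAULT_TEMPERATURES = (30.0, 40.0, 65.0, 77.0)
DEFAULT_GROWTH_RATES = {30.0: 0.006, 40.0: 0.087, 65.0: 0.274, 77.0: 0.107}
DEFAULT_CLASS_MIX = {
    "null": 0.70,
    "temp_responsive": 0.15,
    "rate_linear": 0.10,
    "mixed": 0.05,
}
REFERENCE_TEMPERATURE = 65.0


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a simulated expression experiment.

    ``growth_rates`` maps each temperature to the specific growth rate
    (h^-1) of the culture it was sampled from; the defaults are the four
    rates of the study design.  ``dispersion`` is the NB dispersion phi in
    the variance function var = mu + phi * mu^2.
    """

    seed: int
    n_genes: int = 2000
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    replicates: int = 2
    growth_rates: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_GROWTH_RATES)
    )
    dispersion: float = 0.05
    library_size_median: float = 3.0e6
    library_size_sigma: float = 0.15
    gene_length_range: tuple[int, int] = (300, 3000)
    base_log2_mean: float = 8.0   # log2 of the median per-gene mean count
    base_log2_sd: float = 1.5

    def __post_init__(self) -> None:
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ConfigError("temperatures must be distinct")
        if self.replicates < 1:
            raise ConfigError("at least one replicate per temperature is required")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        for t in self.temperatures:
            if t not in self.growth_rates:
                raise ConfigError(f"no growth rate given for temperature {t:g} C")
            if self.growth_rates[t] < 0:
                raise ConfigError("growth rates must be non-negative")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid gene length range")

    @property
    def mean_growth_rate(self) -> float:
        return float(np.mean([self.growth_rates[t] for t in self.temperatures]))


def _draw_nb(rng, mean, dispersion):
    """NB(mean, phi) draws with var = mu + phi mu^2; phi=0 reduces to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression_experiment(
    config: SimulationConfig,
    class_mix: dict[str, float] | None = None,
    effect_log2: float = 2.0,
    rate_slope_log2: float = 8.0,
    target_temperature: float | None = None,
) -> tuple[ExpressionExperiment, pd.DataFrame]:
    """Simulate a count matrix with planted differential-expression truth.

    Parameters
    ----------
    class_mix
        Proportions over {null, temp_responsive, rate_linear, mixed};
        must sum to 1.
    effect_log2
        Magnitude of the planted log2 offset for temperature-responsive
        genes (sign drawn at random per gene).
    rate_slope_log2
        Magnitude of the planted slope (log2 expression per unit growth
        rate, h) for rate-linear genes.  Over the default rate span
        (0.006..0.274 h^-1) the default of 8 gives a ~2.1 log2-unit sweep.
    target_temperature
        If given, every temp_responsive/mixed gene gets its offset at this
        temperature; otherwise each gene picks one non-reference
        temperature at random.

    Returns
    -------
    (experiment, truth)
        ``truth`` has one row per gene: de_class, per-temperature
        ``offset_log2_<T>C`` columns, and ``rate_slope``.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
        raise ConfigError("class_mix proportions must be non-negative and sum to 1")
    if not (math.isfinite(effect_log2) and math.isfinite(rate_slope_log2)):
        raise ConfigError("effect sizes must be finite")

    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    temps = list(config.temperatures)
    gene_ids = [f"gene_{i:05d}" for i in range(n)]

    classes = rng.choice(list(mix), size=n, p=list(mix.values()))
    base_log2 = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)

    truth = empty_truth(gene_ids, temps)
    truth["de_class"] = classes
    truth["base_log2_mean"] = base_log2

    non_ref = [t for t in temps if t != REFERENCE_TEMPERATURE]
    signs = rng.choice([-1.0, 1.0], size=n)
    chosen_temp = rng.choice(non_ref, size=n)
    slope_signs = rng.choice([-1.0, 1.0], size=n)
    for i, cls in enumerate(classes):
        if cls in ("temp_responsive", "mixed"):
            t = target_temperature if target_temperature is not None else chosen_temp[i]
            truth.iloc[i, truth.columns.get_loc(f"offset_log2_{t:g}C")] = (
                signs[i] * effect_log2
            )
        if cls in ("rate_linear", "mixed"):
            truth.iloc[i, truth.columns.get_loc("rate_slope")] = (
                slope_signs[i] * rate_slope_log2
            )

    # sample sheet
    sample_rows = []
    for t in temps:
        for r in range(1, config.replicates + 1):
            sample_rows.append(
                {
                    "sample_id": f"T{t:g}_r{r}",
                    "temperature_C": t,
                    "growth_rate_per_h": config.growth_rates[t],
                    "replicate": r,
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    lib_sizes = config.library_size_median * np.exp(
        rng.normal(0.0, config.library_size_sigma, size=len(samples))
    )

    # per-gene, per-temperature log2 mean; rate effect centred on the mean
    # rate so that planting a slope does not shift overall abundance
    mean_rate = config.mean_growth_rate
    offsets = truth[[f"offset_log2_{t:g}C" for t in temps]].to_numpy()
    slopes = truth["rate_slope"].to_numpy()
    log2_mean = np.empty((n, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        ti = temps.index(row["temperature_C"])
        log2_mean[:, j] = (
            base_log2
            + offsets[:, ti]
            + slopes * (row["growth_rate_per_h"] - mean_rate)
        )
    scale = lib_sizes / config.library_size_median
    mean = (2.0 ** log2_mean) * scale[None, :]
    counts = _draw_nb(rng, mean, config.dispersion)

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    cats = list(COG_CATEGORIES)
    primary = rng.choice(cats, size=n)
    secondary = rng.choice(cats, size=n)
    two = rng.random(n) < 0.1
    cogs = [
        f"{p};{s}" if (t and s != p) else p
        for p, s, t in zip(primary, secondary, two)
    ]
    genes = pd.DataFrame(
        {"length_nt": lengths, "cog_categories": cogs},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    counts_df = pd.DataFrame(
        counts, index=genes.index, columns=samples.index
    )
    exp = ExpressionExperiment(counts=counts_df, samples=samples, genes=genes)
    return exp, truth


def simulate_growth_curves(
    ratkowsky: RatkowskyParams,
    temperatures,
    noise_sd: float = 0.05,
    seed: int = 0,
    replicates: int = 3,
    od_start: float = 0.02,
    od_max: float = 0.5,
    lag_fraction: float = 0.15,
    n_points: int = 48,
) -> list[GrowthCurve]:
    """Three-phase OD600 curves whose log-phase rate follows the model.

    Each curve is flat at ``od_start`` through the lag, grows exponentially
    at the Ratkowsky-predicted rate, and saturates at ``od_max``;
    multiplicative lognormal noise of standard deviation ``noise_sd`` (on
    the log scale) is applied pointwise.  With ``noise_sd=0`` the log-phase
    slope of the curve equals the model rate exactly.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    curves = []
    for t in temperatures:
        if not (ratkowsky.t_min < t < ratkowsky.t_max):
            raise ConfigError(
                f"temperature {t:g} C outside the growth-permissive range "
                f"({ratkowsky.t_min:g}, {ratkowsky.t_max:g}) C"
            )
        rate = float(ratkowsky.rate(t))
        if rate <= 0:
            raise ConfigError(f"model predicts zero growth at {t:g} C")
        t_exp = math.log(od_max / od_start) / rate
        lag = lag_fraction * t_exp
        duration = lag + t_exp * 1.3
        times = np.linspace(0.0, duration, n_points)
        log_od = np.where(
            times < lag,
            math.log(od_start),
            np.minimum(math.log(od_start) + rate * (times - lag), math.log(od_max)),
        )
        for r in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd, size=n_points) if noise_sd > 0 else 0.0
            curves.append(
                GrowthCurve(
                    temperature=float(t),
                    replicate=f"{t:g}C_rep{r}",
                    times=times,
                    od600=np.exp(log_od + noise),
                )
            )
    return curves


# ---------------------------------------------------------------------------
# homology-hit simulation for LGT detection
# ---------------------------------------------------------------------------

#: default lineage scheme: label -> full lineage path (semicolon-joined when
#: serialised).  "self" = own genus, "close" = sister genus and the rest of
#: the order, "distal" = everything else.
DEFAULT_TAXONOMY = {
    "self": [
        ("Kosmotoga olearia", "Bacteria;Thermotogae;Thermotogales;Kosmotogaceae;Kosmotoga;Kosmotoga olearia"),
        ("Kosmotoga sp. DU53", "Bacteria;Thermotogae;Thermotogales;Kosmotogaceae;Kosmotoga;Kosmotoga sp. DU53"),
    ],
    "sister": [
        ("Mesotoga prima", "Bacteria;Thermotogae;Thermotogales;Kosmotogaceae;Mesotoga;Mesotoga prima"),
        ("Mesotoga infera", "Bacteria;Thermotogae;Thermotogales;Kosmotogaceae;Mesotoga;Mesotoga infera"),
    ],
    "order": [
        ("Thermotoga maritima", "Bacteria;Thermotogae;Thermotogales;Thermotogaceae;Thermotoga;Thermotoga maritima"),
        ("Thermotoga neapolitana", "Bacteria;Thermotogae;Thermotogales;Thermotogaceae;Thermotoga;Thermotoga neapolitana"),
        ("Petrotoga mobilis", "Bacteria;Thermotogae;Thermotogales;Petrotogaceae;Petrotoga;Petrotoga mobilis"),
    ],
    "distal": [
        ("Escherichia coli", "Bacteria;Proteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia;Escherichia coli"),
        ("Bacillus subtilis", "Bacteria;Firmicutes;Bacillales;Bacillaceae;Bacillus;Bacillus subtilis"),
        ("Clostridium acetobutylicum", "Bacteria;Firmicutes;Clostridiales;Clostridiaceae;Clostridium;Clostridium acetobutylicum"),
        ("Methanococcus maripaludis", "Archaea;Euryarchaeota;Methanococcales;Methanococcaceae;Methanococcus;Methanococcus maripaludis"),
        ("Aquifex aeolicus", "Bacteria;Aquificae;Aquificales;Aquificaceae;Aquifex;Aquifex aeolicus"),
    ],
}

HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_len",
    "evalue", "bitscore", "qcov", "lineage",
]


def _hit_row(rng, query, subject_tag, taxon, lineage, bitscore, cov):
    return {
        "query_id": query,
        "subject_id": subject_tag,
        "pct_identity": round(float(rng.uniform(35, 99)), 1),
        "aln_len": int(rng.integers(100, 600)),
        "evalue": float(10.0 ** rng.uniform(-180, -6)),
        "bitscore": round(float(bitscore), 1),
        "qcov": round(float(cov), 3),
        "lineage": lineage,
    }


def simulate_homology_hits(
    n_genes: int = 1000,
    transfer_fraction: float = 0.3,
    taxonomy: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate filtered homology-search hits with planted transfer labels.

    Vertical genes get strong Close-group support (sister genus and the
    rest of the order) and weak Distal support; transferred genes get
    essentially no Close support — populating the zero peak of the Close
    score distribution — and strong Distal support.  Transferred genes are
    split between recent acquisitions with no hits in the home phylum at
    all (``transferred_K``) and older transfers shared with the sister
    genus only (``transferred_KM``).

    Returns ``(hit_table, truth)`` where ``truth`` carries ``lgt_class``
    per gene.
    """
    if not (0.0 <= transfer_fraction <= 1.0):
        raise ConfigError("transfer_fraction must be in [0, 1]")
    tax = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    if not tax or not any(tax.values()):
        raise ConfigError("taxonomy scheme must not be empty")
    rng = np.random.default_rng(seed)

    rows = []
    truth_rows = []
    for i in range(n_genes):
        gene = f"gene_{i:05d}"
        u = rng.random()
        if u < transfer_fraction:
            lgt = "transferred_KM" if rng.random() < 0.4 else "transferred_K"
        else:
            lgt = "vertical"
        truth_rows.append({"gene_id": gene, "lgt_class": lgt})

        self_best = rng.uniform(400, 700)
        # the query's own self-match (always present, excluded from scores)
        name, lin = tax["self"][0]
        rows.append(_hit_row(rng, gene, gene, name, lin, self_best, 1.0))
        # a congeneric self-group hit
        name, lin = tax["self"][1]
        rows.append(
            _hit_row(rng, gene, f"{gene}|self1", name, lin,
                     self_best * rng.uniform(0.85, 0.98), rng.uniform(0.8, 1.0))
        )

        if lgt == "vertical":
            # per-gene conservation factor spreads close support into a
            # continuum, as poorly conserved genes do in real screens
            conservation = rng.uniform(0.15, 1.0)
            n_sister = rng.integers(2, 6)
            n_order = rng.integers(3, 8)
            n_distal = rng.integers(1, 4)
            for k in range(n_sister):
                name, lin = tax["sister"][rng.integers(len(tax["sister"]))]
                rows.append(_hit_row(rng, gene, f"{gene}|sis{k}", name, lin,
                                     self_best * conservation * rng.uniform(0.5, 0.9),
                                     rng.uniform(0.75, 1.0)))
            for k in range(n_order):
                name, lin = tax["order"][rng.integers(len(tax["order"]))]
                rows.append(_hit_row(rng, gene, f"{gene}|ord{k}", name, lin,
                                     self_best * conservation * rng.uniform(0.4, 0.8),
                                     rng.uniform(0.75, 1.0)))
            for k in range(n_distal):
                name, lin = tax["distal"][rng.integers(len(tax["distal"]))]
                rows.append(_hit_row(rng, gene, f"{gene}|dis{k}", name, lin,
                                     self_best * rng.uniform(0.03, 0.15),
                                     rng.uniform(0.7, 0.95)))
        else:
            # transferred: many strong distal hits, near-zero close support
            n_distal = rng.integers(8, 19)
            for k in range(n_distal):
                name, lin = tax["distal"][rng.integers(len(tax["distal"]))]
                rows.append(_hit_row(rng, gene, f"{gene}|dis{k}", name, lin,
                                     self_best * rng.uniform(0.4, 0.9),
                                     rng.uniform(0.75, 1.0)))
            if lgt == "transferred_KM":
                # shared with the sister genus: small Mesotoga-only support
                for k in range(int(rng.integers(1, 3))):
                    name, lin = tax["sister"][rng.integers(len(tax["sister"]))]
                    rows.append(_hit_row(rng, gene, f"{gene}|sis{k}", name, lin,
                                         self_best * rng.uniform(0.005, 0.03),
                                         rng.uniform(0.7, 0.9)))

    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return hits, truth


# ---------------------------------------------------------------------------
# annotated genome pairs for ANI / coding-density testing
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_annotated_genome(
    length: int,
    coding_fraction: float = 0.885,
    divergence: float = 0.0,
    seed: int = 0,
) -> tuple[str, str, list[tuple[str, int, int, str, str]]]:
    """A random genome, a diverged copy, and a gene annotation.

    Non-overlapping gene features are laid down to cover the target coding
    fraction within +-1%; the second sequence is the first with independent
    per-site substitutions at probability ``divergence``.  Annotation
    coordinates are 1-based inclusive, as in GFF3/GenBank.

    Returns ``(sequence_a, sequence_b, features)`` with features as
    ``(id, start, end, strand, type)`` tuples.
    """
    if length < 1000:
        raise ConfigError("genome length must be at least 1000 nt")
    if not (0.0 < coding_fraction <= 1.0):
        raise ConfigError("coding fraction must be in (0, 1]")
    if not (0.0 <= divergence < 1.0):
        raise ConfigError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)

    seq_a = rng.integers(0, 4, size=length)

    # alternate gene / intergenic blocks sized to hit the coding target
    features = []
    pos = 0  # 0-based cursor
    gene_mean = 900.0
    gap_mean = max(gene_mean * (1.0 / coding_fraction - 1.0), 0.0)
    i = 0
    coding_nt = 0
    while pos < length:
        glen = int(np.clip(rng.normal(gene_mean, 200.0), 300, 1500))
        glen = min(glen, length - pos)
        strand = "+" if rng.random() < 0.5 else "-"
        features.append((f"feat_{i:05d}", pos + 1, pos + glen, strand, "gene"))
        coding_nt += glen
        pos += glen
        i += 1
        if gap_mean > 0:
            gap = int(max(rng.exponential(gap_mean), 1.0))
        else:
            gap = 0
        pos += gap
    # redistribute the sampling error so the achieved fraction is within +-1%:
    # shrink genes (never below 100 nt) when over target, grow them into the
    # following intergenic gap when under.
    target = coding_fraction * length
    err = coding_nt - target  # positive = too much coding sequence
    if err > 0:
        for j in range(len(features) - 1, -1, -1):
            if err <= 0:
                break
            fid, start, end, strand, ftype = features[j]
            reducible = (end - start + 1) - 100
            delta = int(min(reducible, math.ceil(err)))
            if delta > 0:
                features[j] = (fid, start, end - delta, strand, ftype)
                err -= delta
    elif err < 0:
        deficit = -err
        for j in range(len(features) - 1, -1, -1):
            if deficit <= 0:
                break
            fid, start, end, strand, ftype = features[j]
            next_start = features[j + 1][1] if j + 1 < len(features) else length + 1
            gap_after = next_start - 1 - end
            delta = int(min(gap_after, math.ceil(deficit)))
            if delta > 0:
                features[j] = (fid, start, end + delta, strand, ftype)
                deficit -= delta

    if divergence > 0:
        mutate = rng.random(length) < divergence
        shift = rng.integers(1, 4, size=length)
        seq_b = np.where(mutate, (seq_a + shift) % 4, seq_a)
    else:
        seq_b = seq_a.copy()

    to_str = lambda arr: _BASES[arr].tobytes().decode("ascii")
    return to_str(seq_a), to_str(seq_b), features
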