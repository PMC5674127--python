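"""Flat-file input/output for every pipeline stage.

All tabular outputs are TSV/CSV with a comment header recording the tool
version, the configuration hash and the seed, so any file can be traced
back to the run that produced it.  Readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import ExpressionExperiment
from .growth import GrowthCurve


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed, cfg_hash) -> str:
    return f"# thermotx v{__version__} seed={seed} config={cfg_hash}\n"


def write_table(
    df: pd.DataFrame, path, seed=0, cfg_hash="-", sep="\t", index=True
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep="\t", index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def write_json(obj, path, seed=0, cfg_hash="-") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_tool": f"thermotx v{__version__}", "_seed": seed,
               "_config": cfg_hash, **obj}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


# -- experiment bundles ------------------------------------------------------

def write_experiment(exp: ExpressionExperiment, outdir, seed=0, cfg_hash="-"):
    outdir = Path(outdir)
    write_table(exp.counts, outdir / "counts.tsv", seed, cfg_hash)
    write_table(exp.samples, outdir / "samples.csv", seed, cfg_hash, sep=",")
    write_table(exp.genes, outdir / "genes.tsv", seed, cfg_hash)


def read_experiment(counts_path, samples_path, genes_path) -> ExpressionExperiment:
    counts = read_table(counts_path)
    samples = read_table(samples_path, sep=",")
    genes = read_table(genes_path)
    return ExpressionExperiment(counts=counts, samples=samples, genes=genes)


# -- growth curves -----------------------------------------------------------

def write_growth_curves(curves, path, seed=0, cfg_hash="-"):
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od600):
            rows.append(
                {
                    "temperature_C": c.temperature,
                    "replicate": c.replicate,
                    "time_h": t,
                    "od600": od,
                }
            )
    write_table(pd.DataFrame(rows), path, seed, cfg_hash, sep=",", index=False)


def read_growth_curves(path) -> list[GrowthCurve]:
    df = pd.read_csv(path, comment="#")
    curves = []
    for (temp, rep), sub in df.groupby(["temperature_C", "replicate"], sort=True):
        sub = sub.sort_values("time_h")
        curves.append(
            GrowthCurve(
                temperature=float(temp),
                replicate=str(rep),
                times=sub["time_h"].to_numpy(),
                od600=sub["od600"].to_numpy(),
            )
        )
    return curves


# -- FASTA -------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
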