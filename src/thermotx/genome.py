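"""Comparative genome statistics: homolog presence, coding density, ANI.

Average nucleotide identity follows the fragment recipe of Goris et al.:
the query genome is cut into consecutive non-overlapping 1020-nt fragments
(trailing partial fragment dropped), each fragment is aligned to the
subject genome, and fragments aligning over at least 70% of their length
with at least 30% identity contribute their percent identity to the mean.

The built-in aligner seeds on exact 15-mers (both strands) and extends
ungapped along the seed diagonal, which is adequate for the >=80% identity
regime of within-genus comparisons; any callable with the same signature
can be plugged in to reuse external alignment results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ConfigError, DataError


# ---------------------------------------------------------------------------
# annotations and coding density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeAnnotation:
    """Feature table with 1-based inclusive coordinates."""

    length: int
    features: tuple  # of (id, start, end, strand, type)

    def __post_init__(self) -> None:
        ids = set()
        for fid, start, end, strand, ftype in self.features:
            if not (1 <= start <= end <= self.length):
                raise DataError(
                    f"feature {fid} span [{start}, {end}] outside genome "
                    f"of length {self.length}"
                )
            if fid in ids:
                raise DataError(f"duplicate feature id {fid}")
            ids.add(fid)


def genome_coding_stats(
    annotation: GenomeAnnotation, feature_types: tuple[str, ...] | None = None
) -> dict:
    """Coding / non-coding nucleotide totals and their ratio.

    Coding nucleotides are the size of the union of all feature spans
    (overlaps counted once, strands merged).  ``feature_types`` restricts
    the union (e.g. ``("CDS",)``); the default counts every feature,
    including RNA genes.
    """
    spans = [
        (start, end)
        for _, start, end, _, ftype in annotation.features
        if feature_types is None or ftype in feature_types
    ]
    coding = 0
    if spans:
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                coding += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        coding += cur_e - cur_s + 1
    noncoding = annotation.length - coding
    return {
        "coding_nt": int(coding),
        "noncoding_nt": int(noncoding),
        "noncoding_to_coding_ratio": (noncoding / coding) if coding else float("inf"),
    }


def read_annotation(path: str) -> GenomeAnnotation:
    """Parse a GenBank or GFF3 annotation into the internal 1-based form."""
    text = open(path).read(200)
    if text.startswith("LOCUS") or path.endswith((".gb", ".gbk", ".genbank")):
        return _read_genbank(path)
    return _read_gff3(path)


def _read_genbank(path: str) -> GenomeAnnotation:
    record = next(SeqIO.parse(path, "genbank"))
    feats = []
    i = 0
    for f in record.features:
        if f.type in ("source",):
            continue
        fid = f.qualifiers.get("locus_tag", [f"{f.type}_{i}"])[0]
        start = int(f.location.start) + 1  # Biopython is 0-based half-open
        end = int(f.location.end)
        strand = "+" if (f.location.strand or 1) >= 0 else "-"
        feats.append((fid, start, end, strand, f.type))
        i += 1
    return GenomeAnnotation(length=len(record.seq), features=tuple(feats))


def _read_gff3(path: str) -> GenomeAnnotation:
    feats = []
    length = 0
    i = 0
    for ln, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if line.startswith("##sequence-region"):
            parts = line.split()
            length = int(parts[3])
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise DataError(f"malformed GFF3 line {ln}: expected 9 columns")
        _, _, ftype, start, end, _, strand, _, attrs = parts
        fid = None
        for kv in attrs.split(";"):
            if kv.startswith("ID="):
                fid = kv[3:]
        if fid is None:
            fid = f"{ftype}_{i}"
        feats.append((fid, int(start), int(end), strand, ftype))
        i += 1
    if length == 0:
        length = max((e for _, _, e, _, _ in feats), default=0)
    return GenomeAnnotation(length=length, features=tuple(feats))


def write_gff3(annotation: GenomeAnnotation, path: str, seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.length}\n")
        for fid, start, end, strand, ftype in annotation.features:
            fh.write(
                f"{seqid}\tthermotx\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\tID={fid}\n"
            )


# ---------------------------------------------------------------------------
# homolog presence / absence
# ---------------------------------------------------------------------------

def homolog_presence(
    gene_ids,
    hit_tables: dict[str, pd.DataFrame],
    max_evalue: float = 1e-3,
) -> pd.DataFrame:
    """Present/absent call per gene from protein and translated searches.

    ``hit_tables`` maps a channel name (e.g. ``"blastp"``, ``"tblastn"``)
    to a table with at least ``query_id`` and ``evalue`` columns.  A gene
    is present iff any channel holds a hit with E-value < ``max_evalue``;
    the supporting channels are recorded.
    """
    evidence: dict[str, list[str]] = {g: [] for g in gene_ids}
    for channel, tab in hit_tables.items():
        if not {"query_id", "evalue"}.issubset(tab.columns):
            raise DataError(f"hit table {channel!r} lacks query_id/evalue columns")
        ok = tab[pd.to_numeric(tab["evalue"], errors="coerce") < max_evalue]
        for qid in ok["query_id"].unique():
            if qid in evidence:
                evidence[qid].append(channel)
    rows = [
        {
            "gene_id": g,
            "present": bool(ch),
            "evidence": ";".join(sorted(set(ch))),
        }
        for g, ch in evidence.items()
    ]
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# fragment-based ANI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AniConfig:
    fragment_length: int = 1020
    min_identity: float = 30.0        # percent
    min_alignable_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise ConfigError("fragment length must be positive")
        if not (0 < self.min_identity <= 100):
            raise ConfigError("min identity must be in (0, 100]")
        if not (0 < self.min_alignable_fraction <= 1):
            raise ConfigError("min alignable fraction must be in (0, 1]")


@dataclass(frozen=True)
class AniResult:
    ani_percent: float
    fragments_total: int
    fragments_used: int


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, code in _ENC.items():
        out[arr == ord(base)] = code
    return out


def fragment_count(genome_length: int, fragment_length: int = 1020) -> int:
    """Number of whole fragments: floor(L / fragment length)."""
    return genome_length // fragment_length


class KmerAligner:
    """Exact-k-mer seeded, ungapped fragment aligner.

    Indexes the subject's k-mers (forward strand; the fragment is also
    tried reverse-complemented), collects seed diagonals, and scores the
    best diagonals by direct base comparison over the overlap of fragment
    and subject.  Returns ``(identity_percent, alignable_fraction)`` of
    the best placement, or ``(0, 0)`` when no seed is found.  Substitution
    -only divergence is handled exactly; indels shift diagonals and are
    out of scope for this aligner.
    """

    def __init__(self, subject: str, k: int = 15):
        if k < 4:
            raise ConfigError("k must be at least 4")
        self.k = k
        self.subject = _encode(subject)
        self.index: dict[int, list[int]] = {}
        enc = self.subject
        if len(enc) >= k:
            valid = enc < 4
            kmer = 0
            mask = (1 << (2 * k)) - 1
            run = 0
            for i, b in enumerate(enc):
                if not valid[i]:
                    run = 0
                    kmer = 0
                    continue
                kmer = ((kmer << 2) | int(b)) & mask
                run += 1
                if run >= k:
                    self.index.setdefault(kmer, []).append(i - k + 1)

    def _frag_kmers(self, frag: np.ndarray):
        k = self.k
        mask = (1 << (2 * k)) - 1
        kmer = 0
        run = 0
        for i, b in enumerate(frag):
            if b >= 4:
                run = 0
                kmer = 0
                continue
            kmer = ((kmer << 2) | int(b)) & mask
            run += 1
            if run >= k:
                yield i - k + 1, kmer

    def _align_encoded(self, frag: np.ndarray) -> tuple[float, float]:
        diagonals: dict[int, int] = {}
        stride = max(1, self.k // 3)
        hits = 0
        for pos, kmer in self._frag_kmers(frag):
            if pos % stride:
                continue
            for spos in self.index.get(kmer, ()):
                d = spos - pos
                diagonals[d] = diagonals.get(d, 0) + 1
                hits += 1
            if hits > 5000:  # repeat-heavy fragment; enough evidence
                break
        if not diagonals:
            return 0.0, 0.0
        best_ident, best_frac = 0.0, 0.0
        top = sorted(diagonals, key=diagonals.get, reverse=True)[:5]
        L = len(frag)
        for d in top:
            s0 = max(0, -d)                 # fragment start of overlap
            s1 = min(L, len(self.subject) - d)
            if s1 - s0 <= 0:
                continue
            sub = self.subject[s0 + d:s1 + d]
            fr = frag[s0:s1]
            comparable = (fr < 4) & (sub < 4)
            matches = int(((fr == sub) & comparable).sum())
            aligned = int(comparable.sum())
            if aligned == 0:
                continue
            ident = 100.0 * matches / aligned
            frac = aligned / L
            if ident * frac > best_ident * best_frac:
                best_ident, best_frac = ident, frac
        return best_ident, best_frac

    def __call__(self, fragment: str) -> tuple[float, float]:
        frag = _encode(fragment)
        fwd = self._align_encoded(frag)
        rc = _encode(str(Seq(fragment).reverse_complement()))
        rev = self._align_encoded(rc)
        return fwd if fwd[0] * fwd[1] >= rev[0] * rev[1] else rev


def ani_fragments(
    genome_a: str,
    genome_b: str,
    config: AniConfig = AniConfig(),
    aligner=None,
) -> AniResult:
    """One-way ANI of genome A against genome B.

    A is fragmented on a grid anchored at position 1; each whole fragment
    is aligned to B with the built-in k-mer aligner unless another
    callable ``fragment -> (identity_percent, alignable_fraction)`` is
    supplied.  Fragments passing both retention filters contribute their
    identity to the mean; zero retained fragments yields NaN ANI, flagged
    by ``fragments_used == 0``.
    """
    L = len(genome_a)
    if L < config.fragment_length or len(genome_b) < config.fragment_length:
        raise DataError("both genomes must be at least one fragment long")
    if aligner is None:
        aligner = KmerAligner(genome_b)
    n_frag = fragment_count(L, config.fragment_length)
    identities = []
    for i in range(n_frag):
        frag = genome_a[i * config.fragment_length:(i + 1) * config.fragment_length]
        try:
            ident, frac = aligner(frag)
        except Exception as exc:
            raise DataError(f"aligner failed on fragment {i}: {exc}") from exc
        if frac >= config.min_alignable_fraction and ident >= config.min_identity:
            identities.append(ident)
    ani = float(np.mean(identities)) if identities else float("nan")
    return AniResult(
        ani_percent=ani, fragments_total=n_frag, fragments_used=len(identities)
    )


def ani_two_way(
    genome_a: str, genome_b: str, config: AniConfig = AniConfig()
) -> dict:
    """ANI in both directions plus their mean (the two-way convention)."""
    ab = ani_fragments(genome_a, genome_b, config)
    ba = ani_fragments(genome_b, genome_a, config)
    return {
        "ani_ab": ab.ani_percent,
        "ani_ba": ba.ani_percent,
        "ani_mean": float(np.nanmean([ab.ani_percent, ba.ani_percent])),
        "fragments_ab": (ab.fragments_used, ab.fragments_total),
        "fragments_ba": (ba.fragments_used, ba.fragments_total),
    }
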