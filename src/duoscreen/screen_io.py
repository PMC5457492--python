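"""Readers, writers and core containers for pooled-screen analysis.

All genomic coordinates are 0-based, half-open internally.  BED input is
already 0-based and passes through unchanged; any 1-based format would be
converted at the boundary.  Every reader has a matching writer and the pair
round-trips bit-exactly on well-formed files.

File conventions
----------------
* Library TSV: columns ``spacer_id, spacer_seq, chrom, cut_anchor, strand,
  target_gene, target_class, tss_rank``.  Non-targeting controls leave the
  coordinate fields empty.
* Count TSV: first column ``sgrna_id``, one column per sample named
  ``<condition>.<replicate>`` (an optional sidecar TSV with columns
  ``sample, condition, replicate`` overrides the naming convention).
* TSS annotation: BED6 where ``name`` is the gene symbol and ``score`` is the
  CAGE peak height; the record position is the centre of the interval.
* Copy number: BED4 where the 4th field is an integer copy number; anything
  not covered by a segment is diploid (CN = 2).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TARGET_CLASSES = ("exon", "tss_1", "tss_2", "tss_3", "aavs1", "nontargeting")
SPACER_RE = re.compile(r"^[ACGT]{20}$")

LIBRARY_COLUMNS = [
    "spacer_id",
    "spacer_seq",
    "chrom",
    "cut_anchor",
    "strand",
    "target_gene",
    "target_class",
    "tss_rank",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ScreenIOError(ValueError):
    """Malformed input file or inconsistent screen data."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SgRNARecord:
    """One sgRNA of a pooled library.

    ``cut_anchor`` is the genomic position of the 'N' of the NGG PAM
    (0-based), the anchor used for all distance-to-TSS computations.
    Non-targeting guides carry no coordinates (``chrom == ""``).
    """

    spacer_id: str
    spacer_seq: str
    chrom: str = ""
    cut_anchor: int | None = None
    strand: str = ""
    target_gene: str = ""
    target_class: str = "nontargeting"
    tss_rank: int | None = None

    def __post_init__(self) -> None:
        if not SPACER_RE.match(self.spacer_seq):
            raise ScreenIOError(
                f"sgRNA {self.spacer_id!r}: spacer {self.spacer_seq!r} is not a "
                "20-nt ACGT sequence"
            )
        if self.target_class not in TARGET_CLASSES:
            raise ScreenIOError(
                f"sgRNA {self.spacer_id!r}: unknown target_class {self.target_class!r}"
            )
        if self.target_class == "nontargeting" and self.chrom:
            raise ScreenIOError(
                f"sgRNA {self.spacer_id!r}: nontargeting guides must not carry coordinates"
            )
        if self.target_class.startswith("tss_"):
            k = int(self.target_class.split("_")[1])
            if self.tss_rank != k:
                raise ScreenIOError(
                    f"sgRNA {self.spacer_id!r}: class {self.target_class} requires "
                    f"tss_rank {k}, got {self.tss_rank}"
                )


@dataclass(frozen=True)
class TSSRecord:
    """A CAGE-derived transcription start site (centre of the peak cluster)."""

    gene: str
    chrom: str
    position: int
    strand: str
    peak_height: float
    rank_within_gene: int = 1


@dataclass
class GenomeModel:
    """Contig sequences plus copy-number segments (diploid by default)."""

    sequences: dict[str, str]
    copy_number: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, cn in self.copy_number:
            if chrom not in self.sequences:
                raise ScreenIOError(f"CN segment on unknown contig {chrom!r}")
            if not (0 <= start < end <= len(self.sequences[chrom])):
                raise ScreenIOError(
                    f"CN segment {chrom}:{start}-{end} outside contig bounds"
                )
            if cn < 0:
                raise ScreenIOError("copy number must be >= 0")

    def cn_at(self, chrom: str, position: int) -> int:
        """Copy number at a genomic position (2 where no segment applies)."""
        for seg_chrom, start, end, cn in self.copy_number:
            if seg_chrom == chrom and start <= position < end:
                return cn
        return 2


# ---------------------------------------------------------------------------
# Count and abundance matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw sgRNA read counts, sgRNAs x samples.

    ``counts`` is an integer DataFrame indexed by sgRNA id; ``sample_meta``
    maps each sample column to its condition and replicate labels.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame  # index: sample, columns: condition, replicate

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ScreenIOError("duplicate sgRNA ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ScreenIOError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ScreenIOError("negative counts")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ScreenIOError(f"samples without metadata: {sorted(missing)}")

    @property
    def sgrna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        sel = self.sample_meta[self.sample_meta["condition"] == condition]
        return [s for s in self.sample_ids if s in set(sel.index)]


def infer_sample_meta(sample_ids: list[str]) -> pd.DataFrame:
    """Parse ``condition.replicate`` column names into a metadata table."""
    rows = []
    for s in sample_ids:
        cond, dot, rep = s.partition(".")
        rows.append({"sample": s, "condition": cond, "replicate": rep if dot else ""})
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Library table
# ---------------------------------------------------------------------------


def read_library_table(path: str | Path) -> list[SgRNARecord]:
    """Read a library TSV into validated records.

    Raises :class:`ScreenIOError` naming the offending row on duplicate
    spacer ids or malformed spacers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"spacer_id", "spacer_seq", "target_gene", "target_class"}
    if not required.issubset(df.columns):
        raise ScreenIOError(
            f"library table missing columns: {sorted(required - set(df.columns))}"
        )
    dup = df["spacer_id"][df["spacer_id"].duplicated()]
    if len(dup):
        raise ScreenIOError(f"duplicate spacer_id(s): {sorted(set(dup))}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        d = row._asdict()
        try:
            records.append(
                SgRNARecord(
                    spacer_id=d["spacer_id"],
                    spacer_seq=d["spacer_seq"],
                    chrom=d.get("chrom", ""),
                    cut_anchor=int(d["cut_anchor"]) if d.get("cut_anchor") else None,
                    strand=d.get("strand", ""),
                    target_gene=d["target_gene"],
                    target_class=d["target_class"],
                    tss_rank=int(d["tss_rank"]) if d.get("tss_rank") else None,
                )
            )
        except ScreenIOError as exc:
            raise ScreenIOError(f"row {i}: {exc}") from exc
    return records


def write_library_table(records: list[SgRNARecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "spacer_id": r.spacer_id,
                "spacer_seq": r.spacer_seq,
                "chrom": r.chrom,
                "cut_anchor": "" if r.cut_anchor is None else r.cut_anchor,
                "strand": r.strand,
                "target_gene": r.target_gene,
                "target_class": r.target_class,
                "tss_rank": "" if r.tss_rank is None else r.tss_rank,
            }
        )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, meta_path: str | Path | None = None) -> CountMatrix:
    """Read a count TSV (first column sgRNA id, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ScreenIOError("non-integer read counts")
        df = df.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ScreenIOError("negative read counts")
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample")
    else:
        meta = infer_sample_meta(list(df.columns))
    return CountMatrix(counts=df, sample_meta=meta)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("sgrna_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# TSS annotation (BED6 + score) and copy-number segments (BED4)
# ---------------------------------------------------------------------------


def rank_tss(records: list[TSSRecord]) -> list[TSSRecord]:
    """Assign per-gene ranks by descending peak height, ties to the leftmost."""
    out: list[TSSRecord] = []
    by_gene: dict[str, list[TSSRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    for gene in by_gene:
        ordered = sorted(by_gene[gene], key=lambda r: (-r.peak_height, r.position))
        out.extend(replace(r, rank_within_gene=i) for i, r in enumerate(ordered, 1))
    return out


def read_tss_bed(path: str | Path) -> list[TSSRecord]:
    """Read a BED6 TSS annotation; ranks are (re)assigned per gene."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ScreenIOError(f"{path}:{ln}: expected BED6, got {len(parts)} fields")
            chrom, start, end, gene, score, strand = parts[:6]
            start_i, end_i = int(start), int(end)
            records.append(
                TSSRecord(
                    gene=gene,
                    chrom=chrom,
                    position=(start_i + end_i) // 2,
                    strand=strand,
                    peak_height=float(score),
                )
            )
    return rank_tss(records)


def write_tss_bed(records: list[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.gene}\t"
                f"{r.peak_height:g}\t{r.strand}\n"
            )


def primary_tss(records: list[TSSRecord]) -> dict[str, TSSRecord]:
    """Map gene -> its rank-1 (highest CAGE peak) TSS."""
    return {r.gene: r for r in records if r.rank_within_gene == 1}


def tss_for_gene(records: list[TSSRecord], gene: str) -> list[TSSRecord]:
    got = sorted((r for r in records if r.gene == gene), key=lambda r: r.rank_within_gene)
    if not got:
        raise ScreenIOError(f"no TSS annotation for gene {gene!r}")
    return got


def read_cn_bed(path: str | Path) -> list[tuple[str, int, int, int]]:
    segs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ScreenIOError(f"{path}:{ln}: expected BED4 with CN field")
            segs.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
    return segs


def write_cn_bed(segments: list[tuple[str, int, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, cn in segments:
            fh.write(f"{chrom}\t{start}\t{end}\t{cn}\n")


def read_genome_fasta(path: str | Path, cn_path: str | Path | None = None) -> GenomeModel:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ScreenIOError(f"no sequences in {path}")
    cn = read_cn_bed(cn_path) if cn_path is not None else []
    return GenomeModel(sequences=seqs, copy_number=cn)


def write_genome_fasta(genome: GenomeModel, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
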