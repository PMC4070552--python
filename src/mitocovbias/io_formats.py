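"""Readers and writers for the external formats the pipeline touches.

Four formats cross the package boundary: samtools-mpileup six-column text
(one file per sequenced individual), FASTA references and alignments, BED
gene annotation, and an internal per-site TSV table. Internally every
coordinate is 0-based half-open; 1-based coordinates appear only at the
pileup boundary, which is the single conversion point.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mitocovbias")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
GENE_TYPES = ("protein_coding", "tRNA", "rRNA", "intergenic")

PathOrStream = Union[str, Path, TextIO]


def _as_text_stream(source: PathOrStream, mode: str = "r"):
    """Return (stream, needs_close) for a path or an already-open handle."""
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedReference:
    """A circular consensus sequence plus gene-type intervals.

    Features are ``(start, end, gene_type, strand)`` tuples, 0-based
    half-open, non-overlapping, covering every position exactly once after
    intergenic gap-filling.
    """

    name: str
    sequence: str
    circular: bool = True
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        for start, end, gene_type, _strand in self.features:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"feature ({start},{end}) outside reference of length "
                    f"{len(self.sequence)}"
                )
            if gene_type not in GENE_TYPES:
                raise ValueError(f"unknown gene_type {gene_type!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_type_per_site(self) -> np.ndarray:
        """Per-position gene-type labels (dtype object)."""
        out = np.array(["intergenic"] * len(self.sequence), dtype=object)
        for start, end, gene_type, _strand in self.features:
            out[start:end] = gene_type
        return out


@dataclass
class SiteProfile:
    """Per-site read-base counts for one individual.

    ``counts`` has one row per position in A, C, G, T column order;
    depth is always recomputed as the row sum, never stored separately.
    Deletion placeholders are tallied in ``n_del`` and excluded from depth.
    """

    individual_id: str
    positions: np.ndarray
    ref_bases: np.ndarray
    counts: np.ndarray
    n_del: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_bases = np.asarray(self.ref_bases, dtype="<U1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.n_del = np.asarray(self.n_del, dtype=np.int64)
        n = len(self.positions)
        if self.counts.shape != (n, 4):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, 4)")
        if len(self.ref_bases) != n or len(self.n_del) != n:
            raise ValueError("field lengths disagree")
        if n and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.counts < 0) or np.any(self.n_del < 0):
            raise ValueError("negative counts")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SiteProfile):
            return NotImplemented
        return (
            self.individual_id == other.individual_id
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref_bases, other.ref_bases)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.n_del, other.n_del)
        )


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


def _decode_pileup_bases(bases: str, ref: str, lineno: int) -> tuple[np.ndarray, int]:
    """Decode one mpileup base column into ACGT counts and a deletion tally.

    ``.``/``,`` count toward the reference base, letters toward themselves;
    ``^`` consumes the following mapping-quality character, ``$`` is a read
    end, ``+n<seq>``/``-n<seq>`` indel runs contribute no site bases, ``*``
    is a deletion placeholder, ``<``/``>`` are reference skips, and ``N``/``n``
    read bases contribute nothing.
    """
    counts = np.zeros(4, dtype=np.int64)
    n_del = 0
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise ValueError(f"line {lineno}: dangling '^' in base string")
            i += 2
        elif c == "$":
            i += 1
        elif c in ".,":
            if ref in BASE_INDEX:
                counts[BASE_INDEX[ref]] += 1
            i += 1
        elif c.upper() in BASE_INDEX:
            counts[BASE_INDEX[c.upper()]] += 1
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ValueError(f"line {lineno}: indel marker without length")
            run = int(bases[i + 1 : j])
            if j + run > n:
                raise ValueError(f"line {lineno}: indel run exceeds base string")
            i = j + run
        elif c == "*":
            n_del += 1
            i += 1
        elif c in "<>":
            i += 1
        elif c in "Nn":
            i += 1
        else:
            raise ValueError(f"line {lineno}: unexpected pileup character {c!r}")
    return counts, n_del


def parse_pileup(
    source: PathOrStream,
    individual_id: str,
    ref_length: int | None = None,
) -> SiteProfile:
    """Parse samtools-mpileup six-column text into a :class:`SiteProfile`.

    Positions are converted to 0-based. Depth is recomputed from the decoded
    base string; a mismatch with the declared depth column is logged and the
    decoded value wins. When ``ref_length`` is given, positions absent from
    the stream become zero-count records (reference base ``N``) so the
    profile covers the whole reference.
    """
    stream, close = _as_text_stream(source)
    records: dict[int, tuple[str, np.ndarray, int]] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(
                    f"line {lineno}: expected >=6 tab-separated columns, got {len(cols)}"
                )
            pos1 = int(cols[1])
            ref = cols[2].upper()
            if ref not in "ACGTN":
                raise ValueError(f"line {lineno}: reference base {cols[2]!r} not ACGTN")
            declared_depth = int(cols[3])
            counts, n_del = _decode_pileup_bases(cols[4], ref, lineno)
            decoded_depth = int(counts.sum()) + n_del
            if decoded_depth != declared_depth:
                logger.warning(
                    "line %d: declared depth %d != decoded %d; using decoded",
                    lineno,
                    declared_depth,
                    decoded_depth,
                )
            records[pos1 - 1] = (ref, counts, n_del)
    finally:
        if close:
            stream.close()

    n_sites = ref_length if ref_length is not None else (max(records) + 1 if records else 0)
    positions = np.arange(n_sites, dtype=np.int64)
    ref_bases = np.full(n_sites, "N", dtype="<U1")
    counts = np.zeros((n_sites, 4), dtype=np.int64)
    n_del = np.zeros(n_sites, dtype=np.int64)
    for pos, (ref, c, nd) in records.items():
        if pos >= n_sites:
            raise ValueError(f"position {pos + 1} beyond declared reference length {n_sites}")
        ref_bases[pos] = ref
        counts[pos] = c
        n_del[pos] = nd
    return SiteProfile(individual_id, positions, ref_bases, counts, n_del)


def write_pileup(profile: SiteProfile, dest: PathOrStream, chrom: str = "chrM") -> None:
    """Emit a profile as mpileup text, inverse-consistent with :func:`parse_pileup`.

    Reference-matching reads are written as ``.``, mismatches as upper-case
    letters and deletion placeholders as ``*``; qualities are constant ``I``.
    Zero-depth sites are emitted with empty base and quality columns and
    round-trip to zero-count records.
    """
    stream, close = _as_text_stream(dest, "w")
    try:
        for i in range(len(profile)):
            ref = profile.ref_bases[i]
            parts = []
            for b, cnt in zip(BASES, profile.counts[i]):
                if cnt == 0:
                    continue
                parts.append(("." if b == ref else b) * int(cnt))
            parts.append("*" * int(profile.n_del[i]))
            bases = "".join(parts)
            total = int(profile.counts[i].sum() + profile.n_del[i])
            stream.write(
                f"{chrom}\t{int(profile.positions[i]) + 1}\t{ref}\t{total}\t"
                f"{bases}\t{'I' * total}\n"
            )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta_records(source: PathOrStream) -> list[tuple[str, str]]:
    """Read a multi-FASTA into (name, upper-cased DNA sequence) pairs."""
    stream, close = _as_text_stream(source)
    try:
        records = [(r.id, str(r.seq).upper().replace("U", "T")) for r in SeqIO.parse(stream, "fasta")]
    finally:
        if close:
            stream.close()
    if not records:
        raise ValueError("no FASTA records found")
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate FASTA record names")
    return records


def read_reference(source: PathOrStream, circular: bool = True) -> AnnotatedReference:
    """Read a single-record FASTA as an (unannotated) reference."""
    records = read_fasta_records(source)
    if len(records) != 1:
        raise ValueError(f"expected exactly one reference record, found {len(records)}")
    name, seq = records[0]
    return AnnotatedReference(name=name, sequence=seq, circular=circular)


def write_fasta(records: Iterable[tuple[str, str]], dest: PathOrStream, width: int = 70) -> None:
    stream, close = _as_text_stream(dest, "w")
    try:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            stream,
            "fasta",
        )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# BED annotation
# ---------------------------------------------------------------------------


def read_bed_annotation(source: PathOrStream, ref_length: int) -> list:
    """Read BED gene features and gap-fill intergenic intervals.

    Gene type comes from column 7 when present, otherwise from a ``|type``
    suffix on the name column. Overlaps resolve first-listed-wins (logged);
    uncovered positions become ``intergenic``. The returned intervals are
    non-overlapping, sorted and cover ``[0, ref_length)`` exactly.
    """
    stream, close = _as_text_stream(source)
    raw = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"line {lineno}: BED needs >=4 columns")
            start, end = int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            if end > ref_length:
                raise ValueError(f"line {lineno}: end {end} > reference length {ref_length}")
            name = cols[3]
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            if len(cols) > 6 and cols[6] in GENE_TYPES:
                gene_type = cols[6]
            elif "|" in name and name.rsplit("|", 1)[1] in GENE_TYPES:
                gene_type = name.rsplit("|", 1)[1]
            else:
                raise ValueError(
                    f"line {lineno}: no gene_type in column 7 or name tag for {name!r}"
                )
            raw.append((start, end, gene_type, strand))
    finally:
        if close:
            stream.close()

    # first-listed wins on overlap
    claimed = np.zeros(ref_length, dtype=bool)
    type_per_site = np.array(["intergenic"] * ref_length, dtype=object)
    strand_per_site = np.array(["+"] * ref_length, dtype=object)
    for start, end, gene_type, strand in raw:
        free = ~claimed[start:end]
        if not free.all():
            logger.warning(
                "feature (%d,%d,%s) overlaps an earlier feature; first-listed wins",
                start,
                end,
                gene_type,
            )
        idx = np.arange(start, end)[free]
        type_per_site[idx] = gene_type
        strand_per_site[idx] = strand
        claimed[start:end] = True

    # collapse runs back into intervals
    features = []
    i = 0
    while i < ref_length:
        j = i
        while (
            j + 1 < ref_length
            and type_per_site[j + 1] == type_per_site[i]
            and strand_per_site[j + 1] == strand_per_site[i]
        ):
            j += 1
        features.append((i, j + 1, str(type_per_site[i]), str(strand_per_site[i])))
        i = j + 1
    return features


# ---------------------------------------------------------------------------
# Site-table TSV
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = ["individual", "pos", "ref", "n_A", "n_C", "n_G", "n_T", "n_del", "depth"]


def write_site_table(profiles: Sequence[SiteProfile], dest: PathOrStream) -> None:
    """Write profiles as a single TSV with one row per individual x position."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "individual": p.individual_id,
                    "pos": p.positions,
                    "ref": p.ref_bases,
                    "n_A": p.counts[:, 0],
                    "n_C": p.counts[:, 1],
                    "n_G": p.counts[:, 2],
                    "n_T": p.counts[:, 3],
                    "n_del": p.n_del,
                    "depth": p.depth,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SITE_TABLE_COLUMNS)
    stream, close = _as_text_stream(dest, "w")
    try:
        table.to_csv(stream, sep="\t", index=False)
    finally:
        if close:
            stream.close()


def read_site_table(source: PathOrStream) -> list[SiteProfile]:
    """Read the internal TSV back into per-individual profiles."""
    stream, close = _as_text_stream(source)
    try:
        table = pd.read_csv(stream, sep="\t", dtype={"ref": str, "individual": str})
    finally:
        if close:
            stream.close()
    for col in SITE_TABLE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"site table missing column {col!r}")
    profiles = []
    for ind, group in table.groupby("individual", sort=False):
        group = group.sort_values("pos")
        profiles.append(
            SiteProfile(
                individual_id=str(ind),
                positions=group["pos"].to_numpy(),
                ref_bases=group["ref"].to_numpy(dtype="<U1"),
                counts=group[["n_A", "n_C", "n_G", "n_T"]].to_numpy(),
                n_del=group["n_del"].to_numpy(),
            )
        )
    return profiles
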