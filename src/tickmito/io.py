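"""Annotated mitogenome records and flat-file I/O.

Internal coordinates are 0-based half-open on the heavy strand (the strand
the flat file prints). GenBank 1-based inclusive coordinates are converted
at the I/O boundary. Features spanning the origin of a circular molecule
carry ``wraps_origin=True`` with ``start`` near the end of the sequence and
``end`` at the tail of the wrapped span.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genes import CANONICAL_GENES, PCGS, UnknownGeneError, category_of, normalize_gene_name

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    pass


class GenBankParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region on a mitogenome.

    ``start``/``end`` are 0-based half-open heavy-strand coordinates;
    ``strand`` is +1 (heavy) or -1 (light); ``category`` is one of
    PCG / tRNA / rRNA / CR / other.
    """

    name: str
    start: int
    end: int
    strand: int
    category: str = ""
    wraps_origin: bool = False

    def __post_init__(self):
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")
        if self.start < 0 or self.end < 0:
            raise CoordinateError(f"negative coordinate on {self.name}")
        if not self.wraps_origin and self.end <= self.start:
            raise CoordinateError(
                f"end must exceed start for non-wrapping feature {self.name}"
            )
        if not self.category:
            try:
                object.__setattr__(self, "category", category_of(self.name))
            except UnknownGeneError:
                object.__setattr__(self, "category", "other")

    def length(self, seq_len: int) -> int:
        if self.wraps_origin:
            return (seq_len - self.start) + self.end
        return self.end - self.start


@dataclass
class MitogenomeRecord:
    """A (usually circular) annotated mitochondrial genome."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    organism: str = ""
    circular: bool = True

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self._validate()

    def _validate(self) -> None:
        n = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if f.start >= n or f.end > n:
                raise CoordinateError(
                    f"feature {f.name} [{f.start},{f.end}) outside sequence of length {n}"
                )
            if f.wraps_origin and not self.circular:
                raise CoordinateError(f"wrapping feature {f.name} on linear record")
            if f.name in CANONICAL_GENES:
                if f.name in seen:
                    raise ValueError(f"duplicate canonical feature {f.name} in {self.id}")
                seen.add(f.name)

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name} in record {self.id}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)


def extract_gene_sequence(record: MitogenomeRecord, name: str) -> str:
    """Coding-orientation sequence of a named feature.

    Light-strand features are reverse-complemented; origin-spanning
    features concatenate the tail and head slices before orientation.
    """
    feat = record.feature_by_name(name)
    return extract_feature_sequence(record, feat)


def extract_feature_sequence(record: MitogenomeRecord, feat: GeneFeature) -> str:
    if feat.wraps_origin:
        raw = record.sequence[feat.start:] + record.sequence[: feat.end]
    else:
        raw = record.sequence[feat.start : feat.end]
    return reverse_complement(raw) if feat.strand == -1 else raw


START_CODONS = frozenset({"ATA", "ATT", "ATC", "ATG"})
STOP_CODONS = frozenset({"TAA", "TAG"})


@dataclass(frozen=True)
class CodonReport:
    gene: str
    start_codon: str
    stop_codon: str
    start_ok: bool
    stop_ok: bool


def validate_pcg_codons(record: MitogenomeRecord) -> list[CodonReport]:
    """QC report of start/stop codons for every annotated PCG.

    Accepted starts: ATA/ATT/ATC/ATG. Accepted stops: TAA/TAG, or a lone
    trailing T (truncated stop completed by polyadenylation). Anything
    else is flagged, never fatal.
    """
    out = []
    for feat in record.features:
        if feat.category != "PCG":
            continue
        seq = extract_feature_sequence(record, feat)
        start = seq[:3]
        rem = len(seq) % 3
        if rem == 0:
            stop = seq[-3:]
            stop_ok = stop in STOP_CODONS
        elif rem == 1:
            stop = seq[-1]
            stop_ok = stop == "T"
        else:
            stop = seq[-2:]
            stop_ok = False
        out.append(
            CodonReport(feat.name, start, stop, start in START_CODONS, stop_ok)
        )
    return out


def rotate_record(record: MitogenomeRecord, offset: int) -> MitogenomeRecord:
    """Rotate a circular record so old position ``offset`` becomes position 0."""
    n = len(record)
    offset %= n
    seq = record.sequence[offset:] + record.sequence[:offset]
    feats = []
    for f in record.features:
        length = f.length(n)
        start = (f.start - offset) % n
        end = start + length
        if end <= n:
            feats.append(replace(f, start=start, end=end, wraps_origin=False))
        else:
            feats.append(replace(f, start=start, end=end - n, wraps_origin=True))
    return MitogenomeRecord(
        record.id, seq, feats, organism=record.organism, circular=record.circular
    )


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "gene", "D-loop", "misc_feature"}


def _feature_label(bio_feat) -> str | None:
    q = bio_feat.qualifiers
    for key in ("gene", "product", "note", "standard_name"):
        if key in q and q[key]:
            return str(q[key][0])
    if bio_feat.type == "D-loop":
        return "control region"
    return None


def read_genbank(path: str | Path) -> list[MitogenomeRecord]:
    """Read one or more annotated mitogenomes from a GenBank flat file."""
    records = []
    try:
        bio_records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc
    if not bio_records:
        raise GenBankParseError(f"{path}: no GenBank records found")
    for rec in bio_records:
        records.append(_convert_bio_record(rec))
    return records


def _convert_bio_record(rec: SeqRecord) -> MitogenomeRecord:
    seq = str(rec.seq).upper()
    n = len(seq)
    circular = rec.annotations.get("topology", "circular") == "circular"
    by_name: dict[tuple, GeneFeature] = {}
    order: list[tuple] = []
    for bf in rec.features:
        if bf.type not in _FEATURE_TYPES or bf.type == "source":
            continue
        label = _feature_label(bf)
        if label is None:
            continue
        try:
            name = normalize_gene_name(label)
        except UnknownGeneError:
            name = label
        strand = -1 if bf.location.strand == -1 else 1
        parts = sorted(bf.location.parts, key=lambda p: int(p.start))
        if len(parts) > 1 and int(parts[-1].end) == n and int(parts[0].start) == 0:
            start, end, wraps = int(parts[-1].start), int(parts[0].end), True
        else:
            start, end, wraps = int(bf.location.start), int(bf.location.end), False
        if end > n or start >= n:
            raise CoordinateError(
                f"{rec.id}: feature {name} [{start},{end}) outside sequence ({n} bp)"
            )
        feat = GeneFeature(name, start, end, strand, wraps_origin=wraps)
        key = (name, start, end, strand)
        if key not in by_name:
            # CDS/tRNA/rRNA outrank the paired bare 'gene' feature
            by_name[key] = feat
            order.append(key)
    feats = [by_name[k] for k in order]
    feats.sort(key=lambda f: f.start)
    organism = rec.annotations.get("organism", "")
    return MitogenomeRecord(rec.id or rec.name, seq, feats, organism=organism,
                            circular=circular)


_CATEGORY_TO_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                     "CR": "D-loop", "other": "misc_feature"}


def write_genbank(records: list[MitogenomeRecord], path: str | Path) -> None:
    bio_records = []
    for rec in records:
        n = len(rec)
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, name=rec.id.split(".")[0][:16],
                       description=rec.organism or rec.id)
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if rec.circular else "linear"
        sr.annotations["organism"] = rec.organism
        for f in rec.features:
            if f.wraps_origin:
                loc = CompoundLocation([
                    SimpleLocation(f.start, n, f.strand),
                    SimpleLocation(0, f.end, f.strand),
                ])
            else:
                loc = SimpleLocation(f.start, f.end, f.strand)
            ftype = _CATEGORY_TO_TYPE.get(f.category, "misc_feature")
            sr.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.name]}))
        bio_records.append(sr)
    with open(path, "w") as fh:
        SeqIO.write(bio_records, fh, "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature TSV (id, name, start, end, strand) + companion FASTA
# ---------------------------------------------------------------------------

def read_feature_table(tsv_path: str | Path, fasta_path: str | Path,
                       circular: bool = True) -> list[MitogenomeRecord]:
    """Read records from a feature TSV plus a FASTA of the full sequences.

    Columns: record id, gene name (normalized on read), start, end (0-based
    half-open), strand (+1/-1). A row with start > end denotes an
    origin-spanning feature on a circular record.
    """
    seqs = read_fasta(fasta_path)
    feats: dict[str, list[GeneFeature]] = {rid: [] for rid in seqs}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("record_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{tsv_path}:{lineno}: expected 5 columns")
            rid, raw_name, start, end, strand = parts
            if rid not in feats:
                raise ValueError(f"{tsv_path}:{lineno}: unknown record id {rid}")
            try:
                name = normalize_gene_name(raw_name)
            except UnknownGeneError:
                name = raw_name
            start_i, end_i = int(start), int(end)
            wraps = start_i > end_i
            feats[rid].append(
                GeneFeature(name, start_i, end_i, int(strand), wraps_origin=wraps)
            )
    out = []
    for rid, seq in seqs.items():
        flist = sorted(feats[rid], key=lambda f: f.start)
        out.append(MitogenomeRecord(rid, seq, flist, circular=circular))
    return out


def write_feature_table(records: list[MitogenomeRecord], tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("record_id\tname\tstart\tend\tstrand\n")
        for rec in records:
            for f in rec.features:
                fh.write(f"{rec.id}\t{f.name}\t{f.start}\t{f.end}\t{f.strand}\n")


def genome_tiling_check(record: MitogenomeRecord) -> bool:
    """True iff oriented feature slices plus intergenic gaps tile the genome.

    Valid only for records with non-overlapping features.
    """
    n = len(record)
    extracted = sum(len(extract_feature_sequence(record, f)) for f in record.features)
    annotated = sum(f.length(n) for f in record.features)
    return extracted == annotated and extracted <= n
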