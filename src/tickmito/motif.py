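"""IUPAC degenerate consensus scanning on both strands.

The default pattern is the 17 bp degenerate consensus found at fixed
positions of tick mitogenomes (near ND1 and the 3' end of rrnL/trnL1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io import GeneFeature, MitogenomeRecord, reverse_complement

#: 17 bp tick control-motif consensus
TICK_BOX = "TTGYRTCHWWWTWWGDA"

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    pattern: str
    allowed: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.pattern)


def parse_iupac(pattern: str) -> MotifPattern:
    """Compile an IUPAC degenerate string into per-position base sets."""
    if not pattern:
        raise PatternError("empty pattern")
    allowed = []
    for pos, ch in enumerate(pattern.upper(), start=1):
        try:
            allowed.append(IUPAC_SETS[ch])
        except KeyError:
            raise PatternError(
                f"invalid IUPAC code {ch!r} at position {pos}"
            ) from None
    return MotifPattern(pattern.upper(), tuple(allowed))


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    start: int          # heavy-strand, 0-based half-open; may wrap on circular
    end: int
    strand: int
    matched: str        # match in pattern orientation
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 0-based positions within the pattern
    context: str = ""


def _mismatches(window: str, pattern: MotifPattern) -> tuple[int, tuple[int, ...]]:
    bad = tuple(i for i, (b, allowed) in enumerate(zip(window, pattern.allowed))
                if b not in allowed)
    return len(bad), bad


def scan(record: MitogenomeRecord | str, pattern: MotifPattern,
         max_mismatch: int = 1) -> list[MotifHit]:
    """All windows on either strand within the mismatch tolerance.

    Light-strand hits carry strand -1 with heavy-strand coordinates and the
    matched sequence in pattern (5'->3') orientation. Circular records are
    scanned across the origin; such hits have ``start >= end``.
    """
    if isinstance(record, MitogenomeRecord):
        seq, rid, circular = record.sequence, record.id, record.circular
    else:
        seq, rid, circular = record.upper(), "", False
    m = len(pattern)
    n = len(seq)
    if n < m:
        return []
    search = seq + seq[: m - 1] if circular else seq
    rc_pattern = parse_iupac(reverse_complement(pattern.pattern))
    hits = []
    for i in range(len(search) - m + 1):
        window = search[i : i + m]
        start, end = i, (i + m) if i + m <= n else (i + m - n)
        count, pos = _mismatches(window, pattern)
        if count <= max_mismatch:
            hits.append(MotifHit(rid, start, end, 1, window, count, pos))
        count, pos = _mismatches(window, rc_pattern)
        if count <= max_mismatch:
            # report in pattern orientation; mismatch positions flip with it
            flipped = tuple(sorted(m - 1 - p for p in pos))
            hits.append(MotifHit(rid, start, end, -1,
                                 reverse_complement(window), count, flipped))
    hits.sort(key=lambda h: (h.start, -h.strand))
    return hits


def _hit_positions(hit: MotifHit, n: int) -> list[int]:
    if hit.start < hit.end:
        return list(range(hit.start, hit.end))
    return list(range(hit.start, n)) + list(range(0, hit.end))


def _feature_positions(feat: GeneFeature, n: int) -> set[int]:
    if feat.wraps_origin:
        return set(range(feat.start, n)) | set(range(0, feat.end))
    return set(range(feat.start, feat.end))


def annotate_hits(hits: list[MotifHit], record: MitogenomeRecord,
                  downstream_window: int = 100) -> list[MotifHit]:
    """Label each hit: within <gene> / downstream of <gene> / intergenic.

    A hit fully inside a feature is "within" it. Otherwise, if it begins
    within ``downstream_window`` bases 3' of a gene (strand-aware: past
    ``end`` for heavy-strand genes, before ``start`` for light-strand
    genes), it is "downstream of" that gene.
    """
    n = len(record)
    feats = [f for f in record.features if f.category != "other"]
    out = []
    for hit in hits:
        positions = _hit_positions(hit, n)
        label = "intergenic"
        for f in feats:
            if set(positions) <= _feature_positions(f, n):
                label = f"within {f.name}"
                break
        if label == "intergenic":
            best: tuple[int, str] | None = None
            for f in feats:
                d = _downstream_distance(hit, f, n)
                if d is not None and d < downstream_window:
                    if best is None or d < best[0]:
                        best = (d, f.name)
            if best is not None:
                label = f"downstream of {best[1]}"
        out.append(replace(hit, context=label))
    return out


def _downstream_distance(hit: MotifHit, feat: GeneFeature, n: int) -> int | None:
    """Circular distance from the feature's 3' end to the hit's near edge."""
    if feat.strand == 1:
        three_prime = feat.end % n          # first base past the gene
        edge = hit.start
        d = (edge - three_prime) % n
    else:
        three_prime = (feat.start - 1) % n  # first base before the gene
        edge = (hit.end - 1) % n
        d = (three_prime - edge) % n
    return d if d < n // 2 else None
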