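"""Perfect microsatellite (SSR) mining.

Reports every maximal, primitive, perfect tandem repeat of a 1-6 bp motif
whose whole-unit repeat count reaches the per-motif-length minimum
(default 10/5/4/3/3/3 for mono- through hexa-nucleotides). Motif classes
are standardized by cyclic rotation and reverse complement so e.g. poly-T
tracts count toward the ``A`` class.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

_TYPE_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRConfig:
    min_repeats: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_motif_len: int = 6
    group_revcomp: bool = True

    def __post_init__(self):
        for m in range(1, self.max_motif_len + 1):
            if self.min_repeats.get(m, 0) < 2:
                raise ValueError(f"min repeat for motif length {m} must be >= 2")


@dataclass(frozen=True)
class SSRLocus:
    record_id: str
    start: int
    end: int
    motif: str
    std_motif: str
    repeats: int

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def type(self) -> str:
        return _TYPE_NAMES[self.motif_len]


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def standardize_motif(motif: str, group_revcomp: bool = True) -> str:
    """Standard class of a primitive motif.

    The lexicographically smallest string among all cyclic rotations of the
    motif and (by default) of its reverse complement. Idempotent and
    invariant under rotation/reverse-complement of the input.
    """
    m = motif.upper()
    if not m or any(b not in "ACGT" for b in m):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    candidates = {m[i:] + m[:i] for i in range(len(m))}
    if group_revcomp:
        rc = m.translate(_COMPLEMENT)[::-1]
        candidates |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(candidates)


def find_perfect_ssrs(seq: str, config: SSRConfig | None = None,
                      record_id: str = "") -> list[SSRLocus]:
    """All maximal primitive perfect tandem repeats meeting their threshold.

    A tract is maximal when neither flanking base extends the periodicity;
    repeats count whole units only (a partial trailing unit lengthens the
    tract but not the count). ``N`` and other non-ACGT characters never
    participate in a repeat. Loci are returned sorted by start position.
    """
    cfg = config or SSRConfig()
    s = seq.upper()
    n = len(s)
    valid = [b in "ACGT" for b in s]
    loci: list[SSRLocus] = []
    for m in range(1, cfg.max_motif_len + 1):
        threshold = cfg.min_repeats[m]
        i = 0
        while i + m * 2 <= n:
            # left-maximal start of a period-m run: s[i-1] must not extend it
            if i > 0 and valid[i - 1] and s[i - 1] == s[i + m - 1] and _run_at(s, valid, i - 1, m) > m:
                i += 1
                continue
            span = _run_at(s, valid, i, m)
            if span >= 2 * m:
                repeats = span // m
                motif = s[i : i + m]
                if repeats >= threshold and _is_primitive(motif) and all(valid[i : i + m]):
                    loci.append(SSRLocus(
                        record_id, i, i + span, motif,
                        standardize_motif(motif, cfg.group_revcomp), repeats,
                    ))
                i += span - m + 1
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, l.motif_len))
    return loci


def _run_at(s: str, valid: list[bool], i: int, m: int) -> int:
    """Length of the maximal period-m run starting at i (in bases)."""
    n = len(s)
    j = i + m
    while j < n and valid[j] and valid[j - m] and s[j] == s[j - m]:
        j += 1
    return j - i


def relative_abundance(n_loci: int, genome_size: int) -> float:
    """Microsatellite loci per kilobase: n_loci / genome_size * 1000."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return n_loci / genome_size * 1000.0


@dataclass
class SSRSummary:
    total: int
    type_counts: dict[str, int]
    std_motif_counts: dict[str, int]
    relative_abundance: float | None = None

    @property
    def type_percentages(self) -> dict[str, float]:
        """Per-type share of all loci, in percent (NaN map when empty)."""
        if self.total == 0:
            return {t: math.nan for t in self.type_counts}
        return {t: 100.0 * c / self.total for t, c in self.type_counts.items()}

    @classmethod
    def from_counts(cls, type_counts: dict[str, int],
                    total: int | None = None) -> "SSRSummary":
        """Build a summary from a pre-tabulated per-type count table."""
        tot = sum(type_counts.values()) if total is None else total
        return cls(total=tot, type_counts=dict(type_counts), std_motif_counts={})


def summarize(loci: list[SSRLocus], genome_size: int | None = None) -> SSRSummary:
    """Per-type and per-standard-motif counts for one or more locus lists."""
    type_counts = Counter(l.type for l in loci)
    motif_counts = Counter(l.std_motif for l in loci)
    ra = relative_abundance(len(loci), genome_size) if genome_size else None
    return SSRSummary(len(loci), dict(type_counts), dict(motif_counts), ra)


def brute_force_ssrs(seq: str, config: SSRConfig | None = None,
                     record_id: str = "") -> list[SSRLocus]:
    """Independent exhaustive oracle: test every (start, motif length).

    Quadratic-ish and deliberately naive; used to validate the scanner.
    """
    cfg = config or SSRConfig()
    s = seq.upper()
    n = len(s)
    found = set()
    loci = []
    for i in range(n):
        for m in range(1, cfg.max_motif_len + 1):
            if i + m > n:
                break
            motif = s[i : i + m]
            if any(b not in "ACGT" for b in motif) or not _is_primitive(motif):
                continue
            # extend perfect periodicity base by base
            j = i + m
            while j < n and s[j] in "ACGT" and s[j] == s[j - m]:
                j += 1
            repeats = (j - i) // m
            if repeats < cfg.min_repeats[m]:
                continue
            # maximality on the left
            if i > 0 and s[i - 1] in "ACGT" and s[i - 1] == s[i + m - 1]:
                continue
            key = (i, j, m)
            if key in found:
                continue
            found.add(key)
            loci.append(SSRLocus(record_id, i, j, motif,
                                 standardize_motif(motif, cfg.group_revcomp), repeats))
    loci.sort(key=lambda l: (l.start, l.motif_len))
    return loci
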