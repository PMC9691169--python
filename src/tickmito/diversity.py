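"""Variable sites, nucleotide diversity (pi), sliding windows, supermatrix.

Pairwise deletion throughout: a site contributes to a pair only when both
sequences carry an unambiguous base there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

_BASES = frozenset("ACGT")


def _check_alignment(alignment: dict[str, str], min_seqs: int = 2) -> None:
    if len(alignment) < min_seqs:
        raise ValueError(f"alignment needs at least {min_seqs} sequences")
    if len({len(s) for s in alignment.values()}) != 1:
        raise ValueError("ragged alignment")


@dataclass(frozen=True)
class DiversityResult:
    alignment_id: str
    sites: int              # columns with >= 2 usable characters
    variable_sites: int
    variable_pct: float
    pi: float


def variable_sites(alignment: dict[str, str]) -> tuple[int, float]:
    """(count, percentage) of variable columns.

    A column is variable when >= 2 distinct unambiguous bases occur among
    its non-gap characters; the percentage denominator is the number of
    columns with >= 2 usable characters.
    """
    _check_alignment(alignment)
    seqs = [s.upper() for s in alignment.values()]
    usable_cols = variable = 0
    for col in zip(*seqs):
        bases = {c for c in col if c in _BASES}
        n_usable = sum(1 for c in col if c in _BASES)
        if n_usable >= 2:
            usable_cols += 1
            if len(bases) >= 2:
                variable += 1
    pct = 100.0 * variable / usable_cols if usable_cols else math.nan
    return variable, pct


def nucleotide_diversity(alignment: dict[str, str]) -> float:
    """pi: mean pairwise p-distance with pairwise deletion.

    Pairs with zero usable sites are skipped.
    """
    _check_alignment(alignment)
    seqs = [s.upper() for s in alignment.values()]
    pair_values = []
    for s1, s2 in combinations(seqs, 2):
        usable = diffs = 0
        for a, b in zip(s1, s2):
            if a in _BASES and b in _BASES:
                usable += 1
                if a != b:
                    diffs += 1
        if usable:
            pair_values.append(diffs / usable)
    if not pair_values:
        return math.nan
    return sum(pair_values) / len(pair_values)


def diversity_result(alignment: dict[str, str], alignment_id: str = "") -> DiversityResult:
    var, pct = variable_sites(alignment)
    seqs = [s.upper() for s in alignment.values()]
    usable_cols = sum(
        1 for col in zip(*seqs) if sum(1 for c in col if c in _BASES) >= 2
    )
    return DiversityResult(alignment_id, usable_cols, var, pct,
                           nucleotide_diversity(alignment))


@dataclass(frozen=True)
class DiversityTrack:
    window: int
    step: int
    points: tuple[tuple[int, float, float], ...]  # (start, midpoint, pi)


def sliding_window_pi(alignment: dict[str, str], window: int = 200,
                      step: int = 20) -> DiversityTrack:
    """Per-window pi along alignment columns; trailing partial window dropped."""
    _check_alignment(alignment)
    length = len(next(iter(alignment.values())))
    if window > length:
        raise ValueError("window exceeds alignment length")
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    points = []
    for start in range(0, length - window + 1, step):
        sub = {k: v[start : start + window] for k, v in alignment.items()}
        points.append((start, start + window / 2.0, nucleotide_diversity(sub)))
    return DiversityTrack(window, step, tuple(points))


@dataclass
class Supermatrix:
    taxa: list[str]
    alignment: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene, 1-based start, end inclusive)

    @property
    def length(self) -> int:
        return len(next(iter(self.alignment.values())))

    def write_raxml_partitions(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene, start, end in self.partitions:
                fh.write(f"DNA, {gene} = {start}-{end}\n")

    def write_nexus_sets(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#nexus\nbegin sets;\n")
            for gene, start, end in self.partitions:
                fh.write(f"    charset {gene} = {start}-{end};\n")
            fh.write("end;\n")


def concatenate_alignments(per_gene: dict[str, dict[str, str]]) -> Supermatrix:
    """Concatenate per-gene alignments into one partitioned supermatrix.

    Taxa are matched by id across genes; a taxon missing from a gene gets
    an all-gap filler for that partition.
    """
    taxa: list[str] = []
    for aln in per_gene.values():
        _check_alignment(aln, min_seqs=1)
        for taxon in aln:
            if taxon not in taxa:
                taxa.append(taxon)
    rows = {t: [] for t in taxa}
    partitions = []
    offset = 0
    for gene, aln in per_gene.items():
        glen = len(next(iter(aln.values())))
        for t in taxa:
            rows[t].append(aln.get(t, "-" * glen))
        partitions.append((gene, offset + 1, offset + glen))
        offset += glen
    return Supermatrix(taxa, {t: "".join(parts) for t, parts in rows.items()},
                       partitions)
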