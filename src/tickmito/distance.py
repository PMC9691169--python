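"""Kimura 2-parameter distances and threshold species delimitation.

Distances use pairwise deletion: alignment columns where either sequence
has a gap or an ambiguous base are excluded from that pair's counts.
Transitions are A<->G and C<->T; everything else is a transversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: recommended tick species-boundary thresholds per marker
DEFAULT_THRESHOLDS: dict[str, float] = {"rrnL": 0.0525, "COX1": 0.0613}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PairCounts:
    """Usable-site and substitution counts for one aligned pair."""

    usable: int
    transitions: int
    transversions: int


def count_pair(seq1: str, seq2: str) -> PairCounts:
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    usable = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in _BASES or b not in _BASES:
            continue
        usable += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    return PairCounts(usable, ts, tv)


def k2p_from_counts(counts: PairCounts) -> float:
    """d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)); NaN outside the valid domain."""
    if counts.usable == 0:
        raise ValueError("no usable sites")
    p = counts.transitions / counts.usable
    q = counts.transversions / counts.usable
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(seq1: str, seq2: str) -> float:
    """K2P distance between two aligned sequences (pairwise deletion)."""
    return k2p_from_counts(count_pair(seq1, seq2))


@dataclass
class DistanceMatrix:
    marker: str
    ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal; NaN = undefined

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match id count")

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id", float_format="%.4f")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.4f}" for v in self.values[i])
                fh.write(f"{name:<12s}{row}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, marker: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: matrix row/column ids differ")
        return cls(marker or Path(path).stem, list(df.index), df.to_numpy())


def pairwise_matrix(alignment: dict[str, str], marker: str = "") -> DistanceMatrix:
    """Symmetric K2P matrix over all pairs of an aligned sequence set."""
    ids = list(alignment)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    k = len(ids)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = k2p_distance(alignment[ids[i]], alignment[ids[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(marker, ids, mat)


@dataclass(frozen=True)
class SpeciesGroupingConfig:
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    rule: str = "all-markers-below"

    def __post_init__(self):
        if self.rule not in ("all-markers-below", "any-marker-below"):
            raise ValueError(f"unknown grouping rule {self.rule!r}")
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValueError("thresholds must be positive")


def delimit_species_groups(matrices: dict[str, DistanceMatrix],
                           config: SpeciesGroupingConfig | None = None,
                           ) -> dict[int, list[str]]:
    """Single-linkage partition of individuals into numbered species groups.

    Two individuals are linked when their distance is below the marker
    threshold for every marker (default rule) or for at least one marker.
    Undefined (NaN) distances count as above-threshold. Groups are numbered
    1.. in order of first appearance of their earliest member.
    """
    cfg = config or SpeciesGroupingConfig()
    if not matrices:
        raise ValueError("no distance matrices supplied")
    id_sets = [tuple(m.ids) for m in matrices.values()]
    ids = list(id_sets[0])
    if any(set(s) != set(ids) for s in id_sets):
        raise ValueError("matrices do not share one individual set")
    for marker in matrices:
        if marker not in cfg.thresholds:
            raise ValueError(f"no threshold configured for marker {marker!r}")

    def linked(i: str, j: str) -> bool:
        verdicts = []
        for marker, mat in matrices.items():
            d = mat.get(i, j)
            verdicts.append((not math.isnan(d)) and d < cfg.thresholds[marker])
        return all(verdicts) if cfg.rule == "all-markers-below" else any(verdicts)

    assigned: dict[str, int] = {}
    groups: dict[int, list[str]] = {}
    next_group = 1
    for seed in ids:
        if seed in assigned:
            continue
        stack = [seed]
        members = []
        while stack:
            cur = stack.pop()
            if cur in assigned:
                continue
            assigned[cur] = next_group
            members.append(cur)
            stack.extend(o for o in ids
                         if o not in assigned and o != cur and linked(cur, o))
        groups[next_group] = sorted(members, key=ids.index)
        next_group += 1
    return groups
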