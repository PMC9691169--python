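"""Nucleotide composition, A+T content, and strand-skew statistics.

Skews are the strand-asymmetry ratios AT-skew = (A - T)/(A + T) and
GC-skew = (G - C)/(G + C), computed on unambiguous base counts only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io import MitogenomeRecord, extract_gene_sequence
from .genes import PCGS, RRNAS

#: regions reported per genome in the per-gene table
TABLE_REGIONS: tuple[str, ...] = PCGS + RRNAS + ("CR",)


@dataclass(frozen=True)
class CompositionStats:
    a: int
    c: int
    g: int
    t: int
    other: int

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.t + self.other

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.length

    @property
    def pct_a(self) -> float:
        return self._pct(self.a)

    @property
    def pct_c(self) -> float:
        return self._pct(self.c)

    @property
    def pct_g(self) -> float:
        return self._pct(self.g)

    @property
    def pct_t(self) -> float:
        return self._pct(self.t)

    @property
    def pct_at(self) -> float:
        return self._pct(self.a + self.t)

    @property
    def pct_gc(self) -> float:
        return self._pct(self.g + self.c)

    @property
    def at_skew(self) -> float:
        """(A - T)/(A + T); NaN when A + T == 0."""
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else math.nan

    @property
    def gc_skew(self) -> float:
        """(G - C)/(G + C); NaN when G + C == 0."""
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else math.nan


def base_composition(seq: str) -> CompositionStats:
    """Count bases case-insensitively; non-ACGT characters land in ``other``."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return CompositionStats(a, c, g, t, len(s) - a - c - g - t)


def skew(seq: str) -> tuple[float, float]:
    """(at_skew, gc_skew) of a sequence; NaN components when undefined."""
    st = base_composition(seq)
    return st.at_skew, st.gc_skew


def _stats_row(record_id: str, region: str, seq: str | None) -> dict:
    if not seq:
        return {"record_id": record_id, "region": region, "length": math.nan,
                "A": math.nan, "C": math.nan, "G": math.nan, "T": math.nan,
                "other": math.nan, "pct_AT": math.nan, "pct_GC": math.nan,
                "at_skew": math.nan, "gc_skew": math.nan}
    st = base_composition(seq)
    return {"record_id": record_id, "region": region, "length": st.length,
            "A": st.a, "C": st.c, "G": st.g, "T": st.t, "other": st.other,
            "pct_AT": st.pct_at, "pct_GC": st.pct_gc,
            "at_skew": st.at_skew, "gc_skew": st.gc_skew}


def genome_gene_table(records: list[MitogenomeRecord],
                      gene_strand: str = "coding") -> pd.DataFrame:
    """Composition table: one row per record x (genome, 13 PCGs, rRNAs, CR).

    ``gene_strand`` selects the orientation for per-gene rows: ``coding``
    (light-strand genes reverse-complemented, the default) or ``heavy``
    (raw heavy-strand slice).
    """
    if gene_strand not in ("coding", "heavy"):
        raise ValueError("gene_strand must be 'coding' or 'heavy'")
    rows = []
    for rec in records:
        rows.append(_stats_row(rec.id, "genome", rec.sequence))
        for region in TABLE_REGIONS:
            if rec.has_feature(region):
                seq = extract_gene_sequence(rec, region)
                if gene_strand == "heavy":
                    feat = rec.feature_by_name(region)
                    if feat.strand == -1:
                        from .io import reverse_complement
                        seq = reverse_complement(seq)
                rows.append(_stats_row(rec.id, region, seq))
            else:
                rows.append(_stats_row(rec.id, region, None))
    return pd.DataFrame(rows)


def genus_aggregates(table: pd.DataFrame, genus_map: dict[str, str]) -> pd.DataFrame:
    """Per-genus mean/min/max of pct_AT, at_skew, gc_skew on whole-genome rows."""
    g = table[table["region"] == "genome"].copy()
    g["genus"] = g["record_id"].map(genus_map)
    g = g.dropna(subset=["genus"])
    agg = g.groupby("genus")[["pct_AT", "at_skew", "gc_skew"]].agg(
        ["mean", "min", "max"]
    )
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    return agg.reset_index()
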