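"""Signed circular gene orders and rearrangement scoring vs a benchmark.

Per-gene status against the benchmark uses the gene's own strand sign and
the identity of its circular predecessor: kept (both match), translocated
(predecessor changed), inverted (sign flipped in place), or both; a second
control-region copy scores as a duplication. RS is the sum of per-gene
scores (kept 0, translocated 1, inverted 1, both 2, duplicated 1); RF of
a gene is the percentage of arrangements in which its score is positive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .genes import normalize_gene_name, UnknownGeneError
from .io import MitogenomeRecord

#: ancestral arthropod arrangement (control region between rrnS and trnI),
#: anchored at trnI on the heavy strand
ANCESTRAL_ARTHROPOD: tuple[tuple[str, int], ...] = (
    ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("ND2", 1), ("trnW", 1),
    ("trnC", -1), ("trnY", -1), ("COX1", 1), ("trnL2", 1), ("COX2", 1),
    ("trnK", 1), ("trnD", 1), ("ATP8", 1), ("ATP6", 1), ("COX3", 1),
    ("trnG", 1), ("ND3", 1), ("trnA", 1), ("trnR", 1), ("trnN", 1),
    ("trnS1", 1), ("trnE", 1), ("trnF", -1), ("ND5", -1), ("trnH", -1),
    ("ND4", -1), ("ND4L", -1), ("trnT", 1), ("trnP", -1), ("ND6", 1),
    ("CYTB", 1), ("trnS2", 1), ("ND1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1), ("CR", 1),
)

STATUS_SCORES = {"kept": 0, "translocated": 1, "inverted": 1,
                 "inverted+translocated": 2, "duplicated": 1}

DEFAULT_ANCHOR = "trnI"


@dataclass(frozen=True)
class GeneOrder:
    """A signed circular gene permutation in canonical rotation."""

    id: str
    elements: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.elements]
        dup = [n for n, c in Counter(names).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate elements in gene order {self.id}: {dup}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.elements)

    def sign_of(self, name: str) -> int:
        for n, s in self.elements:
            if n == name:
                return s
        raise KeyError(name)

    def predecessor_of(self, name: str) -> str:
        idx = self.names.index(name)
        return self.names[idx - 1]

    def canonical(self, anchor: str = DEFAULT_ANCHOR) -> "GeneOrder":
        """Rotate to the anchor at index 0 with positive sign.

        If the anchor sits on the minus strand the whole order is reflected
        and sign-flipped first (the two readings of one circle). Falls back
        to the lexicographically smallest element when the anchor is absent.
        """
        elems = list(self.elements)
        if anchor not in self.names:
            anchor = min(self.names)
        if dict(elems)[anchor] == -1:
            elems = [(n, -s) for n, s in reversed(elems)]
        idx = [n for n, _ in elems].index(anchor)
        return GeneOrder(self.id, tuple(elems[idx:] + elems[:idx]))


def parse_order_string(text: str, order_id: str = "") -> GeneOrder:
    """Parse a comma-separated signed arrangement like ``trnI,-trnQ,trnM,...``."""
    elems = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        sign = 1
        if token.startswith("-"):
            sign, token = -1, token[1:]
        try:
            name = normalize_gene_name(token)
        except UnknownGeneError:
            name = token
        elems.append((name, sign))
    if len(elems) < 2:
        raise ValueError(f"arrangement {order_id!r} needs at least two elements")
    return GeneOrder(order_id, tuple(elems))


def format_order(order: GeneOrder) -> str:
    return ",".join(("-" if s == -1 else "") + n for n, s in order.elements)


def extract_gene_order(record: MitogenomeRecord,
                       anchor: str = DEFAULT_ANCHOR) -> GeneOrder:
    """Canonical signed gene order of an annotated record.

    Features sort by start coordinate (an origin-wrapping feature sorts by
    its start); ``other``-category features are ignored.
    """
    feats = [f for f in record.features if f.category != "other"]
    if len(feats) < 2:
        raise ValueError(f"record {record.id} has fewer than 2 ordered features")
    feats.sort(key=lambda f: f.start)
    order = GeneOrder(record.id, tuple((f.name, f.strand) for f in feats))
    return order.canonical(anchor)


@dataclass(frozen=True)
class ArrangementComparison:
    target_id: str
    benchmark_id: str
    status: dict[str, str]
    scores: dict[str, int]

    @property
    def rs(self) -> int:
        return sum(self.scores.values())


def compare_to_benchmark(target: GeneOrder, benchmark: GeneOrder,
                         anchor: str = DEFAULT_ANCHOR) -> ArrangementComparison:
    target = target.canonical(anchor)
    benchmark = benchmark.canonical(anchor)
    status: dict[str, str] = {}
    scores: dict[str, int] = {}
    for name, sign in target.elements:
        if name == "CR2":
            status[name] = "duplicated"
        elif name not in benchmark.names:
            status[name] = "translocated"
        else:
            pred_t = target.predecessor_of(name)
            pred_b = benchmark.predecessor_of(name)
            # a CR duplicate next door should not disturb its neighbor
            if pred_t == "CR2" and "CR2" not in benchmark.names:
                idx = target.names.index(name)
                pred_t = target.names[idx - 2]
            same_pred = pred_t == pred_b
            same_sign = sign == benchmark.sign_of(name)
            if same_pred and same_sign:
                status[name] = "kept"
            elif same_pred:
                status[name] = "inverted"
            elif same_sign:
                status[name] = "translocated"
            else:
                status[name] = "inverted+translocated"
        scores[name] = STATUS_SCORES[status[name]]
    return ArrangementComparison(target.id, benchmark.id, status, scores)


def rearrangement_frequency(comparisons: list[ArrangementComparison],
                            benchmark: GeneOrder,
                            ) -> tuple[dict[str, float], list[str]]:
    """RF per gene and the maximal circular run of RF==0 genes.

    RF(g) = 100 x (number of arrangements where g scored > 0) / N over the
    union of genes seen in any comparison.
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    n = len(comparisons)
    genes: list[str] = [g for g, _ in benchmark.canonical().elements]
    for comp in comparisons:
        for g in comp.scores:
            if g not in genes:
                genes.append(g)
    rf = {}
    for g in genes:
        hits = sum(1 for comp in comparisons if comp.scores.get(g, 0) > 0)
        rf[g] = 100.0 * hits / n
    conserved = _max_zero_run([g for g, _ in benchmark.canonical().elements], rf)
    return rf, conserved


def _max_zero_run(ring: list[str], rf: dict[str, float]) -> list[str]:
    k = len(ring)
    if all(rf.get(g, 0.0) == 0.0 for g in ring):
        return list(ring)
    best: list[str] = []
    for start in range(k):
        if rf.get(ring[start], 0.0) != 0.0:
            continue
        if rf.get(ring[start - 1], 0.0) == 0.0:
            continue  # not the head of a run
        run = []
        i = start
        while rf.get(ring[i % k], 0.0) == 0.0 and len(run) < k:
            run.append(ring[i % k])
            i += 1
        if len(run) > len(best):
            best = run
    return best


@dataclass
class ArrangementCatalog:
    orders: dict[str, GeneOrder] = field(default_factory=dict)

    @classmethod
    def builtin(cls) -> "ArrangementCatalog":
        return cls({"T1": GeneOrder("T1", ANCESTRAL_ARTHROPOD)})

    @classmethod
    def from_file(cls, path: str | Path, include_builtin: bool = True,
                  ) -> "ArrangementCatalog":
        """Load ``label = trnI,-trnQ,...`` lines; '#' starts a comment."""
        cat = cls.builtin() if include_builtin else cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'label = order'")
                label, text = (part.strip() for part in line.split("=", 1))
                cat.orders[label] = parse_order_string(text, label)
        return cat


def assign_arrangement_type(order: GeneOrder, catalog: ArrangementCatalog,
                            anchor: str = DEFAULT_ANCHOR) -> str:
    """Exact canonical-form match against the catalog, else ``novel``."""
    if not catalog.orders:
        raise ValueError("empty arrangement catalog")
    target = order.canonical(anchor).elements
    for label, ref in catalog.orders.items():
        if ref.canonical(anchor).elements == target:
            return label
    return "novel"
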