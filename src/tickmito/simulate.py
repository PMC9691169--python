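"""Seeded synthetic mitogenomes and alignments with known ground truth.

Everything here is deterministic under a fixed seed. Sequence background
is i.i.d. per position with base probabilities chosen to hit the target
A+T fraction and strand skews; planted microsatellites and degenerate-
consensus instances are written into named host regions and logged with
exact coordinates so every downstream stage can be validated against a
truth log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .gene_order import ANCESTRAL_ARTHROPOD, GeneOrder
from .genes import category_of, UnknownGeneError
from .io import GeneFeature, MitogenomeRecord, reverse_complement
from .ssr import SSRConfig, find_perfect_ssrs

#: per-gene length table (bp), loosely modeled on tick mitogenomes
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND1": 921, "ND2": 960, "ND3": 336, "ND4": 1332, "ND4L": 270,
    "ND5": 1644, "ND6": 435, "COX1": 1530, "COX2": 672, "COX3": 780,
    "CYTB": 1080, "ATP6": 660, "ATP8": 153,
    "rrnS": 705, "rrnL": 1200, "CR": 340, "CR2": 120,
    **{f"trn{x}": 65 for x in "ARNDCEQGHIKMFPTWYV"},
    "trnL1": 65, "trnL2": 65, "trnS1": 65, "trnS2": 65,
}

IG_REGION = "IG"  # dedicated unannotated intergenic span


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    repeats: int
    host: str = "CR"
    offset: int | None = None  # within host; random if None


@dataclass(frozen=True)
class PlantedMotif:
    instance: str
    host: str = IG_REGION
    strand: int = 1
    offset: int | None = None


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str                       # transposition | inversion | cr_duplication
    genes: tuple[str, ...] = ()
    after: str | None = None        # insertion point for transposition/CR2


@dataclass
class SimulationParams:
    seed: int = 0
    record_id: str = "SIM1"
    organism: str = "Ixodes simulans"
    at_fraction: float = 0.78
    at_skew: float = 0.0
    gc_skew: float = -0.15
    gene_template: tuple[tuple[str, int], ...] = ANCESTRAL_ARTHROPOD
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    spacer: int = 2                 # bases between consecutive features
    intergenic_length: int = 0      # unannotated span inserted before CR
    planted_ssrs: tuple[PlantedSSR, ...] = ()
    planted_motifs: tuple[PlantedMotif, ...] = ()
    max_retries: int = 25

    def __post_init__(self):
        if not 0.0 < self.at_fraction < 1.0:
            raise ValueError("A+T fraction must be in (0, 1)")


@dataclass
class TruthLog:
    record_id: str = ""
    ssrs: list[dict] = field(default_factory=list)
    motifs: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    distances: dict[str, float] = field(default_factory=dict)
    groups: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def base_probabilities(at_fraction: float, at_skew: float = 0.0,
                       gc_skew: float = 0.0) -> dict[str, float]:
    """Per-base probabilities hitting the A+T fraction and both skews."""
    at, gc = at_fraction, 1.0 - at_fraction
    return {
        "A": at * (1 + at_skew) / 2, "T": at * (1 - at_skew) / 2,
        "G": gc * (1 + gc_skew) / 2, "C": gc * (1 - gc_skew) / 2,
    }


def random_sequence(length: int, probs: dict[str, float],
                    rng: np.random.Generator) -> str:
    bases = np.array(list(probs))
    p = np.array([probs[b] for b in bases])
    p = p / p.sum()
    return "".join(rng.choice(bases, size=length, p=p))


class GenerationError(RuntimeError):
    pass


def simulate_mitogenome(params: SimulationParams,
                        ) -> tuple[MitogenomeRecord, TruthLog]:
    """Generate an annotated circular mitogenome plus its truth log.

    Planted SSRs are re-verified with the scanner after generation; on an
    accidental collision (the planted tract extends or merges with
    background repeats) the background is regenerated with a fresh
    substream, up to ``max_retries`` times.
    """
    for attempt in range(params.max_retries):
        rng = np.random.default_rng([params.seed, attempt])
        try:
            record, truth = _build_genome(params, rng)
        except GenerationError:
            continue
        if _verify_planted(record, truth, params):
            return record, truth
    raise GenerationError(
        f"could not place planted features cleanly after {params.max_retries} tries"
    )


def _build_genome(params: SimulationParams,
                  rng: np.random.Generator) -> tuple[MitogenomeRecord, TruthLog]:
    probs = base_probabilities(params.at_fraction, params.at_skew, params.gc_skew)
    chunks: list[str] = []
    features: list[GeneFeature] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0

    def emit(text: str) -> None:
        nonlocal pos
        chunks.append(text)
        pos += len(text)

    for name, strand in params.gene_template:
        if params.spacer:
            emit(random_sequence(params.spacer, probs, rng))
        if name == "CR" and params.intergenic_length:
            spans[IG_REGION] = (pos, pos + params.intergenic_length)
            emit(random_sequence(params.intergenic_length, probs, rng))
            emit(random_sequence(params.spacer, probs, rng))
        length = params.gene_lengths[name]
        coding = random_sequence(length, probs, rng)
        try:
            cat = category_of(name)
        except UnknownGeneError:
            cat = "other"
        if cat == "PCG":
            coding = "ATG" + coding[3:-3] + "TAA"
        emit(coding if strand == 1 else reverse_complement(coding))
        features.append(GeneFeature(name, pos - length, pos, strand))
        spans[name] = (pos - length, pos)

    sequence = list("".join(chunks))
    truth = TruthLog(record_id=params.record_id)
    _plant_ssrs(sequence, spans, params, truth, rng)
    _plant_motifs(sequence, spans, params, truth, rng)
    record = MitogenomeRecord(params.record_id, "".join(sequence), features,
                              organism=params.organism, circular=True)
    return record, truth


def _host_window(spans: dict[str, tuple[int, int]], host: str,
                 needed: int, offset: int | None,
                 rng: np.random.Generator) -> int:
    if host not in spans:
        raise GenerationError(f"unknown host region {host!r}")
    lo, hi = spans[host]
    # one guard base on each side so flanks can break the repeat
    if hi - lo < needed + 2:
        raise GenerationError(f"host {host} too small for planted feature")
    if offset is not None:
        start = lo + offset
        if start + needed + 1 > hi or start <= lo:
            raise GenerationError("planted offset outside host capacity")
        return start
    return int(rng.integers(lo + 1, hi - needed))


def _plant_ssrs(sequence: list[str], spans: dict[str, tuple[int, int]],
                params: SimulationParams, truth: TruthLog,
                rng: np.random.Generator) -> None:
    from .ssr import standardize_motif

    for plant in params.planted_ssrs:
        tract = plant.motif.upper() * plant.repeats
        start = _host_window(spans, plant.host, len(tract), plant.offset, rng)
        sequence[start : start + len(tract)] = tract
        # break periodicity at both flanks
        m = len(plant.motif)
        left_bad, right_bad = tract[m - 1], tract[len(tract) - m]
        sequence[start - 1] = _other_base(left_bad, rng)
        if start + len(tract) < len(sequence):
            sequence[start + len(tract)] = _other_base(right_bad, rng)
        truth.ssrs.append({
            "start": start, "end": start + len(tract), "motif": plant.motif.upper(),
            "std_motif": standardize_motif(plant.motif),
            "repeats": plant.repeats, "host": plant.host,
        })


def _other_base(avoid: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != avoid]
    return options[int(rng.integers(0, len(options)))]


def _plant_motifs(sequence: list[str], spans: dict[str, tuple[int, int]],
                  params: SimulationParams, truth: TruthLog,
                  rng: np.random.Generator) -> None:
    for plant in params.planted_motifs:
        inst = plant.instance.upper()
        heavy = inst if plant.strand == 1 else reverse_complement(inst)
        start = _host_window(spans, plant.host, len(heavy), plant.offset, rng)
        sequence[start : start + len(heavy)] = heavy
        truth.motifs.append({
            "start": start, "end": start + len(heavy), "strand": plant.strand,
            "instance": inst, "host": plant.host,
        })


def _verify_planted(record: MitogenomeRecord, truth: TruthLog,
                    params: SimulationParams) -> bool:
    if not truth.ssrs:
        return True
    found = {(l.start, l.end, l.std_motif)
             for l in find_perfect_ssrs(record.sequence, SSRConfig())}
    from .ssr import standardize_motif

    for planted in truth.ssrs:
        key = (planted["start"], planted["end"], planted["std_motif"])
        if key not in found:
            return False
    return True


# ---------------------------------------------------------------------------
# K2P sequence evolution
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def k2p_event_probabilities(d_star: float, kappa: float) -> tuple[float, float]:
    """Exact (transition, transversion) difference probabilities at distance d.

    With transition rate alpha and per-target transversion rate beta,
    kappa = alpha/beta and d = (alpha + 2 beta) t.
    """
    if d_star < 0:
        raise ValueError("target distance must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    bt = d_star / (kappa + 2.0)
    at = kappa * bt
    # past this point the chain is effectively at stationarity and the
    # distance is no longer identifiable from (P, Q)
    if math.exp(-2.0 * (at + bt)) < 1e-9:
        raise ValueError("target distance beyond the model's resolvable range")
    p = 0.25 + 0.25 * math.exp(-4.0 * bt) - 0.5 * math.exp(-2.0 * (at + bt))
    q = 0.5 - 0.5 * math.exp(-4.0 * bt)
    return p, q


def evolve_pair(seq: str, d_star: float, kappa: float = 2.0,
                seed: int | np.random.Generator = 0) -> str:
    """Mutate a sequence so the expected K2P distance to it equals d_star."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if d_star == 0:
        return seq.upper()
    p, q = k2p_event_probabilities(d_star, kappa)
    if p + q >= 1.0:
        raise ValueError("target distance beyond the model's resolvable range")
    u = rng.random(len(seq))
    v = rng.random(len(seq))
    out = []
    for base, ui, vi in zip(seq.upper(), u, v):
        if base not in "ACGT":
            out.append(base)
        elif ui < p:
            out.append(_TRANSITION[base])
        elif ui < p + q:
            tv = _TRANSVERSIONS[base]
            out.append(tv[0] if vi < 0.5 else tv[1])
        else:
            out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# Gene-order rearrangement events
# ---------------------------------------------------------------------------

def apply_rearrangement_events(order: GeneOrder,
                               events: Sequence[RearrangementEvent],
                               seed: int = 0) -> tuple[GeneOrder, TruthLog]:
    rng = np.random.default_rng(seed)
    elems = list(order.elements)
    truth = TruthLog(record_id=order.id)
    for ev in events:
        names = [n for n, _ in elems]
        if ev.kind == "inversion":
            for g in ev.genes:
                if g not in names:
                    raise ValueError(f"inversion target {g} absent from order")
                i = names.index(g)
                elems[i] = (elems[i][0], -elems[i][1])
        elif ev.kind == "transposition":
            for g in ev.genes:
                if g not in names:
                    raise ValueError(f"transposition target {g} absent from order")
                i = names.index(g)
                moved = elems.pop(i)
                names = [n for n, _ in elems]
                if ev.after is not None:
                    j = names.index(ev.after) + 1
                else:
                    j = int(rng.integers(0, len(elems) + 1))
                elems.insert(j, moved)
                names = [n for n, _ in elems]
        elif ev.kind == "cr_duplication":
            if "CR2" in names:
                raise ValueError("order already contains CR2")
            if ev.after is not None:
                j = names.index(ev.after) + 1
            else:
                j = int(rng.integers(0, len(elems) + 1))
            elems.insert(j, ("CR2", 1))
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        truth.events.append({"kind": ev.kind, "genes": list(ev.genes),
                             "after": ev.after})
    return GeneOrder(order.id, tuple(elems)), truth


# ---------------------------------------------------------------------------
# Marker alignments with group structure
# ---------------------------------------------------------------------------

def simulate_marker_alignment(n_taxa: int, length: int,
                              group_sizes: Sequence[int],
                              d_within: float, d_between: float,
                              seed: int = 0, kappa: float = 2.0,
                              at_fraction: float = 0.75,
                              prefix: str = "tax",
                              ) -> tuple[dict[str, str], dict[str, int]]:
    """Star-like two-level alignment: groups diverged by ~d_between, members
    within a group by ~d_within. Returns ({id: seq}, {id: true group})."""
    if sum(group_sizes) != n_taxa:
        raise ValueError("group sizes must sum to n_taxa")
    if d_within >= d_between:
        raise ValueError("within-group divergence must be below between-group")
    rng = np.random.default_rng(seed)
    probs = base_probabilities(at_fraction)
    root = random_sequence(length, probs, rng)
    seqs: dict[str, str] = {}
    labels: dict[str, int] = {}
    idx = 1
    for gnum, size in enumerate(group_sizes, start=1):
        ancestor = evolve_pair(root, d_between / 2.0, kappa, rng)
        for _ in range(size):
            seqs[f"{prefix}{idx}"] = evolve_pair(ancestor, d_within / 2.0, kappa, rng)
            labels[f"{prefix}{idx}"] = gnum
            idx += 1
    return seqs, labels
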