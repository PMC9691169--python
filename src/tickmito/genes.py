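"""Canonical mitochondrial gene vocabulary and name normalization.

The canonical vocabulary covers the 37 genes of a metazoan mitogenome
(13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus the control region
(``CR``, optionally duplicated as ``CR2``).
"""

from __future__ import annotations

PCGS: tuple[str, ...] = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COX1", "COX2", "COX3", "CYTB", "ATP6", "ATP8",
)

TRNAS: tuple[str, ...] = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG",
    "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
    "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV",
)

RRNAS: tuple[str, ...] = ("rrnS", "rrnL")

CONTROL_REGIONS: tuple[str, ...] = ("CR", "CR2")

CANONICAL_GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS + CONTROL_REGIONS

#: category per canonical name
CATEGORY: dict[str, str] = (
    {g: "PCG" for g in PCGS}
    | {g: "tRNA" for g in TRNAS}
    | {g: "rRNA" for g in RRNAS}
    | {g: "CR" for g in CONTROL_REGIONS}
)

# amino-acid three-letter code -> one-letter tRNA id (Leu/Ser resolved below)
_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "glu": "E", "gln": "Q", "gly": "G", "his": "H", "ile": "I",
    "lys": "K", "met": "M", "phe": "F", "pro": "P", "thr": "T",
    "trp": "W", "tyr": "Y", "val": "V",
}

# anticodon-family disambiguation for the duplicated Leu and Ser tRNAs
_LEU_SER_CODONS = {
    ("leu", "cun"): "trnL1", ("leu", "uur"): "trnL2",
    ("leu", "tag"): "trnL1", ("leu", "taa"): "trnL2",
    ("leu", "uag"): "trnL1", ("leu", "uaa"): "trnL2",
    ("ser", "agn"): "trnS1", ("ser", "ucn"): "trnS2",
    ("ser", "gct"): "trnS1", ("ser", "tga"): "trnS2",
    ("ser", "gcu"): "trnS1", ("ser", "uga"): "trnS2",
}


class UnknownGeneError(ValueError):
    """Raised when a free-text gene label cannot be mapped to the canonical set."""

    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"cannot map gene label to canonical vocabulary: {raw!r}")


def _build_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}

    def add(raw: str, canon: str) -> None:
        table[_squash(raw)] = canon

    for g in CANONICAL_GENES:
        add(g, g)
    # protein-coding synonyms
    for i in (1, 2, 3, 4, 5, 6):
        add(f"nad{i}", f"ND{i}")
        add(f"nadh{i}", f"ND{i}")
        add(f"nd{i}", f"ND{i}")
        add(f"nadh dehydrogenase subunit {i}", f"ND{i}")
    add("nad4l", "ND4L")
    add("nadh4l", "ND4L")
    add("nadh dehydrogenase subunit 4l", "ND4L")
    roman = {"1": "i", "2": "ii", "3": "iii"}
    for i in ("1", "2", "3"):
        add(f"cox{i}", f"COX{i}")
        add(f"co{i}", f"COX{i}")
        add(f"co{roman[i]}", f"COX{i}")
        add(f"cytochrome c oxidase subunit {i}", f"COX{i}")
        add(f"cytochrome oxidase subunit {i}", f"COX{i}")
    add("cob", "CYTB")
    add("cytb", "CYTB")
    add("cyt b", "CYTB")
    add("cytochrome b", "CYTB")
    for i in ("6", "8"):
        add(f"atp{i}", f"ATP{i}")
        add(f"atpase{i}", f"ATP{i}")
        add(f"atpase {i}", f"ATP{i}")
        add(f"atp synthase f0 subunit {i}", f"ATP{i}")
    # rRNAs
    for raw in ("rrns", "12s", "12s rrna", "12s ribosomal rna", "srrna",
                "s-rrna", "small subunit ribosomal rna", "rns", "mt-rns"):
        add(raw, "rrnS")
    for raw in ("rrnl", "16s", "16s rrna", "16s ribosomal rna", "lrrna",
                "l-rrna", "large subunit ribosomal rna", "rnl", "mt-rnl"):
        add(raw, "rrnL")
    # control region
    for raw in ("cr", "control region", "d-loop", "dloop", "at rich region",
                "a+t rich region", "a+t-rich region", "at-rich region",
                "putative control region"):
        add(raw, "CR")
    add("cr2", "CR2")
    add("control region 2", "CR2")
    # tRNA simple forms (trnI, trn i, tRNA-Ile ...)
    for aa3, one in _AA3_TO_1.items():
        add(f"trn{one}", f"trn{one}")
        add(f"trna-{aa3}", f"trn{one}")
        add(f"trna {aa3}", f"trn{one}")
        add(f"trn{aa3}", f"trn{one}")
    return table


def _squash(raw: str) -> str:
    return " ".join(raw.strip().lower().replace("_", " ").split())


_SYNONYMS = _build_synonyms()


def normalize_gene_name(raw: str) -> str:
    """Map a free-text gene label to its canonical id.

    Handles case, separators, common synonyms (``nad1`` -> ``ND1``,
    ``COI`` -> ``COX1``, ``12S`` -> ``rrnS``, ``A+T rich region`` -> ``CR``)
    and anticodon-qualified Leu/Ser tRNAs (``tRNA-Leu(CUN)`` -> ``trnL1``).

    Raises :class:`UnknownGeneError` for labels outside the vocabulary.
    """
    if not raw or not raw.strip():
        raise UnknownGeneError(raw)
    key = _squash(raw)
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    # anticodon-qualified tRNA forms: trnL(cun), tRNA-Leu (CUN), trnL-uur, trnS2(uga)
    m = _parse_trna_with_codon(key)
    if m is not None:
        return m
    raise UnknownGeneError(raw)


def _parse_trna_with_codon(key: str) -> str | None:
    import re

    pat = re.compile(
        r"^(?:trna[- ]?|trn ?)"
        r"(?P<aa>[a-z]{1,4}[12]?)"
        r"[- (]+(?P<codon>[acgturyn]{3})\)?$"
    )
    m = pat.match(key)
    if m is None:
        return None
    aa, codon = m.group("aa"), m.group("codon")
    # resolve the amino-acid part to a three-letter code
    aa3 = None
    if aa in _AA3_TO_1:
        aa3 = aa
    elif aa in ("leu", "l", "l1", "l2"):
        aa3 = "leu"
    elif aa in ("ser", "s", "s1", "s2"):
        aa3 = "ser"
    elif len(aa) == 1:
        for three, one in _AA3_TO_1.items():
            if one.lower() == aa:
                aa3 = three
                break
    if aa3 is None:
        return None
    if aa3 in ("leu", "ser"):
        hit = _LEU_SER_CODONS.get((aa3, codon))
        if hit:
            return hit
        return None
    return f"trn{_AA3_TO_1[aa3]}"


def category_of(name: str) -> str:
    """Category (PCG / tRNA / rRNA / CR) for a canonical gene id."""
    try:
        return CATEGORY[name]
    except KeyError:
        raise UnknownGeneError(name) from None
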