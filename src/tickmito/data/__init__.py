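"""Packaged reference tables.

``load_matrix`` returns one of the published pairwise K2P matrices for the
two tick species complexes (markers ``rrnL`` and ``COX1``); the SSR count
tables carry the published per-type microsatellite totals.
"""

from __future__ import annotations

from importlib import resources

from ..distance import DistanceMatrix

_MATRICES = {
    ("ovatus", "rrnL"): "ovatus_rrnL.tsv",
    ("ovatus", "COX1"): "ovatus_COX1.tsv",
    ("acutitarsus", "rrnL"): "acutitarsus_rrnL.tsv",
    ("acutitarsus", "COX1"): "acutitarsus_COX1.tsv",
}


def data_path(filename: str):
    return resources.files(__package__) / filename


def load_matrix(complex_name: str, marker: str) -> DistanceMatrix:
    try:
        fname = _MATRICES[(complex_name, marker)]
    except KeyError:
        raise KeyError(f"no packaged matrix for {complex_name}/{marker}") from None
    with resources.as_file(data_path(fname)) as p:
        return DistanceMatrix.read_tsv(p, marker=marker)


def load_ssr_type_counts(taxon: str = "ixodidae") -> dict[str, int]:
    fname = f"{taxon.lower()}_ssr_type_counts.tsv"
    counts: dict[str, int] = {}
    with resources.as_file(data_path(fname)) as p, open(p) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("type\t"):
                continue
            t, c = line.split("\t")
            counts[t] = int(c)
    return counts
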