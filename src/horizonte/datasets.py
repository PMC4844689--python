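"""Bundled published data: the AviRTE consensus distance table and the
three leaf-area codings used by the biogeographic analysis variants."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .biogeography import DEFAULT_AREAS, AreaAssignment, read_leaf_areas
from .divergence import DistanceMatrix
from .errors import FormatError


def _data_path(name: str) -> Path:
    return Path(str(resources.files("horizonte").joinpath("data", name)))


def load_published_distances() -> DistanceMatrix:
    """Published pairwise K2P distances between the eleven full-length
    AviRTE consensus sequences (bird and nematode host genomes)."""
    lines = [ln for ln in
             _data_path("avirte_consensus_k2p.tsv").read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    pairs: dict[tuple[str, str], float] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        taxon = fields[0]
        for other, val in zip(header, fields[1:]):
            if val:
                pairs[(taxon, other)] = float(val)
    if len(pairs) != len(header) * (len(header) - 1) // 2:
        raise FormatError("published distance table is incomplete")
    return DistanceMatrix.from_pairs(header, pairs)


AREA_VARIANTS = ("widest", "fossil", "main")


def load_area_coding(variant: str = "main") -> AreaAssignment:
    """One of the three bundled leaf-area codings of the AviRTE-bearing
    lineages over the five tropical avifaunal regions."""
    if variant not in AREA_VARIANTS:
        raise FormatError(
            f"unknown area-coding variant {variant!r}; "
            f"choose from {AREA_VARIANTS}")
    return read_leaf_areas(_data_path(f"areas_{variant}.tsv"),
                           universe=DEFAULT_AREAS)
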