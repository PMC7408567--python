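"""Built-in glycolysis / hypoxia gene signatures.

The catalog ships as a packaged GMT resource so that users can point any
stage at an alternate GMT file with the same dialect:

* ``glycolysis22`` — 22 core glycolytic-pathway enzymes and transporters.
* ``hypoxia14`` — 14-gene hypoxia-response classifier signature.
* ``glycolysis16`` — glycolysis22 with the six genes shared with hypoxia14
  removed, used to show that the glycolysis–hypoxia score correlation is not
  an artifact of shared membership.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .io_formats import GeneSet, read_gmt

CATALOG_NAMES = ("glycolysis22", "hypoxia14", "glycolysis16")

_EXPECTED_SIZES = {"glycolysis22": 22, "hypoxia14": 14, "glycolysis16": 16}


@lru_cache(maxsize=1)
def _catalog() -> dict[str, GeneSet]:
    with resources.as_file(
        resources.files("glycoscape.data").joinpath("signatures.gmt")
    ) as path:
        sets = {s.name: s for s in read_gmt(path)}
    for name, size in _EXPECTED_SIZES.items():
        if len(sets[name]) != size:
            raise RuntimeError(
                f"packaged signature {name} has {len(sets[name])} genes, expected {size}"
            )
    return sets


def builtin_signature(name: str) -> GeneSet:
    """Return a copy of a built-in signature by catalog name."""
    cat = _catalog()
    if name not in cat:
        raise KeyError(f"unknown signature {name!r}; catalog: {sorted(cat)}")
    src = cat[name]
    return GeneSet(name=src.name, genes=list(src.genes))


def all_signatures() -> list[GeneSet]:
    return [builtin_signature(n) for n in CATALOG_NAMES]


def overlap_genes(a: GeneSet, b: GeneSet) -> list[str]:
    """Sorted intersection of two gene sets."""
    return sorted(set(a.genes) & set(b.genes))
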