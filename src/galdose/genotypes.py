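"""Copy-number genotypes on the four-gene GAL regulatory lattice.

The study design halves the dosage (2 -> 1 copies in a diploid) of each of the
four regulatory genes of the yeast galactose-utilization network — *GAL2*
(permease), *GAL3* (signal transducer), *GAL4* (activator) and *GAL80*
(inhibitor) — in every combination, giving a 2^4 lattice of 16 genotypes.
A genotype is identified either by its copy-number code (e.g. ``"2212"`` in
gene order GAL2, GAL3, GAL4, GAL80) or by its *reduced set* M, the set of
genes carried at a single copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Tuple

#: Canonical gene order used for codes and subset enumeration.
GENES: Tuple[str, str, str, str] = ("GAL2", "GAL3", "GAL4", "GAL80")

_GENE_INDEX = {g: i for i, g in enumerate(GENES)}


def _check_gene(gene: str) -> str:
    if gene not in _GENE_INDEX:
        raise ValueError(f"unknown gene {gene!r}; expected one of {GENES}")
    return gene


@dataclass(frozen=True, order=True)
class Genotype:
    """Copy numbers of the four regulatory genes, in the order of :data:`GENES`."""

    copies: Tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.copies) != len(GENES):
            raise ValueError(f"expected {len(GENES)} copy numbers, got {len(self.copies)}")
        if any(c not in (1, 2) for c in self.copies):
            raise ValueError(f"copy numbers must be 1 or 2, got {self.copies}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def wild_type(cls) -> "Genotype":
        return cls((2, 2, 2, 2))

    @classmethod
    def from_reduced(cls, genes: Iterable[str]) -> "Genotype":
        """Genotype with the named genes at one copy and the rest at two."""
        reduced = {_check_gene(g) for g in genes}
        return cls(tuple(1 if g in reduced else 2 for g in GENES))

    @classmethod
    def from_copies(cls, copies: Dict[str, int]) -> "Genotype":
        if set(copies) != set(GENES):
            raise ValueError(f"copy map must cover exactly {GENES}, got {sorted(copies)}")
        return cls(tuple(copies[g] for g in GENES))

    @classmethod
    def from_code(cls, code: str) -> "Genotype":
        if len(code) != len(GENES) or any(ch not in "12" for ch in code):
            raise ValueError(f"invalid genotype code {code!r}")
        return cls(tuple(int(ch) for ch in code))

    # -- views -------------------------------------------------------------
    @property
    def code(self) -> str:
        """Copy-number string in gene order, e.g. ``'2212'``."""
        return "".join(str(c) for c in self.copies)

    @property
    def reduced(self) -> FrozenSet[str]:
        """The set M of genes present at a single copy."""
        return frozenset(g for g, c in zip(GENES, self.copies) if c == 1)

    @property
    def order(self) -> int:
        """Number of dosage-reduced genes, |M|."""
        return len(self.reduced)

    def copy_of(self, gene: str) -> int:
        return self.copies[_GENE_INDEX[_check_gene(gene)]]

    def as_dict(self) -> Dict[str, int]:
        return dict(zip(GENES, self.copies))

    def with_copy(self, gene: str, count: int) -> "Genotype":
        idx = _GENE_INDEX[_check_gene(gene)]
        copies = list(self.copies)
        copies[idx] = count
        return Genotype(tuple(copies))

    def __str__(self) -> str:
        if not self.reduced:
            return "WT"
        return "+".join(sorted(self.reduced, key=_GENE_INDEX.__getitem__))


WILD_TYPE = Genotype.wild_type()


def gene_subsets(min_size: int = 0, max_size: int = 4) -> List[FrozenSet[str]]:
    """All subsets of the four genes with ``min_size <= |S| <= max_size``.

    Canonical order: by size, then lexicographically by gene position.
    """
    subsets: List[FrozenSet[str]] = []
    for k in range(min_size, max_size + 1):
        for combo in combinations(GENES, k):
            subsets.append(frozenset(combo))
    return subsets


def enumerate_genotypes() -> List[Genotype]:
    """The full 2^4 design, wild type first, then by reduced set in canonical order."""
    return [Genotype.from_reduced(s) for s in gene_subsets()]


def subset_label(genes: FrozenSet[str]) -> str:
    """Stable human-readable label for a gene set, e.g. ``'GAL2+GAL80'``."""
    if not genes:
        return "WT"
    return "+".join(sorted(genes, key=_GENE_INDEX.__getitem__))
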