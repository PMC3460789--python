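"""Cross-species ortholog-group mapping and homology enrichment.

Two genes from different species are treated as homologues when they share
an ortholog group (HomoloGene-style annotation).  Given a gene set per
species, the summary counts the groups hit by both species and expresses the
overlap as a fraction of the union::

    fraction = n_shared / (n_a + n_b − n_shared)

Enrichment of a gene set's homology over the genome background is assessed
with an exact one-sided binomial tail P(X ≥ k), X ~ Binomial(n, p0),
evaluated via the regularized incomplete beta function so that vanishingly
small tails stay accurate and representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

from scipy.special import bdtrc


@dataclass
class HomologyTable:
    """Ortholog groups: group id → taxon id → member gene ids."""

    groups: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, group_id: str, taxon_id: str, gene_id: str) -> None:
        self.groups.setdefault(group_id, {}).setdefault(taxon_id, set()).add(gene_id)

    def group_of(self, taxon_id: str, gene_id: str) -> str | None:
        for gid, members in self.groups.items():
            if gene_id in members.get(taxon_id, ()):
                return gid
        return None

    def taxa(self) -> set[str]:
        return {t for members in self.groups.values() for t in members}


@dataclass
class HomologySummary:
    n_a: int
    n_b: int
    n_shared: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_shared <= min(self.n_a, self.n_b):
            raise ValueError("need 0 <= n_shared <= min(n_a, n_b)")

    @property
    def union(self) -> int:
        return self.n_a + self.n_b - self.n_shared

    @property
    def fraction(self) -> float:
        return homolog_fraction(self.n_a, self.n_b, self.n_shared)


def parse_homologene(
    stream: TextIO | str | Path, ncbi_layout: bool = False
) -> HomologyTable:
    """Parse a tab-delimited ortholog-group table.

    Default dialect: ``group_id  taxon_id  gene_id  gene_symbol``.  With
    ``ncbi_layout`` the 6-column NCBI ``homologene.data`` layout is accepted,
    using its first three columns (group, taxon, gene).  Exact duplicate rows
    collapse silently; a gene listed in two different groups for one taxon is
    an error.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as handle:
            return parse_homologene(handle, ncbi_layout=ncbi_layout)

    table = HomologyTable()
    seen: dict[tuple[str, str], str] = {}  # (taxon, gene) -> group
    min_cols = 3 if ncbi_layout else 4
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < min_cols:
            raise ValueError(f"line {lineno}: expected >= {min_cols} tab-separated columns")
        group_id, taxon_id, gene_id = parts[0], parts[1], parts[2]
        prev = seen.get((taxon_id, gene_id))
        if prev is not None and prev != group_id:
            raise ValueError(
                f"line {lineno}: gene {gene_id!r} (taxon {taxon_id}) appears in "
                f"groups {prev!r} and {group_id!r}"
            )
        seen[(taxon_id, gene_id)] = group_id
        table.add(group_id, taxon_id, gene_id)
    return table


def map_homologs(
    set_a: set[str],
    taxon_a: str,
    set_b: set[str],
    taxon_b: str,
    table: HomologyTable,
) -> HomologySummary:
    """Count ortholog groups hit by both gene sets.

    A group is *shared* when it contains at least one ``set_a`` gene under
    ``taxon_a`` and at least one ``set_b`` gene under ``taxon_b``; counting is
    group-based, which stays well-defined for many-to-many groups.
    """
    if taxon_a == taxon_b:
        raise ValueError("the two gene sets must come from different taxa")
    set_a, set_b = set(set_a), set(set_b)
    n_shared = 0
    for members in table.groups.values():
        if members.get(taxon_a, set()) & set_a and members.get(taxon_b, set()) & set_b:
            n_shared += 1
    return HomologySummary(n_a=len(set_a), n_b=len(set_b), n_shared=n_shared)


def homolog_fraction(n_a: int, n_b: int, n_shared: int) -> float:
    """Shared fraction over the two-species union, n_shared/(n_a+n_b−n_shared)."""
    if n_shared > min(n_a, n_b) or n_shared < 0:
        raise ValueError("need 0 <= n_shared <= min(n_a, n_b)")
    union = n_a + n_b - n_shared
    if union == 0:
        raise ValueError("union of the two sets is empty")
    return n_shared / union


def enrichment_test(n_shared: int, n_union: int, p0: float) -> float:
    """Exact upper binomial tail P(X >= n_shared), X ~ Binomial(n_union, p0).

    Evaluated through the regularized incomplete beta function,
    P(X >= k) = I_p0(k, n−k+1), which is monotone in ``n_shared`` to machine
    precision and keeps extreme tails (down to ~1e-300) representable —
    naive pmf summation loses both properties.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    if not 0 <= n_shared <= n_union:
        raise ValueError("need 0 <= n_shared <= n_union")
    if n_shared == 0:
        return 1.0
    return float(bdtrc(n_shared - 1, n_union, p0))


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-column gene-id list (blank lines and ``#`` comments skipped)."""
    genes: set[str] = set()
    with open(path) as handle:
        for line in handle:
            token = line.strip()
            if token and not token.startswith("#"):
                genes.add(token.split("\t")[0])
    return genes
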