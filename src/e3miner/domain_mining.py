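"""E3 catalogue construction from profile-HMM domain search output.

Proteins carrying a RING (Pfam ``zf-C3HC4``), HECT or U-box domain are the
classical single-subunit E3 ubiquitin ligases.  This module parses HMMER
per-domain tabular output (``--domtblout``), keeps hits whose full-sequence
E-value is no more than a cutoff (default 0.1, boundary inclusive), collapses
protein isoforms onto genes, and assigns each gene exactly one family — that
of its best-E-value hit, with the fixed precedence RING > HECT > U-box
breaking exact ties.  The result is an exclusive per-gene catalogue: every
gene with at least one retained hit appears exactly once.

Running the HMM search itself is out of scope; the tested boundary is the
domtblout text, which any HMMER 3.x ``hmmsearch``/``hmmscan`` run produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

FAMILIES = ("RING", "HECT", "U-box")
_FAMILY_PRECEDENCE = {fam: i for i, fam in enumerate(FAMILIES)}

#: Pfam model names (and common aliases) → catalogue family
DOMAIN_ALIASES: dict[str, str] = {
    "zf-C3HC4": "RING",
    "RING": "RING",
    "HECT": "HECT",
    "U-box": "U-box",
    "Ubox": "U-box",
}


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match on a protein."""

    target_protein_id: str
    query_domain: str
    full_seq_evalue: float
    domain_i_evalue: float
    bit_score: float
    envelope_from: int
    envelope_to: int

    def __post_init__(self) -> None:
        if self.full_seq_evalue < 0 or self.domain_i_evalue < 0:
            raise ValueError("E-values must be non-negative")
        if not (1 <= self.envelope_from <= self.envelope_to):
            raise ValueError("envelope coordinates must satisfy 1 <= from <= to")

    @property
    def family(self) -> str | None:
        """Catalogue family, or None for a pass-through (unknown) domain."""
        return DOMAIN_ALIASES.get(self.query_domain)


@dataclass
class E3Catalog:
    """Exclusive gene → family map with provenance."""

    entries: dict[str, str]
    species: str = ""
    provenance: str = ""
    best_evalue: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> set[str]:
        return set(self.entries)

    def family_counts(self) -> dict[str, int]:
        counts = {fam: 0 for fam in FAMILIES}
        for fam in self.entries.values():
            counts[fam] += 1
        return counts

    def to_frame(self):
        import pandas as pd

        rows = [
            (g, fam, self.best_evalue.get(g, float("nan")))
            for g, fam in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "family", "best_evalue"])


# domtblout column positions (0-based), per the HMMER 3 tabular convention
_COL_TARGET = 0
_COL_QUERY = 3
_COL_FULL_EVALUE = 6
_COL_FULL_SCORE = 7
_COL_I_EVALUE = 12
_COL_ENV_FROM = 19
_COL_ENV_TO = 20
_MIN_FIELDS = 22


def parse_domtblout(stream: TextIO | str | Path) -> list[DomainHit]:
    """Parse HMMER per-domain tabular output into :class:`DomainHit` records.

    ``#`` lines are comments.  Unknown query domains are retained with their
    name passed through unchanged (classification ignores them later).
    Malformed data lines raise ``ValueError`` naming the line number.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as handle:
            return parse_domtblout(handle)

    hits: list[DomainHit] = []
    for lineno, line in enumerate(stream, start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split()
        if len(fields) < _MIN_FIELDS:
            raise ValueError(
                f"line {lineno}: expected >= {_MIN_FIELDS} fields, got {len(fields)}"
            )
        try:
            hit = DomainHit(
                target_protein_id=fields[_COL_TARGET],
                query_domain=fields[_COL_QUERY],
                full_seq_evalue=float(fields[_COL_FULL_EVALUE]),
                domain_i_evalue=float(fields[_COL_I_EVALUE]),
                bit_score=float(fields[_COL_FULL_SCORE]),
                envelope_from=int(fields[_COL_ENV_FROM]),
                envelope_to=int(fields[_COL_ENV_TO]),
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed domtblout record ({exc})") from exc
        hits.append(hit)
    return hits


def filter_hits(hits: Iterable[DomainHit], e_max: float = 0.1) -> list[DomainHit]:
    """Keep hits with full-sequence E-value <= ``e_max`` (order preserved)."""
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    return [h for h in hits if h.full_seq_evalue <= e_max]


def classify_families(
    hits: Iterable[DomainHit],
    protein_to_gene: dict[str, str],
    species: str = "",
    provenance: str = "",
) -> E3Catalog:
    """Collapse retained hits onto genes and assign one family per gene.

    A gene enters the catalogue iff any of its proteins carries at least one
    retained hit from a known E3 family.  The gene's family is that of the
    lowest full-sequence E-value across all its proteins' hits; exact
    E-value ties fall back on the precedence RING > HECT > U-box.
    """
    hits = list(hits)
    known = [h for h in hits if h.family is not None]
    orphans = sorted({h.target_protein_id for h in hits} - set(protein_to_gene))
    if orphans:
        raise KeyError(f"proteins with no gene mapping: {', '.join(orphans)}")

    best: dict[str, tuple[float, int]] = {}
    entries: dict[str, str] = {}
    for hit in known:
        gene = protein_to_gene[hit.target_protein_id]
        key = (hit.full_seq_evalue, _FAMILY_PRECEDENCE[hit.family])
        if gene not in best or key < best[gene]:
            best[gene] = key
            entries[gene] = hit.family
    return E3Catalog(
        entries=entries,
        species=species,
        provenance=provenance,
        best_evalue={g: ev for g, (ev, _) in best.items()},
    )


def annotate_membrane(
    catalog: E3Catalog, annotation: dict[str, dict[str, bool]]
) -> dict[str, int]:
    """Tally catalogue genes annotated with a signal peptide and/or a TMD.

    ``annotation`` maps gene → {"has_signal_peptide": bool, "has_tmd": bool};
    genes absent from the table count as neither, genes annotated but not in
    the catalogue are ignored (prediction itself is a user-supplied input).
    """
    signal = tmd = either = 0
    for gene in catalog.entries:
        ann = annotation.get(gene, {})
        sp = bool(ann.get("has_signal_peptide", False))
        tm = bool(ann.get("has_tmd", False))
        signal += sp
        tmd += tm
        either += sp or tm
    return {"signal_peptide": signal, "tmd": tmd, "either": either}


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column protein → gene TSV (no header required)."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping
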