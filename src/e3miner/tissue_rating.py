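"""Five-level tissue-specificity rating with cross-dataset balloting.

Each expression dataset ("voter") rates every gene in every tissue on an
ordinal scale of increasing tissue specificity::

    A < P < HP < MS < SP

``A`` (absent) is forced by the MAS5 Present/Absent call (or by a zero EST
count); the remaining levels derive from the gene's z-score across tissues
within that dataset, ``z_t = (x_t − μ) / s``:

* ``SP``  — specific:             z_t ≥ z3 and z_i ≤ z2 for every other tissue
* ``MS``  — multi-tissue specific: z_t ≥ z2
* ``HP``  — highly present:        z_t ≥ z1
* ``P``   — present:               otherwise (call is "P")

with default thresholds z1 = 1, z2 = 1.96, z3 = 2.58 and the most specific
satisfied level winning.  Voters are then aggregated by ballot: the level
with the most votes is assigned when it is supported by at least
``min_votes`` datasets; ties at the top resolve to the least specific tied
level; insufficient support yields ``UNCLASSIFIED``.

With ``n`` tissues and sample standard deviation the largest achievable
z-score is ``(n − 1)/√n`` (a one-hot-high profile), so SP is structurally
unattainable below 9 tissues under the default z3 — the rater warns when a
dataset is in that regime.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import EST_COUNTS, ExpressionDataset

LEVELS = ("A", "P", "HP", "MS", "SP")
UNCLASSIFIED = "UNCLASSIFIED"
ABSTAIN = None

_SPECIFICITY = {level: i for i, level in enumerate(LEVELS)}


class AttainabilityWarning(UserWarning):
    """The tissue count makes one or more rating levels unreachable."""


@dataclass
class RatingConfig:
    z1: float = 1.0
    z2: float = 1.96
    z3: float = 2.58
    min_votes: int = 2
    sd_mode: str = "sample"

    def __post_init__(self) -> None:
        if not (0 < self.z1 < self.z2 < self.z3):
            raise ValueError("thresholds must satisfy 0 < z1 < z2 < z3")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError("sd_mode must be 'sample' or 'population'")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_mode == "sample" else 0


@dataclass
class RatingMatrix:
    """Per-dataset level calls plus the final balloted level, genes × tissues."""

    per_dataset: dict[str, pd.DataFrame]
    final: pd.DataFrame
    config: RatingConfig = field(default_factory=RatingConfig)


def max_zscore(n_tissues: int, sd_mode: str = "sample") -> float:
    """Largest z reachable by any profile over ``n_tissues`` tissues.

    The maximizer is a one-hot-high profile; with sample sd the bound is
    (n − 1)/√n, with population sd it is √(n − 1).
    """
    n = n_tissues
    return (n - 1) / np.sqrt(n) if sd_mode == "sample" else float(np.sqrt(n - 1))


def zscores(values, sd_mode: str = "sample") -> np.ndarray:
    """Standardize one gene's per-tissue expression vector.

    A zero-variance (constant) vector maps to all-zero z-scores.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("zscores expects a 1-D per-tissue vector")
    if x.size < 2:
        raise ValueError("need expression in at least 2 tissues")
    ddof = 1 if sd_mode == "sample" else 0
    sd = x.std(ddof=ddof)
    # sd at rounding-error scale means a numerically constant vector
    if sd <= 1e-12 * np.abs(x).mean():
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _zscore_matrix(values: pd.DataFrame, ddof: int) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = sd <= 1e-12 * np.abs(x).mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(degenerate, z.shape)] = 0.0
    return z


def _cpm(values: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million by tissue column; all-zero columns stay zero."""
    totals = values.sum(axis=0).replace(0, np.nan)
    return (values / totals * 1e6).fillna(0.0)


def rate_one_dataset(dataset: ExpressionDataset, config: RatingConfig | None = None) -> pd.DataFrame:
    """Rate every (gene, tissue) of a single voter on the A..SP scale.

    EST-count voters have no MAS5 calls: presence is defined as count > 0 and
    z-scores are taken on counts-per-million-normalized columns, so library
    depth differences between tissues do not masquerade as specificity.
    """
    config = config or RatingConfig()
    n = dataset.values.shape[1]
    if n < 2:
        raise ValueError("need at least 2 tissues to rate")
    if max_zscore(n, config.sd_mode) < config.z3:
        warnings.warn(
            f"SP is unattainable with {n} tissues "
            f"(max z {max_zscore(n, config.sd_mode):.3f} < z3 {config.z3}); "
            "ratings will never exceed MS",
            AttainabilityWarning,
            stacklevel=2,
        )

    if dataset.kind == EST_COUNTS:
        present = dataset.values.to_numpy() > 0
        z = _zscore_matrix(_cpm(dataset.values), config.ddof)
    else:
        if dataset.calls is not None:
            present = dataset.calls.to_numpy() == "P"
        else:
            present = np.ones(dataset.values.shape, dtype=bool)
        z = _zscore_matrix(dataset.values, config.ddof)

    # Most specific satisfied level; the SP condition needs the largest z
    # among the *other* tissues, obtained from the row's top two z-scores.
    top1 = z.max(axis=1, keepdims=True)
    part = np.partition(z, -2, axis=1)
    top2 = part[:, -2][:, None]
    max_other = np.where(z == top1, top2, top1)
    # Duplicate maxima: every tissue then sees another tissue at top1.
    dup = (z == top1).sum(axis=1, keepdims=True) > 1
    max_other = np.where(dup & (z == top1), top1, max_other)

    level = np.full(z.shape, "P", dtype=object)
    level[z >= config.z1] = "HP"
    level[z >= config.z2] = "MS"
    level[(z >= config.z3) & (max_other <= config.z2)] = "SP"
    level[~present] = "A"
    return pd.DataFrame(level, index=dataset.genes, columns=dataset.tissues)


def ballot(votes, config: RatingConfig | None = None) -> str:
    """Aggregate one (gene, tissue)'s per-dataset levels into a final level.

    ``votes`` may contain ``None`` (abstentions, e.g. the gene is absent from
    that dataset).  The winning level needs at least ``min_votes`` supporters;
    ties at the maximum resolve to the least specific tied level.
    """
    config = config or RatingConfig()
    cast = [v for v in votes if v is not None]
    if not cast:
        raise ValueError("all voters abstained")
    for v in cast:
        if v not in _SPECIFICITY:
            raise ValueError(f"unknown level {v!r}")
    counts = Counter(cast)
    top = max(counts.values())
    if top < config.min_votes:
        return UNCLASSIFIED
    tied = [lvl for lvl, c in counts.items() if c == top]
    return min(tied, key=_SPECIFICITY.__getitem__)


def rate_all(datasets: list[ExpressionDataset], config: RatingConfig | None = None) -> RatingMatrix:
    """Rate each voter, then ballot per gene and tissue.

    Datasets must share the tissue panel; genes missing from a dataset
    abstain there.  The gene universe of the result is the union of all
    datasets' genes.
    """
    config = config or RatingConfig()
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to ballot")
    tissues = datasets[0].tissues
    for d in datasets[1:]:
        if set(d.tissues) != set(tissues):
            raise ValueError(
                f"dataset {d.name!r} tissue panel differs from {datasets[0].name!r}"
            )
    gene_sets = [set(d.genes) for d in datasets]
    overlap = set()
    for i, a in enumerate(gene_sets):
        for b in gene_sets[i + 1 :]:
            overlap |= a & b
    if not overlap:
        raise ValueError("no gene is shared by any two datasets; nothing can be balloted")

    genes = sorted(set().union(*gene_sets))
    per_dataset: dict[str, pd.DataFrame] = {}
    # level codes: -1 abstain, 0..4 = A..SP
    stack = np.full((len(datasets), len(genes), len(tissues)), -1, dtype=np.int8)
    for k, d in enumerate(datasets):
        rated = rate_one_dataset(d, config).reindex(columns=tissues)
        per_dataset[d.name] = rated
        coded = np.vectorize(_SPECIFICITY.__getitem__, otypes=[np.int8])(
            rated.to_numpy()
        ) if rated.size else np.empty(rated.shape, dtype=np.int8)
        idx = pd.Index(genes).get_indexer(rated.index)
        stack[k, idx, :] = coded

    counts = np.stack([(stack == code).sum(axis=0) for code in range(len(LEVELS))])
    top = counts.max(axis=0)
    # argmax over levels in ascending specificity → least specific tied level
    winner = (counts == top).argmax(axis=0)
    final = np.where(
        top >= config.min_votes,
        np.asarray(LEVELS, dtype=object)[winner],
        UNCLASSIFIED,
    )
    final_df = pd.DataFrame(final, index=pd.Index(genes, name="gene_id"), columns=tissues)
    return RatingMatrix(per_dataset=per_dataset, final=final_df, config=config)


def level_cross_tab(catalog, ratings: RatingMatrix, tissue: str) -> pd.DataFrame:
    """Family × level contingency table for one tissue, with totals.

    Rows are E3 families, columns the five levels (most specific first) plus
    UNCLASSIFIED; catalogue genes missing from the ratings count as
    UNCLASSIFIED.  A ``total`` row/column is appended.
    """
    from .domain_mining import FAMILIES  # local import avoids a cycle

    if tissue not in ratings.final.columns:
        raise KeyError(f"tissue {tissue!r} not in ratings")
    columns = ["SP", "MS", "HP", "P", "A", UNCLASSIFIED]
    table = pd.DataFrame(0, index=list(FAMILIES), columns=columns)
    levels = ratings.final[tissue]
    for gene, family in catalog.entries.items():
        level = levels.get(gene, UNCLASSIFIED)
        table.loc[family, level] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table
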