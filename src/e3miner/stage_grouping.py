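"""Spermatogenesis stage-group assignment from ordered expression profiles.

Spermatogenesis proceeds through mitotic proliferation of spermatogonia,
meiosis of spermatocytes, and post-meiotic spermatid morphogenesis.  A gene's
developmental profile (ordered cell types SG-A → pacSC → rST → eST, or a
days-postpartum series) is classified by *when its expression first rises*:

* ``MI`` — already high at the mitotic stage,
* ``ME`` — rises first at a meiotic stage,
* ``PM`` — rises first post-meiotically,
* ``NONE`` — never at least ``fold_threshold``-fold differential (default 3×).

The onset is the first stage reaching half-maximum,
``value >= min + 0.5·(max − min)`` — a deterministic, scale-invariant
operationalization of "the stage where expression starts to increase" that
replaces manual inspection of clustered heat maps.  Per-dataset assignments
are aggregated by voting: a gene joins a group only when at least
``min_votes`` datasets agree (``NONE`` votes count, so a gene differential in
a single dataset stays ungrouped).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import PHASES, StageDataset

GROUPS = ("MI", "ME", "PM")
NONE_GROUP = "NONE"

_PHASE_TO_GROUP = {"mitotic": "MI", "meiotic": "ME", "post-meiotic": "PM"}
_GROUP_ORDER = {g: i for i, g in enumerate(GROUPS)}

#: default days-postpartum → phase breakpoints: SG-A appear by 8 dpp and
#: pachytene spermatocytes by 17 dpp, so <=8 dpp testis is mitotic, 10–17 dpp
#: meiotic, and >=20 dpp contains post-meiotic cells.
DPP_BREAKPOINTS = {"mitotic_max": 8.0, "meiotic_max": 17.0}


@dataclass
class StageConfig:
    fold_threshold: float = 3.0
    floor: float = 1.0
    onset_definition: str = "half_max"
    min_votes: int = 2

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        if self.onset_definition != "half_max":
            raise ValueError("only the half_max onset rule is implemented")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")


def phases_from_dpp(days: list[float], breakpoints: dict | None = None) -> list[str]:
    """Map a days-postpartum series to phase tags via the standard breakpoints."""
    bp = breakpoints or DPP_BREAKPOINTS
    out = []
    for d in days:
        if d <= bp["mitotic_max"]:
            out.append("mitotic")
        elif d <= bp["meiotic_max"]:
            out.append("meiotic")
        else:
            out.append("post-meiotic")
    return out


def fold_filter(profile, config: StageConfig | None = None) -> bool:
    """True iff the profile is at least ``fold_threshold``-fold differential.

    The ratio is (max + floor)/(min + floor); the floor pseudo-intensity
    guards against division by near-zero array values.
    """
    config = config or StageConfig()
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("profile needs at least 2 stages")
    if (x < 0).any():
        raise ValueError("negative expression values")
    return bool(
        (x.max() + config.floor) / (x.min() + config.floor) >= config.fold_threshold
    )


def onset_stage(profile, config: StageConfig | None = None) -> int:
    """First stage index at or above half-maximum (0 = high from the start)."""
    x = np.asarray(profile, dtype=float)
    half = x.min() + 0.5 * (x.max() - x.min())
    return int(np.argmax(x >= half))


def assign_group(profile, phases: list[str], config: StageConfig | None = None) -> str:
    """Classify one profile as MI/ME/PM by its onset stage's phase, or NONE."""
    config = config or StageConfig()
    x = np.asarray(profile, dtype=float)
    if len(phases) != x.size:
        raise ValueError("one phase tag per stage is required")
    if not fold_filter(x, config):
        return NONE_GROUP
    return _PHASE_TO_GROUP[phases[onset_stage(x, config)]]


def assign_groups(dataset: StageDataset, config: StageConfig | None = None) -> pd.Series:
    """Vectorized per-gene group assignment for one dataset."""
    config = config or StageConfig()
    x = dataset.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression values")
    hi = x.max(axis=1)
    lo = x.min(axis=1)
    passed = (hi + config.floor) / (lo + config.floor) >= config.fold_threshold
    half = lo + 0.5 * (hi - lo)
    onset = (x >= half[:, None]).argmax(axis=1)
    group_of_stage = np.asarray([_PHASE_TO_GROUP[p] for p in dataset.phases], dtype=object)
    groups = np.where(passed, group_of_stage[onset], NONE_GROUP)
    return pd.Series(groups, index=dataset.genes, name=dataset.name)


def group_ballot(assignments, config: StageConfig | None = None) -> str:
    """Aggregate per-dataset group votes; NONE is an explicit vote.

    A group in {MI, ME, PM} wins with at least ``min_votes`` supporters;
    among such groups the highest vote count wins, ties resolving to the
    earlier phase (MI < ME < PM).  Otherwise the gene stays NONE.
    """
    config = config or StageConfig()
    votes = list(assignments)
    if len(votes) < config.min_votes:
        raise ValueError(
            f"need at least {config.min_votes} voters, got {len(votes)}"
        )
    for v in votes:
        if v not in GROUPS and v != NONE_GROUP:
            raise ValueError(f"unknown stage group {v!r}")
    counts = Counter(v for v in votes if v != NONE_GROUP)
    eligible = [(g, c) for g, c in counts.items() if c >= config.min_votes]
    if not eligible:
        return NONE_GROUP
    top = max(c for _, c in eligible)
    tied = [g for g, c in eligible if c == top]
    return min(tied, key=_GROUP_ORDER.__getitem__)


def group_ballot_all(
    per_dataset: list[pd.Series], config: StageConfig | None = None
) -> pd.DataFrame:
    """Ballot every gene across datasets.

    Genes missing from a dataset abstain there; a gene assessed by fewer than
    ``min_votes`` datasets cannot reach the support threshold and is NONE.
    Returns one column per dataset plus a ``final`` column.
    """
    config = config or StageConfig()
    if len(per_dataset) < config.min_votes:
        raise ValueError(f"need at least {config.min_votes} datasets")
    frame = pd.concat(per_dataset, axis=1)
    final = []
    for _, row in frame.iterrows():
        votes = [v for v in row if isinstance(v, str)]
        counts = Counter(v for v in votes if v != NONE_GROUP)
        eligible = [(g, c) for g, c in counts.items() if c >= config.min_votes]
        if not eligible:
            final.append(NONE_GROUP)
        else:
            top = max(c for _, c in eligible)
            tied = [g for g, c in eligible if c == top]
            final.append(min(tied, key=_GROUP_ORDER.__getitem__))
    frame["final"] = final
    frame.index.name = "gene_id"
    return frame


def stage_cross_tab(groups: pd.Series, ratings, tissue: str) -> pd.DataFrame:
    """Stage group × testis-expression-level contingency table with totals.

    ``groups`` holds final per-gene MI/ME/PM/NONE labels; ``ratings`` is a
    :class:`~e3miner.tissue_rating.RatingMatrix`.  Only grouped genes and the
    expressed levels (SP, MS, HP, P) are tabulated.
    """
    levels = ratings.final[tissue]
    columns = ["SP", "MS", "HP", "P"]
    table = pd.DataFrame(0, index=list(GROUPS), columns=columns)
    for gene, group in groups.items():
        if group == NONE_GROUP:
            continue
        level = levels.get(gene)
        if level in columns:
            table.loc[group, level] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table
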