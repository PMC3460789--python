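"""Ground-truth synthetic inputs for every pipeline stage.

The generators emulate the study conditions the pipeline was built for —
multi-tissue microarray voters with MAS5-style P/A calls plus a UniGene-like
EST count voter, spermatogenesis time courses, and toy domain-search /
ortholog-group fixtures — each with planted labels so that downstream
recovery is measurable.

Tissue panels
-------------
Expression is generated on log2 scale and exponentiated to MAS5-like
intensities.  Each gene receives a planted specificity class at the target
tissue (default "testis"):

* ``A``  — low intensity everywhere, called Absent;
* ``P``  — flat baseline, z ≈ 0 everywhere;
* ``HP`` — target tissue elevated so its z lands midway in [z1, z2);
* ``MS`` — target elevated so its z lands midway in [z2, z3);
* ``SP`` — one-hot elevation of the target tissue (z = (n−1)/√n).

Because the z-score of a profile depends only on its *shape*, equal
elevation of k tissues pins the z at sqrt((n−k)(n−1)/(nk)) regardless of the
fold — with 10 tissues that is 2.846 (k=1), 1.897 (k=2), 1.449 (k=3), so no
equal-elevation pattern can reach the MS window at the default tissue count.
HP and MS plants therefore use the target tissue at its configured fold plus
secondary tissues whose height is solved by bisection to put the target
z-score at the mid-point of the desired window; at zero noise the rater then
recovers every planted label exactly (where the tissue count permits it).

All randomness flows from the config seed through one named substream per
dataset, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ARRAY, EST_COUNTS, ExpressionDataset, StageDataset
from .tissue_rating import RatingConfig, max_zscore, zscores

CLASSES = ("A", "P", "HP", "MS", "SP")
STAGE_GROUPS = ("MI", "ME", "PM", "NONE")

DEFAULT_TISSUES = (
    "testis",
    "brain",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "ovary",
    "spleen",
    "thymus",
)

#: ordered spermatogenic cell types with their phases
DEFAULT_STAGES = (
    ("SG-A", "mitotic"),
    ("pacSC", "meiotic"),
    ("rST", "post-meiotic"),
    ("eST", "post-meiotic"),
)

_FIXTURE_DOMAINS = ("zf-C3HC4", "HECT", "U-box")


def apportion(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer class sizes by largest-remainder (Hamilton) apportionment.

    Quotas n·p are floored; leftover units go to the largest fractional
    remainders, ties broken by the key order of ``proportions``.
    """
    keys = list(proportions)
    quotas = {k: n * proportions[k] for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        keys, key=lambda k: (-(quotas[k] - counts[k]), keys.index(k))
    )
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts


@dataclass
class PanelConfig:
    """Conditions for the multi-tissue voter panel.

    Class proportions default to roughly the mix observed for the mouse-testis
    E3 catalogue (about 15% absent, two-thirds present, ~10% highly present,
    rare multi-tissue-specific, ~8% testis-specific).
    """

    n_genes: int = 1000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    target_tissue: str = "testis"
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.15, "P": 0.67, "HP": 0.10, "MS": 0.005, "SP": 0.075}
    )
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 0.25
    sp_fold: float = 16.0
    ms_fold: float = 8.0
    hp_fold: float = 4.0
    absent_level: float = 4.0
    call_threshold: float = 16.0
    call_flip_rate: float = 0.02
    noise_log_sd: float = 0.2
    n_datasets: int = 4
    est_mean_counts: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 tissues")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue names must be unique")
        if self.target_tissue not in self.tissues:
            raise ValueError(f"target tissue {self.target_tissue!r} not in panel")
        if set(self.class_proportions) - set(CLASSES):
            raise ValueError("class proportions keyed outside A/P/HP/MS/SP")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.sp_fold < 8:
            raise ValueError("sp_fold must be >= 8")
        for name in ("ms_fold", "hp_fold", "baseline_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.call_flip_rate <= 1:
            raise ValueError("call_flip_rate must lie in [0, 1]")
        if self.noise_log_sd < 0:
            raise ValueError("noise_log_sd must be non-negative")
        if self.n_datasets < 1:
            raise ValueError("need at least one array dataset")


@dataclass
class CourseConfig:
    """Conditions for the spermatogenesis time-course voters."""

    n_genes: int = 2000
    stages: tuple[tuple[str, str], ...] = DEFAULT_STAGES
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {"MI": 0.12, "ME": 0.14, "PM": 0.04, "NONE": 0.70}
    )
    onset_fold: float = 10.0
    base_level: float = 100.0
    noise_log_sd: float = 0.2
    n_datasets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")
        phases = [p for _, p in self.stages]
        order = {"mitotic": 0, "meiotic": 1, "post-meiotic": 2}
        for p in phases:
            if p not in order:
                raise ValueError(f"unknown phase {p!r}")
        ranks = [order[p] for p in phases]
        if any(a > b for a, b in zip(ranks, ranks[1:])):
            raise ValueError("phases must be ordered mitotic <= meiotic <= post-meiotic")
        if set(self.group_proportions) - set(STAGE_GROUPS):
            raise ValueError("group proportions keyed outside MI/ME/PM/NONE")
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if self.onset_fold < 3:
            raise ValueError(
                "onset_fold must be >= 3 (planted onsets must pass the 3-fold filter)"
            )
        needed = {"MI": "mitotic", "ME": "meiotic", "PM": "post-meiotic"}
        for grp, phase in needed.items():
            if self.group_proportions.get(grp, 0) > 0 and phase not in phases:
                raise ValueError(f"group {grp} planted but no {phase} stage present")
        if self.noise_log_sd < 0 or self.base_level <= 0 or self.n_datasets < 1:
            raise ValueError("invalid noise/base level/dataset count")


@dataclass
class TruthLabels:
    """Planted ground truth, one label per gene per truth axis."""

    specificity: dict[str, str] | None = None
    target_tissue: str | None = None
    stage_group: dict[str, str] | None = None
    family: dict[str, str] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for axis, mapping in (
            ("specificity", self.specificity),
            ("stage_group", self.stage_group),
            ("family", self.family),
        ):
            if mapping:
                rows += [(g, axis, lab) for g, lab in sorted(mapping.items())]
        return pd.DataFrame(rows, columns=["gene_id", "axis", "label"])


def _solve_window_pattern(
    n: int, target_fold: float, target_z: float
) -> tuple[int, float]:
    """Secondary-tissue count k and height a placing the target z at ``target_z``.

    The pattern is [target_fold, a×k, 1×(n−1−k)].  At a→1 it is one-hot
    (z = (n−1)/√n, above any window); raising a toward target_fold lowers the
    target z continuously, so the smallest k whose equal-height endpoint
    undershoots ``target_z`` brackets a bisection root.
    """

    def z_target(a: float, k: int) -> float:
        x = np.concatenate([[target_fold], np.full(k, a), np.ones(n - 1 - k)])
        return zscores(x)[0]

    for k in range(1, n - 1):
        if z_target(target_fold, k) < target_z:
            lo, hi = 1.0, target_fold
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if z_target(mid, k) > target_z:
                    lo = mid
                else:
                    hi = mid
            return k, 0.5 * (lo + hi)
    raise ValueError(
        f"no secondary pattern reaches z = {target_z:.3f} with {n} tissues"
    )


def _planted_patterns(config: PanelConfig, rating: RatingConfig) -> dict[str, dict]:
    """Per-class fold templates (relative to the gene baseline)."""
    n = len(config.tissues)
    out: dict[str, dict] = {
        "A": {"kind": "absent"},
        "P": {"kind": "flat"},
        "SP": {"kind": "pattern", "target": config.sp_fold, "k": 0, "secondary": 1.0},
    }
    hp_mid = 0.5 * (rating.z1 + rating.z2)
    ms_mid = 0.5 * (rating.z2 + rating.z3)
    k, a = _solve_window_pattern(n, config.hp_fold, hp_mid)
    out["HP"] = {"kind": "pattern", "target": config.hp_fold, "k": k, "secondary": a}
    k, a = _solve_window_pattern(n, config.ms_fold, ms_mid)
    out["MS"] = {"kind": "pattern", "target": config.ms_fold, "k": k, "secondary": a}
    return out


def _assign_classes(config: PanelConfig) -> tuple[list[str], dict[str, str]]:
    counts = apportion(config.n_genes, config.class_proportions)
    genes = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    labels: dict[str, str] = {}
    i = 0
    for cls in config.class_proportions:
        for _ in range(counts[cls]):
            labels[genes[i]] = cls
            i += 1
    return genes, labels


def _fold_matrix(
    config: PanelConfig, genes: list[str], labels: dict[str, str], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free fold template per gene × tissue plus the absent-gene mask."""
    rating = RatingConfig()
    patterns = _planted_patterns(config, rating)
    tissues = list(config.tissues)
    t_idx = tissues.index(config.target_tissue)
    others = [i for i in range(len(tissues)) if i != t_idx]

    folds = np.ones((len(genes), len(tissues)))
    absent = np.zeros(len(genes), dtype=bool)
    for gi, gene in enumerate(genes):
        spec = patterns[labels[gene]]
        if spec["kind"] == "absent":
            absent[gi] = True
        elif spec["kind"] == "pattern":
            folds[gi, t_idx] = spec["target"]
            if spec["k"]:
                partners = rng.choice(others, size=spec["k"], replace=False)
                folds[gi, partners] = spec["secondary"]
    return folds, absent


def generate_tissue_panel(
    config: PanelConfig | None = None,
) -> tuple[list[ExpressionDataset], TruthLabels]:
    """Generate ``n_datasets`` array voters sharing one planted truth.

    All voters share gene ids, planted patterns and per-gene baselines; noise
    and call flips are drawn independently per voter.
    """
    config = config or PanelConfig()
    truth_rng = np.random.default_rng([config.seed, 0])
    genes, labels = _assign_classes(config)
    folds, absent = _fold_matrix(config, genes, labels, truth_rng)
    baselines = 2.0 ** (
        config.baseline_log_mean
        + truth_rng.normal(0.0, config.baseline_log_sd, size=len(genes))
    )
    clean = folds * baselines[:, None]
    clean[absent] = config.absent_level

    datasets = []
    for d in range(config.n_datasets):
        rng = np.random.default_rng([config.seed, 1 + d])
        noise = 2.0 ** rng.normal(0.0, config.noise_log_sd, size=clean.shape)
        values = clean * noise
        calls = np.where(values >= config.call_threshold, "P", "A").astype(object)
        calls[absent] = "A"  # planted absents are absent regardless of jitter
        if config.call_flip_rate > 0:
            flip = rng.random(size=values.shape) < config.call_flip_rate
            calls[flip] = np.where(calls[flip] == "P", "A", "P")
        index = pd.Index(genes, name="gene_id")
        datasets.append(
            ExpressionDataset(
                name=f"array{d + 1}",
                values=pd.DataFrame(values, index=index, columns=list(config.tissues)),
                calls=pd.DataFrame(calls, index=index, columns=list(config.tissues)),
                kind=ARRAY,
            )
        )
    truth = TruthLabels(specificity=labels, target_tissue=config.target_tissue)
    return datasets, truth


def generate_est_voter(config: PanelConfig | None = None) -> ExpressionDataset:
    """Generate the EST-count voter: Poisson counts, no P/A calls.

    Rates are proportional to the same planted fold patterns as the array
    voters (zero for planted-absent genes), scaled to ``est_mean_counts``
    transcripts per gene.
    """
    config = config or PanelConfig()
    truth_rng = np.random.default_rng([config.seed, 0])
    genes, labels = _assign_classes(config)
    folds, absent = _fold_matrix(config, genes, labels, truth_rng)
    if len(genes):
        rates = folds / folds.sum(axis=1, keepdims=True) * config.est_mean_counts
        rates[absent] = 0.0
    else:
        rates = folds
    rng = np.random.default_rng([config.seed, 1000])
    counts = rng.poisson(rates)
    return ExpressionDataset(
        name="est",
        values=pd.DataFrame(
            counts, index=pd.Index(genes, name="gene_id"), columns=list(config.tissues)
        ),
        kind=EST_COUNTS,
    )


def generate_full_panel(
    config: PanelConfig | None = None,
) -> tuple[list[ExpressionDataset], TruthLabels]:
    """Array voters plus the EST voter — the five-voter study condition."""
    config = config or PanelConfig()
    datasets, truth = generate_tissue_panel(config)
    datasets.append(generate_est_voter(config))
    return datasets, truth


def attainable_classes(n_tissues: int, rating: RatingConfig | None = None) -> set[str]:
    """Planted classes the rater can recover given the tissue count.

    SP needs the one-hot bound (n−1)/√n to reach z3; below that the most a
    one-hot profile can score is MS.
    """
    rating = rating or RatingConfig()
    out = {"A", "P", "HP", "MS"}
    if max_zscore(n_tissues, rating.sd_mode) >= rating.z3:
        out.add("SP")
    return out


def generate_stage_course(
    config: CourseConfig | None = None,
) -> tuple[list[StageDataset], TruthLabels]:
    """Generate developmental time-course voters with planted MI/ME/PM/NONE.

    MI genes are high from the first mitotic stage and decline afterwards;
    ME (PM) genes sit at baseline and rise ``onset_fold``-fold at the first
    meiotic (post-meiotic) stage; NONE genes are flat apart from noise.
    """
    config = config or CourseConfig()
    phases = [p for _, p in config.stages]
    stage_names = [s for s, _ in config.stages]
    counts = apportion(config.n_genes, config.group_proportions)
    genes = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    labels: dict[str, str] = {}
    i = 0
    for grp in config.group_proportions:
        for _ in range(counts[grp]):
            labels[genes[i]] = grp
            i += 1

    onset_of_group = {
        "MI": None,  # high at mitotic stages, low after
        "ME": phases.index("meiotic") if "meiotic" in phases else None,
        "PM": phases.index("post-meiotic") if "post-meiotic" in phases else None,
    }
    clean = np.ones((len(genes), len(phases)))
    for gi, gene in enumerate(genes):
        grp = labels[gene]
        if grp == "MI":
            clean[gi, [p == "mitotic" for p in phases]] = config.onset_fold
        elif grp in ("ME", "PM"):
            clean[gi, onset_of_group[grp] :] = config.onset_fold
    clean *= config.base_level

    datasets = []
    for d in range(config.n_datasets):
        rng = np.random.default_rng([config.seed, 2000 + d])
        noise = 2.0 ** rng.normal(0.0, config.noise_log_sd, size=clean.shape)
        datasets.append(
            StageDataset(
                name=f"course{d + 1}",
                values=pd.DataFrame(
                    clean * noise,
                    index=pd.Index(genes, name="gene_id"),
                    columns=stage_names,
                ),
                phases=list(phases),
            )
        )
    return datasets, TruthLabels(stage_group=labels)


_DOMTBL_HEADER = (
    "#                                                               --- full sequence ---"
    " -------------- this domain -------------   hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target\n"
    "#------------------- ---------- ----- -------------------- ---------- -----"
    " --------- ------ ----- --- --- --------- --------- ------ ----- ----- -----"
    " ----- ----- ----- ----- ---- ---------------------\n"
)


def write_domtblout(
    records: list[tuple[str, str, float]], path: str | Path, length: int = 60
) -> Path:
    """Write one well-formed domtblout line per (protein, domain, E-value)."""
    path = Path(path)
    with open(path, "w") as out:
        out.write(_DOMTBL_HEADER)
        for protein, domain, evalue in records:
            fields = [
                protein, "-", "400", domain, "PF00000.1", str(length),
                f"{evalue:.2g}", "55.0", "0.1", "1", "1",
                f"{evalue:.2g}", f"{evalue:.2g}", "54.0", "0.1",
                "1", str(length), "10", str(9 + length), "8", str(11 + length),
                "0.95", "synthetic fixture",
            ]
            out.write(" ".join(fields) + "\n")
        out.write("#\n# Program:         hmmsearch\n")
    return path


def write_domain_fixture(
    families: dict[str, str],
    path: str | Path,
    evalues: dict[str, float] | None = None,
    default_evalue: float = 1e-8,
) -> Path:
    """Write a domtblout fixture with one hit per gene (protein id = gene id).

    ``families`` maps gene → planted domain name (zf-C3HC4, HECT or U-box);
    unknown names are rejected.  The file round-trips through
    :func:`e3miner.domain_mining.parse_domtblout` with an identity
    protein→gene map.
    """
    for gene, domain in families.items():
        if domain not in _FIXTURE_DOMAINS:
            raise ValueError(f"unknown family domain {domain!r} for gene {gene!r}")
    evalues = evalues or {}
    records = [
        (gene, domain, evalues.get(gene, default_evalue))
        for gene, domain in sorted(families.items())
    ]
    return write_domtblout(records, path)


def write_homology_fixture(
    groups: list[tuple[str, dict[str, list[str]]]], path: str | Path
) -> Path:
    """Write a 4-column ortholog-group table (group, taxon, gene, symbol)."""
    seen: set[tuple[str, str, str]] = set()
    path = Path(path)
    with open(path, "w") as out:
        out.write("# group_id\ttaxon_id\tgene_id\tgene_symbol\n")
        for group_id, members in groups:
            for taxon, gene_ids in members.items():
                for gene in gene_ids:
                    row = (group_id, taxon, gene)
                    if row in seen:
                        raise ValueError(f"duplicate row {row}")
                    seen.add(row)
                    out.write(f"{group_id}\t{taxon}\t{gene}\t{gene}\n")
    return path


def make_e3_homology_example() -> tuple[
    list[tuple[str, dict[str, list[str]]]], set[str], set[str], tuple[str, str]
]:
    """Planted two-species E3 homology structure: 398 + 411 genes, 335 shared.

    Returns (groups, mouse gene set, human gene set, (mouse taxon, human
    taxon)).  The union spans 474 ortholog positions, so the shared fraction
    is 335/474 = 70.7%.
    """
    mouse_taxon, human_taxon = "10090", "9606"
    groups: list[tuple[str, dict[str, list[str]]]] = []
    mouse, human = [], []
    for i in range(1, 336):
        m, h = f"MmE3_{i:03d}", f"HsE3_{i:03d}"
        mouse.append(m)
        human.append(h)
        groups.append((f"shared{i:03d}", {mouse_taxon: [m], human_taxon: [h]}))
    for i in range(1, 64):
        m = f"MmOnly_{i:03d}"
        mouse.append(m)
        groups.append((f"mouse{i:03d}", {mouse_taxon: [m]}))
    for i in range(1, 77):
        h = f"HsOnly_{i:03d}"
        human.append(h)
        groups.append((f"human{i:03d}", {human_taxon: [h]}))
    return groups, set(mouse), set(human), (mouse_taxon, human_taxon)
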