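"""Synthetic cohorts, interaction databases, PPI edges, gene sets and
time courses with planted ground truth.

Every downstream stage of the pipeline — the moderated-t screen, the
evidence-count filter, sign-consistent triple assembly, hub ranking,
over-representation and soft time-course clustering — is verifiable against
the truth objects planted here, without any external download.

The generative model is deliberately simple: Gaussian noise on the log2
scale around per-feature baselines, a location shift of ``effect_size`` for
planted differentially expressed (DE) features, interaction databases that
contain each true miRNA-mRNA pair independently with probability
``db_coverage`` plus Poisson-distributed decoy pairs, and three-timepoint
trend shapes of unit amplitude. Probe-level artifacts, batch effects and
sequence-based targeting are out of scope.

Randomness: one global seed drives independent named substreams (one per
generator), so adding or re-running one generator never perturbs another's
draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "TrueDEFeature",
    "TREND_CLASSES",
    "generate_truth",
    "generate_cohort",
    "generate_interaction_dbs",
    "generate_timecourse",
    "generate_ppi",
    "generate_genesets",
]

TREND_CLASSES = ("rise-fall", "fall-rise", "up", "down", "flat")

# fixed substream keys: adding a generator must not shift another's stream
_STREAM_TRUTH = 0
_STREAM_COHORT = 1
_STREAM_DBS = 2
_STREAM_TIMECOURSE = 3
_STREAM_PPI = 4
_STREAM_GENESETS = 5

#: shape of each trend class at unit amplitude over (0 h, 3 h, 20 h)
_TREND_SHAPES = {
    "up": (0.0, 0.5, 1.0),
    "down": (1.0, 0.5, 0.0),
    "rise-fall": (0.0, 1.0, 0.0),
    "fall-rise": (1.0, 0.0, 1.0),
    "flat": (0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study's default shapes.

    Cohort sizes default to 10 vs 10 (a small case/control cohort); the
    bundle writer additionally emits a 3-vs-3 replicate cohort. The
    time-course defaults to three timepoints with 31/31/34 samples,
    matching an unequal monocyte-to-macrophage differentiation design.
    """

    n_case: int = 10
    n_control: int = 10
    n_lnc: int = 300
    n_mir: int = 100
    n_mrna: int = 600
    frac_de: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_triples: int = 10
    n_databases: int = 5
    db_coverage: float = 0.9
    db_noise: float = 50.0
    n_timepoints: int = 3
    samples_per_timepoint: tuple[int, ...] = (31, 31, 34)
    timepoint_labels: tuple[str, ...] = ("0h", "3h", "20h")
    n_trend_genes: int = 250
    trend_amplitude: float = 1.0
    flat_noise_sd: float = 0.02
    ppi_edge_prob: float = 0.05
    n_gene_sets: int = 50
    gene_set_size: int = 25
    n_enriched_sets: int = 3
    enrichment_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_lnc", "n_mir", "n_mrna",
                     "n_databases", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_de", "db_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_triples < 0:
            raise ValueError("n_triples must be >= 0")
        if self.n_triples > min(self.n_lnc, self.n_mir, self.n_mrna):
            raise ValueError("n_triples exceeds the smallest feature pool")
        if self.n_timepoints != 3:
            raise ValueError("the time-course design is fixed at 3 timepoints")
        if len(self.samples_per_timepoint) != self.n_timepoints:
            raise ValueError("need one sample count per timepoint")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True, order=True)
class TrueDEFeature:
    feature: str
    feature_class: str
    direction: str  # up | down
    log2fc: float


@dataclass
class SyntheticTruth:
    """Planted ground truth shared by all generators.

    ``de_features`` maps feature id to its planted effect; ``triples`` are
    the planted (lncRNA, miRNA, mRNA) ceRNA triples, whose members are
    always DE with the lncRNA and mRNA sharing a direction opposite to the
    miRNA's; ``trend_class`` partitions the time-course genes;
    ``enriched_sets`` names the gene sets planted to overlap the query.
    """

    de_features: dict[str, TrueDEFeature] = field(default_factory=dict)
    triples: list[tuple[str, str, str]] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)
    trend_class: dict[str, str] = field(default_factory=dict)

    def de_by_class(self, feature_class: str) -> dict[str, TrueDEFeature]:
        return {
            f: r
            for f, r in self.de_features.items()
            if r.feature_class == feature_class
        }

    def check_consistency(self) -> None:
        """Assert the planted sign rule on every triple."""
        for lnc, mir, mrna in self.triples:
            dl = self.de_features[lnc].direction
            dm = self.de_features[mir].direction
            dg = self.de_features[mrna].direction
            if not (dl == dg and dl != dm):
                raise AssertionError(
                    f"triple ({lnc}, {mir}, {mrna}) violates the sign rule"
                )
        if self.trend_class:
            bad = set(self.trend_class.values()) - set(TREND_CLASSES)
            if bad:
                raise AssertionError(f"unknown trend classes: {bad}")


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


_CLASS_PREFIX = {"lncRNA": "LNC", "miRNA": "MIR", "mRNA": "MRNA"}
_CLASS_SIZES = {"lncRNA": "n_lnc", "miRNA": "n_mir", "mRNA": "n_mrna"}


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Plant DE features of all three RNA classes and sign-consistent triples.

    Triple members are pairwise disjoint across triples (each planted triple
    uses its own lncRNA, miRNA and mRNA) and are drawn from each class's DE
    budget ``round(frac_de * n_class)``.

    Raises
    ------
    ValueError
        If ``n_triples`` exceeds any class's DE budget — there would not be
        enough DE features of the required directions to host the triples.
    """
    rng = _rng(config, _STREAM_TRUTH)
    truth = SyntheticTruth()
    ids = {
        cls: _feature_ids(_CLASS_PREFIX[cls], getattr(config, _CLASS_SIZES[cls]))
        for cls in _CLASS_PREFIX
    }
    de_sets: dict[str, list[str]] = {}
    for cls in ("lncRNA", "miRNA", "mRNA"):
        pool = ids[cls]
        n_de = int(round(config.frac_de * len(pool)))
        if config.n_triples > n_de:
            raise ValueError(
                f"n_triples={config.n_triples} exceeds the {cls} DE budget "
                f"({n_de} = round(frac_de * {len(pool)}))"
            )
        chosen = sorted(rng.choice(len(pool), size=n_de, replace=False))
        de_sets[cls] = [pool[i] for i in chosen]

    # triples occupy the head of each class's shuffled DE list
    triple_members = {}
    for cls in ("lncRNA", "miRNA", "mRNA"):
        order = rng.permutation(len(de_sets[cls]))
        triple_members[cls] = [de_sets[cls][i] for i in order[: config.n_triples]]

    directions: dict[str, str] = {}
    for t in range(config.n_triples):
        mir_up = bool(rng.integers(0, 2))
        lnc, mir, mrna = (
            triple_members["lncRNA"][t],
            triple_members["miRNA"][t],
            triple_members["mRNA"][t],
        )
        directions[mir] = "up" if mir_up else "down"
        directions[lnc] = directions[mrna] = "down" if mir_up else "up"
        truth.triples.append((lnc, mir, mrna))
    truth.triples.sort()

    for cls in ("lncRNA", "miRNA", "mRNA"):
        for f in de_sets[cls]:
            d = directions.get(f) or ("up" if rng.integers(0, 2) else "down")
            lfc = config.effect_size if d == "up" else -config.effect_size
            truth.de_features[f] = TrueDEFeature(f, cls, d, lfc)
    truth.check_consistency()
    return truth


def generate_cohort(
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
    n_case: int | None = None,
    n_control: int | None = None,
    cohort: int = 0,
) -> tuple[dict[str, ExpressionMatrix], SyntheticTruth]:
    """Simulate one case/control cohort per RNA class.

    Control samples are drawn around a per-feature baseline
    ``N(baseline_mean, baseline_sd)``; case samples of a planted DE feature
    are shifted by its true log2FC. All within-group noise is
    ``N(0, noise_sd)`` on the log2 scale. Passing the same ``truth`` with a
    different ``cohort`` index yields an independent replicate cohort with
    the same planted effects (emulating a second dataset measuring the same
    biology).
    """
    if truth is None:
        truth = generate_truth(config)
    n_case = config.n_case if n_case is None else n_case
    n_control = config.n_control if n_control is None else n_control
    rng = _rng(config, _STREAM_COHORT, cohort)
    out: dict[str, ExpressionMatrix] = {}
    samples = [f"c{cohort}_case{i + 1}" for i in range(n_case)] + [
        f"c{cohort}_ctrl{i + 1}" for i in range(n_control)
    ]
    meta = pd.DataFrame(
        {"group": ["CAD"] * n_case + ["control"] * n_control},
        index=pd.Index(samples, name="sample"),
    )
    for cls in ("lncRNA", "miRNA", "mRNA"):
        ids = _feature_ids(_CLASS_PREFIX[cls], getattr(config, _CLASS_SIZES[cls]))
        base = rng.normal(config.baseline_mean, config.baseline_sd, len(ids))
        shift = np.zeros(len(ids))
        for i, f in enumerate(ids):
            rec = truth.de_features.get(f)
            if rec is not None:
                shift[i] = rec.log2fc
        vals = base[:, None] + rng.normal(
            0.0, config.noise_sd, (len(ids), n_case + n_control)
        )
        vals[:, :n_case] += shift[:, None]
        out[cls] = ExpressionMatrix(
            pd.DataFrame(vals, index=pd.Index(ids, name="feature"),
                         columns=samples),
            meta,
        )
    return out, truth


def _decoy_pairs(
    rng: np.random.Generator,
    regulators: list[str],
    targets: list[str],
    forbidden: set[tuple[str, str]],
    n_expected: float,
) -> list[tuple[str, str]]:
    """Poisson(n_expected) unique decoy pairs avoiding the forbidden set."""
    n = int(rng.poisson(n_expected)) if n_expected > 0 else 0
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    guard = 0
    while len(out) < n and guard < 50 * (n + 1):
        guard += 1
        pair = (
            regulators[int(rng.integers(len(regulators)))],
            targets[int(rng.integers(len(targets)))],
        )
        if pair in forbidden or pair in seen:
            continue
        seen.add(pair)
        out.append(pair)
    return out


def generate_interaction_dbs(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate miRNA-target evidence tables.

    Returns ``(mir_mrna, lnc_mir)`` long-form tables with columns
    ``mirna, target, database``. Each true miRNA-mRNA pair (from the planted
    triples) enters each of the ``n_databases`` tables independently with
    probability ``db_coverage``; each table additionally carries
    ``Poisson(db_noise)`` decoy pairs. The single miRNA-lncRNA table
    contains every true pair plus decoys — mirroring a design where the
    lncRNA edge type has exactly one evidence source.
    """
    rng = _rng(config, _STREAM_DBS)
    mirs = _feature_ids("MIR", config.n_mir)
    mrnas = _feature_ids("MRNA", config.n_mrna)
    lncs = _feature_ids("LNC", config.n_lnc)
    true_mm = sorted({(m, g) for (_, m, g) in truth.triples})
    true_ml = sorted({(m, l) for (l, m, _) in truth.triples})

    rows = []
    for d in range(config.n_databases):
        db = f"DB{d + 1}"
        present = rng.random(len(true_mm)) < config.db_coverage
        for (m, g), keep in zip(true_mm, present):
            if keep:
                rows.append((m, g, db))
        for m, g in _decoy_pairs(rng, mirs, mrnas, set(true_mm), config.db_noise):
            rows.append((m, g, db))
    mir_mrna = pd.DataFrame(rows, columns=["mirna", "target", "database"])

    rows = [(m, l, "LNCDB") for m, l in true_ml]
    rows += [
        (m, l, "LNCDB")
        for m, l in _decoy_pairs(rng, mirs, lncs, set(true_ml), config.db_noise)
    ]
    lnc_mir = pd.DataFrame(rows, columns=["mirna", "target", "database"])
    return mir_mrna, lnc_mir


def generate_timecourse(
    config: SimulationConfig, truth: SyntheticTruth | None = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the three-timepoint differentiation series over mRNA genes.

    ``n_trend_genes`` genes are split evenly across the four non-flat trend
    classes and follow their class's centroid shape at ``trend_amplitude``;
    all remaining genes are flat. Flat genes carry only a small technical
    noise (``flat_noise_sd``) so that the standard deviation of their
    per-timepoint means stays below the usual 0.05 screening threshold —
    they are removable by the SD filter, which is exactly the behaviour the
    filter exists to exploit.
    """
    if truth is None:
        truth = SyntheticTruth()
    rng = _rng(config, _STREAM_TIMECOURSE)
    genes = _feature_ids("MRNA", config.n_mrna)
    if config.n_trend_genes > len(genes):
        raise ValueError("n_trend_genes exceeds the mRNA pool")
    nonflat = [c for c in TREND_CLASSES if c != "flat"]
    chosen = rng.choice(len(genes), size=config.n_trend_genes, replace=False)
    classes = dict.fromkeys(genes, "flat")
    for i, gi in enumerate(sorted(chosen)):
        classes[genes[gi]] = nonflat[i % len(nonflat)]
    truth.trend_class = classes

    labels = list(config.timepoint_labels)
    counts = list(config.samples_per_timepoint)
    sample_ids, tp_of_sample = [], []
    for lab, n in zip(labels, counts):
        for i in range(n):
            sample_ids.append(f"{lab}_s{i + 1}")
            tp_of_sample.append(lab)
    meta = pd.DataFrame(
        {"group": "timecourse", "timepoint": tp_of_sample},
        index=pd.Index(sample_ids, name="sample"),
    )

    base = rng.normal(config.baseline_mean, config.baseline_sd, len(genes))
    vals = np.empty((len(genes), len(sample_ids)))
    col = 0
    for t, n in enumerate(counts):
        shape_t = np.array(
            [_TREND_SHAPES[classes[g]][t] for g in genes]
        ) * config.trend_amplitude
        sd = np.array(
            [
                config.flat_noise_sd if classes[g] == "flat" else config.noise_sd
                for g in genes
            ]
        )
        vals[:, col : col + n] = (
            base[:, None]
            + shape_t[:, None]
            + rng.normal(0.0, 1.0, (len(genes), n)) * sd[:, None]
        )
        col += n
    em = ExpressionMatrix(
        pd.DataFrame(vals, index=pd.Index(genes, name="feature"),
                     columns=sample_ids),
        meta,
    )
    return em, truth


def generate_ppi(
    genes: list[str], config: SimulationConfig
) -> pd.DataFrame:
    """Random scored protein-interaction table over the given genes.

    Each unordered pair is an edge independently with probability
    ``ppi_edge_prob``; combined scores are uniform on [0, 1]. No self-edges,
    each pair at most once.
    """
    rng = _rng(config, _STREAM_PPI)
    genes = sorted(genes)
    n = len(genes)
    if n < 2:
        return pd.DataFrame(columns=["protein1", "protein2", "combined_score"])
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < config.ppi_edge_prob
    a = np.asarray(genes)[iu[0][mask]]
    b = np.asarray(genes)[iu[1][mask]]
    scores = rng.random(mask.sum())
    return pd.DataFrame(
        {"protein1": a, "protein2": b, "combined_score": scores}
    )


def generate_genesets(
    genes: list[str],
    config: SimulationConfig,
    query: list[str],
    truth: SyntheticTruth | None = None,
):
    """Gene-set collection with sets planted to over-represent the query.

    Background sets are uniform draws from the universe. Each of the
    ``n_enriched_sets`` planted sets draws each member from the query list
    with probability ``enrichment_factor * |query| / |universe|`` (capped at
    1), so its expected query overlap is ``enrichment_factor`` times the
    hypergeometric expectation ``K * n / N``.
    """
    from .enrichment import GeneSetCollection  # local import, avoids a cycle

    if truth is None:
        truth = SyntheticTruth()
    rng = _rng(config, _STREAM_GENESETS)
    universe = sorted(genes)
    query = sorted(set(query) & set(universe))
    non_query = sorted(set(universe) - set(query))
    k = min(config.gene_set_size, len(universe))
    p_q = min(1.0, config.enrichment_factor * len(query) / len(universe))

    sets: dict[str, list[str]] = {}
    for i in range(config.n_enriched_sets):
        name = f"SET_ENR{i + 1:02d}"
        n_from_query = int(rng.binomial(k, p_q)) if query else 0
        n_from_query = min(n_from_query, len(query), k)
        members = list(
            rng.choice(query, size=n_from_query, replace=False)
        ) + list(
            rng.choice(
                non_query, size=min(k - n_from_query, len(non_query)),
                replace=False,
            )
        )
        sets[name] = sorted(members)
        truth.enriched_sets.append(name)
    for i in range(config.n_gene_sets):
        name = f"SET{i + 1:04d}"
        sets[name] = sorted(rng.choice(universe, size=k, replace=False))
    coll = GeneSetCollection.from_dict(sets, universe=universe)
    return coll, truth
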