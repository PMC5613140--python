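"""Synthetic expression data with planted operon structure.

The generator emulates a multi-condition bacterial expression study: a
circular genome of a few hundred genes, a share of which are organized in
co-transcribed operon blocks of 2-17 genes, profiled across 7 carbon-source
conditions in triplicate (21 samples) on a log2 intensity scale, with
background/random probe rows for expression-detection calls.

Model: every transcription unit u (an operon block or a singleton gene)
draws an independent condition mean mu_{u,c} ~ Normal(mu0, tau^2); gene g
in unit u has a fixed baseline offset b_g ~ Normal(0, baseline_sd^2); the
log2 intensity of gene g in sample s is

    mu_{u, c(s)} + b_g + eps,   eps ~ Normal(0, sigma^2).

A de_frac fraction of units per non-reference condition additionally
receives a fixed up-shift in that condition, giving the differential-
expression machinery true positives. Background rows are pure noise around
mu0 - 3. Everything is drawn from a single seeded stream, so runs are
bit-reproducible.

Genes within an operon share mu_{u,c} and therefore co-vary almost
perfectly across conditions; genes of different units are independent.
Operon sizes follow a geometric distribution truncated to [2, 17]
(success probability 0.5, mean about 3 genes — typical of bacterial
operon annotations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenomeLayout, LayoutElement, SampleDesign
from .errors import DataError

STUDY_CONDITIONS = (
    "glucose", "alginate", "laminarin", "agar",
    "porphyran", "kappa_carrageenan", "iota_carrageenan",
)

GENE_LENGTH = 900
GENE_SPACING = 1000


@dataclass
class SyntheticTruth:
    """Ground truth of a generated instance."""

    operons: list[tuple[str, ...]]
    singletons: list[str]
    background_ids: list[str]
    conditions: list[str]
    reference: str
    unit_means: dict[str, np.ndarray] = field(repr=False)
    de_shifts: dict[tuple[str, str], float]  # (unit key, condition) -> shift
    params: dict = field(repr=False)
    seed: int = 0


def _truncated_geometric_sizes(rng, n: int, p: float, lo: int, hi: int) -> np.ndarray:
    ks = np.arange(lo, hi + 1)
    pmf = (1.0 - p) ** (ks - lo)
    pmf = pmf / pmf.sum()
    return rng.choice(ks, size=n, p=pmf)


def generate(
    n_genes: int = 300,
    n_operons: int = 40,
    n_conditions: int = 7,
    n_reps: int = 3,
    tau: float = 1.5,
    sigma: float = 0.3,
    background_frac: float = 0.05,
    de_frac: float = 0.05,
    mu0: float = 8.0,
    baseline_sd: float = 0.2,
    de_shift: float = 3.0,
    operon_size_p: float = 0.5,
    operon_size_range: tuple[int, int] = (2, 17),
    seed: int = 0,
) -> tuple[ExpressionMatrix, GenomeLayout, SampleDesign, SyntheticTruth]:
    """Generate (matrix, layout, design, truth); see the module docstring.

    The returned matrix is log2-scale and includes
    ``round(background_frac * n_genes)`` background probe rows flagged in
    ``background_ids``.
    """
    if n_genes < 2 or n_operons < 1 or n_conditions < 2 or n_reps < 2:
        raise DataError("need n_genes >= 2, n_operons >= 1, n_conditions >= 2, n_reps >= 2")
    if tau <= 0 or sigma < 0 or not (0 <= de_frac <= 1) or not (0 <= background_frac <= 1):
        raise DataError("invalid noise / fraction parameters")
    rng = np.random.default_rng(seed)

    lo, hi = operon_size_range
    sizes = _truncated_geometric_sizes(rng, n_operons, operon_size_p, lo, hi)
    if sizes.sum() > n_genes:
        raise DataError(
            f"operons require {int(sizes.sum())} genes but n_genes={n_genes}"
        )
    n_singletons = n_genes - int(sizes.sum())

    # genome = shuffled sequence of operon blocks and singleton blocks
    blocks = [("operon", int(s)) for s in sizes] + [("singleton", 1)] * n_singletons
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    width = max(4, len(str(n_genes)))
    gene_ids: list[str] = []
    elements: list[LayoutElement] = []
    operons: list[tuple[str, ...]] = []
    singletons: list[str] = []
    unit_of: dict[str, str] = {}
    gi = 0
    for kind, size in blocks:
        strand = "+" if rng.random() < 0.5 else "-"
        members = []
        for _ in range(size):
            gid = f"ZSYN_{gi + 1:0{width}d}"
            start = gi * GENE_SPACING + 1
            elements.append(LayoutElement(gid, start, start + GENE_LENGTH - 1, strand))
            members.append(gid)
            gene_ids.append(gid)
            gi += 1
        if kind == "operon":
            operons.append(tuple(members))
            ukey = f"operon_{len(operons)}"
        else:
            singletons.append(members[0])
            ukey = f"singleton_{members[0]}"
        for m in members:
            unit_of[m] = ukey
    layout = GenomeLayout(elements, circular=True,
                          genome_length=n_genes * GENE_SPACING, chrom="synthetic_chr")

    if n_conditions <= len(STUDY_CONDITIONS):
        conditions = list(STUDY_CONDITIONS[:n_conditions])
    else:
        conditions = list(STUDY_CONDITIONS) + [
            f"condition_{i}" for i in range(len(STUDY_CONDITIONS) + 1, n_conditions + 1)
        ]
    reference = conditions[0]
    sample_ids = [f"{c}_rep{r + 1}" for c in conditions for r in range(n_reps)]
    design = SampleDesign({s: s.rsplit("_rep", 1)[0] for s in sample_ids}, reference)

    unit_keys = [f"operon_{i + 1}" for i in range(len(operons))] + \
                [f"singleton_{g}" for g in singletons]
    unit_means = {
        u: rng.normal(mu0, tau, size=n_conditions) for u in unit_keys
    }
    baseline = {g: rng.normal(0.0, baseline_sd) for g in gene_ids}

    de_shifts: dict[tuple[str, str], float] = {}
    n_de = int(round(de_frac * len(unit_keys)))
    for c in conditions[1:]:
        chosen = rng.choice(len(unit_keys), size=n_de, replace=False)
        for ui in chosen:
            de_shifts[(unit_keys[int(ui)], c)] = de_shift

    cond_index = {c: i for i, c in enumerate(conditions)}
    values = np.empty((len(gene_ids), len(sample_ids)))
    for i, g in enumerate(gene_ids):
        u = unit_of[g]
        means = unit_means[u]
        for j, s in enumerate(sample_ids):
            c = design.condition_of[s]
            shift = de_shifts.get((u, c), 0.0)
            values[i, j] = means[cond_index[c]] + shift + baseline[g]
    values += rng.normal(0.0, sigma, size=values.shape)

    n_bg = int(round(background_frac * n_genes))
    bg_ids = [f"RANDOM_{i + 1:0{width}d}" for i in range(n_bg)]
    bg_values = rng.normal(mu0 - 3.0, max(sigma, 1e-12), size=(n_bg, len(sample_ids)))

    data = pd.DataFrame(
        np.vstack([values, bg_values]) if n_bg else values,
        index=gene_ids + bg_ids,
        columns=sample_ids,
    )
    matrix = ExpressionMatrix(data, scale="log2", background_ids=frozenset(bg_ids))
    truth = SyntheticTruth(
        operons=operons,
        singletons=singletons,
        background_ids=bg_ids,
        conditions=conditions,
        reference=reference,
        unit_means=unit_means,
        de_shifts=de_shifts,
        params=dict(
            n_genes=n_genes, n_operons=n_operons, n_conditions=n_conditions,
            n_reps=n_reps, tau=tau, sigma=sigma, background_frac=background_frac,
            de_frac=de_frac, mu0=mu0, baseline_sd=baseline_sd, de_shift=de_shift,
            operon_size_p=operon_size_p, operon_size_range=operon_size_range,
        ),
        seed=seed,
    )
    return matrix, layout, design, truth


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float
    n_segments: int
    n_operons: int
    empty_detection: bool = False


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def recovery_metrics(
    segments,
    truth: SyntheticTruth,
    mode: str = "jaccard",
    jaccard_min: float = 0.5,
) -> RecoveryMetrics:
    """Precision / recall / F1 of detected segments against planted operons.

    ``mode="exact"``: a segment matches an operon when their member sets
    are identical. ``mode="jaccard"``: Jaccard index >= ``jaccard_min``.
    Precision is over segments, recall over operons; an empty detection has
    recall 0 and precision defined as 1 with ``empty_detection`` flagged.
    """
    if mode not in ("exact", "jaccard"):
        raise DataError(f"unknown match mode {mode!r}")
    operon_sets = [frozenset(o) for o in truth.operons]
    seg_sets = [frozenset(s.member_ids) for s in segments]

    def matches(seg: frozenset, op: frozenset) -> bool:
        if mode == "exact":
            return seg == op
        return _jaccard(seg, op) >= jaccard_min

    if not seg_sets:
        return RecoveryMetrics(1.0, 0.0, 0.0, 0, len(operon_sets), empty_detection=True)
    tp_seg = sum(1 for s in seg_sets if any(matches(s, o) for o in operon_sets))
    recovered = sum(1 for o in operon_sets if any(matches(s, o) for s in seg_sets))
    precision = tp_seg / len(seg_sets)
    recall = recovered / len(operon_sets) if operon_sets else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return RecoveryMetrics(precision, recall, f1, len(seg_sets), len(operon_sets))
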