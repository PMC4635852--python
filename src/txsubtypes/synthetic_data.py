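"""Synthetic expression cohorts with planted, recoverable ground truth.

The generator emulates a two-subtype case cohort plus controls on a log2
intensity scale: per-gene baselines with additive Gaussian noise, three
planted differential-expression classes (*core* genes shifted in both
subtypes versus control, *unique_a* / *unique_b* genes shifted in one
subtype only), a large null background, and a few outlier samples carrying
a large coherent shift on a random half of the genes (a technically
aberrant specimen, not label noise).  Companion generators build gene-set
collections enriched for each planted class and interaction tables whose
induced modules recover per-class regulators and drugs.

Default cohort sizes (14 + 14 subtype samples, 8 controls, 3 outliers)
match a small biopsy study; every draw is fully determined by the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    Interaction,
    InteractionTable,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "generate_genesets",
    "generate_interactions",
    "simulate_to_dir",
]

GENE_CLASSES = ("core", "unique_a", "unique_b", "null")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Counts are samples/genes; shifts are in units of the per-gene noise sd
    on the log2 scale.  ``baseline_range`` bounds the uniform per-gene
    mean intensity of background genes; planted DE genes draw their
    baseline from the narrower ``de_baseline_range`` so that the default
    expression/CV filter always retains them (high scaled mean, high CV).
    """

    n_genes: int = 2000
    n_per_subtype: int = 14
    n_control: int = 8
    n_outliers: int = 3
    frac_core: float = 0.05
    frac_unique_a: float = 0.03
    frac_unique_b: float = 0.03
    effect_size: float = 2.0
    outlier_shift: float = 6.0
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (4.0, 12.0)
    de_baseline_range: tuple[float, float] = (5.8, 7.0)
    case_group: str = "TCMR"
    control_group: str = "Control"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_per_subtype, self.n_control) <= 0:
            raise ValueError("gene and sample counts must be positive")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")
        fracs = (self.frac_core, self.frac_unique_a, self.frac_unique_b)
        if any(f < 0 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("DE-class fractions must be >= 0 and sum to < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """What was planted: subtype per sample, outliers, and gene classes."""

    subtype: dict[str, str]            # sample id -> "A" | "B" (cases only)
    outliers: list[str]
    gene_class: dict[str, str]         # gene id -> core/unique_a/unique_b/null
    control_samples: list[str] = field(default_factory=list)

    def genes_in_class(self, name: str) -> list[str]:
        if name not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {name!r}")
        return [g for g, c in self.gene_class.items() if c == name]

    @property
    def core_genes(self) -> list[str]:
        return self.genes_in_class("core")

    @property
    def unique_a_genes(self) -> list[str]:
        return self.genes_in_class("unique_a")

    @property
    def unique_b_genes(self) -> list[str]:
        return self.genes_in_class("unique_b")

    @property
    def null_genes(self) -> list[str]:
        return self.genes_in_class("null")

    @property
    def between_subtype_de_genes(self) -> list[str]:
        """Genes whose planted shift differs between the two subtypes."""
        return [g for g, c in self.gene_class.items()
                if c in ("unique_a", "unique_b")]

    def retained_case_samples(self) -> list[str]:
        out = set(self.outliers)
        return [s for s in self.subtype if s not in out]

    def to_json(self) -> str:
        return json.dumps(
            {
                "subtype": self.subtype,
                "outliers": self.outliers,
                "gene_class": self.gene_class,
                "control_samples": self.control_samples,
            },
            indent=2,
        )


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate(config: SyntheticConfig | None = None
             ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic cohort; bit-identical for a fixed config.

    Core genes shift by ``effect_size * noise_sd`` (random sign per gene)
    in both subtypes relative to control; unique genes shift in one
    subtype only.  Shifts are mean-preserving (each planted gene is
    re-centered to its drawn baseline) so that the group contrast never
    drags a gene's overall intensity across the expression filter.
    Outlier samples belong to the case cohort (alternating subtype
    membership) and additionally shift by ``outlier_shift * noise_sd`` on
    a random half of the genes.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n_core = round(config.frac_core * config.n_genes)
    n_ua = round(config.frac_unique_a * config.n_genes)
    n_ub = round(config.frac_unique_b * config.n_genes)
    if n_core + n_ua + n_ub >= config.n_genes:
        raise ValueError("DE-class fractions leave no null genes")
    genes = _gene_ids(config.n_genes)
    classes = (["core"] * n_core + ["unique_a"] * n_ua + ["unique_b"] * n_ub
               + ["null"] * (config.n_genes - n_core - n_ua - n_ub))
    gene_class = dict(zip(genes, classes))
    is_de = np.array([c != "null" for c in classes])

    n_cases = 2 * config.n_per_subtype + config.n_outliers
    case_ids = [f"T{i + 1:02d}" for i in range(n_cases)]
    control_ids = [f"N{i + 1:02d}" for i in range(config.n_control)]
    subtype = {}
    for i, s in enumerate(case_ids[: 2 * config.n_per_subtype]):
        subtype[s] = "A" if i < config.n_per_subtype else "B"
    outliers = case_ids[2 * config.n_per_subtype:]
    for i, s in enumerate(outliers):
        subtype[s] = "A" if i % 2 == 0 else "B"

    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    de_lo, de_hi = config.de_baseline_range
    baseline[is_de] = rng.uniform(de_lo, de_hi, size=int(is_de.sum()))

    sample_ids = case_ids + control_ids
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(sample_ids)))

    sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    shift = config.effect_size * config.noise_sd * sign
    class_arr = np.array(classes)
    mask_a = (class_arr == "core") | (class_arr == "unique_a")
    mask_b = (class_arr == "core") | (class_arr == "unique_b")
    col = {s: j for j, s in enumerate(sample_ids)}
    n_shifted = np.zeros(config.n_genes)
    for s, st in subtype.items():
        mask = mask_a if st == "A" else mask_b
        values[mask, col[s]] += shift[mask]
        n_shifted += mask
    # re-center each planted gene so its overall mean stays at the drawn
    # baseline: the group contrast is unchanged but the expression filter
    # sees the intended mean intensity regardless of shift direction
    values -= (shift * n_shifted / len(sample_ids))[:, None]

    for s in outliers:
        half = rng.choice(config.n_genes, size=config.n_genes // 2,
                          replace=False)
        values[half, col[s]] += config.outlier_shift * config.noise_sd

    groups = {s: config.case_group for s in case_ids}
    groups.update({s: config.control_group for s in control_ids})
    matrix = ExpressionMatrix(genes, sample_ids, values, groups)
    truth = GroundTruth(subtype=subtype, outliers=list(outliers),
                        gene_class=gene_class, control_samples=control_ids)
    return matrix, truth


def generate_genesets(truth: GroundTruth, n_decoy_sets: int = 5,
                      set_size: int = 30, class_fraction: float = 0.8,
                      seed: int = 0) -> GeneSetCollection:
    """One gene set per planted DE class plus decoy sets of null genes.

    Each class set draws ``class_fraction`` (>= 0.8 by default) of its
    members from the planted class and the rest from null genes, so it is
    strongly over-represented in the matching gene list and (having no
    members from the other classes) silent elsewhere.  Decoy sets are
    uniform draws from the null background.
    """
    if not 0.8 <= class_fraction <= 1.0:
        raise ValueError("class_fraction must lie in [0.8, 1.0]")
    rng = np.random.default_rng(seed)
    null_genes = truth.null_genes
    sets: list[GeneSet] = []
    for name in ("core", "unique_a", "unique_b"):
        members = truth.genes_in_class(name)
        n_class = min(len(members), max(1, round(class_fraction * set_size)))
        n_fill = min(len(null_genes), set_size - n_class)
        picked = list(rng.choice(members, size=n_class, replace=False))
        picked += list(rng.choice(null_genes, size=n_fill, replace=False))
        sets.append(GeneSet(f"SET_{name.upper()}",
                            f"planted {name} gene set", frozenset(picked)))
    for i in range(n_decoy_sets):
        n = min(len(null_genes), set_size)
        picked = rng.choice(null_genes, size=n, replace=False)
        sets.append(GeneSet(f"DECOY_{i + 1:02d}", "null decoy set",
                            frozenset(picked)))
    return GeneSetCollection(sets)


def generate_interactions(truth: GroundTruth, density: float = 0.05,
                          seed: int = 0) -> InteractionTable:
    """Random interaction table with per-class structure.

    PPI edges appear within each planted class with probability *density*
    (plus a sparser random background across all genes); one synthetic
    transcription factor per class regulates eight class genes and one
    synthetic drug per class targets five.  PPI confidences are uniform on
    [0.5, 1]; regulator and drug edges are high-confidence (uniform on
    [0.9, 1]) so module induction recovers them at the default floor.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges: list[Interaction] = []
    all_genes = list(truth.gene_class)

    for name in ("core", "unique_a", "unique_b"):
        members = truth.genes_in_class(name)
        iu, ju = np.triu_indices(len(members), k=1)
        picked = rng.random(iu.size) < density
        confidences = rng.uniform(0.5, 1.0, size=int(picked.sum()))
        for a, b, c in zip(iu[picked], ju[picked], confidences):
            edges.append(Interaction(members[a], members[b], "ppi",
                                     confidence=float(c)))
        tag = {"core": "CORE", "unique_a": "A", "unique_b": "B"}[name]
        if members:
            n_reg = min(8, len(members))
            targets = rng.choice(members, size=n_reg, replace=False)
            for t in targets:
                role = "activator" if rng.random() < 0.5 else "repressor"
                edges.append(Interaction(
                    f"TF_{tag}", str(t), "regulatory", role=role,
                    confidence=float(rng.uniform(0.9, 1.0))))
            n_drug = min(5, len(members))
            targets = rng.choice(members, size=n_drug, replace=False)
            for t in targets:
                edges.append(Interaction(
                    f"DRUG_{tag}", str(t), "drug_target",
                    confidence=float(rng.uniform(0.9, 1.0))))

    n_background = int(density * len(all_genes))
    for _ in range(n_background):
        a, b = rng.choice(len(all_genes), size=2, replace=False)
        edges.append(Interaction(all_genes[a], all_genes[b], "ppi",
                                 confidence=float(rng.uniform(0.5, 1.0))))
    return InteractionTable(edges)


def simulate_to_dir(out_dir, config: SyntheticConfig | None = None,
                    n_decoy_sets: int = 5, set_size: int = 30,
                    density: float = 0.05) -> dict[str, str]:
    """Write a full synthetic dataset (expression, groups, truth, gene
    sets, interaction tables) under *out_dir*; returns the path map."""
    from pathlib import Path
    from .io_formats import (write_expression_tsv, write_group_map, write_gmt,
                             write_interactions)

    config = config or SyntheticConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate(config)
    sets = generate_genesets(truth, n_decoy_sets=n_decoy_sets,
                             set_size=set_size, seed=config.seed)
    table = generate_interactions(truth, density=density, seed=config.seed)
    paths = {
        "expr": out / "expr.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.json",
        "gmt": out / "sets.gmt",
        "ppi": out / "ppi.tsv",
        "regulatory": out / "regulatory.tsv",
        "drugs": out / "drugs.tsv",
    }
    write_expression_tsv(matrix, paths["expr"])
    write_group_map(matrix.groups, paths["groups"])
    paths["truth"].write_text(truth.to_json())
    write_gmt(sets, paths["gmt"])
    for kind, key in (("ppi", "ppi"), ("regulatory", "regulatory"),
                      ("drug_target", "drugs")):
        write_interactions(InteractionTable(table.of_kind(kind)), paths[key])
    return {k: str(v) for k, v in paths.items()}
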