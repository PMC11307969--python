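"""Synthetic inputs with the statistical structure the analyses assume.

No patient sequencing data or external reference cohorts (TCGA, CCLE) are
required anywhere in this package: this module generates

* a multi-class reference expression cohort with class-specific signature
  genes and a nested subgroup metadata layer (log-normal expression:
  baseline + signature shifts + Gaussian noise, all on the log2 scale),
* bulk mixtures of cancer / CAF / immune component profiles with known
  Dirichlet-drawn fractions and component-exclusive marker genes,
* MAF-like variant tables with known filter outcomes per record,
* two-arm xenograft growth series and two-group survival records.

Every generator takes an explicit seed and is fully deterministic; each
emitted sample/record is covered by a ground-truth object so downstream
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .deconv import MarkerSet, ProportionsTable
from .expression import ExpressionMatrix
from .knn import ReferenceCohort
from .variants import CANONICAL_COLUMNS

__all__ = [
    "ClassSpec",
    "CohortTruth",
    "MixtureSpec",
    "VariantScenario",
    "GrowthSpec",
    "SurvivalSpec",
    "SimulationConfig",
    "make_reference_cohort",
    "draw_queries",
    "make_bulk_mixtures",
    "fibroblast_markers",
    "macrophage_markers",
    "make_variant_table",
    "make_growth_and_survival",
    "write_fixture_dir",
]


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class ClassSpec:
    """One reference class: label, cohort size, signature block, effect."""

    label: str
    n_samples: int = 20
    n_signature_genes: int = 50
    log2_effect: float = 4.0


@dataclass
class MixtureSpec:
    """Bulk-mixture generator settings.

    ``components`` maps a component label to its Dirichlet concentration;
    larger concentrations give larger, less variable fractions.  Marker
    genes are expressed only in their own component.
    """

    n_samples: int = 40
    components: dict[str, float] = field(
        default_factory=lambda: {
            "uncharacterized": 8.0,
            "CAF": 4.0,
            "T_cell": 1.2,
            "macrophage": 1.2,
            "B_cell": 0.6,
            "endothelial": 0.6,
        }
    )
    n_background_genes: int = 200
    marker_log2_level: float = 8.0  # marker rpkm in its own component
    background_log2_mean: float = 4.0
    noise_sd: float = 0.1  # multiplicative log2-scale noise ("low noise")


@dataclass
class VariantScenario:
    """Record counts per filter category for the variant-table generator."""

    n_pop_filtered: int = 2
    n_whitelist_rescued: int = 1
    n_pdx_recurrent_pairs: int = 1
    n_clean: int = 5


@dataclass
class GrowthSpec:
    """Two-arm exponential growth with lognormal measurement noise.

    ``arms`` maps group → (rate before response_day, rate after), in
    per-day exponential growth units.  The TIL-responder default mimics a
    tumor growing until infusion and regressing afterwards.
    """

    arms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"TIL": (0.07, -0.06), "no_TIL": (0.07, 0.07)}
    )
    n_per_arm: int = 5
    days: tuple[int, ...] = (0, 7, 14, 21, 28)
    response_day: int = 7
    baseline_mm3: float = 100.0
    noise_sd: float = 0.15  # sd of log-scale measurement noise

    @classmethod
    def null(cls) -> "GrowthSpec":
        """Identical arms; for calibration of the day-wise testing."""
        return cls(arms={"TIL": (0.07, 0.07), "no_TIL": (0.07, 0.07)})


@dataclass
class SurvivalSpec:
    """Exponential survival per group with random censoring."""

    groups: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "tumor_formed": (8, 0.002),
            "no_tumor": (13, 0.002),
        }
    )  # group -> (n subjects, hazard per day)
    censoring_rate: float = 0.2


@dataclass
class SimulationConfig:
    """Complete generator configuration; the seed is mandatory."""

    seed: int
    n_genes: int = 600
    classes: list[ClassSpec] = field(
        default_factory=lambda: [
            ClassSpec("PAAD"), ClassSpec("ESCA"), ClassSpec("STAD"),
        ]
    )
    noise_sd: float = 0.5
    mixture: MixtureSpec = field(default_factory=MixtureSpec)
    variants: VariantScenario = field(default_factory=VariantScenario)
    growth: GrowthSpec = field(default_factory=GrowthSpec)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        if "seed" not in payload:
            raise ValueError("simulation config must state a seed")
        if "classes" in payload:
            payload["classes"] = [ClassSpec(**c) for c in payload["classes"]]
        if "mixture" in payload:
            payload["mixture"] = MixtureSpec(**payload["mixture"])
        if "variants" in payload:
            payload["variants"] = VariantScenario(**payload["variants"])
        if "growth" in payload:
            growth = payload["growth"]
            if "arms" in growth:
                growth["arms"] = {g: tuple(r) for g, r in growth["arms"].items()}
            if "days" in growth:
                growth["days"] = tuple(growth["days"])
            payload["growth"] = GrowthSpec(**growth)
        if "survival" in payload:
            surv = payload["survival"]
            if "groups" in surv:
                surv["groups"] = {g: tuple(v) for g, v in surv["groups"].items()}
            payload["survival"] = SurvivalSpec(**surv)
        return cls(**payload)


# ---------------------------------------------------------------------------
# Reference cohort


@dataclass
class CohortTruth:
    """Generative parameters of a simulated reference cohort."""

    gene_ids: list[str]
    baseline_log2: np.ndarray
    signatures: dict[str, np.ndarray]  # class label -> gene indices
    subgroup_signatures: dict[str, np.ndarray]  # subgroup label -> gene indices
    log2_effects: dict[str, float]
    noise_sd: float
    labels: pd.Series
    subgroups: pd.Series


def _validate_cohort_config(cfg: SimulationConfig) -> None:
    if len(cfg.classes) < 2:
        raise ValueError("need at least 2 classes")
    if any(c.n_samples < 2 for c in cfg.classes):
        raise ValueError("each class needs at least 2 samples")
    if cfg.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    needed = sum(c.n_signature_genes + 2 * (c.n_signature_genes // 2)
                 for c in cfg.classes)
    if needed > cfg.n_genes:
        raise ValueError(
            f"{cfg.n_genes} genes cannot host {needed} signature genes"
        )


def make_reference_cohort(cfg: SimulationConfig) -> tuple[ReferenceCohort, CohortTruth]:
    """Simulate a labelled multi-class reference cohort.

    Expression of sample s is ``2 ** (baseline + shifts + noise)`` where
    the class signature genes of s's class are shifted up by that class's
    ``log2_effect`` and each class is split into two nested subgroups
    (labels ``<class>.1``/``<class>.2``) whose own smaller signature
    blocks are shifted by half the class effect.  Two metadata categories
    are emitted: ``tumor_type`` (the class itself) and ``subtype`` (the
    nested subgroup).
    """
    _validate_cohort_config(cfg)
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    baseline = rng.normal(5.0, 1.5, size=cfg.n_genes)

    cursor = 0
    signatures: dict[str, np.ndarray] = {}
    subgroup_signatures: dict[str, np.ndarray] = {}
    log2_effects: dict[str, float] = {}
    for spec in cfg.classes:
        signatures[spec.label] = np.arange(cursor, cursor + spec.n_signature_genes)
        cursor += spec.n_signature_genes
        log2_effects[spec.label] = spec.log2_effect
        for sub in (1, 2):
            size = spec.n_signature_genes // 2
            subgroup_signatures[f"{spec.label}.{sub}"] = np.arange(cursor, cursor + size)
            cursor += size

    sample_ids, labels, subgroups = [], [], []
    columns = []
    for spec in cfg.classes:
        for j in range(spec.n_samples):
            sid = f"{spec.label}_{j:03d}"
            sub = f"{spec.label}.{1 if j < spec.n_samples // 2 else 2}"
            sample_ids.append(sid)
            labels.append(spec.label)
            subgroups.append(sub)
            log2 = baseline.copy()
            log2[signatures[spec.label]] += spec.log2_effect
            log2[subgroup_signatures[sub]] += spec.log2_effect / 2.0
            log2 += rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
            columns.append(2.0 ** log2)

    data = pd.DataFrame(np.column_stack(columns), index=gene_ids, columns=sample_ids)
    labels_s = pd.Series(labels, index=sample_ids, name="label")
    subgroups_s = pd.Series(subgroups, index=sample_ids, name="subtype")
    cohort = ReferenceCohort(
        expression=ExpressionMatrix(data, unit="rpkm"),
        labels=labels_s,
        metadata={"tumor_type": labels_s.copy(), "subtype": subgroups_s},
    )
    truth = CohortTruth(
        gene_ids=gene_ids,
        baseline_log2=baseline,
        signatures=signatures,
        subgroup_signatures=subgroup_signatures,
        log2_effects=log2_effects,
        noise_sd=cfg.noise_sd,
        labels=labels_s,
        subgroups=subgroups_s,
    )
    return cohort, truth


def draw_queries(
    truth: CohortTruth, class_labels: list[str], seed: int
) -> tuple[ExpressionMatrix, pd.Series]:
    """Draw fresh samples from the class generators of a simulated cohort.

    Queries are generated like cohort members (class signature shift plus
    noise; no subgroup shift) under an independent seed, so they are
    held-out draws, not copies.
    """
    rng = np.random.default_rng(seed)
    columns, sample_ids = [], []
    for i, label in enumerate(class_labels):
        if label not in truth.signatures:
            raise ValueError(f"unknown class label {label!r}")
        log2 = truth.baseline_log2.copy()
        log2[truth.signatures[label]] += truth.log2_effects[label]
        log2 += rng.normal(0.0, truth.noise_sd, size=len(truth.gene_ids))
        columns.append(2.0 ** log2)
        sample_ids.append(f"query_{i:03d}")
    data = pd.DataFrame(np.column_stack(columns), index=truth.gene_ids,
                        columns=sample_ids)
    return (
        ExpressionMatrix(data, unit="rpkm"),
        pd.Series(class_labels, index=sample_ids, name="true_label"),
    )


# ---------------------------------------------------------------------------
# Bulk mixtures

_COMPONENT_MARKERS = {
    "CAF": ["COL1A1", "COL1A2", "COL3A1", "DCN", "LUM", "FAP", "PDGFRB",
            "ACTA2", "THY1", "POSTN"],
    "macrophage": ["CD68", "CD163", "CSF1R", "MRC1", "AIF1", "ITGAM"],
    "T_cell": ["CD3D", "CD3E", "CD2", "CD8A", "IL7R"],
    "B_cell": ["CD79A", "CD79B", "MS4A1"],
    "endothelial": ["PECAM1", "VWF", "CDH5"],
    "uncharacterized": ["KRT8", "KRT18", "KRT19", "EPCAM", "MUC1"],
}


def fibroblast_markers() -> MarkerSet:
    """Fibroblast/mesenchymal marker panel used by the synthetic mixtures.

    An illustrative panel of canonical fibroblast genes, user-replaceable
    for real analyses.
    """
    return MarkerSet("fibroblast", list(_COMPONENT_MARKERS["CAF"]))


def macrophage_markers() -> MarkerSet:
    """Macrophage/monocyte marker panel matching the synthetic mixtures."""
    return MarkerSet("macrophage", list(_COMPONENT_MARKERS["macrophage"]))


def make_bulk_mixtures(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ProportionsTable]:
    """Simulate bulk RNA-seq samples as convex mixtures of cell profiles.

    Each bulk sample is sum(fraction_c * profile_c) over the configured
    components, fractions drawn from a Dirichlet with the configured
    concentrations (summing to 1 exactly), followed by multiplicative
    lognormal noise.  Marker genes are expressed only in their own
    component, so marker-panel scores track the true fractions.  Returns
    the mixed expression (rpkm unit) and the true fractions.
    """
    mix = cfg.mixture
    if not mix.components:
        raise ValueError("mixture needs at least one component")
    unknown = set(mix.components) - set(_COMPONENT_MARKERS)
    if unknown:
        raise ValueError(f"no marker panel for component {sorted(unknown)[0]!r}")
    rng = np.random.default_rng(cfg.seed + 1)

    components = list(mix.components)
    # every known marker panel is present in the gene set, so marker scores
    # of absent components remain measurable (and flat)
    marker_genes = [g for panel in _COMPONENT_MARKERS.values() for g in panel]
    background = [f"BG{i:04d}" for i in range(mix.n_background_genes)]
    gene_ids = marker_genes + background
    n_genes = len(gene_ids)

    # Component profiles: shared background levels everywhere, with each
    # component's own markers elevated only in that component.
    profiles = pd.DataFrame(0.0, index=gene_ids, columns=components)
    base_levels = pd.Series(
        2.0 ** rng.normal(mix.background_log2_mean, 1.0, size=n_genes),
        index=gene_ids,
    )
    for comp in components:
        profiles[comp] = base_levels * 2.0 ** rng.normal(0.0, 0.25, size=n_genes)
        profiles.loc[_COMPONENT_MARKERS[comp], comp] = 2.0 ** rng.normal(
            mix.marker_log2_level, 0.5, size=len(_COMPONENT_MARKERS[comp])
        )

    alphas = np.array([mix.components[c] for c in components])
    fractions = rng.dirichlet(alphas, size=mix.n_samples)
    sample_ids = [f"bulk_{i:03d}" for i in range(mix.n_samples)]

    bulk = profiles.to_numpy() @ fractions.T
    noise = 2.0 ** rng.normal(0.0, mix.noise_sd, size=(n_genes, mix.n_samples))
    bulk = bulk * noise

    expr = ExpressionMatrix(
        pd.DataFrame(bulk, index=gene_ids, columns=sample_ids), unit="rpkm"
    )
    truth = ProportionsTable(
        pd.DataFrame(fractions, index=sample_ids, columns=components),
        source="truth",
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Variant tables


def make_variant_table(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a MAF-like table with a known filter outcome per record.

    Categories: population-filtered (high gnomAD/ExAC AF or rsID, no
    whitelist), whitelist-rescued (rsID-carrying oncogene hotspot with
    exact COSMIC match), PDX-only recurrent pairs (same variant in two PDX
    samples, no biopsy) and clean somatic records.  The truth table states
    the expected keep/remove decision and reason for every record.
    """
    scenario = cfg.variants
    rng = np.random.default_rng(cfg.seed + 2)
    rows: list[dict] = []
    truth: list[dict] = []

    def add(row: dict, kept: bool, reason: str) -> None:
        base = {
            "patient_id": "P01", "sample_id": "P01_biopsy",
            "sample_class": "biopsy", "protein_change": "",
            "gnomad_af": None, "exac_af": None, "dbsnp_id": "",
            "cgc_role": "", "cosmic_exact_match": False,
        }
        base.update(row)
        rows.append(base)
        truth.append(
            {"variant_key": base["variant_key"], "sample_id": base["sample_id"],
             "expected_kept": kept, "expected_reason": reason}
        )

    counter = 0

    def key() -> str:
        nonlocal counter
        counter += 1
        pos = 1_000_000 + counter * 137
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        return f"chr{1 + counter % 22}:{pos}:{ref}:{alt}"

    pop_modes = ["gnomad", "exac", "dbsnp"]
    for i in range(scenario.n_pop_filtered):
        mode = pop_modes[i % 3]
        row = {"gene": f"GENE{i:03d}", "variant_key": key()}
        if mode == "gnomad":
            row["gnomad_af"] = float(rng.uniform(0.002, 0.05))
            reason = "pop_freq_gnomad"
        elif mode == "exac":
            row["exac_af"] = float(rng.uniform(0.002, 0.05))
            reason = "pop_freq_exac"
        else:
            row["dbsnp_id"] = f"rs{rng.integers(10_000, 999_999)}"
            reason = "dbsnp"
        add(row, kept=False, reason=reason)

    for i in range(scenario.n_whitelist_rescued):
        add(
            {"gene": "KRAS", "variant_key": key(), "protein_change": "p.G12D",
             "dbsnp_id": f"rs{rng.integers(10_000, 999_999)}",
             "cgc_role": "oncogene", "cosmic_exact_match": True},
            kept=True, reason="whitelisted_oncogene_cosmic",
        )

    for i in range(scenario.n_pdx_recurrent_pairs):
        shared = key()
        for m in (1, 2):
            add(
                {"gene": f"ART{i:03d}", "variant_key": shared,
                 "patient_id": f"P{m:02d}", "sample_id": f"P{m:02d}_pdx",
                 "sample_class": "pdx"},
                kept=False, reason="pdx_only_recurrent",
            )

    for i in range(scenario.n_clean):
        sample_class = "biopsy" if i % 2 == 0 else "pdx"
        add(
            {"gene": f"SOM{i:03d}", "variant_key": key(),
             "patient_id": f"P{10 + i:02d}",
             "sample_id": f"P{10 + i:02d}_{sample_class}",
             "sample_class": sample_class},
            kept=True, reason="clean",
        )

    table = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return table, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Growth and survival


def make_growth_and_survival(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate caliper series and survival records.

    Volumes follow per-arm exponential growth (rate switching at
    ``response_day``) with lognormal measurement noise, then are converted
    back to width/length pairs under the convention length = 1.5 x width,
    consistent with the volume formula width^2 x length / 2.  Survival
    times are exponential per group; a ``censoring_rate`` fraction of
    subjects is censored at a uniform fraction of its event time.
    """
    growth, surv = cfg.growth, cfg.survival
    if len(growth.arms) < 2:
        raise ValueError("growth simulation needs at least 2 arms")
    if growth.n_per_arm < 2 or not growth.days:
        raise ValueError("degenerate growth spec")
    rng = np.random.default_rng(cfg.seed + 3)

    rows = []
    for group, (rate_before, rate_after) in growth.arms.items():
        for animal in range(growth.n_per_arm):
            animal_id = f"{group}_{animal:02d}"
            v0 = growth.baseline_mm3 * 2.0 ** rng.normal(0.0, growth.noise_sd)
            for day in growth.days:
                t_before = min(day, growth.response_day)
                t_after = max(0, day - growth.response_day)
                volume = v0 * np.exp(rate_before * t_before + rate_after * t_after)
                volume *= 2.0 ** rng.normal(0.0, growth.noise_sd)
                # v = w^2 * l / 2 with l = 1.5 w  =>  w = (2 v / 1.5)^(1/3)
                width = (2.0 * volume / 1.5) ** (1.0 / 3.0)
                rows.append(
                    {"animal_id": animal_id, "group": group, "day": int(day),
                     "width_mm": float(width), "length_mm": float(1.5 * width)}
                )
    measurements = pd.DataFrame(rows)

    surv_rows = []
    for group, (n, hazard) in surv.groups.items():
        if n < 1 or hazard <= 0:
            raise ValueError(f"degenerate survival spec for group {group!r}")
        times = rng.exponential(1.0 / hazard, size=n)
        censored = rng.random(n) < surv.censoring_rate
        observed = np.where(censored, times * rng.uniform(0.1, 0.9, size=n), times)
        for i in range(n):
            surv_rows.append(
                {"subject_id": f"{group}_{i:02d}", "group": group,
                 "time": float(max(observed[i], 1e-3)),
                 "event": bool(not censored[i])}
            )
    survival = pd.DataFrame(surv_rows)
    return measurements, survival


# ---------------------------------------------------------------------------
# Fixture writing


def write_fixture_dir(cfg: SimulationConfig, out_dir) -> dict[str, str]:
    """Write every generated input in the TSV dialects the modules read.

    Returns a name → path map of the files written.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    cohort, truth = make_reference_cohort(cfg)
    cohort.expression.to_tsv(out / "reference_expression.tsv")
    cohort.labels.rename("label").rename_axis("sample_id").reset_index().to_csv(
        out / "reference_labels.tsv", sep="\t", index=False
    )
    meta_rows = []
    for category, sub in cohort.metadata.items():
        for sample_id, subgroup in sub.items():
            meta_rows.append(
                {"sample_id": sample_id, "category": category, "subgroup": subgroup}
            )
    pd.DataFrame(meta_rows).to_csv(out / "reference_metadata.tsv", sep="\t", index=False)

    queries, query_truth = draw_queries(
        truth, [c.label for c in cfg.classes for _ in range(2)], seed=cfg.seed + 10
    )
    queries.to_tsv(out / "queries.tsv")
    query_truth.rename_axis("sample_id").reset_index().to_csv(
        out / "query_truth.tsv", sep="\t", index=False
    )

    expr, proportions = make_bulk_mixtures(cfg)
    expr.to_tsv(out / "bulk_expression.tsv")
    proportions.to_tsv(out / "true_proportions.tsv")
    with open(out / "fibroblast_markers.json", "w") as handle:
        import json

        json.dump(asdict(fibroblast_markers()), handle, indent=2)

    variants, variant_truth = make_variant_table(cfg)
    variants.to_csv(out / "variants.maf.tsv", sep="\t", index=False)
    variant_truth.to_csv(out / "variant_truth.tsv", sep="\t", index=False)

    measurements, survival = make_growth_and_survival(cfg)
    measurements.to_csv(out / "growth_measurements.tsv", sep="\t", index=False)
    survival.to_csv(out / "survival.tsv", sep="\t", index=False)

    for name in [
        "reference_expression.tsv", "reference_labels.tsv", "reference_metadata.tsv",
        "queries.tsv", "query_truth.tsv", "bulk_expression.tsv",
        "true_proportions.tsv", "fibroblast_markers.json", "variants.maf.tsv",
        "variant_truth.tsv", "growth_measurements.tsv", "survival.tsv",
    ]:
        paths[name] = str(out / name)
    return paths
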