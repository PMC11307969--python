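"""Post-annotation somatic-variant filtering with a cancer-gene whitelist.

Annotated somatic variants (MAF-like rows) are filtered in two stages:

1. Population filter — a variant is removed when its gnomAD or ExAC allele
   frequency exceeds 0.001, or it carries a dbSNP rsID, unless it is
   whitelisted.  A variant is whitelisted when its gene is a Cancer Gene
   Census oncogene AND the exact mutation is listed in COSMIC, or when the
   gene is a Cancer Gene Census tumor suppressor.
2. PDX-recurrence filter — a variant seen in more than one PDX sample but
   in no patient biopsy is removed cohort-wide as a suspected engraftment
   or calling artifact.

Removal is variant-level: an excessive population frequency removes that
variant, never every variant of the gene.  CGC roles and COSMIC matches
are consumed as precomputed columns (or supplied as lookup files); no
remote databases are queried.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import pandas as pd

__all__ = [
    "SampleClass",
    "FilterReason",
    "FilterConfig",
    "FilterDecision",
    "CANONICAL_COLUMNS",
    "read_maf",
    "write_maf",
    "is_whitelisted",
    "population_filter",
    "pdx_recurrence_filter",
    "filter_pipeline",
]


class SampleClass(str, Enum):
    BIOPSY = "biopsy"
    PDX = "pdx"
    NORMAL = "normal"


class FilterReason(str, Enum):
    POP_FREQ_GNOMAD = "pop_freq_gnomad"
    POP_FREQ_EXAC = "pop_freq_exac"
    DBSNP = "dbsnp"
    WHITELISTED_ONCOGENE_COSMIC = "whitelisted_oncogene_cosmic"
    WHITELISTED_TSG = "whitelisted_tsg"
    PDX_ONLY_RECURRENT = "pdx_only_recurrent"


CANONICAL_COLUMNS = [
    "patient_id", "sample_id", "sample_class", "gene", "variant_key",
    "protein_change", "gnomad_af", "exac_af", "dbsnp_id", "cgc_role",
    "cosmic_exact_match",
]

# Standard MAF column names accepted on read.
_MAF_ALIASES = {
    "Hugo_Symbol": "gene",
    "Tumor_Sample_Barcode": "sample_id",
    "HGVSp_Short": "protein_change",
    "gnomAD_AF": "gnomad_af",
    "ExAC_AF": "exac_af",
    "dbSNP_RS": "dbsnp_id",
}


@dataclass
class FilterConfig:
    """Tunable thresholds and conventions for the filter pipeline."""

    gnomad_threshold: float = 0.001  # strict: removal requires af > threshold
    exac_threshold: float = 0.001
    pdx_min_samples: int = 2  # "more than one PDX sample"
    pdx_count_unit: str = "sample"  # or "patient"
    whitelist_shields_recurrence: bool = False


@dataclass
class FilterDecision:
    variant_key: str
    sample_id: str
    kept: bool
    reasons: list[FilterReason] = field(default_factory=list)


def read_maf(path, column_mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a MAF-like TSV into the canonical column set.

    ``column_mapping`` maps input column names to canonical names on top of
    the standard MAF aliases.  Missing optional annotation columns are
    filled with neutral values; a missing ``variant_key`` is built from
    chrom/pos/ref/alt columns when present.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    rename = dict(_MAF_ALIASES)
    if column_mapping:
        rename.update(column_mapping)
    df = df.rename(columns=rename)
    if "variant_key" not in df.columns:
        pos_cols = ["Chromosome", "Start_Position", "Reference_Allele",
                    "Tumor_Seq_Allele2"]
        if all(c in df.columns for c in pos_cols):
            df["variant_key"] = df[pos_cols].agg(":".join, axis=1)
        else:
            raise ValueError("input lacks variant_key and chrom/pos/ref/alt columns")
    for col, default in [
        ("protein_change", ""), ("gnomad_af", None), ("exac_af", None),
        ("dbsnp_id", ""), ("cgc_role", ""), ("cosmic_exact_match", "False"),
        ("patient_id", ""),
    ]:
        if col not in df.columns:
            df[col] = default
    for col in ("gnomad_af", "exac_af"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ~df[col].between(0, 1)
        if bad.any():
            raise ValueError(
                f"{col} outside [0,1] at input row {int(df.index[bad][0]) + 2}"
            )
    df["dbsnp_id"] = df["dbsnp_id"].fillna("").replace({"novel": "", ".": ""})
    df["cosmic_exact_match"] = (
        df["cosmic_exact_match"].astype(str).str.lower().isin(["true", "1", "yes"])
    )
    df["sample_class"] = df["sample_class"].astype(str).str.lower()
    valid = {c.value for c in SampleClass}
    bad_class = ~df["sample_class"].isin(valid)
    if bad_class.any():
        raise ValueError(
            f"unknown sample_class {df.loc[bad_class, 'sample_class'].iloc[0]!r} "
            f"at input row {int(df.index[bad_class][0]) + 2}"
        )
    empty_key = df["variant_key"].fillna("") == ""
    if empty_key.any():
        raise ValueError(f"empty variant_key at input row {int(df.index[empty_key][0]) + 2}")
    return df[CANONICAL_COLUMNS + [c for c in df.columns if c not in CANONICAL_COLUMNS]]


def write_maf(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _roles(record) -> set[str]:
    raw = record.get("cgc_role", "") if isinstance(record, Mapping) else record["cgc_role"]
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return set()
    if isinstance(raw, (set, frozenset, list, tuple)):
        return {str(r) for r in raw if str(r)}
    return {part.strip() for part in str(raw).split(",") if part.strip()}


def is_whitelisted(record) -> tuple[bool, FilterReason | None]:
    """Whitelist rule: CGC oncogene with exact COSMIC listing, or CGC TSG.

    An oncogene annotation alone does not suffice — the exact mutation must
    be catalogued in COSMIC.  A tumor-suppressor annotation suffices on its
    own.
    """
    roles = _roles(record)
    if "tumor_suppressor" in roles:
        return True, FilterReason.WHITELISTED_TSG
    if "oncogene" in roles and bool(record["cosmic_exact_match"]):
        return True, FilterReason.WHITELISTED_ONCOGENE_COSMIC
    return False, None


def population_filter(record, config: FilterConfig | None = None) -> FilterDecision:
    """Remove a variant common in the population, unless whitelisted.

    Removal triggers on gnomAD AF > threshold, ExAC AF > threshold
    (strict inequalities; a missing AF never triggers) or a non-empty
    dbSNP rsID.  A whitelisted variant is kept regardless, with the
    whitelist reason recorded.
    """
    config = config or FilterConfig()
    whitelisted, wl_reason = is_whitelisted(record)
    if whitelisted:
        return FilterDecision(
            variant_key=str(record["variant_key"]),
            sample_id=str(record["sample_id"]),
            kept=True,
            reasons=[wl_reason],
        )
    reasons: list[FilterReason] = []
    gnomad = record["gnomad_af"]
    exac = record["exac_af"]
    if gnomad is not None and not pd.isna(gnomad) and float(gnomad) > config.gnomad_threshold:
        reasons.append(FilterReason.POP_FREQ_GNOMAD)
    if exac is not None and not pd.isna(exac) and float(exac) > config.exac_threshold:
        reasons.append(FilterReason.POP_FREQ_EXAC)
    dbsnp = record["dbsnp_id"]
    if dbsnp is not None and not pd.isna(dbsnp) and str(dbsnp) != "":
        reasons.append(FilterReason.DBSNP)
    return FilterDecision(
        variant_key=str(record["variant_key"]),
        sample_id=str(record["sample_id"]),
        kept=not reasons,
        reasons=reasons,
    )


def pdx_recurrence_filter(
    table: pd.DataFrame, config: FilterConfig | None = None
) -> pd.Series:
    """Flag variants recurrent in PDX samples but absent from all biopsies.

    Returns a boolean Series (aligned to the table index) that is True for
    every record of a variant_key carried by at least ``pdx_min_samples``
    distinct PDX samples (or patients, per ``pdx_count_unit``) and by zero
    biopsy samples.
    """
    config = config or FilterConfig()
    if table.empty:
        return pd.Series(dtype=bool)
    unit_col = "sample_id" if config.pdx_count_unit == "sample" else "patient_id"
    is_pdx = table["sample_class"] == SampleClass.PDX.value
    is_biopsy = table["sample_class"] == SampleClass.BIOPSY.value
    pdx_counts = (
        table.loc[is_pdx].groupby("variant_key")[unit_col].nunique()
        if is_pdx.any() else pd.Series(dtype=int)
    )
    biopsy_keys = set(table.loc[is_biopsy, "variant_key"])
    flagged_keys = {
        key for key, n in pdx_counts.items()
        if n >= config.pdx_min_samples and key not in biopsy_keys
    }
    return table["variant_key"].isin(flagged_keys)


def filter_pipeline(
    table: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Population filter, then PDX-recurrence filter, over a variant table.

    Returns the kept rows, a per-record decision log (variant_key,
    sample_id, kept, comma-joined reasons) and summary counts per reason
    plus ``kept``/``removed`` totals.  Deterministic, row-order independent
    and idempotent: surviving rows pass both filters again unchanged.
    """
    config = config or FilterConfig()
    if table.empty:
        log = pd.DataFrame(columns=["variant_key", "sample_id", "kept", "reasons"])
        counts = {reason.value: 0 for reason in FilterReason}
        counts.update({"kept": 0, "removed": 0})
        return table.copy(), log, counts

    decisions: list[FilterDecision] = [
        population_filter(row, config) for _, row in table.iterrows()
    ]
    pop_kept_mask = pd.Series([d.kept for d in decisions], index=table.index)

    # Recurrence is assessed on the population-filter survivors: an
    # artifact must recur among variants still under consideration.
    survivors = table.loc[pop_kept_mask]
    recurrent = pdx_recurrence_filter(survivors, config)
    for decision, idx in zip(decisions, table.index):
        if decision.kept and idx in recurrent.index and recurrent.loc[idx]:
            shielded = config.whitelist_shields_recurrence and any(
                r in (FilterReason.WHITELISTED_TSG,
                      FilterReason.WHITELISTED_ONCOGENE_COSMIC)
                for r in decision.reasons
            )
            if not shielded:
                decision.kept = False
                decision.reasons.append(FilterReason.PDX_ONLY_RECURRENT)

    kept_mask = pd.Series([d.kept for d in decisions], index=table.index)
    log = pd.DataFrame(
        {
            "variant_key": [d.variant_key for d in decisions],
            "sample_id": [d.sample_id for d in decisions],
            "kept": [d.kept for d in decisions],
            "reasons": [",".join(r.value for r in d.reasons) for d in decisions],
        },
        index=table.index,
    )
    reason_counts: Counter[str] = Counter()
    for decision in decisions:
        for reason in decision.reasons:
            reason_counts[reason.value] += 1
    counts = {reason.value: reason_counts.get(reason.value, 0) for reason in FilterReason}
    counts["kept"] = int(kept_mask.sum())
    counts["removed"] = int((~kept_mask).sum())
    return table.loc[kept_mask].copy(), log, counts
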