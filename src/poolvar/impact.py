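"""Protein-impact classes (H / Mdel / Mtol / L) and the variant summaries.

Variants are classified from their snpEff-style impact tier and SIFT call:
HIGH-tier effects are H; MODERATE effects split into Mdel (SIFT deleterious)
and Mtol (tolerated or no SIFT prediction); LOW/MODIFIER synonymous and
start-gained effects are L.  "Strong impact" means H or Mdel, "mild" Mtol or
L.  The summaries stratify counts by gene group, frequency class and protein
decile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from poolvar.frequencies import FrequencyRecord
from poolvar.io_formats import EffectAnnotation

__all__ = [
    "ImpactClass",
    "SUMMARY_COLUMNS",
    "classify_impact",
    "frequency_by_impact_table",
    "impact_summary_table",
    "protein_decile_bin",
    "protein_decile_distribution",
    "rare_high_table",
]


@dataclass(frozen=True)
class ImpactClass:
    value: str  # one of H, Mdel, Mtol, L

    def __post_init__(self) -> None:
        if self.value not in {"H", "Mdel", "Mtol", "L"}:
            raise ValueError(f"unknown impact class: {self.value!r}")

    @property
    def strong(self) -> bool:
        return self.value in {"H", "Mdel"}


def classify_impact(annotation: EffectAnnotation) -> ImpactClass:
    """Map one annotation to H / Mdel / Mtol / L."""
    tier = annotation.impact_tier
    if tier == "HIGH":
        return ImpactClass("H")
    if tier == "MODERATE":
        if annotation.sift_class == "deleterious":
            return ImpactClass("Mdel")
        # tolerated or no SIFT prediction are pooled
        return ImpactClass("Mtol")
    if tier in {"LOW", "MODIFIER"} and annotation.effect_term in {
        "synonymous",
        "start_gained",
    }:
        return ImpactClass("L")
    raise ValueError(
        f"unmappable tier/term combination: {tier!r} / {annotation.effect_term!r}"
    )


#: Effect-category columns of the impact summary, in report order.
SUMMARY_COLUMNS = (
    "splice",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frame_shift",
    "Mdel",
    "Mtol",
    "synonymous",
    "start_gained",
)

_STRONG_COLUMNS = ("splice", "stop_gained", "stop_lost", "start_lost", "frame_shift", "Mdel")


def _summary_category(annotation: EffectAnnotation) -> str:
    term = annotation.effect_term
    if term in {"splice_site_donor", "splice_site_acceptor"}:
        return "splice"
    if term in {"non_synonymous", "codon_change_or_deletion"}:
        return classify_impact(annotation).value  # Mdel or Mtol
    return term


def impact_summary_table(
    annotations: Iterable[EffectAnnotation],
    gene_groups: Mapping[str, str],
    fixed_keys: set[str] | frozenset[str] | None = None,
) -> pd.DataFrame:
    """Counts per effect category and gene group, with percent strong impact.

    ``gene_groups`` maps gene_id to its group label (e.g. taste-receptor vs
    appetite-reward); every annotated gene must be assigned.  Variants whose
    key is in ``fixed_keys`` (alternative allele fixed in all pools) are
    reported on a separate row and excluded from the segregating rows and the
    group totals.  Percent strong impact is 100*(H + Mdel)/total rounded to
    one decimal.
    """
    fixed_keys = fixed_keys or set()
    groups = sorted(set(gene_groups.values()))
    counts: dict[str, dict[str, int]] = {
        g: {c: 0 for c in SUMMARY_COLUMNS} for g in groups
    }
    counts["Alternative allele fixed"] = {c: 0 for c in SUMMARY_COLUMNS}
    for ann in annotations:
        if ann.gene_id not in gene_groups:
            raise ValueError(f"gene {ann.gene_id!r} not assigned to any group")
        cat = _summary_category(ann)
        if ann.variant_key in fixed_keys:
            counts["Alternative allele fixed"][cat] += 1
        else:
            counts[gene_groups[ann.gene_id]][cat] += 1

    def _row(label: str, c: Mapping[str, int]) -> dict[str, object]:
        total = sum(c.values())
        strong = sum(c[col] for col in _STRONG_COLUMNS)
        pct = round(100 * strong / total, 1) if total else 0.0
        return {"group": label, **c, "strong": strong, "pct_strong": pct, "total": total}

    rows = [_row(g, counts[g]) for g in groups]
    segregating = {
        c: sum(counts[g][c] for g in groups) for c in SUMMARY_COLUMNS
    }
    rows.append(_row("Total segregating", segregating))
    rows.append(_row("Alternative allele fixed", counts["Alternative allele fixed"]))
    grand = {
        c: segregating[c] + counts["Alternative allele fixed"][c]
        for c in SUMMARY_COLUMNS
    }
    rows.append(_row("Total", grand))
    return pd.DataFrame(rows)


def frequency_by_impact_table(
    records: Sequence[FrequencyRecord],
    classes: Mapping[str, ImpactClass],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Frequency-class distribution within each (gene group, strength) cell.

    Strength is strong (H + Mdel) or mild (Mtol + L); percentages are over the
    cell total; min/max/mean pMAF summarize the cell.  Records without a class
    or group assignment are ignored.
    """
    cells: dict[tuple[str, str], list[FrequencyRecord]] = {}
    for r in records:
        cls = classes.get(r.variant_key)
        grp = groups.get(r.variant_key)
        if cls is None or grp is None:
            continue
        strength = "strong" if cls.strong else "mild"
        cells.setdefault((grp, strength), []).append(r)
    rows = []
    for (grp, strength) in sorted(cells):
        recs = cells[(grp, strength)]
        total = len(recs)
        row: dict[str, object] = {"group": grp, "strength": strength}
        for fc in ("very_rare", "rare", "common"):
            n = sum(1 for r in recs if r.freq_class == fc)
            row[fc] = n
            row[f"{fc}_pct"] = round(100 * n / total, 1)
        pmafs = [r.pmaf for r in recs]
        row.update(
            total=total,
            pmaf_min=min(pmafs),
            pmaf_max=max(pmafs),
            pmaf_mean=sum(pmafs) / total,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def rare_high_table(
    records: Sequence[FrequencyRecord],
    classes: Mapping[str, ImpactClass],
    annotations: Mapping[str, Sequence[EffectAnnotation]],
    max_pmaf: float = 0.01,
) -> pd.DataFrame:
    """List the rare high-impact variants (class H, pMAF at or below the cut).

    Rows are sorted by gene then variant key, mirroring the catalogue layout
    used for rare loss-of-function candidates.
    """
    rows = []
    for r in records:
        cls = classes.get(r.variant_key)
        if cls is None or cls.value != "H" or r.pmaf > max_pmaf:
            continue
        for ann in annotations.get(r.variant_key, ()):
            rows.append(
                {
                    "variant_key": r.variant_key,
                    "effect": ann.effect_term.upper(),
                    "gene": ann.gene_id,
                    "pmaf": r.pmaf,
                }
            )
    df = pd.DataFrame(rows, columns=["variant_key", "effect", "gene", "pmaf"])
    return df.sort_values(["gene", "variant_key"], ignore_index=True)


def protein_decile_bin(protein_pos: int, protein_len: int) -> int:
    """Decile bin of a protein position: ceil(10*pos/len), clamped to [1, 10]."""
    if protein_pos <= 0 or protein_len <= 0:
        raise ValueError("protein coordinates must be positive")
    return min(10, max(1, math.ceil(10 * protein_pos / protein_len)))


def _decile_strength(ann: EffectAnnotation, cls: ImpactClass) -> str | None:
    # strong: premature stop, frame shift, Mdel; mild: Mtol, in-frame, synonymous
    if cls.value == "Mdel" or (
        cls.value == "H" and ann.effect_term in {"stop_gained", "frame_shift"}
    ):
        return "strong"
    if cls.value == "Mtol" or (
        cls.value == "L" and ann.effect_term == "synonymous"
    ):
        return "mild"
    return None


def protein_decile_distribution(
    annotations: Iterable[EffectAnnotation],
    classes: Mapping[str, ImpactClass],
    records: Mapping[str, FrequencyRecord] | Sequence[FrequencyRecord],
) -> tuple[pd.DataFrame, int]:
    """Variant counts and mean pMAF per protein decile, strong vs mild sets.

    The protein body of each gene is divided into ten consecutive bins of
    equal amino-acid length.  Variants without protein coordinates are
    skipped; their number is returned alongside the table.
    """
    if not isinstance(records, Mapping):
        records = {r.variant_key: r for r in records}
    acc: dict[str, dict[int, list[float]]] = {
        "strong": {b: [] for b in range(1, 11)},
        "mild": {b: [] for b in range(1, 11)},
    }
    skipped = 0
    for ann in annotations:
        cls = classes.get(ann.variant_key)
        rec = records.get(ann.variant_key)
        if cls is None or rec is None:
            continue
        strength = _decile_strength(ann, cls)
        if strength is None:
            continue
        if ann.protein_pos is None or ann.protein_len is None:
            skipped += 1
            continue
        b = protein_decile_bin(ann.protein_pos, ann.protein_len)
        acc[strength][b].append(rec.pmaf)
    rows = []
    for b in range(1, 11):
        row: dict[str, object] = {"bin": b}
        for strength in ("strong", "mild"):
            vals = acc[strength][b]
            row[f"{strength}_count"] = len(vals)
            row[f"{strength}_mean_pmaf"] = (
                sum(vals) / len(vals) if vals else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows), skipped
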