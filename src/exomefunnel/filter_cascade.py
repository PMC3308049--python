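"""The candidate-mutation nomination funnel.

Ordered pure-predicate filters reduce the full set of called variants to
one or a few putative causative mutations:

    in_gene -> novel -> map_overlap -> allele_ratio -> damaging -> unique

Each stage keeps the variants satisfying its predicate, so per-stage
survivor counts are non-increasing and the *final* survivor set does not
depend on stage order. When no coding/splice candidate survives, the
report falls back to UTR variants that pass every non-consequence filter
(the three observed outcome classes: coding/splice candidate found,
UTR-only candidate, none).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .genome_model import GenomicInterval
from .variant_annotation import AnnotatedVariant, SEVERITY_ORDER

__all__ = [
    "FilterConfig",
    "FunnelReport",
    "apply_cascade",
    "rank_survivors",
    "compare_runs",
    "DEFAULT_STAGE_ORDER",
    "DEFAULT_DAMAGING",
]

DEFAULT_STAGE_ORDER: tuple[str, ...] = (
    "in_gene",
    "novel",
    "map_overlap",
    "allele_ratio",
    "damaging",
    "unique",
)

DEFAULT_DAMAGING = frozenset(
    {
        "nonsense",
        "missense",
        "splice_donor",
        "splice_acceptor",
        "inframe_del",
        "frameshift",
    }
)

_UTR = ("utr5", "utr3")


@dataclass
class FilterConfig:
    """Parameters of one nomination run.

    Allele-ratio thresholds are inclusive (>= 0.95 homozygous, >= 0.2
    heterozygous) so a boundary case like a capture-biased heterozygous
    deletion at ratio exactly 0.2 is retained. No upper bound is applied
    to heterozygous ratios.
    """

    inheritance: str = "recessive_homozygous"
    hom_ratio_min: float = 0.95
    het_ratio_min: float = 0.2
    map_intervals: list[GenomicInterval] = field(default_factory=list)
    novelty_catalogs: tuple[str, ...] = ("dbSNP",)
    uniqueness_panels: tuple[str, ...] = ()
    damaging_categories: frozenset[str] = DEFAULT_DAMAGING
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self):
        if self.inheritance not in ("recessive_homozygous", "dominant_heterozygous"):
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if not (0 < self.het_ratio_min <= self.hom_ratio_min <= 1):
            raise ValueError(
                "require 0 < het_ratio_min <= hom_ratio_min <= 1, got "
                f"{self.het_ratio_min}/{self.hom_ratio_min}"
            )
        if sorted(self.stage_order) != sorted(DEFAULT_STAGE_ORDER):
            raise ValueError(
                f"stage_order must be a permutation of {DEFAULT_STAGE_ORDER}"
            )

    @property
    def ratio_min(self) -> float:
        return (
            self.hom_ratio_min
            if self.inheritance == "recessive_homozygous"
            else self.het_ratio_min
        )


@dataclass
class FunnelReport:
    """Per-stage survivor counts plus the final candidates."""

    sample_id: str
    n_input: int
    stage_counts: dict[str, int]
    survivors: list[AnnotatedVariant]
    utr_fallback: list[AnnotatedVariant]
    config: FilterConfig

    @property
    def outcome(self) -> str:
        """'candidate' | 'utr_fallback' | 'none' (the three outcome classes)."""
        if self.survivors:
            return "candidate"
        if self.utr_fallback:
            return "utr_fallback"
        return "none"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": "variants_called", "survivors": self.n_input}]
        rows += [
            {"stage": s, "survivors": n} for s, n in self.stage_counts.items()
        ]
        return pd.DataFrame(rows)


def load_filter_config(path, reference=None, **overrides) -> FilterConfig:
    """Build a FilterConfig from a YAML key-value file.

    Recognized keys mirror the FilterConfig fields; ``map_intervals`` is a
    list of 'chrom' or 'chrom:start-end' strings (bare chromosome names
    need ``reference``). Keyword ``overrides`` win over file values.
    """
    import yaml

    from .variant_annotation import parse_region

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - {
        "inheritance", "hom_ratio_min", "het_ratio_min", "map_intervals",
        "novelty_catalogs", "uniqueness_panels", "damaging_categories", "stage_order",
    }
    if unknown:
        raise ValueError(f"unknown filter-config keys: {sorted(unknown)}")
    kwargs: dict = dict(data)
    if "map_intervals" in kwargs:
        kwargs["map_intervals"] = [
            parse_region(str(m), reference) for m in kwargs["map_intervals"]
        ]
    for key in ("novelty_catalogs", "uniqueness_panels", "stage_order"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "damaging_categories" in kwargs:
        kwargs["damaging_categories"] = frozenset(kwargs["damaging_categories"])
    kwargs.update(overrides)
    return FilterConfig(**kwargs)


def _stage_predicates(
    cfg: FilterConfig,
    panels: Mapping[str, set] | None,
) -> dict[str, Callable[[AnnotatedVariant], bool]]:
    panels = panels or {}
    panel_keys: list[set] = [
        panels[name] for name in cfg.uniqueness_panels if name in panels
    ]

    def in_gene(av: AnnotatedVariant) -> bool:
        # any consequence tied to a transcript, introns included
        return av.consequence.category != "intergenic"

    def novel(av: AnnotatedVariant) -> bool:
        return not set(av.known_in) & set(cfg.novelty_catalogs)

    def map_overlap(av: AnnotatedVariant) -> bool:
        if not cfg.map_intervals:
            return True  # no mapping data: stage passes everything
        v = av.variant
        return any(iv.contains(v.chrom, v.pos - 1) for iv in cfg.map_intervals)

    def ratio(av: AnnotatedVariant) -> bool:
        return av.allele_ratio >= cfg.ratio_min

    def damaging(av: AnnotatedVariant) -> bool:
        return av.consequence.category in cfg.damaging_categories

    def unique(av: AnnotatedVariant) -> bool:
        key = av.variant.key
        if panel_keys:
            return not any(key in keys for keys in panel_keys)
        return not set(av.known_in) & set(cfg.uniqueness_panels)

    return {
        "in_gene": in_gene,
        "novel": novel,
        "map_overlap": map_overlap,
        "allele_ratio": ratio,
        "damaging": damaging,
        "unique": unique,
    }


def apply_cascade(
    variants: Sequence[AnnotatedVariant],
    cfg: FilterConfig,
    panels: Mapping[str, set] | None = None,
) -> FunnelReport:
    """Run the nomination funnel and report per-stage survivor counts.

    ``panels`` maps uniqueness-panel names to exact-allele key sets; when
    omitted, panel membership is read from each variant's ``known_in``.
    The UTR fallback list is populated only when the funnel empties.
    """
    preds = _stage_predicates(cfg, panels)
    sample_ids = {av.variant.sample_id for av in variants}
    sample_id = sample_ids.pop() if len(sample_ids) == 1 else ""

    current = list(variants)
    counts: dict[str, int] = {}
    for stage in cfg.stage_order:
        current = [av for av in current if preds[stage](av)]
        counts[stage] = len(current)

    utr_fallback: list[AnnotatedVariant] = []
    if not current:
        non_consequence = [s for s in cfg.stage_order if s != "damaging"]
        utr_fallback = [
            av
            for av in variants
            if av.consequence.category in _UTR
            and all(preds[s](av) for s in non_consequence)
        ]
        utr_fallback = rank_survivors(utr_fallback)

    return FunnelReport(
        sample_id=sample_id,
        n_input=len(variants),
        stage_counts=counts,
        survivors=rank_survivors(current),
        utr_fallback=utr_fallback,
        config=cfg,
    )


def rank_survivors(survivors: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Order candidates by severity, then quality (desc), then position."""
    rank = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    return sorted(
        survivors,
        key=lambda av: (
            rank[av.consequence.category],
            -av.variant.quality,
            av.variant.chrom,
            av.variant.pos,
        ),
    )


def render_funnel_table(reports: Sequence[FunnelReport]) -> pd.DataFrame:
    """Funnel counts as one row per sample, one column per stage.

    Columns follow the run's stage order, prefixed by the total variant
    count, mirroring the conventional per-mutant funnel table layout.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for rep in reports:
        row = {"sample": rep.sample_id, "variants_called": rep.n_input}
        row.update(rep.stage_counts)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_runs(reports: Mapping[str, FunnelReport]) -> pd.DataFrame:
    """Validation-burden table across map resolutions on one variant set.

    ``reports`` maps a label (e.g. 'no_map', 'chromosome', 'fine') to the
    funnel run with that map configuration; all runs must come from the
    same sample. Returns one row per label with the final burden.
    """
    sample_ids = {r.sample_id for r in reports.values()}
    if len(sample_ids) > 1:
        raise ValueError(f"reports mix samples: {sorted(sample_ids)}")
    rows = []
    for label, rep in reports.items():
        rows.append(
            {
                "map": label,
                "validation_burden": len(rep.survivors),
                "outcome": rep.outcome,
                "top_gene": (
                    rep.survivors[0].consequence.gene_symbol if rep.survivors else ""
                ),
            }
        )
    return pd.DataFrame(rows)
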