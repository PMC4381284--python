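"""Locate siRNA target sites and compute their structural predictors.

For every siRNA the pipeline derives one :class:`SiteFeatureVector`:
targeted-base counts per structure element, unpaired-base counts and runs,
the hydrogen-bond (H-b) accessibility index, the three binding free-energy
terms and the guide GC%.

The H-b index of a target window is the ensemble-average number of
hydrogen bonds its bases form:

    H-b = sum_i (1 - ss_count[i] / N) * b_i,   b_i = 3 for G/C else 2

where ``ss_count[i]`` is the number of ensemble structures with position i
single-stranded.  The per-base weights approximate pair bonds without
knowing the partner base (ss-count files do not record partners), so a
G or C pairing via a GU wobble is counted at 3 rather than 2 — a
documented approximation inherited from the index's construction.
Low H-b (below the conventional cut-point of 25) marks an accessible site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

from .fold_engine import FoldParams, StructureEnsemble, ss_count
from .loop_annotation import ELEMENT_COLUMNS, ELEMENT_LABELS, annotate, element_counts_in_site
from .structure_io import (
    MrnaRecord,
    SecondaryStructure,
    SirnaRecord,
    SsCountVector,
    reverse_complement,
)
from . import thermo

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSite:
    """The mRNA interval exactly reverse-complementary to a guide."""

    mrna_id: str
    sirna_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid site interval {self.start}..{self.end}")

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SiteFeatureVector:
    """One row of the analysis: all predictors for one siRNA."""

    sirna_id: str
    efficacy_code: int
    loop5: int
    loop3: int
    int_loop: int
    mb_loop: int
    h_loop: int
    b_loop: int
    one_bb: int
    stem: int
    n_unpaired: int
    runs: Tuple[int, ...]
    max_run: int
    hb_index: float
    dg_overall: float
    dg_duplex: float
    dg_break_target: float
    dg_oligo_self: float
    gc_percent: float

    def __post_init__(self) -> None:
        if self.efficacy_code not in (0, 1):
            raise ValueError("efficacy code must be 0 (L) or 1 (VH)")
        site_len = self.site_length
        if self.n_unpaired != sum(self.runs):
            raise ValueError("n_unpaired must equal the sum of run lengths")
        if self.max_run != (max(self.runs) if self.runs else 0):
            raise ValueError("max_run inconsistent with runs")
        non_stem = site_len - self.stem
        if self.n_unpaired != non_stem:
            raise ValueError(
                f"n_unpaired={self.n_unpaired} but site has {non_stem} non-stem bases"
            )
        if not 0.0 <= self.hb_index <= 3.0 * site_len + 1e-9:
            raise ValueError("H-b index outside [0, 3 * site length]")

    @property
    def site_length(self) -> int:
        return (
            self.loop5
            + self.loop3
            + self.int_loop
            + self.mb_loop
            + self.h_loop
            + self.b_loop
            + self.one_bb
            + self.stem
        )


def locate_guide(guide: str, mrna: MrnaRecord, sirna_id: str = "?") -> TargetSite:
    """Exact-match search of a guide's reverse complement in an mRNA.

    If several hits exist the 5'-most is returned and all hit positions
    are logged as a warning.  No mismatches are tolerated.
    """
    target = reverse_complement(guide)
    hits = []
    start = mrna.sequence.find(target)
    while start != -1:
        hits.append(start + 1)
        start = mrna.sequence.find(target, start + 1)
    if not hits:
        raise ValueError(
            f"target site not found: siRNA {sirna_id!r} has no exact "
            f"reverse-complement match in mRNA {mrna.id!r}"
        )
    if len(hits) > 1:
        logger.warning(
            "siRNA %s matches mRNA %s at multiple positions %s; using the 5'-most",
            sirna_id,
            mrna.id,
            hits,
        )
    return TargetSite(
        mrna_id=mrna.id,
        sirna_id=sirna_id,
        start=hits[0],
        end=hits[0] + len(target) - 1,
    )


def locate_site(sirna: SirnaRecord, mrna: MrnaRecord) -> TargetSite:
    """:func:`locate_guide` for a full siRNA record."""
    return locate_guide(sirna.guide, mrna, sirna_id=sirna.id)


def unpaired_stats(
    structure: SecondaryStructure, site: Tuple[int, int]
) -> Tuple[int, Tuple[int, ...], int]:
    """Unpaired bases within a window: total, maximal runs, longest run.

    Runs are maximal blocks of unpaired positions inside the window and
    are truncated at its boundaries (a run continuing outside the site
    counts only its inside portion).
    """
    start, end = site
    if not (1 <= start <= end <= structure.length):
        raise ValueError(f"site {site} outside 1..{structure.length}")
    runs = []
    current = 0
    for i in range(start, end + 1):
        if structure.pairs[i] == 0:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    n_unpaired = sum(runs)
    max_run = max(runs) if runs else 0
    return n_unpaired, tuple(runs), max_run


def hb_index(ss: SsCountVector, sequence: str, site: Tuple[int, int]) -> float:
    """Ensemble-average hydrogen bonds formed by the bases of a window."""
    start, end = site
    if not (1 <= start <= end <= ss.length):
        raise ValueError(f"site {site} outside the ss-count length {ss.length}")
    if len(sequence) < ss.length:
        raise ValueError("sequence shorter than the ss-count vector")
    total = 0.0
    for i in range(start, end + 1):
        bonds = 3.0 if sequence[i - 1] in "GC" else 2.0
        total += (1.0 - ss.counts[i] / ss.n_structures) * bonds
    return total


def classify_accessibility(hb: float, cutpoint: float = 25.0) -> str:
    """Dichotomize an H-b index: strictly below the cut-point = accessible."""
    if hb < 0:
        raise ValueError("H-b index must be >= 0")
    return "accessible" if hb < cutpoint else "inaccessible"


def compute_site_features(
    guide: str,
    mrna: MrnaRecord,
    ensemble: StructureEnsemble,
    fold_params: Optional[FoldParams] = None,
    nn_params: Optional[thermo.NNParameterSet] = None,
    ss: Optional[SsCountVector] = None,
    external_break_energies: Optional[Tuple[float, float]] = None,
    sirna_id: str = "?",
) -> Tuple[TargetSite, dict]:
    """All predictor fields for one guide on one folded mRNA.

    Element counts are taken on the ensemble's optimal (first) structure —
    the single structure the site is aligned to — while the H-b index uses
    the whole ensemble through its ss-count vector (or an externally
    supplied ``ss``).  Element counts are targeted bases per element;
    counting element *instances* instead is available through
    :func:`sirna_access.loop_annotation.element_counts_in_site`.
    """
    if ensemble.sequence != mrna.sequence:
        raise ValueError("ensemble was folded on a different sequence")
    site = locate_guide(guide, mrna, sirna_id=sirna_id)
    optimal = ensemble.optimal
    ann = annotate(optimal)
    counts = element_counts_in_site(ann, site.interval, unit="bases")
    n_unp, runs, max_run = unpaired_stats(optimal, site.interval)
    if ss is None:
        ss = ss_count(ensemble)
    hb = hb_index(ss, mrna.sequence, site.interval)
    site_seq = mrna.sequence[site.start - 1 : site.end]
    duplex = thermo.dg_duplex(guide, site_seq, nn_params)
    brk = thermo.dg_break_target(
        mrna.sequence, site.interval, fold_params, external_break_energies
    )
    self_ = thermo.dg_oligo_self(guide, fold_params)
    overall = thermo.dg_overall(duplex, brk, self_)
    fields = dict(
        loop5=counts["LOOP_5P"],
        loop3=counts["LOOP_3P"],
        int_loop=counts["INT_LOOP"],
        mb_loop=counts["MB_LOOP"],
        h_loop=counts["H_LOOP"],
        b_loop=counts["B_LOOP"],
        one_bb=counts["ONE_BB"],
        stem=counts["STEM"],
        n_unpaired=n_unp,
        runs=runs,
        max_run=max_run,
        hb_index=hb,
        dg_overall=overall,
        dg_duplex=duplex,
        dg_break_target=brk,
        dg_oligo_self=self_,
        gc_percent=thermo.gc_percent(guide),
    )
    return site, fields


def build_feature_vector(
    sirna: SirnaRecord,
    mrna: MrnaRecord,
    ensemble: StructureEnsemble,
    fold_params: Optional[FoldParams] = None,
    nn_params: Optional[thermo.NNParameterSet] = None,
    ss: Optional[SsCountVector] = None,
    external_break_energies: Optional[Tuple[float, float]] = None,
) -> SiteFeatureVector:
    """Assemble the full predictor row for one VH or L siRNA."""
    if sirna.efficacy_class not in ("VH", "L"):
        raise ValueError(
            f"siRNA {sirna.id!r} has class {sirna.efficacy_class}; only VH and L "
            "enter the two-group analysis"
        )
    _, fields = compute_site_features(
        sirna.guide,
        mrna,
        ensemble,
        fold_params=fold_params,
        nn_params=nn_params,
        ss=ss,
        external_break_energies=external_break_energies,
        sirna_id=sirna.id,
    )
    return SiteFeatureVector(
        sirna_id=sirna.id,
        efficacy_code=1 if sirna.efficacy_class == "VH" else 0,
        **fields,
    )
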